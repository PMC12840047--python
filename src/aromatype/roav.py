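"""Relative odor activity values (ROAV) and aroma-contributor classification.

The odor activity of a compound is its content divided by its odor threshold,
C_i / OT_i. ROAV rescales these activities so the most odor-active compound of
a sample scores exactly 100::

    ROAV_i = 100 * (C_i / OT_i) / max_j (C_j / OT_j)

Compounds with ROAV >= 1 are principal aroma contributors, those with
0.1 <= ROAV < 1 modify the overall flavor, and smaller values are minor.
Compounds without a literature threshold or not detected in the sample are
excluded (not scored zero), so reports can distinguish "cannot be scored" from
"scored and negligible". Thresholds are literature values in water (μg/L) while
contents are semi-quantified μg/kg; the ratio is treated as a unitless activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .compound_library import GcmsLibrary

ROAV_PRINCIPAL = 1.0
ROAV_MODIFIER = 0.1


@dataclass(frozen=True)
class RoavResult:
    """ROAV scores for one sample or aroma type."""

    group: str
    scores: Mapping[str, float]
    c_over_ot: Mapping[str, float]
    reference_compound: str
    excluded: tuple[str, ...]


def compute_roav(
    contents: Mapping[str, float],
    thresholds: Mapping[str, float | None],
    group: str = "",
) -> RoavResult:
    """ROAV of every scoreable compound in one sample/group.

    A compound is scoreable when its content is positive and its threshold is
    known; all others are listed as excluded. The compound with the largest
    C/OT ratio is the reference and scores exactly 100 (ties broken
    alphabetically, which leaves the scores unchanged).
    """
    ratios: dict[str, float] = {}
    excluded: list[str] = []
    for name, content in contents.items():
        ot = thresholds.get(name)
        if ot is None or content <= 0:
            excluded.append(name)
            continue
        ratios[name] = content / ot
    if not ratios:
        raise ValueError("no reference compound: no detected compound has a threshold")
    max_ratio = max(ratios.values())
    reference = min(n for n, r in ratios.items() if r == max_ratio)
    scores = {n: 100.0 * r / max_ratio for n, r in ratios.items()}
    scores[reference] = 100.0  # exact, immune to rounding
    return RoavResult(
        group=group,
        scores=scores,
        c_over_ot=ratios,
        reference_compound=reference,
        excluded=tuple(excluded),
    )


def roav_by_group(library: GcmsLibrary) -> list[RoavResult]:
    """ROAV per aroma type from a library's per-group mean contents."""
    groups = sorted(next(iter(library)).group_content)
    thresholds = library.thresholds()
    return [
        compute_roav(library.group_means(g), thresholds, group=g) for g in groups
    ]


def classify_roav(score: float) -> str:
    """'principal' (>=1), 'modifier' ([0.1, 1)), or 'minor' (<0.1)."""
    if score < 0:
        raise ValueError("ROAV cannot be negative")
    if score >= ROAV_PRINCIPAL:
        return "principal"
    if score >= ROAV_MODIFIER:
        return "modifier"
    return "minor"


def roav_scatter_data(results: Iterable[RoavResult]) -> pd.DataFrame:
    """Long-format (group, compound, c_over_ot, roav, class) scatter-plot table."""
    rows = [
        {
            "group": res.group,
            "compound": name,
            "c_over_ot": res.c_over_ot[name],
            "roav": score,
            "class": classify_roav(score),
        }
        for res in results
        for name, score in sorted(res.scores.items())
    ]
    return pd.DataFrame(rows, columns=["group", "compound", "c_over_ot", "roav", "class"])
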