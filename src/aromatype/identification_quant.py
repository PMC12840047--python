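"""Retention-index identification and internal-standard semi-quantification.

Analytes are placed on a reference ladder (n-alkanes or n-ketones) with the
linear, temperature-programmed retention-index formula of van den Dool and
Kratz::

    RI = 100 * (n + (t - t_n) / (t_{n+1} - t_n))

where ``t`` is the analyte retention time bracketed by the rungs of carbon
numbers ``n`` and ``n+1``. An observed RI matches a library RI when the
absolute difference is strictly below a tolerance of 50 index units.

Contents are semi-quantified against a known mass of internal standard: the
analyte/IS peak-area ratio times the IS mass, per kilogram of sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .compound_library import GcmsLibrary

RI_MATCH_TOLERANCE = 50.0


@dataclass(frozen=True)
class ReferenceLadder:
    """A homologous reference series: (carbon_number, retention_time_s) rungs."""

    rungs: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.rungs) < 2:
            raise ValueError("ladder needs at least two rungs")
        ns = [n for n, _ in self.rungs]
        ts = [t for _, t in self.rungs]
        if any(b <= a for a, b in zip(ns, ns[1:])) or any(
            b <= a for a, b in zip(ts, ts[1:])
        ):
            raise ValueError("ladder must be strictly increasing in index and time")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceLadder":
        """Two-column CSV/TSV: carbon_number, retention_time_s."""
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep)
        return cls(tuple(zip(df.iloc[:, 0].astype(int), df.iloc[:, 1].astype(float))))

    @property
    def t_min(self) -> float:
        return self.rungs[0][1]

    @property
    def t_max(self) -> float:
        return self.rungs[-1][1]


def retention_index(
    rt: float, ladder: ReferenceLadder, extrapolate: bool = False
) -> float:
    """Linear (van den Dool-Kratz) retention index of a peak at ``rt`` seconds.

    Piecewise-linear interpolation between the bracketing rungs; exactly at a
    rung the RI is 100x its carbon number. Retention times outside the ladder
    span raise unless ``extrapolate`` is set, in which case the first/last
    segment is extended linearly with a warning.
    """
    times = np.array([t for _, t in ladder.rungs])
    ris = np.array([100.0 * n for n, _ in ladder.rungs])
    if rt < ladder.t_min or rt > ladder.t_max:
        if not extrapolate:
            raise ValueError(
                f"retention time {rt} s outside ladder span "
                f"[{ladder.t_min}, {ladder.t_max}] s"
            )
        warnings.warn(
            f"extrapolating RI for rt={rt} s outside the ladder span", stacklevel=2
        )
        if rt < ladder.t_min:
            i0, i1 = 0, 1
        else:
            i0, i1 = len(times) - 2, len(times) - 1
        slope = (ris[i1] - ris[i0]) / (times[i1] - times[i0])
        return float(ris[i0] + slope * (rt - times[i0]))
    return float(np.interp(rt, times, ris))


def match_library(
    ri_observed: float, ri_library: float, tolerance: float = RI_MATCH_TOLERANCE
) -> bool:
    """Strict <tolerance match rule: a difference of exactly 50 does not match."""
    if ri_observed <= 0 or ri_library <= 0:
        raise ValueError("retention indices must be positive")
    return abs(ri_observed - ri_library) < tolerance


def identify_peak(
    ri_observed: float,
    library: GcmsLibrary,
    tolerance: float = RI_MATCH_TOLERANCE,
) -> str | None:
    """Name of the best library match for an observed RI, or None.

    Among entries within tolerance the closest RI wins; exact distance ties are
    broken alphabetically by compound name.
    """
    candidates = [
        (abs(ri_observed - r.retention_index), r.name)
        for r in library
        if match_library(ri_observed, r.retention_index, tolerance)
    ]
    if not candidates:
        return None
    return min(candidates)[1]


@dataclass(frozen=True)
class QuantConfig:
    """Internal-standard quantification settings (IS mass in μg, sample mass in g)."""

    is_name: str = "2-Methyl-3-heptanone"
    is_mass_ug: float = 0.816
    sample_mass_g: float = 2.0

    def __post_init__(self) -> None:
        if self.is_mass_ug <= 0 or self.sample_mass_g <= 0:
            raise ValueError("masses must be positive")


def semi_quantify(
    area_analyte: float, area_is: float, config: QuantConfig | None = None
) -> float:
    """Semi-quantified content in μg per kg of sample.

    content = (area_analyte / area_IS) * m_IS / m_sample, with the sample mass
    converted from grams to kilograms; linear in the area ratio.
    """
    config = config or QuantConfig()
    if area_is <= 0:
        raise ValueError("internal standard peak area must be positive")
    if area_analyte < 0:
        raise ValueError("analyte peak area must be >= 0")
    return (area_analyte / area_is) * config.is_mass_ug / (config.sample_mass_g / 1000.0)


def identify_peak_table(
    peaks: Sequence[float] | pd.DataFrame,
    ladder: ReferenceLadder,
    library: GcmsLibrary,
    tolerance: float = RI_MATCH_TOLERANCE,
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Assign observed peaks to library compounds via the RI match rule.

    ``peaks`` is a sequence of retention times in seconds (or a DataFrame with
    an ``rt_s`` column). Returns one row per peak: rt_s, ri_observed, match
    (compound name or None), ri_library, ri_difference.
    """
    if isinstance(peaks, pd.DataFrame):
        rts = peaks["rt_s"].to_numpy(dtype=float)
    else:
        rts = np.asarray(peaks, dtype=float)
    rows = []
    for rt in rts:
        ri = retention_index(rt, ladder, extrapolate=extrapolate)
        name = identify_peak(ri, library, tolerance)
        ri_lib = library.get(name).retention_index if name else np.nan
        rows.append(
            {
                "rt_s": rt,
                "ri_observed": ri,
                "match": name,
                "ri_library": ri_lib,
                "ri_difference": abs(ri - ri_lib) if name else np.nan,
            }
        )
    return pd.DataFrame(rows)
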