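"""Synthetic per-sample data generators emulating the study design.

The published analysis starts from 11 commercial rice samples in three aroma
types (3/4/4), each measured in technical triplicate, but only group-level
summary statistics were published. These generators draw per-sample data with
exactly that statistical structure so every downstream stage of the pipeline is
testable end to end:

* compound concentrations ~ truncated normal around the published per-type
  mean ± SD (ND compounds stay exactly zero);
* QDA sensory scores = archetype profile + noise, snapped to the 0-9
  half-point grid;
* GC chromatographic peak lists from a reference ladder by inverting the
  linear retention-index formula;
* GC-IMS peak volumes ~ lognormal with the published per-type volume as median.

All generators are pure functions of their inputs and a seed: one global seed
fans out to independent per-stream child seeds via ``numpy.random.SeedSequence``
so each stage can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .compound_library import GcmsLibrary

# Stream indices for fanning a global seed out to the generator stages.
_STREAMS = {"concentrations": 0, "sensory": 1, "peaks": 2, "ims": 3}


@dataclass(frozen=True)
class StudyDesign:
    """The sampling design: group sizes, technical replicates, and seed."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"A": 3, "B": 4, "C": 4}
    )
    replicates_per_sample: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    def sample_ids(self) -> list[tuple[str, str]]:
        """(sample_id, group) pairs, e.g. ('A1', 'A') ... ('C4', 'C')."""
        return [
            (f"{g}{i + 1}", g)
            for g in self.group_sizes
            for i in range(self.group_sizes[g])
        ]


@dataclass(frozen=True)
class SensoryArchetypes:
    """Archetype QDA profiles for the aroma types, on the 0-9 scale."""

    attributes: tuple[str, ...]
    archetype_means: Mapping[str, np.ndarray]
    noise_sd: float = 0.5
    sample_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sample_sd < 0:
            raise ValueError("sample_sd must be >= 0")
        for g, means in self.archetype_means.items():
            means = np.asarray(means, dtype=float)
            if len(means) != len(self.attributes):
                raise ValueError(f"archetype {g}: wrong number of attribute means")
            if (means < 0).any() or (means > 9).any():
                raise ValueError(f"archetype {g}: means must lie in [0, 9]")


def default_archetypes() -> SensoryArchetypes:
    """The packaged archetype profiles (qualitative spider-plot reconstruction)."""
    cfg = yaml.safe_load(
        resources.files("aromatype.data").joinpath("sensory_archetypes.yaml").read_text()
    )
    return SensoryArchetypes(
        attributes=tuple(cfg["attributes"]),
        archetype_means={
            g: np.asarray(v, dtype=float) for g, v in cfg["archetype_means"].items()
        },
        noise_sd=float(cfg["noise_sd"]),
        sample_sd=float(cfg["sample_sd"]),
    )


def _rng(seed: int, stream: str) -> np.random.Generator:
    child = np.random.SeedSequence(seed).spawn(len(_STREAMS))[_STREAMS[stream]]
    return np.random.default_rng(child)


def _truncnorm_draw(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray, size=None
) -> np.ndarray:
    """Normal(mean, sd) truncated at zero, elementwise over arrays.

    Degenerates to max(mean, 0) where sd = 0. Uses the inverse-CDF transform so
    one uniform draw per cell suffices (no rejection loop).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if (sd < 0).any():
        raise ValueError("negative sd")
    shape = np.broadcast_shapes(mean.shape, sd.shape) if size is None else size
    u = rng.random(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = stats.norm.cdf(np.where(sd > 0, -mean / sd, 0.0))
        draws = mean + sd * stats.norm.ppf(alpha + u * (1 - alpha))
    return np.where(sd > 0, draws, np.maximum(mean, 0.0))


def simulate_concentrations(
    library: GcmsLibrary,
    design: StudyDesign,
    noise_scale: float = 1.0,
    replicate_cv: float = 0.05,
) -> pd.DataFrame:
    """Per-sample compound concentrations with the published group structure.

    For each sample in group ``g`` and compound ``i``, a latent sample value is
    drawn from Normal(mean_gi, noise_scale * sd_gi) truncated at zero; technical
    replicates add multiplicative noise of coefficient of variation
    ``replicate_cv`` and are averaged into the reported value. ND compounds are
    exactly zero. Deterministic given ``design.seed``.

    Returns a samples x compounds DataFrame with a ``group`` column first.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if replicate_cv < 0:
        raise ValueError("replicate_cv must be >= 0")
    rng = _rng(design.seed, "concentrations")
    samples = design.sample_ids()
    names = library.names
    # samples x compounds matrices of group means/SDs and detection masks
    means = np.array(
        [[r.group_content[g].mean for r in library] for _, g in samples]
    )
    sds = np.array(
        [[r.group_content[g].sd for r in library] for _, g in samples]
    )
    detected = np.array(
        [[r.group_content[g].detected for r in library] for _, g in samples]
    )
    latent = _truncnorm_draw(rng, means, noise_scale * sds)
    rep_sd = replicate_cv * noise_scale * latent
    reps = _truncnorm_draw(
        rng,
        np.broadcast_to(latent, (design.replicates_per_sample, *latent.shape)),
        np.broadcast_to(rep_sd, (design.replicates_per_sample, *rep_sd.shape)),
    )
    values = np.where(detected, reps.mean(axis=0), 0.0)  # ND stays an exact zero
    out = pd.DataFrame(values, index=[sid for sid, _ in samples], columns=names)
    out.insert(0, "group", [g for _, g in samples])
    out.index.name = "sample"
    return out


def snap_to_half_grid(scores: np.ndarray) -> np.ndarray:
    """Snap to the nearest 0.5 increment and clip to the [0, 9] scale."""
    return np.clip(np.round(np.asarray(scores, dtype=float) * 2) / 2, 0.0, 9.0)


def simulate_sensory(
    archetypes: SensoryArchetypes,
    design: StudyDesign,
    n_panelists: int = 10,
) -> pd.DataFrame:
    """QDA panel scores around the archetype profiles.

    Each sample gets a persistent deviation from its archetype (SD
    ``sample_sd``), each panelist adds independent noise (SD ``noise_sd``), and
    scores are snapped to the half-point grid and clipped to [0, 9].

    Returns a long-format DataFrame (panelist, sample, group, attribute, score).
    """
    if n_panelists < 1:
        raise ValueError("need at least one panelist")
    rng = _rng(design.seed, "sensory")
    n_attr = len(archetypes.attributes)
    rows = []
    for sid, g in design.sample_ids():
        true_profile = np.asarray(archetypes.archetype_means[g], dtype=float)
        sample_profile = true_profile + rng.normal(0, archetypes.sample_sd, n_attr)
        for p in range(1, n_panelists + 1):
            noisy = sample_profile + rng.normal(0, archetypes.noise_sd, n_attr)
            snapped = snap_to_half_grid(noisy)
            for attr, s in zip(archetypes.attributes, snapped):
                rows.append((f"P{p:02d}", sid, g, attr, s))
    return pd.DataFrame(
        rows, columns=["panelist", "sample", "group", "attribute", "score"]
    )


def invert_retention_index(
    ri: float, ladder: Sequence[tuple[int, float]]
) -> float:
    """Retention time at which an analyte of the given RI elutes on the ladder.

    Inverse of the linear (van den Dool-Kratz) interpolation: RI = 100 n maps to
    the rung time, intermediate RIs interpolate linearly between rungs.
    """
    _check_ladder(ladder)
    ris = np.array([100.0 * n for n, _ in ladder])
    times = np.array([t for _, t in ladder])
    if not (ris[0] <= ri <= ris[-1]):
        raise ValueError(f"RI {ri} outside ladder span [{ris[0]}, {ris[-1]}]")
    return float(np.interp(ri, ris, times))


def _check_ladder(ladder: Sequence[tuple[int, float]]) -> None:
    if len(ladder) < 2:
        raise ValueError("ladder needs at least two rungs")
    ns = [n for n, _ in ladder]
    ts = [t for _, t in ladder]
    if any(b <= a for a, b in zip(ns, ns[1:])) or any(
        b <= a for a, b in zip(ts, ts[1:])
    ):
        raise ValueError("ladder must be strictly increasing in index and time")


def simulate_peak_list(
    ladder: Sequence[tuple[int, float]],
    analyte_ris: Sequence[float],
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Chromatographic peak list for analytes of known retention index.

    Retention times come from inverting the linear RI formula on the reference
    ladder, plus Gaussian jitter of SD ``jitter_sd`` seconds.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    _check_ladder(ladder)
    rng = _rng(seed, "peaks")
    rts = np.array([invert_retention_index(ri, ladder) for ri in analyte_ris])
    rts = rts + rng.normal(0, jitter_sd, len(rts)) if jitter_sd > 0 else rts
    return pd.DataFrame({"true_ri": list(analyte_ris), "rt_s": rts})


def simulate_ims_volumes(
    records: pd.DataFrame,
    cv: float = 0.1,
    design: StudyDesign | None = None,
) -> pd.DataFrame:
    """Per-sample GC-IMS peak volumes around the published per-type values.

    Volumes are lognormal with median equal to the printed per-type volume and
    coefficient of variation ``cv`` (cv=0 reproduces the table exactly).
    ``records`` is a signals table with ``signal`` plus one ``volume_<g>``
    column per group, as produced by :mod:`aromatype.gcims_fingerprint`.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    design = design or StudyDesign()
    rng = _rng(design.seed, "ims")
    sigma = np.sqrt(np.log1p(cv**2))
    rows = {}
    for sid, g in design.sample_ids():
        medians = records[f"volume_{g.lower()}"].to_numpy(dtype=float)
        if cv == 0:
            rows[sid] = medians
        else:
            draws = np.exp(np.log(np.where(medians > 0, medians, 1.0))
                           + rng.normal(0, sigma, len(medians)))
            rows[sid] = np.where(medians > 0, draws, 0.0)
    out = pd.DataFrame(rows, index=records["signal"]).T
    out.insert(0, "group", [g for _, g in design.sample_ids()])
    out.index.name = "sample"
    return out
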