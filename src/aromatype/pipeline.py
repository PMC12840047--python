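"""End-to-end orchestration: simulate → quantify → ROAV → cluster → screen → IMS.

A single :class:`RunConfig` (seed, study design, decision thresholds) drives
every stage; the output is one JSON-serializable report whose fields each trace
to exactly one module output. Identical config + seed reproduces an identical
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import compound_library as lib
from . import differential_stats as diff
from . import gcims_fingerprint as ims
from . import roav as roav_mod
from . import sensory_analysis as sensory
from . import synthetic_data as synth

logger = logging.getLogger("aromatype")

REPORT_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class Thresholds:
    alpha: float = 0.05
    vip_min: float = 1.0
    roav_principal: float = 1.0
    roav_modifier: float = 0.1
    ri_tolerance: float = 50.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.vip_min, self.roav_principal,
               self.roav_modifier, self.ri_tolerance) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.roav_modifier >= self.roav_principal:
            raise ValueError("roav_modifier must be below roav_principal")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    design: synth.StudyDesign = field(default_factory=synth.StudyDesign)
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_panelists: int = 10
    k_max: int = 6
    gcms_table: str | None = None  # packaged 74-compound fixture when None
    ims_table: str | None = None   # packaged 55-signal fixture when None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        design = synth.StudyDesign(
            group_sizes=cfg.get("group_sizes", {"A": 3, "B": 4, "C": 4}),
            replicates_per_sample=cfg.get("replicates_per_sample", 3),
            seed=cfg.get("seed", 0),
        )
        return cls(
            seed=cfg.get("seed", 0),
            design=design,
            thresholds=Thresholds(**cfg.get("thresholds", {})),
            n_panelists=cfg.get("n_panelists", 10),
            k_max=cfg.get("k_max", 6),
            gcms_table=cfg.get("gcms_table"),
            ims_table=cfg.get("ims_table"),
        )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s complete", name)
            return out
        return inner
    return wrap


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Run every stage of the analysis and return a structured report."""
    design = synth.StudyDesign(
        group_sizes=config.design.group_sizes,
        replicates_per_sample=config.design.replicates_per_sample,
        seed=config.seed,
    )
    thr = config.thresholds

    library = _stage("library")(lib.load_gcms_table)(
        config.gcms_table or lib.packaged_fixture("table3_gcms.tsv")
    )
    logger.info("library: %d compounds", len(library))
    dist = lib.category_distribution(library)
    flavor_count, flavor_pct = lib.flavor_characterized_fraction(library)

    # ROAV per aroma type from the library's group means
    roav_results = _stage("roav")(roav_mod.roav_by_group)(library)
    roav_table = roav_mod.roav_scatter_data(roav_results)

    # synthetic sensory panel -> Ward clustering -> elbow
    archetypes = synth.default_archetypes()
    panel = _stage("sensory-sim")(synth.simulate_sensory)(
        archetypes, design, n_panelists=config.n_panelists
    )
    profiles = sensory.aggregate_qda(panel)
    curve = sensory.wcss_curve(profiles, k_max=min(config.k_max, len(profiles)))
    k_star = sensory.elbow_k(curve)
    clusters = _stage("sensory-cluster")(sensory.ward_cluster)(profiles, k_star)
    spider = sensory.cluster_profiles(profiles, clusters.assignments)

    # synthetic per-sample concentrations -> differential screens
    conc = _stage("concentration-sim")(synth.simulate_concentrations)(
        library, design
    )
    logger.info("concentrations: %d samples x %d compounds",
                conc.shape[0], conc.shape[1] - 1)
    screens = {}
    diff_sets = {}
    groups = sorted(design.group_sizes)
    for a, b in [(x, y) for i, x in enumerate(groups) for y in groups[i + 1:]]:
        res = _stage(f"screen-{a}-vs-{b}")(diff.pairwise_screen)(
            conc, a, b, alpha=thr.alpha, vip_min=thr.vip_min
        )
        screens[f"{a} vs {b}"] = res
        diff_sets[f"{a} vs {b}"] = set(
            res.loc[res["verdict"] != "not significant", "compound"]
        )
    venn = diff.venn_counts(diff_sets)
    pca_scores, ellipse, inside = diff.pca_hotelling(conc.drop(columns="group"))

    # GC-IMS fingerprints
    records = _stage("ims")(ims.load_ims_table)(config.ims_table)
    pairs, orphans = ims.pair_monomer_dimer(records)
    class_counts = ims.ims_class_counts(records)
    fingerprint = ims.build_fingerprint(records)
    reference = fingerprint.index[0]
    differences = ims.difference_matrix(fingerprint, reference)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {
            "seed": config.seed,
            "group_sizes": dict(design.group_sizes),
            "replicates_per_sample": design.replicates_per_sample,
            "n_panelists": config.n_panelists,
            "thresholds": asdict(thr),
        },
        "library": {
            "n_compounds": len(library),
            "category_counts": dict(dist.counts),
            "category_percents": dict(dist.percents),
            "flavor_characterized": {"count": flavor_count, "percent": flavor_pct},
        },
        "roav": {
            "reference_compounds": {r.group: r.reference_compound
                                    for r in roav_results},
            "principal_counts": {
                r.group: sum(s >= thr.roav_principal for s in r.scores.values())
                for r in roav_results
            },
            "table": roav_table.to_dict(orient="records"),
        },
        "sensory": {
            "elbow_k": k_star,
            "wcss_curve": {str(k): v for k, v in curve.items()},
            "assignments": dict(clusters.assignments),
            "cluster_profiles": {
                str(c): {a: float(v) for a, v in row.items()}
                for c, row in spider.iterrows()
            },
        },
        "differential": {
            name: table.to_dict(orient="records") for name, table in screens.items()
        },
        "venn_regions": {" & ".join(k): v for k, v in venn.items()},
        "pca": {
            "inside_ellipse": {str(s): bool(f)
                               for s, f in zip(pca_scores.index, inside)},
            "t2_limit": ellipse["t2_limit"],
        },
        "ims": {
            "n_signals": len(records),
            "class_counts": class_counts,
            "n_monomer_dimer_pairs": len(pairs),
            "pairs": [b for b, _, _ in pairs],
            "orphans": [r.signal for r in orphans],
            "reference": str(reference),
            "difference_sign": {
                col: {str(g): float(v) for g, v in differences[col].items()}
                for col in differences.columns
            },
        },
    }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
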