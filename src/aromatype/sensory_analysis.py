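"""QDA sensory aggregation and Ward clustering with WCSS elbow selection.

Panel scores (0-9 scale, half-point grid) are averaged over panelists into one
aroma profile per sample. Samples are then clustered by Ward's minimum-variance
criterion on Euclidean distances, the number of aroma types is chosen where the
within-cluster sum of squares (WCSS) curve bends — operationalized as the
interior k maximizing the second difference of WCSS — and per-cluster attribute
means are exported as spider-plot profiles.

Attributes are not standardized before clustering by default: all ten share the
same 0-9 intensity scale. A ``standardize`` flag enables z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class ClusterResult:
    """A Ward clustering cut: assignments, the WCSS curve, and the merge tree."""

    k: int
    assignments: Mapping[str, int]
    wcss_curve: Mapping[int, float]
    linkage_tree: np.ndarray  # scipy linkage matrix (heights, merged pairs)


def validate_panel_scores(panel: pd.DataFrame) -> None:
    """Check that all scores sit on the half-point grid inside [0, 9]."""
    scores = panel["score"].to_numpy(dtype=float)
    if ((scores < 0) | (scores > 9)).any():
        bad = scores[(scores < 0) | (scores > 9)][0]
        raise ValueError(f"score {bad} outside the 0-9 scale")
    off_grid = scores * 2 != np.round(scores * 2)
    if off_grid.any():
        raise ValueError(f"score {scores[off_grid][0]} is off the half-point grid")


def aggregate_qda(panel: pd.DataFrame) -> pd.DataFrame:
    """Average panel scores into a sample x attribute profile matrix.

    ``panel`` is long-format with columns (panelist, sample, attribute, score).
    Scores are validated against the 0-9 half-point grid first. Row and column
    order follow first appearance in the input.
    """
    if panel.empty:
        raise ValueError("empty panel data")
    validate_panel_scores(panel)
    profiles = panel.pivot_table(
        index="sample", columns="attribute", values="score", aggfunc="mean",
        sort=False,
    )
    # preserve input appearance order
    profiles = profiles.loc[
        panel["sample"].drop_duplicates(), panel["attribute"].drop_duplicates()
    ]
    profiles.columns.name = None
    return profiles


def _ordered_labels(raw_labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw_labels)
    for i, lab in enumerate(raw_labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def wcss(profiles: pd.DataFrame, labels: np.ndarray) -> float:
    """Total squared Euclidean deviation of samples from their cluster centroids."""
    X = profiles.to_numpy(dtype=float)
    total = 0.0
    for lab in np.unique(labels):
        block = X[labels == lab]
        total += ((block - block.mean(axis=0)) ** 2).sum()
    return float(total)


def ward_linkage(profiles: pd.DataFrame) -> np.ndarray:
    """Ward minimum-variance linkage matrix on Euclidean distances."""
    if len(profiles) < 2:
        raise ValueError("need at least two samples to cluster")
    return hierarchy.linkage(pdist(profiles.to_numpy(dtype=float)), method="ward")


def ward_cluster(profiles: pd.DataFrame, k: int) -> ClusterResult:
    """Cut the Ward tree at ``k`` clusters.

    Cluster labels are integers 1..k ordered by first-sample appearance. The
    result also carries the full WCSS curve for cuts 1..n.
    """
    n = len(profiles)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    Z = ward_linkage(profiles)
    labels = _ordered_labels(hierarchy.fcluster(Z, t=k, criterion="maxclust"))
    curve = wcss_curve(profiles, k_max=n)
    return ClusterResult(
        k=k,
        assignments=dict(zip(profiles.index, (int(x) for x in labels))),
        wcss_curve=curve,
        linkage_tree=Z,
    )


def wcss_curve(profiles: pd.DataFrame, k_max: int) -> dict[int, float]:
    """WCSS of the Ward cut at each k = 1..k_max."""
    n = len(profiles)
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the number of samples {n}")
    Z = ward_linkage(profiles) if n > 1 else None
    curve = {}
    for k in range(1, k_max + 1):
        if k == n:
            curve[k] = 0.0
        elif k == 1:
            curve[k] = wcss(profiles, np.ones(n, dtype=int))
        else:
            labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
            curve[k] = wcss(profiles, labels)
    return curve


def elbow_k(curve: Mapping[int, float]) -> int:
    """Elbow of a WCSS curve: interior k maximizing the second difference.

    The second difference (WCSS(k-1) - WCSS(k)) - (WCSS(k) - WCSS(k+1)) is
    largest where a rapid decrease turns flat. Ties return the smallest k.
    """
    ks = sorted(curve)
    if len(ks) < 3:
        raise ValueError("need WCSS at >= 3 consecutive k to locate an elbow")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("WCSS curve must be defined on consecutive k")
    best_k, best_d2 = None, -np.inf
    for k in ks[1:-1]:
        d2 = (curve[k - 1] - curve[k]) - (curve[k] - curve[k + 1])
        if d2 > best_d2:  # strict: ties keep the smallest k
            best_k, best_d2 = k, d2
    return int(best_k)


def cluster_profiles(
    profiles: pd.DataFrame, assignments: Mapping[str, int]
) -> pd.DataFrame:
    """Per-cluster attribute means (spider-plot data), one row per cluster."""
    missing = set(profiles.index) - set(assignments)
    if missing:
        raise ValueError(f"samples without a cluster label: {sorted(missing)}")
    labels = pd.Series({s: assignments[s] for s in profiles.index}, name="cluster")
    if labels.isna().any():
        raise ValueError("empty cluster label")
    out = profiles.groupby(labels).mean()
    out.index.name = "cluster"
    return out


def standardized(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score attributes (optional pre-clustering transform)."""
    sd = profiles.std(ddof=0)
    if (sd == 0).any():
        raise ValueError(f"zero-variance attributes: {list(sd.index[sd == 0])}")
    return (profiles - profiles.mean()) / sd


def tree_to_dict(Z: np.ndarray, labels: list[str]) -> dict:
    """JSON-serializable merge history of a linkage tree."""
    return {
        "labels": labels,
        "merges": [
            {"left": int(a), "right": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in Z
        ],
    }
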