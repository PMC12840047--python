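"""Differential screening of volatiles across and between aroma types.

The screen follows standard untargeted flavor-metabolomics practice: a one-way
ANOVA flags compounds varying across all types, pairwise pooled-variance
Student t-tests combined with OPLS-DA variable importance (VIP > 1) flag
between-type differences, and log2 fold changes give direction. Supporting
outputs cover volcano plots, Venn region counts, PCA with a Hotelling T²
confidence ellipse, and hierarchically clustered heatmap orderings.

The OPLS-DA here is the Trygg-Wold orthogonal projections to latent structures
algorithm: variation in X orthogonal to the class vector y is estimated
component by component and removed, then a single predictive PLS component is
fit on the filtered matrix. With ``n_ortho=0`` the model reduces exactly to
one-component PLS-DA. VIP is computed on the predictive component only
(normalized so mean(VIP²) = 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

ALPHA = 0.05
VIP_MIN = 1.0


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

def anova_oneway(
    matrix: pd.DataFrame, compound: str, group_col: str = "group"
) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA for one compound.

    ``matrix`` is a samples x compounds table with a group-label column. The
    degenerate case of zero within-group variance everywhere with unequal means
    is reported as the limit (F=inf, p=0) with a warning.
    """
    groups = [
        g[compound].to_numpy(dtype=float) for _, g in matrix.groupby(group_col)
    ]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if max(len(g) for g in groups) < 2:
        raise ValueError("at least one group needs >= 2 samples")
    means = [g.mean() for g in groups]
    if all(np.ptp(g) == 0 for g in groups):
        if np.ptp(means) == 0:
            return 0.0, 1.0
        warnings.warn(
            f"{compound}: zero within-group variance with unequal means; "
            "F unbounded, p -> 0",
            stacklevel=2,
        )
        return float("inf"), 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> tuple[float, float]:
    """One-way ANOVA from per-group summary statistics (mean, sd, n).

    Identical to :func:`anova_oneway` fed the summaries of the raw data:
    SSB = Σ n_g (m_g - m)², MSW = Σ (n_g - 1) s_g² / (N - g). SDs are taken as
    sample standard deviations (ddof=1).
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if (ns < 1).any() or (ns >= 2).sum() < 1:
        raise ValueError("all ns >= 1 and at least one group with n >= 2")
    if (sds < 0).any():
        raise ValueError("negative sd")
    g, n_total = len(ns), int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        warnings.warn(
            "zero within-group variance with unequal means; F unbounded, p -> 0",
            stacklevel=2,
        )
        return float("inf"), 0.0
    f = (ssb / (g - 1)) / (ssw / (n_total - g))
    p = float(stats.f.sf(f, g - 1, n_total - g))
    return float(f), p


def student_ttest(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test.

    Zero pooled variance is handled as a limit: p=1 for equal means, p=0 (with
    a warning) for unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn(
            "zero pooled variance with unequal means; |t| unbounded, p -> 0",
            stacklevel=2,
        )
        return float("inf") if x.mean() > y.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def default_epsilon(matrix: pd.DataFrame) -> float:
    """Half the smallest nonzero content in a concentration matrix."""
    values = matrix.select_dtypes("number").to_numpy(dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("matrix has no nonzero contents")
    return float(nonzero.min() / 2)


def log2_fold_change(mean_num: float, mean_den: float, epsilon: float) -> float:
    """log2((mean_num + ε) / (mean_den + ε)); ε guards not-detected zeros.

    Both means zero is degenerate and returns 0 with a warning.
    """
    if mean_num < 0 or mean_den < 0:
        raise ValueError("means must be >= 0")
    if mean_num == 0 and mean_den == 0:
        warnings.warn("fold change of two not-detected means; returning 0",
                      stacklevel=2)
        return 0.0
    if epsilon <= 0 and (mean_num == 0 or mean_den == 0):
        raise ValueError("epsilon must be positive when a mean is zero")
    return float(np.log2((mean_num + epsilon) / (mean_den + epsilon)))


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsdaModel:
    """A fitted OPLS-DA model with one predictive component."""

    variables: list[str]
    weights: np.ndarray          # predictive weight vector w (unit norm)
    loadings: np.ndarray         # predictive loading vector p
    scores: np.ndarray           # predictive score vector t
    ortho_weights: list[np.ndarray] = field(default_factory=list)
    ortho_loadings: list[np.ndarray] = field(default_factory=list)
    ortho_scores: list[np.ndarray] = field(default_factory=list)
    n_ortho: int = 0
    scaling: str = "autoscale"
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None


def _scale_x(X: np.ndarray, scaling: str, variables: Sequence[str]):
    mean = X.mean(axis=0)
    if scaling == "autoscale":
        sd = X.std(axis=0, ddof=1)
        constant = np.flatnonzero(sd == 0)
        if constant.size:
            names = [variables[i] for i in constant]
            raise ValueError(f"constant variables under autoscaling: {names}")
    elif scaling == "center-only":
        sd = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (X - mean) / sd, mean, sd


def fit_oplsda(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    n_ortho: int = 1,
    scaling: str = "autoscale",
) -> OplsdaModel:
    """Fit OPLS-DA with ``n_ortho`` orthogonal components and one predictive.

    ``y`` is a binary class indicator in any two-value encoding; it is centered
    internally, so {0,1} and {-1,+1} give identical models. Each orthogonal
    component captures X-variation uncorrelated with y (w_o = p - (w'p)w) and
    is deflated from X before the final predictive component is fit.
    """
    if isinstance(X, pd.DataFrame):
        variables = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        variables = [f"x{j}" for j in range(Xm.shape[1])]
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    classes = np.unique(np.asarray(y))
    if len(classes) != 2:
        raise ValueError("y must contain exactly two classes")
    yv = np.where(np.asarray(y) == classes[0], -1.0, 1.0)
    yc = yv - yv.mean()

    Xs, x_mean, x_scale = _scale_x(Xm, scaling, variables)
    model = OplsdaModel(
        variables=variables, weights=np.empty(0), loadings=np.empty(0),
        scores=np.empty(0), n_ortho=n_ortho, scaling=scaling,
        x_mean=x_mean, x_scale=x_scale,
    )

    Xd = Xs.copy()
    for _ in range(n_ortho):
        w = Xd.T @ yc
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        model.ortho_weights.append(w_o)
        model.ortho_loadings.append(p_o)
        model.ortho_scores.append(t_o)

    w = Xd.T @ yc
    w /= np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    model.weights, model.scores, model.loadings = w, t, p
    model.n_ortho = len(model.ortho_scores)
    return model


def vip_scores(model: OplsdaModel) -> pd.Series:
    """Variable importance in projection over the predictive component(s).

    With a single predictive component and a unit-norm weight vector this is
    sqrt(p_vars) * |w_j|, which satisfies mean(VIP²) = 1 exactly.
    """
    w = model.weights
    if w.size == 0:
        raise ValueError("model is not fitted")
    p_vars = len(w)
    vip = np.sqrt(p_vars) * np.abs(w)  # single-component VIP_pred
    return pd.Series(vip, index=model.variables, name="vip")


# ---------------------------------------------------------------------------
# screening and set summaries
# ---------------------------------------------------------------------------

def screen_differential(
    p_values: Mapping[str, float],
    vips: Mapping[str, float],
    fold_changes: Mapping[str, float],
    alpha: float = ALPHA,
    vip_min: float = VIP_MIN,
) -> pd.DataFrame:
    """Combine p, VIP and log2 FC into per-compound verdicts.

    A compound is differential iff p < alpha (strict) and VIP > vip_min
    (strict); direction is the sign of the log2 fold change.
    """
    rows = []
    for name in p_values:
        p = p_values[name]
        vip = vips.get(name, float("nan"))
        fc = fold_changes.get(name, float("nan"))
        significant = p < alpha and vip > vip_min
        verdict = "not significant"
        if significant:
            verdict = "up" if fc > 0 else "down"
        rows.append(
            {"compound": name, "p_ttest": p, "vip": vip, "log2fc": fc,
             "verdict": verdict}
        )
    return pd.DataFrame(
        rows, columns=["compound", "p_ttest", "vip", "log2fc", "verdict"]
    )


def pairwise_screen(
    matrix: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = ALPHA,
    vip_min: float = VIP_MIN,
    n_ortho: int = 1,
    group_col: str = "group",
) -> pd.DataFrame:
    """Full two-group differential screen on a labeled concentration matrix.

    Runs Student t-tests per compound, one OPLS-DA of group_a vs group_b for
    VIP, and log2 fold changes (group_a over group_b) with the half-minimum
    epsilon rule. Compounds constant across both groups cannot carry class
    information (and break autoscaling); they get VIP = NaN and are never
    significant.
    """
    sub = matrix[matrix[group_col].isin([group_a, group_b])]
    values = sub.drop(columns=[group_col])
    labels = sub[group_col]
    eps = default_epsilon(values)

    variable = values.columns[values.nunique() > 1]
    model = fit_oplsda(values[variable], (labels == group_a).astype(int),
                       n_ortho=n_ortho)
    vips = vip_scores(model).reindex(values.columns)

    xa = values[labels == group_a]
    xb = values[labels == group_b]
    p_values, fcs = {}, {}
    for name in values.columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p_values[name] = student_ttest(xa[name], xb[name])
            fcs[name] = log2_fold_change(xa[name].mean(), xb[name].mean(), eps)
    out = screen_differential(p_values, vips.to_dict(), fcs, alpha, vip_min)
    out.insert(0, "comparison", f"{group_a} vs {group_b}")
    return out


def venn_counts(sets: Mapping[str, Iterable]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts of the Venn diagram over named sets.

    Keys are tuples of the set names a region belongs to (sorted); values are
    the number of elements exactly in those sets and no others. Regions sum to
    the size of the union.
    """
    sets = {name: set(v) for name, v in sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                *(sets[n] for n in names if n not in combo), set()
            )
            counts[combo] = len(inside - outside)
    return counts


def pca_hotelling(
    X: pd.DataFrame | np.ndarray,
    n_components: int = 2,
    confidence: float = 0.95,
) -> tuple[pd.DataFrame, dict, np.ndarray]:
    """PCA scores with a Hotelling T² confidence region.

    X is autoscaled (constant columns dropped); the T² limit is
    a(n-1)/(n-a) * F_{confidence}(a, n-a) with a = n_components. Returns
    (scores, ellipse parameters, inside flags).
    """
    if isinstance(X, pd.DataFrame):
        index = X.index
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        index = pd.RangeIndex(len(Xm))
    n = Xm.shape[0]
    if n <= n_components + 1:
        raise ValueError("need n samples > n_components + 1")
    sd = Xm.std(axis=0, ddof=1)
    Xs = (Xm[:, sd > 0] - Xm[:, sd > 0].mean(axis=0)) / sd[sd > 0]
    if np.linalg.matrix_rank(Xs) < n_components:
        raise ValueError("data rank below the requested number of components")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xs)
    lam = scores.var(axis=0, ddof=1)
    t2 = (scores**2 / lam).sum(axis=1)
    a = n_components
    t2_limit = a * (n - 1) / (n - a) * stats.f.ppf(confidence, a, n - a)
    ellipse = {
        "t2_limit": float(t2_limit),
        # semi-axes of the ellipse in score space (2-component case)
        "semi_axes": [float(np.sqrt(l * t2_limit)) for l in lam],
        "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio_],
    }
    score_df = pd.DataFrame(
        scores, index=index, columns=[f"PC{i + 1}" for i in range(a)]
    )
    score_df["t2"] = t2
    return score_df, ellipse, t2 <= t2_limit


def hclust_heatmap(
    matrix: pd.DataFrame, row_scale: str = "zscore"
) -> tuple[list, list, pd.DataFrame]:
    """Complete-linkage heatmap ordering on Euclidean distances.

    Rows are optionally z-scored first (zero-variance rows are scaled to zeros
    with a warning); rows and columns are then each ordered by their
    complete-linkage dendrogram. Returns (row order, column order, scaled
    matrix).
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    X = matrix.to_numpy(dtype=float)
    if row_scale == "zscore":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            warnings.warn(
                f"zero-variance rows scaled to zeros: "
                f"{list(matrix.index[flat])}",
                stacklevel=2,
            )
        X = np.where(sd == 0, 0.0, (X - mu) / np.where(sd == 0, 1.0, sd))
    elif row_scale != "none":
        raise ValueError(f"unknown row_scale {row_scale!r}")
    scaled = pd.DataFrame(X, index=matrix.index, columns=matrix.columns)
    row_order = hierarchy.leaves_list(
        hierarchy.linkage(pdist(X), method="complete")
    )
    col_order = hierarchy.leaves_list(
        hierarchy.linkage(pdist(X.T), method="complete")
    )
    return (
        [matrix.index[i] for i in row_order],
        [matrix.columns[j] for j in col_order],
        scaled,
    )
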