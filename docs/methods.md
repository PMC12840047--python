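# Methods

## Scope and data model

The package analyzes rice aroma at three coupled levels: trained-panel QDA
sensory profiles, GC-MS volatile compound tables with internal-standard
semi-quantification, and GC-IMS peak tables. The canonical in-memory objects
are a `GcmsLibrary` of `CompoundRecord`s (identity, category, descriptors, odor
threshold, per-type content mean ± SD with explicit not-detected flags), a
samples × compounds concentration `DataFrame` with a group-label column,
long-format panel scores, and `ImsPeakRecord`s (monomer/dimer form, retention
index, retention time, drift time, per-type peak volume).

Source-table sentinels are preserved on load rather than imputed: `ND` (not
detected) is stored as an exact zero measurement with `detected=False` —
downstream statistics treat it as a true zero, which is what allows ANOVA
across groups that include ND; `n.f.` becomes a missing odor threshold, which
excludes the compound from ROAV rather than scoring it zero; `——` is an empty
descriptor list. Contents are kept in one semi-quantitative unit (μg per kg of
sample, internal-standard equivalents); the source material labels the same
values μg/L in one table and μg/kg in another, a discrepancy we document but do
not resolve. Odor thresholds are literature values in water (μg/L), so the
C/OT ratio inside ROAV is treated as a unitless activity, as is standard
practice for semi-quantitative ROAV screening.

Known verbatim quirks of the packaged fixtures, kept deliberately: one alkane
is printed ND in type B in the compound table but carries a nonzero type-B mean
in the differential table; hexanal is ND in type B by GC-MS yet detected in all
types by GC-IMS; the propanal monomer and dimer print identical type-B volumes.

## Sensory clustering

Panel scores are validated against the 0–9 half-point grid, then averaged over
panelists per (sample, attribute). Clustering uses Ward's minimum-variance
criterion on Euclidean distances (scipy's Lance–Williams implementation);
attributes share one scale, so they are not standardized by default (a z-score
switch exists). WCSS(k) is the total squared deviation from cluster centroids
of the Ward cut at k. The elbow is defined as the interior k maximizing the
second difference `(WCSS(k−1) − WCSS(k)) − (WCSS(k) − WCSS(k+1))`, ties going
to the smallest k — a concrete operationalization of "rapid decrease, then
flat". Cluster labels are renumbered by first-sample appearance so output is
stable.

Greedy agglomeration is not exact: against exhaustive enumeration of all
partitions (n = 7, k = 3), Ward attains the true minimum-variance partition on
≈97% of mildly clustered datasets (cluster-center SD twice the within-cluster
SD) but only ≈80–85% of fully unstructured Gaussian datasets. The test suite
asserts near-optimality in the clustered regime, which is the regime the
method is used in; on unstructured data no hierarchical cut is meaningful.

## ROAV

`ROAV_i = 100 · (C_i/OT_i) / max_j (C_j/OT_j)` over compounds with detected
content and a known threshold; the maximizing compound is the reference and
scores exactly 100 (ties broken alphabetically, which cannot change any
score). Classification: principal at ROAV ≥ 1, modifier in [0.1, 1), minor
below — both boundaries inclusive on the left. ROAV is invariant to rescaling
all contents by a positive constant, so semi-quantitative units do not affect
ranking. No numeric ROAV values are published for this design; the checks on
this module are identities and oracle arithmetic (e.g. the type-A reference is
hexanal with C/OT = 307.27/4).

## Identification and quantification

The linear retention index is used for both temperature-programmed runs (the
logarithmic Kovats form applies to isothermal chromatography); it is
piecewise-linear interpolation between ladder rungs, monotone over the ladder
span, with no extrapolation by default (an opt-in flag extends the terminal
segments with a warning, since the published ladders are ambiguous: C9–C23
standards are described while a table footnote cites C5–C28). Library matching
uses the strict rule |ΔRI| < 50 — a difference of exactly 50 fails. When
several library entries qualify, the closest RI wins, exact ties broken
alphabetically (the source is silent). Semi-quantification is
`(A_analyte/A_IS) · m_IS/m_sample` with defaults m_IS = 0.816 μg and
m_sample = 2 g, i.e. an area ratio of 1 ↦ 408 μg/kg.

## Differential screening

ANOVA is the classical one-way fixed-effects F-test; a summary-statistics
variant (means, SDs, ns) is provided and is exactly identical to the raw-data
test (property-tested to 1e-10), with SDs interpreted as ddof = 1 sample
standard deviations. Degenerate zero-variance cases return the appropriate
limits (F = 0, p = 1 for equal means; F → ∞, p → 0 flagged by a warning
otherwise). Note the published per-compound ANOVA p-values are **not**
recoverable from the published summary statistics under any plausible group
sizes (e.g. the 6-undecanone summaries give F ≈ 2.30, p ≈ 0.16, not the
printed 0.022); the raw per-sample data were never released, so the
summary-ANOVA is validated as machinery, not against printed p-values, and
published Q-values are carried through, never recomputed.

Pairwise screening uses the pooled-variance Student t-test (not Welch, per the
source's wording), OPLS-DA VIP, and log2 fold changes. The screen rule is
strict on both thresholds: differential iff p < α and VIP > 1. Fold changes
use `log2((m₁ + ε)/(m₂ + ε))` with ε = half the smallest nonzero content in
the matrix, so not-detected denominators are defined; a both-ND fold change is
0 with a warning. Compounds constant across the two groups being compared
carry no class information and break autoscaling; they receive VIP = NaN and
are never significant.

OPLS-DA follows the Trygg–Wold orthogonal-projections algorithm on
autoscaled X and a centered two-level y: the predictive weight is
`w ∝ Xᵀy`; each orthogonal component takes `w_o ∝ p − (wᵀp)w` from the current
loading, deflates X by `t_o p_oᵀ`, and the final single predictive component is
fit on the filtered matrix. With n_ortho = 0 this reduces exactly to
one-component PLS-DA (verified against scikit-learn's PLS to 1e-10), and the
predictive scores with one orthogonal component match an independently coded
iterative NIPALS O-PLS to 1e-8. Orthogonal scores are uncorrelated with y by
construction (< 1e-8). VIP is computed on the predictive component only
(`VIP_j = √p · |w_j|` for one component), the convention under which
mean(VIP²) = 1 holds exactly; the variant choice matters only with multiple
predictive components, which this two-class design never needs. Autoscaling
before OPLS-DA/PCA is the metabolomics default; y-encoding ({0,1} vs {−1,+1})
provably does not affect the model.

PCA diagnostics autoscale X and flag samples outside the Hotelling T² limit
`a(n−1)/(n−a) · F₀.₉₅(a, n−a)` with a = 2 components. Heatmap orderings use
complete-linkage agglomeration on Euclidean distances of the optionally
row-z-scored matrix; zero-variance rows are scaled to zeros and flagged. No
multiple-testing correction is applied in the primary screen (the screening
convention being reproduced works at raw p < 0.05).

## GC-IMS

Analysis starts from vendor-exported peak tables; drift-spectrum processing and
RIP normalization happen upstream in instrument software and are out of scope.
Signal names ending in `-M`/`-D` are split into (base name, form); monomer and
dimer rows are distinct signals. Class counting uses a packaged curated
name → class map, because the peak table itself carries no class column; with
monoterpenes/styrene as aromatic hydrocarbons and acetic acid as "other", the
map reproduces the published 14/13/12/8/4/3/1 split over 55 signals exactly,
which is also the observation forcing signals (not base compounds) to be the
counting unit. Fingerprints are group × signal matrices ordered by retention
time then drift time; difference matrices subtract a reference row, so
positive cells are signals enriched relative to the reference.

## Synthetic data generator

The generator emulates the study design: 11 samples in groups of 3/4/4, three
technical replicates, 10 panelists.

* **Concentrations**: per-sample latent values ~ Normal(mean_g, sd_g)
  truncated at zero (matching mean ± SD reporting; a lognormal would distort
  the printed means), replicates add 5% CV multiplicative noise and are
  averaged; ND compounds stay exactly zero. A `noise_scale` of 0 reproduces
  the group means exactly.
* **Sensory**: scores = archetype mean + persistent per-sample deviation
  (SD 0.25) + per-panelist noise (SD 0.5), snapped to the half-point grid and
  clipped to [0, 9]. The archetype vectors are a qualitative reconstruction of
  the published spider plots (numbers are not printed there): type A
  sweet/popcorn-forward, type B cereal/starchy with suppressed sweetness,
  type C balanced-high "complex". They are stored in a config fixture, not in
  code, and are chosen roughly equidistant in attribute space — the structure
  the published dendrogram and its WCSS elbow at three clusters imply. The
  within-group SDs are free choices (the source reports no variance split
  between samples and replicates); both are exposed as parameters.
* **Peak lists**: retention times invert the linear RI formula on a reference
  ladder plus Gaussian jitter; 1 s of jitter on a 60 s rung spacing moves the
  recovered RI by ≈1.7 units per second, well inside the 50-unit match rule.
* **IMS volumes**: lognormal with the printed per-type volume as median and a
  chosen coefficient of variation (volumes span four decades, where additive
  noise would be meaningless); cv = 0 reproduces the table.

All generators are pure functions of (inputs, seed); one global seed fans out
to per-stream child seeds via `numpy.random.SeedSequence`, so stages can be
regenerated independently.

What a green synthetic test does and does not establish: it shows the
pipeline recovers structure that is actually present at the stated noise
levels (three aroma types, headline differential compounds, all samples inside
the Hotelling ellipse). It does not validate instrument behavior, matrix
effects, panelist bias, or the published p-values, none of which are
computable from the released material.

## Numerical conventions

Category percentages are truncated toward zero at one decimal using integer
arithmetic (the published class percentages are consistent only under
truncation); the flavor-characterized percentage is rounded to two decimals.
A compound is flavor-characterized when its descriptor list is non-empty — in
the packaged table that yields 52 of 74 (70.27%); an optional exclusion set
allows discounting bare class labels like "Alkane". Elbow ties take the
smallest k; ROAV and RI-match ties are alphabetical; cluster labels follow
first appearance. Thresholds in the screen are strict inequalities. Reports
are JSON with sorted keys, byte-identical for identical config and seed.

## Limitations

No mass-spectral similarity scoring (identification is RI-only), no odor-mixture
interaction modeling, no OPLS-DA permutation validation or R²/Q²
cross-validation, no multiple-testing correction in the primary screen, no
figure rendering (data exports only), and no attempt to reproduce printed
p-values that the released summary data demonstrably cannot yield.
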