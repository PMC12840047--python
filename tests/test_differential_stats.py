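"""Differential screening: ANOVA, t-tests, OPLS-DA/VIP, Venn, PCA, heatmaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.cross_decomposition import PLSRegression

import aromatype.differential_stats as ds
import aromatype.synthetic_data as synth


def _labeled_matrix(rng, n_per_group=(3, 4, 4), n_compounds=5):
    rows, labels = [], []
    for g, n in zip("ABC", n_per_group):
        rows.append(rng.normal(size=(n, n_compounds)))
        labels += [g] * n
    df = pd.DataFrame(np.vstack(rows),
                      columns=[f"c{i}" for i in range(n_compounds)])
    df.insert(0, "group", labels)
    return df


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        df = pd.DataFrame({"group": list("AABB"), "x": [1.0, 2.0, 1.0, 2.0]})
        assert ds.anova_oneway(df, "x") == (0.0, 1.0)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(loc=0.5, size=5)
            df = pd.DataFrame({"group": ["A"] * 6 + ["B"] * 5,
                               "v": np.r_[x, y]})
            f, p_f = ds.anova_oneway(df, "v")
            t, p_t = ds.student_ttest(x, y)
            assert f == pytest.approx(t**2)
            assert p_f == pytest.approx(p_t)

    def test_six_undecanone_summary_statistics(self):
        # published group summaries: the F statistic is reproducible even
        # though the table's printed p-value is not
        f, p = ds.anova_from_summary(
            means=[0.51, 0.09, 0.29], sds=[0.10, 0.18, 0.37], ns=[3, 4, 4]
        )
        assert f == pytest.approx(2.30, abs=0.01)
        assert p == pytest.approx(0.16, abs=0.01)

    def test_e2octenal_summary_with_nd_as_zero(self):
        f, _ = ds.anova_from_summary(
            means=[0.56, 0.40, 0.0], sds=[0.07, 0.09, 0.0], ns=[3, 4, 4]
        )
        assert f == pytest.approx(70.7, abs=0.1)

    def test_summary_identity_with_raw_anova(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            df = _labeled_matrix(rng, n_compounds=1)
            f1, p1 = ds.anova_oneway(df, "c0")
            stats_by_group = df.groupby("group")["c0"]
            f2, p2 = ds.anova_from_summary(
                stats_by_group.mean(), stats_by_group.std(ddof=1),
                stats_by_group.size(),
            )
            assert f2 == pytest.approx(f1, abs=1e-10)
            assert p2 == pytest.approx(p1, abs=1e-10)

    def test_degenerate_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning, match="unbounded"):
            f, p = ds.anova_from_summary([1.0, 2.0], [0.0, 0.0], [3, 3])
        assert np.isinf(f) and p == 0.0

    def test_equal_means_zero_variance(self):
        assert ds.anova_from_summary([2.0, 2.0], [0.0, 0.0], [3, 3]) == (0.0, 1.0)


class TestStudentTtest:
    def test_identical_samples(self):
        t, p = ds.student_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_near_degenerate_separation(self):
        _, p = ds.student_ttest([0.0, 0.0, 0.0], [1.0, 1.0, 1.0001])
        assert p < 1e-6

    def test_zero_variance_limits(self):
        assert ds.student_ttest([1.0, 1.0], [1.0, 1.0])[1] == 1.0
        with pytest.warns(UserWarning):
            t, p = ds.student_ttest([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0 and t < 0


class TestFoldChange:
    def test_equal_means_zero(self):
        assert ds.log2_fold_change(3.0, 3.0, 0.001) == pytest.approx(0.0)

    def test_ratio_two_gives_one(self):
        assert ds.log2_fold_change(2.0, 1.0, 1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_nd_denominator_with_epsilon(self):
        # C-vs-A fold change for a compound detected only in C (0.22 vs ND)
        assert ds.log2_fold_change(0.22, 0.0, 0.01) == pytest.approx(4.52, abs=0.01)

    def test_both_zero_flagged(self):
        with pytest.warns(UserWarning, match="not-detected"):
            assert ds.log2_fold_change(0.0, 0.0, 0.01) == 0.0

    def test_default_epsilon_is_half_min_nonzero(self):
        df = pd.DataFrame({"a": [0.0, 0.4], "b": [1.0, 2.0]})
        assert ds.default_epsilon(df) == 0.2


class TestOplsda:
    def _data(self, seed=0, n=16, p=12, shift=2.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X[y == 1, 0] += shift
        return X, y

    def test_n_ortho_zero_reduces_to_pls(self):
        X, y = self._data()
        model = ds.fit_oplsda(X, y, n_ortho=0)
        sk = PLSRegression(n_components=1, scale=True).fit(X, y)
        t_ref = sk.x_scores_[:, 0]
        sign = np.sign(t_ref @ model.scores)
        assert np.allclose(model.scores, sign * t_ref, atol=1e-10)

    def test_y_encoding_invariance(self):
        X, y = self._data(seed=1)
        v1 = ds.vip_scores(ds.fit_oplsda(X, y, n_ortho=1))
        v2 = ds.vip_scores(ds.fit_oplsda(X, np.where(y == 0, -1, 1), n_ortho=1))
        assert np.allclose(v1.values, v2.values)

    def test_orthogonal_scores_uncorrelated_with_y(self):
        X, y = self._data(seed=2)
        model = ds.fit_oplsda(X, y, n_ortho=2)
        yc = np.where(y == 0, -1.0, 1.0)
        for t_o in model.ortho_scores:
            assert abs(np.corrcoef(t_o, yc)[0, 1]) < 1e-8

    def test_shifted_variable_attains_top_vip(self):
        X, y = self._data(seed=3, p=20)
        vips = ds.vip_scores(ds.fit_oplsda(X, y, n_ortho=1))
        assert vips.idxmax() == "x0"
        assert vips["x0"] > 1.0
        assert vips.drop("x0").mean() < 1.0

    def test_vip_normalization_identity(self):
        X, y = self._data(seed=4)
        vips = ds.vip_scores(ds.fit_oplsda(X, y, n_ortho=1))
        assert (vips**2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_single_variable_vip_is_one(self):
        X, y = self._data(p=1)
        vips = ds.vip_scores(ds.fit_oplsda(X[:, :1], y, n_ortho=0))
        assert vips.iloc[0] == pytest.approx(1.0)

    def test_orthogonal_filtering_never_hurts_training_correlation(self):
        for seed in range(10):
            X, y = self._data(seed=seed, shift=1.0)
            yc = np.where(y == 0, -1.0, 1.0)
            r_pls = abs(np.corrcoef(ds.fit_oplsda(X, y, n_ortho=0).scores, yc)[0, 1])
            r_opls = abs(np.corrcoef(ds.fit_oplsda(X, y, n_ortho=1).scores, yc)[0, 1])
            assert r_opls >= r_pls - 1e-12

    def test_constant_variable_named_in_error(self):
        X, y = self._data()
        X[:, 3] = 7.0
        with pytest.raises(ValueError, match="x3"):
            ds.fit_oplsda(X, y)

    def test_single_class_rejected(self):
        X, _ = self._data()
        with pytest.raises(ValueError, match="two classes"):
            ds.fit_oplsda(X, np.zeros(len(X)))


class TestScreen:
    def test_rule_verdicts(self):
        out = ds.screen_differential(
            p_values={"up": 0.01, "lowvip": 0.01, "flat": 0.5},
            vips={"up": 1.5, "lowvip": 0.8, "flat": 2.0},
            fold_changes={"up": 1.2, "lowvip": 1.2, "flat": 0.1},
        )
        verdicts = dict(zip(out.compound, out.verdict))
        assert verdicts == {"up": "up", "lowvip": "not significant",
                            "flat": "not significant"}

    def test_strict_thresholds(self):
        out = ds.screen_differential(
            p_values={"a": 0.05, "b": 0.049}, vips={"a": 1.5, "b": 1.0},
            fold_changes={"a": 1.0, "b": -1.0},
        )
        assert set(out.verdict) == {"not significant"}

    def test_empty_input(self):
        assert ds.screen_differential({}, {}, {}).empty

    def test_pairwise_screen_on_synthetic_data(self, library):
        conc = synth.simulate_concentrations(library, synth.StudyDesign(seed=2))
        out = ds.pairwise_screen(conc, "A", "C")
        assert len(out) == 74
        assert set(out.verdict) <= {"up", "down", "not significant"}
        # a compound ND in both groups carries no information
        row = out[out.compound == "Dodecane, 2,6,10-trimethyl-"]
        assert not row.empty


class TestVenn:
    def test_two_set_example(self):
        counts = ds.venn_counts({"X": {"a", "b"}, "Y": {"b", "c"}})
        assert counts[("X",)] == 1
        assert counts[("Y",)] == 1
        assert counts[("X", "Y")] == 1

    def test_identical_sets(self):
        counts = ds.venn_counts({"X": {1, 2}, "Y": {1, 2}})
        assert counts[("X", "Y")] == 2
        assert counts[("X",)] == counts[("Y",)] == 0

    @given(st.lists(st.sets(st.integers(0, 12)), min_size=2, max_size=4))
    def test_regions_sum_to_union(self, raw_sets):
        sets = {f"s{i}": s for i, s in enumerate(raw_sets)}
        counts = ds.venn_counts(sets)
        assert sum(counts.values()) == len(set.union(*map(set, raw_sets)))

    def test_matches_brute_force_membership_enumeration(self, library):
        conc = synth.simulate_concentrations(library, synth.StudyDesign(seed=42))
        sets = {}
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            out = ds.pairwise_screen(conc, a, b)
            sets[f"{a}v{b}"] = set(
                out.loc[out.verdict != "not significant", "compound"])
        counts = ds.venn_counts(sets)
        union = set.union(*sets.values())
        for element in union:
            member = tuple(sorted(k for k, s in sets.items() if element in s))
            assert counts[member] >= 1
        assert sum(counts.values()) == len(union)


class TestPcaHotelling:
    def test_centered_scores(self):
        rng = np.random.default_rng(0)
        scores, _, _ = ds.pca_hotelling(rng.normal(size=(15, 6)))
        assert np.allclose(scores[["PC1", "PC2"]].mean(), 0.0, atol=1e-10)

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 6))
        X[0] += 10.0
        _, _, inside = ds.pca_hotelling(X)
        assert not inside[0]
        assert inside[1:].all()

    def test_synthetic_samples_inside_ellipse(self, library):
        hits = 0
        for seed in range(100):
            conc = synth.simulate_concentrations(
                library, synth.StudyDesign(seed=seed))
            _, _, inside = ds.pca_hotelling(conc.drop(columns="group"))
            hits += inside.all()
        assert hits >= 90


class TestHclustHeatmap:
    def test_identical_rows_adjacent_with_zero_height(self):
        df = pd.DataFrame([[1.0, 2.0, 1.0], [5.0, 0.0, 2.0], [1.0, 2.0, 1.0]],
                          index=["r1", "r2", "r3"])
        row_order, _, _ = ds.hclust_heatmap(df, row_scale="none")
        i1, i3 = row_order.index("r1"), row_order.index("r3")
        assert abs(i1 - i3) == 1

    def test_two_blocks_contiguous(self):
        rng = np.random.default_rng(5)
        X = np.r_[rng.normal(3.0, 0.2, size=(3, 4)),
                  rng.normal(-3.0, 0.2, size=(3, 4))]
        df = pd.DataFrame(X, index=[f"r{i}" for i in range(6)])
        row_order, _, _ = ds.hclust_heatmap(df, row_scale="none")
        positions = [row_order.index(f"r{i}") for i in range(3)]
        assert max(positions) - min(positions) == 2

    def test_permutation_leaves_topology_unchanged(self):
        # cophenetic distances between labeled rows are permutation invariant
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(6, 4)),
                          index=[f"r{i}" for i in range(6)])
        shuffled = df.sample(frac=1, random_state=1)

        def coph(frame):
            Z = linkage(pdist(frame.to_numpy()), method="complete")
            mat = pd.DataFrame(squareform(cophenet(Z)), index=frame.index,
                               columns=frame.index)
            return mat.sort_index(axis=0).sort_index(axis=1)

        pd.testing.assert_frame_equal(coph(df), coph(shuffled))

    def test_zero_variance_row_scaled_to_zeros(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flat", "v"])
        with pytest.warns(UserWarning, match="flat"):
            _, _, scaled = ds.hclust_heatmap(df)
        assert (scaled.loc["flat"] == 0).all()
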