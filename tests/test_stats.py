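"""Inferential statistics: ANOVA oracles, t-family, Bayes factor, clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import smrloop as sl
from smrloop.stats import TTestResult, bh_fdr


def _long(groups):
    """groups: {group: [(y1, y2), ...]} -> long-format table."""
    rows = []
    sid = 0
    for g, pairs in groups.items():
        for y1, y2 in pairs:
            sid += 1
            rows += [(sid, g, 1, y1), (sid, g, 2, y2)]
    return pd.DataFrame(rows, columns=["subject", "group", "within", "value"])


class TestMixedAnova:
    def test_hand_computed_sums_of_squares(self):
        """4-subject split-plot; SS computed by hand arithmetic.

        g1: (1,3), (2,6); g2: (5,4), (7,8). SS_group=18, SS_within=4.5,
        SS_interaction=4.5, error terms 13 (between) and 2 (within) on
        df=2 -> F = 2.7692.., 4.5, 4.5; SS_total=42.
        """
        data = _long({"g1": [(1, 3), (2, 6)], "g2": [(5, 4), (7, 8)]})
        res = sl.mixed_anova_2x2(data)
        assert res.loc["group", "F"] == pytest.approx(18 / (13 / 2))
        assert res.loc["within", "F"] == pytest.approx(4.5)
        assert res.loc["interaction", "F"] == pytest.approx(4.5)
        assert (res["df1"] == 1).all() and (res["df2"] == 2).all()
        assert res.loc["group", "eta_sq"] == pytest.approx(18 / 42)
        assert res.loc["interaction", "eta_sq"] == pytest.approx(4.5 / 42)

    def test_constant_data_null(self):
        data = _long({"g1": [(3, 3), (3, 3)], "g2": [(3, 3), (3, 3)]})
        res = sl.mixed_anova_2x2(data)
        assert (res["F"] == 0).all()
        assert (res["p"] == 1).all()

    def test_matches_reference_package(self):
        """F agrees with pingouin to 1e-8 on random (un)balanced designs."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        for sizes in ((6, 6), (9, 7)):
            data = _long({
                "a": [tuple(rng.normal(size=2)) for _ in range(sizes[0])],
                "b": [tuple(rng.normal(size=2)) for _ in range(sizes[1])],
            })
            mine = sl.mixed_anova_2x2(data)
            ref = pg.mixed_anova(data, dv="value", within="within",
                                 between="group", subject="subject")
            for eff, src in (("group", "group"), ("within", "within"),
                             ("interaction", "Interaction")):
                f_ref = float(ref.loc[ref.Source == src, "F"].iloc[0])
                assert mine.loc[eff, "F"] == pytest.approx(f_ref, abs=1e-8)

    def test_missing_cell_rejected(self):
        data = _long({"g1": [(1, 2), (3, 4)], "g2": [(5, 6), (7, 8)]})
        with pytest.raises(ValueError):
            sl.mixed_anova_2x2(data.iloc[:-1])

    def test_single_subject_group_rejected(self):
        data = _long({"g1": [(1, 2)], "g2": [(5, 6), (7, 8)]})
        with pytest.raises(ValueError):
            sl.mixed_anova_2x2(data)


class TestArtAnova:
    def test_all_equal_data_null(self):
        data = _long({"g1": [(3, 3), (3, 3)], "g2": [(3, 3), (3, 3)]})
        res = sl.art_anova(data)
        assert (res["F"] == 0).all()

    def test_affine_transform_invariance(self):
        """Positive affine maps preserve aligned ranks, hence every F."""
        rng = np.random.default_rng(3)
        data = _long({
            "a": [tuple(rng.normal(size=2)) for _ in range(6)],
            "b": [tuple(rng.normal(1.0, 1.0, size=2)) for _ in range(6)],
        })
        scaled = data.copy()
        scaled["value"] = 3.0 * scaled["value"] + 10.0
        pd.testing.assert_frame_equal(sl.art_anova(data),
                                      sl.art_anova(scaled))

    def test_pure_interaction_detected_selectively(self):
        rng = np.random.default_rng(4)
        pairs_a = [(rng.normal(0, 0.5), rng.normal(2, 0.5))
                   for _ in range(8)]
        pairs_b = [(rng.normal(2, 0.5), rng.normal(0, 0.5))
                   for _ in range(8)]
        res = sl.art_anova(_long({"a": pairs_a, "b": pairs_b}))
        assert res.loc["interaction", "p"] < 0.001
        assert res.loc["group", "p"] > 0.05
        assert res.loc["within", "p"] > 0.05


class TestTTestFamily:
    def test_two_sample_textbook_value(self):
        res = sl.ttest([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3 / np.sqrt(2 / 3))
        assert res.df == 4
        ref = sstats.ttest_ind([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(ref.pvalue)

    def test_paired_identical_null(self):
        with pytest.raises(ValueError):
            sl.ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        res = sl.ttest([1.0, 2.1, 3.0], [1.0, 2.0, 3.0], paired=True)
        ref = sstats.ttest_rel([1.0, 2.1, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(ref.statistic)

    def test_cohen_d_unit_definition(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 4000)
        b = rng.normal(1, 1, 4000)
        assert sl.ttest(a, b).cohen_d == pytest.approx(-1.0, abs=0.1)

    def test_one_sample_against_mu(self):
        res = sl.ttest([1.0, 2.0, 3.0], mu=2.0)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)


class TestBonferroni:
    def test_scaling_and_cap(self):
        np.testing.assert_allclose(sl.bonferroni([0.01, 0.7], m=2),
                                   [0.02, 1.0])

    def test_never_decreases(self):
        p = np.array([0.001, 0.2, 0.9])
        assert np.all(sl.bonferroni(p, m=3) >= p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sl.bonferroni([1.5])


class TestPearson:
    def test_perfect_correlation(self):
        r, p = sl.pearson_r([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_hand_computable_triple(self):
        r, _ = sl.pearson_r([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_matches_scipy_and_null_behavior(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=500), rng.normal(size=500)
        r, p = sl.pearson_r(x, y)
        ref = sstats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)
        assert abs(r) < 0.15


class TestJZSBayesFactor:
    def test_null_data_favors_null(self):
        rng = np.random.default_rng(7)
        logbf = sl.jzs_bayes_factor_t(rng.normal(0, 1, 100),
                                      rng.normal(0, 1, 100))
        assert logbf < 0

    def test_monotone_in_separation(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 30)
        logbfs = [
            sl.jzs_bayes_factor_t(base, rng.normal(d, 1, 30))
            for d in (0.5, 1.5, 3.0)
        ]
        assert logbfs[0] < logbfs[1] < logbfs[2]
        assert logbfs[2] > 0

    def test_agrees_with_independent_oracle(self):
        """Within 1% of pingouin's independent quadrature on random data."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.normal(0, 1, 15)
            b = rng.normal(rng.uniform(-1, 1), 1, 12)
            mine = np.exp(sl.jzs_bayes_factor_t(a, b))
            ref = float(pg.bayesfactor_ttest(sl.ttest(a, b).t, 15, 12))
            assert mine == pytest.approx(ref, rel=0.01)


class TestBHFDR:
    def test_monotone_in_sorted_p(self):
        p = np.array([0.001, 0.02, 0.03, 0.5, 0.9])
        q = bh_fdr(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)


class TestClusterFDR:
    def test_inserted_effect_recovered(self):
        rng = np.random.default_rng(10)
        maps = rng.normal(0, 1, (12, 25, 40))
        true = np.zeros((25, 40), dtype=bool)
        true[7:13, 20:35] = True
        maps[:, true] += 1.8
        res = sl.cluster_fdr_map(maps, threshold_p=1e-3,
                                 n_permutations=300, seed=1)
        overlap = (res.significant_mask & true).sum() / true.sum()
        assert overlap >= 0.8
        assert res.significant_mask[true].any()

    def test_null_maps_mostly_clean(self):
        rng = np.random.default_rng(11)
        res = sl.cluster_fdr_map(rng.normal(0, 1, (10, 25, 40)),
                                 threshold_p=1e-4, n_permutations=200,
                                 seed=2)
        assert res.significant_mask.sum() == 0

    def test_mask_subset_of_suprathreshold(self):
        rng = np.random.default_rng(12)
        maps = rng.normal(0, 1, (10, 20, 30))
        maps[:, 5:9, 10:20] += 2.0
        res = sl.cluster_fdr_map(maps, threshold_p=1e-3,
                                 n_permutations=200, seed=3)
        t_crit = sstats.t.isf(1e-3 / 2, 9)
        assert not (res.significant_mask & (np.abs(res.t_map) <= t_crit)).any()

    def test_q_monotone_in_mass(self):
        rng = np.random.default_rng(13)
        maps = rng.normal(0, 1, (12, 30, 40))
        maps[:, 5:10, 5:15] += 1.5
        maps[:, 20:22, 25:28] -= 1.2
        res = sl.cluster_fdr_map(maps, threshold_p=5e-3,
                                 n_permutations=300, seed=4)
        clusters = sorted(res.clusters, key=lambda c: -c.mass)
        ps = [c.p for c in clusters]
        assert ps == sorted(ps)

    def test_single_map_rejected(self):
        with pytest.raises(ValueError):
            sl.cluster_fdr_map(np.zeros((1, 5, 5)))

    def test_two_sample_mode(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, (10, 20, 30))
        b = rng.normal(0, 1, (9, 20, 30))
        a[:, 4:8, 10:20] += 2.5
        res = sl.cluster_fdr_map(a, b, threshold_p=1e-3,
                                 n_permutations=300, seed=5)
        assert res.significant_mask[4:8, 10:20].mean() > 0.5
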