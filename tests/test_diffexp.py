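import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeocomp import diffexp as D
from homeocomp.diffexp import (
    CountMatrix,
    DEResult,
    adjust_bh,
    classify_de,
    estimate_dispersion,
    estimate_size_factors,
    run_de,
    wald_test,
)
from homeocomp.synthetic import SimulationConfig, simulate_experiment


def make_matrix(counts, genotypes):
    counts = np.asarray(counts)
    samples = [f"s{i}" for i in range(counts.shape[1])]
    return CountMatrix(
        counts=pd.DataFrame(
            counts, index=[f"g{i}" for i in range(counts.shape[0])], columns=samples
        ),
        samples=pd.DataFrame(
            {
                "genotype": genotypes,
                "replicate": list(range(1, len(samples) + 1)),
            },
            index=pd.Index(samples, name="sample"),
        ),
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = np.tile([[5], [10], [20]], (1, 4))
        np.testing.assert_allclose(estimate_size_factors(m), np.ones(4))

    def test_hand_computed_median_of_ratios(self):
        # genes (2,8) and (4,16): ratios to geometric means are (0.5, 2)
        m = np.array([[2, 8], [4, 16]])
        np.testing.assert_allclose(estimate_size_factors(m), [0.5, 2.0])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        m = rng.poisson(50, size=(200, 4)) + 1
        base = estimate_size_factors(m)
        scaled = m.astype(float).copy()
        scaled[:, 2] *= 3.0
        out = estimate_size_factors(scaled)
        # size factors are defined up to a common scale: the scaled
        # sample's factor triples relative to every other sample
        np.testing.assert_allclose(
            (out[2] / out[0]) / (base[2] / base[0]), 3.0, rtol=1e-9
        )
        np.testing.assert_allclose(out[1] / out[0], base[1] / base[0], rtol=1e-9)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.poisson(30, size=(100, 3)) + 1
        perm = rng.permutation(100)
        np.testing.assert_allclose(
            estimate_size_factors(m), estimate_size_factors(m[perm])
        )

    def test_all_zero_error(self):
        m = np.array([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            estimate_size_factors(m)


class TestDispersion:
    def test_poisson_gene_near_floor(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(100, size=(2000, 6))
        matrix = make_matrix(counts, ["WT"] * 3 + ["m"] * 3)
        disp = estimate_dispersion(
            matrix, np.ones(6), shrinkage_weight=1.0
        )
        # trend should settle near zero for Poisson data
        assert np.median(disp) < 5e-3

    def test_nb_dispersion_recovery(self):
        rng = np.random.default_rng(3)
        alpha, mu = 0.05, 200.0
        shape = 1.0 / alpha
        counts = rng.negative_binomial(
            shape, shape / (shape + mu), size=(2000, 6)
        )
        matrix = make_matrix(counts, ["WT"] * 3 + ["m"] * 3)
        disp = estimate_dispersion(matrix, np.ones(6))
        assert abs(np.median(disp) - alpha) / alpha < 0.2

    def test_constant_gene_gets_floor(self):
        counts = np.vstack([np.full(6, 7), np.arange(1, 7) * 10])
        matrix = make_matrix(counts, ["WT"] * 3 + ["m"] * 3)
        disp = estimate_dispersion(matrix, np.ones(6), shrinkage_weight=0.0)
        assert disp[0] == D.DISPERSION_FLOOR


class TestWaldTest:
    def test_identical_conditions_zero_lfc(self):
        block = np.array([[10, 20, 30]])
        counts = np.hstack([block, block])
        matrix = make_matrix(counts, ["m"] * 3 + ["WT"] * 3)
        res = wald_test(matrix, np.ones(6), np.array([0.1]), ("m", "WT"))
        assert res[0].log2_fold_change == pytest.approx(0.0, abs=1e-9)
        assert res[0].pvalue == pytest.approx(1.0)

    def test_all_zero_gene(self):
        counts = np.zeros((1, 6), dtype=int)
        matrix = make_matrix(counts, ["m"] * 3 + ["WT"] * 3)
        res = wald_test(matrix, np.ones(6), np.array([0.1]), ("m", "WT"))
        assert np.isnan(res[0].fold_change)
        assert res[0].pvalue == 1.0

    def test_equal_size_factor_mle_is_mean_ratio(self):
        counts = np.array([[10, 12, 14, 30, 36, 42]])
        matrix = make_matrix(counts, ["WT"] * 3 + ["m"] * 3)
        res = wald_test(matrix, np.ones(6), np.array([0.05]), ("m", "WT"))
        assert res[0].fold_change == pytest.approx(3.0, rel=1e-9)

    def test_power_tenfold_shift(self):
        rng = np.random.default_rng(4)
        alpha, n_sim = 0.01, 300
        shape = 1.0 / alpha
        hits = 0
        wt = rng.negative_binomial(shape, shape / (shape + 256.0), size=(n_sim, 3))
        mut = rng.negative_binomial(shape, shape / (shape + 2560.0), size=(n_sim, 3))
        counts = np.hstack([wt, mut])
        matrix = make_matrix(counts, ["WT"] * 3 + ["m"] * 3)
        res = wald_test(
            matrix, np.ones(6), np.full(n_sim, alpha), ("m", "WT")
        )
        hits = sum(1 for r in res if r.pvalue < 0.05)
        assert hits / n_sim > 0.99

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(80, size=(50, 6))
        matrix = make_matrix(counts, ["WT"] * 3 + ["m"] * 3)
        sf = estimate_size_factors(matrix)
        disp = estimate_dispersion(matrix, sf)
        res = wald_test(matrix, sf, disp, ("m", "WT"))
        perm = [3, 1, 5, 0, 4, 2]
        matrix2 = CountMatrix(
            counts=matrix.counts.iloc[:, perm],
            samples=matrix.samples.iloc[perm],
        )
        sf2 = estimate_size_factors(matrix2)
        disp2 = estimate_dispersion(matrix2, sf2)
        res2 = wald_test(matrix2, sf2, disp2, ("m", "WT"))
        for a, b in zip(res, res2):
            assert a.pvalue == pytest.approx(b.pvalue, abs=1e-9)
            assert a.log2_fold_change == pytest.approx(
                b.log2_fold_change, abs=1e-9
            )


class TestAdjustBH:
    def test_single_value(self):
        np.testing.assert_allclose(adjust_bh([1.0]), [1.0])

    def test_hand_computed_equal_adjustments(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_hand_computed_two_values(self):
        np.testing.assert_allclose(adjust_bh([0.005, 0.1]), [0.01, 0.1])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(size=500)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adjust_bh(p), expected, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_properties(self, p):
        out = adjust_bh(p)
        assert np.all(out >= np.asarray(p) - 1e-15)  # padj >= p
        assert np.all(out <= 1.0)
        # monotone when input sorted ascending
        s = np.sort(p)
        out_sorted = adjust_bh(s)
        assert np.all(np.diff(out_sorted) >= -1e-15)
        # order preservation: adjustment never swaps two p-values
        p_arr = np.asarray(p)
        for i in range(len(p)):
            smaller = p_arr < p_arr[i]
            assert np.all(out[smaller] <= out[i] + 1e-15)


class TestClassifyDE:
    def result(self, fc, padj):
        return DEResult(
            gene="g", base_mean=10, fold_change=fc,
            log2_fold_change=np.log2(fc) if fc > 0 else np.nan,
            se_log2=0.1, pvalue=padj, padj=padj,
        )

    def test_strong_downregulation(self):
        # headline NMD-like case: FC 0.18 at padj 7.8e-19
        assert classify_de(self.result(0.18, 7.8e-19)) == D.DOWN

    def test_not_significant(self):
        assert classify_de(self.result(1.5, 0.2)) == D.NO_CHANGE

    def test_up(self):
        assert classify_de(self.result(2.0, 0.01)) == D.UP

    def test_undefined_fc(self):
        r = DEResult(
            gene="g", base_mean=0, fold_change=np.nan,
            log2_fold_change=np.nan, se_log2=np.nan, pvalue=1.0, padj=1.0,
        )
        assert classify_de(r) == D.NO_CHANGE


class TestNullCalibration:
    def test_null_pvalues_near_uniform(self):
        """KS distance < 0.05 and rejection near nominal on a null sim."""
        config = SimulationConfig(
            n_groups=1700, ptc_fraction=0.5, syn_fraction=0.5,
            nmd_fold=1.0, compensation_rate=0.0, nb_dispersion=0.05, seed=11,
        )
        exp = simulate_experiment(config)
        sf = estimate_size_factors(exp.counts)
        disp = estimate_dispersion(exp.counts, sf)
        res = wald_test(exp.counts, sf, disp, ("mut1", "WT"))
        p = np.array([r.pvalue for r in res])
        assert p.size >= 5000
        from scipy.stats import kstest

        assert kstest(p, "uniform").statistic < 0.05
        assert 0.04 <= (p < 0.05).mean() <= 0.06


class TestRunDE:
    def test_statuses_and_padj_consistency(self, small_experiment):
        res = run_de(small_experiment.counts, "mut1", "WT")
        for r in res:
            if not np.isnan(r.padj):
                assert r.padj >= r.pvalue - 1e-12
            assert r.status == classify_de(r)

    def test_null_size_factors_all_one(self):
        config = SimulationConfig(n_groups=50, nmd_fold=1.0, seed=2)
        exp = simulate_experiment(config)
        sf = estimate_size_factors(exp.counts)
        np.testing.assert_allclose(sf, np.ones(6), rtol=0.15)
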