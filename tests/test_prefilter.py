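import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.isotonic import IsotonicRegression

from txpod import prefilter, simulate as sim
from txpod.errors import DataError

from conftest import make_design, make_experiment


CONCS = [0.0, 0.1, 0.5, 1.0, 5.0, 10.0, 100.0]


class TestNormalize:
    def test_identical_samples_have_unit_size_factors(self):
        counts = np.tile(np.array([[10], [200], [3000]]), (1, len(CONCS) * 3))
        exp = make_experiment(counts, CONCS)
        mat = prefilter.normalize_log2cpm(exp)
        assert np.allclose(mat.size_factors, 1.0)
        assert np.allclose(mat.values.to_numpy(), mat.values.to_numpy()[:, [0]])

    def test_stated_formula_arithmetic(self):
        # library of two probes summing to 1e6: probe at 1000 -> log2(1001)
        counts = np.tile(np.array([[1000], [999000]]), (1, len(CONCS) * 3))
        exp = make_experiment(counts, CONCS)
        mat = prefilter.normalize_log2cpm(exp)
        assert mat.values.iloc[0, 0] == pytest.approx(np.log2(1001), abs=1e-9)

    def test_scale_invariance_of_one_sample(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(200.0, size=(40, len(CONCS) * 3))
        exp = make_experiment(counts, CONCS)
        doubled = counts.copy()
        doubled[:, 5] *= 2
        exp2 = make_experiment(doubled, CONCS)
        a = prefilter.normalize_log2cpm(exp).values.to_numpy()
        b = prefilter.normalize_log2cpm(exp2).values.to_numpy()
        assert np.allclose(a, b, atol=1e-9)

    def test_zero_total_sample_is_data_error(self):
        counts = np.ones((5, len(CONCS) * 3), dtype=int)
        counts[:, 2] = 0
        exp = make_experiment(counts, CONCS)
        with pytest.raises(DataError, match="zero total"):
            prefilter.normalize_log2cpm(exp)


class TestPava:
    @given(
        values=st.lists(st.floats(-10, 10), min_size=2, max_size=12),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=80, deadline=None)
    def test_monotone_and_mean_preserving(self, values, seed):
        y = np.array(values)
        w = np.random.default_rng(seed).uniform(0.5, 3.0, y.size)
        fit = prefilter.pava(y, w)
        assert np.all(np.diff(fit) >= -1e-9)
        assert np.dot(fit, w) == pytest.approx(np.dot(y, w), rel=1e-9, abs=1e-9)

    @given(
        values=st.lists(st.floats(-5, 5), min_size=2, max_size=10),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_sklearn_isotonic(self, values):
        y = np.array(values)
        w = np.ones_like(y)
        ours = prefilter.pava(y, w)
        theirs = IsotonicRegression().fit_transform(np.arange(y.size), y)
        assert np.allclose(ours, theirs, atol=1e-9)

    def test_decreasing_direction(self):
        y = np.array([1.0, 2.0, 0.0])
        fit = prefilter.pava(y, np.ones(3), increasing=False)
        assert np.all(np.diff(fit) <= 1e-9)


class TestWilliamsTrend:
    def test_flat_probe(self):
        design = make_design(CONCS)
        values = np.full(len(design), 3.14)
        res = prefilter.williams_trend_p(values, design.reset_index(), n_permutations=99)
        assert res["t_stat"] == 0.0
        assert res["p"] == 1.0

    def test_strong_trend_hits_permutation_floor(self):
        design = make_design(CONCS)
        conc = design["concentration_uM"].to_numpy()
        rng = np.random.default_rng(1)
        values = 10.0 * np.argsort(np.argsort(conc)) + rng.normal(0, 0.01, conc.size)
        one_sided = prefilter.williams_trend_p(
            values, design.reset_index(), n_permutations=999, seed=0, two_sided=False
        )
        assert one_sided["p"] == pytest.approx(1 / 1000)
        two_sided = prefilter.williams_trend_p(
            values, design.reset_index(), n_permutations=999, seed=0
        )
        assert two_sided["p"] == pytest.approx(2 / 1000)
        assert two_sided["direction"] == "up"

    def test_zero_variance_unequal_means_floors_p(self, caplog):
        design = make_design(CONCS)
        conc = design["concentration_uM"].to_numpy()
        values = (conc > 0).astype(float)  # constant within groups
        with caplog.at_level("WARNING"):
            res = prefilter.williams_trend_p(values, design.reset_index(),
                                             n_permutations=99)
        assert res["p"] == pytest.approx(1 / 100)

    def test_top_amalgamated_mean_equals_pava_fit(self):
        # the suffix-average shortcut must agree with explicit PAVA
        design = make_design(CONCS, n_replicates=2)
        conc = design["concentration_uM"].to_numpy()
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, (5, conc.size))
        groups = np.unique(conc)
        sizes = np.array([(conc == g).sum() for g in groups], dtype=float)
        for row in y:
            means = np.array([row[conc == g].mean() for g in groups])
            pava_fit = prefilter.pava(means[1:], sizes[1:])
            dose_means = means[1:]
            wsum = np.cumsum((dose_means * sizes[1:])[::-1])[::-1]
            wn = np.cumsum(sizes[1:][::-1])[::-1]
            assert pava_fit[-1] == pytest.approx(np.max(wsum / wn), rel=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        design = make_design(CONCS)
        conc = design["concentration_uM"].to_numpy()
        values = rng.normal(0, 1, (500, conc.size))
        res = prefilter.williams_trend_test(values, conc, n_permutations=199, seed=5)
        rate = (res["p"] < 0.05).mean()
        bound = 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / 500)
        assert rate <= bound


class TestPrefilterProbes:
    def _matrix(self, values, conc):
        design = make_design(CONCS)
        df = pd.DataFrame(values, columns=design.index)
        return prefilter.ExpressionMatrix(
            values=df, size_factors=pd.Series(1.0, index=design.index), design=design
        )

    def test_fold_change_arithmetic(self):
        design = make_design(CONCS)
        conc = design["concentration_uM"].to_numpy()
        base = np.full(conc.size, 5.0)
        strong = base + np.where(conc >= 10.0, 0.7, 0.0)
        weak = base + np.where(conc >= 10.0, 0.5, 0.0)
        mat = self._matrix(np.vstack([strong, weak]), conc)
        fc = prefilter.max_fold_change(mat.values, conc)
        assert fc.iloc[0] == pytest.approx(2**0.7)
        assert fc.iloc[1] == pytest.approx(2**0.5)
        assert fc.iloc[0] >= 1.5 and fc.iloc[1] < 1.5

    def test_fc_threshold_is_inclusive(self):
        design = make_design(CONCS)
        conc = design["concentration_uM"].to_numpy()
        shift = np.log2(1.5)
        values = np.full(conc.size, 5.0) + np.where(conc > 0, shift, 0.0)
        mat = self._matrix(values[None, :], conc)
        passing, table = prefilter.prefilter_probes(mat, n_permutations=99, seed=0)
        # monotone step with zero within-group variance: p at floor, FC == 1.5
        assert table["max_fc"].iloc[0] == pytest.approx(1.5)
        assert table["max_fc"].iloc[0] >= 1.5
        assert table["passed"].iloc[0]
        assert len(passing) == 1

    def test_empty_pass_set_is_legal(self):
        rng = np.random.default_rng(0)
        design = make_design(CONCS)
        conc = design["concentration_uM"].to_numpy()
        mat = self._matrix(rng.normal(5, 0.01, (10, conc.size)), conc)
        passing, table = prefilter.prefilter_probes(
            mat, p_threshold=1e-6, n_permutations=99, seed=0
        )
        assert passing == set()

    def test_pass_set_shrinks_with_tighter_thresholds(self):
        cfg = sim.SimConfig(n_probes=300, fraction_responsive=0.3)
        exp, _, _ = sim.simulate_experiment(cfg, seed=6)
        mat = prefilter.normalize_log2cpm(exp)
        loose, _ = prefilter.prefilter_probes(mat, 0.05, 1.5, n_permutations=199, seed=1)
        tight_p, _ = prefilter.prefilter_probes(mat, 0.01, 1.5, n_permutations=199, seed=1)
        tight_fc, _ = prefilter.prefilter_probes(mat, 0.05, 2.0, n_permutations=199, seed=1)
        assert tight_p <= loose
        assert tight_fc <= loose
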