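import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from txpod import bmc as bmc_mod
from txpod.bmc.fit import BMCRecord, ModelFit, _make_fit, _saturated_loglik
from txpod.bmc.models import Exp2, Exp4, Linear, Poly2
from txpod.errors import DesignError, ModelingError

CONCS = np.array([0.0, 0.05, 0.16, 0.5, 1.6, 5.0, 16.0, 50.0, 100.0])


def _samples(n_reps=3):
    return np.repeat(CONCS, n_reps)


def _fit_stub(family_model, params, sigma=1.0, loglik=-10.0, aic=24.0,
              fit_p=0.5, converged=True, c=None, y=None):
    return ModelFit(
        family=family_model.name, model=family_model,
        params=np.asarray(params, dtype=float), sigma=sigma, loglik=loglik,
        aic=aic, fit_p=fit_p, converged=converged,
        n_mean_params=family_model.n_mean_params,
        c=c if c is not None else _samples(), y=y,
    )


class TestFitFamily:
    def test_linear_truth_recovered(self):
        rng = np.random.default_rng(0)
        c = _samples()
        y = 2.0 + 0.03 * c + rng.normal(0, 0.01, c.size)
        fits = {f.family: f for f in bmc_mod.fit_family(c, y)}
        assert fits["linear"].params[0] == pytest.approx(2.0, abs=0.02)
        assert fits["linear"].params[1] == pytest.approx(0.03, abs=0.001)
        assert fits["poly2"].params[2] == pytest.approx(0.0, abs=1e-4)

    def test_power_exponent_never_below_one(self):
        rng = np.random.default_rng(1)
        c = _samples()
        # concave-up shape whose unconstrained exponent would be < 1
        y = 1.0 + np.sqrt(c) + rng.normal(0, 0.02, c.size)
        fits = {f.family: f for f in bmc_mod.fit_family(c, y)}
        assert fits["power"].params[2] >= 1.0

    def test_exp4_at_least_as_good_as_linear_on_exp4_truth(self):
        rng = np.random.default_rng(2)
        c = _samples()
        truth = Exp4(increasing=True)
        y = truth.predict(np.array([5.0, 0.3, 1.6]), c) + rng.normal(0, 0.02, c.size)
        fits = {f.family: f for f in bmc_mod.fit_family(c, y)}
        assert fits["exp4"].loglik >= fits["linear"].loglik

    def test_too_few_groups_is_design_error(self):
        c = np.repeat([0.0, 1.0, 10.0, 50.0, 100.0], 3)
        with pytest.raises(DesignError):
            bmc_mod.fit_family(c, np.zeros(c.size))

    def test_aic_counts_sigma(self):
        rng = np.random.default_rng(3)
        c = _samples()
        y = 1.0 + 0.01 * c + rng.normal(0, 0.1, c.size)
        fits = {f.family: f for f in bmc_mod.fit_family(c, y)}
        lin = fits["linear"]
        assert lin.aic == pytest.approx(2 * 3 - 2 * lin.loglik)


class TestSelectModel:
    def test_nested_test_keeps_linear_under_linear_truth(self):
        rng = np.random.default_rng(4)
        c = _samples()
        kept_linear = 0
        n_sim = 100
        for _ in range(n_sim):
            y = 1.0 + 0.02 * c + rng.normal(0, 0.2, c.size)
            ll_sat, n_groups = _saturated_loglik(c, y)
            lin = _make_fit(Linear(), Linear().fit_exact(c, y), c, y, True, ll_sat, n_groups)
            poly = _make_fit(Poly2(), Poly2().fit_exact(c, y), c, y, True, ll_sat, n_groups)
            dev = 2.0 * (poly.loglik - lin.loglik)
            assert dev >= -1e-9
            if chi2.sf(max(dev, 0.0), 1) >= 0.05:
                kept_linear += 1
        assert kept_linear >= 0.9 * n_sim

    def test_aic_tie_prefers_fewer_parameters(self):
        three = _fit_stub(Exp4(), [1.0, 1.0, 2.0], aic=10.0)
        four = _fit_stub(
            bmc_mod.FAMILIES["exp5"](increasing=True), [1.0, 1.0, 2.0, 1.0], aic=10.0
        )
        assert bmc_mod.select_model([three, four]).family == "exp4"

    def test_singleton_selection(self):
        only = _fit_stub(Exp2(), [1.0, 0.1])
        assert bmc_mod.select_model([only]).family == "exp2"

    def test_never_selects_non_converged(self):
        good = _fit_stub(Exp2(), [1.0, 0.1], aic=50.0)
        bad = _fit_stub(Exp4(), [1.0, 1.0, 2.0], aic=1.0, converged=False)
        assert bmc_mod.select_model([good, bad]).family == "exp2"
        with pytest.raises(ModelingError):
            bmc_mod.select_model([bad])


class TestBmcFromFit:
    def test_linear_closed_form(self):
        fit = _fit_stub(Linear(), [0.0, 2.0], sigma=1.0)
        bmc, flags = bmc_mod.bmc_from_fit(fit, bmr_k=1.0, c_top=100.0)
        assert bmc == pytest.approx(0.5, rel=1e-6)

    def test_exp2_closed_form(self):
        a, b, sigma = 8.0, 0.1, 0.4
        fit = _fit_stub(Exp2(), [a, b], sigma=sigma)
        bmc, _ = bmc_mod.bmc_from_fit(fit, bmr_k=1.0, c_top=100.0)
        assert bmc == pytest.approx((1 / b) * np.log1p(sigma / a), rel=1e-6)

    def test_oracle_equivalence_on_random_draws(self):
        # bisection path vs closed-form inversion, 100 draws per family
        rng = np.random.default_rng(5)
        for _ in range(100):
            b0, b1 = rng.uniform(-5, 5), rng.choice([-1, 1]) * rng.uniform(0.05, 5)
            sigma = rng.uniform(0.1, 2.0)
            fit = _fit_stub(Linear(), [b0, b1], sigma=sigma)
            bmc, _ = bmc_mod.bmc_from_fit(fit, c_top=100.0)
            closed = sigma / abs(b1)
            if closed <= 100.0:
                assert bmc == pytest.approx(closed, rel=1e-5)
            a = rng.uniform(0.5, 10.0)
            beta = rng.choice([-1, 1]) * rng.uniform(0.01, 1.0)
            sigma = rng.uniform(0.05, 0.5) * a / 2
            fit = _fit_stub(Exp2(), [a, beta], sigma=sigma)
            bmc, _ = bmc_mod.bmc_from_fit(fit, c_top=100.0)
            delta = sigma if beta > 0 else -sigma
            closed = np.log1p(delta / a) / beta
            if 0 < closed <= 100.0:
                assert bmc == pytest.approx(closed, rel=1e-5)

    def test_flat_fit_has_no_crossing(self):
        fit = _fit_stub(Linear(), [3.0, 0.0], sigma=1.0)
        bmc, flags = bmc_mod.bmc_from_fit(fit, c_top=100.0)
        assert bmc is None
        assert flags == ["no BMC <= top"]

    def test_zero_sigma_is_modeling_error(self):
        fit = _fit_stub(Linear(), [0.0, 1.0], sigma=0.0)
        with pytest.raises(ModelingError):
            bmc_mod.bmc_from_fit(fit, c_top=100.0)

    def test_extrapolation_flag_below_lowest_dose(self):
        fit = _fit_stub(Linear(), [0.0, 100.0], sigma=1.0)  # bmc = 0.01
        bmc, flags = bmc_mod.bmc_from_fit(fit, c_top=100.0, lowest_nonzero=0.05)
        assert bmc == pytest.approx(0.01, rel=1e-6)
        assert "extrapolated-below-lowest-dose" in flags


def _fitted_probe(seed=0, slope=0.05, noise=0.05, n_reps=3):
    rng = np.random.default_rng(seed)
    c = _samples(n_reps)
    y = 1.0 + slope * c + rng.normal(0, noise, c.size)
    fits = bmc_mod.fit_family(c, y)
    best = bmc_mod.select_model(fits)
    bmc, _ = bmc_mod.bmc_from_fit(best, c_top=100.0)
    return best, bmc


class TestProfileBounds:
    def test_ordering_invariant(self):
        for seed in range(4):
            best, bmc = _fitted_probe(seed)
            bmcl, bmcu, _ = bmc_mod.profile_bounds(best, bmc, c_top=100.0)
            assert bmcl <= bmc <= bmcu

    def test_interval_shrinks_with_replication(self):
        widths = []
        for n_reps in (3, 12):
            best, bmc = _fitted_probe(seed=1, noise=0.2, n_reps=n_reps)
            bmcl, bmcu, _ = bmc_mod.profile_bounds(best, bmc, c_top=100.0)
            widths.append(np.log10(bmcu / bmcl))
        assert widths[1] < widths[0]


class TestPostfilter:
    def _record(self, **kw):
        defaults = dict(probe_id="P0", chemical_id="x", fit=None, bmc=1.0,
                        bmcl=0.5, bmcu=2.0)
        defaults.update(kw)
        return BMCRecord(**defaults)

    def test_low_fit_p_dropped(self):
        rec = self._record(fit=_fit_stub(Linear(), [0, 1], fit_p=0.05))
        assert bmc_mod.postfilter_records([rec], c_top=100.0) == []
        assert "fit p" in rec.dropped_reason

    def test_wide_interval_dropped(self):
        rec = self._record(bmcl=0.1, bmcu=4.5)
        assert bmc_mod.postfilter_records([rec], c_top=100.0) == []
        assert "BMCU/BMCL" in rec.dropped_reason

    def test_bmc_at_top_retained(self):
        rec = self._record(bmc=100.0, bmcl=80.0, bmcu=120.0)
        assert bmc_mod.postfilter_records([rec], c_top=100.0) == [rec]

    def test_bmc_above_top_dropped(self):
        rec = self._record(bmc=100.01, bmcl=80.0, bmcu=120.0)
        assert bmc_mod.postfilter_records([rec], c_top=100.0) == []

    def test_output_is_subset(self):
        recs = [self._record(probe_id=f"P{i}", bmcu=2.0 + i * 30) for i in range(4)]
        retained = bmc_mod.postfilter_records(recs, c_top=100.0)
        assert set(r.probe_id for r in retained) <= set(r.probe_id for r in recs)


class TestCollapse:
    def _rec(self, probe, bmc):
        return BMCRecord(probe_id=probe, chemical_id="x", fit=None, bmc=bmc,
                         bmcl=bmc / 2, bmcu=bmc * 2)

    def test_min_bmc_wins(self):
        pm = pd.DataFrame({"probe_id": ["P1", "P2"], "gene_id": ["G1", "G1"]})
        genes = bmc_mod.collapse_to_genes([self._rec("P1", 0.5), self._rec("P2", 2.0)], pm)
        assert len(genes) == 1
        assert genes.iloc[0]["bmc"] == 0.5
        assert genes.iloc[0]["probe_id"] == "P1"

    def test_identity_for_one_probe_per_gene(self):
        pm = pd.DataFrame({"probe_id": ["P1", "P2"], "gene_id": ["G1", "G2"]})
        genes = bmc_mod.collapse_to_genes([self._rec("P1", 0.5), self._rec("P2", 2.0)], pm)
        assert list(genes["gene_id"]) == ["G1", "G2"]

    def test_unmapped_probe_excluded_with_warning(self, caplog):
        pm = pd.DataFrame({"probe_id": ["P1"], "gene_id": ["G1"]})
        with caplog.at_level("WARNING"):
            genes = bmc_mod.collapse_to_genes(
                [self._rec("P1", 0.5), self._rec("P9", 0.1)], pm
            )
        assert list(genes["gene_id"]) == ["G1"]
        assert "P9" in caplog.text
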