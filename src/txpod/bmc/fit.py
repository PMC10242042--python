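"""Fitting, model selection, BMC inversion, and profile bounds.

All fits maximize a normal constant-variance likelihood, which for the
mean parameters reduces to least squares; sigma-hat is the residual SD.
AIC counts the mean parameters plus one for sigma. The goodness-of-fit
p-value is the likelihood-ratio deviance against the saturated
group-means model on ``#groups - #mean-parameters`` degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from ..config import BmcConfig
from ..errors import DesignError, ModelingError
from .models import (
    FAMILY_ORDER,
    Exp2,
    Exp3,
    Exp4,
    Exp5,
    Family,
    Linear,
    Poly2,
    Power,
    from_unconstrained,
    loglik_from_rss,
    to_unconstrained,
)

logger = logging.getLogger(__name__)

MIN_GROUPS = 6


@dataclass
class ModelFit:
    """One converged (or attempted) fit of a single family to one probe."""

    family: str
    model: Family
    params: np.ndarray
    sigma: float
    loglik: float
    aic: float
    fit_p: float
    converged: bool
    n_mean_params: int
    c: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    def predict(self, c: np.ndarray) -> np.ndarray:
        return self.model.predict(self.params, c)

    @property
    def control_mean(self) -> float:
        return self.model.control_mean(self.params)


@dataclass
class BMCRecord:
    probe_id: str
    chemical_id: str
    fit: ModelFit | None
    bmc: float | None = None
    bmcl: float | None = None
    bmcu: float | None = None
    gene_id: str | None = None
    flags: list[str] = field(default_factory=list)
    dropped_reason: str | None = None

    @property
    def retained(self) -> bool:
        return self.dropped_reason is None


def _saturated_loglik(c: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    groups, inverse = np.unique(c, return_inverse=True)
    means = np.bincount(inverse, weights=y) / np.bincount(inverse)
    rss = float(((y - means[inverse]) ** 2).sum())
    return loglik_from_rss(rss, y.size), groups.size


def _make_fit(
    model: Family, params: np.ndarray, c: np.ndarray, y: np.ndarray,
    converged: bool, ll_sat: float, n_groups: int,
) -> ModelFit:
    resid = y - model.predict(params, c)
    rss = float((resid**2).sum())
    n = y.size
    ll = loglik_from_rss(rss, n)
    k = model.n_mean_params + 1  # + sigma
    dev = max(0.0, 2.0 * (ll_sat - ll))
    df = n_groups - model.n_mean_params
    fit_p = float(chi2.sf(dev, df)) if df >= 1 else 1.0
    return ModelFit(
        family=model.name, model=model, params=np.asarray(params, dtype=float),
        sigma=float(np.sqrt(rss / n)), loglik=ll, aic=2.0 * k - 2.0 * ll,
        fit_p=fit_p, converged=converged, n_mean_params=model.n_mean_params,
        c=c, y=y,
    )


def _fit_nm(model: Family, c: np.ndarray, y: np.ndarray, config: BmcConfig):
    """Multi-start Nelder-Mead on the unconstrained parameterization."""

    def objective(u):
        params = from_unconstrained(model.kinds, u)
        with np.errstate(over="ignore", invalid="ignore"):
            resid = y - model.predict(params, c)
            val = float((resid**2).sum())
        return val if np.isfinite(val) else 1e12

    best_u, best_val, converged = None, np.inf, False
    for start in model.starts(c, y)[: config.n_starts]:
        u0 = to_unconstrained(model.kinds, start)
        res = optimize.minimize(
            objective, u0, method="Nelder-Mead",
            options={"maxiter": config.max_iterations, "xatol": 1e-7, "fatol": 1e-10},
        )
        if res.fun < best_val:
            best_u, best_val = res.x, res.fun
            converged = bool(res.success)
        elif res.success and abs(res.fun - best_val) < 1e-9:
            converged = True
    if best_u is None:
        return None, False
    # one polish restart from the incumbent: a fresh simplex often escapes
    # the shrunken one Nelder-Mead terminates with
    res = optimize.minimize(
        objective, best_u, method="Nelder-Mead",
        options={"maxiter": config.max_iterations, "xatol": 1e-7, "fatol": 1e-10},
    )
    if res.fun < best_val:
        best_u, best_val = res.x, res.fun
        converged = converged or bool(res.success)
    return from_unconstrained(model.kinds, best_u), converged


def _fit_power(c: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Profile the power exponent on [1, 18]; (g, b) are exact for fixed exponent."""

    def rss_for(d: float) -> tuple[float, np.ndarray]:
        X = np.column_stack([np.ones_like(c), c**d])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float((resid**2).sum()), beta

    res = optimize.minimize_scalar(lambda d: rss_for(d)[0], bounds=(1.0, 18.0),
                                   method="bounded")
    d = float(res.x)
    rss_d, beta = rss_for(d)
    # the boundary d=1 is a legal solution (the exponent is restricted >= 1)
    rss_1, beta_1 = rss_for(1.0)
    if rss_1 <= rss_d:
        d, beta = 1.0, beta_1
    return np.array([beta[0], beta[1], d]), True


def fit_family(
    c: np.ndarray, y: np.ndarray, config: BmcConfig | None = None
) -> list[ModelFit]:
    """Fit all seven families to one probe's per-sample responses."""
    config = config or BmcConfig()
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.unique(c)
    if groups.size < MIN_GROUPS:
        raise DesignError(
            f"need >= {MIN_GROUPS} concentration groups incl. control, got {groups.size}"
        )
    ll_sat, n_groups = _saturated_loglik(c, y)
    up = y[c == c.max()].mean() >= y[c == 0].mean()

    fits: list[ModelFit] = []
    lin = Linear()
    fits.append(_make_fit(lin, lin.fit_exact(c, y), c, y, True, ll_sat, n_groups))
    poly = Poly2()
    fits.append(_make_fit(poly, poly.fit_exact(c, y), c, y, True, ll_sat, n_groups))
    pw_params, pw_ok = _fit_power(c, y)
    fits.append(_make_fit(Power(), pw_params, c, y, pw_ok, ll_sat, n_groups))
    for model in (Exp2(), Exp3(sign=1.0 if up else -1.0),
                  Exp4(increasing=up), Exp5(increasing=up)):
        params, ok = _fit_nm(model, c, y, config)
        if params is None:
            continue
        fits.append(_make_fit(model, params, c, y, ok, ll_sat, n_groups))
    return fits


def select_model(fits: list[ModelFit], alpha_nested: float = 0.05) -> ModelFit:
    """Nested linear-vs-poly2 chi-square, then lowest AIC among the rest.

    Non-converged fits are never selected. AIC ties go to the model with
    fewer parameters, then to family list order.
    """
    by_name = {f.family: f for f in fits if f.converged}
    if not by_name:
        raise ModelingError("no converged fit to select from")

    candidates: list[ModelFit] = []
    lin, poly = by_name.get("linear"), by_name.get("poly2")
    if lin is not None and poly is not None:
        dev = max(0.0, 2.0 * (poly.loglik - lin.loglik))
        keep_poly = chi2.sf(dev, 1) < alpha_nested
        candidates.append(poly if keep_poly else lin)
    elif lin is not None or poly is not None:
        candidates.append(lin or poly)
    for name in ("power", "exp2", "exp3", "exp4", "exp5"):
        if name in by_name:
            candidates.append(by_name[name])

    def sort_key(f: ModelFit):
        return (round(f.aic, 10), f.n_mean_params, FAMILY_ORDER.index(f.family))

    return min(candidates, key=sort_key)


def bmc_from_fit(
    fit: ModelFit,
    bmr_k: float = 1.0,
    c_top: float | None = None,
    lowest_nonzero: float | None = None,
    sd: float | None = None,
) -> tuple[float | None, list[str]]:
    """Smallest c in (0, c_top] where |mu(c) - mu(0)| equals ``bmr_k * sd``.

    Located by sign-bracketing on a log grid followed by Brent root
    refinement (relative tolerance 1e-6). Returns ``(None, [reason])``
    when the response never reaches the benchmark within the tested
    range; sets an ``extrapolated-below-lowest-dose`` flag when the BMC
    falls below the lowest nonzero tested concentration.
    """
    sd = fit.sigma if sd is None else sd
    if sd <= 0:
        raise ModelingError("sigma-hat is zero; BMR undefined")
    if c_top is None:
        c_top = float(fit.c.max())
    bmr = bmr_k * sd
    mu0 = fit.control_mean

    def f(c):
        return np.abs(fit.predict(np.asarray(c, dtype=float)) - mu0) - bmr

    grid = np.logspace(np.log10(c_top) - 8.0, np.log10(c_top), 400)
    vals = f(grid)
    crossing = np.nonzero(vals >= 0)[0]
    if crossing.size == 0:
        return None, ["no BMC <= top"]
    i = crossing[0]
    lo = grid[i - 1] if i > 0 else c_top * 1e-12
    hi = grid[i]
    if f(lo) >= 0:
        bmc = float(lo)
    else:
        bmc = float(optimize.brentq(lambda x: float(f(x)), lo, hi,
                                    rtol=1e-9, xtol=1e-300))
    flags = []
    if lowest_nonzero is not None and bmc < lowest_nonzero:
        flags.append("extrapolated-below-lowest-dose")
    return bmc, flags


def profile_bounds(
    fit: ModelFit,
    bmc: float,
    conf: float = 0.95,
    bmr_k: float = 1.0,
    c_top: float | None = None,
) -> tuple[float, float, list[str]]:
    """Profile-likelihood BMC bounds at ``chi2_1(2*conf - 1)`` per side.

    The BMC is made an explicit parameter by solving one model parameter
    from the benchmark identity ``mu(bmc) - mu(0) = sign * bmr_k * sigma``
    and re-optimizing the remaining parameters (including sigma) at each
    candidate BMC. Bounds where the search leaves
    ``[c_top * 1e-6, c_top * 1e3]`` are clamped to the limit and flagged.
    """
    if c_top is None:
        c_top = float(fit.c.max())
    target = float(chi2.ppf(2.0 * conf - 1.0, 1))
    model, c, y = fit.model, fit.c, fit.y
    n = y.size
    delta_hat = fit.predict(np.array([bmc]))[0] - fit.control_mean
    sign = 1.0 if delta_hat >= 0 else -1.0

    free_kinds = model.free_kinds() + ["log"]  # trailing log-sigma
    u_hat = np.append(
        to_unconstrained(model.free_kinds(), model.free_values(fit.params)),
        np.log(max(fit.sigma, 1e-12)),
    )

    def negll_at(b: float, u: np.ndarray) -> float:
        sigma = np.exp(np.clip(u[-1], -700, 700))
        free_nat = from_unconstrained(model.free_kinds(), u[:-1])
        params = model.assemble(free_nat, b, sign * bmr_k * sigma)
        if params is None:
            return 1e8 + float((u**2).sum())
        resid = y - model.predict(params, c)
        val = 0.5 * n * np.log(2.0 * np.pi * sigma**2) + float((resid**2).sum()) / (
            2.0 * sigma**2
        )
        return val if np.isfinite(val) else 1e8

    warm = {"u": u_hat.copy()}

    def deviance(b: float) -> float:
        res = optimize.minimize(
            lambda u: negll_at(b, u), warm["u"], method="Nelder-Mead",
            options={"maxiter": 250, "xatol": 1e-6, "fatol": 1e-8},
        )
        if np.isfinite(res.fun) and res.fun < 1e7:
            warm["u"] = res.x
        dev = 2.0 * (fit.loglik + res.fun)
        if not np.isfinite(dev):
            raise ModelingError("CI failure: profile deviance not finite")
        return dev

    flags: list[str] = []

    def search(direction: int) -> float:
        """Geometric bracketing then log-scale bisection on the deviance."""
        warm["u"] = u_hat.copy()
        limit = c_top * (1e3 if direction > 0 else 1e-6)
        inner = bmc  # deviance ~ 0 by construction
        outer = None
        b = bmc
        for _ in range(40):
            b = min(b * 3.0, limit) if direction > 0 else max(b / 3.0, limit)
            if deviance(b) >= target:
                outer = b
                break
            inner = b
            if b == limit:
                flags.append(
                    "upper-bound-at-search-limit" if direction > 0
                    else "lower-bound-at-search-limit"
                )
                return limit
        if outer is None:
            raise ModelingError("CI failure: bound search did not terminate")
        for _ in range(60):
            if max(inner, outer) / min(inner, outer) < 1.005:
                break
            mid = float(np.sqrt(inner * outer))
            if deviance(mid) >= target:
                outer = mid
            else:
                inner = mid
        return float(np.sqrt(inner * outer))

    bmcl = search(-1)
    bmcu = search(+1)
    bmcl = min(bmcl, bmc)
    bmcu = max(bmcu, bmc)
    return bmcl, bmcu, flags


def postfilter_records(
    records: list[BMCRecord],
    c_top: float,
    fit_p_min: float = 0.1,
    bmcu_bmcl_max: float = 40.0,
) -> list[BMCRecord]:
    """Apply the post-modeling filters; dropped records carry their reason."""
    retained = []
    for rec in records:
        if rec.dropped_reason is not None:
            continue
        if rec.fit is not None and rec.fit.fit_p < fit_p_min:
            rec.dropped_reason = f"fit p < {fit_p_min}"
        elif rec.bmcl is not None and rec.bmcu is not None and (
            rec.bmcu / rec.bmcl > bmcu_bmcl_max
        ):
            rec.dropped_reason = f"BMCU/BMCL > {bmcu_bmcl_max}"
        elif rec.bmc is not None and rec.bmc > c_top:
            rec.dropped_reason = "BMC > top concentration"
        else:
            retained.append(rec)
    return retained


def collapse_to_genes(
    records: list[BMCRecord], probe_map: pd.DataFrame | dict
) -> pd.DataFrame:
    """Gene-level BMC list: per gene, the probe with the lowest BMC wins."""
    if isinstance(probe_map, pd.DataFrame):
        mapping = dict(zip(probe_map["probe_id"], probe_map["gene_id"]))
    else:
        mapping = dict(probe_map)
    rows = []
    for rec in records:
        if not rec.retained or rec.bmc is None:
            continue
        gene = mapping.get(rec.probe_id)
        if gene is None:
            logger.warning("probe %s has no gene mapping; excluded", rec.probe_id)
            continue
        rec.gene_id = gene
        rows.append(
            {
                "gene_id": gene,
                "probe_id": rec.probe_id,
                "family": rec.fit.family if rec.fit else "",
                "bmc": rec.bmc,
                "bmcl": rec.bmcl,
                "bmcu": rec.bmcu,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["gene_id", "probe_id", "family", "bmc", "bmcl", "bmcu"])
    df = pd.DataFrame(rows)
    idx = df.groupby("gene_id")["bmc"].idxmin()
    return df.loc[idx].sort_values("bmc").reset_index(drop=True)


def derive_bmc_records(
    matrix,
    passing: set[str],
    chemical_id: str,
    config: BmcConfig | None = None,
    skip_bounds: bool = False,
) -> list[BMCRecord]:
    """Fit, select, invert, and bound every passing probe of one experiment.

    Returns one record per probe (retained or dropped-with-reason); apply
    :func:`postfilter_records` afterwards to get the retained set.
    """
    config = config or BmcConfig()
    conc = matrix.sample_concentrations
    c_top = float(conc.max())
    lowest_nonzero = float(conc[conc > 0].min())
    records: list[BMCRecord] = []
    for probe_id in sorted(passing):
        y = matrix.values.loc[probe_id].to_numpy(dtype=float)
        rec = BMCRecord(probe_id=probe_id, chemical_id=chemical_id, fit=None)
        records.append(rec)
        try:
            fits = fit_family(conc, y, config)
            best = select_model(fits, alpha_nested=config.alpha_nested)
            rec.fit = best
            sd = best.sigma
            if config.bmr_sd_source == "control":
                sd = float(np.std(y[conc == 0], ddof=1))
            bmc, flags = bmc_from_fit(
                best, bmr_k=config.bmr_k, c_top=c_top,
                lowest_nonzero=lowest_nonzero, sd=sd,
            )
            rec.flags.extend(flags)
            if bmc is None:
                rec.dropped_reason = flags[0] if flags else "no BMC <= top"
                continue
            rec.bmc = bmc
            if best.fit_p < config.fit_p_min or bmc > c_top:
                # record will be dropped by the post-filter before the
                # BMCU/BMCL ratio is ever examined; bounds are not needed
                continue
            if skip_bounds:
                rec.bmcl, rec.bmcu = bmc, bmc
            else:
                bmcl, bmcu, bflags = profile_bounds(
                    best, bmc, conf=config.confidence, bmr_k=config.bmr_k,
                    c_top=c_top,
                )
                rec.bmcl, rec.bmcu = bmcl, bmcu
                rec.flags.extend(bflags)
        except ModelingError as exc:
            rec.dropped_reason = str(exc)
    return records
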