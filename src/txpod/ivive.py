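"""Reverse dosimetry: tPOD (uM) to administered equivalent dose (mg/kg/day).

A three-compartment steady-state model reduced to its closed form: oral
dosing at rate D (mg/kg-bw/day) with gut absorption fraction fabs, a
well-stirred liver (hepatic blood flow Qh, scaled intrinsic clearance),
and renal filtration of unbound chemical (GFR * fub) give

    Css (mg/L) = D * fabs / (GFR * fub + CLh)
    CLh        = Qh * fub * CLint / (Qh + fub * CLint)

where CLint is intrinsic clearance scaled from uL/min/1e6 hepatocytes to
L/day/kg body weight. Blood:plasma partitioning is assumed 1. Population
variability is represented by independent lognormal multipliers (median
1) on fub, CLint, GFR, and Qh; the reported Css is the empirical 95th
quantile over draws, and AED = tPOD / Css at unit dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .config import PhysiologyConfig
from .errors import ModelingError

MINUTES_PER_DAY = 1440.0


@dataclass
class TKResult:
    chemical_id: str
    css_unit: float
    css_q95: float
    n_draws: int
    seed: int


@dataclass
class AEDRecord:
    chemical_id: str
    method: str
    tpod_uM: float
    aed: float
    track: str  # "bmc-distribution" or "gene-set"
    cell_model: str = ""
    exposure_days: float = 0.0


def _scaled_clint(clint: float, physiology: PhysiologyConfig) -> float:
    """uL/min/1e6 hepatocytes -> L/day/kg body weight."""
    return (
        clint
        * physiology.hepatocellularity
        * physiology.liver_mass_per_kg
        * MINUTES_PER_DAY
        * 1e-6
    )


def _css_mg_per_l(
    fub: np.ndarray, clint_scaled: np.ndarray, gfr: np.ndarray,
    qh: np.ndarray, fabs: float,
) -> np.ndarray:
    clh = qh * fub * clint_scaled / (qh + fub * clint_scaled)
    total_clearance = gfr * fub + clh
    with np.errstate(divide="ignore"):
        return fabs / total_clearance


def css_unit_dose(tk_row: Mapping[str, float], physiology: PhysiologyConfig | None = None) -> float:
    """Deterministic steady-state plasma concentration (uM) at 1 mg/kg-bw/day."""
    physiology = physiology or PhysiologyConfig()
    fub = float(tk_row["fub"])
    if fub <= 0:
        raise ModelingError("fraction unbound must be > 0 (total clearance is zero)")
    clint_scaled = _scaled_clint(float(tk_row["clint"]), physiology)
    fabs = float(tk_row.get("fabs", 1.0))
    css = _css_mg_per_l(
        np.asarray(fub), np.asarray(clint_scaled),
        np.asarray(physiology.gfr), np.asarray(physiology.hepatic_blood_flow), fabs,
    )
    if not np.isfinite(css) or css <= 0:
        raise ModelingError("steady-state concentration undefined (zero clearance)")
    return float(css) / float(tk_row["mw"]) * 1e3


def css_quantile_mc(
    tk_row: Mapping[str, float],
    physiology: PhysiologyConfig | None = None,
    n_draws: int = 1000,
    cv: float = 0.3,
    seed: int = 0,
    quantile: float = 0.95,
) -> TKResult:
    """Monte Carlo population quantile of the unit-dose Css.

    Each draw multiplies fub (truncated at 1), CLint, GFR, and Qh by
    independent lognormal factors with median 1 and the given CV.
    """
    physiology = physiology or PhysiologyConfig()
    if n_draws < 100:
        raise ModelingError("quantile requires >= 100 draws")
    css_point = css_unit_dose(tk_row, physiology)
    if cv == 0:
        return TKResult(
            chemical_id=str(tk_row.get("casrn", "")), css_unit=css_point,
            css_q95=css_point, n_draws=n_draws, seed=seed,
        )
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    factors = rng.lognormal(mean=0.0, sigma=sigma, size=(4, n_draws))
    fub = np.minimum(float(tk_row["fub"]) * factors[0], 1.0)
    clint_scaled = _scaled_clint(float(tk_row["clint"]), physiology) * factors[1]
    gfr = physiology.gfr * factors[2]
    qh = physiology.hepatic_blood_flow * factors[3]
    css = _css_mg_per_l(fub, clint_scaled, gfr, qh, float(tk_row.get("fabs", 1.0)))
    ok = np.isfinite(css) & (css > 0)
    if ok.sum() < 0.5 * n_draws:
        raise ModelingError("steady-state concentration undefined in most draws")
    css_uM = css[ok] / float(tk_row["mw"]) * 1e3
    return TKResult(
        chemical_id=str(tk_row.get("casrn", "")), css_unit=css_point,
        css_q95=float(np.quantile(css_uM, quantile)), n_draws=int(n_draws),
        seed=int(seed),
    )


def aed_from_tpod(tpod_uM: float, css_uM: float) -> float:
    """Administered equivalent dose: tPOD divided by the unit-dose Css."""
    if tpod_uM <= 0 or css_uM <= 0:
        raise ModelingError("tPOD and Css must be > 0")
    return tpod_uM / css_uM
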