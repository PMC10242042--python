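"""Synthetic concentration-response count data with known ground truth.

Counts are negative-binomial around a baseline mean that is shifted, for
responsive probes, by a Hill curve on the log2 scale:

    mean(c) = mu_p * 2 ** (sign * E * c**h / (AC50**h + c**h))

which gives a closed-form ground-truth benchmark concentration for any
target log2 shift. A matching toxicokinetic table and apical-POD table can
be constructed with a designed log10 margin so that end-to-end outlier
flags are known in advance.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import ivive
from .config import MonteCarloConfig, PhysiologyConfig
from .errors import ConfigError, ModelingError
from .io import ApicalPODTable, Experiment, GeneSetCollection, TKTable

DEFAULT_CONCENTRATIONS = tuple(np.logspace(np.log10(0.0005), np.log10(100.0), 10))


@dataclass
class SimConfig:
    """Knobs for one simulated experiment."""

    n_probes: int = 3000
    fraction_responsive: float = 0.1
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    n_replicates: int = 3
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.02
    library_size_cv: float = 0.05
    ac50_log10_range: tuple[float, float] = (-2.0, 1.0)
    e_range: tuple[float, float] = (1.5, 3.0)
    hill_range: tuple[float, float] = (1.0, 3.0)
    p_up: float = 0.5
    probes_per_gene: int = 1

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ConfigError("n_probes must be >= 1")
        if not 0 <= self.fraction_responsive <= 1:
            raise ConfigError("fraction_responsive must be in [0, 1]")
        if 0 < self.fraction_responsive and self.fraction_responsive * self.n_probes < 1:
            raise ConfigError(
                "fraction_responsive * n_probes < 1: no responsive probe can be drawn"
            )
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if min(self.e_range) <= 0:
            raise ConfigError("max log2 effect E must be > 0 for responsive probes")
        for pair in (self.ac50_log10_range, self.e_range, self.hill_range):
            if not all(np.isfinite(pair)):
                raise ConfigError("distribution parameters must be finite")


@dataclass
class TruthTable:
    """Ground truth for one simulated experiment.

    ``probes`` has one row per probe: responsive flag, sign, ac50, e_max,
    hill, the per-probe benchmark shift delta_log2, and true_bmc (NaN for
    null probes). ``chemical`` holds experiment-level truth such as the
    designed tPOD (lowest true BMC among responsive probes).
    """

    probes: pd.DataFrame
    chemical: dict = field(default_factory=dict)


def hill_shift(c: np.ndarray, e_max: float, hill: float, ac50: float) -> np.ndarray:
    """Log2-scale shift at concentration(s) ``c``."""
    c = np.asarray(c, dtype=float)
    return e_max * c**hill / (ac50**hill + c**hill)


def true_bmc(probe_truth: Mapping[str, float], delta_log2: float) -> float:
    """Concentration at which the true log2 shift equals ``delta_log2``.

    Closed form ``ac50 * (delta / (E - delta)) ** (1 / h)``; raises when the
    curve never reaches the target shift.
    """
    e_max = float(probe_truth["e_max"])
    hill = float(probe_truth["hill"])
    ac50 = float(probe_truth["ac50"])
    if not probe_truth.get("responsive", True):
        raise ModelingError("true_bmc is defined only for responsive probes")
    if not 0 < delta_log2 < e_max:
        raise ModelingError(
            f"delta_log2={delta_log2} does not cross the Hill curve (E={e_max})"
        )
    return ac50 * (delta_log2 / (e_max - delta_log2)) ** (1.0 / hill)


def _rng_for(seed: int, chemical_id: str) -> np.random.Generator:
    # One stream per (global seed, chemical id): reproducible under parallelism.
    return np.random.default_rng([seed, zlib.crc32(chemical_id.encode())])


def _expected_log2cpm_sd(mean_counts: np.ndarray, dispersion: float) -> np.ndarray:
    """Delta-method SD of log2(CPM + 1) for NB counts at the expected library size."""
    library = mean_counts.sum()
    f = 1e6 / library
    var_count = mean_counts + dispersion * mean_counts**2
    deriv = f / ((f * mean_counts + 1.0) * np.log(2.0))
    return deriv * np.sqrt(var_count)


def simulate_experiment(
    config: SimConfig,
    seed: int,
    chemical_id: str = "100000-00-0",
    cell_model: str = "SIM",
    exposure_days: float = 1.0,
    ac50_center_log10: float | None = None,
    ac50_spread_log10: float | None = None,
) -> tuple[Experiment, pd.DataFrame, TruthTable]:
    """Generate one experiment plus its probe->gene map and truth table.

    ``ac50_center_log10``/``ac50_spread_log10`` optionally cluster the AC50s
    of responsive probes around a per-chemical potency (normal on log10)
    instead of drawing them uniformly over ``ac50_log10_range``.
    """
    config.validate()
    rng = _rng_for(seed, chemical_id)
    n = config.n_probes
    conc = np.asarray(config.concentrations, dtype=float)

    # Per-probe truth
    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    n_resp = int(round(config.fraction_responsive * n))
    responsive = np.zeros(n, dtype=bool)
    responsive[rng.choice(n, size=n_resp, replace=False)] = True
    sign = np.where(rng.random(n) < config.p_up, 1.0, -1.0)
    if ac50_center_log10 is None:
        log_ac50 = rng.uniform(*config.ac50_log10_range, size=n)
    else:
        spread = 0.3 if ac50_spread_log10 is None else ac50_spread_log10
        log_ac50 = rng.normal(ac50_center_log10, spread, size=n)
    ac50 = 10.0**log_ac50
    e_max = rng.uniform(*config.e_range, size=n)
    hill = rng.uniform(*config.hill_range, size=n)

    # Mean matrix: groups x probes, then replicate columns
    all_conc = np.concatenate([[0.0], conc])
    shift = np.zeros((n, all_conc.size))
    if n_resp:
        idx = np.where(responsive)[0]
        cmat = np.broadcast_to(all_conc, (idx.size, all_conc.size))
        num = cmat ** hill[idx, None]
        shift[idx, :] = sign[idx, None] * e_max[idx, None] * num / (
            ac50[idx, None] ** hill[idx, None] + num
        )
    group_mean = baseline[:, None] * 2.0**shift

    sample_ids, sample_conc, sample_rep = [], [], []
    for j, c in enumerate(all_conc):
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"c{j:02d}_r{r}")
            sample_conc.append(c)
            sample_rep.append(r)
    lib_factor = (
        rng.lognormal(mean=0.0, sigma=np.sqrt(np.log(1 + config.library_size_cv**2)),
                      size=len(sample_ids))
        if config.library_size_cv > 0
        else np.ones(len(sample_ids))
    )
    group_of_sample = np.arange(len(sample_ids)) // config.n_replicates
    mean_matrix = group_mean[:, group_of_sample] * lib_factor[None, :]

    if config.dispersion > 0:
        size = 1.0 / config.dispersion
        p = size / (size + mean_matrix)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mean_matrix)

    probe_ids = [f"P{i:05d}" for i in range(n)]
    counts_df = pd.DataFrame(counts, index=pd.Index(probe_ids, name="probe_id"),
                             columns=sample_ids)
    design = pd.DataFrame(
        {"concentration_uM": sample_conc, "replicate": sample_rep},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    experiment = Experiment(
        chemical_id=chemical_id,
        cell_model=cell_model,
        exposure_days=exposure_days,
        counts=counts_df,
        design=design,
    ).validate()

    gene_ids = [f"G{i // config.probes_per_gene:05d}" for i in range(n)]
    probe_map = pd.DataFrame({"probe_id": probe_ids, "gene_id": gene_ids})

    delta = _expected_log2cpm_sd(baseline, config.dispersion)
    tbmc = np.full(n, np.nan)
    sub_range = np.zeros(n, dtype=bool)
    for i in np.where(responsive)[0]:
        if delta[i] < e_max[i]:
            tbmc[i] = ac50[i] * (delta[i] / (e_max[i] - delta[i])) ** (1.0 / hill[i])
            sub_range[i] = tbmc[i] < conc.min()
    probes = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_id": gene_ids,
            "responsive": responsive,
            "sign": np.where(responsive, sign, 0.0),
            "ac50": np.where(responsive, ac50, np.nan),
            "e_max": np.where(responsive, e_max, np.nan),
            "hill": np.where(responsive, hill, np.nan),
            "delta_log2": delta,
            "true_bmc": tbmc,
            "below_range": sub_range,
        }
    )
    designed = float(np.nanmin(tbmc)) if np.isfinite(tbmc).any() else float("nan")
    truth = TruthTable(
        probes=probes,
        chemical={
            "chemical_id": chemical_id,
            "designed_tpod_uM": designed,
            "n_responsive": int(n_resp),
            "seed": int(seed),
        },
    )
    return experiment, probe_map, truth


def simulate_gene_sets(
    probe_map: pd.DataFrame,
    truth: TruthTable,
    seed: int,
    n_sets: int = 25,
    set_size: int = 20,
    n_enriched: int = 5,
    database_label: str = "SIMDB",
) -> GeneSetCollection:
    """Gene sets over the simulated genes; the first ``n_enriched`` sets are
    drawn preferentially from responsive genes."""
    rng = np.random.default_rng([seed, 7])
    genes = probe_map["gene_id"].unique()
    resp_genes = truth.probes.loc[truth.probes["responsive"], "gene_id"].unique()
    null_genes = np.setdiff1d(genes, resp_genes)
    collection = GeneSetCollection(database_label=database_label)
    for k in range(n_sets):
        if k < n_enriched and resp_genes.size:
            n_hit = min(int(0.8 * set_size), resp_genes.size)
            members = list(rng.choice(resp_genes, n_hit, replace=False))
            members += list(rng.choice(null_genes, set_size - n_hit, replace=False))
        else:
            members = list(rng.choice(genes, min(set_size, genes.size), replace=False))
        set_id = f"{database_label}:{k:04d}"
        collection.sets[set_id] = (f"simulated set {k}", list(dict.fromkeys(members)))
        collection.sizes[set_id] = len(collection.sets[set_id][1])
    return collection


def simulate_reference(
    chemicals: Mapping[str, float],
    seed: int,
    margin_log10: float | Mapping[str, float] = 1.0,
    physiology: PhysiologyConfig | None = None,
    mc: MonteCarloConfig | None = None,
) -> tuple[TKTable, ApicalPODTable]:
    """Construct TK parameters and apical PODs for designed-tPOD chemicals.

    The apical POD is ``designed_AED * 10**m`` where ``designed_AED`` is the
    dose whose 95th-quantile steady-state plasma concentration equals the
    designed tPOD, so the expected sign of the final log10 ratio is the sign
    of ``m``.
    """
    physiology = physiology or PhysiologyConfig()
    mc = mc or MonteCarloConfig()
    rng = np.random.default_rng([seed, 11])
    tk_rows, pod_rows = [], []
    for casrn, designed_tpod in chemicals.items():
        row = {
            "casrn": casrn,
            "mw": float(rng.uniform(100.0, 500.0)),
            "fub": float(10.0 ** rng.uniform(-2.0, 0.0)),
            "clint": float(10.0 ** rng.uniform(0.0, 2.3)),
            "fabs": 1.0,
        }
        tk_rows.append(row)
        tkres = ivive.css_quantile_mc(row, physiology, n_draws=mc.n_draws,
                                      cv=mc.cv, seed=seed, quantile=mc.quantile)
        designed_aed = ivive.aed_from_tpod(designed_tpod, tkres.css_q95)
        m = margin_log10[casrn] if isinstance(margin_log10, Mapping) else margin_log10
        pod_rows.append(
            {
                "source": "simulated",
                "name": casrn,
                "casrn": casrn,
                "animal": "synthetic",
                "study_type": "repeat dose",
                "method": "NOAEL",
                "effect_level": designed_aed * 10.0**m,
            }
        )
    return (
        TKTable(table=pd.DataFrame(tk_rows)),
        ApicalPODTable(table=pd.DataFrame(pod_rows)),
    )


def write_manifest(config: SimConfig, seed: int, path: str | Path) -> None:
    payload = {"seed": seed, "config": asdict(config)}
    payload["config"]["concentrations"] = list(config.concentrations)
    Path(path).write_text(json.dumps(payload, indent=2))
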