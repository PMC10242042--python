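"""End-to-end orchestration for one experiment and for cohorts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import bmc as bmc_mod
from . import compare as compare_mod
from . import ivive, prefilter, tpod
from .config import PipelineConfig
from .io import ApicalPODTable, Experiment, GeneSetCollection, TKTable

logger = logging.getLogger(__name__)


@dataclass
class ExperimentResult:
    experiment: Experiment
    trend: pd.DataFrame
    records: list = field(default_factory=list)
    gene_bmcs: pd.DataFrame = None
    tpods: list = field(default_factory=list)
    spread: float | None = None

    def tpod_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.tpods:
            rows.append(
                {
                    "chemical_id": self.experiment.chemical_id,
                    "cell_model": self.experiment.cell_model,
                    "exposure_days": self.experiment.exposure_days,
                    "method": r.method,
                    "tpod_uM": r.value,
                    "n_genes": r.n_genes,
                    "active": r.active,
                    "geneset_db": r.geneset_db,
                    "geneset_id": r.geneset_id,
                }
            )
        return pd.DataFrame(rows)


def run_experiment(
    experiment: Experiment,
    probe_map: pd.DataFrame,
    collections: list[GeneSetCollection] = (),
    config: PipelineConfig | None = None,
    seed: int = 0,
    skip_bounds: bool = False,
) -> ExperimentResult:
    """Normalize, prefilter, model BMCs, collapse to genes, derive tPODs."""
    config = config or PipelineConfig()
    matrix = prefilter.normalize_log2cpm(experiment)
    passing, trend = prefilter.prefilter_probes(
        matrix,
        p_threshold=config.prefilter.p_threshold,
        fc_threshold=config.prefilter.fc_threshold,
        n_permutations=config.prefilter.n_permutations,
        seed=seed,
        two_sided=config.prefilter.two_sided,
    )
    logger.info("%s: %d/%d probes pass prefilter", experiment.chemical_id,
                len(passing), matrix.values.shape[0])
    records = bmc_mod.derive_bmc_records(
        matrix, passing, experiment.chemical_id, config.bmc, skip_bounds=skip_bounds
    )
    retained = bmc_mod.postfilter_records(
        records,
        c_top=float(matrix.sample_concentrations.max()),
        fit_p_min=config.bmc.fit_p_min,
        bmcu_bmcl_max=config.bmc.bmcu_bmcl_max,
    )
    gene_bmcs = bmc_mod.collapse_to_genes(retained, probe_map)
    bmc_by_gene = dict(zip(gene_bmcs["gene_id"], gene_bmcs["bmc"]))
    tpods, spread = tpod.derive_all(bmc_by_gene, collections, config.tpod)
    return ExperimentResult(
        experiment=experiment, trend=trend, records=records,
        gene_bmcs=gene_bmcs, tpods=tpods, spread=spread,
    )


def aed_records_for(
    result: ExperimentResult,
    tk: TKTable,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> list[ivive.AEDRecord]:
    """Convert every defined tPOD of one experiment to an AED."""
    config = config or PipelineConfig()
    casrn = result.experiment.chemical_id
    try:
        tk_row = tk.row_for(casrn)
    except KeyError:
        logger.info("%s not modelable (no TK parameters)", casrn)
        return []
    tkres = ivive.css_quantile_mc(
        tk_row, config.physiology, n_draws=config.mc.n_draws,
        cv=config.mc.cv, seed=seed, quantile=config.mc.quantile,
    )
    out = []
    for r in result.tpods:
        if not r.active or r.value is None:
            continue
        track = "gene-set" if r.method == "geneset" else "bmc-distribution"
        out.append(
            ivive.AEDRecord(
                chemical_id=casrn, method=r.method, tpod_uM=r.value,
                aed=ivive.aed_from_tpod(r.value, tkres.css_q95), track=track,
                cell_model=result.experiment.cell_model,
                exposure_days=result.experiment.exposure_days,
            )
        )
    return out


def compare_cohort(
    aed_records: list[ivive.AEDRecord],
    apical: ApicalPODTable,
    tpod_table: pd.DataFrame | None = None,
):
    """Comparison records, coverage, and concordance for a cohort."""
    records, coverage = compare_mod.compare_tracks(aed_records, apical)
    summary = None
    if tpod_table is not None and not tpod_table.empty:
        summary = compare_mod.concordance_summary(tpod_table, aed_records)
    return records, coverage, summary
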