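"""Lowest-AED selection, apical-POD comparison, and concordance summaries.

The headline statistic is the log10 ratio of the traditional (animal)
POD to the NAM-based AED: positive means the in vitro estimate is
conservative; negative flags the chemical as an outlier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import ModelingError
from .io import ApicalPODTable
from .ivive import AEDRecord

logger = logging.getLogger(__name__)

TRACKS = ("bmc-distribution", "gene-set")
_TRACK_METHODS = {
    "bmc-distribution": ("p5", "mode1", "rank25", "lcrd"),
    "gene-set": ("geneset",),
}


@dataclass
class ComparisonRecord:
    chemical_id: str
    track: str
    aed_nam: float
    pod_traditional: float
    study_type: str
    pod_method: str
    log10_ratio: float
    outlier: bool
    aed_method: str = ""


def select_apical_pod(apical: ApicalPODTable, casrn: str) -> tuple[float, str, str]:
    """Minimum effect level across all rows for the chemical.

    Ties keep the first row in input order; returns (effect_level,
    study_type, method).
    """
    rows = apical.rows_for(casrn)
    if rows.empty:
        raise KeyError(f"no apical POD rows for {casrn}")
    levels = rows["effect_level"].to_numpy()
    if (levels == levels.min()).sum() > 1:
        logger.info("apical POD tie for %s; first row kept", casrn)
    best = rows.iloc[int(np.argmin(levels))]
    return float(best["effect_level"]), str(best["study_type"]), str(best["method"])


def select_lowest_aed(
    aed_records: list[AEDRecord], track: str
) -> dict[str, AEDRecord]:
    """Per-chemical minimum AED within a track, with provenance.

    The bmc-distribution track pools the four distribution methods across
    all of a chemical's experiments; the gene-set track pools gene-set
    AEDs. Chemicals with no defined AED in a track are simply absent.
    """
    if track not in _TRACK_METHODS:
        raise ValueError(f"unknown track {track!r}")
    methods = _TRACK_METHODS[track]
    lowest: dict[str, AEDRecord] = {}
    for rec in aed_records:
        if rec.method not in methods:
            continue
        cur = lowest.get(rec.chemical_id)
        if cur is None or rec.aed < cur.aed:
            lowest[rec.chemical_id] = rec
    return lowest


def log10_ratio(
    pod: float,
    aed: float,
    chemical_id: str = "",
    track: str = "",
    study_type: str = "",
    pod_method: str = "",
    aed_method: str = "",
) -> ComparisonRecord:
    """log10(traditional POD) - log10(NAM AED); outlier iff the ratio < 0."""
    if pod <= 0 or aed <= 0:
        raise ModelingError("POD and AED must be > 0")
    ratio = math.log10(pod) - math.log10(aed)
    return ComparisonRecord(
        chemical_id=chemical_id, track=track, aed_nam=aed, pod_traditional=pod,
        study_type=study_type, pod_method=pod_method, log10_ratio=ratio,
        outlier=ratio < 0, aed_method=aed_method,
    )


def compare_tracks(
    aed_records: list[AEDRecord], apical: ApicalPODTable
) -> tuple[list[ComparisonRecord], pd.DataFrame]:
    """Per-track, per-chemical comparison records plus a coverage table.

    Chemicals lacking either an AED or an apical POD appear in the
    coverage table rather than being silently dropped.
    """
    records: list[ComparisonRecord] = []
    coverage_rows = []
    chems = set(apical.casrns) | {r.chemical_id for r in aed_records}
    lowest = {track: select_lowest_aed(aed_records, track) for track in TRACKS}
    for casrn in sorted(chems):
        has_pod = casrn in apical.casrns
        row = {"casrn": casrn, "has_apical_pod": has_pod}
        for track in TRACKS:
            rec = lowest[track].get(casrn)
            row[f"has_aed_{track}"] = rec is not None
            if rec is not None and has_pod:
                pod, study_type, method = select_apical_pod(apical, casrn)
                records.append(
                    log10_ratio(
                        pod, rec.aed, chemical_id=casrn, track=track,
                        study_type=study_type, pod_method=method,
                        aed_method=rec.method,
                    )
                )
        coverage_rows.append(row)
    return records, pd.DataFrame(coverage_rows)


def concordance_summary(
    tpod_table: pd.DataFrame, aed_records: list[AEDRecord]
) -> dict:
    """Spread, per-dataset medians, cross-track correlation, and agreement bands.

    ``tpod_table`` is tidy with columns ``chemical_id``, ``method``,
    ``tpod_uM`` and optionally ``dataset``. Correlation of log10 lowest
    AEDs between the two tracks is reported over chemicals present in
    both (undefined below 3 shared chemicals).
    """
    out: dict = {}
    defined = tpod_table.dropna(subset=["tpod_uM"])
    spreads = {}
    for chem, grp in defined.groupby("chemical_id"):
        vals = grp["tpod_uM"].to_numpy(dtype=float)
        if vals.size >= 2:
            spreads[chem] = float(np.log10(vals.max()) - np.log10(vals.min()))
    out["per_chemical_spread"] = spreads
    if "dataset" in defined.columns:
        per_dataset = {}
        for ds, grp in defined.groupby("dataset"):
            ds_spreads = [spreads[c] for c in grp["chemical_id"].unique() if c in spreads]
            per_dataset[ds] = {
                "median_log10_tpod": float(np.median(np.log10(grp["tpod_uM"]))),
                "median_spread": float(np.median(ds_spreads)) if ds_spreads else None,
            }
        out["per_dataset"] = per_dataset

    lowest_a = select_lowest_aed(aed_records, "bmc-distribution")
    lowest_b = select_lowest_aed(aed_records, "gene-set")
    shared = sorted(set(lowest_a) & set(lowest_b))
    out["n_shared_chemicals"] = len(shared)
    if len(shared) >= 3:
        x = np.log10([lowest_a[c].aed for c in shared])
        y = np.log10([lowest_b[c].aed for c in shared])
        if np.std(x) > 0 and np.std(y) > 0:
            r, p = pearsonr(x, y)
            out["pearson_r"] = float(r)
            out["pearson_p"] = float(p)
        else:
            out["pearson_r"] = None
            out["pearson_p"] = None
        diff = np.abs(x - y)
        out["within_1_log10"] = int((diff <= 1.0).sum())
        out["within_2_log10"] = int((diff <= 2.0).sum())
    else:
        out["pearson_r"] = None
        out["pearson_p"] = None
    return out


def comparisons_to_frame(records: list[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chemical_id": r.chemical_id,
                "track": r.track,
                "aed_nam": r.aed_nam,
                "pod_traditional": r.pod_traditional,
                "study_type": r.study_type,
                "pod_method": r.pod_method,
                "aed_method": r.aed_method,
                "log10_ratio": r.log10_ratio,
                "outlier": r.outlier,
            }
            for r in records
        ]
    )
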