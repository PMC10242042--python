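"""Readers and validators for all tabular inputs.

File dialects
-------------
Counts: TSV/CSV, first column probe id, remaining columns sample ids.
Design: CSV/TSV with columns ``sample_id``, ``concentration_uM``, ``replicate``.
Gene sets: GMT (one set per line: id, description, member genes, tab-separated).
Inventory: CSV with columns ``dataset``, ``name``, ``abbrev``, ``casrn``,
``model``, ``exposure_days`` (semicolon-separated list), ``cell_states``
(optional, semicolon-separated list of cell states to expand into).
Apical PODs: CSV with ``source``, ``name``, ``casrn``, ``animal``,
``study_type``, ``method``, ``effect_level`` (mg/kg-bw/day).
TK parameters: CSV with ``casrn``, ``mw`` (g/mol), ``fub``, ``clint``
(uL/min/1e6 hepatocytes), ``fabs`` (optional, defaults to 1).

Delimiters are auto-detected between tab and comma; headers are mandatory.
Concentrations are in uM throughout and 0 encodes the solvent control.
CASRN is the join key across all tables; names are display-only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import DataError, DesignError, FormatError, SchemaError

logger = logging.getLogger(__name__)

MIN_NONZERO_CONCENTRATIONS = 5

_CASRN_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Experiment:
    """A single concentration-response experiment (one chemical, one model).

    ``counts`` is a probe x sample non-negative integer matrix whose columns
    match ``design`` rows exactly; ``design`` is indexed by sample id and
    sorted by ascending concentration (0 = solvent control) then replicate.
    """

    chemical_id: str
    cell_model: str
    exposure_days: float
    counts: pd.DataFrame
    design: pd.DataFrame

    @property
    def concentrations(self) -> np.ndarray:
        """Distinct tested concentrations, ascending, control (0) first."""
        return np.sort(self.design["concentration_uM"].unique())

    @property
    def sample_concentrations(self) -> np.ndarray:
        """Per-sample concentrations in count-column order."""
        return self.design.loc[self.counts.columns, "concentration_uM"].to_numpy()

    def validate(self) -> "Experiment":
        if list(self.counts.columns) != list(self.design.index):
            raise SchemaError(
                f"{self.chemical_id}: count columns do not match design rows"
            )
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError(f"{self.chemical_id}: counts are not numeric")
        bad = np.argwhere((values < 0) | (values != np.floor(values)))
        if bad.size:
            i, j = bad[0]
            raise DataError(
                f"{self.chemical_id}: invalid count at probe "
                f"{self.counts.index[i]!r}, sample {self.counts.columns[j]!r}: "
                f"{values[i, j]!r} (counts must be non-negative integers)"
            )
        conc = self.design["concentration_uM"].to_numpy()
        if (conc < 0).any():
            raise DesignError(f"{self.chemical_id}: negative concentration in design")
        nonzero = np.unique(conc[conc > 0])
        if 0 not in conc:
            raise DesignError(f"{self.chemical_id}: no solvent-control (0 uM) samples")
        if len(nonzero) < MIN_NONZERO_CONCENTRATIONS:
            raise DesignError(
                f"{self.chemical_id}: only {len(nonzero)} nonzero concentrations; "
                f"at least {MIN_NONZERO_CONCENTRATIONS} are required"
            )
        return self


@dataclass
class GeneSetCollection:
    """Named gene sets from one database (e.g. a GO / Reactome / KEGG role)."""

    database_label: str
    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]


@dataclass
class ApicalPODTable:
    """Animal-study points of departure, possibly several rows per CASRN."""

    table: pd.DataFrame

    def rows_for(self, casrn: str) -> pd.DataFrame:
        return self.table[self.table["casrn"] == casrn]

    @property
    def casrns(self) -> set[str]:
        return set(self.table["casrn"])


@dataclass
class TKTable:
    """Toxicokinetic parameters keyed by CASRN."""

    table: pd.DataFrame

    def row_for(self, casrn: str) -> pd.Series:
        hit = self.table[self.table["casrn"] == casrn]
        if hit.empty:
            raise KeyError(casrn)
        return hit.iloc[0]

    @property
    def casrns(self) -> set[str]:
        return set(self.table["casrn"])


class ReferenceTables(NamedTuple):
    inventory: pd.DataFrame
    apical: ApicalPODTable
    tk: TKTable

    @property
    def unmodelable(self) -> set[str]:
        """CASRNs with an apical POD but no TK parameters."""
        return self.apical.casrns - self.tk.casrns


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a delimited table, auto-detecting tab vs comma from the header."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    try:
        return pd.read_csv(path, sep=sep, **kwargs)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as delimited table: {exc}") from exc


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str | Path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def read_counts_and_design(
    counts_path: str | Path,
    design_path: str | Path,
    inventory_row: Mapping[str, object],
) -> Experiment:
    """Load one experiment's count matrix and design and validate both.

    ``inventory_row`` supplies ``casrn``, ``model`` and ``exposure_days``
    (a single number here, not a list).
    """
    design = _read_table(design_path)
    _require_columns(design, ["sample_id", "concentration_uM", "replicate"], design_path)
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"{design_path}: duplicated sample id {dup!r}")
    design = design.set_index("sample_id")

    counts = _read_table(counts_path, index_col=0)
    count_samples = set(counts.columns)
    design_samples = set(design.index)
    if count_samples != design_samples:
        extra = sorted(count_samples - design_samples)
        absent = sorted(design_samples - count_samples)
        raise SchemaError(
            f"sample id mismatch between {counts_path} and {design_path}: "
            f"count-only={extra[:5]}, design-only={absent[:5]}"
        )

    design = design.sort_values(["concentration_uM", "replicate"])
    counts = counts[design.index]

    exp = Experiment(
        chemical_id=str(inventory_row["casrn"]),
        cell_model=str(inventory_row.get("model", "")),
        exposure_days=float(inventory_row.get("exposure_days", 0) or 0),
        counts=counts,
        design=design,
    )
    return exp.validate()


def write_counts_and_design(
    experiment: Experiment, counts_path: str | Path, design_path: str | Path
) -> None:
    """Write an experiment back to the same dialects the readers accept."""
    experiment.counts.to_csv(counts_path, sep="\t", index_label="probe_id")
    experiment.design.to_csv(design_path, index_label="sample_id")


def read_gene_sets(gmt_path: str | Path, database_label: str) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated id, description, members.

    Duplicate member ids are collapsed (first occurrence kept); set size is
    the deduplicated member count.
    """
    collection = GeneSetCollection(database_label=database_label)
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            set_id, description, *members = fields
            deduped = list(dict.fromkeys(m for m in members if m))
            if not deduped:
                raise FormatError(f"{gmt_path}:{lineno}: gene set {set_id!r} is empty")
            collection.sets[set_id] = (description, deduped)
            collection.sizes[set_id] = len(deduped)
    return collection


def write_gene_sets(collection: GeneSetCollection, gmt_path: str | Path) -> None:
    with open(gmt_path, "w") as fh:
        for set_id, (description, members) in collection.sets.items():
            fh.write("\t".join([set_id, description, *members]) + "\n")


def read_inventory(path: str | Path) -> pd.DataFrame:
    """Read the chemical inventory (one row per dataset x chemical)."""
    inv = _read_table(path, dtype=str).fillna("")
    _require_columns(inv, ["dataset", "name", "casrn", "model", "exposure_days"], path)
    if "cell_states" not in inv.columns:
        inv["cell_states"] = ""
    for _, row in inv.iterrows():
        if not _CASRN_RE.match(row["casrn"]):
            logger.warning("inventory: malformed CASRN %r (row kept)", row["casrn"])
    return inv


def expand_experiments(inventory: pd.DataFrame) -> pd.DataFrame:
    """Expand inventory rows into one row per experiment.

    Each row contributes one experiment per listed exposure duration, times
    one per listed cell state (rows without ``cell_states`` count as one
    state).
    """
    records = []
    for _, row in inventory.iterrows():
        days = [d.strip() for d in str(row["exposure_days"]).split(";") if d.strip()]
        states = [s.strip() for s in str(row.get("cell_states", "")).split(";") if s.strip()]
        if not states:
            states = [""]
        for day in days:
            for state in states:
                records.append(
                    {
                        "dataset": row["dataset"],
                        "name": row["name"],
                        "casrn": row["casrn"],
                        "model": row["model"],
                        "cell_state": state,
                        "exposure_days": float(day),
                    }
                )
    return pd.DataFrame.from_records(records)


def read_apical_pods(path: str | Path) -> ApicalPODTable:
    pods = _read_table(path)
    _require_columns(pods, ["casrn", "study_type", "method", "effect_level"], path)
    pods["casrn"] = pods["casrn"].astype(str)
    if pods["casrn"].str.strip().eq("").any():
        raise DataError(f"{path}: empty CASRN in apical-POD table")
    pods["effect_level"] = pd.to_numeric(pods["effect_level"])
    if (pods["effect_level"] <= 0).any():
        bad = pods.loc[pods["effect_level"] <= 0].iloc[0]
        raise DataError(
            f"{path}: non-positive effect level {bad['effect_level']} for {bad['casrn']}"
        )
    for casrn in pods["casrn"]:
        if not _CASRN_RE.match(casrn):
            logger.warning("apical PODs: malformed CASRN %r (row kept)", casrn)
    return ApicalPODTable(table=pods.reset_index(drop=True))


def read_tk_table(path: str | Path) -> TKTable:
    tk = _read_table(path)
    _require_columns(tk, ["casrn", "mw", "fub", "clint"], path)
    tk["casrn"] = tk["casrn"].astype(str)
    if "fabs" not in tk.columns:
        tk["fabs"] = 1.0
    tk["fabs"] = pd.to_numeric(tk["fabs"]).fillna(1.0)
    for col in ("mw", "fub", "clint"):
        tk[col] = pd.to_numeric(tk[col])
    if (tk["mw"] <= 0).any():
        raise DataError(f"{path}: molecular weight must be > 0")
    if ((tk["fub"] <= 0) | (tk["fub"] > 1)).any():
        raise DataError(f"{path}: fraction unbound must be in (0, 1]")
    if (tk["clint"] < 0).any():
        raise DataError(f"{path}: intrinsic clearance must be >= 0")
    if ((tk["fabs"] <= 0) | (tk["fabs"] > 1)).any():
        raise DataError(f"{path}: fraction absorbed must be in (0, 1]")
    return TKTable(table=tk.reset_index(drop=True))


def read_reference_tables(
    inventory_path: str | Path, pod_path: str | Path, tk_path: str | Path
) -> ReferenceTables:
    """Load the inventory, apical-POD, and TK tables together.

    Chemicals present in the apical table but absent from the TK table are
    reported via :attr:`ReferenceTables.unmodelable` rather than dropped.
    """
    tables = ReferenceTables(
        inventory=read_inventory(inventory_path),
        apical=read_apical_pods(pod_path),
        tk=read_tk_table(tk_path),
    )
    if tables.unmodelable:
        logger.info(
            "%d chemicals have an apical POD but no TK parameters (not modelable)",
            len(tables.unmodelable),
        )
    return tables
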