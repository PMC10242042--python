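"""Bundled reference tables (chemical inventory and apical PODs)."""

from importlib.resources import files
from pathlib import Path

import pandas as pd

from . import io


def inventory_path() -> Path:
    return Path(str(files("txpod").joinpath("data/inventory.tsv")))


def apical_pods_path() -> Path:
    return Path(str(files("txpod").joinpath("data/apical_pods.tsv")))


def load_inventory() -> pd.DataFrame:
    return io.read_inventory(inventory_path())


def load_apical_pods() -> io.ApicalPODTable:
    return io.read_apical_pods(apical_pods_path())
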