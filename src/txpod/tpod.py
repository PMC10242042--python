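"""The five tPOD derivation methods over a gene-level BMC list.

Methods: fifth-percentile gene (floor-index rule), first mode of the
log10-BMC density, 25th-ranked gene, modified LCRD (lowest dose of the
largest consistent-response group), and lowest qualifying gene-set
median. Each returns a :class:`TPODResult`; methods whose minimum data
requirement fails return an inactive result instead of raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .config import TpodConfig
from .io import GeneSetCollection

METHODS = ("p5", "mode1", "rank25", "lcrd", "geneset")


@dataclass
class TPODResult:
    method: str
    value: float | None
    n_genes: int
    active: bool
    flags: list[str] = field(default_factory=list)
    geneset_db: str | None = None
    geneset_id: str | None = None
    geneset_n_members: int | None = None

    @classmethod
    def inactive(cls, method: str, n_genes: int = 0) -> "TPODResult":
        return cls(method=method, value=None, n_genes=n_genes, active=False)


def _sorted(bmcs: Iterable[float]) -> np.ndarray:
    arr = np.sort(np.asarray(list(bmcs), dtype=float))
    if arr.size and (arr <= 0).any():
        raise ValueError("BMC values must be > 0")
    return arr


def tpod_fifth_percentile(
    bmcs: Iterable[float], percentile: float = 0.05, interpolated: bool = False
) -> TPODResult:
    """Rank ``max(1, floor(percentile * n))`` of the ascending BMC list.

    With ``interpolated=True`` the conventional linear-interpolation
    percentile is used instead of the floor-index rule.
    """
    arr = _sorted(bmcs)
    if arr.size == 0:
        return TPODResult.inactive("p5")
    if interpolated:
        value = float(np.percentile(arr, percentile * 100.0))
    else:
        rank = max(1, math.floor(percentile * arr.size))
        value = float(arr[rank - 1])
    return TPODResult(method="p5", value=value, n_genes=int(arr.size), active=True)


def tpod_first_mode(
    bmcs: Iterable[float], grid_points: int = 512, min_genes: int = 5
) -> TPODResult:
    """First local maximum of a Gaussian KDE on log10(BMC).

    Silverman bandwidth; the grid spans the data range +/- one bandwidth.
    First and second derivatives are taken by centered differences
    (one-sided at the boundaries); the mode is the first grid point where
    the first derivative crosses from positive to negative with a
    negative second derivative. A monotone density yields the boundary
    maximum, flagged.
    """
    arr = _sorted(bmcs)
    if arr.size < min_genes:
        return TPODResult.inactive("mode1", n_genes=int(arr.size))
    x = np.log10(arr)
    spread = x.std(ddof=1) if arr.size > 1 else 0.0
    if spread == 0:
        return TPODResult(method="mode1", value=float(arr[0]), n_genes=int(arr.size),
                          active=True, flags=["degenerate-distribution"])
    kde = gaussian_kde(x, bw_method="silverman")
    bw = float(kde.factor * spread)
    grid = np.linspace(x.min() - bw, x.max() + bw, grid_points)
    f = kde(grid)
    d1 = np.gradient(f, grid)
    d2 = np.gradient(d1, grid)
    crossings = np.nonzero((d1[:-1] > 0) & (d1[1:] <= 0) & (d2[:-1] < 0))[0]
    if crossings.size:
        i = crossings[0]
        j = i if f[i] >= f[i + 1] else i + 1
        return TPODResult(method="mode1", value=float(10.0 ** grid[j]),
                          n_genes=int(arr.size), active=True)
    j = int(np.argmax(f))
    return TPODResult(method="mode1", value=float(10.0 ** grid[j]),
                      n_genes=int(arr.size), active=True, flags=["monotone-density"])


def tpod_nth_ranked(bmcs: Iterable[float], n_rank: int = 25) -> TPODResult:
    """The ``n_rank``-th lowest BMC; inactive below that many genes."""
    arr = _sorted(bmcs)
    if arr.size < n_rank:
        return TPODResult.inactive("rank25", n_genes=int(arr.size))
    return TPODResult(method="rank25", value=float(arr[n_rank - 1]),
                      n_genes=int(arr.size), active=True)


def crgb_groups(sorted_bmcs: Sequence[float], ratio: float = 1.66) -> list[list[float]]:
    """Partition ascending BMCs into maximal runs of adjacent ratios <= ratio."""
    groups: list[list[float]] = []
    for value in sorted_bmcs:
        if groups and value / groups[-1][-1] <= ratio * (1.0 + 1e-12):
            groups[-1].append(value)
        else:
            groups.append([value])
    return groups


def tpod_lcrd(bmcs: Iterable[float], ratio: float = 1.66) -> TPODResult:
    """Modified LCRD: lowest BMC of the largest consistent-response group.

    Size ties go to the group with the smaller minimum BMC (groups are in
    ascending order, so the first largest group wins).
    """
    arr = _sorted(bmcs)
    if arr.size < 2:
        return TPODResult.inactive("lcrd", n_genes=int(arr.size))
    groups = crgb_groups(arr.tolist(), ratio=ratio)
    best = max(groups, key=len)  # first of the largest => smallest minimum
    return TPODResult(method="lcrd", value=float(best[0]), n_genes=int(arr.size),
                      active=True)


def tpod_lowest_gene_set(
    gene_bmcs: dict[str, float],
    collections: Sequence[GeneSetCollection],
    min_genes: int = 3,
    min_frac: float = 0.05,
) -> TPODResult:
    """Minimum per-set median BMC over all qualifying sets of all collections.

    A set qualifies when it has at least ``min_genes`` member genes with a
    BMC and those members cover at least ``min_frac`` of the annotated set
    size.
    """
    best: TPODResult | None = None
    for collection in collections:
        for set_id, (_desc, members) in collection.sets.items():
            hits = [gene_bmcs[g] for g in members if g in gene_bmcs]
            size = collection.sizes[set_id]
            if len(hits) < min_genes or len(hits) / size < min_frac:
                continue
            median = float(np.median(hits))
            if best is None or median < best.value:
                best = TPODResult(
                    method="geneset", value=median, n_genes=len(hits), active=True,
                    geneset_db=collection.database_label, geneset_id=set_id,
                    geneset_n_members=size,
                )
    if best is None:
        return TPODResult.inactive("geneset")
    return best


def derive_all(
    gene_bmcs: dict[str, float],
    collections: Sequence[GeneSetCollection] = (),
    config: TpodConfig | None = None,
) -> tuple[list[TPODResult], float | None]:
    """Run all five methods; also report the log10 min-max spread.

    The spread is ``log10(max defined tPOD) - log10(min defined tPOD)``,
    or None when fewer than two methods produced a value.
    """
    config = config or TpodConfig()
    values = list(gene_bmcs.values())
    results = [
        tpod_fifth_percentile(values, percentile=config.percentile,
                              interpolated=config.percentile_interpolated),
        tpod_first_mode(values, grid_points=config.mode_grid_points,
                        min_genes=config.mode_min_genes),
        tpod_nth_ranked(values, n_rank=config.n_rank),
        tpod_lcrd(values, ratio=config.lcrd_ratio),
        tpod_lowest_gene_set(gene_bmcs, collections,
                             min_genes=config.geneset_min_genes,
                             min_frac=config.geneset_min_frac),
    ]
    defined = [r.value for r in results if r.active and r.value is not None]
    spread = (
        float(np.log10(max(defined)) - np.log10(min(defined)))
        if len(defined) >= 2 else None
    )
    return results, spread
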