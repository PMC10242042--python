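"""Normalization and concentration-response prefiltering.

Counts are normalized to log2 counts-per-million; probes are then gated on
a monotone-trend test against the solvent control (permutation p-value)
and on a minimum fold change at some tested concentration.

The trend statistic follows the classical amalgamation construction: dose
group means are isotonized (pool-adjacent-violators, weights = group
sizes) and the amalgamated mean of the top concentration is compared to
the raw control mean, standardized by the pooled within-group variance.
Both directions are tested; the reported p-value is the Bonferroni-doubled
minimum of the two one-directional permutation p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DesignError
from .io import Experiment

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Log2-CPM matrix plus the design it was computed from."""

    values: pd.DataFrame
    size_factors: pd.Series
    design: pd.DataFrame

    @property
    def sample_concentrations(self) -> np.ndarray:
        return self.design.loc[self.values.columns, "concentration_uM"].to_numpy()


def normalize_log2cpm(experiment: Experiment) -> ExpressionMatrix:
    """Median-of-ratios size factors, then log2(CPM + 1).

    The size factor for each sample is the median ratio of its counts to
    the per-probe geometric mean, over probes with all-positive counts.
    The reported value is ``log2(norm / sum(norm) * 1e6 + 1)`` where
    ``norm = count / size_factor``.
    """
    counts = experiment.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        sample = experiment.counts.columns[np.argmax(totals == 0)]
        raise DataError(f"sample {sample!r} has zero total count")

    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        log_geo = np.log(counts[all_positive]).mean(axis=1)
        ratios = np.log(counts[all_positive]) - log_geo[:, None]
        size_factors = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning("no probe has all-positive counts; size factors set to 1")
        size_factors = np.ones(counts.shape[1])

    norm = counts / size_factors
    cpm = norm / norm.sum(axis=0) * 1e6
    values = pd.DataFrame(
        np.log2(cpm + 1.0), index=experiment.counts.index, columns=experiment.counts.columns
    )
    return ExpressionMatrix(
        values=values,
        size_factors=pd.Series(size_factors, index=experiment.counts.columns),
        design=experiment.design,
    )


def pava(values: np.ndarray, weights: np.ndarray, increasing: bool = True) -> np.ndarray:
    """Weighted pool-adjacent-violators isotonic fit of a 1-D sequence."""
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not increasing:
        return -pava(-y, w, increasing=True)
    # blocks as (mean, weight, length)
    means, wts, lens = [], [], []
    for yi, wi in zip(y, w):
        means.append(yi)
        wts.append(wi)
        lens.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, l2 = means.pop(), wts.pop(), lens.pop()
            m1, w1, l1 = means.pop(), wts.pop(), lens.pop()
            means.append((m1 * w1 + m2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
            lens.append(l1 + l2)
    out = np.concatenate([np.full(l, m) for m, l in zip(means, lens)])
    return out


def _group_layout(sample_conc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted distinct concentrations, per-sample group index, group sizes."""
    groups = np.unique(sample_conc)
    if groups[0] != 0:
        raise DesignError("no solvent-control (0 uM) group present")
    gidx = np.searchsorted(groups, sample_conc)
    sizes = np.bincount(gidx, minlength=groups.size).astype(float)
    return groups, gidx, sizes


def _trend_stats(
    y: np.ndarray, gidx: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Both-direction amalgamated trend statistics for a (P, N) matrix.

    Returns (t_up, t_down, group_means). The amalgamated mean of the top
    dose group under a non-decreasing constraint over the dose groups
    equals the maximum over u of the weighted mean of groups u..K, which
    is what is computed here (and is identical to the PAVA fit at K).
    """
    n_samples = y.shape[1]
    n_groups = sizes.size
    ind = np.zeros((n_samples, n_groups))
    ind[np.arange(n_samples), gidx] = 1.0
    sums = y @ ind
    means = sums / sizes
    sumsq = (y**2) @ ind
    ss_within = (sumsq - sizes * means**2).sum(axis=1)
    dof = n_samples - n_groups
    s2 = ss_within / dof if dof > 0 else np.full(y.shape[0], np.nan)

    # weighted suffix averages over dose groups 1..K
    dose_means = means[:, 1:]
    dose_sizes = sizes[1:]
    wsum = np.cumsum((dose_means * dose_sizes)[:, ::-1], axis=1)[:, ::-1]
    wn = np.cumsum(dose_sizes[::-1])[::-1]
    suffix_avg = wsum / wn
    top_inc = suffix_avg.max(axis=1)
    top_dec = suffix_avg.min(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(s2, 0.0) * (1.0 / sizes[-1] + 1.0 / sizes[0]))
        t_up = (top_inc - means[:, 0]) / se
        t_down = (means[:, 0] - top_dec) / se
    return t_up, t_down, means


def williams_trend_test(
    values: np.ndarray | pd.DataFrame,
    sample_conc: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Permutation trend test for every row of ``values``.

    Returns a DataFrame with columns ``t_stat``, ``direction``, ``p``.
    Sample-to-group labels are permuted ``n_permutations`` times (the same
    permutations are shared across rows); one-directional p-values are
    ``(1 + #{t* >= t}) / (B + 1)`` and, when ``two_sided``, the reported p
    is ``min(1, 2 * min(p_up, p_down))``.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if isinstance(values, pd.DataFrame):
        index = values.index
        y = values.to_numpy(dtype=float)
    else:
        y = np.atleast_2d(np.asarray(values, dtype=float))
        index = pd.RangeIndex(y.shape[0])
    sample_conc = np.asarray(sample_conc, dtype=float)
    groups, gidx, sizes = _group_layout(sample_conc)
    if groups.size < 2:
        raise DesignError("need at least one nonzero concentration group")

    t_up, t_down, means = _trend_stats(y, gidx, sizes)
    rng = np.random.default_rng(seed)
    count_up = np.ones(y.shape[0])  # the +1 of the permutation p-value
    count_down = np.ones(y.shape[0])
    n = y.shape[1]
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        tu, td, _ = _trend_stats(y[:, perm], gidx, sizes)
        count_up += _ge(tu, t_up)
        count_down += _ge(td, t_down)
    b1 = n_permutations + 1
    p_up = count_up / b1
    p_down = count_down / b1
    if two_sided:
        p = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))
    else:
        p = np.minimum(p_up, p_down)
    direction = np.where(t_up >= t_down, "up", "down")
    t_stat = np.maximum(t_up, t_down)

    # degenerate probes: zero pooled variance
    flat = ~np.isfinite(t_stat)
    if flat.any():
        mean_range = means.max(axis=1) - means.min(axis=1)
        constant = flat & (mean_range == 0)
        separated = flat & (mean_range > 0)
        t_stat[constant] = 0.0
        p[constant] = 1.0
        if separated.any():
            logger.warning(
                "%d probes have zero pooled variance with unequal means; "
                "p set to permutation floor",
                int(separated.sum()),
            )
            t_stat[separated] = np.inf
            p[separated] = 1.0 / b1
    return pd.DataFrame({"t_stat": t_stat, "direction": direction, "p": p}, index=index)


def _ge(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a >= b treating non-finite permutation stats conservatively."""
    with np.errstate(invalid="ignore"):
        out = (a >= b).astype(float)
    out[~np.isfinite(b)] = 0.0
    return out


def williams_trend_p(
    probe_values: np.ndarray,
    design: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
    two_sided: bool = True,
) -> dict:
    """Single-probe convenience wrapper around :func:`williams_trend_test`."""
    res = williams_trend_test(
        np.asarray(probe_values, dtype=float)[None, :],
        design["concentration_uM"].to_numpy(),
        n_permutations=n_permutations,
        seed=seed,
        two_sided=two_sided,
    )
    row = res.iloc[0]
    return {"t_stat": float(row["t_stat"]), "direction": row["direction"], "p": float(row["p"])}


def max_fold_change(values: pd.DataFrame, sample_conc: np.ndarray) -> pd.Series:
    """Max over nonzero concentrations of 2**|group mean - control mean|."""
    groups, gidx, sizes = _group_layout(np.asarray(sample_conc, dtype=float))
    y = values.to_numpy(dtype=float)
    ind = np.zeros((y.shape[1], groups.size))
    ind[np.arange(y.shape[1]), gidx] = 1.0
    means = (y @ ind) / sizes
    max_abs = np.abs(means[:, 1:] - means[:, [0]]).max(axis=1)
    return pd.Series(2.0**max_abs, index=values.index, name="max_fc")


def prefilter_probes(
    matrix: ExpressionMatrix,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    n_permutations: int = 999,
    seed: int = 0,
    two_sided: bool = True,
) -> tuple[set[str], pd.DataFrame]:
    """Trend + fold-change gate; both thresholds must be met (FC inclusive).

    Returns the set of passing probe ids and the full per-probe table
    (``t_stat``, ``direction``, ``p``, ``max_fc``, ``passed``). An empty
    pass-set is a legal outcome (the chemical may simply be inactive).
    """
    sample_conc = matrix.sample_concentrations
    trend = williams_trend_test(
        matrix.values, sample_conc, n_permutations=n_permutations,
        seed=seed, two_sided=two_sided,
    )
    trend["max_fc"] = max_fold_change(matrix.values, sample_conc)
    trend["passed"] = (trend["p"] < p_threshold) & (trend["max_fc"] >= fc_threshold)
    passing = set(trend.index[trend["passed"]])
    return passing, trend
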