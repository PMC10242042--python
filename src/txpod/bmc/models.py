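"""Continuous dose-response model family.

Seven families under a normal constant-variance error model:

==========  =====================================  ===========================
family      mean function                          constraints
==========  =====================================  ===========================
linear      b0 + b1*c
poly2       b0 + b1*c + b2*c**2
power       g + b*c**delta                         delta in [1, 18]
exp2        a*exp(beta*c)                          a > 0 (beta sign = direction)
exp3        a*exp(s*(b*c)**d)                      a > 0, b > 0, d in [1, 18]
exp4        a*(k - (k-1)*exp(-b*c))                a > 0, b > 0; k > 1 up,
exp5        a*(k - (k-1)*exp(-(b*c)**d))           0 < k < 1 down; d in [1, 18]
==========  =====================================  ===========================

Each family knows how to predict, propose deterministic moment-based
starting values, map its parameters to and from an unconstrained space
for the optimizer, and re-assemble a full parameter vector when one
parameter is tied to a candidate BMC during profiling.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import logit

_DELTA_HI = 18.0


def loglik_from_rss(rss: float, n: int) -> float:
    """Maximized normal log-likelihood given the residual sum of squares."""
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def _to_unconstrained(kind: str, x: float) -> float:
    if kind == "id":
        return x
    if kind == "log":
        return np.log(max(x, 1e-12))
    if kind == "unit18":  # [1, 18]
        frac = np.clip((x - 1.0) / (_DELTA_HI - 1.0), 1e-9, 1 - 1e-9)
        return logit(frac)
    if kind == "kgt1":  # k > 1
        return np.log(max(x - 1.0, 1e-9))
    if kind == "klt1":  # 0 < k < 1
        return logit(np.clip(x, 1e-9, 1 - 1e-9))
    raise ValueError(kind)


def _from_unconstrained(kind: str, u: float) -> float:
    # scalar math on purpose: this sits in the optimizer's hot loop
    u = min(max(float(u), -700.0), 700.0)
    if kind == "id":
        return u
    if kind == "log":
        return math.exp(u)
    if kind == "unit18":
        return 1.0 + (_DELTA_HI - 1.0) / (1.0 + math.exp(-u))
    if kind == "kgt1":
        return 1.0 + math.exp(u)
    if kind == "klt1":
        return 1.0 / (1.0 + math.exp(-u))
    raise ValueError(kind)


def to_unconstrained(kinds: list[str], params: np.ndarray) -> np.ndarray:
    return np.array([_to_unconstrained(k, x) for k, x in zip(kinds, params)])


def from_unconstrained(kinds: list[str], u: np.ndarray) -> np.ndarray:
    return np.array([_from_unconstrained(k, x) for k, x in zip(kinds, u)])


def _direction(c: np.ndarray, y: np.ndarray) -> float:
    """Sign of the response at the top concentration relative to control."""
    top = y[c == c.max()].mean()
    ctrl = y[c == c.min()].mean()
    return 1.0 if top >= ctrl else -1.0


def _start_scales(c: np.ndarray) -> list[float]:
    nz = np.unique(c[c > 0])
    picks = [nz[len(nz) // 4], nz[len(nz) // 2], nz[(3 * len(nz)) // 4]]
    return [1.0 / p for p in picks]


def _half_shift_conc(c: np.ndarray, y: np.ndarray) -> float:
    """Concentration where the group-mean response crosses half its total shift.

    Log-interpolated between the bracketing tested concentrations; used to
    seed the rate parameter of the saturating families.
    """
    groups = np.unique(c)
    means = np.array([y[c == g].mean() for g in groups])
    shift = means - means[0]
    total = shift[-1]
    if total == 0:
        return float(np.sqrt(groups[1] * groups[-1]))
    frac = shift / total
    above = np.nonzero(frac >= 0.5)[0]
    above = above[above > 0]
    if above.size == 0:
        return float(groups[-1])
    j = above[0]
    lo = groups[j - 1] if groups[j - 1] > 0 else groups[1] / 10.0
    f_lo = frac[j - 1] if j - 1 > 0 else 0.0
    t = (0.5 - f_lo) / max(frac[j] - f_lo, 1e-9)
    return float(np.exp(np.log(lo) + t * (np.log(groups[j]) - np.log(lo))))


class Family:
    """Base class; subclasses define the mean function and its plumbing."""

    name: str = ""
    param_names: list[str] = []
    kinds: list[str] = []
    closed_form: bool = False

    @property
    def n_mean_params(self) -> int:
        return len(self.param_names)

    def predict(self, params: np.ndarray, c: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def control_mean(self, params: np.ndarray) -> float:
        return float(self.predict(params, np.array([0.0]))[0])

    def starts(self, c: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    # -- profiling: tie one parameter so predict(bmc) - predict(0) == delta --
    free_mask: list[bool] = []

    def assemble(self, free: np.ndarray, bmc: float, delta: float) -> np.ndarray | None:
        """Full parameter vector with the tied parameter solved from (bmc, delta),
        or None when no feasible value exists."""
        raise NotImplementedError

    def free_kinds(self) -> list[str]:
        return [k for k, f in zip(self.kinds, self.free_mask) if f]

    def free_values(self, params: np.ndarray) -> np.ndarray:
        return params[np.asarray(self.free_mask)]


class Linear(Family):
    name = "linear"
    param_names = ["b0", "b1"]
    kinds = ["id", "id"]
    closed_form = True
    free_mask = [True, False]

    def predict(self, params, c):
        b0, b1 = params
        return b0 + b1 * np.asarray(c, dtype=float)

    def fit_exact(self, c, y):
        X = np.column_stack([np.ones_like(c), c])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta

    def assemble(self, free, bmc, delta):
        return np.array([free[0], delta / bmc])


class Poly2(Family):
    name = "poly2"
    param_names = ["b0", "b1", "b2"]
    kinds = ["id", "id", "id"]
    closed_form = True
    free_mask = [True, False, True]

    def predict(self, params, c):
        b0, b1, b2 = params
        c = np.asarray(c, dtype=float)
        return b0 + b1 * c + b2 * c**2

    def fit_exact(self, c, y):
        X = np.column_stack([np.ones_like(c), c, c**2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta

    def assemble(self, free, bmc, delta):
        b0, b2 = free
        return np.array([b0, (delta - b2 * bmc**2) / bmc, b2])


class Power(Family):
    name = "power"
    param_names = ["g", "b", "delta_exp"]
    kinds = ["id", "id", "unit18"]
    free_mask = [True, False, True]

    def predict(self, params, c):
        g, b, d = params
        return g + b * np.asarray(c, dtype=float) ** d

    def starts(self, c, y):
        # exact profile over the exponent is done in fit.py; starts unused
        return []

    def assemble(self, free, bmc, delta):
        g, d = free
        return np.array([g, delta / bmc**d, d])


class Exp2(Family):
    name = "exp2"
    param_names = ["a", "beta"]
    kinds = ["log", "id"]
    free_mask = [True, False]

    def predict(self, params, c):
        a, beta = params
        return a * np.exp(np.clip(beta * np.asarray(c, dtype=float), -700, 700))

    def starts(self, c, y):
        a0 = max(y[c == 0].mean(), 1e-6)
        s = _direction(c, y)
        out = []
        for scale in _start_scales(c):
            top = y[c == c.max()].mean()
            ratio = max(top / a0, 1e-6)
            beta = np.log(ratio) / c.max()
            out.append(np.array([a0, beta if beta != 0 else s * scale * 0.01]))
            out.append(np.array([a0, s * scale * 0.1]))
        return out

    def assemble(self, free, bmc, delta):
        (a,) = free
        if a <= 0 or delta / a <= -1:
            return None
        return np.array([a, np.log1p(delta / a) / bmc])


class Exp3(Family):
    name = "exp3"
    param_names = ["a", "b", "d"]
    kinds = ["log", "log", "unit18"]
    free_mask = [True, False, True]

    def __init__(self, sign: float = 1.0):
        self.sign = sign

    def predict(self, params, c):
        a, b, d = params
        c = np.asarray(c, dtype=float)
        return a * np.exp(np.clip(self.sign * (b * c) ** d, -700, 700))

    def starts(self, c, y):
        a0 = max(y[c == 0].mean(), 1e-6)
        c_half = _half_shift_conc(c, y)
        out = [np.array([a0, math.log(2.0) ** (1.0 / d) / c_half, d])
               for d in (1.0, 2.0, 4.0)]
        for scale in _start_scales(c)[:2]:
            out.append(np.array([a0, scale, 1.0]))
        return out

    def assemble(self, free, bmc, delta):
        a, d = free
        if a <= 0 or delta / a <= -1:
            return None
        target = self.sign * np.log1p(delta / a)
        if target <= 0:
            return None
        return np.array([a, target ** (1.0 / d) / bmc, d])


class Exp4(Family):
    name = "exp4"
    param_names = ["a", "b", "k"]
    free_mask = [True, False, True]

    def __init__(self, increasing: bool = True):
        self.increasing = increasing
        self.kinds = ["log", "log", "kgt1" if increasing else "klt1"]

    def predict(self, params, c):
        a, b, k = params
        c = np.asarray(c, dtype=float)
        return a * (k - (k - 1.0) * np.exp(-np.clip(b * c, 0, 700)))

    def starts(self, c, y):
        a0 = max(y[c == 0].mean(), 1e-6)
        top = y[c == c.max()].mean()
        k0 = np.clip(top / a0, 1.001, None) if self.increasing else np.clip(top / a0, 1e-3, 0.999)
        c_half = _half_shift_conc(c, y)
        out = [np.array([a0, math.log(2.0) / c_half, k0])]
        for scale in _start_scales(c):
            out.append(np.array([a0, scale, k0]))
        out.append(np.array([a0, math.log(2.0) / c_half, 2.0 if self.increasing else 0.5]))
        return out

    def assemble(self, free, bmc, delta):
        a, k = free
        if a <= 0 or k == 1.0:
            return None
        x = 1.0 - delta / (a * (k - 1.0))
        if not 0.0 < x < 1.0:
            return None
        return np.array([a, -np.log(x) / bmc, k])


class Exp5(Family):
    name = "exp5"
    param_names = ["a", "b", "k", "d"]
    free_mask = [True, False, True, True]

    def __init__(self, increasing: bool = True):
        self.increasing = increasing
        self.kinds = ["log", "log", "kgt1" if increasing else "klt1", "unit18"]

    def predict(self, params, c):
        a, b, k, d = params
        c = np.asarray(c, dtype=float)
        return a * (k - (k - 1.0) * np.exp(-np.clip((b * c) ** d, 0, 700)))

    def starts(self, c, y):
        a0 = max(y[c == 0].mean(), 1e-6)
        top = y[c == c.max()].mean()
        k0 = np.clip(top / a0, 1.001, None) if self.increasing else np.clip(top / a0, 1e-3, 0.999)
        c_half = _half_shift_conc(c, y)
        out = [np.array([a0, math.log(2.0) ** (1.0 / d) / c_half, k0, d])
               for d in (1.0, 2.0, 4.0)]
        for scale in _start_scales(c)[:2]:
            out.append(np.array([a0, scale, k0, 1.0]))
        return out

    def assemble(self, free, bmc, delta):
        a, k, d = free
        if a <= 0 or k == 1.0:
            return None
        x = 1.0 - delta / (a * (k - 1.0))
        if not 0.0 < x < 1.0:
            return None
        return np.array([a, (-np.log(x)) ** (1.0 / d) / bmc, k, d])


FAMILY_ORDER = ["linear", "poly2", "power", "exp2", "exp3", "exp4", "exp5"]

FAMILIES = {
    "linear": Linear,
    "poly2": Poly2,
    "power": Power,
    "exp2": Exp2,
    "exp3": Exp3,
    "exp4": Exp4,
    "exp5": Exp5,
}
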