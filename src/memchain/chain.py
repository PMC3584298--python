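"""Forward model: a feedforward chain of declining memory stores.

A memory is represented by point-like traces. Store 1 (hippocampus/MTL in
two-store fits, working memory in three-store fits) starts with an expected
trace count -- the *intensity* -- of ``mu1`` immediately after learning.
Traces in store ``i`` die at constant rate ``a_i`` and, while alive, induce
traces in store ``i+1`` at rate ``mu_{i+1}`` (systems consolidation). The
expected counts follow the linear cascade

    dr_i/dt = mu_i * r_{i-1}(t) - a_i * r_i(t),
    r_1(0) = mu_1,  r_i(0) = 0 for i > 1,

whose solution with pairwise-distinct exponential decline rates is the
classical sum-of-exponentials (Bateman) form; e.g. for two stores with
``a2 = 0``:

    r_1(t) = mu1 * exp(-a1 t)
    r_2(t) = (mu1 mu2 / a1) * (1 - exp(-a1 t)).

Because trace counts are Poisson and retrieval recovers each surviving trace
independently with probability ``q`` (cue quality), recall succeeds with

    p(t) = 1 - exp(-q * (r_1(t) + ... + r_k(t))),

optionally raised onto a chance-guessing floor ``g`` for forced-choice tasks:
``p = g + (1 - g) * (1 - exp(-q r))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import integrate

if TYPE_CHECKING:  # pragma: no cover
    from .pathology import LesionProfile

__all__ = [
    "EXPONENTIAL",
    "POWER",
    "StoreParams",
    "ChainParams",
    "IntensityCurve",
    "store_intensity",
    "intensity_components",
    "total_intensity",
    "recall_probability",
    "probability_from_intensity",
    "intensity_from_probability",
    "ode_oracle",
]

EXPONENTIAL = "exponential"
POWER = "power"

# Pairs of decline rates closer than this (relative, with a small absolute
# floor) make the distinct-rate closed form cancel catastrophically; the
# cascade is then integrated numerically instead.
_TIE_REL = 1e-9
_TIE_ABS = 1e-12


@dataclass(frozen=True)
class StoreParams:
    """One store of the chain.

    mu : for store 1 the intensity acquired per learning episode; for store
        i > 1 the induction (consolidation) rate per unit donor intensity
        per time unit.
    a : decline rate of the store, 1/time-unit.
    decline_kind : "exponential" (default) or "power"; the power variant
        declines as (1 + t) ** (-a), finite at t = 0.
    """

    mu: float
    a: float
    decline_kind: str = EXPONENTIAL

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or self.mu < 0:
            raise ValueError(f"store mu must be finite and >= 0, got {self.mu}")
        if not np.isfinite(self.a) or self.a < 0:
            raise ValueError(f"store decline rate a must be finite and >= 0, got {self.a}")
        if self.decline_kind not in (EXPONENTIAL, POWER):
            raise ValueError(f"unknown decline_kind {self.decline_kind!r}")

    def decline(self, age):
        """Survival fraction of a trace of the given age."""
        age = np.asarray(age, dtype=float)
        if self.decline_kind == EXPONENTIAL:
            return np.exp(-self.a * age)
        return (1.0 + age) ** (-self.a)


@dataclass(frozen=True)
class ChainParams:
    """Full generative model: ordered stores, cue quality q, guess floor g."""

    stores: tuple[StoreParams, ...]
    q: float = 1.0
    g: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stores", tuple(self.stores))
        if len(self.stores) < 1:
            raise ValueError("chain needs at least one store")
        if not all(isinstance(s, StoreParams) for s in self.stores):
            raise TypeError("stores must be StoreParams instances")
        if not np.isfinite(self.q) or self.q <= 0:
            raise ValueError(f"cue quality q must be > 0, got {self.q}")
        if not 0 <= self.g < 1:
            raise ValueError(f"guess rate g must be in [0, 1), got {self.g}")

    @property
    def n_stores(self) -> int:
        return len(self.stores)


@dataclass(frozen=True)
class IntensityCurve:
    """Per-store effective (cue-weighted, lesion-adjusted) intensities.

    ``per_store[k, i]`` is store i+1's contribution to the retrievable
    intensity at ``times[k]``; ``total`` is their row sum.
    """

    times: np.ndarray
    per_store: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.per_store.sum(axis=1)


def two_store(mu1: float, a1: float, mu2: float, a2: float = 0.0,
              q: float = 1.0, g: float = 0.0) -> ChainParams:
    """Convenience constructor for the standard hippocampus->neocortex chain."""
    return ChainParams((StoreParams(mu1, a1), StoreParams(mu2, a2)), q=q, g=g)


# ---------------------------------------------------------------------------
# closed forms and numeric fallbacks

def _check_times(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("times must be finite and >= 0")
    return arr


def _rates_tied(rates: Sequence[float]) -> bool:
    for i in range(len(rates)):
        for j in range(i + 1, len(rates)):
            tol = max(_TIE_REL * max(abs(rates[i]), abs(rates[j])), _TIE_ABS)
            if abs(rates[i] - rates[j]) <= tol:
                return True
    return False


def _bateman(mus: Sequence[float], rates: Sequence[float], t: np.ndarray) -> np.ndarray:
    """Sum-of-exponentials solution of the cascade for distinct rates."""
    coef = mus[0] * float(np.prod(mus[1:])) if len(mus) > 1 else mus[0]
    out = np.zeros_like(t, dtype=float)
    for j, aj in enumerate(rates):
        denom = 1.0
        for l, al in enumerate(rates):
            if l != j:
                denom *= al - aj
        out += np.exp(-aj * t) / denom
    return coef * out


def _ode_solve(mus: Sequence[float], rates: Sequence[float], times: np.ndarray) -> np.ndarray:
    """Integrate the exponential cascade numerically; rows follow `times`."""
    mus_arr = np.asarray(mus, dtype=float)
    rates_arr = np.asarray(rates, dtype=float)
    uniq, inverse = np.unique(times, return_inverse=True)
    y0 = np.zeros(len(mus_arr))
    y0[0] = mus_arr[0]
    if uniq[-1] == 0.0:
        return np.tile(y0, (len(times), 1))

    def rhs(_t, y):
        dy = -rates_arr * y
        dy[1:] += mus_arr[1:] * y[:-1]
        return dy

    t_eval = uniq if uniq[0] == 0.0 else np.concatenate(([0.0], uniq))
    sol = integrate.solve_ivp(rhs, (0.0, float(uniq[-1])), y0, method="DOP853",
                              rtol=1e-11, atol=1e-13, t_eval=t_eval)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"cascade integration failed: {sol.message}")
    table = sol.y.T if uniq[0] == 0.0 else sol.y.T[1:]
    return table[inverse]


def _convolved_intensity(params: ChainParams, index: int, t: float) -> float:
    """Recursive convolution for chains containing power-decline stores.

    Traces induced into store i at time s survive to t with store i's
    decline function, so r_i(t) = mu_i * int_0^t r_{i-1}(s) D_i(t-s) ds.
    """
    store = params.stores[index - 1]
    if index == 1:
        return params.stores[0].mu * float(store.decline(t))
    if t == 0.0:
        return 0.0

    def integrand(s):
        return _convolved_intensity(params, index - 1, s) * float(store.decline(t - s))

    val, _err = integrate.quad(integrand, 0.0, t, limit=200)
    return store.mu * val


def _store_intensity_raw(params: ChainParams, index: int, t: np.ndarray) -> np.ndarray:
    """Unlesioned, cue-free r_index(t); `t` is a 1-D array."""
    prefix = params.stores[:index]
    mus = [s.mu for s in prefix]
    rates = [s.a for s in prefix]
    if all(s.decline_kind == EXPONENTIAL for s in prefix):
        if not _rates_tied(rates):
            return np.maximum(_bateman(mus, rates, t), 0.0)
        return np.maximum(_ode_solve(mus, rates, t)[:, index - 1], 0.0)
    return np.array([_convolved_intensity(params, index, float(tv)) for tv in t])


# ---------------------------------------------------------------------------
# public surface

def store_intensity(params: ChainParams, store_index: int, t):
    """Intensity r_i(t) of a single store (cue quality not applied).

    ``store_index`` is 1-based, matching the subscripts r_1, r_2, ...
    Accepts scalar or array ``t``.
    """
    if not 1 <= store_index <= params.n_stores:
        raise IndexError(f"store_index {store_index} out of range 1..{params.n_stores}")
    arr = _check_times(t)
    scalar = arr.ndim == 0
    vals = _store_intensity_raw(params, store_index, np.atleast_1d(arr))
    return float(vals[0]) if scalar else vals


def intensity_components(params: ChainParams, t) -> np.ndarray:
    """Matrix of r_i(t) for every store, shape (n_times, n_stores); cue-free."""
    arr = np.atleast_1d(_check_times(t))
    return np.column_stack([_store_intensity_raw(params, i, arr)
                            for i in range(1, params.n_stores + 1)])


def total_intensity(params: ChainParams, t):
    """q * (r_1(t) + ... + r_k(t)): acquired intensity x decline x cue quality."""
    arr = _check_times(t)
    scalar = arr.ndim == 0
    tot = params.q * intensity_components(params, np.atleast_1d(arr)).sum(axis=1)
    return float(tot[0]) if scalar else tot


def probability_from_intensity(intensity, g: float = 0.0):
    """Link function p = g + (1 - g) * (1 - exp(-intensity))."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be >= 0")
    p = g + (1.0 - g) * (-np.expm1(-intensity))
    return float(p) if p.ndim == 0 else p


def recall_probability(params: ChainParams, t):
    """Probability of recalling the memory at age t."""
    return probability_from_intensity(total_intensity(params, t), params.g)


def intensity_from_probability(p, g: float = 0.0, strict: bool = False):
    """Invert the recall link: -ln(1 - p), after removing the guess floor g.

    Probabilities at or above 1 (possible in noisy observed proportions) are
    clipped to 1 - 1e-12 with a warning, or rejected when ``strict``.
    """
    arr = np.asarray(p, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr).copy()
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ValueError("probabilities must be finite and >= 0")
    if g:
        arr = (arr - g) / (1.0 - g)
        if np.any(arr < 0):
            if strict:
                raise ValueError("probability below the guess floor g")
            warnings.warn("probability below guess floor; clipping to 0", stacklevel=2)
            arr = np.maximum(arr, 0.0)
    if np.any(arr >= 1):
        if strict:
            raise ValueError("probability >= 1 has infinite intensity")
        warnings.warn("probability >= 1 clipped to 1 - 1e-12 before log transform",
                      stacklevel=2)
        arr = np.minimum(arr, 1.0 - 1e-12)
    out = -np.log1p(-arr)
    return float(out[0]) if scalar else out


def _grid_convolve(params: ChainParams, times: np.ndarray, n_grid: int = 4001) -> np.ndarray:
    """Fixed-grid trapezoid evaluation of the cascade convolutions.

    Independent of the adaptive-quadrature path used by ``store_intensity``
    for power-decline chains, so it can serve as its oracle.
    """
    tmax = float(times.max()) if times.size and times.max() > 0 else 1.0
    grid = np.linspace(0.0, tmax, n_grid)
    table = np.empty((n_grid, params.n_stores))
    table[:, 0] = params.stores[0].mu * params.stores[0].decline(grid)
    for i in range(1, params.n_stores):
        store = params.stores[i]
        vals = np.empty(n_grid)
        vals[0] = 0.0
        for k in range(1, n_grid):
            seg = grid[: k + 1]
            vals[k] = np.trapezoid(table[: k + 1, i - 1] * store.decline(grid[k] - seg), seg)
        table[:, i] = store.mu * vals
    return np.column_stack([np.interp(times, grid, table[:, i])
                            for i in range(params.n_stores)])


def ode_oracle(params: ChainParams, times, lesion: "LesionProfile | None" = None,
               ) -> IntensityCurve:
    """Numerically integrated intensity curve, independent of the closed forms.

    For purely exponential chains the cascade ODE is integrated with a
    high-order Runge-Kutta method; chains containing power-decline stores are
    evaluated by dense fixed-grid convolution. Lesions are applied exactly as
    in :func:`memchain.pathology.lesioned_intensity`: induction-rate scaling
    before integration, intensity fractions (1 - lambda_i) and the retrieval
    scale afterwards.
    """
    arr = np.atleast_1d(_check_times(times))
    if np.any(np.diff(arr) < 0):
        raise ValueError("times must be sorted ascending")
    n = params.n_stores
    if lesion is None:
        lam = np.zeros(n)
        scale = np.ones(n)
        retrieval = 1.0
    else:
        lam, scale, retrieval = lesion.arrays(n)
    eff_stores = tuple(StoreParams(s.mu * scale[i], s.a, s.decline_kind)
                       for i, s in enumerate(params.stores))
    eff = ChainParams(eff_stores, q=params.q, g=params.g)
    if all(s.decline_kind == EXPONENTIAL for s in eff.stores):
        raw = _ode_solve([s.mu for s in eff.stores], [s.a for s in eff.stores], arr)
    else:
        raw = _grid_convolve(eff, arr)
    per_store = params.q * retrieval * raw * (1.0 - lam)[None, :]
    return IntensityCurve(times=arr, per_store=per_store)
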