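"""Synthetic recall data and a trace-level Monte-Carlo oracle.

Two generators, both seed-deterministic:

* :func:`simulate_retention` draws binomial success counts at each retention
  lag from the exact model probabilities, optionally after per-lag
  item-difficulty distortion (multipliers on the acquired intensity), which
  is how clinical retrograde-amnesia tests with non-counterbalanced items
  are emulated;
* :func:`simulate_traces` runs the trace process itself, event-driven:
  store-1 traces start as a Poisson(mu1) count and die after Exp(a1)
  lifetimes; induction generates store-(i+1) traces, which die at rate
  a_{i+1}; recall succeeds when the cue (thinning probability q) recovers
  at least one surviving trace.

Two induction semantics are offered. Under ``induction="population"`` (the
default) store-(i+1) births form an inhomogeneous Poisson process with the
deterministic rate mu_{i+1} * r_i(s): every store's count then stays Poisson
at all times, which is exactly the assumption under which
p = 1 - exp(-q r(t)) is the recall law, so agreement between this simulator
and the closed forms is the package's core internal-consistency check.
Under ``induction="branching"`` each *realized* store-i trace generates
independently at rate mu_{i+1} while it is alive; that literal reading
couples parent survival to offspring counts, makes higher-store counts
overdispersed (compound Poisson), and systematically undershoots the
closed-form recall probability -- it is provided to make that distinction
measurable, not as the model's oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import chain
from .chain import ChainParams
from .fitting import RetentionDataset
from .pathology import LesionProfile, lesioned_intensity

__all__ = ["GroupDesign", "SimDesign", "group_probabilities",
           "simulate_retention", "TraceSimResult", "simulate_traces"]


@dataclass(frozen=True)
class GroupDesign:
    """One group's generative model, retention lags, trials and distortion.

    difficulty : per-lag multiplier on the acquired intensity mu1 (> 0);
        because intensity is linear in mu1 it simply scales the total
        intensity at that lag. Default: no distortion.
    """

    params: ChainParams
    times: tuple[float, ...]
    n: int | tuple[int, ...]
    lesion: LesionProfile | None = None
    difficulty: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if any(t < 0 for t in self.times):
            raise ValueError("retention lags must be >= 0")
        n = self.n
        n = (int(n),) * len(self.times) if np.isscalar(n) else tuple(int(x) for x in n)
        object.__setattr__(self, "n", n)
        if len(n) != len(self.times) or any(x < 1 for x in n):
            raise ValueError("trial counts must be positive, one per lag")
        if self.difficulty is not None:
            d = tuple(float(x) for x in self.difficulty)
            object.__setattr__(self, "difficulty", d)
            if len(d) != len(self.times) or any(x <= 0 for x in d):
                raise ValueError("difficulty multipliers must be > 0, one per lag")


@dataclass(frozen=True)
class SimDesign:
    groups: Mapping[str, GroupDesign]
    seed: int

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group")
        object.__setattr__(self, "groups", dict(self.groups))


def group_probabilities(design: GroupDesign) -> np.ndarray:
    """Exact model recall probabilities at the design's lags, after distortion."""
    t = np.asarray(design.times)
    if design.lesion is None:
        inten = np.atleast_1d(chain.total_intensity(design.params, t))
    else:
        inten = np.atleast_1d(lesioned_intensity(design.params, design.lesion, t))
    if design.difficulty is not None:
        inten = inten * np.asarray(design.difficulty)
    return np.asarray(chain.probability_from_intensity(inten, design.params.g))


def simulate_retention(design: SimDesign, seed: int | None = None) -> RetentionDataset:
    """Binomial retention dataset: successes ~ Binomial(n, p(t)) per point."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    for name in sorted(design.groups):
        grp = design.groups[name]
        p = group_probabilities(grp)
        successes = rng.binomial(np.asarray(grp.n), p)
        for t, s, n in zip(grp.times, successes, grp.n):
            rows.append({"group": name, "time": t, "successes": int(s), "trials": int(n)})
    return RetentionDataset(pd.DataFrame(rows))


@dataclass(frozen=True)
class TraceSimResult:
    """Empirical store counts and recall frequency over replicates."""

    counts: np.ndarray            # (replicates, n_stores), post-lesion survivors
    recalled: np.ndarray          # (replicates,) bool
    t: float

    @property
    def replicates(self) -> int:
        return self.counts.shape[0]

    @property
    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def count_se(self) -> np.ndarray:
        return self.counts.std(axis=0, ddof=1) / np.sqrt(self.replicates)

    @property
    def recall_frequency(self) -> float:
        return float(self.recalled.mean())

    @property
    def recall_se(self) -> float:
        f = self.recall_frequency
        return float(np.sqrt(f * (1 - f) / self.replicates))


def _lifetimes(rng: np.random.Generator, rate: float, size: int) -> np.ndarray:
    if rate == 0:
        return np.full(size, np.inf)
    return rng.exponential(1.0 / rate, size)


def _count_survivors(rep: np.ndarray, death: np.ndarray, t: float,
                     lam_i: float, p_retrieve: float, counts_col: np.ndarray,
                     retrieved: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply lesion thinning and retrieval thinning; returns surviving reps."""
    alive = death > t
    surv_rep = rep[alive]
    if lam_i > 0 and surv_rep.size:
        surv_rep = surv_rep[rng.random(surv_rep.size) >= lam_i]
    counts_col[:] = np.bincount(surv_rep, minlength=counts_col.size)
    if surv_rep.size:
        hit = rng.random(surv_rep.size) < p_retrieve
        retrieved[surv_rep[hit]] = True
    return surv_rep


def simulate_traces(params: ChainParams, t: float, replicates: int,
                    lesion: LesionProfile | None = None,
                    seed: int = 0, induction: str = "population",
                    ) -> TraceSimResult:
    """Event-driven simulation of the trace process up to test time t.

    Exact exponential waiting times, no time discretization. Intensity
    lesions act as independent destruction of surviving traces at test;
    induction scalings shrink the generation rates; cue quality and the
    retrieval scale act as thinning at retrieval. See the module docstring
    for the two ``induction`` semantics.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if induction not in ("population", "branching"):
        raise ValueError("induction must be 'population' or 'branching'")
    t = float(t)
    if t < 0:
        raise ValueError("t must be >= 0")
    rng = np.random.default_rng(seed)
    n_stores = params.n_stores
    if lesion is None:
        lam = np.zeros(n_stores)
        scale = np.ones(n_stores)
        retrieval = 1.0
    else:
        lam, scale, retrieval = lesion.arrays(n_stores)
    if any(s.decline_kind != chain.EXPONENTIAL for s in params.stores):
        raise NotImplementedError("trace simulation assumes exponential decline")

    counts = np.zeros((replicates, n_stores), dtype=np.int64)
    p_retrieve = params.q * retrieval
    retrieved = np.zeros(replicates, dtype=bool)
    scaled = ChainParams(tuple(
        chain.StoreParams(s.mu * scale[i], s.a, s.decline_kind)
        for i, s in enumerate(params.stores)), q=params.q, g=params.g)

    # store 1: initial Poisson counts, born at time 0
    n1 = rng.poisson(scaled.stores[0].mu, replicates)
    rep = np.repeat(np.arange(replicates), n1)
    birth = np.zeros(rep.size)
    death = birth + _lifetimes(rng, scaled.stores[0].a, rep.size)
    _count_survivors(rep, death, t, lam[0], p_retrieve, counts[:, 0],
                     retrieved, rng)

    if induction == "branching":
        for i in range(1, n_stores):
            nxt = scaled.stores[i]
            window = np.maximum(np.minimum(death, t) - birth, 0.0)
            n_child = rng.poisson(nxt.mu * window)
            rep = np.repeat(rep, n_child)
            birth = (np.repeat(birth, n_child)
                     + rng.random(rep.size) * np.repeat(window, n_child))
            death = birth + _lifetimes(rng, nxt.a, rep.size)
            _count_survivors(rep, death, t, lam[i], p_retrieve, counts[:, i],
                             retrieved, rng)
    else:
        # births into store i arrive as an inhomogeneous Poisson process with
        # rate mu_i * r_{i-1}(s); for the donor intensity, store 1 uses its
        # definitional exponential decline, deeper donors the cascade forms
        grid = np.linspace(0.0, t, 2049) if t > 0 else np.zeros(1)
        for i in range(1, n_stores):
            nxt = scaled.stores[i]
            if i == 1:
                donor = scaled.stores[0].mu * scaled.stores[0].decline(grid)
            else:
                donor = chain.intensity_components(scaled, grid)[:, i - 1]
            cum = np.concatenate(([0.0], np.cumsum(
                0.5 * (donor[1:] + donor[:-1]) * np.diff(grid))))
            m_total = nxt.mu * cum[-1]
            n_births = rng.poisson(m_total, replicates)
            rep = np.repeat(np.arange(replicates), n_births)
            # birth times by inverse-CDF sampling of the normalized rate
            if cum[-1] > 0:
                u = rng.random(rep.size) * cum[-1]
                birth = np.interp(u, cum, grid)
            else:
                birth = np.zeros(rep.size)
            death = birth + _lifetimes(rng, nxt.a, rep.size)
            _count_survivors(rep, death, t, lam[i], p_retrieve, counts[:, i],
                             retrieved, rng)

    if params.g > 0:
        retrieved = retrieved | (rng.random(replicates) < params.g)
    return TraceSimResult(counts=counts, recalled=retrieved, t=t)
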