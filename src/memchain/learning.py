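"""Multi-trial acquisition.

The cascade is linear, so intensities acquired at separate learning episodes
superpose: after episodes at times t_1 < ... < t_k, the intensity at test
time T is sum_e m_e * r(T - t_e), where r is the single-episode chain
intensity and m_e the episode's effective trial count. Massed repetitions
within an episode are less effective than their nominal count (e.g. eight
massed foot shocks acting like 3.34 single shocks); m_e captures that as a
multiplier on the acquired intensity, applied before any decline. Learning
saturation is deliberately not modelled, so superposition is exact here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chain
from .chain import ChainParams

__all__ = ["LearningSchedule", "accumulated_intensity", "schedule_recall_probability"]


@dataclass(frozen=True)
class LearningSchedule:
    """Episode times, nominal trials per episode, and effectiveness factors.

    massed_factor : effective trial count m per episode; defaults to the
        nominal count (pure superposition). Must satisfy
        1 <= m <= trials_per_episode whenever the episode has > 1 trial.
    """

    trial_times: tuple[float, ...]
    trials_per_episode: tuple[int, ...] | None = None
    massed_factor: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.trial_times)
        object.__setattr__(self, "trial_times", times)
        if not times:
            raise ValueError("schedule needs at least one learning episode")
        if any(t < 0 for t in times):
            raise ValueError("trial times must be >= 0")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("trial times must be sorted ascending")
        k = len(times)
        trials = self.trials_per_episode
        trials = tuple(int(n) for n in trials) if trials is not None else (1,) * k
        object.__setattr__(self, "trials_per_episode", trials)
        if len(trials) != k or any(n < 1 for n in trials):
            raise ValueError("trials_per_episode must give a positive count per episode")
        m = self.massed_factor
        m = tuple(float(x) for x in m) if m is not None else tuple(float(n) for n in trials)
        object.__setattr__(self, "massed_factor", m)
        if len(m) != k:
            raise ValueError("massed_factor must give one value per episode")
        for n, me in zip(trials, m):
            if me <= 0 or me > n or (n > 1 and me < 1):
                raise ValueError(f"effective trial count {me} inconsistent with "
                                 f"{n} nominal trials (need 1 <= m <= trials)")


def accumulated_intensity(params: ChainParams, schedule: LearningSchedule,
                          t_test: float) -> float:
    """Total intensity at the test time: sum of per-episode chain intensities."""
    t_test = float(t_test)
    if t_test < schedule.trial_times[-1]:
        raise ValueError("t_test must not precede the last learning episode")
    lags = t_test - np.asarray(schedule.trial_times)
    weights = np.asarray(schedule.massed_factor)
    return float(weights @ chain.total_intensity(params, lags))


def schedule_recall_probability(params: ChainParams, schedule: LearningSchedule,
                                t_test: float) -> float:
    return chain.probability_from_intensity(
        accumulated_intensity(params, schedule, t_test), params.g)
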