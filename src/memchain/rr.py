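"""The relative retrograde (rr) gradient.

Clinical retrograde-amnesia tests deliberately make remote-period questions
easier than recent ones, which distorts the shape of both the patient and the
control retention curve. Because intensity is linear in the acquired
intensity mu1 and in cue quality q, the *ratio* of lesioned to control
intensity cancels both, and so is immune to per-time-period item-difficulty
manipulation. Observed recall proportions are mapped back to intensity with
-ln(1 - p) before taking the ratio:

    rr(t) = -ln(1 - p_lesioned(t)) / -ln(1 - p_control(t)).

For a partial store-1 lesion the model rr curve rises from 1 - lambda at
t = 0 toward 1; a pure retrieval deficit gives a flat rr curve at q_H.
Taking the ratio of raw probabilities instead does NOT share this invariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chain
from .chain import ChainParams
from .pathology import LesionProfile, lesioned_intensity

__all__ = ["RRCurve", "rr_transform", "rr_model", "rr_intercept"]


@dataclass(frozen=True)
class RRCurve:
    times: np.ndarray
    rr: np.ndarray
    source: str  # "data" | "model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "rr", np.asarray(self.rr, dtype=float))
        if self.times.shape != self.rr.shape:
            raise ValueError("times and rr must have matching shapes")
        if self.source not in ("data", "model"):
            raise ValueError("source must be 'data' or 'model'")
        if np.any(self.rr < 0):
            raise ValueError("rr values must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "rr": self.rr, "source": self.source})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rr_transform(p_lesioned, p_control, times=None, g: float = 0.0,
                 trials=None, strict: bool = False) -> RRCurve:
    """Empirical rr curve from matched recall proportions.

    Proportions of exactly 1 are clipped to 1 - 1/(2n) when the number of
    trials n at that point is known (a standard continuity correction), else
    to 1 - 1e-12; ``strict`` raises instead. Points where the control is at 0
    (intensity 0, ratio undefined) are excluded with a warning. When a guess
    floor g is declared, both curves are corrected to (p - g)/(1 - g) first.
    """
    pl = np.atleast_1d(np.asarray(p_lesioned, dtype=float)).copy()
    pc = np.atleast_1d(np.asarray(p_control, dtype=float)).copy()
    if pl.shape != pc.shape:
        raise ValueError("lesioned and control probability vectors must be matched")
    t = np.arange(len(pl), dtype=float) if times is None else \
        np.atleast_1d(np.asarray(times, dtype=float))
    if t.shape != pl.shape:
        raise ValueError("times must match the probability vectors")

    if trials is not None:
        n = np.atleast_1d(np.asarray(trials, dtype=float))
        for arr in (pl, pc):
            at_one = arr >= 1
            if np.any(at_one):
                if strict:
                    raise ValueError("observed proportion of 1 in strict mode")
                warnings.warn("perfect score clipped to 1 - 1/(2n) before log transform",
                              stacklevel=2)
                arr[at_one] = 1.0 - 1.0 / (2.0 * n[at_one])

    r_les = chain.intensity_from_probability(pl, g=g, strict=strict)
    r_ctl = chain.intensity_from_probability(pc, g=g, strict=strict)
    defined = r_ctl > 0
    if not np.all(defined):
        warnings.warn(f"rr undefined at {int((~defined).sum())} point(s) with zero "
                      "control intensity; excluded", stacklevel=2)
    return RRCurve(times=t[defined], rr=r_les[defined] / r_ctl[defined], source="data")


def rr_model(params: ChainParams, lesion: LesionProfile, times) -> RRCurve:
    """Model rr curve: lesioned over control intensity.

    mu1 and q cancel exactly (both intensities are linear in them), so the
    curve depends only on decline rates, induction rates past store 1, and
    the lesion. t = 0 is evaluated as the analytic limit
    retrieval_scale * induction_scale_1 * (1 - lambda_1).
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    lam, scale, retrieval = lesion.arrays(params.n_stores)
    out = np.empty_like(t)
    pos = t > 0
    if np.any(pos):
        num = lesioned_intensity(params, lesion, t[pos])
        den = chain.total_intensity(params, t[pos])
        out[pos] = np.atleast_1d(num) / np.atleast_1d(den)
    out[~pos] = retrieval * scale[0] * (1.0 - lam[0])
    return RRCurve(times=t, rr=out, source="model")


def rr_intercept(lesion: LesionProfile) -> float:
    """Ordinate intercept of the model rr curve.

    1 - lambda_1 for an intensity lesion of store 1; q_H for a pure retrieval
    deficit; their product in the combined case.
    """
    lam1 = lesion.intensity_lesion[0] if lesion.intensity_lesion else 0.0
    scale1 = lesion.induction_scale[0] if lesion.induction_scale else 1.0
    return lesion.retrieval_scale * scale1 * (1.0 - lam1)
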