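"""Lesion operators and named pathology profiles.

Two distinct lesion semantics coexist, because both occur in amnesia work:

* *intensity lesions* destroy a fraction ``lambda_i`` of store i's surviving
  traces at (or just before) test -- the retrograde-amnesia reading, giving
  the Ribot gradient ``p(t) = 1 - exp(-[(1 - lambda) r_1(t) + r_2(t)])``;
* *induction-rate scalings* reduce the rate at which a store writes into the
  next one -- the anterograde-amnesia reading (e.g. working-memory-to-MTL
  learning rates shrunk by a functional MTL lesion);
* a *retrieval scaling* multiplies cue quality q, modelling a pure retrieval
  deficit (Huntington's disease), which leaves every stored trace intact.

All three live in one :class:`LesionProfile`; an all-default profile is the
identity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import chain
from .chain import ChainParams, StoreParams

__all__ = [
    "LesionProfile",
    "IDENTITY",
    "lesioned_intensity",
    "lesioned_recall_probability",
    "ribot_gradient",
    "post_lesion_decay",
    "pathology_profile",
    "functional_lesion_size",
]


@dataclass(frozen=True)
class LesionProfile:
    """Per-store lesion fractions, induction scalings and retrieval scaling.

    intensity_lesion : fraction lambda_i of store i's intensity destroyed,
        each in [0, 1]; shorter tuples are padded with 0 (intact).
    induction_scale : multiplier in [0, 1] on store i's acquisition/induction
        rate mu_i; padded with 1.
    retrieval_scale : multiplier in (0, 1] on cue quality (q_H for a
        Huntington-style retrieval deficit).
    lesion_time : memory ages are measured up to this lesion time t_l; None
        means "lesion at test" (the usual simplification, since post-lesion
        forgetting is negligible in the datasets this model targets).
    """

    intensity_lesion: tuple[float, ...] = ()
    induction_scale: tuple[float, ...] = ()
    retrieval_scale: float = 1.0
    lesion_time: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensity_lesion", tuple(float(x) for x in self.intensity_lesion))
        object.__setattr__(self, "induction_scale", tuple(float(x) for x in self.induction_scale))
        if any(not 0 <= x <= 1 for x in self.intensity_lesion):
            raise ValueError("intensity lesion fractions must lie in [0, 1]")
        if any(not 0 <= x <= 1 for x in self.induction_scale):
            raise ValueError("induction scalings must lie in [0, 1]")
        if not 0 < self.retrieval_scale <= 1:
            raise ValueError("retrieval_scale must lie in (0, 1]")
        if self.lesion_time is not None and self.lesion_time < 0:
            raise ValueError("lesion_time must be >= 0")

    def arrays(self, n_stores: int) -> tuple[np.ndarray, np.ndarray, float]:
        """(lambda, induction scale, retrieval scale) padded to n_stores."""
        if len(self.intensity_lesion) > n_stores or len(self.induction_scale) > n_stores:
            raise ValueError("lesion profile refers to more stores than the chain has")
        lam = np.zeros(n_stores)
        lam[: len(self.intensity_lesion)] = self.intensity_lesion
        scale = np.ones(n_stores)
        scale[: len(self.induction_scale)] = self.induction_scale
        return lam, scale, self.retrieval_scale

    @property
    def is_identity(self) -> bool:
        return (all(x == 0 for x in self.intensity_lesion)
                and all(x == 1 for x in self.induction_scale)
                and self.retrieval_scale == 1.0)


IDENTITY = LesionProfile()


def _scaled_chain(params: ChainParams, scale: np.ndarray) -> ChainParams:
    if np.all(scale == 1.0):
        return params
    stores = tuple(StoreParams(s.mu * scale[i], s.a, s.decline_kind)
                   for i, s in enumerate(params.stores))
    return ChainParams(stores, q=params.q, g=params.g)


def _check_age(lesion: LesionProfile, t) -> None:
    if lesion.lesion_time is not None and np.any(np.asarray(t, dtype=float) > lesion.lesion_time):
        raise ValueError("memory age t exceeds the lesion time t_l; "
                         "use post_lesion_decay for post-lesion retention")


def lesioned_intensity(params: ChainParams, lesion: LesionProfile, t):
    """Retrievable intensity under a lesion.

    q * retrieval_scale * sum_i (1 - lambda_i) r_i(t), with the r_i computed
    from induction-scaled rates. The identity profile reproduces
    :func:`memchain.chain.total_intensity` exactly.
    """
    _check_age(lesion, t)
    lam, scale, retrieval = lesion.arrays(params.n_stores)
    comps = chain.intensity_components(_scaled_chain(params, scale), t)
    vals = params.q * retrieval * comps @ (1.0 - lam)
    arr = np.asarray(t, dtype=float)
    return float(vals[0]) if arr.ndim == 0 else vals


def lesioned_recall_probability(params: ChainParams, lesion: LesionProfile, t):
    return chain.probability_from_intensity(lesioned_intensity(params, lesion, t), params.g)


def ribot_gradient(params: ChainParams, lesion: LesionProfile, times) -> np.ndarray:
    """Recall probability for memories of increasing age at lesion time.

    With a full store-1 lesion and no neocortical decline this is
    non-decreasing in t: older memories are better preserved (Ribot's Law).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    return np.asarray(chain.probability_from_intensity(
        lesioned_intensity(params, lesion, times), params.g))


def post_lesion_decay(params: ChainParams, lesion: LesionProfile, t_l: float, tau):
    """Intensity tau time units after a lesion administered at memory age t_l.

    After the lesion nothing is induced any more, so what survives declines
    at the last (slowest) store's rate: lesioned_intensity(t_l) * exp(-a_k tau).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    at_test = dataclasses.replace(lesion, lesion_time=None)
    base = lesioned_intensity(params, at_test, float(t_l))
    out = base * np.exp(-params.stores[-1].a * tau)
    return float(out) if tau.ndim == 0 else out


def pathology_profile(name: str, **kwargs) -> LesionProfile:
    """Named lesion profiles for the pathologies this model distinguishes.

    korsakoff(lam): partial destruction of the hippocampal/MTL store only.
    alzheimer(lam, lam2): MTL destruction plus a neocortical functional
        lesion, (1 - lam2) * r_2(t).
    huntington(q_h): intact storage, impaired retrieval (cue quality q_h).
    custom(...): pass LesionProfile fields through.
    """
    name = name.lower()
    if name == "korsakoff":
        lam = _require(kwargs, "lam")
        return LesionProfile(intensity_lesion=(lam, 0.0))
    if name == "alzheimer":
        lam = _require(kwargs, "lam")
        lam2 = _require(kwargs, "lam2")
        return LesionProfile(intensity_lesion=(lam, lam2))
    if name == "huntington":
        q_h = _require(kwargs, "q_h")
        return LesionProfile(retrieval_scale=q_h)
    if name == "custom":
        return LesionProfile(**kwargs)
    raise ValueError(f"unknown pathology {name!r}")


def _require(kwargs: dict, key: str) -> float:
    if key not in kwargs:
        raise ValueError(f"pathology profile requires parameter {key!r}")
    val = float(kwargs[key])
    return val


def functional_lesion_size(intact_mu: float, lesioned_mu: float) -> float:
    """Relative functional lesion, 1 - mu_lesioned / mu_intact.

    Used for anterograde amnesia fits where the lesion manifests as a reduced
    induction rate into the damaged store.
    """
    if intact_mu <= 0:
        raise ValueError("intact induction rate must be > 0")
    if lesioned_mu < 0 or lesioned_mu > intact_mu:
        raise ValueError("lesioned rate must lie in [0, intact rate]")
    return 1.0 - lesioned_mu / intact_mu
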