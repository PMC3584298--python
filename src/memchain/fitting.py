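"""Simultaneous nonlinear fitting of retention curves and rr-gradients.

A fit couples one chain (shared parameters mu1, a1, mu2, a2, ..., q, g)
to several observed groups, each transformed by its own lesion profile whose
fields (lam1, lam2, retrieval, induction1, ...) may themselves be free. The
default objective is unweighted least squares on recall proportions -- the
convention under which goodness of fit is reported as SSE and a pooled R^2
-- with binomial maximum likelihood available as an alternative. The
optimizer is a bounded trust-region least-squares (or L-BFGS-B for the
likelihood loss) started from a seeded Latin-hypercube set of initial
points, so results are deterministic given (dataset, spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from . import chain
from .chain import ChainParams, StoreParams
from .pathology import LesionProfile, lesioned_intensity
from .rr import RRCurve, rr_model

__all__ = [
    "RetentionDataset",
    "ParamSpec",
    "FitSpec",
    "FitResult",
    "GoodnessOfFit",
    "two_store_spec",
    "fit",
    "fit_rr",
    "mtl_lifetime",
    "goodness",
]

DEFAULT_BOUNDS = {
    "mu": (0.0, 100.0),
    "a": (0.0, 10.0),
    "q": (1e-6, 1.0),
    "g": (0.0, 0.999),
    "lam": (0.0, 1.0),
    "retrieval": (1e-6, 1.0),
    "induction": (0.0, 1.0),
}

_LOSSES = ("ls_prob", "binom")
_BOUND_EPS = 1e-6


# ---------------------------------------------------------------------------
# dataset container

class RetentionDataset:
    """Grouped observed recall points (group, time, successes, trials).

    Wraps a tidy DataFrame. Counts may be absent (proportion-only data, as
    read from published averages); the binomial loss then refuses to run.
    """

    COLUMNS = ("group", "time", "successes", "trials", "proportion")

    def __init__(self, frame: pd.DataFrame):
        self.frame = self._validate(frame)

    @staticmethod
    def _validate(frame: pd.DataFrame) -> pd.DataFrame:
        df = frame.copy()
        problems: list[str] = []
        if "group" not in df.columns or "time" not in df.columns:
            raise ValueError("dataset needs 'group' and 'time' columns")
        has_counts = "successes" in df.columns and "trials" in df.columns
        if not has_counts and "proportion" not in df.columns:
            raise ValueError("dataset needs either successes/trials or proportion")
        for col in ("successes", "trials", "proportion"):
            if col not in df.columns:
                df[col] = np.nan
        df["group"] = df["group"].astype(str)
        df["time"] = df["time"].astype(float)
        counts = df["successes"].notna() & df["trials"].notna()
        df.loc[counts, "proportion"] = (df.loc[counts, "successes"]
                                        / df.loc[counts, "trials"])
        for idx, row in df.iterrows():
            if row["time"] < 0 or not np.isfinite(row["time"]):
                problems.append(f"row {idx}: invalid time {row['time']}")
            if pd.notna(row["trials"]) and row["trials"] < 1:
                problems.append(f"row {idx}: trials {row['trials']} < 1")
            if pd.notna(row["successes"]) and pd.notna(row["trials"]):
                if row["successes"] < 0 or row["successes"] > row["trials"]:
                    problems.append(f"row {idx}: successes {row['successes']} outside "
                                    f"[0, trials={row['trials']}]")
            if pd.notna(row["proportion"]) and not 0 <= row["proportion"] <= 1:
                problems.append(f"row {idx}: proportion {row['proportion']} outside [0, 1]")
            if pd.isna(row["proportion"]):
                problems.append(f"row {idx}: no proportion and no complete counts")
        dup = df.duplicated(subset=["group", "time"], keep=False)
        for idx in df.index[dup]:
            problems.append(f"row {idx}: duplicate (group, time) = "
                            f"({df.loc[idx, 'group']}, {df.loc[idx, 'time']})")
        if problems:
            raise ValueError("invalid retention data:\n  " + "\n  ".join(problems))
        df = df.sort_values(["group", "time"], kind="stable").reset_index(drop=True)
        return df[list(RetentionDataset.COLUMNS)]

    @classmethod
    def from_counts(cls, group, time, successes, trials) -> "RetentionDataset":
        return cls(pd.DataFrame({"group": group, "time": time,
                                 "successes": successes, "trials": trials}))

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def group(self, name: str) -> pd.DataFrame:
        sub = self.frame[self.frame["group"] == name]
        if sub.empty:
            raise KeyError(f"no group named {name!r}")
        return sub.reset_index(drop=True)

    @property
    def n_points(self) -> int:
        return len(self.frame)

    @property
    def has_counts(self) -> bool:
        return bool(self.frame["successes"].notna().all()
                    and self.frame["trials"].notna().all())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RetentionDataset):
            return NotImplemented
        return self.frame.equals(other.frame)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"RetentionDataset({self.n_points} points, "
                f"groups={self.groups})")


# ---------------------------------------------------------------------------
# parameter specification

@dataclass(frozen=True)
class ParamSpec:
    """One parameter's status: fixed at a value, or free within bounds."""

    value: float | None = None
    is_free: bool = False
    bounds: tuple[float, float] = (0.0, 100.0)

    @classmethod
    def free(cls, lo: float, hi: float, init: float | None = None) -> "ParamSpec":
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("free parameters need finite bounds lo < hi")
        if init is not None and not lo <= init <= hi:
            raise ValueError("initial value outside bounds")
        return cls(value=init, is_free=True, bounds=(float(lo), float(hi)))

    @classmethod
    def fixed(cls, value: float) -> "ParamSpec":
        return cls(value=float(value), is_free=False)

    def start(self) -> float:
        if self.value is not None:
            return self.value
        lo, hi = self.bounds
        return 0.5 * (lo + hi)


def _default_bounds(name: str) -> tuple[float, float]:
    for prefix, b in DEFAULT_BOUNDS.items():
        if name.startswith(prefix):
            return b
    return (0.0, 100.0)


@dataclass
class FitSpec:
    """Model structure and per-parameter status for a simultaneous fit.

    chain : shared chain parameters, keyed mu1, a1, mu2, a2, ..., q, g.
        Missing q/g default to fixed 1 and 0.
    lesions : per-group lesion parameters keyed lam1, lam2, ...,
        retrieval, induction1, ...; groups not listed get the identity.
    """

    n_stores: int = 2
    chain: dict[str, ParamSpec] = field(default_factory=dict)
    lesions: dict[str, dict[str, ParamSpec]] = field(default_factory=dict)
    loss: str = "ls_prob"
    multistart: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}")
        if self.n_stores < 1:
            raise ValueError("n_stores must be >= 1")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        chain_names = self._chain_names()
        for name in self.chain:
            if name not in chain_names:
                raise ValueError(f"unknown chain parameter {name!r} for "
                                 f"{self.n_stores} stores")
        for i in range(1, self.n_stores + 1):
            for name in (f"mu{i}", f"a{i}"):
                if name not in self.chain:
                    raise ValueError(f"chain parameter {name!r} must be specified "
                                     "(free or fixed)")
        self.chain.setdefault("q", ParamSpec.fixed(1.0))
        self.chain.setdefault("g", ParamSpec.fixed(0.0))
        lesion_names = self._lesion_names()
        for grp, entries in self.lesions.items():
            for name in entries:
                if name not in lesion_names:
                    raise ValueError(f"unknown lesion parameter {name!r} "
                                     f"in group {grp!r}")

    def _chain_names(self) -> list[str]:
        names = []
        for i in range(1, self.n_stores + 1):
            names += [f"mu{i}", f"a{i}"]
        return names + ["q", "g"]

    def _lesion_names(self) -> set[str]:
        names = {"retrieval"}
        for i in range(1, self.n_stores + 1):
            names |= {f"lam{i}", f"induction{i}"}
        return names


def two_store_spec(free: tuple[str, ...] = ("mu1", "a1", "mu2"),
                   fixed: dict[str, float] | None = None,
                   lesions: dict[str, dict[str, ParamSpec]] | None = None,
                   bounds: dict[str, tuple[float, float]] | None = None,
                   init: dict[str, float] | None = None,
                   loss: str = "ls_prob", multistart: int = 32,
                   seed: int = 0) -> FitSpec:
    """Standard hippocampus->neocortex spec: a2 = 0, q = 1, g = 0 unless told otherwise."""
    fixed = dict(fixed or {})
    fixed.setdefault("a2", 0.0)
    bounds = bounds or {}
    init = init or {}
    chain_spec: dict[str, ParamSpec] = {}
    for name in ("mu1", "a1", "mu2", "a2", "q", "g"):
        if name in free:
            lo, hi = bounds.get(name, _default_bounds(name))
            chain_spec[name] = ParamSpec.free(lo, hi, init.get(name))
        elif name in fixed:
            chain_spec[name] = ParamSpec.fixed(fixed[name])
    return FitSpec(n_stores=2, chain=chain_spec, lesions=dict(lesions or {}),
                   loss=loss, multistart=multistart, seed=seed)


# ---------------------------------------------------------------------------
# results

@dataclass
class GoodnessOfFit:
    sse: float
    r2: float
    chisq: float
    chisq_p: float
    df: int


@dataclass
class FitResult:
    """Estimates, fit quality, and optimizer diagnostics."""

    params: dict[str, float]
    free_names: list[str]
    sse: float
    r2: float
    predictions: pd.DataFrame
    success: bool
    message: str
    at_bounds: list[str]
    n_free: int
    cost: float
    seed: int

    def chain_params(self, n_stores: int = 2) -> ChainParams:
        stores = tuple(StoreParams(self.params[f"mu{i}"], self.params[f"a{i}"])
                       for i in range(1, n_stores + 1))
        return ChainParams(stores, q=self.params.get("q", 1.0),
                           g=self.params.get("g", 0.0))

    def lesion_profile(self, group: str, n_stores: int = 2) -> LesionProfile:
        lam = tuple(self.params.get(f"{group}:lam{i}", 0.0)
                    for i in range(1, n_stores + 1))
        scale = tuple(self.params.get(f"{group}:induction{i}", 1.0)
                      for i in range(1, n_stores + 1))
        return LesionProfile(intensity_lesion=lam, induction_scale=scale,
                             retrieval_scale=self.params.get(f"{group}:retrieval", 1.0))


# ---------------------------------------------------------------------------
# assembly helpers

def _collect_entries(spec: FitSpec, groups: list[str]):
    """Ordered (qualified name, ParamSpec) pairs: chain first, then per group."""
    entries: list[tuple[str, ParamSpec]] = []
    for name in spec._chain_names():
        if name in spec.chain:
            entries.append((name, spec.chain[name]))
    for grp in groups:
        for name, ps in sorted(spec.lesions.get(grp, {}).items()):
            entries.append((f"{grp}:{name}", ps))
    return entries


def _values_from_vector(entries, x: np.ndarray) -> dict[str, float]:
    values: dict[str, float] = {}
    k = 0
    for name, ps in entries:
        if ps.is_free:
            values[name] = float(x[k])
            k += 1
        else:
            values[name] = float(ps.value)
    return values


def _build_models(values: dict[str, float], n_stores: int,
                  groups: list[str]) -> tuple[ChainParams, dict[str, LesionProfile]]:
    stores = tuple(StoreParams(values[f"mu{i}"], values[f"a{i}"])
                   for i in range(1, n_stores + 1))
    params = ChainParams(stores, q=values.get("q", 1.0), g=values.get("g", 0.0))
    lesions = {}
    for grp in groups:
        lam = tuple(values.get(f"{grp}:lam{i}", 0.0) for i in range(1, n_stores + 1))
        scale = tuple(values.get(f"{grp}:induction{i}", 1.0)
                      for i in range(1, n_stores + 1))
        retrieval = values.get(f"{grp}:retrieval", 1.0)
        lesions[grp] = LesionProfile(intensity_lesion=lam, induction_scale=scale,
                                     retrieval_scale=max(retrieval, 1e-12))
    return params, lesions


def _start_points(entries, multistart: int, seed: int,
                  extra: list[np.ndarray] | None = None) -> np.ndarray:
    """Initial points: user/midpoint start, heuristic extras, LHS fill.

    Rate-like parameters (bounds spanning more than two decades above 1)
    are sampled log-uniformly -- retention problems put mu and a anywhere
    between 1e-3 and 10, which uniform sampling over [0, 100] never visits.
    """
    free_specs = [ps for _n, ps in entries if ps.is_free]
    d = len(free_specs)
    x0 = np.array([ps.start() for ps in free_specs])
    rows = [x0]
    if extra:
        rows += [np.asarray(e, dtype=float) for e in extra]
    n_lhs = multistart - len(rows)
    if d == 0 or n_lhs <= 0:
        return np.vstack(rows)[: max(multistart, 1)]
    lo = np.array([ps.bounds[0] for ps in free_specs])
    hi = np.array([ps.bounds[1] for ps in free_specs])
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    u = sampler.random(n_lhs)
    pts = np.empty_like(u)
    for j in range(d):
        if hi[j] > 1.0 and hi[j] / max(lo[j], 1e-4 * hi[j]) > 100.0:
            llo = np.log(max(lo[j], 1e-4 * hi[j]))
            lhi = np.log(hi[j])
            pts[:, j] = np.exp(llo + u[:, j] * (lhi - llo))
        else:
            pts[:, j] = lo[j] + u[:, j] * (hi[j] - lo[j])
    return np.vstack(rows + [pts])


def _pooled_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    sse = float(np.sum((observed - predicted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        return 1.0 if sse == 0 else float("nan")
    return 1.0 - sse / sst


def _minimize_multistart(entries, objective, kind: str, multistart: int, seed: int,
                         extra_starts: list[np.ndarray] | None = None):
    """Run bounded optimization from Latin-hypercube starts; return the best."""
    free_specs = [(n, ps) for n, ps in entries if ps.is_free]
    lo = np.array([ps.bounds[0] for _n, ps in free_specs])
    hi = np.array([ps.bounds[1] for _n, ps in free_specs])
    starts = _start_points(entries, multistart, seed, extra_starts)
    starts = np.clip(starts, lo, hi)
    best_x, best_cost, best_ok = None, np.inf, False
    for x0 in starts:
        if kind == "residuals":
            try:
                sol = optimize.least_squares(objective, x0, bounds=(lo, hi),
                                             method="trf", xtol=1e-14,
                                             ftol=1e-14, gtol=1e-14)
            except Exception:  # pragma: no cover - defensive
                continue
            cost, x, ok = 2.0 * sol.cost, sol.x, sol.success
        else:
            sol = optimize.minimize(objective, x0, method="L-BFGS-B",
                                    bounds=list(zip(lo, hi)),
                                    options={"maxiter": 500, "ftol": 1e-14})
            cost, x, ok = float(sol.fun), sol.x, bool(sol.success)
        if cost < best_cost - 1e-15 or (best_x is None):
            best_x, best_cost, best_ok = x, cost, ok
    if best_x is None:  # pragma: no cover - defensive
        raise RuntimeError("all optimizer starts failed")
    at_bounds = []
    for (name, ps), xi in zip(free_specs, best_x):
        lo_i, hi_i = ps.bounds
        if xi - lo_i <= _BOUND_EPS * (hi_i - lo_i) or hi_i - xi <= _BOUND_EPS * (hi_i - lo_i):
            at_bounds.append(name)
    return best_x, best_cost, best_ok, at_bounds


def _heuristic_start(entries, per_group, groups) -> np.ndarray:
    """Moment-style initial guesses from the intensity transform of the data."""
    r_by_group = {}
    for g in groups:
        p = np.clip(per_group[g]["proportion"].to_numpy(), 0.0, 0.99)
        r_by_group[g] = -np.log1p(-p)
    t_all = np.concatenate([per_group[g]["time"].to_numpy() for g in groups])
    span = max(float(t_all.max()), 1e-6)
    best = max(groups, key=lambda g: r_by_group[g][0])
    r0 = max(r_by_group[best][0], 1e-3)
    r_end = max(r_by_group[best][-1], 1e-6)
    a1_h = np.log(r0 / r_end) / span if r0 > r_end else 1.0 / span
    a1_h = max(a1_h, 1e-4)
    r_late = min(max(r[-1], 1e-6) for r in r_by_group.values())
    guesses = {"mu1": r0, "a1": a1_h, "mu2": max(r_late * a1_h / r0, 1e-5)}
    vec = []
    for name, ps in entries:
        if ps.is_free:
            vec.append(guesses.get(name.split(":")[-1], ps.start()))
    return np.asarray(vec)


# ---------------------------------------------------------------------------
# fitting entry points

def fit(dataset: RetentionDataset, spec: FitSpec) -> FitResult:
    """Minimize the chosen loss over all groups jointly.

    Raises before optimizing when the number of free parameters reaches the
    number of data points (under-identified).
    """
    groups = dataset.groups
    entries = _collect_entries(spec, groups)
    free_names = [n for n, ps in entries if ps.is_free]
    n_free = len(free_names)
    if n_free >= dataset.n_points:
        raise ValueError(f"under-identified: {n_free} free parameters for "
                         f"{dataset.n_points} data points")
    if spec.loss == "binom" and not dataset.has_counts:
        raise ValueError("binomial loss needs successes/trials counts")

    per_group = {g: dataset.group(g) for g in groups}
    obs = np.concatenate([per_group[g]["proportion"].to_numpy() for g in groups])
    flat_data = bool(np.ptp(obs) < 1e-9)
    if flat_data:
        warnings.warn("no temporal signal in the data: decline and consolidation "
                      "parameters are unidentifiable (degenerate fit)", stacklevel=2)

    def predict(x: np.ndarray) -> np.ndarray:
        values = _values_from_vector(entries, x)
        params, lesions = _build_models(values, spec.n_stores, groups)
        preds = []
        for g in groups:
            t = per_group[g]["time"].to_numpy()
            inten = lesioned_intensity(params, lesions[g], t)
            preds.append(chain.probability_from_intensity(np.atleast_1d(inten),
                                                          params.g))
        return np.concatenate(preds)

    if spec.loss == "ls_prob":
        objective = lambda x: predict(x) - obs
        kind = "residuals"
    else:
        succ = np.concatenate([per_group[g]["successes"].to_numpy() for g in groups])
        n = np.concatenate([per_group[g]["trials"].to_numpy() for g in groups])

        def objective(x):
            p = np.clip(predict(x), 1e-12, 1 - 1e-12)
            return -float(np.sum(succ * np.log(p) + (n - succ) * np.log1p(-p)))

        kind = "scalar"

    best_x, best_cost, ok, at_bounds = _minimize_multistart(
        entries, objective, kind, spec.multistart, spec.seed,
        extra_starts=[_heuristic_start(entries, per_group, groups)])

    values = _values_from_vector(entries, best_x)
    pred = predict(best_x)
    sse = float(np.sum((obs - pred) ** 2))
    r2 = _pooled_r2(obs, pred)
    predictions = pd.concat(
        [per_group[g].assign(predicted=np.nan) for g in groups],
        ignore_index=True)
    predictions["predicted"] = pred
    message = "converged" if ok else "optimizer did not report convergence"
    if flat_data:
        message += "; degenerate: no temporal signal"
    if at_bounds:
        message += f"; at bounds: {', '.join(at_bounds)} (possible degeneracy)"
        warnings.warn(f"fitted parameter(s) at bounds: {at_bounds}", stacklevel=2)
    return FitResult(params=values, free_names=free_names, sse=sse, r2=r2,
                     predictions=predictions[["group", "time", "proportion",
                                              "predicted"]],
                     success=ok, message=message, at_bounds=at_bounds,
                     n_free=n_free, cost=best_cost, seed=spec.seed)


def fit_rr(rr_curve: RRCurve, spec: dict[str, ParamSpec] | None = None,
           n_stores: int = 2, multistart: int = 32, seed: int = 0) -> FitResult:
    """Least-squares fit of the model rr curve to an empirical one.

    Fits a1, mu2 and lam1 by default (lam2, a2 etc. may be added through
    ``spec``); mu1 and q are structurally absent from the objective because
    they cancel in the intensity ratio. Requires at least four points, the
    usual inclusion rule for retrograde-amnesia curves.
    """
    t = rr_curve.times
    y = rr_curve.rr
    if len(t) < 4:
        raise ValueError("rr fits need at least four points")
    if not np.all(np.isfinite(y)):
        raise ValueError("rr values must be finite")
    default: dict[str, ParamSpec] = {
        "a1": ParamSpec.free(*DEFAULT_BOUNDS["a"]),
        "mu2": ParamSpec.free(*DEFAULT_BOUNDS["mu"]),
        "lam1": ParamSpec.free(0.0, 1.0),
    }
    if spec:
        default.update(spec)
    chain_names = {"a1", "mu2", "a2"} | {f"a{i}" for i in range(1, n_stores + 1)} \
        | {f"mu{i}" for i in range(2, n_stores + 1)}
    lesion_names = {f"lam{i}" for i in range(1, n_stores + 1)} | {"retrieval"}
    entries = []
    for name in sorted(default):
        if name not in chain_names | lesion_names:
            raise ValueError(f"parameter {name!r} not available in an rr fit "
                             "(mu1 and q cancel out)")
        entries.append((name, default[name]))
    free_names = [n for n, ps in entries if ps.is_free]
    if len(free_names) >= len(t):
        raise ValueError(f"under-identified: {len(free_names)} free parameters "
                         f"for {len(t)} rr points")

    def model_rr(x: np.ndarray) -> np.ndarray:
        values = _values_from_vector(entries, x)
        stores = [StoreParams(1.0, values.get("a1", 0.0))]
        for i in range(2, n_stores + 1):
            stores.append(StoreParams(values.get(f"mu{i}", 0.0),
                                      values.get(f"a{i}", 0.0)))
        params = ChainParams(tuple(stores))
        lesion = LesionProfile(
            intensity_lesion=tuple(values.get(f"lam{i}", 0.0)
                                   for i in range(1, n_stores + 1)),
            retrieval_scale=max(values.get("retrieval", 1.0), 1e-12))
        return rr_model(params, lesion, t).rr

    objective = lambda x: model_rr(x) - y
    best_x, best_cost, ok, at_bounds = _minimize_multistart(
        entries, objective, "residuals", multistart, seed)
    values = _values_from_vector(entries, best_x)
    pred = model_rr(best_x)
    sse = float(np.sum((y - pred) ** 2))
    r2 = _pooled_r2(y, pred)
    message = "converged" if ok else "optimizer did not report convergence"
    if np.ptp(y) < 1e-3:
        message += ("; flat rr curve: a1 and mu2 unidentifiable "
                    "(retrieval-deficit signature)")
        warnings.warn("flat rr curve: decline/consolidation rates unidentifiable",
                      stacklevel=2)
    if at_bounds:
        message += f"; at bounds: {', '.join(at_bounds)}"
    predictions = pd.DataFrame({"time": t, "rr": y, "predicted": pred})
    return FitResult(params=values, free_names=free_names, sse=sse, r2=r2,
                     predictions=predictions, success=ok, message=message,
                     at_bounds=at_bounds, n_free=len(free_names),
                     cost=best_cost, seed=seed)


def mtl_lifetime(a1: float) -> float:
    """Expected lifetime 1/a1 of a single MTL trace, in the data's time unit."""
    if a1 <= 0:
        raise ValueError("decline rate must be > 0 for a finite lifetime")
    return 1.0 / a1


def goodness(observed, predicted, trials, n_free: int = 0) -> GoodnessOfFit:
    """SSE, pooled R^2, and a Pearson chi-square against binomial sampling.

    chisq = sum_i n_i (o_i - p_i)^2 / (p_i (1 - p_i)), df = points - n_free.
    Undefined when a prediction sits exactly at 0 or 1 while the observation
    disagrees; the statistic is then NaN with a warning.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    n = np.asarray(trials, dtype=float)
    if not (o.shape == p.shape == n.shape):
        raise ValueError("observed, predicted and trials must be matched")
    if np.any(n < 1):
        raise ValueError("trials must be >= 1")
    sse = float(np.sum((o - p) ** 2))
    r2 = _pooled_r2(o, p)
    degenerate = ((p <= 0) | (p >= 1)) & (o != p)
    if np.any(degenerate):
        warnings.warn("chi-square undefined: prediction at 0 or 1 disagrees with "
                      "observation", stacklevel=2)
        chisq = float("nan")
        chisq_p = float("nan")
    else:
        var = p * (1 - p)
        terms = np.where(var > 0, n * (o - p) ** 2 / np.where(var > 0, var, 1.0), 0.0)
        chisq = float(terms.sum())
        df = len(o) - n_free
        chisq_p = float(stats.chi2.sf(chisq, df)) if df > 0 else float("nan")
    return GoodnessOfFit(sse=sse, r2=r2, chisq=chisq, chisq_p=chisq_p,
                         df=len(o) - n_free)
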