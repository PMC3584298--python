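# Methods

## Model

`memchain` implements a feedforward chain of memory stores. A newly learned
item deposits an expected trace count ("intensity") of `mu1` in store 1 —
the hippocampus/medial temporal lobe (MTL) in two-store analyses, working
memory in short-delay three-store analyses. Traces in store *i* are lost at
a constant hazard `a_i` and, while the store still holds the item,
induction deposits traces in store *i+1* at rate `mu_{i+1}` per unit of
donor intensity (systems consolidation). The expected intensities obey the
linear cascade

    dr_i/dt = mu_i r_{i-1}(t) - a_i r_i(t),   r_1(0) = mu_1, r_i(0) = 0,

with the familiar two-store, `a2 = 0` solution

    r_1(t) = mu1 e^{-a1 t},    r_2(t) = (mu1 mu2 / a1)(1 - e^{-a1 t}).

Trace counts are Poisson with mean r_i(t); retrieval recovers each
surviving trace independently with probability `q` (cue quality), so recall
succeeds with

    p(t) = 1 - exp(-q * sum_i r_i(t)).

Derived quantities:

* **Ribot gradient** — recall after destroying a fraction `lambda_i` of
  each store's traces, `p(t) = 1 - exp(-q sum_i (1 - lambda_i) r_i(t))`;
  with a full store-1 lesion and `a2 = 0` it rises monotonically with
  memory age (Ribot's Law).
* **Relative retrograde (rr) gradient** — lesioned over control intensity.
  Both intensities are linear in `mu1` and `q`, so the ratio cancels them,
  making the curve immune to per-time-period item-difficulty manipulation.
  Observed proportions enter through the inverse link `-ln(1 - p)`. For a
  partial store-1 lesion the curve rises from `1 - lambda` toward 1; a pure
  retrieval deficit (cue quality `q_H < 1`, the Huntington profile) gives a
  flat curve at `q_H`.
* **Multi-trial learning** — the cascade is linear, so intensities from
  separate episodes superpose exactly; a massed block of trials enters as
  an effective trial count `m` (e.g. 8 massed shocks acting like 3.34
  spaced ones). Learning saturation is deliberately out of scope, so
  superposition is exact in this package.
* **MTL lifetime** — the expected survival time of a single store-1 trace,
  `1/a1`, reported in the dataset's own time unit.

## Parameters, units, defaults

| parameter | meaning | units | default bounds in fits |
|---|---|---|---|
| `mu1` | intensity acquired per learning episode | traces | [0, 100] |
| `mu_i (i>1)` | induction rate into store *i* | 1/(donor-intensity x time) | [0, 100] |
| `a_i` | decline rate of store *i* | 1/time | [0, 10] |
| `q` | cue quality (retrieval thinning) | — | (0, 1] |
| `g` | chance-guessing floor | — | 0 (off) |
| `lambda_i` | fraction of store *i* destroyed | — | [0, 1] |

Time is always the dataset's own unit (seconds to decades across the
studies this model targets); the library never converts units.

The guess floor `g` is an extension for forced-choice tasks (chance 1/2,
1/3, 1/4): `p = g + (1 - g)(1 - e^{-q r})`. It defaults to 0, under which
every published equation above is recovered verbatim. The rr transform
removes a declared `g` before taking logs.

## Lesion semantics

A `LesionProfile` carries three distinct operators because amnesia data
need all three:

* `intensity_lesion` (retrograde): fractions `lambda_i` of surviving traces
  destroyed at test;
* `induction_scale` (anterograde): multipliers on the `mu_i`, modelling a
  functional lesion as a reduced learning/consolidation rate; the reported
  "functional lesion size" is `1 - mu_lesioned / mu_intact`;
* `retrieval_scale` (retrieval deficit): a multiplier on `q`.

Named profiles: Korsakoff = partial store-1 intensity lesion; Alzheimer =
store-1 lesion plus a neocortical intensity lesion `(1 - lambda_2) r_2(t)`;
Huntington = retrieval scaling only. The lesion time defaults to "at test";
`post_lesion_decay` gives the retention `r(t_l) e^{-a_k tau}` after a lesion
at memory age `t_l` (constant when the last store does not decline).

## Numerical choices

* **Closed forms.** All-exponential chains use the distinct-rate
  sum-of-exponentials (Bateman) solution. When two decline rates agree to
  within 1e-9 (relative, 1e-12 absolute floor) the form cancels
  catastrophically, and evaluation falls back to numerical integration of
  the cascade; the confluent two-store limit `mu1 mu2 t e^{-a t}` is
  reproduced this way to 1e-8.
* **ODE oracle.** An independent high-order Runge-Kutta integration
  (`DOP853`, rtol 1e-11/atol 1e-13) of the same cascade; closed forms agree
  with it to 1e-8 on randomized chains, which the test suite asserts.
* **Power decline.** A pluggable alternative decline `(1 + t)^{-a}`
  (finite at t = 0; the exact functional form is a documented package
  choice). Store 1 is closed-form; higher stores are adaptive-quadrature
  convolutions, cross-checked against a fixed-grid trapezoid evaluation.
  Only the exponential kind is acceptance-grade.
* **Inverse link.** Observed proportions of exactly 1 are clipped to
  `1 - 1/(2n)` when the trial count is known (continuity correction), else
  to `1 - 1e-12`, with a warning; strict mode raises. Zero-control points
  make the rr ratio undefined and are excluded with a warning.
* **Optimization.** Bounded trust-region least squares on proportions
  (binomial likelihood via L-BFGS-B as an option), started from a seeded
  Latin-hypercube set (default 32 points). Rate-like parameters whose
  bounds span more than two decades are sampled log-uniformly, and one
  moment-style start is derived from the `-ln(1-p)` transform of the data;
  without these, uniform starts over [0,100] x [0,10] x [0,100] miss the
  narrow basins typical of retention problems. Fits are bit-reproducible
  given (data, spec, seed).
* **R² definition.** Pooled over all simultaneously fitted points,
  `1 - SSE/SST` with SST about the pooled grand mean: one number per
  multi-curve fit. The chi-square report uses Pearson's
  `sum n_i (o_i - p_i)^2 / (p_i (1 - p_i))` with `df = points - free
  parameters`.
* **Degenerate data.** A dataset with no temporal signal (constant
  proportions) is fit perfectly by the balanced ridge `mu2 = a1`
  (consolidation exactly offsets decline); `fit` flags this with an
  explicit degeneracy warning rather than pretending the parameters are
  identified. Parameters that land on a bound are flagged likewise.

## Synthetic data and the trace-level oracle

`simulate_retention` draws `successes ~ Binomial(n, p(t))` from the exact
model probabilities, optionally after per-lag difficulty multipliers on
`mu1` — emulating clinical tests whose remote-period items are made easier.
It emulates sampling noise and item-difficulty artifacts only: no subject
heterogeneity, item correlations, or drop-out, so passing recovery tests
speak to estimator behaviour under binomial noise, not to every property of
real clinical data.

`simulate_traces` is event-driven (exact exponential waiting times, no time
stepping). Two induction semantics are provided:

* `population` (default): births into store *i+1* form an inhomogeneous
  Poisson process with the deterministic rate `mu_{i+1} r_i(s)`. Every
  store's count then remains Poisson, which is precisely the assumption
  under which `p = 1 - e^{-qr}` is exact; the simulated recall frequency
  agrees with the closed forms to Monte-Carlo error, and this agreement is
  the package's core internal-consistency check.
* `branching`: each realized trace generates offspring independently while
  alive. This literal reading couples parent survival to offspring counts,
  producing overdispersed (compound-Poisson) higher-store counts and a
  recall frequency measurably *below* `1 - e^{-qr}`. It is retained to
  make that distinction explicit, with a regression test demonstrating the
  undershoot; it is not the model's oracle.

Intensity lesions act as independent thinning of survivors at test,
retrieval as thinning with probability `q x retrieval_scale` — both exact
for Poisson counts.

## Problem sizes used by the test suite

Trace-simulation checks run 1e5 replicates per grid point (recall SE
~0.0016). The parameter-recovery study simulates the published mouse
spatial-discrimination design: two curves (control, full lesion) at 4
geometrically spaced lags over 3.5–56 days, n = 30 trials per point, 200
replicates. At that n the lesioned curve carries only ~4 expected successes
in total, which bounds the attainable precision of the consolidation-rate
estimate at roughly 50% relative SE regardless of estimator; the suite
documents measured medians and verifies that errors shrink as n grows
(7–11% at n = 300, 2–4% at n = 3000).

## Known limitations

* Learning saturation and spacing effects are not modelled; superposition
  over episodes is exact by construction.
* The power-decline variant's higher-store quadrature is slower and only
  validated to ~1e-5.
* No variance-stabilizing weighting is applied to empirical rr curves,
  which amplify noise near floor and ceiling; fitting weights are the
  default unweighted least squares unless the binomial loss is chosen.
* Lesion fractions are functional quantities; they carry no claim about
  anatomical tissue volume.
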