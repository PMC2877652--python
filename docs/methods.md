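# Methods

## Model and assumptions

`lnflare` implements a deliberately reduced, lumped description of a lupus
nephritis flare cycle. Four state variables aggregate whole arms of the
immune response: immune complexes `I` stand in for the entire
autoantibody/antigen axis; pro-inflammatory mediators `P` lump complement
activation products, chemokines (MCP-1 among them) and activated
leukocytes; damaged tissue `D` is apoptotic/necrotic renal tissue; and
anti-inflammatory mediators `A` combine endogenous regulators (IL-10,
TGF-β) with the effect of anti-inflammatory drugs. The model is
non-spatial and non-compartmental — no blood/tissue distinction — and
takes autoimmunity as already established: there are no explicit T-cell,
B-cell or complement-cascade variables.

The right-hand side (see `lnflare.model.rhs`) couples the four states as
follows. Immune complexes arrive at a deposition rate `s_i` and are
additionally induced by accumulated debris through a Hill function of
order 2, `D²/(k_id² + D²)`, saturating at `s_id`: a few self-antigens
raise little response, abundant debris saturates the induction. They are
cleared by inflammatory phagocytosis at `k_ip·I·P`. `P` is produced in
response to `I`, itself (positive feedback `k_pp`) and `D`, and decays at
`mu_p`. Damage arises from phagocytosis of complexes (`k_dip·I·P`) and
from collateral inflammation (`k_dp·P`) and resolves at `mu_d`. `A` has a
therapy/source term `s_a`, induction by `P` and `D`, and decay `mu_a`.
Every production group is inhibited by the anti-inflammatory state
through the shared factor

    f(x) = x / (1 + (A / A_inf)²),

so `f` halves production at `A = A_inf`. Clearance and decay terms are
not inhibited. Applying one factor per equation's production sum (rather
than per term) is the minimal consistent reading of "all inhibition
functions equal"; the whole algebraic form sits behind the single `rhs`
function and is tagged `EQUATION_VERSION` in outputs, so an alternative
reading can be swapped in and traced.

Model units are generic (`I`-units, `P`-units, …) because each variable
aggregates heterogeneous species. The package maps them 1:1 onto the
clinical observables — `P`-units ≡ measured uMCP-1 units, `D`-units ≡
uP:C units — which is what lets initial conditions and fits anchor
directly to the measurements.

## Therapy as piecewise-constant forcing

Therapy changes are represented as piecewise-constant values of
(`s_i`, `s_id`, `s_a`) over intervals of the flare cycle. The default
timeline uses 1 month = 30 days and 1 week = 7 days, giving breakpoints
(−180, −120, −60, −14, 0, +14, +42, +60, +120) days with the flare at 0 —
eight intervals spanning the 10-month cycle. Intervals are right-open
(`[t_k, t_{k+1})`): a lookup exactly at a breakpoint returns the
*following* interval's levels, so dose changes take effect at their start
time; the final breakpoint belongs to the last interval. Piecewise
constancy is a computational simplification — the underlying dosing is
smoother — so simulated kinks at breakpoints are artefacts of the
parameterisation, not predictions.

The four bundled fixtures carry the calibrated rates and schedules for
study patients 416, 444, 448 and 491. `mu_a`, `A_inf` and `k_id` are
identical across patients (2.2/day, 0.45 A-units, 1 D-unit) but stored
per patient to preserve the table structure; `mu_a` comes from a 7.5-hour
anti-inflammatory half-life (0.3125 days, ln 2 / 0.3125 ≈ 2.2/day) rather
than from fitting. `k_dip` equals `k_ip` in every fixture but is kept as
a distinct parameter: the two rates describe different processes
(damage per phagocytosis event vs. clearance) that happen to share a
value.

## Numerics

Integration is adaptive (LSODA, rtol 1e-8, atol 1e-10 by default) and
restarts at every breakpoint, so a parameter discontinuity never sits
inside a solver step; the state is carried continuously across
breakpoints — parameters jump, states do not. The output grid defaults to
0.5-day spacing plus all breakpoints. Negative undershoot within
10·atol of zero is clipped to zero with a logged warning; anything larger
raises, since the nonnegative orthant is forward-invariant for the exact
flow (every production term vanishes or is nonnegative on the orthant
faces) and a real excursion signals an integration failure or invalid
parameters. The test suite cross-checks the solver against an
independently coded fixed-step RK4 (h = 0.01 day) at 1e-5 relative
sup-norm on all four fixtures; observed agreement is ~3e-8.

## Calibration

Fitting minimises the sum of squared residuals between simulated (P, D)
sampled at the visit times and the observed (uMCP-1, uP:C) series.
Choices the study conditions leave open, fixed here as package defaults:

- **Weights.** Residuals of each observable are divided by its baseline
  (mean of the two remote out-of-flare measurements) or, absent a
  baseline, by the series mean, so the two biomarkers contribute
  comparably despite different scales.
- **Optimizer.** Bounded trust-region-reflective least squares
  (`scipy.optimize.least_squares`) with multistart: the base values plus
  `multistart − 1` uniform draws over the bounds from a fixed seed
  (default 20 starts). The original curve fits used a proprietary tool
  whose algorithm is not reproduced; any competent bounded NLS finds the
  same optima on this smooth, low-dimensional problem.
- **Initial conditions.** `P0`, `D0` from the first visit's observations;
  `I0 = A0 = 0.1` (pre-existing disease activity); all overridable.
- **Free parameters.** Any kinetic rate by name, or a single therapy
  level on one interval (`"s_a@3"`).

Sparse bimonthly data (12 observations over 10 months) cannot identify
many parameters jointly. `profile_parameter` re-fits the remaining free
parameters along a grid of one parameter's values; a flat SSR profile
(max/min ratio ≈ 1) flags structural redundancy — for example `s_i` vs
`s_id` when damage sits far above the Hill half-saturation, where only
their sum matters.

## Synthetic patients

The generator emulates the study's sampling design: visits every two
months at (−180, −120, −60, 0, +60, +120) days, multiplicative lognormal
observation noise `obs = truth·exp(ε)`, `ε ~ N(0, σ²)` with σ = 0.15 per
observable by default, optional missingness, and baselines taken from the
truth trajectory at the schedule start. Lognormal noise was chosen
because both biomarkers are nonnegative concentration-like ratios with
roughly scale-proportional assay error; the real inter-visit variability
and assay noise are unpublished, so σ is a convention, not an estimate.
Cohorts jitter the truth parameters lognormally around a base patient
with per-patient sub-seeds derived from one master seed.

What the generator does *not* emulate: real visit-date irregularity,
serum complement (C3/C4) observables, therapy-record text, and any
between-flare long-term dynamics. Passing recovery tests on these
synthetic series therefore demonstrates that the calibration machinery is
correct and well-seeded, not that the model is identifiable from any
particular clinical data set.

## Scenario semantics

A scenario is a list of edits: therapy edits override (`s_i`, `s_id`,
`s_a`) on `[t_from, t_until)` — splitting intervals when the edit
boundaries fall inside one — and rate overrides replace a global kinetic
constant. Metrics (peaks with times, values at flare and at cycle end,
trapezoid area above baseline) are computed on a grid shared with the
unedited baseline so scenarios are directly comparable.

One behavioural subtlety found while testing: a *sustained* increase of
`s_a` (from any start time through the end of the cycle) never raises the
peak P or D on any fixture, but a boost confined to an isolated pre-flare
interval can raise the later peak. The mechanism is in the equations:
suppressing P also suppresses immune-complex clearance (`k_ip·I·P`), so
complexes accumulate during the boost and drive a stronger flare once it
lapses. The monotonicity property tested is therefore the sustained
version, which is also the form of every published intervention
simulated here.

## Problem sizes

Default analyses integrate the 10-month cycle on a 601-point grid (~20 ms
per run); fitting uses 20 multistarts over 2 free parameters against 12
observations (~15 s); the RK4 cross-check uses 30 000 fixed steps per
patient. Monte-Carlo checks of the noise model use 1000 single-visit
replicates and 500-patient cohorts.

## Known limitations

- The equation set is a documented reconstruction (see `EQUATION_VERSION`);
  variant readings (e.g. inhibition applied per term, or `k_ip·I`
  clearance) would change fitted values.
- Whether `A_inf` is best read as a half-inhibition scale is a modelling
  convention here.
- No drug pharmacokinetics: therapy maps directly onto source rates.
- No formal identifiability analysis beyond SSR profiles, and no
  hierarchical multi-patient fitting.
- Trajectory-level agreement, not per-interval parameter recovery, is the
  honest target when fitting per-interval therapy levels to bimonthly
  data: sparse sampling underdetermines individual interval values.
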