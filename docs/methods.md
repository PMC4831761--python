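# Methods

## Model representation and compilation

A process-based model is a set of entity instances and processes
instantiated from library templates. Only ordinary differential
contributions (`td(target) = expression`) are supported; each endogenous
variable's derivative is the sum of all contributions targeting it (the
`sum` aggregation — the only one implemented), and a variable with no
contribution has derivative zero. Expressions are limited to `+ - * /`,
unary minus, parentheses, decimal literals, process constants and dotted
`role.variable` references; there are no functions. Units are opaque
strings and never checked.

Two notational conventions from the predator–prey library are honored
as written:

* `LogisticGrowth` is evaluated exactly as printed, `gR·d / (1 − d/gR)`,
  reusing `gR` as both rate and capacity and *dividing* by the saturation
  term. This body has a pole at `d = gR`; parameter vectors that drive a
  trajectory into the pole produce a failed simulation, which downstream
  code scores as a worst-case fit.
* In the two-role interaction templates the equations are written with the
  shorthand target `td(pop.d)` although the declared roles are `pop1`,
  `pop2`. Targets naming an undeclared role are resolved positionally: the
  i-th such equation feeds the i-th declared role. For `UnsaturatedPP` /
  `SaturatedPP` the first (efficiency-weighted, positive) equation
  therefore feeds `pop1` — the predator — and the second (negative) feeds
  `pop2`, the prey, which is the only reading consistent with the worked
  predator–prey model.

Role and constant declarations are inherited down the process hierarchy
(`ExponentialGrowth : Growth` sees `pop` and `gR`). Parameter vectors are
ordered by slot declaration order, then constant declaration order, with
qualified names `slot.constant`; this ordering is part of the public
contract so that fits are reproducible.

## Library samples

For each open choice template (an unresolved slot's template with its leaf
alternatives) a sample retains a non-empty subset *S* of alternatives. The
sampling law is size-proportional: P(sample) ∝ |L_S|, the number of
candidate structures the sampled library induces. Per template this means
P(S) ∝ |S| raised to the number of slots bound to that template, drawn as
an exact categorical over the 2^m − 1 subsets (m is small — it is a count
of modeling alternatives, not of data). The categorical draw generalizes
the "anchor leaf plus independent coin flips" construction, which matches
it only when a template serves a single slot. Probabilities are normalized
over achievable samples; for the worked predator–prey space this yields
nine samples with probabilities 1/4, 1/8 (×4) and 1/16 (×4).

## Simulation

`simulate` integrates the compiled system at absolute and relative
tolerances 10⁻³ (configurable) and reports values exactly at the dataset's
time points. The default solver is DOP853; at these tolerances it keeps a
pure exponential decay within 7·10⁻³ of the closed form and the
Lotka–Volterra first integral within 10⁻³ over twenty days, and it costs
2–4 ms per year-length trajectory. The stiff-capable LSODA and Radau are
selectable (`method=`); they are respectively less accurate at the same
tolerance (decay error 0.04) and an order of magnitude slower. Exogenous
variables are interpolated (cubic spline by default, linear selectable)
with query times clamped to the observed span to guard solver overshoot.
Initial state defaults to the first finite endogenous observation.

Robustness choices: a trajectory is failed (and scored +∞ by callers)
when the solver reports failure, any value is non-finite, |y| exceeds 10⁸
(a terminal event), or the right-hand side has been evaluated more than
20,000 times in one simulation. The last guard exists because pole-bearing
candidates (the as-written logistic) can otherwise make any variable-step
solver crawl indefinitely at collapsing step sizes.

## Parameter estimation

Differential evolution, strategy rand/1/bin: population 50 (independent of
dimension), F = 0.6, Cr = 0.6, budget of 1000 objective evaluations per
free parameter, where one objective evaluation is one simulation. Initial
population uniform over the declared ranges from the seeded generator;
mutants are clipped to the box; binomial crossover forces one coordinate;
ties are accepted (trial replaces incumbent when not worse). A structure
with no free parameters is simulated once. The implementation is
hand-rolled so the population size, evaluation accounting and clipping
behavior are exactly as stated; scipy's DE (which scales its population
with dimension and repairs bounds by resampling) serves as an independent
cross-check in the test suite, not as the implementation.

On smooth low-dimensional objectives (the one-parameter decay recovery)
this reliably reaches the global optimum: the recovered rate is within
10⁻² of the truth, and matches scipy's optimizer to 5·10⁻³. On 4–5
parameter oscillatory predator–prey trajectories with full Table-range
boxes, the RMSE landscape is a wide plateau with a narrow funnel, and
*no* plain DE (ours or scipy's) finds the funnel reliably within the
stated budget — relative parameter errors of 5–30% remain common. This is
a genuine property of global trajectory fitting, visible in the real-data
behavior of single process-based models (occasionally enormous test
errors); it is why quantitative parameter-recovery guarantees in the test
suite are stated on the decay scenario, and why structure-identification
checks use the aquatic scenario below.

## Ensembles

Confidence of a fitted model on a dataset (Algorithm-2 style): per-point
squared discrepancies normalized by the largest one, averaged over the
points — the printed sum is divided by the number of points, otherwise the
average loss could exceed 1 and β = L̄/(1 − L̄) would go negative — and
mapped to β. A perfect fit defines β = 0 (floored at 10⁻⁹ when used in a
weight); a failed simulation gets β = 10⁹, which is also the cap as
L̄ → 1. β is computed on the same set used for constituent selection.

Weighted combining uses w = ln(1/β), the regression-boosting convention,
floored at 0 so that constituents with β ≥ 1 (worse than the
maximum-discrepancy baseline) get no weight; all-zero weight vectors are
an error. With non-negative weights every combined prediction lies within
the constituents' envelope at every time point. The weighted median is the
smallest value whose cumulative weight reaches half the total; the plain
median of an even count is the average of the middle two.

Library sampling loops: sample → enumerate the sampled space → fit every
structure on the training set → rank on the selection set (validation by
default, the training set when no validation set is given) → add the best
with its β. With duplicates allowed the loop runs exactly k times
(default k = 10, average combining — the configuration found best in the
original design-choice experiments); without duplicates it runs until k
distinct constituents (same structure and parameter vectors equal to
relative 10⁻⁹ count as duplicates) and fails after 50·k iterations. The
fast variant fits each structure of the full library once, with the DE
seed derived deterministically from the structure's identity (CRC32 of the
base seed and the slot→leaf assignment), and is therefore exactly
equivalent to the naive loop — a property the suite verifies
constituent-by-constituent.

Bagging (default k = 25) draws bootstrap replicates of the training time
points and fits with multiplicity-weighted RMSE; replicates with fewer
than two distinct points are redrawn. Boosting (default k = 25) maintains
a distribution over training points, fits with distribution-weighted RMSE,
computes per-point losses normalized by the worst one, stops early when
the average loss reaches 0.5 (warning plus a single constituent if that
happens immediately), and reweights by β^(1−loss) renormalized. Reweights
drive full refitting of every structure, not mere re-ranking.

## Evaluation

ReRMSE uses the observed-variance denominator Σ(yₜ − ȳ)², following the
definition of relativity to the test variable's variability; this is the
form under which the mean predictor scores exactly 1 and the measure is
invariant under common affine maps. The printed-formula variant with
Σ(ȳ − ŷₜ)² is available behind `printed_variant=True`. Ranks are
ascending with ties averaged. The Friedman statistic is computed from
average ranks, corrected to an F statistic with (k−1, (k−1)(N−1)) degrees
of freedom; critical distances use q-values computed at runtime from the
studentized-range distribution (Nemenyi, q_α = ppf(1−α; k, ∞)/√2) or the
Bonferroni-corrected normal quantile (Bonferroni–Dunn), which reproduce
the published constants (k = 4, α = 0.05: 2.569 and 2.394).

## Synthetic data

The generator simulates a known ground-truth structure, adds observation
noise (Gaussian, σ expressed as a fraction of the trajectory's standard
deviation; no process noise), and emits contiguous, time-ordered
train/validation/test splits. Two scenario families:

* **Predator–prey**: truth ExponentialGrowth + UnsaturatedPP with
  gR = 0.8, iR = 0.4, eF = 0.5, dR = 0.6 (a stable cycle around prey 3,
  predator 2), both populations observed daily for 100 days, splits
  60/20/20. The logistic + saturated alternative suggested by the library
  cannot serve as a simulable truth: at mid-range parameters the printed
  logistic pole is reached in finite time for every initial condition
  (the predator's per-capita gain iR·eF·prey/(prey+sR) < dR can never
  balance the super-linear growth).
* **Aquatic**: one endogenous variable (phytoplankton biomass) with a
  four-candidate space — {UnlimitedGrowth, LimitedGrowth} ×
  {LinearLoss, TemperatureLoss} — driven by two smooth 365-day periodic
  forcings (temperature 12 ± 8 °C peaking in late July; normalized light
  0.575 ± 0.375 with a 0.2 winter floor that maintains the year-round
  residual biomass real lakes show). Truth is LimitedGrowth +
  TemperatureLoss (maxGrowth 0.8, capacity 40, lossRate 0.3), giving a
  summer bloom near 24 mg/l and a winter minimum near 0.2 mg/l, sampled
  daily over three simulated years: one year each for training,
  validation, and testing. Noisy observations are clipped to
  [0.05, 100] mg/l — a detection-limit convention; without it Gaussian
  noise makes winter observations negative, and a simulation initialized
  from a negative first observation diverges for these multiplicative
  dynamics.

What the generator does *not* emulate: irregular monthly sampling with
spline interpolation artifacts, inter-annual forcing variability,
multiple interacting nutrient limitations, and non-Gaussian measurement
error. Passing tests therefore demonstrate the machinery's correctness
and the ensembles' behavior under controlled conditions, not field
performance.

## Benchmark and test-scale choices

The end-to-end benchmark runs 10 seeded aquatic scenarios. Per scenario
the full 4-candidate space is fitted once (population 20, 60 evaluations
per parameter — structures here have at most 3 parameters and smooth
objectives, so this reduced budget reaches workable fits at a fraction of
the cost), the single model is the best candidate by validation error,
and the k = 10 library-sampling ensemble (duplicates allowed, average
combining) is served from the same fitted pool. The headline comparison
is the median over scenarios of the ensemble's test ReRMSE against the
median over scenarios of the *median-performing* candidate's test ReRMSE
— the ensemble-vs-typical-single-model contrast; the best-on-validation
single model is also reported. Structure identification under 5% noise is
checked on the same aquatic space (the truth wins validation in ≥ 8 of 10
seeded repetitions at the reduced budget); the predator–prey space is
unsuitable for that check at any affordable budget, both because its
oscillatory objective defeats the optimizer (above) and because its
unsaturated truth is nested inside the saturated alternative (sR = 0), so
converged fits tie.

## Known limitations

* One aggregation (`sum`), differential contributions only; no algebraic
  equations, optional processes, or cardinality constraints.
* Multi-variable errors average per-variable errors — a neutral extension
  beyond the single-variable setting the error measures were defined for.
* Plain rand/1/bin DE is the only optimizer; on wide-range multi-modal
  trajectory objectives it finds workable but not optimal fits.
* The without-duplicates sampler can fail by construction when the model
  space holds fewer than k distinct constituents; the 50·k guard turns
  the unbounded loop into an explicit error.
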