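# Methods

## Model

One *unit* (an RNA or protein species) is a pool of molecules indexed by
age x ∈ {0, …, n}. Each discrete step the age-x cohort survives into age
x+1 with fraction d_x ∈ [0, 1]; molecules reaching the maximum age are
removed entirely (implicitly d_n = 0), so the lifespan is n steps. Total
abundance TB is the sum over ages; total activity TA weights each age by a
non-negative coefficient a_x. Production is pulsed: a fixed nascent amount
B0 enters at age 0 in any step whose demand for activity DA exceeds the
pool's activity. The dynamics are deterministic; abundances are real
valued throughout (no rounding during simulation — the reference age
ladder 100, 90, 72, 50, 31, 15, 6 contains printed-rounding artefacts such
as 72 × 0.694̄ = 50.0, which exact arithmetic reproduces only because the
survival fractions are defined as the ladder ratios themselves).

### Gating-time semantics

The recursion leaves open whether the trigger compares demand against
activity before or after the aging of step t. The package gates on the
*previous step's reported activity*: a pulse fires at step t iff
TA[t−1] < DA[t] (strict inequality; equality suppresses production), and
the pulse is included in the reported TB[t]/TA[t]. This ordering
reproduces the reference cycle length of 5 ages at demand 50 with the
type-B ladder; gating on the post-aging activity instead shortens that
cycle to 4 and is available as `gate="aged"` for comparison.

### Shape families

Survival and activity coefficients follow four age-shape families:
constant (A), decreasing (B), parabolic/unimodal (C — e.g. a maturation
period before peak activity), increasing (D). The default type-B survival
is not smooth: it is the exact ratio sequence of the reference age ladder
(0.9, 0.8, 50/72, 0.62, 15/31, 0.4, then 0), chosen so the package is
self-contained and reproduces the ladder and the published cycle lengths
without external parameter tables. Consequences: the measured oscillation
amplitudes at demands 50 and 80 are 84 and 94 units, within the ±2-unit
band expected of the reconstruction (reference values 85 and 96). The
generic family generators (linear ramps, parabola through anchored
endpoints) are for exploration; their anchor values are free parameters.

### Coupled units

In the two-unit RNA→protein model the protein faces the external demand
DPA; the deficit max(0, DPA − TPA), scaled by a coupling gain (default 1,
raw passthrough), becomes the demand for RNA activity. All gating reads
previous-step quantities, so within a step the update order (RNA then
protein) cannot create simultaneity artefacts. Protein pulses additionally
require previous-step RNA activity > 0 — translation needs a template —
with the pulse magnitude a constant nascent amount per step (an
RNA-proportional variant, pulse = min(T_p0, β·TRA), is provided as an
option). Default nascent amounts are 100 (RNA) and 48 (protein) units per
step; these are the peak per-step rates the model attains when demand is
unattainable, and were chosen to match the published peak transcription
and translation rates since the full two-unit parameter table is not
shipped with the package. Exact demand thresholds separating the
cycling/stable regime pairs therefore differ from the published figures;
the regime *classifier* (cycling vs stable per unit) is exercised on
configurations where each regime is forced by construction.

The n-unit generalisation is a chain or DAG web: units without successors
face the top-level demand; every other unit's demand is the sum of its
successors' deficits weighted by edge gains, evaluated successors-first
(cyclic topologies are rejected). A 1-unit chain is bit-identical to the
core simulator, a 2-unit chain to the two-unit model.

## Cycle analysis

Because the dynamics are deterministic with quantized pulses, every run
under an eventually-periodic demand schedule converges to a fixed point or
an exact periodic orbit. Periods are therefore detected by exact
recurrence of the full age vector (quantized at 1e−9), jointly with the
demand value so that schedule phase is respected — never by spectral
estimation, which would be biased on short series. A period is accepted
only if the periodic tail spans at least three full periods before the
horizon; shorter evidence is reported as inconclusive rather than guessed.
The amplitude is max − min of TB over one steady period. For square-wave
demand schedules the report also carries sub-cycles: the analysis window
is anchored at a demand switch and each dwell phase is scanned for an
internal short cycle (two repeats required, the dwell being finite).
Decimating a trajectory every k steps emulates sparse experimental
sampling; on an exact period-p orbit the apparent period of the decimated
series is p / gcd(p, k) — in particular sampling at the true period
aliases the oscillation to a flat line.

## Labelling design

Group g of the staggered design switches to labelled media g steps before
the common harvest, so its labelled pool is the partial sum of the age
vector over ages 0..g at harvest; labelling is perfect cohort marking and
does not perturb the dynamics. Differencing adjacent groups inverts the
partial sums exactly — the inference reproduces the simulator's internal
age vector to machine precision for any profile, schedule and design (ages
older than the oldest group are not covered by any label and are not
recovered). Optional multiplicative Gaussian measurement noise (seeded,
off by default) can make inferred levels negative; they are reported raw
with a warning, with clamping to zero available, since negative
differences are themselves a useful noise diagnostic.

## Fitting

The estimator is a pure exhaustive search: every grid point is simulated
and the minimum sum of squared errors against the observations selected.
No gradients, no stochasticity — identical inputs give identical results.

* **Ages.** Five ages (0..4): the lifespan divides into four aging
  periods, so one model step is lifespan/4 on the wall clock. Survival is
  estimated for the three transitions into ages 1–3; the terminal
  transition is fixed at 0. Activity is fixed at 1 per age, making TA = TB.
* **Alignment.** Observations are compared at the nearest model step;
  exact when the sampling interval is an integer multiple or divisor of
  the step, otherwise a warning is raised. Several observations may share
  a step when sampling is denser than the step.
* **Grids.** Defaults are data-driven: survival 0, 0.1, …, 1 per age;
  pulse levels spanning 0.1–1.5× the series maximum in 20 steps, refined
  to 0.1-unit resolution around the first-pass optimum (estimates are
  conventionally reported at that precision); demands from max(0,
  min(obs)) to 1.5× max(obs) in 20 steps; lifespans at multiples of the
  sampling interval between the organism lower bound (10 min for yeast,
  2 h for mammalian cells, in the series' own time unit) and the series
  duration; initial age distribution over all {0, pulse}-per-age patterns,
  since the pre-experiment pool is among the unknowns. The full default
  product is deliberately guarded by an evaluation budget
  (`max_evaluations`, default 2×10⁶) that errors with the grid cardinality
  rather than run unbounded; practical fits restrict grids, as the tests
  and examples do.
* **Ties.** Exact SSE ties are resolved deterministically by enumeration
  order: shorter lifespan, then smaller pulse, then larger survival rates,
  then smaller demand, then the initial-pattern order. Ties are real —
  demand is identified only up to the gap between reachable activity
  levels, a threshold-identifiability limit inherent to gated production.
* **Windowed demand.** For irregularly fluctuating series, each
  consecutive block of ≥ 4 observations is first fitted alone retaining
  only its demand; the remaining parameters are then re-fitted globally
  with the per-window demands fixed (mapped to steps by which observation
  a step precedes). The final window absorbs any remainder shorter than a
  block.
* **Diagnostics.** R² = 1 − SS_res/SS_tot (undefined, and reported as
  null, for constant observations) and MdAPE, the median of |obs −
  pred|/|obs| with near-zero observations (|obs| < 1e−9, possible for
  baseline-subtracted data) dropped from the median and their count
  logged. Accumulated transcription and degradation are read off the
  winning trajectory; net rates divide them by the experiment duration.
  Conservation (ΔTB = produced − degraded each step) holds for the fitted
  trajectory by construction.

The batch engine simulates all candidates of a chunk (≤ 200 000) in
lock-step with vectorized array operations, which keeps even 10⁵–10⁶-point
grids in the seconds range.

## Synthetic data

The generator runs the simulator at known parameters, decimates the total
abundance at a chosen interval, and perturbs it with seeded noise —
additive Gaussian with σ expressed as a fraction of the series mean by
default, since the emulated measurements are normalized fold changes on an
arbitrary scale (multiplicative noise is available). It emulates the
*structure* of single-cell time courses (uniform sampling, baseline-scale
fluctuations, a known demand regime) but not instrument-specific effects
(photon statistics, bleaching) or biological confounders (cell cycle,
extrinsic noise); passing recovery tests therefore demonstrates
correctness of the inversion machinery, not robustness to real-data
artefacts. Reference-scale test series are generated at the published
parameter estimates (e.g. a 20-minute lifespan, 1.4-unit pulses, survival
0.9/0.9/0.5 sampled every 5 minutes for 70 minutes) and are synthetic
stand-ins: the original digitized experimental tables are not
redistributed with the package.

## Problem sizes and determinism

Test and acceptance runs use horizons of 60–400 steps, grids of 10²–10³
candidates (10⁴ × 100 seeds for the noisy-recovery study), and 1000+
randomized property cases — all desk-scale, completing in seconds on one
core. All randomness (noise, property-test instances) flows through seeded
`numpy` generators; the simulators themselves are deterministic.

## Known limitations

* Discrete time only; no continuous-time or stochastic-kinetics variant.
* Survival/activity profiles are per-age lookup tables; no parametric
  hazard models.
* The exhaustive search returns point estimates with no uncertainty
  quantification; resolution is bounded by the grids.
* Demand is identified only up to gating-equivalence classes (see Ties).
* The two-unit default parameters are a reconstruction from published
  peak rates, not a shipped parameter table.
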