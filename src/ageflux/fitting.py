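"""Exhaustive-search estimation of RNA metabolic parameters.

Given a time series of RNA abundance in one cell, every candidate parameter
combination on a finite grid — lifespan, per-age survival rates, pulse
level, demand, and initial age distribution — is simulated forward and the
combination minimizing the sum of squared errors against the observations
is selected (minimum-square selection over an exhaustive grid).  Activity
coefficients are fixed at 1, so total activity equals total abundance and
the demand for activity is a demand for RNA level.

The fitted model uses five RNA ages (0..4): the lifespan is divided into
four aging periods, so one model step spans ``lifespan / 4`` wall-clock
units, and molecules do not survive past age 3 (the terminal survival
fraction is 0).  Survival at ages beyond the observable window would be
unidentifiable anyway.

Two scenarios are supported: a single stable demand over the whole series,
or a *windowed* mode for irregularly fluctuating series, where each
consecutive block of >= 4 observations is first fitted on its own keeping
only the demand estimate, and the remaining parameters are then re-fitted
globally with the per-window demands held fixed.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (AgeProfile, ConstantDemand, ExplicitDemand, PulsePolicy,
                   Trajectory, UnitState, simulate)
from .errors import BudgetExceededError, ValidationError

logger = logging.getLogger(__name__)

#: Lifespan lower bounds by organism class, in minutes.
LIFESPAN_LOWER_BOUND_MIN = {"yeast": 10.0, "mammalian": 120.0, "other": 0.0}

_TIME_UNIT_MINUTES = {"min": 1.0, "h": 60.0}


# ---------------------------------------------------------------------------
# observed data
# ---------------------------------------------------------------------------

@dataclass
class ObservedSeries:
    """A (time, level) abundance series from one cell.

    Levels may be baseline-subtracted and hence non-positive.  Times must
    be strictly increasing and (near-)uniformly spaced; the organism class
    sets the lifespan lower bound used by the default fitting grids.
    """

    times: np.ndarray
    levels: np.ndarray
    organism_class: str = "other"
    time_unit: str = "min"
    units_note: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.levels.size:
            raise ValidationError("times and levels must be equal-length 1-D")
        if self.times.size < 4:
            raise ValidationError("need at least 4 observations")
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise ValidationError(f"times not strictly increasing at row {row}")
        if np.any(np.abs(diffs - diffs[0]) > 1e-6 * abs(diffs[0])):
            raise ValidationError("observation times must be uniformly spaced")
        if self.organism_class not in LIFESPAN_LOWER_BOUND_MIN:
            raise ValidationError(
                f"organism_class must be one of {sorted(LIFESPAN_LOWER_BOUND_MIN)}")
        if self.time_unit not in _TIME_UNIT_MINUTES:
            raise ValidationError(f"time_unit must be one of {sorted(_TIME_UNIT_MINUTES)}")

    @property
    def spacing(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)

    def lifespan_lower_bound(self) -> float:
        """Organism lifespan lower bound expressed in this series' unit."""
        minutes = LIFESPAN_LOWER_BOUND_MIN[self.organism_class]
        return minutes / _TIME_UNIT_MINUTES[self.time_unit]


# ---------------------------------------------------------------------------
# fit diagnostics
# ---------------------------------------------------------------------------

def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValidationError("need equal-length 1-D series of length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValidationError("total variation is zero; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def mdape(observed: Sequence[float], predicted: Sequence[float],
          eps: float = 1e-9) -> float:
    """Median absolute percentage error, median |obs - pred| / |obs|.

    Points with |obs| < eps (possible for baseline-subtracted data) are
    dropped from the median; the dropped count is logged.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 1:
        raise ValidationError("need equal-length 1-D series")
    keep = np.abs(obs) >= eps
    dropped = int(np.count_nonzero(~keep))
    if dropped:
        logger.info("MdAPE: dropped %d near-zero observations", dropped)
    if not keep.any():
        raise ValidationError("all observed values are (near) zero; "
                              "MdAPE undefined")
    return float(np.median(np.abs(obs[keep] - pred[keep]) / np.abs(obs[keep])))


# ---------------------------------------------------------------------------
# grid specification
# ---------------------------------------------------------------------------

@dataclass
class FitSpec:
    """Grids and options for the exhaustive search.

    Unset grids are resolved from the data: pulse levels span 0.1-1.5x
    the series maximum in 20 steps (refined to 0.1-unit resolution around
    the first-pass optimum), demands span max(0, min(obs))-1.5x max(obs)
    in 20 steps, survival rates run over 0, 0.1, ..., 1 per free age, the
    lifespan candidates are multiples of the sampling interval between the
    organism lower bound and the series duration, and the initial age
    distribution is either empty or one pulse-level per age (all binary
    patterns).  ``max_evaluations`` bounds the total grid cardinality.
    """

    n_ages: int = 5
    lifespans: Optional[Sequence[float]] = None
    survival_grids: Optional[Sequence[Sequence[float]]] = None
    terminal_survival: float = 0.0
    pulse_grid: Optional[Sequence[float]] = None
    refine_pulse: bool = True
    pulse_resolution: float = 0.1
    demand_grid: Optional[Sequence[float]] = None
    initial_patterns: Optional[np.ndarray] = None
    scenario: str = "stable_demand"
    window_size: int = 4
    gate: str = "previous"
    max_evaluations: int = 2_000_000

    def __post_init__(self):
        if self.n_ages < 2:
            raise ValidationError("n_ages must be >= 2")
        if self.scenario not in ("stable_demand", "windowed_demand"):
            raise ValidationError(
                "scenario must be stable_demand or windowed_demand")
        if self.window_size < 4:
            raise ValidationError("window_size must be >= 4")
        if not 0.0 <= self.terminal_survival <= 1.0:
            raise ValidationError("terminal_survival must be in [0, 1]")

    @property
    def max_age(self) -> int:
        return self.n_ages - 1

    @property
    def n_free_survival(self) -> int:
        return self.max_age - 1

    # ---- grid resolution against a concrete series ----

    def resolved_lifespans(self, series: ObservedSeries) -> np.ndarray:
        if self.lifespans is not None:
            arr = np.asarray(self.lifespans, dtype=float)
        else:
            dt = series.spacing
            arr = np.arange(dt, series.duration + 0.5 * dt, dt)
        lo = series.lifespan_lower_bound()
        arr = arr[arr >= max(lo, 1e-12)]
        if arr.size == 0:
            raise ValidationError("no lifespan candidates above the organism "
                                  "lower bound")
        return np.sort(arr)

    def resolved_survival_combos(self) -> np.ndarray:
        grids = self.survival_grids
        if grids is None:
            grids = [np.round(np.arange(0.0, 1.0001, 0.1), 10)
                     for _ in range(self.n_free_survival)]
        if len(grids) != self.n_free_survival:
            raise ValidationError(
                f"need {self.n_free_survival} survival grids, got {len(grids)}")
        for g in grids:
            g = np.asarray(g, dtype=float)
            if np.any(g < 0) or np.any(g > 1):
                raise ValidationError("survival grid values must be in [0, 1]")
        # descending per age so that enumeration order prefers larger rates
        desc = [np.sort(np.asarray(g, dtype=float))[::-1] for g in grids]
        combos = np.array(list(itertools.product(*desc)), dtype=float)
        return combos

    def resolved_pulses(self, series: ObservedSeries) -> np.ndarray:
        if self.pulse_grid is not None:
            arr = np.asarray(self.pulse_grid, dtype=float)
        else:
            top = float(np.max(series.levels))
            if top <= 0:
                raise ValidationError("cannot derive a pulse grid from a "
                                      "series with no positive level")
            arr = np.linspace(0.1 * top, 1.5 * top, 20)
        if np.any(arr < 0):
            raise ValidationError("pulse levels must be >= 0")
        return np.sort(arr)

    def resolved_demands(self, series: ObservedSeries) -> np.ndarray:
        if self.demand_grid is not None:
            arr = np.asarray(self.demand_grid, dtype=float)
        else:
            top = float(np.max(series.levels))
            lo = max(0.0, float(np.min(series.levels)))
            arr = np.linspace(lo, 1.5 * top, 20)
        if np.any(arr < 0):
            raise ValidationError("demand levels must be >= 0")
        return np.sort(arr)

    def resolved_patterns(self) -> np.ndarray:
        if self.initial_patterns is not None:
            pat = np.asarray(self.initial_patterns, dtype=float)
            if pat.ndim != 2 or pat.shape[1] != self.n_ages:
                raise ValidationError(
                    f"initial_patterns must be (K, {self.n_ages})")
            return pat
        return np.array(list(itertools.product((0.0, 1.0),
                                               repeat=self.n_ages)))


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Selected grid point with metabolic quantities and diagnostics."""

    lifespan: float
    step_length: float
    pulse_level: float
    survival_rates: Tuple[float, ...]  # free ages 1..max_age-1
    demand: Union[float, List[float]]
    initial_age_distribution: Tuple[float, ...]
    accumulated_transcription: float
    accumulated_degradation: float
    net_transcription_rate: float
    net_degradation_rate: float
    r_squared: Optional[float]
    mdape: Optional[float]
    sse: float
    fitted_times: np.ndarray
    fitted_levels: np.ndarray
    n_evaluations: int
    window_bounds: Optional[List[Tuple[int, int]]] = None
    trajectory: Optional[Trajectory] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "lifespan": self.lifespan,
            "step_length": self.step_length,
            "pulse_level": self.pulse_level,
            "survival_rates": list(self.survival_rates),
            "demand": self.demand,
            "initial_age_distribution": list(self.initial_age_distribution),
            "accumulated_transcription": self.accumulated_transcription,
            "accumulated_degradation": self.accumulated_degradation,
            "net_transcription_rate": self.net_transcription_rate,
            "net_degradation_rate": self.net_degradation_rate,
            "r_squared": self.r_squared,
            "mdape": self.mdape,
            "sse": self.sse,
            "fitted_times": self.fitted_times.tolist(),
            "fitted_levels": self.fitted_levels.tolist(),
            "n_evaluations": self.n_evaluations,
            "window_bounds": self.window_bounds,
        }


# ---------------------------------------------------------------------------
# vectorized grid engine
# ---------------------------------------------------------------------------

_CHUNK = 200_000


def _observation_steps(series: ObservedSeries, step_length: float
                       ) -> np.ndarray:
    rel = (series.times - series.times[0]) / step_length
    steps = np.rint(rel).astype(int)
    if np.max(np.abs(rel - steps)) > 1e-9:
        warnings.warn(
            f"sampling interval is not an integer multiple/divisor of the "
            f"model step ({step_length:g}); using nearest-step alignment",
            stacklevel=3)
    return steps


def _batch_sse(obs: np.ndarray, obs_steps: np.ndarray,
               survivals: np.ndarray, pulses: np.ndarray,
               demands: np.ndarray, inits: np.ndarray,
               gate: str) -> np.ndarray:
    """SSE for a batch of candidates, simulated in lock-step.

    ``survivals`` (B, max_age) includes the terminal entry; ``demands`` is
    (B,) for a constant demand or (T+1, B) per-step; ``inits`` is (B,
    n_ages).  Activity is 1 everywhere, so TA == TB.
    """
    horizon = int(obs_steps[-1])
    state = inits.copy()
    ta = state.sum(axis=1)
    per_step = demands.ndim == 2
    n_obs = obs.size
    sse = np.zeros(state.shape[0])
    # several observations may share a step under nearest-step alignment
    obs_at: dict = {}
    for i, s in enumerate(obs_steps):
        obs_at.setdefault(int(s), []).append(i)
    hits = np.zeros((state.shape[0], n_obs))
    for i in obs_at.get(0, ()):
        hits[:, i] = ta
    for t in range(1, horizon + 1):
        aged = state[:, :-1] * survivals
        d_t = demands[t] if per_step else demands
        if gate == "previous":
            gate_ta = ta
        else:  # aged
            gate_ta = aged.sum(axis=1)
        state[:, 1:] = aged
        state[:, 0] = np.where(gate_ta < d_t, pulses, 0.0)
        ta = state.sum(axis=1)
        for i in obs_at.get(t, ()):
            hits[:, i] = ta
    np.sum((hits - obs[None, :]) ** 2, axis=1, out=sse)
    return sse


@dataclass
class _GridSearchOutcome:
    sse: float
    lifespan: float
    survival: np.ndarray
    pulse: float
    demand_idx: int
    pattern: np.ndarray
    n_evaluations: int


def _search(series: ObservedSeries, spec: FitSpec,
            lifespans: np.ndarray, combos: np.ndarray, pulses: np.ndarray,
            demands: np.ndarray,
            demand_steps_builder=None) -> _GridSearchOutcome:
    """Enumerate the full grid; first minimal SSE in preference order wins.

    The enumeration order implements the tie-break policy: shorter
    lifespan first, then smaller pulse level, then larger survival rates
    (the survival combos arrive in descending order), then smaller demand,
    then the initial-distribution pattern order.
    """
    patterns = spec.resolved_patterns()
    n_s, n_p, n_d, n_i = (combos.shape[0], pulses.size, demands.size,
                          patterns.shape[0])
    per_lifespan = n_s * n_p * n_d * n_i
    total = per_lifespan * lifespans.size
    if total > spec.max_evaluations:
        raise BudgetExceededError(total, spec.max_evaluations)
    logger.info("grid search: %d candidates (%d lifespans x %d)",
                total, lifespans.size, per_lifespan)

    obs = series.levels
    best: Optional[_GridSearchOutcome] = None
    shape = (n_p, n_s, n_d, n_i)  # preference order after lifespan
    for lifespan in lifespans:
        step_len = lifespan / spec.max_age
        obs_steps = _observation_steps(series, step_len)
        demand_steps = None
        if demand_steps_builder is not None:
            demand_steps = demand_steps_builder(obs_steps)  # (T+1,)
        for start in range(0, per_lifespan, _CHUNK):
            stop = min(start + _CHUNK, per_lifespan)
            flat = np.arange(start, stop)
            ip, is_, id_, ii = np.unravel_index(flat, shape)
            surv = np.empty((flat.size, spec.max_age))
            surv[:, :-1] = combos[is_]
            surv[:, -1] = spec.terminal_survival
            pulse = pulses[ip]
            init = patterns[ii] * pulse[:, None]
            if demand_steps is not None:
                dem = np.broadcast_to(demand_steps[:, None],
                                      (demand_steps.size, flat.size))
            else:
                dem = demands[id_]
            sse = _batch_sse(obs, obs_steps, surv, pulse, dem, init,
                             spec.gate)
            k = int(np.argmin(sse))
            if best is None or sse[k] < best.sse:
                best = _GridSearchOutcome(
                    sse=float(sse[k]), lifespan=float(lifespan),
                    survival=surv[k].copy(), pulse=float(pulse[k]),
                    demand_idx=int(id_[k]), pattern=patterns[ii[k]].copy(),
                    n_evaluations=total)
    assert best is not None
    return best


def _finalize(series: ObservedSeries, spec: FitSpec,
              outcome: _GridSearchOutcome,
              demand: Union[float, List[float]],
              demand_schedule, window_bounds=None) -> FitResult:
    """Re-simulate the winning candidate and assemble diagnostics."""
    step_len = outcome.lifespan / spec.max_age
    obs_steps = _observation_steps(series, step_len)
    horizon = max(int(obs_steps[-1]), 1)
    profile = AgeProfile(outcome.survival, np.ones(spec.n_ages))
    policy = PulsePolicy(outcome.pulse)
    init = UnitState(outcome.pattern * outcome.pulse)
    traj = simulate(profile, policy, demand_schedule, horizon, initial=init,
                    gate=spec.gate, step_length=step_len)
    fitted = traj.tb[obs_steps]
    try:
        r2 = r_squared(series.levels, fitted)
    except ValidationError:
        r2 = None
    try:
        err = mdape(series.levels, fitted)
    except ValidationError:
        err = None
    duration = series.duration if series.duration > 0 else np.nan
    acc_t = float(traj.acc_production[-1])
    acc_d = float(traj.acc_degradation[-1])
    return FitResult(
        lifespan=outcome.lifespan,
        step_length=step_len,
        pulse_level=outcome.pulse,
        survival_rates=tuple(float(v) for v in outcome.survival[:-1]),
        demand=demand,
        initial_age_distribution=tuple(outcome.pattern * outcome.pulse),
        accumulated_transcription=acc_t,
        accumulated_degradation=acc_d,
        net_transcription_rate=acc_t / duration,
        net_degradation_rate=acc_d / duration,
        r_squared=r2,
        mdape=err,
        sse=outcome.sse,
        fitted_times=series.times.copy(),
        fitted_levels=fitted,
        n_evaluations=outcome.n_evaluations,
        window_bounds=window_bounds,
        trajectory=traj,
    )


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def fit_exhaustive(series: ObservedSeries, spec: Optional[FitSpec] = None
                   ) -> FitResult:
    """Fit the stable-demand model by exhaustive grid search.

    Returns the grid point minimizing the SSE between the simulated total
    abundance (sampled at the observation times) and the observed levels.
    Deterministic: identical series and spec give identical results.
    """
    spec = spec or FitSpec()
    lifespans = spec.resolved_lifespans(series)
    combos = spec.resolved_survival_combos()
    pulses = spec.resolved_pulses(series)
    demands = spec.resolved_demands(series)

    outcome = _search(series, spec, lifespans, combos, pulses, demands)
    if spec.pulse_grid is None and spec.refine_pulse and pulses.size > 1:
        # second pass on resolution-aligned pulses around the first optimum
        res = spec.pulse_resolution
        width = float(pulses[1] - pulses[0])
        lo = max(res, outcome.pulse - width)
        hi = outcome.pulse + width
        k0 = int(np.ceil(lo / res - 1e-9))
        k1 = int(np.floor(hi / res + 1e-9))
        fine = np.round(np.arange(k0, k1 + 1) * res, 10)
        refined = _search(series, spec, lifespans, combos, fine, demands)
        if refined.sse <= outcome.sse:
            refined.n_evaluations += outcome.n_evaluations
            outcome = refined
    demand_level = float(demands[outcome.demand_idx])
    return _finalize(series, spec, outcome, demand_level,
                     ConstantDemand(demand_level))


def estimate_demand_windowed(series: ObservedSeries,
                             spec: Optional[FitSpec] = None
                             ) -> FitResult:
    """Two-stage fit for irregularly fluctuating series.

    Stage 1 fits each consecutive window of ``spec.window_size``
    observations independently, retaining only the demand estimates.
    Stage 2 re-fits lifespan, survival, pulse and initial distribution
    globally with the per-window demands held fixed.  The result carries
    the demand as a per-window list plus the window boundaries
    (observation-index ranges).
    """
    spec = spec or FitSpec(scenario="windowed_demand")
    w = spec.window_size
    n = len(series)
    if n < w:
        raise ValidationError(f"series shorter than one window ({w})")
    bounds: List[Tuple[int, int]] = []
    start = 0
    while n - start >= 2 * w:
        bounds.append((start, start + w))
        start += w
    bounds.append((start, n))  # last window absorbs the remainder

    window_demands: List[float] = []
    evals = 0
    for lo, hi in bounds:
        sub = ObservedSeries(series.times[lo:hi], series.levels[lo:hi],
                             organism_class=series.organism_class,
                             time_unit=series.time_unit)
        sub_fit = fit_exhaustive(sub, spec)
        window_demands.append(float(sub_fit.demand))
        evals += sub_fit.n_evaluations

    # stage 2: demands fixed, refit everything else on the full series
    lifespans = spec.resolved_lifespans(series)
    combos = spec.resolved_survival_combos()
    pulses = spec.resolved_pulses(series)
    window_of_obs = np.empty(n, dtype=int)
    for wi, (lo, hi) in enumerate(bounds):
        window_of_obs[lo:hi] = wi

    def builder(obs_steps: np.ndarray) -> np.ndarray:
        horizon = int(obs_steps[-1])
        per_step = np.empty(horizon + 1)
        # step t in (obs_steps[i-1], obs_steps[i]] takes obs i's window
        owner = np.searchsorted(obs_steps, np.arange(horizon + 1),
                                side="left")
        owner = np.clip(owner, 0, n - 1)
        per_step[:] = np.asarray(window_demands)[window_of_obs[owner]]
        return per_step

    outcome = _search(series, spec, lifespans, combos, pulses,
                      np.array([0.0]), demand_steps_builder=builder)
    outcome.n_evaluations += evals
    step_len = outcome.lifespan / spec.max_age
    per_step = builder(_observation_steps(series, step_len))
    return _finalize(series, spec, outcome, window_demands,
                     ExplicitDemand(per_step), window_bounds=bounds)


def metabolic_report(result: FitResult, duration: Optional[float] = None
                     ) -> dict:
    """Net metabolic rates from a fit, in observed units per wall-clock.

    Net rates are accumulated amounts divided by the experiment duration;
    the lifespan is already in wall-clock units (number of aging periods
    times the step length).
    """
    if duration is None:
        duration = float(result.fitted_times[-1] - result.fitted_times[0])
    if duration <= 0:
        raise ValidationError("duration must be positive")
    return {
        "lifespan": result.lifespan,
        "step_length": result.step_length,
        "pulse_level": result.pulse_level,
        "survival_rates": list(result.survival_rates),
        "demand": result.demand,
        "accumulated_transcription": result.accumulated_transcription,
        "accumulated_degradation": result.accumulated_degradation,
        "net_transcription_rate": result.accumulated_transcription / duration,
        "net_degradation_rate": result.accumulated_degradation / duration,
        "r_squared": result.r_squared,
        "mdape": result.mdape,
    }
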