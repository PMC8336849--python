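"""One-unit, discrete-time, age-structured biomolecule dynamics.

A cell holds a pool of molecules (RNAs or proteins) indexed by *age* — the
number of time steps since each molecule was produced.  At every step each
age-x cohort survives into age x+1 with a per-age survival fraction d_x
(molecules at the maximum age are fully degraded), and a production pulse of
fixed size B0 is injected at age 0 whenever the pool's total *activity*
(abundance weighted by per-age activity coefficients a_x) falls short of the
current demand for activity.  The recursion is

    B[x, t] = B[x-1, t-1] * d[x-1]          (aging with survival)
    B[0, t] = B0  if gated on, else 0       (pulse production)
    TB[t]   = sum_x B[x, t]                 (total abundance)
    TA[t]   = sum_x B[x, t] * a[x]          (total activity)

with production gated by ``TA[t-1] < DA[t]`` — the previous step's reported
activity against this step's demand (strict inequality; equality does not
trigger).  A variant that gates on the post-aging activity of the current
step is available via ``gate="aged"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

PULSE_MODES = ("demand_gated", "unregulated_continuous", "silent")
GATE_MODES = ("previous", "aged")


# ---------------------------------------------------------------------------
# profiles, policies, schedules
# ---------------------------------------------------------------------------

class AgeProfile:
    """Per-age survival and activity coefficients for one biomolecule unit.

    Parameters
    ----------
    survival
        d_0 .. d_{n-1}: fraction of the age-x cohort surviving into age
        x+1, each in [0, 1].  Molecules reaching the maximum age n are
        removed entirely (implicit d_n = 0), so ``len(survival)`` equals the
        maximum age n and the model carries n+1 ages, 0..n.
    activity
        a_0 .. a_n: activity contributed per unit abundance at each age;
        non-negative, length n+1.
    label
        Optional tag, conventionally one of the shape families A-D.
    """

    def __init__(self, survival: Sequence[float], activity: Sequence[float],
                 label: Optional[str] = None):
        survival = np.asarray(survival, dtype=float)
        activity = np.asarray(activity, dtype=float)
        if survival.ndim != 1 or survival.size < 1:
            raise ValidationError("survival must be a non-empty 1-D sequence")
        if np.any(survival < 0) or np.any(survival > 1):
            raise ValidationError("survival fractions must lie in [0, 1]")
        if activity.ndim != 1 or activity.size != survival.size + 1:
            raise ValidationError(
                f"activity must have length {survival.size + 1} "
                f"(one per age 0..{survival.size}), got {activity.size}"
            )
        if np.any(activity < 0):
            raise ValidationError("activity coefficients must be >= 0")
        self.survival = survival
        self.activity = activity
        self.label = label

    @property
    def max_age(self) -> int:
        return int(self.survival.size)

    @property
    def n_ages(self) -> int:
        """Number of ages carried, i.e. max_age + 1."""
        return int(self.survival.size + 1)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = f", label={self.label!r}" if self.label else ""
        return f"AgeProfile(max_age={self.max_age}{tag})"


@dataclass(frozen=True)
class PulsePolicy:
    """How production pulses are emitted.

    ``pulse_level`` is the abundance of nascent molecules per pulse (B0).
    ``mode`` is one of ``demand_gated`` (pulse only while total activity is
    below demand), ``unregulated_continuous`` (pulse every step) or
    ``silent`` (never pulse).
    """

    pulse_level: float
    mode: str = "demand_gated"

    def __post_init__(self):
        if self.pulse_level < 0:
            raise ValidationError("pulse_level must be >= 0")
        if self.mode not in PULSE_MODES:
            raise ValidationError(f"mode must be one of {PULSE_MODES}")


class DemandSchedule:
    """Maps a time index t to a non-negative demand-for-activity DA_t."""

    kind = "abstract"

    def __call__(self, t: int) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def describe(self) -> dict:
        return {"kind": self.kind}


class ConstantDemand(DemandSchedule):
    kind = "constant"

    def __init__(self, level: float):
        if level < 0:
            raise ValidationError("demand level must be >= 0")
        self.level = float(level)

    def __call__(self, t: int) -> float:
        return self.level

    def describe(self) -> dict:
        return {"kind": self.kind, "level": self.level}


class RotationDemand(DemandSchedule):
    """Square-wave alternation between two levels with fixed dwell times."""

    kind = "rotation"

    def __init__(self, levels: Sequence[float], dwells: Sequence[int],
                 offset: int = 0):
        levels = [float(v) for v in levels]
        dwells = [int(w) for w in dwells]
        if len(levels) != len(dwells) or len(levels) < 2:
            raise ValidationError("rotation needs >= 2 (level, dwell) pairs")
        if any(v < 0 for v in levels):
            raise ValidationError("demand levels must be >= 0")
        if any(w < 1 for w in dwells):
            raise ValidationError("dwell times must be >= 1")
        self.levels = levels
        self.dwells = dwells
        self.offset = int(offset)
        self._period = sum(dwells)
        bounds = np.cumsum(dwells)
        self._bounds = bounds

    @property
    def period(self) -> int:
        return self._period

    def __call__(self, t: int) -> float:
        phase = (t - self.offset) % self._period
        idx = int(np.searchsorted(self._bounds, phase, side="right"))
        return self.levels[idx]

    def describe(self) -> dict:
        return {"kind": self.kind, "levels": self.levels,
                "dwells": self.dwells, "offset": self.offset}


class LogisticDemand(DemandSchedule):
    """Logistic ramp DA_t = L / (1 + exp(c - r t))."""

    kind = "logistic"

    def __init__(self, limit: float = 400.0, c: float = 4.0, r: float = 0.2):
        if limit < 0:
            raise ValidationError("logistic limit must be >= 0")
        self.limit = float(limit)
        self.c = float(c)
        self.r = float(r)

    def __call__(self, t: int) -> float:
        return self.limit / (1.0 + math.exp(self.c - self.r * t))

    def describe(self) -> dict:
        return {"kind": self.kind, "limit": self.limit, "c": self.c,
                "r": self.r}


class ExplicitDemand(DemandSchedule):
    """Demand given as an explicit per-step series; holds the last value."""

    kind = "explicit_series"

    def __init__(self, values: Sequence[float]):
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValidationError("explicit demand needs a 1-D series")
        if np.any(values < 0):
            raise ValidationError("demand values must be >= 0")
        self.values = values

    def __call__(self, t: int) -> float:
        idx = min(max(int(t), 0), self.values.size - 1)
        return float(self.values[idx])

    def describe(self) -> dict:
        return {"kind": self.kind, "values": self.values.tolist()}


class CallableDemand(DemandSchedule):
    """Wrap an arbitrary function of the time index."""

    kind = "callable"

    def __init__(self, fn: Callable[[int], float]):
        self.fn = fn

    def __call__(self, t: int) -> float:
        return float(self.fn(t))


# ---------------------------------------------------------------------------
# state and trajectory containers
# ---------------------------------------------------------------------------

@dataclass
class UnitState:
    """Abundance-by-age vector at one time index."""

    abundance: np.ndarray
    time_index: int = 0

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.ndim != 1:
            raise ValidationError("abundance must be a 1-D vector")
        if np.any(self.abundance < 0):
            raise ValidationError("abundance entries must be >= 0")

    @classmethod
    def empty(cls, max_age: int, time_index: int = 0) -> "UnitState":
        return cls(np.zeros(max_age + 1), time_index)

    @property
    def total_abundance(self) -> float:
        return float(self.abundance.sum())

    def total_activity(self, profile: AgeProfile) -> float:
        if self.abundance.size != profile.n_ages:
            raise ValidationError(
                f"state carries {self.abundance.size} ages but the profile "
                f"expects {profile.n_ages}"
            )
        return float(self.abundance @ profile.activity)


@dataclass
class Trajectory:
    """Time-indexed record of a simulation.

    Row 0 is the initial condition (produced = degraded = 0); rows 1..T are
    the simulated steps.  ``ages[t]`` is the abundance-by-age snapshot at
    time t.  Conservation holds exactly by construction:
    ``tb[t] - tb[t-1] == produced[t] - degraded[t]``.
    """

    time: np.ndarray
    tb: np.ndarray
    ta: np.ndarray
    da: np.ndarray
    produced: np.ndarray
    degraded: np.ndarray
    acc_production: np.ndarray
    acc_degradation: np.ndarray
    ages: np.ndarray
    step_length: Optional[float] = None  # wall-clock units per step
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def horizon(self) -> int:
        return int(self.time[-1])

    def conservation_residual(self) -> np.ndarray:
        """Per-step |dTB - (produced - degraded)|; all ~0 for a valid run."""
        dtb = np.diff(self.tb)
        return np.abs(dtb - (self.produced[1:] - self.degraded[1:]))

    def to_frame(self, include_ages: bool = True) -> pd.DataFrame:
        frame = pd.DataFrame({
            "time": self.time,
            "TB": self.tb,
            "TA": self.ta,
            "DA": self.da,
            "produced": self.produced,
            "degraded": self.degraded,
            "acc_production": self.acc_production,
            "acc_degradation": self.acc_degradation,
        })
        if include_ages:
            for x in range(self.ages.shape[1]):
                frame[f"age_{x}"] = self.ages[:, x]
        return frame


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _validate_state(state: UnitState, profile: AgeProfile) -> None:
    if state.abundance.size != profile.n_ages:
        raise ValidationError(
            f"state carries {state.abundance.size} ages but the profile "
            f"expects {profile.n_ages}"
        )


def step(state: UnitState, profile: AgeProfile, policy: PulsePolicy,
         demand: float, *, gate: str = "previous", allow_pulse: bool = True,
         pulse_override: Optional[float] = None
         ) -> tuple[UnitState, float, float]:
    """Advance one time step; return ``(new_state, produced, degraded)``.

    Aging with survival is applied first; the cohort at the maximum age is
    removed.  The production decision compares the pre-aging (``gate=
    "previous"``, default) or post-aging (``gate="aged"``) total activity
    against ``demand``, with strict inequality (activity exactly equal to
    demand does not trigger).  ``allow_pulse=False`` vetoes production for
    this step (used by coupled models when the upstream substrate is absent)
    and ``pulse_override`` substitutes the pulse magnitude.
    """
    _validate_state(state, profile)
    if demand < 0:
        raise ValidationError("demand must be >= 0")
    if gate not in GATE_MODES:
        raise ValidationError(f"gate must be one of {GATE_MODES}")

    prev = state.abundance
    prev_ta = float(prev @ profile.activity)

    aged = np.empty_like(prev)
    aged[0] = 0.0
    aged[1:] = prev[:-1] * profile.survival
    degraded = float(prev.sum() - aged.sum())

    pulse = policy.pulse_level if pulse_override is None else float(pulse_override)
    if policy.mode == "silent" or not allow_pulse:
        produced = 0.0
    elif policy.mode == "unregulated_continuous":
        produced = pulse
    else:  # demand_gated
        gate_ta = prev_ta if gate == "previous" else float(aged @ profile.activity)
        produced = pulse if gate_ta < demand else 0.0

    aged[0] = produced
    return UnitState(aged, state.time_index + 1), produced, degraded


def simulate(profile: AgeProfile, policy: PulsePolicy,
             demand: DemandSchedule, horizon: int,
             initial: Optional[UnitState] = None, *,
             gate: str = "previous",
             step_length: Optional[float] = None) -> Trajectory:
    """Run the one-unit model for ``horizon`` steps from ``initial``.

    The initial state defaults to an empty pool (all ages zero).  The
    returned trajectory has ``horizon + 1`` rows: the initial condition at
    time 0 followed by the simulated steps 1..horizon.
    """
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    if initial is None:
        initial = UnitState.empty(profile.max_age)
    _validate_state(initial, profile)

    n_rows = horizon + 1
    ages = np.zeros((n_rows, profile.n_ages))
    tb = np.zeros(n_rows)
    ta = np.zeros(n_rows)
    da = np.zeros(n_rows)
    produced = np.zeros(n_rows)
    degraded = np.zeros(n_rows)

    state = initial
    ages[0] = state.abundance
    tb[0] = state.total_abundance
    ta[0] = state.total_activity(profile)
    da[0] = demand(0)
    for t in range(1, n_rows):
        da[t] = demand(t)
        state, produced[t], degraded[t] = step(
            state, profile, policy, da[t], gate=gate)
        ages[t] = state.abundance
        tb[t] = state.total_abundance
        ta[t] = state.total_activity(profile)

    return Trajectory(
        time=np.arange(n_rows, dtype=int),
        tb=tb, ta=ta, da=da, produced=produced, degraded=degraded,
        acc_production=np.cumsum(produced),
        acc_degradation=np.cumsum(degraded),
        ages=ages, step_length=step_length,
        meta={"demand": demand.describe(), "pulse_level": policy.pulse_level,
              "mode": policy.mode, "gate": gate},
    )


def steady_state_abundance(profile: AgeProfile, pulse_level: float) -> float:
    """Fixed-point total abundance under continuous (every-step) pulsing.

    With a pulse injected every step, the age ladder converges to
    B0 * (1 + d_0 + d_0 d_1 + ...), summed over all carried ages.
    """
    if pulse_level < 0:
        raise ValidationError("pulse_level must be >= 0")
    ladder = np.concatenate([[1.0], np.cumprod(profile.survival)])
    return float(pulse_level * ladder.sum())
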