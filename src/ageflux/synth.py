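"""Parameter presets and synthetic pseudo-experimental series.

Survival and activity coefficients follow four shape families over age:

* **A** — constant at all ages;
* **B** — decreasing with age;
* **C** — parabolic (low at the youngest and oldest ages, peaking mid-life,
  e.g. a maturation period before full activity);
* **D** — increasing with age.

The default type-B survival ladder is reconstructed from the printed
steady-state per-age levels 100, 90, 72, 50, 31, 15, 6 reached under
continuous pulsing of 100: d = (0.9, 0.8, 50/72, 0.62, 15/31, 0.4, 0, ...).
The ratios are deliberately left non-smooth; they reproduce that ladder
exactly.

`generate_series` produces a noisy "experimental" RNA time series from a
fully known ground-truth model, for round-trip tests of the fitting engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .core import (AgeProfile, ConstantDemand, DemandSchedule,
                   ExplicitDemand, LogisticDemand, PulsePolicy,
                   RotationDemand, simulate)
from .errors import ValidationError

#: Steady-state per-age levels under continuous pulses of 100 (ages 0..6).
TYPE_B_LADDER = (100.0, 90.0, 72.0, 50.0, 31.0, 15.0, 6.0)


@dataclass(frozen=True)
class ProfileFamily:
    """Shape-family recipe for one coefficient sequence.

    ``start``/``end`` anchor the monotone families (B decreasing requires
    start > end; D increasing the reverse); ``peak`` is the mid-age maximum
    of the parabolic family C.
    """

    family: str  # A | B | C | D
    applies_to: str  # survival | activity
    start: float = 1.0
    end: float = 0.0
    peak: float = 1.0

    def __post_init__(self):
        if self.family not in "ABCD" or len(self.family) != 1:
            raise ValidationError("family must be one of A, B, C, D")
        if self.applies_to not in ("survival", "activity"):
            raise ValidationError("applies_to must be survival or activity")


def _family_values(fam: ProfileFamily, length: int) -> np.ndarray:
    x = np.linspace(0.0, 1.0, length)
    if fam.family == "A":
        vals = np.full(length, fam.start)
    elif fam.family == "B":
        if fam.start <= fam.end:
            raise ValidationError("type B requires start > end")
        vals = fam.start + (fam.end - fam.start) * x
    elif fam.family == "D":
        if fam.start >= fam.end:
            raise ValidationError("type D requires start < end")
        vals = fam.start + (fam.end - fam.start) * x
    else:  # C: parabola through (0, start), (0.5, peak), (1, end)
        lo = min(fam.start, fam.end)
        if fam.peak <= lo:
            raise ValidationError("type C requires peak above the endpoints")
        vals = fam.peak - 4.0 * (x - 0.5) ** 2 * (fam.peak - (fam.start + fam.end) / 2.0)
        vals = vals + (fam.end - fam.start) * (x - 0.5)
    if fam.applies_to == "survival" and (vals.min() < 0 or vals.max() > 1):
        raise ValidationError("survival family values must stay in [0, 1]")
    if vals.min() < 0:
        raise ValidationError("activity family values must be >= 0")
    return vals


def type_b_survival(max_age: int = 10) -> np.ndarray:
    """Survival fractions reproducing the printed type-B age ladder."""
    ladder = np.asarray(TYPE_B_LADDER)
    d = np.zeros(max_age)
    k = min(max_age, ladder.size - 1)
    d[:k] = ladder[1:k + 1] / ladder[:k]
    return d


def make_profile(survival: Union[str, ProfileFamily, np.ndarray] = "B",
                 activity: Union[str, ProfileFamily, np.ndarray] = "A",
                 max_age: int = 10) -> AgeProfile:
    """Build an :class:`AgeProfile` from shape families or raw sequences.

    String shorthands use the package defaults: survival "B" is the printed
    age-ladder reconstruction, "A" a constant 0.9; activity "A" is all
    ones, "B" falls 1 -> 0.2, "C" is parabolic peaking at 1 with 0.2
    endpoints, "D" rises 0.2 -> 1.
    """
    label = None
    if isinstance(survival, str):
        label = survival
        if survival == "B":
            surv = type_b_survival(max_age)
        elif survival == "A":
            surv = np.full(max_age, 0.9)
        elif survival == "C":
            surv = _family_values(
                ProfileFamily("C", "survival", start=0.2, end=0.2, peak=0.9),
                max_age)
        elif survival == "D":
            surv = _family_values(
                ProfileFamily("D", "survival", start=0.2, end=0.9), max_age)
        else:
            raise ValidationError("unknown survival family " + survival)
    elif isinstance(survival, ProfileFamily):
        surv = _family_values(survival, max_age)
    else:
        surv = np.asarray(survival, dtype=float)
        max_age = surv.size

    if isinstance(activity, str):
        if activity == "A":
            act = np.ones(max_age + 1)
        elif activity == "B":
            act = _family_values(
                ProfileFamily("B", "activity", start=1.0, end=0.2),
                max_age + 1)
        elif activity == "C":
            act = _family_values(
                ProfileFamily("C", "activity", start=0.2, end=0.2, peak=1.0),
                max_age + 1)
        elif activity == "D":
            act = _family_values(
                ProfileFamily("D", "activity", start=0.2, end=1.0),
                max_age + 1)
        else:
            raise ValidationError("unknown activity family " + activity)
    elif isinstance(activity, ProfileFamily):
        act = _family_values(activity, max_age + 1)
    else:
        act = np.asarray(activity, dtype=float)

    return AgeProfile(surv, act, label=label)


def make_demand(kind: str, **params) -> DemandSchedule:
    """Demand-schedule factory: constant, rotation, logistic or explicit."""
    if kind == "constant":
        return ConstantDemand(**params)
    if kind == "rotation":
        return RotationDemand(**params)
    if kind == "logistic":
        return LogisticDemand(**params)
    if kind == "explicit_series":
        return ExplicitDemand(**params)
    raise ValidationError(f"unknown demand kind {kind!r}")


@dataclass
class SyntheticSeriesSpec:
    """Recipe for one noisy pseudo-experimental RNA series.

    The defaults mirror the fitting setting: five ages (maximum age 4),
    activity 1 at every age, gated pulses against a constant demand, and
    observations at every model step on the wall clock defined by
    ``step_length``.  Additive Gaussian noise with a standard deviation
    expressed as a fraction of the series mean emulates normalized
    fold-change measurement error.
    """

    survival: np.ndarray = field(
        default_factory=lambda: np.array([0.9, 0.9, 0.5, 0.0]))
    pulse_level: float = 1.4
    demand: Union[float, DemandSchedule] = 2.0
    horizon: int = 14
    sample_interval: int = 1
    sample_offset: int = 0
    step_length: float = 5.0  # wall-clock units per model step
    noise: str = "none"  # none | additive | multiplicative
    sigma: float = 0.05  # fraction of the series mean (additive) or level
    seed: Optional[int] = None

    def demand_schedule(self) -> DemandSchedule:
        if isinstance(self.demand, DemandSchedule):
            return self.demand
        return ConstantDemand(float(self.demand))


def generate_series(spec: SyntheticSeriesSpec):
    """Simulate, decimate and perturb; returns ``(series, ground_truth)``.

    With ``noise="none"`` the series equals the simulator's TB output
    exactly; a fixed seed makes the noisy output bit-reproducible.  The
    ground-truth dict records every generating parameter for recovery
    tests.
    """
    from .fitting import ObservedSeries

    if spec.noise not in ("none", "additive", "multiplicative"):
        raise ValidationError("noise must be none, additive or multiplicative")
    survival = np.asarray(spec.survival, dtype=float)
    profile = AgeProfile(survival, np.ones(survival.size + 1))
    policy = PulsePolicy(spec.pulse_level, "demand_gated")
    schedule = spec.demand_schedule()
    traj = simulate(profile, policy, schedule, spec.horizon,
                    step_length=spec.step_length)
    idx = np.arange(spec.sample_offset, spec.horizon + 1, spec.sample_interval)
    levels = traj.tb[idx].copy()
    if spec.noise != "none":
        rng = np.random.default_rng(spec.seed)
        if spec.noise == "additive":
            scale = spec.sigma * float(np.mean(np.abs(levels)))
            levels = levels + scale * rng.standard_normal(levels.size)
        else:
            levels = levels * (1.0 + spec.sigma * rng.standard_normal(levels.size))
    series = ObservedSeries(times=idx * spec.step_length, levels=levels,
                            units_note="synthetic")
    truth = {
        "survival": survival.tolist(),
        "pulse_level": spec.pulse_level,
        "demand": schedule.describe(),
        "lifespan": survival.size * spec.step_length,
        "step_length": spec.step_length,
        "horizon": spec.horizon,
        "noise": spec.noise,
        "sigma": spec.sigma,
        "seed": spec.seed,
        "trajectory_tb": traj.tb.tolist(),
        "accumulated_transcription": float(traj.acc_production[-1]),
        "accumulated_degradation": float(traj.acc_degradation[-1]),
    }
    return series, truth
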