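"""Cycle, amplitude and aliasing analysis of simulated trajectories.

The dynamics are deterministic with an effectively finite state space
(pulses are quantized), so every run either converges to a fixed point or
enters an exact periodic orbit.  Periods are therefore found by exact
recurrence of the full abundance-by-age vector (quantized at 1e-9), never by
spectral estimation: the smallest p such that the state sequence satisfies
``ages[t] == ages[t + p]`` from some transient onward, with at least three
full periods observed before the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .core import Trajectory
from .errors import ValidationError

QUANTUM = 1e-9


@dataclass
class CycleReport:
    """Steady-regime structure of one trajectory."""

    regime: str  # fixed_point | periodic | aperiodic_within_horizon
    period: Optional[int]
    amplitude: float  # max - min of TB over one steady period
    transient_length: int
    inconclusive: bool = False
    sub_cycles: List[Tuple[str, Optional[int]]] = field(default_factory=list)
    global_period: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "period": self.period,
            "amplitude": self.amplitude,
            "transient_length": self.transient_length,
            "inconclusive": self.inconclusive,
            "sub_cycles": [list(sc) for sc in self.sub_cycles],
            "global_period": self.global_period,
        }


def _quantize(rows: np.ndarray) -> np.ndarray:
    return np.round(rows / QUANTUM).astype(np.int64)


def _tail_period(rows: np.ndarray, min_repeats: int
                 ) -> Tuple[Optional[int], int]:
    """Smallest p with rows[t] == rows[t+p] for all t >= s, requiring the
    periodic tail to span >= min_repeats periods.  Returns (p, transient s).
    """
    n = rows.shape[0]  # indices 0..n-1
    max_p = (n - 1) // min_repeats
    for p in range(1, max_p + 1):
        mismatch = np.any(rows[:-p] != rows[p:], axis=1)
        s = int(np.max(np.nonzero(mismatch)[0])) + 1 if mismatch.any() else 0
        if (n - 1) - s >= min_repeats * p:
            return p, s
    return None, n


def detect_cycles(traj: Trajectory, min_repeats: int = 3) -> CycleReport:
    """Classify the steady regime of a trajectory.

    A period-1 orbit with zero TB amplitude is reported as a fixed point.
    For piecewise-constant demand schedules (detected from the recorded DA
    series) the report additionally carries per-dwell-phase sub-cycles and
    the schedule-wide global period.
    """
    if min_repeats < 2:
        raise ValidationError("min_repeats must be >= 2")
    rows = _quantize(np.column_stack([traj.ages, traj.da[:, None]]))
    period, transient = _tail_period(rows, min_repeats)

    if period is None:
        return CycleReport(regime="aperiodic_within_horizon", period=None,
                           amplitude=float("nan"),
                           transient_length=int(len(traj)),
                           inconclusive=True)

    steady_tb = traj.tb[len(traj) - period:]
    amplitude = float(steady_tb.max() - steady_tb.min())
    if period == 1:
        # constant state
        report = CycleReport(regime="fixed_point", period=None, amplitude=0.0,
                             transient_length=transient)
    else:
        report = CycleReport(regime="periodic", period=period,
                             amplitude=amplitude, transient_length=transient)
        _attach_sub_cycles(traj, report)
    return report


def _attach_sub_cycles(traj: Trajectory, report: CycleReport) -> None:
    """Sub-cycle structure inside the dwell phases of a square-wave demand.

    Uses the final full period of the orbit; if the demand takes more than
    one value there, the period is reported as the global period and each
    maximal run of constant demand is scanned for an internal short cycle
    (>= 2 repeats within the dwell).
    """
    p = report.period
    window = slice(len(traj) - p, len(traj))
    if np.allclose(traj.da[window], traj.da[window][0]):
        return
    report.global_period = p
    # anchor the window at a demand switch so no dwell phase is cut in two
    if len(traj) >= 2 * p:
        tail = traj.da[len(traj) - 2 * p:]
        changes = np.flatnonzero(np.diff(tail) != 0)
        if changes.size and changes[0] + 1 + p <= 2 * p:
            start = len(traj) - 2 * p + int(changes[0]) + 1
            window = slice(start, start + p)
    da = traj.da[window]
    ages = traj.ages[window]
    # maximal runs of constant demand within one global period
    change = np.flatnonzero(np.diff(da) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [p]])
    for s, e in zip(starts, ends):
        label = f"DA={da[s]:g}"
        sub_rows = _quantize(ages[s:e])
        sub_p, _ = _tail_period(sub_rows, min_repeats=2)
        if sub_p is not None and sub_p >= e - s:
            sub_p = None
        report.sub_cycles.append((label, sub_p))


def resample(traj: Trajectory, interval: int, offset: int = 0):
    """Decimate a trajectory's TB series into an observed series.

    Returns the total abundance at times ``offset, offset+interval, ...``,
    emulating an experiment that samples every ``interval`` model steps.
    The returned series records the decimation in its ``units_note``.
    """
    from .fitting import ObservedSeries

    if interval < 1:
        raise ValidationError("interval must be >= 1")
    if offset < 0:
        raise ValidationError("offset must be >= 0")
    if interval >= len(traj):
        raise ValidationError("interval must be shorter than the trajectory")
    times = np.arange(offset, len(traj), interval)
    scale = traj.step_length or 1.0
    return ObservedSeries(
        times=times * scale,
        levels=traj.tb[times],
        units_note=f"resampled every {interval} steps from offset {offset}",
    )


def compare_demand_levels(traj_a: Trajectory, traj_b: Trajectory) -> dict:
    """Per-time TB differences between two runs and a sign summary.

    Illustrates that under cycling dynamics the run with the higher demand
    can be measured either above or below the other depending on sampling
    time.
    """
    if len(traj_a) != len(traj_b):
        raise ValidationError("trajectories must have equal horizons")
    diff = traj_a.tb - traj_b.tb
    n = diff.size
    return {
        "difference": diff,
        "fraction_a_higher": float(np.count_nonzero(diff > 0) / n),
        "fraction_b_higher": float(np.count_nonzero(diff < 0) / n),
        "fraction_equal": float(np.count_nonzero(diff == 0) / n),
        "sign_changes": int(np.count_nonzero(np.diff(np.sign(diff)) != 0)),
    }
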