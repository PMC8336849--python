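"""Readers, writers and configuration handling.

CSV dialect: comma-separated, '.' decimal, UTF-8, mandatory header;
``#``-prefixed lines are metadata comments.  Times stay in the file's
native wall-clock unit (mixing minutes for yeast and hours for mammalian
series is expected); the unit is carried as metadata, not converted.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .core import Trajectory
from .errors import ConfigurationError, ValidationError
from .fitting import FitResult, ObservedSeries

logger = logging.getLogger(__name__)


def read_series(path: Union[str, Path], organism: str = "other",
                time_unit: str = "min") -> ObservedSeries:
    """Read a (time, level) CSV into an :class:`ObservedSeries`.

    Requires header columns ``time`` and ``level``; comment lines are
    skipped (their count is logged).  Non-numeric cells, duplicate or
    non-increasing times and series shorter than 4 rows are errors.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    n_comments = sum(1 for line in text if line.lstrip().startswith("#"))
    if n_comments:
        logger.info("%s: skipped %d comment lines", path.name, n_comments)
    frame = pd.read_csv(path, comment="#")
    missing = {"time", "level"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path.name}: missing columns {sorted(missing)}")
    for col in ("time", "level"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 2  # 1-based + header
            raise ValidationError(f"{path.name}: non-numeric {col} at line {row}")
        frame[col] = vals
    times = frame["time"].to_numpy(dtype=float)
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        line = int(np.argmax(diffs <= 0)) + 3  # header + 1-based + pair end
        raise ValidationError(
            f"{path.name}: time not strictly increasing at row {line}")
    return ObservedSeries(times=times,
                          levels=frame["level"].to_numpy(dtype=float),
                          organism_class=organism, time_unit=time_unit)


def write_series(series: ObservedSeries, path: Union[str, Path]) -> None:
    pd.DataFrame({"time": series.times, "level": series.levels}).to_csv(
        path, index=False)


def write_trajectory(traj: Trajectory, path: Union[str, Path],
                     include_ages: bool = True) -> None:
    """Write a trajectory as tidy CSV (optionally with per-age columns)."""
    if len(traj) == 0:
        raise ValidationError("refusing to write an empty trajectory")
    traj.to_frame(include_ages=include_ages).to_csv(path, index=False)


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    """Read back a trajectory CSV written by :func:`write_trajectory`."""
    frame = pd.read_csv(path, comment="#")
    needed = ["time", "TB", "TA", "DA", "produced", "degraded",
              "acc_production", "acc_degradation"]
    missing = set(needed) - set(frame.columns)
    if missing:
        raise ValidationError(f"missing trajectory columns {sorted(missing)}")
    age_cols = sorted((c for c in frame.columns if c.startswith("age_")),
                      key=lambda c: int(c.split("_")[1]))
    if age_cols:
        ages = frame[age_cols].to_numpy(dtype=float)
    else:
        # fall back to a TB-only "state": cycle analysis degrades gracefully
        ages = frame[["TB"]].to_numpy(dtype=float)
    return Trajectory(
        time=frame["time"].to_numpy(dtype=int),
        tb=frame["TB"].to_numpy(dtype=float),
        ta=frame["TA"].to_numpy(dtype=float),
        da=frame["DA"].to_numpy(dtype=float),
        produced=frame["produced"].to_numpy(dtype=float),
        degraded=frame["degraded"].to_numpy(dtype=float),
        acc_production=frame["acc_production"].to_numpy(dtype=float),
        acc_degradation=frame["acc_degradation"].to_numpy(dtype=float),
        ages=ages,
    )


def write_fit(result: FitResult, path: Union[str, Path]) -> None:
    """Serialize a fit result (without the trajectory) to JSON."""
    Path(path).write_text(json.dumps(result.to_dict(), indent=2),
                          encoding="utf-8")


def read_fit(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: Union[str, Path], allowed_keys: Optional[set] = None
                ) -> dict:
    """Load a YAML/JSON config; unknown top-level keys are rejected."""
    raw = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(raw)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - allowed_keys
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown keys {sorted(unknown)}; "
                f"allowed: {sorted(allowed_keys)}")
    return cfg


SIMULATE_KEYS = {"n_ages", "max_age", "survival", "activity", "pulse_level",
                 "mode", "demand", "horizon", "gate", "seed", "step_length",
                 "initial"}


def build_simulation(cfg: dict):
    """Construct (profile, policy, schedule, horizon, options) from config."""
    from .core import AgeProfile, PulsePolicy, UnitState
    from .synth import make_demand, make_profile

    unknown = set(cfg) - SIMULATE_KEYS
    if unknown:
        raise ConfigurationError(f"unknown simulate keys {sorted(unknown)}")
    max_age = int(cfg.get("max_age", cfg.get("n_ages", 11) - 1))
    if "survival" in cfg and not isinstance(cfg["survival"], str):
        profile = AgeProfile(np.asarray(cfg["survival"], dtype=float),
                             np.asarray(cfg.get("activity",
                                                [1.0] * (len(cfg["survival"]) + 1)),
                                        dtype=float))
    else:
        profile = make_profile(cfg.get("survival", "B"),
                               cfg.get("activity", "A"), max_age=max_age)
    policy = PulsePolicy(float(cfg.get("pulse_level", 100.0)),
                         cfg.get("mode", "demand_gated"))
    dem_cfg = cfg.get("demand", {"kind": "constant", "level": 50.0})
    if isinstance(dem_cfg, (int, float)):
        dem_cfg = {"kind": "constant", "level": float(dem_cfg)}
    schedule = make_demand(dem_cfg.pop("kind"), **dem_cfg)
    horizon = int(cfg.get("horizon", 100))
    initial = None
    if "initial" in cfg:
        initial = UnitState(np.asarray(cfg["initial"], dtype=float))
    options = {"gate": cfg.get("gate", "previous"),
               "step_length": cfg.get("step_length"),
               "initial": initial}
    return profile, policy, schedule, horizon, options
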