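"""Coupled units: the RNA->protein two-unit model and n-unit chains/webs.

A downstream unit (e.g. protein) faces an external demand for its activity;
whatever part of that demand its current total activity cannot cover is a
*deficit*, and the deficit — scaled by a coupling gain — becomes the demand
driving the upstream unit (e.g. the demand for RNA activity that gates
transcription).  Within each step every gating quantity is read from the
previous step, so the update order across units cannot create simultaneity
paradoxes: demands are derived from last step's activities, then every unit
ages and (possibly) pulses.

A downstream unit additionally needs its substrate: by default protein
pulses require the previous step's total RNA activity to be positive.  The
pulse magnitude is the unit's constant nascent amount per step; an
RNA-proportional variant (pulse = min(T_p0, beta * TRA)) is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (AgeProfile, DemandSchedule, PulsePolicy, Trajectory,
                   UnitState, step)
from .errors import ConfigurationError, ValidationError


def derive_upstream_demand(downstream_demand: float,
                           downstream_total_activity: float,
                           gain: float = 1.0) -> float:
    """Demand passed upstream: ``gain * max(0, demand - activity)``."""
    if downstream_demand < 0 or downstream_total_activity < 0 or gain < 0:
        raise ValidationError("demands, activities and gains must be >= 0")
    return gain * max(0.0, downstream_demand - downstream_total_activity)


@dataclass
class UnitSpec:
    """One unit of a chain or web."""

    profile: AgeProfile
    policy: PulsePolicy
    initial: Optional[UnitState] = None
    label: str = ""


@dataclass
class ChainSpec:
    """Units plus coupling topology.

    ``edges`` are ``(upstream, downstream, gain)`` index triples: the
    upstream unit's product is the downstream unit's substrate, and the
    downstream unit's unmet demand (times the gain) contributes to the
    upstream unit's demand.  Units without a downstream successor face the
    top-level demand schedule directly.  The successor graph must be
    acyclic.
    """

    units: List[UnitSpec]
    demand: DemandSchedule
    edges: List[Tuple[int, int, float]] = field(default_factory=list)
    require_substrate: bool = True

    @classmethod
    def chain(cls, units: Sequence[UnitSpec], demand: DemandSchedule,
              gains: Optional[Sequence[float]] = None, **kw) -> "ChainSpec":
        """Linear chain: unit 0 feeds unit 1 feeds ... feeds unit n-1."""
        units = list(units)
        if gains is None:
            gains = [1.0] * (len(units) - 1)
        if len(gains) != len(units) - 1:
            raise ValidationError("need one gain per adjacent pair")
        edges = [(k, k + 1, float(g)) for k, g in enumerate(gains)]
        return cls(units=units, demand=demand, edges=edges, **kw)

    def _check(self) -> List[int]:
        """Validate topology; return units in reverse-topological order
        (demand-facing units first)."""
        n = len(self.units)
        if n < 1:
            raise ValidationError("need at least one unit")
        succ: List[List[Tuple[int, float]]] = [[] for _ in range(n)]
        pred: List[List[int]] = [[] for _ in range(n)]
        for u, v, g in self.edges:
            if not (0 <= u < n and 0 <= v < n) or u == v:
                raise ConfigurationError(f"bad edge ({u}, {v})")
            if g < 0:
                raise ConfigurationError("edge gains must be >= 0")
            succ[u].append((v, g))
            pred[v].append(u)
        # Kahn's algorithm on the successor graph; a leftover means a cycle.
        out_deg = [len(s) for s in succ]
        order = []
        ready = [i for i in range(n) if out_deg[i] == 0]
        remaining = out_deg[:]
        while ready:
            i = ready.pop()
            order.append(i)
            for p in pred[i]:
                remaining[p] -= 1
                if remaining[p] == 0:
                    ready.append(p)
        if len(order) != n:
            raise ConfigurationError(
                "cyclic coupling topology without a declared evaluation order")
        self._succ = succ
        self._pred = pred
        return order


def simulate_chain(spec: ChainSpec, horizon: int,
                   gate: str = "previous") -> List[Trajectory]:
    """Simulate every unit of a chain/web for ``horizon`` steps.

    A single unit reduces exactly to the one-unit simulator; a two-unit
    chain is the RNA->protein model.
    """
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    order = spec._check()
    n = len(spec.units)
    states = []
    for u in spec.units:
        s = u.initial if u.initial is not None else UnitState.empty(u.profile.max_age)
        states.append(s)

    n_rows = horizon + 1
    rec = [dict(tb=np.zeros(n_rows), ta=np.zeros(n_rows), da=np.zeros(n_rows),
                produced=np.zeros(n_rows), degraded=np.zeros(n_rows),
                ages=np.zeros((n_rows, u.profile.n_ages)))
           for u in spec.units]
    for i, (u, s) in enumerate(zip(spec.units, states)):
        rec[i]["ages"][0] = s.abundance
        rec[i]["tb"][0] = s.total_abundance
        rec[i]["ta"][0] = s.total_activity(u.profile)

    prev_ta = [rec[i]["ta"][0] for i in range(n)]
    for t in range(1, n_rows):
        top_da = spec.demand(t)
        # demands from last step's activities, demand-facing units first
        da = [0.0] * n
        for i in order:
            if not spec._succ[i]:
                da[i] = top_da
            else:
                da[i] = sum(
                    derive_upstream_demand(da[v], prev_ta[v], g)
                    for v, g in spec._succ[i]
                )
        new_ta = [0.0] * n
        for i, (u, s) in enumerate(zip(spec.units, states)):
            allow = True
            if spec.require_substrate and spec._pred[i]:
                allow = any(prev_ta[p] > 0.0 for p in spec._pred[i])
            states[i], produced, degraded = step(
                s, u.profile, u.policy, da[i], gate=gate, allow_pulse=allow)
            r = rec[i]
            r["da"][t] = da[i]
            r["produced"][t] = produced
            r["degraded"][t] = degraded
            r["ages"][t] = states[i].abundance
            r["tb"][t] = states[i].total_abundance
            new_ta[i] = r["ta"][t] = states[i].total_activity(u.profile)
        prev_ta = new_ta

    time = np.arange(n_rows, dtype=int)
    return [
        Trajectory(time=time, tb=r["tb"], ta=r["ta"], da=r["da"],
                   produced=r["produced"], degraded=r["degraded"],
                   acc_production=np.cumsum(r["produced"]),
                   acc_degradation=np.cumsum(r["degraded"]),
                   ages=r["ages"],
                   meta={"unit": i, "label": spec.units[i].label})
        for i, r in enumerate(rec)
    ]


# ---------------------------------------------------------------------------
# the two-unit RNA -> protein model
# ---------------------------------------------------------------------------

@dataclass
class CoupledModel:
    """RNA and protein units coupled through the protein-activity deficit.

    The demand for protein activity (DPA) is external; the demand for RNA
    activity is ``coupling_gain * max(0, DPA - TPA)`` read from the previous
    step.  Protein pulses additionally require the previous step's total
    RNA activity to be positive (set ``require_rna=False`` to drop that),
    and ``rna_proportional`` switches the protein pulse magnitude to
    ``min(T_p0, beta * TRA)``.
    """

    rna_profile: AgeProfile
    rna_policy: PulsePolicy
    protein_profile: AgeProfile
    protein_policy: PulsePolicy
    dpa: DemandSchedule
    coupling_gain: float = 1.0
    require_rna: bool = True
    rna_proportional: bool = False
    beta: float = 1.0

    def __post_init__(self):
        if self.coupling_gain < 0:
            raise ValidationError("coupling_gain must be >= 0")


@dataclass
class CoupledTrajectories:
    rna: Trajectory
    protein: Trajectory


def simulate_coupled(model: CoupledModel, horizon: int,
                     rna_initial: Optional[UnitState] = None,
                     protein_initial: Optional[UnitState] = None,
                     gate: str = "previous") -> CoupledTrajectories:
    """Simulate the two-unit model for ``horizon`` steps."""
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    r_state = rna_initial or UnitState.empty(model.rna_profile.max_age)
    p_state = protein_initial or UnitState.empty(model.protein_profile.max_age)

    n_rows = horizon + 1
    def blank(profile):
        return dict(tb=np.zeros(n_rows), ta=np.zeros(n_rows),
                    da=np.zeros(n_rows), produced=np.zeros(n_rows),
                    degraded=np.zeros(n_rows),
                    ages=np.zeros((n_rows, profile.n_ages)))

    R, P = blank(model.rna_profile), blank(model.protein_profile)
    for r, st, prof in ((R, r_state, model.rna_profile),
                        (P, p_state, model.protein_profile)):
        r["ages"][0] = st.abundance
        r["tb"][0] = st.total_abundance
        r["ta"][0] = st.total_activity(prof)
    R["da"][0] = derive_upstream_demand(model.dpa(0), P["ta"][0],
                                        model.coupling_gain)
    P["da"][0] = model.dpa(0)

    for t in range(1, n_rows):
        tra_prev, tpa_prev = R["ta"][t - 1], P["ta"][t - 1]
        dpa_t = model.dpa(t)
        dra_t = derive_upstream_demand(dpa_t, tpa_prev, model.coupling_gain)

        r_state, R["produced"][t], R["degraded"][t] = step(
            r_state, model.rna_profile, model.rna_policy, dra_t, gate=gate)
        allow = (not model.require_rna) or tra_prev > 0.0
        override = None
        if model.rna_proportional:
            override = min(model.protein_policy.pulse_level,
                           model.beta * tra_prev)
        p_state, P["produced"][t], P["degraded"][t] = step(
            p_state, model.protein_profile, model.protein_policy, dpa_t,
            gate=gate, allow_pulse=allow, pulse_override=override)

        for r, st, prof in ((R, r_state, model.rna_profile),
                            (P, p_state, model.protein_profile)):
            r["ages"][t] = st.abundance
            r["tb"][t] = st.total_abundance
            r["ta"][t] = st.total_activity(prof)
        R["da"][t] = dra_t
        P["da"][t] = dpa_t

    time = np.arange(n_rows, dtype=int)
    def pack(r, label):
        return Trajectory(time=time, tb=r["tb"], ta=r["ta"], da=r["da"],
                          produced=r["produced"], degraded=r["degraded"],
                          acc_production=np.cumsum(r["produced"]),
                          acc_degradation=np.cumsum(r["degraded"]),
                          ages=r["ages"], meta={"label": label})
    return CoupledTrajectories(rna=pack(R, "RNA"), protein=pack(P, "protein"))


def classify_regimes(trajs: CoupledTrajectories) -> Tuple[str, str]:
    """Label each unit's steady regime as ``cycling`` or ``stable``."""
    from .oscillation import detect_cycles

    out = []
    for traj in (trajs.rna, trajs.protein):
        report = detect_cycles(traj)
        if report.regime == "periodic" and report.amplitude > 0:
            out.append("cycling")
        elif report.regime == "fixed_point":
            out.append("stable")
        else:
            out.append("unresolved")
    return tuple(out)


@dataclass
class RateRatioSummary:
    """Windowed production rates and their ratios for a coupled run."""

    window: int
    transcription_rate: np.ndarray  # units/time per window
    translation_rate: np.ndarray
    rate_ratio: np.ndarray  # translation / transcription (nan if both 0)
    tpro_tr_ratio: np.ndarray  # per step; inf where TR == 0 and TPro > 0
    unbounded_steps: np.ndarray  # boolean mask of TR == 0 steps

    @property
    def rate_ratio_range(self) -> Tuple[float, float]:
        finite = self.rate_ratio[np.isfinite(self.rate_ratio)]
        return float(finite.min()), float(finite.max())

    @property
    def transcription_rate_range(self) -> Tuple[float, float]:
        return (float(self.transcription_rate.min()),
                float(self.transcription_rate.max()))


def rate_ratio_summary(rna_traj: Trajectory, protein_traj: Trajectory,
                       window: int = 10,
                       skip_transient: int = 0) -> RateRatioSummary:
    """Translation/transcription rate ratios and the TPro/TR level ratio.

    Rates are produced amounts averaged over non-overlapping windows of
    ``window`` steps (units per time step).  The level ratio TPro/TR is
    reported per step with explicit flagging of TR = 0 steps, where it is
    unbounded.
    """
    if len(rna_traj) != len(protein_traj):
        raise ValidationError("trajectories must have equal length")
    if window < 1:
        raise ValidationError("window must be >= 1")
    prod_r = rna_traj.produced[1 + skip_transient:]
    prod_p = protein_traj.produced[1 + skip_transient:]
    n_win = prod_r.size // window
    if n_win < 1:
        raise ValidationError("trajectory shorter than one window")
    tr_rate = prod_r[:n_win * window].reshape(n_win, window).mean(axis=1)
    tl_rate = prod_p[:n_win * window].reshape(n_win, window).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tr_rate > 0, tl_rate / tr_rate,
                         np.where(tl_rate > 0, np.inf, np.nan))
        tb_r, tb_p = rna_traj.tb, protein_traj.tb
        level_ratio = np.where(tb_r > 0, tb_p / tb_r,
                               np.where(tb_p > 0, np.inf, np.nan))
    return RateRatioSummary(
        window=window,
        transcription_rate=tr_rate,
        translation_rate=tl_rate,
        rate_ratio=ratio,
        tpro_tr_ratio=level_ratio,
        unbounded_steps=(tb_r == 0) & (tb_p > 0),
    )


def default_coupled_model(dpa: DemandSchedule,
                          coupling_gain: float = 1.0,
                          t_r0: float = 100.0,
                          t_p0: float = 48.0) -> CoupledModel:
    """Two-unit model with the package's reconstructed default parameters.

    Both units use the type-B survival ladder and constant activity 1; the
    nascent amounts default to 100 RNA and 48 protein units per pulse, the
    peak per-step rates the model reaches when demand is unattainable.
    """
    from .synth import make_profile

    return CoupledModel(
        rna_profile=make_profile("B", "A"),
        rna_policy=PulsePolicy(t_r0),
        protein_profile=make_profile("B", "A"),
        protein_policy=PulsePolicy(t_p0),
        dpa=dpa,
        coupling_gain=coupling_gain,
    )
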