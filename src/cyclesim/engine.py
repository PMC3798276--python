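"""Deterministic age-structured simulation of proliferating cell cohorts.

The population is organized by cycle index ``i`` (0..f), phase (G1, S, G2M)
and age compartment within the phase.  Each step advances the state by one
grid step ``delta_h``:

1. per-age phase exits via the exit probabilities ``beta`` (modulated by a
   type-I delay module where bound);
2. a fraction of the exiting flux is diverted to the blocked compartment if
   a type II/III/IV module is bound; the blocked pool loses cells to death
   and (type III/IV) recycling;
3. cycling-cell death and quiescent/G0/polyploid death;
4. phase completers are routed G1 -> S -> G2M -> mitosis; newborns split
   between re-entry into cycle ``i`` and progression to cycle ``i+1``
   according to ``p_out[i]``; a fraction ``p_pol`` of newborns re-fuses into
   the polyploid pool of the destination cycle;
5. cells entering a phase are first processed by that phase's quiescence
   module; G1 entry optionally transits a single-compartment G0 sub-phase
   (bypass probability ``theta``, exit rate ``gamma``, death ``dr_g0``).

Setting ``p_out[0] = 0`` gives a single-cycle model; ``p_out[i] = 1`` for all
i makes cycle index coincide with generation number (the multi-generation
model used to render time-lapse data).  ``p_out[f] = 0`` pools generations
``>= f`` in the final cycle.

BrdU pulse-chase experiments are rendered by splitting the asynchronous
starting state into BrdU- (G1 + G2M + quiescent) and BrdU+ (S) sub-states
simulated independently, each with its own label-scoped perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import SimpleNamespace
from typing import Sequence

import numpy as np

from .phase_kinetics import (
    AgeGrid,
    DurationDistribution,
    PhaseDurationSpec,
    build_duration_distribution,
)
from .perturbations import (
    PHASES,
    PerturbationSpec,
    TimedParam,
    apply_block_recycle,
    apply_cycling_death,
    apply_delay,
    apply_quiescence,
    divide,
    refuse_polyploid,
)

__all__ = [
    "G0Spec",
    "ConfluenceSpec",
    "ModelConfig",
    "CycleState",
    "Trajectory",
    "compile_model",
    "step",
    "desynchronize",
    "apply_brdu_pulse",
    "simulate",
    "igrov1_like_config",
]

PH_IDX = {"G1": 0, "S": 1, "G2M": 2}
LABELS = ("neg", "pos")


@dataclass(frozen=True)
class G0Spec:
    """Single-compartment G0 sub-phase before G1 (probability-transition model).

    gamma: per-step probability of leaving G0 for G1; theta: probability for
    a newborn to bypass G0 entirely; dr: per-step death probability in G0.
    """

    gamma: float
    theta: float = 0.0
    dr: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("gamma", self.gamma), ("theta", self.theta), ("dr", self.dr)):
            if not 0 <= v <= 1:
                raise ValueError(f"G0 {name} must be in [0, 1], got {v}")
        if self.gamma + self.dr > 1:
            raise ValueError("gamma + dr must be <= 1 per step")


@dataclass(frozen=True)
class ConfluenceSpec:
    """Hill increase of G1 quiescence probability with total cell number.

    Effective extra quiescence: ``pq_max * N^slope / (n50^slope + N^slope)``,
    added to the baseline pQ_G1 (clipped to 1).  Off by default.
    """

    n50: float
    slope: float = 4.0
    pq_max: float = 0.5


@dataclass(frozen=True)
class ModelConfig:
    """Full specification of a simulation run.

    The default cycle wiring is the multi-generation model with the final
    cycle pooling all later generations (``p_out = 1,1,...,1,0``).
    """

    durations: dict
    grid: AgeGrid = field(default_factory=AgeGrid)
    n_cycles: int = 6
    p_out: tuple = None  # type: ignore[assignment]
    p_q: dict = field(default_factory=dict)  # baseline quiescence prob per phase
    dr_q: dict = field(default_factory=dict)  # quiescent death per phase
    g0: G0Spec | None = None
    confluence: ConfluenceSpec | None = None
    m_div: float = 2.0
    perturbations: tuple = ()

    def __post_init__(self) -> None:
        if set(self.durations) != set(PHASES):
            raise ValueError(f"durations must cover exactly {PHASES}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        p_out = self.p_out
        if p_out is None:
            p_out = tuple([1.0] * (self.n_cycles - 1) + [0.0])
        p_out = tuple(float(p) for p in p_out)
        if len(p_out) != self.n_cycles:
            raise ValueError("p_out must have one entry per cycle")
        if any(not 0 <= p <= 1 for p in p_out):
            raise ValueError("p_out entries must be in [0, 1]")
        object.__setattr__(self, "p_out", p_out)
        for d in (self.p_q, self.dr_q):
            for ph, v in d.items():
                if ph not in PHASES or not 0 <= v <= 1:
                    raise ValueError(f"invalid quiescence entry {ph}={v}")
        if not 0 < self.m_div <= 2:
            raise ValueError("m_div must be in (0, 2]")
        object.__setattr__(self, "perturbations", tuple(self.perturbations))
        for p in self.perturbations:
            if not isinstance(p, PerturbationSpec):
                raise ValueError("perturbations must be PerturbationSpec instances")
            if max(p.cycles) >= self.n_cycles:
                raise ValueError(
                    f"perturbation {p.kind} bound to cycle {max(p.cycles)} "
                    f">= n_cycles={self.n_cycles}"
                )

    def unperturbed(self) -> "ModelConfig":
        return replace(self, perturbations=())


class _LabelParams:
    """Per-label static parameter tensors plus timed overrides."""

    def __init__(self, n_cycles: int):
        z = lambda: np.zeros(n_cycles)
        self.delay = {ph: z() for ph in PHASES}
        self.p_bl = {ph: z() for ph in PHASES}
        self.dr_bl = {ph: z() for ph in PHASES}
        self.rec = {ph: z() for ph in PHASES}
        self.dr = {ph: z() for ph in PHASES}
        self.p_q = {ph: z() for ph in PHASES}
        self.dr_q = {ph: z() for ph in PHASES}
        self.p_pol = z()
        self.dr_pol = z()
        self.m_div = np.full(n_cycles, 2.0)
        self.timed: list[tuple] = []  # (attr, phase_or_None, cycles, name, TimedParam)

    def at(self, t: float) -> "SimpleNamespace | _LabelParams":
        if not self.timed:
            return self
        eff = SimpleNamespace(
            delay=self.delay,
            p_bl=dict(self.p_bl),
            dr_bl=dict(self.dr_bl),
            rec=dict(self.rec),
            dr=self.dr,
            p_q=self.p_q,
            dr_q=self.dr_q,
            p_pol=self.p_pol,
            dr_pol=self.dr_pol,
            m_div=self.m_div,
        )
        for attr, phase, cycles, tp in self.timed:
            v = tp.value(t)
            if phase is None:
                arr = getattr(eff, attr).copy()
                arr[list(cycles)] = v
                setattr(eff, attr, arr)
            else:
                d = getattr(eff, attr)
                arr = d[phase].copy()
                arr[list(cycles)] = v
                d[phase] = arr
        return eff


@dataclass
class CompiledModel:
    config: ModelConfig
    dists: dict  # phase -> DurationDistribution
    beta: dict  # phase -> ndarray
    n_age: dict  # phase -> int
    p_out: np.ndarray
    labels: dict  # label -> _LabelParams


def compile_model(config: ModelConfig) -> CompiledModel:
    """Resolve duration laws and bind perturbation modules to parameter tensors."""
    dists = {
        ph: build_duration_distribution(config.durations[ph], config.grid)
        for ph in PHASES
    }
    nc = config.n_cycles
    labels = {lab: _LabelParams(nc) for lab in LABELS}
    for lab in LABELS:
        lp = labels[lab]
        for ph in PHASES:
            lp.p_q[ph][:] = config.p_q.get(ph, 0.0)
            lp.dr_q[ph][:] = config.dr_q.get(ph, 0.0)
        lp.m_div[:] = config.m_div

    _KIND_PARAMS = {
        "delay": [("del_ph", "delay")],
        "block": [("p_bl", "p_bl"), ("dr_bl", "dr_bl")],
        "block_recycle": [("p_bl", "p_bl"), ("dr_bl", "dr_bl"), ("rec", "rec")],
        "block_recycle_timed": [("p_bl", "p_bl"), ("dr_bl", "dr_bl"), ("rec", "rec")],
        "cycling_death": [("dr", "dr")],
        "mitosis": [("m_div", "m_div")],
        "polyploid": [("p_pol", "p_pol"), ("dr_pol", "dr_pol")],
        "quiescence": [("p_q", "p_q"), ("dr_q", "dr_q")],
    }
    for spec in config.perturbations:
        target_labels = LABELS if spec.label == "both" else (spec.label,)
        for lab in target_labels:
            lp = labels[lab]
            for key, attr in _KIND_PARAMS[spec.kind]:
                value = spec.params[key]
                if isinstance(value, TimedParam):
                    lp.timed.append((attr, spec.phase, spec.cycles, value))
                    continue
                if spec.phase is None:
                    getattr(lp, attr)[list(spec.cycles)] = value
                else:
                    getattr(lp, attr)[spec.phase][list(spec.cycles)] = value
    # validate competing per-step probabilities after binding
    for lab in LABELS:
        lp = labels[lab]
        for ph in PHASES:
            if np.any(lp.dr_bl[ph] + lp.rec[ph] > 1 + 1e-12):
                raise ValueError(f"dr_bl + rec > 1 in phase {ph} ({lab})")
    return CompiledModel(
        config=config,
        dists=dists,
        beta={ph: dists[ph].beta for ph in PHASES},
        n_age={ph: dists[ph].mass.size for ph in PHASES},
        p_out=np.asarray(config.p_out, dtype=float),
        labels=labels,
    )


@dataclass
class CycleState:
    """Age-structured population state at one time point.

    ``a[ph]`` has shape (n_cycles, n_age[ph]); pools ``q``/``b`` are
    (n_cycles, 3) with phase columns ordered G1, S, G2M.  ``dead`` and
    ``entered`` are cumulative per-cycle counters; ``cum_births`` counts net
    births (divisions minus sibling-fusion losses and discarded overflow), so
    that ``alive + sum(dead) == n0 + cum_births`` at all times.
    """

    t: float
    a: dict
    q: np.ndarray
    b: np.ndarray
    g0: np.ndarray
    pol: np.ndarray
    dead: np.ndarray
    entered: np.ndarray
    cum_births: float = 0.0
    label: str = "neg"

    @classmethod
    def empty(cls, model: CompiledModel, label: str = "neg") -> "CycleState":
        nc = model.config.n_cycles
        return cls(
            t=0.0,
            a={ph: np.zeros((nc, model.n_age[ph])) for ph in PHASES},
            q=np.zeros((nc, 3)),
            b=np.zeros((nc, 3)),
            g0=np.zeros(nc),
            pol=np.zeros(nc),
            dead=np.zeros(nc),
            entered=np.zeros(nc),
            label=label,
        )

    def copy(self) -> "CycleState":
        return CycleState(
            t=self.t,
            a={ph: self.a[ph].copy() for ph in PHASES},
            q=self.q.copy(),
            b=self.b.copy(),
            g0=self.g0.copy(),
            pol=self.pol.copy(),
            dead=self.dead.copy(),
            entered=self.entered.copy(),
            cum_births=self.cum_births,
            label=self.label,
        )

    # --- aggregates -------------------------------------------------------
    def phase_totals(self, include_blocked: bool = True, include_quiescent: bool = True):
        """Alive cells per phase (G1, S, G2M), summed over cycles."""
        out = np.array([self.a[ph].sum() for ph in PHASES])
        if include_quiescent:
            out += self.q.sum(axis=0)
        if include_blocked:
            out += self.b.sum(axis=0)
        return out

    def cycle_totals(self) -> np.ndarray:
        """Alive diploid-cycle cells per cycle (polyploids excluded)."""
        out = self.q.sum(axis=1) + self.b.sum(axis=1) + self.g0
        for ph in PHASES:
            out = out + self.a[ph].sum(axis=1)
        return out

    def total_alive(self) -> float:
        return float(self.cycle_totals().sum() + self.pol.sum())


def step(state: CycleState, model: CompiledModel) -> CycleState:
    """Advance the population by one grid step ``delta_h``."""
    cfg = model.config
    lp = model.labels[state.label].at(state.t)
    new = state.copy()
    new.t = state.t + cfg.grid.delta_h
    deaths = np.zeros(cfg.n_cycles)

    # 1-3: aging/exit, block module, deaths — all from the time-t state
    forward = {}
    for ph in PHASES:
        j = PH_IDX[ph]
        occ, exits = apply_delay(state.a[ph], model.beta[ph], lp.delay[ph])
        fwd, b_new, d_b = apply_block_recycle(
            exits, lp.p_bl[ph], lp.dr_bl[ph], lp.rec[ph], state.b[:, j]
        )
        occ, d_c = apply_cycling_death(occ, lp.dr[ph])
        q_col = state.q[:, j]
        d_q = lp.dr_q[ph] * q_col
        new.a[ph] = occ
        new.b[:, j] = b_new
        new.q[:, j] = q_col - d_q
        forward[ph] = fwd
        deaths += d_b + d_c + d_q

    # 4: division and routing of newborns
    completers = forward["G2M"]
    newborns, mito_d = divide(completers, lp.m_div)
    deaths += mito_d
    out = model.p_out * newborns
    arrivals = (newborns - out).copy()
    arrivals[1:] += out[:-1]
    discarded = out[-1]  # only non-zero when p_out[f] > 0
    new.entered += arrivals

    g1_arr, pol_new, d_pol = refuse_polyploid(arrivals, lp.p_pol, lp.dr_pol, state.pol)
    fused = (lp.p_pol * arrivals).sum()
    new.pol = pol_new
    deaths += d_pol

    # 5: phase entries, each through the destination quiescence module
    if cfg.g0 is not None:
        g0s = cfg.g0
        bypass = g0s.theta * g1_arr
        d_g0 = g0s.dr * state.g0
        g1_in = bypass + g0s.gamma * state.g0
        new.g0 = state.g0 - d_g0 - g0s.gamma * state.g0 + (1 - g0s.theta) * g1_arr
        deaths += d_g0
    else:
        g1_in = g1_arr

    p_q_g1 = lp.p_q["G1"]
    if cfg.confluence is not None:
        c = cfg.confluence
        n_tot = state.total_alive()
        extra = c.pq_max * n_tot**c.slope / (c.n50**c.slope + n_tot**c.slope)
        p_q_g1 = np.clip(p_q_g1 + extra, 0.0, 1.0)

    for ph, influx, pq in (
        ("G1", g1_in, p_q_g1),
        ("S", forward["G1"], lp.p_q["S"]),
        ("G2M", forward["S"], lp.p_q["G2M"]),
    ):
        j = PH_IDX[ph]
        entry, q_new, d_entry_q = apply_quiescence(influx, pq, 0.0, new.q[:, j])
        new.a[ph][:, 0] += entry
        new.q[:, j] = q_new

    new.dead = state.dead + deaths
    new.cum_births = (
        state.cum_births
        + float(newborns.sum() - completers.sum() + mito_d.sum())
        - fused / 2.0
        - float(discarded)
    )
    return new


@dataclass
class Trajectory:
    """Ordered per-step snapshots of the simulated state."""

    states: list
    model: CompiledModel

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]


def desynchronize(
    config: ModelConfig,
    tol: float = 0.1,
    n0: float = 1000.0,
    max_steps: int = 100_000,
    growth_rtol: float = 1e-9,
) -> CycleState:
    """Asynchronous steady-state age distribution, normalized to ``n0`` cells.

    Iterates the unperturbed single-cycle model from a rough seed until the
    G1/S/G2M percentages change by less than ``tol`` percentage points per
    step *and* the per-step growth factor is stationary to ``growth_rtol``
    (so that the returned state sits on the asynchronous exponential-growth
    attractor), then rescales the converged distribution to ``n0`` cells in
    cycle 0 of the full configuration at t = 0.
    """
    base = replace(
        config.unperturbed(), n_cycles=1, p_out=(0.0,), confluence=None
    )
    model = compile_model(base)
    state = CycleState.empty(model)
    # seed: uniform over ages, phase shares proportional to mean durations
    means = np.array([config.durations[ph].mean_h for ph in PHASES])
    for ph, share in zip(PHASES, means / means.sum()):
        state.a[ph][0, :] = share / model.n_age[ph]

    prev = _phase_percent(state)
    prev_n = state.total_alive()
    prev_ratio = None
    for i in range(max_steps):
        state = step(state, model)
        cur = _phase_percent(state)
        delta = np.abs(cur - prev).max()
        n_tot = state.total_alive()
        ratio = n_tot / prev_n
        ratio_delta = abs(ratio - prev_ratio) / ratio if prev_ratio else np.inf
        prev, prev_n, prev_ratio = cur, n_tot, ratio
        # renormalize to avoid float overflow on long runs
        if n_tot > 1e12:
            _scale_state(state, 1.0 / n_tot)
            prev_n = 1.0
        if delta < tol and ratio_delta < growth_rtol and i > 10:
            break
    else:
        raise RuntimeError(
            f"desynchronization did not converge in {max_steps} steps "
            f"(last per-step change {delta:.3g}%)"
        )

    full = compile_model(config)
    out = CycleState.empty(full)
    scale = n0 / state.total_alive()
    for ph in PHASES:
        out.a[ph][0, :] = state.a[ph][0, :] * scale
    out.q[0, :] = state.q[0, :] * scale
    out.g0[0] = state.g0[0] * scale
    out.entered[0] = n0
    return out


def _phase_percent(state: CycleState) -> np.ndarray:
    tot = state.phase_totals()
    return 100.0 * tot / tot.sum()


def _scale_state(state: CycleState, f: float) -> None:
    for ph in PHASES:
        state.a[ph] *= f
    state.q *= f
    state.b *= f
    state.g0 *= f
    state.pol *= f
    state.dead *= f
    state.entered *= f
    state.cum_births *= f


def apply_brdu_pulse(state: CycleState) -> tuple[CycleState, CycleState]:
    """Split a t=0 state into independently evolving BrdU- and BrdU+ states.

    Cells in S at the pulse are labelled (BrdU+); G1, G2M, quiescent and G0
    cells stay unlabelled.  Totals are conserved exactly.
    """
    if state.t != 0:
        raise ValueError("BrdU pulse must be applied to a t=0 state")
    neg = state.copy()
    pos = state.copy()
    neg.label, pos.label = "neg", "pos"
    js = PH_IDX["S"]
    pos.a["G1"][:] = 0.0
    pos.a["G2M"][:] = 0.0
    pos.q[:] = 0.0
    pos.b[:] = 0.0
    pos.g0[:] = 0.0
    pos.pol[:] = 0.0
    neg.a["S"][:] = 0.0
    # cumulative counters split proportionally to the alive split
    tot = state.total_alive()
    s_tot = pos.total_alive()
    w_pos = s_tot / tot if tot > 0 else 0.0
    for st, w in ((neg, 1 - w_pos), (pos, w_pos)):
        st.dead = state.dead * w
        st.entered = state.entered * w
        st.cum_births = state.cum_births * w
    return neg, pos


def simulate(
    config: ModelConfig,
    t_end: float,
    brdu_pulse: bool = False,
    n0: float = 1000.0,
    tol: float = 0.1,
    start: CycleState | None = None,
):
    """Desynchronize, then step to ``t_end`` recording every snapshot.

    Returns a :class:`Trajectory`, or a ``(neg, pos)`` pair of trajectories
    when ``brdu_pulse`` is set.  ``start`` may supply a precomputed t=0 state
    (e.g. a cached desynchronization).
    """
    dt = config.grid.delta_h
    n_steps = round(t_end / dt)
    if abs(n_steps * dt - t_end) > 1e-9:
        raise ValueError(f"t_end={t_end} is not a multiple of delta_h={dt}")
    model = compile_model(config)
    state0 = start if start is not None else desynchronize(config, tol=tol, n0=n0)
    if brdu_pulse:
        parts = apply_brdu_pulse(state0)
    else:
        parts = (state0,)
    trajectories = []
    for s in parts:
        states = [s]
        cur = s
        for _ in range(n_steps):
            cur = step(cur, model)
            states.append(cur)
        trajectories.append(Trajectory(states=states, model=model))
    return tuple(trajectories) if brdu_pulse else trajectories[0]


def simulate_continuous_labelling(
    config: ModelConfig,
    t_end: float,
    washout_h: float = np.inf,
    n0: float = 1000.0,
    tol: float = 0.1,
    start: CycleState | None = None,
) -> tuple[Trajectory, Trajectory]:
    """Continuous BrdU labelling: cells entering S are transferred from the
    BrdU- to the BrdU+ sub-population until ``washout_h``.

    The starting state is split as for a pulse; thereafter, after each step
    taken before washout, the cycling cells that entered the first S
    compartment of the unlabelled run are moved to the labelled run
    (quiescent-in-S cells are not synthesizing DNA and stay unlabelled).
    With washout at infinity the labelled share of cycling cells tends
    to 100%.
    """
    dt = config.grid.delta_h
    n_steps = round(t_end / dt)
    if abs(n_steps * dt - t_end) > 1e-9:
        raise ValueError(f"t_end={t_end} is not a multiple of delta_h={dt}")
    model = compile_model(config)
    state0 = start if start is not None else desynchronize(config, tol=tol, n0=n0)
    neg, pos = apply_brdu_pulse(state0)
    neg_states, pos_states = [neg], [pos]
    for _ in range(n_steps):
        t_prev = neg.t
        delay_s_neg = model.labels["neg"].at(t_prev).delay["S"]
        retained = delay_s_neg * neg.a["S"][:, 0]
        neg = step(neg, model)
        pos = step(pos, model)
        if t_prev < washout_h:
            entrants = neg.a["S"][:, 0] - retained
            neg.a["S"][:, 0] -= entrants
            pos.a["S"][:, 0] += entrants
        neg_states.append(neg)
        pos_states.append(pos)
    return (
        Trajectory(states=neg_states, model=model),
        Trajectory(states=pos_states, model=model),
    )


def igrov1_like_config(
    grid: AgeGrid | None = None,
    n_cycles: int = 6,
    perturbations: Sequence[PerturbationSpec] = (),
    **overrides,
) -> ModelConfig:
    """Baseline configuration for an exponentially growing ovarian-carcinoma-like
    line with a ~24 h cell cycle, a few percent quiescence and slow quiescent
    death (values chosen as typical for such cultures; see docs/methods.md)."""
    return ModelConfig(
        durations={
            "G1": PhaseDurationSpec(mean_h=11.0, cv=0.25),
            "S": PhaseDurationSpec(mean_h=9.0, cv=0.15),
            "G2M": PhaseDurationSpec(mean_h=4.0, cv=0.25),
        },
        grid=grid or AgeGrid(delta_h=0.5),
        n_cycles=n_cycles,
        p_q={"G1": 0.04, "S": 0.01, "G2M": 0.01},
        dr_q={"G1": 0.002, "S": 0.002, "G2M": 0.002},
        perturbations=tuple(perturbations),
        **overrides,
    )
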