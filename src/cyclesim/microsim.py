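"""Stochastic single-cell microsimulation of the population model.

Runs the same discrete-time process as the deterministic engine, but as
per-cell Bernoulli draws on the same grid and with the same sub-step
ordering: movement/exit draws, checkpoint interception, blocked-pool
death/recycling, cycling and quiescent death, division with re-entry/
progression routing, sibling re-fusion into polyploids, G0 transit and entry
quiescence.  The expectation of every aggregate equals the deterministic
trajectory, which is the basis of the engine cross-validation tests; with
lineage tracking enabled it doubles as the generator of synthetic time-lapse
lineage databases.

Not supported here: the confluence option (density feedback on pQ_G1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (
    LABELS,
    PH_IDX,
    PHASES,
    CompiledModel,
    ModelConfig,
    compile_model,
    desynchronize,
)

__all__ = ["MicroResult", "microsimulate"]

# cell statuses
CYCLING, QUIESCENT, BLOCKED, G0, POL, DEAD, GONE, LOST, DISCARDED = range(9)
_ALIVE_DIPLOID = (CYCLING, QUIESCENT, BLOCKED, G0)


@dataclass
class MicroResult:
    """Aggregate snapshots (and optional lineage records) of a microsimulation."""

    times: np.ndarray
    phase_counts: np.ndarray  # (n_snap, 3) cycling+quiescent+blocked per phase
    cycle_counts: np.ndarray  # (n_snap, n_cycles) alive diploid cells
    pol_counts: np.ndarray  # (n_snap,)
    dead_by_cycle: np.ndarray  # (n_snap, n_cycles) cumulative
    entered_by_cycle: np.ndarray  # final cumulative entrants per cycle
    brdu_pos: np.ndarray  # (n_snap,) alive labelled cells
    und_pos: np.ndarray  # (n_snap,) labelled diploid cells still in cycle 0
    n_sampled: int
    records: pd.DataFrame | None = None


class _Cells:
    """Growable struct-of-arrays cell store."""

    def __init__(self, n: int):
        self.status = np.full(n, CYCLING, dtype=np.int8)
        self.phase = np.zeros(n, dtype=np.int8)
        self.age = np.ones(n, dtype=np.int32)
        self.cycle = np.zeros(n, dtype=np.int16)
        self.pos = np.zeros(n, dtype=bool)  # BrdU label
        self.birth_step = np.zeros(n, dtype=np.int32)
        self.root = np.arange(n, dtype=np.int32)
        self.outcome = np.full(n, "", dtype="U2")
        self.outcome_step = np.full(n, -1, dtype=np.int32)

    def __len__(self) -> int:
        return self.status.size

    def append(self, **arrays) -> None:
        n_new = arrays["status"].size
        for name in vars(self):
            arr = getattr(self, name)
            add = arrays.get(name)
            if add is None:
                add = np.zeros(n_new, dtype=arr.dtype)
            setattr(self, name, np.concatenate([arr, add]))


def _sample_initial(
    model: CompiledModel, n0: int, rng: np.random.Generator, brdu_pulse: bool
) -> _Cells:
    """Multinomial sample of n0 cells from the asynchronous age distribution."""
    state = desynchronize(model.config)
    slots = []  # (prob, status, phase, age)
    for ph in PHASES:
        occ = state.a[ph][0]
        for k, w in enumerate(occ):
            if w > 0:
                slots.append((w, CYCLING, PH_IDX[ph], k + 1))
    for j, ph in enumerate(PHASES):
        if state.q[0, j] > 0:
            slots.append((state.q[0, j], QUIESCENT, j, 0))
    if state.g0[0] > 0:
        slots.append((state.g0[0], G0, 0, 0))
    probs = np.array([s[0] for s in slots])
    probs /= probs.sum()
    counts = rng.multinomial(n0, probs)
    cells = _Cells(n0)
    pos = 0
    for (w, st, ph, k), c in zip(slots, counts):
        cells.status[pos : pos + c] = st
        cells.phase[pos : pos + c] = ph
        cells.age[pos : pos + c] = k
        pos += c
    if brdu_pulse:
        cells.pos[:] = (cells.status == CYCLING) & (cells.phase == PH_IDX["S"])
    return cells


def microsimulate(
    config: ModelConfig,
    t_end: float,
    n0: int = 10_000,
    seed: int | np.random.Generator = 0,
    brdu_pulse: bool = False,
    lineage: bool = False,
    fl_rate: float = 0.0,
    snapshot_every: int = 1,
    treatment: str = "ctrl",
    capture_interval_h: float | None = None,
    roots_per_field: int = 50,
) -> MicroResult:
    """Stochastic microsimulation of ``n0`` cells up to ``t_end`` hours.

    Parameters
    ----------
    lineage : bool
        Track per-cell records (treatment/field/lineage/generation, birth and
        outcome times, outcome code M/D/S/R/FL) as in a time-lapse lineage
        database.  Generation is meaningful when the configuration is the
        multi-generation wiring (``p_out[i] = 1``).
    fl_rate : float
        Per-step probability that a tracked cell is lost from the field of
        view (FL); lineage mode only.
    capture_interval_h : float, optional
        Event times in the records are rounded to this capture grid
        (default: 20 minutes, as for a time-lapse acquisition).
    """
    if config.confluence is not None:
        raise NotImplementedError("confluence feedback is not microsimulated")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = compile_model(config)
    cfg = model.config
    dt = cfg.grid.delta_h
    n_steps = round(t_end / dt)
    if abs(n_steps * dt - t_end) > 1e-9:
        raise ValueError("t_end must be a multiple of delta_h")
    nc = cfg.n_cycles
    p_out = model.p_out
    g0s = cfg.g0

    cells = _Cells(0)
    cells.append(**vars(_sample_initial(model, n0, rng, brdu_pulse)))
    entered = np.zeros(nc)
    entered[0] = n0

    snap_idx = list(range(0, n_steps + 1, snapshot_every))
    if snap_idx[-1] != n_steps:
        snap_idx.append(n_steps)
    snaps = {i: None for i in snap_idx}

    def snapshot():
        alive = np.isin(cells.status, _ALIVE_DIPLOID)
        in_phase = alive & (cells.status != G0)
        phase_counts = np.bincount(cells.phase[in_phase], minlength=3).astype(float)
        cycle_counts = np.bincount(cells.cycle[alive], minlength=nc).astype(float)[:nc]
        pol = float((cells.status == POL).sum())
        dead = np.bincount(
            cells.cycle[cells.status == DEAD], minlength=nc
        ).astype(float)[:nc]
        pos_alive = float(((alive | (cells.status == POL)) & cells.pos).sum())
        und = float((alive & cells.pos & (cells.cycle == 0)).sum())
        return phase_counts, cycle_counts, pol, dead, pos_alive, und

    snaps[0] = snapshot()

    for s in range(n_steps):
        t = s * dt
        for lab in LABELS:
            lp = model.labels[lab].at(t)
            lmask = cells.pos if lab == "pos" else ~cells.pos
            forward: dict[str, list[np.ndarray]] = {ph: [] for ph in PHASES}

            # blocked pool: simultaneous death/recycle draws on start-of-step pool
            for ph in PHASES:
                j = PH_IDX[ph]
                idx = np.nonzero(lmask & (cells.status == BLOCKED) & (cells.phase == j))[0]
                if not idx.size:
                    continue
                cy = cells.cycle[idx]
                u = rng.random(idx.size)
                dr = lp.dr_bl[ph][cy]
                rec = lp.rec[ph][cy]
                die = u < dr
                recyc = (~die) & (u < dr + rec)
                _kill(cells, idx[die], s)
                forward[ph].append(idx[recyc])

            # cycling movement + interception + cycling death
            ph0 = cells.phase.copy()
            st0 = cells.status.copy()
            for ph in PHASES:
                j = PH_IDX[ph]
                idx = np.nonzero(lmask & (st0 == CYCLING) & (ph0 == j))[0]
                if not idx.size:
                    continue
                cy = cells.cycle[idx]
                beta_k = model.beta[ph][cells.age[idx] - 1]
                mob = 1.0 - lp.delay[ph][cy]
                u = rng.random(idx.size)
                p_exit = mob * beta_k
                exiting = u < p_exit
                advancing = (~exiting) & (u < mob)
                cells.age[idx[advancing]] += 1
                stayers = idx[~exiting]
                u2 = rng.random(stayers.size)
                _kill(cells, stayers[u2 < lp.dr[ph][cells.cycle[stayers]]], s)
                comp = idx[exiting]
                if comp.size:
                    u3 = rng.random(comp.size)
                    blocked = u3 < lp.p_bl[ph][cells.cycle[comp]]
                    cells.status[comp[blocked]] = BLOCKED
                    forward[ph].append(comp[~blocked])

            # quiescent, G0 and polyploid deaths; G0 -> G1 exits
            g1_entrants = []  # index arrays of existing cells entering G1 at age 1
            for ph in PHASES:
                j = PH_IDX[ph]
                idx = np.nonzero(lmask & (st0 == QUIESCENT) & (ph0 == j))[0]
                if idx.size:
                    u = rng.random(idx.size)
                    _kill(cells, idx[u < lp.dr_q[ph][cells.cycle[idx]]], s)
            idx = np.nonzero(lmask & (st0 == POL))[0]
            if idx.size:
                u = rng.random(idx.size)
                dies = u < lp.dr_pol[cells.cycle[idx]]
                cells.status[idx[dies]] = DEAD  # no lineage record for fused entities
            if g0s is not None:
                idx = np.nonzero(lmask & (st0 == G0))[0]
                if idx.size:
                    u = rng.random(idx.size)
                    _kill(cells, idx[u < g0s.dr], s)
                    exits = idx[(u >= g0s.dr) & (u < g0s.dr + g0s.gamma)]
                    g1_entrants.append(exits)

            # phase transitions G1->S, S->G2M with entry quiescence
            for src, dst in (("G1", "S"), ("S", "G2M")):
                idx = _cat(forward[src])
                if idx.size:
                    _enter_phase(cells, idx, dst, lp, rng)

            # division, routing and re-fusion
            mothers = _cat(forward["G2M"])
            if mothers.size:
                cy = cells.cycle[mothers]
                u = rng.random(mothers.size)
                fertile = u < lp.m_div[cy] / 2.0
                _kill(cells, mothers[~fertile], s)  # death in mitosis (m_div < 2)
                mothers = mothers[fertile]
                cells.status[mothers] = GONE
                cells.outcome[mothers] = "M"
                cells.outcome_step[mothers] = s + 1
                cy = cells.cycle[mothers]
                dest = cy + (rng.random(mothers.size) < p_out[cy]).astype(np.int16)
                keep = dest < nc
                disc = mothers[~keep]  # p_out[f]=1: generation f+1 not considered
                mothers, dest = mothers[keep], dest[keep]
                np.add.at(entered, dest, 2.0)
                refuse = rng.random(mothers.size) < lp.p_pol[dest]
                rm, rd = mothers[refuse], dest[refuse]
                if rm.size:
                    # two newborn records with outcome R + one unrecorded
                    # polyploid entity per re-fused pair
                    _spawn(cells, rm, rd, s, lab, status=GONE, n_per=2, outcome="R")
                    _spawn(cells, rm, rd, s, lab, status=POL, n_per=1)
                km, kd = mothers[~refuse], dest[~refuse]
                if km.size:
                    child_idx = _spawn(cells, km, kd, s, lab, status=CYCLING, n_per=2)
                    # G0 / quiescence processing for newborns
                    if g0s is not None:
                        u = rng.random(child_idx.size)
                        to_g0 = u >= g0s.theta
                        cells.status[child_idx[to_g0]] = G0
                        child_idx = child_idx[~to_g0]
                    if child_idx.size:
                        g1_entrants.append(child_idx)

            idx = _cat(g1_entrants)
            if idx.size:
                _enter_phase(cells, idx, "G1", lp, rng)

        # field loss (lineage mode)
        if fl_rate > 0:
            alive = np.isin(cells.status, _ALIVE_DIPLOID)
            idx = np.nonzero(alive)[0]
            u = rng.random(idx.size)
            lost = idx[u < fl_rate]
            cells.status[lost] = LOST
            cells.outcome[lost] = "FL"
            cells.outcome_step[lost] = s + 1

        if (s + 1) in snaps:
            snaps[s + 1] = snapshot()

    # survivors at the end of observation
    alive = np.isin(cells.status, _ALIVE_DIPLOID)
    cells.outcome[alive] = "S"
    cells.outcome_step[alive] = n_steps

    records = None
    if lineage:
        tracked = cells.outcome != ""
        # polyploid entities and discarded overflow have no lineage record
        birth = cells.birth_step[tracked] * dt
        outcome_t = cells.outcome_step[tracked] * dt
        cap = capture_interval_h if capture_interval_h is not None else 1.0 / 3.0
        birth = np.where(birth > 0, np.round(birth / cap) * cap, 0.0)
        is_end = cells.outcome[tracked] == "S"
        outcome_t = np.where(is_end, t_end, np.round(outcome_t / cap) * cap)
        outcome_t = np.maximum(outcome_t, birth)
        records = pd.DataFrame(
            {
                "treatment": treatment,
                "field": cells.root[tracked] // roots_per_field,
                "lineage": cells.root[tracked],
                "generation": cells.cycle[tracked].astype(int),
                "birth_time_h": birth,
                "outcome_time_h": outcome_t,
                "outcome": cells.outcome[tracked],
            }
        ).sort_values(["field", "lineage", "birth_time_h"], kind="stable")
        records = records.reset_index(drop=True)

    order = sorted(snaps)
    phase_counts = np.array([snaps[i][0] for i in order])
    cycle_counts = np.array([snaps[i][1] for i in order])
    return MicroResult(
        times=np.array(order) * dt,
        phase_counts=phase_counts,
        cycle_counts=cycle_counts,
        pol_counts=np.array([snaps[i][2] for i in order]),
        dead_by_cycle=np.array([snaps[i][3] for i in order]),
        entered_by_cycle=entered,
        brdu_pos=np.array([snaps[i][4] for i in order]),
        und_pos=np.array([snaps[i][5] for i in order]),
        n_sampled=n0,
        records=records,
    )


def _cat(parts: list) -> np.ndarray:
    parts = [p for p in parts if p is not None and len(p)]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(parts)


def _kill(cells: _Cells, idx: np.ndarray, s: int) -> None:
    if idx.size:
        cells.status[idx] = DEAD
        cells.outcome[idx] = "D"
        cells.outcome_step[idx] = s + 1


def _enter_phase(cells, idx, phase: str, lp, rng) -> None:
    """Route entrants through the destination phase's quiescence module."""
    j = PH_IDX[phase]
    cells.phase[idx] = j
    u = rng.random(idx.size)
    q = u < lp.p_q[phase][cells.cycle[idx]]
    cells.status[idx[q]] = QUIESCENT
    rest = idx[~q]
    cells.status[rest] = CYCLING
    cells.age[rest] = 1


def _spawn(cells, mothers, dest, s, lab, status, n_per, outcome="") -> np.ndarray:
    """Create offspring entries; returns their indices."""
    n = mothers.size * n_per
    rep = np.repeat(mothers, n_per)
    start = len(cells)
    cells.append(
        status=np.full(n, status, dtype=np.int8),
        phase=np.zeros(n, dtype=np.int8),
        age=np.ones(n, dtype=np.int32),
        cycle=np.repeat(dest, n_per).astype(np.int16),
        pos=np.full(n, lab == "pos"),
        birth_step=np.full(n, s + 1, dtype=np.int32),
        root=cells.root[rep],
        outcome=np.full(n, outcome, dtype="U2"),
        outcome_step=np.full(n, s + 1 if outcome else -1, dtype=np.int32),
    )
    return np.arange(start, start + n, dtype=np.int64)
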