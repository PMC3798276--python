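"""Derived, measurement-like quantities from simulated trajectories.

Maps the age-structured state onto what the two experimental platforms see:
flow-cytometry phase percentages and BrdU subsets, and time-lapse-like
per-generation cell counts, death fractions and the intermitotic-time
distribution.  Blocked and quiescent cells count in the phase whose DNA
content they carry; polyploid cells are excluded from the diploid-cycle
percentage denominator by default (their DNA content lies beyond G2M in a
histogram) but can be included with a switch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import PHASES, Trajectory
from .phase_kinetics import convolve, mass_mean_h

__all__ = [
    "phase_percentages",
    "generation_counts",
    "brdu_series",
    "tc_distribution",
    "death_fraction_per_generation",
    "observable_table",
]


def _as_traj_list(traj) -> list[Trajectory]:
    if isinstance(traj, Trajectory):
        return [traj]
    return list(traj)


def phase_percentages(traj, include_polyploid: bool = False) -> pd.DataFrame:
    """%G1/%S/%G2M over time (cycling + quiescent + blocked, all cycles and labels).

    ``traj`` is a Trajectory or a (BrdU-, BrdU+) pair; pairs are summed.
    Percentages are over the diploid-cycle total unless ``include_polyploid``.
    """
    trajs = _as_traj_list(traj)
    times = trajs[0].times
    rows = []
    for i, t in enumerate(times):
        tot = np.zeros(3)
        pol = 0.0
        for tr in trajs:
            s = tr[i]
            tot += s.phase_totals()
            pol += s.pol.sum()
        denom = tot.sum() + (pol if include_polyploid else 0.0)
        if denom <= 0:
            raise ValueError(f"empty population at t={t}: percentages undefined")
        rows.append(100.0 * tot / denom)
    out = pd.DataFrame(rows, columns=["pct_g1", "pct_s", "pct_g2m"])
    out.insert(0, "time_h", times)
    return out


def generation_counts(traj, n0_norm: float = 1000.0) -> pd.DataFrame:
    """Cells per generation over time, normalized so that N(0) = ``n0_norm``.

    Columns ``n_gen0 .. n_gen{f}`` (the final cycle pools generations >= f
    when ``p_out[f] = 0``), plus ``n_pol`` and the total ``n``.
    """
    trajs = _as_traj_list(traj)
    times = trajs[0].times
    nc = trajs[0].model.config.n_cycles
    gen = np.zeros((len(times), nc))
    pol = np.zeros(len(times))
    for tr in trajs:
        for i in range(len(times)):
            s = tr[i]
            gen[i] += s.cycle_totals()
            pol[i] += s.pol.sum()
    n0 = gen[0].sum() + pol[0]
    scale = n0_norm / n0
    out = pd.DataFrame(gen * scale, columns=[f"n_gen{i}" for i in range(nc)])
    out["n_pol"] = pol * scale
    out["n"] = out.sum(axis=1)
    out.insert(0, "time_h", times)
    return out


def brdu_series(traj_neg: Trajectory, traj_pos: Trajectory) -> pd.DataFrame:
    """%BrdU+ and %Und+ time courses from a paired pulse-chase run.

    %BrdU+ is the labelled share of the whole population; %Und+ is the share
    of labelled cells still in generation 0 (cycling, blocked or quiescent),
    i.e. labelled cells that have not yet divided.
    """
    if len(traj_neg) != len(traj_pos) or traj_neg[0].label == traj_pos[0].label:
        raise ValueError("brdu_series needs a paired (neg, pos) pulse run")
    rows = []
    for s_neg, s_pos in zip(traj_neg.states, traj_pos.states):
        total = s_neg.total_alive() + s_pos.total_alive()
        und = s_pos.cycle_totals()[0]
        rows.append(
            (s_neg.t, 100.0 * s_pos.total_alive() / total, 100.0 * und / total)
        )
    return pd.DataFrame(rows, columns=["time_h", "pct_brdu_pos", "pct_und_pos"])


def tc_distribution(
    dists: dict,
    delays: dict | None = None,
) -> tuple[np.ndarray, float]:
    """Intermitotic-time distribution F(Tc) and its mean.

    F(Tc) is the double convolution of the G1, S and G2M duration masses
    (meaningful for untreated or delay-only configurations).  With type-I
    delays the mean stretches to ``sum T_ph / (1 - del_ph)`` while the full
    distribution is reported for the undelayed law only.

    Returns ``(mass, mean_h)``; ``mass[k-1]`` is the probability that the
    whole cycle takes ``k`` grid steps.
    """
    delays = delays or {}
    f = convolve(dists["G1"].mass, dists["S"].mass)
    f = convolve(f, dists["G2M"].mass)
    dt = dists["G1"].grid.delta_h
    mean = sum(
        mass_mean_h(dists[ph].mass, dt) / (1.0 - delays.get(ph, 0.0)) for ph in PHASES
    )
    return f, mean


def death_fraction_per_generation(traj) -> pd.DataFrame:
    """Percentage of cells that died, among cells entered in each generation,
    over the whole observation window."""
    trajs = _as_traj_list(traj)
    nc = trajs[0].model.config.n_cycles
    dead = np.zeros(nc)
    entered = np.zeros(nc)
    for tr in trajs:
        dead += tr[-1].dead
        entered += tr[-1].entered
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(entered > 0, 100.0 * dead / entered, np.nan)
    return pd.DataFrame(
        {"generation": np.arange(nc), "entered": entered, "died": dead,
         "pct_died": frac}
    )


def observable_table(traj, dose: float = 0.0, brdu: bool = True) -> pd.DataFrame:
    """Tidy long-format table (dose, time_h, quantity, value) of all series."""
    trajs = _as_traj_list(traj)
    frames = []
    pct = phase_percentages(trajs)
    frames.append(pct.melt("time_h", var_name="quantity", value_name="value"))
    gen = generation_counts(trajs)
    frames.append(gen.melt("time_h", var_name="quantity", value_name="value"))
    if brdu and len(trajs) == 2:
        bs = brdu_series(*trajs)
        frames.append(bs.melt("time_h", var_name="quantity", value_name="value"))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "dose", dose)
    return out
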