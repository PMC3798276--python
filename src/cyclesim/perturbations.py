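"""Treatment-effect modules bindable to any (phase, cycle) slot.

Checkpoint activity and cell loss after treatment are rendered by small
operators superimposed on the unperturbed flow of cell cohorts:

* ``delay`` (type I) — a fraction ``del_ph`` of the cells that would move to
  the next age compartment is retained, stretching the realized mean transit
  time to ``T/(1-del_ph)``; ``del_ph = 1`` freezes the phase.
* ``block`` (type II) — a fraction ``p_bl`` of phase-completing cells is
  diverted to a blocked compartment where they may die at per-step
  probability ``dr_bl``.
* ``block_recycle`` (type III) — adds a per-step recycling probability
  ``rec``: blocked cells either die, recycle into the next phase, or remain
  blocked.
* ``block_recycle_timed`` (type IV) — type III with ``p_bl``/``dr_bl``/``rec``
  following a Hill time-course (delayed onset of block, recovery or death).
* ``cycling_death`` — first-order loss of all non-blocked cells of a phase.
* ``mitosis`` — multiplies phase-completing G2M cells by ``m_div``
  (default 2; ``m_div < 2`` renders death in mitosis).
* ``polyploid`` — a fraction ``p_pol`` of newborn sibling pairs re-fuses into
  single polyploid cells pooled outside the diploid cycle, dying at
  ``dr_pol`` per step.
* ``quiescence`` — a fraction ``p_q`` of cells entering a phase becomes
  definitively quiescent, with spontaneous death ``dr_q``.

All probabilities/rates are per step of the simulation grid.  Any module at
its neutral parameter values is an exact no-op on trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PerturbationSpec",
    "TimedParam",
    "hill_time",
    "apply_delay",
    "apply_block",
    "apply_block_recycle",
    "apply_cycling_death",
    "apply_quiescence",
    "apply_mitosis_polyploid",
]

PHASES = ("G1", "S", "G2M")
KINDS = (
    "delay",
    "block",
    "block_recycle",
    "block_recycle_timed",
    "cycling_death",
    "mitosis",
    "polyploid",
    "quiescence",
)
LABEL_SCOPES = ("both", "neg", "pos")


def hill_time(t: float, start: float, end: float, it50: float, m: float) -> float:
    """Hill time-course ``start + (end-start) * t^m / (it50^m + t^m)``.

    ``it50`` is the time at which half of the start-to-end transition is
    reached; ``m`` sets the steepness.
    """
    if it50 <= 0:
        raise ValueError("it50 must be > 0")
    if m <= 0:
        raise ValueError("m must be > 0")
    if t <= 0:
        return start
    x = (t / it50) ** m
    return start + (end - start) * x / (1.0 + x)


@dataclass(frozen=True)
class TimedParam:
    """Hill-shaped per-step parameter time course (checkpoint module type IV).

    ``it50`` and ``m`` are fixed configuration constants, not fitted.
    """

    start: float
    end: float
    it50: float = 24.0
    m: float = 4.0

    def value(self, t: float) -> float:
        return hill_time(t, self.start, self.end, self.it50, self.m)


@dataclass(frozen=True)
class PerturbationSpec:
    """One treatment module bound to phase/cycle/label slots.

    Parameters
    ----------
    kind : str
        One of ``delay, block, block_recycle, block_recycle_timed,
        cycling_death, mitosis, polyploid, quiescence``.
    phase : str or None
        G1/S/G2M for phase-bound kinds; ``None`` for mitosis/polyploid
        (they act at division, i.e. between cycles).
    cycles : tuple of int
        Cycle indices the module applies to.  For ``polyploid`` these are
        destination cycles (the generation the newborns enter).
    label : {"both", "neg", "pos"}
        BrdU sub-population scope.
    params : dict
        Module parameters; scalar floats, or :class:`TimedParam` for the
        timed entries of type IV (and optionally ``p_pol``).
    """

    kind: str
    phase: str | None = None
    cycles: tuple[int, ...] = (0,)
    label: str = "both"
    params: dict = field(default_factory=dict)

    _SCALAR_RANGES = {
        "del_ph": (0.0, 1.0),
        "p_bl": (0.0, 1.0),
        "dr_bl": (0.0, 1.0),
        "rec": (0.0, 1.0),
        "dr": (0.0, 1.0),
        "p_pol": (0.0, 1.0),
        "dr_pol": (0.0, 1.0),
        "p_q": (0.0, 1.0),
        "dr_q": (0.0, 1.0),
    }
    _REQUIRED = {
        "delay": ("del_ph",),
        "block": ("p_bl", "dr_bl"),
        "block_recycle": ("p_bl", "dr_bl", "rec"),
        "block_recycle_timed": ("p_bl", "dr_bl", "rec"),
        "cycling_death": ("dr",),
        "mitosis": ("m_div",),
        "polyploid": ("p_pol", "dr_pol"),
        "quiescence": ("p_q", "dr_q"),
    }
    _PHASE_BOUND = (
        "delay",
        "block",
        "block_recycle",
        "block_recycle_timed",
        "cycling_death",
        "quiescence",
    )

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.label not in LABEL_SCOPES:
            raise ValueError(f"unknown label scope {self.label!r}")
        if self.kind in self._PHASE_BOUND:
            if self.phase not in PHASES:
                raise ValueError(f"{self.kind} module requires phase in {PHASES}")
        elif self.phase is not None:
            raise ValueError(f"{self.kind} module is not phase-bound")
        if not self.cycles or any(c < 0 for c in self.cycles):
            raise ValueError("cycles must be non-empty, non-negative")
        object.__setattr__(self, "cycles", tuple(self.cycles))
        missing = [p for p in self._REQUIRED[self.kind] if p not in self.params]
        if missing:
            raise ValueError(f"{self.kind} module missing parameters {missing}")
        for name, value in self.params.items():
            if isinstance(value, TimedParam):
                if self.kind not in ("block_recycle_timed", "polyploid"):
                    raise ValueError(
                        f"timed parameter {name!r} only allowed in type IV / polyploid"
                    )
                lo, hi = self._SCALAR_RANGES.get(name, (-np.inf, np.inf))
                if not (lo <= value.start <= hi and lo <= value.end <= hi):
                    raise ValueError(f"timed {name!r} endpoints out of range")
                continue
            if name == "m_div":
                if not 0 < value <= 2:
                    raise ValueError(f"m_div must be in (0, 2], got {value}")
                continue
            lo, hi = self._SCALAR_RANGES.get(name, (None, None))
            if lo is not None and not (lo <= value <= hi):
                raise ValueError(f"parameter {name!r}={value} outside [{lo}, {hi}]")
        if self.kind in ("block_recycle", "block_recycle_timed"):
            dr, rec = self.params["dr_bl"], self.params["rec"]
            dr_hi = max(dr.start, dr.end) if isinstance(dr, TimedParam) else dr
            rec_hi = max(rec.start, rec.end) if isinstance(rec, TimedParam) else rec
            if dr_hi + rec_hi > 1.0 + 1e-12:
                raise ValueError(
                    f"dr_bl + rec must be <= 1 per step (got {dr_hi} + {rec_hi})"
                )


# ---------------------------------------------------------------------------
# vectorized module operators (shared by the deterministic engine and tests)
# ---------------------------------------------------------------------------


def apply_delay(
    occupancy: np.ndarray, beta: np.ndarray, del_ph: float | np.ndarray = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """One aging step of a phase, with optional type-I delay.

    Of the cells in compartment ``k``, a fraction ``del_ph`` is retained
    (neither ages nor exits); of the mobile remainder, ``beta[k]`` exits the
    phase and the rest advances to ``k+1``.  ``beta[-1] == 1`` guarantees no
    cell outlives the truncation.

    Parameters
    ----------
    occupancy : (..., n) array
        Cell counts per age compartment; leading axes (e.g. cycles) are
        broadcast.
    beta : (n,) array
    del_ph : scalar or (...,) array of per-slot delays in [0, 1]

    Returns
    -------
    new_occupancy : same shape as ``occupancy``
    exit_flux : (...,) total cells completing the phase this step
    """
    occ = np.asarray(occupancy, dtype=float)
    delay = np.asarray(del_ph, dtype=float)
    if np.any((delay < 0) | (delay > 1)):
        raise ValueError("del_ph must lie in [0, 1]")
    mobile = (1.0 - delay)[..., None] * occ if delay.ndim else (1.0 - delay) * occ
    exits = mobile * beta
    advancing = mobile - exits
    new = occ - mobile
    new[..., 1:] += advancing[..., :-1]
    return new, exits.sum(axis=-1)


def apply_block(
    exit_flux: np.ndarray,
    p_bl: float | np.ndarray,
    dr_bl: float | np.ndarray,
    blocked: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Type-II checkpoint: permanent block of a fraction of completers.

    Returns ``(forward_flux, new_blocked, deaths)``.
    """
    return apply_block_recycle(exit_flux, p_bl, dr_bl, 0.0, blocked)


def apply_block_recycle(
    exit_flux: np.ndarray,
    p_bl: float | np.ndarray,
    dr_bl: float | np.ndarray,
    rec: float | np.ndarray,
    blocked: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Type-III checkpoint: block with competing per-step death and recycling.

    A fraction ``p_bl`` of the phase-completing flux is intercepted into the
    blocked pool.  Death (``dr_bl``) and recycling (``rec``) act
    simultaneously on the start-of-step blocked pool, so the eventual fates
    of a blocked cell are ``dr_bl/(dr_bl+rec)`` death and ``rec/(dr_bl+rec)``
    recycling (when the pool drains).  Recycled cells join the forward flux
    into the next phase at age 1.

    Returns ``(forward_flux, new_blocked, deaths)``.
    """
    if np.any(np.asarray(dr_bl) + np.asarray(rec) > 1.0 + 1e-12):
        raise ValueError("dr_bl + rec must be <= 1 per step")
    intercepted = np.asarray(p_bl) * exit_flux
    deaths = np.asarray(dr_bl) * blocked
    recycled = np.asarray(rec) * blocked
    new_blocked = blocked - deaths - recycled + intercepted
    forward = exit_flux - intercepted + recycled
    return forward, new_blocked, deaths


def apply_cycling_death(
    occupancy: np.ndarray, dr: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First-order death of all cycling cells of a phase.

    Returns ``(new_occupancy, deaths_per_slot)``.
    """
    occ = np.asarray(occupancy, dtype=float)
    d = np.asarray(dr, dtype=float)
    loss = (d[..., None] if d.ndim else d) * occ
    return occ - loss, loss.sum(axis=-1)


def apply_quiescence(
    entering_flux: np.ndarray,
    p_q: float | np.ndarray,
    dr_q: float | np.ndarray,
    quiescent: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Divert a fraction of phase entrants to the quiescent pool.

    Quiescent cells never re-enter the cycle; they die at ``dr_q`` per step.
    Returns ``(cycling_entry, new_quiescent, deaths)``.
    """
    diverted = np.asarray(p_q) * entering_flux
    deaths = np.asarray(dr_q) * quiescent
    return entering_flux - diverted, quiescent - deaths + diverted, deaths


def divide(completers: np.ndarray, m_div: float | np.ndarray = 2.0):
    """Mitosis: ``m_div`` newborns per completing cell; the ``2 - m_div``
    deficit per division is booked as mitotic death."""
    newborns = np.asarray(m_div) * completers
    mitotic_deaths = (2.0 - np.asarray(m_div)) / 2.0 * completers
    return newborns, mitotic_deaths


def refuse_polyploid(
    arrivals: np.ndarray,
    p_pol: float | np.ndarray,
    dr_pol: float | np.ndarray,
    pol_pool: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Re-fusion of newborn sibling pairs into single polyploid cells.

    A fraction ``p_pol`` of newborns arriving in a generation re-fuses
    pairwise: ``p_pol * arrivals`` cells are removed from G1 entry and
    ``p_pol * arrivals / 2`` fused cells join the polyploid pool, which
    decays at ``dr_pol`` per step.

    Returns ``(g1_entry, new_pol_pool, deaths)``.
    """
    fused_away = np.asarray(p_pol) * arrivals
    deaths = np.asarray(dr_pol) * pol_pool
    new_pool = pol_pool - deaths + fused_away / 2.0
    return arrivals - fused_away, new_pool, deaths


def apply_mitosis_polyploid(
    completers: np.ndarray,
    m_div: float | np.ndarray,
    p_pol: float | np.ndarray,
    dr_pol: float | np.ndarray,
    pol_pool: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Combined division + polyploidization for a single destination slot.

    Returns ``(g1_bound_newborns, new_pol_pool, deaths)`` where deaths
    include polyploid-pool losses and mitotic deficit when ``m_div < 2``.
    """
    newborns, mito_deaths = divide(completers, m_div)
    g1_entry, new_pool, pol_deaths = refuse_polyploid(newborns, p_pol, dr_pol, pol_pool)
    return g1_entry, new_pool, pol_deaths + mito_deaths
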