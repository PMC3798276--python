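"""Parameter estimation from FC + TL datasets.

A *model structure* is an untreated baseline configuration plus a list of
perturbation-module slots whose parameter entries may name free parameters.
Single-dose fits estimate those parameters directly; multi-dose fits
constrain each effect parameter to a smooth dose-response law (Hill or
gamma form) and estimate the dose-response coefficients jointly on all
doses, which keeps the free-parameter count well below independent per-dose
fits.  Optimization is bounded nonlinear least squares on the residual
vector (trust-region-reflective with finite-difference gradients) with
seeded multi-starts; the deterministic simulation output turns out smooth
enough in its parameters for this to outperform derivative-free simplex or
line-search methods by more than an order of magnitude in function
evaluations (both remain selectable via ``method``).  Uncertainty comes
from a parametric bootstrap: synthetic datasets are generated from the
best-fit model with the measurement-noise model and refitted.

The objective is a weighted sum of squared residuals over all series:
FC percentages (%G1, %S, %G2M and, when present, %BrdU+, %Und+) weighted by
inverse replicate variance (with a floor), and TL per-generation cell
numbers expressed in percent of the starting population (N(0)=1000 -> /10).
Mean absolute errors are reported separately per platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .data_io import FC_BRDU, TLStats
from .engine import PHASES, ModelConfig, desynchronize, simulate
from .perturbations import PerturbationSpec

__all__ = [
    "FreeParameter",
    "ModelStructure",
    "DoseData",
    "DoseResponseSpec",
    "FitResult",
    "build_config",
    "dose_response_eval",
    "objective",
    "fit_single_dose",
    "fit_multi_dose",
    "bootstrap_uncertainty",
]

_SD_FLOOR = 1.0  # percentage points; avoids infinite weight on tiny replicate SDs
_TL_STRIDE_H = 4.0  # TL generation-count residuals are taken every 4 h
_N0_NORM = 1000.0


@dataclass(frozen=True)
class FreeParameter:
    name: str
    bounds: tuple[float, float]
    init: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"empty bounds for {self.name}")
        if self.init is not None and not lo <= self.init <= hi:
            raise ValueError(f"init for {self.name} outside bounds")


@dataclass(frozen=True)
class ModelStructure:
    """Untreated baseline + perturbation slots with free-parameter references.

    ``slots`` entries are dicts with keys ``kind, phase, cycles, label,
    params``; parameter values that are strings name free parameters (a name
    used in several slots is shared across them).
    """

    base: ModelConfig
    slots: tuple = ()

    def free_names(self) -> list[str]:
        names = []
        for slot in self.slots:
            for v in slot["params"].values():
                if isinstance(v, str) and v not in names:
                    names.append(v)
        return names


def build_config(structure: ModelStructure, values: dict) -> ModelConfig:
    """Substitute free-parameter values into the structure's slots."""
    perts = list(structure.base.perturbations)
    for slot in structure.slots:
        params = {
            k: (values[v] if isinstance(v, str) else v)
            for k, v in slot["params"].items()
        }
        perts.append(
            PerturbationSpec(
                kind=slot["kind"],
                phase=slot.get("phase"),
                cycles=tuple(slot.get("cycles", (0,))),
                label=slot.get("label", "both"),
                params=params,
            )
        )
    return replace(structure.base, perturbations=tuple(perts))


@dataclass
class DoseData:
    """One dose's measurements: FC table rows and/or TL statistics."""

    fc: pd.DataFrame | None = None
    tl: TLStats | None = None
    dose: float = 0.0

    def __post_init__(self) -> None:
        if self.fc is None and self.tl is None:
            raise ValueError("DoseData needs at least one platform")


@dataclass(frozen=True)
class DoseResponseSpec:
    """Smooth dose-response law binding a module parameter across doses.

    ``hill``: y(D) = max * D^slope / (ed50^slope + D^slope)  (y(0) = 0)
    ``gamma``: y(D) = a * D^b * exp(-c * D)  (non-monotone for c > 0, with
    an interior maximum at D = b/c)

    Coefficient values may be numbers or strings naming free coefficients
    of a multi-dose fit.
    """

    form: str
    coeffs: dict

    _REQUIRED = {"hill": ("max", "ed50", "slope"), "gamma": ("a", "b", "c")}

    def __post_init__(self) -> None:
        if self.form not in self._REQUIRED:
            raise ValueError(f"unknown dose-response form {self.form!r}")
        missing = [k for k in self._REQUIRED[self.form] if k not in self.coeffs]
        if missing:
            raise ValueError(f"{self.form} dose-response missing {missing}")

    def resolve(self, values: dict) -> "DoseResponseSpec":
        coeffs = {
            k: (values[v] if isinstance(v, str) else v)
            for k, v in self.coeffs.items()
        }
        return DoseResponseSpec(self.form, coeffs)


def dose_response_eval(
    dose: float, spec: DoseResponseSpec, bounds: tuple[float, float] = (0.0, 1.0)
) -> float:
    """Evaluate a (numeric) dose-response law, clipped to the target bounds."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    c = spec.coeffs
    if any(isinstance(v, str) for v in c.values()):
        raise ValueError("unresolved free coefficients in dose-response spec")
    if spec.form == "hill":
        if dose == 0:
            y = 0.0
        else:
            x = (dose / c["ed50"]) ** c["slope"]
            y = c["max"] * x / (1.0 + x)
    else:  # gamma
        y = 0.0 if dose == 0 else c["a"] * dose ** c["b"] * np.exp(-c["c"] * dose)
    return float(np.clip(y, *bounds))


# ---------------------------------------------------------------------------
# model series extraction and objective
# ---------------------------------------------------------------------------


class _SimCache:
    """Caches the desynchronized start state of the shared untreated base."""

    def __init__(self):
        self.start = None
        self.base_key = None

    def start_for(self, config: ModelConfig):
        key = (
            tuple(config.durations[ph] for ph in PHASES),
            config.grid,
            config.n_cycles,
            config.p_out,
            tuple(sorted(config.p_q.items())),
            tuple(sorted(config.dr_q.items())),
            config.g0,
        )
        if key != self.base_key:
            self.start = desynchronize(config)
            self.base_key = key
        return self.start


def _extract_series(trajs, times) -> dict:
    """Model observables at the requested times only (cheap fit-path).

    Returns arrays keyed ``pct_g1/pct_s/pct_g2m``, ``pct_brdu_pos``/
    ``pct_und_pos`` (paired runs), ``n_gen{i}`` and ``n_pol`` normalized to
    N(0) = 1000, and ``n``.
    """
    dt = trajs[0].model.config.grid.delta_h
    nc = trajs[0].model.config.n_cycles
    idxs = [round(t / dt) for t in times]
    paired = len(trajs) == 2
    n0 = sum(t[0].total_alive() for t in trajs)
    out = {
        "time_h": np.asarray(times, dtype=float),
        "pct_g1": np.empty(len(idxs)),
        "pct_s": np.empty(len(idxs)),
        "pct_g2m": np.empty(len(idxs)),
        "n_pol": np.empty(len(idxs)),
        "n": np.empty(len(idxs)),
    }
    for i in range(nc):
        out[f"n_gen{i}"] = np.empty(len(idxs))
    if paired:
        out["pct_brdu_pos"] = np.empty(len(idxs))
        out["pct_und_pos"] = np.empty(len(idxs))
    # per-generation death fractions over the whole window (final state)
    dead = sum(t[-1].dead for t in trajs)
    entered = sum(t[-1].entered for t in trajs)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_died_by_gen"] = np.where(
            entered > 0, 100.0 * dead / np.maximum(entered, 1e-300), np.nan
        )
    out["dead_by_gen"] = dead
    out["entered_by_gen"] = entered
    scale = _N0_NORM / n0
    for j, idx in enumerate(idxs):
        states = [t[idx] for t in trajs]
        ph_tot = sum(s.phase_totals() for s in states)
        denom = ph_tot.sum()
        out["pct_g1"][j], out["pct_s"][j], out["pct_g2m"][j] = (
            100.0 * ph_tot / denom
        )
        cyc = sum(s.cycle_totals() for s in states)
        pol = sum(s.pol.sum() for s in states)
        for i in range(nc):
            out[f"n_gen{i}"][j] = cyc[i] * scale
        out["n_pol"][j] = pol * scale
        out["n"][j] = (cyc.sum() + pol) * scale
        if paired:
            grand = sum(s.total_alive() for s in states)
            out["pct_brdu_pos"][j] = 100.0 * states[1].total_alive() / grand
            out["pct_und_pos"][j] = 100.0 * states[1].cycle_totals()[0] / grand
    return out


def _tl_times(tl: TLStats, t_end: float) -> np.ndarray:
    t = tl.gen_counts["time_h"].to_numpy()
    frac = np.abs(t / _TL_STRIDE_H - np.round(t / _TL_STRIDE_H))
    return t[(frac < 1e-9) & (t <= t_end)]


def _model_series(config, t_end, need_brdu, cache: _SimCache, times):
    start = cache.start_for(config)
    if need_brdu:
        trajs = simulate(config, t_end, brdu_pulse=True, start=start)
    else:
        trajs = (simulate(config, t_end, start=start),)
    return _extract_series(trajs, times)


def _series_residuals(data: DoseData, series: dict):
    """(weighted residual arrays, fc abs errors, tl abs errors, % units)."""
    res, fc_abs, tl_abs = [], [], []
    t_model = series["time_h"]

    def pos_of(t):
        return int(np.argmin(np.abs(t_model - t)))

    if data.fc is not None:
        fc = data.fc
        idx = [pos_of(t) for t in fc["time_h"]]
        cols = ["pct_g1", "pct_s", "pct_g2m"] + [
            c for c in FC_BRDU if c in fc.columns and c in series
        ]
        for col in cols:
            r = series[col][idx] - fc[col].to_numpy()
            sd_col = col + "_sd"
            if sd_col in fc.columns:
                w = 1.0 / np.maximum(fc[sd_col].to_numpy(), _SD_FLOOR)
            else:
                w = np.ones_like(r)
            res.append(r * w)
            fc_abs.append(np.abs(r))
    if data.tl is not None:
        tl = data.tl.gen_counts
        keep_t = _tl_times(data.tl, t_model.max())
        sub = tl[tl["time_h"].isin(keep_t)]
        idx = [pos_of(t) for t in sub["time_h"]]
        gen_cols = [c for c in tl.columns if c.startswith("n_gen")]
        gmax = len(gen_cols) - 1
        model_gen = [c for c in series if c.startswith("n_gen")]
        n_roots = max(data.tl.n_roots, 1)

        def tl_weight(counts):
            # inverse sampling SD of a normalized count from n_roots tracked
            # cells (~Poisson: var ≈ N * N0/n_roots), floored like FC
            sd_pct = np.sqrt(np.maximum(counts, 10.0) * _N0_NORM / n_roots) / 10.0
            return 1.0 / np.maximum(sd_pct, _SD_FLOOR)

        for gi, col in enumerate(gen_cols):
            if gi < gmax:
                mv = series[col][idx] if col in series else np.zeros(len(idx))
            else:  # pool model generations >= gmax into the data's last class
                mv = sum(series[c][idx] for c in model_gen if int(c[5:]) >= gmax)
            dv = sub[col].to_numpy()
            r = (mv - dv) / 10.0  # percent of N(0)=1000
            res.append(r * tl_weight(dv))
            tl_abs.append(np.abs(r))
        if "n_pol" in sub.columns:
            dv = sub["n_pol"].to_numpy()
            r = (series["n_pol"][idx] - dv) / 10.0
            res.append(r * tl_weight(dv))
            tl_abs.append(np.abs(r))
        # per-generation death fractions: % died among cells of known fate
        freq = data.tl.event_frequencies
        if freq is not None and "D" in freq.columns:
            fl = freq["FL"].to_numpy() if "FL" in freq.columns else 0.0
            known = np.maximum(1.0 - fl, 1e-9)
            data_died = 100.0 * freq["D"].to_numpy() / known
            gens = freq.index.to_numpy()
            model_died = _model_died_for(series, gens)
            counts = data.tl.gen_record_counts
            n_g = (counts.reindex(gens).to_numpy(dtype=float)
                   if counts is not None else np.full(gens.size, 100.0))
            p = data_died / 100.0
            sd = 100.0 * np.sqrt(np.maximum(p * (1 - p), 1e-4)
                                 / np.maximum(n_g, 1.0))
            ok = ~np.isnan(model_died)
            r = model_died[ok] - data_died[ok]
            res.append(r / np.maximum(sd[ok], _SD_FLOOR))
            tl_abs.append(np.abs(r))
    return res, fc_abs, tl_abs


def _model_died_for(series: dict, gens: np.ndarray) -> np.ndarray:
    """Model % died per data generation class (last class pools the rest)."""
    dead, entered = series["dead_by_gen"], series["entered_by_gen"]
    model_died = np.full(gens.size, np.nan)
    gmax_d = gens.max()
    for j, g in enumerate(gens):
        if g < gmax_d:
            d_g = dead[g] if g < dead.size else 0.0
            e_g = entered[g] if g < entered.size else 0.0
        else:  # pool model generations >= the data's last class
            d_g, e_g = dead[g:].sum(), entered[g:].sum()
        if e_g > 0:
            model_died[j] = 100.0 * d_g / e_g
    return model_died


def _needed_times(data: DoseData, t_end: float) -> list:
    times = {0.0}
    if data.fc is not None:
        times.update(float(t) for t in data.fc["time_h"])
    if data.tl is not None:
        times.update(float(t) for t in _tl_times(data.tl, t_end))
    return sorted(times)


def residual_vector(
    values: dict,
    structure: ModelStructure,
    data: DoseData,
    t_end: float = 72.0,
    cache: _SimCache | None = None,
) -> np.ndarray:
    """Weighted residuals of one dose's model against its FC/TL series."""
    cache = cache or _SimCache()
    config = build_config(structure, values)
    need_brdu = data.fc is not None and any(c in data.fc.columns for c in FC_BRDU)
    series = _model_series(config, t_end, need_brdu, cache, _needed_times(data, t_end))
    res, _, _ = _series_residuals(data, series)
    if not res:
        raise ValueError("no overlapping series between model and data")
    return np.concatenate(res)


def objective(
    values: dict,
    structure: ModelStructure,
    data: DoseData,
    t_end: float = 72.0,
    cache: _SimCache | None = None,
    return_details: bool = False,
):
    """Weighted SSE of one dose's model against its FC/TL series."""
    cache = cache or _SimCache()
    config = build_config(structure, values)
    need_brdu = data.fc is not None and any(c in data.fc.columns for c in FC_BRDU)
    series = _model_series(config, t_end, need_brdu, cache, _needed_times(data, t_end))
    res, fc_abs, tl_abs = _series_residuals(data, series)
    if not res:
        raise ValueError("no overlapping series between model and data")
    sse = float(sum((r**2).sum() for r in res))
    if not return_details:
        return sse
    details = {
        "fc_mae": float(np.concatenate(fc_abs).mean()) if fc_abs else np.nan,
        "tl_mae": float(np.concatenate(tl_abs).mean()) if tl_abs else np.nan,
    }
    return sse, details


@dataclass
class FitResult:
    params: dict
    objective: float
    fc_mae: float
    tl_mae: float
    n_evals: int
    converged: bool
    starts: list = field(default_factory=list)
    seed: int | None = None
    ci: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [f"objective: {self.objective:.6g}  (evals {self.n_evals}, "
                 f"converged {self.converged})"]
        lines.append(f"mean abs error: FC {self.fc_mae:.2f}%  TL {self.tl_mae:.2f}%")
        for k, v in self.params.items():
            lines.append(f"  {k} = {v:.4g}")
        return "\n".join(lines)


def _multistart_minimize(
    fun, resid, free, x0, n_starts, seed, maxiter, xatol, fatol, method="lsq"
):
    """Seeded multi-start bounded minimization.

    ``method="lsq"`` (default) runs trust-region-reflective nonlinear least
    squares on the residual vector with finite-difference gradients — the
    simulation objective is smooth enough in its parameters for this to
    converge in tens of evaluations where simplex/line-search methods need
    thousands.  ``"nelder-mead"`` and ``"powell"`` remain available
    (``maxiter`` then caps iterations instead of function evaluations).
    """
    names = [p.name for p in free]
    bounds = np.array([p.bounds for p in free])
    rng = np.random.default_rng(seed)
    starts = []
    if x0 is not None:
        starts.append(np.array([x0[n] for n in names], dtype=float))
    else:
        starts.append(
            np.array([p.init if p.init is not None else np.mean(p.bounds)
                      for p in free])
        )
    while len(starts) < n_starts:
        starts.append(bounds[:, 0] + rng.random(len(free)) * (bounds[:, 1] - bounds[:, 0]))
    best, best_obj, log, n_evals, converged = None, np.inf, [], 0, False
    for x_start in starts:
        if method == "lsq":
            r = optimize.least_squares(
                resid,
                np.clip(x_start, bounds[:, 0] + 1e-12, bounds[:, 1] - 1e-12),
                bounds=(bounds[:, 0], bounds[:, 1]),
                method="trf",
                diff_step=1e-2,
                xtol=xatol * 1e-2,
                ftol=fatol,
                max_nfev=maxiter,
            )
            obj = float(2.0 * r.cost)  # cost = 0.5 * sum(resid^2)
        else:
            options = (
                {"maxiter": maxiter, "xtol": xatol, "ftol": fatol}
                if method == "powell"
                else {"maxiter": maxiter, "xatol": xatol, "fatol": fatol}
            )
            r = optimize.minimize(
                fun, x_start, method=method, bounds=bounds, options=options
            )
            obj = float(r.fun)
        n_evals += r.nfev
        log.append({"x0": dict(zip(names, x_start)), "objective": obj,
                    "success": bool(r.success)})
        if obj < best_obj:
            best, best_obj = r, obj
            converged = bool(r.success)
    if not converged:
        warnings.warn("optimizer did not report convergence; best iterate returned")
    return best, log, n_evals, converged, names


def fit_single_dose(
    data: DoseData,
    structure: ModelStructure,
    free: list[FreeParameter],
    seed: int = 0,
    n_starts: int = 5,
    maxiter: int = 300,
    x0: dict | None = None,
    t_end: float = 72.0,
    xatol: float = 1e-3,
    fatol: float = 1e-6,
    method: str = "lsq",
) -> FitResult:
    """Bounded local fit of one dose's free module parameters."""
    cache = _SimCache()
    names = [p.name for p in free]

    def fun(x):
        return objective(dict(zip(names, x)), structure, data, t_end, cache)

    def resid(x):
        return residual_vector(dict(zip(names, x)), structure, data, t_end, cache)

    best, log, n_evals, converged, names = _multistart_minimize(
        fun, resid, free, x0, n_starts, seed, maxiter, xatol, fatol, method
    )
    values = dict(zip(names, best.x))
    sse, det = objective(values, structure, data, t_end, cache, return_details=True)
    return FitResult(
        params=values,
        objective=sse,
        fc_mae=det["fc_mae"],
        tl_mae=det["tl_mae"],
        n_evals=n_evals,
        converged=converged,
        starts=log,
        seed=seed,
    )


def fit_multi_dose(
    data_by_dose: dict,
    structure: ModelStructure,
    dr_map: dict,
    free: list[FreeParameter],
    seed: int = 0,
    n_starts: int = 3,
    maxiter: int = 500,
    x0: dict | None = None,
    t_end: float = 72.0,
    xatol: float = 1e-3,
    fatol: float = 1e-6,
    method: str = "lsq",
) -> FitResult:
    """Joint fit of all doses with dose-response-constrained parameters.

    ``dr_map`` maps each free module parameter of ``structure`` to a
    :class:`DoseResponseSpec` whose coefficients may name entries of
    ``free``.  Requires at least two doses.
    """
    if len(data_by_dose) < 2:
        raise ValueError("multi-dose fitting requires >= 2 doses")
    missing = [n for n in structure.free_names() if n not in dr_map]
    if missing:
        raise ValueError(f"no dose-response binding for parameters {missing}")
    cache = _SimCache()
    names = [p.name for p in free]

    def per_dose_values(cvals: dict, dose: float) -> dict:
        return {
            pname: dose_response_eval(dose, spec.resolve(cvals))
            for pname, spec in dr_map.items()
        }

    def fun(x):
        cvals = dict(zip(names, x))
        return sum(
            objective(per_dose_values(cvals, dose), structure, dd, t_end, cache)
            for dose, dd in data_by_dose.items()
        )

    def resid(x):
        cvals = dict(zip(names, x))
        return np.concatenate([
            residual_vector(per_dose_values(cvals, dose), structure, dd,
                            t_end, cache)
            for dose, dd in data_by_dose.items()
        ])

    best, log, n_evals, converged, names = _multistart_minimize(
        fun, resid, free, x0, n_starts, seed, maxiter, xatol, fatol, method
    )
    cvals = dict(zip(names, best.x))
    sse = 0.0
    fc_abs, tl_abs = [], []
    for dose, dd in data_by_dose.items():
        s, det = objective(
            per_dose_values(cvals, dose), structure, dd, t_end, cache,
            return_details=True,
        )
        sse += s
        if not np.isnan(det["fc_mae"]):
            fc_abs.append(det["fc_mae"])
        if not np.isnan(det["tl_mae"]):
            tl_abs.append(det["tl_mae"])
    return FitResult(
        params=cvals,
        objective=sse,
        fc_mae=float(np.mean(fc_abs)) if fc_abs else np.nan,
        tl_mae=float(np.mean(tl_abs)) if tl_abs else np.nan,
        n_evals=n_evals,
        converged=converged,
        starts=log,
        seed=seed,
    )


def bootstrap_uncertainty(
    fit: FitResult,
    data_by_dose: dict,
    structure: ModelStructure,
    free: list[FreeParameter],
    dr_map: dict | None = None,
    n_reps: int = 50,
    seed: int = 0,
    refit_maxiter: int = 60,
    t_end: float = 72.0,
    ci_level: float = 0.95,
    method: str = "lsq",
    tl_regenerate: bool = True,
    fl_rate: float = 0.0005,
) -> pd.DataFrame:
    """Parametric-bootstrap confidence intervals for fitted parameters.

    Synthetic replicate datasets are generated from the best-fit model: FC
    percentages receive Gaussian noise with the dataset's replicate SDs
    (as stated, so a zero-noise dataset yields zero-width CIs); the TL side
    is regenerated by re-running the stochastic single-cell lineage
    generator from the best-fit configuration with the dataset's number of
    tracked roots (``tl_regenerate=True``, the default) — TL curves are
    counts of the same cells over time, so independent per-point noise
    would badly understate their sampling variability.  With
    ``tl_regenerate=False`` a cheap independent-Gaussian approximation is
    used instead.  Each replicate is refitted (warm-started at the best fit
    with a reduced iteration budget) and percentile CIs are reported;
    replicates whose refit raises are excluded and counted.
    """
    from .data_io import lineage_statistics
    from .microsim import microsimulate

    rng = np.random.default_rng(seed)
    cache = _SimCache()
    names = [p.name for p in free]
    multi = dr_map is not None

    # model series and configs at the best fit, per dose
    model_series, best_configs = {}, {}
    for dose, dd in data_by_dose.items():
        if multi:
            values = {
                p: dose_response_eval(dose, spec.resolve(fit.params))
                for p, spec in dr_map.items()
            }
        else:
            values = fit.params
        config = build_config(structure, values)
        best_configs[dose] = config
        need_brdu = dd.fc is not None and any(c in dd.fc.columns for c in FC_BRDU)
        model_series[dose] = _model_series(
            config, t_end, need_brdu, cache, _needed_times(dd, t_end)
        )

    estimates, n_failed = [], 0
    for _ in range(n_reps):
        rep = {}
        for dose, dd in data_by_dose.items():
            series = model_series[dose]
            t_model = series["time_h"]
            fc_rep = None
            if dd.fc is not None:
                fc_rep = dd.fc.copy()
                idx = [int(np.argmin(np.abs(t_model - t))) for t in fc_rep["time_h"]]
                for col in [c for c in fc_rep.columns
                            if c.startswith("pct_") and not c.endswith("_sd")]:
                    if col not in series:
                        continue
                    mv = series[col][idx]
                    sd_col = col + "_sd"
                    sd = (fc_rep[sd_col].to_numpy()
                          if sd_col in fc_rep.columns else _SD_FLOOR)
                    fc_rep[col] = np.clip(mv + rng.normal(0, 1, mv.size) * sd, 0, 100)
            tl_rep = None
            if dd.tl is not None and tl_regenerate:
                mr = microsimulate(
                    best_configs[dose],
                    t_end,
                    n0=max(dd.tl.n_roots, 1),
                    seed=rng,
                    lineage=True,
                    fl_rate=fl_rate,
                    treatment=f"{dose}",
                )
                grid_h = float(np.diff(
                    dd.tl.gen_counts["time_h"].to_numpy()[:2]
                )[0]) if len(dd.tl.gen_counts) > 1 else 1.0
                tl_rep = lineage_statistics(
                    mr.records, t_end=t_end, grid_h=grid_h,
                    n0_norm=dd.tl.n0_norm,
                )
            elif dd.tl is not None:
                gc = dd.tl.gen_counts.copy()
                idx = [int(np.argmin(np.abs(t_model - t))) for t in gc["time_h"]]
                n_roots = max(dd.tl.n_roots, 1)
                for col in [c for c in gc.columns if c.startswith("n_")]:
                    if col not in series:
                        continue
                    mv = series[col][idx]
                    # sampling noise of normalized counts from n_roots cells
                    sd = np.sqrt(np.maximum(mv, 10.0) * _N0_NORM / n_roots)
                    gc[col] = np.maximum(mv + rng.normal(0, 1, mv.size) * sd, 0.0)
                freq_rep = None
                freq = dd.tl.event_frequencies
                if freq is not None and "D" in freq.columns:
                    gens = freq.index.to_numpy()
                    p = _model_died_for(series, gens) / 100.0
                    p = np.nan_to_num(p, nan=0.0)
                    counts = dd.tl.gen_record_counts
                    n_g = (counts.reindex(gens).to_numpy(dtype=float)
                           if counts is not None else np.full(gens.size, 100.0))
                    sd = np.sqrt(np.maximum(p * (1 - p), 0.0)
                                 / np.maximum(n_g, 1.0))
                    p_rep = np.clip(p + rng.normal(0, 1, p.size) * sd, 0.0, 1.0)
                    freq_rep = pd.DataFrame({"D": p_rep}, index=gens)
                tl_rep = replace(
                    dd.tl,
                    gen_counts=gc,
                    event_frequencies=(freq_rep if freq_rep is not None
                                       else dd.tl.event_frequencies),
                )
            rep[dose] = DoseData(fc=fc_rep, tl=tl_rep, dose=dose)
        try:
            if multi:
                r = fit_multi_dose(
                    rep, structure, dr_map, free, seed=int(rng.integers(2**31)),
                    n_starts=1, maxiter=refit_maxiter, x0=fit.params, t_end=t_end,
                    method=method,
                )
            else:
                only = rep[next(iter(rep))]
                r = fit_single_dose(
                    only, structure, free, seed=int(rng.integers(2**31)),
                    n_starts=1, maxiter=refit_maxiter, x0=fit.params, t_end=t_end,
                    method=method,
                )
            estimates.append([r.params[n] for n in names])
        except Exception as e:  # failed refits are excluded and counted
            n_failed += 1
            last_error = e
    if not estimates:
        raise RuntimeError(f"all bootstrap replicates failed: {last_error!r}")
    est = np.array(estimates)
    alpha = (1.0 - ci_level) / 2.0
    table = pd.DataFrame(
        {
            "parameter": names,
            "estimate": [fit.params[n] for n in names],
            "lo": np.quantile(est, alpha, axis=0),
            "hi": np.quantile(est, 1.0 - alpha, axis=0),
            "sd": est.std(axis=0, ddof=1) if len(estimates) > 1 else 0.0,
            "n_reps": len(estimates),
            "n_failed": n_failed,
        }
    )
    return table
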