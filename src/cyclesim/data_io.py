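"""Reading/writing flow-cytometry tables and time-lapse lineage databases,
time-lapse population statistics, and synthetic dataset generation.

CSV schemas
-----------
Lineage database (one row per tracked cell)::

    treatment,field,lineage,generation,birth_time_h,outcome_time_h,outcome

``outcome`` is one of M (mitosis), D (death), S (alive at the end of
observation), R (re-fusion of two newborn siblings into a polyploid cell) or
FL (lost from the field of view).

FC time-course table (one row per dose and time)::

    dose,time_h,pct_g1,pct_s,pct_g2m[,pct_brdu_pos,pct_und_pos][,*_sd]

Datasets without the BrdU columns are flagged monoparametric-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ModelConfig, desynchronize, simulate
from .microsim import microsimulate
from .observables import brdu_series, phase_percentages

__all__ = [
    "OUTCOME_CODES",
    "LineageValidationError",
    "TLStats",
    "FCDataset",
    "NoiseSpec",
    "read_lineage_db",
    "write_lineage_db",
    "lineage_statistics",
    "read_fc_table",
    "write_fc_table",
    "write_observables",
    "generate_synthetic_dataset",
]

OUTCOME_CODES = ("M", "D", "S", "R", "FL")
LINEAGE_COLUMNS = [
    "treatment",
    "field",
    "lineage",
    "generation",
    "birth_time_h",
    "outcome_time_h",
    "outcome",
]
FC_REQUIRED = ["dose", "time_h", "pct_g1", "pct_s", "pct_g2m"]
FC_BRDU = ["pct_brdu_pos", "pct_und_pos"]


class LineageValidationError(ValueError):
    pass


@dataclass
class TLStats:
    """Population statistics derived from a lineage database.

    ``gen_counts`` holds N_gen(i)(t) per generation (plus ``n_pol``) on the
    observation time grid, normalized so N(0) = ``n0_norm`` and corrected for
    cells lost to follow-up (FL) by risk-set reweighting.  ``intermitotic_h``
    are the observed cell-cycle durations (birth to mitosis);
    ``event_frequencies`` are the per-generation proportions of outcomes.
    """

    gen_counts: pd.DataFrame
    intermitotic_h: np.ndarray
    event_frequencies: pd.DataFrame
    n_roots: int
    n0_norm: float = 1000.0
    gen_record_counts: pd.Series | None = None  # tracked cells per generation

    def mean_tc(self) -> float:
        return float(np.mean(self.intermitotic_h))


@dataclass
class FCDataset:
    """Per-dose flow-cytometry time courses (percentages, optional SDs)."""

    table: pd.DataFrame
    monoparametric_only: bool = False

    @property
    def doses(self) -> np.ndarray:
        return np.unique(self.table["dose"].to_numpy())

    def for_dose(self, dose: float) -> pd.DataFrame:
        return self.table[self.table["dose"] == dose].reset_index(drop=True)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic datasets.

    fc_sd: Gaussian SD (percentage points) added to every FC percentage;
    fl_rate: per-step probability that a tracked time-lapse cell leaves the
    field of view; tl_roots: tracked starting cells per dose.
    """

    fc_sd: float = 1.5
    fl_rate: float = 0.0005
    tl_roots: int = 1000

    def __post_init__(self) -> None:
        if self.fc_sd < 0 or self.fl_rate < 0:
            raise ValueError("noise parameters must be non-negative")


# ---------------------------------------------------------------------------
# lineage database
# ---------------------------------------------------------------------------


def read_lineage_db(path) -> pd.DataFrame:
    """Read and validate a lineage database CSV.

    Raises :class:`LineageValidationError` naming the offending rows for
    unknown outcome codes, malformed/negative times, or outcome times before
    birth.  An empty file yields an empty collection with a warning.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"lineage database {path} is empty")
        return pd.DataFrame(columns=LINEAGE_COLUMNS)
    missing = [c for c in LINEAGE_COLUMNS if c not in df.columns]
    if missing:
        raise LineageValidationError(f"missing columns {missing} in {path}")
    df = df[LINEAGE_COLUMNS].copy()
    bad = ~df["outcome"].isin(OUTCOME_CODES)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        codes = df.loc[bad, "outcome"].unique().tolist()
        raise LineageValidationError(
            f"unknown outcome codes {codes} at file rows {rows}"
        )
    for col in ("birth_time_h", "outcome_time_h"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        nan = df[col].isna()
        if nan.any():
            raise LineageValidationError(
                f"malformed {col} at file rows {(df.index[nan] + 2).tolist()}"
            )
    neg = (df["birth_time_h"] < 0) | (df["outcome_time_h"] < df["birth_time_h"])
    if neg.any():
        raise LineageValidationError(
            f"inconsistent times at file rows {(df.index[neg] + 2).tolist()}"
        )
    if (df["generation"] < 0).any():
        raise LineageValidationError("generation must be >= 0")
    return df


def write_lineage_db(path, records: pd.DataFrame) -> None:
    records[LINEAGE_COLUMNS].to_csv(path, index=False)


def lineage_statistics(
    records: pd.DataFrame,
    t_end: float = 72.0,
    grid_h: float = 1.0,
    n0_norm: float = 1000.0,
) -> TLStats:
    """Population statistics from one treatment condition's lineage records.

    * intermitotic times: ``outcome_time - birth_time`` of M-outcome cells;
    * N_gen(i)(t): number of cells alive in generation i at each grid time,
      scaled so N(0) = ``n0_norm``.  Cells lost to follow-up are treated as
      censored: from each loss time onward, counts are multiplied by
      ``n_at_risk/(n_at_risk - 1)`` (cumulative over losses), the
      Kaplan-Meier-style risk-set renormalization for censored data;
    * polyploid counts: each pair of R-outcome siblings contributes one fused
      cell from the re-fusion time onward;
    * event frequencies: per-generation proportions of M/D/S/R/FL outcomes.
    """
    if records.empty:
        raise ValueError("no lineage records")
    if records["treatment"].nunique() > 1:
        raise ValueError("records must span a single treatment condition")
    last_event = records["outcome_time_h"].max()
    if t_end < last_event:
        raise ValueError(f"t_end={t_end} precedes last recorded event {last_event}")

    df = records.reset_index(drop=True)
    times = np.arange(0.0, t_end + grid_h / 2, grid_h)
    gens = np.arange(int(df["generation"].max()) + 1)
    birth = df["birth_time_h"].to_numpy()
    out_t = df["outcome_time_h"].to_numpy()
    outcome = df["outcome"].to_numpy()
    gen = df["generation"].to_numpy()
    # a cell counts in its generation from birth up to (excl.) its outcome
    # time (division, death, re-fusion or loss); S cells live to the end
    alive_until = np.where(outcome == "S", np.inf, out_t)

    # FL censoring: from each loss time onward, counts are inflated by the
    # inverse retained fraction (Kaplan-Meier-style risk-set renormalization)
    # -- cumulative factor prod alive/(alive - 1) over losses up to t.
    fl_times = np.sort(out_t[outcome == "FL"])
    fl_factors = np.ones(fl_times.size)
    for i, t_loss in enumerate(fl_times):
        n_at_risk = np.sum((birth <= t_loss) & (alive_until >= t_loss))
        # sequential handling of simultaneous losses
        n_at_risk -= np.sum(fl_times[:i] == t_loss)
        if n_at_risk > 1:
            fl_factors[i] = n_at_risk / (n_at_risk - 1)
    cum_factor = np.cumprod(fl_factors)

    def inflation(t: float) -> float:
        k = np.searchsorted(fl_times, t, side="right")
        return float(cum_factor[k - 1]) if k else 1.0

    counts = np.zeros((times.size, gens.size))
    pol = np.zeros(times.size)
    for i, t in enumerate(times):
        f = inflation(t)
        alive = (birth <= t) & (alive_until > t)
        np.add.at(counts[i], gen[alive], f)
        fused = (outcome == "R") & (out_t <= t)
        pol[i] = fused.sum() * f / 2.0
    n0 = counts[0].sum() + pol[0]
    scale = n0_norm / n0
    gen_counts = pd.DataFrame(
        counts * scale, columns=[f"n_gen{g}" for g in gens]
    )
    gen_counts["n_pol"] = pol * scale
    gen_counts["n"] = gen_counts.sum(axis=1)
    gen_counts.insert(0, "time_h", times)

    mitotic = outcome == "M"
    intermitotic = (out_t - birth)[mitotic]

    freq = (
        df.groupby("generation")["outcome"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(OUTCOME_CODES), fill_value=0.0)
    )
    n_roots = int((df["generation"] == 0).sum())
    return TLStats(
        gen_counts=gen_counts,
        intermitotic_h=np.sort(intermitotic),
        event_frequencies=freq,
        n_roots=n_roots,
        n0_norm=n0_norm,
        gen_record_counts=df.groupby("generation").size(),
    )


# ---------------------------------------------------------------------------
# FC tables
# ---------------------------------------------------------------------------


def read_fc_table(path) -> FCDataset:
    df = pd.read_csv(path)
    missing = [c for c in FC_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"FC table {path} missing columns {missing}")
    pct_cols = [c for c in df.columns if c.startswith("pct_") and not c.endswith("_sd")]
    for c in pct_cols:
        if ((df[c] < 0) | (df[c] > 100)).any():
            raise ValueError(f"FC table {path}: column {c} outside [0, 100]")
    if (df["time_h"] < 0).any():
        raise ValueError("times must be non-negative")
    mono = not all(c in df.columns for c in FC_BRDU)
    return FCDataset(table=df, monoparametric_only=mono)


def write_fc_table(path, dataset: FCDataset) -> None:
    dataset.table.to_csv(path, index=False)


def write_observables(path, series: pd.DataFrame) -> None:
    """Write a tidy observable table (dose, time_h, quantity, value)."""
    expected = ["dose", "time_h", "quantity", "value"]
    missing = [c for c in expected if c not in series.columns]
    if missing:
        raise ValueError(f"observable table missing columns {missing}")
    series[expected].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic data generation
# ---------------------------------------------------------------------------


def generate_synthetic_dataset(
    configs: dict,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    fc_times=(0.0, 6.0, 24.0, 48.0, 72.0),
    t_end: float = 72.0,
    brdu: bool = True,
) -> tuple[FCDataset, pd.DataFrame]:
    """Emulated FC + TL experiment for a set of dose-specific model configs.

    ``configs`` maps dose -> :class:`~cyclesim.engine.ModelConfig`.  The FC
    side samples the deterministic observables at ``fc_times`` and adds
    Gaussian noise with SD ``noise.fc_sd`` (clipped to [0, 100]); the TL side
    runs the stochastic microsimulation with ``noise.tl_roots`` tracked
    starting cells per dose, emitting lineage records with 20-minute event
    rounding and field losses at ``noise.fl_rate`` per step.  Fully
    reproducible from ``seed``.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    fc_rows = []
    tl_frames = []
    for dose in sorted(configs):
        config = configs[dose]
        start = desynchronize(config)
        if brdu:
            neg, pos = simulate(config, t_end, brdu_pulse=True, start=start)
            pct = phase_percentages((neg, pos))
            bs = brdu_series(neg, pos)
        else:
            traj = simulate(config, t_end, start=start)
            pct = phase_percentages(traj)
            bs = None
        for t in fc_times:
            i = int(np.argmin(np.abs(pct["time_h"].to_numpy() - t)))
            row = {
                "dose": dose,
                "time_h": pct["time_h"].iloc[i],
                "pct_g1": pct["pct_g1"].iloc[i],
                "pct_s": pct["pct_s"].iloc[i],
                "pct_g2m": pct["pct_g2m"].iloc[i],
            }
            if bs is not None:
                row["pct_brdu_pos"] = bs["pct_brdu_pos"].iloc[i]
                row["pct_und_pos"] = bs["pct_und_pos"].iloc[i]
            for k in list(row):
                if k.startswith("pct_"):
                    noisy = row[k] + rng.normal(0.0, noise.fc_sd) if noise.fc_sd else row[k]
                    row[k] = float(np.clip(noisy, 0.0, 100.0))
                    row[k + "_sd"] = noise.fc_sd
            fc_rows.append(row)

        mr = microsimulate(
            config,
            t_end,
            n0=noise.tl_roots,
            seed=rng,
            lineage=True,
            fl_rate=noise.fl_rate,
            treatment=f"{dose}",
        )
        tl_frames.append(mr.records)

    fc = FCDataset(table=pd.DataFrame(fc_rows), monoparametric_only=not brdu)
    tl = pd.concat(tl_frames, ignore_index=True)
    return fc, tl
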