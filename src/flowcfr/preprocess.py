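"""EHR-style abstraction of irregular measurement streams into T0 features.

The rules mirror common critical-care pipelines: measurements are grouped into
one-hour bins by their median, carried forward for up to 24 h, and any
remaining gaps are mean-imputed with statistics from the training split only.
On top of the current (hour-T0) values, three derived features are computed
per channel: a 72-h trailing baseline mean, a short-term slope per hour
between the last two non-missing values (dt capped at 24 h), and the time
since the channel was last measured (TSLM).  The final vector is
4 * n_channels + n_statics long, z-scored with training-split statistics.

Conventions pinned by tests: the carry-forward age boundary is inclusive at
exactly 24 h; TSLM is the age of the last *true* observation (carried-forward
values do not reset it); the baseline window uses observed, pre-imputation
values only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import LongitudinalRecord, SyntheticCohort

__all__ = [
    "bin_hourly",
    "carry_forward",
    "mean_impute",
    "derive_features",
    "FeatureMatrix",
    "PreprocessStats",
    "extract_feature_table",
    "assemble_features",
    "DEFAULT_STATICS",
]

DEFAULT_STATICS = ("age", "sex", "sofa_t0", "cci", "risk_t0")

TSLM_CAP = 72.0  # hours; also the fill value when a channel was never observed
DELTA_DT_CAP = 24.0
BASELINE_WINDOW = 72.0
CARRY_HOURS = 24


def bin_hourly(
    record: LongitudinalRecord, n_hours: int | None = None
) -> pd.DataFrame:
    """Resample a record onto an hourly grid, taking the median within each
    one-hour bin [h, h+1); empty bins are NaN.

    Returns a DataFrame indexed by hour 0..n_hours-1 with one column per
    channel.  An empty record yields an all-NaN grid.
    """
    if n_hours is None:
        n_hours = max(1, int(np.ceil(record.duration_hours())))
    index = pd.RangeIndex(n_hours, name="hour")
    cols = {}
    for ch, obs in record.channels.items():
        grid = np.full(n_hours, np.nan)
        if obs:
            t = np.array([o[0] for o in obs])
            v = np.array([o[1] for o in obs])
            hrs = np.floor(t).astype(int)
            keep = (hrs >= 0) & (hrs < n_hours)
            ser = pd.Series(v[keep]).groupby(hrs[keep]).median()
            grid[ser.index.to_numpy()] = ser.to_numpy()
        cols[ch] = grid
    return pd.DataFrame(cols, index=index)


def carry_forward(
    grid: pd.DataFrame, max_hours: int = CARRY_HOURS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing bins with the most recent value aged <= ``max_hours``
    (boundary inclusive); older or never-observed bins stay NaN.

    Returns ``(filled, tslm)`` where ``tslm[h, ch]`` is the age in hours of
    the last true observation at hour h (0 when freshly observed, NaN before
    the first observation); carried-forward values do not reset it.
    """
    hours = grid.index.to_numpy()[:, None].astype(float)
    observed = grid.notna()
    last_obs_hour = pd.DataFrame(
        np.where(observed, hours, np.nan), index=grid.index, columns=grid.columns
    ).ffill()
    tslm = pd.DataFrame(
        np.broadcast_to(hours, grid.shape).copy(),
        index=grid.index, columns=grid.columns,
    ) - last_obs_hour
    filled = grid.ffill()
    filled = filled.where(tslm <= max_hours)  # NaN where age > max or no prior obs
    return filled, tslm


def mean_impute(
    grid: pd.DataFrame, training_means: pd.Series | dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace remaining missing cells with per-channel training-split means.

    Returns ``(complete, imputed_mask)``.  Raises KeyError if a channel has no
    training mean.
    """
    means = pd.Series(training_means, dtype=float)
    missing_channels = [c for c in grid.columns if c not in means.index]
    if missing_channels:
        raise KeyError(
            f"channels {missing_channels} absent from training_means"
        )
    mask = grid.isna()
    complete = grid.fillna(means[grid.columns])
    return complete, mask


def derive_features(
    grid: pd.DataFrame,
    t0_hour: int,
    baseline_window: float = BASELINE_WINDOW,
    delta_dt_cap: float = DELTA_DT_CAP,
    tslm_cap: float = TSLM_CAP,
) -> pd.DataFrame:
    """Per-channel T0 summary from the raw (pre-imputation) hourly grid.

    Columns: ``raw`` (carried-forward value at T0, NaN if expired), ``baseline``
    (mean of observed bins in (t0 - baseline_window, t0]), ``delta``
    ((last - second-last observed) / dt with dt capped, 0 with < 2
    observations), ``tslm`` (hours since last true observation at T0, capped).
    """
    if t0_hour < 0:
        raise ValueError(f"t0_hour must be >= 0, got {t0_hour}")
    if t0_hour >= len(grid):
        raise ValueError(
            f"t0_hour {t0_hour} outside grid of {len(grid)} hours"
        )
    filled, tslm_grid = carry_forward(grid)
    out = {}
    for ch in grid.columns:
        col = grid[ch]
        obs_hours = col.index.to_numpy()[col.notna().to_numpy()]
        obs_upto = obs_hours[obs_hours <= t0_hour]
        lo = t0_hour - baseline_window
        in_window = obs_upto[obs_upto > lo]
        baseline = float(col.loc[in_window].mean()) if in_window.size else np.nan
        if obs_upto.size >= 2:
            h2, h1 = obs_upto[-1], obs_upto[-2]
            dt = min(float(h2 - h1), delta_dt_cap)
            delta = float(col.loc[h2] - col.loc[h1]) / dt
        else:
            delta = 0.0
        tslm_val = tslm_grid[ch].iloc[t0_hour]
        tslm = float(min(tslm_val, tslm_cap)) if np.isfinite(tslm_val) else tslm_cap
        out[ch] = {
            "raw": filled[ch].iloc[t0_hour],
            "baseline": baseline,
            "delta": delta,
            "tslm": tslm,
        }
    return pd.DataFrame(out).T[["raw", "baseline", "delta", "tslm"]]


# ---------------------------------------------------------------------------
# cohort-level feature assembly


@dataclass
class FeatureMatrix:
    """Model-ready feature block.

    X is fully finite (imputed + z-scored); ``tslm_raw`` keeps the per-channel
    staleness in hours for the model's TSLM gate; ``gated_idx`` lists, per
    channel, the columns of X the gate multiplies (raw, baseline, delta).
    """

    X: np.ndarray
    columns: list[str]
    tslm_raw: np.ndarray  # (n, n_channels), hours
    channels: list[str]
    gated_idx: list[np.ndarray]
    imputed_mask: np.ndarray
    ids: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]


def extract_feature_table(
    records: list[LongitudinalRecord],
    t0_hours: dict[int, int],
    channels: list[str],
) -> pd.DataFrame:
    """One row per encounter of raw/baseline/delta/tslm columns (may contain
    NaN where carry-forward expired or the baseline window was empty)."""
    rows = []
    ids = []
    for rec in records:
        grid = bin_hourly(rec)[channels]
        t0 = int(t0_hours[rec.encounter_id])
        if t0 >= len(grid):
            grid = grid.reindex(pd.RangeIndex(t0 + 1, name="hour"))
        feats = derive_features(grid, t0)
        row = {}
        for ch in channels:
            for kind in ("raw", "baseline", "delta", "tslm"):
                row[f"{ch}__{kind}"] = feats.loc[ch, kind]
        rows.append(row)
        ids.append(rec.encounter_id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="encounter_id"))


@dataclass
class PreprocessStats:
    """Training-split statistics: imputation means and z-score parameters."""

    impute_means: pd.Series = field(default_factory=pd.Series)
    z_mean: pd.Series = field(default_factory=pd.Series)
    z_std: pd.Series = field(default_factory=pd.Series)

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "PreprocessStats":
        impute_means = table.mean()
        # all-NaN training column (never-observed channel): impute with 0
        impute_means = impute_means.fillna(0.0)
        complete = table.fillna(impute_means)
        z_mean = complete.mean()
        z_std = complete.std(ddof=0).replace(0.0, 1.0)
        return cls(impute_means=impute_means, z_mean=z_mean, z_std=z_std)

    def transform(self, table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        missing = [c for c in table.columns if c not in self.impute_means.index]
        if missing:
            raise KeyError(f"columns {missing} absent from training statistics")
        mask = table.isna()
        complete = table.fillna(self.impute_means)
        z = (complete - self.z_mean[table.columns]) / self.z_std[table.columns]
        if not np.all(np.isfinite(z.to_numpy())):
            raise ValueError("non-finite values survived imputation")
        return z, mask


def assemble_features(
    cohort: SyntheticCohort,
    records: list[LongitudinalRecord],
    train_mask: np.ndarray,
    channels: list[str] | None = None,
    statics: tuple[str, ...] = DEFAULT_STATICS,
    include_x: bool = True,
    stats: PreprocessStats | None = None,
) -> tuple[FeatureMatrix, PreprocessStats]:
    """Build the model feature matrix for a cohort with longitudinal streams.

    ``train_mask`` selects the encounters whose statistics drive imputation and
    z-scoring (no leakage from validation/test rows); pass a precomputed
    ``stats`` to reuse another site's preprocessing.
    """
    if channels is None:
        channels = list(cohort.config.channels)
    t0_hours = dict(
        zip(cohort.frame["encounter_id"].astype(int), cohort.frame["t0_hour"].astype(int))
    )
    table = extract_feature_table(records, t0_hours, channels)
    table = table.loc[cohort.frame["encounter_id"].to_numpy()]

    static_tab = cohort.frame[list(statics)].copy()
    if include_x:
        static_tab = pd.concat(
            [static_tab, cohort.frame[cohort.x_cols]], axis=1
        )
    static_tab.index = table.index
    full = pd.concat([table, static_tab], axis=1)

    if stats is None:
        stats = PreprocessStats.fit(full.loc[train_mask.astype(bool).tolist()])
    z, mask = stats.transform(full)

    tslm_cols = [f"{ch}__tslm" for ch in channels]
    tslm_raw = table[tslm_cols].to_numpy(dtype=float)
    columns = list(z.columns)
    gated_idx = [
        np.array([columns.index(f"{ch}__{k}") for k in ("raw", "baseline", "delta")])
        for ch in channels
    ]
    fm = FeatureMatrix(
        X=z.to_numpy(dtype=float),
        columns=columns,
        tslm_raw=tslm_raw,
        channels=list(channels),
        gated_idx=gated_idx,
        imputed_mask=mask.to_numpy(),
        ids=table.index.to_numpy(),
    )
    return fm, stats
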