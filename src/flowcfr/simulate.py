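"""Synthetic ICU cohort simulator with known causal ground truth.

Emulates the observational setting the estimator is built for: ICU encounters
flagged by a risk model at an alert time T0, then treated with one of two
non-invasive respiratory-support arms (NIV, coded a=0, or HFNC, coded a=1),
with the binary outcome being subsequent invasive mechanical ventilation
(IMV).  Treatment assignment is confounded both by measured covariates x and
by a hidden severity scalar u, whose influence is controlled by a single dial
``gamma_hidden``.  Potential outcomes are drawn with a shared uniform noise
variate (monotone coupling), so the individual risk difference equals the
difference of the two arm probabilities exactly.

Sign convention, used package-wide: ``tau_true = P(IMV | NIV) - P(IMV | HFNC)``,
i.e. negative values mean the encounter does better under NIV.  This matches
the downstream ITE definition, so a perfect estimator has zero PEHE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "LongitudinalRecord",
    "generate_cohort",
    "generate_longitudinal",
    "standin_risk_trigger",
    "longitudinal_to_frame",
    "longitudinal_from_frame",
]

DEFAULT_CHANNELS = ("hr", "rr", "spo2", "sbp", "lactate")

#: per-channel loading of the latent severity path onto the measurement mean
_CHANNEL_LOADINGS = {"hr": 1.0, "rr": 0.8, "spo2": -0.9, "sbp": -0.7, "lactate": 1.2}
_CHANNEL_MEANS = {"hr": 88.0, "rr": 20.0, "spo2": 95.0, "sbp": 115.0, "lactate": 1.8}
_CHANNEL_SCALES = {"hr": 12.0, "rr": 4.0, "spo2": 2.5, "sbp": 14.0, "lactate": 0.8}

@dataclass
class SimConfig:
    """Configuration of one simulated cohort.

    Parameters
    ----------
    n_encounters : number of ICU encounters (>= 2).
    d_measured : dimension of the measured covariate vector x.
    gamma_hidden : strength (>= 0) with which the hidden severity scalar u
        enters both treatment selection and outcome risk; 0 recovers
        no-hidden-confounding.
    beta_select : selection coefficients on x (length d_measured); None means
        a default alternating +/-0.6 pattern.
    tau_fn_id : 'constant' | 'linear' | 'sign_flipping' - shape of the true
        conditional risk difference tau(x) on the probability scale.
    tau_scale : magnitude of tau(x); for 'constant' this IS the risk
        difference P(IMV|NIV) - P(IMV|HFNC).
    base_rate : target factual IMV prevalence, hit by intercept bisection.
    ts_hours : length of the longitudinal window in hours (>= 2).
    missing_rate : per-(channel, hour) probability of observing nothing.
    seed : master seed; everything is reproducible from it.
    """

    n_encounters: int = 2000
    d_measured: int = 8
    gamma_hidden: float = 0.0
    beta_select: np.ndarray | None = None
    tau_fn_id: str = "constant"
    tau_scale: float = 0.10
    base_rate: float = 0.25
    ts_hours: int = 48
    missing_rate: float = 0.3
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encounters < 2:
            raise ValueError("n_encounters must be >= 2")
        if not (0.0 < self.base_rate < 1.0):
            raise ValueError("base_rate must lie in (0, 1)")
        if self.gamma_hidden < 0:
            raise ValueError("gamma_hidden must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.tau_fn_id not in ("constant", "linear", "sign_flipping"):
            raise ValueError(f"unknown tau_fn_id {self.tau_fn_id!r}")
        if self.beta_select is not None:
            self.beta_select = np.asarray(self.beta_select, dtype=float)
            if not np.all(np.isfinite(self.beta_select)):
                raise ValueError("beta_select contains non-finite coefficients")
            if self.beta_select.shape != (self.d_measured,):
                raise ValueError(
                    f"beta_select has shape {self.beta_select.shape}, "
                    f"expected ({self.d_measured},)"
                )
        if not np.isfinite(self.tau_scale):
            raise ValueError("tau_scale must be finite")

    def resolved_beta(self) -> np.ndarray:
        """Default selection coefficients: half of the covariates drive
        treatment choice, partially overlapping the risk gradient (clinicians
        select on some, not all, of the prognostic factors)."""
        if self.beta_select is not None:
            return self.beta_select
        beta = np.zeros(self.d_measured)
        upper = np.arange(self.d_measured) >= self.d_measured // 2
        beta[upper] = 0.6 * np.where(np.flatnonzero(upper) % 2 == 0, 1.0, -1.0)
        return beta


@dataclass
class SyntheticCohort:
    """Encounter table plus full causal ground truth.

    ``frame`` holds one row per encounter with columns:
    encounter_id, x0..x{d-1}, u_true, a (0=NIV, 1=HFNC), y (IMV),
    y0, y1 (potential outcomes under NIV / HFNC), tau_true, t0_hour,
    y_mort_hospice, and adjusters age, sex (female=1), sofa_t0, cci, risk_t0.
    """

    frame: pd.DataFrame
    config: SimConfig
    x_cols: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def x(self) -> np.ndarray:
        return self.frame[self.x_cols].to_numpy()

    def write(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class LongitudinalRecord:
    """Irregular per-encounter measurement stream.

    channels maps channel name -> list of (timestamp_hours, value), with
    strictly increasing timestamps per channel.
    """

    encounter_id: int
    channels: dict[str, list[tuple[float, float]]]

    def duration_hours(self) -> float:
        times = [obs[-1][0] for obs in self.channels.values() if obs]
        return max(times) if times else 0.0


def _tau_of_x(x: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """True conditional risk difference tau(x) = P(IMV|NIV) - P(IMV|HFNC)."""
    if cfg.tau_fn_id == "constant":
        tau = np.full(x.shape[0], cfg.tau_scale)
    elif cfg.tau_fn_id == "linear":
        tau = cfg.tau_scale * x[:, 0]
    else:
        # sign_flipping: half the population benefits from each arm
        tau = cfg.tau_scale * np.sign(x[:, 0] + 1e-12)
    return np.clip(tau, -0.8, 0.8)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def generate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Draw a confounded cohort with stored potential outcomes.

    Treatment propensity: P(a=HFNC | x, u) = sigmoid(beta·x + gamma·u).
    Arm risks sit symmetrically around a baseline squashed away from the
    probability boundary: p_mid = m + (1-2m)·sigmoid(c0 + w_base·x + gamma·u)
    with margin m = |tau(x)|/2 + 1e-3, and p_niv = p_mid + tau/2,
    p_hfnc = p_mid - tau/2, so the risk difference equals tau(x) *exactly*
    for every encounter (no boundary clipping distorts the effect).  The
    intercept c0 is calibrated by bisection so the factual IMV rate matches
    ``base_rate``.  Both potential outcomes use one shared uniform draw per
    encounter (monotone coupling), hence E[y0 - y1 | x, u] = tau_true.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_encounters, cfg.d_measured
    x = rng.standard_normal((n, d))
    u = rng.standard_normal(n)
    beta = cfg.resolved_beta()

    # outcome model weights: fixed (seed-independent) so cohorts of different
    # seeds share the same data-generating law
    w_base = 0.5 * np.where(np.arange(d) % 3 == 0, 1.0, 0.4) * np.where(
        np.arange(d) % 2 == 0, 1.0, -1.0
    )
    tau = _tau_of_x(x, cfg)
    lin = x @ w_base + cfg.gamma_hidden * u
    propensity = _sigmoid(x @ beta + cfg.gamma_hidden * u)
    margin = np.abs(tau) / 2.0 + 1e-3

    def arm_probs(c0: float):
        p_mid = margin + (1.0 - 2.0 * margin) * _sigmoid(c0 + lin)
        return p_mid + tau / 2.0, p_mid - tau / 2.0

    def factual_rate(c0: float) -> float:
        p0, p1 = arm_probs(c0)
        return float(np.mean(propensity * p1 + (1 - propensity) * p0))

    lo, hi = -20.0, 20.0
    if factual_rate(lo) > cfg.base_rate or factual_rate(hi) < cfg.base_rate:
        raise ValueError(
            f"base_rate={cfg.base_rate} unreachable by intercept search in "
            f"[{lo}, {hi}]; rate range is "
            f"[{factual_rate(lo):.4f}, {factual_rate(hi):.4f}]"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if factual_rate(mid) < cfg.base_rate:
            lo = mid
        else:
            hi = mid
    c0 = 0.5 * (lo + hi)

    p0, p1 = arm_probs(c0)
    tau_true = p0 - p1

    a = (rng.uniform(size=n) < propensity).astype(int)
    shared = rng.uniform(size=n)  # monotone coupling of the two arms
    y0 = (shared < p0).astype(int)
    y1 = (shared < p1).astype(int)
    y = np.where(a == 1, y1, y0)

    # adjusters: noisy transforms of (x, u) so the concordance regression has
    # genuine measured confounding to adjust for
    age = np.clip(62 + 8 * x[:, 0] + 4 * u + 6 * rng.standard_normal(n), 18, 100)
    sex = (rng.uniform(size=n) < 0.42).astype(int)  # female = 1
    sofa = np.clip(
        np.round(1.5 + 1.2 * np.abs(u) + 0.8 * np.abs(x[:, 1]) + rng.normal(0, 0.8, n)),
        0,
        24,
    ).astype(int)
    cci = np.clip(
        np.round(2.0 + 1.0 * x[:, 2] + 0.5 * u + rng.normal(0, 1.0, n)), 0, 15
    ).astype(int)
    risk_t0 = _sigmoid(0.8 * x[:, 0] + 0.6 * u + 0.4 * rng.standard_normal(n))

    # secondary outcome: in-hospital mortality or hospice discharge, driven by
    # severity and by whether the encounter was intubated
    p_mh = _sigmoid(-1.6 + 0.9 * u + 0.4 * x[:, 0] + 1.0 * y)
    y_mh = (rng.uniform(size=n) < p_mh).astype(int)

    t0_hour = rng.integers(4, max(5, cfg.ts_hours - 8), size=n)

    x_cols = [f"x{j}" for j in range(d)]
    frame = pd.DataFrame(x, columns=x_cols)
    frame.insert(0, "encounter_id", np.arange(n))
    frame["u_true"] = u
    frame["a"] = a
    frame["y"] = y
    frame["y0"] = y0
    frame["y1"] = y1
    frame["tau_true"] = tau_true
    frame["t0_hour"] = t0_hour
    frame["y_mort_hospice"] = y_mh
    frame["age"] = age
    frame["sex"] = sex
    frame["sofa_t0"] = sofa
    frame["cci"] = cci
    frame["risk_t0"] = risk_t0
    return SyntheticCohort(frame=frame, config=cfg, x_cols=x_cols)


def generate_longitudinal(
    cohort: SyntheticCohort, cfg: SimConfig
) -> list[LongitudinalRecord]:
    """Draw irregular hourly measurement streams for every encounter.

    Each channel follows ``mean + scale * loading * severity(t) + noise`` where
    the severity path blends the hidden confounder u with a ramp rising toward
    the encounter's trigger hour, so the preprocessing pipeline carries causal
    signal.  Observation times are jittered inside their hour; a channel-hour
    is unobserved with probability ``missing_rate`` and occasionally holds two
    samples (so median binning matters).
    """
    if cfg.ts_hours < 2:
        raise ValueError("ts_hours must be >= 2")
    rng = np.random.default_rng(cfg.seed + 1)
    records: list[LongitudinalRecord] = []
    hours = np.arange(cfg.ts_hours)
    for row in cohort.frame.itertuples(index=False):
        u = row.u_true
        t0 = row.t0_hour
        ramp = 1.5 * _sigmoid((hours - t0 + 2.0) / 2.0)
        severity = 0.8 * u + ramp
        channels: dict[str, list[tuple[float, float]]] = {}
        for ch in cfg.channels:
            load = _CHANNEL_LOADINGS.get(ch, 0.5)
            mu = _CHANNEL_MEANS.get(ch, 0.0)
            sc = _CHANNEL_SCALES.get(ch, 1.0)
            observed = rng.uniform(size=cfg.ts_hours) >= cfg.missing_rate
            double = rng.uniform(size=cfg.ts_hours) < 0.15
            obs: list[tuple[float, float]] = []
            for h in hours[observed]:
                k = 2 if double[h] else 1
                ts = np.sort(h + rng.uniform(0.05, 0.95, size=k))
                vals = mu + sc * (load * severity[h] + 0.4 * rng.standard_normal(k))
                obs.extend(zip(ts.tolist(), vals.tolist()))
            channels[ch] = obs
        records.append(LongitudinalRecord(encounter_id=int(row.encounter_id), channels=channels))
    return records


def standin_risk_trigger(
    record: LongitudinalRecord,
    weights: dict[str, float] | None = None,
    bias: float = -2.0,
    threshold: float = 0.5,
) -> int | None:
    """First hour >= 4 at which a fixed logistic score of current (hourly
    median, forward-filled) channel values crosses ``threshold``; None if it
    never does.

    This is a deliberately simple stand-in for the deployed risk model that
    defines the alert time T0 in real cohorts; only its trigger semantics
    (first crossing, predictions starting at hour 4) are reproduced.
    """
    if record.duration_hours() < 4:
        warnings.warn(
            f"encounter {record.encounter_id}: record shorter than 4 h, "
            "no trigger evaluated",
            stacklevel=2,
        )
        return None
    if weights is None:
        # standardized severity direction of the default channels
        weights = {
            ch: _CHANNEL_LOADINGS.get(ch, 0.5) / _CHANNEL_SCALES.get(ch, 1.0)
            for ch in record.channels
        }
        centers = {ch: _CHANNEL_MEANS.get(ch, 0.0) for ch in record.channels}
    else:
        centers = {ch: 0.0 for ch in record.channels}

    n_hours = int(np.ceil(record.duration_hours()))
    score_in = np.zeros(n_hours)
    for ch, obs in record.channels.items():
        w = weights.get(ch, 0.0)
        grid = np.full(n_hours, np.nan)
        for t, v in obs:
            h = int(t)
            if h < n_hours:
                grid[h] = v if np.isnan(grid[h]) else 0.5 * (grid[h] + v)
        filled = pd.Series(grid).ffill().fillna(centers[ch]).to_numpy()
        score_in += w * (filled - centers[ch])
    score = _sigmoid(bias + score_in)
    for h in range(4, n_hours):
        if score[h] > threshold:
            return h
    return None


def longitudinal_to_frame(records: list[LongitudinalRecord]) -> pd.DataFrame:
    """Long-format table: encounter_id, channel, hour, value."""
    rows = []
    for rec in records:
        for ch, obs in rec.channels.items():
            for t, v in obs:
                rows.append((rec.encounter_id, ch, t, v))
    return pd.DataFrame(rows, columns=["encounter_id", "channel", "hour", "value"])


def longitudinal_from_frame(frame: pd.DataFrame) -> list[LongitudinalRecord]:
    records = []
    for eid, grp in frame.groupby("encounter_id", sort=True):
        channels = {
            ch: list(zip(sub["hour"].tolist(), sub["value"].tolist()))
            for ch, sub in grp.sort_values("hour").groupby("channel")
        }
        records.append(LongitudinalRecord(encounter_id=int(eid), channels=channels))
    return records
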