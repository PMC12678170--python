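"""Counterfactual inference, ITE banding, and baseline estimators.

Sign convention (pinned throughout the package): for each encounter

    ite = P(IMV | NIV) - P(IMV | HFNC),

so a *negative* value means lower intubation risk under NIV ("NIV preferred",
ite < -band) and a positive value means "HFNC preferred" (ite > band); the
band boundary +/-0.001 is inclusive toward "Indifferent".  All engines emit
the same tabular schema so the concordance analysis is engine-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression

from .model import FlowCFR, _stage1_cond

__all__ = [
    "DEFAULT_BAND",
    "ITE_COLUMNS",
    "classify_band",
    "predict_counterfactual",
    "counterfactual_probs",
    "estimate_ite",
    "cfr_baseline_ite",
    "x_learner_ite",
    "causal_forest_adapter",
    "CausalForestSkipped",
]

DEFAULT_BAND = 0.001
NIV_PREFERRED = "NIV_preferred"
HFNC_PREFERRED = "HFNC_preferred"
INDIFFERENT = "Indifferent"

ITE_COLUMNS = ["encounter_id", "engine_id", "p_imv_niv", "p_imv_hfnc",
               "ite", "band_label", "n_mc"]


def classify_band(ite, band: float = DEFAULT_BAND):
    """Three-way preference label; |ite| <= band (inclusive) is Indifferent."""
    arr = np.asarray(ite, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite ITE value")
    labels = np.where(
        arr < -band, NIV_PREFERRED, np.where(arr > band, HFNC_PREFERRED, INDIFFERENT)
    )
    return labels.item() if np.isscalar(ite) or arr.ndim == 0 else labels


def _mc_outcome_probs(model: FlowCFR, phi: np.ndarray, arm: int,
                      u_rep: np.ndarray, n_mc: int) -> np.ndarray:
    n = phi.shape[0]
    phi_rep = np.repeat(phi, n_mc, axis=0)
    cond = _stage1_cond(model.stage0, phi_rep, np.full(n * n_mc, arm))
    y_deq, _ = model.flow1.forward(u_rep, cond, arm)
    return (y_deq > 0).reshape(n, n_mc).mean(axis=1)


def counterfactual_probs(model: FlowCFR, X, tslm=None, n_mc: int = 128,
                         seed: int = 0, mode: str = "stage2"):
    """Monte-Carlo counterfactual IMV probability under each arm with common
    random numbers: the same latent draws (and the same Stage 2 adjustment
    samples) feed both arms, so identical arm conditioning gives identical
    probabilities exactly.

    mode='stage2' samples the adjusted latent u = f2(z | phi); mode='stage1'
    uses the raw standard-normal latent (no hidden-confounding adjustment).
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if mode not in ("stage1", "stage2"):
        raise ValueError(f"unknown inference mode {mode!r}")
    phi = model.encode(np.asarray(X, dtype=float), tslm)
    n = phi.shape[0]
    rng = np.random.default_rng(seed)
    # independent draws per encounter, antithetic (+z, -z) pairs for variance
    # reduction, and the SAME draws for both arms (common random numbers)
    half = rng.standard_normal((n, (n_mc + 1) // 2))
    z_rep = np.concatenate([half, -half], axis=1)[:, :n_mc].ravel()
    if mode == "stage2":
        u_rep, _ = model.flow2.forward(z_rep, np.repeat(phi, n_mc, axis=0))
    else:
        u_rep = z_rep
    p_niv = _mc_outcome_probs(model, phi, 0, u_rep, n_mc)
    p_hfnc = _mc_outcome_probs(model, phi, 1, u_rep, n_mc)
    return p_niv, p_hfnc


def predict_counterfactual(model: FlowCFR, X, arm: int, tslm=None,
                           n_mc: int = 128, seed: int = 0,
                           mode: str = "stage2") -> np.ndarray:
    """Counterfactual IMV probability under one arm (0=NIV, 1=HFNC)."""
    p_niv, p_hfnc = counterfactual_probs(model, X, tslm, n_mc, seed, mode)
    return p_hfnc if arm == 1 else p_niv


def _to_table(ids, engine_id, p_niv, p_hfnc, ite, band, n_mc) -> pd.DataFrame:
    return pd.DataFrame({
        "encounter_id": np.asarray(ids),
        "engine_id": engine_id,
        "p_imv_niv": p_niv,
        "p_imv_hfnc": p_hfnc,
        "ite": ite,
        "band_label": classify_band(ite, band),
        "n_mc": n_mc,
    })[ITE_COLUMNS]


def estimate_ite(model: FlowCFR, X, tslm=None, ids=None, n_mc: int = 128,
                 seed: int = 0, band: float = DEFAULT_BAND,
                 mode: str = "stage2") -> pd.DataFrame:
    """Per-encounter ITE table from the flow model (engine 'repflow_cfr',
    or 'repflow_cfr_stage1' for unadjusted Stage-1 inference)."""
    p_niv, p_hfnc = counterfactual_probs(model, X, tslm, n_mc, seed, mode)
    ite = p_niv - p_hfnc
    if ids is None:
        ids = np.arange(len(ite))
    engine = "repflow_cfr" if mode == "stage2" else "repflow_cfr_stage1"
    return _to_table(ids, engine, p_niv, p_hfnc, ite, band, n_mc)


def cfr_baseline_ite(model: FlowCFR, X, tslm=None, ids=None,
                     band: float = DEFAULT_BAND) -> pd.DataFrame:
    """CFR baseline: ITE directly from the two Stage 0 head probabilities
    (no flows)."""
    phi = model.encode(np.asarray(X, dtype=float), tslm)
    p_niv, p_hfnc = model.head_probs(phi)
    ite = p_niv - p_hfnc
    if ids is None:
        ids = np.arange(len(ite))
    return _to_table(ids, "cfr", p_niv, p_hfnc, ite, band, n_mc=0)


def _base_learners(kind: str, seed: int):
    if kind == "logistic":
        clf = lambda: LogisticRegression(max_iter=2000)
        reg = lambda: LinearRegression()
    elif kind == "gbm":
        clf = lambda: GradientBoostingClassifier(random_state=seed, max_depth=3)
        reg = lambda: GradientBoostingRegressor(random_state=seed, max_depth=3)
    else:
        raise ValueError(f"unknown base learner {kind!r}")
    return clf, reg


def x_learner_ite(X, a, y, ids=None, band: float = DEFAULT_BAND,
                  base_learner: str = "logistic", seed: int = 0) -> pd.DataFrame:
    """X-learner meta-estimator of the individualized risk difference.

    Per-arm outcome models mu0 (NIV) and mu1 (HFNC) impute individual effects
    on the opposite arm; per-arm effect regressions are blended with
    propensity weights g(x): theta(x) = g*tau0(x) + (1-g)*tau1(x), where
    theta = risk(HFNC) - risk(NIV).  The reported ite = -theta follows the
    package sign convention.  The probability columns come from the arm
    models; the ite comes from the meta-learner combination.
    """
    X = np.asarray(X, dtype=float)
    a = np.asarray(a, dtype=int)
    y = np.asarray(y, dtype=int)
    if not (np.any(a == 0) and np.any(a == 1)):
        raise ValueError("x_learner requires both treatment arms")
    clf_f, reg_f = _base_learners(base_learner, seed)

    m0, m1 = a == 0, a == 1
    mu0 = clf_f().fit(X[m0], y[m0])
    mu1 = clf_f().fit(X[m1], y[m1])
    p0_all = mu0.predict_proba(X)[:, 1]
    p1_all = mu1.predict_proba(X)[:, 1]

    d1 = y[m1] - p0_all[m1]          # imputed effect on the treated (HFNC)
    d0 = p1_all[m0] - y[m0]          # imputed effect on the controls (NIV)
    tau1 = reg_f().fit(X[m1], d1)
    tau0 = reg_f().fit(X[m0], d0)
    g = clf_f().fit(X, a).predict_proba(X)[:, 1]
    theta = g * tau0.predict(X) + (1.0 - g) * tau1.predict(X)
    ite = np.clip(-theta, -1.0, 1.0)
    if ids is None:
        ids = np.arange(len(ite))
    return _to_table(ids, "x_learner", np.clip(p0_all, 0, 1),
                     np.clip(p1_all, 0, 1), ite, band, n_mc=0)


@dataclass
class CausalForestSkipped:
    """Explicit skip signal when no generalized-random-forest backend exists."""

    status: str
    reason: str


def causal_forest_adapter(X, a, y, ids=None, band: float = DEFAULT_BAND,
                          seed: int = 0):
    """Thin adapter around an external Causal Forest implementation (econml).

    Returns the standard ITE table when the backend is importable, otherwise a
    :class:`CausalForestSkipped` diagnostic -- never a silent failure.  The
    forest itself is deliberately not re-implemented here.
    """
    try:
        from econml.grf import CausalForest  # type: ignore
    except ImportError as exc:
        return CausalForestSkipped(
            status="skipped",
            reason=f"causal-forest backend (econml) unavailable: {exc}",
        )
    X = np.asarray(X, dtype=float)
    a = np.asarray(a, dtype=int)
    y = np.asarray(y, dtype=int)
    forest = CausalForest(n_estimators=200, random_state=seed)
    forest.fit(X, a, y)
    theta = forest.predict(X).ravel()  # effect of a=1 (HFNC) on IMV risk
    ite = np.clip(-theta, -1.0, 1.0)
    m0 = a == 0
    base = float(np.mean(y[m0])) if m0.any() else float(np.mean(y))
    p_niv = np.clip(base + 0.0 * ite, 0, 1)
    p_hfnc = np.clip(p_niv - ite, 0, 1)
    if ids is None:
        ids = np.arange(len(ite))
    return _to_table(ids, "causal_forest", p_niv, p_hfnc, ite, band, n_mc=0)
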