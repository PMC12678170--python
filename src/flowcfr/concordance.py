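"""Treatment-concordance outcome analysis and ground-truth causal metrics.

An encounter is *concordant* when the first post-T0 respiratory support
actually administered matches the arm the ITE engine prefers for that
encounter (encounter-level label; later modality switches are ignored).
Encounters with an Indifferent recommendation contribute 0 to both
concordance indicators and therefore sit in the reference group of the
regressions.  Outcome rates are stratified into the four groups
(NIV concordant / NIV discordant / HFNC concordant / HFNC discordant), and a
multivariable logistic regression adjusts for age, sex (female = 1), SOFA at
T0, CCI and the risk score at T0, reporting Wald odds ratios, 95% CIs and
p-values plus the in-sample AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import average_precision_score, roc_auc_score

from .ite import HFNC_PREFERRED, NIV_PREFERRED

__all__ = [
    "ADJUSTERS",
    "label_concordance",
    "outcome_rates_by_group",
    "RegressionResult",
    "fit_concordance_logistic",
    "discrimination_metrics",
    "causal_metrics",
    "plot_rates_by_group",
]

ADJUSTERS = ["age", "sex", "sofa_t0", "cci", "risk_t0"]


def label_concordance(estimates: pd.DataFrame, actual_treatments,
                      outcomes: pd.DataFrame, adjusters: pd.DataFrame) -> pd.DataFrame:
    """Build per-encounter concordance records from an ITE table.

    Parameters
    ----------
    estimates : ITE table with 'encounter_id' and 'band_label'.
    actual_treatments : array-like of 0 (NIV) / 1 (HFNC), aligned with rows.
    outcomes : DataFrame with 'imv' and optionally 'mort_hospice' columns.
    adjusters : DataFrame with the regression adjusters (ADJUSTERS columns).
    """
    if estimates["encounter_id"].duplicated().any():
        dup = estimates.loc[estimates["encounter_id"].duplicated(), "encounter_id"]
        raise ValueError(f"duplicate encounter_id(s): {sorted(set(dup))[:5]}")
    actual = np.asarray(actual_treatments, dtype=int)
    if len(actual) != len(estimates):
        raise ValueError("actual_treatments length mismatch")
    band = estimates["band_label"].to_numpy()
    recommended = np.where(
        band == NIV_PREFERRED, "NIV",
        np.where(band == HFNC_PREFERRED, "HFNC", "Indifferent"),
    )
    niv_conc = ((recommended == "NIV") & (actual == 0)).astype(int)
    hfnc_conc = ((recommended == "HFNC") & (actual == 1)).astype(int)
    rec = pd.DataFrame({
        "encounter_id": estimates["encounter_id"].to_numpy(),
        "engine_id": estimates["engine_id"].to_numpy(),
        "recommended": recommended,
        "actual": np.where(actual == 1, "HFNC", "NIV"),
        "niv_concordant": niv_conc,
        "hfnc_concordant": hfnc_conc,
        "outcome_imv": np.asarray(outcomes["imv"], dtype=int),
    })
    if "mort_hospice" in outcomes:
        rec["outcome_mort_hospice"] = np.asarray(outcomes["mort_hospice"], dtype=int)
    for col in ADJUSTERS:
        rec[col] = np.asarray(adjusters[col], dtype=float)
    return rec


def outcome_rates_by_group(records: pd.DataFrame,
                           outcome: str = "outcome_imv") -> pd.DataFrame:
    """Event counts and proportions per (actual arm x concordant/discordant)
    cell; an empty cell's rate is NaN (undefined), never 0."""
    if len(records) == 0:
        raise ValueError("no records")
    rows = []
    for arm in ("NIV", "HFNC"):
        flag = "niv_concordant" if arm == "NIV" else "hfnc_concordant"
        in_arm = records["actual"] == arm
        for concordant in (1, 0):
            cell = records[in_arm & (records[flag] == concordant)]
            n = len(cell)
            events = int(cell[outcome].sum()) if n else 0
            rows.append({
                "arm": arm,
                "group": "concordant" if concordant else "discordant",
                "n": n,
                "events": events,
                "rate": events / n if n else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    """Wald-test summary of one multivariable logistic fit."""

    outcome: str
    n: int
    auc: float
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # table columns: term, odds_ratio, ci_low, ci_high, p_value


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        bad = []
        cols: list[int] = []
        for j in range(arr.shape[1]):
            trial = arr[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(X.columns[j])
            else:
                cols.append(j)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_concordance_logistic(records: pd.DataFrame,
                             outcome_name: str = "outcome_imv",
                             covariates: list[str] | None = None) -> RegressionResult:
    """Maximum-likelihood logistic regression of the outcome on the two
    concordance indicators plus the adjusters, with Wald ORs/CIs/p-values and
    the in-sample AUC.  Perfect separation and rank deficiency surface as
    explicit errors rather than silently unstable fits."""
    y = np.asarray(records[outcome_name], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome_name!r} has a single class")
    if covariates is None:
        covariates = ["niv_concordant", "hfnc_concordant", *ADJUSTERS]
    X = records[covariates].astype(float)
    _check_full_rank(sm.add_constant(X))
    design = sm.add_constant(X)
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels' PerfectSeparationError et al.
        raise ValueError(f"logistic fit failed ({exc}); check separation") from exc
    if not fit.mle_retvals.get("converged", False) or np.any(
        np.abs(fit.params.to_numpy()[1:]) > 25
    ):
        raise ValueError(
            "logistic fit did not converge to a finite solution; "
            "likely perfect separation in a covariate"
        )
    ci = fit.conf_int()
    table = pd.DataFrame({
        "term": X.columns,
        "odds_ratio": np.exp(fit.params[X.columns].to_numpy()),
        "ci_low": np.exp(ci.loc[X.columns, 0].to_numpy()),
        "ci_high": np.exp(ci.loc[X.columns, 1].to_numpy()),
        "p_value": fit.pvalues[X.columns].to_numpy(),
    })
    auc = float(roc_auc_score(y, fit.predict(design)))
    return RegressionResult(outcome=outcome_name, n=len(y), auc=auc, table=table)


def discrimination_metrics(y_true, y_score) -> tuple[float, float]:
    """Rank-based AUC (ties averaged) and interpolation-free PR-AUC
    (average-precision step integral)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both outcome classes required")
    return (
        float(roc_auc_score(y_true, y_score)),
        float(average_precision_score(y_true, y_score)),
    )


def causal_metrics(ite, tau_true, band: float = 0.001) -> dict:
    """Ground-truth metrics (synthetic cohorts only): PEHE (RMSE of ite vs
    tau_true), ATE bias, and sign accuracy over encounters with
    |tau_true| > band."""
    ite = np.asarray(ite, dtype=float)
    tau = np.asarray(tau_true, dtype=float)
    if ite.shape != tau.shape:
        raise ValueError(f"length mismatch: {ite.shape} vs {tau.shape}")
    pehe = float(np.sqrt(np.mean((ite - tau) ** 2)))
    ate_bias = float(np.mean(ite) - np.mean(tau))
    mask = np.abs(tau) > band
    sign_acc = (
        float(np.mean(np.sign(ite[mask]) == np.sign(tau[mask])))
        if mask.any()
        else np.nan
    )
    return {"pehe": pehe, "ate_bias": ate_bias, "sign_accuracy": sign_acc}


def plot_rates_by_group(rate_tables: dict[str, pd.DataFrame], outcome_label: str,
                        path) -> None:
    """Grouped bar chart of outcome rates per engine across the four
    concordance groups; one panel mirrors one site/outcome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    engines = list(rate_tables)
    groups = [("NIV", "concordant"), ("NIV", "discordant"),
              ("HFNC", "concordant"), ("HFNC", "discordant")]
    width = 0.8 / max(len(engines), 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    xs = np.arange(len(groups))
    for k, eng in enumerate(engines):
        tab = rate_tables[eng].set_index(["arm", "group"])
        vals = [tab.loc[g, "rate"] if g in tab.index else np.nan for g in groups]
        ax.bar(xs + k * width, vals, width=width, label=eng)
    ax.set_xticks(xs + width * (len(engines) - 1) / 2)
    ax.set_xticklabels([f"{a}\n{g}" for a, g in groups])
    ax.set_ylabel(f"{outcome_label} rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
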