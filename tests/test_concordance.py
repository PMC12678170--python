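"""Concordance labeling, stratified rates, adjusted regression, metrics."""

import numpy as np
import pandas as pd
import pytest

from flowcfr.concordance import (
    causal_metrics,
    discrimination_metrics,
    fit_concordance_logistic,
    label_concordance,
    outcome_rates_by_group,
)


def make_estimates(labels, ids=None):
    n = len(labels)
    return pd.DataFrame({
        "encounter_id": ids if ids is not None else np.arange(n),
        "engine_id": "test",
        "band_label": labels,
    })


def make_adjusters(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "age": rng.uniform(30, 90, n),
        "sex": rng.integers(0, 2, n),
        "sofa_t0": rng.integers(0, 10, n),
        "cci": rng.integers(0, 8, n),
        "risk_t0": rng.uniform(0, 1, n),
    })


class TestLabelConcordance:
    def test_exhaustive_recommendation_by_actual_grid(self):
        labels = ["NIV_preferred", "HFNC_preferred", "Indifferent"] * 2
        actual = [0, 0, 0, 1, 1, 1]
        rec = label_concordance(
            make_estimates(labels),
            actual,
            pd.DataFrame({"imv": [0] * 6}),
            make_adjusters(6),
        )
        assert rec["niv_concordant"].tolist() == [1, 0, 0, 0, 0, 0]
        assert rec["hfnc_concordant"].tolist() == [0, 0, 0, 0, 1, 0]
        # at most one indicator set; Indifferent contributes to neither
        assert ((rec["niv_concordant"] + rec["hfnc_concordant"]) <= 1).all()

    def test_duplicate_encounter_id_rejected(self):
        est = make_estimates(["Indifferent", "Indifferent"], ids=[3, 3])
        with pytest.raises(ValueError, match="duplicate"):
            label_concordance(est, [0, 1], pd.DataFrame({"imv": [0, 0]}),
                              make_adjusters(2))

    def test_length_mismatch_rejected(self):
        est = make_estimates(["Indifferent"])
        with pytest.raises(ValueError, match="mismatch"):
            label_concordance(est, [0, 1], pd.DataFrame({"imv": [0]}),
                              make_adjusters(1))


class TestOutcomeRates:
    def test_hand_built_eight_encounter_table(self):
        labels = ["NIV_preferred"] * 4 + ["HFNC_preferred"] * 4
        actual = [0, 0, 1, 1, 1, 1, 0, 0]
        imv = [1, 0, 1, 1, 0, 1, 1, 1]
        rec = label_concordance(make_estimates(labels), actual,
                                pd.DataFrame({"imv": imv}), make_adjusters(8))
        rates = outcome_rates_by_group(rec).set_index(["arm", "group"])
        assert rates.loc[("NIV", "concordant"), "n"] == 2
        assert rates.loc[("NIV", "concordant"), "rate"] == 0.5
        assert rates.loc[("NIV", "discordant"), "rate"] == 1.0
        assert rates.loc[("HFNC", "concordant"), "rate"] == 0.5
        assert rates.loc[("HFNC", "discordant"), "rate"] == 1.0

    def test_empty_cell_rate_is_undefined_not_zero(self):
        labels = ["NIV_preferred"] * 3
        rec = label_concordance(make_estimates(labels), [0, 0, 0],
                                pd.DataFrame({"imv": [0, 1, 0]}),
                                make_adjusters(3))
        rates = outcome_rates_by_group(rec).set_index(["arm", "group"])
        assert np.isnan(rates.loc[("NIV", "discordant"), "rate"])
        assert np.isnan(rates.loc[("HFNC", "concordant"), "rate"])

    def test_rates_always_proportions(self, small_cohort, tiny_model):
        from flowcfr.ite import cfr_baseline_ite

        est = cfr_baseline_ite(tiny_model, small_cohort.x)
        est["encounter_id"] = small_cohort.frame["encounter_id"].to_numpy()
        rec = label_concordance(
            est, small_cohort.frame["a"],
            pd.DataFrame({"imv": small_cohort.frame["y"]}),
            small_cohort.frame[["age", "sex", "sofa_t0", "cci", "risk_t0"]],
        )
        rates = outcome_rates_by_group(rec)
        valid = rates["rate"].dropna()
        assert ((valid >= 0) & (valid <= 1)).all()


class TestLogisticRegression:
    @staticmethod
    def _binary_records(n11, e11, n10, e10, seed=0):
        """Single binary covariate x: (n, events) per x level."""
        rows = []
        for x, n, e in ((1, n11, e11), (0, n10, e10)):
            rows += [{"xbin": x, "y": 1}] * e + [{"xbin": x, "y": 0}] * (n - e)
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("seed", range(6))
    def test_single_binary_covariate_matches_cross_product_ratio(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(10, 40, 2)
        e1 = rng.integers(2, n1 - 1)
        e0 = rng.integers(2, n0 - 1)
        rec = self._binary_records(n1, e1, n0, e0)
        res = fit_concordance_logistic(rec, "y", covariates=["xbin"])
        expected = (e1 * (n0 - e0)) / ((n1 - e1) * e0)
        got = res.table.set_index("term").loc["xbin", "odds_ratio"]
        assert got == pytest.approx(expected, rel=1e-6)

    def test_null_covariate_or_confidence_interval_coverage(self):
        rng = np.random.default_rng(7)
        covered = 0
        for _ in range(50):
            n = 300
            rec = pd.DataFrame({
                "xbin": rng.integers(0, 2, n),
                "y": rng.integers(0, 2, n),
            })
            res = fit_concordance_logistic(rec, "y", covariates=["xbin"])
            row = res.table.set_index("term").loc["xbin"]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 45  # nominal 95% coverage, >=90% required

    def test_or_inside_reported_confidence_interval(self):
        rec = self._binary_records(30, 12, 25, 5)
        res = fit_concordance_logistic(rec, "y", covariates=["xbin"])
        row = res.table.set_index("term").loc["xbin"]
        assert row["ci_low"] <= row["odds_ratio"] <= row["ci_high"]
        assert row["odds_ratio"] > 0

    def test_single_class_outcome_rejected(self):
        rec = pd.DataFrame({"xbin": [0, 1, 0], "y": [1, 1, 1]})
        with pytest.raises(ValueError, match="single class"):
            fit_concordance_logistic(rec, "y", covariates=["xbin"])

    def test_rank_deficiency_names_collinear_column(self):
        rng = np.random.default_rng(8)
        n = 100
        x = rng.normal(size=n)
        rec = pd.DataFrame({"x1": x, "x2": 2 * x,
                            "y": rng.integers(0, 2, n)})
        with pytest.raises(ValueError, match="x2"):
            fit_concordance_logistic(rec, "y", covariates=["x1", "x2"])

    def test_perfect_separation_raises_diagnostic(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        rec = pd.DataFrame({"xbin": x, "y": x.astype(int)})
        with pytest.raises(ValueError):
            fit_concordance_logistic(rec, "y", covariates=["xbin"])


class TestDiscriminationMetrics:
    def test_perfect_ranking(self):
        auc, pr = discrimination_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0
        assert pr == 1.0

    def test_anti_ranking(self):
        auc, _ = discrimination_metrics([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert auc == 0.0

    def test_matches_all_pairs_counting_oracle(self):
        rng = np.random.default_rng(9)
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1])
        s = rng.normal(size=10)
        s[3] = s[0]  # inject a tie across classes
        auc, _ = discrimination_metrics(y, s)
        pos = s[y == 1]
        neg = s[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            discrimination_metrics([1, 1, 1], [0.1, 0.2, 0.3])


class TestCausalMetrics:
    def test_perfect_estimates(self):
        tau = np.array([0.1, -0.2, 0.05])
        m = causal_metrics(tau, tau)
        assert m["pehe"] == 0.0
        assert m["ate_bias"] == 0.0
        assert m["sign_accuracy"] == 1.0

    def test_constant_offset_shows_in_ate_bias(self):
        tau = np.array([0.1, -0.1, 0.0, 0.2])
        m = causal_metrics(tau + 0.1, tau)
        assert m["ate_bias"] == pytest.approx(0.1)

    def test_matches_hand_computed_rmse(self):
        rng = np.random.default_rng(10)
        ite = rng.normal(size=8)
        tau = rng.normal(size=8)
        m = causal_metrics(ite, tau)
        assert m["pehe"] == pytest.approx(np.sqrt(np.mean((ite - tau) ** 2)))

    def test_sign_accuracy_excludes_within_band_truth(self):
        tau = np.array([0.0005, 0.2, -0.2])
        ite = np.array([-0.5, 0.1, -0.1])  # wrong sign only on banded entry
        m = causal_metrics(ite, tau, band=0.001)
        assert m["sign_accuracy"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            causal_metrics(np.zeros(3), np.zeros(4))
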