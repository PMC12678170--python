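"""ITE banding, counterfactual inference, and baseline estimators.

Sign convention under test everywhere: ite = P(IMV|NIV) - P(IMV|HFNC), so a
positive value (higher risk under NIV) labels the encounter HFNC_preferred.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flowcfr.ite import (
    CausalForestSkipped,
    ITE_COLUMNS,
    causal_forest_adapter,
    cfr_baseline_ite,
    classify_band,
    counterfactual_probs,
    estimate_ite,
    predict_counterfactual,
    x_learner_ite,
)
from flowcfr.model import ModelData
from flowcfr.simulate import SimConfig, generate_cohort


class TestClassifyBand:
    @pytest.mark.parametrize("ite,label", [
        (-0.05, "NIV_preferred"),
        (-0.0011, "NIV_preferred"),
        (-0.001, "Indifferent"),
        (0.0, "Indifferent"),
        (0.001, "Indifferent"),
        (0.0011, "HFNC_preferred"),
        (0.05, "HFNC_preferred"),
    ])
    def test_banding_rule(self, ite, label):
        assert classify_band(ite) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_band(np.nan)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-1, 1, allow_nan=False), st.floats(1e-6, 0.2))
    def test_label_consistent_with_band(self, ite, band):
        label = classify_band(ite, band=band)
        if label == "Indifferent":
            assert abs(ite) <= band
        elif label == "NIV_preferred":
            assert ite < -band
        else:
            assert ite > band


class TestCounterfactualInference:
    def test_n_mc_must_be_positive(self, tiny_model, small_data):
        with pytest.raises(ValueError, match="n_mc"):
            counterfactual_probs(tiny_model, small_data.X[:3], n_mc=0)

    def test_symmetric_model_gives_exactly_zero_ite(self, tiny_model, small_data):
        import copy

        model = copy.deepcopy(tiny_model)
        # make the two arms literally identical
        model.flow1.flows[1].params = {
            k.replace("f1a", "f1b"): v.copy()
            for k, v in model.flow1.flows[0].params.items()
        }
        model.flow1.cal[1] = model.flow1.cal[0]
        model.flow1.cal_scale[1] = model.flow1.cal_scale[0]
        for k in list(model.stage0.params):
            if k.startswith("h1"):
                model.stage0.params[k] = model.stage0.params[
                    "h0" + k[2:]].copy()
        tab = estimate_ite(model, small_data.X[:20], n_mc=64, seed=3)
        assert np.all(tab["ite"].to_numpy() == 0.0)
        assert (tab["band_label"] == "Indifferent").all()

    def test_degenerate_flow_maps_everything_to_event(self, tiny_model, small_data):
        import copy

        model = copy.deepcopy(tiny_model)
        model.flow1.cal[1] = 50.0  # pushes every latent above the threshold
        p = predict_counterfactual(model, small_data.X[:10], arm=1,
                                   n_mc=64, seed=0)
        assert np.all(p == 1.0)

    def test_mc_standard_error_shrinks_with_n_mc(self, tiny_model, small_data):
        x = small_data.X[:1]
        sds = []
        for n_mc in (16, 256, 4096):
            ps = [predict_counterfactual(tiny_model, x, arm=0, n_mc=n_mc,
                                         seed=s)[0] for s in range(12)]
            sds.append(np.std(ps))
        assert sds[2] < sds[1] < sds[0]
        assert sds[2] < 0.35 * sds[0]

    def test_ite_table_is_internally_consistent(self, tiny_model, small_data):
        tab = estimate_ite(tiny_model, small_data.X[:30], n_mc=32, seed=1)
        assert list(tab.columns) == ITE_COLUMNS
        assert tab["p_imv_niv"].between(0, 1).all()
        assert tab["p_imv_hfnc"].between(0, 1).all()
        assert np.allclose(tab["ite"],
                           tab["p_imv_niv"] - tab["p_imv_hfnc"])
        relabeled = [classify_band(v) for v in tab["ite"]]
        assert (tab["band_label"] == relabeled).all()


class TestCfrBaseline:
    def test_identical_heads_give_zero_ite(self, tiny_model, small_data):
        import copy

        model = copy.deepcopy(tiny_model)
        for k in list(model.stage0.params):
            if k.startswith("h1"):
                model.stage0.params[k] = model.stage0.params["h0" + k[2:]].copy()
        tab = cfr_baseline_ite(model, small_data.X[:15])
        assert np.all(tab["ite"].to_numpy() == 0.0)

    def test_matches_hand_computed_logistic_difference(self):
        from flowcfr.model import FlowCFR, Stage0Net, Stage1Flows, CondFlow, TrainConfig

        cfg = TrainConfig(phi_dim=2, enc_hidden=(2,), head_hidden=2,
                          normalize_phi=False)
        rng = np.random.default_rng(0)
        net = Stage0Net(2, 0, cfg, rng)
        # identity-ish encoder: zero hidden weights so phi = output bias
        for k in list(net.params):
            if k.startswith(("eW", "eb", "h0", "h1")):
                net.params[k][:] = 0.0
        net.params["eb1"][:] = [1.0, -2.0]
        net.params["h0W0"][:] = [[0.5, 0.0], [0.0, 0.5]]
        net.params["h0W1"][:] = [[1.0], [1.0]]
        net.params["h1W1"][:] = [[0.0], [0.0]]
        model = FlowCFR(stage0=net,
                        flow1=Stage1Flows(3, 1, 4, rng),
                        flow2=CondFlow(2, 1, 4, rng, prefix="f2"),
                        config=cfg, gated_idx=[])
        X = np.zeros((1, 2))
        phi = np.array([1.0, -2.0])
        l0 = np.tanh(0.5 * phi).sum()
        expected = 1 / (1 + np.exp(-l0)) - 0.5
        tab = cfr_baseline_ite(model, X)
        assert tab["ite"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_band_labels_delegate_to_classifier(self, tiny_model, small_data):
        tab = cfr_baseline_ite(tiny_model, small_data.X[:25])
        assert (tab["band_label"] == [classify_band(v) for v in tab["ite"]]).all()


class TestXLearner:
    def test_null_effect_estimates_near_zero(self):
        cfg = SimConfig(n_encounters=4000, tau_fn_id="constant", tau_scale=0.0,
                        seed=31)
        cohort = generate_cohort(cfg)
        tab = x_learner_ite(cohort.x, cohort.frame["a"], cohort.frame["y"])
        assert np.mean(np.abs(tab["ite"])) <= 0.03

    def test_constant_effect_recovered(self):
        # averaged over three cohort draws: the single-draw sampling sd of
        # the plug-in mean effect at n=2000 is ~0.03
        means = []
        for seed in (31, 32, 33):
            cfg = SimConfig(n_encounters=2000, tau_fn_id="constant",
                            tau_scale=0.10, seed=seed)
            cohort = generate_cohort(cfg)
            tab = x_learner_ite(cohort.x, cohort.frame["a"], cohort.frame["y"])
            means.append(tab["ite"].mean())
        assert abs(np.mean(means) - 0.10) <= 0.04

    def test_deterministic_given_seed_and_data(self, small_data):
        t1 = x_learner_ite(small_data.X, small_data.a, small_data.y, seed=2)
        t2 = x_learner_ite(small_data.X, small_data.a, small_data.y, seed=2)
        assert np.array_equal(t1["ite"], t2["ite"])

    def test_single_arm_rejected(self, small_data):
        with pytest.raises(ValueError, match="arms"):
            x_learner_ite(small_data.X, np.zeros_like(small_data.a),
                          small_data.y)

    def test_unknown_base_learner_rejected(self, small_data):
        with pytest.raises(ValueError, match="base learner"):
            x_learner_ite(small_data.X, small_data.a, small_data.y,
                          base_learner="svm")


class TestSignRecovery:
    def test_sign_flipping_effects_recovered_without_hidden_confounding(self):
        """With gamma_hidden = 0 and a sign-flipping true effect, both the
        trained flow model and the X-learner get the per-encounter effect
        sign right for at least 80% of encounters (n = 5000)."""
        sim = SimConfig(n_encounters=5000, d_measured=8, gamma_hidden=0.0,
                        tau_fn_id="sign_flipping", tau_scale=0.12, seed=7)
        cohort = generate_cohort(sim)
        data = ModelData(X=cohort.x, a=cohort.frame["a"].to_numpy(),
                         y=cohort.frame["y"].to_numpy())
        tau = cohort.frame["tau_true"].to_numpy()
        mask = np.abs(tau) > 0.001

        from flowcfr.model import TrainConfig, train_model

        model = train_model(data, TrainConfig(seed=0))
        rf = estimate_ite(model, data.X, n_mc=256, seed=1)["ite"].to_numpy()
        xl = x_learner_ite(data.X, data.a, data.y)["ite"].to_numpy()
        for name, ite in (("flow_model", rf), ("x_learner", xl)):
            acc = np.mean(np.sign(ite[mask]) == np.sign(tau[mask]))
            assert acc >= 0.80, (name, acc)


class TestCausalForestAdapter:
    def test_missing_backend_yields_documented_skip(self, small_data):
        res = causal_forest_adapter(small_data.X, small_data.a, small_data.y)
        if isinstance(res, CausalForestSkipped):
            assert res.status == "skipped"
            assert "econml" in res.reason
        else:  # backend present: schema must match the other engines
            assert list(res.columns) == ITE_COLUMNS
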