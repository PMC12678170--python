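# flowcfr

Flow-adjusted counterfactual regression for individualized treatment
effects between high-flow nasal cannula (HFNC) and non-invasive ventilation
(NIV) in ICU patients at risk of invasive mechanical ventilation (IMV).

When a deterioration alert fires at time T0, clinicians choose the first
escalation modality — HFNC or NIV — under genuine equipoise: trials report
mixed population-level results, and the average effect can hide patients who
benefit from one modality and are harmed by the other.  `flowcfr` estimates,
per encounter, the individualized risk difference

    ITE = P(IMV | NIV) − P(IMV | HFNC)

from observational data, labels each encounter *NIV preferred*
(ITE < −0.001), *HFNC preferred* (ITE > 0.001) or *Indifferent*
(|ITE| ≤ 0.001), and evaluates whether *concordance* — receiving the arm the
model prefers — is associated with better outcomes after adjusting for age,
sex, SOFA, comorbidity burden, and the alert-model risk score.

The estimator is a three-stage deep counterfactual model, written in plain
numpy with hand-derived gradients:

- **Stage 0** — a counterfactual-regression (CFR) backbone: a
  staleness-gated encoder maps T0 features to a representation φ, two
  arm-specific heads predict the factual outcome, and an *exact*
  Wasserstein-1 penalty `λ·W1(φ|NIV, φ|HFNC)` (closed form in 1-D, a
  transport linear program otherwise) balances the arms' representation
  distributions.
- **Stage 1** — a conditional normalizing flow per arm models the
  (uniformly dequantized) outcome distribution `p(y | φ, a)` by exact
  change-of-variables maximum likelihood.
- **Stage 2** — a second flow, conditioned on φ only, re-models the latent
  driving the outcome flow, intended to absorb hidden-confounding signal
  such as unmeasured severity or clinician preference.

Counterfactual probabilities are Monte-Carlo averages through the flows with
common random numbers across arms.  Baselines (CFR-heads, X-learner, a
Causal Forest adapter), the EHR-style preprocessing rules (hourly median
binning, 24-h carry-forward, 72-h baselines, short-term slopes,
time-since-last-measurement gating), a synthetic ICU cohort generator with
known ground truth, and the concordance regression complete the pipeline.
`docs/methods.md` documents the model, the generator's assumptions, and
known limitations — including why the Stage-2 adjustment is not identified
for binary outcomes.

## Worked example

```python
import numpy as np
from flowcfr import (SimConfig, generate_cohort, TrainConfig, train_model,
                     estimate_ite, causal_metrics)
from flowcfr.model import ModelData

sim = SimConfig(n_encounters=2000, d_measured=8, gamma_hidden=0.5,
                tau_fn_id="sign_flipping", tau_scale=0.12, seed=7)
cohort = generate_cohort(sim)
data = ModelData(X=cohort.x, a=cohort.frame["a"].to_numpy(),
                 y=cohort.frame["y"].to_numpy())
model = train_model(data, TrainConfig(seed=0))
ite = estimate_ite(model, data.X, n_mc=128, seed=1)
print("factual IMV rate:", round(cohort.frame["y"].mean(), 3))
print(ite["band_label"].value_counts().to_string())
metrics = causal_metrics(ite["ite"].to_numpy(),
                         cohort.frame["tau_true"].to_numpy())
print({k: round(v, 3) for k, v in metrics.items()})
```

prints

```
factual IMV rate: 0.25
band_label
NIV_preferred     1003
HFNC_preferred     888
Indifferent        109
{'pehe': 0.112, 'ate_bias': -0.002, 'sign_accuracy': 0.697}
```

The simulated cohort has a 25% intubation rate and a sign-flipping true
effect of ±0.12 with moderate hidden confounding (`gamma_hidden=0.5`).  The
model splits the cohort into the three preference bands; against the
generator's ground truth the per-encounter error (PEHE) is 0.112, the mean
effect is nearly unbiased (−0.002), and the preferred-arm sign is right for
70% of encounters — hidden confounding at this strength costs roughly ten
points of sign accuracy relative to the unconfounded setting.

The same pipeline is scriptable end to end:

```bash
flowcfr all --out run_dir --seed 5          # simulate → preprocess → train
                                            # → ITE (all engines) → evaluate
```

which writes the cohort, features, model checkpoint, per-engine ITE tables,
concordance rates/regressions, figures, and a checksummed manifest.

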