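# Methods

`flowcfr` estimates individualized treatment effects (ITEs) between two
non-invasive respiratory-support strategies — non-invasive positive-pressure
ventilation (NIV, arm 0) and high-flow nasal cannula (HFNC, arm 1) — on the
binary outcome of subsequent invasive mechanical ventilation (IMV), from
observational ICU data anchored at a risk-alert time T0.  Because real EHR
cohorts of this kind are not publicly distributable, the package ships a
synthetic cohort generator with full causal ground truth; every claim the
test suite makes is a claim about the method's behaviour under that
generator.

## Sign convention

One convention is used everywhere:

    ite = tau = P(IMV | NIV) - P(IMV | HFNC).

Negative values mean NIV is the safer arm ("NIV preferred", `ite < -band`),
positive values mean HFNC is ("HFNC preferred", `ite > band`), and
`|ite| <= band` (inclusive) is "Indifferent".  The default band is 0.001 —
a 0.1-percentage-point risk difference, deliberately conservative so that
near-zero estimation noise is not acted on.

## The estimator

**Stage 0 — balanced representation (CFR backbone).**  A feature vector
(current values, 72-h baselines, short-term slopes, per-channel
time-since-last-measurement (TSLM), and static covariates) is passed through
a staleness gate — each channel's features are multiplied by
`exp(-softplus(rho_c) * tslm_c)`, a learnable monotone-nonincreasing gate
equal to 1 for fresh data — then through a tanh feedforward encoder to a
representation `phi`, L2-normalized per row.  Two arm-specific heads predict
the factual outcome.  The loss is

    L0 = BCE(factual head) + lambda * W1(phi | a=0, phi | a=1),

where `W1` is the *exact* empirical Wasserstein-1 distance between the
per-arm representation batches: closed form in one dimension, otherwise a
transport linear program (HiGHS) with subgradients read off the optimal plan.
Design notes that matter in practice:

- The representation is normalized to the unit sphere because the W1 term is
  otherwise degenerate — the encoder can shrink `phi` while the heads
  rescale, driving the penalty to zero without balancing anything.
- `lambda` ramps in after a warm-up (default 20 epochs) so the balancing
  pull acts on a formed predictive fit rather than collapsing a random one.
- Early stopping and snapshot selection use the *factual validation BCE
  alone*.  Folding the W1 term into the selection criterion systematically
  prefers collapsed representations.
- After the encoder snapshot is chosen, both heads are refit to convergence
  on the frozen representation: the main risk signal converges in a few
  epochs while the arm contrast develops more slowly.

**Stage 1 — conditional outcome flow.**  The binary outcome is uniformly
dequantized, `y' = logit((y + eps)/2)`, `eps ~ U(0,1)`, so that `P(y' > 0) =
P(y = 1)` exactly, and a conditional normalizing flow models `p(y' | phi, a)`
by exact change-of-variables maximum likelihood.  Arm conditioning is
realized as one flow per arm.  Each flow is a stack of blocks that are, in
the normalizing direction, `v = (y - t(h)) * exp(-s(h))`, `z = v + alpha *
tanh(v)` with `|alpha| < 0.95` (strictly increasing) and `s` tanh-clamped to
±2.5; `s` and `t` come from a shared tanh conditioner plus direct linear
skip connections from the conditioning vector.  The conditioning vector is
`[phi, head_logit(phi, a)]`: reusing the frozen head logit hands the flow a
calibrated location signal instead of forcing it to relearn one, and the
location skip weight is initialized at 1 so training starts from
`y' = z + head_logit`.  The normalizing direction is closed form (used for
training); the generative direction inverts each perturbation by bracketed
bisection with Newton polish (round-trip error ~1e-13).

Because the dequantized likelihood is only weakly sensitive to how much
probability mass sits on either side of the binary threshold, each arm's
flow carries a final affine latent calibration layer (`y = flow(k*z + c)`,
an exact flow block) whose shift and scale are refit against the factual
binary cross-entropy after density training.  This step is what brings the
flow path's effect estimates to the same accuracy as the heads.

**Stage 2 — latent adjustment flow.**  A second flow `f2(. | phi)` —
conditioned on the representation only, never on the treatment — is trained
so that `f1(f2(z))` still reproduces the observed outcomes (composed
likelihood; Stage 0/1 frozen; identity at initialization).  The retained
snapshot is selected by the factual validation BCE of Stage-2 inference, so
an adjustment that does not improve observable calibration resolves to no
adjustment.

**Inference.**  Counterfactual probabilities are Monte-Carlo averages:
latents are drawn per encounter (antithetic ± pairs), mapped through `f2`
and then through each arm's Stage-1 flow, and thresholded at 0.  The same
draws serve both arms (common random numbers), so a symmetric model yields
an ITE of exactly zero.  Default `n_mc = 128`.  A `mode="stage1"` path skips
`f2` for ablation.

**Baselines.**  The CFR baseline reads ITEs directly off the two Stage-0
heads.  The X-learner uses scikit-learn base learners (logistic outcome and
propensity models, linear effect regressions by default).  The Causal Forest
entry is a thin adapter around `econml` that returns an explicit skip
diagnostic when that backend is not installed; the forest is intentionally
not re-implemented.

## Training protocol

Stages are trained strictly in order (0 → 1 → 2) with Adam, minibatches,
and early stopping with best-snapshot restore; earlier stages are frozen
when later ones train.  All randomness flows from a single seed; two runs
with the same seed and data produce bit-identical parameters.  An
improvement smaller than `min_delta` (1e-5 for Stage 0, 1e-3 for flows) does
not displace the incumbent snapshot.  Fine-tuning to a new site warm-starts
every stage from the checkpoint on a treatment-by-outcome stratified subset
(default 25%) with the original hyperparameters.  Hyperparameter search is a
seeded random search scored by internal-validation AUC of the factual head;
trials whose training history contains a non-finite loss are marked diverged
and score `-inf`.

Key defaults: `phi_dim=8`, encoder width 32, head width 16, 3 flow blocks,
conditioner width 16, `lambda_ipm=0.05`, lr 0.003 (flows 0.02), batch 256
(per-batch per-arm W1 subsample cap 64), patience 30 (flows 40), 20%
internal validation stratified by arm × outcome.

## The synthetic cohort

Measured covariates `x ~ N(0, I_d)` (default d=8) and a hidden severity
scalar `u ~ N(0,1)`.  Treatment selection is `P(HFNC | x, u) =
sigmoid(beta·x + gamma*u)`; the default `beta` loads on half of the
covariates (partial overlap with the risk gradient, propensity-logit sd
~1.2).  Arm risks sit symmetrically around a margin-squashed baseline so the
risk difference equals `tau(x)` *exactly* for every encounter (constant,
linear, or sign-flipping shapes; default magnitude 0.10–0.12, in the range
of clinically meaningful absolute risk differences for escalation
decisions).  The intercept is calibrated by bisection to a target factual
IMV prevalence (default 0.25, matching the 20–30% regime of real post-alert
cohorts).  Both potential outcomes share one uniform draw per encounter
(monotone coupling), so `tau_true` is deterministic given `(x, u)`.
`gamma_hidden` is the single dial for hidden confounding: it sends `u` into
both selection and outcome.

Longitudinal streams (5 vital/lab channels by default) follow a per-channel
loading on a severity path that blends `u` with a ramp rising toward the
encounter's trigger hour; observations are jittered within hours,
occasionally duplicated (so median binning matters), and dropped
per-channel-hour with probability `missing_rate`.  A stand-in risk trigger —
a fixed logistic score of current channel values, evaluated from hour 4 —
reproduces only the *semantics* of a deployed alert model (first threshold
crossing defines T0), not any particular model.  Adjusters (age, sex, SOFA,
CCI, risk score) are noisy transforms of `(x, u)` so the concordance
regression has genuine confounding to adjust for.

What the generator does *not* emulate: real EHR feature inventories
(hundreds of channels), missingness that is informative beyond the severity
ramp (MNAR mechanisms), treatment switching after T0, competing risks, or
site heterogeneity beyond a seed change.  Passing tests therefore establish
internal correctness and recovery under the stated generative assumptions,
not clinical performance.

## Preprocessing rules

Hourly median binning; carry-forward for up to 24 h with the boundary
*inclusive* at exactly 24 h; TSLM is the age of the last true observation
(carried-forward values do not reset it; capped at 72 h, which is also the
fill value for never-observed channels); 72-h trailing baseline mean over
observed, pre-imputation values only; short-term slope between the last two
non-missing values with the time gap capped at 24 h, and 0 with fewer than
two observations; remaining gaps mean-imputed and all features z-scored with
training-split statistics only (leakage asserted against by recomputation in
the tests).

## Concordance analysis

An encounter is concordant when the first post-T0 modality matches the
engine's preferred arm; Indifferent recommendations contribute to neither
indicator and sit in the regression reference group.  Outcome proportions
are reported per (actual arm × concordant/discordant) cell, with empty cells
undefined rather than zero.  The multivariable logistic model regresses the
outcome on both concordance indicators plus age, sex (female = 1), SOFA at
T0, CCI, and the risk score at T0, reporting Wald odds ratios, 95% CIs,
p-values, and the in-sample AUC; perfect separation and rank deficiency
raise explicit errors (no penalized fallback).  Discrimination metrics are
the rank-based AUC (ties averaged) and the average-precision PR-AUC.  With
synthetic ground truth, `causal_metrics` reports PEHE (RMSE of ITE against
truth), ATE bias, and sign accuracy outside the indifference band.

## Numerical choices

Exact-W1 subgradients use the optimal transport plan with unit-vector cost
gradients (denominator floored at 1e-12).  Generative flow inversion uses 60
bisection steps on the bracket `[target - |alpha|, target + |alpha|]` plus
three Newton steps.  Dequantization clips the interior probability at 1e-7.
Logistic fits use statsmodels MLE with a convergence/|coef|>25 guard that
surfaces probable separation.  Non-finite intermediates in flows raise an
error naming the offending block.

## Known limitations

- **The Stage-2 adjustment is not identified for binary outcomes.**  The
  factual law contributes only `p(y | x, a)` and the propensity; a Bernoulli
  mixture over a latent severity is still Bernoulli, so the interventional
  quantity is not recoverable without further assumptions.  Mechanically,
  `f2` applies the same monotone latent shift to both arms at a given `phi`,
  whereas removing confounding bias would require opposite-signed per-arm
  corrections.  Empirically, on cohorts with `gamma_hidden = 1`, Stage-2
  inference changes the ATE bias by ~±0.001–0.002 with essentially random
  sign, and the dedicated directional test in the suite documents this by
  failing.  The adjustment should be read as a diagnostic layer, not a
  guarantee.
- Effect estimates shrink toward the confounded contrast when selection is
  strongly aligned with the risk gradient; under such geometry no
  regularized estimator in the package meets tight mean-effect tolerances.
- The flow path's per-encounter effects are slightly noisier than the
  heads'; Monte-Carlo inference adds `~sqrt(p(1-p)/n_mc)` noise per arm
  (mitigated, not removed, by common random numbers and antithetic draws).
- Problem sizes in the test suite and acceptance script (n = 2000–5000,
  ten replicates for seeded comparisons) are the package's chosen benchmark
  scale; sampling noise at these sizes is accounted for in the test bounds.
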