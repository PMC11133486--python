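# Methods

## Problem setting

Clinical-trial panel data couple, per patient, a static vector `x_s`
(demographics, medical history; mixed continuous/categorical/ordinal
types) with a variable-length sequence of visit vectors `x_{1:T}`
(labs, scores, adverse-event flags) and a drop-off outcome. The aim is
a *patient digital twin*: a generative model of
`p(x_t | x_s, x_{1:t-1})` that can (a) simulate whole journeys from
static conditionals alone (Type A), (b) continue a partially observed
journey (Type B), and (c) report a per-visit drop-off probability so
simulated journeys terminate realistically.

## Model

All learning happens in a latent space produced by a sequential
autoencoder. Seven parameterized components are trained together:

| component | form | role |
|---|---|---|
| `Enc_s` | MLP | static vector → conditional latent `h_s` |
| `Enc_t` | GRU | `h_t = Enc_t(h_s, h_{t-1}, x_t)`, causal |
| `Dec_s`, `Dec_t` | MLP | latents → feature space; sigmoid heads for continuous/ordinal blocks, softmax per categorical block |
| `G` | GRU | `ĥ_t = G(h_s, ĥ_{t-1}, z_t)`, Wiener-path noise `z_t` |
| `D` | bi-GRU + MLP | static score + per-step scores of (conditioned) latent sequences; deliberately non-causal |
| `AuxC` | MLP | predicts `h_s` back from a journey's final latent; penalizes condition-incoherent generation |
| `S` | GRU | next-latent-step prediction `S(h_s, h_{t-1})`, the supervised signal |
| `T_r` | GRU + sigmoid | per-step drop-off probability `p_t = T_r(h_s, h_{t-1})` |

Initial recurrent states are zero vectors. The noise process is a
discrete Wiener path: `z_t = z_{t-1} + N(0, I)` with unit increments,
`z_0 = 0`, dimension defaulting to the temporal latent dimension.

### Objectives

* Reconstruction `L_R`: batch mean of `||x_s - x̃_s|| + Σ_t ||x_t - x̃_t||`
  over observed steps. Norms are plain (non-squared) Euclidean norms of
  the per-step residual, matching the printed objective; a `squared`
  flag switches to the squared variant common in practice.
* Termination `L_Tr`: positive-class-weighted binary cross entropy of
  `p_t` against the terminal-step labels (per-patient mean over
  observed steps, batch mean). The default positive weight is
  (non-terminal observed steps)/(terminal steps) on the training
  split. A multi-class cross-entropy variant (drop-off reasons) is
  implemented and reduces exactly to the binary form at C = 2.
* Adversarial `L_U = L_D + L_G` (relativistic pairing):
  `L_D = -E[Σ_t log σ(y_t - ỹ_t)]`, `L_G = -E[Σ_t log σ(ỹ_t - y_t)]`
  on pre-sigmoid logits through a stable log-sigmoid. Step terms are
  summed per patient and averaged over the batch; the discriminator's
  static score enters as one extra relativistic term (weight 1 by
  default). Probabilities are clamped at 1e-7 wherever a log is taken.
* Auxiliary `L_AuxC`: mean Euclidean error of `AuxC(h*_T)` against
  `h_s`, averaged over real- and generated-derived predictions.
* Supervised `L_S`: `Σ_t ||h_t - f(h_s, h_{t-1}, ·)||` with `f = S`
  during pre-training and `f = G` during joint training; the step-1
  prediction is made from the zero initial state.

### Training schedule

Phase 1 pre-trains the supervised components: the autoencoder on
`L_R + λ L_S`, the supervisor on `L_S`, the termination head on
`L_Tr`. Phase 2 alternates per minibatch: (1) discriminator and
auxiliary-classifier updates on real and generated latents; (2) a
generator update on `L_G + η L_S + δ L_AuxC`; (3) autoencoder
fine-tuning (every step by default, cadence configurable); (4)
termination fine-tuning on the updated latent space.

λ, η, δ are auto-calibrated once at the start of the joint phase so
each weighted term equals the adversarial-loss magnitude at that point
(the losses are brought into similar value ranges); the calibrated
values are logged and can be frozen by disabling `auto_calibrate`.
Optimizers are Adam with 1e-3 (supervised nets) and 5e-4 (G/D/AuxC);
the D:G update ratio is 1:1.

Generator conditioning follows the loop mode: *open loop* feeds the
generator its own previous latent, *closed loop* feeds the ground-truth
previous latent (teacher forcing). The default schedule alternates per
epoch so both the Type A (own-rollout) and Type B (prefix-conditioned)
inference regimes are exercised during training. The literature's
naming of these two modes is not used consistently; this package fixes
the definitions above and makes the schedule configurable.

Full-scale deployments of this architecture family train far longer
(on the order of 2500 pre-training epochs per supervised component and
10,000 joint epochs for cohorts of ~1000 patients). The package
defaults are desk-scale — 200 pre-training and 500 joint epochs on
cohorts of ~200 patients with 16-dimensional temporal latents — which
the bundled tests and the acceptance script use throughout; all
documented recovery properties hold at that scale.

Determinism contract: given identical seed, configuration and backend,
logged scalar series reproduce to 1e-6 relative; bit-exactness is not
promised.

### Numerical backend

No deep-learning framework is used: the package includes a minimal
vectorized reverse-mode autodiff engine over numpy arrays
(`cohortwin.autodiff`) with exactly the operations the model needs,
plus seeded Glorot-initialized Linear/MLP/GRU building blocks
(`cohortwin.nn`). Gradients of every operation and of the GRU
composite are verified against central finite differences in the test
suite. Networks here are small (latent dims ≲ 32, sequences ≲ 12
steps), where this backend trains the full model in minutes on one
CPU core.

## Simulation

Type A: `h_s = Enc_s(s)`; for `t = 1..max_len`, draw `z_t`, set
`ĥ_t = G(h_s, ĥ_{t-1}, z_t)` and `p_t = T_r(h_s, ĥ_{t-1})`; stop at
the first termination trigger. The default termination rule samples
Bernoulli(`p_t`) — preserving the stochastic-journey premise — with a
deterministic threshold rule (`p_t ≥ τ`, τ = 0.5) available for
audits. The termination head consumes generated latents, matching its
training-time signature over latents. Trajectories that reach
`max_len` untriggered are labelled censored and contribute `max_len`
to the simulation-averaged drop-off visit (an option excludes them).

Two corrections matter for simulation realism:

* *Hazard calibration.* The termination head is trained with a
  positive-class weight `w` (class imbalance: one terminal step per
  dropped journey). A `w`-weighted cross entropy is minimized not by
  the event probability `q` but by `p = wq / (1 + (w-1)q)` — roughly a
  3x inflation at the default `w ≈ 8` — so sampling the raw output
  would terminate journeys far too early. The simulator therefore
  inverts the weighting exactly, `q = p / (w - (w-1)p)`, using the
  weight stored with the trained model (`termination_hazard`). The
  correction is the identity when `w = 1` and leaves ROC-type
  evaluations unchanged (it is monotone).
* *Administrative censoring.* Real journeys end either by drop-off or
  by the trial's planned visit schedule; hazard-only simulation
  over-represents hazard-stopped journeys and skews any side-by-side
  distributional comparison. `apply_administrative_censoring`
  truncates simulated trajectories with per-trajectory planned lengths
  drawn from the trial design (Uniform{len_min..len_max} for the
  bundled cohorts); the evaluation pipelines apply it when building
  generated cohorts for comparison with real data.

Type B teacher-force encodes the observed prefix, echoes it unmodified
into every trajectory, and generates the continuation from the last
real latent. Per-patient noise streams derive from
`SeedSequence(seed).spawn(...)`, so simulation sets are reproducible
patient by patient.

## Evaluation suite

* **ACD** — mean absolute difference of mixed-type bivariate
  correlations over all unordered feature pairs, computed on one pooled
  table per cohort (every observed visit row, static features repeated
  per visit). Pearson for continuous-continuous, correlation ratio
  (η, the square root of between-category variance over total
  variance) for continuous-categorical, Theil's U for
  categorical-categorical. Theil's U is directional; the matrix cell
  averages both directions so the statistic is invariant to feature
  ordering. Ordinal variables are treated as continuous. Zero-variance
  inputs define the correlation as 0 with a warning.
* **FID** — Fréchet distance `||μ_R - μ_G||² + Tr(Σ_R + Σ_G - 2(Σ_R Σ_G)^{1/2})`
  between Gaussian fits to sequence embeddings (final observed hidden
  state of the shared temporal encoder). The matrix square root uses a
  symmetric eigendecomposition of `Σ_R^{1/2} Σ_G Σ_R^{1/2}`; a 1e-6
  ridge keeps covariances PSD at modest N; tiny negative round-off is
  clamped to 0.
* **Alpha-precision** — fraction of generated embeddings inside a
  one-sphere estimate of the α-support of the real embedding
  distribution: ball centered at the real mean with radius the
  empirical α-quantile of real distances (α = 0.95 by default). This
  single-sphere support estimate is a deliberate simplification of
  richer support estimators; it is exact for elliptical embedding
  clouds and is validated by self-consistency (an independent half of
  the real set scores ≈ α). One caveat follows directly from the
  construction: the score is purely radial, so any *under-dispersed*
  cohort — including degenerate ones whose embeddings happen to sit
  slightly closer to the real mean than real data do — can score above
  α, i.e. above what a perfect replica achieves in expectation. When
  ranking generators against such baselines, alpha-precision should be
  read together with FID, which penalizes the same concentration.
* **Discriminator score** — AUROC/PR-AUC/F1 of a fresh post-hoc GRU
  sequence classifier (never the training discriminator) on raw
  encoded sequences, stratified 70/30 train/eval. Scores near 0.5 mean
  indistinguishable generation.
* **Next-step prediction** — identical post-hoc GRU regressors trained
  on real-train vs generated data, both scored (masked MSE in encoded
  space) on the common real test set.
* **Look-ahead JSD** — for each prefix length i, Type B continuations
  are simulated and the generated value distribution at each later step
  j is compared with the real step-j distribution at horizon j - i.
  The distance is the square root of the base-2 Jensen-Shannon
  divergence of per-variable histograms (16 equal-width bins over the
  pooled real range for continuous variables, native categories
  otherwise, ε = 1e-12 smoothing), averaged over variables.
* **Drop-off MAPE** — `|pred - actual| / actual` of the
  simulation-averaged drop-off visit, grouped by number of known
  visits; the bundled predictive baseline is an XGBoost regressor on
  mean-summarized histories.

## Synthetic cohorts and what they do (not) show

Real cohorts of this kind are access-restricted, so the package ships
a generator whose structure mirrors published Alzheimer's-trial
panels: ~10²–10³ patients, 2–12 visits (defaults give mean length
≈ 5.4), 4 static + 10 temporal mixed-type variables. Its generative
rules are a latent disease-state random walk
`s_t = s_{t-1} + μ + β_g·g + ε` (group g is the conditional effect to
recover; defaults μ = 0.35, β_g = 0.5, σ_s = 0.5), linear mixing into
continuous features with loadings W and noise σ_e = 0.5, Bernoulli
adverse-event flags in `sigmoid(κ s_t)`, thresholded ordinal stages,
and a drop-off hazard `sigmoid(a + b s_t + c Δs_t)` with defaults
(a, b, c) = (−7, 2, 0.5). These hazard defaults define the package's
"strong-hazard" regime: the realized hazard separates terminal from
non-terminal steps with AUC ≈ 0.95, so termination-recovery checks
have headroom, while ≈ half the journeys end administratively
(censored, `dropped=False`) at a Uniform{2..12} length.

Because the data-generating process is known, held-out evaluation is
not limited to the 20% test fold of the training cohort: the bundled
end-to-end checks train at desk scale (200 patients) and then evaluate
on a larger fresh cohort (400 patients, distinct seed) drawn from the
same distribution. A 40-patient fold yields ROC-AUC estimates from
~25 positive steps and 16-dimensional Gaussian FID fits from 40
sequences, both dominated by sampling noise; the larger held-out
sample estimates the same population quantities with usable precision
while still containing no patient the model ever saw.

The random walk was chosen because it admits parameter-free oracles:
pooled cross-feature correlations follow from the mixing rules (checked
by a vectorized Monte-Carlo oracle at 10⁶ pooled visits with a fixed,
distinct oracle seed), and group-wise drop-off rates follow from the
hazard rules (10⁶-trajectory oracle). What passing on these cohorts
does *not* show: robustness to missing data, irregular visit spacing,
measurement artifacts, nonlinear feature interactions, or the higher
dimensionality of real trial tables — none of which the generator
emulates.

## Design choices on open points

* Continuous features are min-max scaled to [0, 1] (not z-scored) so
  sigmoid decoder heads are range-valid by construction; ordinal
  features are equally spaced scalars in [0, 1] decoded by
  nearest-level snap.
* Visit indices are 1-based consecutive integers; timestamps and
  missing values are out of scope (the reader rejects NaNs).
* Categories unseen at fit time map to a reserved unknown slot rather
  than dropping rows; the slot decodes back only when it carries
  dominant (≥ 0.5) mass, so soft decoder outputs snap to known levels.
* The train split is floor(N · train_frac), by patient, seeded.
* The auxiliary classifier's target is the conditional latent `h_s`
  (the stated purpose of the component); the loss function is
  target-agnostic, so the alternative final-latent pairing can be
  recovered by passing different arguments.
* Recurrent components are single-layer GRUs; deeper stacks are not
  currently supported (`n_recurrent_layers` must be 1).
* Checkpoints are single `.npz` files carrying parameters, network
  configuration, the fitted transform and a format version tag.

## Known limitations

Sequences are regular-interval and fully observed; the adversarial
phase has no early stopping (fixed epochs, as in the reference
schedule); the alpha-support estimate is a single sphere; multi-class
drop-off reasons are implemented at the loss level but not exercised
end to end; single-CPU numpy training is practical at desk scale but
not for latent dimensions or cohort sizes orders of magnitude larger.
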