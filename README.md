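# cohortwin

Patient digital twins for clinical-trial monitoring: a conditional,
termination-aware generative model of mixed-type, variable-length
patient journeys, with a full generation-quality evaluation suite and
a synthetic-cohort generator for end-to-end validation.

## Who this is for

Biostatisticians and trial-analytics engineers who want to move
patient-retention modelling from single point-predictions to
*simulation*: given a patient's demographics and history, draw many
plausible future trajectories — each with a per-visit drop-off
probability — and read risk, expected drop-off visit, and likely paths
off the simulated distribution. The same machinery produces synthetic
private versions of trial datasets.

## The model

Panel data per patient: a static vector `x_s` (mixed
continuous/categorical/ordinal) and a visit sequence `x_{1:T}` with a
drop-off outcome. The joint density is factored autoregressively,

&nbsp;&nbsp;`p(x_s, x_{1:T}) = p(x_s) ∏_t p(x_t | x_s, x_{1:t-1})`,

and learned in a latent space: a sequential autoencoder (MLP static
encoder, GRU temporal encoder `h_t = Enc_t(h_s, h_{t-1}, x_t)`) maps
features to latents; a conditional GRU generator
`ĥ_t = G(h_s, ĥ_{t-1}, z_t)` (Wiener-path noise `z_t`) produces
latent journeys; a bidirectional-GRU discriminator scores them with a
relativistic adversarial objective
`L_D = −E[Σ_t log σ(y_t − ỹ_t)]`, `L_G = −E[Σ_t log σ(ỹ_t − y_t)]`;
an auxiliary classifier predicts `h_s` back from the final latent
(penalizing condition-incoherent generation and mode collapse); a
supervisor network provides a next-step supervised loss; and a dynamic
termination network emits `p_t = T_r(h_s, h_{t-1})`, the per-visit
drop-off probability that ends simulated journeys. Training is
two-phase (supervised pre-training, then joint adversarial training);
simulation is *Type A* (whole journeys from static conditionals) or
*Type B* (continuation of an observed prefix). See
[docs/methods.md](docs/methods.md) for the full account.

The package has no deep-learning-framework dependency: networks run on
a small bundled numpy autodiff engine, sized for desk-scale problems
(hundreds of patients, ≤ 12 visits, latent dims ≈ 16).

## Worked example

```python
import cohortwin as cw
from cohortwin.trainer import TrainConfig, fit
from cohortwin.simulator import (SimulationConfig, simulate_type_a,
                                 predict_dropoff_visit)

# a seeded synthetic trial: 200 patients, 2-12 visits, 14 mixed-type
# variables, group-dependent progression, trajectory-dependent drop-off
cohort, truth = cw.generate(cw.SynthConfig(n_patients=200, seed=1))
train, test = cw.split_cohort(cohort, train_frac=0.8, seed=1)
transform = cw.fit_transform(train)

model, pre_log, joint_log = fit(train, transform,
                                train_config=TrainConfig(seed=1))
print(f"reconstruction loss {pre_log.first('L_R'):.2f} -> {pre_log.last('L_R'):.2f}")

sims = simulate_type_a(model, transform, test.records[:1],
                       SimulationConfig(n_sims=1000, max_len=12, seed=7))
print(f"patient {sims[0].patient_id}: "
      f"predicted drop-off visit {predict_dropoff_visit(sims[0]):.2f}, "
      f"{sum(c == 'dropped' for c in sims[0].causes)} of 1000 journeys drop off")
```

Output from this exact snippet:

```
reconstruction loss 8.33 -> 1.60
patient p00000: predicted drop-off visit 7.70, 972 of 1000 journeys drop off
```

The reconstruction loss falling ~5x over pre-training says the
autoencoder learned a faithful latent space; the simulation line reads
one patient's digital twin — across 1000 simulated futures this
patient eventually drops off in 97% of them, on average around visit
7.7, information a monitoring team can act on well before the event.

The same pipeline is scriptable from the shell:

```bash
cohortwin synth --out-dir data/ --seed 1 --n-patients 200
cohortwin train --data-dir data/ --out model.ckpt.npz --seed 1
cohortwin simulate --model model.ckpt.npz --static data/static.csv \
    --n-sims 1000 --out sims.csv
cohortwin evaluate --model model.ckpt.npz --data-dir data/ --report report.json
```

`evaluate` writes the generation-quality report: ACD (mean absolute
difference of mixed-type correlation matrices), FID on encoder
embeddings, alpha-precision (diversity), a post-hoc discriminator
score, next-step prediction transfer, and the look-ahead
Jensen-Shannon distance table.

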