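"""Two-phase optimization of the journey-generation model.

Phase 1 (pre-training) fits the supervised components independently:
the auto-encoder on reconstruction (plus a lambda-weighted supervised
term), the supervisor on next-latent-step prediction, and the
termination head on drop-off cross entropy.  Phase 2 (joint training)
alternates, per minibatch: (1) discriminator + auxiliary-classifier
updates on real and generated latents; (2) a generator update on the
relativistic adversarial term plus eta-weighted supervised and
delta-weighted auxiliary terms; (3) auto-encoder fine-tuning; (4)
termination-head fine-tuning on the updated latent space.

The generator's autoregressive conditioning follows the configured
loop mode: ``closed`` feeds ground-truth previous latents (teacher
forcing), ``open`` feeds the generator's own previous output, and
``alternating`` (default) switches per epoch so both generation
scenarios are exercised during training.

Training runs a fixed number of epochs.  The package defaults are the
desk-scale 200 pre-training / 500 joint epochs used throughout the
docs and tests; full-scale runs of this architecture family use on the
order of 2500 pre-training epochs per supervised component and 10000
joint epochs.  All
randomness flows from ``TrainConfig.seed``; logged scalar series are
reproducible to 1e-6 relative across runs on the same backend.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import losses as L
from . import networks as net
from .autodiff import Adam, Tensor, no_grad
from .losses import LossWeights
from .panel_schema import EncodedBatch

logger = logging.getLogger(__name__)


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    pretrain_epochs: int = 200      # full-scale reference: 2500 per component
    joint_epochs: int = 500         # full-scale reference: 10000
    batch_size: int = 64
    lr_supervised: float = 2e-3
    lr_adversarial: float = 5e-4
    weights: LossWeights = field(default_factory=LossWeights)
    auto_calibrate: bool = True     # rescale eta/delta at joint start
    loop_mode: str = "alternating"  # open | closed | alternating
    ae_finetune_every: int = 1      # joint-phase AE update cadence (steps)
    squared_norm: bool = False
    seed: int = 0
    log_every: int = 1

    def __post_init__(self):
        if self.pretrain_epochs < 1 or self.joint_epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loop_mode not in ("open", "closed", "alternating"):
            raise ValueError(f"unknown loop_mode {self.loop_mode!r}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class TrainLog:
    phase: str
    seed: int
    config_hash: str
    epochs: list = field(default_factory=list)
    series: dict = field(default_factory=dict)
    wall_clock: float = 0.0
    calibrated_weights: dict = field(default_factory=dict)

    def append(self, epoch: int, **scalars):
        self.epochs.append(epoch)
        for k, v in scalars.items():
            self.series.setdefault(k, []).append(float(v))

    def last(self, key: str) -> float:
        return self.series[key][-1]

    def first(self, key: str) -> float:
        return self.series[key][0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epochs, **self.series})


def _check_finite(value: float, component: str, epoch: int):
    if not np.isfinite(value):
        raise TrainingDiverged(
            f"non-finite loss in {component} at epoch {epoch}")


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield perm[i:i + batch_size]


def _slice_batch(data: EncodedBatch, idx: np.ndarray) -> EncodedBatch:
    return EncodedBatch(
        s=data.s[idx], x=data.x[idx], mask=data.mask[idx],
        lengths=data.lengths[idx], drop_labels=data.drop_labels[idx],
        patient_ids=[data.patient_ids[i] for i in idx] if data.patient_ids else [])


def _shifted_prev(h_seq: Tensor | np.ndarray, d_ht: int) -> np.ndarray:
    """Previous-step latents aligned so index t holds h_{t-1} (h_0 = 0)."""
    arr = h_seq.data if isinstance(h_seq, Tensor) else np.asarray(h_seq)
    prev = np.zeros_like(arr)
    prev[:, 1:] = arr[:, :-1]
    return prev


def _supervisor_predictions(model, h_s: Tensor, h_prev: np.ndarray) -> Tensor:
    from . import autodiff as ad
    t_max = h_prev.shape[1]
    outs = [net.supervise_step(model, h_s, Tensor(h_prev[:, t]))
            for t in range(t_max)]
    return ad.stack(outs, axis=1)


def _termination_probs(model, h_s: Tensor, h_prev: np.ndarray) -> Tensor:
    from . import autodiff as ad
    t_max = h_prev.shape[1]
    outs = [net.termination_prob(model, h_s, Tensor(h_prev[:, t]))
            for t in range(t_max)]
    return ad.stack(outs, axis=1)


def _zero_all(model):
    for p in model.parameters():
        p.grad = None


# ---------------------------------------------------------------------------
# phase 1: pre-training
# ---------------------------------------------------------------------------
def pretrain(model: net.ModelState, train_data: EncodedBatch,
             config: TrainConfig) -> tuple:
    """Supervised warm-up of auto-encoder, supervisor and termination head.

    Generator, discriminator and auxiliary-classifier parameters are
    untouched in this phase.
    """
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    w = config.weights
    opt_ae = Adam(model.params_ae(), lr=config.lr_supervised)
    opt_s = Adam(model.params_sup(), lr=config.lr_supervised)
    opt_t = Adam(model.params_term(), lr=config.lr_supervised)
    log = TrainLog(phase="pretrain", seed=config.seed,
                   config_hash=config.config_hash())

    for epoch in range(config.pretrain_epochs):
        acc = {"L_R": 0.0, "L_S": 0.0, "L_Tr": 0.0}
        nb = 0
        for idx in _minibatches(train_data.n, config.batch_size, rng):
            mb = _slice_batch(train_data, idx)
            # (a) auto-encoder on L_R + lam * L_S
            _zero_all(model)
            h_s = net.encode_static(model, mb.s)
            h_seq = net.encode_sequence(model, h_s, mb.x, mb.mask)
            s_tilde, x_tilde = net.decode(model, h_s, h_seq)
            l_r = L.reconstruction_loss(mb.s, s_tilde, mb.x, x_tilde, mb.mask,
                                        squared=config.squared_norm)
            h_prev = _shifted_prev(h_seq, model.config.d_ht)
            sup_pred = _supervisor_predictions(model, h_s, h_prev)
            l_s_ae = L.supervised_loss(h_seq, sup_pred, mb.mask,
                                       squared=config.squared_norm)
            (l_r + w.lam * l_s_ae).backward()
            opt_ae.step()

            # (b,c) supervisor & termination head on detached latents
            with no_grad():
                h_s_d = net.encode_static(model, mb.s)
                h_seq_d = net.encode_sequence(model, h_s_d, mb.x, mb.mask)
            h_s_d = h_s_d.detach()
            h_prev_d = _shifted_prev(h_seq_d, model.config.d_ht)
            _zero_all(model)
            sup_pred = _supervisor_predictions(model, h_s_d, h_prev_d)
            l_s = L.supervised_loss(h_seq_d.data, sup_pred, mb.mask,
                                    squared=config.squared_norm)
            l_s.backward()
            opt_s.step()

            _zero_all(model)
            probs = _termination_probs(model, h_s_d, h_prev_d)
            l_tr = L.termination_bce(probs, mb.drop_labels, mb.mask, w.w_pos)
            l_tr.backward()
            opt_t.step()

            acc["L_R"] += float(l_r.data)
            acc["L_S"] += float(l_s.data)
            acc["L_Tr"] += float(l_tr.data)
            nb += 1
        for k in acc:
            acc[k] /= nb
            _check_finite(acc[k], k, epoch)
        if epoch % config.log_every == 0 or epoch == config.pretrain_epochs - 1:
            log.append(epoch, **acc)
    model.phase = "pretrained"
    model.term.pos_weight = float(w.w_pos)
    log.wall_clock = time.time() - t0
    return model, log


# ---------------------------------------------------------------------------
# phase 2: joint adversarial training
# ---------------------------------------------------------------------------
def _generator_rollout(model, h_s: Tensor, h_prev_real: np.ndarray,
                       z: np.ndarray, open_loop: bool):
    """Generated latent sequence; conditioning per loop mode."""
    from . import autodiff as ad
    n, t_max, _ = z.shape
    outs = []
    h_prev = Tensor(np.zeros((n, model.config.d_ht)))
    for t in range(t_max):
        cond = h_prev if open_loop else Tensor(h_prev_real[:, t])
        h_t = net.generate_step(model, h_s, cond, Tensor(z[:, t]))
        outs.append(h_t)
        h_prev = h_t
    return ad.stack(outs, axis=1)


def _calibrate_weights(model, data: EncodedBatch, config: TrainConfig,
                       noise: net.NoiseSource) -> dict:
    """One-time rescaling of eta/delta so each weighted generator term
    starts at the magnitude of the adversarial loss (losses brought into
    similar value ranges).

    lam (the auto-encoder's supervised weight) is deliberately NOT
    rescaled: the adversarial loss is much larger than the supervised
    one at this point, and inflating lam accordingly over-smooths the
    latent space — the encoder then maps structurally broken sequences
    next to real ones, which blinds every embedding-based metric
    downstream.  lam keeps its configured (pre-training) value.
    """
    w = config.weights
    with no_grad():
        h_s = net.encode_static(model, data.s)
        h_seq = net.encode_sequence(model, h_s, data.x, data.mask)
        h_prev = _shifted_prev(h_seq, model.config.d_ht)
        sup_pred = _supervisor_predictions(model, h_s, h_prev)
        l_s = float(L.supervised_loss(h_seq.data, sup_pred, data.mask,
                                      squared=config.squared_norm).data)
        z = noise.sample_paths(data.n, data.x.shape[1])
        h_fake = _generator_rollout(model, h_s, h_prev, z, open_loop=False)
        sr, yr = net.discriminate_logits(model, h_s, h_seq, data.mask)
        sf, yf = net.discriminate_logits(model, h_s, h_fake, data.mask)
        _, l_g = L.rsgan_losses(yr, yf, data.mask, sr, sf, w.static_score_weight)
        l_g = float(l_g.data)
        h_T_real = net.select_final_latents(h_seq, data.lengths)
        h_T_fake = net.select_final_latents(h_fake, data.lengths)
        l_aux = float(L.auxc_loss(h_s, net.aux_predict(model, h_T_real),
                                  net.aux_predict(model, h_T_fake),
                                  squared=config.squared_norm).data)

    def ratio(target, value):
        return target / value if value > 1e-12 else 1.0

    cal = {"lam": w.lam, "eta": ratio(l_g, l_s), "delta": ratio(l_g, l_aux)}
    logger.info("loss weights at joint start (eta/delta calibrated): %s", cal)
    return cal


def joint_train(model: net.ModelState, train_data: EncodedBatch,
                config: TrainConfig) -> tuple:
    """Adversarial phase over a pre-trained model (see module docstring
    for the per-step update schedule)."""
    if model.phase not in ("pretrained", "trained"):
        logger.warning("joint_train called on a model in phase %r", model.phase)
    t0 = time.time()
    rng = np.random.default_rng(config.seed + 1)
    noise = net.NoiseSource(model.config.d_z, seed=config.seed + 2)
    w = LossWeights(**asdict(config.weights))
    if config.auto_calibrate:
        cal = _calibrate_weights(model, train_data, config, noise)
        w.lam, w.eta, w.delta = cal["lam"], cal["eta"], cal["delta"]
    opt_d = Adam(model.params_disc(), lr=config.lr_adversarial)
    opt_aux = Adam(model.params_auxc(), lr=config.lr_adversarial)
    opt_g = Adam(model.params_gen(), lr=config.lr_adversarial)
    opt_ae = Adam(model.params_ae(), lr=config.lr_supervised)
    opt_t = Adam(model.params_term(), lr=config.lr_supervised)
    log = TrainLog(phase="joint", seed=config.seed,
                   config_hash=config.config_hash(),
                   calibrated_weights={"lam": w.lam, "eta": w.eta, "delta": w.delta})

    saturated_steps = 0
    step = 0
    for epoch in range(config.joint_epochs):
        if config.loop_mode == "alternating":
            open_loop = epoch % 2 == 1
        else:
            open_loop = config.loop_mode == "open"
        acc = {k: 0.0 for k in ("L_R", "L_S", "L_Tr", "L_D", "L_G", "L_AuxC")}
        nb = 0
        for idx in _minibatches(train_data.n, config.batch_size, rng):
            mb = _slice_batch(train_data, idx)
            t_max = mb.x.shape[1]
            with no_grad():
                h_s_d = net.encode_static(model, mb.s)
                h_seq_d = net.encode_sequence(model, h_s_d, mb.x, mb.mask)
            h_s_d = h_s_d.detach()
            h_real = h_seq_d.data
            h_prev_real = _shifted_prev(h_real, model.config.d_ht)
            z = noise.sample_paths(mb.n, t_max)

            # (1) discriminator + auxiliary classifier
            with no_grad():
                h_fake_d = _generator_rollout(model, h_s_d, h_prev_real, z, open_loop)
            _zero_all(model)
            sr, yr = net.discriminate_logits(model, h_s_d, Tensor(h_real), mb.mask)
            sf, yf = net.discriminate_logits(model, h_s_d, h_fake_d.detach(), mb.mask)
            l_d, _ = L.rsgan_losses(yr, yf, mb.mask, sr, sf, w.static_score_weight)
            l_d.backward()
            opt_d.step()

            _zero_all(model)
            h_T_real = Tensor(h_real[np.arange(mb.n), mb.lengths - 1])
            h_T_fake = Tensor(h_fake_d.data[np.arange(mb.n), mb.lengths - 1])
            l_aux = L.auxc_loss(h_s_d, net.aux_predict(model, h_T_real),
                                net.aux_predict(model, h_T_fake),
                                squared=config.squared_norm)
            l_aux.backward()
            opt_aux.step()

            # (2) generator
            _zero_all(model)
            h_fake = _generator_rollout(model, h_s_d, h_prev_real, z, open_loop)
            sr, yr = net.discriminate_logits(model, h_s_d, Tensor(h_real), mb.mask)
            sf, yf = net.discriminate_logits(model, h_s_d, h_fake, mb.mask)
            _, l_g = L.rsgan_losses(yr, yf, mb.mask, sr, sf, w.static_score_weight)
            l_sup_g = L.supervised_loss(h_real, h_fake, mb.mask,
                                        squared=config.squared_norm)
            h_T_fake_g = net.select_final_latents(h_fake, mb.lengths)
            l_aux_g = L.auxc_loss(h_s_d, net.aux_predict(model, h_T_fake_g),
                                  squared=config.squared_norm)
            (l_g + w.eta * l_sup_g + w.delta * l_aux_g).backward()
            g_grad_norm = float(np.sqrt(sum(
                (p.grad**2).sum() for p in model.params_gen() if p.grad is not None)))
            opt_g.step()
            if g_grad_norm < 1e-12:
                saturated_steps += 1
                if saturated_steps == 50:
                    logger.warning(
                        "discriminator saturation: generator gradient ~0 for 50 steps")
            else:
                saturated_steps = 0

            # (3) auto-encoder fine-tuning
            if step % config.ae_finetune_every == 0:
                _zero_all(model)
                h_s = net.encode_static(model, mb.s)
                h_seq = net.encode_sequence(model, h_s, mb.x, mb.mask)
                s_tilde, x_tilde = net.decode(model, h_s, h_seq)
                l_r = L.reconstruction_loss(mb.s, s_tilde, mb.x, x_tilde, mb.mask,
                                            squared=config.squared_norm)
                sup_pred = _supervisor_predictions(
                    model, h_s, _shifted_prev(h_seq, model.config.d_ht))
                l_s_ae = L.supervised_loss(h_seq, sup_pred, mb.mask,
                                           squared=config.squared_norm)
                (l_r + w.lam * l_s_ae).backward()
                opt_ae.step()
            else:
                with no_grad():
                    h_s = net.encode_static(model, mb.s)
                    h_seq = net.encode_sequence(model, h_s, mb.x, mb.mask)
                    s_tilde, x_tilde = net.decode(model, h_s, h_seq)
                    l_r = L.reconstruction_loss(mb.s, s_tilde, mb.x, x_tilde,
                                                mb.mask, squared=config.squared_norm)
                    sup_pred = _supervisor_predictions(
                        model, h_s, _shifted_prev(h_seq, model.config.d_ht))
                    l_s_ae = L.supervised_loss(h_seq.data, sup_pred, mb.mask,
                                               squared=config.squared_norm)

            # (4) termination head on the updated latent space
            with no_grad():
                h_s_d2 = net.encode_static(model, mb.s)
                h_seq_d2 = net.encode_sequence(model, h_s_d2, mb.x, mb.mask)
            _zero_all(model)
            probs = _termination_probs(model, h_s_d2.detach(),
                                       _shifted_prev(h_seq_d2, model.config.d_ht))
            l_tr = L.termination_bce(probs, mb.drop_labels, mb.mask, w.w_pos)
            l_tr.backward()
            opt_t.step()

            acc["L_D"] += float(l_d.data)
            acc["L_G"] += float(l_g.data)
            acc["L_AuxC"] += float(l_aux.data)
            acc["L_R"] += float(l_r.data)
            acc["L_S"] += float(l_s_ae.data)
            acc["L_Tr"] += float(l_tr.data)
            nb += 1
            step += 1
        for k in acc:
            acc[k] /= nb
            _check_finite(acc[k], k, epoch)
        if epoch % config.log_every == 0 or epoch == config.joint_epochs - 1:
            log.append(epoch, **acc)
    model.phase = "trained"
    model.term.pos_weight = float(w.w_pos)
    log.wall_clock = time.time() - t0
    return model, log


def default_pos_weight(train_data: EncodedBatch) -> float:
    """Class-imbalance weight: non-terminal observed steps / terminal steps."""
    n_pos = float(train_data.drop_labels.sum())
    n_obs = float(train_data.mask.sum())
    if n_pos == 0:
        return 1.0
    return (n_obs - n_pos) / n_pos


def fit(cohort_train, transform, net_config=None, train_config=None):
    """Convenience end-to-end fit: encode, build, pretrain, joint-train.

    Returns (model, pretrain_log, joint_log)."""
    from .panel_schema import encode_batch

    data = encode_batch(cohort_train, transform)
    if train_config is None:
        train_config = TrainConfig()
    if train_config.weights.w_pos == 1.0:
        train_config.weights.w_pos = default_pos_weight(data)
    if net_config is None:
        net_config = net.NetConfig(d_s=data.s.shape[1], d_x=data.x.shape[2],
                                   seed=train_config.seed)
    model = net.build_model(net_config, transform)
    model, pre_log = pretrain(model, data, train_config)
    model, joint_log = joint_train(model, data, train_config)
    return model, pre_log, joint_log
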