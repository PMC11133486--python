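"""Training objectives as pure functions of network outputs.

Conventions (documented here once, mirrored by the loop oracles in the
test suite):

* ``||.||_2`` is the plain (non-squared) Euclidean norm of the
  per-sample / per-step residual vector, as in the model's
  reconstruction, auxiliary and supervised objectives; a
  ``squared=True`` flag switches every MSE-style loss to the squared
  variant common in practice.
* Norm-based losses SUM per-patient step terms over observed steps,
  then average over the batch (``normalize_by_length=True`` divides
  each patient's sum by its observed length first); the termination
  cross entropies average over all observed steps pooled, so a
  terminal step carries the same weight whatever its journey's length.
* Padded steps (mask = 0) contribute exactly zero.
* Wherever a log is taken, probabilities are clamped to
  [eps, 1 - eps] with eps = 1e-7; adversarial scores are consumed as
  pre-sigmoid logits through a numerically stable log-sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

EPS = 1e-7


@dataclass
class LossWeights:
    """Relative weights of the multi-objective training terms."""

    lam: float = 1.0            # supervised weight in the auto-encoder objective
    eta: float = 1.0            # supervised weight in the generator objective
    delta: float = 1.0          # auxiliary-classifier weight
    w_pos: float = 1.0          # positive-class weight for termination BCE
    w_classes: tuple = ()       # per-class weights for the multi-class variant
    static_score_weight: float = 1.0

    def __post_init__(self):
        for name in ("lam", "eta", "delta", "static_score_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.w_pos <= 0:
            raise ValueError("w_pos must be > 0")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _residual_norm(diff: Tensor, squared: bool) -> Tensor:
    """Per-row Euclidean norm (or squared norm) along the last axis."""
    if squared:
        return (diff * diff).sum(axis=-1)
    return ad.l2norm(diff, axis=-1)


def reconstruction_loss(s, s_tilde, x, x_tilde, mask, squared: bool = False) -> Tensor:
    """Auto-encoder reconstruction error:
    E[ ||x_s - x~_s|| + sum_t ||x_t - x~_t|| ] over the batch, with
    padded steps excluded."""
    s, s_tilde = _as_tensor(s), _as_tensor(s_tilde)
    x, x_tilde = _as_tensor(x), _as_tensor(x_tilde)
    if s.shape != s_tilde.shape or x.shape != x_tilde.shape:
        raise ValueError("shape mismatch in reconstruction_loss")
    static_term = _residual_norm(s - s_tilde, squared)
    m = np.asarray(mask, dtype=float)
    step_norms = _residual_norm((x - x_tilde) * m[..., None], squared)
    temporal_term = (step_norms * m).sum(axis=-1)
    return (static_term + temporal_term).mean()


def termination_bce(p, drop_labels, mask, w_pos: float = 1.0) -> Tensor:
    """Positive-class-weighted binary cross entropy on per-step drop-off
    probabilities; mean over all observed steps (so a terminal step gets
    the same weight whatever its journey's length)."""
    p = _as_tensor(p)
    y = np.asarray(drop_labels, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("drop labels must be 0/1")
    m = np.asarray(mask, dtype=float)
    pc = p.clip(EPS, 1.0 - EPS)
    ll = w_pos * y * pc.log() + (1.0 - y) * (1.0 - pc).log()
    return (-(ll * m)).sum() / max(float(m.sum()), 1.0)


def termination_ce(logits, class_labels, mask, w_classes=None) -> Tensor:
    """Multi-class drop-off-reason cross entropy (class 0 = continues).

    Reduces to :func:`termination_bce` for C = 2 with matching weights
    (w_classes = (1, w_pos))."""
    logits = _as_tensor(logits)
    c = logits.shape[-1]
    if c < 2:
        raise ValueError("need at least 2 classes")
    y = np.asarray(class_labels, dtype=int)
    if y.max() >= c or y.min() < 0:
        raise ValueError("class label outside [0, C)")
    w = np.ones(c) if w_classes is None else np.asarray(w_classes, dtype=float)
    m = np.asarray(mask, dtype=float)
    probs = ad.softmax(logits, axis=-1)
    onehot = np.eye(c)[y]
    logp = probs.clip(EPS, 1.0).log()
    per_step = -((logp * onehot) * w[None, None, :]).sum(axis=-1)
    return (per_step * m).sum() / max(float(m.sum()), 1.0)


def rsgan_losses(y_real, y_fake, mask, static_real=None, static_fake=None,
                 static_score_weight: float = 1.0,
                 normalize_by_length: bool = False) -> tuple:
    """Relativistic adversarial objectives on pre-sigmoid logits.

    L_D = -E[ sum_t log sigmoid(y_t - y~_t) ],
    L_G = -E[ sum_t log sigmoid(y~_t - y_t) ];
    real and fake score sequences are paired by position.  When static
    logits are supplied, their relativistic term is added with weight
    ``static_score_weight``.
    """
    y_real, y_fake = _as_tensor(y_real), _as_tensor(y_fake)
    if y_real.shape != y_fake.shape:
        raise ValueError("real/fake score shape mismatch")
    m = np.asarray(mask, dtype=float)

    def one_side(a, b):
        per_step = -ad.log_sigmoid(a - b) * m
        per_patient = per_step.sum(axis=-1)
        if normalize_by_length:
            per_patient = per_patient / np.maximum(m.sum(axis=-1), 1.0)
        return per_patient.mean()

    l_d = one_side(y_real, y_fake)
    l_g = one_side(y_fake, y_real)
    if static_real is not None and static_fake is not None:
        sr, sf = _as_tensor(static_real), _as_tensor(static_fake)
        l_d = l_d + static_score_weight * (-ad.log_sigmoid(sr - sf)).mean()
        l_g = l_g + static_score_weight * (-ad.log_sigmoid(sf - sr)).mean()
    return l_d, l_g


def auxc_loss(h_s_true, pred_real, pred_fake=None, squared: bool = False) -> Tensor:
    """Auxiliary-classifier reconstruction error of the conditional
    latent: mean over real- and generated-derived predictions of
    ||h_s - AuxC(h*_T)||."""
    h_s_true = _as_tensor(h_s_true)
    preds = [p for p in (pred_real, pred_fake) if p is not None]
    if not preds:
        raise ValueError("need at least one prediction")
    total = None
    for p in preds:
        p = _as_tensor(p)
        if p.shape != h_s_true.shape:
            raise ValueError("prediction shape mismatch in auxc_loss")
        term = _residual_norm(h_s_true - p, squared).mean()
        total = term if total is None else total + term
    return total / len(preds)


def supervised_loss(h_seq, predictions, mask, squared: bool = False) -> Tensor:
    """Next-step latent discrepancy sum_t ||h_t - pred_t||, where the
    prediction at index t targets h_t (step 1 is predicted from the zero
    initial state); padded steps excluded."""
    h_seq, predictions = _as_tensor(h_seq), _as_tensor(predictions)
    if h_seq.shape != predictions.shape:
        raise ValueError("shape mismatch in supervised_loss")
    m = np.asarray(mask, dtype=float)
    step_norms = _residual_norm((h_seq - predictions) * m[..., None], squared)
    return (step_norms * m).sum(axis=-1).mean()
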