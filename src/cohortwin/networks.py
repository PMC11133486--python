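"""The seven parameterized components of the journey-generation model.

All learning happens in a latent space: a static encoder (MLP) maps the
patient's conditional vector to ``h_s``; a temporal encoder (GRU,
conditioned on ``h_s``) maps visit vectors to per-step latents ``h_t``;
decoders map latents back to feature space with range-valid heads
(sigmoid for continuous/ordinal blocks, softmax for categorical
blocks).  A conditional GRU generator produces latent steps from
Wiener-process noise, a bidirectional-GRU discriminator scores static
and per-step latents, an auxiliary MLP predicts the conditional latent
back from a journey's final latent, a GRU supervisor predicts the next
latent step, and a GRU termination head emits a per-step drop-off
probability.

Causal ordering is a contract: encoder, generator, supervisor and
termination outputs at step t depend only on information up to t (the
discriminator alone is intentionally non-causal).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import GRUCell, MLP, Module
from .panel_schema import FittedTransform

__version_tag__ = "cohortwin-checkpoint-1"


@dataclass(frozen=True)
class NetConfig:
    d_s: int                      # encoded static width
    d_x: int                      # encoded temporal width
    d_hs: int = 16                # static latent dim
    d_ht: int = 16                # temporal latent dim
    d_z: int | None = None        # noise dim; defaults to d_ht
    enc_s_hidden: tuple = (64,)
    dec_hidden: tuple = (64,)
    disc_hidden: tuple = (32,)
    auxc_hidden: tuple = (32,)
    term_hidden: tuple = (32,)
    n_recurrent_layers: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("d_s", "d_x", "d_hs", "d_ht"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.d_z is None:
            object.__setattr__(self, "d_z", self.d_ht)
        if self.n_recurrent_layers != 1:
            raise NotImplementedError("only single-layer recurrent components are supported")


class ContractError(ValueError):
    """Shape or dimensional-compatibility violation."""


def _check(cond: bool, msg: str):
    if not cond:
        raise ContractError(msg)


@dataclass
class OutputLayout:
    """Per-feature-block layout of a decoder output: (slice, kind)."""

    blocks: list

    @classmethod
    def from_transform(cls, transform: FittedTransform, role: str) -> "OutputLayout":
        feats = (transform.schema.static_features if role == "static"
                 else transform.schema.temporal_features)
        slices = transform.feature_slices(role)
        return cls([(slices[f.name], f.kind) for f in feats])


class HeadedDecoder(Module):
    """MLP whose raw output is mapped blockwise to valid feature ranges:
    sigmoid for continuous/ordinal scalars, softmax over categorical
    one-hot blocks."""

    def __init__(self, in_dim: int, hidden, layout: OutputLayout,
                 rng: np.random.Generator):
        out_dim = max(sl.stop for sl, _ in layout.blocks)
        self.core = MLP(in_dim, list(hidden), out_dim, rng)
        self.layout = layout

    def __call__(self, h: Tensor) -> Tensor:
        raw = self.core(h)
        parts = []
        for sl, kind in self.layout.blocks:
            block = raw[..., sl]
            if kind == "categorical":
                parts.append(ad.softmax(block, axis=-1))
            else:
                parts.append(block.sigmoid())
        return ad.concat(parts, axis=-1)


class Discriminator(Module):
    """Bidirectional GRU over per-step latents, conditioned on h_s, with
    MLP heads producing one static logit and per-step logits.

    The backward pass runs over each patient's *observed prefix*
    reversed in place, so padded steps never influence observed-step
    scores."""

    def __init__(self, d_hs: int, d_ht: int, hidden, rng: np.random.Generator):
        self.fwd = GRUCell(d_hs + d_ht, d_ht, rng)
        self.bwd = GRUCell(d_hs + d_ht, d_ht, rng)
        self.step_head = MLP(d_hs + 2 * d_ht, list(hidden), 1, rng)
        self.static_head = MLP(d_hs + 2 * d_ht, list(hidden), 1, rng)

    def __call__(self, h_s: Tensor, h_seq: Tensor, lengths: np.ndarray):
        n, t_max, _ = h_seq.shape
        idx_rev = np.arange(t_max)[None, :].repeat(n, axis=0)
        for i in range(n):
            L = int(lengths[i])
            idx_rev[i, :L] = np.arange(L - 1, -1, -1)
        rows = np.arange(n)[:, None]
        h_rev = h_seq[rows, idx_rev]

        f_state = self.fwd.init_state(n)
        b_state = self.bwd.init_state(n)
        f_out, b_out = [], []
        for t in range(t_max):
            f_state = self.fwd(ad.concat([h_s, h_seq[:, t]], axis=-1), f_state)
            b_state = self.bwd(ad.concat([h_s, h_rev[:, t]], axis=-1), b_state)
            f_out.append(f_state)
            b_out.append(b_state)
        fwd_seq = ad.stack(f_out, axis=1)                       # N x T x d
        bwd_rev = ad.stack(b_out, axis=1)
        bwd_seq = bwd_rev[rows, idx_rev]                        # un-reverse
        feats = ad.concat(
            [ad.stack([h_s] * t_max, axis=1), fwd_seq, bwd_seq], axis=-1)
        step_logits = self.step_head(feats).reshape(n, t_max)
        # final observed forward state + first-step backward state summarize the journey
        last = fwd_seq[np.arange(n), lengths - 1]
        first_b = bwd_rev[np.arange(n), lengths - 1]
        static_logit = self.static_head(
            ad.concat([h_s, last, first_b], axis=-1)).reshape(n)
        return static_logit, step_logits


class TerminationNet(Module):
    """GRU step on (h_s, h_{t-1}) with a sigmoid MLP head: per-step
    drop-off probability conditioned on the evolving trajectory latent.

    ``pos_weight`` records the positive-class weight the net was trained
    under; a weighted cross entropy is minimized not by the true event
    probability q but by p = w q / (1 + (w - 1) q), so consumers that
    need a calibrated hazard (the simulator's stopping rule) must invert
    that map — see :func:`termination_hazard`."""

    def __init__(self, d_hs: int, d_ht: int, hidden, rng: np.random.Generator):
        self.cell = GRUCell(d_hs, d_ht, rng)
        self.head = MLP(d_ht, list(hidden), 1, rng)
        self.pos_weight = 1.0

    def logit(self, h_s: Tensor, h_prev: Tensor) -> Tensor:
        state = self.cell(h_s, h_prev)
        return self.head(state).reshape(h_prev.shape[0])

    def __call__(self, h_s: Tensor, h_prev: Tensor) -> Tensor:
        return self.logit(h_s, h_prev).sigmoid()


class NoiseSource:
    """Wiener-path noise: per trajectory, z_t = z_{t-1} + N(0, I) with
    z_0 = 0 and unit time increments."""

    def __init__(self, d_z: int, seed: int = 0):
        self.d_z = d_z
        self.rng = np.random.default_rng(seed)

    def sample_paths(self, n: int, t_max: int) -> np.ndarray:
        incr = self.rng.normal(size=(n, t_max, self.d_z))
        return np.cumsum(incr, axis=1)


class ModelState(Module):
    """All component parameters plus their configuration."""

    def __init__(self, config: NetConfig, static_layout: OutputLayout,
                 temporal_layout: OutputLayout):
        rng = np.random.default_rng(config.seed)
        self.config = config
        c = config
        self.enc_s = MLP(c.d_s, list(c.enc_s_hidden), c.d_hs, rng)
        self.enc_t = GRUCell(c.d_hs + c.d_x, c.d_ht, rng)
        self.dec_s = HeadedDecoder(c.d_hs, c.dec_hidden, static_layout, rng)
        self.dec_t = HeadedDecoder(c.d_ht, c.dec_hidden, temporal_layout, rng)
        self.gen = GRUCell(c.d_hs + c.d_z, c.d_ht, rng)
        self.disc = Discriminator(c.d_hs, c.d_ht, c.disc_hidden, rng)
        self.auxc = MLP(c.d_ht, list(c.auxc_hidden), c.d_hs, rng)
        self.sup = GRUCell(c.d_hs, c.d_ht, rng)
        self.term = TerminationNet(c.d_hs, c.d_ht, c.term_hidden, rng)
        self.phase = "init"

    # component parameter groups, for per-objective optimizers
    def params_ae(self):
        return (self.enc_s.parameters() + self.enc_t.parameters()
                + self.dec_s.parameters() + self.dec_t.parameters())

    def params_sup(self):
        return self.sup.parameters()

    def params_term(self):
        return self.term.parameters()

    def params_gen(self):
        return self.gen.parameters()

    def params_disc(self):
        return self.disc.parameters()

    def params_auxc(self):
        return self.auxc.parameters()

    # -- checkpointing --------------------------------------------------
    def save(self, path, transform: FittedTransform | None = None) -> None:
        meta = {
            "version": __version_tag__,
            "config": asdict(self.config),
            "phase": self.phase,
            "term_pos_weight": float(self.term.pos_weight),
        }
        if transform is not None:
            meta["transform"] = {
                "cont_ranges": transform.cont_ranges,
                "split_tag": transform.split_tag,
                "schema": [
                    {"name": f.name, "role": f.role, "kind": f.kind,
                     "levels": list(f.levels), "units": f.units}
                    for f in transform.schema.features
                ],
            }
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> tuple:
        from .panel_schema import CohortSchema, FeatureSpec
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        cfgd = meta["config"]
        for key, value in cfgd.items():
            if key.endswith("_hidden"):
                cfgd[key] = tuple(value)
        config = NetConfig(**cfgd)
        transform = None
        if "transform" in meta:
            tr = meta["transform"]
            schema = CohortSchema(tuple(
                FeatureSpec(d["name"], d["role"], d["kind"],
                            tuple(d.get("levels") or ()), d.get("units", ""))
                for d in tr["schema"]))
            transform = FittedTransform(
                schema=schema,
                cont_ranges={k: tuple(v) for k, v in tr["cont_ranges"].items()},
                split_tag=tr["split_tag"])
            model = cls(config, OutputLayout.from_transform(transform, "static"),
                        OutputLayout.from_transform(transform, "temporal"))
        else:
            raise ValueError("checkpoint lacks a transform; cannot rebuild decoder layout")
        model.load_arrays(arrays)
        model.phase = meta.get("phase", "init")
        model.term.pos_weight = float(meta.get("term_pos_weight", 1.0))
        return model, transform


def build_model(config: NetConfig, transform: FittedTransform) -> ModelState:
    return ModelState(config,
                      OutputLayout.from_transform(transform, "static"),
                      OutputLayout.from_transform(transform, "temporal"))


# ---------------------------------------------------------------------------
# functional operations
# ---------------------------------------------------------------------------
def encode_static(model: ModelState, s_batch) -> Tensor:
    s = s_batch if isinstance(s_batch, Tensor) else Tensor(s_batch)
    _check(s.shape[-1] == model.config.d_s,
           f"static width {s.shape[-1]} != d_s {model.config.d_s}")
    return model.enc_s(s)


def encode_sequence(model: ModelState, h_s: Tensor, x_batch, mask=None) -> Tensor:
    """Autoregressive temporal encoding: h_t = Enc_t(h_s, h_{t-1}, x_t).

    Output at step t depends only on (h_s, x_{1:t}) — causal."""
    x = x_batch if isinstance(x_batch, Tensor) else Tensor(x_batch)
    _check(x.ndim == 3 and x.shape[-1] == model.config.d_x,
           f"temporal width {x.shape[-1]} != d_x {model.config.d_x}")
    n, t_max, _ = x.shape
    h = model.enc_t.init_state(n)
    outs = []
    for t in range(t_max):
        h = model.enc_t(ad.concat([h_s, x[:, t]], axis=-1), h)
        outs.append(h)
    return ad.stack(outs, axis=1)


def decode(model: ModelState, h_s: Tensor, h_seq: Tensor) -> tuple:
    """Stepwise decoding back to feature space (no cross-step input)."""
    _check(h_s.shape[-1] == model.config.d_hs, "h_s dim mismatch")
    _check(h_seq.shape[-1] == model.config.d_ht, "h_seq dim mismatch")
    return model.dec_s(h_s), model.dec_t(h_seq)


def generate_step(model: ModelState, h_s: Tensor, h_prev: Tensor, z_t) -> Tensor:
    z = z_t if isinstance(z_t, Tensor) else Tensor(z_t)
    _check(z.shape[-1] == model.config.d_z, "noise dim mismatch")
    _check(h_prev.shape[-1] == model.config.d_ht, "latent dim mismatch")
    return model.gen(ad.concat([h_s, z], axis=-1), h_prev)


def discriminate(model: ModelState, h_s: Tensor, h_seq: Tensor,
                 mask: np.ndarray) -> tuple:
    """Probability-scale scores (static, per-step); see
    :func:`discriminate_logits` for the pre-sigmoid values the
    adversarial losses consume."""
    sl, tl = discriminate_logits(model, h_s, h_seq, mask)
    return sl.sigmoid(), tl.sigmoid()


def discriminate_logits(model: ModelState, h_s: Tensor, h_seq: Tensor,
                        mask: np.ndarray) -> tuple:
    _check(h_seq.shape[-1] == model.config.d_ht, "latent dim mismatch")
    lengths = np.asarray(mask).sum(axis=1).astype(int)
    return model.disc(h_s, h_seq, lengths)


def aux_predict(model: ModelState, h_final: Tensor) -> Tensor:
    """Predict the conditional latent from a journey's final-step latent."""
    _check(h_final.shape[-1] == model.config.d_ht, "latent dim mismatch")
    return model.auxc(h_final)


def select_final_latents(h_seq: Tensor, lengths: np.ndarray) -> Tensor:
    """Per-patient latent at the last *observed* step (index lengths-1)."""
    n = h_seq.shape[0]
    return h_seq[np.arange(n), np.asarray(lengths).astype(int) - 1]


def supervise_step(model: ModelState, h_s: Tensor, h_prev: Tensor) -> Tensor:
    _check(h_prev.shape[-1] == model.config.d_ht, "latent dim mismatch")
    return model.sup(h_s, h_prev)


def termination_prob(model: ModelState, h_s: Tensor, h_prev: Tensor) -> Tensor:
    """Raw network output: the minimizer of the positive-weighted cross
    entropy (monotone in, but not equal to, the event probability when
    the training weight != 1)."""
    _check(h_prev.shape[-1] == model.config.d_ht, "latent dim mismatch")
    return model.term(h_s, h_prev)


def termination_hazard(model: ModelState, h_s: Tensor, h_prev: Tensor) -> np.ndarray:
    """Calibrated per-step drop-off probability: the raw output with the
    training-time positive-class weighting inverted,
    q = p / (w - (w - 1) p)."""
    p = termination_prob(model, h_s, h_prev).data
    w = float(getattr(model.term, "pos_weight", 1.0))
    return p / (w - (w - 1.0) * p)


def termination_logit(model: ModelState, h_s: Tensor, h_prev: Tensor) -> Tensor:
    return model.term.logit(h_s, h_prev)
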