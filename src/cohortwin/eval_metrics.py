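"""Generation-quality evaluation suite.

Fidelity: average correlation difference (ACD) over all mixed-type
feature pairs (Pearson for continuous-continuous, correlation ratio for
continuous-categorical, Theil's U for categorical-categorical), Frechet
distance (FID) between Gaussian fits to sequence embeddings, and a
post-hoc discriminator score.  Diversity: alpha-precision (fraction of
generated embeddings inside the alpha-mass support of the real
embedding distribution).  Utility: next-step prediction transfer.
Plus the look-ahead Jensen-Shannon distance protocol and drop-off MAPE
with a gradient-boosted baseline.

Conventions: correlations are computed on one pooled table per cohort
(every observed patient-visit row, with static features repeated per
visit); ordinal variables are treated as continuous; Theil's U is
asymmetric and the upper-triangular cell (i, j), i < j, holds
U(f_i | f_j).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from . import networks as net
from .autodiff import Adam, Tensor, no_grad
from .nn import GRUCell, Linear, Module
from .panel_schema import Cohort, FittedTransform, encode_batch

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# mixed-type bivariate association
# ---------------------------------------------------------------------------
def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance continuous input; correlation defined as 0")
        return 0.0
    return float(np.corrcoef(x.astype(float), y.astype(float))[0, 1])


def _correlation_ratio(categories: np.ndarray, values: np.ndarray) -> float:
    """eta = sqrt( weighted between-category variance of means / total variance )."""
    values = values.astype(float)
    total_var = np.var(values)
    if total_var == 0:
        warnings.warn("zero-variance continuous input; correlation defined as 0")
        return 0.0
    grand = values.mean()
    between = 0.0
    for c in pd.unique(categories):
        grp = values[categories == c]
        between += grp.size * (grp.mean() - grand) ** 2
    return float(np.sqrt(between / (values.size * total_var)))


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels.astype(str), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def theils_u(x: np.ndarray, y: np.ndarray) -> float:
    """Uncertainty coefficient U(X|Y) = (H(X) - H(X|Y)) / H(X) in [0, 1]."""
    x = np.asarray(x).astype(str)
    y = np.asarray(y).astype(str)
    h_x = _entropy(x)
    if h_x == 0.0:
        return 1.0  # X constant: fully determined
    # H(X|Y) = sum_y p(y) H(X | Y = y)
    h_xy = 0.0
    n = x.size
    for c in pd.unique(y):
        sel = y == c
        h_xy += (sel.sum() / n) * _entropy(x[sel])
    return float((h_x - h_xy) / h_x)


def mixed_correlation(values_i, values_j, kind_i: str, kind_j: str,
                      symmetrize_u: bool = True) -> float:
    """Type-dispatched bivariate association; ordinal treated as continuous.

    Theil's U is directional; by default the categorical-categorical cell
    is the mean of both directions so that aggregate statistics built on
    it are invariant to feature ordering (``symmetrize_u=False`` returns
    U(i | j))."""
    vi, vj = np.asarray(values_i), np.asarray(values_j)
    if vi.shape != vj.shape:
        raise ValueError("value vectors must have equal length")
    ki = "continuous" if kind_i == "ordinal" else kind_i
    kj = "continuous" if kind_j == "ordinal" else kind_j
    if ki == "continuous" and kj == "continuous":
        return _pearson(vi.astype(float), vj.astype(float))
    if ki == "categorical" and kj == "categorical":
        if symmetrize_u:
            return 0.5 * (theils_u(vi, vj) + theils_u(vj, vi))
        return theils_u(vi, vj)
    if ki == "continuous":
        return _correlation_ratio(vj, vi)
    return _correlation_ratio(vi, vj)


def _ordinal_to_float(values: np.ndarray, levels: tuple) -> np.ndarray:
    lut = {lev: k for k, lev in enumerate(levels)}
    return np.array([lut[v] for v in values], dtype=float)


def pooled_table(cohort: Cohort) -> dict:
    """One pooled row per observed patient-visit, static features
    repeated per visit.  Ordinal values are mapped to level indices."""
    schema = cohort.schema
    cols: dict = {}
    for j, f in enumerate(schema.static_features):
        vals = np.concatenate([[r.x_s[j]] * r.T for r in cohort.records])
        if f.kind == "ordinal":
            vals = _ordinal_to_float(vals, f.levels)
        elif f.kind == "continuous":
            vals = vals.astype(float)
        cols[f.name] = (vals, f.kind)
    for j, f in enumerate(schema.temporal_features):
        vals = np.concatenate([r.x_seq[:, j] for r in cohort.records])
        if f.kind == "ordinal":
            vals = _ordinal_to_float(vals, f.levels)
        elif f.kind == "continuous":
            vals = vals.astype(float)
        cols[f.name] = (vals, f.kind)
    return cols


def correlation_matrix(cohort: Cohort) -> pd.DataFrame:
    cols = pooled_table(cohort)
    names = list(cols)
    m = np.eye(len(names))
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            va, ka = cols[names[a]]
            vb, kb = cols[names[b]]
            m[a, b] = m[b, a] = mixed_correlation(va, vb, ka, kb)
    return pd.DataFrame(m, index=names, columns=names)


def avg_corr_diff(cohort_real: Cohort, cohort_gen: Cohort) -> float:
    """Mean absolute difference of upper-triangular mixed-type
    correlations between the two cohorts' pooled tables."""
    if cohort_real.schema != cohort_gen.schema:
        raise ValueError("cohorts must share a schema")
    cr = correlation_matrix(cohort_real).to_numpy()
    cg = correlation_matrix(cohort_gen).to_numpy()
    iu = np.triu_indices(cr.shape[0], k=1)
    return float(np.abs(cr[iu] - cg[iu]).mean())


# ---------------------------------------------------------------------------
# embeddings, FID, alpha-precision
# ---------------------------------------------------------------------------
@dataclass
class EmbeddingSet:
    embeddings: np.ndarray  # N x d
    source: str = "real"

    @property
    def mu(self) -> np.ndarray:
        return self.embeddings.mean(axis=0)

    @property
    def sigma(self) -> np.ndarray:
        return np.cov(self.embeddings, rowvar=False)


def embed_cohort(model: net.ModelState, transform: FittedTransform,
                 cohort: Cohort, source: str = "real") -> EmbeddingSet:
    """Sequence embedding = final observed hidden state of the shared
    temporal encoder."""
    batch = encode_batch(cohort, transform)
    with no_grad():
        h_s = net.encode_static(model, batch.s)
        h_seq = net.encode_sequence(model, h_s, batch.x, batch.mask)
        emb = net.select_final_latents(h_seq, batch.lengths).data
    return EmbeddingSet(embeddings=emb, source=source)


def _sym_sqrt(a: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(a)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(emb_real, emb_gen, shrinkage: float = 1e-6) -> float:
    """Frechet distance between Gaussian fits:
    ||mu_R - mu_G||^2 + Tr(S_R + S_G - 2 (S_R S_G)^{1/2}), clamped at 0.

    The cross term is computed via the symmetric eigendecomposition of
    S_R^{1/2} S_G S_R^{1/2}; a small ridge keeps covariances PSD at
    modest sample sizes."""
    er = emb_real.embeddings if isinstance(emb_real, EmbeddingSet) else np.asarray(emb_real)
    eg = emb_gen.embeddings if isinstance(emb_gen, EmbeddingSet) else np.asarray(emb_gen)
    if not (np.isfinite(er).all() and np.isfinite(eg).all()):
        raise ValueError("non-finite embeddings")
    if er.ndim == 1:
        er, eg = er[:, None], eg[:, None]
    mu_r, mu_g = er.mean(axis=0), eg.mean(axis=0)
    d = er.shape[1]
    s_r = np.atleast_2d(np.cov(er, rowvar=False)) + shrinkage * np.eye(d)
    s_g = np.atleast_2d(np.cov(eg, rowvar=False)) + shrinkage * np.eye(d)
    sqrt_r = _sym_sqrt(s_r)
    cross = _sym_sqrt(sqrt_r @ s_g @ sqrt_r)
    value = float(((mu_r - mu_g) ** 2).sum()
                  + np.trace(s_r) + np.trace(s_g) - 2.0 * np.trace(cross))
    return max(value, 0.0)


def alpha_precision(emb_real, emb_gen, alpha: float = 0.95) -> float:
    """Fraction of generated embeddings inside the one-sphere estimate of
    the alpha-support of the real set (ball centered at the real mean
    with radius the alpha-quantile of real distances to that center)."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    er = emb_real.embeddings if isinstance(emb_real, EmbeddingSet) else np.asarray(emb_real)
    eg = emb_gen.embeddings if isinstance(emb_gen, EmbeddingSet) else np.asarray(emb_gen)
    if er.size == 0 or eg.size == 0:
        raise ValueError("empty embedding set")
    center = er.mean(axis=0)
    radius = np.quantile(np.linalg.norm(er - center, axis=1), alpha)
    dist_g = np.linalg.norm(eg - center, axis=1)
    return float((dist_g <= radius).mean())


# ---------------------------------------------------------------------------
# post-hoc sequence models (fresh, never the training discriminator)
# ---------------------------------------------------------------------------
class _SeqClassifier(Module):
    def __init__(self, d_x: int, hidden: int, rng: np.random.Generator):
        self.cell = GRUCell(d_x, hidden, rng)
        self.head = Linear(hidden, 1, rng)

    def __call__(self, x: np.ndarray, lengths: np.ndarray) -> Tensor:
        n, t_max, _ = x.shape
        h = self.cell.init_state(n)
        states = []
        xt = Tensor(x)
        for t in range(t_max):
            h = self.cell(xt[:, t], h)
            states.append(h)
        import cohortwin.autodiff as ad
        h_all = ad.stack(states, axis=1)
        final = h_all[np.arange(n), lengths - 1]
        return self.head(final).reshape(n)


def _common_encoding(cohorts: list, transform: FittedTransform):
    t_max = max(int(c.lengths.max()) for c in cohorts)
    return [encode_batch(c, transform, t_max=t_max) for c in cohorts]


def discriminator_score(cohort_real: Cohort, cohort_gen: Cohort,
                        transform: FittedTransform, seed: int = 0,
                        hidden: int = 16, epochs: int = 80,
                        lr: float = 1e-2) -> dict:
    """Train a fresh post-hoc GRU sequence classifier to tell real from
    generated journeys (stratified 70/30 train/eval); scores near 0.5
    indicate indistinguishable generation."""
    from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
    from sklearn.model_selection import train_test_split

    br, bg = _common_encoding([cohort_real, cohort_gen], transform)
    x = np.concatenate([br.x, bg.x])
    lengths = np.concatenate([br.lengths, bg.lengths])
    y = np.concatenate([np.ones(br.n), np.zeros(bg.n)])
    idx_tr, idx_ev = train_test_split(np.arange(y.size), test_size=0.3,
                                      random_state=seed, stratify=y)
    if len(np.unique(y[idx_ev])) < 2:
        raise ValueError("single-class evaluation fold")
    rng = np.random.default_rng(seed)
    clf = _SeqClassifier(x.shape[2], hidden, rng)
    opt = Adam(clf.parameters(), lr=lr)
    yt = y[idx_tr]
    for _ in range(epochs):
        opt.zero_grad()
        logits = clf(x[idx_tr], lengths[idx_tr])
        # standard BCE-with-logits
        import cohortwin.autodiff as ad
        loss = (-(yt * ad.log_sigmoid(logits)
                  + (1 - yt) * ad.log_sigmoid(-logits))).mean()
        loss.backward()
        opt.step()
    with no_grad():
        scores = clf(x[idx_ev], lengths[idx_ev]).sigmoid().data
    y_ev = y[idx_ev]
    return {
        "auroc": float(roc_auc_score(y_ev, scores)),
        "prauc": float(average_precision_score(y_ev, scores)),
        "f1": float(f1_score(y_ev, scores >= 0.5)),
    }


class _NextStepNet(Module):
    def __init__(self, d_x: int, hidden: int, rng: np.random.Generator):
        self.cell = GRUCell(d_x, hidden, rng)
        self.head = Linear(hidden, d_x, rng)

    def forward_all(self, x: np.ndarray) -> Tensor:
        """Prediction at index t (for target x_{t+1}) from x_{1:t}."""
        import cohortwin.autodiff as ad
        n, t_max, _ = x.shape
        h = self.cell.init_state(n)
        preds = []
        xt = Tensor(x)
        for t in range(t_max - 1):
            h = self.cell(xt[:, t], h)
            preds.append(self.head(h))
        return ad.stack(preds, axis=1)  # n x (t_max-1) x d_x


def _next_step_mse(model: _NextStepNet, batch) -> float:
    mask_next = batch.mask[:, 1:]
    with no_grad():
        preds = model.forward_all(batch.x).data
    err = ((preds - batch.x[:, 1:]) ** 2).mean(axis=-1)
    denom = mask_next.sum()
    return float((err * mask_next).sum() / denom)


def next_step_utility(cohort_real_train: Cohort, cohort_gen: Cohort,
                      cohort_real_test: Cohort, transform: FittedTransform,
                      seed: int = 0, hidden: int = 16, epochs: int = 120,
                      lr: float = 1e-2) -> dict:
    """Train identical post-hoc next-step predictors on real-train and on
    generated data; report both MSEs on the common real test set."""
    btr, bg, bte = _common_encoding(
        [cohort_real_train, cohort_gen, cohort_real_test], transform)
    if int(bte.lengths.max()) < 2:
        raise ValueError("test set has no next step to predict")
    out = {}
    for tag, batch in (("real_mse", btr), ("gen_mse", bg)):
        rng = np.random.default_rng(seed)  # same init for both models
        nxt = _NextStepNet(batch.x.shape[2], hidden, rng)
        opt = Adam(nxt.parameters(), lr=lr)
        m = batch.mask[:, 1:]
        denom = max(m.sum(), 1.0)
        for _ in range(epochs):
            opt.zero_grad()
            preds = nxt.forward_all(batch.x)
            diff = (preds - batch.x[:, 1:]) * m[..., None]
            loss = (diff * diff).sum() / denom
            loss.backward()
            opt.step()
        out[tag] = _next_step_mse(nxt, bte)
    return out


# ---------------------------------------------------------------------------
# Jensen-Shannon distance
# ---------------------------------------------------------------------------
def js_distance_1d(real: np.ndarray, gen: np.ndarray, kind: str,
                   bins: int = 16, eps: float = 1e-12) -> float:
    """JS distance (sqrt of base-2 JS divergence) between histogram
    estimates; continuous bins are equal-width over the pooled real range."""
    if kind in ("continuous", "ordinal"):
        real = real.astype(float)
        gen = gen.astype(float)
        lo, hi = float(real.min()), float(real.max())
        if hi == lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, bins + 1)
        p, _ = np.histogram(np.clip(real, lo, hi), bins=edges)
        q, _ = np.histogram(np.clip(gen, lo, hi), bins=edges)
    else:
        cats = pd.unique(np.concatenate([real, gen]))
        p = np.array([(real == c).sum() for c in cats], dtype=float)
        q = np.array([(gen == c).sum() for c in cats], dtype=float)
    p = p + eps
    q = q + eps
    return float(jensenshannon(p / p.sum(), q / q.sum(), base=2))


def multivariate_jsd(table_real: dict, table_gen: dict, bins: int = 16) -> float:
    """Per-variable JS distances averaged to one scalar."""
    vals = []
    for name, (vr, kind) in table_real.items():
        vg, _ = table_gen[name]
        vals.append(js_distance_1d(np.asarray(vr), np.asarray(vg), kind, bins))
    return float(np.mean(vals))


def lookahead_jsd(model: net.ModelState, transform: FittedTransform,
                  cohort_test: Cohort, horizons: list, n_sims: int = 100,
                  seed: int = 0, bins: int = 16) -> pd.DataFrame:
    """Look-ahead protocol: for each prefix length i, continuations are
    simulated for every test patient with more than i real visits, and
    the distribution of generated values at each later step j is
    compared with the real step-j distribution; horizon = j - i.

    Returns a table with columns (step, horizon, jsd)."""
    from .simulator import SimulationConfig, simulate_type_b

    schema = cohort_test.schema
    feats = schema.temporal_features
    max_len = int(cohort_test.lengths.max())
    if max(horizons) >= max_len:
        raise ValueError("horizon exceeds the longest journey")
    # real per-step pooled values
    real_step: dict = {}
    for j, f in enumerate(feats):
        for rec in cohort_test.records:
            for t in range(rec.T):
                real_step.setdefault((t + 1, f.name), []).append(rec.x_seq[t, j])
    rows = []
    max_prefix = max_len - 1
    for i in range(1, max_prefix + 1):
        partial = [rec for rec in cohort_test.records if rec.T > i]
        if len(partial) < 2:
            continue
        prefixes = [type(rec)(rec.patient_id, rec.x_s, rec.x_seq[:i], False)
                    for rec in partial]
        cfg = SimulationConfig(n_sims=n_sims, max_len=max_len,
                               termination_rule="bernoulli",
                               seed=seed + i)
        sims = simulate_type_b(model, transform, prefixes, cfg)
        for h in horizons:
            j_step = i + h
            if j_step > max_len:
                continue
            gen_vals: dict = {f.name: [] for f in feats}
            for ss in sims:
                sel = ss.lengths >= j_step
                if not sel.any():
                    continue
                from .panel_schema import decode_matrix
                dec = decode_matrix(transform, "temporal",
                                    ss.encoded[sel, j_step - 1])
                for jj, f in enumerate(feats):
                    gen_vals[f.name].extend(dec[:, jj])
            per_var = []
            for f in feats:
                rv = real_step.get((j_step, f.name), [])
                gv = gen_vals[f.name]
                if len(rv) < 2 or len(gv) < 2:
                    continue
                rv = np.asarray(rv)
                gv = np.asarray(gv)
                if f.kind == "ordinal":
                    rv = _ordinal_to_float(rv, f.levels)
                    gv = _ordinal_to_float(gv, f.levels)
                per_var.append(js_distance_1d(rv, gv, f.kind, bins))
            if per_var:
                rows.append({"step": j_step, "horizon": h,
                             "jsd": float(np.mean(per_var))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# drop-off MAPE + gradient-boosted baseline
# ---------------------------------------------------------------------------
def dropoff_mape(predicted_visits, actual_visits, known_visits=None) -> pd.DataFrame:
    """MAPE of predicted drop-off visits, grouped by the number of
    historical visits known at prediction time; includes an aggregate row
    (known = -1)."""
    pred = np.asarray(predicted_visits, dtype=float)
    actual = np.asarray(actual_visits, dtype=float)
    if (actual < 1).any():
        raise ValueError("actual visits must be >= 1")
    ape = np.abs(pred - actual) / actual
    rows = []
    if known_visits is not None:
        known = np.asarray(known_visits)
        for k in sorted(np.unique(known)):
            rows.append({"known_visits": int(k),
                         "mape": float(ape[known == k].mean()),
                         "n": int((known == k).sum())})
    rows.append({"known_visits": -1, "mape": float(ape.mean()), "n": int(ape.size)})
    return pd.DataFrame(rows)


def _history_features(batch, upto: int) -> np.ndarray:
    """Static encoding + per-feature mean of the first ``upto`` visits."""
    x_hist = batch.x[:, :upto]
    m = batch.mask[:, :upto]
    denom = np.maximum(m.sum(axis=1, keepdims=True), 1.0)
    mean_hist = (x_hist * m[..., None]).sum(axis=1) / denom
    return np.concatenate([batch.s, mean_hist, m.sum(axis=1, keepdims=True)], axis=1)


def xgb_dropoff_baseline(cohort_train: Cohort, cohort_test: Cohort,
                         transform: FittedTransform, seed: int = 0) -> pd.DataFrame:
    """Gradient-boosted-tree drop-off-visit predictions for every
    (test patient, known-visit count) pair; histories are summarized by
    averaging, as in the predictive-baseline protocol."""
    from xgboost import XGBRegressor

    btr, bte = _common_encoding([cohort_train, cohort_test], transform)
    feats, targets = [], []
    for upto in range(1, int(btr.lengths.max())):
        sel = btr.lengths > upto
        if not sel.any():
            continue
        f = _history_features(btr, upto)[sel]
        feats.append(f)
        targets.append(btr.lengths[sel])
    X = np.concatenate(feats)
    y = np.concatenate(targets)
    reg = XGBRegressor(n_estimators=100, max_depth=3, random_state=seed,
                       verbosity=0)
    reg.fit(X, y)
    rows = []
    for upto in range(1, int(bte.lengths.max())):
        sel = np.flatnonzero(bte.lengths > upto)
        if sel.size == 0:
            continue
        preds = reg.predict(_history_features(bte, upto)[sel])
        for i, p in zip(sel, preds):
            rows.append({"patient_id": bte.patient_ids[int(i)],
                         "known_visits": upto,
                         "predicted": float(p),
                         "actual": int(bte.lengths[int(i)])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------
@dataclass
class MetricReport:
    acd: float = np.nan
    fid: float = np.nan
    alpha_precision: float = np.nan
    alpha: float = 0.95
    d_score: dict = field(default_factory=dict)
    nxsp: dict = field(default_factory=dict)
    jsd_table: pd.DataFrame | None = None
    mape_table: pd.DataFrame | None = None
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"acd": self.acd, "fid": self.fid,
               "alpha_precision": self.alpha_precision, "alpha": self.alpha,
               "d_score": self.d_score, "nxsp": self.nxsp,
               "settings": self.settings}
        if self.jsd_table is not None:
            out["jsd"] = self.jsd_table.to_dict(orient="records")
        if self.mape_table is not None:
            out["mape"] = self.mape_table.to_dict(orient="records")
        return out


# ---------------------------------------------------------------------------
# baseline cohorts for ordering checks
# ---------------------------------------------------------------------------
def shuffled_baseline(cohort: Cohort, seed: int = 0) -> Cohort:
    """Feature-shuffled copy: each variable's pooled values are permuted
    independently, preserving marginals but destroying cross-feature and
    temporal structure."""
    from .panel_schema import PatientRecord

    rng = np.random.default_rng(seed)
    schema = cohort.schema
    recs = cohort.records
    new_static = []
    for j in range(schema.static_dim):
        col = np.array([r.x_s[j] for r in recs], dtype=object)
        new_static.append(col[rng.permutation(len(recs))])
    pooled = []
    for j in range(schema.temporal_dim):
        col = np.concatenate([r.x_seq[:, j] for r in recs])
        pooled.append(col[rng.permutation(col.size)])
    out = []
    offset = 0
    for i, r in enumerate(recs):
        x_s = np.array([new_static[j][i] for j in range(schema.static_dim)],
                       dtype=object)
        x_seq = np.empty((r.T, schema.temporal_dim), dtype=object)
        for j in range(schema.temporal_dim):
            x_seq[:, j] = pooled[j][offset:offset + r.T]
        offset += r.T
        out.append(PatientRecord(r.patient_id, x_s, x_seq, r.dropped))
    return Cohort(schema, out)


def noise_baseline(cohort: Cohort, transform: FittedTransform,
                   seed: int = 0) -> Cohort:
    """Gaussian-noise copy: continuous values drawn N(mid-range, range/4),
    discrete values drawn uniformly over levels, lengths preserved."""
    from .panel_schema import PatientRecord

    rng = np.random.default_rng(seed)
    schema = cohort.schema

    def draw(f, size):
        if f.kind == "continuous":
            lo, hi = transform.cont_ranges[f.name]
            return rng.normal((lo + hi) / 2, (hi - lo) / 4, size=size)
        return rng.choice(np.array(f.levels, dtype=object), size=size)

    out = []
    for r in cohort.records:
        x_s = np.array([draw(f, None) for f in schema.static_features], dtype=object)
        x_seq = np.empty((r.T, schema.temporal_dim), dtype=object)
        for j, f in enumerate(schema.temporal_features):
            col = draw(f, r.T)
            for t in range(r.T):
                x_seq[t, j] = col[t] if f.kind != "continuous" else float(col[t])
        out.append(PatientRecord(r.patient_id, x_s, x_seq, r.dropped))
    return Cohort(schema, out)
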