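"""Termination-aware journey simulation.

Type A simulates entire journeys from a patient's static conditionals
alone: the generator rolls latent steps forward from Wiener noise while
the termination head emits a per-step drop-off probability that ends
the trajectory stochastically (Bernoulli sampling of p_t, the default)
or deterministically (p_t >= threshold).  Type B continues a partially
observed journey: the real prefix is teacher-force encoded, echoed
unmodified into every trajectory, and the continuation is generated
from the last real latent.

Simulating many trajectories per patient (the reference protocol uses
1000) turns the stochastic generator into a distribution over futures;
averaging the realized termination visits across simulations yields the
predicted drop-off visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import networks as net
from .autodiff import Tensor, no_grad
from .panel_schema import (Cohort, FittedTransform, PatientRecord,
                           decode_matrix, encode_batch)


@dataclass(frozen=True)
class SimulationConfig:
    n_sims: int = 1000
    max_len: int = 12
    termination_rule: str = "bernoulli"   # "bernoulli" | "threshold"
    threshold: float = 0.5
    seed: int = 0
    collect_values: bool = True           # skip value storage for length-only studies

    def __post_init__(self):
        if self.n_sims < 1 or self.max_len < 1:
            raise ValueError("n_sims and max_len must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.termination_rule not in ("bernoulli", "threshold"):
            raise ValueError(f"unknown termination rule {self.termination_rule!r}")


@dataclass
class SimTrajectory:
    values: np.ndarray | None   # (length, temporal_dim) decoded, or None
    drop_probs: np.ndarray      # (length,)
    length: int
    cause: str                  # "dropped" | "max_len"


@dataclass
class SimulationSet:
    """All simulated trajectories for one patient.

    Values are stored encoded (n_sims x max_len x d_x) and decoded
    lazily; ``trajectories`` yields schema-valid per-simulation views.
    """

    patient_id: str
    encoded: np.ndarray | None        # n_sims x max_len x d_x
    drop_probs: np.ndarray            # n_sims x max_len
    lengths: np.ndarray               # n_sims
    causes: list
    prefix_len: int = 0
    transform: FittedTransform = field(repr=False, default=None)

    @property
    def n_sims(self) -> int:
        return self.lengths.shape[0]

    def trajectory(self, k: int) -> SimTrajectory:
        L = int(self.lengths[k])
        values = None
        if self.encoded is not None:
            values = decode_matrix(self.transform, "temporal", self.encoded[k, :L])
        return SimTrajectory(values=values, drop_probs=self.drop_probs[k, :L],
                             length=L, cause=self.causes[k])

    @property
    def trajectories(self) -> list:
        return [self.trajectory(k) for k in range(self.n_sims)]


def _resolve_static(records, transform: FittedTransform) -> tuple:
    """Accept a Cohort or a list of PatientRecords; return (ids, s_matrix)."""
    recs = records.records if isinstance(records, Cohort) else list(records)
    schema = transform.schema
    ids = [r.patient_id for r in recs]
    s_slices = transform.feature_slices("static")
    s = np.zeros((len(recs), transform.encoded_width("static")))
    for i, r in enumerate(recs):
        for j, f in enumerate(schema.static_features):
            s[i, s_slices[f.name]] = transform.forward_value(f, r.x_s[j])
    return ids, s, recs


def _apply_rule(p: np.ndarray, u: np.ndarray, rule: str, tau: float) -> np.ndarray:
    if rule == "bernoulli":
        return u < p
    return p >= tau


def _simulate_one(model: net.ModelState, h_s_row: np.ndarray, config: SimulationConfig,
                  rng: np.random.Generator, start_step: int = 0,
                  h_start: np.ndarray | None = None) -> tuple:
    """Roll n_sims trajectories for one patient from ``start_step``.

    Returns (encoded or None, drop_probs, lengths, causes) covering the
    *generated* steps only.  The active set shrinks as trajectories
    terminate so long horizons with early termination stay cheap.
    """
    n = config.n_sims
    d_ht, d_x = model.config.d_ht, model.config.d_x
    n_gen = config.max_len - start_step
    h_s_all = np.repeat(h_s_row[None, :], n, axis=0)
    h_prev = (np.zeros((n, d_ht)) if h_start is None
              else np.repeat(h_start[None, :], n, axis=0))
    encoded = (np.zeros((n, n_gen, d_x)) if config.collect_values else None)
    drop_probs = np.zeros((n, n_gen))
    lengths = np.full(n, n_gen, dtype=int)
    dropped = np.zeros(n, dtype=bool)
    active = np.arange(n)
    noise = net.NoiseSource(model.config.d_z,
                            seed=int(rng.integers(0, 2**31)))
    z_rng = noise.rng
    z_prev = np.zeros((n, model.config.d_z))
    with no_grad():
        for t in range(n_gen):
            if active.size == 0:
                break
            h_s_a = Tensor(h_s_all[active])
            h_prev_a = Tensor(h_prev[active])
            z_prev[active] += z_rng.normal(size=(active.size, model.config.d_z))
            p_t = net.termination_hazard(model, h_s_a, h_prev_a)
            h_t = net.generate_step(model, h_s_a, h_prev_a,
                                    Tensor(z_prev[active])).data
            drop_probs[active, t] = p_t
            if encoded is not None:
                x_t = model.dec_t(Tensor(h_t)).data
                encoded[active, t] = x_t
            u = rng.uniform(size=active.size)
            stop = _apply_rule(p_t, u, config.termination_rule, config.threshold)
            stopped = active[stop]
            lengths[stopped] = t + 1
            dropped[stopped] = True
            h_prev[active] = h_t
            active = active[~stop]
    causes = ["dropped" if d else "max_len" for d in dropped]
    return encoded, drop_probs, lengths, causes


def simulate_type_a(model: net.ModelState, transform: FittedTransform,
                    static_rows, config: SimulationConfig) -> list:
    """Full journeys from static conditionals alone; one SimulationSet
    per patient, n_sims trajectories each, deterministic given seed."""
    if model.config.d_s != transform.encoded_width("static"):
        raise net.ContractError("model/static-width mismatch")
    ids, s, _ = _resolve_static(static_rows, transform)
    seeds = np.random.SeedSequence(config.seed).spawn(len(ids))
    out = []
    with no_grad():
        h_s_all = net.encode_static(model, s).data
    for i, pid in enumerate(ids):
        rng = np.random.default_rng(seeds[i])
        enc, probs, lengths, causes = _simulate_one(model, h_s_all[i], config, rng)
        out.append(SimulationSet(patient_id=pid, encoded=enc, drop_probs=probs,
                                 lengths=lengths, causes=causes,
                                 transform=transform))
    return out


def simulate_type_b(model: net.ModelState, transform: FittedTransform,
                    partial_records, config: SimulationConfig) -> list:
    """Forecast continuations of partially observed journeys.

    Each record's observed prefix (1 <= T_obs < max_len visits) is
    teacher-force encoded and echoed unmodified into every trajectory;
    generation starts at visit T_obs + 1 from the last real latent.
    """
    ids, s, recs = _resolve_static(partial_records, transform)
    for r in recs:
        if r.T < 1:
            raise ValueError(f"patient {r.patient_id}: empty prefix (use Type A)")
        if r.T >= config.max_len:
            raise ValueError(
                f"patient {r.patient_id}: prefix length {r.T} >= max_len {config.max_len}")
    prefix_cohort = Cohort(transform.schema, [
        PatientRecord(r.patient_id, r.x_s, r.x_seq, dropped=False) for r in recs])
    batch = encode_batch(prefix_cohort, transform)
    seeds = np.random.SeedSequence(config.seed).spawn(len(ids))
    out = []
    with no_grad():
        h_s_all = net.encode_static(model, batch.s)
        h_seq = net.encode_sequence(model, h_s_all, batch.x, batch.mask).data
        h_s_all = h_s_all.data
        # per-step drop probabilities along the real prefix (h_0 = 0)
        prefix_prev = np.zeros_like(h_seq)
        prefix_prev[:, 1:] = h_seq[:, :-1]
    for i, pid in enumerate(ids):
        T_obs = int(batch.lengths[i])
        rng = np.random.default_rng(seeds[i])
        h_last = h_seq[i, T_obs - 1]
        enc_gen, probs_gen, len_gen, causes = _simulate_one(
            model, h_s_all[i], config, rng, start_step=T_obs, h_start=h_last)
        n = config.n_sims
        n_gen = config.max_len - T_obs
        full_enc = None
        if enc_gen is not None:
            full_enc = np.zeros((n, config.max_len, model.config.d_x))
            full_enc[:, :T_obs] = batch.x[i, :T_obs]  # observed prefix echoed
            full_enc[:, T_obs:T_obs + n_gen] = enc_gen
        full_probs = np.zeros((n, config.max_len))
        with no_grad():
            pfx_p = np.array([
                float(net.termination_hazard(
                    model, Tensor(h_s_all[i:i + 1]),
                    Tensor(prefix_prev[i:i + 1, t]))[0])
                for t in range(T_obs)])
        full_probs[:, :T_obs] = pfx_p[None, :]
        full_probs[:, T_obs:T_obs + n_gen] = probs_gen
        out.append(SimulationSet(
            patient_id=pid, encoded=full_enc, drop_probs=full_probs,
            lengths=len_gen + T_obs, causes=causes, prefix_len=T_obs,
            transform=transform))
    return out


def apply_administrative_censoring(sim_sets: list, len_min: int, len_max: int,
                                   seed: int = 0) -> list:
    """Truncate simulated trajectories at per-trajectory planned end
    lengths drawn uniformly from {len_min..len_max}, in place.

    Real trial data end either by drop-off or by the planned visit
    schedule; hazard-only simulations over-represent hazard-stopped
    journeys, so cohorts built for side-by-side comparison with real
    data should be censored with the same administrative design."""
    rng = np.random.default_rng(seed)
    for ss in sim_sets:
        admin = rng.integers(len_min, len_max + 1, size=ss.n_sims)
        admin = np.maximum(admin, ss.prefix_len + 1)
        for k in range(ss.n_sims):
            if admin[k] < ss.lengths[k]:
                ss.lengths[k] = int(admin[k])
                ss.causes[k] = "max_len"
    return sim_sets


def predict_dropoff_visit(sim_set: SimulationSet,
                          include_censored: bool = True) -> float:
    """Simulation-averaged predicted drop-off visit: the arithmetic mean
    of realized termination visits (trajectories that reach max_len
    contribute max_len unless excluded)."""
    if sim_set.n_sims < 1:
        raise ValueError("empty simulation set")
    lengths = sim_set.lengths.astype(float)
    if include_censored:
        return float(lengths.mean())
    dropped = np.array([c == "dropped" for c in sim_set.causes])
    if not dropped.any():
        return float(lengths.mean())
    return float(lengths[dropped].mean())


def simulations_to_cohort(sim_sets: list, static_records,
                          transform: FittedTransform,
                          max_per_patient: int | None = 1) -> Cohort:
    """Materialize simulations as a schema-valid cohort (for the
    evaluation suite).  Takes the first ``max_per_patient`` trajectories
    of each patient; static vectors are copied from the source records."""
    recs_by_id = {r.patient_id: r
                  for r in (static_records.records
                            if isinstance(static_records, Cohort) else static_records)}
    records = []
    for ss in sim_sets:
        if ss.encoded is None:
            raise ValueError("simulations were run with collect_values=False")
        src = recs_by_id[ss.patient_id]
        k_max = ss.n_sims if max_per_patient is None else min(max_per_patient, ss.n_sims)
        for k in range(k_max):
            L = int(ss.lengths[k])
            values = decode_matrix(transform, "temporal", ss.encoded[k, :L])
            records.append(PatientRecord(
                f"{ss.patient_id}__sim{k}", src.x_s.copy(), values,
                dropped=(ss.causes[k] == "dropped")))
    return Cohort(transform.schema, records)
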