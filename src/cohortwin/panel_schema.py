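"""Mixed-type static + temporal clinical-trial panel data.

A cohort couples a static table (one row per patient: demographics,
medical history) with a long-format temporal table (one row per
patient-visit).  Features are declared in a :class:`CohortSchema` as
continuous, categorical or ordinal, with a static or temporal role.
This module owns reading/writing the CSV + YAML file layout, the
invertible numeric encoding used by the networks (min-max scaling for
continuous, one-hot for categorical, equally spaced [0,1] values for
ordinal), padding/masking of variable-length sequences, and the
by-patient train/test split.

Missing values are rejected: visit schedules are regular, 1-based and
consecutive, and every declared feature must be observed at every visit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

UNKNOWN_LABEL = "<unknown>"


class SchemaError(ValueError):
    """A file or record does not match the declared schema."""


class ValidationError(ValueError):
    """Data values violate a cohort invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one variable: its role, kind and (for discrete
    kinds) the ordered list of admissible levels."""

    name: str
    role: str  # "static" | "temporal"
    kind: str  # "continuous" | "categorical" | "ordinal"
    levels: tuple = ()
    units: str = ""

    def __post_init__(self):
        if self.role not in ("static", "temporal"):
            raise SchemaError(f"feature {self.name!r}: bad role {self.role!r}")
        if self.kind not in ("continuous", "categorical", "ordinal"):
            raise SchemaError(f"feature {self.name!r}: bad kind {self.kind!r}")
        if self.kind in ("categorical", "ordinal"):
            if not self.levels:
                raise SchemaError(f"feature {self.name!r}: {self.kind} needs levels")
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"feature {self.name!r}: duplicate levels")
        elif self.levels:
            raise SchemaError(f"feature {self.name!r}: continuous feature has levels")
        object.__setattr__(self, "levels", tuple(self.levels))


@dataclass(frozen=True)
class CohortSchema:
    features: tuple

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        if not self.static_features or not self.temporal_features:
            raise SchemaError("schema needs at least one static and one temporal feature")

    @property
    def static_features(self) -> tuple:
        return tuple(f for f in self.features if f.role == "static")

    @property
    def temporal_features(self) -> tuple:
        return tuple(f for f in self.features if f.role == "temporal")

    @property
    def static_dim(self) -> int:
        return len(self.static_features)

    @property
    def temporal_dim(self) -> int:
        return len(self.temporal_features)

    def to_yaml(self, path) -> None:
        doc = [
            {"name": f.name, "role": f.role, "kind": f.kind,
             "levels": list(f.levels), "units": f.units}
            for f in self.features
        ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSchema":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(tuple(
            FeatureSpec(d["name"], d["role"], d["kind"],
                        tuple(d.get("levels") or ()), d.get("units", ""))
            for d in doc
        ))


@dataclass
class PatientRecord:
    """One patient: static vector, T x temporal_dim visit matrix (values in
    schema order, object dtype to hold mixed types) and drop-off flag."""

    patient_id: str
    x_s: np.ndarray
    x_seq: np.ndarray
    dropped: bool

    @property
    def T(self) -> int:
        return self.x_seq.shape[0]


@dataclass
class Cohort:
    schema: CohortSchema
    records: list

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient_ids in cohort")
        for r in self.records:
            if len(r.x_s) != self.schema.static_dim:
                raise ValidationError(f"patient {r.patient_id}: static length mismatch")
            if r.x_seq.ndim != 2 or r.x_seq.shape[1] != self.schema.temporal_dim:
                raise ValidationError(f"patient {r.patient_id}: temporal width mismatch")
            if r.T < 1:
                raise ValidationError(f"patient {r.patient_id}: empty journey")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patient_ids(self) -> list:
        return [r.patient_id for r in self.records]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([r.T for r in self.records], dtype=int)


@dataclass
class EncodedBatch:
    """Padded, masked numeric view of a cohort for network consumption."""

    s: np.ndarray           # N x d_s
    x: np.ndarray           # N x T_max x d_x
    mask: np.ndarray        # N x T_max, 1 = observed
    lengths: np.ndarray     # N
    drop_labels: np.ndarray  # N x T_max, 1 at final observed visit of dropped patients
    patient_ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.s.shape[0]

    @property
    def t_max(self) -> int:
        return self.x.shape[1]


# ---------------------------------------------------------------------------
# invertible transform
# ---------------------------------------------------------------------------
@dataclass
class FittedTransform:
    """Per-feature scaling parameters fitted on a training split.

    Continuous features carry (min, max) for [0,1] min-max scaling;
    categorical features a level -> one-hot index map with a trailing
    reserved unknown slot; ordinal features are mapped to equally spaced
    values in [0,1] and decoded by nearest-level snap.
    """

    schema: CohortSchema
    cont_ranges: dict
    split_tag: str = "train"

    def _width(self, f: FeatureSpec) -> int:
        if f.kind == "categorical":
            return len(f.levels) + 1  # + unknown slot
        return 1

    def encoded_width(self, role: str) -> int:
        feats = (self.schema.static_features if role == "static"
                 else self.schema.temporal_features)
        return sum(self._width(f) for f in feats)

    def feature_slices(self, role: str) -> dict:
        feats = (self.schema.static_features if role == "static"
                 else self.schema.temporal_features)
        out, off = {}, 0
        for f in feats:
            w = self._width(f)
            out[f.name] = slice(off, off + w)
            off += w
        return out

    # -- per-feature forward/inverse ----------------------------------
    def forward_value(self, f: FeatureSpec, value):
        if f.kind == "continuous":
            lo, hi = self.cont_ranges[f.name]
            return np.array([(float(value) - lo) / (hi - lo)])
        if f.kind == "ordinal":
            idx = f.levels.index(value)
            return np.array([idx / (len(f.levels) - 1) if len(f.levels) > 1 else 0.0])
        # categorical
        out = np.zeros(len(f.levels) + 1)
        try:
            out[f.levels.index(value)] = 1.0
        except ValueError:
            logger.warning("feature %r: unseen category %r mapped to unknown slot",
                           f.name, value)
            out[-1] = 1.0
        return out

    def inverse_value(self, f: FeatureSpec, encoded: np.ndarray):
        if f.kind == "continuous":
            lo, hi = self.cont_ranges[f.name]
            return float(encoded[0]) * (hi - lo) + lo
        if f.kind == "ordinal":
            grid = (np.arange(len(f.levels)) / (len(f.levels) - 1)
                    if len(f.levels) > 1 else np.zeros(1))
            return f.levels[int(np.argmin(np.abs(grid - float(encoded[0]))))]
        # the reserved unknown slot only decodes when it dominates (hard
        # one-hot from an unseen test category); soft decoder outputs snap
        # to the best known level
        if encoded[-1] >= 0.5:
            return UNKNOWN_LABEL
        return f.levels[int(np.argmax(encoded[:-1]))]


def fit_transform(cohort_train: Cohort) -> FittedTransform:
    """Fit the invertible encoding on a training cohort.

    Raises on constant continuous features (max must exceed min).
    """
    if len(cohort_train) == 0:
        raise ValidationError("cannot fit transform on an empty cohort")
    schema = cohort_train.schema
    cont_ranges: dict = {}
    for role, feats in (("static", schema.static_features),
                        ("temporal", schema.temporal_features)):
        for j, f in enumerate(feats):
            if f.kind != "continuous":
                continue
            if role == "static":
                vals = np.array([float(r.x_s[j]) for r in cohort_train.records])
            else:
                vals = np.concatenate([r.x_seq[:, j].astype(float)
                                       for r in cohort_train.records])
            lo, hi = float(vals.min()), float(vals.max())
            if not hi > lo:
                raise ValidationError(
                    f"continuous feature {f.name!r} is constant on the training split")
            cont_ranges[f.name] = (lo, hi)
    return FittedTransform(schema=schema, cont_ranges=cont_ranges)


# ---------------------------------------------------------------------------
# encode / decode
# ---------------------------------------------------------------------------
def encode_batch(cohort: Cohort, transform: FittedTransform,
                 t_max: int | None = None, truncate: bool = False) -> EncodedBatch:
    schema = cohort.schema
    max_len = int(cohort.lengths.max())
    if t_max is None:
        t_max = max_len
    if t_max < max_len:
        if not truncate:
            raise ValidationError(
                f"t_max={t_max} < longest journey ({max_len}); pass truncate=True")
        warnings.warn(f"truncating journeys longer than t_max={t_max}")
    n = len(cohort)
    d_s = transform.encoded_width("static")
    d_x = transform.encoded_width("temporal")
    s = np.zeros((n, d_s))
    x = np.zeros((n, t_max, d_x))
    mask = np.zeros((n, t_max))
    lengths = np.zeros(n, dtype=int)
    drop_labels = np.zeros((n, t_max))
    s_slices = transform.feature_slices("static")
    t_slices = transform.feature_slices("temporal")
    for i, rec in enumerate(cohort.records):
        for j, f in enumerate(schema.static_features):
            s[i, s_slices[f.name]] = transform.forward_value(f, rec.x_s[j])
        T = min(rec.T, t_max)
        lengths[i] = T
        mask[i, :T] = 1.0
        for t in range(T):
            for j, f in enumerate(schema.temporal_features):
                x[i, t, t_slices[f.name]] = transform.forward_value(f, rec.x_seq[t, j])
        if rec.dropped and rec.T <= t_max:
            drop_labels[i, T - 1] = 1.0
    if not (np.isfinite(s).all() and np.isfinite(x).all()):
        raise ValidationError("non-finite values after encoding")
    return EncodedBatch(s=s, x=x, mask=mask, lengths=lengths,
                        drop_labels=drop_labels, patient_ids=cohort.patient_ids)


def decode_batch(batch: EncodedBatch, transform: FittedTransform,
                 schema: CohortSchema, dropped: np.ndarray | None = None) -> Cohort:
    """Invert :func:`encode_batch`.  ``dropped`` defaults to the flags
    implied by ``batch.drop_labels``."""
    if dropped is None:
        dropped = batch.drop_labels.sum(axis=1) > 0
    s_slices = transform.feature_slices("static")
    t_slices = transform.feature_slices("temporal")
    records = []
    for i in range(batch.n):
        x_s = np.empty(schema.static_dim, dtype=object)
        for j, f in enumerate(schema.static_features):
            x_s[j] = transform.inverse_value(f, batch.s[i, s_slices[f.name]])
        T = int(batch.lengths[i])
        x_seq = np.empty((T, schema.temporal_dim), dtype=object)
        for t in range(T):
            for j, f in enumerate(schema.temporal_features):
                x_seq[t, j] = transform.inverse_value(f, batch.x[i, t, t_slices[f.name]])
        pid = batch.patient_ids[i] if batch.patient_ids else f"p{i:04d}"
        records.append(PatientRecord(pid, x_s, x_seq, bool(dropped[i])))
    return Cohort(schema=schema, records=records)


def decode_matrix(transform: FittedTransform, role: str, X: np.ndarray) -> np.ndarray:
    """Vectorized inverse of the numeric encoding for a 2-D block of rows.

    ``X`` is (n, encoded_width(role)); returns an (n, n_features) object
    array of decoded values.  Matches :meth:`FittedTransform.inverse_value`
    row by row.
    """
    feats = (transform.schema.static_features if role == "static"
             else transform.schema.temporal_features)
    slices = transform.feature_slices(role)
    n = X.shape[0]
    out = np.empty((n, len(feats)), dtype=object)
    for j, f in enumerate(feats):
        block = X[:, slices[f.name]]
        if f.kind == "continuous":
            lo, hi = transform.cont_ranges[f.name]
            vals = block[:, 0] * (hi - lo) + lo
            for i in range(n):
                out[i, j] = float(vals[i])
        elif f.kind == "ordinal":
            grid = (np.arange(len(f.levels)) / (len(f.levels) - 1)
                    if len(f.levels) > 1 else np.zeros(1))
            idx = np.argmin(np.abs(block[:, 0][:, None] - grid[None, :]), axis=1)
            for i in range(n):
                out[i, j] = f.levels[int(idx[i])]
        else:
            idx = np.argmax(block[:, :-1], axis=1)
            unknown = block[:, -1] >= 0.5
            for i in range(n):
                out[i, j] = UNKNOWN_LABEL if unknown[i] else f.levels[int(idx[i])]
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------
def read_cohort(static_csv_path, temporal_csv_path, schema: CohortSchema) -> Cohort:
    """Read a cohort from a wide static CSV and a long temporal CSV.

    The temporal table must have ``patient_id``, ``visit`` (1-based
    consecutive integers) and ``dropped_at_visit`` columns.  Patients
    present in only one of the two tables are excluded with a warning.
    """
    static_df = pd.read_csv(static_csv_path)
    temporal_df = pd.read_csv(temporal_csv_path)
    for col in ["patient_id"] + [f.name for f in schema.static_features]:
        if col not in static_df.columns:
            raise SchemaError(f"static CSV missing column {col!r}")
    for col in ["patient_id", "visit", "dropped_at_visit"] + \
            [f.name for f in schema.temporal_features]:
        if col not in temporal_df.columns:
            raise SchemaError(f"temporal CSV missing column {col!r}")
    if static_df.isna().any().any() or temporal_df.isna().any().any():
        raise ValidationError("missing values are not supported; found NaN in input")

    static_df = static_df.astype({"patient_id": str})
    temporal_df = temporal_df.astype({"patient_id": str})
    s_ids = set(static_df["patient_id"])
    t_ids = set(temporal_df["patient_id"])
    both = s_ids & t_ids
    n_excluded = len(s_ids ^ t_ids)
    if n_excluded:
        logger.warning("excluding %d patients present in only one table", n_excluded)

    cat_levels = {f.name: set(f.levels) for f in schema.features
                  if f.kind in ("categorical", "ordinal")}

    def check_levels(df, feats, pid=None):
        for f in feats:
            if f.name not in cat_levels:
                continue
            bad = set(df[f.name].astype(type(f.levels[0]))) - cat_levels[f.name]
            if bad:
                raise ValidationError(
                    f"feature {f.name!r}: unknown label(s) {sorted(map(str, bad))}")

    records = []
    tgroups = dict(list(temporal_df.groupby("patient_id", sort=False)))
    for _, row in static_df.iterrows():
        pid = row["patient_id"]
        if pid not in both:
            continue
        g = tgroups[pid].sort_values("visit")
        visits = g["visit"].to_numpy()
        if not np.array_equal(visits, np.arange(1, len(visits) + 1)):
            raise ValidationError(
                f"patient {pid}: visit indices must be consecutive from 1, got {list(visits)}")
        drop_flags = g["dropped_at_visit"].to_numpy().astype(int)
        if not set(drop_flags) <= {0, 1}:
            raise ValidationError(f"patient {pid}: dropped_at_visit must be 0/1")
        if drop_flags[:-1].any():
            raise ValidationError(
                f"patient {pid}: dropped_at_visit may be 1 only at the last visit")
        x_s = np.empty(schema.static_dim, dtype=object)
        for j, f in enumerate(schema.static_features):
            x_s[j] = _coerce(f, row[f.name])
        x_seq = np.empty((len(g), schema.temporal_dim), dtype=object)
        for j, f in enumerate(schema.temporal_features):
            col = g[f.name].to_numpy()
            for t in range(len(g)):
                x_seq[t, j] = _coerce(f, col[t])
        records.append(PatientRecord(pid, x_s, x_seq, dropped=bool(drop_flags[-1])))
    cohort = Cohort(schema=schema, records=records)
    check_levels(static_df[static_df["patient_id"].isin(both)],
                 schema.static_features)
    check_levels(temporal_df[temporal_df["patient_id"].isin(both)],
                 schema.temporal_features)
    return cohort


def _coerce(f: FeatureSpec, value):
    if f.kind == "continuous":
        return float(value)
    # discrete: match the declared level type
    target = type(f.levels[0])
    try:
        coerced = target(value)
    except (TypeError, ValueError):
        coerced = value
    if coerced not in f.levels:
        raise ValidationError(f"feature {f.name!r}: unknown label {value!r}")
    return coerced


def write_cohort(cohort: Cohort, static_csv_path, temporal_csv_path,
                 schema_yaml_path=None) -> None:
    schema = cohort.schema
    srows = []
    trows = []
    for rec in cohort.records:
        srow = {"patient_id": rec.patient_id}
        for j, f in enumerate(schema.static_features):
            srow[f.name] = rec.x_s[j]
        srows.append(srow)
        for t in range(rec.T):
            trow = {"patient_id": rec.patient_id, "visit": t + 1,
                    "dropped_at_visit": int(rec.dropped and t == rec.T - 1)}
            for j, f in enumerate(schema.temporal_features):
                trow[f.name] = rec.x_seq[t, j]
            trows.append(trow)
    pd.DataFrame(srows).to_csv(static_csv_path, index=False)
    pd.DataFrame(trows).to_csv(temporal_csv_path, index=False)
    if schema_yaml_path is not None:
        schema.to_yaml(schema_yaml_path)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------
def split_cohort(cohort: Cohort, train_frac: float, seed: int) -> tuple:
    """Deterministic by-patient split; train size = floor(N * train_frac)."""
    if not 0.0 < train_frac < 1.0:
        raise ValidationError("train_frac must be in (0, 1)")
    n = len(cohort)
    if n < 2:
        raise ValidationError("cohort too small to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_frac))
    if n_train == 0 or n_train == n:
        raise ValidationError("split would leave an empty partition")
    train_idx = set(perm[:n_train].tolist())
    train = Cohort(cohort.schema,
                   [cohort.records[i] for i in sorted(train_idx)])
    test = Cohort(cohort.schema,
                  [cohort.records[i] for i in range(n) if i not in train_idx])
    return train, test
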