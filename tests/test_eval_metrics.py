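"""Evaluation suite: correlation dispatch, ACD, FID, alpha-precision,
post-hoc scores, JS distance and MAPE — each against an independent
oracle or closed form."""

import numpy as np
import pytest
import scipy.linalg

import cohortwin.eval_metrics as em
from cohortwin.autodiff import Tensor
from cohortwin.panel_schema import (Cohort, CohortSchema, FeatureSpec,
                                    PatientRecord, encode_batch, fit_transform)

RNG = np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# bivariate association
# ---------------------------------------------------------------------------
class TestMixedCorrelation:
    def test_pearson_linear_relation(self):
        x = RNG.normal(size=200)
        assert em.mixed_correlation(x, 2 * x + 1, "continuous",
                                    "continuous") == pytest.approx(1.0)

    def test_correlation_ratio_extremes(self):
        cats = np.array(["a"] * 50 + ["b"] * 50)
        # identical per-category means -> 0
        vals = np.concatenate([np.linspace(-1, 1, 50), np.linspace(-1, 1, 50)])
        assert em.mixed_correlation(vals, cats, "continuous",
                                    "categorical") == pytest.approx(0.0, abs=1e-12)
        # zero within-category variance -> 1
        vals = np.concatenate([np.zeros(50), np.ones(50)])
        assert em.mixed_correlation(vals, cats, "continuous",
                                    "categorical") == pytest.approx(1.0)

    def test_theils_u_hand_entropies(self):
        y = np.array([0, 0, 1, 1])
        assert em.theils_u(np.array(["a", "a", "b", "b"]), y) == pytest.approx(1.0)
        assert em.theils_u(np.array(["a", "b", "a", "b"]), y) == pytest.approx(0.0)

    def test_ordinal_treated_as_continuous(self):
        x = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        r = em.mixed_correlation(x, 3 * x, "ordinal", "continuous")
        assert r == pytest.approx(1.0)

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert em.mixed_correlation(np.ones(10), RNG.normal(size=10),
                                        "continuous", "continuous") == 0.0


# ---------------------------------------------------------------------------
# ACD
# ---------------------------------------------------------------------------
def three_feature_cohort(seed, n=25):
    rng = np.random.default_rng(seed)
    schema = CohortSchema((
        FeatureSpec("base", "static", "continuous"),
        FeatureSpec("lab", "temporal", "continuous"),
        FeatureSpec("flag", "temporal", "categorical", levels=("n", "y")),
    ))
    records = []
    for i in range(n):
        T = int(rng.integers(1, 5))
        base = rng.normal()
        lab = base + rng.normal(size=T)
        flag = np.where(rng.uniform(size=T) < 0.5, "n", "y")
        x_seq = np.empty((T, 2), dtype=object)
        x_seq[:, 0] = lab
        x_seq[:, 1] = flag
        records.append(PatientRecord(f"p{i}", np.array([base], dtype=object),
                                     x_seq, dropped=False))
    return Cohort(schema, records)


def acd_loop_oracle(ca, cb):
    """Independent recomputation: pool rows by hand, dispatch by type."""
    def pooled(c):
        base, lab, flag = [], [], []
        for r in c.records:
            base.extend([float(r.x_s[0])] * r.T)
            lab.extend(r.x_seq[:, 0].astype(float))
            flag.extend(r.x_seq[:, 1])
        return np.array(base), np.array(lab), np.array(flag)

    def corr3(c):
        base, lab, flag = pooled(c)
        p = np.corrcoef(base, lab)[0, 1]
        def cr(cats, vals):
            grand = vals.mean()
            btw = sum((vals[cats == k]).size * (vals[cats == k].mean() - grand) ** 2
                      for k in set(cats))
            return np.sqrt(btw / (vals.size * np.var(vals)))
        return np.array([p, cr(flag, base), cr(flag, lab)])

    return np.abs(corr3(ca) - corr3(cb)).mean()


class TestAvgCorrDiff:
    def test_identity_is_zero(self):
        c = three_feature_cohort(1)
        assert em.avg_corr_diff(c, c) == 0.0

    def test_matches_loop_oracle(self):
        ca, cb = three_feature_cohort(1), three_feature_cohort(2)
        assert em.avg_corr_diff(ca, cb) == pytest.approx(
            acd_loop_oracle(ca, cb), abs=1e-10)

    def test_feature_order_permutation_invariance(self, small_cohort):
        cohort, _ = small_cohort
        schema = cohort.schema
        perm_feats = (schema.static_features
                      + tuple(reversed(schema.temporal_features)))
        perm_schema = CohortSchema(perm_feats)
        recs = [PatientRecord(r.patient_id, r.x_s, r.x_seq[:, ::-1].copy(),
                              r.dropped) for r in cohort.records]
        permuted = Cohort(perm_schema, recs)
        sub = Cohort(schema, cohort.records[:30])
        sub_p = Cohort(perm_schema, recs[:30])
        rest = Cohort(schema, cohort.records[30:])
        rest_p = Cohort(perm_schema, recs[30:])
        assert em.avg_corr_diff(sub, rest) == pytest.approx(
            em.avg_corr_diff(sub_p, rest_p), abs=1e-12)

    def test_schema_mismatch_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError):
            em.avg_corr_diff(cohort, three_feature_cohort(1))


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------
class TestFid:
    def test_identity_near_zero(self):
        e = RNG.normal(size=(300, 6))
        assert em.fid(e, e) == pytest.approx(0.0, abs=1e-6)

    def test_1d_gaussian_closed_form(self):
        a = RNG.normal(0.0, 1.0, size=(20000, 1))
        b = RNG.normal(1.0, 1.0, size=(20000, 1))
        # closed form (mu1-mu2)^2 + (sd1-sd2)^2 = 1
        assert em.fid(a, b) == pytest.approx(1.0, abs=0.05)

    def test_matches_scipy_sqrtm_oracle(self):
        a = RNG.normal(size=(400, 5)) @ RNG.normal(size=(5, 5))
        b = RNG.normal(size=(400, 5)) @ RNG.normal(size=(5, 5)) + 1.0
        mu_a, mu_b = a.mean(0), b.mean(0)
        sa = np.cov(a, rowvar=False) + 1e-6 * np.eye(5)
        sb = np.cov(b, rowvar=False) + 1e-6 * np.eye(5)
        cross = scipy.linalg.sqrtm(sa @ sb).real
        expected = ((mu_a - mu_b) ** 2).sum() + np.trace(sa + sb - 2 * cross)
        assert em.fid(a, b) == pytest.approx(expected, abs=1e-8)

    def test_symmetry(self):
        a = RNG.normal(size=(200, 4))
        b = RNG.normal(size=(200, 4)) + 0.5
        assert em.fid(a, b) == pytest.approx(em.fid(b, a), abs=1e-8)

    def test_nonfinite_rejected(self):
        a = np.full((10, 2), np.nan)
        with pytest.raises(ValueError):
            em.fid(a, a)


# ---------------------------------------------------------------------------
# alpha-precision
# ---------------------------------------------------------------------------
class TestAlphaPrecision:
    def test_independent_half_self_consistency(self):
        all_pts = RNG.normal(size=(4000, 4))
        real, gen = all_pts[:2000], all_pts[2000:]
        alpha = 0.95
        got = em.alpha_precision(real, gen, alpha)
        se = np.sqrt(alpha * (1 - alpha) / 2000)
        assert abs(got - alpha) < 3 * se + 0.01

    def test_far_shifted_generated_scores_zero(self):
        real = RNG.normal(size=(500, 3))
        assert em.alpha_precision(real, real + 100.0, 0.95) == 0.0

    def test_alpha_one_contains_central_subset(self):
        real = RNG.normal(size=(500, 3))
        gen = real[np.linalg.norm(real - real.mean(0), axis=1) < 0.5]
        assert em.alpha_precision(real, gen, 1.0) == 1.0

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            em.alpha_precision(RNG.normal(size=(10, 2)),
                               RNG.normal(size=(10, 2)), 0.0)


# ---------------------------------------------------------------------------
# post-hoc discriminator score / next-step utility
# ---------------------------------------------------------------------------
@pytest.fixture(scope="module")
def medium_cohort():
    import cohortwin as cw
    cohort, _ = cw.generate(cw.SynthConfig(n_patients=220, seed=77))
    return cohort


class TestDiscriminatorScore:
    def test_real_vs_real_halves_near_chance(self, medium_cohort):
        tf = fit_transform(medium_cohort)
        half_a = Cohort(medium_cohort.schema, medium_cohort.records[:110])
        half_b = Cohort(medium_cohort.schema, medium_cohort.records[110:])
        scores = em.discriminator_score(half_a, half_b, tf, seed=0, epochs=40)
        assert abs(scores["auroc"] - 0.5) <= 0.1
        assert 0 <= scores["prauc"] <= 1 and 0 <= scores["f1"] <= 1

    def test_constant_sequences_fully_separable(self, medium_cohort):
        tf = fit_transform(medium_cohort)
        const_records = []
        for r in medium_cohort.records[:110]:
            x_seq = np.empty_like(r.x_seq)
            for j, f in enumerate(medium_cohort.schema.temporal_features):
                const = (tf.cont_ranges[f.name][0] if f.kind == "continuous"
                         else f.levels[0])
                x_seq[:, j] = const
            const_records.append(PatientRecord(r.patient_id, r.x_s, x_seq, False))
        const_cohort = Cohort(medium_cohort.schema, const_records)
        real_half = Cohort(medium_cohort.schema, medium_cohort.records[110:])
        scores = em.discriminator_score(real_half, const_cohort, tf,
                                        seed=0, epochs=40)
        assert scores["auroc"] > 0.95


class TestNextStepUtility:
    def test_self_substitution_is_close(self, medium_cohort):
        import cohortwin as cw
        tf = fit_transform(medium_cohort)
        train, test = cw.split_cohort(medium_cohort, 0.8, 3)
        out = em.next_step_utility(train, train, test, tf, seed=0, epochs=40)
        assert abs(out["gen_mse"] - out["real_mse"]) <= 0.1 * out["real_mse"] + 1e-12

    def test_noise_data_degrades_utility(self, medium_cohort):
        import cohortwin as cw
        tf = fit_transform(medium_cohort)
        train, test = cw.split_cohort(medium_cohort, 0.8, 3)
        noisy = em.noise_baseline(train, tf, seed=1)
        out = em.next_step_utility(train, noisy, test, tf, seed=0, epochs=40)
        assert out["gen_mse"] > out["real_mse"]

    def test_constant_predictor_mse_equals_pooled_variance(self, medium_cohort):
        """A stub that always outputs the per-feature mean of the targets
        must score exactly the pooled per-feature variance (loop-checked)."""
        tf = fit_transform(medium_cohort)
        batch = encode_batch(medium_cohort, tf)
        m = batch.mask[:, 1:]
        targets = batch.x[:, 1:]
        obs = m == 1
        col_mean = targets[obs].mean(axis=0)

        class Stub:
            def forward_all(self, x):
                n, t_max, d = x.shape
                return Tensor(np.broadcast_to(col_mean, (n, t_max - 1, d)).copy())

        got = em._next_step_mse(Stub(), batch)
        acc, cnt = 0.0, 0
        for i in range(batch.x.shape[0]):
            for t in range(1, batch.x.shape[1]):
                if batch.mask[i, t]:
                    acc += ((batch.x[i, t] - col_mean) ** 2).mean()
                    cnt += 1
        assert got == pytest.approx(acc / cnt, abs=1e-10)


# ---------------------------------------------------------------------------
# JS distance
# ---------------------------------------------------------------------------
class TestJsDistance:
    def test_self_substitution_near_zero(self):
        a = RNG.normal(size=4000)
        b = RNG.normal(size=4000)
        assert em.js_distance_1d(a, b, "continuous", bins=16) < 0.05

    def test_disjoint_support_is_one(self):
        a = np.zeros(100)
        b = np.full(100, 10.0)
        # categorical framing keeps the supports truly disjoint
        assert em.js_distance_1d(a.astype(str), b.astype(str),
                                 "categorical") == pytest.approx(1.0, abs=1e-5)

    def test_symmetry(self):
        a = RNG.normal(size=500)
        b = RNG.normal(1.0, 2.0, size=500)
        # symmetric up to binning (bins fixed by the first argument's range)
        d1 = em.js_distance_1d(a, b, "continuous")
        d2 = em.js_distance_1d(b, a, "continuous")
        assert 0 <= d1 <= 1 and 0 <= d2 <= 1

    def test_matches_hand_loop_on_histograms(self):
        a = np.array(["x"] * 30 + ["y"] * 70)
        b = np.array(["x"] * 60 + ["y"] * 40)
        p = np.array([0.3, 0.7])
        q = np.array([0.6, 0.4])
        mm = (p + q) / 2
        kl = lambda u, v: (u * np.log2(u / v)).sum()
        expected = np.sqrt(0.5 * kl(p, mm) + 0.5 * kl(q, mm))
        got = em.js_distance_1d(a, b, "categorical")
        assert got == pytest.approx(expected, abs=1e-6)

    def test_lookahead_table_smoke(self, untrained_model, small_split,
                                   small_transform):
        _, test = small_split
        table = em.lookahead_jsd(untrained_model, small_transform, test,
                                 horizons=[1, 2], n_sims=4, seed=0)
        assert set(table.columns) == {"step", "horizon", "jsd"}
        assert ((table["jsd"] >= 0) & (table["jsd"] <= 1)).all()
        assert set(table["horizon"]) <= {1, 2}


# ---------------------------------------------------------------------------
# MAPE
# ---------------------------------------------------------------------------
class TestDropoffMape:
    def test_exact_prediction_is_zero(self):
        t = em.dropoff_mape([4.0], [4])
        assert t["mape"].iloc[-1] == 0.0

    def test_quarter_error(self):
        t = em.dropoff_mape([5.0], [4])
        assert t["mape"].iloc[-1] == pytest.approx(0.25)

    def test_hand_mean_and_grouping(self):
        t = em.dropoff_mape([5.0, 8.0], [4, 10], known_visits=[1, 2])
        agg = t[t["known_visits"] == -1]["mape"].iloc[0]
        assert agg == pytest.approx((0.25 + 0.2) / 2)
        assert t[t["known_visits"] == 1]["mape"].iloc[0] == pytest.approx(0.25)

    def test_zero_actual_rejected(self):
        with pytest.raises(ValueError):
            em.dropoff_mape([1.0], [0])

    def test_xgb_baseline_produces_predictions(self, small_cohort):
        import cohortwin as cw
        cohort, _ = small_cohort
        train, test = cw.split_cohort(cohort, 0.8, 2)
        tf = fit_transform(train)
        preds = em.xgb_dropoff_baseline(train, test, tf, seed=0)
        assert {"patient_id", "known_visits", "predicted", "actual"} <= set(preds.columns)
        assert len(preds) > 0
        table = em.dropoff_mape(preds["predicted"], preds["actual"],
                                preds["known_visits"])
        assert np.isfinite(table["mape"]).all()


# ---------------------------------------------------------------------------
# baseline cohorts
# ---------------------------------------------------------------------------
class TestBaselines:
    def test_shuffled_baseline_schema_valid_and_decorrelated(self, small_cohort):
        cohort, _ = small_cohort
        tf = fit_transform(cohort)
        shuf = em.shuffled_baseline(cohort, seed=0)
        encode_batch(shuf, tf)  # schema-valid
        assert list(shuf.lengths) == list(cohort.lengths)
        assert em.avg_corr_diff(cohort, shuf) > 0.02

    def test_noise_baseline_schema_valid(self, small_cohort):
        cohort, _ = small_cohort
        tf = fit_transform(cohort)
        noisy = em.noise_baseline(cohort, tf, seed=0)
        assert list(noisy.lengths) == list(cohort.lengths)
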