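"""Loss hand-values, brute-force loop oracles, mask invariance and
gradient sanity."""

import numpy as np
import pytest

import cohortwin.losses as L
from cohortwin.autodiff import Tensor

RNG = np.random.default_rng(100)
LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# independent loop oracles (scalar arithmetic only)
# ---------------------------------------------------------------------------
def oracle_reconstruction(s, st, x, xt, mask):
    total = 0.0
    n = s.shape[0]
    for i in range(n):
        total += np.sqrt(sum((s[i, k] - st[i, k]) ** 2 for k in range(s.shape[1])))
        for t in range(x.shape[1]):
            if mask[i, t]:
                total += np.sqrt(sum((x[i, t, k] - xt[i, t, k]) ** 2
                                     for k in range(x.shape[2])))
    return total / n


def oracle_bce(p, y, mask, w_pos):
    acc, cnt = 0.0, 0
    for i in range(p.shape[0]):
        for t in range(p.shape[1]):
            if mask[i, t]:
                pc = min(max(p[i, t], 1e-7), 1 - 1e-7)
                acc += -(w_pos * y[i, t] * np.log(pc)
                         + (1 - y[i, t]) * np.log(1 - pc))
                cnt += 1
    return acc / max(cnt, 1)


def oracle_ce(logits, y, mask, w):
    acc, cnt = 0.0, 0
    for i in range(logits.shape[0]):
        for t in range(logits.shape[1]):
            if mask[i, t]:
                e = np.exp(logits[i, t] - logits[i, t].max())
                p = e / e.sum()
                acc += -w[y[i, t]] * np.log(max(p[y[i, t]], 1e-7))
                cnt += 1
    return acc / max(cnt, 1)


def oracle_rsgan_side(a, b, mask):
    vals = []
    for i in range(a.shape[0]):
        acc = 0.0
        for t in range(a.shape[1]):
            if mask[i, t]:
                d = a[i, t] - b[i, t]
                acc += -(-np.logaddexp(0.0, -d))
        vals.append(acc)
    return float(np.mean(vals))


def oracle_supervised(h, pred, mask):
    vals = []
    for i in range(h.shape[0]):
        acc = 0.0
        for t in range(h.shape[1]):
            if mask[i, t]:
                acc += np.sqrt(((h[i, t] - pred[i, t]) ** 2).sum())
        vals.append(acc)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# hand values
# ---------------------------------------------------------------------------
class TestHandValues:
    def test_reconstruction_zero_at_identity(self):
        s = RNG.normal(size=(2, 3))
        x = RNG.normal(size=(2, 4, 5))
        mask = np.ones((2, 4))
        assert float(L.reconstruction_loss(s, s, x, x, mask).data) == 0.0

    def test_reconstruction_static_unit_norm(self):
        s = np.array([[1.0, 0.0]])
        st = np.array([[0.0, 0.0]])
        x = np.zeros((1, 1, 2))
        mask = np.zeros((1, 1))
        assert float(L.reconstruction_loss(s, st, x, x, mask).data) == pytest.approx(1.0)

    def test_bce_half_prob_is_ln2(self):
        p = np.full((1, 1), 0.5)
        assert float(L.termination_bce(p, np.zeros((1, 1)), np.ones((1, 1)),
                                       1.0).data) == pytest.approx(LN2, abs=1e-9)

    def test_bce_positive_weight_scales_positive_term(self):
        p = np.full((1, 1), 0.5)
        val = float(L.termination_bce(p, np.ones((1, 1)), np.ones((1, 1)), 3.0).data)
        assert val == pytest.approx(3 * LN2, abs=1e-9)

    def test_ce_uniform_logits_is_ln_c(self):
        logits = np.zeros((1, 1, 4))
        val = float(L.termination_ce(logits, np.zeros((1, 1), dtype=int),
                                     np.ones((1, 1))).data)
        assert val == pytest.approx(np.log(4.0), abs=1e-9)

    def test_ce_confident_correct_is_near_zero(self):
        logits = np.zeros((1, 1, 3))
        logits[0, 0, 2] = 50.0
        val = float(L.termination_ce(logits, np.full((1, 1), 2, dtype=int),
                                     np.ones((1, 1))).data)
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_rsgan_equal_scores_is_t_ln2_per_side(self):
        t = 5
        y = RNG.normal(size=(1, t))
        l_d, l_g = L.rsgan_losses(y, y.copy(), np.ones((1, t)))
        assert float(l_d.data) == pytest.approx(t * LN2, abs=1e-9)
        assert float(l_g.data) == pytest.approx(t * LN2, abs=1e-9)

    def test_rsgan_large_margin_limit(self):
        y_real = np.full((1, 3), 50.0)
        y_fake = np.zeros((1, 3))
        l_d, l_g = L.rsgan_losses(y_real, y_fake, np.ones((1, 3)))
        assert float(l_d.data) == pytest.approx(0.0, abs=1e-6)
        assert float(l_g.data) > 100

    def test_auxc_perfect_and_hand_mean(self):
        h = np.array([[1.0, 0.0]])
        assert float(L.auxc_loss(h, h, h).data) == 0.0
        val = float(L.auxc_loss(h, np.array([[0.0, 0.0]]), h).data)
        assert val == pytest.approx(0.5)

    def test_supervised_three_four_five(self):
        h = np.array([[[3.0, 4.0]]])
        pred = np.zeros((1, 1, 2))
        assert float(L.supervised_loss(h, pred, np.ones((1, 1))).data) == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# loop-oracle agreement on random instances
# ---------------------------------------------------------------------------
class TestLoopOracles:
    def setup_method(self):
        self.rng = np.random.default_rng(7)
        self.n, self.t, self.d = 3, 5, 4
        self.mask = np.zeros((self.n, self.t))
        for i, ln in enumerate([2, 5, 3]):
            self.mask[i, :ln] = 1

    def test_reconstruction_matches_oracle(self):
        r = self.rng
        s, st = r.normal(size=(self.n, 3)), r.normal(size=(self.n, 3))
        x, xt = r.normal(size=(self.n, self.t, self.d)), r.normal(size=(self.n, self.t, self.d))
        got = float(L.reconstruction_loss(s, st, x, xt, self.mask).data)
        assert got == pytest.approx(oracle_reconstruction(s, st, x, xt, self.mask), abs=1e-10)

    def test_bce_matches_oracle(self):
        r = self.rng
        p = r.uniform(0.01, 0.99, size=(self.n, self.t))
        y = (r.uniform(size=(self.n, self.t)) < 0.3).astype(float) * self.mask
        got = float(L.termination_bce(p, y, self.mask, 2.5).data)
        assert got == pytest.approx(oracle_bce(p, y, self.mask, 2.5), abs=1e-10)

    def test_ce_matches_oracle(self):
        r = self.rng
        c = 4
        logits = r.normal(size=(self.n, self.t, c))
        y = r.integers(0, c, size=(self.n, self.t))
        w = np.array([1.0, 2.0, 0.5, 1.5])
        got = float(L.termination_ce(logits, y, self.mask, w).data)
        assert got == pytest.approx(oracle_ce(logits, y, self.mask, w), abs=1e-10)

    def test_ce_c2_equals_bce_with_matched_weights(self):
        r = self.rng
        x_logit = r.normal(size=(self.n, self.t))
        logits = np.stack([np.zeros_like(x_logit), x_logit], axis=-1)
        p = 1.0 / (1.0 + np.exp(-x_logit))
        y = (r.uniform(size=(self.n, self.t)) < 0.4).astype(int)
        w_pos = 3.0
        ce = float(L.termination_ce(logits, y, self.mask, (1.0, w_pos)).data)
        bce = float(L.termination_bce(p, y.astype(float), self.mask, w_pos).data)
        assert ce == pytest.approx(bce, abs=1e-8)

    def test_rsgan_matches_oracle_and_symmetry(self):
        r = self.rng
        yr, yf = r.normal(size=(self.n, self.t)), r.normal(size=(self.n, self.t))
        l_d, l_g = L.rsgan_losses(yr, yf, self.mask)
        assert float(l_d.data) == pytest.approx(oracle_rsgan_side(yr, yf, self.mask), abs=1e-10)
        assert float(l_g.data) == pytest.approx(oracle_rsgan_side(yf, yr, self.mask), abs=1e-10)
        l_d2, l_g2 = L.rsgan_losses(yf, yr, self.mask)  # swap real<->fake
        assert float(l_d2.data) == pytest.approx(float(l_g.data), abs=1e-12)
        assert float(l_g2.data) == pytest.approx(float(l_d.data), abs=1e-12)

    def test_auxc_matches_oracle(self):
        r = self.rng
        h = r.normal(size=(self.n, 4))
        p1, p2 = r.normal(size=(self.n, 4)), r.normal(size=(self.n, 4))
        expected = 0.5 * (np.mean([np.sqrt(((h[i] - p1[i]) ** 2).sum()) for i in range(self.n)])
                          + np.mean([np.sqrt(((h[i] - p2[i]) ** 2).sum()) for i in range(self.n)]))
        assert float(L.auxc_loss(h, p1, p2).data) == pytest.approx(expected, abs=1e-10)

    def test_supervised_matches_oracle(self):
        r = self.rng
        h = r.normal(size=(self.n, self.t, self.d))
        pred = r.normal(size=(self.n, self.t, self.d))
        got = float(L.supervised_loss(h, pred, self.mask).data)
        assert got == pytest.approx(oracle_supervised(h, pred, self.mask), abs=1e-10)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------
class TestInvariants:
    def setup_method(self):
        self.rng = np.random.default_rng(21)
        self.mask = np.array([[1, 1, 1, 0, 0], [1, 1, 0, 0, 0]], dtype=float)

    def _perturb_padding(self, arr):
        out = arr.copy()
        pad = self.mask == 0
        if out.ndim == 3:
            out[pad] += self.rng.normal(size=out[pad].shape)
        else:
            out[pad] += self.rng.normal(size=out[pad].shape)
        return out

    def test_all_losses_mask_invariant(self):
        r = self.rng
        n, t, d = 2, 5, 3
        s, st = r.normal(size=(n, 2)), r.normal(size=(n, 2))
        x, xt = r.normal(size=(n, t, d)), r.normal(size=(n, t, d))
        p = r.uniform(0.1, 0.9, size=(n, t))
        y = np.zeros((n, t)); y[0, 2] = 1
        yr, yf = r.normal(size=(n, t)), r.normal(size=(n, t))
        h, pred = r.normal(size=(n, t, d)), r.normal(size=(n, t, d))

        base = [
            float(L.reconstruction_loss(s, st, x, xt, self.mask).data),
            float(L.termination_bce(p, y, self.mask, 2.0).data),
            float(L.rsgan_losses(yr, yf, self.mask)[0].data),
            float(L.supervised_loss(h, pred, self.mask).data),
        ]
        pert = [
            float(L.reconstruction_loss(s, st, x, self._perturb_padding(xt), self.mask).data),
            float(L.termination_bce(self._perturb_padding(p).clip(1e-6, 1 - 1e-6), y, self.mask, 2.0).data),
            float(L.rsgan_losses(yr, self._perturb_padding(yf), self.mask)[0].data),
            float(L.supervised_loss(h, self._perturb_padding(pred), self.mask).data),
        ]
        assert base == pert

    def test_losses_nonnegative_and_finite(self):
        r = self.rng
        n, t, d = 2, 5, 3
        for _ in range(10):
            x, xt = r.normal(size=(n, t, d)), r.normal(size=(n, t, d))
            s, st = r.normal(size=(n, 2)), r.normal(size=(n, 2))
            vals = [
                float(L.reconstruction_loss(s, st, x, xt, self.mask).data),
                float(L.termination_bce(r.uniform(size=(n, t)),
                                        np.zeros((n, t)), self.mask, 1.0).data),
                float(L.supervised_loss(x, xt, self.mask).data),
            ]
            assert all(np.isfinite(v) and v >= 0 for v in vals)

    def test_gradient_nonzero_at_generic_point(self):
        r = self.rng
        n, t, d = 2, 4, 3
        mask = np.ones((n, t))
        cases = []
        xt = Tensor(r.normal(size=(n, t, d)), requires_grad=True)
        cases.append((xt, L.reconstruction_loss(r.normal(size=(n, 2)),
                                                Tensor(r.normal(size=(n, 2))),
                                                r.normal(size=(n, t, d)), xt, mask)))
        p = Tensor(r.uniform(0.2, 0.8, size=(n, t)), requires_grad=True)
        y = np.zeros((n, t)); y[:, -1] = 1
        cases.append((p, L.termination_bce(p, y, mask, 2.0)))
        yf = Tensor(r.normal(size=(n, t)), requires_grad=True)
        cases.append((yf, L.rsgan_losses(r.normal(size=(n, t)), yf, mask)[1]))
        pred = Tensor(r.normal(size=(n, t, d)), requires_grad=True)
        cases.append((pred, L.supervised_loss(r.normal(size=(n, t, d)), pred, mask)))
        for param, loss in cases:
            loss.backward()
            assert np.abs(param.grad).max() > 0

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            L.termination_bce(np.full((1, 1), 0.5), np.full((1, 1), 2.0),
                              np.ones((1, 1)), 1.0)
        with pytest.raises(ValueError):
            L.termination_ce(np.zeros((1, 1, 3)), np.full((1, 1), 3, dtype=int),
                             np.ones((1, 1)))

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            L.LossWeights(w_pos=0.0)
        with pytest.raises(ValueError):
            L.LossWeights(lam=-1.0)
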