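"""Censored likelihood and pairwise ranking losses with brute-force oracles."""

import numpy as np
import pytest

from vmap.errors import ConfigurationError
from vmap.labeling import Category, TaskLabel
from vmap.losses import (
    LossConfig,
    labels_to_arrays,
    likelihood_loss,
    ranking_loss,
    total_loss,
    total_loss_and_grads,
)
from vmap.network import ModelOutput, softmax


def lab(status, k=None, task="PVI"):
    if status == "pre":
        return TaskLabel(task=task, status=Category.PRE)
    if status == "event":
        return TaskLabel(task=task, status=Category.EVENT, event_bin=k)
    if status == "free":
        return TaskLabel(task=task, status=Category.EVENT_FREE)
    return TaskLabel(task=task, status=Category.CENSORED, censor_bin=k)


def random_labels(rng, n, K):
    out = []
    for _ in range(n):
        s = rng.integers(0, 4)
        if s == 0:
            out.append(lab("pre"))
        elif s == 1:
            out.append(lab("event", int(rng.integers(1, K + 1))))
        elif s == 2:
            out.append(lab("free"))
        else:
            out.append(lab("cens", int(rng.integers(0, K + 1))))
    return out


class TestLikelihood:
    def test_point_mass_examples(self):
        assert likelihood_loss([1.0, 0.0, 0.0], lab("pre")) == 0.0
        assert likelihood_loss([0.25, 0.25, 0.5], lab("free")) == pytest.approx(np.log(2))

    def test_censored_mass_sums_surviving_bins(self):
        # K=2, p=(p_pre, p1, p2, p_free); censored after bin 1 leaves p2+p_free
        p = [0.1, 0.2, 0.3, 0.4]
        assert likelihood_loss(p, lab("cens", 1)) == pytest.approx(-np.log(0.7))
        # censored at 0 still teaches "not pre-intervention"
        assert likelihood_loss(p, lab("cens", 0)) == pytest.approx(-np.log(0.9))

    def test_reduces_to_three_class_cross_entropy_at_k1(self, rng):
        """With K=1 and no censoring the loss IS 3-class cross-entropy."""
        for _ in range(50):
            logits = rng.normal(0, 2, 3)
            p = np.exp(logits) / np.exp(logits).sum()
            for cls, label in enumerate((lab("pre"), lab("event", 1), lab("free"))):
                assert likelihood_loss(p, label) == pytest.approx(-np.log(p[cls]), rel=1e-9)

    def test_nonnegative_and_zero_only_at_point_mass(self, rng):
        for _ in range(100):
            p = rng.dirichlet(np.ones(4))
            label = random_labels(rng, 1, 2)[0]
            value = likelihood_loss(p, label)
            assert value >= 0.0
            if value < 1e-12:
                assert p.max() > 1 - 1e-9


class TestRanking:
    def test_single_pair_formula(self):
        # K=1: F(1) = p_1; event i with F=0.9 against event-free j with F=0.1
        probs = np.array([[0.05, 0.9, 0.05], [0.85, 0.1, 0.05]])
        labels = [lab("event", 1), lab("free")]
        value = ranking_loss(probs, labels, LossConfig(sigma=0.1))
        assert value == pytest.approx(np.exp(-8.0), rel=1e-9)

    def test_tied_cif_contributes_one(self):
        probs = np.array([[0.1, 0.5, 0.4], [0.4, 0.5, 0.1]])
        labels = [lab("event", 1), lab("free")]
        assert ranking_loss(probs, labels, LossConfig()) == pytest.approx(1.0)

    def test_pre_only_batch_has_no_pairs(self, rng):
        probs = rng.dirichlet(np.ones(4), size=5)
        assert ranking_loss(probs, [lab("pre")] * 5, LossConfig()) == 0.0

    def test_matches_bruteforce_pairwise_oracle(self, rng):
        """Exhaustive double-loop restatement of the pair rules."""
        K = 4
        cfg = LossConfig(sigma=0.3)
        for _ in range(20):
            n = int(rng.integers(2, 64))
            probs = rng.dirichlet(np.ones(K + 2), size=n)
            labels = random_labels(rng, n, K)
            F = np.cumsum(probs[:, 1:-1], axis=1)
            total, pairs = 0.0, 0
            for i in range(n):
                li = labels[i]
                if li.status is not Category.EVENT:
                    continue
                k = li.event_bin
                for j in range(n):
                    if j == i:
                        continue
                    lj = labels[j]
                    ok = (
                        lj.status is Category.EVENT_FREE
                        or (lj.status is Category.EVENT and lj.event_bin > k)
                        or (lj.status is Category.CENSORED and lj.censor_bin >= k)
                    )
                    if ok:
                        total += np.exp(-(F[i, k - 1] - F[j, k - 1]) / cfg.sigma)
                        pairs += 1
            expected = total / pairs if pairs else 0.0
            assert ranking_loss(probs, labels, cfg) == pytest.approx(expected, rel=1e-12)

    def test_permutation_invariance_and_margin_monotonicity(self, rng):
        K = 3
        probs = rng.dirichlet(np.ones(K + 2), size=10)
        labels = random_labels(rng, 10, K)
        cfg = LossConfig()
        base = ranking_loss(probs, labels, cfg)
        perm = rng.permutation(10)
        assert ranking_loss(probs[perm], [labels[i] for i in perm], cfg) == pytest.approx(base)
        # widening the margin F_i - F_j strictly reduces the penalty
        margins = np.linspace(-0.5, 0.5, 7)
        vals = []
        for margin in margins:
            f_i = 0.5 + margin / 2
            f_j = 0.5 - margin / 2
            p = np.array([[0.0, f_i, 1 - f_i], [0.0, f_j, 1 - f_j]])
            vals.append(ranking_loss(p, [lab("event", 1), lab("free")], cfg))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            LossConfig(sigma=0.0)


class TestTotalLoss:
    def test_alpha_zero_is_mean_likelihood(self, rng):
        K = 3
        probs_p = rng.dirichlet(np.ones(K + 2), size=6)
        probs_b = rng.dirichlet(np.ones(K + 2), size=6)
        lp = random_labels(rng, 6, K)
        lb = random_labels(rng, 6, K)
        cfg = LossConfig(alpha=0.0, w_pvi=2.0, w_bepvi=0.5)
        got = total_loss(ModelOutput(pvi=probs_p, bepvi=probs_b), lp, lb, cfg)
        want = 2.0 * np.mean([likelihood_loss(p, l) for p, l in zip(probs_p, lp)]) + 0.5 * np.mean(
            [likelihood_loss(p, l) for p, l in zip(probs_b, lb)]
        )
        assert got == pytest.approx(want, rel=1e-12)

    def test_zero_task_weight_silences_that_task(self, rng):
        K = 2
        probs = rng.dirichlet(np.ones(K + 2), size=4)
        lp = random_labels(rng, 4, K)
        cfg = LossConfig(w_bepvi=0.0)
        out = ModelOutput(pvi=probs, bepvi=probs)
        a = total_loss(out, lp, random_labels(rng, 4, K), cfg)
        b = total_loss(out, lp, random_labels(rng, 4, K), cfg)
        assert a == pytest.approx(b)

    def test_analytic_gradient_matches_central_differences(self, rng):
        K = 3
        B = 6
        logits_p = rng.normal(0, 1, (B, K + 2))
        logits_b = rng.normal(0, 1, (B, K + 2))
        lp = labels_to_arrays(random_labels(rng, B, K))
        lb = labels_to_arrays(random_labels(rng, B, K))
        cfg = LossConfig(sigma=0.2, alpha=0.8, w_pvi=1.0, w_bepvi=0.6)
        _, dzp, dzb = total_loss_and_grads(logits_p, logits_b, lp, lb, cfg)
        eps = 1e-6
        for logits, dz, which in ((logits_p, dzp, "p"), (logits_b, dzb, "b")):
            numeric = np.zeros_like(logits)
            for i in range(B):
                for j in range(K + 2):
                    hi, lo = logits.copy(), logits.copy()
                    hi[i, j] += eps
                    lo[i, j] -= eps
                    if which == "p":
                        f_hi = total_loss_and_grads(hi, logits_b, lp, lb, cfg)[0]
                        f_lo = total_loss_and_grads(lo, logits_b, lp, lb, cfg)[0]
                    else:
                        f_hi = total_loss_and_grads(logits_p, hi, lp, lb, cfg)[0]
                        f_lo = total_loss_and_grads(logits_p, lo, lp, lb, cfg)[0]
                    numeric[i, j] = (f_hi - f_lo) / (2 * eps)
            scale = max(np.abs(numeric).max(), 1e-12)
            assert np.abs(numeric - dz).max() / scale < 1e-4

    def test_gradpath_value_matches_probability_api(self, rng):
        K = 2
        logits_p = rng.normal(0, 1, (5, K + 2))
        logits_b = rng.normal(0, 1, (5, K + 2))
        lp = random_labels(rng, 5, K)
        lb = random_labels(rng, 5, K)
        cfg = LossConfig()
        value, _, _ = total_loss_and_grads(logits_p, logits_b, lp, lb, cfg)
        out = ModelOutput(pvi=softmax(logits_p), bepvi=softmax(logits_b))
        assert total_loss(out, lp, lb, cfg) == pytest.approx(value, rel=1e-12)
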