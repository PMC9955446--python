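"""DropWeak masking core: samplers, weak rule, masked application."""

import numpy as np
import pytest

from dropweak import (
    DropWeakSpec,
    absolute,
    apply_dropweak,
    effective_weights,
    magnitude_inverse_rho,
    mc_activation_estimate,
    quantile,
    sample_mask_set,
    sample_node_mask,
    sample_weight_mask,
    weak_weight_mask,
)
from dropweak.masking import WeakRule


class TestBernoulliSamplers:
    @pytest.mark.parametrize("rho,expected", [(0.0, 1.0), (1.0, 0.0)])
    def test_degenerate_probabilities(self, rho, expected):
        mask = sample_weight_mask((7, 5), rho, np.random.default_rng(0))
        assert np.all(mask == expected)

    def test_empirical_drop_fraction_matches_rho(self):
        # binomial oracle: 4-sigma band around rho at n = 10,000
        mask = sample_weight_mask((100, 100), 0.3, np.random.default_rng(42))
        tol = 4 * np.sqrt(0.3 * 0.7 / 10_000)
        assert abs((1.0 - mask.mean()) - 0.3) < tol

    def test_node_mask_degenerate_and_empirical(self):
        assert np.all(sample_node_mask(50, 0.0, np.random.default_rng(0)) == 1)
        assert np.all(sample_node_mask(50, 1.0, np.random.default_rng(0)) == 0)
        kept = sample_node_mask(10_000, 0.5, np.random.default_rng(7)).mean()
        assert abs(kept - 0.5) < 4 * np.sqrt(0.25 / 10_000)

    def test_per_weight_rho_array(self):
        rho = np.array([[0.0, 1.0], [1.0, 0.0]])
        mask = sample_weight_mask((2, 2), rho, np.random.default_rng(0))
        assert np.array_equal(mask, 1.0 - rho)

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_probability_domain_errors(self, bad):
        with pytest.raises(ValueError):
            sample_weight_mask((3, 3), bad, np.random.default_rng(0))
        with pytest.raises(ValueError):
            sample_node_mask(3, bad, np.random.default_rng(0))

    def test_rho_array_shape_mismatch(self):
        with pytest.raises(ValueError):
            sample_weight_mask((3, 3), np.full((2, 2), 0.5), np.random.default_rng(0))

    def test_reproducible_given_seed(self):
        a = sample_weight_mask((20, 20), 0.4, np.random.default_rng(3))
        b = sample_weight_mask((20, 20), 0.4, np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestWeakWeightMask:
    def test_zero_threshold_keeps_everything(self):
        w = np.array([0.0, -1.0, 2.0])
        assert np.all(weak_weight_mask(w, absolute(0.0)) == 1)

    def test_absolute_rule(self):
        w = np.array([1.0, -0.01, 0.5])
        assert np.array_equal(weak_weight_mask(w, absolute(0.1)), [1, 0, 1])

    def test_quantile_rule_smallest_magnitude_zeroed(self):
        assert np.array_equal(weak_weight_mask(np.array([3.0, 1.0, 2.0]), quantile(1 / 3)), [1, 0, 1])

    def test_quantile_tie_break_by_flat_index(self):
        # all magnitudes equal: the earliest flat indices are dropped
        mask = weak_weight_mask(np.array([1.0, -1.0, 1.0, 1.0]), quantile(0.5))
        assert np.array_equal(mask, [0, 0, 1, 1])

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=(6, 6))
        rule = quantile(0.25)
        m1 = weak_weight_mask(w, rule)
        # mask is a deterministic function: recomputing from same weights is stable
        assert np.array_equal(m1, weak_weight_mask(w, rule))
        # and zeroed entries stay in the dropped set when reapplied
        m2 = weak_weight_mask(w * m1, rule)
        assert np.all(m2[m1 == 0] == 0)

    def test_non_finite_weights_rejected(self):
        with pytest.raises(ValueError):
            weak_weight_mask(np.array([1.0, np.nan]), absolute(0.1))

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            WeakRule("absolute", -1.0)
        with pytest.raises(ValueError):
            WeakRule("quantile", 1.5)


class TestApplyDropweak:
    def _dense(self, seed=0, n_in=6, n_out=4, n=5):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n_in, n_out)), rng.normal(size=(n, n_in))

    def test_all_on_masks_identity(self):
        W, x = self._dense()
        spec = DropWeakSpec.off()
        masks = sample_mask_set(W, spec, np.random.default_rng(0))
        out = apply_dropweak(W, x, masks, spec)
        assert np.array_equal(out, x @ W)

    def test_dropped_node_gives_zero_output(self):
        W, x = self._dense()
        spec = DropWeakSpec(0.0, 0.0, weak_rule=None, scale_mode="none")
        masks = sample_mask_set(W, spec, np.random.default_rng(0))
        masks.node_mask[2] = 0.0
        out = apply_dropweak(W, x, masks, spec)
        assert np.all(out[:, 2] == 0.0)

    def test_base_weights_never_modified(self):
        W, x = self._dense()
        before = W.copy()
        spec = DropWeakSpec(0.3, 0.4)
        rng = np.random.default_rng(1)
        for _ in range(10):
            apply_dropweak(W, x, sample_mask_set(W, spec, rng), spec)
        assert np.array_equal(W, before)

    def test_inverted_scaling_is_unbiased(self):
        # MC expectation oracle: mean of masked outputs ~ dense output
        W, x = self._dense(seed=2)
        spec = DropWeakSpec(0.0, 0.4, weak_rule=None, scale_mode="inverted")
        rng = np.random.default_rng(3)
        draws = np.stack(
            [apply_dropweak(W, x, sample_mask_set(W, spec, rng), spec) for _ in range(20_000)]
        )
        se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - x @ W) < 4 * se + 1e-12)

    def test_conv_weights_node_mask_per_channel(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(3, 2, 3, 3))
        x = rng.normal(size=(2, 2, 8, 8))
        spec = DropWeakSpec(0.0, 0.0, weak_rule=None, scale_mode="none")
        masks = sample_mask_set(W, spec, np.random.default_rng(0))
        masks.node_mask[1] = 0.0
        out = apply_dropweak(W, x, masks, spec)
        assert out.shape == (2, 3, 8, 8)
        assert np.all(out[:, 1] == 0.0)

    def test_shape_mismatch_raises(self):
        W, x = self._dense()
        spec = DropWeakSpec.off()
        masks = sample_mask_set(W, spec, np.random.default_rng(0))
        with pytest.raises(ValueError):
            apply_dropweak(W, x[:, :3], masks, spec)


class TestMCActivationEstimate:
    def test_no_stochasticity_mean_equals_single_pass(self):
        rng = np.random.default_rng(0)
        W, x = rng.normal(size=(4, 3)), rng.normal(size=(2, 4))
        spec = DropWeakSpec(0.0, 0.0, weak_rule=absolute(0.0))
        est = mc_activation_estimate(W, x, spec, 7, np.random.default_rng(1))
        assert np.allclose(est, x @ W)

    def test_single_sample_equals_one_draw(self):
        rng = np.random.default_rng(0)
        W, x = rng.normal(size=(4, 3)), rng.normal(size=(2, 4))
        spec = DropWeakSpec(0.2, 0.3, weak_rule=None)
        est = mc_activation_estimate(W, x, spec, 1, np.random.default_rng(9))
        one = apply_dropweak(W, x, sample_mask_set(W, spec, np.random.default_rng(9)), spec)
        assert np.array_equal(est, one)

    def test_converges_to_dense_output(self):
        rng = np.random.default_rng(2)
        W, x = rng.normal(size=(5, 4)), rng.normal(size=(3, 5))
        spec = DropWeakSpec(0.0, 0.3, weak_rule=None, scale_mode="inverted")
        est = mc_activation_estimate(W, x, spec, 5000, np.random.default_rng(3))
        # per-entry SE of the estimate is bounded by sd of one draw / sqrt(M)
        draws = np.stack(
            [apply_dropweak(W, x, sample_mask_set(W, spec, np.random.default_rng(100 + i)), spec) for i in range(200)]
        )
        se = draws.std(axis=0) / np.sqrt(5000)
        assert np.all(np.abs(est - x @ W) < 4 * se + 1e-9)

    def test_invalid_sample_count(self):
        with pytest.raises(ValueError):
            mc_activation_estimate(np.ones((2, 2)), np.ones((1, 2)), DropWeakSpec.off(), 0, np.random.default_rng(0))


class TestReductions:
    """DropWeak degenerates to DropOut / DropConnect stream-for-stream."""

    def test_reduces_to_dropout(self):
        # independent dropout implementation on the same mask stream
        p = 0.4
        rng_a = np.random.default_rng(12)
        ours = sample_node_mask(1000, p, rng_a)
        rng_b = np.random.default_rng(12)
        theirs = (rng_b.random(1000) >= p).astype(float)
        assert np.array_equal(ours, theirs)

    def test_reduces_to_dropconnect(self):
        rho = 0.25
        rng_a = np.random.default_rng(13)
        ours = sample_weight_mask((40, 25), rho, rng_a)
        rng_b = np.random.default_rng(13)
        theirs = (rng_b.random((40, 25)) >= rho).astype(float)
        assert np.array_equal(ours, theirs)

    def test_effective_weights_weak_mask_not_rescaled(self):
        W = np.array([[0.001, 1.0], [2.0, 3.0]])
        spec = DropWeakSpec(0.0, 0.5, weak_rule=absolute(0.01), scale_mode="inverted")
        masks = sample_mask_set(W, spec, np.random.default_rng(0))
        masks.weight_mask[...] = 1.0  # isolate weak-mask handling
        eff = effective_weights(W, masks, spec).effective_weights
        # survivors get 1/(1-rho)=2; the weak-zeroed entry stays exactly 0
        assert eff[0, 0] == 0.0
        assert np.allclose(eff[np.abs(W) >= 0.01], W[np.abs(W) >= 0.01] * 2.0)


def test_magnitude_inverse_schedule_orders_by_magnitude():
    w = np.array([0.1, -5.0, 2.0, 0.01])
    rho = magnitude_inverse_rho(w, rho_max=0.6)
    assert rho[3] == pytest.approx(0.6)  # weakest weight -> rho_max
    assert rho[1] == 0.0  # strongest -> 0
    assert np.all((rho >= 0) & (rho <= 0.6))
    order = np.argsort(np.abs(w))
    assert np.all(np.diff(rho[order]) <= 0)
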