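"""Replay/representation diagnostics against independent oracles."""

import numpy as np
import pytest

from sleepreplay import (DenseNet, PatchesSpec, SleepConfig, ann_to_sleep_ann,
                         class_correlation_matrix, drive_change, generate_patches,
                         identify_task_neurons, inactive_fraction,
                         sleep_firing_comparison, treves_rolls_sparseness,
                         weight_category_histograms, weight_cosine_similarity)
from sleepreplay.sleep import SpikeLog


def _identity_net(d, extra_layer=False):
    """Hidden activations replicate the (non-negative) input exactly."""
    weights = [np.eye(d)]
    sizes = [d, d]
    if extra_layer:
        weights.append(np.eye(d))
        sizes.append(d)
    sizes.append(2)
    weights.append(np.zeros((2, d)))
    return DenseNet(sizes, weights)


class TestClassCorrelation:
    def test_matches_brute_force_pairwise_pearson(self):
        acts = np.array([[1.0, 2.0, 3.0, 0.5],
                         [2.0, 1.0, 0.0, 4.0],
                         [0.3, 0.3, 0.9, 0.1],
                         [5.0, 1.0, 2.0, 2.0]])
        y = np.array([0, 0, 1, 1])
        net = _identity_net(4)
        got = class_correlation_matrix(net, acts, y, layer=0)

        def r(u, v):
            return np.corrcoef(u, v)[0, 1]

        expected = np.array([
            [r(acts[0], acts[1]),
             np.mean([r(acts[0], acts[2]), r(acts[0], acts[3]),
                      r(acts[1], acts[2]), r(acts[1], acts[3])])],
            [np.nan, r(acts[2], acts[3])]])
        expected[1, 0] = expected[0, 1]
        expected[1, 1] = r(acts[2], acts[3])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_orthogonal_one_hot_activations(self):
        acts = np.vstack([np.eye(3), np.eye(3)])  # 2 samples per class
        y = np.array([0, 1, 2, 0, 1, 2])
        got = class_correlation_matrix(_identity_net(3), acts, y, layer=0)
        np.testing.assert_allclose(np.diag(got), 1.0, atol=1e-12)
        off = got[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, -0.5, atol=1e-12)  # centred one-hots

    def test_zero_variance_reported_missing_not_one(self):
        acts = np.ones((4, 3))
        y = np.array([0, 0, 1, 1])
        got = class_correlation_matrix(_identity_net(3), acts, y, layer=0)
        assert np.isnan(got).all()

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        acts = rng.random((20, 6))
        y = rng.integers(0, 3, 20)
        got = class_correlation_matrix(_identity_net(6), acts, y, layer=0)
        np.testing.assert_allclose(got, got.T, atol=1e-12)


class TestTaskNeurons:
    def _snet(self, d):
        net = _identity_net(d)
        snet, _, _ = ann_to_sleep_ann(net, np.ones(len(net.weights)),
                                      SleepConfig(thresholds=0.5,
                                                  use_max_weight=False))
        return snet

    def test_deterministic_responders_are_found(self):
        snet = self._snet(6)
        inputs = {0: np.array([[1.0, 1, 0, 0, 0, 0]]),
                  1: np.array([[0.0, 0, 1, 1, 1, 0]])}
        sets = identify_task_neurons(snet, inputs, k=2, passes=10,
                                     rng=np.random.default_rng(0))
        # silent neuron 5 ties at zero count and is assigned to class 0,
        # but never outranks the true responders
        assert set(sets[0][0]) == {0, 1}
        sets = identify_task_neurons(snet, inputs, k=3, passes=10,
                                     rng=np.random.default_rng(0))
        assert set(sets[0][1]) == {2, 3, 4}

    def test_count_sorting_and_index_tie_break(self):
        snet = self._snet(4)
        # cycling two examples: pixel0 on every pass, pixel1 on half of them
        inputs = {0: np.array([[1.0, 1, 0, 0], [1.0, 0, 0, 0]])}
        sets = identify_task_neurons(snet, inputs, k=2, passes=10,
                                     rng=np.random.default_rng(0))
        np.testing.assert_array_equal(sets[0][0], [0, 1])  # count 10 > count 5
        # pixels 2,3 never fire: counts tie at 0 -> lower index first
        inputs = {0: np.array([[0.0, 0, 0, 0]])}
        sets = identify_task_neurons(self._snet(4), inputs, k=4, passes=5,
                                     rng=np.random.default_rng(0))
        np.testing.assert_array_equal(sets[0][0], [0, 1, 2, 3])

    def test_sets_disjoint_across_classes_and_exclude_output(self):
        snet = self._snet(8)
        rng = np.random.default_rng(3)
        inputs = {c: (rng.random((5, 8)) < 0.4).astype(float) for c in range(3)}
        sets = identify_task_neurons(snet, inputs, k=8, passes=15, rng=rng)
        assert list(sets) == [0]  # only the single hidden layer; output ignored
        all_idx = np.concatenate([sets[0][c] for c in range(3)])
        assert len(all_idx) == len(set(all_idx.tolist()))

    def test_small_pool_warns_and_returns_pool(self):
        snet = self._snet(4)
        inputs = {0: np.array([[1.0, 1, 1, 1]]), 1: np.array([[0.0, 0, 0, 0]])}
        with pytest.warns(UserWarning, match="returning the full pool"):
            sets = identify_task_neurons(snet, inputs, k=100, passes=5,
                                         rng=np.random.default_rng(0))
        assert len(sets[0][0]) == 4


class TestFiringComparison:
    def _log(self, rates, steps=200, seed=0):
        rng = np.random.default_rng(seed)
        hidden = (rng.random((steps, len(rates))) < rates).astype(np.uint8)
        inp = np.zeros((steps, 2), dtype=np.uint8)
        out = np.zeros((steps, 1), dtype=np.uint8)
        return SpikeLog([inp, hidden, out])

    def test_all_equal_rates_give_zero_t(self):
        log = SpikeLog([np.zeros((10, 2), np.uint8),
                        np.ones((10, 40), np.uint8),
                        np.zeros((10, 1), np.uint8)])
        res = sleep_firing_comparison(log, {"s": np.arange(10)}, layer=0,
                                      n_random=10, rng=np.random.default_rng(0))
        assert res["s"].t_statistic == 0.0

    def test_matches_closed_form_pooled_t(self):
        rng = np.random.default_rng(5)
        log = self._log(np.concatenate([np.full(50, 0.2), np.full(50, 0.1)]),
                        steps=400, seed=5)
        res = sleep_firing_comparison(log, {"a": np.arange(50)}, layer=0,
                                      n_random=30, rng=rng)["a"]
        a, b = res.set_rates, res.random_rates
        sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                     / (len(a) + len(b) - 2))
        expected = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
        assert res.t_statistic == pytest.approx(expected, rel=1e-12)
        assert res.df == len(a) + len(b) - 2

    def test_type_one_error_calibrated_under_the_null(self):
        """Same rate distribution for set and random draw: ~alpha rejections."""
        rej = 0
        n_sim = 400
        for s in range(n_sim):
            log = self._log(np.full(300, 0.15), steps=60, seed=s)
            res = sleep_firing_comparison(
                log, {"a": np.random.default_rng(1000 + s).choice(300, 100,
                                                                  replace=False)},
                layer=0, n_random=100, rng=np.random.default_rng(2000 + s))["a"]
            rej += res.p_value_raw < 0.05
        assert rej / n_sim < 0.08  # 0.05 nominal + Monte-Carlo slack

    def test_empty_log_rejected(self):
        log = SpikeLog([np.zeros((0, 2), np.uint8), np.zeros((0, 3), np.uint8)])
        with pytest.raises(ValueError, match="empty"):
            sleep_firing_comparison(log, {"a": [0]}, layer=0)

    def test_bonferroni_scales_p_value(self):
        log = self._log(np.concatenate([np.full(50, 0.6), np.full(250, 0.05)]),
                        steps=100, seed=1)
        kw = dict(neuron_sets={"a": np.arange(50)}, layer=0, n_random=100)
        raw = sleep_firing_comparison(log, rng=np.random.default_rng(3), **kw)["a"]
        corr = sleep_firing_comparison(log, rng=np.random.default_rng(3),
                                       n_comparisons=4, **kw)["a"]
        assert corr.p_value == pytest.approx(min(1.0, 4 * raw.p_value_raw))


class TestDriveChange:
    def test_identical_nets_zero_delta(self, small_net):
        x = np.random.default_rng(0).random((6, 4))
        d = drive_change(small_net, small_net, x, 0, {"all": np.arange(6)})
        assert d["all"] == 0.0

    def test_single_weight_bump_is_linear_in_input_mean(self, small_net):
        x = np.random.default_rng(1).random((50, 4))
        after = small_net.copy()
        c = 0.37
        after.weights[0][2, 1] += c
        d = drive_change(small_net, after, x, 0, {"n2": [2], "other": [0, 1]})
        assert d["n2"] == pytest.approx(c * x[:, 1].mean(), rel=1e-12)
        assert d["other"] == 0.0

    def test_mismatched_architectures_rejected(self, small_net):
        other = DenseNet([4, 5, 3])
        with pytest.raises(ValueError, match="mismatch"):
            drive_change(small_net, other, np.ones((2, 4)), 0, {"a": [0]})


class TestWeightCategories:
    def _toy(self, overlap, seed=0):
        patches = generate_patches(PatchesSpec(overlap=overlap, seed=seed))
        rng = np.random.default_rng(seed)
        net = DenseNet([100, 4], [rng.normal(size=(4, 100))])
        return net, patches

    def test_zero_overlap_has_empty_overlapping_category(self):
        net, patches = self._toy(0)
        hist = weight_category_histograms(net, patches)
        assert hist[("overlapping", "t1")].size == 0
        assert hist[("overlapping", "t2")].size == 0

    def test_category_counts_follow_geometry(self):
        net, patches = self._toy(14)
        hist = weight_category_histograms(net, patches)
        # 14 shared pixels per image pair, two pairs, two outputs per task
        assert hist[("overlapping", "t1")].size == 28 * 2
        assert hist[("overlapping", "t2")].size == 28 * 2
        n_unique = 2 * (patches.spec.n_on_pixels - 14)
        assert hist[("unique_t1", "t2")].size == n_unique * 2
        total = sum(v.size for v in hist.values())
        n_cat_pixels = len(patches.unique_t1_pixels) + \
            len(patches.unique_t2_pixels) + len(patches.overlapping_pixels)
        assert total == n_cat_pixels * 4

    def test_after_t1_training_t1_weights_have_positive_mean(self):
        from sleepreplay import (TrainingConfig, init_network,
                                 train_to_convergence)

        patches = generate_patches(PatchesSpec(overlap=14, seed=1))
        net = init_network([100, 4], TrainingConfig(init_range=0.02, seed=1))
        train_to_convergence(net, patches.images[:2], patches.labels[:2],
                             learning_rate=0.1)
        hist = weight_category_histograms(net, patches)
        assert hist[("unique_t1", "t1")].mean() > 0
        assert hist[("overlapping", "t1")].mean() > 0
        # connections from T1 pixels to the unseen T2 outputs went negative
        assert hist[("unique_t1", "t2")].mean() < 0

    def test_spec_mismatch_rejected(self):
        net = DenseNet([50, 4])
        patches = generate_patches(PatchesSpec(overlap=5))
        with pytest.raises(ValueError, match="do not match"):
            weight_category_histograms(net, patches)


class TestCosine:
    def test_known_values(self):
        w = [np.array([[1.0, 2.0], [3.0, 4.0]])]
        assert weight_cosine_similarity(w, w) == pytest.approx(1.0)
        assert weight_cosine_similarity(w, [-w[0]]) == pytest.approx(-1.0)

    def test_hand_computed_pair(self):
        a = [np.array([[1.0, 0.0], [0.0, 1.0]])]
        b = [np.array([[1.0, 1.0], [0.0, 0.0]])]
        # dot = 1, |a| = sqrt(2), |b| = sqrt(2)
        assert weight_cosine_similarity(a, b) == pytest.approx(0.5)

    def test_zero_vector_missing(self):
        assert np.isnan(weight_cosine_similarity([np.zeros((2, 2))],
                                                 [np.ones((2, 2))]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weight_cosine_similarity([np.ones((2, 2))], [np.ones((3, 2))])


class TestSparseness:
    def test_bounds_and_direction(self):
        dense = _identity_net(4)
        x_dense = np.ones((5, 4))
        x_sparse = np.tile([1.0, 0, 0, 0], (5, 1))
        assert inactive_fraction(dense, x_dense, 0) == 0.0
        assert inactive_fraction(dense, x_sparse, 0) == 0.75
        assert treves_rolls_sparseness(dense, x_dense, 0) == pytest.approx(1.0)
        assert treves_rolls_sparseness(dense, x_sparse, 0) == pytest.approx(0.25)
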