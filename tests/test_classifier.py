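import numpy as np
import pytest

import coactivity as ca
from coactivity.classifier import eligible_frames, hidden_activity, output_activity

from conftest import random_raster


def separable_toy(n_frames=400, seed=0):
    """Two complementary neurons: neuron 0 mirrors the label, neuron 1 its
    negation, so frames of both classes carry activity and hidden units that
    connect to exactly one of them make the classes linearly separable."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n_frames).astype(np.int8)
    raster = np.zeros((2, n_frames), np.uint8)
    raster[0] = labels
    raster[1] = 1 - labels
    return raster, labels


def test_build_network_basics():
    clf = ca.build_network(10, 1.0, 50, seed=0)
    assert clf.connections.all() and clf.connections.shape == (50, 10)
    assert not clf.weights.any()
    # default hidden layer size
    assert ca.build_network(5, 0.5, seed=0).n_hidden == 1000
    # realized density within the binomial 99% CI of p
    clf = ca.build_network(100, 0.3, 1000, seed=1)
    n = 1000 * 100
    density = clf.connections.mean()
    assert abs(density - 0.3) < 2.576 * np.sqrt(0.3 * 0.7 / n)
    with pytest.raises(ValueError):
        ca.build_network(10, 1.5)


def test_training_separates_toy_and_loss_decreases():
    raster, labels = separable_toy()
    part = ca.FramePartition(np.arange(0, 200), np.arange(200, 400))
    clf = ca.build_network(2, 0.5, 100, seed=3, min_active_neurons=0, n_passes=200)
    trained = ca.train(clf, raster, labels, part, seed=4)
    assert ca.evaluate(trained, raster, labels, part.test, seed=5) == 1.0
    assert trained.loss_per_pass[-1] < trained.loss_per_pass[0]
    # connections never change during training
    assert np.array_equal(trained.connections, clf.connections)


def test_min_active_filter_excludes_sparse_frames():
    raster = np.zeros((5, 10), np.uint8)
    raster[:4, 0] = 1   # 4 active
    raster[:2, 1] = 1   # 2 active -> excluded at the default threshold
    labels = np.ones(10, np.int8)
    labels[5:] = -1     # unlabeled frames excluded too
    frames = eligible_frames(raster, labels, min_active_neurons=3)
    assert list(frames) == [0]


def test_evaluate_matches_closed_form_oracle(trained_corr_clf, corr_dataset):
    """The trained network is a logistic model: decisions must agree exactly
    with an independent sigmoid computation from (connections, weights)."""
    _, raster, labels, _, part = corr_dataset
    clf = trained_corr_clf
    frames = eligible_frames(raster, labels, part.test, clf.min_active_neurons)[:500]
    y = output_activity(clf, raster, frames)
    # oracle: per-frame double loop over units and neurons
    for f_i, f in enumerate(frames[:40]):
        logit = 0.0
        for u in range(clf.n_hidden):
            x_u = int(clf.connections[u] @ raster[:, f])
            logit += clf.weights[u] * x_u
        y_oracle = 1.0 / (1.0 + np.exp(-logit))
        assert (y[f_i] > 0.5) == (y_oracle > 0.5)
    # vectorized oracle over all 500 frames
    logits = (raster[:, frames].T.astype(float) @ clf.connections.T.astype(float)) @ clf.weights
    assert np.array_equal(y > 0.5, logits > 0)


def test_untrained_or_disconnected_network_is_at_chance():
    """p_connect = 0 leaves no information path; accuracy is coin-flip 0.5."""
    raster, labels = separable_toy(n_frames=2000, seed=6)
    part = ca.FramePartition(np.arange(0, 1000), np.arange(1000, 2000))
    clf = ca.build_network(2, 0.0, 100, seed=7, min_active_neurons=0)
    trained = ca.train(clf, raster, labels, part, seed=8)
    acc = ca.evaluate(trained, raster, labels, part.test, seed=9)
    assert abs(acc - 0.5) < 2.576 * np.sqrt(0.25 / 1000)


def test_label_permutation_null_is_at_chance(corr_dataset):
    _, raster, labels, _, part = corr_dataset
    rng = np.random.default_rng(21)
    permuted = labels.copy()
    rng.shuffle(permuted)
    clf = ca.build_network(100, 0.3, 300, rng, n_passes=100)
    trained = ca.train(clf, raster, permuted, part, rng)
    acc = ca.evaluate(trained, raster, permuted, part.test, rng)
    assert abs(acc - 0.5) < 0.05


def test_sweep_is_reproducible_and_chance_at_zero_p():
    raster, labels = separable_toy(n_frames=1200, seed=10)
    part = ca.FramePartition(np.arange(0, 600), np.arange(600, 1200))
    kwargs = dict(runs=2, partition=part, n_hidden=50, seed=11,
                  min_active_neurons=0, n_passes=50)
    r1 = ca.sweep_connection_probability(raster, labels, [0.0, 0.5], **kwargs)
    r2 = ca.sweep_connection_probability(raster, labels, [0.0, 0.5], **kwargs)
    for p in (0.0, 0.5):
        assert np.array_equal(r1[p]["accuracies"], r2[p]["accuracies"])
    assert abs(r1[0.0]["mean"] - 0.5) < 0.06
    assert r1[0.5]["mean"] > 0.9


def test_linear_baselines_on_separable_and_degenerate_data():
    raster, labels = separable_toy(seed=12)
    part = ca.FramePartition(np.arange(0, 200), np.arange(200, 400))
    for method in ("logistic", "linear-svm"):
        acc = ca.linear_baseline(raster, labels, part, method, min_active_neurons=0)
        assert acc == 1.0
    single = np.ones(400, np.int8)
    with pytest.raises(ValueError):
        ca.linear_baseline(raster, single, part, "logistic", min_active_neurons=0)


def test_alternating_blocks_partition():
    part = ca.alternating_blocks(2000, 500)
    assert part.train.size == part.test.size == 1000
    assert (part.train < 500).sum() == 500 and (part.test[:500] >= 500).all()
    with pytest.raises(ValueError):
        ca.FramePartition(np.array([1, 2]), np.array([2, 3]))


def test_interaction_labels_from_annotation():
    ann = ca.EpochAnnotation(
        [ca.Epoch("homecage", 0, 100), ca.Epoch("social", 100, 200)],
        [ca.Bout(110, 130)],
    )
    labels = ca.classifier.interaction_labels(ann, 200)
    assert (labels[110:130] == 0).all()
    assert (labels[10:30] == 1).all()
    assert (labels == -1).sum() == 200 - 40
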