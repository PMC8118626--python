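import numpy as np
import pytest

import coactivity as ca
from coactivity.raster import Epoch, EpochAnnotation, blocks_from_raster
from coactivity.surrogates import SharcParams, correlation_matrix

from conftest import random_raster


def block_counts(raster, n_neurons):
    return np.bincount(blocks_from_raster(raster)[0], minlength=n_neurons)


def test_swap_shuffle_conserves_marginals_exactly():
    """Per-frame active counts and per-neuron block counts are invariant."""
    for seed in range(5):
        r = random_raster(30, 2000, 0.04, seed)
        s = ca.swap_shuffle(r, seed=seed + 100)
        assert np.array_equal(r.sum(axis=0), s.sum(axis=0))
        assert np.array_equal(block_counts(r, 30), block_counts(s, 30))


def test_swap_shuffle_single_block_keeps_column_sums():
    r = np.zeros((4, 50), np.uint8)
    r[2, 10:15] = 1
    s = ca.swap_shuffle(r, seed=0)
    assert np.array_equal(r.sum(axis=0), s.sum(axis=0))


def test_swap_shuffle_per_epoch_equals_independent_subshuffles():
    """Per-epoch scope is exactly the concatenation of independently
    shuffled sub-rasters (no cross-epoch leakage)."""
    r = random_raster(20, 600, 0.05, 3)
    ann = EpochAnnotation([Epoch("a", 0, 200), Epoch("b", 200, 600)])
    got = ca.swap_shuffle(r, "epoch", ann, seed=42)
    rng = np.random.default_rng(42)
    manual = np.concatenate(
        [ca.swap_shuffle(r[:, sl], "whole", None, rng) for _, sl in ann.epoch_slices()],
        axis=1,
    )
    assert np.array_equal(got, manual)
    # each epoch's column sums preserved independently
    for _, sl in ann.epoch_slices():
        assert np.array_equal(r[:, sl].sum(axis=0), got[:, sl].sum(axis=0))


def test_swap_preserves_activity_levels_with_heterogeneous_blocks():
    """Activity-level similarity stays high across neurons with widely
    different event rates and block durations (block counts are conserved,
    so per-neuron activity levels survive the shuffle)."""
    rng = np.random.default_rng(5)
    r = np.zeros((30, 4000), np.uint8)
    for n in range(30):
        gap_scale = 10 + 15 * n  # slow neurons have few blocks
        t = int(rng.integers(0, 50))
        while t < 3900:
            ln = int(rng.integers(1, 8))
            r[n, t : t + ln] = 1
            t += ln + int(rng.integers(5, gap_scale))
    s = ca.swap_shuffle(r, seed=6)
    assert ca.activity_similarity(r, s) > 0.9


def test_sharc_respects_activity_budgets():
    """Every per-neuron block-count change lies in [-max_net_loss, +max_net_gain]."""
    r = random_raster(25, 1500, 0.05, 7)
    sur, diag = ca.sharc_shuffle(r, seed=8, return_diagnostics=True)
    assert np.array_equal(r.sum(axis=0), sur.sum(axis=0))
    d = block_counts(sur, 25) - block_counts(r, 25)
    assert d.min() >= -3 and d.max() <= 4
    assert np.array_equal(d, diag.net_block_change)


def test_sharc_beats_swap_on_planted_assembly():
    cfg = ca.SyntheticStateConfig(n_neurons=60, n_frames=3000, n_assemblies=1, seed=9)
    r = ca.insert_assemblies(ca.gen_state_a(cfg), cfg)
    target = correlation_matrix(r)
    wins = 0
    for seed in range(4):
        sh = ca.sharc_shuffle(r, seed=seed)
        sw = ca.swap_shuffle(r, seed=seed + 50)
        sim_sh = ca.correlation_similarity(correlation_matrix(sh), target)
        sim_sw = ca.correlation_similarity(correlation_matrix(sw), target)
        wins += sim_sh > sim_sw
    assert wins >= 3


def test_sharc_tracks_target_even_without_planted_structure():
    """On an unstructured raster SHARC still approaches its target matrix —
    including the target's sampling correlations — while swap shuffling
    leaves correlations unrelated to the source's."""
    r = random_raster(40, 3000, 0.05, 10)
    target = correlation_matrix(r)
    sim_sh = ca.correlation_similarity(correlation_matrix(ca.sharc_shuffle(r, seed=1)), target)
    sim_sw = ca.correlation_similarity(correlation_matrix(ca.swap_shuffle(r, seed=2)), target)
    assert abs(sim_sw) < 0.15
    assert sim_sh > sim_sw
    # the surrogate carries no structure shared with an unrelated raster
    other = correlation_matrix(random_raster(40, 3000, 0.05, 99))
    assert abs(ca.correlation_similarity(
        correlation_matrix(ca.sharc_shuffle(r, seed=3)), other)) < 0.15


def test_sharc_per_epoch_scope_preserves_epoch_column_sums():
    r = random_raster(20, 800, 0.05, 11)
    ann = EpochAnnotation([Epoch("a", 0, 300), Epoch("b", 300, 800)])
    sur = ca.sharc_shuffle(r, scope="epoch", epochs=ann, seed=12,
                           params=SharcParams(reassignment_passes=2))
    for _, sl in ann.epoch_slices():
        assert np.array_equal(r[:, sl].sum(axis=0), sur[:, sl].sum(axis=0))


def test_correlation_similarity_properties():
    r1 = random_raster(20, 1000, 0.1, 13)
    m1 = correlation_matrix(r1)
    assert ca.correlation_similarity(m1, m1) == pytest.approx(1.0)
    # matrices of two independent rasters are unrelated
    m2 = correlation_matrix(random_raster(20, 1000, 0.1, 14))
    assert abs(ca.correlation_similarity(m1, m2)) < 0.15
    with pytest.raises(ValueError):
        ca.correlation_similarity(np.full((2, 2), np.nan), np.full((2, 2), np.nan))


def test_swap_decorrelates_but_keeps_activity():
    cfg = ca.SyntheticStateConfig(n_neurons=50, n_frames=3000, n_assemblies=2, seed=15)
    r = ca.insert_assemblies(ca.gen_state_a(cfg), cfg)
    s = ca.swap_shuffle(r, seed=16)
    assert abs(ca.correlation_similarity(correlation_matrix(s), correlation_matrix(r))) < 0.15
    assert ca.activity_similarity(r, s) > 0.8


def test_circular_percentile_extremes_and_errors():
    F = 4000
    cond = np.arange(500, 1500)
    matched = np.arange(2000, 3000)
    row = np.zeros(F, np.uint8)
    row[cond] = 1
    res = ca.circular_null_percentile(row, cond, matched, n_shuffles=2000, seed=0)
    assert res.percentiles["condition"] == 100.0
    assert res.labels["condition"] == "positive"
    zero = ca.circular_null_percentile(np.zeros(F, np.uint8), cond, matched, seed=0)
    assert np.isnan(zero.percentiles["condition"])
    assert zero.labels["condition"] == "unmodulated"
    with pytest.raises(ValueError):
        ca.circular_null_percentile(row, cond, matched[:10], seed=0)
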