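"""Single-hidden-layer random-projection decoder and linear baselines.

The decoder has 1,000 hidden units.  Each hidden unit sums the activity of a
fixed random subset of input neurons (each connection drawn Bernoulli with
probability ``p_connect``); a single logistic output unit reads the hidden
layer through trainable weights:

    y = 1 / (1 + exp(-sum_i w_i x_i)),    dw_i = eps * y(1-y)(z-y) * x_i

with 500 passes through the training frames in a fresh random order per
pass and weights initialized to zero.  The default step size eps = 0.002 is
chosen for stable symmetry breaking with 1000 count-valued hidden features:
much larger steps saturate the output through the hidden layer's shared
common mode within a single pass (y(1-y) then gates all further plasticity
and the network is frozen at chance), while much smaller steps cannot
escape the flat point at w = 0 within the training budget.  Each hidden
unit is effectively one candidate neuronal ensemble; the delta rule finds
groups of neurons whose *summed* activity tracks the label, which is what
lets this decoder separate conditions that differ only in coactivity, where
optimal linear classifiers on raw neuron activity are at chance.

Frames with fewer than 3 active neurons are excluded from both training and
testing.  Labels use z = 0 for the social condition (or State B) and z = 1
for home cage (or State A); an output y < 0.5 therefore decodes "social".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from . import _kernels
from .raster import as_raster
from .synthetic import as_rng


@dataclass
class HiddenLayerClassifier:
    connections: np.ndarray       # (n_hidden, n_neurons) binary, fixed
    weights: np.ndarray           # (n_hidden,) trainable
    p_connect: float
    learning_rate: float = 0.002
    n_passes: int = 500
    min_active_neurons: int = 3
    seed: int | None = None
    loss_per_pass: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_hidden(self) -> int:
        return self.connections.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.connections.shape[1]


@dataclass
class FramePartition:
    """Disjoint train/test frame sets over one session timeline."""

    train: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=np.int64)
        self.test = np.asarray(self.test, dtype=np.int64)
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test frame sets must be disjoint")


def alternating_blocks(n_frames: int, block: int = 500) -> FramePartition:
    """Alternating fixed-size blocks: even blocks train, odd blocks test.

    The blocks are laid out on the unfiltered session timeline starting at
    frame 0; eligibility filters are applied afterwards.
    """
    idx = np.arange(n_frames)
    block_id = idx // block
    return FramePartition(train=idx[block_id % 2 == 0], test=idx[block_id % 2 == 1])


def build_network(
    n_neurons: int,
    p_connect: float,
    n_hidden: int = 1000,
    seed: int | None | np.random.Generator = None,
    **hyper,
) -> HiddenLayerClassifier:
    """Fresh classifier: Bernoulli(p_connect) connections, zero weights."""
    if not 0.0 <= p_connect <= 1.0:
        raise ValueError("p_connect must lie in [0, 1]")
    rng = as_rng(seed)
    connections = (rng.random((n_hidden, n_neurons)) < p_connect).astype(np.uint8)
    return HiddenLayerClassifier(
        connections=connections,
        weights=np.zeros(n_hidden, dtype=np.float64),
        p_connect=p_connect,
        seed=seed if isinstance(seed, int) else None,
        **hyper,
    )


def eligible_frames(
    raster: np.ndarray,
    labels: np.ndarray,
    frames: np.ndarray | None = None,
    min_active_neurons: int = 3,
) -> np.ndarray:
    """Frames usable for training/testing: labeled, and >= min active neurons.

    ``labels`` holds 0/1 per frame with -1 marking unlabeled frames (outside
    interaction bouts and their matched home-cage intervals).
    """
    raster = as_raster(raster)
    labels = np.asarray(labels)
    if labels.shape[0] != raster.shape[1]:
        raise ValueError("labels must have one entry per frame")
    if frames is None:
        frames = np.arange(raster.shape[1])
    frames = np.asarray(frames, dtype=np.int64)
    counts = raster[:, frames].sum(axis=0)
    keep = (labels[frames] >= 0) & (counts >= min_active_neurons)
    return frames[keep]


def hidden_activity(clf: HiddenLayerClassifier, raster: np.ndarray,
                    frames: np.ndarray) -> np.ndarray:
    """Summed input per hidden unit per frame, shape (n_frames, n_hidden)."""
    cols = as_raster(raster)[:, frames].astype(np.float32)
    return (clf.connections.astype(np.float32) @ cols).T.copy()


def train(
    clf: HiddenLayerClassifier,
    raster: np.ndarray,
    labels: np.ndarray,
    partition: FramePartition | None = None,
    seed: int | None | np.random.Generator = None,
) -> HiddenLayerClassifier:
    """Delta-rule training of the output weights (connections stay fixed).

    Returns a copy of ``clf`` with trained weights and the per-pass logistic
    loss trajectory attached.
    """
    rng = as_rng(seed if seed is not None else clf.seed)
    frames = partition.train if partition is not None else None
    frames = eligible_frames(raster, labels, frames, clf.min_active_neurons)
    if frames.size == 0:
        raise ValueError("no eligible training frames")
    X = hidden_activity(clf, raster, frames)
    z = np.asarray(labels, dtype=np.float64)[frames]
    orders = np.empty((clf.n_passes, frames.size), dtype=np.int64)
    for p in range(clf.n_passes):
        orders[p] = rng.permutation(frames.size)
    w = np.zeros(clf.n_hidden, dtype=np.float64)
    losses = _kernels.delta_rule_train(X.astype(np.float64), z, orders, w, clf.learning_rate)
    out = replace(clf, weights=w)
    out.loss_per_pass = losses
    return out


def output_activity(clf: HiddenLayerClassifier, raster: np.ndarray,
                    frames: np.ndarray) -> np.ndarray:
    """Logistic output y per frame."""
    x = hidden_activity(clf, raster, frames).astype(np.float64)
    return 1.0 / (1.0 + np.exp(-(x @ clf.weights)))


def evaluate(
    clf: HiddenLayerClassifier,
    raster: np.ndarray,
    labels: np.ndarray,
    frames: np.ndarray | None = None,
    seed: int | None | np.random.Generator = None,
) -> float:
    """Fraction of eligible frames where (y > 0.5) matches the label.

    Outputs exactly at 0.5 (e.g. from untrained zero weights) are resolved by
    a seeded coin flip.
    """
    rng = as_rng(seed)
    frames = eligible_frames(raster, labels, frames, clf.min_active_neurons)
    if frames.size == 0:
        raise ValueError("no eligible evaluation frames")
    y = output_activity(clf, raster, frames)
    pred = (y > 0.5).astype(np.int8)
    ties = y == 0.5
    if ties.any():
        pred[ties] = rng.integers(0, 2, size=int(ties.sum()))
    z = np.asarray(labels)[frames]
    return float(np.mean(pred == z))


def sweep_connection_probability(
    raster: np.ndarray,
    labels: np.ndarray,
    p_list,
    runs: int = 25,
    partition: FramePartition | None = None,
    n_hidden: int = 1000,
    seed: int | None | np.random.Generator = None,
    **hyper,
) -> dict[float, dict[str, float | np.ndarray]]:
    """Mean +/- sem test accuracy per connection probability.

    Each run rebuilds the connection matrix with a fresh seed; downstream
    ensemble analyses default to the best p (0.3 on the in vivo data).
    """
    raster = as_raster(raster)
    rng = as_rng(seed)
    if partition is None:
        partition = alternating_blocks(raster.shape[1])
    results: dict[float, dict[str, float | np.ndarray]] = {}
    for p in p_list:
        accs = np.empty(runs)
        for r in range(runs):
            clf = build_network(raster.shape[0], p, n_hidden, rng, **hyper)
            clf = train(clf, raster, labels, partition, rng)
            accs[r] = evaluate(clf, raster, labels, partition.test, rng)
        results[float(p)] = {
            "mean": float(accs.mean()),
            "sem": float(accs.std(ddof=1) / np.sqrt(runs)) if runs > 1 else 0.0,
            "accuracies": accs,
        }
    return results


def linear_baseline(
    raster: np.ndarray,
    labels: np.ndarray,
    partition: FramePartition,
    method: str = "logistic",
    min_active_neurons: int = 3,
    seed: int | None = None,
) -> float:
    """Accuracy of an optimal linear classifier on raw per-frame activity.

    Uses the same frame partition and eligibility filters as the network.
    ``method`` is "logistic" or "linear-svm".
    """
    raster = as_raster(raster)
    tr = eligible_frames(raster, labels, partition.train, min_active_neurons)
    te = eligible_frames(raster, labels, partition.test, min_active_neurons)
    if tr.size == 0 or te.size == 0:
        raise ValueError("no eligible frames for the linear baseline")
    z = np.asarray(labels)
    if np.unique(z[tr]).size < 2:
        raise ValueError("training set is single-class; cannot fit a linear baseline")
    Xtr = raster[:, tr].T.astype(np.float64)
    Xte = raster[:, te].T.astype(np.float64)
    if method == "logistic":
        model = LogisticRegression(max_iter=2000, random_state=seed)
    elif method == "linear-svm":
        model = LinearSVC(random_state=seed)
    else:
        raise ValueError(f"unknown linear baseline {method!r}")
    model.fit(Xtr, z[tr])
    return float(np.mean(model.predict(Xte) == z[te]))


def interaction_labels(ann, n_frames: int, social: str = "social",
                       homecage: str = "homecage") -> np.ndarray:
    """Frame labels from an epoch annotation: z=0 on interaction bouts, z=1 on
    temporally matched home-cage frames, -1 elsewhere."""
    soc, hc, _ = ann.matched_frames(social, homecage)
    labels = np.full(n_frames, -1, dtype=np.int8)
    labels[soc] = 0
    labels[hc] = 1
    return labels
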