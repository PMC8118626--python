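"""Interpretation of trained classifiers: unit groups and neuron ensembles.

Hidden units with strongly negative output weights bias the decision toward
the social condition ("social units"); strongly positive units bias toward
home cage.  The neurons most likely to feed each unit group form the
classifier-derived ensembles whose condition-wise activity and pairwise
correlations dissociate rate coding from correlation coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classifier import HiddenLayerClassifier
from .raster import as_raster

log = logging.getLogger(__name__)


@dataclass
class UnitGroups:
    social_units: np.ndarray     # most negative output weights
    homecage_units: np.ndarray   # most positive output weights
    neutral_units: np.ndarray    # |w| nearest zero
    degenerate: bool = False     # all-zero (or tied) weight vector


@dataclass
class NeuronEnsembles:
    social_ensemble: np.ndarray
    homecage_ensemble: np.ndarray
    neutral_ensemble: np.ndarray


def extract_unit_groups(
    clf: HiddenLayerClassifier, group_size: int = 25, neutral_size: int = 25
) -> UnitGroups:
    """Select social / home-cage / neutral hidden-unit groups from the weights.

    Units are ordered by ascending output weight; ties break by unit index.
    Requires enough hidden units for three disjoint groups.
    """
    w = clf.weights
    if clf.n_hidden < group_size * 2 + neutral_size:
        raise ValueError("too few hidden units to extract disjoint groups")
    order = np.argsort(w, kind="stable")
    social = order[:group_size]
    homecage = order[-group_size:]
    taken = set(social.tolist()) | set(homecage.tolist())
    by_mag = np.argsort(np.abs(w), kind="stable")
    neutral = np.array([u for u in by_mag if u not in taken][:neutral_size])
    degenerate = bool(np.all(w == w[0]))
    if degenerate:
        log.warning("extract_unit_groups: weight vector is constant; groups are arbitrary")
    return UnitGroups(social, homecage, neutral, degenerate)


def input_similarity(
    clf: HiddenLayerClassifier, groups: UnitGroups
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Pairwise correlations between the units' binary input vectors.

    Returns the full unit x unit similarity matrix (NaN rows for units with
    degenerate input vectors, which are logged and excluded) and, per unit,
    its mean similarity to each group with self-pairs excluded.
    """
    conn = clf.connections.astype(np.float64)
    var = conn.var(axis=1)
    bad = var == 0
    if bad.any():
        log.info("input_similarity: excluding %d units with constant input vectors",
                 int(bad.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.corrcoef(conn)
    sim[bad, :] = np.nan
    sim[:, bad] = np.nan
    means: dict[str, np.ndarray] = {}
    for name, units in (
        ("social", groups.social_units),
        ("homecage", groups.homecage_units),
        ("neutral", groups.neutral_units),
    ):
        sub = sim[:, units].copy()
        for col, u in enumerate(units):  # exclude self-pairs
            sub[u, col] = np.nan
        with np.errstate(invalid="ignore"):
            means[name] = np.nanmean(sub, axis=1)
    return sim, means


def define_ensembles(
    clf: HiddenLayerClassifier, groups: UnitGroups, fraction: float = 0.2
) -> NeuronEnsembles:
    """Top ``fraction`` of neurons by connection count into each unit group.

    Count ties break by neuron index; each ensemble has exactly
    ``ceil(fraction * n_neurons)`` members.
    """
    n = clf.n_neurons
    size = int(np.ceil(fraction * n))
    out = {}
    for name, units in (
        ("social_ensemble", groups.social_units),
        ("homecage_ensemble", groups.homecage_units),
        ("neutral_ensemble", groups.neutral_units),
    ):
        counts = clf.connections[units].sum(axis=0)
        order = np.lexsort((np.arange(n), -counts))
        out[name] = np.sort(order[:size])
    return NeuronEnsembles(**out)


def mean_pairwise_correlation(raster: np.ndarray, neurons: np.ndarray,
                              frames: np.ndarray) -> float:
    """Mean off-diagonal Pearson correlation within a neuron set over frames.

    Pairs involving zero-variance rows are excluded; NaN if none are valid.
    """
    sub = as_raster(raster)[np.ix_(np.asarray(neurons), np.asarray(frames))]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 neurons for pairwise correlations")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(sub.astype(np.float64))
    iu = np.triu_indices(sub.shape[0], k=1)
    vals = c[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def ensemble_condition_stats(
    raster: np.ndarray,
    condition_frames: dict[str, np.ndarray],
    ensembles: NeuronEnsembles,
) -> dict[str, dict[str, dict[str, float]]]:
    """Mean activity and mean pairwise correlation per ensemble per condition.

    ``condition_frames`` maps condition name to a frame set; sets should be
    matched in size so correlations are comparable across conditions.
    """
    raster = as_raster(raster)
    sizes = {len(f) for f in condition_frames.values()}
    if len(sizes) > 1:
        log.warning("ensemble_condition_stats: condition frame sets differ in size %s", sizes)
    out: dict[str, dict[str, dict[str, float]]] = {}
    for ens_name in ("social_ensemble", "homecage_ensemble", "neutral_ensemble"):
        members = getattr(ensembles, ens_name)
        out[ens_name] = {}
        for cond, frames in condition_frames.items():
            frames = np.asarray(frames, dtype=np.int64)
            activity = float(raster[np.ix_(members, frames)].mean())
            corr = mean_pairwise_correlation(raster, members, frames)
            out[ens_name][cond] = {"mean_activity": activity, "mean_correlation": corr}
    return out


def paired_rank_test(a, b) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired per-dataset statistics."""
    res = stats.wilcoxon(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return float(res.statistic), float(res.pvalue)
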