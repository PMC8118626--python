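"""Null and structured surrogate rasters, plus similarity diagnostics.

Three surrogate families are provided:

* **swap shuffle** — block timing is kept, block neuron identities are
  permuted by random pairwise swaps.  Per-frame population counts and
  per-neuron block counts are preserved exactly; all relationships between
  specific neurons and behavior (and all pairwise correlations) are
  destroyed.
* **SHARC** (SHuffling Activity to Re-arrange Correlations) — block
  reassignment is guided toward a target pairwise correlation matrix under
  per-neuron activity budgets, so the surrogate keeps both activity levels
  and correlation structure.
* **circular shuffle** — one neuron's row is rotated in time to build a
  per-neuron null for condition-specific activity levels.

Either family can be applied to the whole session or within each behavioral
epoch independently ("per-epoch" scope), which preserves behavior-specific
activity levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _kernels
from .raster import EpochAnnotation, as_raster, blocks_from_raster
from .synthetic import as_rng

log = logging.getLogger(__name__)


@dataclass
class SharcParams:
    """Activity budgets and pass count for SHARC reassignment."""

    max_net_gain: int = 4
    max_net_loss: int = 3
    reassignment_passes: int = 5
    fallback_temperature: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.reassignment_passes < 1:
            raise ValueError("reassignment_passes must be >= 1")


@dataclass
class SharcDiagnostics:
    """Ledger audit of one SHARC run."""

    net_block_change: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    n_fallback: int = 0
    n_kept: int = 0
    n_donor_blocked: int = 0


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def swap_shuffle(
    raster: np.ndarray,
    scope: str = "whole",
    epochs: EpochAnnotation | None = None,
    seed: int | None | np.random.Generator = None,
    max_retries: int = 100,
) -> np.ndarray:
    """Swap-shuffled surrogate raster.

    With ``scope="epoch"`` each epoch's sub-raster is shuffled independently
    and the results concatenated (no blocks cross epoch boundaries).
    """
    raster = as_raster(raster)
    rng = as_rng(seed)
    if scope == "epoch":
        if epochs is None:
            raise ValueError("per-epoch scope requires an EpochAnnotation")
        parts = [
            swap_shuffle(raster[:, sl], "whole", None, rng, max_retries)
            for _, sl in epochs.epoch_slices()
        ]
        return np.concatenate(parts, axis=1)
    if scope != "whole":
        raise ValueError(f"unknown scope {scope!r}")

    neurons, starts, lengths = blocks_from_raster(raster)
    occ = raster.copy()
    n_skipped = _kernels.swap_shuffle_blocks(
        neurons, starts, lengths, occ, _kernel_seed(rng), max_retries
    )
    if n_skipped:
        log.info("swap_shuffle: %d blocks unswapped after retries", n_skipped)
    return occ


def correlation_matrix(raster: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between binary neuron rows.

    Rows with zero variance produce NaN entries (excluded by the similarity
    metrics below).
    """
    raster = as_raster(raster)
    x = raster.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    return c


def sharc_shuffle(
    raster: np.ndarray,
    target: np.ndarray | None = None,
    params: SharcParams | None = None,
    scope: str = "whole",
    epochs: EpochAnnotation | None = None,
    seed: int | None | np.random.Generator = None,
    return_diagnostics: bool = False,
):
    """SHARC surrogate: swap shuffle, then correlation-guided reassignment.

    ``target`` defaults to the correlation matrix of the source raster (per
    epoch, under per-epoch scope).  Per-frame column sums are preserved
    exactly; per-neuron block counts change by at most
    ``[-max_net_loss, +max_net_gain]``.
    """
    raster = as_raster(raster)
    params = params or SharcParams()
    rng = as_rng(seed if seed is not None else params.seed)
    if scope == "epoch":
        if epochs is None:
            raise ValueError("per-epoch scope requires an EpochAnnotation")
        parts = []
        diags = []
        for _, sl in epochs.epoch_slices():
            sub_target = None if target is None else target
            out = sharc_shuffle(
                raster[:, sl], sub_target, params, "whole", None, rng, return_diagnostics
            )
            if return_diagnostics:
                parts.append(out[0])
                diags.append(out[1])
            else:
                parts.append(out)
        result = np.concatenate(parts, axis=1)
        if return_diagnostics:
            agg = SharcDiagnostics(
                net_block_change=np.sum([d.net_block_change for d in diags], axis=0),
                n_fallback=sum(d.n_fallback for d in diags),
                n_kept=sum(d.n_kept for d in diags),
                n_donor_blocked=sum(d.n_donor_blocked for d in diags),
            )
            return result, agg
        return result
    if scope != "whole":
        raise ValueError(f"unknown scope {scope!r}")

    n_neurons, n_frames = raster.shape
    if target is None:
        target = correlation_matrix(raster)
    target = np.nan_to_num(np.asarray(target, dtype=np.float64), nan=0.0)
    if target.shape != (n_neurons, n_neurons):
        raise ValueError("target correlation matrix has wrong shape")

    # initial swap shuffle guarantees every block moves at least once
    occ = swap_shuffle(raster, "whole", None, rng)
    neurons, starts, lengths = blocks_from_raster(occ)
    # block-count ledger is measured against the *source* raster's counts
    src_counts = np.bincount(blocks_from_raster(raster)[0], minlength=n_neurons)
    occ = occ.copy()
    bmap = np.full((n_neurons, n_frames), -1, dtype=np.int64)
    for b, (n, s, ln) in enumerate(zip(neurons, starts, lengths)):
        bmap[n, s : s + ln] = b
    row_sums = occ.sum(axis=1).astype(np.int64)
    overlap = (occ.astype(np.int64) @ occ.T.astype(np.int64))
    np.fill_diagonal(overlap, row_sums)
    net = (np.bincount(neurons, minlength=n_neurons) - src_counts).astype(np.int64)

    n_fallback, n_kept, n_blocked = _kernels.sharc_passes(
        neurons, starts, lengths, occ, bmap, row_sums, overlap, net,
        target, params.reassignment_passes, params.max_net_gain,
        params.max_net_loss, params.fallback_temperature, _kernel_seed(rng),
    )
    if n_kept:
        log.info("sharc_shuffle: %d unassignable blocks kept their neuron", n_kept)
    if return_diagnostics:
        return occ, SharcDiagnostics(net.copy(), int(n_fallback), int(n_kept), int(n_blocked))
    return occ


# ---------------------------------------------------------------------------
# Similarity diagnostics
# ---------------------------------------------------------------------------


def correlation_similarity(m1: np.ndarray, m2: np.ndarray) -> float:
    """Pearson correlation of the vectorized off-diagonal upper triangles.

    Pairs with undefined correlations (NaN from zero-variance rows) are
    excluded from both vectors; fewer than 3 valid pairs is an error.
    """
    m1 = np.asarray(m1, dtype=np.float64)
    m2 = np.asarray(m2, dtype=np.float64)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ValueError("correlation matrices must be square and of equal shape")
    iu = np.triu_indices(m1.shape[0], k=1)
    v1, v2 = m1[iu], m2[iu]
    valid = np.isfinite(v1) & np.isfinite(v2)
    if valid.sum() < 3:
        raise ValueError("fewer than 3 valid correlation pairs")
    return float(stats.pearsonr(v1[valid], v2[valid])[0])


def activity_similarity(r1: np.ndarray, r2: np.ndarray) -> float:
    """Pearson correlation of the per-neuron activity-level vectors."""
    r1, r2 = as_raster(r1), as_raster(r2)
    if r1.shape[0] != r2.shape[0]:
        raise ValueError("rasters must have the same number of neurons")
    a1 = r1.mean(axis=1)
    a2 = r2.mean(axis=1)
    if a1.std() == 0 or a2.std() == 0:
        raise ValueError("activity-level vector has zero variance")
    return float(stats.pearsonr(a1, a2)[0])


# ---------------------------------------------------------------------------
# Circular-shuffle modulation percentiles
# ---------------------------------------------------------------------------


@dataclass
class ModulationResult:
    """Per-condition activity percentiles against a circular-shift null."""

    percentiles: dict[str, float]
    labels: dict[str, str]  # "positive" | "negative" | "unmodulated"


def _rotation_counts(row: np.ndarray, indicator: np.ndarray) -> np.ndarray:
    """Active-frame count inside ``indicator`` for every circular shift of ``row``."""
    fr = np.fft.rfft(row.astype(np.float64))
    fi = np.fft.rfft(indicator.astype(np.float64))
    c = np.fft.irfft(np.conj(fr) * fi, n=row.size)
    return np.rint(c).astype(np.int64)


def circular_null_percentile(
    row: np.ndarray,
    condition_frames: np.ndarray,
    matched_frames: np.ndarray,
    n_shuffles: int = 10_000,
    seed: int | None | np.random.Generator = None,
    labels: tuple[str, str] = ("condition", "matched"),
    upper: float = 90.0,
    lower: float = 10.0,
) -> ModulationResult:
    """Percentile of one neuron's condition activity within a circular null.

    The null rotates the neuron's full-session row by random nonzero shifts
    and re-extracts the condition frames; the observed percent-time-active is
    ranked against the null (mid-rank convention).  A percentile above
    ``upper`` labels the neuron positively modulated, below ``lower``
    negatively modulated.  An all-zero row gives NaN percentiles and the
    label "unmodulated".
    """
    row = np.asarray(row).ravel().astype(np.uint8)
    condition_frames = np.asarray(condition_frames, dtype=np.int64)
    matched_frames = np.asarray(matched_frames, dtype=np.int64)
    if condition_frames.size != matched_frames.size:
        raise ValueError("condition and matched frame sets must have equal size")
    rng = as_rng(seed)
    result = ModulationResult(percentiles={}, labels={})
    shifts = rng.integers(1, row.size, size=n_shuffles)
    for name, frames in zip(labels, (condition_frames, matched_frames)):
        if row.sum() == 0:
            result.percentiles[name] = float("nan")
            result.labels[name] = "unmodulated"
            continue
        indicator = np.zeros(row.size, dtype=np.uint8)
        indicator[frames] = 1
        counts = _rotation_counts(row, indicator)
        observed = counts[0]
        null = counts[shifts]
        pct = 100.0 * (np.sum(null < observed) + 0.5 * np.sum(null == observed)) / n_shuffles
        result.percentiles[name] = float(pct)
        if pct > upper:
            result.labels[name] = "positive"
        elif pct < lower:
            result.labels[name] = "negative"
        else:
            result.labels[name] = "unmodulated"
    return result
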