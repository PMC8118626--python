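"""Core containers: binary event rasters, activity blocks, and epoch annotations.

An event raster is a ``(n_neurons, n_frames)`` binary matrix in which a 1
means the neuron has an ongoing calcium event in that frame.  The raster is
equivalent to a collection of *blocks of activity*: maximal runs of
consecutive active frames for one neuron.  Blocks are the unit moved by the
shuffling procedures in :mod:`coactivity.surrogates`.

Frames are 0-based and all intervals are half-open ``[start, end)``.
Acquisition is assumed to run at 20 Hz unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Default acquisition rate; every frame <-> second conversion uses this.
FRAME_RATE_HZ = 20.0


def as_raster(a: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to a binary uint8 raster."""
    a = np.asarray(a)
    if a.ndim != 2:
        raise ValueError(f"raster must be 2-D (neurons x frames), got shape {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("raster entries must be 0 or 1")
    return a.astype(np.uint8, copy=False)


@dataclass(frozen=True)
class ActivityBlock:
    """One maximal run of consecutive active frames for one neuron."""

    neuron: int
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


def blocks_from_raster(raster: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose a raster into blocks.

    Returns
    -------
    neurons, starts, lengths : int64 arrays, one entry per block, ordered by
        neuron then start frame.
    """
    raster = as_raster(raster)
    n_neurons, n_frames = raster.shape
    padded = np.zeros((n_neurons, n_frames + 2), dtype=np.int8)
    padded[:, 1:-1] = raster
    d = np.diff(padded, axis=1)
    rows_on, starts = np.nonzero(d == 1)
    rows_off, ends = np.nonzero(d == -1)
    # diff aligns onsets/offsets row-by-row in order
    if not np.array_equal(rows_on, rows_off):  # pragma: no cover - structural
        raise AssertionError("block decomposition misaligned")
    return (
        rows_on.astype(np.int64),
        starts.astype(np.int64),
        (ends - starts).astype(np.int64),
    )


def raster_from_blocks(
    neurons: np.ndarray,
    starts: np.ndarray,
    lengths: np.ndarray,
    n_neurons: int,
    n_frames: int,
) -> np.ndarray:
    """Rebuild a raster from blocks; blocks of one neuron must not overlap."""
    raster = np.zeros((n_neurons, n_frames), dtype=np.uint8)
    for n, s, ln in zip(neurons, starts, lengths):
        if s < 0 or s + ln > n_frames:
            raise ValueError(f"block ({n}, {s}, {ln}) outside raster bounds")
        if raster[n, s : s + ln].any():
            raise ValueError(f"overlapping blocks for neuron {n} at frame {s}")
        raster[n, s : s + ln] = 1
    return raster


def iter_blocks(raster: np.ndarray) -> Iterable[ActivityBlock]:
    neurons, starts, lengths = blocks_from_raster(raster)
    for n, s, ln in zip(neurons, starts, lengths):
        yield ActivityBlock(int(n), int(s), int(ln))


# ---------------------------------------------------------------------------
# Epoch annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Epoch:
    """A contiguous run of frames sharing one behavioral condition."""

    condition: str
    start: int
    end: int  # exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Bout:
    """One interval of active interaction inside a social epoch."""

    start: int
    end: int  # exclusive


@dataclass
class EpochAnnotation:
    """Per-frame condition labels plus interaction-bout intervals.

    Epochs must tile the session contiguously (no gaps, no overlap).  Bouts
    must each lie inside a single epoch.
    """

    epochs: list[Epoch]
    bouts: list[Bout] = field(default_factory=list)

    def __post_init__(self) -> None:
        eps = sorted(self.epochs, key=lambda e: e.start)
        pos = 0
        for e in eps:
            if e.start != pos or e.end <= e.start:
                raise ValueError(f"epochs must tile frames contiguously; bad epoch {e}")
            pos = e.end
        self.epochs = eps
        for b in self.bouts:
            if not any(e.start <= b.start and b.end <= e.end for e in eps):
                raise ValueError(f"bout {b} does not lie inside a single epoch")
            if b.end <= b.start:
                raise ValueError(f"empty bout {b}")

    @property
    def n_frames(self) -> int:
        return self.epochs[-1].end

    def frame_labels(self) -> np.ndarray:
        """Condition label per frame, as an object array of strings."""
        labels = np.empty(self.n_frames, dtype=object)
        for e in self.epochs:
            labels[e.start : e.end] = e.condition
        return labels

    def condition_frames(self, condition: str) -> np.ndarray:
        """All frame indices whose epoch carries *condition*."""
        idx = [np.arange(e.start, e.end) for e in self.epochs if e.condition == condition]
        return np.concatenate(idx) if idx else np.empty(0, dtype=np.int64)

    def bout_frames(self) -> np.ndarray:
        idx = [np.arange(b.start, b.end) for b in self.bouts]
        return np.concatenate(idx) if idx else np.empty(0, dtype=np.int64)

    def epoch_slices(self) -> list[tuple[str, slice]]:
        return [(e.condition, slice(e.start, e.end)) for e in self.epochs]

    def matched_frames(
        self, social: str = "social", homecage: str = "homecage"
    ) -> tuple[np.ndarray, np.ndarray, list[Bout]]:
        """Interaction-bout frames and temporally matched home-cage frames.

        For each bout the matched interval sits at the same offset within the
        preceding home-cage epoch, clipped to that epoch; the two returned
        frame sets have equal length.
        """
        soc_frames: list[np.ndarray] = []
        hc_frames: list[np.ndarray] = []
        matched_intervals: list[Bout] = []
        for b in self.bouts:
            epoch = next(e for e in self.epochs if e.start <= b.start and b.end <= e.end)
            if epoch.condition != social:
                continue
            prev_hc = None
            for e in self.epochs:
                if e.end <= epoch.start and e.condition == homecage:
                    prev_hc = e
            if prev_hc is None:
                continue
            offset = b.start - epoch.start
            m_start = prev_hc.start + min(offset, max(prev_hc.length - 1, 0))
            m_end = min(m_start + (b.end - b.start), prev_hc.end)
            usable = m_end - m_start
            if usable <= 0:
                continue
            soc_frames.append(np.arange(b.start, b.start + usable))
            hc_frames.append(np.arange(m_start, m_end))
            matched_intervals.append(Bout(m_start, m_end))
        if not soc_frames:
            return np.empty(0, np.int64), np.empty(0, np.int64), []
        return np.concatenate(soc_frames), np.concatenate(hc_frames), matched_intervals


def split_by_epochs(raster: np.ndarray, ann: EpochAnnotation) -> list[tuple[str, np.ndarray]]:
    """Slice a raster into per-epoch sub-rasters (views)."""
    raster = as_raster(raster)
    if raster.shape[1] != ann.n_frames:
        raise ValueError("annotation length does not match raster")
    return [(cond, raster[:, sl]) for cond, sl in ann.epoch_slices()]
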