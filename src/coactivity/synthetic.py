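"""Synthetic two-state rasters, epoch tracks, and fluorescence fixtures.

The generator emulates the structure of prefrontal microendoscope recordings:
~25-100 neurons, a few percent of neurons active per frame, and a population
rate that oscillates slowly around its mean.  Two kinds of "State B" rasters
are derived from a random "State A" raster:

* *correlation-coded*: coactive cell assemblies are inserted by reciprocal
  swaps, so State B differs from State A only in its pairwise correlations
  (per-neuron activity and per-frame population counts are exactly equal);
* *rate-coded*: a proportion of each donor neuron's activity blocks is
  transferred to a partner neuron, so individual activity levels differ while
  per-frame population counts remain equal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .raster import Bout, Epoch, EpochAnnotation, as_raster, blocks_from_raster

log = logging.getLogger(__name__)


def as_rng(seed: int | None | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SyntheticStateConfig:
    """Parameters of the two-state raster generator.

    Parameters
    ----------
    n_neurons, n_frames : raster dimensions (defaults 100 x 6000).
    mean_activity : mean fraction of neurons active per frame (default 0.05).
    oscillation_period : frames per population-rate cycle (default 1000); the
        per-frame active count is ``round(N * A * (1 + sin(2*pi*f/period)))``.
    assembly_size : neurons per inserted assembly (default 8).
    n_assemblies : number of disjoint assemblies inserted into State B (0-5).
    modulation_bound : max fraction of a donor neuron's blocks transferred to
        its partner when building a rate-coded State B (0-0.5).
    swap_segment : reciprocal swaps during assembly insertion exchange
        activity between frames of the same segment of this length, so
        per-neuron activity levels are preserved on every analysis timescale
        of at least one segment and the two states differ purely in their
        correlations (default 500, one classifier train/test block).
    seed : RNG seed for all draws made from this config.
    """

    n_neurons: int = 100
    n_frames: int = 6000
    mean_activity: float = 0.05
    oscillation_period: float = 1000.0
    assembly_size: int = 8
    n_assemblies: int = 0
    modulation_bound: float = 0.0
    swap_segment: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_activity <= 1.0:
            raise ValueError("mean_activity must lie in [0, 1]")
        if self.n_assemblies * self.assembly_size > self.n_neurons:
            raise ValueError("assemblies must fit disjointly into the population")
        if not 0.0 <= self.modulation_bound <= 1.0:
            raise ValueError("modulation_bound must lie in [0, 1]")
        if self.oscillation_period <= 0:
            raise ValueError("oscillation_period must be positive")

    def per_frame_counts(self) -> np.ndarray:
        """Active-neuron count for every frame, from the oscillation formula."""
        f = np.arange(self.n_frames)
        n = self.n_neurons * self.mean_activity * (
            1.0 + np.sin(2.0 * np.pi * f / self.oscillation_period)
        )
        counts = np.rint(n).astype(np.int64)
        if (counts > self.n_neurons).any():
            raise ValueError("per-frame active count exceeds n_neurons; lower mean_activity")
        return np.clip(counts, 0, self.n_neurons)

    def assemblies(self) -> list[np.ndarray]:
        """Disjoint assembly memberships: neurons 0..size-1, size..2*size-1, ..."""
        return [
            np.arange(k * self.assembly_size, (k + 1) * self.assembly_size)
            for k in range(self.n_assemblies)
        ]


def gen_state_a(config: SyntheticStateConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Random raster whose population rate oscillates around ``mean_activity``.

    In each frame the formula count of distinct neurons is chosen uniformly at
    random.  Reproducible given ``config.seed``.
    """
    rng = rng if rng is not None else as_rng(config.seed)
    counts = config.per_frame_counts()
    raster = np.zeros((config.n_neurons, config.n_frames), dtype=np.uint8)
    for f, k in enumerate(counts):
        if k:
            raster[rng.choice(config.n_neurons, size=k, replace=False), f] = 1
    return raster


def insert_assemblies(
    state_a: np.ndarray,
    config: SyntheticStateConfig,
    rng: np.random.Generator | None = None,
    coactivation_prob: float = 1.0,
    max_retries: int = 200,
) -> np.ndarray:
    """Build a correlation-coded State B raster by planting coactive assemblies.

    Whenever the first neuron of an assembly is active in a frame, the other
    members are made coactive by reciprocal swaps with non-assembly neurons:
    a non-assembly neuron active in the trigger frame gives up that frame to
    the member, and receives one of the member's frames elsewhere in exchange.
    Row sums and column sums are therefore exactly those of ``state_a``.  If
    fewer neurons than ``assembly_size`` are active in the trigger frame, a
    random subset of the assembly of that size is coactivated.

    ``coactivation_prob`` < 1 makes each member's recruitment probabilistic.
    """
    state_a = as_raster(state_a)
    rng = rng if rng is not None else as_rng(config.seed)
    b = state_a.copy()
    if config.n_assemblies == 0:
        return b
    non_assembly = np.ones(config.n_neurons, dtype=bool)
    for members in config.assemblies():
        non_assembly[members] = False

    for a_idx, members in enumerate(config.assemblies()):
        first = members[0]
        outside = np.ones(config.n_neurons, dtype=bool)
        outside[members] = False
        trigger_frames = np.flatnonzero(b[first])
        for f in trigger_frames:
            active = np.flatnonzero(b[:, f])
            k = len(active)
            if k <= 1:
                continue
            # coactivate min(assembly_size, k) members; members already active
            # in the frame count toward the subset first
            inactive_members = members[b[members, f] == 0]
            n_already = len(members) - len(inactive_members)
            need = min(len(members), k) - n_already
            if need <= 0:
                continue
            targets = (
                inactive_members
                if need >= len(inactive_members)
                else rng.choice(inactive_members, size=need, replace=False)
            )
            for m in targets:
                if coactivation_prob < 1.0 and rng.random() > coactivation_prob:
                    continue
                if not _reciprocal_swap(
                    b, m, f, first, non_assembly, outside, rng, max_retries,
                    config.swap_segment,
                ):
                    raise RuntimeError(
                        f"no reciprocal swap found for assembly {a_idx}, "
                        f"member {m}, frame {f}"
                    )
    return b


def _reciprocal_swap(
    b: np.ndarray,
    member: int,
    frame: int,
    trigger_neuron: int,
    non_assembly: np.ndarray,
    outside_assembly: np.ndarray,
    rng: np.random.Generator,
    max_retries: int,
    swap_segment: int,
) -> bool:
    """Swap one frame of activity between ``member`` and an outside donor.

    Finds a neuron q outside the current assembly that is active in
    ``frame`` and a frame f2 where ``member`` is active but q is not, then
    exchanges the two cells.  Donors belonging to no assembly are preferred
    (so earlier-planted assemblies are not eroded).  f2 is drawn from the
    same ``swap_segment``-frame segment as the trigger frame whenever the
    member has spare activity there (keeping activity levels intact segment
    by segment), and frames where the triggering neuron is active are
    avoided when possible.
    """
    donors = np.flatnonzero(b[:, frame] & non_assembly)
    if donors.size == 0:
        donors = np.flatnonzero(b[:, frame] & outside_assembly)
    if donors.size == 0:
        return False
    member_frames = np.flatnonzero(b[member])
    member_frames = member_frames[member_frames != frame]
    if member_frames.size == 0:
        return False
    seg = frame // swap_segment
    local = member_frames[member_frames // swap_segment == seg]
    if local.size == 0:
        local = member_frames[np.abs(member_frames // swap_segment - seg) <= 1]
    if local.size == 0:
        local = member_frames
    preferred = local[b[trigger_neuron, local] == 0]
    pools = [preferred, local] if preferred.size else [local]
    for _ in range(max_retries):
        q = donors[rng.integers(donors.size)]
        pool = pools[0] if rng.random() < 0.9 or len(pools) == 1 else pools[1]
        f2 = pool[rng.integers(pool.size)]
        if b[q, f2]:
            continue
        b[q, frame] = 0
        b[member, frame] = 1
        b[member, f2] = 0
        b[q, f2] = 1
        return True
    return False


def modulate_activity(
    state_a: np.ndarray,
    config: SyntheticStateConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Build a rate-coded State B raster by transferring activity between halves.

    Each donor neuron ``i`` in the first half is paired with recipient
    ``i + n/2``; a uniformly drawn proportion in ``[0, modulation_bound]`` of
    the donor's activity blocks is reassigned to the recipient at the same
    frames.  Transfers that would collide with existing recipient activity are
    skipped (and logged).  Per-frame column sums are preserved exactly.
    """
    state_a = as_raster(state_a)
    n = config.n_neurons
    if n % 2:
        raise ValueError("modulate_activity requires an even number of neurons")
    if not 0.0 <= config.modulation_bound <= 0.5:
        raise ValueError("modulation_bound must lie in [0, 0.5]")
    rng = rng if rng is not None else as_rng(config.seed)
    b = state_a.copy()
    if config.modulation_bound == 0.0:
        return b
    half = n // 2
    neurons, starts, lengths = blocks_from_raster(state_a)
    n_skipped = 0
    for donor in range(half):
        recipient = donor + half
        mask = neurons == donor
        d_starts, d_lens = starts[mask], lengths[mask]
        if d_starts.size == 0:
            continue
        prop = rng.uniform(0.0, config.modulation_bound)
        n_transfer = int(round(prop * d_starts.size))
        if n_transfer == 0:
            continue
        chosen = rng.choice(d_starts.size, size=n_transfer, replace=False)
        for ci in chosen:
            s, ln = d_starts[ci], d_lens[ci]
            if b[recipient, s : s + ln].any():
                n_skipped += 1
                continue
            b[donor, s : s + ln] = 0
            b[recipient, s : s + ln] = 1
    if n_skipped:
        log.info("modulate_activity: skipped %d colliding transfers", n_skipped)
    return b


def two_state_dataset(
    config: SyntheticStateConfig,
    kind: str = "correlation",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, dict[str, slice]]:
    """Concatenated State A + State B raster with per-frame labels.

    Returns ``(raster, labels, state_slices)`` where labels are 1 for State A
    frames and 0 for State B frames, and ``state_slices`` maps state name to
    its column slice.  ``kind`` selects how State B is built: "correlation"
    (inserted assemblies), "rate" (activity transfer), or "control" (an
    independent State A draw; carries no decodable signal).
    """
    rng = rng if rng is not None else as_rng(config.seed)
    a = gen_state_a(config, rng)
    if kind == "correlation":
        b = insert_assemblies(a, config, rng)
    elif kind == "rate":
        b = modulate_activity(a, config, rng)
    elif kind == "control":
        b = gen_state_a(config, rng)
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")
    raster = np.concatenate([a, b], axis=1)
    labels = np.concatenate(
        [np.ones(config.n_frames, dtype=np.int8), np.zeros(config.n_frames, dtype=np.int8)]
    )
    slices = {"A": slice(0, config.n_frames), "B": slice(config.n_frames, 2 * config.n_frames)}
    return raster, labels, slices


# ---------------------------------------------------------------------------
# Epoch / bout tracks
# ---------------------------------------------------------------------------


def gen_epoch_labels(
    n_frames: int,
    epoch_plan: Sequence[tuple[str, int]],
    bout_conditions: Sequence[str] = ("social",),
    mean_bout: float = 100.0,
    mean_gap: float = 100.0,
    seed: int | None | np.random.Generator = None,
) -> EpochAnnotation:
    """Epoch-structured condition track with interaction bouts.

    ``epoch_plan`` is a list of ``(condition, length)`` runs whose lengths
    must sum to ``n_frames``.  Within epochs whose condition is in
    ``bout_conditions``, alternating non-interaction gaps and interaction
    bouts are drawn with geometric lengths of the given means (frames).
    """
    if sum(length for _, length in epoch_plan) != n_frames:
        raise ValueError("epoch plan lengths must sum to n_frames")
    rng = as_rng(seed)
    epochs: list[Epoch] = []
    bouts: list[Bout] = []
    pos = 0
    for condition, length in epoch_plan:
        epochs.append(Epoch(condition, pos, pos + length))
        if condition in bout_conditions:
            t = pos
            end = pos + length
            while t < end:
                gap = int(rng.geometric(1.0 / mean_gap))
                bout = int(rng.geometric(1.0 / mean_bout))
                b_start = min(t + gap, end)
                b_end = min(b_start + bout, end)
                if b_end > b_start:
                    bouts.append(Bout(b_start, b_end))
                t = b_end
        pos += length
    return EpochAnnotation(epochs=epochs, bouts=bouts)


# ---------------------------------------------------------------------------
# Fluorescence-trace fixtures
# ---------------------------------------------------------------------------


@dataclass
class TransientTemplate:
    """Shape of a rendered calcium transient.

    ``amplitude`` is expressed in multiples of ``noise_sd`` (dF/F0 units);
    ``rise_frames`` is the linear rise time and ``decay_tau`` the exponential
    decay constant, both in frames.
    """

    amplitude: float = 20.0
    rise_frames: int = 2
    decay_tau: float = 15.0
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.decay_tau <= 0:
            raise ValueError("amplitude and decay_tau must be positive")


def gen_traces(
    blocks: Sequence[tuple[int, int, int]],
    template: TransientTemplate,
    n_frames: int,
    n_neurons: int | None = None,
    seed: int | None | np.random.Generator = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render ground-truth events as noisy dF/F0 traces.

    ``blocks`` is a list of ``(neuron, start, length)`` ground-truth events.
    Each event is drawn as a linear rise over ``rise_frames`` followed by an
    exponential decay with time constant ``decay_tau``; white Gaussian noise
    of sd ``noise_sd`` is added.  Returns ``(traces, truth_raster)``.
    """
    rng = as_rng(seed)
    if n_neurons is None:
        n_neurons = 1 + max((b[0] for b in blocks), default=0)
    traces = np.zeros((n_neurons, n_frames), dtype=np.float64)
    truth = np.zeros((n_neurons, n_frames), dtype=np.uint8)
    amp = template.amplitude * template.noise_sd
    for neuron, start, length in blocks:
        if start < 0 or start + length > n_frames:
            raise ValueError(f"event ({neuron}, {start}, {length}) outside trace bounds")
        truth[neuron, start : start + length] = 1
        peak_frame = start + template.rise_frames
        rise = np.linspace(0.0, amp, template.rise_frames + 1)[1:]
        for i, v in enumerate(rise):
            f = start + 1 + i
            if f < n_frames:
                traces[neuron, f] += v
        t = np.arange(n_frames - min(peak_frame + 1, n_frames))
        traces[neuron, peak_frame + 1 :] += amp * np.exp(-(t + 1) / template.decay_tau)[
            : max(n_frames - peak_frame - 1, 0)
        ]
    if template.noise_sd > 0:
        traces += rng.normal(0.0, template.noise_sd, size=traces.shape)
    return traces, truth
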