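"""3-neuron coactivity combinations: counting, enrichment, and specificity.

A triplet "occurs" in a frame when all three neurons are active together.
Enrichment is scored against swap-shuffled surrogates, which preserve both
per-neuron block counts (hence activity levels) and per-frame population
counts (hence slow network-rate dynamics) — the two chance factors that
inflate raw coactivity counts.  Counts are stored sparsely, keyed by an
integer code of the unordered triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from . import _kernels
from .raster import Bout, as_raster
from .surrogates import swap_shuffle
from .synthetic import as_rng


def encode_triplet(i: int, j: int, k: int, n_neurons: int) -> int:
    i, j, k = sorted((i, j, k))
    return (i * n_neurons + j) * n_neurons + k


def decode_triplet(code: int, n_neurons: int) -> tuple[int, int, int]:
    k = code % n_neurons
    code //= n_neurons
    j = code % n_neurons
    return (code // n_neurons, j, k)


@dataclass
class TripletCatalog:
    """Sparse per-triplet occurrence counts, optionally with enrichment."""

    n_neurons: int
    codes: np.ndarray                 # int64, sorted, one entry per observed triplet
    counts: np.ndarray                # int64, aligned with codes
    percentiles: np.ndarray | None = None   # mid-rank vs swap-shuffled null
    n_surrogates: int = 0
    bout_support: np.ndarray | None = None  # distinct bouts containing each triplet
    condition: str | None = None

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total_mass(self) -> int:
        return int(self.counts.sum())

    def triplets(self) -> list[tuple[int, int, int]]:
        return [decode_triplet(int(c), self.n_neurons) for c in self.codes]

    def enriched(self, threshold: float = 95.0) -> np.ndarray:
        if self.percentiles is None:
            raise ValueError("enrichment has not been computed")
        return self.codes[self.percentiles > threshold]


def _codes_for(raster: np.ndarray, frames: np.ndarray) -> np.ndarray:
    max_active = int(raster.sum(axis=0).max(initial=0)) + 1
    return _kernels.triplet_codes(raster, np.asarray(frames, dtype=np.int64), max_active)


def count_triplets(
    raster: np.ndarray,
    frames: np.ndarray | None = None,
    condition: str | None = None,
) -> TripletCatalog:
    """Occurrence count of every 3-neuron combination over the given frames.

    Each frame with k >= 3 active neurons increments all C(k, 3) triplets by
    one.  The total catalog mass therefore equals sum_f C(k_f, 3).
    """
    raster = as_raster(raster)
    if frames is None:
        frames = np.arange(raster.shape[1])
    codes = _codes_for(raster, frames)
    uniq, counts = np.unique(codes, return_counts=True)
    return TripletCatalog(raster.shape[0], uniq, counts.astype(np.int64),
                          condition=condition)


def expected_mass(raster: np.ndarray, frames: np.ndarray | None = None) -> int:
    """Closed-form catalog mass from column sums: sum_f C(k_f, 3)."""
    raster = as_raster(raster)
    if frames is None:
        frames = np.arange(raster.shape[1])
    ks = raster[:, np.asarray(frames, dtype=np.int64)].sum(axis=0)
    return int(sum(comb(int(k), 3) for k in ks))


def enrichment(
    raster: np.ndarray,
    frames: np.ndarray | None = None,
    n_surrogates: int = 1000,
    threshold_percentile: float = 95.0,
    seed: int | None | np.random.Generator = None,
    catalog: TripletCatalog | None = None,
    condition: str | None = None,
) -> TripletCatalog:
    """Per-triplet enrichment percentiles against swap-shuffled surrogates.

    Surrogates swap shuffle the *whole session* (preserving per-frame counts
    and per-neuron block counts); counts are then taken over ``frames``.  The
    percentile is the mid-rank of the real count within the surrogate count
    distribution: 100 * (#below + 0.5 * #tied) / n_surrogates.
    """
    raster = as_raster(raster)
    rng = as_rng(seed)
    if frames is None:
        frames = np.arange(raster.shape[1])
    frames = np.asarray(frames, dtype=np.int64)
    if catalog is None:
        catalog = count_triplets(raster, frames, condition)
    codes, counts = catalog.codes, catalog.counts
    below = np.zeros(codes.size, dtype=np.int64)
    tied = np.zeros(codes.size, dtype=np.int64)
    for _ in range(n_surrogates):
        sur = swap_shuffle(raster, "whole", seed=rng)
        sur_codes = _codes_for(sur, frames)
        sur_counts = np.zeros(codes.size, dtype=np.int64)
        if sur_codes.size:
            pos = np.searchsorted(codes, sur_codes)
            ok = (pos < codes.size) & (codes[np.minimum(pos, codes.size - 1)] == sur_codes)
            np.add.at(sur_counts, pos[ok], 1)
        below += sur_counts < counts
        tied += sur_counts == counts
    pct = 100.0 * (below + 0.5 * tied) / n_surrogates
    return TripletCatalog(
        catalog.n_neurons, codes, counts, percentiles=pct,
        n_surrogates=n_surrogates, bout_support=catalog.bout_support,
        condition=condition if condition is not None else catalog.condition,
    )


def bout_support(raster: np.ndarray, catalog: TripletCatalog,
                 bouts: list[Bout]) -> np.ndarray:
    """Number of distinct bouts in which each cataloged triplet occurs."""
    raster = as_raster(raster)
    support = np.zeros(catalog.codes.size, dtype=np.int64)
    for b in bouts:
        frames = np.arange(b.start, b.end)
        codes = np.unique(_codes_for(raster, frames))
        pos = np.searchsorted(catalog.codes, codes)
        ok = (pos < catalog.codes.size) & (
            catalog.codes[np.minimum(pos, catalog.codes.size - 1)] == codes
        )
        support[pos[ok]] += 1
    return support


@dataclass
class SpecificityReport:
    """Behavioral specificity labels and the left-out-neuron overlap tally."""

    labels: dict[int, str]            # code -> social-specific|homecage-specific|both|neither
    social_specific: np.ndarray
    homecage_specific: np.ndarray
    n_overlap_pairs: int = 0
    left_out_social_in_hc: float = float("nan")
    left_out_hc_in_social: float = float("nan")
    details: dict = field(default_factory=dict)


def specificity_and_overlap(
    catalog_social: TripletCatalog,
    catalog_homecage: TripletCatalog,
    enrich_percentile: float = 95.0,
    other_percentile: float = 50.0,
    min_bouts: int = 2,
) -> SpecificityReport:
    """Classify triplets by behavioral specificity and tally overlap structure.

    A triplet is condition-specific when its percentile exceeds
    ``enrich_percentile`` in one condition and falls below
    ``other_percentile`` in the other.  Triplets occurring in fewer than
    ``min_bouts`` distinct bouts are dropped (repetition filter) when bout
    support is available.  The overlap report asks, for every social/home-cage
    specific pair sharing exactly two neurons, whether the left-out neuron
    participates in some enriched triplet of the opposite condition.
    """
    for cat in (catalog_social, catalog_homecage):
        if cat.percentiles is None:
            raise ValueError("enrichment percentiles required for specificity")
    n = catalog_social.n_neurons

    def pct_map(cat: TripletCatalog) -> dict[int, float]:
        return dict(zip(cat.codes.tolist(), cat.percentiles.tolist()))

    soc_pct = pct_map(catalog_social)
    hc_pct = pct_map(catalog_homecage)

    def passes_repetition(cat: TripletCatalog, idx: int) -> bool:
        if cat.bout_support is None:
            return True
        return cat.bout_support[idx] >= min_bouts

    labels: dict[int, str] = {}
    soc_specific: list[int] = []
    hc_specific: list[int] = []
    all_codes = sorted(set(soc_pct) | set(hc_pct))
    soc_idx = {c: i for i, c in enumerate(catalog_social.codes.tolist())}
    hc_idx = {c: i for i, c in enumerate(catalog_homecage.codes.tolist())}
    for code in all_codes:
        sp = soc_pct.get(code, 0.0)
        hp = hc_pct.get(code, 0.0)
        s_enr = sp > enrich_percentile and (
            code not in soc_idx or passes_repetition(catalog_social, soc_idx[code])
        ) and code in soc_idx
        h_enr = hp > enrich_percentile and (
            code not in hc_idx or passes_repetition(catalog_homecage, hc_idx[code])
        ) and code in hc_idx
        if s_enr and hp < other_percentile:
            labels[code] = "social-specific"
            soc_specific.append(code)
        elif h_enr and sp < other_percentile:
            labels[code] = "homecage-specific"
            hc_specific.append(code)
        elif s_enr and h_enr:
            labels[code] = "both"
        else:
            labels[code] = "neither"

    # any-enrichment membership sets for the left-out-neuron lookup
    soc_enriched = set(catalog_social.enriched(enrich_percentile).tolist())
    hc_enriched = set(catalog_homecage.enriched(enrich_percentile).tolist())
    soc_members: set[int] = set()
    for c in soc_enriched:
        soc_members.update(decode_triplet(c, n))
    hc_members: set[int] = set()
    for c in hc_enriched:
        hc_members.update(decode_triplet(c, n))

    n_pairs = 0
    soc_hits = 0
    hc_hits = 0
    soc_sets = [(c, set(decode_triplet(c, n))) for c in soc_specific]
    hc_sets = [(c, set(decode_triplet(c, n))) for c in hc_specific]
    for sc, sset in soc_sets:
        for hc_code, hset in hc_sets:
            if len(sset & hset) != 2:
                continue
            n_pairs += 1
            left_out_social = next(iter(sset - hset))  # in the social triplet only
            left_out_hc = next(iter(hset - sset))
            if left_out_hc in soc_members:
                soc_hits += 1
            if left_out_social in hc_members:
                hc_hits += 1
    report = SpecificityReport(
        labels=labels,
        social_specific=np.array(soc_specific, dtype=np.int64),
        homecage_specific=np.array(hc_specific, dtype=np.int64),
        n_overlap_pairs=n_pairs,
    )
    if n_pairs:
        # fraction of pairs where the neuron dropped from the opposite-condition
        # triplet still appears in some enriched triplet of its own condition
        report.left_out_hc_in_social = soc_hits / n_pairs
        report.left_out_social_in_hc = hc_hits / n_pairs
    return report
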