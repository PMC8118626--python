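# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic fixtures can and cannot show.
Conventions used throughout: frames are 0-based, intervals half-open,
acquisition at 20 Hz; an *event raster* is a binary neurons × frames
matrix; a *block of activity* is a maximal run of consecutive active frames
for one neuron.

## Event detection

Traces enter as per-ROI mean fluorescence plus a surround (annulus) mean.
The corrected signal is `roi − surround`; F0 is the per-neuron median of
the surround, and dF/F0 = corrected / F0. The trace is low-pass filtered
zero-phase with a linear-phase FIR designed for a 0.5 passband edge and
0.65 stopband edge (normalized to Nyquist) with ≥25 dB stopband
attenuation; the filter is realized as a Kaiser-window design meeting those
band edges and attenuation.

σ is the standard deviation of dF/F0 over the 50% of frames with the
lowest 1-s moving average of |dF/F0| ("least active half"); smoothing
before ranking makes the selection robust to isolated spikes. A constant
trace yields σ = 0 and detection is disabled for that neuron.

The cascade: candidate onsets are frames whose max-minus-min rise within
the trailing 1-s window reaches 3σ; the onset is the window's minimum, and
the pre-event baseline is the median of the half-window before the onset
(using the raw minimum makes the "return to baseline" criterion hang on a
low noise excursion and merges consecutive events). A candidate is kept if
the signal rises ≥15σ above baseline within 2 s of onset, the area under
the curve from onset to baseline-return reaches 250 σ·frames (units:
σ × frames at 20 Hz; the threshold is configurable), and the peak exceeds
0.0125 absolute dF/F0. The 15σ confirmation is measured from the pre-onset
baseline. The neuron is marked active from onset until the signal drops
30% from the event peak, capped at 2 s; candidates inside an event's
extent are merged into it. Raising any threshold can only remove events
(monotonicity), and detection is invariant to jointly scaling trace and σ,
except for the absolute 0.0125 floor.

Sensitivity/specificity of the defaults are measured on synthetic traces
(linear rise over 2 frames, exponential decay τ = 0.75 s, amplitude 25σ,
white noise): sensitivity is the fraction of ground-truth transients
overlapped by a detected event; specificity is the fraction of truth-free
2-s windows containing no detected activity. Both exceed 95% at the
default thresholds.

## Surrogate rasters

**Swap shuffling** permutes block neuron identities by random pairwise
swaps, each block swapped at least once. A swap is committed only if
neither neuron ends up with overlapping *or temporally adjacent* activity —
adjacency would merge two blocks on re-decomposition and silently change
block counts. Per-frame population counts and per-neuron block counts are
therefore conserved exactly; activity levels are conserved up to block-
duration heterogeneity.

**SHARC** starts from a swap shuffle (so every block moves), then performs
5 reassignment passes over all blocks in random order. For block i the
candidate score over neurons is

    P⃗ᵢ = Σ_{j∈X} rⱼ/(Lᵢ Lⱼ) · (C⃗_{nⱼ} − C⃗′_{nⱼ})

where X is the set of already-placed blocks overlapping block i, rⱼ the
overlap length, L the block lengths, C the target correlation matrix and C′
the surrogate's current matrix (maintained incrementally from coactivity
counts). Neurons active during (or adjacent to) the block's frames are
ineligible, as are neurons whose net block gain would exceed +4; blocks of
neurons whose net loss would exceed 3 are not reassigned, so every
per-neuron block-count change lies in [−3, +4]. Block i goes to the
argmax of P⃗ᵢ (ties broken uniformly at random). When no eligible entry is
positive — including the all-zero case — the recipient is drawn with
probability softmax(net/T), T = 1 by default, which steers blocks back
toward net donors. Assigning to a neuron with a strictly negative score
would knowingly worsen the fit, so the fallback also covers that case.

The default target is the source raster's own Pearson correlation matrix
(binary rows; zero-variance rows contribute 0). SHARC is strong enough to
reproduce even the *sampling* correlations of an unstructured raster
(similarity to the target ≈0.95 where swap gives ≈0); on rasters with
planted assemblies it restores the correlation structure with similarity
≈0.98.

Per-epoch scope applies either procedure to each epoch's sub-raster
independently (the initial swap inside SHARC, and its per-epoch target
matrix, respect the same scope) and concatenates the results; blocks that
would span an epoch boundary are treated as cut at the boundary.

**Circular shuffling** rotates a neuron's full-session row and re-extracts
the condition frames. Counts for all rotations are computed exactly by
circular cross-correlation (FFT); the null samples 10,000 random nonzero
shifts, and the observed percent-time-active is ranked with the mid-rank
convention. Percentile >90 / <10 labels a neuron positively / negatively
modulated; on stationary Bernoulli neurons each tail flags ≈10%.

**Similarity diagnostics.** Activity similarity is the Pearson correlation
of per-neuron activity-level vectors; correlation similarity is the Pearson
correlation of the vectorized off-diagonal upper triangles, excluding pairs
undefined due to zero-variance rows (≥3 valid pairs required).

## The decoder

1,000 hidden units each receive input from an independent Bernoulli(p)
subset of neurons; a hidden unit's activity is the *sum* of its connected
neurons' binary activity (no bias, identity activation). One logistic
output unit reads the hidden layer: y = 1/(1+e^{−Σwᵢxᵢ}); y < 0.5 decodes
the condition labeled 0 (social / State B). Output weights start at zero
(symmetric and reproducible) and train online with the delta rule
Δwᵢ = ε·y(1−y)(z−y)·xᵢ over 500 passes, a fresh random frame order per
pass, no early stopping or regularization. Training and testing use
alternating 500-frame blocks laid out on the unfiltered session timeline,
restricted to interaction bouts and temporally matched home-cage frames
(same offset within the preceding home-cage epoch) with ≥3 active neurons.
Ties at y = 0.5 are broken by a seeded coin flip; reported accuracies are
averaged over repeated runs (fresh connections each run).

The default step size is ε = 0.002. With 1,000 count-valued hidden
features the per-update logit displacement is ε·y(1−y)·‖x‖², and ‖x‖² here
is of order 10³–10⁴, dominated by a common-mode direction shared by all
frames; steps much above ~0.005 saturate the output within a single pass,
after which y(1−y) gates all further plasticity and every run freezes at
exactly 50%. Steps much below ~0.001 cannot escape the flat point at
w = 0 (for states with matched activity levels the gradient at the origin
vanishes; learning proceeds by stochastic symmetry breaking). The scan
over {0.05, 0.01, 0.002, 5·10⁻⁴, 10⁻⁴} at the standard synthetic scale
shows stable assembly-detecting solutions only near 0.002, which is
therefore the default; the update's functional form is unaffected and ε is
configurable.

The trained network is a logistic model over hidden features — its
decisions must (and do, exactly) match a closed-form sigmoid readout of
(connections, weights). Its value is in the *training dynamics*: each
hidden unit is one candidate ensemble, so the delta rule searches over
groups whose summed activity tracks the label. That is what separates
correlation-coded states, where optimal linear classifiers on raw neuron
activity (logistic regression / linear SVM, fitted with scikit-learn on
identical partitions and filters) remain at chance.

The connection-probability sweep rebuilds the network per run;
p_connect = 0.3 is the default for downstream analyses.

## Ensembles from trained classifiers

Units sorted by ascending output weight define the 25 most negative
("social"), 25 most positive ("home cage"), and the 25 units with |w|
nearest zero ("neutral"; 25 chosen as the default group size, configurable).
Input similarity is the correlation matrix of the binary input-connection
vectors (constant vectors excluded). Each ensemble is the ⌈20%⌉ of neurons
with the most connections into its unit group, ties broken by neuron index.
Per-condition statistics (mean fraction active; mean off-diagonal pairwise
correlation) are computed over matched, equal-sized condition frame sets.
On rate-coded fixtures the up/down-modulated halves are recovered by the
signed ensembles; on correlation-coded fixtures planted assembly members
are over-represented in the extreme-weight ensembles.

## Triplet statistics

Every frame with k ≥ 3 active neurons increments all C(k,3) unordered
triplets; the catalog is stored sparsely (a dense n³ array is infeasible
for realistic n), keyed by an integer code, and its total mass equals
Σ_f C(k_f,3) by construction. Enrichment compares each observed triplet's
count with its counts in 1,000 whole-session swap-shuffled surrogates —
the null that preserves exactly the two chance factors (per-neuron
activity levels and per-frame population counts); the percentile uses the
mid-rank convention. Enriched means >95th percentile (99.9th for the
strong criterion). Specificity: >95th in one condition and <50th in the
other, restricted to triplets occurring in ≥2 distinct bouts (or matched
home-cage intervals). The overlap report enumerates opposite-condition
specific pairs sharing exactly two neurons and asks whether each left-out
neuron participates in some enriched triplet of its own condition. Under a
homogeneous null the 95th-percentile threshold flags ≈5% of triplets.

## Synthetic data

The generator defines the study conditions for everything above: 100
neurons × 6,000 frames per state, mean activity A = 5%. The per-frame
active count is round(N·A·(1 + sin(2πf/period))); the population-rate
oscillation period defaults to 1,000 frames (the source formulation
leaves the period of the slow oscillation open; 50 s at 20 Hz is a
realistic slow rate fluctuation, and the value is configurable).

*Correlation-coded* State B plants 1–5 disjoint 8-neuron assemblies in a
copy of State A: whenever the first neuron of an assembly is active, the
other members (up to the frame's active count; members already active
count first) are recruited by reciprocal swaps with neurons outside the
assembly — the donor cedes the trigger frame to the member and receives
one of the member's frames in exchange. Both marginals are conserved
exactly. Two refinements matter: donors outside *any* assembly are
preferred, so later assemblies do not erode earlier ones; and the
exchanged frame is drawn from the same 500-frame segment as the trigger
(`swap_segment`), so per-neuron activity is conserved segment-by-segment,
not just globally. Without the locality constraint the train and test
halves acquire equal-and-opposite per-neuron rate drifts that hand linear
classifiers a spurious (anti-)signal; with it, the two states differ
purely in correlations at every analysis timescale of ≥1 segment.
Recruitment is deterministic by default (`coactivation_prob` available).

*Rate-coded* State B pairs donor neuron i (first half) with recipient
i + N/2 and moves a uniformly drawn proportion in [0, bound] of the
donor's blocks to the recipient at the same frames (collisions skipped and
logged), conserving per-frame counts while modulating individual rates.

Epoch tracks are alternating condition runs with geometric interaction
bouts and gaps (means 100 frames = 5 s each, configurable; realistic bout
durations for juvenile-interaction assays). Fluorescence fixtures render
ground-truth events as rise-plus-exponential-decay transients with white
noise.

What the fixtures do **not** emulate: calcium indicator kinetics beyond the
single transient template, sub-frame spike timing, nonstationary noise,
movement artifacts, neuropil cross-contamination beyond a static surround,
and the animal-to-animal variability of real recordings. Passing tests
show the *mechanisms* behave as specified (conservation laws, calibration,
dissociation of rate and correlation coding), not that effect sizes in
real cortex will match.

## Numerical and design choices

- Pearson correlation on binary rows is the correlation estimator
  throughout; zero-variance rows give NaN and are excluded from
  similarity metrics (SHARC treats them as 0 in its target).
- Swap conflicts (overlap or adjacency) are rejected-and-resampled with
  bounded retries, then skipped with a log message, keeping marginals
  exact in every committed state.
- Mid-rank percentiles everywhere a rank against a discrete null is
  taken (circular nulls, triplet enrichment).
- The relative improvement (Perf_SHARC − Perf_swap)/(Perf_swap − 0.5) is
  reported only when the swap margin over chance is clearly positive; on
  correlation-only data the denominator is ≈0 and the ratio is
  meaningless, so the raw accuracy difference is reported instead.
- Determinism: every public entry point accepts a seed or Generator; one
  master seed fans out to all stages, and numba kernels are seeded with
  32-bit integers drawn from the master stream. Identical configs produce
  byte-identical result bundles.
- Problem sizes in the test suite and acceptance script (e.g. 10 decoder
  runs for the dissociation test, 200 surrogates per condition in the
  planted-triplet recovery, SHARC conservation audited on 20 of the 100
  random rasters) are chosen so the full suite completes in a few minutes
  on one core while keeping every statistical check well-powered.

## Known limitations

- The delta-rule training is deliberately faithful to its online,
  unregularized form; it is run-to-run variable by design (symmetry
  breaking), and occasional runs land at chance. Reported numbers average
  over runs.
- SHARC's greedy argmax can overshoot the target correlations for strongly
  structured rasters (surrogates can be *more* cleanly correlated than the
  source), which is visible as SHARC-tested decoder accuracy exceeding
  real-data accuracy on synthetic fixtures.
- Per-epoch surrogates cut blocks at epoch boundaries; for epochs much
  longer than typical block durations the effect is negligible.
- Combinations of order >3 are out of scope (statistical power at
  realistic session lengths does not support them).
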