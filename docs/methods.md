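# Methods

This note documents the models and procedures implemented in
`neurostates`, the parameters that matter, the numerical conventions, and
the design choices made where the published descriptions of these methods
leave room. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Greedy state boundary search

The segmentation model assumes a region's timepoints × voxels matrix is
piecewise stationary: within a state, every timepoint's spatial pattern
resembles the state's mean pattern; across a boundary the pattern
changes. The *fit* of a segmentation is the mean over timepoints of the
Pearson correlation (across voxels) between the timepoint and its state
mean. We average per-timepoint correlations rather than correlating
flattened matrices; the two readings differ and the former matches the
definition above.

Each iteration of the search:

1. finds the single boundary location maximizing the fit;
2. finds the pair of locations, both interior to one existing state,
   maximizing the fit (a 2-D search that can carve out a whole new
   state);
3. adopts whichever candidate segmentation has the higher t-distance,
   with two qualifications: candidates are compared *before* fine-tuning,
   and the pair is only eligible when its fit exceeds the single
   candidate's fit by more than numerical round-off (1e-9). On an exact
   fit tie the pair equals the single plus a vacuous boundary — typically
   a 1-TR state that contributes no within-state pairs yet perturbs the
   consecutive-state pair set — and adopting it would insert spurious
   boundaries in near-noiseless data;
4. fine-tunes every boundary once, visiting them from weakest to
   strongest (strength = 1 − r between flanking state means, computed
   once at sweep start; ties broken by earlier position) and shifting
   each by ±1 TR when that strictly improves the fit.

The search stops at `k_max` (default 100, roughly half the timepoint
count of a typical scan) or when no legal placement remains. Placement
ties go to the smallest location, so the algorithm is fully
deterministic. The minimum state length during search is 1 TR; length-1
states simply contribute no within-state pairs to the t-distance.

The fit is evaluated incrementally: with cumulative sums of the data and
of the row-z-scored data plus their Gram matrices, the summed correlation
of any contiguous segment with its own mean is O(1), making every
candidate evaluation O(1) per segment. This is an algebraic identity with
the direct definition (verified to 1e-10 in the tests), not an
approximation. Zero-variance timepoints or state means contribute a
correlation of 0 with a logged warning.

### t-distance and model selection

For a segmentation with states s(t), the t-distance is the pooled-variance
two-sample t statistic comparing the correlations of within-state
timepoint pairs against pairs in *consecutive* states. It is undefined
(NaN, propagated) when either pair set has fewer than two members. The
optimal k maximizes the t-distance over the achieved k values (which may
advance by 2 when a pair is placed); ties go to the smaller k.

Model selection is exact in the well-separated regime but is *not*
guaranteed to return the planted k on noiseless synthetic data: when two
adjacent states receive mean patterns that correlate strongly by chance,
their boundary is genuinely weak and the t-distance may prefer the merged
solution (or, on noisy data, a solution with a few extra weak
boundaries). The recovery tests therefore require exact boundary recovery
at the planted k and bound the selected k, rather than demanding exact k
selection in every draw.

### Durations

State durations are state lengths in TRs times the TR. The variability
index is IQR/median, with quartiles computed by linear interpolation
between order statistics.

## Temporal preprocessing

- **Canonical HRF**: difference of two gamma densities (shapes 6 and 16,
  unit scales, undershoot ratio 1/6), 32 s long, sampled on the TR grid
  from t = 0 and normalized to unit peak. "Canonical" in fMRI denotes
  exactly this kernel; voxel-wise HRF estimation is out of scope.
- **High-pass filter**: 5th-order Butterworth applied forward and
  backward (zero phase, so boundary timing is untouched), default cutoff
  0.008 Hz.
- **Wiener deconvolution**: the non-iterative frequency-domain inverse
  conj(H)·Y/(|H|² + λ) per voxel, FFT length the next power of two ≥ 2n
  (zero padding suppresses circular wrap-around that would plant spurious
  boundaries at the scan edges). λ defaults to 0.1·mean(|H|²); published
  descriptions name the approach but not the constant, so it is exposed
  in the API. Fidelity of the convolve-deconvolve round trip degrades
  monotonically as λ grows.
- **Group averaging**: element-wise mean over participants; single-subject
  boundary detection is unreliable, and averaging n subjects raises the
  pattern SNR by √n.

All three steps are linear, so their order is interchangeable up to
numerical error; the pipeline applies high-pass → deconvolution →
averaging.

## Overlap statistics

Boundary series are per-TR vectors, zero at timepoint 1 by construction
(the first timepoint starts the first state). Event onsets with salience
(observer count) below 5 are discarded; each surviving onset marks the TR
containing it, floor(onset/TR) + 1 — the mapping rule is a convention we
fix and document. No tolerance window is applied when matching
boundaries: overlap is a pointwise product, and hemodynamic lag is
handled by deconvolution, not by shifting event onsets.

OA and OR are scaled against the chance expectation OE = (ΣE)(ΣS)/n as
given in the README. Zero denominators (empty series, or ΣS = OE) yield
NaN, which propagates and is excluded from group statistics with a logged
count — imputing 0 would bias the sign-rank tests. Strength weighting
replaces marks by the flanking-state correlation distance; co-occurrence
weighting replaces them by the fraction of in-scope searchlights sharing
the boundary. Uniform weights provably leave OA unchanged, a scale
invariance the tests assert exactly.

## Searchlights

Sphere centers sit on a step-2 lattice anchored at the mask bounding-box
minimum (the anchor is a convention we fix for reproducibility); members
are the in-mask voxels within a 3-voxel radius (123 lattice offsets for a
full sphere), and searchlights with fewer than 16 members are dropped.
Per-searchlight failures are logged and skipped, never fatal.
Searchlight scalars are projected to voxels by averaging over covering
searchlights; a voxel is marked missing when fewer than half of its
covering searchlights carry a defined value. p-values are projected the
same way (voxel-averaged, then thresholded at the FDR critical value),
not combined by Fisher's method.

The reliability screen keeps searchlights whose boundary series replicate
across two independent participant groups (relative overlap ≥ threshold,
default 0 — exclude only undefined). The exact exclusion rule used with
the original acquisition data is not recoverable from published text;
this split-group proxy is our own, configurable, choice.

## Network partitioning

The asymmetric signed modularity is
Q\* = Q⁺ − (v⁻/(v⁺+v⁻))·Q⁻, where Q± are the resolution-γ modularities of
the positive/negative parts of the matrix; negative weights are therefore
down-weighted by total strength. Equivalently Q\* is the sum over
same-community pairs of a single generalized modularity matrix, which is
what the Louvain-style search optimizes: greedy local moving to
convergence, community aggregation, repeat; then a node-level fine-tuning
pass on the unaggregated matrix. Runs are deterministic given their seed.

Consensus clustering repeats the stochastic search (default 100 times),
forms the co-assignment matrix, zeroes entries below the chance level —
estimated from 1,000 random module-label assignments drawn with the
module-size distributions of the partitions being summarized — and
re-clusters until every repetition agrees (the consensus matrix is
binary), with an iteration cap of 20 producing a diagnostic error.
Missing overlap-matrix entries are treated as zero weight (the neutral
element of the modularity sums) with a logged count. The resolution sweep
covers γ = 1.0 … 3.0 in steps of 0.1 and keeps the partition most similar
to a reference labeling by adjusted mutual information (max-entropy
normalization; two single-cluster labelings count as identical, aMI 1).

## Group inference

Subjects are split into balanced random groups (sizes differing by at
most one; e.g. 265 subjects into 15 groups of 17–18). Per-group pipelines
share no state — independence is what validates the test. The Wilcoxon
signed-rank test drops zeros, midranks ties, uses the exact sign-flip
null for n ≤ 25 (computed by a subset-sum recursion over doubled
midranks, so ties are handled exactly) and a tie-corrected normal
approximation with continuity correction above; fewer than 5 informative
values yield NaN. FDR is Benjamini–Hochberg at q = 0.05 over the defined
p-values; a result is additionally vetoed when the sign of the pooled
effect disagrees with the mean sign across subgroups.

## Synthetic data

The generator emulates the structure the pipeline targets, not the
physics of acquisition. Per region, each state's mean pattern is iid
standard normal per voxel, held constant for the state's duration;
per-subject Gaussian noise (SD `noise_sd`, relative to the unit pattern
SD) is added, white by default with an optional AR(1) coefficient for
temporal structure; the pattern time course can be blurred with the
canonical HRF. Defaults mirror a typical naturalistic scan: 193
timepoints at TR 2.47 s, 40 voxels per region, 20 subjects, noise SD 1,
8–15 states per region.

Boundary sharing is hierarchical: networks are ordered slow → fast, the
fastest network's boundary pool is drawn first (uniformly over sets with
all states ≥ 2 TRs — length-1 states would leave within-state
correlations undefined), and slower networks copy each boundary from the
next-faster pool with probability `nestedness`, drawing fresh otherwise;
regions copy from their network's pool the same way. Event boundaries
are a random half of the slowest network's pool, mirroring the idea that
perceived event transitions coincide with the most widely shared neural
transitions. At nestedness 1 all same-network regions have identical
sets; at 0 sets are independent and the expected pairwise overlap matches
the (ΣE)(ΣS)/n chance formula.

What the generator does **not** emulate: hemodynamic nonlinearity,
physiological noise, motion, spatial autocorrelation, or inter-subject
misalignment. Passing tests therefore demonstrate correctness of the
algorithms and calibration of the statistics under the stated model, not
performance on scanner data.

## Problem sizes used in the validation battery

The acceptance script and test suite use sizes chosen to exercise every
code path at desk scale: exhaustive t-distance checks at n ≤ 12, k ≤ 4;
boundary recovery at 200 TRs × 40 voxels, 15 states, 20 subjects, noise
SD 1; overlap null calibration with 10,000 Monte-Carlo draws; consensus
recovery on a 40-node, 4-block planted matrix at 100 repetitions; FDR
calibration over 1,000 simulated 20-searchlight maps of 15 groups; the
nestedness contrast over 20 seeds. All randomness flows from the single
`--seed` argument.

## Known limitations

- The t-distance can merge adjacent states whose random patterns
  correlate strongly, and can overshoot k on noisy data (see above); the
  group-level machinery, not the point estimate, carries inference.
- Louvain and consensus clustering are heuristic; determinism is per
  seed, and very weak block structure may legitimately fail to converge
  to a binary consensus (reported as an error, never silently).
- The Wiener inverse assumes a known, spatially constant HRF.
- File I/O supports NIfTI-1 volumes and TSV tables only; surface formats
  are out of scope.
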