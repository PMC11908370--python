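# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic validation can show. Notation: an ROI `I` is a set of voxels;
`|I|` its size; `x_v(t)` the time series of voxel `v`; all voxel
coordinates are 0-based `(i, j, k)` indices in native axis order, and
"neighbor" always means face-sharing 6-connectivity.

## Model

The recording is split into consecutive, non-overlapping windows of `L`
samples (default `L = 80`; at the default sampling interval of 0.1 s that
is 8 s of data — long enough for stable consistency estimates, short enough
to resolve fast reorganization). Trailing samples that do not fill a window
are discarded. Each window is parcellated independently; windows become
layers of a multilayer network. Nodes are `(layer, label)` pairs; labels
are arbitrary within a layer and carry no identity across layers. Node
time series are voxel means over the window. Intralayer edges form the
complete weighted graph of Pearson correlations between node series (kept
dense — downstream analyses need the complete network). Interlayer edges
join nodes on consecutive layers only, weighted by the Jaccard index of
their voxel sets; zero overlap means no edge. Longer-range overlaps are
not edges: they are computed on demand by the trajectory analysis.

## Homogeneity metrics

**Spatial consistency** `ϕ(I)` is the mean Pearson correlation over all
distinct voxel pairs of `I`, undefined for `|I| < 2` (the normalization
`|I|(|I|−1)` vanishes). Summing ordered or unordered pairs is equivalent
because correlation is symmetric; the implementation averages the upper
triangle and is tested against an explicit double loop.

**Regional homogeneity (ReHo)** is Kendall's coefficient of concordance
`W = 12 Σ_i (R_i − R̄)² / (K²(n³ − n))` over the voxel and its masked
face-neighbors (`K = 7` in the interior). Ranks are midranks; no
tie-correction term is applied. At the mask boundary the available masked
neighbors are used with `K = count + 1`, since a fixed `K = 7` presumes a
full neighborhood.

**Degenerate series policy.** A constant (zero-variance) series has no
defined Pearson correlation; every correlation involving one is set to 0
and a warning is logged. This single policy is shared by the metrics, the
growers, and the network assembly, so degenerate voxels depress rather
than poison aggregate scores.

**Excess area.** The within- and between-ROI correlation samples are
histogrammed on a shared grid over [−1, 1] (bin width 0.01 — fine enough
that the statistic is insensitive to halving it) with density
normalization; the statistic is `Σ max(0, f_within − f_between)·Δ`. It is
0 for identical distributions and 1 for disjoint supports. Between-ROI
pairs are uniformly subsampled (seeded) above a pair budget, since their
number grows quadratically in voxels.

## Greedy ROI optimization

Seeds come either from an atlas (per atlas ROI, the voxel with maximal
ReHo in the window — inheriting the atlas's spatial coverage) or are given
explicitly. The grower maintains a queue of (ROI, unassigned neighbor
voxel) pairs; each iteration assigns the pair with maximal priority and
updates the queue. Because growth adds one face-adjacent voxel at a time,
ROIs are 6-connected by construction. Two priorities are available:

- *weighted mean consistency*: the size-weighted mean consistency over all
  ROIs, evaluated as if the candidate were assigned, minus
  `λ Σ|I|²/(Σ|I|)²` (default `λ = 100`). The regularizer penalizes uneven
  size distributions; its strength relative to the consistency term scales
  with ROI count and total voxel count, so λ should be recalibrated when
  the problem size changes by orders of magnitude (see the planted-recovery
  paragraph below).
- *minimum correlation*: the lowest correlation between the candidate and
  any voxel already in the ROI. Needs no regularizer, because it does not
  reward the proliferation of small homogeneous ROIs.

**Singleton convention.** The weighted-mean priority formally sums
`|I|ϕ(I)` over all ROIs, including size-1 ROIs for which `ϕ` is 0/0.
Singletons contribute `ϕ = 1` (a lone series is trivially homogeneous).
The choice shifts every candidate's priority equally at a given state, so
it cannot change which candidate wins, only the printed priority values.

**Implementation.** Candidates live in flat arrays holding, per pair, the
sum and minimum of correlations between the candidate and the ROI's
members; these are updated incrementally as ROIs grow, and the full
priority vector is recomputed vectorized at every pop, so the global terms
of the weighted-mean priority are always exact. A unit test verifies
equivalence with a plain textbook queue that recomputes every priority
from the global definitions. Ties are broken by ascending ROI label, then
ascending voxel index (C order over masked voxels), making runs
deterministic. The voxel-voxel correlation matrix is precomputed once per
window (O(V²) memory — fine up to tens of thousands of masked voxels).

**Acceptance threshold.** A popped candidate is accepted only if its mean
correlation to the target ROI ranks among the N% highest (default
N = 30) of a reference distribution; rejected pairs are removed for good,
which is how voxels can remain unassigned and seed ROIs can stay
single-voxel. The reference set is the mean-correlation values of all
currently queued pairs, and the (100−N)th percentile uses linear
interpolation; this is one defensible reading of "among the N% highest"
and is isolated in a single policy hook (`threshold_accept`) so other
reference sets can be swapped in. A consequence of the queue-as-reference
choice: the acceptance pressure adapts to what is still available, so a
threshold that blocks *all* growth is not reachable through N alone — the
degenerate all-singleton outcome requires an external reference
distribution.

**Single-voxel ROIs** are artifacts of the fixed seed count and are
excluded from all analysis; their count is reported.

## NCUT spectral clustering

Masked voxels form a graph with 6-neighbor edges weighted by correlation;
edges below the threshold (default 0.2) are removed, and any surviving
negative weight (possible only for a negative configured threshold) is
clamped to 0, since the normalized-cut cost assumes nonnegative weights.
Connected components are clusters; the largest cluster is repeatedly
bisected until the target count (default 246) is reached or nothing with
at least two nodes and a positive edge remains — hence the method can
return fewer clusters than requested. Each bisection solves the
generalized eigenproblem `(D − W)v = λDv`, takes the second-smallest
eigenvector, and sweeps over all splits of the sorted vector, keeping the
split with minimal `NCUT = cut/assoc(A,V) + cut/assoc(B,V)`. The sweep is
a relaxation, not an exact minimizer; on small well-separated graphs it
attains the brute-force optimum (tested by exhaustive enumeration), and on
arbitrary graphs it is near-optimal. Zero-degree nodes split off
trivially. Final labels are ordered by each cluster's smallest voxel index
for determinism.

## Analytics

The stability score of a node is the maximum interlayer weight to the next
layer (0 if none; undefined on the final layer, and final-layer nodes are
excluded from score pooling). Trajectories are computed from voxel sets
directly against every later layer, not by chaining interlayer edges, and
refuse references below 5 voxels (tiny sets make Jaccard jumpy).
Interaction curves bin per-node observations pooled across layers and
runs — no per-layer averaging first — into width-0.1 bins with a closed
first bin `[0, 0.1]` and half-open subsequent bins `(0.1, 0.2]`, …; values
exactly on an edge belong to the lower bin (guarded against float-division
artifacts). CDFs are plain empirical CDFs over pooled values.

Consistency carryover applies window-t ROI boundaries to windows t and
t+1 and reports per-ROI consistency pairs, the mean change
`mean(ϕ_{t+1} − ϕ_t)` and the relative change (mean change divided by mean
`ϕ_t`). For ROIs optimized on window t the expected sign is negative
(optimization overfits the window it saw); for random or static ROIs on
exchangeable windows it is zero in expectation.

## Synthetic generator

The generator emulates a planted-parcellation recipe: seeds drawn
uniformly without replacement over the mask are grown into 6-connected,
approximately spherical parcels by synchronous rounds (every parcel
absorbs all unassigned face-neighbors each round; contested voxels go to
the lowest label). Each seed carries an independent standard white-noise
series `x(t)`; every other voxel carries
`y(t) = w·x(t) + (1 − w)·a·n(t)` with `w = exp(−d²/(2σ²))`, `d` the
Euclidean distance to its parcel's seed, `σ² = 5` by default, and `n`
voxel-private white noise with amplitude `a` (default 1, the same scale as
the seed signals; the recipe fixes neither the series length nor the noise
amplitude, so both are parameters). Multi-window datasets relocate a
configurable fraction of seeds between windows, regrow, and concatenate
independently generated window volumes — there is deliberately no temporal
autocorrelation across window boundaries.

What the generator does *not* emulate: hemodynamics, scanner noise
spectra, physiological confounds, spatial noise correlations, and smooth
signal drift. Passing the planted-recovery tests therefore shows that the
algorithms recover the structure they assume when it is present and
identifiable; it does not certify performance on real BOLD data.

**Identifiability and test scales.** The mixing weight `w` decays to
~0.2 at `d = 4` voxels and is essentially 0 beyond `d ≈ 6` (for σ² = 5),
so voxels farther than that from their seed are noise and *cannot* be
attributed to any parcel by any method. Planted-recovery tests therefore
run in the identifiable regime: an 8×8×4 grid with 6 parcels (radii ≈ 2–3
voxels), 160 time points, and weak private noise (amplitude 0.1), where
both greedy variants recover every planted parcel with Jaccard ≥ 0.9
across generator seeds. Recovery runs use λ = 0: at 6 ROIs over 256
voxels the default λ = 100 makes the size penalty dominate the
consistency term (its scale grows as ROI count shrinks), which equalizes
ROI sizes instead of tracking planted boundaries — size shaping is the
regularizer's job, not recovery. The carryover sign checks use 50
generator seeds (random parcels, 8³ grid) and 8 seeds (greedy parcels,
8×8×4; the effect is large and every replicate is negative), with
tolerance bounds expressed as multiples of the measured Monte-Carlo
standard error rather than fixed constants.

## Known limitations

- The grower's O(V²) correlation matrix limits single-window inputs to
  roughly 10⁴–10⁵ masked voxels on ordinary hardware.
- The NCUT sweep is a relaxation; pathological graphs may be split
  suboptimally.
- The acceptance-threshold reference set is one reading of an ambiguous
  prescription (see above); results with strong thresholding depend on it.
- Atlas inputs are consumed as integer label volumes in the data's own
  voxel grid; no template-to-native registration is performed.
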