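# Methods

`mescreen` implements the analysis core of a larval zebrafish phenotyping
screen: behavioral profiling of mutant versus wild-type sibling larvae,
whole-brain voxel-wise activity/structure mapping with an empirically
calibrated significance threshold, and microexon sequence utilities.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic cohorts do and do not establish.

## Behavioral model and measures

**Trace model.** Each larva contributes a baseline delta-pixel trace (one
movement magnitude and one centroid per second) and, per stimulus event, a
high-speed burst of 285 samples over 1 s.  The synthetic generator draws
movement as an alternating renewal process: inter-bout intervals are
exponential with day mean `mean_off_s` = 20 s (multiplied by
`night_rate_factor` = 0.3 at night on the 14/10 h cycle, lights-off starting
night), bout durations exponential with mean `mean_on_s` = 1 s, and
per-frame movement during a bout Gamma(shape 2, scale 5).  Planted effects
act multiplicatively on the off-rate (bout-rate multiplier) or the Gamma
scale (magnitude multiplier); the expected detected bout rate is the renewal
rate `1 / (mean_off / mult + mean_on)`, which is the analytic oracle used in
tests.  Effects apply in full to `-/-` and at half dosage to `+/-`.

**Well geometry.** The well is the unit circle and "center" is radius <=
0.5 (area fraction 0.25), so a position-indifferent larva has an expected
center fraction of 0.25.  The center boundary is a parameter; no convention
for it is standard, so it is fixed and documented here.

**Bout detection.** Bouts are maximal runs of samples with `dpix >
threshold` (default threshold 0 on denoised input; a noise floor is a
parameter).  Runs separated by gaps strictly shorter than `merge_gap_s`
(default 0.2 s) are merged, and the merged bout's cumulative movement
includes the sub-threshold gap samples, which preserves the conservation
property (at threshold 0 and merge gap 0 the bout totals partition the trace
total).  Runs strictly shorter than `min_duration_s` (default 0) are
dropped.  A brute-force run-length enumeration is the exact oracle on short
traces.

**Measures and naming.** Baseline measures are computed per epoch and bin
(`numberofbouts`, `activeseconds` — frequency; `boutcumulativemovement`,
`boutvelocity` — magnitude; `boutcenterfraction` — location).  A bout
belongs to the bin containing its start; trailing partial bins are dropped;
frequency measures average per-bin values with empty bins counting zero,
magnitude/location measures average over non-empty bins and are missing when
no bin has bouts.  Stimulus measures per event subset are
`responsefrequency` (fraction of events with a supra-threshold burst
sample), `responselatency` (time to the first supra-threshold sample in ms,
averaged over responders only — onset is the one unambiguous landmark, and
excluding non-responders keeps latency orthogonal to frequency), and
`responsemagnitude` (mean cumulative burst dpix over responders).  Columns
follow the `epoch_measure[_suffix]` grammar
(`day0night_boutcenterfraction_3600`, `day6dpfdf1a_responselatency`), with
the parser splitting on the first two underscores so stimulus-code suffixes
may themselves contain underscores.

## Group statistics

Each measure is compared between one mutant genotype and wild-type siblings
(pairwise contrasts, matching how the screen displays homozygote-versus-wild
type; heterozygote contrasts run through the same machinery).  The test is
the tie-corrected Kruskal–Wallis test, alpha 0.05 per measure with no
multiple-testing correction — replication across two biological replicates
is the screen's guard against false positives; a correction toggle exists.
For total n <= `exact_max_n` (default 10) the p-value is computed exactly by
enumerating all assignments of the pooled values to the two groups, since
the chi-square approximation is unreliable there; the exhaustive-permutation
oracle in the tests checks this path exactly.

The effect size is the strictly standardized mean difference,
`SSMD = (mean_a − mean_b) / sqrt(var_a + var_b)` with sample variances,
undefined (and flagged) when both variances are zero.

**Bubble summary.** Significant measures are merged by category (frequency,
magnitude, location, latency) and split by SSMD sign.  The percent
significant uses the category's **full** measure count as denominator for
each sign group — whether the screen's own denominator excludes untestable
measures is not stated anywhere we could find, so the full count was chosen
as the conservative, order-independent option and is documented here.  Mean
SSMD averages only that sign group's significant measures.  Categories with
nothing significant emit no rows.

## Brain mapping

**Statistic.** Per voxel, a two-sided Mann–Whitney rank-sum Z with tie
correction and **no continuity correction**: with groups of 5 whose values
are fully separated, |Z| = 12.5 / sqrt(275/12) = 2.611.  Z is positive where
the first group is stochastically larger; fully tied voxels get Z = 0.  The
displayed effect magnitude is the difference of group medians (robust and
sign-consistent with the rank statistic).  No spatial smoothing or
cluster-size filtering is applied by default.

**Calibration.** The significance threshold is chosen empirically so that a
target fraction (default 0.05%) of control voxels would be called
significant: controls are repeatedly split at random into two pseudo-groups,
|Z| volumes of these null comparisons are pooled, and the threshold is the
`1 − target` quantile.  Because every pseudo-group is a subset of one
control cohort, the joint midranks are computed once and each split reduces
to a rank sum, so splits are nearly free.  Calibration is per comparison
(whether one global threshold per experiment would be preferable is an open
interpretation; per-comparison is self-contained).  "Control pixels" is read
as voxels of the 3D stack, not projection pixels.

**Discreteness of the achievable level.** The rank-sum null is discrete, so
only certain control-voxel fractions are achievable.  For half-splits of n
controls the two-sided tail probabilities near 0.05% were enumerated
exactly; with 28 controls (14 v 14) the atom at |Z| = 3.3082 has tail
5.2327e-4, the closest stably selectable level at or above the target, so
the validation study simulates 28-stack control cohorts.  For the pooled
quantile to land on the intended atom its sampling error must be well below
the inter-atom gap (~1e-4), hence the study pools 100 splits
(SD ≈ sqrt(5e-4 / (100·65536)) ≈ 9e-6); the library default stays at 20
splits, which is adequate at the looser targets typical of small cohorts.
Two consequences are worth stating plainly: (i) the realized fraction on
held-out null cohorts concentrates on 0.0523% rather than exactly 0.0500% —
a ~5% relative offset that no rank-based pipeline can remove; and (ii) the
validation criterion is therefore that the mean realized fraction over >= 50
seeds lies within three Monte-Carlo SDs (the SD of the per-seed realized
fractions, dominated by per-map binomial noise of ~0.009 percentage points
at 4 held-out maps per seed) of the target.

**Maps and summaries.** The signed significance map is zero where |Z| is
below threshold and carries the signed median difference elsewhere
(positive = increased, negative = decreased).  Region summaries divide the
summed positive and summed |negative| signal by the region voxel count, so a
uniform value over a region returns that value regardless of region size.
Total signal is the sum of |map|, pooling increases and decreases as one
comparison.  Projections sum slices along z or x.  The structure channel
(registration Jacobian determinant around 1) runs through identical
operations; registration and the determinant volume are inputs, never
computed here.

## Synthetic cohorts: what they emulate and what they do not

Brain stacks are baseline plus i.i.d. Gaussian noise with an additive delta
confined to one atlas region (multiplicative scale for structure); the atlas
is a Voronoi partition of random seeds inside an ellipsoid, giving compact,
nonempty, nonoverlapping regions.  Microexon records carry peptide/ortholog
pairs with controlled identity, and upstream introns constructed per layout
class (canonical: >= 2 UGC occurrences in the proximal 30 nt plus a
polypyrimidine tract; partial: exactly one feature; noncanonical: neither).

What the generators deliberately omit: spatially correlated imaging noise
and registration error, per-fish intensity normalization artifacts,
kinematic structure within bouts (no C-bend/O-bend shapes), habituation
dynamics within stimulus blocks, and real codon usage or splice-site
strength.  Passing tests therefore establish that the statistics recover
what was planted under the stated noise model, not that the thresholds are
tuned for any particular imaging rig or tracker.

## Sequence analyses

Percent identity comes from a global alignment with match 1, mismatch 0 and
linear gap −1 (no published scheme exists for these short peptides; this is
the simplest defensible choice), with identity = matched columns / total
alignment columns × 100.  Co-optimal alignments can differ in their
match/column counts; the implementation reports the aligner's first optimal
alignment and the test oracle accepts any co-optimal identity.  The
conservation ratio divides microexon identity by full-protein identity.  The
upstream layout classifier's thresholds (100 nt window, proximal 30 nt,
>= 2 UGC, tract of 10 nt at >= 75% pyrimidine) are explicit stand-ins for a
qualitative published description, all configurable; published
canonical/partial counts are not reproduction targets.  Inclusion fractions
are included/(included+skipped) band intensities; relative expression is
2^(−ΔΔCt) with ΔΔCt taken against the control-group mean ΔCt.  Profile
clustering is average linkage on Euclidean distances (the clustered-heatmap
default), checked against a naive O(n³) agglomeration.

## Problem sizes and determinism

Validation studies use desk-scale conditions chosen once: behavioral
cohorts of 20 larvae per genotype recorded for 1800 s at 1 Hz (the planted
bout-rate-×2 recovery and the null false-positive envelope), 32×32×8 stacks
with 10 fish per group and a +5 SD regional delta for planted-region
recovery, and the criterion-fixed 64×64×16 stacks for calibration.  All
randomness flows through one `numpy` Generator per simulation seed, and the
pipeline writes byte-identical artifacts for identical resolved
configuration and seed (provenance records the config hash, seed and
version).  NRRD output is not provided; stacks travel as TIFF.
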