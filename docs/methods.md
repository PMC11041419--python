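# Methods

This note documents the models, the defaults and the deliberate design
choices behind `gvpatterns`, in the spirit of a statistical package's methods
appendix. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

A CGM trace is a per-patient sequence of (timestamp, glucose) pairs in
mmol/L. mg/dL inputs are divided by 18.016 (glucose molar mass 180.16
g/mol). Timestamps are truncated — not rounded — to the calendar minute, and
multiple readings within one minute are collapsed to their median; this also
resolves daylight-saving duplicates. Rows with unparseable timestamps or
non-positive glucose are dropped and counted in a machine-readable report.
A LibreView-style flash-monitor export dialect is supported; automatically
logged ("historic") readings are used by default and manually scanned
readings are included only on request, since export conventions for scan
records vary.

Traces are sliced into windows of fixed duration on a stride grid anchored at
the patient's first sample (a midnight anchor is available). Windows are
half-open `[start, start + duration)` so a boundary sample belongs to exactly
one window at 0 % overlap. The nominal stride `duration · (1 − overlap/100)`
is rounded to the nearest whole minute (the 3×4 default grid contains
150 min × 25 %, whose exact stride of 112.5 min is not representable on a
minute grid). Windows extending past the last observation are suppressed,
except that the first window is always emitted so a trace shorter than one
duration still contributes. Samples travel as (offset, value) pairs — there
is no resampling before DTW, which handles uneven spacing by construction; a
linear-interpolation resampler to a regular grid exists for sensitivity
analysis only.

The density filter keeps a window iff its average rate
`60 · n_samples / duration` is at least 4 measurements per hour (strictly
fewer are discarded). At nominal 15-minute sampling this boundary is sharp:
a 150-minute window needs all 10 of its nominal samples, so a single sensor
dropout disqualifies it. The filter is intentionally strict rather than
tolerant; users with sparser devices should lower `min_density`.

## DTW distance

The distance between two windows is the minimal cumulative local cost over
monotone, continuity-respecting warping paths, with the symmetric unit-weight
step (diagonal, vertical, horizontal moves each add the local cost once) and
L1 local cost by default. Two choices matter and are deliberate:

* **No input normalisation.** The patterns must separate absolute glucose
  strata (a steady normal window from a steady severely hyperglycemic one);
  z-normalisation would erase precisely that signal. A `normalize_inputs`
  flag exists for methodological comparisons.
* **Raw cumulative cost**, not path-length-normalised. The raw cost is the
  simplest well-defined contract; a `dtw_distance_normalized` variant
  (cost / (len(a)+len(b))) is exposed separately.

An optional Sakoe–Chiba band (|i − j| ≤ w) accelerates long sequences and
errors out when narrower than the length difference. DTW is not a metric —
the triangle inequality fails in general — so nothing downstream assumes it.
The implementation is an O(nm) rolling-row dynamic program; the test suite
checks it against an independent top-down recursive formulation on hundreds
of random pairs and against literal enumeration of every warping path on
short sequences.

## Pattern extraction

Windows are clustered by k-medoids (PAM) on the pairwise DTW matrix:
farthest-point seeding from the run seed, then greedy best-improvement
medoid swaps until no swap lowers the total within-cluster distance (at most
100 rounds), best of 5 restarts. Medoids are actual training windows, which
keeps the "pattern" interpretable as a real glucose excursion. Labels 1..k
are sorted by ascending medoid mean so pattern 1 is always the
lowest-glucose pattern regardless of seed. k-medoids was chosen over
barycenter-averaging alternatives because a medoid is robust to the warping
artifacts of averaged sequences and matches the median-trend summaries the
package reports.

Window duration and overlap are selected by a grid search (defaults
{120, 150, 180} min × {0, 25, 50, 75} %): each cell is windowed, filtered,
subsampled to at most `max_windows` windows for tractability, clustered at a
fixed k, and scored with four internal validity indices computed directly on
the distance matrix — Silhouette, a medoid-based Calinski–Harabasz, COP, and
the modified Davies–Bouldin (DB*). Cells are ranked per index (higher better
for Silhouette/CH, lower for COP/DB*) and the winner minimises the mean
rank; ties go to shorter duration, then lower overlap. Rank aggregation is
an explicit, configurable policy — no single index is privileged.

The number of patterns is chosen by the elbow of the total within-cluster
distance W(k) over k = 3..8: the interior k maximising the discrete second
difference W(k−1) − 2W(k) + W(k+1), ties to the smaller k. A perfectly
linear curve has no elbow; the smallest interior k is returned with a
warning. The rule is deterministic where visual elbow-reading is not.

Per-pattern band summaries map each assigned window onto a common 15-minute
offset grid by nearest sample and report pointwise 20th/50th/80th
percentiles (linear-interpolation percentiles, NumPy default), plus which of
the standard glucose bands (3, 3.9, 10, 13.9 mmol/L) the envelope spans.

## Patient-level metrics

Time in patterns is the percentage of a patient's kept windows carrying each
pattern label; it always sums to 100. Time in range is measurement-weighted
(each reading counts once — near-uniform 15-minute sampling makes this
nearly identical to duration-weighting, which is not implemented). Band
edges follow the conventional row labels "≤3" and "≥13.9": v ≤ 3;
3 < v ≤ 3.9; 3.9 < v ≤ 10; 10 < v < 13.9; v ≥ 13.9. SD uses the n−1
denominator; COV = SD/mean. Consensus-target flags are strict inequalities
(TIR 3.9–10 > 70 %, COV < 0.36, HbA1c < 58 mmol/mol), so a patient exactly
on a cutoff does not meet the target. Diurnal tables attribute each window
to the clock hour of its midpoint.

## Patient clustering

Compositions are compared with the Hellinger distance
`(1/√2)·‖√(p/100) − √(q/100)‖₂`, chosen as the default percentage-data
distance because it is bounded in [0, 1], symmetric, and well-defined at
zero shares (patients often have 0 % of a rare pattern). Bray–Curtis,
Aitchison (with multiplicative zero replacement, δ = half the smallest
positive share) and plain Euclidean are selectable; any conclusion that
depends on the choice of distance should be checked across them.

Agglomeration is complete linkage (scipy), which guarantees monotone merge
heights. The number of clusters comes from the merge sequence: each merge
increases the total within-cluster distance by the sum of the cross pairwise
distances it fuses, and the tree is cut **just before the merge with the
greatest relative increase** (its jump divided by the preceding merge's
jump), restricted to merges adding at least the mean jump and to cluster
counts in [2, 10]. The relative form is essential: absolute jumps scale with
the product of the merging cluster sizes, so on any convexly increasing
curve the raw "greatest difference" criterion degenerates to 2 clusters;
likewise the largest raw gap between merge heights is dominated by a small
but extremely distant patient group (the poorly-controlled archetype) and
also returns 2. A `criterion="height"` option retains the raw height-gap
rule for comparison.

Cluster-versus-clinical comparison: one-way ANOVA for numeric variables
(two-level numeric flags are treated as categorical), Pearson chi-square
without continuity correction for categorical ones, missing values omitted
per variable, two-tailed p-values, significance flagged at p < 0.05, no
multiple-testing correction and no exact-test fallback (small expected cell
counts trigger a warning, not a method switch). A generic tertile-split
comparison (`group_compare`) covers duration-of-use style analyses.

## Synthetic cohorts

The generator emulates a 15-minute flash monitor: six deterministic
templates anchored to the clinically meaningful strata — T1 steady 3–6
mmol/L, T2 slight rise 6→8, T3 decline 11→6, T4 rise 11→16, T5 concave level
14–16.5, T6 peak-and-decline 19–28 — with strictly increasing means, tiled
into days as contiguous 150-minute segments drawn from per-patient mixture
weights. Four patient archetypes (A–D) range from hyperglycemia-dominated to
well-controlled mixtures. Meal-hour segments (09:00, 13:00, 19:00 ± 1 h)
preferentially draw the rising templates T2/T4 and the small hours
(02:00–06:00) the steady low template T1, giving recoverable diurnal
structure. Gaussian noise (default SD 0.5 mmol/L), i.i.d. sample dropout
(default 5 %) and clipping to [1, 30] mmol/L complete the model. Defaults
were fixed once as plausible study conditions: 20 patients × 14 days, the
noise level at roughly the sensor-error scale, dropout mild.

For patient-level studies, compositions are drawn from Dirichlet
distributions centred on the archetype mixtures with concentration 100
(within-archetype spread of a few percentage points on the dominant shares)
and deterministic equal archetype counts, so all four archetypes are always
present.

What the generator does **not** model: autocorrelated sensor error, smooth
transitions between segments (templates abut discontinuously), meal/insulin
pharmacokinetics, inter-day habit variation. Consequently, passing the
planted-recovery tests shows the pipeline recovers block-structured
template mixtures under noise and dropout — not that six patterns is the
right description of any real cohort.

## Known limitations

* Tiling in window-length segments makes ground truth exact only for
  windows aligned with the segment grid; 50 %-overlap windows straddling two
  segments are genuine mixtures with no unique true label, so recovery is
  asserted on grid-aligned windows.
* With archetype frequencies as imbalanced as real cohorts (one archetype at
  a few percent) and within-archetype spreads as wide as real time-in-pattern
  tables, no cut criterion we examined recovers the 4-cluster structure
  reliably; the planted-structure studies use equal archetype counts.
* The pairwise DTW matrix is O(n²) in windows; studies here subsample to a
  few hundred windows (`max_windows`), which is ample for the planted
  structure. Production-scale runs should raise the cap or enable the
  Sakoe–Chiba band.
* The exact percentage-data distance used in comparable clinical analyses is
  often unreported; Hellinger is this package's default, and the distance
  choice is the main faithfulness risk when comparing against published
  cluster structures.
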