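# Methods

## Model and assumptions

The method treats a routine clinical measurement file as an unlabeled
mixture: a dominant normal subpopulation plus abnormal contamination in one
or both tails. Sorted ascending and plotted against rank, such data form an
inverted-S curve; the central plateau — the region of smallest consecutive
differences — is taken to contain the normal values. The working assumptions
are:

* the normal core contributes more than half of the data (otherwise the
  plateau is not the dominant flat region);
* values are recorded at a fixed instrument resolution, so exact ties are
  common and meaningful;
* within the plateau the normal values are approximately Gaussian, which is
  what justifies reporting mean ± 2 SD as the reference interval and
  mean ± 1 SD (≈68% coverage) as the plateau-selection band.

No distributional assumption is made about the contamination.

## Procedure and numerical choices

1. **Tie detection by resolution rounding.** Absolute consecutive
   differences are rounded to the nearest multiple of the series resolution
   before the minimum is taken (computed in integer resolution units to
   avoid float drift). On truly continuous data the minimal difference would
   almost surely be unique and the seed degenerate; at instrument resolution
   ties are the norm and the minimal-difference set is a genuine cluster.
   Resolution is inferred as the finest decimal step present in the input
   (overridable).

2. **Seed membership.** A minimal difference at position i involves
   datapoints i and i+1; the seed is the union of both endpoints over all
   minimal pairs, which makes overlapping pairs contiguous.

3. **Band membership.** The band [seed mean − k·SD, seed mean + k·SD]
   (k = `sd_multiplier`, default 1) is closed, extended by
   ε = 10⁻⁶ · resolution on both sides: differences that far below the
   instrument resolution are floating-point noise, and without ε a datapoint
   that defines the band limit itself can fall out of it. Because the series
   is sorted, membership is one contiguous index run.

4. **Intersections.** The band lines are intersected with the
   piecewise-linear curve through (i, xᵢ). A datapoint within ε of a line
   counts as an exact node; a line coinciding with a flat run takes the
   run's outermost node (first crossing → leftmost, last crossing →
   rightmost), consistent with the inclusive filter. A line outside the data
   range clamps to the corresponding endpoint with a warning. Plateau
   membership is defined by the filter; the intersections are reported as
   coordinates only.

5. **Dispersion.** Sample SD (n−1 denominator) everywhere, matching the
   spreadsheet heritage of the manual workflow. Degenerate cases (seed SD
   0, single plateau point) proceed with a warning rather than inventing a
   fallback, so results never change silently.

6. **Statistics suite.** Welch's t (unequal variances,
   Welch–Satterthwaite df), Mann-Whitney U (U for the first sample,
   midranks; exact p for tie-free n₁·n₂ ≤ 200, tie-corrected normal
   approximation otherwise), and Levene's test (center = mean by default;
   median gives the Brown–Forsythe variant). All two-sided; verdict
   "Sig Diff" iff p < α (default 0.05). Identical-degenerate inputs return
   statistic 0, p 1 by convention. No multiple-testing correction is
   applied across the three tests; the report carries a note saying so.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `resolution` | inferred | smallest meaningful value step (measurement units) |
| `sd_multiplier` | 1.0 | half-width of the plateau-selection band, in seed SDs |
| `ref_multiplier` | 2.0 | half-width of the reported reference interval, in plateau SDs |
| `alpha` | 0.05 | significance level for the comparison verdicts |
| `index_base` | 1 (CLI) | x-coordinate convention for display; internal indices are 0-based |

The two multipliers are conventions (68% band, 95% reference range), kept
configurable because nothing in the algorithm forces them.

## Synthetic cohorts

`default_nerve_cv_spec()` emulates a pooled motor conduction velocity file:
n = 2000, normal core 44.6 ± 2.4 m/s, 25% low-tail contamination at
33 ± 4 m/s (pathology slows conduction), clipped to the physiologic
10–70 m/s range and rounded to 0.1 m/s. Component counts are fixed (not
multinomial) so mixture weights are exact; everything is reproducible from
one seed. The generator supports two-sided contamination for amplitude-like
variables. It does **not** model covariates of real nerve conduction data
(age, height, temperature, measurement site), serial correlation between a
patient's repeat studies, or non-Gaussian core shapes — so passing tests
show the pipeline recovers the parameters of this idealized mixture, not
that any particular clinical file is well described by it.

## Known limitations

* **Contamination bias.** With heavy, overlapping, one-sided contamination
  the method underestimates the core mean. At instrument resolution the
  minimal rounded difference is typically 0 and duplicate ties occur in the
  contaminated tail as well as the core, so the seed cluster spans most of
  the dataset and the ±1 SD band inherits the mixture's skew. On the default
  synthetic cohort (25% low contamination) the plateau mean sits ≈1 m/s
  below the true core mean while the plateau SD tracks the core SD closely —
  the same behaviour reported for other one-pass indirect reference-limit
  methods on skewed mixtures. Lighter or two-sided contamination reduces the
  bias; the acceptance script reports the recovery error honestly rather
  than hiding it.
* One plateau only: a sorted series is monotone and the method assumes a
  single dominant normal core; bimodal normal subpopulations are out of
  scope.
* The reference interval is mean ± 2 SD, which presumes approximate
  normality inside the plateau; no nonparametric percentile option is
  provided.
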