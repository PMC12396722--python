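# Methods

## Shape metrics on glyph rasters

Glyphs are binary ink bitmaps with 0-based (row, col) coordinates. All three
pairwise metrics are symmetric, zero on identical glyphs, and reject empty
rasters rather than returning a sentinel.

**Pixel count.** Ink area. The pairwise distance is the absolute difference
of the two areas — the only symmetric, zero-on-equal combining rule
consistent with reading size differences as the signal. No size
normalization is applied by default, since ink-area differences *are* the
signal for this metric.

**Perimetric complexity.** perimeter² / ink area. The default perimeter is
the exposed-edge count under 4-connectivity (for every ink pixel, the number
of its four sides facing non-ink or the canvas edge). This is integer-exact
and resolution-stable: a filled n×n square scores (4n)²/n² = 16 at every
resolution, which anchors the closed-form tests. A marching-squares contour
length is available via `perimeter(..., method="contour")` for users who
prefer sub-pixel boundaries; it is not used anywhere by default. Perimetric
complexity is translation-invariant by construction.

**Hausdorff distance.** The classic max-min point-set metric on the two ink
coordinate sets, computed via `scipy.spatial.distance.directed_hausdorff` in
both directions. By default both sets are centroid-aligned first so the
measure captures shape rather than placement on the canvas; `align=False`
gives the raw metric, which satisfies the triangle inequality on point sets
and is what the brute-force oracle tests compare against bit-exactly
(alignment introduces non-integer coordinates and hence one-ulp float
divergence between equivalent computation orders).

Binarization thresholds grayscale in [0, 1] at 0.5, dark = ink.

## Phonetic distances

Phonemes are numeric feature vectors (typically binary articulatory
features). Four metrics: Euclidean, cosine (rejecting zero vectors), Jaccard
(defined for binary vectors only; non-binary input is an error rather than a
silent threshold), and feature-edit (Hamming) distance. For binary vectors
Euclidean² equals feature-edit identically, which the property tests
exploit. The built-in ten-pair consonant reference table stores printed
pairwise distances, not feature vectors — the feature inventory behind it is
not public, so reconstructing vectors would be guesswork; user feature
tables load from CSV. Cross-metric correlations of that table are reported
at two decimals, matching how such tables are printed. One quirk of the
reference table is retained as-is: the (p, h) row has Euclidean 2 with
feature-edit 2, breaking the Euclidean² = edit pattern every other row
obeys, implying the original feature space was not fully binary.

## Systematicity scoring and exclusivity

A material's score correlates its 10 phonetic distances with its 10 glyph
distances: Pearson r with a two-sided t-test p (n − 2 df) and Spearman rho
(average ranks) with its standard two-sided p, both via `scipy.stats`. The
items are treated as independent observations; no Mantel-style
distance-matrix permutation is attempted. Two-sided p-values are used
throughout since positive systematicity is the hypothesis but sidedness is
a reporting convention.

Cross-validation scores each material under all three glyph metrics.
**Exclusivity** gates on Pearson p only: a material passes iff its
intended-metric p < α (default 0.05) and both off-metric p ≥ α. Spearman is
reported but not gated — rank correlations of scalar-feature distances are
too entangled across metrics for a rank-based exclusivity criterion to be
attainable (a material optimized for Hausdorff will often rank-correlate
with pixel count, since topologically distinct additions also add ink).

The standard design is 10 pairs over 20 distinct glyphs; the API accepts any
n ≥ 3 for synthetic studies, with `Material.validate_standard()` enforcing
the canonical shape where it matters.

## Stimulus-set optimization

Accept-if-better search: a candidate material replaces the incumbent iff its
target-metric Pearson r strictly improves; ties keep the incumbent so runs
are reproducible from the seed alone. Two proposal moves:

* **restart** (default): each candidate is an independent uniform draw of 20
  glyphs paired and matched to the phoneme pairs at random. This treats the
  search as best-of-N random sampling.
* **swap**: local perturbation of the incumbent (replace one glyph with an
  unused one, exchange glyphs between two symbol pairs, or swap two pairs'
  phoneme-slot assignments). This converges orders of magnitude faster when
  the library actually contains a highly systematic subset, and is what the
  planted-recovery experiments use: restart sampling cannot assemble a
  specific 10-pair subset out of a 40-glyph library in any reasonable
  iteration budget, whereas hill climbing assembles it pair by pair.

With `exclusivity_required`, restart mode rejects non-exclusive candidates
outright. In swap mode the climb itself is on r — a local chain whose every
step must already be exclusive could never leave a random (non-significant)
start — and the result is the best exclusive candidate encountered along the
climb. If no exclusive candidate is ever seen, the best-so-far material is
returned with `exclusivity_ok=False` rather than an exception, making the
constraint's feasibility observable. A final score is always recomputed from
scratch on the returned material; if the library is so degenerate that the
selected distances are constant (e.g. all filled squares under perimetric
complexity), the score is NaN with p = 1.

The objective is Pearson r, not rho and not p, and the trace of incumbent r
values is asserted non-decreasing in the tests.

## Synthetic data

**Glyphs** are stroke/blob compositions, not pixel noise, so the three
metrics stay partially decoupled the way they are for real letterforms: ink
budget drives pixel count, boundary jaggedness (a growth-bias parameter that
switches blob growth between compact and dendritic) drives perimetric
complexity, and the placement of a small satellite component away from the
main body drives Hausdorff distance. Canvases default to 48×48 — large
enough for satellite offsets up to ~19 px and ink areas up to ~160 px
without crowding, small enough that a full pairwise Hausdorff matrix over a
40-glyph library is effectively instant.

**Planted libraries** embed 10 engineered glyph pairs among 20 decoys of the
same visual family. Per target metric:

* *pixel*: the partner's ink area exceeds the base's by ⌊25·d⌋ pixels for
  phonetic distance d (exact, since blob growth hits its pixel budget
  exactly); satellites at random offsets and random jaggedness randomize the
  other two metrics.
* *perimetric complexity*: measure-and-match from a 120-glyph pool spread
  across jaggedness at independently random areas; pairs are picked greedily
  so their PC gaps follow an affine map of the phonetic distances.
* *Hausdorff*: pairs (body, body + small attached edit + satellite), with
  the satellite offset chosen by scanning so the centroid-aligned Hausdorff
  distance follows an affine map of the phonetic distances; the attached
  edit randomizes ink area.

Affine maps preserve Pearson correlation, so the planted material's
target-metric r is ~1 by construction. Construction is verified and retried
(fresh randomness, same seed stream) until the planted material scores
r ≥ 0.95 under the target metric with both off-metric Pearson p ≥ 0.2 — the
retry implements the stated construction goal (off-metric distances carry no
signal), not a fit to any particular dataset.

**Respondents** draw each forced choice i.i.d. from a per-group multinomial
over the three types. Defaults mirror the study cohort this design targets:
271 UK / 308 CN / 266 KR participants, 10 choice questions, chance-level
(uniform) weights — the null configuration; planted preferences are
expressed by overriding the weights. The follow-up symbol→phoneme assignment
is consistent with the material's orientation with probability
`assignment_accuracy` (default 0.8, a realistic above-chance value chosen
once). An optional Dirichlet overdispersion adds participant-level
heterogeneity; it is off by default because the analyses operate on pooled
proportions.

What the generator does *not* emulate: visually faithful archaic
letterforms, question-order or fatigue effects, per-item difficulty, and
any correlation between a participant's choice and their follow-up
assignment. Passing tests therefore demonstrate that the pipeline's
statistics behave correctly under its own generative assumptions, not that
those assumptions describe human respondents.

## Survey analysis

Preference proportions are pooled fractions per group over the three types;
the intended rate is the fraction choosing the type designated for one's
group (UK→english, CN→chinese, KR→korean). The Monte Carlo null simulates
whole cohorts of uniform random choices (the natural "chance ≈ 1/3"
baseline, randomized at the individual choice level) and the p-value is
two-sided, tie-inclusive, with add-one smoothing: p = (1 + #{replicates at
least as far from 1/3}) / (reps + 1) — standard Monte Carlo practice that
never returns 0. Question-level selection-pattern vectors (3 preference + 1
intended per group, 12 in all, n = 10 points each) are correlated pairwise
with Pearson r and two-sided t-test p, flagged with the conventional
significance stars and no multiple-testing correction, matching the
stars-only presentation such matrices conventionally get.

## Problem sizes and numerical choices

The planted-recovery experiments use 20 seeded runs × 3 metrics with 3,000
swap iterations each — enough for the hill climb to plateau at the planted
optimum with a comfortable margin. The null uses 10,000 replicates at
266 × 10 choices; calibration uses 1,000 uniform cohorts against a shared
null (the test is on the null's quantiles, so sharing it costs nothing);
power uses 300 simulated cohorts. Ties in Spearman ranks take average ranks;
ties in the optimizer keep the incumbent; all random streams are
`numpy.random.default_rng` seeded explicitly, and every generator is
bit-reproducible from its config and seed.

## Known limitations

* Exact reproduction of published cross-validation values for real archaic
  letterforms requires the original symbol images and rasterization
  parameters (canvas, font, resolution, alignment), which are not public;
  the planted-library experiments reproduce the qualitative pattern instead.
* The optimizer offers no global-optimality guarantee; the planted setting
  is the regime where its behaviour is verifiable.
* Jaccard distance is undefined for non-binary feature tables and the
  package treats that as an error, not a thresholding opportunity.
* The survey model assumes independence across a participant's answers
  unless overdispersion is enabled, and the permutation null inherits that
  assumption.
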