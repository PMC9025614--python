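# Methods

## The assay and what the package models

The mouse-tail test scores a compound's ability to convert the tail scale
epidermis from its parakeratotic baseline (no granular layer) to
orthokeratotic differentiation. Everything downstream of the stained section
is modelled here: measurement of the primary lengths on (label) images,
derivation of the orthokeratosis degree, mean epidermal thickness and
percentual drug activity, and the nonparametric comparison layer. The wet-lab
side — animals, dosing, sectioning, staining — is out of scope, as is any
rendering of realistic histology texture.

## Synthetic study generator

The generator's defaults are the study conditions: 7 arms, 6 animals per
group, 10 scales per animal (60 scales/group), 5 thickness readings per scale
(300 readings/group), with each arm's mean ± SD of orthokeratosis degree and
epidermal thickness set to the reported group values
(`DEFAULT_GROUP_PARAMS`). The reported number of animals per group is not
stated anywhere; 6 is implied by "10 scales per animal, 60 per group" and is
the configurable default.

Per-scale degrees and thickness readings follow a hierarchical normal model.
Only group-level SDs are reported, so the variance is split between an
animal-level random effect and a scale-level residual by an intraclass
correlation `animal_icc` (default 0.3). The default is chosen so that
animal-level statistics exist at all and so that group means carry a
realistic design effect; the reported pairwise p-value floor (≈ 0.004–0.006)
is consistent with n = 6 exchangeable units per group, not n = 60. Draws are
truncated to the parameter's range (degree to [0, 100], thickness strictly
positive) by clipping; the normal family is a stated assumption, not an
inference — only first and second moments are reported.

The scale length B is entirely unreported; it is drawn from normal(500, 50) µm
truncated at 100 µm (values typical of tail-scale micrographs at low
magnification) and exposed as parameters. A is then `degree/100 × B`, which
makes A ≤ B an identity rather than a property to enforce.

Seeding: one master seed; each (group, animal, scale) gets a substream whose
entropy is a SHA-256 hash of those labels combined with the master seed.
Identical (spec, seed) therefore reproduce byte-identical CSV output, and
any subset of the design regenerates reproducibly.

Two statistical notes that matter when validating the generator:

* The standard error of a simulated group mean includes the clustering
  design effect: `SE = sd·sqrt(icc/n_animals + (1−icc)/n_scales)`, roughly
  twice the naive `sd/√60` at the defaults. Coverage checks use this SE.
* Moment-recovery checks (empirical mean/SD → spec values) are run with
  `animal_icc = 0` and several thousand scales: under clustering, growing the
  per-animal scale count alone cannot shrink the animal-level error, and the
  sampling error of an SD at a few hundred observations exceeds a 2 % band.

### Pseudo-histology images

`generate_label_image` rasterizes one scale as an integer label map
(0 background/dermis, 1 viable epidermis, 2 granular layer, 3 stratum
corneum, 4 follicle): two full-depth follicle columns bounding the scale, an
epidermis band whose thickness profile is piecewise constant over equal
horizontal segments, a stratum-corneum band above, and a single contiguous
granular run of length `degree/100 × B` at a random offset within the
follicle-center-to-center interval. The run is placed relative to the
centers (it may pass above a follicle column) so that `degree = 100`
measures back exactly as A = B. The `.truth.json` sidecar records the exact
requested A, B, degree and thickness values plus the calibration, making
every measurement a round-trip test against ground truth.

These images are schematic: no staining color, noise, tissue curvature or
segmentation ambiguity. Passing the round-trip therefore validates the
measurement *algorithm* (run lengths, landmarks, pixel counting, calibration)
— it says nothing about segmenting real hematoxylin–eosin micrographs, which
this package deliberately does not attempt.

## Morphometry

* **B** is the distance between the *centers* of two adjacent follicle
  column intervals (midpoint, ties downward). Centers are a symmetric,
  reproducible landmark; whether the original on-screen measurements used
  centers or edges is unknowable, and the difference is one follicle width.
* **A** is the longest contiguous run of columns containing at least one
  granular-class pixel inside the scale window ("continuous" is read as
  qualifying the measured segment). A total-coverage `sum` mode exists for
  sensitivity analysis; on data with a single contiguous granular segment
  the two modes coincide. A minimum-pixels-per-column threshold (default 1)
  is available for noisy label maps.
* **Thickness** is the count of viable-epidermis pixels in a sampled column
  times the calibration — the stratum corneum is excluded by construction.
  The 5 columns sit at fractions 1/6 … 5/6 of the window (placement within
  the scale is not specified anywhere; equal spacing is the symmetric
  choice). A sampled column with no epidermis pixels is excluded and logged,
  never silently reported as zero thickness.

Guarantees: 0 ≤ A ≤ B for every window; all outputs in µm; results invariant
under horizontal translation of the image content. Expected accuracy against
the generator's ground truth: degree within `100 · 2 px / B` percentage
points (one rounding pixel at each end of the run), thickness within 1 px.

## Scoring

Group summaries report the mean and sample SD (n − 1 denominator) of
per-scale degrees, and of pooled thickness readings (per-animal means are
available as an alternative unit; whether the reported SDs are over scales
or animals is not stated — over scales is the default). Drug activity is
computed from group *mean* degrees, is exactly 0 for the vehicle control,
is left blank for the untreated arm, and is reported unclipped when
negative: the formula admits it, and clipping would hide compounds that
perform worse than vehicle. Internal values keep full precision; report
tables round half-away-from-zero to 2 decimals.

## Statistics

The omnibus test is the tie-corrected Kruskal–Wallis H on midranks with the
chi-square (k − 1 df) approximation. Pairwise comparisons run the two-sample
special case (equivalent to a tie-corrected two-sided rank-sum test) — the
published comparisons are labelled Kruskal–Wallis, and for two groups that
name is well-defined without committing to any particular post-hoc
procedure.

**Unit of analysis.** The single biggest open choice: p-values can be
computed over animals (n = 6), scales (n = 60) or readings (n = 300) per
group, and the published values do not say which. The default is per-animal
means with an exact permutation p — animals are the independent units, and
the resulting p-value floor 2/C(12,6) ≈ 0.00216 matches the order of
magnitude of the published floor (≈ 0.004). Scale- and reading-level modes
are available but treat correlated observations as independent.

Exact permutation p-values enumerate all C(N, n1) assignments of the pooled
midranks (up to 200 000; Monte-Carlo with a stated resample count beyond
that, and for k > 2 groups). The observed assignment is included, so
p ∈ (0, 1]. H for permuted assignments is computed from per-group rank sums
with the same tie correction; tests pin this to the library H to 1e-12.
Degenerate all-identical input yields H = 0, p = 1 with a warning. No
multiple-testing correction is applied by default (matching how such
matrices are conventionally presented); Holm and Benjamini–Hochberg are
opt-in, in which case adjusted p-values populate the matrix.

Exact reproduction of the published pairwise p-values is *not* claimed: the
raw data are unavailable and the original unit/procedure is unstated. The
simulation layer instead checks the qualitative pattern: type-I error within
Monte-Carlo error of the 5 % level under the null, near-certain `S` verdicts
for the largest reported group separation, and a substantial fraction of `N`
verdicts between the two negative-control arms.

## Numerical choices and degenerate inputs

* Degrees clip `100·A/B` at 100 to guard the A = B case against 1-ulp
  floating-point round-up.
* CSV output uses a fixed `%.6f` float format so identical runs are
  byte-identical across platforms.
* Rasterization rounds lengths to the nearest pixel; thickness bands are at
  least 1 px.
* Empty groups, missing control labels, fewer than two follicles, geometry
  that does not fit the canvas, and `Okc = 100` all raise explicit errors.
* Pipeline failures name the failing stage and remove partial outputs.

## Problem sizes

Validation suites use the study-sized design (420 scales per simulated
study), 100 generated images for measurement round-trips, 1000 replicates
for null calibration and 200 for power — sizes chosen to put Monte-Carlo
error well inside the asserted bands while keeping a full run in the tens of
seconds.

## Known limitations

* Label-map input only; no segmentation of real micrographs.
* The normal/ICC generative model is the minimal structure consistent with
  reported moments — real per-scale degree distributions may be skewed or
  bounded away from the truncation limits in ways the generator does not
  emulate.
* Published pairwise p-values are reproduced only in qualitative S/N
  pattern, not numerically (raw data unavailable).
* Dose–response modelling across the 1 %/2 % arms is out of scope.
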