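# Methods

This note documents the quantification model, the parameter defaults and
the numerical choices behind `sish-score`, and states what the synthetic
test bed does and does not establish about real slides.

## Scoring model

Dual-probe brightfield ISH scoring estimates HER2 gene amplification from
the ratio of HER2 to CEP17 signals over a representative set of tumor
nuclei. The package computes, over the selected nuclei,

- `ratio = Σ her2_i / Σ cep17_i` — the amplification ratio;
- `copies = Σ her2_i / n` — mean HER2 copies per quantified nucleus.

Representativeness follows manual practice: qualified nuclei are ranked by
their *differentiation* `her2_i − cep17_i` (descending; ties broken by
higher HER2 count, then lower instance label, giving a deterministic total
order) and the top 20 are selected. The differentiation ranking
deliberately favors nuclei that display amplification most clearly, which
is how human scorers pick fields; for heterogeneous scenes it therefore
biases the ratio upward relative to an all-nuclei average — this is a
property of the scoring convention, not a defect.

When `copies` falls in the equivocal copy-number band `[4, 6)` and more
ranked nuclei are available, the next 20 are counted and totals recomputed
over ≥ 40 nuclei before classification (`extra_set_counted`). Fewer than 20
qualified nuclei do not abort the score; the result is flagged
`low_confidence`, since reference tables show legitimately scored regions
with fewer qualifying nuclei.

Status calls: the default `binary_ratio` mode is Positive iff the unrounded
ratio is ≥ 2.0 — the only reading consistent with the reference table's
labels and its two known misclassifications; the published three-way bands
overlap as printed (Equivocal up to 2.2 but Positive above 2.0), so
`three_way_ratio` mode resolves Equivocal to `[1.8, 2.0]`. An `asco_full`
mode adds copy-number bands (≥ 6 Positive, `[4, 6)` Equivocal) for
sub-cutoff ratios. Reported ratios are rounded to 2 decimals half away from
zero to match printed tables; classification always uses the unrounded
value.

### CEP17 qualification and the high-positivity fallback

Only nuclei with ≥ 2 CEP17 signals qualify. In strongly amplified samples
no nucleus may meet that criterion (silver deposits can obscure the red
probe); the pipeline then admits single-CEP17 nuclei and sets
`fallback_used`, mirroring the flexibility of manual assessment. With the
fallback disabled the region fails with a structured error instead.

## Preprocessing

Per-channel min–max rescaling (`value_range` mode, the literal formula
`x' = (x − min)/(max − min)·(upper − lower) + lower`) standardizes
contrast; channels are never mixed, so probe color identity survives. The
canonical bounds `[1, 99.8]` look like percentile-clipping percentages, so
a `percentile` mode is provided in which the extrema are replaced by the
corresponding percentiles and the result is clipped to `[0, 1]`. Constant
(blank) tiles map to the lower bound with a warning rather than failing, so
degenerate tiles do not abort batch runs. A gamma transfer curve
`clip(gain·x^γ, 0, 1)` is applied before detection; of the three canonical
configurations (0.9, 1), (0.5, 1), (0.5, 2) the default is (0.5, 1), the
middle listed one. The published parameter names ("Sigma and alpha") are
mapped to (exponent, gain), the only reading on which the configurations
are well-formed.

Note that global per-channel min–max stretching assumes the tile exercises
a reasonable tonal range (background plus stain plus dots). On degenerate
two-color images the stretch can collapse the nuclear stain to black; real
ROIs and the synthetic scenes are unaffected.

## Signal detection

Classification runs in HSV on the normalized image, restricted to
foreground (background = all channels above a whiteness threshold, default
0.82):

- HER2 (black): `V ≤ 0.35` and `S ≤ 0.45` (dark and chromatically
  neutral); contrast = `1 − V`.
- CEP17 (red): hue within ±25° of pure red, `S ≥ 0.30`,
  `V ∈ [0.20, 0.90]`; contrast = `S · redness`, where redness decays
  linearly with angular hue distance from 0°.

No numeric thresholds are published for this stage; the defaults are
repository choices derived from the qualitative appearance (black vs red
dots) and all are exposed in the `signals.*` config block. Candidates are
grouped by 8-connectivity; components outside the physical size bounds
(0.4–2.5 µm equivalent diameter, converted to pixel area via the image's
µm/px calibration — typical ISH dot scale at 0.13 µm/px) are discarded, and
components below `faint_contrast_min` (default 0.15) are removed as noise.

**Cluster decomposition.** HER2 probes cluster; whether a cluster counts as
one signal or many is left open in the field, so both behaviors sit behind
`cluster_split` (default on). A component's multiplicity is
`max(1, round(area / singleton_area))` where `singleton_area` is the median
area of components no larger than twice the *25th-percentile* component
area. The lower-quartile pivot is deliberate: anchoring on the minimum
observed area lets border-clipped dot fragments poison the estimate, and
anchoring on the median fails when clusters are half the population; the
quartile pivot recovers planted 2-, 3- and 4-fold clusters exactly in both
regimes.

## Nucleus segmentation and qualification

Segmentation is a backend contract (`segment: RoiImage → LabelMap`,
deterministic for fixed input). The default classical backend thresholds
the bluish-purple nuclear counterstain (hue 0.50–0.92, S ≥ 0.12,
non-background), fills the holes punched by probe dots, smooths the
Euclidean distance transform (Gaussian σ = 2) so each convex nucleus has a
single regional maximum, seeds at maxima separated by at least 4 µm, and
separates touching instances by watershed. Instances under 20 µm² are
treated as debris. An adapter for a pretrained star-convex-polygon
segmenter is provided for environments with that runtime installed; the
filters and scoring downstream are backend-agnostic.

Spots are attributed to the nucleus covering their *rounded centroid* —
unambiguous for dots straddling a boundary, and exactly testable. A cluster
spot contributes its full multiplicity. Qualification then applies, in
fixed order:

1. **Truncation** — any nucleus whose mask touches an image edge is
   excluded (partial nuclei under-count).
2. **Overlap** — for polygon backends that can emit overlapping instances,
   pairwise overlap fractions (intersection / own area, on rasterized
   masks) are computed once on the full set and every nucleus whose largest
   fraction exceeds 0.5 is removed; when both members of a pair exceed the
   bound, both are removed. Computing fractions once makes the outcome
   deterministic and independent of processing order. Label-map backends
   cannot overlap and pass trivially.
3. **CEP17 rule** with the fallback described above.

"Missing or excessively overlapped information" is operationalized solely
as these two geometric rules; no further shape heuristics are applied.

## Evaluation statistics

Bland-Altman agreement on paired (method, reference) region ratios: bias =
mean difference, limits of agreement = bias ± 1.96 × sample SD (n − 1
denominator; the 1.96 multiplier is fixed, matching standard practice).
Limits are reported **signed**; published limit pairs that cannot bracket
their own bias symmetrically indicate a dropped minus sign, which
recomputation from the packaged table confirms (−2.91 / 3.10 around 0.09).

The paired t-test defaults to two-sided: the p-value printed alongside the
reference table (0.72) is reproduced only by the two-sided computation
(0.728; the one-sided value is 0.364), so the accompanying "one-sided"
label appears to be a misstatement. Sidedness is configurable. Degenerate
zero-variance differences are handled explicitly (t = 0, p = 1 when the
bias is also zero; p = 0 toward the favored side otherwise).

Misclassification: method ratios thresholded at 2.0 against the reference
Pos/Neg call. On the packaged table this yields exactly two disagreements —
a false negative at image 168138203 (ratio 1.19 vs expert 5.0) and a false
positive at the region printed with ratio 2.59. The table's footnote
attributes the 2.59 score to image 169283911, but the table body prints
2.59 for image 169284039 (169283911 carries 1.39); the package follows the
table body, so the false positive is reported as 169284039.

The standard bias CI (bias ± t₀.₉₇₅,df · sd/√n) is provided; the published
interval (0.07–0.17) is inconsistent with the table's dispersion and is not
asserted. Likewise the published correlation of 0.91 does not recompute
from the table's ratio columns (0.36); `pearson_correlation` is exposed but
that value is not asserted — which paired quantities produced it is
unstated.

The packaged `table4_fixture.csv` transcribes the reference table verbatim:
33 rows (22 non-amplified, 11 amplified), including the two repeated-ID
rows, because the bias and limits reproduce only at n = 33.

## Synthetic scenes

The generator emulates the documented appearance: light eosin-toned
background, bluish elliptical nuclei, black/red probe disks. Defaults:
640×640 px at 0.13 µm/px, 25 nuclei of radius 4.5 ± 0.3 µm (large enough to
pack up to ~9 well-separated 0.45 µm dots), eccentricity ≤ 0.10, dot radius
0.45 µm, Gaussian pixel noise on the 8-bit scale. Clusters are rendered as
single disks of k-fold singleton area with recorded multiplicity; faint
dots at reduced contrast; truncated nuclei planted across borders;
overlapping pairs as equal circles at 0.6 r separation (≈ 62 % mutual
overlap, safely beyond the 50 % bound). Count distributions (`fixed`,
`uniform`, `poisson_floor`) emulate normal (2/2), amplified (6/2),
borderline (4/2 — copies 4.0, exercising the extra-20 recount) and
high-positivity (8/1, exercising the fallback) regions; these are the
preset scenes. Identical spec + seed gives bit-identical output.

**What passing on synthetic scenes shows — and what it does not.** The
scenes validate the counting, qualification and scoring logic end-to-end
against exact ground truth, including exact ratio recovery on noise-free
scenes and ±0.1 under pixel noise. They do not emulate stain variability,
out-of-focus blur, scanner artifacts, touching nuclei in dense sheets,
stromal tissue or debris; perfect recovery here therefore bounds algorithmic
correctness, not clinical performance. The published whole-slide results
(nucleus counts per region, the 0.91 concordance) depend on a fine-tuned
segmentation model and real tissue and are not reproducible at desk scale.

## Numerical conventions

Floating-point arithmetic throughout; conversion to 8-bit only at explicit
export, rounding half away from zero. Coordinates are 0-based, row-major,
pixel-center. Connectivity is 8-neighbor for spots, and watershed regions
inherit scikit-image's conventions. Problem sizes in the test suite and the
acceptance script (10–45 nuclei per scene, 512–832 px tiles, 10–20 seeds
per property) were chosen as the smallest scenes that exercise every rule —
selection needs > 20 qualified nuclei, the recount needs > 40 — while
keeping the whole suite quick to run.

## Known limitations

- The default classical backend assumes separable, roughly convex nuclei;
  dense sheets of touching nuclei need the star-convex backend.
- Per-channel global normalization can mis-map degenerate tiles (see
  Preprocessing).
- Case-level aggregation across multiple ROIs, IHC scoring and invasive-
  region detection are out of scope; the unit of analysis is one ROI.
- Cluster multiplicity is an area-ratio estimate and saturates at the upper
  spot-size bound; very large coalesced clusters are undercounted.
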