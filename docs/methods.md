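# Methods

`neglectmap` implements a multi-level lesion-symptom mapping pipeline for
egocentric and allocentric visuospatial neglect and validates it end to end
on synthetic stroke cohorts with planted effects. This note documents the
models, the synthetic study conditions, the numerical choices, and what the
validation experiments do and do not show.

## Behavioural model and scoring

Neglect severity is measured from a cancellation task: a page of target
items among left-gap and right-gap distractors, spanning normalized
horizontal positions `x ∈ [−1, 1]` (rightward positive) divided into five
equal-width columns.

* **Egocentric raw asymmetry**: hits in the two right-most columns minus
  hits in the two left-most columns; the central column is excluded.
  Positive values indicate left egocentric neglect. Impairment cut-off:
  `|ego_raw| > 2`.
* **Allocentric raw asymmetry**: left-gap false positives minus right-gap
  false positives; positive values indicate left allocentric neglect.
  Cut-off: `|allo_raw| > 1`.
* **Centre of cancellation (CoC)**: the mean `x` of correctly marked
  targets — the egocentric severity metric. We use the plain normalized
  mean rather than any position-weighting scheme; this is a deliberate,
  documented simplification.
* **Allocentric proportion**: the lateralized false-positive asymmetry
  divided by the number of correctly identified targets, which controls for
  how much of the array the patient explored.
* **Validity**: a record with fewer than five correctly marked targets is
  invalid and excluded from all analyses.

Column bins are half-open `[left, right)` with the rightmost bin closed.
Consequently the left-right mirror symmetry of all four scores is exact
except for items placed exactly on a column boundary (a measure-zero set
the synthetic layout avoids).

For each analysis condition (left/right × ego/allo) the cohort severity
vector assigns patients classified with that condition their severity
magnitude (|CoC| or |allocentric proportion|) and **exactly zero to
everyone else**, including patients impaired in the opposite
lateralization. Magnitudes (rather than signed scores) are the default so
that every analysis tests a one-sided, positive damage→severity
association; the signed variant is available via configuration.

## Voxel-wise mapping

Each patient's binary mask is transformed by direct total lesion volume
control (dTLVC): lesioned voxels carry `1/√V` with `V` the lesion's voxel
count, so each lesion has unit sum-of-squares and small lesions are
up-weighted. `V` is counted in voxels, not mm³, which makes the unit-norm
invariant exact and scale-free.

Only voxels damaged in **strictly more than** `min_coverage` patients
(default 10) are tested; the same coverage mask is shared by all four
conditions so voxel-wise power is constant across them. (The inclusive
`>=` variant used for describing group coverage maps is available via
`inclusive=True`.)

Per tested voxel, severity is regressed on the dTLVC value by simple OLS;
the slope t statistic (df = n−2) is mapped to a z score through
`z = Φ⁻¹(F_t(t))` and a p value per the configured sidedness (one-sided,
damage→greater severity, by default — consistent with magnitude severity
vectors). Family-wise control is Bonferroni: `alpha = family_alpha /
n_tested_voxels`. Significant voxels are grouped into 26-connected
clusters (6/18 available) reported with voxel count, cm³ volume, peak z
and the world-mm coordinate of the peak.

Numerical details: the upper z tail is computed through the survival
function (`norm.isf(t.sf(t, df))`) because composing `ppf(cdf(·))` loses
all resolution once the tail probability drops below ~1e−16; z is clamped
to |z| ≤ 37 (the double-precision limit of the normal quantile). Cluster
peaks are *located* by the t statistic, which does not saturate, and
*reported* as z. Voxels with zero predictor variance inside the analysis
mask are flagged, assigned t = 0 and p = 1, and never counted as tested
discoveries. A zero-variance severity vector is a degenerate outcome and
raises rather than returning an all-zero map.

## Disconnection quantification

The normative connectome stand-in is a set of polylines in world mm, each
carrying one tract label, plus a labelled parcellation with a node table
(hemisphere, network, declared homologue). A streamline is *disconnected*
by a lesion when its path intersects any lesioned voxel.

The hit test walks every polyline segment through the voxel grid with an
exact parametric traversal (Amanatides–Woo style). We chose exact
traversal over the conventional densified point sampling because it is
step-free and its hit set provably contains that of any point-sampling
scheme along the same polyline; in randomized comparisons against a
0.1 mm sampling oracle the only disagreements ever observed are grazing
chords shorter than the oracle's own step, where the traversal is right.
Point sampling at a caller-chosen step remains available
(`streamline_hit(..., step=...)`) and is used as the independent oracle in
tests. Per-streamline voxel sets are cached in a sparse incidence matrix,
so cohort-level hit testing is a single sparse product.

* **Tract level**: percent disconnection = 100 × (hit streamlines in the
  tract) / (streamlines in the tract).
* **Edge level**: streamlines are assigned to the unordered pair of
  parcels containing their first and last vertices (exact endpoint voxel,
  no dilation; streamlines with a background endpoint are excluded from
  every edge). The per-patient disconnection matrix stores, for each node
  pair with atlas streamlines, the percent disconnected; it is symmetric,
  and pairs with no atlas streamlines are undefined (flagged through the
  denominator matrix, stored as 0). The edge universe follows the
  node-by-node convention — K nodes give K² matrix entries (135 → 18,225)
  — while analyses test deduplicated unordered pairs.
* **Group counts**: per edge, the number of patients with at least a
  threshold disconnection (default 50%, inclusive).

## Tract- and edge-level regressions

Each unit (tract or included edge) is tested with
`severity ~ 1 + b₁·disconnection + b₂·lesion_volume`; inference concerns
`b₁` only (one-sided positive by default, df = n−3). The implementation
solves all units at once by Frisch–Waugh–Lovell residualization, which is
algebraically identical to per-unit normal equations (asserted to 1e−10
against statsmodels in the tests). Reported per unit: slope, t, p, the
**adjusted R² of the full two-predictor model** `1−(1−R²)(n−1)/(n−3)`,
and, for transparency, the partial R² of the disconnection term
`t²/(t²+df)`.

Edges enter the analysis only when damaged in strictly more than
`min_patients` (default 10) patients; the damage definition (any positive
disconnection, or at-least-x-percent) is configurable with any-positive as
default. Bonferroni divides the family alpha by the tested-unit count
(70 tracts → 0.0007; 2,708 edges → 1.85e−5). When no unit survives, a
Benjamini–Hochberg 5% step-up (via statsmodels) is applied as a fallback
and the results are flagged as FDR-level. Degenerate units (zero-variance
disconnection) are skipped with a recorded reason; disconnection collinear
with volume is flagged and the reduced-model p marked invalid.

## Homologue overlap

Cross-hemisphere comparison mirrors one thresholded map across the
midline (an exact voxel-column reflection, requiring the midline at the
grid's x mid-extent — an involution preserving volume) and computes the
Dice coefficient `2|A∩B|/(|A|+|B|)`, together with the overlap as a
percent of each map. Interpretation bins use strict lower bounds
(>0.8 excellent, >0.6 substantial, >0.4 moderate, >0.2 slight, otherwise
poor); boundary values fall to the lower label. Tract correlates are
matched by contralateral name (L_/R_ prefix or _left/_right suffix
swapping) and edges by mirrored node identity from the parcellation's
declared homologue pairs; units without a defined homologue (e.g. edges
with a midline subcortical node) are reported as unmatched, never
silently dropped.

## Synthetic study generator

The generator emulates the statistical structure the analyses assume,
not anatomical realism:

* **Template**: a 40×48×40 grid at 1 mm by default (24³ for the
  validation experiments); midline at the x mid-extent.
* **Parcellation**: recursive-bisection block parcels — a left cortical
  compartment, its exact mirrored right counterpart (left parcel i ↔
  right parcel i+n as declared homologues), and a midline subcortical
  slab without homologues. Defaults 50+50 cortical + 35 subcortical =
  135 nodes. Parcels are contiguous and non-overlapping by construction.
* **Streamlines**: quadratic Bezier bundles between random voxel centres
  of endpoint parcel pairs, bowed by a random control point
  (`curvature_jitter` × endpoint distance), sampled so consecutive
  vertices are at most half the minimum voxel spacing apart, clipped to
  the template box; tract grouping maps named tracts to edge lists.
* **Lesions**: single 26-connected blobs — the sublevel set of a
  randomly rotated, anisotropic ellipsoidal distance field multiplied by
  a smoothed noise field (surface jitter), cut at exactly the sampled
  volume; if jitter fragments the set, the component holding the field
  minimum is kept and topped up with the cheapest adjacent voxels.
  Sides are drawn from (left, right, bilateral) = (178, 237, 65)/480,
  the lateralization of a representative acute stroke cohort; unilateral
  blobs are confined to their hemisphere and bilateral blobs must cross
  the midline. Volumes are Gamma-distributed, by default with mean 10%
  of the hemisphere's voxels and cv 0.6. The 10% scale was set by a
  coverage-adequacy calculation: at cohort sizes of a few hundred it
  keeps the central portion of each hemisphere — including planted
  targets — inside the >10-patient coverage territory, mirroring the
  clinical situation in which the reported correlates lie inside the
  covered territory. At 5% the filter admits only ~2% of the grid and
  the voxel-wise analysis would exclude the planted region entirely.
* **Behaviour**: `severity = Σ_k ±effect_k·damage_k·gate_k + ε`, with
  damage the fractional damage to the target (voxel-region fraction,
  tract %/100 or edge %/100), the sign set by the effect's laterality
  (left-neglect positive), `gate ~ Bernoulli(impaired_fraction)`
  modelling susceptibility, and Gaussian ε. Severities are rendered into
  item-level responses through a logistic link — the per-target cancel
  probability decays with |x| into the neglected side as egocentric
  severity grows (base hit probability 0.95·expit(4) ≈ 0.93), and the
  false-positive probability on the neglected gap side rises from a 2%
  base with allocentric severity. The link is a modelling convenience
  (no generative model of real response data is claimed) and is fully
  configurable. Ground truth (damage, gates, linear predictors,
  severities) is always emitted alongside the rendered data.

Zero-inflation of the cohort (an unimpaired majority) emerges from the
anatomy: most lesions miss the planted targets, and the zero-constraint
assigns exact zeros to everyone not classified with the condition.

### What the synthetic data does not show

The generator produces blob lesions, block parcels and short synthetic
bundles. Passing tests therefore demonstrates the correctness and
calibration of the *statistics and geometry* — not that the pipeline
recovers effects under real vascular lesion distributions, real
tractography, registration error, or behaviourally realistic response
noise. Loaders accept real NIfTI masks, parcellations and TCK
streamline sets, but none are bundled.

## Validation experiments

Both experiments use a compact study — 24³ grid, 200 patients, a 15-node
mirrored parcellation, 6 tracts × 2 edges × 8 streamlines — sized so the
full suite runs in about a minute.

* **Null calibration** (100 cohorts): severity is pure Gaussian noise
  (a planted effect of size 0, unit noise). The family-wise error of the
  Bonferroni-corrected voxel, tract and edge analyses is the fraction of
  cohorts with any significant unit; each must stay within the binomial
  95% band around the nominal 0.05 (≤ 0.08). Bonferroni is conservative
  under the strong spatial correlation of lesion data, so observed rates
  sit at or below nominal.
* **Parameter recovery** (20 cohorts; effect 1.0, noise sd 0.1): with a
  single planted voxel-region / tract / edge effect, recovery requires
  the global peak (by t) to fall inside the planted region, and the
  planted tract/edge to rank first by adjusted R², in ≥ 90% of cohorts.

## Known limitations

* The voxel-wise statistic is an OLS slope test, a deliberate continuous
  -score regression choice; rank-based alternatives are not implemented.
* Endpoint parcel assignment uses the exact endpoint voxel with no
  dilation (a configuration extension point).
* Mirroring requires the midline at the grid mid-extent; arbitrary
  midlines would need resampling, which is out of scope.
* The cancellation layout composition (item counts and positions) is
  configuration, not a claim about any clinical array.
* Permutation-based FWER, multivariate lesion-symptom mapping and
  probabilistic disconnection maps are out of scope.
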