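# Methods

## Vessel model and branch taxonomy

The pipeline consumes manually traced vasculature: per-segment centerline
polylines in continuous pixel coordinates (origin at the image top-left,
x rightward, y downward), an arteriole/venule label per segment, a parent
link, and the optic-disc position. Artery/vein identity is taken from the
annotation — in practice graders separate them by caliber (veins are wider),
position and morphology — and no automatic classifier is attempted. Only
trees are accepted; a cycle in the parent links is a hard error at ingest.
Segments without a parent must start within a configurable radius
(default 50 px) of the optic disc.

**Diameter.** Vessel width is sampled at pre-set intervals of arc length
(default 20 px) plus, always, the most proximal and most distal positions;
the segment diameter is the arithmetic mean of those samples. Widths come
from a supplied per-vertex profile or are measured as perpendicular chords
through a binary vessel mask (quarter-pixel marching in both normal
directions). A zero chord anywhere is treated as a broken mask and raised,
not silently skipped.

**Branch classes.** Roots are `primary_main`. At a split off a main branch,
daughters with caliber below `small_ratio_threshold` × parent diameter
(default 0.6) are protruding `small` vessels of the parent's order; if two
or more daughters are non-small, the split is a bifurcation and each
non-small daughter advances one order (primary → secondary → tertiary); a
trifurcation is one bifurcation event; a single non-small daughter simply
continues its parent's class. Everything downstream of the second main
bifurcation is `tertiary`, and so is any descendant of a small branch (the
grading convention groups all distal, similar-caliber vessels as tertiary).
The 0.6 ratio is this package's convention — the underlying grading
protocol distinguishes "bifurcation daughters" from "protruding small
vessels" visually without a stated threshold — and is exposed as a
parameter. For reporting, `primary_total` / `secondary_total` are the
unions of the corresponding main and small classes.

## Perivascular zones

The perivascular zone of a segment is the stroked line of total width 3*d*
centered on the centerline: one vessel diameter of tissue on either side
*including* the lumen strip (the grading protocol draws a single 3*d*-wide
stroke and counts every signal inside it, so plaques overlying the vessel
are perivascular). End caps are flat by default (no disk beyond the
endpoints; round caps available). Geometrically the band is the exact union
of per-segment perpendicular strips plus the round-join turn wedges at
interior vertices — the point set within 1.5 *d* of the polyline whose
nearest polyline point is not an endpoint.

Rasterization tests pixel centers with a half-open convention (an edge
passing exactly through pixel centers claims its low side only), which
keeps pixel-count areas unbiased: a 30 × 100 px axis-aligned band counts
exactly 3000 px². The centerline's own pixels are always included, which
can add a one-pixel sliver at the flat caps. Zones of different segments
are built independently and may overlap; per-vessel-type total areas are
union areas (overlap counted once). Overlapping arteriolar and venular
zones are both kept intact — no clipping priority is imposed.

## Plaque detection, assignment, counting

Detection is a deliberately transparent spot operator standing in for
proprietary enhancement chains: white top-hat (disk radius 12 px) to remove
smooth background, a matched Gaussian filter (σ = 1.5 px), a robust
threshold at median + 6 × MAD-scaled σ of the filtered image, 8-connected
components filtered to [4, 400] px². All parameters are exposed; the
pipeline equally accepts externally detected plaque lists (CSV of
centroids), which bypass detection entirely. A flat image yields an empty
list with a warning. Analysis can be restricted to a quadrant polygon;
plaques outside it are ignored entirely, including in the non-perivascular
remainder.

A plaque belongs to a zone iff its footprint overlaps the zone mask by at
least one pixel — the border-touch rule: touching the boundary suffices,
full containment is not required. A plaque may belong to several zones.
Counting rules per subject:

* each (scope, exclusive-class) cell counts distinct plaques touching at
  least one zone of that type and class;
* `primary_total` / `secondary_total` rows are arithmetic sums of their
  main and small cells, so row additivity holds exactly;
* scope grand totals are distinct-plaque counts, so a plaque touching both
  an arteriolar and a venular zone increments both type totals but the
  combined perivascular total once — which is why type totals can sum to
  more than the combined row;
* `non_perivascular` = plaques touching no zone; the partition
  `total = perivascular + non_perivascular` is an enforced invariant.

## Statistics layer

* **Gaussian gate:** D'Agostino–Pearson omnibus and Shapiro–Wilk at
  α = 0.05; a sample is Gaussian if *either* test's p exceeds α. Below the
  omnibus test's minimum n (8) the decision rests on Shapiro–Wilk alone.
* **Two-group contrasts:** pooled-variance unpaired two-tailed Student's t
  when both groups pass the gate, two-tailed Mann–Whitney U otherwise.
  Pooled (not Welch) variance is used deliberately: recomputing the
  reference cohort's secondary-branch contrast from its printed summary
  cells under pooled df = 26 reproduces the printed p = 0.0037 exactly.
  A summary-statistics mode takes (mean, SD, n) per group directly so
  printed table cells can be checked without raw data.
* **Fold change:** ratio of group means with a Fieller 95% CI for the
  ratio of independent normal means (percentile bootstrap offered as an
  alternative). When the reference mean's own CI reaches zero (g ≥ 1) the
  interval is unbounded and reported as NaN. CIs are descriptive, never
  used as gates. The published CI construction is unstated, so intervals
  are not validated against printed values.
* **Severity analysis:** one-way ANOVA with Tukey HSD adjusted pairwise p
  across CDR levels 0.5 / 1 / 2; a level with n < 2 is dropped with a
  warning.
* **Correlations:** Pearson r per (count column, clinical variable) cell on
  pairwise-complete observations (so n varies per cell, as in the reference
  tables). Holm–Bonferroni is applied within a family; the default family
  is one clinical variable's column across all vascular categories, with a
  global-family option (the reference tables do not state their family).
* **Stratifications:** diagnosis (NC vs IC), MOCA (> 26 vs ≤ 26; 26 itself
  falls in the impaired side), CDR (0.5/1/2). Missing values are excluded
  with a reported count.
* Display rounding (FC to 1 decimal, r to 2, p to 2 significant figures)
  applies to report output only; tests run on full precision.

## Synthetic data

**Trees.** One venular and one arteriolar tree grow from an optic disc in
a corner of a 640 × 640 px field (emulating a supero-temporal quadrant
view): root calibers 14 px (vein) and 11 px (artery), gently curved
segments (sinusoidal lateral offset, amplitude 4 px), two main bifurcation
generations with daughter/parent caliber ratios drawn from [0.70, 0.85],
and protruding small twigs at ratio [0.25, 0.45] with probability 0.7 per
main segment. Because the caliber ratios stay strictly on either side of
the 0.6 threshold, the growth labels are exactly recoverable by the
rule-based classifier — that is the label oracle used in testing. Geometry
that escapes the field is steered back or retried.

**Images.** Plaque centers are drawn from an inhomogeneous spatial Poisson
process: background intensity λ_bg = 0.6 per 10⁴ px² outside zones and
λ_bg × multiplier inside (defaults 3.0 arteriolar / 2.0 venular, reflecting
the peri-arteriolar predominance of the reference cohort; overlapping zones
take the maximum rate). Centers are thinned to a 12 px minimum separation
so spots stay individually resolvable, then rendered as Gaussian profiles
(amplitude 120–200 above a background of 60, σ 1.6–2.6 px) on Gaussian
noise of SD 8 — a spot SNR of 15–25, comfortably above the SNR ≥ 5 regime
the detector is validated in. Ground truth records each plant's position
and true zone memberships (by center pixel).

**Cohorts.** Per-subject counts are drawn cell-by-cell from the reference
cohort's published (mean, SD) per group — truncated normal rounded to
integers by default, negative binomial optionally — for the exclusive
cells; totals are recomputed as sums so per-subject additivity holds
exactly. The three scopes (combined, peri-venular, peri-arteriolar) are
drawn as separate marginals: the published cells themselves are not
additive across scopes because each cell has its own missing-data n, so no
single joint distribution matches all printed cells at once. The
non-perivascular cell is not published as a table cell; its defaults
(NC 120 ± 40, IC 156 ± 40) mirror the reported 1.3-fold group contrast.
Clinical covariates (MOCA, CDR, hippocampal volume, WMHI count, cognitive
Z-scores) carry planted Pearson correlations with designated count columns
via a Gaussian copula applied within group; CDR is discretized from its
latent score at quantiles reproducing the reference 11/14/3 severity split.
Group-level marginal differences plus within-group planting mean that a
cohort-wide correlation mixes both sources; recovery experiments therefore
use a homogeneous cohort (identical group cells and marginals) when the
planted coefficient itself is the target.

**What passing tests do and do not show.** The generators reproduce the
statistical skeleton of the reference data — group-difference magnitudes,
correlation signs, count additivity, vessel-caliber conventions — not the
appearance of real SLO fundus images: no uneven illumination, no vessel
autofluorescence, no tracing error, no plaque-size/shape heterogeneity
beyond isotropic Gaussians, no inter-eye or inter-grader variability.
Recovery results bound the pipeline's self-consistency, not its accuracy
on real images.

## Problem sizes and numerical choices

Validation workloads are sized for quick, repeatable runs: 100 random
layouts for the pixel-exhaustive membership oracle (60 × 60 px frames),
100 generated trees for label agreement, 20 rendered 512 × 512 px images
for detection recovery, 500 replicate cohorts at the reference sizes
(9 vs 19) for effect-direction recovery, and n = 200 for planted
correlation recovery (sampling SD of r at ρ = −0.5 is ≈ 0.053, so the
±0.12 acceptance bound is ≈ 2.3 SD). Detection is deterministic for fixed
input; every stochastic step takes an explicit seed, and all pipeline
outputs carry provenance sidecars (config digest, package version, seed).

Known limitations: no automatic vessel segmentation or artery/vein
classification; no physical-unit calibration (the analysis is
scale-relative); plaque counting treats the quadrant mask as the universe,
so deposits outside it are invisible rather than non-perivascular; the
far periphery and capillaries are out of scope.
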