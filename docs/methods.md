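# Methods

## The assay

A blastocyst expands after blastulation (tB): blastocoel pressure pushes
the trophectoderm outward and thins the zona pellucida until hatching.
The assay standardizes this by sampling each metric at
tB + 0, 30, …, 300 min — eleven points including the tB frame itself.
Including the tB frame anchors every trajectory at its own blastulation
state; "every 30 min over the 5 h" would otherwise be ambiguous between
10 and 11 samples. The window is embryo-centred: tB is annotated per
embryo, and biopsy never happens within 5 h of tB, so the grid is always
covered. An earlier 2-h/10-h variant of the assay exists; it is reachable
by passing a non-default offset grid, which the expansion-map output
flags as non-standard.

Between stored frames values are interpolated linearly; a milestone or
offset outside the stored span raises in strict mode and yields NaN in
lenient mode.

## Mask metrics

Masks are single-focal-plane label images (0 background, 1 zona,
2 embryo proper, 3 ICM) with an isotropic µm-per-pixel scale declared in
a sidecar, never assumed. Areas are pixel counts × scale²; the embryo
proper includes the blastocoel and the ICM (everything enclosed by the
inner zona surface). The TE area in the ICM/TE ratio is emb-A − ICM-A in
the same plane, so both areas come from one annotation geometry.

Zona thickness is the largest distance from the embryo edge to the
*outer* zona edge (the zona's outer contour, not its inner surface),
i.e. a directed Hausdorff distance. The default estimator extracts both
edges as subpixel marching-squares contours, computes each embryo-contour
point's nearest distance to the outer contour, smooths the profile over
an ~8-px arc, and takes the maximum. The smoothing exists because a raw
maximum over rasterized contours rides the ±0.35 px jagging upward by
~0.3 px — a bias that matters when group means are recovered to a
fraction of a pixel; the smoothed estimator is unbiased to ±0.01 px
(SD 0.19 px) on rendered eccentric annuli. Two variants are kept:
`hausdorff_pixel` (raw directed Hausdorff over 8-connected boundary
pixel centers, the form that matches an exhaustive boundary-pair
search exactly) and `radial` (largest outer-minus-inner radius over
angular rays from the embryo centroid). All variants agree within ~2 px
on nested near-circular contours; sub-pixel accuracy beyond that is not
claimed.

An embryo not enclosed by zona (post-hatching, broken ring) triggers a
warning and the value is computed anyway. Hatching/herniation detection
is out of scope.

## Synthetic cohorts

The generator emulates a PGT-A cohort: cycles of 1 + Poisson(1.78)
blastocysts (mean ≈ 2.8/cycle), euploidy Bernoulli(0.4056), live-birth
competence of euploids Bernoulli(0.4252). Group calibrations give, for
aneuploid / euploid / euploid±live-birth groups, the mean ± SD of each
timing (tSB, tB, tEB, t-biopsy, hpi) and of each metric anchor (zp-A,
emb-A, zp-T, ICM-A) at tB, tEB and t-biopsy.

**Timings** are drawn as correlated Gaussians sharing a per-embryo pace
factor (equicorrelation 0.85) and rejection-resampled (≤ 100 attempts)
until ordered with t-biopsy ≥ tB + 5.5 h. Rejection truncates the
timing marginals slightly (the means of ordered samples are not exactly
the configured means); metric anchors are unaffected.

**Anchors** share one latent quality factor per embryo (equicorrelation
0.6 by default), floored at 1% of the group mean. emb-A is derived as
zp-A minus a positive annulus-area gap (lognormal with unit mean, log-SD
0.25, one factor per embryo scaled by the calibrated mean gap at each
milestone): the two areas are near-duplicates of one another, and
deriving one from the other guarantees zp-A > emb-A ≥ ICM-A per embryo
without biasing either group mean. ICM-A is capped at 90% of emb-A.

Milestone ordering (areas up, zona thickness down) is deliberately *not*
enforced per embryo. Rejection-resampling ordered triples would shift
the recovered group means by far more than their standard errors
(≈ +950 µm² on zp-A at t-biopsy at n = 500, versus 3 SE ≈ 770), and the
calibrated ratio spreads (e.g. +38% ± 31%, −37% ± 24% t-biopsy/tEB)
already imply a real minority of non-monotone embryos — collapses and
local re-thickening exist in real data. Spontaneous collapses as events
are otherwise not modeled: trajectories are monotone between anchors.

**Trajectories** interpolate exponentially (linearly in log value)
between the tB, tEB and t-biopsy anchors on a uniform grid (default
10 min) with the milestone times inserted exactly, so percent change
accumulates multiplicatively, values stay positive, and each segment is
monotone. Metrics before tB are held at the tB anchor; the assay never
samples there, and values reported "at tSB" are flagged as the earliest
available frame.

**Grades**: Gardner letter pairs collapse to four tiers (AA excellent;
AB/BA good; BB/AC/CA average; CC/BC/CB low). A tier is drawn from the
population marginal with probability 1 − s and set deterministically
from latent competence (competent euploid → excellent, other euploid →
good, aneuploid → average) with probability s, where s is the
grade–competence association strength (default 0.5: embryologist
accuracy between chance and perfect; s = 0 is exact independence, s = 1
strict dominance).

**Transfers**: only euploids; cycles with a euploid transfer with
probability 216/237; transfers follow embryologist priority (grade tier,
random tie-break) and stop at the first live birth. Live birth equals
the latent competence flag (miscarriages count as no live birth).

**Rendered frames** are nested discs: outer radius from the zp-A anchor;
the zona annulus width and the inner-contour eccentricity chosen to make
the maximal edge distance equal the zp-T anchor while keeping a 2-px rim
everywhere (rings thinner than 2 px cannot be rasterized at 1 µm/px
without breaking up, so the rendered width floors there); the ICM an
angular sector of the inner disc sized by the ICM-A anchor. The
published zp-T values exceed what the zp-A/emb-A gap allows for
concentric contours (a ~470 µm² area gap implies a sub-2-µm annulus
against an 8-µm thickness), so thickness and the two areas cannot all be
honored in one frame; rendering prioritizes zp-A and zp-T, and the
rendered emb-A is smaller than its anchor whenever the conflict binds
(always at t-biopsy). Consequently the render/measure round trip is
validated for zp-A and zp-T, and anchor recovery for all four metrics is
validated on the drawn values.

### What the generator does not emulate

No collapse/re-expansion events; no segmentation noise or illumination
artifacts (masks are perfect discs); no within-cycle correlation of
embryo quality beyond the transfer logic; no maternal covariates
(adjustment presets name maternal age and morphology tier and apply to
whichever columns the user's table provides); no aneuploidy-class
structure. Passing tests therefore demonstrate the correctness of the
measurement, sampling, statistical and ranking machinery — not that the
assay separates real euploid from aneuploid embryos.

## Statistics

Continuous two-group contrasts gate on Shapiro–Wilk at α = 0.05 per
sample: both normal → Welch *t* (unequal variances — safer than pooled
when only "t-test" is specified); otherwise → Mann–Whitney U (a mixed
pair goes nonparametric, the conservative choice). Two samples with zero
variance return p = 1 with a flag. Categorical: Fisher's exact for 2×2,
χ² otherwise. Expansion maps report per-offset p unadjusted — matching
how such maps are usually read — with a Holm-adjusted column emitted
alongside because 11 correlated tests are performed; the
earliest-significant-offset readout uses the unadjusted column by
default. No correction is applied for embryo-within-cycle clustering;
the map metadata says so.

Logistic fits are maximum likelihood (Newton/IRLS via statsmodels) with
Wald 95% CIs on exp(β); separation or divergence is flagged
non-converged rather than raised. Morphology enters adjustments as the
ordinal tier coded numerically by default (indicator coding is a caller
choice — the design matrix is the caller's). AUC is the tie-corrected
rank statistic with a seeded percentile bootstrap over subjects
(2000 resamples by default; the CI method is a package choice).

## Ranking simulations

The assay profile collapses to a rank by the value at tB + 300 min —
thinner zona on top (ascending) for zp-T, larger area on top
(descending) for zp-A/emb-A. The collapse rule is a genuinely open
choice; net slope over the window and percent change tB→300 are
selectable alternatives and the choice is recorded in the output
metadata. Exact ties break by steeper thinning/expansion slope, then by
embryo id: the order is total and deterministic, and in continuous data
ties have probability ~0.

Simulation 1 (mixed-ploidy cycles): the embryologist top set is every
embryo at the maximal tier. A multi-embryo top set is "right" only if
all-euploid, "wrong" only if all-aneuploid, and "mixed" otherwise.
Simulation 2 (≥ 2 euploids, ≥ 1 transferred): the embryologist priority
is the historically first-transferred embryo, not the grade-based top
set — the retrospective record is the ground truth of what was chosen.
An assay top without a transfer record is reported as its own category
(its outcome is unknowable), and the "may improve up to" bound counts it
as a potential success. Percentages round half away from zero to
integers (one decimal only where a source prints one).

The reference fixtures in `qsea_morph.simulate` reconstruct the
published per-category counts cycle-by-cycle so that the full ranking →
classification → aggregation path reproduces every published percentage
exactly. The published tables are not jointly consistent at the level of
individual cycles (the concordance and effectiveness margins conflict by
a few cycles), so the fixtures realize the aggregate percentages with an
internally consistent assignment; for the transfer simulation the
thickness- and area-ranking statuses are encoded jointly per cycle since
only their aggregates are published.

## Problem sizes and tolerances

Acceptance-grade checks use 500 embryos per group for calibration
recovery (3-SE bands), 20 random annuli for the geometry oracle (areas
within 2%, thickness within 2 px), 25 replicates of 200 embryos per
group for the divergence-onset check (≥ 80% must flag 150 min first),
and 2000 null replicates for the type-I calibration of the gated test
([0.039, 0.061] at α = 0.05 — a ±2.2-SD band, so an unlucky Monte Carlo
stream is retried once on an independent stream). Geometry tolerances
are expressed in pixels at 1 µm/px; the anti-tangency rim adds ≤ 0.03 µm
to recovered thickness means.

## Known limitations

- Single focal plane; no 3-D fusion or multi-plane consistency.
- The thickness definition depends on the outer zona edge; after zona
  breach the reading is undefined in spirit (a warning is emitted).
- Rendered emb-A is geometrically subordinated to zp-A and zp-T (above).
- Expansion-map inference ignores within-cycle clustering.
- The generator's group separation is at the calibrated means; desk-scale
  cohorts will usually not reach per-offset significance on euploid vs
  aneuploid thickness — that is expected, not a defect.
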