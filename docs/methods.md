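# Methods

## The test system and its estimators

A square grid of pitch `d = 12.25 μm` (area per point `d² = 150.0625 μm²`)
is overlaid on each 318 μm × 429 μm field at an offset drawn uniformly on
`[0, d)²` from a seeded generator and recorded in the output. Grid lines lie
strictly inside the open field interval `(0, dim)`; a line landing exactly
on the border (a measure-zero event, reachable only with a hand-fixed zero
offset) is excluded. Each family then contains `⌊dim/d⌋` or `⌊dim/d⌋ + 1`
lines with expectation `dim/d`, which is what makes the point-count and
line-intersection estimators unbiased:

- `E[d²·P]` equals the total profile area exactly (uniform-offset lattice);
- `E[(π/2)·L·d]` with `L = (hI + vI)/2` equals the total boundary length for
  isotropic boundaries (Cauchy–Crofton), and exactly for circles regardless
  of orientation.

The boundary formula is implemented as `B = 0.5·π·L·d`. Together with the
area-per-point rule `A = d²·P` this makes the normalised pair
(`B_A`, `A_A`) identical to the classical `(π/2)·I_L` and point-count
estimators for a square grid whose total test-line length is `2·A_ref/d`,
and is the only dimensionally consistent reading of the conventional
shorthand forms.

Intersections are counted at pixel resolution as foreground/background
transitions along each grid line, with the vessel mask restricted to the
ROI. An interior run of foreground contributes 2 (entry + exit); a run
clipped by the field edge contributes 1. A single-pixel touch counts as a
full crossing pair — a deterministic, resolution-stable tie-break for the
measure-zero tangency case.

Profile number uses an unbiased counting frame: a profile is counted when
any of its pixels lies in the frame and none touches the forbidden line
(left edge extended upward, bottom edge extended rightward). The frame
defaults to the whole field.

### Cavity exclusion

Lesion cavities are removed from the reference space
(`ROI_eff = ROI ∧ ¬cavity`). When the cavity fraction of a field reaches a
threshold (default 0.95, configurable) the field is flagged missing and
contributes *absent* values — it is excluded from every downstream mean and
test, never imputed as zero. A zero-area ROI without a cavity flag raises an
error, since that indicates a segmentation failure rather than a cavity.

## TEM thickness morphometry

Basement-membrane and intercellular-cleft thicknesses are measured from
inner/outer contour traces (ordered point lists in nm). At each sample
point — placed equidistantly along the inner trace, 8 per basement membrane
and 4 per cleft by default — the local tangent is a central difference over
a small arc-length window (one-sided at open-trace endpoints), and the
thickness is the distance along the local normal to the nearest crossing of
the outer trace, cast in both directions. Measurements are skipped (with a
logged warning for degenerate tangents) when the normal misses the outer
trace or exceeds a 1 μm sanity bound; both structures are far thinner than
that in any condition.

Capillaries enter summaries only with ≥ 4 basement-membrane or ≥ 2 cleft
measurements. Group summaries pool technical replicates (individual
measurements) by default, matching how the source data are reported with
n = 2 animals per group; per-capillary means are available behind
`level="capillary"` for users who prefer the capillary as the unit of
analysis.

## Cohort aggregation and statistics

Aggregation is means-of-means: fields → section, sections → animal, so
replicate sections are weighted equally even when cavity exclusion removes
fields. Every cell is Shapiro–Wilk tested and flagged, but the flag only
annotates the output: the pipeline applies the study design's fixed test
choices (two-way ANOVA for stereology, Kruskal–Wallis for TEM) regardless.

The two-way (group × segment) ANOVA uses sum-to-zero contrasts with
type-III sums of squares so the unbalanced day-45 group (n = 3) and
missing cells are handled by dropping observations, not imputing; the
interaction F is reported with `(df_interaction, df_within)` as computed
from the data actually present. Tukey-adjusted pairwise comparisons are run
within each segment and restricted to group-vs-sham contrasts by default
(full pairwise behind a flag). Dunn's post-hoc test is implemented
in-package (rank-based z statistics with tie correction, Bonferroni
adjustment) since no installed library provides it; it is validated against
the closed-form two-sample rank statistic and calibrated under the null in
the test suite. No correction is applied across regions or measures, by
design.

## The synthetic generator

Vessel profiles are ellipses from a tilted-cylinder model: a capillary of
lumen radius `r` cut at tilt `θ` gives semi-axes `(r/cos θ, r)`. Defaults:

| parameter | default | rationale |
|---|---|---|
| baseline density (VG/DG/VW/DW) | 571 / 484 / 90 / 88 mm⁻² | intact sham thoracic means |
| radius | log-normal, median 2.3 μm, σ = 0.62, truncated at 1 μm | see below |
| tilt θ | uniform on [0°, 60°] | oblique sections produce elliptical profiles |
| animal effect | log-normal, σ_A = 0.07, mean 1 | reproduces ~8% between-animal CV (571 ± 45) |
| field noise | Poisson profile count | count data at fixed density |

The radius σ was set analytically so that the population surface-to-volume
ratio `Σperimeter/Σarea` lands in the sham band 0.41–0.44 μm⁻¹
(σ = 0.60 → 0.450, σ = 0.62 → 0.432, σ = 0.65 → 0.407). The truncation at
1 μm removes unphysical sub-micron lumina, which would also fall below the
renderer's resolution floor (semi-minor axis ≥ 3 px). The true study-animal
size distribution is unreported, so these defaults are calibrated to density
and S/V only; the per-vessel perimeter and area they imply are smaller than
the reported sham surface/areal densities would suggest.

Group × segment × region density multipliers default to the printed day-2
reductions (99.2%/95.3% at the T10 epicentre for ventral/dorsal grey, 47%/34%
at T9, 75%/62% at T11) and day-45 epicentre values (44%/49%); perilesional
day-5 cells recover to a 20% reduction, and the remaining epicentre and
white-matter cells follow a plausible monotone recovery (day-5 epicentre
0.15–0.40, day-15 0.35–0.60, white matter restored by day 45). These filled
cells are this package's own defaults, chosen once; all multipliers are
ordinary configuration.

Profiles are placed uniformly, fully inside the field, and without overlap
by bounding-circle rejection (area fraction at these densities is a few
percent, so rejection rarely triggers); an overlap-permitting mode exists
for stress tests. Keeping profiles fully inside means the analytic ground
truth (profile count, Σ ellipse areas, Σ elliptic-integral perimeters)
describes the rendered mask exactly. Rendering uses the pixel-centre-inside
rule at 0.33 μm/px by default, origin top-left, half-open pixel extents.

TEM samples are truncated-normal (at 0) draws at the printed group
mean ± SD, 53 basement-membrane and 33 cleft measurements per cell,
distributed over capillaries so the minimum-measurement rules hold by
construction.

### What the generator does and does not emulate

It emulates the *statistical* structure of the study — densities, effect
map, animal variance, replicate hierarchy, cavity exclusion — on clean
post-segmentation masks. It does not emulate fluorescence imaging (noise,
blur, bleed-through), staining artefacts, vessel branching or tortuosity,
or spatially structured lesions. Passing recovery tests therefore validates
the estimators and pipeline arithmetic, not any particular segmentation.

## Numerical and design choices

- **Seeds.** All randomness flows through `numpy` `SeedSequence`; a single
  root seed reproduces the entire cohort tree, grid offsets, and tables
  byte-identically. Per-field grid seeds derive from the run seed and the
  manifest row index.
- **Null calibration.** Type-I-error checks of the test stages use a null
  generator with no effects and no animal variance. A shared animal effect
  (constant across segments within an animal) leaves the interaction
  mean-square untouched while inflating the residual, making the interaction
  F conservative — a property of the design, not of the implementation, and
  noted here rather than "fixed".
- **Problem sizes.** Validation runs use 1000 random grid offsets for
  unbiasedness checks, 100-field density recovery, 200-run power and
  1000-run calibration studies at reduced replication (one region,
  2 sections × 2 fields), and a 72-field end-to-end recovery cohort. These
  sizes put Monte-Carlo error comfortably below the tolerances they are
  checked against.
- **S/V of an empty field.** When no vessel area is sampled (`P = 0`), S/V
  is NaN and excluded downstream — the within-df of S/V tests can therefore
  be smaller than that of the other read-outs, as in heavily lesioned cells.
- **Degenerate inputs.** Mismatched raster shapes, negative counts,
  out-of-range offsets, non-integer label masks, crossing TEM traces and
  sub-minimum traces all raise informative errors; all-tied Kruskal–Wallis
  input and empty ANOVA cells are rejected with the offending cells named.

## Known limitations

- The counting frame equals the field, and the generator keeps profiles
  fully inside it, so frame edge losses are exercised only in dedicated
  tests with clippable scenes; real images with profiles crossing the field
  border rely on the forbidden-line rule implemented here but unverified
  against a human operator's convention.
- Ellipse profiles cannot represent branching or highly irregular vessel
  cross-sections; boundary-length unbiasedness for such shapes holds in
  expectation over isotropic orientation only.
- The statistics mirror the study design (no mixed-effects modelling, no
  cross-region multiplicity correction); with n = 2 animals per TEM group,
  pooled technical replicates overstate the effective sample size, which is
  why the per-capillary mode exists.
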