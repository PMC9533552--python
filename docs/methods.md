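# Methods

## Problem and pipeline

`retquant` quantifies immunofluorescence in retinal cross-sections at the
pixel level. A cross-section image carries one intensity channel per
stain (red: amyloid-beta via Cy3, or glutamine synthetase in the GS
cohort; green: a cell-type marker via FITC — TUBB3 for neurons, GFAP for
macroglia, IBA-1 for microglia, or GFAP paired with GS; blue: DAPI
nuclei, visualization only). A manually drawn label mask assigns every
pixel to one of six retinal layers (RNFL, GCL, IPL, INL, OPL, ONL,
inner to outer along the rows), background, or artifact.

The pipeline stages are:

1. **Thresholding** — each analysis channel is binarized; a pixel is
   positive iff intensity ≥ threshold.
2. **Quantification** — per image and layer: percent positive pixels per
   channel; the conditional colocalization pair (red-positive percent
   inside vs outside the green footprint); the GS/GFAP three-way
   partition pooled into inner (RNFL+GCL+IPL) and outer (INL+OPL+ONL)
   layer groups; and the percent of amyloid-positive pixels covered by
   the microglial footprint.
3. **Aggregation** — image values are averaged per donor within each
   *geo-layer* (region × layer; regions are central ≈5 mm and
   mid-peripheral ≈10 mm from the optic nerve head). One donor in one
   geo-layer is one data point, normally the mean of 2 sections × 2
   images.
4. **Statistics** — per geo-layer: AD vs control by two-sided Wilcoxon
   rank-sum; colocalization within each group by two-sided Wilcoxon
   signed-rank on the donor-level paired differences p_pos − p_neg,
   declared significant at p < 0.05 with a positive median difference.
   Star tiers: * p<0.05, ** p<0.01, *** p<0.001.

## Statistical details

**Exact small-sample tests.** For combined n ≤ 20 (rank-sum) or n ≤ 15
(signed-rank) p-values are exact: every assignment of the observed
midranks to groups (or every sign pattern) is enumerated, and
p = P(|T − E T| ≥ |t − E T|). Midranks are doubled to integers so the
enumeration uses exact integer arithmetic; conditioning on the observed
midranks keeps the enumeration exact under ties, which scipy's exact
methods do not support. Larger samples use scipy's tie-corrected normal
approximation. Zero differences are dropped before signed-ranking
(classic Wilcoxon convention); an all-zero difference vector returns
p = 1 and is flagged rather than treated as evidence.

**Outlier removal.** Before each test, each group's data points pass
through a modified z-score filter: exclude x when
0.6745·|x − median| / MAD > 3.5, with the Iglewicz–Hoaglin
mean-absolute-deviation fallback when the MAD is zero. The rule is
*iterated to convergence*: a gross outlier can mask a moderate one on
the first pass, and the fixed point makes removal idempotent (a property
the test suite checks). No exclusion is attempted below n = 3. Excluded
values are logged with the results. The filter is deliberately simple
and deterministic; the original workflow's exact rule is not published,
so this is the package's documented default and alternative criteria can
be wired through the same hook.

**No multiple-testing correction by default.** Results are reported per
geo-layer with raw p-values, mirroring how such layer-wise analyses are
conventionally presented; a correction can be applied downstream from
the machine-readable p-value dump (`all_p_values.csv`).

## Thresholding

The default policy computes an Otsu threshold per image and channel over
the tissue pixels only (background and artifact labels excluded), then
returns the midpoint of the gap between the two classes so that the ≥
comparison reproduces the Otsu split exactly. A `fixed` policy (global
or per-cohort overrides) injects externally chosen values — e.g. a
rater-selected threshold per cohort — and reproduces an Otsu mask
bit-exactly when handed the Otsu value. `rater_panel` writes
outline-overlay PNGs for candidate thresholds to support human review.
No denoising or local adaptation is applied by default.

## Synthetic cross-sections

Ground truth for validation comes from a generator rather than donor
tissue. Within one layer, each pixel independently draws a (red, green)
positivity pair from a joint law parameterized by the marginals p_red,
p_green and an enrichment ratio ρ = P(red+|green+) / P(red+|green−),
with the red marginal held fixed:

    q_neg = p_red / (p_green·ρ + 1 − p_green),   q_pos = ρ·q_neg.

ρ = 1 is channel independence; infeasible triples (a conditional outside
[0,1]) are rejected at scenario validation with the offending geo-layer
named. Intensities are foreground/background Gaussians (defaults
45000 ± 3000 vs 8000 ± 3000 on the 16-bit scale), clipped to [0, 65535]
— separable by global thresholding by construction. No spatial texture
is imposed: every statistic under study is a pixel count, so per-pixel
independence is the appropriate null canvas. Consequently the synthetic
data do **not** emulate spatially clustered deposits, cell morphology,
optics/PSF blur, uneven illumination, or autofluorescence; passing tests
demonstrate correctness of the measurement and inference machinery, not
robustness to those real-data complications.

**Default scenario (the demo cohort).** 5 AD and 7 control donors, 2
cross-sections per donor, 2 images per region per section, 140×200 px
geometry (layer thicknesses 15/15/25/20/15/30 px, 10 px background
margins). Amyloid positive fraction is 2.5% everywhere except AD
mid-peripheral GCL/IPL/INL/OPL at 6%; the central-retina AD−control
difference is set to exactly zero, encoding the qualitative finding that
only mid-peripheral layers separate. Marker fractions per cohort are
realistic layer profiles (e.g. GFAP concentrated in RNFL/GCL and reduced
×0.6 in AD; IBA-1 sparse, doubled in AD mid-peripherally; TUBB3 dense in
inner layers). Amyloid enrichment: ρ = 2 on TUBB3 (both groups), ρ = 1.1
on GFAP, ρ = 3 control / 1.3 AD on IBA-1 — encoding strong neuronal
colocalization, weak astrocytic colocalization, and the control>AD
microglial contrast. The GS cohort uses red = GS (15%, reduced to 10% in
AD mid-peripheral inner layers), green = GFAP, ρ = 3 control / 2 AD so
the double-labelled (activated Müller) class falls in AD. Donor-level
heterogeneity is a per-donor lognormal factor (σ = 0.25) on the positive
fractions, clipped to feasibility; the *realized* per-image fractions
are recorded in the manifest as ground truth. These sizes keep a full
four-cohort simulate+analyze run under a minute on one CPU while leaving
the group contrasts detectable at the cohort's donor counts.

## Numerical and design choices

- Percentages are 0–100 throughout; no silent scale mixing.
- Undefined ratios (empty denominators) are NaN with a `defined` flag,
  never 0, and simply do not contribute to donor means.
- Layer-group percentages pool pixel counts across layers before
  normalizing; averaging per-layer percentages would weight unequal-size
  layers incorrectly.
- Artifact pixels are a mask label (7) painted inside layers; painting a
  whole layer is equivalent to the per-layer exclusion flag. Denominators
  always exclude them. Whole-layer exclusions are recorded with a reason
  and persist through an audit CSV.
- Masks and channels must share shapes exactly; there is no resampling.
- Determinism: one integer seed fixes the entire simulated dataset
  (per-image seeds are spawned from it) and re-analysis of the same
  inputs is bit-identical.

## Known limitations

- The synthetic generator's realism limits are listed above; in
  particular Otsu thresholding on real images with very sparse signal or
  heavy background structure may behave worse than on the separable
  synthetic mixtures, which is why the fixed per-cohort policy exists.
- Geometry is in pixels; no physical pixel size is modelled.
- Sections, eyes, and images are treated as exchangeable within a donor
  (simple means); nested random-effects modelling is out of scope.
- The rank-sum/normal-approximation crossover at combined n = 20 is a
  pragmatic bound for exact enumeration cost, not a statistical claim.
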