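# retquant

Layer-wise quantification of immunofluorescence in retinal
cross-sections, for studies comparing amyloid-beta (Aβ) load and glial
or neuronal marker distributions between Alzheimer's-disease (AD) and
control donor eyes.

Post-mortem retina is an accessible window on AD pathology: Aβ deposits,
macroglial (GFAP, glutamine synthetase/GS) and microglial (IBA-1)
changes appear layer by layer. `retquant` implements the quantitative
core of such an analysis as a tested, reusable pipeline: given
multi-channel fluorescence images and manual layer label masks
(ITK-SNAP-style: 0 background, 1–6 = RNFL, GCL, IPL, INL, OPL, ONL,
7 artifact), it thresholds each channel, computes pixel-count statistics
per retinal layer, aggregates them into donor-level data points per
*geo-layer* (region × layer; central vs mid-peripheral retina), and runs
nonparametric group comparisons. A synthetic cross-section generator
with exact ground truth stands in for donor tissue, so every stage is
validated end to end.

## The statistics

For a binary positivity mask of channel C within layer L (pixel sets):

- **Layer positive percentage** — `100·|C ∩ L| / |L|`.
- **Conditional colocalization** of Aβ (A) with a marker (M) —
  `p⁺ = 100·|A∩M∩L|/|M∩L|` vs `p⁻ = 100·|A∩Mᶜ∩L|/|Mᶜ∩L|`.
  Under random Aβ placement p⁺ = p⁻; per group and geo-layer, donor-level
  paired differences p⁺ − p⁻ are tested with the two-sided Wilcoxon
  signed-rank test (significant colocalization: p < 0.05 with positive
  median difference).
- **Macroglia partition** (GS cohort) — pixels positive for GS∩GFAP
  (activated Müller cells), GS-only (resting Müller cells), and
  GFAP-only (astrocytes), as percentages of the inner (RNFL+GCL+IPL) and
  outer (INL+OPL+ONL) layer-group pixel counts.
- **Coverage** — `100·|A∩M∩L|/|A∩L|` with M the microglial mask: how
  much of the Aβ footprint is engaged by microglia.
- **Group contrasts** — AD vs control per geo-layer via the two-sided
  Wilcoxon rank-sum test on donor data points (each the mean over up to
  2 sections × 2 images), after modified-z-score outlier removal
  (0.6745·|x − median|/MAD > 3.5, iterated, min n = 3). Small samples
  get exact, tie-safe enumerated p-values.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Simulate the default four-cohort dataset (5 AD vs 7 control donors) and
analyze it in one step:

```sh
retquant demo --out demo_run --seed 1
```

```
GFAP: 24 comparisons, 11 significant at alpha=0.05
GS: 12 comparisons, 1 significant at alpha=0.05
IBA-1: 24 comparisons, 12 significant at alpha=0.05
TUBB3: 24 comparisons, 15 significant at alpha=0.05
outputs in demo_run
```

Each cohort directory contains the per-image quantification tables, the
geo-layer comparison results with group means ± SEM, bar plots with star
annotations, and `all_p_values.csv` collects every p-value of the run.
The amyloid rows of `demo_run/TUBB3/comparisons.csv` for the
mid-peripheral region:

```
        region  key  p_value  mean_AD  sem_AD  mean_control  sem_control
mid-peripheral RNFL   0.8763   2.5233  0.2678        2.5345       0.1576
mid-peripheral  GCL   0.0025   5.9900  0.6274        2.5214       0.1397
mid-peripheral  IPL   0.0025   5.9380  0.5607        2.5186       0.1666
mid-peripheral  INL   0.0025   6.0062  0.5443        2.5045       0.1635
mid-peripheral  OPL   0.0025   6.0283  0.5549        2.5726       0.2174
mid-peripheral  ONL   0.2667   2.9194  0.0241        2.5768       0.1846
```

The generator elevated AD amyloid only in mid-peripheral GCL/IPL/INL/OPL
(6% vs 2.5% baseline); the pipeline recovers exactly those four
geo-layers as significant (p = 0.0025 is the smallest two-sided exact
rank-sum p at n = 5 vs 7) and reports the percent-positive group means
it measured from the images.

`simulate --config cfg.yaml` and `analyze --config cfg.yaml` run the two
halves separately from a YAML config (threshold policy, cohorts, outlier
and significance settings); `analyze` works equally on real manifests
pointing at TIFF channels and TIFF/NIfTI label masks.

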