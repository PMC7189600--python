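# secretomics

Quantification and priming-contrast analysis of mesenchymal stromal cell
(MSC) secretomes: soluble factors measured by multiplex ELISA and
extracellular-vesicle (EV) miRNAs measured on two-panel qPCR arrays, in a
paired resting vs IFNγ-primed donor design.

Secretome potency studies ask two questions of the same samples: *what*
does an MSC population secrete (and how much, per cell), and *how does
inflammatory priming shift that portfolio*. This package implements the
desk side of such a study as a tested, reusable pipeline for bench
scientists and analysts working with conditioned-medium ELISA panels,
OpenArray-style Crt exports and summarized flow-cytometry readouts.

## What it computes

**Secreted factors (ELISA).** Concentrations `c` (pg/ml) become absolute
per-cell amounts

```
amount [pg/10⁶ cells] = c · dilution · V · 10⁶ / N_cells
```

with `V` the conditioned-medium volume (ml) and `N_cells` the producing
cells at harvest. A factor is *detected* in a condition only when above
its single-assay threshold in **every** sample of that condition.
Detected factors are tiered by mean amount (>100, 10–100, 1–10, ≤1 ng)
and donor concordance is reported as mean ± SD pairwise Pearson R.

**EV-miRNAs (qPCR array).** Raw Crt values are processed as:
ath-miR-159a spike-in equalization of panel B onto panel A → censoring of
Crt > 28 as unamplified → per-sample global-mean normalization,
ΔCrt = Crt − mean(Crt), relative expression `2^−ΔCrt` → detection (all
samples of a condition) → first-quartile selection (top ⌈n/4⌉ by mean
relative expression) → *genetic weight*: a miRNA set's percent share of
the summed relative expression of the condition's detected set, used to
score functional categories (cartilage-protective/destructive, macrophage
M1/M2 polarizing) whose annotation tables ship with the package.

**Priming contrasts.** Per analyte, per-donor ratios primed/resting are
tested with a one-sample t-test against 1 (no modulation), after an
optional Grubbs outlier screen, and classified as
gained / lost / up / down / trend / unchanged (fold > 2, p < 0.05 by
default). The model surface is statsmodels-style:
`PrimingContrast(...).fit()` returns results with a `summary()`.

**Flow-cytometry readouts.** Background-subtracted MFI folds vs control,
the CD86/CD163 polarization ratio, and VCAM1-positivity ratios.

**Synthetic studies.** `secretomics.simulate` generates complete paired
donor panels (ELISA + Crt + flow) with known injected effects, so every
pipeline stage has a ground-truth recovery test without any external data.

## Worked example

```
$ secretomics simulate demo/sim --seed 7
$ secretomics elisa demo/sim/elisa_panel.csv demo/sim/config.yaml demo/elisa
resting: 57 detected, 143 below threshold in >=1 sample
primed: 58 detected, 142 below threshold in >=1 sample
$ secretomics mirna demo/sim/crt_table.csv demo/sim/config.yaml demo/mirna
resting: 242 detected, quartile of 61 covers 95.5%
primed: 222 detected, quartile of 56 covers 95.9%
$ secretomics contrast demo/sim/elisa_panel.csv demo/sim/config.yaml demo/contrast
Priming contrast (primed/resting ratios vs 1)
======================================================
analytes: 200   fold threshold: 2.0   alpha: 0.05   trend alpha: 0.1
calls: unchanged=189, gained=6, lost=5
```

The simulated study has 57 factors detectable in all resting samples and
58 in primed ones; 242 of 754 miRNAs are detected at rest and 222 after
priming, and the top quartile (61 and 56 miRNAs) carries ~95–96% of the
genetic message — the dominance structure the heavy-tailed abundance law
is calibrated to produce. The contrast summary recovers the six
gained and five lost factors the generator injected.

From the library, the packaged category tables score directly:

```python
>>> import secretomics as sx
>>> from secretomics.mirna import category_weight_from_reference
>>> mac = {c.name: c for c in sx.load_reference_categories("macrophage")}
>>> category_weight_from_reference(mac["M2_phenotype"], "resting")
26.22
>>> category_weight_from_reference(mac["M1_phenotype"], "resting")
4.49
```

In resting EVs the five M2-polarizing miRNAs carry 26.22% of the genetic
message against 4.49% for the seven M1-related ones — a strong
anti-inflammatory bias of the vesicle cargo.

## Layout

- `secretomics.io` — validated readers/writers for ELISA panels, Crt
  tables, category annotations and flow summaries (CSV/TSV + YAML config)
- `secretomics.elisa` — per-cell amounts, detection, tiers, concordance
- `secretomics.mirna` — spike-in equalization, censoring, global-mean
  normalization, quartile selection, genetic weights
- `secretomics.contrast` — `PrimingContrast` model, Grubbs, KS normality,
  row-centered PCA
- `secretomics.cytometry` — MFI folds, polarization and positivity ratios
- `secretomics.simulate` — synthetic paired studies with ground truth
- `secretomics.cli` — `secretomics simulate|elisa|mirna|contrast|flow`

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
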