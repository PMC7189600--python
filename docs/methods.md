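# Methods

This note documents the quantitative procedures the package implements,
the defaults and why they hold, what the synthetic generator does and does
not emulate, and the numerical conventions that make results reproducible.

## Study design assumed

A paired design: each donor (default 4) contributes one resting and one
IFNγ-primed culture. The same conditioned medium feeds three measurement
layers — a multiplex ELISA factor panel, a two-panel qPCR miRNA array on
the EV fraction, and flow-cytometry validation on reporter cells. All
statistics treat the donor as the pairing unit.

## ELISA quantification

Per-cell amount = concentration (pg/ml) × dilution factor × medium volume
(ml) × 10⁶ / cell count. Volume and cell count have no defaults: they are
required run-config fields, because a wrong volume silently rescales every
amount. Dilution ≥ 1 is a single scalar per panel run.

Detection uses the *all-samples* rule: an analyte counts as detected in a
condition only if its concentration is strictly above the per-assay
threshold in every sample of that condition. "Strictly above" is a fixed
convention; thresholds are continuous so the boundary has measure zero.
The rule is deliberately conservative — one censored donor removes the
analyte — and is monotone in the threshold (tested).

Abundance tiers partition detected analytes by the arithmetic mean amount
across the condition's donors, in ng/10⁶ cells: >100, 10–100, 1–10, ≤1,
with upper-inclusive boundaries (exactly 100 ng falls in 10–100).

Donor concordance is the mean ± SD of Pearson R over all unordered sample
pairs, computed on per-cell amounts of the condition's detected set
(missing values excluded pairwise). Computing it on amounts rather than
raw concentrations is a package decision: amounts are the quantity of
record, and with per-sample volumes/cell counts the two differ; the choice
is recorded here because either convention appears in practice.

## EV-miRNA quantification

1. **Spike-in equalization.** The two array panels (A/B) are independent
   reverse-transcription and preamplification reactions; the shared
   ath-miR-159a spike-in measures their relative offset. Per sample,
   panel-B Crt values are shifted by spike(A) − spike(B). Anchoring B to A
   is arbitrary and harmless: any common anchor gives identical ΔCrt,
   which the shift-invariance tests assert bitwise on dyadic fixtures.
2. **Censoring.** Crt strictly greater than 28 cycles is unamplified;
   28.00 itself is retained. Rows that never amplify stay in the table and
   are flagged, never dropped.
3. **Global-mean normalization.** Per sample, ΔCrt = Crt − arithmetic mean
   of that sample's amplified Crt values (spike-in excluded); relative
   expression is 2^−ΔCrt. The per-sample mean of ΔCrt over amplified
   miRNAs is asserted to be 0 (tolerance 1e−9) after every normalization.
   A sample with zero amplified miRNAs is a domain error, not a NaN.
4. **Detection and gain/loss.** Detected in a condition = amplified in all
   its samples. "Gained on priming" = detected only in primed; "lost" =
   the converse.
5. **First quartile.** The top ⌈n/4⌉ detected miRNAs ranked by
   condition-mean relative expression, descending, ties at the cutoff
   broken lexicographically by identifier. The ceiling rule is chosen
   because it is the unique simple quartile convention mapping both study
   sizes correctly (242→61, 222→56).
6. **Genetic weight.** For a subset S of the detected set D of a
   condition: weight = 100 · Σ_S mean(2^−ΔCrt) / Σ_D mean(2^−ΔCrt), means
   across the condition's samples. Condition-mean weighting makes the
   category tables single-valued per condition; a per-sample variant
   (weight computed within each sample, then averaged) is available via
   `per_sample=True` and documented as the alternative convention.
   Weights over any partition of D sum to 100% (tolerance 1e−9, tested).
   Subset members outside D contribute 0 with a warning rather than
   erroring, since annotation lists routinely cite miRNAs a given
   experiment does not detect.

### Packaged category tables

`secretomics/data/` ships two annotation tables: cartilage
protective/destructive miRNAs and macrophage M1/M2 phenotype miRNAs, each
member carrying its published "% weight" of the EV genetic message in
resting (weight_ev) and primed (weight_iev) vesicles. These are reference
values, retained as published; `category_weight_from_reference` sums them
at their recorded two-decimal precision. Note that two of the published
category totals are not exactly the sum of their published member weights
(the protective totals and the primed M2 total); the package reports
column sums and takes no step to force agreement. hsa-miR-21-5p appears
in both cartilage categories and is counted in each independently.

## Priming contrasts

Per analyte, per-donor ratios r_d = primed_d / resting_d (zero or missing
resting values exclude that donor, with a warning). The test is a
two-sided one-sample t-test of mean(r) against 1 on the **arithmetic**
scale — mean of ratios, not of log-ratios. The arithmetic convention is
the package's primary contract (it is what the ratio-vs-1 formulation
means); `log_scale=True` switches to mean(log r) vs 0 for users who prefer
symmetric treatment of up/down. Degenerate SD = 0 cases: p = 1 if the
common ratio is exactly 1, else p = 0 (logged).

Call vocabulary: analytes detected in only one condition are *gained* or
*lost* (no test). Otherwise *up*/*down* require mean ratio > 2 (or < 0.5)
and p < 0.05; *trend* keeps the fold criterion with 0.05 ≤ p < 0.1 —
whether a trend should also require the fold criterion is ambiguous in
the underlying reporting conventions; this package requires it; *unchanged*
otherwise. All thresholds are arguments.

A Grubbs two-sided single-outlier screen (critical value from the
t-quantile formula, α = 0.05) is applied to the donor ratios before the
t-test; a flagged donor is removed, recorded in the results row, and the
test proceeds while n ≥ 2. Screening before testing is a package decision
(the order is otherwise unspecified); with n = 4 a removal costs a third
of the degrees of freedom, so removals are always surfaced.

Benjamini–Hochberg q-values are emitted per family for information only;
calls are driven by raw p-values, matching the per-analyte reporting
convention of small-donor secretome panels.

`ks_normality` is a Lilliefors-style KS test (statistic against a normal
with estimated mean/SD) whose p-value comes from a fixed-seed Monte-Carlo
null (default 2000 draws) rather than the parameter-free KS law, which
would be anticonservative once parameters are estimated. The statistic is
cross-checked against statsmodels' `lilliefors` in the tests.

`pca_row_centered` centers each analyte row and takes scores from the
SVD; each component's sign is fixed by making its largest-magnitude
loading positive. Rows with any missing value are dropped (complete-case
across samples).

### Calibration caveats at n = 4

Under a log-normal null around 1 with 20% CV and n = 4 donors, the
arithmetic-scale t-test's type-I error at α = 0.05 is only approximately
nominal (skewed ratios, tiny sample); the acceptance simulation asserts
the rejection rate lies in [0.03, 0.08] over 10,000 draws and treats
that as the realistic calibration statement. Power for a genuine 4-fold
effect at 20% CV and n = 4 exceeds 80% (1,000-draw simulation).

## Flow-cytometry readouts

MFI fold = (MFI − unstained MFI) / (control MFI − control unstained MFI);
the control condition is 1 by construction, a non-positive control net
MFI is a domain error, and a negative sample net MFI is clamped to 0 with
a warning. Folds are invariant to a common detector gain (tested). The
polarization ratio is CD86 fold / CD163 fold; VCAM1 positivity ratios are
per-donor ratios of %-positive cells averaged (mean ± SD) whenever
donor-level data exist, and a plain ratio-of-summaries otherwise — the
output states which was used by its shape.

## Synthetic-data generator

The generator draws what the pipeline's recovery tests need and nothing
more:

- **Factors** (default 200, 57 detectable at rest, 5 lost and 6 gained on
  priming): per-analyte median concentrations log-uniform between 10× and
  1000× the assay threshold; undetectable analytes sit at 0.2× threshold.
  Concentrations are median × condition fold × log-normal noise
  (CV 20%, unit mean, exactly 1 at CV = 0). With these gaps the
  configured detected-set sizes are realized in every sample essentially
  surely.
- **miRNAs** (default 754, 242 detected at rest, 30 lost, 10 gained):
  true log2 abundance ~ Normal(0, σ = 3.6 cycles). σ is calibrated so the
  first quartile of a detected set of ~240 carries about 95% of total
  expression (asymptotically Φ(σ·ln2 − 0.674) ≈ 0.96; across seeds the
  per-table value ranges roughly 90–98%). Crt = offset − log2(abundance
  · fold) + per-sample loading shift (SD 0.5 cycles) + replicate noise
  (SD 0.25 cycles, typical qPCR replicate variation) + panel-B spike
  offset (1 cycle). Detectable entries are anchored ≥ 2.5 cycles below
  the censoring limit and undetectable ones 4 cycles above it; 2.5 cycles
  is ~4.5× the combined per-entry noise SD, which is what makes the
  configured detection counts exact by construction. Real arrays have no
  such gap — borderline miRNAs drift in and out of detection across
  samples — so passing count tests says nothing about detection stability
  on real data.
- **Flow**: per-donor net MFIs = control net × true fold × log-normal
  noise (CV 10%); VCAM1 %-positive per donor from base 24% / inflamed 65%
  with true suppression ratios 0.58 (resting secretome) and 0.47 (primed).
  Macrophage CD86/CD163 default folds encode an M1 stimulus (1.41 / 0.74)
  partially reverted by secretome treatments.

Determinism: each layer uses `default_rng([seed, layer_index])`, so
identical configs give byte-identical tables and the three layers are
independently reproducible.

What the generator does **not** emulate: donor-specific baseline
covariance between analytes (donors are exchangeable), miRNA–miRNA
abundance correlation, amplification-efficiency drift within a panel,
plate-position effects, and the detection-boundary drift noted above.
Recovery tests on synthetic data therefore validate the *arithmetic and
logic* of the pipeline, not its robustness to those real-world artifacts.

## Numerical conventions

- Ratios and weights are computed in double precision; invariance tests
  use dyadic-rational fixtures (Crt values in multiples of 0.25,
  power-of-two sample counts) so shift-cancellation is exact and asserted
  bitwise.
- Ties in quartile selection break lexicographically by identifier.
- "Noise-free reproduces truth exactly" assertions use relative
  tolerances of 1e−9 to 1e−12, i.e. machine-precision equality through
  the full arithmetic chain.
- All stochastic tests and utilities take explicit seeds; nothing reads
  global RNG state.

## Problem sizes

The default synthetic study (4 donors, 200 factors, 754 miRNAs) is the
scale every end-to-end test and the CLI smoke run use; the calibration
simulations use 10,000 null draws and 1,000 power draws at n = 4. These
sizes were chosen to match the emulated design while keeping the full
test suite fast on a laptop.

## Known limitations

- The arithmetic-ratio t-test is faithful to common practice but is not
  the statistically efficient choice for multiplicative data; the log
  option exists and is off by default.
- Genetic weights depend on the detected set: gaining or losing miRNAs
  between conditions changes the denominator, so cross-condition weight
  comparisons mix composition and abundance effects.
- Global-mean normalization rescales all ratios by a common factor when
  the amplified sets differ between conditions; per-analyte contrasts on
  miRNA relative expression are therefore interpretable relative to the
  bulk, not absolutely.
- Flow inputs are pre-summarized MFI/% tables; no event-level gating or
  compensation is performed.
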