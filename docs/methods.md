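# Methods

This note documents the models, defaults and numerical choices behind
`rospanel`, and what the synthetic validation does and does not show.

## Dose-response model and IC25

Resazurin fluorescence is proportional to viable metabolic activity.
Responses are means over replicates divided by the (cell line,
treatment) control mean; responses above 1 (stimulated metabolism) are
kept, because clipping would bias shallow fits. The default viability
model is the two-parameter log-logistic

v(d) = 1 / (1 + (d / EC50)^h),

fitted by least squares in response space on log10 dose. With the 3–4
dose designs typical of panel screens, a four-parameter fit (free top
and bottom) is under-determined, so top is fixed at 1 and bottom at 0; a
three-parameter variant with free bottom b ∈ [0, 1) is selectable and
needs ≥ 4 dose points. IC25 — the dose at 75% of control viability — is
inverted analytically: EC50·3^(−1/h) (two-parameter; always below EC50)
or EC50·(0.25/(0.75−b))^(1/h) (three-parameter, defined only for
b < 0.75; otherwise the estimate is reported missing with a
diagnostic).

"Dose" can be a concentration (µM, mM) or, for the gas-plasma jet, an
exposure time in seconds; both titrate identically on the log scale, so
the plasma IC25 is an exposure time.

Numerical choices: multi-start optimization with EC50 initialized at
every tested dose crossed with Hill slopes {0.5, 1, 2, 4}; bounds
log10 EC50 within ±3 of the tested dose range and h ∈ [0.01, 50];
tolerances 1e-14 so that noiseless data is recovered to ≈ machine
precision; the lowest-RMSE solution wins, ties broken toward the
smaller slope. A group whose responses all sit at or above 0.75 with no
downward trend carries no information about 25% inhibition and is
reported unconverged ("no 25% inhibition in tested range") rather than
extrapolated to an arbitrary value. An IC25 outside the tested dose
range is reported but flagged `extrapolated`. Missing estimates
propagate as missing: the line is dropped from that treatment's ranking
with a logged count, never imputed.

## Ranks and cross-treatment statistics

Rank 1 = most sensitive = lowest IC25, with average ranks for ties, so
each treatment's ranks sum to N(N+1)/2. Cross-treatment agreement is
the Spearman correlation of the IC25 vectors (identical on ranks by
monotone invariance); lines missing in either treatment are dropped
pairwise. Rank ratios divide one treatment's rank by another's per
line (reciprocal by construction), and rank sums aggregate a line's
ranks over all treatments as a global sensitivity index.

## Expression preparation

Input is a gene × sample log2 matrix already summarized per gene
(probe-level processing such as RMA happens upstream and is out of
scope). Replicates are arithmetic-averaged per line first, then the
matrix is normalized to the RPL13A housekeeping gene by subtraction on
the log2 scale — the log equivalent of ratio-to-reference. The
operation is idempotent and cancels any per-line global shift, but
because the housekeeping value varies across lines (if only by noise)
it subtracts a *line-varying* constant: screens before and after
normalization genuinely differ unless housekeeping expression is
constant across lines. This is documented, tested behaviour, not an
invariance. Averaging before normalizing is a choice; the operations
are exposed separately so the other order can be run and compared.
Genes whose annotation symbol is empty or missing are removed before
screening; duplicate gene identifiers are rejected rather than
averaged.

## Correlation screen

Spearman r is the Pearson correlation of average-tie ranks. The
default two-sided p uses the t approximation t = r·√((n−2)/(1−r²)) with
df = n−2 — the standard choice at panel sizes around n = 35, and
consistent with the published per-gene (r, p) pairs the package embeds
(evaluating the p over the rounding interval of each printed r brackets
the printed p). A full-permutation exact p is available for n ≤ 8. At
|r| = 1 the t statistic diverges; the p is reported as the smallest
positive float with a flag. Genes with constant expression are dropped
with a diagnostic; genes with missing values use pairwise-complete
observations with a floor of 10 pairs (an invented, logged threshold).

Selection uses raw p < α (default 0.05) with no multiple-testing
correction, matching the screening convention the pipeline reproduces;
Benjamini–Hochberg q-values are reported as an extra column for
reference and never used for selection. Top-k lists (k = 20 per sign,
k = 500 overall by default) are restricted to significant records and
sorted by p ascending, ties broken by |r| descending then gene id —
the tie-break beyond p is a package convention. If fewer than k
significant genes exist the list is shorter, logged, never padded.

## Overlap analysis

Gene identity is the annotation symbol, upper-cased, exact match; no
alias resolution. Pairwise overlaps get an upper-tail hypergeometric
p against a universe equal to the number of genes surviving the
annotation filter — the lists' true sampling frame. This test is an
extension beyond plain overlap counting and is labelled as such in
outputs. For three sets, all seven exclusive Venn region counts are
reported (they sum to the union size by construction).

## Synthetic panel generator

The generator emulates the study design the pipeline targets, with
defaults fixed once:

- **Panel and treatments.** 35 cell lines; gas plasma dosed at
  30/60/120 s, H2O2 at 1/10/100/1000 µM, HOCl at 0.1/1/10/100 mM.
- **Latent sensitivity structure.** A Gaussian copula with target
  Spearman correlations 0.64 (plasma–H2O2), 0.10 (plasma–HOCl) and
  0.02 (H2O2–HOCl); the conversion ρ_P = 2·sin(πρ_S/6) is exact for
  the bivariate normal, so sample rank correlations are calibrated to
  the targets. Non-positive-semidefinite targets are rejected naming
  the offending eigenvalue.
- **IC25 map.** log10 IC25 is affine in the latent trait (positive
  slope: higher latent value = more resistant), anchored so the
  realized panel spans per-treatment ranges chosen to reproduce the
  characteristic dynamic-range factors: 35-fold for plasma
  (10–350 s), >1000-fold for H2O2 (1–1259 µM), 64-fold for HOCl
  (1–64 mM). A degenerate constant latent column maps to the range
  midpoint.
- **Dose-response readouts.** fluorescence = per-line control mean ×
  v(d) × multiplicative lognormal noise with CV 5% (resazurin assay
  noise is not well characterized in the literature; 5–10% is a
  realistic bench value and 5% is the fixed default). Per-line control
  means are lognormal around 10,000 a.u. with 0.15 log-scale spread.
  Three replicates per dose, dose-0 control rows included.
- **Expression.** 2000 genes by default (a desk-scale stand-in for a
  ~26k-target array), three replicates per line, per-gene baselines
  uniform on log2 4–12. A planted gene targeting treatments S follows
  x = sign·β·z̄ + ε with z̄ the standardized mean of the targeted
  latent traits and ε unit normal; the effect size is specified on the
  Spearman scale and converted through the same sine map before
  β = ρ_P/√(1−ρ_P²), so the expected rank correlation with IC25 equals
  the configured value (genes planted for several treatments correlate
  with each at √((1+ρ_pair)/2) times the nominal effect). Default
  planted structure: 40+40 genes (±) shared plasma–H2O2 at ρ = 0.6,
  60+60 plasma-only and 30+30 H2O2-only and 25+25 HOCl-only at
  ρ = 0.5–0.6. Replicate-level technical noise is N(0, 0.25²) log2
  units. One housekeeping gene (RPL13A) is constant across lines with
  small replicate noise. Ten percent of genes are left unannotated
  (empty symbol), drawn from background genes only so the annotation
  filter never silently removes planted signal.
- **Reproducibility.** One global seed; each stage (latent, IC25,
  expression, dose-response) draws from its own fixed substream, so
  regenerating one stage does not perturb the others. All outputs are
  bit-identical under a fixed seed.

What the generator does *not* emulate: probe-level microarray
structure, batch effects, line-specific expression covariance beyond
the planted factors, medium scavenging chemistry (HOCl's high
concentration scale is simply part of its dose grid), or non-monotone
dose-response shapes. Passing the synthetic validation therefore shows
the *analysis* is correct and calibrated under the stated statistical
assumptions — not that those assumptions hold for any particular real
dataset.

## Validation strategy and problem sizes

The package's own validation (test suite and `scripts/acceptance.py`)
uses: a 5000-gene null panel for type-I calibration (significance rate
at α = 0.05 within [0.04, 0.06]); 50 panels with 100 genes planted at
|ρ| = 0.6 among 5000 for top-500 recovery (median ≥ 70%, and off-target
appearance at background rate when the other treatment is independent);
200 panels for copula calibration (mean pairwise Spearman within ±0.05
of targets); 100 lines for noisy IC25 recovery (median relative error
< 15% at CV 5% on a bracketing 4-dose design) and exact (≈ 1e-14)
noiseless recovery; and byte-level comparison of two identically
seeded end-to-end runs. These sizes were chosen as the smallest that
make the stochastic bands statistically comfortable.

## Embedded reference tables

`rospanel.reference_tables` embeds the published top-20 positive and
negative correlating gene lists (with printed p and r) for the three
oxidant treatments of a 35-line screen. The underlying per-line
measurements are not public, so the screen itself cannot be re-run;
the printed lists fully determine the top-20 overlap structure, which
the overlap module reproduces exactly (4 genes shared between the
plasma and H2O2 positive lists; nothing elsewhere). One HOCl-table row
(PTH2) prints a p-value inconsistent with its own printed r under any
two-sided p method monotone in |r| (and out of the table's p-sort
order); it is treated as a typo in the source and excluded from
consistency anchoring, which uses the gas-plasma table.

## Known limitations

- The log-logistic model family is a convention; the package does not
  attempt model selection, and systematically non-log-logistic curves
  will bias IC25 estimates.
- Extrapolated IC25 values (common when a dose grid is narrow relative
  to the panel's sensitivity spread, e.g. 3-point plasma designs) are
  retained with a flag; under noise they can inflate the apparent
  dynamic range substantially.
- The hypergeometric overlap test assumes exchangeable gene lists; the
  package applies it to p-ranked lists as a descriptive index, not a
  calibrated enrichment test.
- No multiple-testing control in selection (by design, matching the
  raw-p screening convention); at 5000 null genes the top lists are
  expected to contain ~250 false positives at α = 0.05.
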