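# rospanel

Oxidant-sensitivity profiling of cell-line panels: IC25 estimation from
resazurin dose-response data, rank-based cross-treatment comparison, a
transcriptome-wide expression-vs-IC25 Spearman screen, and gene-set
overlap analysis — plus a synthetic panel generator with known ground
truth for end-to-end validation.

## The problem

Reactive oxygen species (ROS) kill cancer cells, but different oxidants
kill differently: a cold argon gas-plasma jet (dosed by exposure time in
seconds), H2O2 and HOCl (dosed by concentration) produce distinct
sensitivity profiles across a panel of cell lines. Which basal
(pre-treatment) gene-expression features predict a line's vulnerability?
This package implements the full analysis chain linking the two
measurements made on the same panel:

1. **IC25 estimation.** Resazurin fluorescence, normalized to the
   untreated control, is fitted per (cell line, treatment) with a
   two-parameter log-logistic viability model on log10 dose,

   v(d) = 1 / (1 + (d / EC50)^h),

   and the IC25 — the dose at which fitted viability equals 0.75 —
   follows analytically as IC25 = EC50 · 3^(−1/h). A three-parameter
   variant with a free lower asymptote b is available (IC25 defined for
   b < 0.75).

2. **Sensitivity profiling.** IC25 values are converted to ranks
   (rank 1 = most sensitive, average ranks for ties); treatments are
   compared by Spearman correlation of their IC25 vectors, per-line
   rank ratios, rank sums, and the panel dynamic range
   max(IC25)/min(IC25).

3. **Correlation screen.** The basal log2 expression matrix — replicate
   averaged, normalized to the RPL13A housekeeping gene by log-scale
   subtraction, and restricted to annotated genes — is screened gene by
   gene against each treatment's IC25 vector with Spearman correlation.
   Two-sided p-values use the t approximation
   t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom (an exact
   permutation p is available for n ≤ 8). Genes with raw p < 0.05 feed
   the top-k lists: top-20 per correlation sign and top-500 overall,
   sorted by p (ties: |r| descending, then gene id).

4. **Overlap analysis.** Top-k lists are intersected across treatments,
   with 3-set Venn region counts and an upper-tail hypergeometric test
   against the annotated-gene universe.

The generator (`rospanel.synthetic`) reproduces the statistical
structure this analysis assumes — a Gaussian copula gives the latent
sensitivities a prescribed Spearman correlation structure (Pearson
parameter 2·sin(πρ/6)), log10 IC25 is affine in the latent trait, and
planted gene sets correlate with IC25 at configurable effect sizes — so
every stage can be validated against known ground truth.

## Worked example

`examples/` holds one short script per capability. Fitting an IC25 from
a toy H2O2 titration (`examples/01_fit_ic25.py`):

```text
responses at [10.0, 50.0, 250.0, 1000.0] uM: [0.945 0.748 0.286 0.07 ]
fitted EC50 = 119.3 uM, Hill slope = 1.22
IC25 = 48.6 uM (true 48.0 uM)
converged=True, extrapolated=False
```

The four normalized responses bracket the 25% inhibition point, so the
fitted IC25 (48.6 µM) lands within ~1% of the value used to generate the
data despite 3% measurement noise.

Set arithmetic on the embedded published top-20 gene lists
(`examples/04_overlap_published_lists.py`):

```text
positive top-20 lists:
  plasma & h2o2: 4 shared -> AREG, BLVRB, CFAP300, ME1
  plasma & hocl: 0 shared
  h2o2 & hocl: 0 shared
  all three: 0 shared
```

Only the gas plasma and H2O2 positive lists overlap — consistent with
H2O2 being a principal effector of gas-plasma cytotoxicity while HOCl
acts through different routes.

A full simulated run (`examples/05_full_pipeline.py`) writes the IC25
table, sensitivity ranks, cross-treatment report, per-treatment screen
tables, gene lists and overlap report under an output directory,
together with a manifest that makes the run exactly reproducible.

There is also a thin CLI mirroring the stages:

```bash
rospanel simulate --seed 1 --out panel/
rospanel fit-ic25 panel/dose_response.csv --out ic25.tsv
rospanel run --simulate --seed 1 --out run_out/
```

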