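# Methods

## The analysis this package implements

`ewasmeta` implements a blood-leukocyte epigenome-wide association
analysis run across three array batches on two overlapping probe
panels, of the kind used to relate CpG methylation in peripheral blood
to ovarian-cancer case-control status and to overall survival among
cases. The pipeline is: probe/sample quality control; logit-residual
batch-effect correction ("adjusted beta"); assembly of an analysis
probe set that excludes cell-type-associated and cross-reactive probes;
per-batch rank-based association models; per-batch left-truncated Cox
survival models; and DerSimonian-Laird (DL) random-effects
meta-analysis across batches with a Woolf homogeneity test per probe.
No raw array data are consumed: a synthetic-cohort generator with known
truth provides the inputs, and three published worked examples anchor
the meta-analysis arithmetic to printed values.

## Generative model (`synthio`)

Methylation is generated additively on the logit scale and mapped
through the inverse logit, so every beta value lies strictly in (0, 1):

    logit(beta_ij) = mu_j + b_j X_i + l_j (c_i - c0) + plate(i) + chip(i) + e_ij

- `mu_j ~ N(0, 1.8^2)` — probe baselines spanning the unit interval.
- `b_j` — disease effect at planted risk probes; default 0.5 on the
  logit scale for all of them (`risk_effect_size`).
- `l_j (c_i - c0)` — cell-type loading times the sample's first
  leukocyte-compartment fraction, drawn from a Dirichlet whose mean
  differs between cases (0.52/0.38/0.10 at the default shift 0.08) and
  controls (0.60/0.30/0.10), concentration 60. Because the fraction is
  shifted in cases, cell-type probes show a marginal case-control
  difference even under a null disease effect — the confounding the
  probe-exclusion step exists to remove. Loadings have random sign and
  magnitude ~N(1, 0.25) x `celltype_shift` (default 3 logits per unit
  fraction).
- plate and chip offsets `~N(0, 0.4^2)` and `N(0, 0.2^2)` — scalar
  technical shifts shared by all probes on a plate/chip. Plates hold 8
  chips x 12 samples; samples are randomized to wells within batch.
- `e_ij ~ N(0, 0.5^2)` — measurement noise.

The logit-additive choice is deliberate: the batch-adjustment model is
a one-way linear model on the logit scale, so under the generator its
assumptions hold exactly and orthogonality/mean-preservation tests can
assert to numerical tolerance rather than approximately.

Per-batch sample sizes default to the modeled study's post-QC arms
(69/87, 146/176, 121/135 cases/controls; 336 + 398 = 734). Probe-panel
sizes are scaled down (defaults 800 / 1,200 with 600 shared) from the
tens-to-hundreds of thousands of probes on real arrays; panel size only
multiplies runtime, while every per-probe model is independent, so
nothing about the statistical behavior depends on it. Covariate
categories (parity/age-at-first-birth combination, alcohol, smoking,
state, enrollment year; and for cases stage, ascites, debulking, age at
diagnosis) are drawn from the study's marginal frequencies; the split
of the parity combination by age at first birth is not tabulated
anywhere and is fixed at 30/70. Covariates are sampled independently of
methylation, so they exercise the model plumbing (explicit "missing"
levels, per-batch empty-level handling) but do not themselves confound
— a limitation relative to real cohorts.

Assay controls per batch: CEPH replicates (shared underlying profile,
assay noise SD 0.15 on the logit scale), positive bisulfite controls
near full methylation, negative controls near zero methylation with
configurable outlier probes, and duplicate study-sample pairs. QC
failures are injected with truth labels: low-detection probes,
negative-control-outlier probes, low-call-rate / bisulfite-failure /
low-mean-beta samples — so filter recall can be asserted exactly.

Survival for cases: hazard `0.2 * exp(sum_j loghr_j z_ij)` per year,
with `z` the within-batch standardized logit methylation at planted
survival probes (default |log-HR| 0.3 per SD, random sign). Entry is
uniform on the first year after diagnosis; event times before entry are
redrawn, so the sampled population is the left-truncated one. Censoring
emulates a fixed analysis date with staggered enrollment — uniform on
(entry, 11.4] years — which yields roughly 55-60% deaths and mean
follow-up near 3.4 years, matching the modeled cohort, while a fixed
horizon at 11.4 would give ~82%.

## Quality control (`qc`)

Probe rules, in fixed order for primary-reason reporting: Y-chromosome
(X is retained), SNP-at-probe, high signal in negative bisulfite
controls (probe mean beyond `k_sd` = 4 SDs above the grand mean of
probe means across negatives — the published rule does not say whether
the 4-SD cut is per-probe or global, so the global form is used and the
constant is configurable), and detection below 70% of study samples at
detection p < 0.05. The 70% boundary is strict ("less than"): exactly
70% passes.

Sample rules: call rate < 0.95; bisulfite conversion ratio < 0.90 (the
source formula is not published; the threshold is configurable and no
fidelity is claimed); mean beta below the across-sample median minus 4
scaled MADs (1.4826 x raw MAD). The original analysis judged sample
outliers from histograms; fixed numeric rules replace that for
reproducibility.

Replicate concordance reports pairwise Pearson correlations and
ICC(1,1), the one-way random-effects intraclass correlation, computed
from the ANOVA mean squares (probes as targets, replicates as raters)
and cross-checked against pingouin in the tests.

## Batch adjustment (`normalize`)

Per probe: logit-transform (betas clamped to [1e-3, 1-1e-3]; the
published procedure transforms back "to the 0 to 1 scale" without
addressing exact 0/1 values, so the clamp constant is explicit and
configurable), fit a one-way fixed-effects model on the technical
factor — chip for the two small-panel batches, plate for the large one
— keep the unstandardized residuals, add back the probe's mean logit,
and inverse-logit. Since residualization on a one-way factor subtracts
level means, adjusted values are exactly orthogonal to the factor, the
per-probe mean logit is conserved (assertable at 1e-10), and the
operation is idempotent. Missing betas are excluded from the fit and
stay missing. Whether the original model used treatment coding or cell
means is immaterial — fitted values, hence residuals, are identical.

PCA diagnostics run on probe-centered logit betas (samples as
observations, no scaling — matching the adjustment scale) and report
one-way ANOVA R^2 of each PC on plate, chip, batch and case status.

Only the designated factor is removed (chip for batches 1-2, plate for
batch 3), as in the source analysis; technical variance on the other
factor remains and shows up as mild inflation (lambda ~ 1.05-1.10) in
the association scan on default simulations. This is a property of the
design being emulated, not a defect.

## Probe-set assembly (`probeset`)

Analysis probes = (QC-passing small panel ∩ QC-passing large panel)
minus the cell-type-associated list minus the cross-reactive list,
applied as sets with any overlap between the two lists counted once and
reported. The two lists are consumed as plain-text probe-id files; the
generator writes synthetic stand-ins flagged in its truth. At the
published counts (24,520 common; 9,341 cell-type; 1,363 cross-reactive,
effectively disjoint) the arithmetic leaves 13,816 probes, asserted
exactly in the acceptance suite. Nearest-gene lookup treats intervals
as 1-based inclusive; distance is 0 inside a gene and the bp gap to the
nearest interval end otherwise, ties breaking toward the smaller start
coordinate.

## Case-control association (`assoc`)

Within each batch, each probe's adjusted betas over study samples are
Van der Waerden transformed — value i maps to Phi^-1(r_i / (n + 1))
with average ranks for ties — and regressed by OLS on the case
indicator plus covariates. Missing covariate values are explicit
categories, never dropped samples; enrollment year enters continuously,
centered at 2005; reference levels are the first level of each category
set. Two-sided p-values use the t distribution with residual degrees of
freedom (the normal is indistinguishable at these n, but t is the OLS
convention). Effects are therefore in rank-normal SD units.

The scan shares one design matrix per batch and solves all probes at
once by QR; the tests assert bitwise-level agreement (1e-10) with
statsmodels OLS per probe. Rank-deficient or zero-residual fits are
flagged, not dropped. The genomic inflation factor lambda is the median
observed chi-square over the chi-square median (0.4549), computed on
the per-batch scan p-values.

## Survival (`survmod`)

Cases only, per batch: Cox proportional hazards with delayed entry —
risk set at event time t is {i : entry_i < t <= exit_i} — fit by
lifelines with Efron tie handling (the source is silent on ties; Efron
is the least-biased common default). Methylation enters on the same
rank-normal scale as the case-control model, so hazard ratios are per
rank-normal SD — the published per-unit scale is not stated, and this
interpretation is used for the worked example only. Covariates: age at
diagnosis, stage (III/IV vs I/II), ascites, debulking, each categorical
with an explicit missing level. A monotone partial likelihood (e.g. a
single-carrier dummy level whose carrier has an early event) halts
Newton-Raphson; such probes are refit with a small ridge penalty
(0.01) and flagged `ridge_stabilized`; genuine non-convergence is
flagged, never raised mid-scan.

The scaled-Schoenfeld proportionality diagnostic is computed directly
over the left-truncation risk sets (lifelines does not provide
residuals for delayed-entry fits): per event, the covariate minus its
risk-set weighted mean; Grambsch-Therneau scaling by d times the
inverse average risk-set covariance; then a correlation test against
the rank of event time. It is a diagnostic only and never gates
results.

## Meta-analysis (`meta`)

Per probe, per-batch estimates theta_k with SEs se_k are combined by
the DL moment estimator (formulas in the module docstring); the
combined p uses the normal approximation without Knapp-Hartung, the
flavor the worked examples validate against (and the default
random-effects behavior of the classical R meta-analysis packages). Q
doubles as Woolf's homogeneity statistic on chi-square with k-1 df.
Significance is declared at p < 5e-6, strict, configurable. Probes
absent from any batch are excluded by default (the analysis set is the
common set), relaxable to k >= 2. Survival meta runs on log-HR and is
exponentiated for reporting.

Worked examples: for three probes the published tables print per-batch
estimates (or HRs) with two-sided p-values and the combined value;
per-batch SEs are recovered as |estimate| / Phi^-1(1 - p/2) and the DL
combination then reproduces the printed -0.65, -0.94 (within 0.02 —
the inputs are rounded to 2 figures) and HR 0.95, with Woolf q_p >
0.05 for each.

### A deliberate caveat: DL with k = 3 is conservative under the null

With three batches and a homogeneous null, Q ~ chi-square(2), and the
moment estimator truncates tau^2 at zero; whenever Q > 2 the combined
SE is inflated although the truth is homogeneous. By direct Monte
Carlo on the DL arithmetic (200k simulated probe triplets), the
two-sided rejection rate at alpha = 0.05 is ~0.037 and the median
chi-square ratio of the combined z is ~0.79. The pipeline reproduces
this (empirical rate ~0.034 at 2,000 null probes, 734 samples). The
deviation is one-sided — conservative, never anti-conservative — and
intrinsic to the estimator, not an implementation artifact: per-batch
p-values are KS-uniform in the same simulations, and the acceptance
test asserting a symmetric +-3-binomial-SD band around 0.05 for the
meta p is left failing rather than widened. Calibration statements
(lambda) in this package are therefore made on the per-batch scan
statistics.

## Orchestration and problem sizes

`pipeline.run_all` executes simulate -> qc -> normalize -> probeset ->
assoc -> survival -> meta -> summarize, writing each stage's outputs
plus a JSONL manifest (stage, parameters, SHA-256 of outputs); reruns
with the same config and seed are byte-identical. The `analysis/`
scripts are thin drivers over these stages at the default cohort size
(734 study samples, 800/1,200-probe panels, ~490 analysis probes).
Test-suite simulations use smaller panels (tens to hundreds of probes,
and 40-probe panels for the 200-replicate sign-recovery study) with the
default effect sizes and full per-batch sample counts; panel size was
chosen for turnaround and, because probes are independent, does not
change per-probe operating characteristics.

## Known limitations

- Covariates are independent of methylation; covariate-confounding is
  not exercised, only covariate plumbing.
- Detection p-values are simulated directly (uniform below the cut for
  detected entries) rather than derived from an intensity model; the
  bisulfite-ratio formula is a stand-in threshold.
- No Infinium I/II chemistry differences, no mQTL/genotype structure,
  no intensity-level artifacts; quantile/functional normalization is
  out of scope because the emulated analysis used none.
- Hazard-ratio scale interpretation (per rank-normal SD) is an
  assumption; published per-unit scales were not stated.
- The DL small-k conservatism above applies to any quantity built on
  the combined z-scores.
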