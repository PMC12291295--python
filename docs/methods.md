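# Methods

This note documents the models, estimators and design choices behind
`mpa_recirc`, in the spirit of the methods documentation of simulation and
statistics packages: what is assumed, what is tunable, and what passing the
test suite does and does not demonstrate.

## Reactivation-rate estimation

The ex vivo assay incubates fecal lysate (50 µg/mL total protein) with
200 µM MPAG and measures MPA and MPAG in triplicate at
0, 0.25, 0.5, 1, 1.5 and 2 h.  Within this window, and while substrate
remains in excess, MPA formation is treated as zero-order: the reactivation
rate is the OLS slope of MPA concentration (µM) versus time (h) with a free
intercept.

Processing rules, in order:

1. **Blank baseline.**  If the matching blank control's MPA concentration
   exceeds the LLOQ (0.25 mg/L), it is subtracted from every measurement
   (floored at zero) before fitting, and the estimate is flagged.  Applied
   per analyte independently.
2. **Sub-LLOQ values.**  Measurements above zero but below the LLOQ are
   replaced by LLOQ/2 — a common bioanalytical convention — and counted in
   the output.  Measurements of exactly zero are retained: a zero here is
   the true absence of analyte (e.g. the time-zero sample), and replacing
   it with LLOQ/2 would inject phantom intercept mass and bias the slope.
3. **Fit on all replicate points**, not replicate means.  For a balanced
   design the slope is identical either way; fitting points preserves the
   residual degrees of freedom behind the reported standard error.

A slope more than two standard errors below zero is *flagged* as an assay
failure, never truncated to zero — whether negative rates should be clamped
is a reporting decision left to the caller.  A linearity guard warns when
MPAG depletion exceeds 50 % of the 200 µM start by 2 h, since the zero-order
approximation then degrades; rates up to the observed maximum (86 µM/h)
remain admissible, and rates that would exhaust the substrate entirely
within the incubation (> 100 µM/h) are rejected.

**Control QC.**  The negative control (buffer + MPAG) passes when its fitted
slope's 95 % CI contains zero *and* every MPA measurement is below the LLOQ;
the two conditions together operationalize "no spontaneous hydrolysis".
Each replicate positive-control run passes within ±20 % of the reference
rate, and the between-series CV (100·SD/mean across runs) is reported.  The
paper's validated bound for this CV is < 7 %.

## Non-compartmental PK and the degree of EHR

AUCs use the linear trapezoidal rule on *recorded* (not nominal) sampling
times, with no extrapolation; endpoints must be observed samples.  The
log-linear trapezoid was deliberately not used: the headline statistic is a
ratio of AUCs over the same profile, insensitive to the shared rule.

The degree of enterohepatic recirculation is

    EHR% = 100 · AUC(n, 12) / AUC(0, 12)

with *n* the last sampling time before the onset of recirculation.  No
operational definition of "onset" is standard, so the detector is explicit
and configurable: a candidate is an interior local minimum of the profile
whose time lies in a window (default 3–11 h, bracketing the 6–10 h
secondary-peak region with margin) and that is followed at any later sample
by a concentration at least 10 % above the minimum.  The *latest* qualifying
candidate is taken, and the 10 % rise threshold guards against noise-level
rebounds.  Profiles with no qualifying rebound score EHR% = 0 with an
explicit "no recirculation detected" diagnostic rather than erroring, so
cohort summaries remain computable; multiple secondary peaks resolve to the
last qualifying minimum.  Both window and threshold are exposed in the
configuration.

Because AUC(n,12) includes the tail of the primary absorption peak, EHR%
systematically *upper-bounds* the true recycled fraction of exposure; it is
monotone in it (verified on noiseless sweeps), which is what a rank-based
downstream analysis needs.  The trough C₁₂ is the last observed
concentration.

## β-GUS marker screen

Marker read counts are normalized to RPKM
(count ÷ (length/1000) ÷ (library/10⁶)).  Markers detected (value > 0, with
a configurable epsilon) in at least 50 % of samples are retained — the
boundary is inclusive — and each surviving marker's abundance is correlated
with per-sample reactivation rates.  Spearman with average-rank ties is the
default (Pearson available by flag); p-values are exact permutation values
for n ≤ 10 and t-approximations above.  BH correction is applied across the
marker family actually tested, i.e. within the filtered set; re-running with
the filter disabled reproduces the unfiltered analysis.  Constant-abundance
markers have undefined correlation and are excluded from the BH family
rather than silently assigned a value.  Taxon labels are carried from the
catalog as annotation only — no pooling across markers of one taxon.

## Community statistics

* **Shannon diversity** is computed in natural-log units (the convention of
  the ecology toolchain this emulates); the base is exposed.
* **Bray–Curtis** is Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on relative abundances.
* **PERMANOVA** uses the Gower-centering construction: squared distances are
  double-centered to an inner-product matrix, a hat matrix from the
  predictor's design partitions the total sum of squares, and significance
  comes from permuting sample labels (999 by default, p floored at
  1/(n_perm+1); an exact enumeration mode exists for small n).  One
  formulation serves both factor predictors (patient vs healthy) and
  continuous covariates (the reactivation rate), matching the behaviour of
  the standard distance-based ANOVA implementations.
* The **within-group distance test** compares pooled within-group pairwise
  Bray–Curtis distances between two groups with a Welch t-test.  Pairwise
  distances sharing a sample are not independent; the result carries an
  explicit caveat flag instead of silently endorsing the assumption.
* The **restriction filter** keeps taxa at ≥ 0.01 % relative abundance in at
  least half of the samples pooled across the two compared groups (boundary
  inclusive).  The **differential-abundance screen** on the surviving taxa
  is deliberately descriptive — geometric-mean fold change with a
  pseudocount of half the restriction threshold, Wilcoxon rank-sum (or
  signed-rank when paired), BH-corrected.  It is labeled as such and is not
  a count-model (negative-binomial) analysis.
* Samples with metagenomic libraries below 2.9 M reads are excluded before
  analysis, and a utility selects one sample per subject by largest library,
  mirroring the study's sample-selection rules.
* Wilcoxon tests use exact null distributions for small untied samples
  (≤ 25 paired differences; both groups ≤ 10 for the rank-sum) and the
  continuity-corrected normal approximation otherwise.  All permutation
  procedures are reproducible from a seed.

## The synthetic cohort generator

The generator's defaults *are* the study conditions; they are not tuned per
analysis.

**Rate marginals.**  Each visit group draws true reactivation rates from a
normal distribution truncated below at 2 µM/h (the smallest rate observed in
any cohort) and above at 100 µM/h (the substrate-exhaustion ceiling of the
assay), with the underlying parameters solved numerically so that the
truncated distribution's mean and SD equal the published cohort statistics
exactly (30.3 ± 17.6, 27.2 ± 16.9, 49.5 ± 18.1, 32.5 ± 7.6 µM/h for the
four patient visits; 19.2 ± 12.3 µM/h for healthy individuals).  Naively
truncating a normal with the printed parameters would inflate the healthy
cohort mean by about 2 µM/h; moment matching keeps the printed numbers
directly interpretable as the cohort mean and SD.  For the healthy group
this yields a right-skewed marginal, which is physiologically reasonable
for an enzymatic capacity bounded below.

**Rate–EHR coupling.**  The recycled fraction is tied to the *cohort-wide*
rate rank through a Gaussian copula: normal scores of the pooled rate ranks
are mixed with independent noise at latent correlation 2·sin(πρ/6), the
exact inverse of the Gaussian-copula Spearman map, so the pooled Spearman
correlation converges to the configured ρ (default 0.76) with no small-angle
bias.  Coupling to the pooled rank rather than the within-group latent
encodes the mechanism being modeled: a faster-reactivating microbiome
recycles more MPAG regardless of which visit group the subject belongs to.
The fraction's marginal is uniform on (0.05, 0.55), centered near the
literature's ~40 % exposure-contribution bound while spanning the
between-patient variability seen in individual profiles.

**Assay observables.**  Noiseless truth is MPA(t) = rate·t,
MPAG(t) = 200 − rate·t (µM), converted to mg/L and multiplied by independent
mean-one lognormal noise with CV 5 % per replicate (three replicates per
time point), matching the validated bioanalytical precision (< 5–6 %).
With 10 % probability a lysate contributes a constant MPA baseline above
the LLOQ, recorded as the blank-control measurement so the estimator's
subtraction rule is exercised.  Negative controls force a zero rate;
positive controls draw near a 40 µM/h standardized-culture reference with
3 % between-run CV (the reference rate itself is not published; only the
< 7 % CV bound is asserted anywhere).

**PK observables.**  Concentrations follow a double-Bateman curve
C(t) = A·B(t; ka, ke) + A₂·B(t−τ; ka₂, ke), with the second amplitude solved
in closed form so the delayed component contributes exactly the subject's
recycled fraction of the 0–12 h integral (the closed form is cross-checked
against fine-grid quadrature to 1e-6 relative).  Shape parameters are
lognormal around ka = 3/h, ke = 0.45/h, ka₂ = 1.5/h and amplitude 12 mg/L —
oral-MPA-like kinetics with an early primary peak.  The *secondary peak
time* is drawn uniformly on 6.5–9.5 h and the recirculation lag τ derived
from the delayed component's own time-to-peak, guaranteeing the rendered
bump lands in the clinically observed 6–10 h window.  Recorded sampling
times jitter ±3 min around the nominal 16-point grid (time zero excepted),
and concentrations carry mean-one lognormal noise with CV 5 %.

**Marker tables.**  Each catalog marker has a lognormal baseline RPKM
(σ_log = 0.7), a detection probability, and a causal weight: causal markers
scale by exp(weight · z) with z the standardized true rate.  The default
catalog contains several causal variants attributed to
*Faecalibacterium prausnitzii*, a deliberately abundant-but-inert variant,
and low-prevalence variants that the 50 % filter removes.  Expected RPKM is
converted to Poisson read counts through marker length and a lognormal
library size, so downstream RPKM recomputation is a genuine inversion.

**Taxa tables.**  Lognormal relative abundances (σ_log = 0.6) around
group-specific geometric means for the focal species — *A. muciniphila*
falling from 2.52 % pre-transplant to 0.14 % at week 1 and 0.02 % at weeks
3–6, *F. prausnitzii* rising from 4.2 % toward 7 % — over a fixed background
community, renormalized to 100 % per sample.  Renormalization perturbs
ratios by a few percent, absorbed by the simulation tolerances.

**What the generator does not emulate.**  Real microbiomes have heavier
compositional tails, strain structure, zero inflation at the taxon level,
within-subject correlation across visits (visits are independent draws per
group; the study does not report within-subject rate stability), and
sequencing depth effects beyond a lognormal library size.  Passing
parameter-recovery tests therefore demonstrates that the estimators are
consistent and approximately unbiased *under the stated noise model*, not
that they are robust to every feature of real data.

## Numerical choices

* One configuration seed; each stage derives an independent child stream
  (tagged integers into `numpy` `default_rng`), so stages can be regenerated
  in isolation and runs are byte-identical.
* Permutation p-values are never reported as 0 (floor 1/(n_perm+1)).
* Degenerate inputs error loudly: constant predictors, all-zero profiles,
  zero-sum samples, confounded designs.
* An all-constant regression reports R² = 0 and zero standard error rather
  than NaN.
* Trapezoidal endpoints must match observed times to 1e-9 absolute.

## Problem sizes

Simulated checks use cohorts of 500 subjects for coupling recovery, 1000
per group for mean-rate recovery, ~5000 for the copula's Monte-Carlo
convergence (±0.03), and 10–20 seeds for seed-robustness rates; these sizes
put Monte-Carlo noise comfortably inside the asserted tolerances.

## Known limitations

* EHR% depends on the onset rule; the implemented detector is a documented,
  configurable substitute for an operational definition the source analyses
  leave unstated.  Estimates are comparable across profiles analyzed with
  the same rule, but absolute values shift with the window/threshold.
* The differential-abundance screen is descriptive; effect sizes on
  low-abundance taxa are sensitive to the pseudocount.
* The distance t-test inherits the non-independence of pairwise distances
  (flagged in its output).
* Spearman exact permutation p is enumerated only up to n = 10 (10!
  orderings, chunked); beyond that the t-approximation applies.
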