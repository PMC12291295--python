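# mpa-recirc

Toolkit for studying how the gut microbiome drives the enterohepatic
recirculation (EHR) of mycophenolic acid (MPA), the active moiety of the
immunosuppressant mycophenolate mofetil used after solid-organ
transplantation.

MPA is glucuronidated in the liver to MPAG and excreted in bile; gut
bacterial β-glucuronidases (β-GUS) cleave the glucuronide, regenerating MPA
for re-absorption.  This recycling produces a secondary plasma peak 6–10 h
after dosing and contributes a large, highly variable share of total MPA
exposure — a major obstacle to dose individualization.  The package is
aimed at pharmacometricians and microbiome researchers who want to link an
ex vivo lysate assay to in vivo pharmacokinetics and to metagenomic
readouts.

It implements, as a tested reusable pipeline:

* **Reactivation assay analysis** — the microbiome-derived reactivation rate
  is the OLS slope of MPA (µM) versus incubation time over 0–2 h in a fecal
  lysate exposed to 200 µM MPAG, with blank-baseline subtraction above the
  0.25 mg/L LLOQ, sub-LLOQ handling, and control QC (negative controls must
  show no spontaneous hydrolysis; replicate positive controls with a
  standardized cultured microbiota must stay within ±20 % of the reference
  rate, with between-series CV reported).
* **Non-compartmental PK** — linear trapezoidal AUC on recorded sampling
  times, detection of the recirculation onset *n* (last qualifying local
  minimum followed by a ≥10 % rebound), and the degree of EHR,
  `EHR% = 100 · AUC(n,12) / AUC(0,12)`.
* **β-GUS marker screen** — RPKM normalization of gene-variant read
  counts, a ≥50 % prevalence filter, per-marker Spearman correlation with
  reactivation rates with Benjamini–Hochberg correction, taxon annotation,
  and a Welch test of group total mapping.
* **Community statistics** — Shannon diversity, Bray–Curtis dissimilarities,
  PERMANOVA (factor *or* continuous predictor via Gower centering and
  pseudo-F), within-group distance comparison, an abundance/prevalence
  restriction filter and a descriptive differential-abundance screen.
* **Synthetic cohorts** — a seeded generator that couples true reactivation
  rates (floor-truncated normals moment-matched to published per-visit
  cohort means ± SD) to true recycled fractions through a Gaussian copula
  (default Spearman coupling 0.76), then renders assay time courses, 16-point
  double-Bateman PK profiles with a 6–10 h secondary peak, ShortBRED-style
  marker counts and MetaPhlAn-style taxa tables, so every stage of the
  analysis is testable without access to patient data.

## Worked example

Simulate a 15-subject post-transplant cohort, estimate each subject's
reactivation rate from its assay time course and its degree of EHR from its
PK profile, and correlate the two:

```python
import numpy as np
from mpa_recirc import synthetic as syn
from mpa_recirc.assay import estimate_reactivation_rate
from mpa_recirc.pk import degree_ehr
from mpa_recirc.community import spearman_test

design = syn.single_group_design("week3_6", 15, seed=42)
subjects = syn.simulate_cohort(design)
rates, ehr = [], []
for s in subjects:
    tc = syn.simulate_assay_timecourse(s, "sample", design)
    rates.append(estimate_reactivation_rate(tc).rate_um_h)
    ehr.append(degree_ehr(syn.simulate_pk_profile(s, design)).ehr_percent)
res = spearman_test(rates, ehr)
print(f"reactivation rates (uM/h): min {min(rates):.1f}, max {max(rates):.1f}, mean {np.mean(rates):.1f}")
print(f"degree of EHR (%):        min {min(ehr):.1f}, max {max(ehr):.1f}, mean {np.mean(ehr):.1f}")
print(f"Spearman rho = {res.statistic:.2f} (p = {res.p_value:.4f}, n = {len(rates)})")
```

prints

```
reactivation rates (uM/h): min 9.6, max 81.1, mean 47.4
degree of EHR (%):        min 9.0, max 57.9, mean 31.1
Spearman rho = 0.77 (p = 0.0007, n = 15)
```

The rates span roughly an order of magnitude across subjects, EHR
contributes between ~10 % and ~60 % of the 12-h exposure, and the rank
correlation between the two estimates recovers the configured coupling.
(Subjects whose rate depletes more than half of the MPAG substrate within
2 h trigger a linearity warning from the estimator; their slopes are still
reported.)

The same analysis is available from the shell:

```bash
mpa-recirc run --seed 42 --outdir runs/demo   # full pipeline + report.json
mpa-recirc simulate --seed 42 --outdir data/  # just the synthetic tables
mpa-recirc rate data/assay.csv --out rates.csv
```

## Layout

```
src/mpa_recirc/
  assay.py       rate estimation, unit conversion, control QC, inhibition, 4-MU activity
  pk.py          trapezoidal AUC, EHR onset detection, degree of EHR, cohort summary
  gus.py         RPKM, prevalence filter, marker-rate association, group totals
  community.py   Shannon, Bray-Curtis, PERMANOVA, distance tests, DA screen, stat primitives
  synthetic.py   cohort/assay/PK/marker/taxa generators
  io.py          CSV/TSV readers and writers with validation
  pipeline.py    end-to-end orchestration and run report
  cli.py         `mpa-recirc` command-line interface
docs/methods.md  model and design notes
```
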