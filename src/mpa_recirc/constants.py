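"""Physical constants and study-level parameters shared across modules.

Molecular weights bridge the bioanalytical scale (mg/L) and the assay scale
(µM).  The cohort statistics are the per-visit reactivation-rate mean ± SD
(µM/h) and group size for kidney-transplant recipients at each sampling
visit and for healthy individuals; they parameterize the synthetic-cohort
generator and the worked fold-difference examples.
"""

MW_MPA = 320.34  # g/mol, mycophenolic acid
MW_MPAG = 496.46  # g/mol, 7-O-MPA-glucuronide

LLOQ_MG_L = 0.25  # lower limit of quantification of the UPLC-MS/MS assay

MPAG_START_UM = 200.0  # MPAG concentration at reaction start, µM
ASSAY_TIMES_H = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0)
ASSAY_REPLICATES = 3

# Nominal blood-sampling grid over one 12-h dosing interval.
PK_NOMINAL_TIMES_H = (
    0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0,
    7.0, 8.0, 9.0, 10.0, 11.0, 12.0,
)

MIN_LIBRARY_READS = 2_900_000  # metagenomic library-size exclusion threshold

# label -> (mean µM/h, SD µM/h, n subjects)
COHORT_RATE_STATS = {
    "pre_tx": (30.3, 17.6, 22),
    "week1": (27.2, 16.9, 21),
    "week3_6": (49.5, 18.1, 11),
    "year1": (32.5, 7.6, 8),
    "healthy": (19.2, 12.3, 15),
}

# Observed reactivation-rate ranges (min, max) in µM/h.
OBSERVED_RATE_RANGES = {
    "transplant": (6.0, 86.0),
    "healthy": (2.0, 46.0),
}

RATE_FLOOR_UM_H = 2.0  # smallest rate observed in any cohort
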