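"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator produces, from one seed, a cohort of subjects whose latent
truth couples the ex vivo MPA reactivation rate to the in vivo recycled
fraction, then renders every observable the pipeline consumes:

* assay time courses — linear MPA formation / MPAG depletion from a 200 µM
  start, triplicates on the 0-2 h grid, multiplicative lognormal noise,
  occasional lysate MPA baselines, negative/positive controls;
* PK profiles — a double-Bateman concentration curve whose delayed component
  contributes exactly the subject's recycled fraction of the 0-12 h integral
  and produces a secondary peak 6-10 h post-dose;
* β-GUS marker tables — lognormal baselines, causal markers whose abundance
  scales with the true rate, abundant-but-inert markers, zero inflation for
  prevalence structure, Poisson read counts with library sizes;
* taxa tables — lognormal relative abundances renormalized to 100% with
  group-specific geometric means for the focal species.

Rate marginals per visit group are floor-truncated normals *moment-matched*
to the published cohort mean ± SD, so the printed statistics are the
distribution's actual moments.  The rate/recycled-fraction coupling is a
Gaussian copula whose latent correlation is 2·sin(πρ/6), making the
population Spearman correlation equal ρ exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import constants as C
from .assay import AssayTimeCourse, to_mg_per_l
from .community import AbundanceTable
from .gus import FeatureTable
from .pk import PKProfile

__all__ = [
    "GroupSpec",
    "CohortDesign",
    "PKParams",
    "SyntheticSubject",
    "default_design",
    "single_group_design",
    "default_gene_catalog",
    "simulate_cohort",
    "simulate_assay_timecourse",
    "simulate_cohort_assays",
    "simulate_pk_profile",
    "simulate_cohort_pk",
    "simulate_gus_gene_table",
    "simulate_taxa_table",
    "bateman",
    "bateman_auc",
]

# rng stream tags, so stages can be regenerated in isolation from one seed
_STREAM_COHORT = 1
_STREAM_ASSAY = 2
_STREAM_PK = 3
_STREAM_GENES = 4
_STREAM_TAXA = 5
_STREAM_CONTROLS = 6


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int
    rate_mean: float  # µM/h
    rate_sd: float  # µM/h


@dataclass(frozen=True)
class CohortDesign:
    """Cohort-level simulation parameters.

    ``copula_rho`` is the target Spearman correlation between the true
    reactivation rate and the true recycled fraction; ``ehr_fraction_range``
    maps the copula's uniform margin to a physiologic recycled-fraction
    window (enterohepatic recirculation contributes up to ~40-50% of MPA
    exposure).  Noise CVs are multiplicative lognormal per measurement.
    """

    groups: tuple[GroupSpec, ...]
    rate_floor: float = C.RATE_FLOOR_UM_H
    copula_rho: float = 0.76
    ehr_fraction_range: tuple[float, float] = (0.05, 0.55)
    assay_noise_cv: float = 0.05
    pk_noise_cv: float = 0.05
    baseline_contamination_prob: float = 0.10
    control_reference_rate: float = 40.0  # µM/h, standardized-culture reference
    control_between_run_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for g in self.groups:
            if g.n_subjects < 1:
                raise ValueError(f"group {g.label!r}: n_subjects must be >= 1")
            if g.rate_sd < 0:
                raise ValueError(f"group {g.label!r}: rate_sd must be >= 0")
        lo, hi = self.ehr_fraction_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("ehr_fraction_range must satisfy 0 <= low < high <= 1")
        if abs(self.copula_rho) > 1:
            raise ValueError("|copula_rho| must be <= 1")
        for name in ("assay_noise_cv", "pk_noise_cv", "control_between_run_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.baseline_contamination_prob <= 1:
            raise ValueError("baseline_contamination_prob must be in [0, 1]")


@dataclass(frozen=True)
class PKParams:
    """Double-Bateman parameters: primary amplitude (mg/L scale), absorption
    and elimination rate constants (1/h), recirculation lag (h) and the
    slower absorption constant of the recirculated component (1/h)."""

    dose_scale: float
    ka: float
    ke: float
    tau_recirc: float
    ka2: float


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    group: str
    true_rate: float  # µM/h
    true_ehr_fraction: float
    pk_params: PKParams
    index: int = 0


def default_design(seed: int = 0, n_scale: int = 1, **overrides) -> CohortDesign:
    """The study-structured design: all five visit groups at published sizes
    (optionally scaled) and published rate means/SDs."""
    groups = tuple(
        GroupSpec(label, n * n_scale, mean, sd)
        for label, (mean, sd, n) in C.COHORT_RATE_STATS.items()
    )
    return CohortDesign(groups=groups, seed=seed, **overrides)


def single_group_design(label: str, n_subjects: int, seed: int = 0, **overrides) -> CohortDesign:
    """A one-group design drawn from the published statistics for ``label``."""
    mean, sd, _ = C.COHORT_RATE_STATS[label]
    return CohortDesign(groups=(GroupSpec(label, n_subjects, mean, sd),), seed=seed, **overrides)


# ---------------------------------------------------------------------------
# rate marginal: floor-truncated normal moment-matched to the target mean/SD


@lru_cache(maxsize=64)
def _truncnorm_underlying(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """Solve for (m, s) such that a normal(m, s) truncated below at ``floor``
    has mean ``mean`` and SD ``sd``."""
    if mean <= floor:
        raise ValueError("target mean must exceed the floor")

    def eqs(p):
        m, log_s = p
        s = math.exp(log_s)
        a = (floor - m) / s
        mu, var = stats.truncnorm.stats(a, np.inf, loc=m, scale=s, moments="mv")
        return [float(mu) - mean, math.sqrt(float(var)) - sd]

    sol = optimize.root(eqs, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"truncated-normal moment matching failed for ({mean}, {sd})")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


# Hard physiologic/assay ceiling: a faster rate would exhaust the 200 µM
# MPAG start within the 2-h incubation and leave the linear regime.
_RATE_CAP_UM_H = C.MPAG_START_UM / C.ASSAY_TIMES_H[-1]


def _rate_from_normal_score(z: np.ndarray, g: GroupSpec, floor: float) -> np.ndarray:
    if g.rate_sd == 0:
        if g.rate_mean < floor:
            raise ValueError(f"group {g.label!r}: degenerate mean below floor")
        return np.full(z.size, g.rate_mean)
    m, s = _truncnorm_underlying(g.rate_mean, g.rate_sd, floor)
    a, b = (floor - m) / s, (_RATE_CAP_UM_H - m) / s
    return stats.truncnorm.ppf(stats.norm.cdf(z), a, b, loc=m, scale=s)


def simulate_cohort(design: CohortDesign) -> list[SyntheticSubject]:
    """Draw the latent truth for every subject.

    Rate and recycled fraction share a Gaussian copula: both are strictly
    monotone transforms of a pair of latent normals with Pearson correlation
    2·sin(π·copula_rho/6), so their Spearman correlation is copula_rho.
    PK shape parameters are drawn independently per subject with the delayed
    component lagged 5-8 h, which places the secondary peak at 6-10 h.
    """
    rng = np.random.default_rng([design.seed, _STREAM_COHORT])
    latent_r = 2.0 * math.sin(math.pi * design.copula_rho / 6.0)
    lo, hi = design.ehr_fraction_range

    rates_all: list[np.ndarray] = []
    labels: list[str] = []
    for g in design.groups:
        z1 = rng.standard_normal(g.n_subjects)
        rates_all.append(_rate_from_normal_score(z1, g, design.rate_floor))
        labels.extend([g.label] * g.n_subjects)
    rates = np.concatenate(rates_all)
    n = rates.size

    # Couple the recycled fraction to the *cohort-wide* rate rank: whichever
    # visit group a subject belongs to, a faster-reactivating microbiome
    # recycles more MPAG.  Normal scores of the pooled ranks keep the copula
    # Gaussian, so the pooled Spearman correlation converges to copula_rho.
    q = stats.norm.ppf((stats.rankdata(rates, method="average") - 0.5) / n)
    z2 = latent_r * q + math.sqrt(1.0 - latent_r**2) * rng.standard_normal(n)
    ehr = lo + (hi - lo) * stats.norm.cdf(z2)

    dose_scale = rng.lognormal(math.log(12.0), 0.3, n)
    ka = rng.lognormal(math.log(3.0), 0.2, n)
    ke = rng.lognormal(math.log(0.45), 0.15, n)
    ke = np.minimum(ke, 0.8 * ka)  # absorption faster than elimination
    ka2 = rng.lognormal(math.log(1.5), 0.2, n)
    # Draw the *secondary peak time* inside the observed 6-10 h window (with
    # margin) and derive the recirculation lag from the component's own
    # time-to-peak, so the rendered bump lands where the clinic sees it.
    peak_time = rng.uniform(6.5, 9.5, n)
    tmax2 = np.log(ka2 / ke) / (ka2 - ke)
    tau = np.clip(peak_time - tmax2, 4.2, 9.8)
    return [
        SyntheticSubject(
            subject_id=f"S{i:04d}",
            group=labels[i],
            true_rate=float(rates[i]),
            true_ehr_fraction=float(ehr[i]),
            pk_params=PKParams(
                float(dose_scale[i]), float(ka[i]), float(ke[i]),
                float(tau[i]), float(ka2[i]),
            ),
            index=i,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# assay time courses


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, shape))


def simulate_assay_timecourse(
    subject_or_rate: SyntheticSubject | float,
    kind: str = "sample",
    config: CohortDesign | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> AssayTimeCourse:
    """Render one assay time course from a true rate (µM/h).

    Noiseless truth: MPA(t) = rate·t, MPAG(t) = 200 − rate·t (µM), converted
    to mg/L, with independent mean-one lognormal noise per replicate.  With
    probability ``baseline_contamination_prob`` a constant MPA baseline above
    the LLOQ contaminates the lysate; it is recorded as the blank-control
    measurement so the estimator can subtract it.  Negative controls force a
    zero rate and no baseline; positive controls draw their rate near the
    standardized-culture reference.
    """
    if config is None:
        raise ValueError("config (CohortDesign) is required")
    if isinstance(subject_or_rate, SyntheticSubject):
        rate = subject_or_rate.true_rate
        sid = sample_id or subject_or_rate.subject_id
        sub_idx = subject_or_rate.index
    else:
        rate = float(subject_or_rate)
        sid = sample_id or "sample"
        sub_idx = 0
    if rng is None:
        stream = _STREAM_CONTROLS if kind.endswith("_control") else _STREAM_ASSAY
        rng = np.random.default_rng([config.seed, stream, sub_idx])

    if kind == "negative_control":
        rate = 0.0
    elif kind == "positive_control":
        rate = config.control_reference_rate * float(
            _lognormal_factors(rng, config.control_between_run_cv, ())
        )
    elif kind != "sample":
        raise ValueError(f"unsupported kind {kind!r}")
    if rate < 0:
        raise ValueError("rate must be non-negative")

    t = np.asarray(C.ASSAY_TIMES_H)
    if rate * t[-1] > C.MPAG_START_UM:
        raise ValueError(
            f"rate {rate:g} µM/h would exhaust the {C.MPAG_START_UM:g} µM MPAG start "
            f"within {t[-1]:g} h (outside the linear regime)"
        )

    mpa_um = rate * t
    mpag_um = C.MPAG_START_UM - rate * t
    mpa_mg = to_mg_per_l(mpa_um, "MPA")
    mpag_mg = to_mg_per_l(mpag_um, "MPAG")

    baseline = None
    if kind == "sample" and rng.uniform() < config.baseline_contamination_prob:
        baseline = float(rng.uniform(1.2, 8.0)) * C.LLOQ_MG_L  # above LLOQ

    nrep = C.ASSAY_REPLICATES
    shape = (t.size, nrep)
    mpa_true = np.tile(mpa_mg[:, None], (1, nrep)) + (baseline or 0.0)
    mpag_true = np.tile(mpag_mg[:, None], (1, nrep))
    mpa_obs = mpa_true * _lognormal_factors(rng, config.assay_noise_cv, shape)
    mpag_obs = mpag_true * _lognormal_factors(rng, config.assay_noise_cv, shape)

    return AssayTimeCourse(
        sample_id=sid,
        kind=kind,
        times_h=t,
        mpa_mg_l=mpa_obs,
        mpag_mg_l=mpag_obs,
        blank_mpa_mg_l=baseline,
        lloq_mg_l=C.LLOQ_MG_L,
        truth={"rate_um_h": rate, "baseline_mg_l": baseline},
    )


def simulate_cohort_assays(
    subjects: Sequence[SyntheticSubject], design: CohortDesign
) -> list[AssayTimeCourse]:
    return [simulate_assay_timecourse(s, "sample", design) for s in subjects]


# ---------------------------------------------------------------------------
# PK profiles


def bateman(t, ka: float, ke: float):
    """Bateman absorption/elimination curve, zero before t=0, unit dose scale."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if abs(ka - ke) < 1e-9:
        out[pos] = ka * t[pos] * np.exp(-ka * t[pos])
    else:
        out[pos] = ka / (ka - ke) * (np.exp(-ke * t[pos]) - np.exp(-ka * t[pos]))
    return out


def bateman_auc(t_end: float, ka: float, ke: float) -> float:
    """Closed-form ∫₀ᵀ of the Bateman curve."""
    if t_end <= 0:
        return 0.0
    if abs(ka - ke) < 1e-9:
        return (1.0 - math.exp(-ka * t_end) * (1.0 + ka * t_end)) / ka
    return ka / (ka - ke) * (
        (1.0 - math.exp(-ke * t_end)) / ke - (1.0 - math.exp(-ka * t_end)) / ka
    )


def simulate_pk_profile(
    subject: SyntheticSubject,
    config: CohortDesign,
    rng: np.random.Generator | None = None,
    visit: str = "pk",
) -> PKProfile:
    """Render one 16-sample PK profile with a recirculation component.

    The noiseless curve is A·B(t; ka, ke) + A₂·B(t−τ; ka₂, ke) with A₂ chosen
    so the delayed component contributes exactly ``true_ehr_fraction`` of the
    0-12 h integral.  Recorded times jitter ±3 min around the nominal grid
    (the time-zero sample stays at 0) and concentrations carry mean-one
    lognormal noise.
    """
    p = subject.pk_params
    if not 4.0 <= p.tau_recirc <= 10.0:
        raise ValueError("tau_recirc must lie in [4, 10] h")
    if rng is None:
        rng = np.random.default_rng([config.seed, _STREAM_PK, subject.index])

    t_nom = np.asarray(C.PK_NOMINAL_TIMES_H)
    t_end = float(t_nom[-1])
    f = subject.true_ehr_fraction
    i1 = bateman_auc(t_end, p.ka, p.ke)
    i2 = bateman_auc(t_end - p.tau_recirc, p.ka2, p.ke)
    a1 = p.dose_scale
    if f > 0:
        if i2 <= 0:
            raise ValueError("recirculation component has zero support before 12 h")
        a2 = f / (1.0 - f) * a1 * i1 / i2
    else:
        a2 = 0.0

    times = t_nom.copy()
    times[1:] += rng.uniform(-0.05, 0.05, t_nom.size - 1)
    conc_true = a1 * bateman(times, p.ka, p.ke) + a2 * bateman(times - p.tau_recirc, p.ka2, p.ke)
    conc = conc_true * _lognormal_factors(rng, config.pk_noise_cv, times.shape)

    return PKProfile(
        patient_id=subject.subject_id,
        visit=visit,
        times_h=times,
        conc_mg_l=conc,
        truth={
            "true_ehr_fraction": f,
            "primary_auc_0_12": a1 * i1,
            "secondary_auc_0_12": a2 * i2,
            "noiseless_conc_mg_l": conc_true,
            "params": p,
        },
    )


def simulate_cohort_pk(
    subjects: Sequence[SyntheticSubject], design: CohortDesign
) -> list[PKProfile]:
    return [simulate_pk_profile(s, design) for s in subjects]


# ---------------------------------------------------------------------------
# β-GUS marker tables


def default_gene_catalog() -> pd.DataFrame:
    """A compact marker catalog emulating a β-GUS gene-variant database.

    ``causal_weight`` scales marker abundance with the standardized true
    rate (0 for inert markers); ``base_rpkm`` is the geometric-mean baseline
    and ``prevalence`` the detection probability per sample.  The catalog
    deliberately contains an abundant-but-inert marker
    (high ``base_rpkm``, zero weight) alongside the causal ones.
    """
    rows = [
        # marker_id, length_bp, taxon, causal_weight, base_rpkm, prevalence
        ("SRS014923_34218-NL", 1812, "Faecalibacterium prausnitzii", 1.2, 6.0, 1.0),
        ("SRS015663_18708-NL", 1806, "Faecalibacterium prausnitzii", 0.5, 4.0, 0.9),
        ("SRS015065_66511-NL", 1875, "Faecalibacterium prausnitzii", 0.4, 3.0, 0.85),
        ("SRS015264_38260-NL", 1842, "Faecalibacterium prausnitzii", 0.3, 2.5, 0.8),
        ("SRS015264_139063-NL-L2-6", 1890, "Faecalibacterium prausnitzii", 0.0, 45.0, 0.95),
        ("SRS011134_42102-NL", 1800, "Faecalibacterium prausnitzii", 0.0, 8.0, 0.9),
        ("SRS019582_27043-NL", 1950, "Bacteroides fragilis", 0.0, 1.5, 0.35),
        ("SRS013951_77502-NL", 1932, "Bacteroides fragilis", 0.0, 1.0, 0.3),
        ("SRS014459_64550-NL", 1845, "Bacteroides uniformis", 0.0, 12.0, 0.9),
        ("SRS017433_11271-NL", 1818, "Escherichia coli", 0.0, 5.0, 0.7),
        ("SRS019601_43290-NL", 1866, "Ruminococcus gnavus", 0.0, 7.0, 0.8),
        ("SRS016335_82001-NL", 1821, "Roseburia hominis", 0.0, 3.5, 0.75),
        ("SRS018313_55120-NL", 1903, "Akkermansia muciniphila", 0.0, 2.0, 0.6),
    ]
    cat = pd.DataFrame(
        rows, columns=["marker_id", "length_bp", "taxon", "causal_weight", "base_rpkm", "prevalence"]
    ).set_index("marker_id")
    return cat


def validate_gene_catalog(catalog: pd.DataFrame) -> None:
    if catalog.empty:
        raise ValueError("catalog must be non-empty")
    if catalog.index.duplicated().any():
        raise ValueError("marker ids must be unique")
    if (catalog["length_bp"] <= 0).any():
        raise ValueError("marker lengths must be positive")
    if (catalog["causal_weight"] < 0).any():
        raise ValueError("causal weights must be >= 0")


def simulate_gus_gene_table(
    subjects: Sequence[SyntheticSubject],
    catalog: pd.DataFrame | None = None,
    config: CohortDesign | None = None,
    rng: np.random.Generator | None = None,
    marker_sigma_log: float = 0.7,
) -> FeatureTable:
    """Simulate a ShortBRED-style counts table (markers × subjects).

    Marker RPKM is lognormal around its catalog baseline; causal markers are
    additionally scaled by exp(weight · z) with z the standardized true rate,
    entries are zeroed per the catalog prevalence, and read counts are
    Poisson draws at the expectation implied by marker length and a lognormal
    library size — so RPKM is recomputable downstream.
    """
    if config is None:
        raise ValueError("config (CohortDesign) is required")
    if catalog is None:
        catalog = default_gene_catalog()
    validate_gene_catalog(catalog)
    if rng is None:
        rng = np.random.default_rng([config.seed, _STREAM_GENES])

    n = len(subjects)
    sample_ids = [s.subject_id for s in subjects]
    rates = np.array([s.true_rate for s in subjects])
    sd = rates.std(ddof=0)
    z = (rates - rates.mean()) / sd if sd > 0 else np.zeros(n)

    libs = np.clip(rng.lognormal(math.log(30e6), 0.7, n), 2.0e6, 1.2e8).astype(np.int64)
    counts = np.zeros((len(catalog), n), dtype=np.int64)
    for i, (marker, row) in enumerate(catalog.iterrows()):
        present = rng.uniform(size=n) < row["prevalence"]
        log_noise = rng.normal(0.0, marker_sigma_log, n)
        rpkm = row["base_rpkm"] * np.exp(log_noise + row["causal_weight"] * z)
        expected = rpkm * (row["length_bp"] / 1e3) * (libs / 1e6) * present
        counts[i] = rng.poisson(expected)

    values = pd.DataFrame(counts, index=catalog.index, columns=sample_ids)
    return FeatureTable(
        values=values,
        value_kind="counts",
        library_sizes=pd.Series(libs, index=sample_ids, name="library_size"),
        catalog=catalog,
    )


# ---------------------------------------------------------------------------
# taxa tables

# Focal species with published per-visit geometric-mean relative abundances (%);
# "default" applies to groups without a specific entry.
FOCAL_TAXA_PERCENT = {
    "Faecalibacterium prausnitzii": {
        "pre_tx": 4.2, "week1": 8.2, "week3_6": 10.9, "year1": 7.0,
        "healthy": 5.0, "default": 5.0,
    },
    "Akkermansia muciniphila": {
        "pre_tx": 2.52, "week1": 0.14, "week3_6": 0.02, "year1": 0.10,
        "healthy": 2.0, "default": 1.5,
    },
    "Roseburia intestinalis": {
        "pre_tx": 0.5, "week1": 1.4, "week3_6": 1.5, "year1": 0.8,
        "healthy": 0.6, "default": 0.6,
    },
    "Clostridium sp. AF34-10BH": {
        "pre_tx": 0.06, "week1": 0.22, "week3_6": 0.25, "year1": 0.10,
        "healthy": 0.05, "default": 0.06,
    },
    "Prevotellaceae SGB1699": {
        "pre_tx": 0.9, "week1": 0.25, "week3_6": 0.4, "year1": 0.6,
        "healthy": 0.9, "default": 0.8,
    },
    "Ruminococcaceae SGB15356": {
        "pre_tx": 0.5, "week1": 0.15, "week3_6": 0.3, "year1": 0.4,
        "healthy": 0.5, "default": 0.45,
    },
    "Ruminococcaceae SGB15106": {
        "pre_tx": 0.35, "week1": 0.12, "week3_6": 0.2, "year1": 0.3,
        "healthy": 0.35, "default": 0.3,
    },
    "Ruminococcaceae SGB15031": {
        "pre_tx": 0.25, "week1": 0.08, "week3_6": 0.15, "year1": 0.2,
        "healthy": 0.25, "default": 0.2,
    },
}

# Background community with group-independent geometric means (%).
BACKGROUND_TAXA_PERCENT = {
    "Bacteroides uniformis": 9.0,
    "Phocaeicola vulgatus": 8.0,
    "Phocaeicola dorei": 5.0,
    "Eubacterium rectale": 6.0,
    "Ruminococcus bromii": 4.0,
    "Alistipes putredinis": 3.5,
    "Blautia wexlerae": 3.0,
    "Bifidobacterium adolescentis": 2.8,
    "Bacteroides stercoris": 2.5,
    "Escherichia coli": 2.5,
    "Parabacteroides distasonis": 2.2,
    "Bacteroides thetaiotaomicron": 2.0,
    "Anaerostipes hadrus": 1.8,
    "Collinsella aerofaciens": 1.5,
    "Dorea longicatena": 1.2,
    "Coprococcus comes": 1.0,
    "Ruminococcus gnavus": 0.9,
    "Dialister invisus": 0.8,
    "Eubacterium siraeum": 0.7,
    "Streptococcus salivarius": 0.4,
}


def simulate_taxa_table(
    subjects: Sequence[SyntheticSubject],
    config: CohortDesign,
    rng: np.random.Generator | None = None,
    sigma_log: float = 0.6,
) -> AbundanceTable:
    """Simulate a MetaPhlAn-style relative-abundance table (% per sample).

    Each taxon's abundance is lognormal around its (group-specific for focal
    taxa) geometric mean, then every sample is renormalized to 100%.
    Metadata carries subject, group and a lognormal library size so the
    library-size filter and per-subject selection utilities are exercisable.
    """
    if len(FOCAL_TAXA_PERCENT) + len(BACKGROUND_TAXA_PERCENT) < 2:
        raise ValueError("need at least 2 taxa")
    if rng is None:
        rng = np.random.default_rng([config.seed, _STREAM_TAXA])

    sample_ids = [s.subject_id for s in subjects]
    taxa = list(FOCAL_TAXA_PERCENT) + list(BACKGROUND_TAXA_PERCENT)
    n = len(subjects)
    raw = np.zeros((len(taxa), n))
    for i, taxon in enumerate(taxa):
        if taxon in FOCAL_TAXA_PERCENT:
            means = FOCAL_TAXA_PERCENT[taxon]
            g = np.array([means.get(s.group, means["default"]) for s in subjects])
        else:
            g = np.full(n, BACKGROUND_TAXA_PERCENT[taxon])
        raw[i] = g * np.exp(rng.normal(0.0, sigma_log, n))
    values = pd.DataFrame(raw, index=taxa, columns=sample_ids)
    values = values.div(values.sum(axis=0), axis=1) * 100.0

    libs = np.clip(rng.lognormal(math.log(25e6), 1.0, n), 1.0e6, 1.2e8).astype(np.int64)
    metadata = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "library_size": libs,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return AbundanceTable(values=values, metadata=metadata, total=100.0)
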