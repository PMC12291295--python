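"""End-to-end orchestration: simulate → rates → QC → NCA → association → community.

One seed in the configuration drives every stochastic stage through
deterministically derived sub-streams, so a run is byte-identical given the
same configuration and the report records what each stage produced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C
from . import io as tio
from .assay import estimate_reactivation_rate, qc_controls
from .community import (
    bray_curtis,
    differential_abundance_screen,
    filter_by_library_size,
    permanova,
    restriction_filter,
    shannon,
    spearman_test,
    within_group_distance_test,
)
from .gus import compute_rpkm, correlate_markers_with_rates, prevalence_filter
from .pk import summarize_cohort
from .synthetic import (
    CohortDesign,
    default_design,
    simulate_assay_timecourse,
    simulate_cohort,
    simulate_cohort_assays,
    simulate_cohort_pk,
    simulate_gus_gene_table,
    simulate_taxa_table,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    outdir: Path
    design: CohortDesign | None = None
    # input paths used when no simulation design is given
    assay_path: str | None = None
    pk_path: str | None = None
    taxa_path: str | None = None
    taxa_metadata_path: str | None = None
    marker_path: str | None = None
    catalog_path: str | None = None
    libraries_path: str | None = None
    # analysis constants
    lloq_mg_l: float = C.LLOQ_MG_L
    onset_window_h: tuple[float, float] = (3.0, 11.0)
    rise_threshold: float = 0.10
    prevalence_min_fraction: float = 0.5
    restriction_min_rel: float = 0.01
    n_perm: int = 999
    min_library_reads: int = C.MIN_LIBRARY_READS
    n_positive_controls: int = 3
    qc_abort: bool = False
    seed: int = 0


def load_config(path) -> PipelineConfig:
    """Read a YAML configuration file into a :class:`PipelineConfig`.

    A ``simulate:`` block maps onto :func:`default_design` overrides
    (``seed`` and ``n_scale`` plus any CohortDesign field).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(outdir=Path(raw.pop("outdir", "runs/out")), **raw)
    if sim is not None:
        n_scale = sim.pop("n_scale", 1)
        sim.setdefault("seed", cfg.seed)
        if "ehr_fraction_range" in sim:
            sim["ehr_fraction_range"] = tuple(sim["ehr_fraction_range"])
        cfg.design = default_design(n_scale=n_scale, **sim)
        cfg.seed = cfg.design.seed
    return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, Path):
        return str(o)
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write per-stage tables plus ``report.json``.

    Returns the report dictionary.  With a simulation design the stages run
    on freshly generated tables; otherwise the configured input paths are
    read.  QC failure aborts when ``qc_abort`` is set, otherwise it is
    recorded in the report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "outputs": {}}

    # ------------------------------------------------------------------ inputs
    if config.design is not None:
        design = config.design
        subjects = simulate_cohort(design)
        assays = simulate_cohort_assays(subjects, design)
        profiles = simulate_cohort_pk(subjects, design)
        markers = simulate_gus_gene_table(subjects, config=design)
        taxa = simulate_taxa_table(subjects, design)
        truth = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "group": [s.group for s in subjects],
                "true_rate_um_h": [s.true_rate for s in subjects],
                "true_ehr_fraction": [s.true_ehr_fraction for s in subjects],
            }
        )
        truth.to_csv(outdir / "subjects_truth.csv", index=False)
        tio.write_assay_csv(assays, outdir / "assay.csv")
        tio.write_pk_csv(profiles, outdir / "pk.csv")
        tio.write_marker_table(
            markers, outdir / "markers.tsv", outdir / "catalog.tsv", outdir / "libraries.csv"
        )
        tio.write_taxa_table(taxa, outdir / "taxa.tsv", outdir / "taxa_metadata.csv")
        report["stages"]["simulate"] = {
            "n_subjects": len(subjects),
            "groups": {g.label: g.n_subjects for g in design.groups},
            "seed": design.seed,
        }
        negative = simulate_assay_timecourse(0.0, "negative_control", design)
        positives = [
            simulate_assay_timecourse(0.0, "positive_control", design,
                                      rng=np.random.default_rng([design.seed, 6, 100 + k]))
            for k in range(config.n_positive_controls)
        ]
        group_of = dict(zip(truth["subject_id"], truth["group"]))
    else:
        if config.assay_path is None:
            raise ValueError("either a simulation design or input paths are required")
        design = None
        assays = tio.read_assay_csv(config.assay_path)
        profiles = tio.read_pk_csv(config.pk_path) if config.pk_path else []
        markers = (
            tio.read_marker_table(config.marker_path, config.catalog_path, config.libraries_path)
            if config.marker_path
            else None
        )
        taxa = (
            tio.read_taxa_table(config.taxa_path, config.taxa_metadata_path)
            if config.taxa_path
            else None
        )
        negative, positives = None, []
        group_of = taxa.metadata["group"].to_dict() if taxa is not None else {}

    # ------------------------------------------------------------------ rates
    estimates = [estimate_reactivation_rate(tc) for tc in assays if tc.kind == "sample"]
    tio.write_rates_csv(estimates, outdir / "rates.csv")
    rates = pd.Series({e.sample_id: e.rate_um_h for e in estimates})
    by_group: dict[str, list[float]] = {}
    for sid, r in rates.items():
        by_group.setdefault(group_of.get(sid, "all"), []).append(r)
    report["stages"]["rates"] = {
        "n_samples": len(estimates),
        "group_mean_um_h": {g: float(np.mean(v)) for g, v in sorted(by_group.items())},
        "group_sd_um_h": {
            g: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            for g, v in sorted(by_group.items())
        },
    }

    # --------------------------------------------------------------------- QC
    if negative is not None and len(positives) >= 2:
        ref = design.control_reference_rate if design is not None else float(
            np.mean([estimate_reactivation_rate(p).rate_um_h for p in positives])
        )
        qc = qc_controls(negative, positives, ref)
        qc_ok = qc.negative_control_pass and all(qc.positive_pass)
        report["stages"]["qc"] = {
            "cv_percent": qc.cv_percent,
            "negative_control_pass": qc.negative_control_pass,
            "positive_pass": list(qc.positive_pass),
            "pass": qc_ok,
        }
        if config.qc_abort and not qc_ok:
            raise RuntimeError("stage qc: control acceptance failed (code QC_FAIL)")

    # -------------------------------------------------------------------- NCA
    if profiles:
        summary, nca = summarize_cohort(
            profiles, window=config.onset_window_h, rise_threshold=config.rise_threshold
        )
        summary.to_csv(outdir / "pk_mean_sem.csv", index=False)
        nca.to_csv(outdir / "nca.csv", index=False)
        ehr = nca.set_index("patient_id")["ehr_percent"]
        common = [s for s in rates.index if s in ehr.index]
        corr = None
        if len(common) >= 4 and np.ptp(rates[common].to_numpy()) > 0:
            res = spearman_test(rates[common].to_numpy(), ehr[common].to_numpy())
            corr = {"rho": res.statistic, "p_value": res.p_value, "n": len(common)}
        report["stages"]["nca"] = {
            "n_profiles": len(profiles),
            "mean_ehr_percent": float(nca["ehr_percent"].mean()),
            "onset_detected_fraction": float(nca["onset_n"].notna().mean()),
            "rate_ehr_spearman": corr,
        }

    # -------------------------------------------------------------- association
    if markers is not None:
        rpkm = compute_rpkm(markers) if markers.value_kind == "counts" else markers
        kept = prevalence_filter(rpkm, config.prevalence_min_fraction)
        shared = [s for s in kept.values.columns if s in rates.index]
        assoc = correlate_markers_with_rates(
            dataclasses.replace(kept, values=kept.values[shared]), rates
        )
        assoc.to_csv(outdir / "association.csv", index=False)
        top = assoc.iloc[0]
        report["stages"]["association"] = {
            "n_markers_tested": int(len(assoc)),
            "top_marker": str(top["marker"]),
            "top_rho": float(top["rho"]),
            "top_taxon": str(top["taxon"]),
        }

    # ---------------------------------------------------------------- community
    if taxa is not None:
        taxa_f = (
            filter_by_library_size(taxa, config.min_library_reads)
            if "library_size" in taxa.metadata.columns
            else taxa
        )
        alpha = {
            s: shannon(taxa_f.values[s].to_numpy()) for s in taxa_f.values.columns
        }
        pd.Series(alpha, name="shannon").rename_axis("sample_id").to_csv(
            outdir / "shannon.csv"
        )
        dist = bray_curtis(taxa_f.values)
        dist.to_csv(outdir / "bray_curtis.tsv", sep="\t")
        groups = taxa_f.metadata.loc[list(taxa_f.values.columns), "group"]
        community: dict = {"n_samples": int(taxa_f.values.shape[1])}
        if groups.nunique() >= 2:
            status = groups.map(lambda g: "healthy" if g == "healthy" else "patient")
            if status.nunique() == 2:
                pv = permanova(dist, status, kind="factor", n_perm=config.n_perm,
                               seed=config.seed)
                community["permanova_patient_vs_healthy"] = {
                    "pseudo_F": pv.statistic, "R2": pv.effect_size, "p_value": pv.p_value,
                }
                wt, wsum = within_group_distance_test(dist, status.to_dict())
                community["within_group_distance"] = {
                    "t": wt.statistic, "p_value": wt.p_value,
                    "means": dict(zip(wsum["group"], wsum["mean_distance"])),
                }
        shared = [s for s in taxa_f.values.columns if s in rates.index]
        if len(shared) >= 5 and np.ptp(rates[shared].to_numpy()) > 0:
            pv = permanova(
                dist.loc[shared, shared], rates[shared], kind="continuous",
                n_perm=config.n_perm, seed=config.seed,
            )
            community["permanova_rate"] = {
                "pseudo_F": pv.statistic, "R2": pv.effect_size, "p_value": pv.p_value,
            }
        labels = set(groups.unique())
        if {"pre_tx", "week1"} <= labels:
            sub = restriction_filter(
                taxa_f, "pre_tx", "week1", config.restriction_min_rel
            )
            da = differential_abundance_screen(
                sub, "pre_tx", "week1", min_rel=config.restriction_min_rel
            )
            da.to_csv(outdir / "da_pre_vs_week1.csv", index=False)
            community["da_pre_vs_week1_significant"] = int((da["q_value"] < 0.05).sum())
        report["stages"]["community"] = community

    report["outputs"] = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "report.json"
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report
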