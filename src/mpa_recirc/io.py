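"""Readers and writers for the plain-text table formats the pipeline uses.

Every table is CSV or TSV (chosen by extension): long-format assay and PK
tables, MetaPhlAn-style taxa TSV (taxon rows × sample columns, percent),
ShortBRED-style marker TSV with a separate catalog and library-size table,
and the rates CSV emitted by the assay stage.  Readers validate schema and
invariants and name the offending row/column in errors; write→read round
trips are value-identical.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import constants as C
from .assay import AssayTimeCourse, RateEstimate
from .community import AbundanceTable
from .gus import FeatureTable
from .pk import PKProfile

__all__ = [
    "write_assay_csv", "read_assay_csv",
    "write_pk_csv", "read_pk_csv",
    "write_taxa_table", "read_taxa_table",
    "write_marker_table", "read_marker_table",
    "write_rates_csv", "read_rates_csv",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column {missing[0]!r}")


# ---------------------------------------------------------------------------
# assay tables


def write_assay_csv(tcs: Sequence[AssayTimeCourse], path) -> None:
    rows = []
    for tc in tcs:
        for i, t in enumerate(tc.times_h):
            for r in range(tc.mpa_mg_l.shape[1]):
                rows.append(
                    {
                        "sample_id": tc.sample_id,
                        "kind": tc.kind,
                        "time_h": t,
                        "replicate": r + 1,
                        "mpa_mg_l": tc.mpa_mg_l[i, r],
                        "mpag_mg_l": tc.mpag_mg_l[i, r],
                        "blank_mpa_mg_l": tc.blank_mpa_mg_l,
                        "amoxapine_mg_ml": tc.amoxapine_mg_ml,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def read_assay_csv(path) -> list[AssayTimeCourse]:
    df = pd.read_csv(path, sep=_sep(path))
    _require_columns(
        df, ["sample_id", "kind", "time_h", "replicate", "mpa_mg_l", "mpag_mg_l"], path
    )
    for col in ("time_h", "mpa_mg_l", "mpag_mg_l"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"{path}: non-numeric {col!r} at row {bad}")
    out = []
    for sid, sub in df.groupby("sample_id", sort=False):
        times = np.sort(sub["time_h"].unique())
        reps = np.sort(sub["replicate"].unique())
        mpa = np.full((times.size, reps.size), np.nan)
        mpag = np.full((times.size, reps.size), np.nan)
        t_idx = {t: i for i, t in enumerate(times)}
        r_idx = {r: i for i, r in enumerate(reps)}
        for _, row in sub.iterrows():
            i, j = t_idx[row["time_h"]], r_idx[row["replicate"]]
            if not np.isnan(mpa[i, j]):
                raise ValueError(f"{path}: duplicate (sample, time, replicate) for {sid!r}")
            mpa[i, j] = row["mpa_mg_l"]
            mpag[i, j] = row["mpag_mg_l"]
        if np.isnan(mpa).any() or np.isnan(mpag).any():
            raise ValueError(f"{path}: sample {sid!r} has an incomplete time × replicate grid")
        blank = sub["blank_mpa_mg_l"].iloc[0] if "blank_mpa_mg_l" in sub else np.nan
        amox = sub["amoxapine_mg_ml"].iloc[0] if "amoxapine_mg_ml" in sub else np.nan
        out.append(
            AssayTimeCourse(
                sample_id=str(sid),
                kind=str(sub["kind"].iloc[0]),
                times_h=times,
                mpa_mg_l=mpa,
                mpag_mg_l=mpag,
                blank_mpa_mg_l=None if pd.isna(blank) else float(blank),
                amoxapine_mg_ml=None if pd.isna(amox) else float(amox),
            )
        )
    return out


# ---------------------------------------------------------------------------
# PK tables


def write_pk_csv(profiles: Sequence[PKProfile], path) -> None:
    rows = []
    for p in profiles:
        for t, c in zip(p.times_h, p.conc_mg_l):
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "visit": p.visit,
                    "time_h": t,
                    "conc_mg_l": c,
                    "dose_mg": p.dose_mg,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def read_pk_csv(path) -> list[PKProfile]:
    df = pd.read_csv(path, sep=_sep(path))
    _require_columns(df, ["patient_id", "visit", "time_h", "conc_mg_l"], path)
    out = []
    for (pid, visit), sub in df.groupby(["patient_id", "visit"], sort=False):
        sub = sub.sort_values("time_h")
        if sub["time_h"].duplicated().any():
            raise ValueError(f"{path}: duplicate time for profile ({pid!r}, {visit!r})")
        dose = sub["dose_mg"].iloc[0] if "dose_mg" in sub else np.nan
        out.append(
            PKProfile(
                patient_id=str(pid),
                visit=str(visit),
                times_h=sub["time_h"].to_numpy(),
                conc_mg_l=sub["conc_mg_l"].to_numpy(),
                dose_mg=None if pd.isna(dose) else float(dose),
            )
        )
    return out


# ---------------------------------------------------------------------------
# taxa tables


def write_taxa_table(table: AbundanceTable, values_path, metadata_path=None) -> None:
    out = table.values.copy()
    out.index.name = "taxon"
    out.to_csv(values_path, sep=_sep(values_path))
    if metadata_path is not None:
        table.metadata.to_csv(metadata_path, sep=_sep(metadata_path))


def read_taxa_table(values_path, metadata_path=None, total: float = 100.0) -> AbundanceTable:
    values = pd.read_csv(values_path, sep=_sep(values_path), index_col=0)
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            raise ValueError(f"{values_path}: non-numeric abundance in sample {col!r}")
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep=_sep(metadata_path), index_col=0)
    else:
        metadata = pd.DataFrame(
            {"group": ["unknown"] * values.shape[1]}, index=values.columns
        )
    return AbundanceTable(values=values, metadata=metadata, total=total)


# ---------------------------------------------------------------------------
# marker tables


def write_marker_table(table: FeatureTable, values_path, catalog_path, libraries_path) -> None:
    out = table.values.copy()
    out.index.name = "marker_id"
    out.to_csv(values_path, sep=_sep(values_path))
    if table.catalog is not None:
        cat = table.catalog.copy()
        cat.index.name = "marker_id"
        cat.to_csv(catalog_path, sep=_sep(catalog_path))
    if table.library_sizes is not None:
        lib = table.library_sizes.rename("library_size").to_frame()
        lib.index.name = "sample_id"
        lib.to_csv(libraries_path, sep=_sep(libraries_path))


def read_marker_table(
    values_path, catalog_path=None, libraries_path=None, value_kind: str = "counts"
) -> FeatureTable:
    values = pd.read_csv(values_path, sep=_sep(values_path), index_col=0)
    catalog = None
    if catalog_path is not None:
        catalog = pd.read_csv(catalog_path, sep=_sep(catalog_path), index_col=0)
        _require_columns(catalog.reset_index(), ["marker_id", "length_bp", "taxon"], catalog_path)
    libraries = None
    if libraries_path is not None:
        lib_df = pd.read_csv(libraries_path, sep=_sep(libraries_path), index_col=0)
        _require_columns(lib_df.reset_index(), ["sample_id", "library_size"], libraries_path)
        libraries = lib_df["library_size"]
    return FeatureTable(
        values=values, value_kind=value_kind, library_sizes=libraries, catalog=catalog
    )


# ---------------------------------------------------------------------------
# rates


def write_rates_csv(estimates: Sequence[RateEstimate], path) -> None:
    pd.DataFrame([vars(e) for e in estimates]).to_csv(path, sep=_sep(path), index=False)


def read_rates_csv(path) -> pd.Series:
    df = pd.read_csv(path, sep=_sep(path))
    _require_columns(df, ["sample_id", "rate_um_h"], path)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    return df.set_index("sample_id")["rate_um_h"]
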