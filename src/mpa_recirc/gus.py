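"""β-glucuronidase gene-marker association screen.

ShortBRED-style marker tables (mapped-read counts per β-GUS gene variant per
sample) are normalized to RPKM (reads per kilobase of target sequence per
million reads in library), filtered on prevalence, and ranked by the
correlation of their abundance with the per-sample MPA reactivation rate.
Taxon annotation is carried from the marker catalog; a group-level Welch test
compares total β-GUS mapping between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .community import TestResult, bh_adjust, spearman_test, welch_t

__all__ = [
    "FeatureTable",
    "compute_rpkm",
    "prevalence_filter",
    "correlate_markers_with_rates",
    "compare_group_totals",
]

_VALUE_KINDS = ("counts", "rpkm", "relative_percent")


@dataclass
class FeatureTable:
    """Marker × sample abundance matrix with catalog and library sizes.

    ``values`` rows are markers, columns samples.  ``catalog`` is indexed by
    marker id with at least ``length_bp`` and ``taxon``; ``library_sizes``
    (reads per sample) is required when ``value_kind == "counts"``.
    """

    values: pd.DataFrame
    value_kind: str
    library_sizes: pd.Series | None = None
    catalog: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in _VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {_VALUE_KINDS}")
        v = self.values
        if v.index.duplicated().any() or v.columns.duplicated().any():
            raise ValueError("marker and sample labels must be unique")
        if (v.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.value_kind == "counts":
            if self.library_sizes is None:
                raise ValueError("counts tables require library_sizes")
            missing = [s for s in v.columns if s not in self.library_sizes.index]
            if missing:
                raise ValueError(f"library size missing for sample {missing[0]!r}")
            if (self.library_sizes.loc[list(v.columns)] <= 0).any():
                raise ValueError("library sizes must be positive")


def compute_rpkm(table: FeatureTable) -> FeatureTable:
    """Normalize raw mapped-read counts to RPKM.

    rpkm = count / (length_bp / 1000) / (library_size / 1e6)
    """
    if table.value_kind != "counts":
        raise ValueError("compute_rpkm expects a counts table")
    if table.catalog is None or "length_bp" not in table.catalog.columns:
        raise ValueError("marker lengths missing from catalog")
    missing = [m for m in table.values.index if m not in table.catalog.index]
    if missing:
        raise ValueError(f"catalog entry missing for marker {missing[0]!r}")
    lengths = table.catalog.loc[table.values.index, "length_bp"].astype(float)
    if (lengths <= 0).any():
        raise ValueError("marker lengths must be positive")
    libs = table.library_sizes.loc[list(table.values.columns)].astype(float)
    rpkm = table.values.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)
    return FeatureTable(
        values=rpkm, value_kind="rpkm", library_sizes=table.library_sizes,
        catalog=table.catalog,
    )


def prevalence_filter(
    table: FeatureTable, min_fraction: float = 0.5, detection_epsilon: float = 0.0
) -> FeatureTable:
    """Keep markers detected (> ``detection_epsilon``) in at least
    ``min_fraction`` of samples (boundary inclusive); row order preserved."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if table.values.empty:
        raise ValueError("empty feature table")
    frac = (table.values > detection_epsilon).mean(axis=1)
    kept = table.values.index[frac >= min_fraction]
    return FeatureTable(
        values=table.values.loc[kept], value_kind=table.value_kind,
        library_sizes=table.library_sizes, catalog=table.catalog,
    )


def correlate_markers_with_rates(
    table: FeatureTable,
    rates: pd.Series,
    method: str = "spearman",
) -> pd.DataFrame:
    """Per-marker correlation of abundance with reactivation rate.

    Returns a table (sorted by rho descending) of rho, p, BH q computed across
    the marker set actually tested, prevalence, mean abundance and the
    catalog taxon.  Constant-abundance markers get NaN correlation and are
    excluded from the BH family.  ``method`` is ``"spearman"`` (default;
    average-rank ties, exact permutation p for n <= 10) or ``"pearson"``.
    """
    samples = list(table.values.columns)
    missing = [s for s in samples if s not in rates.index]
    if missing:
        raise ValueError(f"rate missing for sample {missing[0]!r}")
    if len(samples) < 4:
        raise ValueError("need at least 4 samples")
    r = rates.loc[samples].to_numpy(dtype=float)
    if np.ptp(r) == 0:
        raise ValueError("constant rate vector: correlation undefined")

    rows = []
    for marker in table.values.index:
        x = table.values.loc[marker, samples].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rho, p = np.nan, np.nan
        elif method == "spearman":
            res = spearman_test(x, r)
            rho, p = res.statistic, res.p_value
        elif method == "pearson":
            pr = stats.pearsonr(x, r)
            rho, p = float(pr.statistic), float(pr.pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
        taxon = (
            table.catalog.loc[marker, "taxon"]
            if table.catalog is not None and marker in table.catalog.index
            else ""
        )
        rows.append(
            {
                "marker": marker,
                "rho": rho,
                "p_value": p,
                "prevalence": float((table.values.loc[marker, samples] > 0).mean()),
                "mean_abundance": float(x.mean()),
                "taxon": taxon,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    tested = out["p_value"].notna()
    if tested.any():
        out.loc[tested, "q_value"] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    return out.sort_values("rho", ascending=False, kind="stable").reset_index(drop=True)


def compare_group_totals(table: FeatureTable, groups: Mapping[str, str]) -> TestResult:
    """Welch two-sample t-test of per-sample total abundance between the two
    group labels present in ``groups``."""
    totals = table.values.sum(axis=0)
    labels = pd.Series({s: groups[s] for s in totals.index if s in groups})
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(names)}")
    a = totals[labels.index[labels == names[0]]].to_numpy(dtype=float)
    b = totals[labels.index[labels == names[1]]].to_numpy(dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs >=2 samples")
    for name, v in zip(names, (a, b)):
        if v.size == 2 and np.ptp(v) == 0:
            raise ValueError(f"group {name!r} has zero variance with n=2")
    res = welch_t(a, b)
    res.extras.update({"groups": names, "n": (int(a.size), int(b.size))})
    return res
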