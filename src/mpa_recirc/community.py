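"""Gut-community diversity and composition statistics.

Covers the community-level analyses applied to MetaPhlAn-style relative
abundance tables: Shannon diversity, Bray-Curtis dissimilarities, PERMANOVA
(factor or continuous predictor via the Gower-centering / pseudo-F
construction, so a continuous covariate such as the MPA reactivation rate is
supported in the same formulation), a within-group distance comparison, the
abundance/prevalence restriction filter, and a descriptive differential
abundance screen (geometric-mean fold change + rank test; this is an
explicitly descriptive stand-in for a count-model analysis, not one).

Shared small-sample statistical primitives (Spearman with exact permutation
p for n <= 10, exact Wilcoxon tests, Welch's t, Benjamini-Hochberg) live here
so the marker-association and assay modules use one set of definitions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from . import constants as C

__all__ = [
    "AbundanceTable",
    "TestResult",
    "shannon",
    "bray_curtis",
    "permanova",
    "within_group_distance_test",
    "restriction_filter",
    "differential_abundance_screen",
    "spearman_test",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "welch_t",
    "bh_adjust",
    "filter_by_library_size",
    "select_one_sample_per_subject",
]


@dataclass
class AbundanceTable:
    """Taxon × sample relative abundances plus per-sample metadata.

    ``values`` columns are samples; each column must sum to ``total``
    (100 for percent tables, 1 for proportions) within 1e-6 relative.
    ``metadata`` is indexed by sample id with at least ``group``; optional
    ``subject_id`` and ``library_size`` columns feed the sample-selection
    utilities.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    total: float = 100.0

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any() or v.columns.duplicated().any():
            raise ValueError("taxon and sample labels must be unique")
        if (v.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        sums = v.sum(axis=0)
        bad = sums[~np.isclose(sums, self.total, rtol=1e-6, atol=1e-6 * self.total)]
        if len(bad):
            raise ValueError(
                f"sample {bad.index[0]!r} sums to {bad.iloc[0]:g}, expected {self.total:g}"
            )
        missing = [s for s in v.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"metadata missing for sample {missing[0]!r}")

    def subset(self, samples: Sequence[str], taxa: Sequence[str] | None = None) -> "AbundanceTable":
        """Restrict to given samples (and optionally taxa) without renormalizing."""
        v = self.values.loc[taxa if taxa is not None else self.values.index, list(samples)]
        tbl = AbundanceTable.__new__(AbundanceTable)  # skip sum check: subsets need not renormalize
        tbl.values = v
        tbl.metadata = self.metadata.loc[list(samples)]
        tbl.total = self.total
        return tbl


@dataclass
class TestResult:
    """Uniform container for a statistical test outcome."""

    statistic: float
    kind: str  # "pseudo-F", "t", "W", "U", "rho"
    p_value: float
    df: float | tuple | None = None
    n_permutations: int | None = None
    effect_size: float | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# diversity and distances


def shannon(abundances, base: float | None = None) -> float:
    """Shannon diversity −Σ pᵢ log pᵢ over nonzero proportions (natural log
    by default; pass ``base`` for other units)."""
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    s = a.sum()
    if s <= 0:
        raise ValueError("all-zero sample")
    p = a[a > 0] / s
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base) if base is not None else h


def bray_curtis(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between sample columns."""
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = values.to_numpy(dtype=float).T
    if np.any(x.sum(axis=1) <= 0):
        raise ValueError("zero-sum sample")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


# ---------------------------------------------------------------------------
# PERMANOVA


def _design_matrix(predictor: pd.Series, kind: str) -> np.ndarray:
    vals = predictor.to_numpy()
    if kind == "auto":
        kind = "continuous" if np.issubdtype(np.asarray(vals).dtype, np.number) else "factor"
    n = len(vals)
    if kind == "continuous":
        x = np.asarray(vals, dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("continuous predictor has zero variance")
        return np.column_stack([np.ones(n), x])
    levels = pd.unique(vals)
    if len(levels) < 2:
        raise ValueError("factor predictor needs at least 2 levels")
    cols = [np.ones(n)] + [(vals == lv).astype(float) for lv in levels[1:]]
    return np.column_stack(cols)


def permanova(
    dist: pd.DataFrame,
    predictor,
    kind: str = "auto",
    n_perm: int | str = 999,
    seed: int | None = None,
) -> TestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Squared distances are Gower-centered to an inner-product matrix G; the
    predictor's hat matrix partitions trace(G) into model and residual sums
    of squares, giving pseudo-F and R².  The p-value permutes sample labels
    (``n_perm`` random permutations with ``+1`` correction, or every
    permutation when ``n_perm="exact"``, feasible for n <= 8).

    ``kind`` is ``"factor"``, ``"continuous"`` or ``"auto"`` (numeric dtype
    means continuous).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("dist must be a square symmetric zero-diagonal matrix")
    if n < 3:
        raise ValueError("need at least 3 samples")
    labels = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    pred = predictor.reindex(labels) if isinstance(predictor, pd.Series) else pd.Series(
        np.asarray(predictor), index=labels
    )
    if pred.isna().any():
        raise ValueError("predictor missing for some samples")

    x = _design_matrix(pred, kind)
    rank = np.linalg.matrix_rank(x)
    df_model, df_resid = rank - 1, n - rank
    if df_model < 1:
        raise ValueError("predictor provides no contrast")
    if df_resid < 1:
        raise ValueError("confounded design: zero residual degrees of freedom")

    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    h = x @ np.linalg.pinv(x)
    ss_total = float(np.trace(g))
    ss_model = float(np.sum(h * g))  # trace(HGH) = trace(HG) for idempotent H
    ss_resid = ss_total - ss_model
    f_obs = (ss_model / df_model) / (ss_resid / df_resid)
    r2 = ss_model / ss_total

    def f_of(perm: np.ndarray) -> float:
        hp = h[np.ix_(perm, perm)]
        ssm = float(np.sum(hp * g))
        return (ssm / df_model) / ((ss_total - ssm) / df_resid)

    if n_perm == "exact":
        if n > 8:
            raise ValueError("exact enumeration supported for n <= 8")
        fs = np.array([f_of(np.array(p)) for p in itertools.permutations(range(n))])
        p_value = float(np.mean(fs >= f_obs - 1e-12))
        n_permutations = fs.size
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_perm)):
            if f_of(rng.permutation(n)) >= f_obs - 1e-12:
                count += 1
        p_value = (1 + count) / (1 + int(n_perm))
        n_permutations = int(n_perm)

    return TestResult(
        statistic=f_obs,
        kind="pseudo-F",
        p_value=p_value,
        df=(df_model, df_resid),
        n_permutations=n_permutations,
        effect_size=r2,
        seed=seed,
        extras={"ss_model": ss_model, "ss_total": ss_total},
    )


def within_group_distance_test(
    dist: pd.DataFrame, groups: Mapping[str, str]
) -> tuple[TestResult, pd.DataFrame]:
    """Compare within-group pairwise distances between two groups.

    Pools each group's within-group Bray-Curtis distances and applies an
    unpaired (Welch) t-test.  Pairwise distances sharing a sample are not
    independent, so the result carries ``caveat_nonindependent_pairs``.
    """
    labels = pd.Series({s: groups[s] for s in dist.index if s in groups})
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(names)}")
    pooled = {}
    for g in names:
        members = labels.index[labels == g]
        if len(members) < 2:
            raise ValueError(f"group {g!r} needs >=2 samples")
        sub = dist.loc[members, members].to_numpy()
        pooled[g] = sub[np.triu_indices(len(members), k=1)]
    res = welch_t(pooled[names[0]], pooled[names[1]])
    res.extras["caveat_nonindependent_pairs"] = True
    summary = pd.DataFrame(
        {
            "group": names,
            "n_pairs": [pooled[g].size for g in names],
            "mean_distance": [float(pooled[g].mean()) for g in names],
            "sd_distance": [float(pooled[g].std(ddof=1)) for g in names],
        }
    )
    return res, summary


# ---------------------------------------------------------------------------
# restriction filter and descriptive differential-abundance screen


def restriction_filter(
    table: AbundanceTable,
    group_a: str,
    group_b: str,
    min_rel: float = 0.01,
    min_fraction: float = 0.5,
) -> AbundanceTable:
    """Keep taxa observed at >= ``min_rel`` (same units as the table) in at
    least ``min_fraction`` of the samples pooled across the two groups."""
    if min_rel < 0:
        raise ValueError("min_rel must be non-negative")
    grp = table.metadata["group"]
    samples = [s for s in table.values.columns if grp.get(s) in (group_a, group_b)]
    for g in (group_a, group_b):
        if not any(grp.get(s) == g for s in samples):
            raise ValueError(f"group {g!r} has no samples")
    sub = table.values[samples]
    frac = (sub >= min_rel).mean(axis=1)
    kept = sub.index[frac >= min_fraction]
    return table.subset(samples, kept)


def differential_abundance_screen(
    table: AbundanceTable,
    group_a: str,
    group_b: str,
    paired: bool = False,
    min_rel: float = 0.01,
) -> pd.DataFrame:
    """Descriptive per-taxon screen: geometric-mean fold change (pseudocount
    ``min_rel/2``) plus a Wilcoxon rank test, BH-adjusted across taxa.

    Apply :func:`restriction_filter` first.  ``paired`` matches samples of
    the two groups by ``subject_id`` and uses the signed-rank test.
    """
    grp = table.metadata["group"]
    a_samples = [s for s in table.values.columns if grp.get(s) == group_a]
    b_samples = [s for s in table.values.columns if grp.get(s) == group_b]
    if len(a_samples) < 3 or len(b_samples) < 3:
        raise ValueError("each group needs >=3 samples")
    if paired:
        subj = table.metadata["subject_id"]
        by_subj_a = {subj[s]: s for s in a_samples}
        by_subj_b = {subj[s]: s for s in b_samples}
        common = sorted(set(by_subj_a) & set(by_subj_b))
        if len(common) < 3 or len(common) != len(a_samples) or len(common) != len(b_samples):
            raise ValueError("paired screen requires matched subjects in both groups")
        a_samples = [by_subj_a[s] for s in common]
        b_samples = [by_subj_b[s] for s in common]

    pc = min_rel / 2.0
    rows = []
    for taxon in table.values.index:
        a = table.values.loc[taxon, a_samples].to_numpy(dtype=float) + pc
        b = table.values.loc[taxon, b_samples].to_numpy(dtype=float) + pc
        gm_a = float(np.exp(np.mean(np.log(a))))
        gm_b = float(np.exp(np.mean(np.log(b))))
        if np.ptp(np.concatenate([a, b])) == 0 or (
            a.size == b.size and np.array_equal(np.sort(a), np.sort(b))
        ):
            p = 1.0
        elif paired:
            p = wilcoxon_signed_rank(np.log(a), np.log(b)).p_value
        else:
            p = wilcoxon_rank_sum(a, b).p_value
        rows.append(
            {
                "taxon": taxon,
                "gm_a": gm_a,
                "gm_b": gm_b,
                "fold_change": gm_a / gm_b,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values("q_value", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# shared statistical primitives


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (enumerates all n!
    orderings of one margin; average ranks for ties)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.linalg.norm(rxc) * np.linalg.norm(ryc)
    n = len(x)
    count = 0
    total = 0
    chunk: list[tuple] = []

    def flush(chunk_arr: list[tuple]) -> int:
        perm = np.array(chunk_arr)
        rhos = (rxc[perm] @ ryc) / denom
        return int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))

    for p in itertools.permutations(range(n)):
        chunk.append(p)
        total += 1
        if len(chunk) == 200_000:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return count / total


def spearman_test(x, y, exact_max_n: int = 10) -> TestResult:
    """Spearman rank correlation with average-rank ties.

    Exact permutation p for n <= ``exact_max_n``; t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched vectors of length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p_t = stats.spearmanr(x, y)
    if x.size <= exact_max_n:
        p = _spearman_exact_p(x, y, rho)
        method = "exact"
    else:
        p, method = p_t, "t-approximation"
    return TestResult(
        statistic=float(rho), kind="rho", p_value=float(p), df=x.size - 2,
        extras={"n": int(x.size), "method": method},
    )


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Wilcoxon signed-rank test on paired differences (or a single vector).

    Exact distribution when <= 25 nonzero untied differences, otherwise the
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    nz = d[d != 0]
    if nz.size < 5:
        raise ValueError("need >=5 non-zero differences")
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ties and nz.size == d.size) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return TestResult(
        statistic=float(res.statistic), kind="W", p_value=float(res.pvalue),
        extras={"n_nonzero": int(nz.size), "method": method},
    )


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test; exact null for small untied
    samples (both n <= 10), normal approximation with continuity otherwise.

    The reported statistic is the rank sum W of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >=2 observations")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return TestResult(
        statistic=w, kind="W", p_value=float(res.pvalue),
        extras={"U": float(res.statistic), "method": method},
    )


def welch_t(x, y) -> TestResult:
    """Welch's two-sample t-test (unequal variances, Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >=2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("t statistic undefined: both groups have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic), kind="t", p_value=float(res.pvalue),
        df=float(res.df),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# sample-selection utilities


def filter_by_library_size(
    table: AbundanceTable, min_reads: int = C.MIN_LIBRARY_READS
) -> AbundanceTable:
    """Drop samples whose metagenomic library is below ``min_reads``."""
    lib = table.metadata["library_size"]
    keep = [s for s in table.values.columns if lib[s] >= min_reads]
    return table.subset(keep)


def select_one_sample_per_subject(table: AbundanceTable) -> AbundanceTable:
    """Keep each subject's single sample with the largest library."""
    md = table.metadata.loc[list(table.values.columns)]
    keep = (
        md.sort_values("library_size", ascending=False)
        .groupby("subject_id", sort=False)
        .head(1)
        .index
    )
    ordered = [s for s in table.values.columns if s in set(keep)]
    return table.subset(ordered)
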