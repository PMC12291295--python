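"""Community statistics: diversity, distances, PERMANOVA and stat primitives."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpa_recirc.community import (
    AbundanceTable,
    bh_adjust,
    bray_curtis,
    differential_abundance_screen,
    filter_by_library_size,
    permanova,
    restriction_filter,
    select_one_sample_per_subject,
    shannon,
    spearman_test,
    welch_t,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
    within_group_distance_test,
)


class TestShannon:
    def test_uniform_four_taxa(self):
        assert shannon([25, 25, 25, 25]) == pytest.approx(math.log(4))

    def test_single_taxon_zero(self):
        assert shannon([100, 0, 0]) == 0.0

    def test_hand_computed(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    def test_base_option(self):
        assert shannon([1, 1, 1, 1], base=2) == pytest.approx(2.0)

    def test_concentration_decreases_diversity(self):
        assert shannon([40, 30, 30]) > shannon([80, 10, 10])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        df = pd.DataFrame({"a": [60, 40, 0], "b": [60, 40, 0], "c": [0, 0, 100]},
                          index=["t1", "t2", "t3"])
        d = bray_curtis(df[["a", "b"]])
        assert d.loc["a", "b"] == 0.0
        d2 = bray_curtis(df[["a", "c"]])
        assert d2.loc["a", "c"] == pytest.approx(1.0)

    def test_hand_computed(self):
        df = pd.DataFrame({"x": [60, 30, 10], "y": [30, 30, 40]})
        assert bray_curtis(df).loc["x", "y"] == pytest.approx(0.3)

    def test_matrix_properties_and_renormalization_invariance(self, rng):
        raw = rng.uniform(0, 5, (8, 6))
        df = pd.DataFrame(raw, columns=list("abcdef"))
        d = bray_curtis(df)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert ((d.to_numpy() >= 0) & (d.to_numpy() <= 1)).all()
        norm = df / df.sum(axis=0) * 100
        # joint renormalization of both samples to a common total preserves d
        np.testing.assert_allclose(bray_curtis(norm), bray_curtis(norm * 3), atol=1e-12)

    def test_zero_sum_sample_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]}))


def _toy_distance(n=6, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, (n, 4))
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(x, "braycurtis"))
    labels = [f"s{i}" for i in range(n)]
    return pd.DataFrame(d, index=labels, columns=labels)


class TestPermanova:
    def test_constant_predictor_rejected(self):
        d = _toy_distance()
        with pytest.raises(ValueError):
            permanova(d, ["g"] * 6, kind="factor")

    def test_perfect_separation(self):
        labels = ["a1", "a2", "b1", "b2"]
        d = pd.DataFrame(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]],
            index=labels, columns=labels, dtype=float,
        )
        res = permanova(d, pd.Series(["A", "A", "B", "B"], index=labels),
                        kind="factor", n_perm=999, seed=0)
        assert res.effect_size == pytest.approx(1.0)
        # 2+2 design has only 3 distinct partitions; the observed one is the
        # unique maximizer, so the permutation floor is 1/3
        assert res.p_value == pytest.approx(1 / 3, abs=0.05)

    def test_exact_enumeration_matches_partition_oracle(self):
        """Permutation p over all 6! index permutations equals the p computed
        by enumerating the C(6,3)=20 distinct group assignments."""
        d = _toy_distance(6, seed=3)
        groups = pd.Series(["A", "A", "A", "B", "B", "B"], index=d.index)
        res = permanova(d, groups, kind="factor", n_perm="exact")

        def f_for(assign):
            g = pd.Series(assign, index=d.index)
            return permanova(g_dist, g, kind="factor", n_perm=1, seed=0).statistic

        g_dist = d
        fs = []
        for comb in itertools.combinations(range(6), 3):
            assign = ["B"] * 6
            for i in comb:
                assign[i] = "A"
            fs.append(f_for(assign))
        fs = np.array(fs)
        f_obs = permanova(d, groups, kind="factor", n_perm=1, seed=0).statistic
        oracle_p = float(np.mean(fs >= f_obs - 1e-12))
        assert res.p_value == pytest.approx(oracle_p)

    def test_factor_pseudo_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        d = _toy_distance(12, seed=5)
        groups = ["A"] * 6 + ["B"] * 6
        res = permanova(d, pd.Series(groups, index=d.index), kind="factor",
                        n_perm=99, seed=1)
        dm = skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        ref = skbio.stats.distance.permanova(dm, grouping=groups, permutations=99)
        assert res.statistic == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_continuous_predictor(self):
        d = _toy_distance(10, seed=2)
        x = pd.Series(np.arange(10.0), index=d.index)
        res = permanova(d, x, kind="continuous", n_perm=99, seed=0)
        assert 0 <= res.effect_size <= 1
        assert res.df == (1, 8)

    def test_confounded_design_rejected(self):
        d = _toy_distance(4)
        with pytest.raises(ValueError):
            permanova(d, pd.Series(list("abcd"), index=d.index), kind="factor")

    def test_orthogonal_r2_sum_at_most_one(self):
        d = _toy_distance(8, seed=9)
        a = pd.Series(["x"] * 4 + ["y"] * 4, index=d.index)
        b = pd.Series(["u", "v"] * 4, index=d.index)
        r2 = sum(
            permanova(d, p, kind="factor", n_perm=9, seed=0).effect_size for p in (a, b)
        )
        assert r2 <= 1.0 + 1e-9

    def test_p_uniform_under_null(self):
        """Permutation p-values are uniform when labels carry no signal."""
        ps = []
        for seed in range(80):
            d = _toy_distance(12, seed=1000 + seed)
            rng = np.random.default_rng(seed)
            groups = pd.Series(rng.permutation(["A"] * 6 + ["B"] * 6), index=d.index)
            ps.append(
                permanova(d, groups, kind="factor", n_perm=199, seed=seed).p_value
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_seeded_reproducibility(self):
        d = _toy_distance(10, seed=4)
        g = pd.Series(["A"] * 5 + ["B"] * 5, index=d.index)
        p1 = permanova(d, g, n_perm=199, seed=42).p_value
        p2 = permanova(d, g, n_perm=199, seed=42).p_value
        assert p1 == p2


class TestWithinGroupDistances:
    def test_identical_multisets_t_zero(self):
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        d = pd.DataFrame(0.0, index=labels, columns=labels)
        for (i, j), v in zip([(0, 1), (0, 2), (1, 2)], [0.5, 0.6, 0.7]):
            d.iloc[i, j] = d.iloc[j, i] = v
            d.iloc[i + 3, j + 3] = d.iloc[j + 3, i + 3] = v
        res, summary = within_group_distance_test(
            d, dict(zip(labels, ["A"] * 3 + ["B"] * 3))
        )
        assert res.statistic == pytest.approx(0.0)
        assert list(summary["mean_distance"]) == [pytest.approx(0.6)] * 2

    def test_pair_counts_and_mean_difference(self):
        labels = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        d = pd.DataFrame(0.0, index=labels, columns=labels)
        for i, j in itertools.combinations(range(4), 2):
            d.iloc[i, j] = d.iloc[j, i] = 0.8
            d.iloc[i + 4, j + 4] = d.iloc[j + 4, i + 4] = 0.6
        d += np.diag(np.zeros(8))
        groups = dict(zip(labels, ["A"] * 4 + ["B"] * 4))
        # perturb to give nonzero variance for the t-test
        d.iloc[0, 1] = d.iloc[1, 0] = 0.82
        d.iloc[4, 5] = d.iloc[5, 4] = 0.58
        res, summary = within_group_distance_test(d, groups)
        assert list(summary["n_pairs"]) == [6, 6]
        diff = summary["mean_distance"].iloc[0] - summary["mean_distance"].iloc[1]
        assert diff == pytest.approx(0.2, abs=0.01)
        assert res.extras["caveat_nonindependent_pairs"]

    def test_small_group_rejected(self):
        d = _toy_distance(4)
        with pytest.raises(ValueError):
            within_group_distance_test(d, dict(zip(d.index, ["A", "B", "B", "B"])))


def _abundance_table(values: dict, groups: dict, total=100.0, subjects=None, libs=None):
    df = pd.DataFrame(values)
    meta = pd.DataFrame(
        {
            "group": pd.Series(groups),
            "subject_id": pd.Series(subjects) if subjects else pd.Series(
                {s: s for s in df.columns}
            ),
            "library_size": pd.Series(libs) if libs else pd.Series(
                {s: 10_000_000 for s in df.columns}
            ),
        }
    )
    return AbundanceTable(values=df, metadata=meta, total=total)


class TestRestrictionFilter:
    def _table(self):
        # 4 samples, boundary taxa crafted by hand
        vals = {
            "s1": [0.010, 0.009, 50.0, 49.981],
            "s2": [0.005, 0.009, 50.0, 49.986],
            "s3": [0.010, 0.009, 50.0, 49.981],
            "s4": [0.002, 0.009, 50.0, 49.989],
        }
        df = pd.DataFrame(vals, index=["boundary", "low", "big", "rest"])
        meta = pd.DataFrame(
            {"group": ["A", "A", "B", "B"]}, index=["s1", "s2", "s3", "s4"]
        )
        return AbundanceTable(values=df, metadata=meta, total=100.0)

    def test_boundary_inclusive_and_exclusions(self):
        out = restriction_filter(self._table(), "A", "B", min_rel=0.01, min_fraction=0.5)
        kept = list(out.values.index)
        assert "boundary" in kept  # exactly 0.01% in exactly half the samples
        assert "low" not in kept  # 0.009% everywhere
        assert "big" in kept and "rest" in kept

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            restriction_filter(self._table(), "A", "B", min_rel=-0.1)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError):
            restriction_filter(self._table(), "A", "Z")


class TestDifferentialAbundance:
    def test_identical_groups_unit_fold_change(self):
        vals = {f"s{i}": [30.0, 70.0] for i in range(6)}
        t = _abundance_table(vals, {f"s{i}": "A" if i < 3 else "B" for i in range(6)})
        t.values.index = ["t1", "t2"]
        out = differential_abundance_screen(t, "A", "B")
        np.testing.assert_allclose(out["fold_change"], 1.0)
        assert (out["p_value"] == 1.0).all()

    def test_rank_sum_p_matches_enumeration(self):
        a = np.array([1.2, 3.4, 5.6])
        b = np.array([2.1, 7.8, 9.9])
        res = wilcoxon_rank_sum(a, b)
        ranks = stats.rankdata(np.concatenate([a, b]))
        uobs = ranks[:3].sum() - 3 * 4 / 2
        us = np.array(
            [ranks[list(c)].sum() - 6 for c in itertools.combinations(range(6), 3)]
        )
        p_oracle = min(1.0, 2 * min((us <= uobs).mean(), (us >= uobs).mean()))
        assert res.p_value == pytest.approx(p_oracle)
        assert res.extras["U"] == uobs

    def test_paired_requires_matched_subjects(self):
        vals = {f"s{i}": [30.0, 70.0] for i in range(6)}
        t = _abundance_table(
            vals,
            {f"s{i}": "A" if i < 3 else "B" for i in range(6)},
            subjects={f"s{i}": f"subj{i}" for i in range(6)},  # all distinct
        )
        t.values.index = ["t1", "t2"]
        with pytest.raises(ValueError):
            differential_abundance_screen(t, "A", "B", paired=True)


class TestPrimitives:
    def test_spearman_perfect_monotone(self):
        res = spearman_test([1, 2, 3, 4, 5, 6], [10, 20, 30, 40, 50, 60])
        assert res.statistic == 1.0
        assert res.p_value == pytest.approx(2 / 720)  # only the two comonotone orders

    def test_spearman_exact_p_matches_brute_force(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        res = spearman_test(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rhos = np.array(
            [np.corrcoef(rx[list(p)], ry)[0, 1] for p in itertools.permutations(range(6))]
        )
        oracle = float(np.mean(np.abs(rhos) >= abs(res.statistic) - 1e-12))
        assert res.p_value == pytest.approx(oracle)
        assert res.extras["method"] == "exact"

    def test_spearman_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_signed_rank_exact_matches_enumeration(self):
        d = np.array([1.5, -2.5, 3.5, -4.5, 5.5, 6.5])
        res = wilcoxon_signed_rank(d)
        ranks = stats.rankdata(np.abs(d))
        tobs = ranks[d > 0].sum()
        ts = np.array(
            [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([True, False], repeat=6)
            ]
        )
        p_oracle = min(1.0, 2 * min((ts <= tobs).mean(), (ts >= tobs).mean()))
        assert res.p_value == pytest.approx(p_oracle)
        assert res.extras["method"] == "exact"

    def test_signed_rank_needs_five_nonzero(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0, 1.0, -1.0, 2.0, 0.0])

    def test_welch_hand_computed(self):
        res = welch_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0))
        assert res.df == pytest.approx(4.0)

    def test_welch_location_invariance(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        t1 = welch_t(a, b).statistic
        t2 = welch_t([v + 10 for v in a], [v + 10 for v in b]).statistic
        assert t1 == pytest.approx(t2)

    def test_bh_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_bh_matches_definition_oracle(self, rng):
        for _ in range(20):
            p = np.sort(rng.uniform(0, 1, rng.integers(2, 11)))
            m = p.size
            oracle = np.array(
                [min((p[j] * m / (j + 1)) for j in range(i, m)) for i in range(m)]
            )
            oracle = np.minimum(oracle, 1.0)
            np.testing.assert_allclose(bh_adjust(p), oracle, rtol=1e-12)


class TestSampleSelection:
    def test_library_size_filter(self):
        vals = {f"s{i}": [40.0, 60.0] for i in range(4)}
        t = _abundance_table(
            vals, {f"s{i}": "A" for i in range(4)},
            libs={"s0": 5_000_000, "s1": 2_000_000, "s2": 3_000_000, "s3": 1_000_000},
        )
        t.values.index = ["t1", "t2"]
        out = filter_by_library_size(t)
        assert list(out.values.columns) == ["s0", "s2"]

    def test_one_sample_per_subject_keeps_largest_library(self):
        vals = {f"s{i}": [40.0, 60.0] for i in range(4)}
        t = _abundance_table(
            vals, {f"s{i}": "A" for i in range(4)},
            subjects={"s0": "u1", "s1": "u1", "s2": "u2", "s3": "u2"},
            libs={"s0": 5_000_000, "s1": 9_000_000, "s2": 3_000_000, "s3": 4_000_000},
        )
        t.values.index = ["t1", "t2"]
        out = select_one_sample_per_subject(t)
        assert sorted(out.values.columns) == ["s1", "s3"]
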