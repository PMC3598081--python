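from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiometh.screening import (
    SelectionRules,
    aggregate_gene_beta,
    classify_direction,
    platform_coverage,
    rank_sum_test,
    select_candidates,
    wilcoxon_gene_screen,
)
from cardiometh.synthetic import CohortDesign, gen_beta_matrix


def enumeration_ranksum_p(case, control):
    """Independent oracle: two-sided rank-sum p by enumerating every group
    assignment of the pooled observations (tie-aware via average ranks)."""
    pooled = np.asarray(list(case) + list(control), dtype=float)
    ranks = stats.rankdata(pooled)
    n1 = len(case)
    w_obs = ranks[:n1].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), n1)]
    sums = np.asarray(sums)
    p_le = np.mean(sums <= w_obs + 1e-9)
    p_ge = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestRankSumTest:
    def test_separated_groups_exact_p(self):
        # C(6,3)=20 assignments, only the extremes as extreme -> p = 2/20
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_label_swap_symmetry(self, rng):
        a, b = rng.uniform(0, 1, 5), rng.uniform(0, 1, 4)
        assert rank_sum_test(a, b) == pytest.approx(rank_sum_test(b, a))

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4)])
    def test_matches_enumeration_without_ties(self, n1, n2, rng):
        for _ in range(20):
            a, b = rng.uniform(0, 1, n1), rng.uniform(0, 1, n2)
            assert rank_sum_test(a, b) == pytest.approx(
                enumeration_ranksum_p(a, b), abs=1e-12
            )

    def test_matches_enumeration_with_ties(self, rng):
        fixtures = [
            ([1, 1, 2], [1, 2, 2]),
            ([0.5, 0.5, 0.7, 0.7], [0.5, 0.7, 0.9]),
            ([1, 2, 2, 3], [2, 2, 4, 4]),
        ]
        for a, b in fixtures:
            assert rank_sum_test(a, b) == pytest.approx(
                enumeration_ranksum_p(a, b), abs=1e-12
            )
        for _ in range(10):
            a = rng.integers(0, 3, 4).astype(float)
            b = rng.integers(0, 3, 4).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            assert rank_sum_test(a, b) == pytest.approx(
                enumeration_ranksum_p(a, b), abs=1e-12
            )

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 28)
        p = rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                 use_continuity=False).pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])


class TestPlatformCoverage:
    def test_worked_example(self):
        assert platform_coverage(2018, 1858) == 92.1

    @pytest.mark.parametrize(
        "annotated,covered,expected", [(100, 100, 100.0), (3, 1, 33.3)]
    )
    def test_arithmetic(self, annotated, covered, expected):
        assert platform_coverage(annotated, covered) == expected

    def test_validation(self):
        with pytest.raises(ValueError):
            platform_coverage(0, 0)
        with pytest.raises(ValueError):
            platform_coverage(10, 11)


class TestAggregateGeneBeta:
    def _fixture(self):
        beta = pd.DataFrame(
            {"s1": [0.2, 0.4, 0.7], "s2": [0.1, 0.3, 0.9]},
            index=["p1", "p2", "p3"],
        )
        ann = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "gene_id": ["gA", "gA", "gB"],
                "heart_expressed": [True, True, False],
            }
        )
        return beta, ann

    def test_probe_mean_per_gene(self):
        beta, ann = self._fixture()
        out = aggregate_gene_beta(beta, ann)
        assert out.loc["gA", "s1"] == pytest.approx(0.3)
        assert out.loc["gB", "s2"] == pytest.approx(0.9)

    def test_heart_restriction_drops_unflagged_genes(self):
        beta, ann = self._fixture()
        out = aggregate_gene_beta(beta, ann, restrict_heart=True)
        assert list(out.index) == ["gA"]

    def test_single_probe_genes_pass_through(self):
        beta = pd.DataFrame({"s1": [0.2, 0.8]}, index=["p1", "p2"])
        ann = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["g1", "g2"]})
        out = aggregate_gene_beta(beta, ann)
        assert np.allclose(out.to_numpy().ravel(), [0.2, 0.8])

    def test_unannotated_probe_rejected(self):
        beta, ann = self._fixture()
        with pytest.raises(ValueError):
            aggregate_gene_beta(beta, ann.iloc[:2], restrict_heart=False)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "diff,eps,expected",
        [(0.10, 0.01, "hyper"), (-0.10, 0.01, "hypo"), (0.005, 0.01, "unchanged")],
    )
    def test_dead_band(self, diff, eps, expected):
        assert classify_direction(diff, eps) == expected

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            classify_direction(0.1, -0.1)


class TestSelectCandidates:
    def test_top_per_direction(self, screen_table):
        rules = SelectionRules(top_n_per_direction=2)
        out = select_candidates(screen_table, rules)
        # two largest |median_diff| in each direction
        assert set(out["gene_id"]) == {"g0", "g2", "g1", "g3"}

    def test_p_threshold_filter(self, screen_table):
        rules = SelectionRules(p_max=0.05)
        out = select_candidates(screen_table, rules)
        assert set(out["gene_id"]) == {"g0", "g1", "g2", "g3", "g4"}

    def test_union_of_p_and_effect_rules_ordered_by_p(self, screen_table):
        rules = SelectionRules(top_n_by_p=2, top_n_per_direction=1)
        out = select_candidates(screen_table, rules)
        assert list(out["gene_id"]) == ["g0", "g1"]
        assert list(out["candidate_rank"]) == [1, 2]

    def test_flag_filters(self, screen_table):
        flags = pd.DataFrame(
            {
                "has_cgi": [True] * 5 + [False] * 5,
                "heart_expressed": [True] * 10,
            },
            index=screen_table["gene_id"],
        )
        rules = SelectionRules(require_cgi=True)
        out = select_candidates(screen_table, rules, gene_flags=flags)
        assert set(out["gene_id"]) == {"g0", "g1", "g2", "g3", "g4"}

    def test_planted_genes_dominate_top20(self):
        design = CohortDesign(n_genes=500, n_planted=90, delta=0.2, seed=3)
        dataset, truth = gen_beta_matrix(design)
        gene_beta = aggregate_gene_beta(dataset.beta, dataset.annotation)
        res = wilcoxon_gene_screen(gene_beta, dataset.groups())
        out = select_candidates(res, SelectionRules(top_n_by_p=20))
        planted = set(truth.loc[truth["is_differential"], "gene_id"])
        assert len(set(out["gene_id"]) & planted) >= 15


class TestWilcoxonGeneScreen:
    def test_constant_gene_flagged_degenerate(self):
        mat = pd.DataFrame(
            [[0.5] * 5, [0.1, 0.2, 0.3, 0.8, 0.9]],
            index=["gConst", "gVar"],
            columns=["c1", "c2", "x1", "x2", "x3"],
        )
        groups = {"c1": "case", "c2": "case", "x1": "control", "x2": "control",
                  "x3": "control"}
        res = wilcoxon_gene_screen(mat, groups).set_index("gene_id")
        assert res.loc["gConst", "degenerate"]
        assert res.loc["gConst", "p_value"] == 1.0
        assert not res.loc["gVar", "degenerate"]

    def test_median_diff_and_direction(self):
        mat = pd.DataFrame(
            [[0.8, 0.9, 0.1, 0.2, 0.15]],
            index=["g1"],
            columns=["c1", "c2", "x1", "x2", "x3"],
        )
        groups = {"c1": "case", "c2": "case", "x1": "control", "x2": "control",
                  "x3": "control"}
        res = wilcoxon_gene_screen(mat, groups)
        assert res.loc[0, "median_diff"] == pytest.approx(0.85 - 0.15)
        assert res.loc[0, "direction"] == "hyper"
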