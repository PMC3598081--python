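import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiometh.finemap import (
    AmpliconPanel,
    anova_dunnett,
    calibration_check,
    direction_consistency,
    group_ttest,
    match_subsample,
    mean_cpg_methylation,
)
from cardiometh.synthetic import gen_amplicon_panel


def _panel():
    data = pd.DataFrame(
        {
            "candidate": ["LY75"] * 6 + ["ERBB3"] * 2,
            "cpg_unit": ["u1", "u2", "u3"] * 2 + ["v1", "v1"],
            "sample": ["s1"] * 3 + ["s2"] * 3 + ["s1", "s2"],
            "fraction": [0.2, 0.4, 0.6, 0.1, 0.3, np.nan, 0.9, 0.8],
        }
    )
    meta = pd.DataFrame(
        {"sample": ["s1", "s2"], "group": ["case", "control"]}
    )
    return AmpliconPanel(data, meta)


class TestMeanCpGMethylation:
    def test_mean_over_units(self):
        out = mean_cpg_methylation(_panel(), "LY75").set_index("sample")
        assert out.loc["s1", "mean_fraction"] == pytest.approx(0.4)
        assert out.loc["s1", "n_units"] == 3

    def test_missing_units_skipped_and_counted(self):
        out = mean_cpg_methylation(_panel(), "LY75").set_index("sample")
        assert out.loc["s2", "mean_fraction"] == pytest.approx(0.2)
        assert out.loc["s2", "n_units"] == 2

    def test_single_cpg_candidate(self):
        out = mean_cpg_methylation(_panel(), "ERBB3").set_index("sample")
        assert out.loc["s1", "mean_fraction"] == pytest.approx(0.9)

    def test_absent_candidate_rejected(self):
        with pytest.raises(ValueError):
            mean_cpg_methylation(_panel(), "HOXB13")

    def test_fraction_range_validated(self):
        data = pd.DataFrame(
            {"candidate": ["x"], "cpg_unit": ["u"], "sample": ["s"], "fraction": [1.2]}
        )
        meta = pd.DataFrame({"sample": ["s"], "group": ["case"]})
        with pytest.raises(ValueError):
            AmpliconPanel(data, meta)


class TestGroupTTest:
    def test_identical_groups_degenerate(self):
        res = group_ttest([0.5, 0.5], [0.5, 0.5])
        assert res.t == 0 and res.p == 1 and res.degenerate

    def test_pooled_variance_hand_value(self):
        res = group_ttest([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674, abs=5e-4)
        assert res.p == pytest.approx(2 * stats.t.sf(3.674, 4), abs=1e-3)
        assert res.mean_diff == pytest.approx(-3.0)

    def test_paired_identical_degenerate(self):
        res = group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.p == 1.0 and res.degenerate

    def test_paired_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        res = group_ttest(a, b, paired=True)
        ref = stats.ttest_rel(a, b)
        assert res.p == pytest.approx(ref.pvalue)

    def test_group_exchange_symmetry(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 7)
        assert group_ttest(a, b).p == pytest.approx(group_ttest(b, a).p)

    def test_size_validation(self):
        with pytest.raises(ValueError):
            group_ttest([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            group_ttest([1.0, 2.0], [2.0, 3.0, 4.0], paired=True)


class TestAnovaDunnett:
    def test_two_group_reduction_to_ttest(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        res = anova_dunnett([a, b], mc_draws=200_000, seed=1)
        t_p = stats.ttest_ind(b, a, equal_var=True).pvalue
        assert res.adjusted_p[0] == pytest.approx(t_p, abs=0.005)

    def test_identical_groups(self):
        g = [np.array([1.0, 2.0, 3.0])] * 3
        res = anova_dunnett(g, mc_draws=10_000, seed=0)
        assert res.f_statistic == 0.0
        assert (res.adjusted_p == 1.0).all()

    def test_matches_scipy_dunnett(self, rng):
        control = rng.normal(0, 1, 10)
        t1 = rng.normal(0.9, 1, 10)
        t2 = rng.normal(0.2, 1, 10)
        res = anova_dunnett([control, t1, t2], mc_draws=400_000, seed=2)
        ref = stats.dunnett(t1, t2, control=control)
        assert np.allclose(res.adjusted_p, ref.pvalue, atol=0.01)

    def test_never_anticonservative_vs_unadjusted(self, rng):
        control = rng.normal(0, 1, 6)
        groups = [control] + [rng.normal(d, 1, 6) for d in (0.3, 0.6, 1.0)]
        res = anova_dunnett(groups, mc_draws=100_000, seed=3)
        for g, adj in zip(groups[1:], res.adjusted_p):
            raw = stats.ttest_ind(g, control, equal_var=True).pvalue
            assert adj >= raw - 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_dunnett([np.array([1.0, 2.0])])


class TestCalibration:
    nominal = [0, 20, 40, 60, 80, 100]

    def test_perfect_standards(self):
        res = calibration_check(self.nominal, self.nominal)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.unbiased

    def test_half_slope_flagged_biased(self):
        res = calibration_check(self.nominal, [0.5 * x for x in self.nominal])
        assert res.slope == pytest.approx(0.5)
        assert not res.unbiased

    def test_matches_closed_form_least_squares(self, rng):
        y = np.array(self.nominal) + rng.normal(0, 2, 6)
        res = calibration_check(self.nominal, y)
        x = np.array(self.nominal, dtype=float)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            calibration_check([0, 100], [0, 100])


class TestDirectionConsistency:
    def _tables(self, n_match=12, n_total=20):
        genes = [f"g{i}" for i in range(n_total)]
        screen = pd.DataFrame({"gene_id": genes, "median_diff": [0.1] * n_total})
        rep_diff = [0.05] * n_match + [-0.05] * (n_total - n_match)
        rep = pd.DataFrame(
            {"gene_id": genes, "mean_diff": rep_diff, "p": [0.01] * n_total}
        )
        return screen, rep

    def test_all_signs_match(self):
        screen, rep = self._tables(n_match=20)
        out = direction_consistency(screen, rep)
        assert out["n_same_direction"] == 20

    def test_twelve_of_twenty_scenario(self):
        screen, rep = self._tables(n_match=12)
        out = direction_consistency(screen, rep)
        assert out["n_same_direction"] == 12
        assert out["n_significant"] == 12

    def test_zero_replication_diff_not_consistent(self):
        screen = pd.DataFrame({"gene_id": ["g"], "median_diff": [0.2]})
        rep = pd.DataFrame({"gene_id": ["g"], "mean_diff": [0.0], "p": [0.001]})
        assert direction_consistency(screen, rep)["n_same_direction"] == 0

    def test_missing_candidate_flagged_and_excluded(self):
        screen = pd.DataFrame({"gene_id": ["g1"], "median_diff": [0.2]})
        rep = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "mean_diff": [0.1, 0.1], "p": [0.01, 0.01]}
        )
        out = direction_consistency(screen, rep)
        assert out["n_candidates"] == 1
        assert out["table"].set_index("gene_id").loc["g2", "missing"]

    def test_significance_requires_alpha(self):
        screen, rep = self._tables(n_match=12)
        rep.loc[:3, "p"] = 0.2
        out = direction_consistency(screen, rep, alpha=0.05)
        assert out["n_same_direction"] == 12
        assert out["n_significant"] == 8

    def test_zero_noise_panel_recovers_planted_fraction(self):
        cands = [f"c{i}" for i in range(20)]
        panel, truth = gen_amplicon_panel(
            cands, consistent_fraction=12 / 20, precision=None, seed=4
        )
        groups = panel.groups()
        rows = []
        for c in cands:
            m = mean_cpg_methylation(panel, c).set_index("sample")["mean_fraction"]
            case = m[[s for s in m.index if groups[s] == "case"]]
            ctrl = m[[s for s in m.index if groups[s] == "control"]]
            rows.append({"gene_id": c, "mean_diff": case.mean() - ctrl.mean(),
                         "p": group_ttest(case, ctrl).p})
        screen = pd.DataFrame({"gene_id": cands, "median_diff": [
            0.1 if d == "hyper" else -0.1
            for d in truth.set_index("gene_id").loc[cands, "direction"]
        ]})
        out = direction_consistency(screen, pd.DataFrame(rows))
        assert out["n_same_direction"] == 12


class TestMatchSubsample:
    def _meta(self, case_f=10, case_m=6, ctrl_f=8, ctrl_m=8):
        rows = []
        for grp, nf, nm in (("case", case_f, case_m), ("control", ctrl_f, ctrl_m)):
            rows += [{"sample": f"{grp}F{i}", "group": grp, "sex": "F"} for i in range(nf)]
            rows += [{"sample": f"{grp}M{i}", "group": grp, "sex": "M"} for i in range(nm)]
        return pd.DataFrame(rows)

    def test_one_to_one_balances_sexes(self):
        out = match_subsample(self._meta(), mode="one_to_one", seed=0)
        counts = out.groupby(["group", "sex"]).size()
        assert counts["case", "F"] == counts["case", "M"] == 6
        assert counts["control", "F"] == counts["control", "M"] == 8

    def test_satisfied_ratio_keeps_everything(self):
        meta = self._meta(case_f=8, case_m=8, ctrl_f=8, ctrl_m=8)
        out = match_subsample(
            meta, mode="ratio", target_female_fraction={"case": 0.5, "control": 0.5}
        )
        assert len(out) == len(meta)

    def test_seeded_draw_reproducible(self):
        meta = self._meta()
        a = match_subsample(meta, mode="one_to_one", seed=42)
        b = match_subsample(meta, mode="one_to_one", seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_ratio_reports_counts(self):
        meta = self._meta(case_f=0, case_m=5, ctrl_f=5, ctrl_m=5)
        with pytest.raises(ValueError, match="0F / 5M"):
            match_subsample(
                meta, mode="ratio", target_female_fraction={"case": 0.5, "control": 0.5}
            )
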