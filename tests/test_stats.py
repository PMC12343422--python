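"""Statistical primitives and the cohort analysis model."""

import numpy as np
import pandas as pd
import pytest

from hepavol.stats import (
    CohortVVRAnalysis,
    bonferroni,
    classify_stage,
    kruskal_wallis,
    mann_whitney_u,
    median_iqr,
    pairwise_mwu_bonferroni,
    percent_decrease,
    spearman_map,
)


class TestClassifyStage:
    def test_high_fib4_is_acld(self):
        ga = classify_stage(3.5, decompensated=False)
        assert ga.group == "ACLD" and ga.acld_stage == "compensated"
        assert ga.fib4_category == "high"

    def test_low_fib4_is_non_acld(self):
        ga = classify_stage(0.8, decompensated=False)
        assert ga.group == "non-ACLD" and ga.fib4_category == "low"

    def test_decompensation_overrides_fib4(self):
        ga = classify_stage(1.0, decompensated=True)
        assert ga.group == "ACLD" and ga.acld_stage == "decompensated"

    def test_cutoff_is_closed_on_acld(self):
        assert classify_stage(1.75, False).group == "ACLD"
        assert classify_stage(1.7499, False).group == "non-ACLD"

    def test_fib4_category_boundaries(self):
        assert classify_stage(1.3, False).fib4_category == "intermediate"
        assert classify_stage(2.67, False).fib4_category == "intermediate"
        assert classify_stage(2.671, False).fib4_category == "high"

    def test_missing_fib4_unclassifiable(self):
        with pytest.raises(ValueError):
            classify_stage(None, decompensated=False)

    def test_control_bypass(self):
        assert classify_stage(None, False, is_cld=False).group == "control"


class TestMedianIqr:
    def test_odd_sample(self):
        med, q1, q3 = median_iqr([1, 2, 3, 4, 5])
        assert med == 3.0

    def test_constant_vector_zero_width(self):
        med, q1, q3 = median_iqr([4.2] * 7)
        assert q3 - q1 == 0.0 and med == 4.2

    def test_linear_interpolation_rule(self):
        # type-7 on 1..8: q1 = 1 + 0.25*7 = 2.75, q3 = 1 + 0.75*7 = 6.25
        med, q1, q3 = median_iqr(range(1, 9))
        assert (med, q1, q3) == (4.5, 2.75, 6.25)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestKruskalWallis:
    def test_hand_computed_h(self):
        # three tie-free groups occupying rank blocks: H = 7.2
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2)

    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([5, 5], [5, 5], [5, 5])
        assert h == 0.0 and p == 1.0

    def test_two_group_consistency_with_mwu(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 40), rng.normal(0.8, 1, 40)
        _, p_kw = kruskal_wallis(x, y)
        p_mwu = mann_whitney_u(x, y)
        assert p_kw == pytest.approx(p_mwu, abs=0.01)


class TestMannWhitneyBonferroni:
    def test_exact_matches_asymptotic_on_small_samples(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 7)
        y = rng.normal(1.0, 1, 8)
        p_exact = mann_whitney_u(x, y)  # auto exact (both n <= 8, no ties)
        p_asym = mann_whitney_u(np.concatenate([x, [99.0]]), y)  # force asymptotic
        assert 0 < p_exact < 1 and 0 < p_asym < 1

    def test_bonferroni_clamp_and_arithmetic(self):
        assert bonferroni(0.4, 3) == 1.0
        assert bonferroni(0.002, 3) == pytest.approx(0.006)
        assert bonferroni(0.0, 3) == 0.0

    def test_bonferroni_monotone_in_raw_p(self):
        grid = np.linspace(0, 1, 101)
        corrected = [bonferroni(p, 3) for p in grid]
        assert all(b >= a for a, b in zip(corrected, corrected[1:]))
        assert all(0 <= c <= 1 for c in corrected)

    def test_pairwise_table_with_degenerate_group(self):
        groups = {"a": np.arange(10.0), "b": np.arange(10.0) + 5, "c": np.array([])}
        out = pairwise_mwu_bonferroni(groups, (("a", "b"), ("a", "c"), ("b", "c")))
        assert np.isfinite(out[("a", "b")])
        assert np.isnan(out[("a", "c")]) and np.isnan(out[("b", "c")])

    def test_type_i_error_controlled_under_null(self):
        """Corrected rejections at 0.05 on identical distributions stay
        near or below nominal (Bonferroni is conservative)."""
        rng = np.random.default_rng(42)
        n_reject = 0
        n_rep = 400
        for _ in range(n_rep):
            g = {k: rng.normal(size=50) for k in ("a", "b", "c")}
            ps = pairwise_mwu_bonferroni(g, (("a", "b"), ("a", "c"), ("b", "c")))
            n_reject += any(p < 0.05 for p in ps.values())
        rate = n_reject / n_rep
        mc_margin = 2 * np.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= 0.05 + mc_margin


class TestPercentDecrease:
    @pytest.mark.parametrize(
        "ref,new,expected",
        [(3.9, 2.8, 28.2), (2.1, 1.0, 52.4), (1.2, 1.2, 0.0), (2.8, 2.3, 17.9)],
    )
    def test_reference_values(self, ref, new, expected):
        assert percent_decrease(ref, new) == expected

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            percent_decrease(0.0, 1.0)


class TestSpearmanMap:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.linspace(0.1, 3, 30)
        vvr = pd.DataFrame({"tvvr_pct": x, "hvvr_pct": x, "pvvr_pct": x})
        bio = pd.DataFrame({"albumin": np.exp(x)})
        out = spearman_map(vvr, bio, biomarkers=("albumin",))
        assert out.rho.tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_hand_computed_rho(self):
        vvr = pd.DataFrame({"tvvr_pct": [1, 2, 3], "hvvr_pct": [1, 2, 3], "pvvr_pct": [1, 2, 3]})
        bio = pd.DataFrame({"fib4": [2, 1, 3]})
        out = spearman_map(vvr, bio, vvr_columns=("tvvr_pct",), biomarkers=("fib4",))
        assert out.rho.iloc[0] == pytest.approx(0.5)  # 1 - 6*2/(3*8)

    def test_antitone_pair(self):
        vvr = pd.DataFrame({"tvvr_pct": [1, 2, 3, 4], "hvvr_pct": [1, 2, 3, 4], "pvvr_pct": [1, 2, 3, 4]})
        bio = pd.DataFrame({"albi": [9.0, 5.0, 3.0, 1.0]})
        out = spearman_map(vvr, bio, vvr_columns=("hvvr_pct",), biomarkers=("albi",))
        assert out.rho.iloc[0] == pytest.approx(-1.0)

    def test_pairwise_complete_n(self):
        vvr = pd.DataFrame({"tvvr_pct": np.arange(10.0), "hvvr_pct": np.arange(10.0),
                            "pvvr_pct": np.arange(10.0)})
        bio = pd.DataFrame({"hvpg_mmhg": [np.nan] * 6 + [3.0, 2.0, 5.0, 6.0]})
        out = spearman_map(vvr, bio, vvr_columns=("hvvr_pct",), biomarkers=("hvpg_mmhg",))
        assert out.n.iloc[0] == 4

    def test_insufficient_pairs_undefined(self):
        vvr = pd.DataFrame({"tvvr_pct": [1.0, 2.0], "hvvr_pct": [1.0, 2.0], "pvvr_pct": [1.0, 2.0]})
        bio = pd.DataFrame({"lsm_kpa": [1.0, np.nan]})
        out = spearman_map(vvr, bio, vvr_columns=("hvvr_pct",), biomarkers=("lsm_kpa",))
        assert np.isnan(out.rho.iloc[0])


class TestCohortAnalysisModel:
    @staticmethod
    def toy_cohort(n=120, seed=0):
        rng = np.random.default_rng(seed)
        groups = ["control"] * (n // 3) + ["non-ACLD"] * (n // 3) + ["ACLD"] * (n // 3)
        shift = {"control": 2.1, "non-ACLD": 1.7, "ACLD": 1.0}
        hvvr = np.array([rng.lognormal(np.log(shift[g]), 0.25) for g in groups])
        pvvr = np.array([rng.lognormal(np.log(1.4), 0.2) for _ in groups])
        cohort = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(groups))],
                "group": groups,
                "fib4": np.where(np.array(groups) == "ACLD", 3.5, 0.9),
                "decompensated": [g == "ACLD" and i % 2 == 0 for i, g in enumerate(groups)],
                "albumin": rng.normal(40, 3, len(groups)),
            }
        )
        vvr = pd.DataFrame(
            {
                "subject_id": cohort.subject_id,
                "hvvr_pct": hvvr,
                "pvvr_pct": pvvr,
                "tvvr_pct": hvvr + pvvr,
            }
        )
        return cohort, vvr

    def test_detects_hvvr_gradient(self):
        cohort, vvr = self.toy_cohort()
        results = CohortVVRAnalysis(cohort, vvr).fit()
        comp = results.comparison("hvvr_pct")
        assert comp.kw_p < 0.001
        assert comp.pairwise_p[("control", "ACLD")] < 0.01
        assert comp.percent_decreases[("control", "ACLD")] > 30

    def test_subgroup_partitions_are_exhaustive(self):
        cohort, vvr = self.toy_cohort()
        results = CohortVVRAnalysis(cohort, vvr).fit()
        stage_comp = results.subgroup_comparisons["clinical_stage"][0]
        n_cld = (cohort.group != "control").sum()
        assert sum(stage_comp.group_sizes.values()) == n_cld

    def test_empty_subgroup_is_undefined_not_fatal(self):
        cohort, vvr = self.toy_cohort(n=30)
        cohort.loc[cohort.group == "ACLD", "decompensated"] = False  # no dACLD
        results = CohortVVRAnalysis(cohort, vvr).fit()
        comp = results.subgroup_comparisons["clinical_stage"][0]
        assert np.isnan(comp.pairwise_p[("cACLD", "dACLD")])

    def test_summary_contains_all_vvrs(self):
        cohort, vvr = self.toy_cohort(n=30)
        text = CohortVVRAnalysis(cohort, vvr).fit().summary()
        for name in ("tvvr_pct", "hvvr_pct", "pvvr_pct"):
            assert name in text
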