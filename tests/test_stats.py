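"""Group statistics: behavioral aggregation, effect sizes, the mixed-ANOVA
sums-of-squares oracle, t-tests, power, and exclusion rules."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ctpcit.stats import (
    ExclusionThresholds, PowerSpec, apply_exclusions, behavioral_summary,
    cohen_d_within, diff_scores, independent_ttest, mixed_anova, paired_ttest,
    power_mixed_interaction, simulate_power_mixed,
)


class TestBehavioralSummary:
    def test_fast_response_excluded_from_valid(self):
        beh = pd.DataFrame({
            "category": ["animal"] * 3, "role": ["probe"] * 3,
            "rt_ms": [149.0, 151.0, 300.0], "correct": [True, True, True],
        })
        out = behavioral_summary(beh).table
        assert out.n_valid.iloc[0] == 2

    def test_all_correct_accuracy_one(self):
        beh = pd.DataFrame({
            "category": ["animal"] * 4, "role": ["probe"] * 4,
            "rt_ms": [300.0] * 4, "correct": [True] * 4,
        })
        assert behavioral_summary(beh).table.accuracy.iloc[0] == 1.0

    def test_hand_computed_toy_table(self):
        # RTs 100 (valid? no), 300, 400 correct; 500, 600 incorrect
        beh = pd.DataFrame({
            "category": ["animal"] * 5, "role": ["probe"] * 5,
            "rt_ms": [100.0, 300.0, 400.0, 500.0, 600.0],
            "correct": [True, True, True, False, False],
        })
        row = behavioral_summary(beh).table.iloc[0]
        assert row.n_valid == 4
        assert row.accuracy == 0.5
        assert row.rt_mean_ms == pytest.approx(350.0)  # mean of {300, 400}

    def test_empty_cell_flagged_not_dropped(self):
        beh = pd.DataFrame({
            "category": ["animal", "animal"], "role": ["probe", "irrelevant"],
            "rt_ms": [100.0, 300.0], "correct": [True, True],
        })
        out = behavioral_summary(beh)
        assert ("animal", "probe") in out.empty_cells
        assert len(out.table) == 2

    def test_diff_scores_sign(self):
        tab = pd.DataFrame({
            "subject": [1, 1, 2, 2], "category": ["a"] * 4,
            "role": ["probe", "irrelevant"] * 2,
            "rt_mean_ms": [420.0, 400.0, 430.0, 425.0],
        })
        out = diff_scores(tab, "rt_mean_ms", by=("subject", "category"))
        assert out.rt_mean_ms_diff.tolist() == [20.0, 5.0]


class TestCohenD:
    def test_symmetric_diffs_give_zero(self):
        assert cohen_d_within([-2.0, -1.0, 1.0, 2.0]) == 0.0

    def test_one_two_three_gives_two(self):
        assert cohen_d_within([1.0, 2.0, 3.0]) == pytest.approx(2.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            cohen_d_within([1.0, 1.0, 1.0])

    def test_recovers_known_ratio_in_simulation(self):
        rng = np.random.default_rng(0)
        diffs = rng.normal(3.0, 2.0, 200)  # true d = 1.5
        assert cohen_d_within(diffs) == pytest.approx(1.5, abs=0.2)

    def test_dav_variant(self):
        d = cohen_d_within([1.0, 3.0], kind="dav", sd_pair=(2.0, 2.0))
        assert d == pytest.approx(1.0)


def _ss_oracle(wide: np.ndarray, groups: np.ndarray):
    """Independent textbook sums-of-squares for a balanced two-group
    split-plot design; wide is subjects x within-levels."""
    g_levels = np.unique(groups)
    n_per = [np.sum(groups == g) for g in g_levels]
    assert len(set(n_per)) == 1, "oracle assumes balanced groups"
    n = n_per[0]
    g, m = len(g_levels), wide.shape[1]
    GM = wide.mean()
    ss_total = ((wide - GM) ** 2).sum()
    subj_means = wide.mean(axis=1)
    grp_means = np.array([wide[groups == gl].mean() for gl in g_levels])
    w_means = wide.mean(axis=0)
    cell = np.array([wide[groups == gl].mean(axis=0) for gl in g_levels])
    ss_between = m * n * ((grp_means - GM) ** 2).sum()
    ss_subj = m * sum(
        ((subj_means[groups == gl] - grp_means[i]) ** 2).sum()
        for i, gl in enumerate(g_levels))
    ss_within = g * n * ((w_means - GM) ** 2).sum()
    ss_inter = n * ((cell - grp_means[:, None] - w_means[None, :] + GM) ** 2).sum()
    ss_err = ss_total - ss_between - ss_subj - ss_within - ss_inter
    df_subj = g * (n - 1)
    df_err = g * (n - 1) * (m - 1)
    out = {}
    out["between"] = ((g - 1), df_subj,
                      (ss_between / (g - 1)) / (ss_subj / df_subj),
                      ss_between / (ss_between + ss_subj))
    out["within"] = ((m - 1), df_err,
                     (ss_within / (m - 1)) / (ss_err / df_err),
                     ss_within / (ss_within + ss_err))
    out["interaction"] = ((g - 1) * (m - 1), df_err,
                          (ss_inter / ((g - 1) * (m - 1))) / (ss_err / df_err),
                          ss_inter / (ss_inter + ss_err))
    return out


def _long(wide, groups, within_labels):
    rows = []
    for s in range(wide.shape[0]):
        for w, lab in enumerate(within_labels):
            rows.append({"subject": s, "group": groups[s], "cond": lab,
                         "y": wide[s, w]})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_toy_dataset_matches_ss_oracle(self):
        """8 subjects, 2 groups x 2 within, integer data: F, df, partial
        eta-squared all equal the textbook decomposition."""
        wide = np.array([[3, 5], [4, 7], [2, 6], [5, 9],
                         [6, 4], [7, 6], [5, 3], [8, 7]], dtype=float)
        groups = np.array(["std"] * 4 + ["ind"] * 4)
        oracle = _ss_oracle(wide, groups)
        aov = mixed_anova(_long(wide, groups, ["probe", "irrelevant"]),
                          "y", "cond", "subject", "group").set_index("effect")
        for eff in ("between", "within", "interaction"):
            df1, df2, F, np2 = oracle[eff]
            row = aov.loc[eff]
            assert row.F == pytest.approx(F, rel=1e-9), eff
            assert row.df1 == df1 and row.df2 == df2
            assert row.np2 == pytest.approx(np2, rel=1e-9)

    def test_three_level_within_matches_oracle_uncorrected(self):
        rng = np.random.default_rng(3)
        wide = rng.integers(0, 10, (10, 3)).astype(float)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        oracle = _ss_oracle(wide, groups)
        aov = mixed_anova(_long(wide, groups, ["x", "y", "z"]),
                          "y", "cond", "subject", "group").set_index("effect")
        for eff in ("between", "within", "interaction"):
            assert aov.loc[eff].F == pytest.approx(oracle[eff][2], rel=1e-9)

    def test_identical_groups_between_f_near_zero(self):
        wide = np.array([[3, 5], [4, 7], [2, 6], [5, 9]] * 2, dtype=float)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        aov = mixed_anova(_long(wide, groups, ["p", "i"]),
                          "y", "cond", "subject", "group").set_index("effect")
        assert aov.loc["between"].F == pytest.approx(0.0, abs=1e-12)
        assert aov.loc["interaction"].F == pytest.approx(0.0, abs=1e-12)

    def test_two_level_within_eps_exactly_one(self):
        rng = np.random.default_rng(4)
        wide = rng.normal(0, 1, (8, 2))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        aov = mixed_anova(_long(wide, groups, ["p", "i"]),
                          "y", "cond", "subject", "group")
        assert (aov.eps == 1.0).all()
        assert np.allclose(aov.p_gg[aov.effect != "between"],
                           aov.p_unc[aov.effect != "between"])

    def test_gg_correction_applied_to_within_terms(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, (12, 1))
        # correlated 3-level within data with unequal variances -> eps < 1
        wide = np.hstack([base + rng.normal(0, s, (12, 1)) for s in (0.2, 1, 3)])
        groups = np.array(["a"] * 6 + ["b"] * 6)
        aov = mixed_anova(_long(wide, groups, ["x", "y", "z"]),
                          "y", "cond", "subject", "group").set_index("effect")
        eps = aov.loc["within"].eps
        assert 0.5 <= eps < 1.0
        assert aov.loc["within"].p_gg >= aov.loc["within"].p_unc - 1e-12
        assert aov.loc["interaction"].eps == eps

    def test_collapsed_within_reproduces_oneway_anova(self):
        rng = np.random.default_rng(6)
        wide = rng.normal(0, 1, (10, 2))
        wide[5:] += 1.0
        groups = np.array(["a"] * 5 + ["b"] * 5)
        aov = mixed_anova(_long(wide, groups, ["p", "i"]),
                          "y", "cond", "subject", "group").set_index("effect")
        f_one = scipy.stats.f_oneway(wide[:5].mean(axis=1),
                                     wide[5:].mean(axis=1))
        assert aov.loc["between"].F == pytest.approx(f_one.statistic, rel=1e-9)

    def test_missing_cell_rejected(self):
        df = _long(np.zeros((4, 2)), np.array(["a", "a", "b", "b"]), ["p", "i"])
        with pytest.raises(ValueError):
            mixed_anova(df.iloc[:-1], "y", "cond", "subject", "group")


class TestTTests:
    def test_identical_paired_samples_t_zero(self):
        t, df, p = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and df == 2 and p == 1.0

    def test_paired_toy_arithmetic(self):
        # pairs (1,0),(2,1),(3,1): diffs {1,1,2} -> t = 4, df = 2
        t, df, p = paired_ttest([1.0, 2.0, 3.0], [0.0, 1.0, 1.0])
        assert t == pytest.approx(4.0)
        assert df == 2

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_independent_pooled_df(self):
        t, df, p = independent_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0])
        assert df == 5

    def test_planted_rating_ordering_recovered_at_n35(self):
        """Importance ratings with the expected ordering (forename > birthday
        > animal) come out significant in paired t-tests at n = 35."""
        rng = np.random.default_rng(35)
        n = 35
        forename = np.clip(rng.normal(5.57, 1.0, n), 1, 6)
        birthday = np.clip(rng.normal(4.34, 1.0, n), 1, 6)
        animal = np.clip(rng.normal(3.34, 1.21, n), 1, 6)
        for hi, lo in [(forename, birthday), (birthday, animal),
                       (forename, animal)]:
            t, df, p = paired_ttest(hi, lo)
            assert df == 34
            assert t > 0 and p < 0.05


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert power_mixed_interaction(f=0.0) == pytest.approx(0.05, abs=1e-9)

    def test_reference_design_gives_point_eight_two(self):
        p = power_mixed_interaction(PowerSpec())
        assert round(p, 2) == 0.82

    def test_monotone_in_f_n_and_rho(self):
        base = power_mixed_interaction(PowerSpec())
        assert power_mixed_interaction(f=0.35) > base
        assert power_mixed_interaction(n_total=50) > base
        assert power_mixed_interaction(rho=0.7) > base

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(alpha=1.5)
        with pytest.raises(ValueError):
            PowerSpec(n_total=2)

    def test_monte_carlo_agrees_quickly(self):
        # small-rep sanity version of the full cross-check
        mc = simulate_power_mixed(PowerSpec(), n_reps=800, seed=0)
        assert mc == pytest.approx(power_mixed_interaction(PowerSpec()), abs=0.05)


class TestExclusions:
    @pytest.fixture
    def qc(self):
        return pd.DataFrame({
            "subject": [1, 2, 3, 4],
            "probe_accuracy": [0.49, 0.95, 0.97, 0.98],
            "target_accuracy": [0.90, 0.85, 0.56, 0.88],
            "recall_failures": [0, 0, 1, 7],
        })

    def test_quoted_cases_excluded(self, qc):
        out = apply_exclusions(qc).set_index("subject")
        assert not out.loc[1, "kept"]            # 49% probe accuracy
        assert not out.loc[3, "kept"]            # 56% target accuracy
        assert not out.loc[4, "kept"]            # 7 of 9 recall failures
        assert "recall" in out.loc[4, "reasons"]

    def test_perfect_subject_retained(self, qc):
        out = apply_exclusions(qc).set_index("subject")
        assert out.loc[2, "kept"] and out.loc[2, "reasons"] == ""

    def test_thresholds_configurable(self, qc):
        th = ExclusionThresholds(min_probe_accuracy=0.99)
        out = apply_exclusions(qc, th)
        assert not out.kept.iloc[1]
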