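import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from plinet.stats import (StatResult, build_tables, fdr_correct, paired_t,
                          rm_anova_interaction)


def cohort_frame(rng, n_pat=8, n_con=6, pat_shift=0.0, con_shift=0.0,
                 band="alpha", measure="leaf_number"):
    rows = []
    for group, n, shift in (("patient", n_pat, pat_shift),
                            ("control", n_con, con_shift)):
        for i in range(n):
            base = rng.normal(10, 2)
            rows.append(dict(subject_id=f"{group[0]}{i}", group=group,
                             condition="routine", band=band,
                             measure=measure, value=base,
                             added_value=(group == "patient" and i % 2 == 0)))
            rows.append(dict(subject_id=f"{group[0]}{i}", group=group,
                             condition="sd", band=band, measure=measure,
                             value=base + shift + rng.normal(0, 1),
                             added_value=(group == "patient" and i % 2 == 0)))
    return pd.DataFrame(rows)


class TestPairedT:
    def test_identical_samples_give_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, x)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_nonzero_shift_is_degenerate(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t(np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 4, 5]))

    def test_matches_hand_formula_and_scipy(self, rng):
        pre = rng.normal(size=25)
        post = pre + rng.normal(0.3, 1.0, size=25)
        res = paired_t(pre, post)
        d = post - pre
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(25))
        assert res.statistic == pytest.approx(t_hand)
        t_sp, p_sp = sps.ttest_rel(post, pre)
        assert res.statistic == pytest.approx(t_sp)
        assert res.p == pytest.approx(p_sp)
        assert res.df == (24,)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 pairs"):
            paired_t(np.array([1.0, 2]), np.array([2.0, 1]))


class TestRmAnovaInteraction:
    def test_parallel_shift_gives_near_zero_f(self, rng):
        df = cohort_frame(rng, pat_shift=3.0, con_shift=3.0)
        res = rm_anova_interaction(df)
        # both groups move identically; only subject noise remains
        assert res.p > 0.05

    def test_equals_squared_difference_score_t(self, rng):
        df = cohort_frame(rng, pat_shift=-2.0, con_shift=1.0)
        res = rm_anova_interaction(df)
        pivot = df.pivot_table(index=["subject_id", "group"],
                               columns="condition", values="value")
        diff = pivot["sd"] - pivot["routine"]
        g = diff.index.get_level_values("group")
        t, p = sps.ttest_ind(diff[g == "control"], diff[g == "patient"])
        assert res.statistic == pytest.approx(t**2)
        assert res.p == pytest.approx(p)
        assert res.df == (1, 12)

    def test_matches_pingouin_mixed_anova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = cohort_frame(rng, pat_shift=-2.0, con_shift=1.0)
        res = rm_anova_interaction(df)
        aov = pingouin.mixed_anova(data=df, dv="value", within="condition",
                                   subject="subject_id", between="group")
        inter = aov[aov["Source"] == "Interaction"].iloc[0]
        assert res.statistic == pytest.approx(inter["F"])
        assert res.p == pytest.approx(inter["p_unc"])

    def test_missing_condition_is_hard_error(self, rng):
        df = cohort_frame(rng)
        df = df.drop(df[(df.subject_id == "p0")
                        & (df.condition == "sd")].index)
        with pytest.raises(ValueError, match="p0"):
            rm_anova_interaction(df)

    def test_permuted_labels_reject_at_nominal_rate(self, rng):
        df = cohort_frame(rng, n_pat=10, n_con=10)
        pivot = df.pivot_table(index=["subject_id", "group"],
                               columns="condition", values="value")
        diff = (pivot["sd"] - pivot["routine"]).to_numpy()
        n = diff.size
        rejections = 0
        n_perm = 1000
        crit = sps.f.isf(0.05, 1, n - 2)
        for _ in range(n_perm):
            labels = rng.permutation(np.arange(n) < 10)
            a, b = diff[labels], diff[~labels]
            t, _ = sps.ttest_ind(a, b)
            rejections += (t**2) > crit
        assert 0.02 < rejections / n_perm < 0.09


class TestFdrCorrect:
    @staticmethod
    def results(pvals, band="alpha"):
        return [StatResult(test="t", statistic=1.0, df=(5,), p=p, band=band)
                for p in pvals]

    def test_bh_step_up_by_hand(self):
        res = fdr_correct(self.results([0.001, 0.8, 0.9, 0.95]))
        assert [r.fdr_significant for r in res] == [True, False, False,
                                                    False]

    def test_all_p_one_none_flagged(self):
        res = fdr_correct(self.results([1.0, 1.0, 1.0]))
        assert not any(r.fdr_significant for r in res)

    def test_uniform_borderline_family_all_flagged(self):
        res = fdr_correct(self.results([0.01] * 4))
        assert all(r.fdr_significant for r in res)

    def test_families_are_per_band(self):
        res = (self.results([0.012, 0.9], band="alpha")
               + self.results([0.012, 0.013, 0.9], band="beta"))
        fdr_correct(res)
        alpha_flags = [r.fdr_significant for r in res if r.band == "alpha"]
        beta_flags = [r.fdr_significant for r in res if r.band == "beta"]
        # 0.012 passes alone in a family of 2 (0.012 <= 0.05 * 1/2) but the
        # beta family of 3 requires 0.05 * 1/3 at the first rank
        assert alpha_flags == [True, False]
        assert beta_flags[2] is False

    def test_empty_input_noop(self):
        assert fdr_correct([]) == []

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12))
    def test_flags_monotone_in_p(self, pvals):
        res = fdr_correct(self.results(pvals))
        flagged = sorted(r.p for r in res if r.fdr_significant)
        unflagged = [r.p for r in res if not r.fdr_significant]
        if flagged and unflagged:
            assert max(flagged) <= min(unflagged)


class TestBuildTables:
    def measures(self, rng, pat_shift=-3.0, con_shift=3.0):
        frames = []
        for band in ("delta", "theta", "alpha", "beta"):
            for measure in ("path_length", "clustering", "diameter",
                            "leaf_number"):
                shift_here = (pat_shift, con_shift) if band == "alpha" and \
                    measure == "leaf_number" else (0.0, 0.0)
                frames.append(cohort_frame(rng, band=band, measure=measure,
                                           pat_shift=shift_here[0],
                                           con_shift=shift_here[1]))
        for pband in ("delta", "theta", "alpha1", "alpha2", "beta"):
            f = cohort_frame(rng, band="broadband",
                             measure=f"power_{pband}")
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def test_schema_and_effect_recovery(self, rng):
        tables = build_tables(self.measures(rng))
        paired = tables["paired_patients"]
        assert list(paired.index) == ["path_length", "clustering",
                                      "diameter", "leaf_number"]
        assert {"alpha_t", "alpha_p", "beta_t", "beta_p"} <= set(
            paired.columns)
        inter = tables["interaction"]
        assert set(inter["cohort"]) == {"all", "added_value"}
        hit = inter[(inter.cohort == "all") & (inter.band == "alpha")
                    & (inter.measure == "leaf_number")].iloc[0]
        assert hit["p"] < 0.01 and hit["fdr_significant"]
        power = tables["power_paired"]
        assert len(power) == 10  # 5 bands x 2 groups

    def test_null_cohort_mostly_unflagged(self, rng):
        tables = build_tables(self.measures(rng, 0.0, 0.0))
        inter = tables["interaction"]
        assert inter["fdr_significant"].mean() < 0.2

    def test_empty_added_value_subset_warns(self, rng):
        m = self.measures(rng)
        m["added_value"] = False
        with pytest.warns(UserWarning, match="added-value"):
            tables = build_tables(m)
        assert set(tables["interaction"]["cohort"]) == {"all"}
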