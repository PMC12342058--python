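"""Statistical toolkit: ANOVA, Holm–Šídák, Mann–Whitney, power, gates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

import somnostress as ss
from _glm_oracle import glm_projection_ss


def balanced_design(n_per_cell=4, between=("sex", "phenotype"), times=3, seed=0,
                    effects=None):
    rng = np.random.default_rng(seed)
    levels = {"sex": ["F", "M"], "phenotype": ["res", "sus"]}
    rows, sid = [], 0
    combos = [()]
    for b in between:
        combos = [c + (lv,) for c in combos for lv in levels[b]]
    for combo in combos:
        for _ in range(n_per_cell):
            base = rng.normal(0, 1)
            for t in range(times):
                val = base + 0.4 * t + rng.normal(0, 0.5)
                if effects:
                    val += effects(dict(zip(between, combo)), t)
                rows.append({"subject_id": f"s{sid}", "time_bin": f"t{t}",
                             "value": val, **dict(zip(between, combo))})
            sid += 1
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_all_equal_values_give_zero_F(self):
        df = balanced_design(3)
        df["value"] = 5.0
        res = ss.mixed_anova(df, between=("sex", "phenotype"))
        tested = res[res["F"].notna()]
        assert np.allclose(tested["F"], 0.0)
        assert np.allclose(tested["p"], 1.0)

    @pytest.mark.parametrize("between", [(), ("sex",), ("sex", "phenotype")])
    def test_ss_matches_glm_projection_on_balanced_toys(self, between):
        df = balanced_design(4, between=between or ("sex",), seed=3)
        if not between:
            df = df[df["sex"] == "F"]
        res = ss.mixed_anova(df, between=between)
        oracle = glm_projection_ss(df, between=between)
        for name, expected in oracle.items():
            got = res.loc[res["effect"] == name, "SS"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-8), name

    def test_permuting_subjects_within_groups_preserves_F(self):
        df = balanced_design(4, seed=5)
        res1 = ss.mixed_anova(df, between=("sex", "phenotype"))
        relabel = {}
        for (sex, ph), grp in df.groupby(["sex", "phenotype"]):
            sids = grp["subject_id"].unique()
            perm = np.random.default_rng(1).permutation(sids)
            relabel.update(dict(zip(sids, perm)))
        df2 = df.assign(subject_id=df["subject_id"].map(relabel))
        res2 = ss.mixed_anova(df2, between=("sex", "phenotype"))
        assert np.allclose(res1["F"].dropna(), res2["F"].dropna())

    def test_matches_pingouin_one_between_factor(self):
        pg = pytest.importorskip("pingouin")
        df = balanced_design(5, between=("sex",), seed=7)
        mine = ss.mixed_anova(df, between=("sex",))
        ref = pg.mixed_anova(df, dv="value", within="time_bin",
                             subject="subject_id", between="sex", correction=False)
        ref_map = {"sex": "sex", "time_bin": "time_bin",
                   "Interaction": "sex * time_bin"}
        for _, row in ref.iterrows():
            mrow = mine[mine["effect"] == ref_map[row["Source"]]].iloc[0]
            assert mrow["F"] == pytest.approx(row["F"], rel=1e-9)

    def test_ss_components_sum_to_total_when_balanced(self):
        df = balanced_design(4, seed=11)
        res = ss.mixed_anova(df, between=("sex", "phenotype"))
        y = df["value"].to_numpy()
        total = float(np.sum((y - y.mean()) ** 2))
        assert res["SS"].sum() == pytest.approx(total, rel=1e-9)

    def test_incomplete_series_rejected(self):
        df = balanced_design(3).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            ss.mixed_anova(df, between=("sex", "phenotype"))

    def test_singleton_cells_rejected(self):
        df = balanced_design(1)
        with pytest.raises(ValueError, match="at least 2 subjects"):
            ss.mixed_anova(df, between=("sex", "phenotype"))


class TestHolmSidak:
    def test_single_pvalue_threshold_is_alpha(self):
        out = ss.holm_sidak([0.03])
        assert out["adjusted_alpha"].iloc[0] == pytest.approx(0.05)
        assert bool(out["reject"].iloc[0])

    def test_worked_three_comparison_family(self):
        out = ss.holm_sidak([0.001, 0.02, 0.04])
        assert np.allclose(out["adjusted_alpha"],
                           [1 - 0.95 ** (1 / 3), 1 - 0.95 ** (1 / 2), 0.05])
        assert out["reject"].all()

    def test_step_down_stops_at_first_failure(self):
        out = ss.holm_sidak([0.001, 0.04, 0.045])
        # 0.04 > 1-0.95^(1/2)=0.0253 -> stop; 0.045 < 0.05 but not tested
        assert list(out["reject"]) == [True, False, False]

    def test_all_ones_reject_nothing(self):
        assert not ss.holm_sidak([1.0] * 5)["reject"].any()

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(hst.lists(hst.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_between_single_step_sidak_and_unadjusted(self, pvals):
        k = len(pvals)
        hs = ss.holm_sidak(pvals)["reject"].to_numpy()
        single_step = np.array(pvals) <= 1 - 0.95 ** (1 / k)
        unadjusted = np.array(pvals) <= 0.05
        assert np.all(hs[single_step])        # superset of single-step Šídák
        assert np.all(unadjusted[hs])         # subset of unadjusted


class TestMannWhitney:
    def test_fully_separated_samples(self):
        res = ss.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0.0
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(0.1, abs=1e-9)  # 2/20

    def test_identical_samples_with_ties(self):
        res = ss.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res["U"] == pytest.approx(4.5)  # n^2/2

    def test_u_sum_identity_without_ties(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=9), rng.normal(size=7)
        ux = ss.mann_whitney_u(x, y)["U"]
        uy = ss.mann_whitney_u(y, x)["U"]
        assert ux + uy == pytest.approx(63)

    def test_exact_p_matches_independent_enumeration(self):
        from itertools import combinations
        x = [1.0, 5.0, 2.0]
        y = [4.0, 6.0, 3.0, 8.0]
        res = ss.mann_whitney_u(x, y)
        pooled = np.array(x + y)
        nx, mu = len(x), len(x) * len(y) / 2

        def u_of(ix):
            xs = pooled[list(ix)]
            ys = np.delete(pooled, list(ix))
            return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

        obs = abs(u_of(range(nx)) - mu)
        devs = [abs(u_of(c) - mu) for c in combinations(range(7), nx)]
        assert res["p"] == pytest.approx(np.mean([d >= obs - 1e-12 for d in devs]))

    def test_large_samples_use_normal_approx_near_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        res = ss.mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res["method"] == "normal"
        assert res["p"] == pytest.approx(ref.pvalue, rel=0.02)


class TestSampleSize:
    def test_reference_inputs_give_six_per_group(self):
        assert ss.sample_size(sd=14.6, diff=25) == 6

    def test_huge_difference_floors_at_two(self):
        assert ss.sample_size(sd=1.0, diff=1e9) == 2

    def test_exact_t_mode_is_more_conservative(self):
        assert ss.sample_size(sd=14.6, diff=25, method="exact-t") == 7

    def test_monotone_in_sd_and_diff(self):
        ns_sd = [ss.sample_size(sd, 25) for sd in (5, 10, 15, 25, 40)]
        assert ns_sd == sorted(ns_sd)
        ns_diff = [ss.sample_size(14.6, d) for d in (5, 10, 20, 40)]
        assert ns_diff == sorted(ns_diff, reverse=True)

    def test_returned_n_achieves_simulated_power(self):
        """Monte-Carlo power of the known-variance z-test at the returned n."""
        sd, diff = 14.6, 25.0
        n = ss.sample_size(sd, diff)
        rng = np.random.default_rng(0)
        reps = 10_000
        a = rng.normal(0, sd, (reps, n))
        b = rng.normal(diff, sd, (reps, n))
        z = (b.mean(axis=1) - a.mean(axis=1)) / (sd * np.sqrt(2 / n))
        power = np.mean(np.abs(z) > sps.norm.ppf(0.975))
        assert power >= 0.8


class TestGatesAndTTests:
    def test_normal_draws_usually_pass_gate(self):
        passed = 0
        for seed in range(100):
            v = np.random.default_rng(seed).normal(size=500)
            passed += ss.shapiro_wilk_gate(v)["normal"]
        assert passed >= 90

    def test_two_point_mass_fails_gate(self):
        v = np.array([0.0, 1.0] * 250)
        assert not ss.shapiro_wilk_gate(v)["normal"]

    def test_constant_sample_gates_false(self):
        res = ss.shapiro_wilk_gate([3.0, 3.0, 3.0, 3.0])
        assert res["normal"] is False and np.isnan(res["p"])

    def test_paired_identical_samples(self):
        res = ss.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_two_sample_hand_computed_toy(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        res = ss.two_sample_t(x, y)
        # pooled sd: sx2=1, sy2=4 -> sp2=2.5, se=sqrt(2.5*2/3), t=-2/se
        expect = -2.0 / np.sqrt(2.5 * 2 / 3)
        assert res["t"] == pytest.approx(expect)
        assert res["df"] == 4

    def test_sign_flip_negates_t(self):
        x = np.array([1.0, 3.0, 2.5, 4.0])
        y = np.array([0.5, 2.0, 3.0, 3.5])
        t1 = ss.paired_t(x, y)["t"]
        t2 = ss.paired_t(y, x)["t"]
        assert t1 == pytest.approx(-t2)


class TestFamilywiseError:
    def test_null_pipeline_type_I_at_most_6pct(self):
        """ANOVA gate then Holm–Šídák post-hocs under a global null."""
        rng = np.random.default_rng(42)
        reps, false_alarms = 2000, 0
        for _ in range(reps):
            groups = rng.normal(size=(2, 5, 3))  # 2 groups, 5 subj, 3 times
            rows = []
            for g in range(2):
                for j in range(5):
                    for t in range(3):
                        rows.append({"subject_id": f"g{g}s{j}", "sex": "MF"[g],
                                     "time_bin": t, "value": groups[g, j, t]})
            df = pd.DataFrame(rows)
            res = ss.mixed_anova(df, between=("sex",))
            gate = res.loc[res["effect"].isin(["sex", "sex * time_bin"]), "p"]
            if (gate < 0.05).any():
                pvals = [ss.two_sample_t(groups[0, :, t], groups[1, :, t])["p"]
                         for t in range(3)]
                if ss.holm_sidak(pvals)["reject"].any():
                    false_alarms += 1
        assert false_alarms / reps <= 0.06
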