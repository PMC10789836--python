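"""Trial statistics against enumeration oracles and simulation calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mmtt_metab.trial_stats import (
    compare_groups,
    mannwhitney_exact_pvalues,
    mmtt_anova,
    null_power_mannwhitney,
    power_mannwhitney,
    reconcile_diaries,
    rm_anova,
    spearman,
    tertile_stratify,
)


def make_trial_table(rng, n=10, weeks=(0, 4, 8, 12), diet=0.0, group=0.0,
                     inter=0.0, subject_sd=1.0, noise_sd=1.0, variable="v"):
    rows = []
    wmax = max(weeks)
    for arm in ("eTRC", "Med"):
        for i in range(n):
            base = subject_sd * rng.standard_normal()
            for w in weeks:
                f = w / wmax
                val = (base + diet * f + group * (arm == "eTRC")
                       + inter * f * (arm == "eTRC") + noise_sd * rng.standard_normal())
                rows.append({"subject_id": f"{arm}{i}", "arm": arm, "visit_week": w,
                             "variable": variable, "value": val})
    return pd.DataFrame(rows)


class TestPowerMannWhitney:
    def test_exact_table_matches_scipy(self):
        tab = mannwhitney_exact_pvalues(6, 5)
        rng = np.random.default_rng(0)
        for _ in range(100):
            x, y = rng.normal(size=6), rng.normal(size=5)
            u = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact")
            assert tab[int(u.statistic)] == pytest.approx(u.pvalue, abs=1e-12)

    def test_null_calibration(self):
        rate, se = null_power_mannwhitney(11, 3.0, reps=10_000, seed=2)
        assert abs(rate - 0.05) < max(3 * se, 0.01)

    def test_design_power_exceeds_eighty_percent(self):
        power, _ = power_mannwhitney(11, 4.0, 3.0, alpha=0.05, reps=10_000, seed=1)
        assert power >= 0.80

    def test_analytic_t_test_cross_check(self):
        """MC power within 5 points of ARE-adjusted two-sample t power."""
        n, delta, sd = 11, 4.0, 3.0
        neff = n * 0.955  # asymptotic relative efficiency of Mann-Whitney
        df = 2 * neff - 2
        ncp = delta / (sd * np.sqrt(2 / neff))
        tc = scipy.stats.t.ppf(0.975, df)
        analytic = (1 - scipy.stats.nct.cdf(tc, df, ncp)
                    + scipy.stats.nct.cdf(-tc, df, ncp))
        power, _ = power_mannwhitney(n, delta, sd, reps=10_000, seed=1)
        assert abs(power - analytic) < 0.05

    def test_monotone_in_n_and_effect(self):
        p_small, _ = power_mannwhitney(6, 4.0, 3.0, reps=4000, seed=3)
        p_mid, _ = power_mannwhitney(11, 4.0, 3.0, reps=4000, seed=3)
        p_big, _ = power_mannwhitney(20, 4.0, 3.0, reps=4000, seed=3)
        assert p_small <= p_mid + 0.02 <= p_big + 0.04
        p_weak, _ = power_mannwhitney(11, 2.0, 3.0, reps=4000, seed=3)
        assert p_weak < p_mid

    def test_input_validation(self):
        with pytest.raises(ValueError):
            power_mannwhitney(2, 4.0, 3.0)
        with pytest.raises(ValueError):
            power_mannwhitney(11, 4.0, 3.0, reps=10)


class TestCompareGroups:
    def test_balanced_samples_exact_p_one(self):
        # U exactly nm/2: the two-sided exact p caps at 1
        x = [1.0, 4.0, 5.0, 8.0]
        y = [2.0, 3.0, 6.0, 7.0]
        _, p = compare_groups(x, y)
        assert p == 1.0

    def test_fisher_crossed_table(self):
        _, p = compare_groups(np.array([[5, 0], [0, 5]]), kind="fisher")
        assert p == pytest.approx(2.0 / 252.0, rel=1e-9)

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[7, 3], [2, 8]])
        _, p = compare_groups(table, kind="fisher")
        # brute force over all tables with the observed margins
        r1, r2 = table.sum(axis=1)
        c1 = table[:, 0].sum()
        n = table.sum()
        probs = []
        for a in range(max(0, c1 - r2), min(r1, c1) + 1):
            probs.append((a, scipy.stats.hypergeom.pmf(a, n, r1, c1)))
        obs = scipy.stats.hypergeom.pmf(table[0, 0], n, r1, c1)
        expect = sum(pr for _, pr in probs if pr <= obs * (1 + 1e-9))
        assert p == pytest.approx(expect, rel=1e-9)

    def test_mannwhitney_matches_full_enumeration(self):
        """Exact p on 4 vs 4 equals enumeration over all 70 assignments."""
        x = np.array([1.3, 2.9, 4.1, 6.2])
        y = np.array([2.0, 5.5, 7.3, 8.8])
        stat, p = compare_groups(x, y)
        pooled = np.concatenate([x, y])
        u_obs = sum(xi > yi for xi in x for yi in y)
        null_us = []
        for idx in itertools.combinations(range(8), 4):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(8) if i not in idx]]
            null_us.append(sum(a > b for a in xs for b in ys))
        null_us = np.array(null_us)
        lo = np.mean(null_us <= u_obs)
        hi = np.mean(null_us >= u_obs)
        assert p == pytest.approx(min(1.0, 2 * min(lo, hi)), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0, 2.0])


class TestSpearman:
    def test_perfectly_monotone(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 25, 40, 90])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_exhaustive_permutation_oracle(self):
        x = np.array([1.0, 5.0, 2.0, 4.0, 3.0, 6.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 6.0, 4.0])
        rho, p = spearman(x, y)
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        rho_obs = np.corrcoef(rx, ry)[0, 1]
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho_obs) - 1e-12
            total += 1
        assert rho == pytest.approx(rho_obs)
        assert p == pytest.approx(count / total, rel=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman(x, y)
        rho_s, p_s = scipy.stats.spearmanr(x, y)
        assert rho == pytest.approx(rho_s) and p == pytest.approx(p_s)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [4, 5, 6])


class TestRmAnova:
    def test_null_type_one_error(self):
        """Classical mixed-ANOVA F tests hold the nominal 5% level."""
        rng = np.random.default_rng(0)
        n_runs = 300
        rej = np.zeros(3)
        for _ in range(n_runs):
            tab = make_trial_table(rng, n=8, weeks=(0, 12))
            eff = rm_anova(tab, "v")
            rej += (eff["p"] < 0.05).to_numpy()
        rates = rej / n_runs
        tol = 3 * np.sqrt(0.05 * 0.95 / n_runs)
        assert np.all(np.abs(rates - 0.05) < tol + 0.01)

    def test_diet_effect_isolated(self):
        rng = np.random.default_rng(5)
        tab = make_trial_table(rng, n=60, weeks=(0, 12), diet=-1.0, noise_sd=0.5)
        eff = rm_anova(tab, "v").set_index("effect")
        assert eff.loc["diet", "p"] < 1e-6
        assert eff.loc["diet x group", "p"] > 0.01

    def test_group_permutation_leaves_diet_f_unchanged(self):
        rng = np.random.default_rng(7)
        tab = make_trial_table(rng, n=10, weeks=(0, 12), diet=-2.0)
        f0 = rm_anova(tab, "v").set_index("effect").loc["diet", "F"]
        flipped = tab.copy()
        flipped["arm"] = flipped["arm"].map({"eTRC": "Med", "Med": "eTRC"})
        f1 = rm_anova(flipped, "v").set_index("effect").loc["diet", "F"]
        assert f0 == pytest.approx(f1, rel=1e-9)

    def test_incomplete_subjects_dropped_and_counted(self):
        rng = np.random.default_rng(3)
        tab = make_trial_table(rng, n=6, weeks=(0, 12))
        tab = tab[~((tab["subject_id"] == "eTRC0") & (tab["visit_week"] == 12))]
        eff = rm_anova(tab, "v")
        assert eff.attrs["dropped"] == 1

    def test_too_few_complete_subjects(self):
        rng = np.random.default_rng(3)
        tab = make_trial_table(rng, n=1, weeks=(0, 12))
        with pytest.raises(ValueError):
            rm_anova(tab, "v")


class TestMmttAnova:
    def test_single_within_matches_pingouin(self):
        """Collapsed to one within factor, the split-plot partition must
        reproduce the classical mixed-ANOVA oracle exactly."""
        import pingouin as pg

        rng = np.random.default_rng(5)
        tab = make_trial_table(rng, n=9, weeks=(0, 12), diet=1.0, group=0.5)
        # unbalance the groups: drop one subject entirely
        tab = tab[tab["subject_id"] != "Med8"]
        mine = mmtt_anova(tab.assign(time_min=0), "v").set_index("effect")
        ref = pg.mixed_anova(data=tab, dv="value", within="visit_week",
                             subject="subject_id", between="arm").set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["arm", "F"], rel=1e-9)
        assert mine.loc["diet", "F"] == pytest.approx(ref.loc["visit_week", "F"], rel=1e-9)
        assert mine.loc["diet x group", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)

    def test_null_calibration_with_time_factor(self):
        rng = np.random.default_rng(1)
        n_runs = 150
        rej = {}
        for _ in range(n_runs):
            rows = []
            for arm in ("eTRC", "Med"):
                for i in range(6):
                    base = rng.standard_normal()
                    for w in (0, 12):
                        for t in (0, 60, 120, 180):
                            rows.append({"subject_id": f"{arm}{i}", "arm": arm,
                                         "visit_week": w, "time_min": t,
                                         "variable": "g",
                                         "value": base + rng.standard_normal()})
            eff = mmtt_anova(pd.DataFrame(rows), "g")
            for r in eff.itertuples():
                rej[r.effect] = rej.get(r.effect, 0) + (r.p < 0.05)
        for effect, k in rej.items():
            assert abs(k / n_runs - 0.05) < 0.05, effect

    def test_time_effect_detected(self):
        rng = np.random.default_rng(8)
        rows = []
        for arm in ("eTRC", "Med"):
            for i in range(10):
                base = rng.standard_normal()
                for w in (0, 12):
                    for t in (0, 60, 120, 180):
                        rows.append({"subject_id": f"{arm}{i}", "arm": arm,
                                     "visit_week": w, "time_min": t, "variable": "g",
                                     "value": base + 0.02 * t + 0.3 * rng.standard_normal()})
        eff = mmtt_anova(pd.DataFrame(rows), "g").set_index("effect")
        assert eff.loc["time", "p"] < 1e-6
        assert eff.loc["time x group", "p"] > 0.001


class TestTertileStratify:
    @staticmethod
    def diaries_with_shares(shares):
        rows = []
        for i, share in enumerate(shares):
            for day in (1, 2, 3):
                total = 200.0
                rows.append({"subject_id": f"s{i}", "day": day, "meal": "breakfast",
                             "carb_g": total * (1 - share) * 0.5})
                rows.append({"subject_id": f"s{i}", "day": day, "meal": "lunch",
                             "carb_g": total * (1 - share) * 0.5})
                rows.append({"subject_id": f"s{i}", "day": day, "meal": "dinner",
                             "carb_g": total * share})
        return pd.DataFrame(rows)

    def test_constructed_shares_recovered_exactly(self):
        shares = [0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45]
        diaries = self.diaries_with_shares(shares)
        outcomes = pd.DataFrame({"subject_id": [f"s{i}" for i in range(9)],
                                 "w": np.arange(9, dtype=float)})
        res = tertile_stratify(diaries, outcomes)
        assert np.allclose(np.sort(res["metric"].to_numpy()),
                           100 * np.array(shares))
        counts = res["tertile"].value_counts()
        assert counts[1] == 3 and counts[2] == 3 and counts[3] == 3

    def test_degenerate_ties_rejected(self):
        diaries = self.diaries_with_shares([0.2] * 9)
        outcomes = pd.DataFrame({"subject_id": [f"s{i}" for i in range(9)],
                                 "w": np.arange(9, dtype=float)})
        with pytest.raises(ValueError, match="degenerate"):
            tertile_stratify(diaries, outcomes)

    def test_too_few_subjects(self):
        diaries = self.diaries_with_shares([0.1, 0.2, 0.3])
        outcomes = pd.DataFrame({"subject_id": ["s0", "s1", "s2"], "w": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            tertile_stratify(diaries, outcomes)


class TestReconcileDiaries:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(rows, columns=["subject_id", "assessor_id",
                                           "energy_kj", "carb_g"])

    def test_agreement_no_flag(self):
        out = reconcile_diaries(self.frame([("a", 1, 100.0, 50.0),
                                            ("a", 2, 100.0, 50.0)]))
        row = out.iloc[0]
        assert row["energy_kj"] == 100.0 and not row["flagged"]

    def test_twenty_two_percent_discrepancy_flagged(self):
        # |100-125|/112.5 = 22.2% >= 20%
        out = reconcile_diaries(self.frame([("a", 1, 100.0, 50.0),
                                            ("a", 2, 125.0, 50.0)]))
        assert out.iloc[0]["flagged"]

    def test_seventeen_percent_consensus_mean(self):
        # |100-119|/109.5 = 17.4% < 20% -> consensus 109.5, no flag
        out = reconcile_diaries(self.frame([("a", 1, 100.0, 40.0),
                                            ("a", 2, 119.0, 40.0)]))
        row = out.iloc[0]
        assert not row["flagged"]
        assert row["energy_kj"] == pytest.approx(109.5)

    def test_third_assessor_resolves_by_median(self):
        out = reconcile_diaries(self.frame([("a", 1, 100.0, 30.0),
                                            ("a", 2, 130.0, 30.0),
                                            ("a", 3, 104.0, 31.0)]))
        row = out.iloc[0]
        assert row["flagged"] and row["n_assessors"] == 3
        assert row["energy_kj"] == pytest.approx(104.0)

    def test_single_assessment_passthrough_flagged(self):
        out = reconcile_diaries(self.frame([("a", 1, 90.0, 20.0)]))
        row = out.iloc[0]
        assert row["flagged"] and row["n_assessors"] == 1 and row["energy_kj"] == 90.0

    def test_carb_discrepancy_alone_triggers(self):
        out = reconcile_diaries(self.frame([("a", 1, 100.0, 30.0),
                                            ("a", 2, 101.0, 60.0)]))
        assert out.iloc[0]["flagged"]
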