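"""ANOVA variants, post hoc tests, and the significance ledger."""

import numpy as np
import pandas as pd
import pingouin
import pytest
import scipy.stats as sps

from palmraman.errors import DegenerateDataError, ValidationError
from palmraman.io import FEATURE_NAMES, RipenessLabel
from palmraman.stats import (
    SignificanceLedger,
    brown_forsythe_anova,
    build_significance_ledger,
    classify_tier,
    gabriel_posthoc,
    games_howell_posthoc,
    levene_homogeneity,
    oneway_anova,
    reference_ledger,
    studentized_max_modulus_sf,
    welch_anova,
)


class TestLevene:
    def test_identical_groups_give_zero_statistic(self):
        g = [1.0, 2.0, 3.0]
        res = levene_homogeneity([g, g])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_formula_by_hand(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([10.0, 20.0, 30.0])]
        # median-centered absolute deviations, then one-way ANOVA on them
        z = [np.abs(g - np.median(g)) for g in groups]
        zbar = np.mean(np.concatenate(z))
        num = sum(len(zi) * (zi.mean() - zbar) ** 2 for zi in z) / (2 - 1)
        den = sum(((zi - zi.mean()) ** 2).sum() for zi in z) / (6 - 2)
        res = levene_homogeneity(groups)
        assert res.statistic == pytest.approx(num / den, rel=1e-12)

    def test_p_in_unit_interval_on_random_inputs(self, rng):
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 12)) for _ in range(3)]
            assert 0.0 <= levene_homogeneity(groups).p_value <= 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            levene_homogeneity([[1.0], [1.0, 2.0]])


class TestAnovaFamily:
    def test_hand_computed_triple_group_example(self):
        res = oneway_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.statistic == pytest.approx(3.0)
        assert res.df == (2, 6)

    def test_equal_means_give_zero_f(self):
        res = oneway_anova([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert res.statistic == pytest.approx(0.0)

    def test_two_groups_equal_squared_pooled_t(self, rng):
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=14)
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert oneway_anova([a, b]).statistic == pytest.approx(t**2, rel=1e-10)

    def test_constant_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            oneway_anova([[2.0, 2.0], [2.0, 2.0]])

    def test_welch_two_groups_equal_squared_welch_t(self, rng):
        a, b = rng.normal(size=8), rng.normal(0.5, 3.0, size=20)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        res = welch_anova([a, b])
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-6)

    def test_welch_matches_pingouin(self, rng):
        groups = [rng.normal(m, s, size=n) for m, s, n in ((0, 1, 14), (1, 2, 20), (2, 0.5, 12))]
        frame = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat([0, 1, 2], [14, 20, 12])}
        )
        expected = pingouin.welch_anova(data=frame, dv="y", between="g")
        res = welch_anova(groups)
        assert res.statistic == pytest.approx(float(expected["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(expected["p_unc"].iloc[0]), rel=1e-6)
        assert res.df[1] == pytest.approx(float(expected["ddof2"].iloc[0]), rel=1e-9)

    def test_brown_forsythe_agrees_with_classic_when_balanced(self):
        # equal sizes and exactly equal variances: same data shifted
        base = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        groups = [base, base + 1.0, base + 2.5]
        classic = oneway_anova(groups)
        assert brown_forsythe_anova(groups).statistic == pytest.approx(
            classic.statistic, rel=1e-6
        )

    def test_welch_agrees_with_classic_for_two_balanced_groups(self):
        # for k=2 the Welch correction factor is exactly 1, and with equal
        # sizes and variances the Welch and pooled standard errors coincide
        base = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        groups = [base, base + 1.5]
        classic = oneway_anova(groups)
        assert welch_anova(groups).statistic == pytest.approx(classic.statistic, rel=1e-10)

    def test_welch_converges_to_classic_as_groups_grow(self):
        # k=3: the correction factor is 1 + O(1/n), so the statistics
        # approach each other as the balanced groups grow
        base = np.linspace(0.0, 1.0, 8)
        gaps = []
        for reps in (1, 10, 100):
            groups = [np.tile(base, reps), np.tile(base + 0.3, reps), np.tile(base + 0.7, reps)]
            classic = oneway_anova(groups).statistic
            gaps.append(abs(welch_anova(groups).statistic / classic - 1.0))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-3

    def test_identical_groups_give_zero_robust_statistics(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert welch_anova([g, g]).statistic == pytest.approx(0.0)
        assert brown_forsythe_anova([g, g]).statistic == pytest.approx(0.0)

    def test_shift_invariance(self, rng):
        groups = [rng.normal(size=8) for _ in range(3)]
        shifted = [g + 100.0 for g in groups]
        for test in (oneway_anova, welch_anova, brown_forsythe_anova):
            assert test(groups).statistic == pytest.approx(test(shifted).statistic, rel=1e-8)

    def test_classic_f_scale_invariance(self, rng):
        groups = [rng.normal(size=8) for _ in range(3)]
        scaled = [g * 3.7 for g in groups]
        assert oneway_anova(groups).statistic == pytest.approx(
            oneway_anova(scaled).statistic, rel=1e-10
        )


class TestStudentizedMaxModulus:
    def test_reduces_to_two_sided_t_for_one_contrast(self):
        for q, df in ((1.5, 10.0), (2.5, 40.0)):
            assert studentized_max_modulus_sf(q, 1, df) == pytest.approx(
                2 * sps.t.sf(q, df), abs=1e-6
            )

    def test_monotone_in_q_and_bounded(self):
        ps = [studentized_max_modulus_sf(q, 3, 43.0) for q in (0.5, 1.5, 2.5, 3.5)]
        assert all(0.0 <= p <= 1.0 for p in ps)
        assert ps == sorted(ps, reverse=True)


class TestGabriel:
    def test_identical_copies_are_clearly_null(self, rng):
        g = rng.normal(size=10)
        res = gabriel_posthoc([g, g.copy(), g + 1e-12])
        for pair in res:
            assert pair.p_value > 0.99

    def test_symmetric_under_group_order_swap(self, rng):
        groups = [rng.normal(size=n) for n in (14, 20, 12)]
        fwd = {r.pair: r.p_value for r in gabriel_posthoc(groups, labels=["a", "b", "c"])}
        rev = {r.pair: r.p_value for r in gabriel_posthoc(groups[::-1], labels=["c", "b", "a"])}
        assert fwd[("a", "b")] == pytest.approx(rev[("b", "a")], abs=1e-12)
        assert fwd[("a", "c")] == pytest.approx(rev[("c", "a")], abs=1e-12)

    def test_produces_all_unique_pairs(self, rng):
        groups = [rng.normal(size=6) for _ in range(4)]
        res = gabriel_posthoc(groups)
        assert len(res) == 6
        assert len({tuple(sorted(r.pair)) for r in res}) == 6


class TestGamesHowell:
    def test_two_groups_reduce_to_welch_t(self, rng):
        a, b = rng.normal(size=9), rng.normal(1.0, 2.5, size=15)
        _, p_welch = sps.ttest_ind(a, b, equal_var=False)
        res = games_howell_posthoc([a, b])
        assert res[0].p_value == pytest.approx(p_welch, abs=1e-6)

    def test_identical_groups_are_null(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = games_howell_posthoc([g, [x + 1e-9 for x in g]])
        assert res[0].p_value > 0.99

    def test_matches_pingouin(self, rng):
        groups = [rng.normal(m, s, size=n) for m, s, n in ((0, 1, 14), (0.8, 2, 20), (1.5, 0.5, 12))]
        frame = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat(["u", "r", "o"], [14, 20, 12])}
        )
        expected = pingouin.pairwise_gameshowell(data=frame, dv="y", between="g")
        got = {tuple(sorted(r.pair)): r.p_value for r in
               games_howell_posthoc(groups, labels=["u", "r", "o"])}
        for _, row in expected.iterrows():
            key = tuple(sorted((row["A"], row["B"])))
            assert got[key] == pytest.approx(float(row["pval"]), abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            games_howell_posthoc([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])

    def test_familywise_error_bounded_under_unequal_variances(self):
        """Null familywise error stays <= 0.07 at alpha=0.05 with the field
        sampling plan (n = 14/20/12) and unequal variances, over 2000
        replicates.  Statistics are vectorized against an interpolated
        studentized-range critical value and spot-checked against
        games_howell_posthoc itself."""
        ns, sds, reps = (14, 20, 12), (1.0, 2.0, 0.5), 2000
        df_grid = np.linspace(4.0, 46.0, 22)
        crit_grid = sps.studentized_range.ppf(0.95, 3, df_grid)
        rng = np.random.default_rng(9)
        draws = [rng.normal(0.0, sd, size=(reps, n)) for n, sd in zip(ns, sds)]
        means = [d.mean(axis=1) for d in draws]
        variances = [d.var(axis=1, ddof=1) for d in draws]
        rejected = np.zeros(reps, dtype=bool)
        for i, j in ((0, 1), (0, 2), (1, 2)):
            vi, vj = variances[i] / ns[i], variances[j] / ns[j]
            t = (means[i] - means[j]) / np.sqrt(vi + vj)
            df = (vi + vj) ** 2 / (vi**2 / (ns[i] - 1) + vj**2 / (ns[j] - 1))
            rejected |= np.abs(t) * np.sqrt(2.0) > np.interp(df, df_grid, crit_grid)
        assert rejected.mean() <= 0.07
        for r in range(5):
            res = games_howell_posthoc([d[r] for d in draws])
            assert any(pr.significant for pr in res) == bool(rejected[r])


def synthetic_feature_table(rng, shift=0.0, n=(30, 30, 30)):
    """Feature table whose int_nu1b separates classes by ``shift`` sds."""
    rows = []
    for lab, ni in zip(RipenessLabel, n):
        for i in range(ni):
            rec = {"sample_id": f"{lab.short}{i}", "label": lab}
            for name in FEATURE_NAMES:
                rec[name] = rng.normal(10.0, 1.0)
            rec["int_nu1b"] = rng.normal(10.0 + shift * int(lab), 1.0)
            rows.append(rec)
    return pd.DataFrame.from_records(rows, columns=["sample_id", "label", *FEATURE_NAMES])


class TestLedger:
    def test_tier_rule(self):
        assert classify_tier(True, [True, True, True]) == "main"
        assert classify_tier(True, [True, False, False]) == "reserved"
        assert classify_tier(True, [False, False, False]) == "excluded"
        assert classify_tier(False, [True, True, True]) == "excluded"

    def test_reference_pattern_retains_nine_features(self):
        ledger = reference_ledger()
        assert len(ledger.main) == 2
        assert len(ledger.reserved) == 7
        assert len(ledger.retained) == 9
        assert set(ledger.main) == {"int_nu1b", "int_nu1c"}
        assert set(ledger.main + ledger.reserved + ledger.excluded) == set(FEATURE_NAMES)

    def test_strong_effect_is_main(self, rng):
        table = synthetic_feature_table(rng, shift=10.0)
        ledger = build_significance_ledger(table)
        assert ledger.table.loc["int_nu1b", "tier"] == "main"

    def test_global_null_has_no_main_features(self, rng):
        table = synthetic_feature_table(rng, shift=0.0, n=(80, 80, 80))
        ledger = build_significance_ledger(table)
        assert ledger.main == []
        assert len(ledger.reserved) <= 3  # alpha-level false positives only

    def test_tiers_partition_the_features(self, feature_table):
        ledger = build_significance_ledger(feature_table)
        assert sorted(ledger.main + ledger.reserved + ledger.excluded) == sorted(FEATURE_NAMES)
        # the strongly encoded intensity trends survive screening; the weak
        # nu1d (neoxanthin) band may drop to reserved once fit noise is added
        for band in ("nu1a", "nu1b", "nu1c"):
            assert ledger.table.loc[f"int_{band}", "tier"] == "main"
        assert ledger.table.loc["int_nu1d", "tier"] in ("main", "reserved")

    def test_from_tiers_requires_all_features(self):
        with pytest.raises(ValidationError):
            SignificanceLedger.from_tiers({"int_nu1b": "main"})
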