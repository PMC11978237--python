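import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pelvikin.stats import (
    OUTCOME_UNITS,
    bland_altman,
    bonferroni,
    build_agreement_report,
    classify_icc,
    compare_groups,
    compare_tasks,
    icc_average,
    test_bias as bias_test,
)


def anova_oracle(table):
    """Independent two-way decomposition via explicit effect residuals."""
    table = np.asarray(table, float)
    n, k = table.shape
    grand = table.mean()
    rows = table.mean(axis=1, keepdims=True)
    cols = table.mean(axis=0, keepdims=True)
    resid = table - rows - cols + grand
    msr = k * np.sum((rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((cols - grand) ** 2) / (k - 1)
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return msr, msc, mse


def oracle_icc(table):
    msr, msc, mse = anova_oracle(table)
    n = table.shape[0]
    consistency = (msr - mse) / msr
    absolute = (msr - mse) / (msr + (msc - mse) / n)
    return consistency, absolute


class TestBiasGate:
    def test_identical_pairs_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bias_test(x, x)
        assert res.test == "degenerate"
        assert res.mean_difference == 0.0
        assert res.p is None and not res.significant

    def test_normal_shift_selects_t_and_detects(self):
        rng = np.random.default_rng(4)
        phone = rng.standard_normal(52)
        mocap = phone + 0.1 + 0.05 * rng.standard_normal(52)
        res = bias_test(mocap, phone)
        assert res.test == "paired_t"
        assert res.p < 1e-3
        assert res.mean_difference == pytest.approx(0.1, abs=0.03)

    def test_heavy_tails_select_wilcoxon_in_most_seeds(self):
        """Shapiro-Wilk flags t(2)-distributed differences at n=52 in >= 90%
        of seeds, routing the analysis to the signed-rank test."""
        chosen = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            phone = np.zeros(52)
            mocap = 0.05 * rng.standard_t(2, 52)
            if bias_test(mocap, phone).test == "wilcoxon":
                chosen += 1
        assert chosen >= 45

    def test_minimum_pairs(self):
        with pytest.raises(ValueError):
            bias_test(np.ones(2), np.zeros(2))


class TestICC:
    def test_identical_raters_both_forms_one(self):
        table = np.column_stack([np.arange(8.0), np.arange(8.0)])
        for model in ("consistency", "absolute"):
            res = icc_average(table, model=model)
            assert res.estimate == pytest.approx(1.0, abs=1e-12)
            assert res.ci95[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_consistency_one_absolute_below(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(10)
        table = np.column_stack([base, base + 1.5])
        cons = icc_average(table, model="consistency")
        absd = icc_average(table, model="absolute")
        assert cons.estimate == pytest.approx(1.0, abs=1e-12)
        assert absd.estimate < 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = rng.integers(5, 20)
            table = rng.standard_normal((n, 2)) + rng.standard_normal((n, 1))
            c_o, a_o = oracle_icc(table)
            assert icc_average(table, "consistency").estimate == pytest.approx(
                c_o, abs=1e-12
            )
            assert icc_average(table, "absolute").estimate == pytest.approx(
                a_o, abs=1e-12
            )

    def test_matches_pingouin_estimates_and_cis(self):
        """Cross-check both average-measures forms against an established
        implementation (point estimates and 95% CIs)."""
        import pingouin as pg

        rng = np.random.default_rng(12)
        table = rng.standard_normal((12, 2)) + 2.0 * rng.standard_normal((12, 1))
        table[:, 1] += 0.4
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile(["a", "b"], 12),
                "scores": table.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            data=long, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        for model, ref_type in (("consistency", "ICC(C,k)"), ("absolute", "ICC(A,k)")):
            mine = icc_average(table, model=model)
            assert mine.estimate == pytest.approx(ref.loc[ref_type, "ICC"], abs=1e-9)
            lo, hi = ref.loc[ref_type, "CI95"]
            assert mine.ci95[0] == pytest.approx(lo, abs=5e-3)
            assert mine.ci95[1] == pytest.approx(hi, abs=5e-3)

    def test_zero_between_participant_variance_degenerate(self):
        table = np.ones((8, 2))
        res = icc_average(table, "consistency")
        assert res.degenerate and res.estimate is None

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.1, 3.0))
    def test_consistency_invariant_absolute_decreasing_under_offset(self, seed, c):
        # start from rater-balanced data (equal column means): any constant
        # offset then strictly moves the raters apart, which the
        # absolute-agreement form penalises and the consistency form ignores
        rng = np.random.default_rng(seed)
        table = 0.3 * rng.standard_normal((9, 2)) + 2.0 * rng.standard_normal((9, 1))
        table = table - table.mean(axis=0, keepdims=True)
        shifted = table.copy()
        shifted[:, 1] += c
        assert icc_average(shifted, "consistency").estimate == pytest.approx(
            icc_average(table, "consistency").estimate, abs=1e-9
        )
        assert (
            icc_average(shifted, "absolute").estimate
            < icc_average(table, "absolute").estimate
        )

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            table = rng.standard_normal((10, 2)) + rng.standard_normal((10, 1))
            for model in ("consistency", "absolute"):
                res = icc_average(table, model)
                assert res.ci95[0] <= res.estimate <= res.ci95[1]


class TestClassifyICC:
    @pytest.mark.parametrize(
        "lower,expected",
        [
            (0.91, "excellent"),
            (0.9, "good"),
            (0.75, "good"),
            (0.65, "moderate"),
            (0.5, "moderate"),
            (0.49, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_category_boundaries(self, lower, expected):
        assert classify_icc(lower) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(1.2)


class TestBlandAltman:
    def test_identical_pairs(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(x, x)
        assert res.bias == 0.0
        assert res.loa_lower == res.loa_upper == 0.0

    def test_hand_computed_example(self):
        """Differences {1,2,3}: bias 2, SD 1, LoA (0.04, 3.96)."""
        res = bland_altman(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert res.bias == pytest.approx(2.0)
        assert res.sd == pytest.approx(1.0)
        assert res.loa_lower == pytest.approx(2.0 - 1.96)
        assert res.loa_upper == pytest.approx(2.0 + 1.96)

    def test_proportional_bias_slope_recovered(self):
        rng = np.random.default_rng(5)
        mean_level = np.linspace(1.0, 3.0, 40)
        diff = 0.3 * mean_level + 0.02 * rng.standard_normal(40)
        mocap = mean_level + diff / 2
        phone = mean_level - diff / 2
        res = bland_altman(mocap, phone)
        assert res.slope == pytest.approx(0.3, abs=0.05)
        assert res.slope_p < 0.01

    def test_loa_cover_95_percent_of_normal_differences(self):
        rng = np.random.default_rng(8)
        phone = rng.standard_normal(2000)
        mocap = phone + 0.2 + 0.5 * rng.standard_normal(2000)
        res = bland_altman(mocap, phone)
        d = mocap - phone
        frac = np.mean((d >= res.loa_lower) & (d <= res.loa_upper))
        assert 0.94 <= frac <= 0.965


class TestCompareTasks:
    def _wide(self, values):
        return pd.DataFrame(values, columns=["SLS", "SD15", "SD20"])

    def test_identical_values_degenerate_no_posthoc(self):
        wide = self._wide(np.ones((10, 3)))
        res = compare_tasks(wide)
        assert not res.significant
        assert res.posthoc == []

    def test_unanimous_ranking_friedman_closed_form(self):
        """Unanimous ordering over 3 tasks: chi-square = 2n exactly."""
        rng = np.random.default_rng(2)
        base = rng.standard_normal((10, 1))
        wide = self._wide(base + np.array([0.0, 1.0, 2.0]))
        res = compare_tasks(wide, method="friedman")
        assert res.statistic == pytest.approx(20.0, abs=1e-9)

    def test_normal_ordered_data_takes_anova_with_posthocs(self):
        rng = np.random.default_rng(0)
        subj = 1.0 * rng.standard_normal((20, 1))
        wide = self._wide(
            subj + np.array([0.0, 1.0, 2.0]) + 0.3 * rng.standard_normal((20, 3))
        )
        res = compare_tasks(wide)
        assert res.test == "rm_anova"
        assert res.significant
        assert len(res.posthoc) == 3
        for row in res.posthoc:
            assert row.significant
            assert row.mean_difference > 0
            assert row.p_adjusted >= row.p_raw

    def test_incomplete_cases_dropped_and_counted(self):
        rng = np.random.default_rng(7)
        wide = self._wide(rng.standard_normal((10, 3)))
        wide.iloc[0, 1] = np.nan
        res = compare_tasks(wide)
        assert res.n == 9 and res.n_dropped == 1


class TestCompareGroups:
    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(10)
        values = np.concatenate(
            [rng.standard_normal(26), 2.0 + rng.standard_normal(26)]
        )
        labels = np.array(["F"] * 26 + ["M"] * 26)
        res = compare_groups(values, labels)
        assert res.p < 0.01

    def test_identical_nonnormal_groups_full_ties(self):
        g = np.array([1.0, 1, 2, 2, 3, 30.0])
        res = compare_groups(np.tile(g, 2), np.array(["F"] * 6 + ["M"] * 6))
        assert res.test == "rank_sum"
        assert res.p > 0.9

    def test_constant_equal_groups_degenerate(self):
        res = compare_groups(np.ones(8), np.array(["F"] * 4 + ["M"] * 4))
        assert res.test == "degenerate" and res.p is None

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.ones(6), np.array(["F"] * 6))


class TestBonferroni:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.0, 1.0), st.integers(1, 10))
    def test_never_below_raw_and_capped(self, p, m):
        adj = bonferroni(p, m)
        assert adj >= p
        assert adj <= 1.0


class TestAgreementReport:
    def _outcome_table(self, n=10, seed=0, drift_participant=None):
        rng = np.random.default_rng(seed)
        records = []
        for p in range(n):
            for task in ("SLS", "SD15", "SD20"):
                base = {
                    "transverse": rng.normal(-5, 2),
                    "frontal": rng.normal(3, 2),
                    "sagittal": rng.normal(2, 3),
                    "ml_acceleration": abs(rng.normal(0.25, 0.05)),
                    "duration": rng.normal(3.4, 0.3),
                }
                for source in ("mocap", "phone"):
                    rec = {
                        "participant": p,
                        "task": task,
                        "source": source,
                        "drift_excluded": (
                            drift_participant == (p, task)
                        ),
                    }
                    noise = 0.02 * rng.standard_normal()
                    rec.update({k: v + noise for k, v in base.items()})
                    records.append(rec)
        return pd.DataFrame.from_records(records)

    def test_fifteen_rows(self):
        rows = build_agreement_report(self._outcome_table())
        assert len(rows) == 15
        assert {(r.outcome, r.task.value) for r in rows} == {
            (o, t) for o in OUTCOME_UNITS for t in ("SLS", "SD15", "SD20")
        }

    def test_drift_exclusion_hits_transverse_rows_only(self):
        rows = build_agreement_report(
            self._outcome_table(drift_participant=(3, "SD20"))
        )
        by_key = {(r.outcome, r.task.value): r for r in rows}
        assert by_key[("transverse", "SD20")].n == 9
        assert by_key[("transverse", "SD20")].n_excluded == 1
        assert by_key[("frontal", "SD20")].n == 10
        assert by_key[("transverse", "SLS")].n == 10

    def test_too_few_pairs_not_computable(self):
        rows = build_agreement_report(self._outcome_table(n=2))
        assert all(not r.computable for r in rows)
        assert all(r.icc is None for r in rows)
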