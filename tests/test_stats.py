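import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tsrzone
from tsrzone import stats
from tsrzone.core import ContingencyTable, PatientRecord
from tsrzone.synthetic import CohortConfig, simulate_cohort, table1_fixtures

#: printed two-sided p-values of the reference baseline table, rounded to
#: the precision they were published at
PRINTED_P = {
    "sex_inner": 1.0,
    "sex_itf": 0.598,
    "age_inner": 0.455,
    "age_itf": 0.647,
    "stage_inner": 0.724,
    "stage_itf": 0.926,
    "differentiation_inner": 0.123,
    "differentiation_itf": 1.0,
    "smoking_inner": 0.93,
    "smoking_itf": 0.976,
    "poi_inner": 0.038,
    "poi_itf": 0.002,
    "wpoi_inner": 0.581,
    "wpoi_itf": 0.035,
    "doi_inner": 0.312,
    "doi_itf": 0.264,
    "pni_itf": 0.001,
}


class TestChiSquare:
    @pytest.mark.parametrize("key", sorted(PRINTED_P))
    def test_reproduces_printed_p(self, key):
        table = table1_fixtures()[key]
        res = stats.chi_square_test(table)
        printed = PRINTED_P[key]
        decimals = max(len(str(printed).split(".")[-1]), 1)
        assert round(res.p_value, decimals) == printed

    def test_pni_inner_below_printed_bound(self):
        res = stats.chi_square_test(table1_fixtures()["pni_inner"])
        assert res.p_value < 0.001

    def test_2x2_uses_yates(self):
        res = stats.chi_square_test(table1_fixtures()["sex_inner"])
        assert res.method == "chi_square_yates"
        assert res.df == 1
        assert res.p_value == 1.0  # corrected deviation truncates to zero

    def test_rxc_uses_pearson(self):
        res = stats.chi_square_test(table1_fixtures()["stage_inner"])
        assert res.method == "chi_square"
        assert res.df == 3

    def test_zero_margin_rejected(self):
        table = ContingencyTable(
            np.array([[0, 0], [3, 4]]), ("a", "b"), ("x", "y")
        )
        with pytest.raises(ValueError, match="margin"):
            stats.chi_square_test(table)

    def test_fisher_option(self):
        res = stats.fisher_exact_test(table1_fixtures()["poi_inner"])
        assert res.method == "fisher_exact"
        assert 0 < res.p_value < 1

    @given(
        counts=st.lists(
            st.lists(st.integers(1, 50), min_size=2, max_size=2),
            min_size=2, max_size=4,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_p_in_unit_interval_and_stat_nonnegative(self, counts):
        table = ContingencyTable(
            np.array(counts),
            tuple(f"r{i}" for i in range(len(counts))),
            ("c0", "c1"),
        )
        res = stats.chi_square_test(table)
        assert 0.0 <= res.p_value <= 1.0
        assert res.statistic >= 0.0


class TestPairedT:
    def test_identical_samples_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="variance"):
            stats.paired_t_test(x, x)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(60, 10, 50)
        y = x - rng.normal(15, 10, 50)
        a = stats.paired_t_test(x, y)
        b = stats.paired_t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.df == 49

    def test_shifted_cohort_strongly_significant(self):
        # inner TSR ~ ITF TSR + 15 with sd 10 at the reference cohort size
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            itf = rng.normal(40, 10, 114)
            inner = itf + rng.normal(15, 10, 114)
            res = stats.paired_t_test(inner, itf)
            if res.p_value < 1e-4 and res.extra["mean_difference"] > 0:
                hits += 1
        assert hits >= 99


class TestSpearman:
    def test_perfect_monotone(self):
        res = stats.spearman_association([1, 2, 3, 4], [10, 20, 30, 80])
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_monotone(self):
        res = stats.spearman_association([1, 2, 3, 4], [8, 6, 4, 2])
        assert res.statistic == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stats.spearman_association([1.0, 1.0, 1.0], [1, 2, 3])


class TestKMLogrank:
    def test_identical_arms_p_one(self):
        recs = []
        for arm, group in enumerate(("tumor_high", "tumor_low")):
            for i, (t, e) in enumerate([(5, 1), (8, 0), (12, 1), (20, 1)]):
                recs.append(
                    PatientRecord(
                        id=f"{arm}-{i}", tsr_itf=30 if group == "tumor_low" else 70,
                        group_itf=group, os_time=t, os_event=e,
                    )
                )
        res, curves = stats.km_logrank(recs, "itf_group_low", "os")
        assert res.p_value == pytest.approx(1.0)
        assert set(curves) == {"0", "1"}

    def test_single_arm_rejected(self):
        recs = [
            PatientRecord(id=str(i), tsr_itf=70.0, group_itf="tumor_high",
                          os_time=i + 1.0, os_event=1)
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="two arms"):
            stats.km_logrank(recs, "itf_group_low", "os")

    def test_all_censored_arm_curve_stays_at_one(self):
        recs = []
        for i in range(5):
            recs.append(PatientRecord(id=f"h{i}", tsr_itf=70.0,
                                      group_itf="tumor_high",
                                      os_time=i + 1.0, os_event=0))
            recs.append(PatientRecord(id=f"l{i}", tsr_itf=30.0,
                                      group_itf="tumor_low",
                                      os_time=i + 1.0, os_event=1))
        res, curves = stats.km_logrank(recs, "itf_group_low", "os")
        assert (curves["0"].values == 1.0).all()

    def test_separated_arms_significant(self):
        cfg = CohortConfig(n=2000, hr_map={"itf_group_low": 4.34},
                           censor_rate=0.3, seed=11)
        frame = stats.records_to_frame(simulate_cohort(cfg))
        res, _ = stats.km_logrank(frame, "itf_group_low", "os")
        assert res.p_value < 1e-4


class TestCox:
    def test_hr_recovery(self):
        cfg = CohortConfig(n=2000, hr_map={"itf_group_low": 4.34},
                           censor_rate=0.3, group_prevalence=0.45, seed=7)
        frame = stats.records_to_frame(simulate_cohort(cfg))
        eff = stats.cox_fit(frame, ["itf_group_low"], "os")["itf_group_low"]
        assert 3.7 <= eff.effect <= 5.1
        assert eff.ci_low <= 4.34 <= eff.ci_high

    def test_null_coverage(self):
        covered = 0
        n_rep = 200
        for seed in range(n_rep):
            frame = stats.records_to_frame(
                simulate_cohort(CohortConfig(n=120, hr_map={}, seed=seed))
            )
            eff = stats.cox_fit(frame, ["itf_group_low"], "dfs")["itf_group_low"]
            if eff.ci_low <= 1.0 <= eff.ci_high:
                covered += 1
        assert 0.90 <= covered / n_rep <= 0.99

    def test_reference_relabel_inverts_hr(self):
        frame = stats.records_to_frame(
            simulate_cohort(CohortConfig(n=500, hr_map={"itf_group_low": 3.0}, seed=2))
        )
        eff = stats.cox_fit(frame, ["itf_group_low"], "dfs")["itf_group_low"]
        flipped = frame.copy()
        flipped["itf_group_low"] = 1 - flipped["itf_group_low"]
        eff_flipped = stats.cox_fit(flipped, ["itf_group_low"], "dfs")["itf_group_low"]
        assert eff_flipped.effect == pytest.approx(1.0 / eff.effect, rel=1e-6)

    def test_multivariate_adjustment_set(self):
        cfg = CohortConfig(n=800, hr_map={"itf_group_low": 3.0, "pni_yes": 1.5},
                           seed=4)
        frame = stats.records_to_frame(simulate_cohort(cfg))
        fit = stats.cox_fit(
            frame, list(stats.MULTIVARIATE_ADJUSTMENT) + ["itf_group_low"], "os"
        )
        assert set(fit.effects) == {"poi_high", "doi_ge5", "pni_yes", "itf_group_low"}

    def test_no_events_rejected(self):
        recs = [
            PatientRecord(id=str(i), tsr_itf=float(20 + i * 40),
                          group_itf="tumor_low" if i == 0 else "tumor_high",
                          os_time=float(i + 1), os_event=0)
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="no events"):
            stats.cox_fit(recs, ["itf_group_low"], "os")

    def test_univariate_loop(self):
        frame = stats.records_to_frame(
            simulate_cohort(CohortConfig(n=300, hr_map={"itf_group_low": 2.0}, seed=6))
        )
        out = stats.univariate_cox(frame, ["itf_group_low", "pni_yes"], "os")
        assert set(out) == {"itf_group_low", "pni_yes"}


class TestLogisticPNI:
    @staticmethod
    def _records_from_counts(counts):
        # counts rows = PNI no/yes, cols = inner high/low
        recs, i = [], 0
        for pni, row in zip(("no", "yes"), counts):
            for group, n in zip(("tumor_high", "tumor_low"), row):
                for _ in range(n):
                    recs.append(
                        PatientRecord(
                            id=str(i), pni=pni,
                            tsr_inner=70.0 if group == "tumor_high" else 30.0,
                            group_inner=group,
                        )
                    )
                    i += 1
        return recs

    def test_univariate_or_equals_cross_product(self):
        recs = self._records_from_counts([[68, 12], [17, 17]])
        out = stats.logistic_pni(recs, predictors=["inner_group_low"])
        assert out["inner_group_low"].effect == pytest.approx(17 * 68 / (12 * 17), rel=1e-6)

    def test_null_coverage(self):
        covered = 0
        n_rep = 100
        for seed in range(n_rep):
            frame = stats.records_to_frame(
                simulate_cohort(CohortConfig(n=200, hr_map={}, seed=seed))
            )
            out = stats.logistic_pni(frame, predictors=["inner_group_low"])
            eff = out["inner_group_low"]
            if eff.ci_low <= 1.0 <= eff.ci_high:
                covered += 1
        assert covered / n_rep >= 0.90

    def test_multivariate_mode(self):
        frame = stats.records_to_frame(
            simulate_cohort(CohortConfig(n=400, hr_map={}, seed=9))
        )
        fit = stats.logistic_pni(frame, mode="multivariate")
        assert fit.model == "logistic"
        assert set(fit.effects) == set(stats.PNI_PREDICTORS)

    def test_constant_outcome_rejected(self):
        recs = [
            PatientRecord(id=str(i), pni="no", tsr_inner=30.0 + i,
                          group_inner="tumor_low")
            for i in range(6)
        ]
        with pytest.raises(ValueError, match="constant"):
            stats.logistic_pni(recs, predictors=["inner_group_low"])

    def test_separation_rejected(self):
        recs = self._records_from_counts([[30, 0], [0, 30]])
        with pytest.raises(RuntimeError, match="separation|failed"):
            stats.logistic_pni(recs, predictors=["inner_group_low"])


class TestProportionSummary:
    def test_tumor_low_inner_share(self):
        assert stats.proportion_summary(29, 114) == 25.44

    def test_death_share(self):
        assert stats.proportion_summary(38, 114) == 33.33

    def test_zero_numerator(self):
        assert stats.proportion_summary(0, 7) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            stats.proportion_summary(1, 0)

    def test_numerator_exceeding_denominator_rejected(self):
        with pytest.raises(ValueError):
            stats.proportion_summary(5, 4)
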