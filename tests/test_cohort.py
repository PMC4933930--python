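import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta as beta_dist

from niptcca import (
    AccuracyCounts,
    CohortConfig,
    ParamError,
    Strategy,
    accuracy_counts,
    clopper_pearson,
    cohort_counts,
    diagnostic_accuracy,
    estimate_params,
    evaluate_pathway,
    read_cohort,
    simulate_cohort,
    write_cohort,
)
from niptcca.cohort import BAND_HIGH, BAND_INT, COHORT_COLUMNS

NO_LOSS = CohortConfig(loss_to_followup=0.0)


def binomial_se(n: float, p: float) -> float:
    return math.sqrt(n * p * (1 - p))


class TestSimulateCohort:
    def test_reproducible(self, national, s150):
        a = simulate_cohort(national, 5000, s150, seed=7)
        b = simulate_cohort(national, 5000, s150, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_forced_path_all_nipt(self, national, s150):
        p = national.replace(
            u_screen=1.0,
            p_risk_high=1.0,
            p_risk_int500=0.0,
            p_risk_int1000=0.0,
            u_nipt_high=1.0,
            u_direct_ipd=0.0,
        )
        c = simulate_cohort(p, 500, s150, seed=0)
        assert (c["choice"] == "nipt").all()

    def test_study_scale_screening_uptake(self, rapid):
        # study-period screening uptake: 30,790 of 40,527 booked women
        p = rapid.replace(u_screen=30_790 / 40_527)
        c = simulate_cohort(p, 40_527, Strategy("contingent", 1000), seed=5)
        se = binomial_se(40_527, p.u_screen)
        assert abs(c["screened"].sum() - 30_790) <= 3 * se

    def test_screened_within_3se_of_generating_uptake(self, rapid):
        c = simulate_cohort(rapid, 40_527, Strategy("contingent", 1000), seed=5)
        expect = 40_527 * rapid.u_screen
        se = binomial_se(40_527, rapid.u_screen)
        assert abs(c["screened"].sum() - expect) <= 3 * se

    def test_bad_n(self, national, s150):
        with pytest.raises(ParamError):
            simulate_cohort(national, 0, s150, seed=0)

    def test_flow_conservation(self, national, s150):
        c = simulate_cohort(national, 50_000, s150, seed=3)
        screened = c["screened"].sum()
        assert (c["risk_band"] != "none").sum() == screened
        # every NIPT positive is confirmed, declined, or lost
        pos = c[c["nipt_result"] == "positive"]
        lost = pos["outcome"] == "lost_to_followup"
        assert (pos["confirmatory_ipd"] | lost | ~pos["confirmatory_ipd"]).all()
        declined_conf = pos[~pos["confirmatory_ipd"] & ~lost]
        assert (declined_conf["ipd_result"] == "none").all()

    def test_invariants(self, national, s150, current):
        for scenario in (s150, current):
            c = simulate_cohort(national, 30_000, scenario, seed=11)
            direct = c["choice"] == "direct_ipd"
            assert (c.loc[direct, "risk_band"] == BAND_HIGH).all()
            nipt = c["choice"] == "nipt"
            assert ((c["nipt_result"] != "none") == nipt).all()
            had_ipd = direct | c["confirmatory_ipd"]
            assert ((c["ipd_result"] != "none") == had_ipd).all()
            assert (~c["procedure_miscarriage"] | had_ipd).all()

    def test_nodirect_scenario_has_no_direct_choosers(self, national, s150_nodirect):
        c = simulate_cohort(national, 30_000, s150_nodirect, seed=2)
        assert not (c["choice"] == "direct_ipd").any()

    def test_threshold_150_offers_nothing_to_intermediates(self, national, s150):
        c = simulate_cohort(national, 30_000, s150, seed=2)
        inter = c["risk_band"] == BAND_INT
        assert (c.loc[inter, "choice"] == "none").all()

    def test_nipt_fully_sensitive(self, national, s150):
        c = simulate_cohort(national, 100_000, s150, seed=4)
        negatives = c[c["nipt_result"] == "negative"]
        assert (negatives["true_status"] == "unaffected").all()


class TestMonteCarloOracle:
    @pytest.mark.parametrize(
        "scenario",
        [Strategy("current"), Strategy("contingent", 150),
         Strategy("contingent", 1000, direct_ipd_allowed=False)],
        ids=lambda s: s.label,
    )
    def test_cohort_agrees_with_deterministic_model(self, national, scenario):
        n = 200_000
        c = simulate_cohort(national, n, scenario, seed=17, config=NO_LOSS)
        counts = cohort_counts(c)
        det = evaluate_pathway(national, scenario)
        scale = n / national.population_size
        for name, observed in counts.items():
            expected = getattr(det, name) * scale
            se = math.sqrt(max(expected, 1.0))
            assert abs(observed - expected) <= 3 * se + 1, (name, observed, expected)


class TestEstimateParams:
    @staticmethod
    def _frame(n: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(n),
                "booked": True,
                "screened": True,
                "screen_type": "combined",
                "risk_band": "<1/1000",
                "sub_band": "none",
                "true_status": "unaffected",
                "choice": "none",
                "nipt_result": "none",
                "nipt_repeated": False,
                "confirmatory_ipd": False,
                "ipd_result": "none",
                "procedure_miscarriage": False,
                "outcome": "continue",
            },
            columns=COHORT_COLUMNS,
        )

    def test_high_risk_nipt_uptake(self):
        # 934 high-risk women, 695 choosing NIPT, 166 direct invasive
        df = self._frame(934)
        df["risk_band"] = BAND_HIGH
        df.loc[:694, "choice"] = "nipt"
        df.loc[:694, "nipt_result"] = "negative"
        df.loc[695:860, "choice"] = "direct_ipd"
        df.loc[695:860, "ipd_result"] = "negative"
        df.loc[861:, "choice"] = "decline"
        est = estimate_params(df)
        assert 100 * est.params.u_nipt_high == pytest.approx(74.4, abs=0.05)
        lo, hi = est.intervals["u_nipt_high"]
        assert lo < 0.744 < hi

    def test_intermediate_nipt_uptake(self):
        # 2241 intermediate women offered, 1799 choosing NIPT
        df = self._frame(2241)
        df["risk_band"] = BAND_INT
        df["sub_band"] = "1/501-1/1000"
        df.loc[:1798, "choice"] = "nipt"
        df.loc[:1798, "nipt_result"] = "negative"
        df.loc[1799:, "choice"] = "decline"
        est = estimate_params(df)
        assert 100 * est.params.u_nipt_int == pytest.approx(80.3, abs=0.05)

    def test_empty_cohort(self):
        with pytest.raises(ParamError):
            estimate_params(self._frame(0))

    def test_zero_denominator_not_estimable(self, national, s150):
        # nobody screened: downstream fields must be flagged, not crash
        df = self._frame(100)
        df["screened"] = False
        df["screen_type"] = "none"
        df["risk_band"] = "none"
        est = estimate_params(df)
        assert "u_screen" in est.intervals
        assert "p_risk_high" not in est.intervals
        assert "u_nipt_high" not in est.intervals

    def test_costs_passed_through(self, national, s150):
        c = simulate_cohort(national, 20_000, s150, seed=1)
        est = estimate_params(c, base=national)
        assert est.params.c_nipt_lab == national.c_nipt_lab
        assert est.params.c_ipd == national.c_ipd

    def test_recovery_calibration(self, national):
        """Simulation-based calibration: over 100 seeds, each estimable
        proportion's exact 95% interval covers the generating value in at
        least 93 runs (cohorts scaled down from the reference size for
        test-time budget; coverage does not depend on n)."""
        scenario = Strategy("contingent", 1000)
        n_seeds, n = 100, 30_000
        hits: dict[str, int] = {}
        totals: dict[str, int] = {}
        for seed in range(n_seeds):
            c = simulate_cohort(national, n, scenario, seed=seed)
            est = estimate_params(c, base=national)
            for name, (lo, hi) in est.intervals.items():
                truth = getattr(national, name)
                totals[name] = totals.get(name, 0) + 1
                if lo <= truth <= hi:
                    hits[name] = hits.get(name, 0) + 1
        assert totals, "no estimable fields"
        for name, total in totals.items():
            if total < n_seeds:
                continue  # field not estimable in every run (tiny denominators)
            assert hits.get(name, 0) >= 93, (name, hits.get(name, 0))


class TestDiagnosticAccuracy:
    def test_ppv_from_discordant_positives(self):
        # 50 concordant of 55 positive results
        acc = diagnostic_accuracy(AccuracyCounts(tp=50, fp=5, tn=0, fn=0))
        point, lo, hi = acc["ppv"]
        assert 100 * point == pytest.approx(90.9, abs=0.05)
        assert lo < point < hi

    def test_perfect_sensitivity_lower_bound(self):
        # with 0/72 failures the exact lower bound is 0.025**(1/72)
        acc = diagnostic_accuracy(AccuracyCounts(tp=72, fp=0, tn=0, fn=0))
        point, lo, hi = acc["sensitivity"]
        assert point == 1.0 and hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 72), abs=1e-9)
        assert lo == pytest.approx(0.95, abs=0.01)

    def test_single_counts(self):
        acc = diagnostic_accuracy(AccuracyCounts(tp=1, fp=0, tn=1, fn=0))
        assert acc["sensitivity"][0] == 1.0
        assert acc["specificity"][0] == 1.0
        assert acc["ppv"][0] == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ParamError):
            diagnostic_accuracy(AccuracyCounts(0, 0, 0, 0))

    def test_missing_denominator_is_none(self):
        acc = diagnostic_accuracy(AccuracyCounts(tp=0, fp=0, tn=5, fn=0))
        assert acc["ppv"] is None
        assert acc["specificity"] is not None

    def test_negative_counts_rejected(self):
        with pytest.raises(ParamError):
            AccuracyCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_interval_contains_point_and_shrinks(self):
        widths = []
        for scale in (1, 10, 100):
            acc = diagnostic_accuracy(
                AccuracyCounts(tp=9 * scale, fp=1 * scale, tn=90 * scale, fn=0)
            )
            point, lo, hi = acc["ppv"]
            assert lo <= point <= hi
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_clopper_pearson_matches_beta_quantiles(self):
        k, n = 17, 80
        lo, hi = clopper_pearson(k, n)
        assert lo == pytest.approx(beta_dist.ppf(0.025, k, n - k + 1))
        assert hi == pytest.approx(beta_dist.ppf(0.975, k + 1, n - k))

    def test_clopper_pearson_errors(self):
        with pytest.raises(ParamError):
            clopper_pearson(1, 0)
        with pytest.raises(ParamError):
            clopper_pearson(5, 3)

    def test_accuracy_counts_from_cohort(self, national, s150):
        c = simulate_cohort(national, 200_000, s150, seed=8)
        counts = accuracy_counts(c)
        acc = diagnostic_accuracy(counts)
        assert counts.fn == 0  # generator is fully sensitive
        assert acc["sensitivity"][0] == 1.0
        # discordance rate ~ 1 - p_ipd_pos_after_nipt by default
        assert acc["ppv"][0] == pytest.approx(national.p_ipd_pos_after_nipt, abs=0.08)


class TestCohortIO:
    def test_round_trip(self, national, s150, tmp_path):
        c = simulate_cohort(national, 2000, s150, seed=9)
        f = tmp_path / "cohort.csv"
        write_cohort(c, f)
        back = read_cohort(f)
        pd.testing.assert_frame_equal(back, c)

    def test_missing_columns_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("id,booked\n1,True\n")
        with pytest.raises(ParamError, match="missing"):
            read_cohort(f)
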