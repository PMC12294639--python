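"""PPV, odds ratios, and logistic regression arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pwud_phenotype.cohort import build_partition
from pwud_phenotype.stats_eval import (
    TwoByTwoTable,
    disparity_report,
    fit_logistic,
    odds_ratio_2x2,
    ppv,
)
from pwud_phenotype.synthetic_emr import simulate_documentation_outcomes
from pwud_phenotype.types import DomainFlags, Encounter


class TestPPV:
    @pytest.mark.parametrize(
        ("confirmed", "reviewed", "pct"),
        [(40, 93, 43), (53, 99, 54), (0, 10, 0), (10, 10, 100), (1, 200, 1)],
    )
    def test_rounded_percent(self, confirmed, reviewed, pct):
        assert ppv(confirmed, reviewed).ppv_pct_rounded == pct

    def test_half_rounds_away_from_zero(self):
        assert ppv(1, 8).ppv_pct_rounded == 13  # 12.5 -> 13

    def test_clopper_pearson_against_beta_quantiles(self):
        # exact interval == beta-distribution quantiles
        for confirmed, reviewed in [(40, 93), (53, 99), (1, 10), (9, 10)]:
            result = ppv(confirmed, reviewed)
            low = stats.beta.ppf(0.025, confirmed, reviewed - confirmed + 1)
            high = stats.beta.ppf(0.975, confirmed + 1, reviewed - confirmed)
            assert result.ci95[0] == pytest.approx(low, abs=1e-10)
            assert result.ci95[1] == pytest.approx(high, abs=1e-10)
            assert result.ci95[0] <= result.ppv <= result.ci95[1]

    def test_boundary_zero_confirmed(self):
        result = ppv(0, 10)
        assert result.ppv == 0
        assert result.ci95[0] == 0

    def test_monotone_in_confirmed(self):
        values = [ppv(k, 50).ppv for k in range(51)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_zero_reviewed_rejected(self):
        with pytest.raises(ValueError):
            ppv(0, 0)


class TestOddsRatio:
    def test_race_table_reproduces_printed_estimate(self):
        result = odds_ratio_2x2(TwoByTwoTable(550, 174, 176, 114))
        assert result.or_point == pytest.approx(2.04, abs=0.01)
        assert result.ci95[0] == pytest.approx(1.53, abs=0.01)
        assert result.ci95[1] == pytest.approx(2.73, abs=0.01)

    def test_svi_table_reproduces_printed_estimate(self):
        result = odds_ratio_2x2(TwoByTwoTable(461, 163, 262, 124))
        assert result.or_point == pytest.approx(1.34, abs=0.01)
        assert result.ci95[0] == pytest.approx(1.01, abs=0.01)
        assert result.ci95[1] == pytest.approx(1.77, abs=0.01)

    def test_symmetric_table_is_null(self):
        result = odds_ratio_2x2(TwoByTwoTable(10, 10, 10, 10))
        assert result.or_point == 1.0
        assert result.ci95[0] < 1.0 < result.ci95[1]

    def test_exposure_transposition_inverts_or(self):
        table = TwoByTwoTable(550, 174, 176, 114)
        fwd = odds_ratio_2x2(table)
        rev = odds_ratio_2x2(table.transposed_exposure())
        assert rev.or_point == pytest.approx(1 / fwd.or_point, rel=1e-12)
        assert rev.ci95[0] == pytest.approx(1 / fwd.ci95[1], rel=1e-12)
        assert rev.ci95[1] == pytest.approx(1 / fwd.ci95[0], rel=1e-12)

    def test_against_scipy_sample_odds_ratio(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 200, size=4)
            ours = odds_ratio_2x2(TwoByTwoTable(a, b, c, d))
            ref = stats.contingency.odds_ratio(
                [[a, b], [c, d]], kind="sample"
            ).statistic
            assert ours.or_point == pytest.approx(ref, rel=1e-12)

    def test_single_zero_cell_haldane_corrected(self):
        result = odds_ratio_2x2(TwoByTwoTable(10, 0, 5, 8))
        assert result.continuity_corrected
        expected = (10.5 * 8.5) / (0.5 * 5.5)
        assert result.or_point == pytest.approx(expected, rel=1e-12)

    def test_cross_zeros_undefined(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(TwoByTwoTable(0, 5, 3, 0))

    def test_log_consistency(self):
        result = odds_ratio_2x2(TwoByTwoTable(461, 163, 262, 124))
        assert math.exp(result.log_or) == pytest.approx(result.or_point, abs=1e-12)


class TestFitLogistic:
    def test_saturated_2x2_equals_cross_product_or(self):
        # expand the race 2x2 into rows: exposure -> outcome
        a, b, c, d = 550, 174, 176, 114
        exposure = [1] * (a + b) + [0] * (c + d)
        outcome = [1] * a + [0] * b + [1] * c + [0] * d
        fit = fit_logistic(outcome, pd.DataFrame({"x": exposure}))
        assert fit.converged
        assert fit.or_estimates["x"] == pytest.approx((a * d) / (b * c), abs=1e-6)

    def test_parameter_recovery_single_run(self):
        data = simulate_documentation_outcomes(
            n=20_000, beta_race=math.log(2.0), beta_svi=math.log(1.4), seed=5
        )
        fit = fit_logistic(data["outcome"], data[["white", "svi_34", "age_z", "male"]])
        assert fit.converged
        assert fit.or_estimates["white"] == pytest.approx(2.0, abs=0.15)
        assert fit.or_estimates["svi_34"] == pytest.approx(1.4, abs=0.15)

    def test_missing_rows_dropped_and_counted(self):
        x = pd.DataFrame({"x": [1.0, 0.0, np.nan, 1.0, 0.0, 1.0, 0.0, 1.0]})
        y = [1, 0, 1, 1, 0, 1, 0, 0]
        fit = fit_logistic(y, x)
        assert fit.n_used == 7
        assert fit.n_dropped_missing == 1

    def test_constant_outcome_flags_separation(self):
        x = pd.DataFrame({"x": [0.0, 1.0] * 10})
        with pytest.warns(UserWarning):
            fit = fit_logistic([1] * 20, x)
        assert not fit.converged


def _fixture_encounter(eid, race, svi, counter):
    return Encounter(
        encounter_id=eid, age=40.0 + (counter % 17),
        sex="male" if counter % 2 else "female",
        race_eth=race, svi_quartile=svi, primary_language="english",
        length_of_stay=10.0,
    )


@pytest.fixture(scope="module")
def fixture_cohort():
    """Comparison groups constructed to the published descriptive margins."""
    encounters, flags = [], []

    def add(n, race, svi, cell, prefix):
        for i in range(n):
            eid = f"{prefix}-{race}-{svi}-{i}"
            encounters.append(_fixture_encounter(eid, race, svi, len(encounters)))
            flags.append((eid, DomainFlags(b="B" in cell, d="D" in cell,
                                           m="M" in cell, n="N" in cell)))

    # Joint race x SVI allocations chosen to hit the published margins:
    # BDMN: 550 white / 176 minoritized; SVI 461 high / 262 low / 3 missing
    add(400, "white_nonhispanic", 3, "BDMN", "hd")
    add(148, "white_nonhispanic", 1, "BDMN", "hd")
    add(2, "white_nonhispanic", None, "BDMN", "hd")
    add(61, "minoritized", 4, "BDMN", "hd")
    add(114, "minoritized", 2, "BDMN", "hd")
    add(1, "minoritized", None, "BDMN", "hd")
    # N-only: 174 white / 114 minoritized; SVI 163 high / 124 low / 1 missing
    add(100, "white_nonhispanic", 4, "N", "np")
    add(74, "white_nonhispanic", 2, "N", "np")
    add(63, "minoritized", 3, "N", "np")
    add(50, "minoritized", 1, "N", "np")
    add(1, "minoritized", None, "N", "np")
    return encounters, flags


class TestDisparityReport:

    def test_reproduces_printed_unadjusted_ors(self, fixture_cohort):
        encounters, flags = fixture_cohort
        report = disparity_report(build_partition(flags), encounters)
        assert report.group_sizes["bdmn"] == 726
        assert report.group_sizes["n_only"] == 288
        assert report.unadjusted["race"].or_point == pytest.approx(2.04, abs=0.01)
        assert report.unadjusted["race"].ci95 == pytest.approx((1.53, 2.73), abs=0.01)
        assert report.unadjusted["svi"].or_point == pytest.approx(1.34, abs=0.01)
        assert report.unadjusted["svi"].ci95 == pytest.approx((1.01, 1.77), abs=0.01)

    def test_missing_svi_excluded_and_reported(self, fixture_cohort):
        encounters, flags = fixture_cohort
        report = disparity_report(build_partition(flags), encounters)
        assert report.n_missing_svi == 4
        assert report.adjusted["svi"].n_dropped_missing == 4

    def test_report_renders(self, fixture_cohort):
        encounters, flags = fixture_cohort
        report = disparity_report(build_partition(flags), encounters)
        text = report.to_markdown()
        assert "unadjusted OR 2.0" in text
        assert "race" in text and "svi" in text

    def test_empty_group_rejected(self):
        flags = [("e1", DomainFlags(b=True, d=True, m=True, n=True))]
        encounters = [_fixture_encounter("e1", "minoritized", 1, 0)]
        with pytest.raises(ValueError):
            disparity_report(build_partition(flags), encounters)
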