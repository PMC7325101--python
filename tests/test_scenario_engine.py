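import numpy as np
import pandas as pd
import pytest

from piburden import ArgumentError, PIPrevalenceTable
from piburden.ontology import N_AGE, N_SEX
from piburden.scenario_engine import (
    apply_accelerometer_adjustment,
    compare_scenarios,
    flat_scenario,
    percent_difference_change,
    relative_prevalence_change,
    round_to_hundred,
    who_trajectory,
)


class TestWhoTrajectory:
    p0 = np.full((N_SEX, N_AGE), 0.159)

    def test_anchor_years(self):
        scen = who_trajectory(self.p0)
        np.testing.assert_allclose(scen.trajectory[2025], 0.159 * 0.90, rtol=1e-12)
        np.testing.assert_allclose(scen.trajectory[2030], 0.159 * 0.85, rtol=1e-12)
        np.testing.assert_allclose(scen.trajectory[2016], 0.159, rtol=1e-12)

    def test_piecewise_linear_segments(self):
        """Second differences vanish within each linear segment."""
        scen = who_trajectory(self.p0)
        vals = np.array([scen.trajectory[y][0, 0] for y in range(2016, 2031)])
        d2 = np.diff(vals, n=2)
        # years 2016..2025 form one segment, 2025..2030 the other; the only
        # nonzero second difference sits at the 2025 kink (index 8)
        assert np.all(np.abs(np.delete(d2, 8)) < 1e-15)

    def test_zero_mid_reduction_flat_through_mid_year(self):
        scen = who_trajectory(self.p0, mid_reduction=0.0)
        for year in range(2016, 2026):
            np.testing.assert_allclose(scen.trajectory[year], 0.159, rtol=1e-12)

    def test_constant_before_start(self):
        scen = who_trajectory(self.p0)
        np.testing.assert_allclose(
            scen.prevalence_for_year(2010), scen.trajectory[2016]
        )

    def test_invalid_reduction(self):
        with pytest.raises(ArgumentError):
            who_trajectory(self.p0, mid_reduction=1.0)


class TestPercentArithmetic:
    @pytest.mark.parametrize(
        "increase, base, expected",
        [
            (10_300, 1_267_400, 0.8),
            (27_100, 2_586_300, 1.0),
            (1_500, 294_000, 0.5),
            (0, 12345, 0.0),
        ],
    )
    def test_percent_difference_change(self, increase, base, expected):
        assert percent_difference_change(increase, base) == expected

    def test_half_up_rounding(self):
        assert percent_difference_change(25, 1000) == 2.5
        assert percent_difference_change(245, 10000) == 2.5  # 2.45 rounds up

    @pytest.mark.parametrize(
        "p_old, p_new, expected",
        [(0.121, 0.159, 31), (0.108, 0.163, 51), (0.144, 0.166, 15), (0.2, 0.2, 0)],
    )
    def test_relative_prevalence_change(self, p_old, p_new, expected):
        assert relative_prevalence_change(p_old, p_new) == expected

    def test_invalid_bases(self):
        with pytest.raises(ArgumentError):
            percent_difference_change(10, 0)
        with pytest.raises(ArgumentError):
            relative_prevalence_change(0.0, 0.1)

    def test_round_to_hundred(self):
        assert round_to_hundred(10_251.0) == 10_300.0
        assert round_to_hundred(10_249.0) == 10_200.0
        assert round_to_hundred(50.0) == 100.0  # half-up


class TestCompareScenarios:
    def test_identical_scenarios_zero_delta(self, bundle):
        scen = flat_scenario(bundle.pi_prevalence, 2006, "b", bundle.base_year, 3)
        delta = compare_scenarios(bundle, scen, scen, 3)
        np.testing.assert_allclose(delta.increase.to_numpy(), 0.0, atol=1e-9)
        assert (delta.percent_change == 0.0).all()

    def test_higher_pi_gives_positive_increases(self, bundle):
        base = flat_scenario(bundle.pi_prevalence, 2006, "e06", bundle.base_year, 7)
        alt = flat_scenario(bundle.pi_prevalence, 2012, "e12", bundle.base_year, 7)
        delta = compare_scenarios(bundle, base, alt, 7)
        assert (delta.increase > 0).all()

    def test_antisymmetry(self, bundle):
        base = flat_scenario(bundle.pi_prevalence, 2006, "e06", bundle.base_year, 4)
        alt = flat_scenario(bundle.pi_prevalence, 2012, "e12", bundle.base_year, 4)
        fwd = compare_scenarios(bundle, base, alt, 4)
        rev = compare_scenarios(bundle, alt, base, 4)
        np.testing.assert_allclose(
            fwd.increase.to_numpy(), -rev.increase.to_numpy(), rtol=1e-10, atol=1e-9
        )

    def test_mismatched_horizon_rejected(self, bundle):
        base = flat_scenario(bundle.pi_prevalence, 2006, "b", bundle.base_year, 2)
        alt = flat_scenario(bundle.pi_prevalence, 2012, "a", bundle.base_year, 7)
        with pytest.raises(ArgumentError):
            compare_scenarios(bundle, base, alt, 7)

    def test_summary_table_rounding(self, bundle):
        base = flat_scenario(bundle.pi_prevalence, 2006, "e06", bundle.base_year, 3)
        alt = flat_scenario(bundle.pi_prevalence, 2012, "e12", bundle.base_year, 3)
        delta = compare_scenarios(bundle, base, alt, 3)
        summary = delta.summary_table()
        assert np.all(summary.base_count.to_numpy() % 100 == 0)
        assert np.all(summary.increase.to_numpy() % 100 == 0)


def _scaled_table(table: PIPrevalenceTable, factor: float) -> PIPrevalenceTable:
    d = table.data.copy()
    for col in ("prevalence", "ci_low", "ci_high"):
        d[col] = np.clip(d[col] * factor, 0.0, 1.0)
    return PIPrevalenceTable(d)


class TestAccelerometerAdjustment:
    def test_identity_substitution(self, bundle):
        table = bundle.pi_prevalence
        out = apply_accelerometer_adjustment(table, table)
        pd.testing.assert_frame_equal(
            out.data.reset_index(drop=True), table.data.reset_index(drop=True)
        )

    def test_missing_stratum_rejected(self, bundle):
        table = bundle.pi_prevalence
        partial = PIPrevalenceTable(table.data.iloc[:-1].copy())
        with pytest.raises(ArgumentError):
            apply_accelerometer_adjustment(table, partial)

    def test_uniformly_higher_prevalence_enlarges_deltas(self, bundle):
        """Protective RRs: a larger inactive population in the counterfactual
        widens every outcome delta."""
        from dataclasses import replace

        table = bundle.pi_prevalence
        adjusted = apply_accelerometer_adjustment(table, _scaled_table(table, 1.5))
        base06 = flat_scenario(table, 2006, "b", bundle.base_year, 5)
        alt12 = flat_scenario(table, 2012, "a", bundle.base_year, 5)
        d_unadj = compare_scenarios(bundle, base06, alt12, 5)

        bundle_adj = replace(bundle, pi_prevalence=adjusted)
        base06a = flat_scenario(adjusted, 2006, "b", bundle.base_year, 5)
        alt12a = flat_scenario(adjusted, 2012, "a", bundle.base_year, 5)
        d_adj = compare_scenarios(bundle_adj, base06a, alt12a, 5)
        assert (d_adj.increase > d_unadj.increase).all()
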