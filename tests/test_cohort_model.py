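import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piburden import ArgumentError, Cohort, RelativeRisk, generate_inputs
from piburden.cohort_model import (
    BridgeParams,
    CycleRates,
    HistoryParams,
    advance_year,
    age_cohort,
    rebalance_pi,
    run_simulation,
)
from piburden.ontology import AGE_BANDS, N_AGE, N_SEX, OUTCOMES
from piburden.scenario_engine import flat_scenario

from oracle import advance_cell


def zero_bridge() -> BridgeParams:
    split = np.zeros((N_SEX, N_AGE, 3))
    split[..., 1] = 1.0  # all incident CHD events are MIs
    return BridgeParams(split, np.zeros((N_SEX, N_AGE, 3)), np.zeros((N_SEX, N_AGE)))


def zero_history() -> HistoryParams:
    z = np.zeros((N_SEX, N_AGE, 3))
    return HistoryParams(z.copy(), z.copy(), z.copy(), z.copy(), z.copy())


def zero_rates(n_strata: int) -> CycleRates:
    z = np.zeros((N_SEX, N_AGE, n_strata))
    return CycleRates(z.copy(), z.copy(), z.copy(), np.zeros((N_SEX, N_AGE)))


class TestAdvanceYear:
    def test_null_dynamics(self, tiny_ontology):
        cells = Cohort.zeros(tiny_ontology)
        cells.counts[0, 0, 0, 0] = 100.0
        cells.counts[1, 2, 3, 1] = 50.0
        new, tallies = advance_year(
            cells, zero_rates(4), zero_bridge(), zero_history()
        )
        np.testing.assert_array_equal(new.counts, cells.counts)
        for outcome in OUTCOMES:
            assert tallies[outcome].sum() == 0.0

    def test_single_cell_incidence_expectation(self, tiny_ontology):
        cells = Cohort.zeros(tiny_ontology)
        cells.counts[0, 0, 0, 0] = 1000.0
        rates = zero_rates(4)
        rates.chd[0, 0, 0] = 0.02
        new, tallies = advance_year(cells, rates, zero_bridge(), zero_history())
        assert tallies["chd_incidence"][0, 0] == pytest.approx(20.0, rel=1e-12)
        assert new.counts[0, 0, 0, 1] == pytest.approx(20.0, rel=1e-12)  # survivors
        assert new.counts[0, 0, 0, 0] == pytest.approx(980.0, rel=1e-12)

    def test_matches_independent_recursion(self, tiny_ontology):
        """Vectorised engine equals a hand-coded scalar expected-value
        recursion on a 4-stratum instance populating all health states."""
        rng = np.random.default_rng(3)
        bridge = BridgeParams(
            chd_type_split=np.broadcast_to([0.1, 0.5, 0.4], (N_SEX, N_AGE, 3)).copy(),
            chd_case_fatality=np.broadcast_to([0.7, 0.12, 0.01], (N_SEX, N_AGE, 3)).copy(),
            stroke_case_fatality=np.full((N_SEX, N_AGE), 0.2),
        )
        h = lambda *vals: np.broadcast_to(np.array(vals), (N_SEX, N_AGE, 3)).copy()
        history = HistoryParams(
            chd_event_rate=h(0.04, 0.015, 0.05),
            stroke_event_rate=h(0.01, 0.03, 0.04),
            revascularization_rate=h(0.02, 0.005, 0.02),
            cvd_death_rate=h(0.012, 0.011, 0.02),
            non_cvd_death_rate=h(0.008, 0.009, 0.012),
        )
        s, a = 0, 2
        cells = Cohort.zeros(tiny_ontology)
        stratum_rates = {
            "t2d": [0.015, 0.012, 0.0, 0.0],  # diabetic strata get zero
            "chd": [0.004, 0.006, 0.009, 0.013],
            "stroke": [0.002, 0.003, 0.004, 0.006],
            "non_cvd_death": 0.005,
        }
        counts = {}
        for k in range(4):
            for j, state in enumerate(("no_cvd", "post_chd", "post_stroke", "post_both")):
                v = float(rng.uniform(10, 100))
                cells.counts[s, a, k, j] = v
                counts[(k, state)] = v
        rates = zero_rates(4)
        for name in ("t2d", "chd", "stroke"):
            getattr(rates, name)[s, a, :] = stratum_rates[name]
        rates.t2d[s, a, tiny_ontology.diabetic_mask] = 0.0
        rates.non_cvd_death[s, a] = stratum_rates["non_cvd_death"]

        new, tallies = advance_year(cells, rates, bridge, history)
        expected_counts, expected_tallies = advance_cell(
            counts, stratum_rates, bridge, history, tiny_ontology, s, a
        )
        for (k, state), val in expected_counts.items():
            j = ("no_cvd", "post_chd", "post_stroke", "post_both").index(state)
            assert new.counts[s, a, k, j] == pytest.approx(val, rel=1e-12)
        for key, val in expected_tallies.items():
            assert tallies[key][s, a] == pytest.approx(val, rel=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_conservation_and_positivity(self, seed):
        """Persons in = persons out + deaths, and no negative compartment,
        for randomized valid rates and populations."""
        from piburden.ontology import StratumOntology

        tiny_ontology = StratumOntology(
            factors={"diabetes": ("no", "yes"), "pi_status": ("active", "inactive")}
        )
        rng = np.random.default_rng(seed)
        cells = Cohort(tiny_ontology, rng.uniform(0, 1000, (N_SEX, N_AGE, 4, 4)))
        rates = CycleRates(
            rng.uniform(0, 0.05, (N_SEX, N_AGE, 4)),
            rng.uniform(0, 0.05, (N_SEX, N_AGE, 4)),
            rng.uniform(0, 0.05, (N_SEX, N_AGE, 4)),
            rng.uniform(0, 0.05, (N_SEX, N_AGE)),
        )
        rates.t2d[:, :, tiny_ontology.diabetic_mask] = 0.0
        split = rng.dirichlet([2, 2, 2], (N_SEX, N_AGE))
        bridge = BridgeParams(
            split,
            rng.uniform(0, 1, (N_SEX, N_AGE, 3)),
            rng.uniform(0, 1, (N_SEX, N_AGE)),
        )
        hist = HistoryParams(
            rng.uniform(0, 0.1, (N_SEX, N_AGE, 3)),
            rng.uniform(0, 0.1, (N_SEX, N_AGE, 3)),
            rng.uniform(0, 0.1, (N_SEX, N_AGE, 3)),
            rng.uniform(0, 0.1, (N_SEX, N_AGE, 3)),
            rng.uniform(0, 0.1, (N_SEX, N_AGE, 3)),
        )
        new, tallies = advance_year(cells, rates, bridge, hist)
        before = cells.counts.sum()
        after = new.counts.sum() + tallies["deaths_total"].sum()
        assert after == pytest.approx(before, rel=1e-9)
        assert np.all(new.counts >= 0)


class TestAgeCohort:
    def test_three_band_hand_arithmetic(self, tiny_ontology):
        cells = Cohort.zeros(tiny_ontology)
        cells.counts[0, 0, 0, 0] = 100.0
        cells.counts[0, 1, 0, 0] = 50.0
        cells.counts[0, 2, 0, 0] = 20.0
        # put the third value in the top band to check the exit stream
        cells.counts[0, 5, 0, 0] = 20.0
        cells.counts[0, 2, 0, 0] = 0.0
        aged, exits = age_cohort(cells)
        assert aged.counts[0, 0, 0, 0] == pytest.approx(90.0)
        assert aged.counts[0, 1, 0, 0] == pytest.approx(55.0)
        assert aged.counts[0, 2, 0, 0] == pytest.approx(5.0)
        assert aged.counts[0, 5, 0, 0] == pytest.approx(18.0)
        assert exits[0] == pytest.approx(2.0)
        # conservation minus top-band exits
        assert aged.counts.sum() + exits.sum() == pytest.approx(cells.counts.sum())

    def test_empty_cohort_identity(self, tiny_ontology):
        aged, exits = age_cohort(Cohort.zeros(tiny_ontology))
        assert aged.counts.sum() == 0.0 and exits.sum() == 0.0


class TestRebalancePI:
    def test_fixed_point(self, bundle):
        cohort = bundle.initial_cohort()
        share = cohort.inactive_share()
        out = rebalance_pi(cohort, share)
        np.testing.assert_allclose(out.counts, cohort.counts, rtol=1e-12)

    def test_target_zero_empties_inactive_strata(self, bundle):
        cohort = bundle.initial_cohort()
        out = rebalance_pi(cohort, np.zeros((N_SEX, N_AGE)))
        inact = bundle.ontology.inactive_mask
        assert out.counts[:, :, inact, :].sum() == 0.0
        assert out.counts.sum() == pytest.approx(cohort.counts.sum(), rel=1e-12)

    def test_hand_computed_target(self, tiny_ontology):
        cells = Cohort.zeros(tiny_ontology)
        # 200 persons in one band, 12.1% inactive
        inact = tiny_ontology.inactive_mask
        act_idx = np.flatnonzero(~inact)
        in_idx = np.flatnonzero(inact)
        cells.counts[0, 0, act_idx[0], 0] = 200 * 0.879
        cells.counts[0, 0, in_idx[0], 0] = 200 * 0.121
        target = np.full((N_SEX, N_AGE), np.nan)
        target[0, 0] = 0.159
        out = rebalance_pi(cells, target)
        assert out.counts[0, 0, inact, :].sum() == pytest.approx(31.8, rel=1e-12)
        assert out.counts.sum() == pytest.approx(200.0, rel=1e-12)

    def test_non_pi_marginals_preserved(self, bundle):
        cohort = bundle.initial_cohort()
        target = np.full((N_SEX, N_AGE), 0.3)
        out = rebalance_pi(cohort, target)
        tab = bundle.ontology.table()
        for factor in ("smoking", "diabetes", "bmi_band"):
            for level in bundle.ontology.factors[factor]:
                mask = (tab[factor] == level).to_numpy()
                before = cohort.counts[:, :, mask, :].sum(axis=(2, 3))
                after = out.counts[:, :, mask, :].sum(axis=(2, 3))
                np.testing.assert_allclose(after, before, rtol=1e-9)
        np.testing.assert_allclose(out.inactive_share(), 0.3, atol=1e-12)

    def test_invalid_target_rejected(self, bundle):
        with pytest.raises(ArgumentError):
            rebalance_pi(bundle.initial_cohort(), np.full((N_SEX, N_AGE), 1.5))


class TestRunSimulation:
    def test_deterministic(self, bundle):
        scen = flat_scenario(bundle.pi_prevalence, 2006, "b", bundle.base_year, 3)
        r1 = run_simulation(bundle, scen, 3)
        r2 = run_simulation(bundle, scen, 3)
        np.testing.assert_array_equal(r1.counts, r2.counts)

    def test_horizon_one_equals_manual_composition(self, bundle):
        from piburden.cohort_model import build_cycle_rates

        scen = flat_scenario(bundle.pi_prevalence, 2012, "alt", bundle.base_year, 1)
        result = run_simulation(bundle, scen, 1)

        cohort = bundle.initial_cohort()
        p_ref = cohort.inactive_share()
        rates = build_cycle_rates(
            bundle.base_rates, bundle.relative_risks, p_ref, bundle.ontology
        )
        cohort = rebalance_pi(cohort, scen.prevalence_for_year(bundle.base_year))
        cohort, tallies = advance_year(
            cohort, rates, bundle.bridge_params, bundle.history_params
        )
        for i, outcome in enumerate(OUTCOMES):
            np.testing.assert_allclose(result.counts[i, 0], tallies[outcome], rtol=1e-12)

    def test_short_trajectory_rejected(self, bundle):
        scen = flat_scenario(bundle.pi_prevalence, 2006, "b", bundle.base_year, 2)
        with pytest.raises(ArgumentError):
            run_simulation(bundle, scen, 5)

    def test_higher_pi_trajectory_increases_every_outcome_yearly(self, bundle):
        """With protective RRs (< 1), the cumulative count of every outcome
        under the higher-PI trajectory dominates the status quo each year."""
        base = flat_scenario(bundle.pi_prevalence, 2006, "lo", bundle.base_year, 7)
        alt = flat_scenario(bundle.pi_prevalence, 2012, "hi", bundle.base_year, 7)
        r_lo = run_simulation(bundle, base, 7)
        r_hi = run_simulation(bundle, alt, 7)
        cum_lo = r_lo.counts[:, :, :, :3].sum(axis=(2, 3)).cumsum(axis=1)
        cum_hi = r_hi.counts[:, :, :, :3].sum(axis=(2, 3)).cumsum(axis=1)
        assert np.all(cum_hi >= cum_lo * (1 - 1e-12))
        assert np.all(cum_hi[:, -1] > cum_lo[:, -1])

    def test_rr_one_makes_pi_trajectory_irrelevant(self, bundle):
        """With all RRs forced to 1, scenarios differing only in the PI
        trajectory produce identical results."""
        from dataclasses import replace

        neutral = replace(
            bundle,
            relative_risks=[
                RelativeRisk(o, "both", 1.0) for o in ("t2d", "chd", "stroke")
            ],
        )
        base = flat_scenario(bundle.pi_prevalence, 2006, "lo", bundle.base_year, 5)
        alt = flat_scenario(bundle.pi_prevalence, 2012, "hi", bundle.base_year, 5)
        r1 = run_simulation(neutral, base, 5)
        r2 = run_simulation(neutral, alt, 5)
        np.testing.assert_allclose(r1.counts, r2.counts, rtol=1e-10, atol=1e-12)

    def test_cumulative_totals_equal_sum_of_years(self, bundle):
        scen = flat_scenario(bundle.pi_prevalence, 2006, "b", bundle.base_year, 4)
        res = run_simulation(bundle, scen, 4)
        cum = res.cumulative()
        manual = res.counts[:, :, :, :3].sum(axis=(1, 2, 3))
        np.testing.assert_allclose(cum.to_numpy(), manual, rtol=1e-12)
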