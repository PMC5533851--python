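"""Transition-matrix construction, mortality layer and the cohort engine."""

import math
from dataclasses import replace

import numpy as np
import pytest

from diabcea import (
    GlucoseState,
    InterventionEffect,
    MortalityTable,
    ScenarioConfig,
    build_transition_matrix,
    expected_covariates,
    mortality_probability,
    run_cohort,
)
from diabcea.risk import CATEGORICAL_FACTORS

from conftest import make_unit_utilities, make_zero_costs

ZERO_COV = {f: 0.0 for f in ("sex", "age", *CATEGORICAL_FACTORS)}


class TestMortalityTable:
    def test_validation(self):
        with pytest.raises(ValueError, match="contiguous"):
            MortalityTable(bands=((0, 50, 0.01, 0.0), (60, 100, 0.02, 0.0)))
        with pytest.raises(ValueError, match="exceeds all-cause"):
            MortalityTable(bands=((0, 100, 0.01, 0.02),))

    def test_lookup_and_bounds(self, params):
        q30 = params.mortality.lookup(32.0)
        q80 = params.mortality.lookup(82.0)
        assert 0 < q30[0] < q80[0] <= 1
        with pytest.raises(ValueError, match="outside"):
            params.mortality.lookup(500.0)

    def test_csv_round_trip(self, params, tmp_path):
        path = tmp_path / "mortality.csv"
        params.mortality.to_csv(path)
        assert MortalityTable.from_csv(path) == params.mortality


class TestMortalityProbability:
    def test_no_t2d_deaths_means_uniform_risk(self, flat_mortality):
        probs = {
            s: mortality_probability(flat_mortality, 40, s)
            for s in GlucoseState
            if s is not GlucoseState.DEAD
        }
        assert set(probs.values()) == {0.01}

    def test_excess_loads_on_t2d_state(self):
        table = MortalityTable(bands=((0, 120, 0.010, 0.001),))
        non_t2d = mortality_probability(table, 50, GlucoseState.NGT, t2d_prevalence=0.061)
        t2d = mortality_probability(table, 50, GlucoseState.T2D, t2d_prevalence=0.061)
        assert non_t2d == pytest.approx(0.009)
        assert t2d == pytest.approx(0.009 + 0.001 / 0.061)

    def test_clamped_to_one(self):
        table = MortalityTable(bands=((0, 120, 0.9, 0.5),))
        assert mortality_probability(table, 50, GlucoseState.T2D, t2d_prevalence=0.01) == 1.0

    def test_dead_state(self, flat_mortality):
        assert mortality_probability(flat_mortality, 40, GlucoseState.DEAD) == 1.0


class TestTransitionMatrix:
    def test_dead_row_absorbing(self, params):
        cov = expected_covariates(params.baseline_profile("male", 50), params.coding)
        M = build_transition_matrix(cov, params.equations, params.mortality, 50)
        np.testing.assert_array_equal(M[GlucoseState.DEAD], [0, 0, 0, 0, 0, 1])

    def test_ngt_row_at_zero_covariates_no_mortality(self, params, zero_mortality):
        M = build_transition_matrix(ZERO_COV, params.equations, zero_mortality, 40)
        row = M[GlucoseState.NGT]
        expit = lambda x: 1 / (1 + math.exp(-x))
        assert row[GlucoseState.IFG] == pytest.approx(expit(-3.07), abs=1e-12)
        assert row[GlucoseState.IGT] == pytest.approx(expit(-7.29), abs=1e-12)
        assert row[GlucoseState.IFG_IGT] == pytest.approx(expit(-6.20), abs=1e-12)
        assert row[GlucoseState.T2D] == 0.0  # not possible within one year
        assert row[GlucoseState.NGT] == pytest.approx(
            1 - expit(-3.07) - expit(-7.29) - expit(-6.20)
        )

    def test_structural_zeros_between_prediabetic_states(self, params):
        cov = expected_covariates(params.baseline_profile("female", 30), params.coding)
        M = build_transition_matrix(cov, params.equations, params.mortality, 30)
        pre = [GlucoseState.IFG, GlucoseState.IGT, GlucoseState.IFG_IGT]
        for a in pre:
            for b in pre:
                if a != b:
                    assert M[a, b] == 0.0
        assert M[GlucoseState.NGT, GlucoseState.T2D] == 0.0

    def test_disable_t2d_reversion_forces_row(self, params, flat_mortality):
        cov = expected_covariates(params.baseline_profile("male", 50), params.coding)
        M = build_transition_matrix(
            cov, params.equations, flat_mortality, 50, disable_t2d_reversion=True
        )
        row = M[GlucoseState.T2D]
        np.testing.assert_allclose(row, [0, 0, 0, 0, 0.99, 0.01], atol=1e-12)

    def test_competing_exit_overflow_reports_row(self, params, zero_mortality):
        eqs = [replace(e, intercept=e.intercept + 5.0) for e in params.equations]
        with pytest.raises(ValueError, match=r"out of state \w+ sum to"):
            build_transition_matrix(ZERO_COV, eqs, zero_mortality, 40)

    def test_rows_stochastic_at_baseline(self, params):
        for sex in ("male", "female"):
            for age in (30.0, 55.0, 90.0):
                cov = expected_covariates(params.baseline_profile(sex, age), params.coding)
                M = build_transition_matrix(cov, params.equations, params.mortality, age)
                np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-9)
                assert (M >= 0).all() and (M <= 1).all()


class TestRunCohort:
    def test_degenerate_horizon_accrues_one_cycle(self, params):
        config = ScenarioConfig(sex="male", start_age=50, horizon_age=50)
        trace = run_cohort(config, params)
        assert len(trace.ages) == 1
        # starting distribution entirely in pre-diabetic states, cost 3853.30 each
        assert trace.total_cost == pytest.approx(3853.30, abs=0.01)

    def test_identity_dynamics_with_zero_transitions(self, params, zero_mortality):
        frozen = replace(
            params,
            equations=[replace(e, intercept=-1e3) for e in params.equations],
            mortality=zero_mortality,
        )
        trace = run_cohort(ScenarioConfig(sex="male", start_age=30, horizon_age=80), frozen)
        np.testing.assert_array_equal(trace.occupancy, np.tile(trace.occupancy[0], (51, 1)))

    def test_occupancy_conserved_and_death_monotone(self, params):
        for arm in ("control", "intervention"):
            trace = run_cohort(ScenarioConfig(sex="female", start_age=30, arm=arm), params)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            dead = trace.occupancy[:, GlucoseState.DEAD]
            assert (np.diff(dead) >= -1e-12).all()
            # lifetime horizon: well under 1% of the cohort alive at the stop age
            assert trace.occupancy[-1, :5].sum() < 0.005

    def test_two_state_geometric_closed_form(self, params, zero_mortality):
        """One living state, constant hazard, unit reward: matches Σ ((1-q)/(1+d))^t."""
        q, d = 0.04, 0.03
        reduced = replace(
            params,
            equations=[replace(e, intercept=-1e3) for e in params.equations],
            mortality=MortalityTable(bands=((0.0, 120.0, q, 0.0),)),
            utilities=make_unit_utilities(),
            costs=make_zero_costs(),
        )
        config = ScenarioConfig(
            sex="male",
            start_age=30,
            horizon_age=105,
            discount_rate=d,
            starting_distribution={GlucoseState.IFG: 1.0},
        )
        trace = run_cohort(config, reduced)
        n = len(trace.ages)
        x = (1 - q) / (1 + d)
        closed_form = (1 - x**n) / (1 - x)
        assert trace.total_qaly == pytest.approx(closed_form, abs=1e-9)

    def test_null_intervention_differs_only_by_programme_cost(self, params):
        null = params.with_effect(
            InterventionEffect(
                weight_reduction_fraction=0.0, pa_target=None, nutrition_target=None
            )
        )
        # female rows of the utility table are identical across arms
        base = ScenarioConfig(sex="female", start_age=50)
        control = run_cohort(replace(base, arm="control"), null)
        intervention = run_cohort(replace(base, arm="intervention"), null)
        np.testing.assert_array_equal(control.occupancy, intervention.occupancy)
        np.testing.assert_array_equal(control.qaly_discounted, intervention.qaly_discounted)
        extra = intervention.cost - control.cost
        living = control.occupancy[:, :5].sum(axis=1)
        expected = [params.costs.intervention_cost(t) * living[t] for t in range(len(living))]
        np.testing.assert_allclose(extra, expected, atol=1e-9)
        assert intervention.total_cost > control.total_cost

    def test_small_microsimulation_agreement(self, params):
        """Cohort occupancy matches an individual-level simulation with shared matrices."""
        occupancy, empirical, n = _microsimulate(params, n_individuals=20_000, n_cycles=6, seed=5)
        se = np.sqrt(occupancy * (1 - occupancy) / n)
        assert (np.abs(empirical - occupancy) <= 3 * se + 1e-12).all()


def _microsimulate(params, n_individuals, n_cycles, seed, sex="male", start_age=30.0):
    """Independent oracle: simulate individuals through the same per-cycle matrices."""
    config = ScenarioConfig(
        sex=sex, start_age=start_age, horizon_age=start_age + n_cycles - 1
    )
    trace = run_cohort(config, params)

    rng = np.random.default_rng(seed)
    start = params.starting_distribution
    p0 = np.zeros(6)
    for s, share in start.items():
        p0[s] = share
    states = rng.choice(6, size=n_individuals, p=p0)
    empirical = np.zeros((n_cycles, 6))
    baseline = params.baseline_profile(sex, start_age)
    for t in range(n_cycles):
        age = start_age + t
        empirical[t] = np.bincount(states, minlength=6) / n_individuals
        if t < n_cycles - 1:
            cov = expected_covariates(baseline.with_age(age), params.coding)
            M = build_transition_matrix(
                cov, params.equations, params.mortality, age,
                t2d_prevalence=params.t2d_prevalence,
            )
            new = states.copy()
            for s in range(6):
                idx = states == s
                if idx.any():
                    new[idx] = rng.choice(6, size=int(idx.sum()), p=M[s])
            states = new
    return trace.occupancy, empirical, n_individuals
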