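"""Microsimulation oracle and randomized fixture generator."""

import numpy as np
import pytest

from chwcea import (
    HealthState,
    ModelConfig,
    ParameterError,
    build_transition_matrix,
    run_cohort,
)
from chwcea.engine import AdherenceDynamics, D
from chwcea.microsim import (
    cross_validate,
    generate_fixture,
    records_to_frame,
    simulate_individuals,
    summarize,
)
from chwcea.scenarios import run_arm

from conftest import assert_occupancy_valid


@pytest.fixture(scope="module")
def intervention(params):
    return ModelConfig().scenarios()[1]


class TestSimulate:
    def test_zero_individuals(self, params, intervention):
        assert simulate_individuals(intervention, params.rates, "male", 3, 0, seed=1) == []

    def test_seed_determinism(self, params, intervention):
        kwargs = dict(utilities=params.utilities, cost_model=params.costs, horizon=30)
        r1 = simulate_individuals(intervention, params.rates, "male", 3, 20, 7, **kwargs)
        r2 = simulate_individuals(intervention, params.rates, "male", 3, 20, 7, **kwargs)
        assert r1 == r2

    def test_growing_n_extends_sample_without_reshuffling(self, params, intervention):
        small = simulate_individuals(intervention, params.rates, "male", 3, 10, 7)
        large = simulate_individuals(intervention, params.rates, "male", 3, 30, 7)
        assert large[:10] == small

    def test_negative_n_rejected(self, params, intervention):
        with pytest.raises(ParameterError):
            simulate_individuals(intervention, params.rates, "male", 3, -1, 1)

    def test_death_is_absorbing_and_entry_states_valid(self, params, intervention):
        records = simulate_individuals(
            intervention, params.rates, "female", 3, 200, 11, horizon=60
        )
        for rec in records:
            assert rec.state_sequence[0] in (
                HealthState.NONADHERENT, HealthState.ADHERENT,
            )
            seq = rec.state_sequence
            died = [i for i, s in enumerate(seq) if s is HealthState.DEATH]
            if died:
                assert all(s is HealthState.DEATH for s in seq[died[0]:])

    def test_certain_death_yields_one_cycle_of_entry_utility(self, params, intervention):
        """With all mortality forced to 1 everyone dies after one cycle and
        accrues exactly the entry state's utility."""
        import dataclasses

        from chwcea.params import AgeBand, BandTable, Sex

        flat = lambda name, v: BandTable(name, ((AgeBand(0, None), v),))
        lethal = dataclasses.replace(
            params.rates,
            mortality_nonadherent=flat("mn", 1.0),
            mortality_adherent=flat("ma", 1.0),
            remission={s: flat("rem", 0.0) for s in Sex},
            background_mortality={s: flat("bg", 1.0) for s in Sex},
        )
        records = simulate_individuals(
            dataclasses.replace(intervention, prob_b_to_a=0.0),
            lethal, "male", 3, 50, 3, utilities=params.utilities, horizon=10,
        )
        u = params.utilities
        for rec in records:
            assert all(s is HealthState.DEATH for s in rec.state_sequence[1:])
            assert rec.qalys == pytest.approx(u.of(rec.state_sequence[0]))

    def test_long_format_export(self, params, intervention):
        records = simulate_individuals(intervention, params.rates, "male", 3, 4, 2, horizon=5)
        df = records_to_frame(records)
        assert len(df) == 4 * 6
        assert set(df["state"]) <= {"A", "B", "C", "D"}


class TestSummarize:
    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            summarize([])

    def test_mean_and_se(self, params, intervention):
        records = simulate_individuals(
            intervention, params.rates, "male", 3, 2, 5,
            utilities=params.utilities, horizon=40,
        )
        import dataclasses

        fixed = [dataclasses.replace(r, qalys=q) for r, q in zip(records, (1.0, 3.0))]
        s = summarize(fixed)
        assert s.mean_qalys == pytest.approx(2.0)
        assert s.se_qalys == pytest.approx(np.std([1, 3], ddof=1) / np.sqrt(2))
        identical = [dataclasses.replace(r, qalys=2.0) for r in records]
        assert summarize(identical).se_qalys == 0.0


class TestCrossValidate:
    def test_perturbed_mean_fails(self, params, intervention):
        cfg = ModelConfig()
        traj, outcome = run_arm(intervention, params, "male", cfg.entry_age, 50, warn=False)
        records = simulate_individuals(
            intervention, params.rates, "male", cfg.entry_age, 400, 1,
            utilities=params.utilities, cost_model=params.costs, horizon=50,
        )
        summary = summarize(records)
        ok = cross_validate(traj, outcome, summary, z=3.0)
        assert ok["checks"]["lifetime_qalys"]["pass"]
        import dataclasses

        shifted = dataclasses.replace(
            summary, mean_qalys=summary.mean_qalys + 10 * max(summary.se_qalys, 1e-9)
        )
        bad = cross_validate(traj, outcome, shifted, z=3.0)
        assert not bad["checks"]["lifetime_qalys"]["pass"]
        assert not bad["pass"]

    def test_mismatched_horizon_rejected(self, params, intervention):
        traj, outcome = run_arm(intervention, params, "male", 3, 50, warn=False)
        records = simulate_individuals(
            intervention, params.rates, "male", 3, 50, 1, horizon=40
        )
        with pytest.raises(ParameterError, match="mismatch"):
            cross_validate(traj, outcome, summarize(records), z=3.0)

    def test_convergence_rate(self, params, intervention):
        """Monte-Carlo error of the occupancy estimate shrinks ~1/sqrt(n)."""
        cfg = ModelConfig()
        traj, _ = run_arm(intervention, params, "male", cfg.entry_age, 40, warn=False)
        errs = []
        for n in (100, 1000, 10000):
            records = simulate_individuals(
                intervention, params.rates, "male", cfg.entry_age, n, 1, horizon=40
            )
            occ = summarize(records).occupancy
            errs.append(np.abs(occ - traj.occupancy).mean())
        assert errs[2] < errs[0]
        # an order of magnitude more samples buys roughly sqrt(10) ~ 3x accuracy
        assert errs[2] < errs[0] / 2


class TestGenerateFixture:
    @pytest.mark.parametrize("seed", range(5))
    def test_fixtures_valid_and_deterministic(self, seed):
        rates1, utilities, costs = generate_fixture(seed, bands=5)
        rates2, _, _ = generate_fixture(seed, bands=5)
        assert rates1 == rates2
        rates1.validate()
        utilities.validate()
        costs.validate()

    def test_ordering_constraints_enforced(self):
        for seed in range(10):
            rates, utilities, _ = generate_fixture(seed, ordering_constraints=True)
            for (_, m_non), (_, m_adh) in zip(
                rates.mortality_nonadherent.entries, rates.mortality_adherent.entries
            ):
                assert m_non >= m_adh
            assert utilities.remission > utilities.adherent > utilities.nonadherent

    def test_random_fixture_cohorts_conserve_mass(self):
        for seed in range(20):
            rates, _, _ = generate_fixture(seed)
            dyn = AdherenceDynamics.constant(0.2, 0.1)
            traj = run_cohort(rates, dyn, 0, "male", [0.5, 0.5, 0, 0], horizon=30)
            assert_occupancy_valid(traj.occupancy)
            assert np.all(np.diff(traj.occupancy[:, D]) >= -1e-12)
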