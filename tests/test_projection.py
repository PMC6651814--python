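import numpy as np
import pytest

from lodsim import (
    IncidenceCurve,
    build_architecture,
    build_population,
    discover,
    fixtures,
    hr_grid,
    onset_delay_slope,
    project_fixed_hr,
    project_population,
    years_to_regain_baseline,
)
from lodsim.agingcoef import AgingCoefficient
from lodsim.demography import LifeTable
from lodsim.projection import BeyondHorizon
from lodsim.therapy import TherapySpec, apply_therapy


def _immortal(n_ages):
    return LifeTable.from_q(np.zeros(n_ages))


def _flat_A(p, n_ages, key=None):
    meta = {"normalization_key": key} if key else {}
    return AgingCoefficient(ages=np.arange(n_ages), A=np.full(n_ages, p), meta=meta)


class TestProjectPopulation:
    def test_two_year_hand_computation(self, homogeneous_pop):
        A = _flat_A(0.1, 2, key="homogeneous")
        res = project_population(A, homogeneous_pop, _immortal(2))
        assert res.density == pytest.approx([0.1, 0.09], abs=1e-12)
        assert res.lifetime_risk == pytest.approx(0.19, abs=1e-12)

    def test_zero_incidence_gives_zero_risk(self, homogeneous_pop, life_table):
        A = _flat_A(0.0, 120, key="homogeneous")
        res = project_population(A, homogeneous_pop, life_table)
        assert np.all(res.density == 0.0)
        assert res.lifetime_risk == 0.0

    def test_no_contribution_after_cohort_extinction(self, homogeneous_pop):
        q = np.zeros(10)
        q[4] = 1.0  # everyone dies in year 4
        lt = LifeTable.from_q(q)
        A = _flat_A(0.1, 10, key="homogeneous")
        res = project_population(A, homogeneous_pop, lt)
        assert np.all(res.density[5:] == 0.0)
        assert np.all(res.density[:5] > 0.0)

    def test_reproduces_incidence_density_identity(self, pop400, cancer_curve, life_table):
        # D(t) = I(t) * disease-free fraction * S(t) when projecting the
        # discovery population with the discovery incidence
        A = discover(cancer_curve, pop400)
        res = project_population(A, pop400, life_table)
        I = cancer_curve.values(np.arange(120))
        free = np.concatenate([[1.0], np.cumprod(1 - I)[:-1]])
        expected = I * free * life_table.S
        assert np.allclose(res.density, expected, rtol=1e-10, atol=1e-15)

    def test_bookkeeping_invariants(self, pop400, cancer_curve, life_table):
        A = discover(cancer_curve, pop400)
        res = project_population(A, pop400, life_table)
        assert np.allclose(res.cumulative, np.cumsum(res.density), atol=0)
        assert np.all(np.diff(res.cumulative) >= 0)
        assert res.lifetime_risk <= 1.0

    def test_unpaired_population_rejected(self, pop400, cancer_curve, life_table):
        A = discover(cancer_curve, pop400)
        other = build_population(build_architecture("common_low", 100))
        with pytest.raises(ValueError, match="not normalized against"):
            project_population(A, other, life_table)


class TestProjectFixedHR:
    def test_zero_hazard_ratio(self, life_table):
        A = _flat_A(0.1, 120)
        assert project_fixed_hr(A, 0.0, life_table).lifetime_risk == 0.0

    def test_two_year_hand_computation(self):
        A = _flat_A(0.1, 2)
        res = project_fixed_hr(A, 1.0, _immortal(2))
        assert res.lifetime_risk == pytest.approx(0.19, abs=1e-12)

    def test_halving_in_proportional_regime(self, pop400, low_risk_cancer_curve, life_table):
        A = discover(low_risk_cancer_curve, pop400)
        lr1 = project_fixed_hr(A, 1.0, life_table).lifetime_risk
        lr05 = project_fixed_hr(A, 0.5, life_table).lifetime_risk
        assert lr05 / lr1 == pytest.approx(0.5, rel=0.02)

    def test_proportionality_degrades_with_risk_level(self, life_table):
        # halving deviation grows monotonically as absolute risk rises
        pop = build_population(build_architecture("common_low", 3575))
        A = discover(fixtures.fixture_incidence("ad_like"), pop)

        def dev(hr):
            hi = project_fixed_hr(A, hr, life_table).lifetime_risk
            lo = project_fixed_hr(A, hr / 2, life_table).lifetime_risk
            return abs(lo / hi - 0.5)

        devs = [dev(h) for h in (0.25, 1.0, 4.0)]
        assert devs[0] < devs[1] < devs[2]


class TestHRGrid:
    def test_single_cell_matches_fixed_hr(self, pop400, cancer_curve, life_table):
        A = discover(cancer_curve, pop400)
        grid = hr_grid(A, life_table, hrs=[1.0], deltas=[0])
        assert grid.loc[1.0, "+0y"] == project_fixed_hr(A, 1.0, life_table).lifetime_risk

    def test_monotone_in_hr_and_delta(self, pop400, cancer_curve, life_table):
        A = discover(cancer_curve, pop400)
        grid = hr_grid(A, life_table)
        # rows ordered by descending hr: each column non-increasing downwards
        assert np.all(np.diff(grid.to_numpy(), axis=0) <= 1e-15)
        # each row non-decreasing across increasing delta
        assert np.all(np.diff(grid.to_numpy(), axis=1) >= -1e-15)


class TestOnsetDelay:
    def test_identical_results_give_zero(self, pop400, cancer_curve, life_table):
        A = discover(cancer_curve, pop400)
        res = project_fixed_hr(A, 1.0, life_table)
        assert onset_delay_slope(res, res) == 0

    def test_geometric_oracle_constant_hazard(self):
        # immortal cohort, constant p: C(t) = 1 - (1-p)^t, lifetime ~ 1, so
        # the 30% threshold age is ln(0.7)/ln(1-p); halving p doubles it and
        # the delay is about the baseline threshold age itself
        n = 400
        A = _flat_A(0.05, n)
        lt = _immortal(n)
        base = project_fixed_hr(A, 1.0, lt)
        half = project_fixed_hr(A, 0.5, lt)
        t30 = np.log(0.7) / np.log(0.95)
        t30_half = np.log(0.7) / np.log(0.975)
        delay = onset_delay_slope(base, half)
        assert delay == pytest.approx(t30_half - t30, abs=1.0)
        assert delay == pytest.approx(t30, abs=1.5)

    def test_delays_add_across_chained_reductions(self, pop400, cancer_curve, life_table):
        A = discover(cancer_curve, pop400)
        r16 = project_fixed_hr(A, 16.0, life_table)
        r4 = project_fixed_hr(A, 4.0, life_table)
        r1 = project_fixed_hr(A, 1.0, life_table)
        total = onset_delay_slope(r16, r1)
        chained = onset_delay_slope(r16, r4) + onset_delay_slope(r4, r1)
        assert abs(total - chained) <= 1

    def test_unreachable_threshold_signals_beyond_horizon(self, life_table):
        A = _flat_A(0.0, 120)
        res = project_fixed_hr(A, 1.0, life_table)
        with pytest.raises(BeyondHorizon):
            res.age_at_cumulative_fraction(0.3)


class TestRegainBaseline:
    def test_untreated_population_regains_immediately(self, pop400, cancer_curve, life_table):
        A = discover(cancer_curve, pop400)
        assert years_to_regain_baseline(A, pop400, pop400, life_table) == 0

    def test_low_risk_disease_stays_below_baseline(self, pop400, cancer_curve, life_table):
        arch = build_architecture("common_low", 400)
        A = discover(cancer_curve, pop400)
        treated = apply_therapy(pop400, TherapySpec(or_multiplier=0.25), arch)
        result = years_to_regain_baseline(A, pop400, treated, life_table)
        assert result is None or result > 15

    def test_steep_high_risk_disease_regains_quickly(self, life_table):
        arch = build_architecture("common_low", 3575)
        pop = build_population(arch)
        A = discover(fixtures.fixture_incidence("ad_like"), pop)
        treated = apply_therapy(pop, TherapySpec(or_multiplier=0.25), arch)
        result = years_to_regain_baseline(A, pop, treated, life_table)
        assert result is not None and 1 <= result <= 5
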