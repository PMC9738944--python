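import numpy as np
import pytest

import carbonscape as cs
from carbonscape.markov_demand import DemandVector


@pytest.fixture(scope="module")
def projection_inputs(small_fixture):
    """Suitability + demand artifacts fitted once on the shared fixture."""
    t0, t1, drivers, _ = small_fixture
    samples = {
        k: cs.extract_expansion(t0, t1, k, sampling_rate=1.0, seed=0)
        for k in t0.class_codes
    }
    valid = t0.valid_mask & t1.valid_mask
    suitability = cs.fit_suitability(samples, drivers, valid, seed=0)
    counts = cs.transition_matrix(t0, t1)
    dw = cs.expansion_share_weights(counts)
    return suitability, dw


def demand_from_map(cmap):
    counts = cmap.class_counts()
    return DemandVector(
        areas_km2={c: n * cmap.cell_area for c, n in counts.items()},
        cells=counts,
        horizon_steps=1,
    )


class TestNeighborhoodEffect:
    def test_fully_surrounded_interior_cell(self):
        grid = np.full((5, 5), 2)
        grid[2, 2] = 1
        m = cs.ClassMap(grid=grid)
        assert cs.neighborhood_effect(m, 2)[2, 2] == 1.0

    def test_isolated_cell_sees_no_own_class(self):
        grid = np.full((5, 5), 2)
        grid[2, 2] = 1
        m = cs.ClassMap(grid=grid)
        assert cs.neighborhood_effect(m, 1)[2, 2] == 0.0

    def test_hand_enumerated_three_of_eight(self):
        grid = np.array([[2, 1, 2], [1, 3, 2], [2, 2, 1]])
        m = cs.ClassMap(grid=grid)
        assert cs.neighborhood_effect(m, 1)[1, 1] == pytest.approx(3 / 8)

    def test_corner_uses_truncated_window(self):
        grid = np.array([[1, 2], [2, 2]])
        m = cs.ClassMap(grid=grid)
        # corner (0,0) has 3 neighbors, all class 2
        assert cs.neighborhood_effect(m, 2)[0, 0] == 1.0

    def test_nodata_excluded_from_both_sides(self):
        grid = np.array([[0, 2, 0], [0, 1, 0], [0, 2, 0]])
        m = cs.ClassMap(grid=grid)
        # only 2 valid neighbors, both class 2
        assert cs.neighborhood_effect(m, 2)[1, 1] == 1.0

    def test_even_window_rejected(self, toy_map):
        with pytest.raises(ValueError, match="odd"):
            cs.neighborhood_effect(toy_map, 1, window=4)


class TestSimulate:
    def test_null_demand_changes_nothing(self, small_fixture, projection_inputs):
        t0, *_ = small_fixture
        suitability, dw = projection_inputs
        cfg = cs.CAConfig(domain_weights=dw, rng_seed=1)
        res = cs.simulate(t0, suitability, demand_from_map(t0), cfg)
        np.testing.assert_array_equal(res.final_map.grid, t0.grid)
        assert res.converged

    def test_demand_satisfied_exactly(self, small_fixture, projection_inputs):
        t0, t1, *_ = small_fixture
        suitability, dw = projection_inputs
        cfg = cs.CAConfig(domain_weights=dw, rng_seed=2)
        res = cs.simulate(t0, suitability, demand_from_map(t1), cfg)
        assert res.converged
        assert res.achieved == res.demanded == t1.class_counts()

    def test_frozen_classes_stay_bit_identical(self, small_fixture, projection_inputs):
        t0, t1, *_ = small_fixture
        suitability, dw = projection_inputs
        allowed = np.ones((6, 6), dtype=int)
        allowed[3] = 0  # water never converts out
        allowed[4] = 0  # settlement never converts out
        allowed[3, 3] = allowed[4, 4] = 1
        cfg = cs.CAConfig(domain_weights=dw, allowed=allowed, rng_seed=3)
        res = cs.simulate(t0, suitability, demand_from_map(t1), cfg)
        for frozen in (4, 5):
            was = t0.grid == frozen
            assert (res.final_map.grid[was] == frozen).all()
        # and no realized transition violates the mask anywhere
        tm = cs.transition_matrix(t0, res.final_map)
        violations = tm.cell_counts() * (1 - allowed)
        assert violations.sum() == 0

    def test_cell_count_conserved_every_round(self, small_fixture, projection_inputs):
        t0, t1, *_ = small_fixture
        suitability, dw = projection_inputs
        cfg = cs.CAConfig(domain_weights=dw, rng_seed=4)
        res = cs.simulate(t0, suitability, demand_from_map(t1), cfg)
        count_cols = [c for c in res.rounds.columns if c.startswith("count_")]
        totals = res.rounds[count_cols].sum(axis=1)
        assert (totals == t0.n_valid).all()
        assert res.final_map.n_valid == t0.n_valid
        np.testing.assert_array_equal(res.final_map.valid_mask, t0.valid_mask)

    def test_seed_determinism_and_real_stochasticity(self, small_fixture, projection_inputs):
        t0, t1, *_ = small_fixture
        suitability, dw = projection_inputs
        demand = demand_from_map(t1)
        runs = {
            s: cs.simulate(
                t0, suitability, demand, cs.CAConfig(domain_weights=dw, rng_seed=s)
            )
            for s in (5, 6)
        }
        repeat = cs.simulate(
            t0, suitability, demand, cs.CAConfig(domain_weights=dw, rng_seed=5)
        )
        np.testing.assert_array_equal(runs[5].final_map.grid, repeat.final_map.grid)
        cross = cs.agreement(runs[5].final_map, runs[6].final_map)
        assert cross.kappa < 1.0

    def test_wrong_demand_total_rejected(self, small_fixture, projection_inputs):
        t0, *_ = small_fixture
        suitability, dw = projection_inputs
        bad = demand_from_map(t0)
        bad.cells[1] += 1
        cfg = cs.CAConfig(domain_weights=dw, rng_seed=0)
        with pytest.raises(ValueError, match="demand total"):
            cs.simulate(t0, suitability, bad, cfg)

    def test_infeasible_demand_names_blocked_class(self, small_fixture, projection_inputs):
        t0, *_ = small_fixture
        suitability, dw = projection_inputs
        demand = demand_from_map(t0)
        # move 10 cells of demand from farmland to settlement, but forbid
        # every conversion into settlement
        demand.cells[1] -= 10
        demand.cells[5] += 10
        allowed = np.ones((6, 6), dtype=int)
        allowed[:, 4] = 0
        np.fill_diagonal(allowed, 1)
        cfg = cs.CAConfig(domain_weights=dw, allowed=allowed, rng_seed=0)
        with pytest.raises(ValueError, match="class 5"):
            cs.simulate(t0, suitability, demand, cfg)


class TestCAConfigContracts:
    def test_even_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            cs.CAConfig(neighborhood_size=4)

    def test_coefficients_bounded(self):
        with pytest.raises(ValueError):
            cs.CAConfig(patch_decay=1.5)
        with pytest.raises(ValueError):
            cs.CAConfig(seed_fraction=-0.1)

    def test_mask_diagonal_must_allow_staying(self):
        allowed = np.ones((6, 6), dtype=int)
        allowed[2, 2] = 0
        with pytest.raises(ValueError, match="diagonal"):
            cs.CAConfig(allowed=allowed)


class TestRunProjection:
    def test_two_horizons_chain_and_satisfy_demand(self, small_fixture, density):
        t0, t1, drivers, _ = small_fixture
        cfg = cs.CAConfig(rng_seed=1)
        res = cs.run_projection(
            t0, t1, drivers, cfg, [2030, 2040],
            density=density, sampling_rate=1.0, seed=1,
        )
        for year in (2030, 2040):
            sim = res.simulations[year]
            assert sim.converged
            assert sim.achieved == res.demands[year].cells
            assert year in res.summaries
        # second horizon starts from the first simulated map
        tm = cs.transition_matrix(res.simulations[2030].final_map,
                                  res.simulations[2040].final_map)
        assert tm.total_area == t0.n_valid * t0.cell_area

    def test_settlement_expansion_monotone_across_horizons(self, small_fixture):
        t0, t1, drivers, _ = small_fixture
        cfg = cs.CAConfig(rng_seed=2)
        res = cs.run_projection(t0, t1, drivers, cfg, [2030, 2040, 2050],
                                sampling_rate=1.0, seed=2)
        # settlement only gains in the calibration decade, so its Markov row
        # is (near-)absorbing and projected demand is non-decreasing
        areas = [res.simulations[y].final_map.class_areas()[5] for y in (2030, 2040, 2050)]
        assert areas == sorted(areas)

    def test_bad_horizon_rejected(self, small_fixture):
        t0, t1, drivers, _ = small_fixture
        with pytest.raises(ValueError, match="horizon"):
            cs.run_projection(t0, t1, drivers, cs.CAConfig(), [2035], sampling_rate=1.0)
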