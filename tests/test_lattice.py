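"""Unit and property tests of the two-row lattice KMC simulator."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tmcoop.equilibrium import EquilibriumSpec, enumerate_equilibrium
from tmcoop.lattice import (
    AbsorbingStateError,
    LatticeParams,
    LatticeState,
    apply_growth,
    local_off_rate,
    local_on_rate,
    simulate,
    config_time_distribution,
    stationary_log_weight,
    step,
    time_averaged_coverage,
    total_propensity,
)


def make_state(row0, row1):
    return LatticeState(np.array([row0, row1], dtype=np.int8))


class TestLocalRates:
    def test_isolated_site_has_base_rates(self):
        params = LatticeParams(kon=2.0, koff=3.0, w=40, c=1.25)
        state = make_state([0, 0, 0], [0, 0, 0])
        assert local_on_rate(state, params, 1, 0) == pytest.approx(2.0)
        state = make_state([0, 1, 0], [0, 0, 0])
        assert local_off_rate(state, params, 1, 0) == pytest.approx(3.0)

    def test_doubly_flanked_on_rate_gains_w_squared(self):
        params = LatticeParams(kon=1.0, koff=1.0, w=40, c=1.25)
        state = make_state([1, 0, 1], [0, 0, 0])
        assert local_on_rate(state, params, 1, 0) == pytest.approx(40**2)

    def test_one_neighbor_plus_opposite(self):
        # k_on * w^1 * c^1 = 1 * 40 * 1.25 = 50
        params = LatticeParams(kon=1.0, koff=1.0, w=40, c=1.25)
        state = make_state([1, 0, 0], [0, 1, 0])
        assert local_on_rate(state, params, 1, 0) == pytest.approx(50.0)

    def test_fully_buried_off_rate(self):
        # k_off / w^2 / c = 300 / 125^2 / 1.25 = 0.01536
        params = LatticeParams(kon=1.0, koff=300.0, w=125, c=1.25)
        state = make_state([1, 1, 1], [0, 1, 0])
        assert local_off_rate(state, params, 1, 0) == pytest.approx(0.01536)

    def test_contract_violations(self):
        params = LatticeParams(kon=1.0, koff=1.0)
        state = make_state([1, 0], [0, 0])
        with pytest.raises(ValueError):
            local_on_rate(state, params, 0, 0)  # occupied
        with pytest.raises(ValueError):
            local_off_rate(state, params, 1, 0)  # empty
        with pytest.raises(IndexError):
            local_on_rate(state, params, 5, 0)

    def test_edge_sites_have_single_neighbor(self):
        params = LatticeParams(kon=1.0, koff=1.0, w=7.0)
        state = make_state([0, 1, 1, 1], [0, 0, 0, 0])
        assert local_on_rate(state, params, 0, 0) == pytest.approx(7.0)
        assert local_off_rate(state, params, 3, 0) == pytest.approx(1.0 / 7.0)


class TestPropensityAndStep:
    def test_empty_fixed_lattice_propensity(self):
        params = LatticeParams(kon=0.7, koff=9.0, w=40, c=2, v_grow=0.0)
        state = LatticeState.empty(6)
        assert total_propensity(state, params) == pytest.approx(2 * 6 * 0.7)

    def test_full_noncooperative_lattice_propensity(self):
        params = LatticeParams(kon=0.7, koff=9.0, w=1, c=1, v_grow=0.0)
        state = LatticeState.full(5)
        assert total_propensity(state, params) == pytest.approx(2 * 5 * 9.0)

    def test_waiting_times_are_exponential(self, rng):
        params = LatticeParams(kon=0.4, koff=2.0, w=3, c=1.5, v_grow=0.0)
        state = make_state([1, 0, 1], [0, 1, 0])
        R = total_propensity(state, params)
        dts = np.array([step(state, params, rng)[1] for _ in range(10_000)])
        assert stats.kstest(dts, "expon", args=(0, 1.0 / R)).pvalue > 0.01

    def test_absorbing_state_signaled(self, rng):
        params = LatticeParams(kon=0.0, koff=1.0, v_grow=0.0)
        with pytest.raises(AbsorbingStateError):
            step(LatticeState.empty(3), params, rng)


class TestGrowth:
    def test_floor_formula(self):
        state = LatticeState.empty(3)
        grown = apply_growth(state, 10.3, 2.0)
        assert grown.N == 20
        assert grown.t == 10.3

    def test_zero_growth_keeps_n(self):
        state = LatticeState.full(4)
        assert apply_growth(state, 50.0, 0.0).N == 4

    def test_new_columns_are_empty_and_n_never_decreases(self):
        state = LatticeState.full(4)
        grown = apply_growth(state, 3.0, 2.0)
        assert grown.N == 6
        assert grown.occupancy[:, :4].all()
        assert not grown.occupancy[:, 4:].any()
        # floor below current N clamps
        assert apply_growth(state, 0.5, 2.0).N == 4


class TestSimulate:
    def test_no_binding_when_kon_zero(self):
        params = LatticeParams(kon=0.0, koff=5.0, v_grow=2.0, max_time=30.0, seed=1)
        traj = simulate(params)
        assert traj.final_state.occupancy.sum() == 0
        assert traj.final_state.N == int(np.floor(traj.times[-1] * 2.0))

    def test_noncooperative_mean_occupancy_is_half(self):
        covs = [
            time_averaged_coverage(
                LatticeParams(
                    kon=1.0, koff=1.0, n0=4, max_time=3000.0, seed=100 + s
                ),
                burn_in=20.0,
            )
            for s in range(10)
        ]
        covs = np.array(covs)
        se = covs.std(ddof=1) / np.sqrt(len(covs))
        assert abs(covs.mean() - 0.5) < 3 * max(se, 1e-3)

    def test_matches_equilibrium_oracle_cooperative(self):
        spec = EquilibriumSpec(K=0.05, w=40, c=1.25, N=4)
        expected = enumerate_equilibrium(spec)
        covs = np.array(
            [
                time_averaged_coverage(
                    LatticeParams(
                        kon=0.05 * 10.0, koff=10.0, w=40, c=1.25, n0=4,
                        max_time=30000.0, seed=200 + s,
                    ),
                    burn_in=200.0,
                )
                for s in range(6)
            ]
        )
        se = covs.std(ddof=1) / np.sqrt(len(covs))
        assert abs(covs.mean() - expected) < 3 * max(se, 1e-3)

    def test_identical_seed_bit_identical_trajectory(self):
        params = LatticeParams(
            kon=0.5, koff=1.0, w=5, c=1.2, v_grow=1.5, max_time=40.0, seed=77
        )
        t1, t2 = simulate(params), simulate(params)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.codes, t2.codes)
        assert np.array_equal(t1.sites, t2.sites)
        assert np.array_equal(t1.final_state.occupancy, t2.final_state.occupancy)

    def test_event_log_replay_reproduces_final_state(self):
        params = LatticeParams(
            kon=0.5, koff=1.0, w=5, c=1.2, v_grow=1.5, max_time=40.0, seed=11
        )
        traj = simulate(params)
        replayed = traj.replay()
        assert np.array_equal(
            replayed.occupancy, traj.final_state.occupancy
        )
        assert (np.diff(traj.times) >= 0).all()

    def test_occupancy_stays_binary_and_n_monotone(self):
        params = LatticeParams(
            kon=2.0, koff=2.0, w=3, c=2, v_grow=2.0, max_time=30.0, seed=5
        )
        traj = simulate(params)
        snaps = traj.snapshots(np.linspace(0, traj.final_state.t, 7))
        lengths = [s.N for s in snaps]
        assert lengths == sorted(lengths)
        for s in snaps:
            assert set(np.unique(s.occupancy)) <= {0, 1}


class TestStationaryLaw:
    def test_detailed_balance_on_small_lattice(self):
        """Config-time frequencies converge to K^n (w^2)^p_row (c^2)^p_cross."""
        K, w, c, n = 0.8, 2.0, 1.5, 2
        params = LatticeParams(
            kon=K * 2.0, koff=2.0, w=w, c=c, n0=n, max_time=60000.0, seed=42
        )
        freq = config_time_distribution(params, burn_in=100.0)
        logpi = np.empty(4**n)
        for bits in range(4**n):
            occ = np.array(
                [[(bits >> (j * n + i)) & 1 for i in range(n)] for j in range(2)]
            )
            logpi[bits] = stationary_log_weight(occ, K, w, c)
        pi = np.exp(logpi - logpi.max())
        pi /= pi.sum()
        tv = 0.5 * np.abs(freq - pi).sum()
        assert tv < 0.02

    def test_rows_independent_without_cooperativity(self):
        """With w=c=1 the joint column distribution factorizes over rows."""
        params = LatticeParams(
            kon=1.0, koff=1.0, w=1, c=1, n0=1, max_time=40000.0, seed=9
        )
        freq = config_time_distribution(params, burn_in=50.0)
        p_row0 = freq[1] + freq[3]
        p_row1 = freq[2] + freq[3]
        assert freq[3] == pytest.approx(p_row0 * p_row1, abs=0.01)


def test_params_validation():
    with pytest.raises(ValueError):
        LatticeParams(kon=-1.0, koff=1.0)
    with pytest.raises(ValueError):
        LatticeParams(kon=1.0, koff=1.0, n0=0)
    with pytest.raises(ValueError):
        LatticeParams(kon=1.0, koff=1.0, site_length_nm=0.0)
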