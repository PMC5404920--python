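"""Tests of the TIRFM-style observation model."""

import numpy as np
import pytest

from tmcoop.lattice import LatticeParams, LatticeState, simulate
from tmcoop.observe import (
    CoverageSummary,
    ObservationSettings,
    apply_labeling,
    broaden,
    coverage_at_length,
    coverage_summary,
    estimate_boundary_velocity,
    process_snapshot,
    render_kymograph,
    sum_rows,
    Kymograph,
)


class TestLabeling:
    def test_full_labeling_is_identity(self, rng):
        occ = (rng.random((2, 50)) < 0.5).astype(np.int8)
        settings = ObservationSettings(labeled_fraction=1.0)
        assert np.array_equal(apply_labeling(occ, settings, rng), occ)

    def test_zero_labeling_blanks_everything(self, rng):
        occ = np.ones((2, 30), dtype=np.int8)
        settings = ObservationSettings(labeled_fraction=0.0)
        assert apply_labeling(occ, settings, rng).sum() == 0

    def test_visible_count_is_binomial(self, rng):
        occ = np.ones((2, 5000), dtype=np.int8)
        settings = ObservationSettings(labeled_fraction=0.2)
        vis = apply_labeling(occ, settings, rng).sum()
        n = occ.sum()
        sd = np.sqrt(n * 0.2 * 0.8)
        assert abs(vis - 0.2 * n) < 3 * sd


class TestBroaden:
    def test_dilation_clipped_at_ends(self):
        row = np.zeros(10, dtype=np.int8)
        row[1] = 1
        out = broaden(row, 4)
        assert list(np.nonzero(out)[0]) == [0, 1, 2, 3, 4, 5]

    def test_empty_row_unchanged(self):
        assert broaden(np.zeros(8, dtype=np.int8), 4).sum() == 0

    def test_nearby_sites_merge_into_one_run(self):
        row = np.zeros(20, dtype=np.int8)
        row[[6, 9]] = 1
        out = broaden(row, 4)
        lit = np.nonzero(out)[0]
        assert list(lit) == list(range(2, 14))  # contiguous

    def test_monotone_in_input(self, rng):
        row = (rng.random(60) < 0.2).astype(np.int8)
        more = row.copy()
        more[rng.integers(0, 60, 5)] = 1
        assert (broaden(more, 3) >= broaden(row, 3)).all()


def test_sum_rows_levels():
    r0 = np.array([0, 1, 1], dtype=np.int8)
    r1 = np.array([0, 0, 1], dtype=np.int8)
    assert list(sum_rows(r0, r1)) == [0, 1, 2]


def test_processing_order_label_then_broaden_differs_from_reverse(rng):
    # broadening before labeling wrongly thins the dilated signal
    occ = np.zeros((2, 40), dtype=np.int8)
    occ[0, 20] = 1
    settings = ObservationSettings(labeled_fraction=0.2, broadening_radius_sites=4)
    n_correct, n_swapped = 0, 0
    for _ in range(300):
        n_correct += process_snapshot(occ, settings, rng).sum()
        swapped = apply_labeling(
            np.stack([broaden(occ[0], 4), broaden(occ[1], 4)]), settings, rng
        )
        n_swapped += swapped.sum()
    assert n_correct != n_swapped


class TestCoverageSummary:
    def test_full_double_coat(self):
        cs = coverage_summary(LatticeState.full(6))
        assert (cs.total_occupancy, cs.single_fraction, cs.double_fraction) == (1, 0, 1)

    def test_one_row_coated(self):
        occ = np.zeros((2, 4), dtype=np.int8)
        occ[0] = 1
        cs = coverage_summary(LatticeState(occ))
        assert (cs.total_occupancy, cs.single_fraction, cs.double_fraction) == (0.5, 1, 0)

    def test_hand_counted_mixture(self):
        cs = coverage_summary(
            LatticeState(np.array([[1, 1, 0, 0], [1, 0, 0, 0]], dtype=np.int8))
        )
        assert cs.total_occupancy == pytest.approx(0.375)
        assert cs.single_fraction == pytest.approx(0.25)
        assert cs.double_fraction == pytest.approx(0.25)

    def test_identity_total_from_single_double(self, rng):
        for _ in range(20):
            occ = (rng.random((2, 17)) < rng.random()).astype(np.int8)
            cs = coverage_summary(LatticeState(occ))
            assert cs.total_occupancy == pytest.approx(
                (cs.single_fraction + 2 * cs.double_fraction) / 2
            )


class TestCoverageAtLength:
    def test_no_binding_gives_zero_fluorescence(self):
        params = LatticeParams(kon=0.0, koff=1.0, v_grow=2.2, max_time=300.0, seed=2)
        res = coverage_at_length(params, ObservationSettings(), n_rep=3)
        assert res.mean_fluorescence == 0.0

    def test_saturating_rates_give_level_two(self):
        params = LatticeParams(
            kon=500.0, koff=1.0, v_grow=2.2, max_time=300.0, seed=3
        )
        settings = ObservationSettings(labeled_fraction=1.0, broadening_radius_sites=0)
        res = coverage_at_length(params, settings, n_rep=3)
        assert res.mean_fluorescence > 1.97
        assert res.double_fraction > 0.97

    def test_oracle_located_midpoint_reads_half_coverage(self):
        # Langmuir case: K = 1 is the exact midpoint; koff fast enough to
        # equilibrate within the growth time.
        params = LatticeParams(
            kon=2.0, koff=2.0, w=1, c=1, v_grow=2.2, max_time=300.0, seed=4
        )
        settings = ObservationSettings(labeled_fraction=1.0, broadening_radius_sites=0)
        res = coverage_at_length(params, settings, n_rep=24)
        per_rep = res.fluorescence_per_rep / 2.0
        se = per_rep.std(ddof=1) / np.sqrt(len(per_rep))
        assert abs(per_rep.mean() - 0.5) < 3 * max(se, 1e-3)

    def test_unreachable_target_raises(self):
        params = LatticeParams(kon=1.0, koff=1.0, v_grow=2.2, max_time=5.0, seed=1)
        with pytest.raises(ValueError, match="max_time"):
            coverage_at_length(params, ObservationSettings(), n_rep=2)


class TestKymograph:
    def test_empty_trajectory_renders_dark(self):
        params = LatticeParams(kon=0.0, koff=1.0, v_grow=2.0, max_time=50.0, seed=6)
        traj = simulate(params)
        kymo = render_kymograph(traj, ObservationSettings(frame_interval=10.0))
        assert set(np.unique(kymo.values)) <= {-1, 0}

    def test_full_labeling_no_broadening_equals_raw_sum(self):
        params = LatticeParams(
            kon=1.0, koff=0.5, w=3, c=1.5, v_grow=2.0, max_time=50.0, seed=8
        )
        traj = simulate(params)
        settings = ObservationSettings(
            labeled_fraction=1.0, broadening_radius_sites=0, frame_interval=10.0
        )
        kymo = render_kymograph(traj, settings)
        snaps = traj.snapshots(kymo.frame_times)
        for f, s in enumerate(snaps):
            assert np.array_equal(kymo.values[f, : s.N], s.occupancy.sum(axis=0))
            assert (kymo.values[f, s.N :] == -1).all()

    def test_seeded_rendering_is_deterministic(self):
        params = LatticeParams(
            kon=1.0, koff=0.5, w=3, c=1.5, v_grow=2.0, max_time=50.0, seed=8
        )
        settings = ObservationSettings(frame_interval=10.0)
        k1 = render_kymograph(simulate(params), settings, np.random.default_rng(3))
        k2 = render_kymograph(simulate(params), settings, np.random.default_rng(3))
        assert np.array_equal(k1.values, k2.values)

    def test_per_snapshot_mode_resamples_labels(self):
        params = LatticeParams(
            kon=5.0, koff=0.01, w=2, c=1, v_grow=2.0, max_time=60.0, seed=10
        )
        traj = simulate(params)
        settings = ObservationSettings(
            labeling_mode="per-snapshot", frame_interval=10.0
        )
        kymo = render_kymograph(traj, settings, np.random.default_rng(0))
        assert (kymo.values > 0).any()


class TestBoundaryVelocity:
    @staticmethod
    def synthetic_kymo(n_frames=30, n_sites=80, speed=1, dt=5.0):
        vals = np.zeros((n_frames, n_sites), dtype=np.int8)
        for f in range(n_frames):
            lo, hi = 30 - speed * f, 40 + speed * f
            vals[f, max(lo, 0) : min(hi, n_sites)] = 1
        return Kymograph(values=vals, frame_times=np.arange(n_frames) * dt)

    def test_unit_speed_cable(self):
        kymo = self.synthetic_kymo(speed=1, dt=5.0)
        vel = estimate_boundary_velocity(kymo)
        assert vel["barbed"] == pytest.approx(1 / 5.0, rel=1e-6)
        assert vel["pointed"] == pytest.approx(1 / 5.0, rel=1e-6)

    def test_static_cable_zero_velocity(self):
        kymo = self.synthetic_kymo(speed=0)
        vel = estimate_boundary_velocity(kymo)
        assert vel["barbed"] == pytest.approx(0.0, abs=1e-9)

    def test_no_qualifying_window_returns_empty(self):
        kymo = self.synthetic_kymo(n_frames=2)
        assert estimate_boundary_velocity(kymo) == {}

    def test_zipper_regime_recovers_kon_w_spreading_rate(self):
        """Deep in the zipper regime a cable edge advances at ~k_on*w sites/s."""
        kon, w = 1e-4, 30000.0
        expect = kon * w  # 3 sites/s
        vels = []
        for s in range(30):
            init = np.zeros((2, 300), dtype=np.int8)
            init[0, 140:160] = 1
            params = LatticeParams(
                kon=kon, koff=0.1, w=w, c=1.0, v_grow=0.0, max_time=30.0,
                seed=3000 + s,
            )
            traj = simulate(
                params,
                initial_state=LatticeState(init),
                stop_when_full=False,
            )
            kymo = render_kymograph(
                traj,
                ObservationSettings(
                    labeled_fraction=1.0, broadening_radius_sites=0,
                    frame_interval=1.0,
                ),
            )
            vel = estimate_boundary_velocity(kymo, min_duration_s=15.0)
            vels.extend([vel["barbed"], vel["pointed"]])
        assert np.mean(vels) == pytest.approx(expect, rel=0.2)
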