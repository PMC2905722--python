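"""Photon-package transport: stepping, absorption, scattering, boundaries,
roulette, tracing, and energy bookkeeping."""

import math

import numpy as np
import pytest

from lumicam import _kernels
from lumicam.errors import ConfigurationError
from lumicam.geometry import CylinderRegion
from lumicam.presets import bench_phantom, slab_absorber
from lumicam.rng import MCGState, uniforms
from lumicam.tissue import (
    ExitRecord,
    OpticalProperties,
    PhotonPacket,
    WeightLedger,
    absorb,
    boundary_event,
    launch,
    roulette,
    run_raycast,
    run_tissue,
    spin,
    step_size,
    trace,
)

PHANTOM = CylinderRegion(np.zeros(3), [0, 0, 1], radius=15.0, height=30.0)


def make_packet(position=(0, 0, 15), direction=(0, 0, 1), weight=1.0):
    return PhotonPacket(np.array(position, float), np.array(direction, float), weight)


class TestOpticalProperties:
    def test_free_space_is_degenerate_forward_scatterer(self):
        fs = OpticalProperties.free_space()
        assert fs.mu_a == 0.0 and fs.mu_s == 0.0 and fs.g == 1.0

    def test_reduced_scattering_roundtrip(self):
        props = OpticalProperties.from_reduced_scattering(0.0138, 0.91, g=0.9)
        assert props.mu_s == pytest.approx(9.1)
        assert props.mu_s_reduced == pytest.approx(0.91)

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigurationError):
            OpticalProperties(mu_a=-1, mu_s=0, g=0)
        with pytest.raises(ConfigurationError):
            OpticalProperties(mu_a=0, mu_s=0, g=2)


class TestStepSize:
    def test_log_identity(self):
        props = OpticalProperties(mu_a=0.5, mu_s=0.5, g=0)
        assert step_size(props, math.exp(-1)) == pytest.approx(1.0, abs=1e-12)

    def test_free_space_step_is_infinite(self):
        assert step_size(OpticalProperties.free_space(), 0.5) == math.inf

    def test_direct_evaluation(self):
        props = OpticalProperties(mu_a=0.0138, mu_s=9.1, g=0.9)
        assert step_size(props, 0.5) == pytest.approx(math.log(2) / 9.1138, rel=1e-12)


class TestAbsorb:
    @pytest.mark.parametrize(
        "mu_a,mu_s,expected_weight",
        [(1.0, 0.0, 0.0), (0.0, 1.0, 1.0), (2.0, 2.0, 0.5)],
        ids=["pure_absorber", "pure_scatterer", "balanced"],
    )
    def test_deposit_fraction(self, mu_a, mu_s, expected_weight):
        props = OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=0)
        ledger = WeightLedger()
        packet = absorb(make_packet(weight=1.0), props, ledger)
        assert packet.weight == pytest.approx(expected_weight)
        assert ledger.absorbed == pytest.approx(1.0 - expected_weight)


class TestSpin:
    def test_forward_scatter_leaves_direction_unchanged(self, minstd):
        packet = make_packet(direction=(0.6, 0.0, 0.8))
        before = packet.direction.copy()
        spin(packet, g=1.0, rng=minstd)
        np.testing.assert_allclose(packet.direction, before, atol=1e-12)

    def test_isotropic_midpoint_gives_perpendicular(self):
        # g=0, xi=0.5 -> cos(theta)=0 exactly
        assert _kernels.hg_cos(0.0, 0.5) == 0.0

    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_hg_first_moment(self, g):
        state = MCGState(current=777)
        out = np.empty(1_000_000)
        _kernels.hg_fill(state.current, state.multiplier, state.modulus, g, out)
        sigma = out.std(ddof=1) / math.sqrt(out.size)
        assert abs(out.mean() - g) < 3 * sigma

    def test_direction_norm_drift_bounded(self, minstd):
        packet = make_packet(direction=(1, 0, 0))
        for _ in range(10_000):
            spin(packet, g=0.9, rng=minstd)
        assert abs(np.linalg.norm(packet.direction) - 1.0) < 1e-6


class TestBoundaryEvent:
    def test_matched_indices_transmit_unchanged(self, minstd):
        packet = make_packet(position=(15, 0, 15), direction=(1, 0, 0))
        out = boundary_event(packet, [1, 0, 0], 1.0, 1.0, minstd)
        assert isinstance(out, ExitRecord)
        np.testing.assert_allclose(out.s_r, [1, 0, 0], atol=1e-12)
        assert minstd.current == 1  # no draw consumed

    def test_total_internal_reflection(self, minstd):
        crit = math.asin(1.0 / 1.4)
        ang = crit + 0.01
        d = np.array([math.sin(ang), 0, math.cos(ang)])
        packet = make_packet(position=(0, 0, 30), direction=(d[2], 0, d[0]))
        # incidence beyond the critical angle: always reflects, no draw
        packet.direction = np.array([math.sin(ang + 0.2), 0, math.cos(ang + 0.2)])
        out = boundary_event(packet, [0, 0, 1], 1.4, 1.0, minstd)
        assert isinstance(out, PhotonPacket)
        assert minstd.current == 1

    def test_normal_incidence_fresnel(self):
        r = _kernels.fresnel_reflectance(1.4, 1.0, 1.0)
        assert r == pytest.approx(((1.4 - 1.0) / (1.4 + 1.0)) ** 2, rel=1e-12)

    def test_snell_refraction_bends_away_from_normal(self):
        ang = 0.3
        state = MCGState(current=424242)
        outs = []
        for _ in range(200):
            p = make_packet(
                position=(0, 0, 30), direction=(math.sin(ang), 0, math.cos(ang))
            )
            res = boundary_event(p, [0, 0, 1], 1.4, 1.0, state)
            if isinstance(res, ExitRecord):
                outs.append(res.s_r)
        assert outs, "most packages transmit at 0.3 rad incidence"
        for s_t in outs:
            # Snell: n_in sin(theta_i) = n_out sin(theta_t)
            sin_t = math.hypot(s_t[0], s_t[1])
            assert sin_t == pytest.approx(1.4 * math.sin(ang), rel=1e-9)


class TestRoulette:
    def test_chance_one_always_survives(self, minstd):
        ledger = WeightLedger()
        packet = make_packet(weight=1e-6)
        out = roulette(packet, threshold=1e-4, chance=1.0, rng=minstd, ledger=ledger)
        assert out is packet and packet.weight == 1e-6
        assert minstd.current == 1  # no draw

    def test_invalid_chance_rejected(self, minstd):
        with pytest.raises(ConfigurationError):
            roulette(make_packet(), 1e-4, 0.0, minstd, WeightLedger())

    def test_unbiasedness(self):
        state = MCGState(current=99)
        ledger = WeightLedger()
        n, w, chance = 100_000, 1e-6, 0.1
        total = 0.0
        for _ in range(n):
            p = make_packet(weight=w)
            out = roulette(p, 1e-4, chance, state, ledger)
            if out is not None:
                total += out.weight
        mean = total / n
        sigma = w * math.sqrt((1 - chance) / chance / n)
        assert abs(mean - w) < 3 * sigma

    def test_ledger_identity_after_roulette(self):
        state = MCGState(current=123)
        for _ in range(1000):
            ledger = WeightLedger(launched=1e-6)
            p = make_packet(weight=1e-6)
            out = roulette(p, 1e-4, 0.1, state, ledger)
            survived = out.weight if out is not None else 0.0
            assert ledger.launched == pytest.approx(
                survived + ledger.roulette_net, rel=1e-12
            )


class TestLaunch:
    def test_weight_is_power_over_count(self, minstd):
        src = CylinderRegion([8, 0, 14], [0, 0, 1], 1.0, 16.0, role="source")
        packet = launch(src, total_power=1.0, n_packets=10**8, rng=minstd)
        assert packet.weight == 1e-8

    def test_zero_count_rejected(self, minstd):
        src = CylinderRegion([0, 0, 0], [0, 0, 1], 1.0, 1.0, role="source")
        with pytest.raises(ConfigurationError):
            launch(src, 1.0, 0, minstd)

    def test_mean_position_and_direction(self, minstd):
        src = CylinderRegion([8, 0, 14], [0, 0, 1], 1.0, 16.0, role="source")
        n = 100_000
        pos = np.empty((n, 3))
        dirs = np.empty((n, 3))
        for i in range(n):
            p = launch(src, 1.0, 1, minstd)
            pos[i] = p.position
            dirs[i] = p.direction
        centroid = np.array([8.0, 0.0, 22.0])
        sigma_pos = pos.std(axis=0, ddof=1) / math.sqrt(n)
        assert np.all(np.abs(pos.mean(axis=0) - centroid) < 3 * sigma_pos)
        sigma_dir = dirs.std(axis=0, ddof=1) / math.sqrt(n)
        assert np.all(np.abs(dirs.mean(axis=0)) < 3 * sigma_dir)


class TestTrace:
    def test_reference_trace_matches_kernel(self):
        """The per-packet Python path and the compiled batch kernel consume
        identical streams and produce identical exit records."""
        cfg = bench_phantom().model_copy(update={"photons": 200})
        props = cfg.phantom.optical.properties()
        src = cfg.source_region()
        state_kernel = MCGState(current=cfg.seed)
        res = run_tissue(
            15.0, 30.0, props, 1.0, src, 1.0, 200, state_kernel,
            roulette_threshold_frac=1e-4,
        )
        state_py = MCGState(current=cfg.seed)
        ledger = WeightLedger()
        exits = []
        w0 = 1.0 / 200
        for _ in range(200):
            packet = launch(src, 1.0, 200, state_py)
            ledger.launched += packet.weight
            out = trace(
                packet, PHANTOM, props, 1.0, state_py, ledger,
                roulette_threshold=1e-4 * w0,
            )
            if out is not None:
                exits.append(out)
        assert state_py.current == state_kernel.current
        assert len(exits) == len(res.exits)
        got_pos = np.array([e.r for e in exits])
        got_dir = np.array([e.s_r for e in exits])
        got_w = np.array([e.power for e in exits])
        assert np.array_equal(got_pos, res.exits.positions)
        assert np.array_equal(got_dir, res.exits.directions)
        assert np.array_equal(got_w, res.exits.weights)

    def test_matched_nonabsorbing_exits_all_weight(self):
        props = OpticalProperties(mu_a=0.0, mu_s=5.0, g=0.5, n=1.0)
        src = CylinderRegion([0, 0, 10], [0, 0, 1], 2.0, 5.0, role="source")
        state = MCGState(current=42)
        res = run_tissue(15.0, 30.0, props, 1.0, src, 1.0, 2000, state)
        # no absorption channel: every package leaves with full weight
        assert res.ledger.exited == pytest.approx(res.ledger.launched, rel=1e-12)
        assert res.ledger.absorbed == 0.0
        assert len(res.exits) == 2000

    def test_beer_lambert_pure_absorber(self):
        cfg = slab_absorber(mu_a=0.1, length=10.0)
        state = MCGState(current=2024)
        res = run_tissue(
            cfg.phantom.radius,
            cfg.phantom.height,
            cfg.phantom.optical.properties(),
            cfg.phantom.n_outside,
            cfg.source_region(),
            1.0,
            20_000,
            state,
            pencil_direction=(0, 0, 1),
        )
        p = math.exp(-1.0)
        frac = res.ledger.exited / res.ledger.launched
        sigma = math.sqrt(p * (1 - p) / 20_000)
        assert abs(frac - p) < 3 * sigma

    def test_empty_run(self):
        state = MCGState(current=1)
        src = CylinderRegion([0, 0, 0], [0, 0, 1], 1.0, 1.0, role="source")
        props = OpticalProperties(0.1, 1.0, 0.5)
        res = run_tissue(15.0, 30.0, props, 1.0, src, 1.0, 0, state)
        assert len(res.exits) == 0
        assert res.ledger.launched == 0.0

    def test_determinism(self):
        cfg = bench_phantom()
        props = cfg.phantom.optical.properties()
        src = cfg.source_region()
        r1 = run_tissue(15.0, 30.0, props, 1.0, src, 1.0, 500, MCGState(current=9))
        r2 = run_tissue(15.0, 30.0, props, 1.0, src, 1.0, 500, MCGState(current=9))
        assert r1.exits == r2.exits
        assert r1.ledger.absorbed == r2.ledger.absorbed

    def test_ballistic_raycast_matches_transport_in_free_space(self):
        src = CylinderRegion([0, 0, 15], [0, 0, 1], 2.0, 4.0, role="source")
        fs = OpticalProperties.free_space()
        r1 = run_tissue(15.0, 30.0, fs, 1.0, src, 1.0, 5000, MCGState(current=31))
        r2 = run_raycast(15.0, 30.0, 1.0, 1.0, src, 1.0, 5000, MCGState(current=31))
        assert r1.exits == r2.exits
        assert len(r1.exits) == 5000

    def test_exit_directions_point_outward(self):
        cfg = bench_phantom()
        res = run_tissue(
            15.0, 30.0, cfg.phantom.optical.properties(), 1.0,
            cfg.source_region(), 1.0, 2000, MCGState(current=77),
        )
        pos = res.exits.positions
        dirs = res.exits.directions
        lateral = np.hypot(pos[:, 0], pos[:, 1]) > 15.0 - 1e-6
        radial = np.where(
            lateral[:, None],
            np.column_stack([pos[:, 0], pos[:, 1], np.zeros(len(pos))]),
            np.column_stack(
                [np.zeros(len(pos)), np.zeros(len(pos)), np.sign(pos[:, 2] - 15.0)]
            ),
        )
        dots = (dirs * radial).sum(axis=1)
        assert np.all(dots > 0)

    def test_absorption_grid_accounts_for_absorbed_weight(self):
        cfg = bench_phantom()
        res = run_tissue(
            15.0, 30.0, cfg.phantom.optical.properties(), 1.0,
            cfg.source_region(), 1.0, 2000, MCGState(current=15),
            absorption_grid_shape=(20, 20, 20),
        )
        assert res.absorption_grid is not None
        assert res.absorption_grid.sum() == pytest.approx(
            res.ledger.absorbed, rel=1e-9
        )
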