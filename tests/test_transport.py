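"""Transport-engine tests: launch, boundaries, conservation, limits, timing."""

import numpy as np
import pytest

from photonmc.geometry import (
    Region,
    Scene,
    first_intersection,
    make_cube_phantom,
    make_sphere_mesh,
)
from photonmc.optics import C_MM_PER_PS, OpticalProperties
from photonmc.transport import (
    AbsorptionGrid,
    FluorophoreSpec,
    PhotonPacket,
    RecorderSpec,
    RunControls,
    SourceSpec,
    TimeGates,
    boundary_event,
    deposit,
    launch_photon,
    propagate,
    run_simulation,
    td_to_fd,
)

AIR_MATCHED = OpticalProperties(0.1, 0.0, 0.0, 1.0)


def _slab_scene(props):
    return Scene([Region("slab", make_cube_phantom(10.0), props)], ambient_n=1.0)


class TestLaunch:
    def test_initial_weight_rule(self, rng):
        src = SourceSpec(kind="internal", volume=("sphere", (0, 0, 0), 1.0))
        p = launch_photon(src, rng, n_photons=10_000_000)
        assert p.weight == pytest.approx(1e-7)

    def test_isotropic_direction_mean(self, rng):
        src = SourceSpec(kind="internal", volume=("sphere", (0, 0, 0), 1.0))
        dirs = np.array([launch_photon(src, rng, n_photons=10).direction for _ in range(20_000)])
        se = 1.0 / np.sqrt(3 * len(dirs))  # component variance of a unit sphere = 1/3
        assert np.all(np.abs(dirs.mean(axis=0)) < 3 * se)

    def test_positions_inside_source_volume(self, rng):
        src = SourceSpec(kind="internal", volume=("box", (-0.5, -0.5, -0.5), (0.5, 0.5, 0.5)))
        pos = np.array([launch_photon(src, rng, n_photons=10).position for _ in range(10_000)])
        assert np.all(np.abs(pos) <= 0.5)
        assert np.all(np.abs(pos.mean(axis=0)) < 0.02)

    def test_invalid_source(self):
        with pytest.raises(ValueError):
            SourceSpec(kind="internal", volume=("sphere", (0, 0, 0), -1.0))
        with pytest.raises(ValueError):
            SourceSpec(kind="beam")


class TestBoundaryEvent:
    def test_matched_indices_always_transmit(self, rng):
        scene = _slab_scene(AIR_MATCHED)
        hit = first_intersection((0, 0, 0), (1, 0, 0), scene)
        p = PhotonPacket(hit.hit_point, (1, 0, 0), 1.0, region="slab")
        out = boundary_event(p, hit, scene, xi=0.999)
        np.testing.assert_allclose(out.direction, [1, 0, 0], atol=1e-12)
        assert out.region is None  # crossed into ambient

    def test_beyond_critical_angle_always_reflects(self):
        scene = _slab_scene(OpticalProperties(0.1, 0.0, 0.0, 1.37))
        d = np.array([np.sin(np.radians(60)), 0, np.cos(np.radians(60))])
        hit = first_intersection((0, 0, 4.9), d, scene)  # hits +z face at 60 deg
        assert hit.region_to is None
        p = PhotonPacket(hit.hit_point, d, 1.0, region="slab")
        out = boundary_event(p, hit, scene, xi=1.0 - 1e-12)
        assert out.region == "slab"
        np.testing.assert_allclose(out.direction, [d[0], d[1], -d[2]], atol=1e-12)

    def test_snell_refraction_angle(self):
        scene = _slab_scene(OpticalProperties(0.1, 0.0, 0.0, 1.37))
        theta_i = np.radians(30.0)
        d = np.array([np.sin(theta_i), 0, np.cos(theta_i)])
        hit = first_intersection((0, 0, 0), d, scene)
        p = PhotonPacket(hit.hit_point, d, 1.0, region="slab")
        out = boundary_event(p, hit, scene, xi=0.9)
        sin_t = np.linalg.norm(np.cross(out.direction, [0, 0, 1.0]))
        # Snell oracle: sin(theta_t) = 1.37 sin(30 deg) -> theta_t ~ 43.24 deg
        expected = np.arcsin(1.37 * np.sin(theta_i))
        assert np.arcsin(sin_t) == pytest.approx(expected, abs=1e-9)


class TestDeposit:
    def test_no_absorption_no_deposit(self):
        p = PhotonPacket((0, 0, 0), (0, 0, 1), 1.0)
        assert deposit(p, OpticalProperties(0.0, 1.0, 0.0, 1.0)) == 0.0
        assert p.weight == 1.0

    def test_equal_split(self):
        p = PhotonPacket((0, 0, 0), (0, 0, 1), 1.0)
        assert deposit(p, OpticalProperties(1.0, 1.0, 0.0, 1.0)) == pytest.approx(0.5)
        assert p.weight == pytest.approx(0.5)

    def test_phantom_fraction(self):
        p = PhotonPacket((0, 0, 0), (0, 0, 1), 1e-7)
        dw = deposit(p, OpticalProperties(0.0002, 11.7, 0.95, 1.37))
        assert dw == pytest.approx(1e-7 * 0.0002 / 11.7002, rel=1e-9)

    def test_out_of_grid_goes_to_overflow(self):
        grid = AbsorptionGrid(origin=(0, 0, 0), voxel_mm=1.0, shape=(2, 2, 2))
        p = PhotonPacket((10, 10, 10), (0, 0, 1), 1.0)
        deposit(p, OpticalProperties(1.0, 1.0, 0.0, 1.0), grid)
        assert grid.overflow.sum() == pytest.approx(0.5)
        assert grid.total() == pytest.approx(0.5)


class TestBallisticLimits:
    def test_ballistic_crossing(self):
        """No scattering, negligible absorption, matched indices: the beam
        exits the far face at full weight after the straight-line flight."""
        scene = _slab_scene(OpticalProperties(1e-12, 0.0, 0.0, 1.0))
        src = SourceSpec(kind="beam", entry=(0.0, 0.0, 5.0), direction=(0, 0, -1))
        res = run_simulation(
            scene, src, RunControls(n_photons=100, seed=1, roulette_threshold=0.0)
        )
        assert res.status_counts["exited"] == 100
        assert res.totals["exited"] == pytest.approx(1.0, rel=1e-9)
        t = res.photon_exit_time
        assert np.allclose(t, 10.0 / C_MM_PER_PS, rtol=1e-5)

    def test_beer_lambert_exit_fraction(self):
        """Non-scattering absorber with mu_a * d = 1: ballistic transmission
        e^-1 within 3 standard errors."""
        scene = _slab_scene(AIR_MATCHED)
        src = SourceSpec(kind="beam", entry=(0.0, 0.0, 5.0), direction=(0, 0, -1))
        res = run_simulation(
            scene, src, RunControls(n_photons=50_000, seed=3, roulette_threshold=0.0)
        )
        frac = res.totals["exited"] / res.totals["launched"]
        p = np.exp(-1.0)
        se = np.sqrt(p * (1 - p) / 50_000)
        assert abs(frac - p) < 3 * se

    def test_point_source_exponential_decay(self):
        """Isotropic point source in a non-scattering absorber: weight
        escaping a sphere of radius r scales as e^(-mu_a r)."""
        mu_a = 0.5
        fractions = {}
        for radius in (2.0, 4.0):
            scene = Scene(
                [
                    Region(
                        "ball",
                        make_sphere_mesh(radius, refinement=3),
                        OpticalProperties(mu_a, 0.0, 0.0, 1.0),
                    )
                ]
            )
            src = SourceSpec(kind="internal", volume=("sphere", (0, 0, 0), 1e-6))
            res = run_simulation(
                scene, src, RunControls(n_photons=40_000, seed=7, roulette_threshold=0.0)
            )
            fractions[radius] = res.totals["exited"] / res.totals["launched"]
        ratio = fractions[4.0] / fractions[2.0]
        expected = np.exp(-mu_a * 2.0)
        se = np.sqrt((1 - fractions[4.0]) / (40_000 * fractions[4.0])) + np.sqrt(
            (1 - fractions[2.0]) / (40_000 * fractions[2.0])
        )
        assert abs(ratio - expected) < 3 * expected * se


class TestConservation:
    def test_exact_ledger_without_roulette(self, offset_source_result):
        assert abs(offset_source_result.conservation_residual) < 1e-9

    def test_roulette_conserves_in_expectation(self, cube_scene):
        """With roulette active the ledger balances only in expectation:
        mean residual over 30 seeds is zero within 3 sigma."""
        src = SourceSpec(kind="internal", volume=("sphere", (0, 0, 0), 0.5))
        scene = _slab_scene(OpticalProperties(1.0, 9.0, 0.5, 1.0))
        net_roulette = []
        for seed in range(30):
            res = run_simulation(
                scene,
                src,
                RunControls(n_photons=300, seed=seed, roulette_threshold=0.05, roulette_m=10),
            )
            t = res.totals
            # the exact ledger (including roulette flows) always balances
            assert abs(res.conservation_residual) < 1e-9
            net_roulette.append((t["roulette_killed"] - t["roulette_injected"]) / t["launched"])
        net_roulette = np.array(net_roulette)
        assert net_roulette.std(ddof=1) > 0  # roulette actually fired
        z = net_roulette.mean() / (net_roulette.std(ddof=1) / np.sqrt(len(net_roulette)))
        assert abs(z) < 3.0


class TestSymmetry:
    def test_face_totals_statistically_equal(self, centered_source_result):
        res = centered_source_result
        counts = res.face_record.face_totals() / res.initial_weight
        for i in range(6):
            for j in range(i + 1, 6):
                assert abs(counts[i] - counts[j]) < 3 * np.sqrt(counts[i] + counts[j])

    def test_face_map_mirror_symmetry(self, centered_source_result):
        """The +z face map is mirror-symmetric about both axes within
        counting error (binned 4x4 to keep per-bin counts high)."""
        res = centered_source_result
        grid = res.face_record.face_map(5) / res.initial_weight
        coarse = grid.reshape(4, 75, 4, 75).sum(axis=(1, 3))
        flipped = coarse[::-1, :]
        diff = np.abs(coarse - flipped)
        assert np.all(diff < 3 * np.sqrt(coarse + flipped))


class TestTimeDomain:
    def test_ballistic_gate_placement(self):
        scene = _slab_scene(OpticalProperties(1e-12, 0.0, 0.0, 1.37))
        src = SourceSpec(kind="beam", entry=(0.0, 0.0, 5.0), direction=(0, 0, -1))
        res = run_simulation(
            scene,
            src,
            RunControls(
                n_photons=50, seed=1, roulette_threshold=0.0,
                mode="TD", gates=TimeGates(0.0, 100.0, 10.0),
            ),
        )
        by_gate = res.triangle_record.data[0].sum(axis=0)
        assert by_gate.shape == (11,)  # 10 gates + overflow
        exited = res.photon_status == 0
        t_exit = res.photon_exit_time[exited]
        # straight-line crossing lands at 10 * 1.37 / c = 45.7 ps
        assert t_exit.min() == pytest.approx(10 * 1.37 / C_MM_PER_PS, abs=1e-3)
        direct = t_exit < 50.0
        assert by_gate[4] == pytest.approx(
            res.photon_exit_weight[exited][direct].sum(), rel=1e-12
        )
        # nothing arrives before the ballistic flight time
        assert by_gate[:4].sum() == 0.0
        # the rest are Fresnel-bounced packets arriving in later gates
        assert by_gate[4] >= 0.9 * res.totals["exited"]

    def test_overflow_gate_keeps_conservation(self):
        scene = _slab_scene(OpticalProperties(1e-12, 0.0, 0.0, 1.37))
        src = SourceSpec(kind="beam", entry=(0.0, 0.0, 5.0), direction=(0, 0, -1))
        res = run_simulation(
            scene,
            src,
            RunControls(
                n_photons=50, seed=1, roulette_threshold=0.0,
                mode="TD", gates=TimeGates(0.0, 20.0, 10.0),
            ),
        )
        # 45.7 ps arrival falls beyond the [0, 20) ps span -> overflow gate
        by_gate = res.triangle_record.data[0].sum(axis=0)
        assert by_gate[-1] == pytest.approx(res.totals["exited"], rel=1e-12)
        assert abs(res.conservation_residual) < 1e-9


class TestTdToFd:
    def test_zero_frequency_reproduces_cw(self):
        h = np.array([1.0, 2.0, 3.0])
        amp, phase = td_to_fd(h, np.array([5.0, 15.0, 25.0]), 0.0)
        assert amp == pytest.approx(6.0)
        assert phase == pytest.approx(0.0)

    def test_single_gate_impulse_phase(self):
        f, t0 = 130.0, 45.0
        amp, phase = td_to_fd(np.array([0.7]), np.array([t0]), f)
        assert amp == pytest.approx(0.7)
        expected = -2 * np.pi * f * 1e6 * t0 * 1e-12
        assert phase == pytest.approx(((expected + np.pi) % (2 * np.pi)) - np.pi)

    def test_half_period_cancellation(self):
        f = 1e6  # 1 THz in MHz units -> half period 0.5 ps
        amp, _ = td_to_fd(np.array([1.0, 1.0]), np.array([10.0, 10.5]), f)
        assert amp == pytest.approx(0.0, abs=1e-9)

    def test_empty_histogram_flagged(self):
        amp, phase = td_to_fd(np.zeros(3), np.array([5.0, 15.0, 25.0]), 100.0)
        assert amp == 0.0
        assert np.isnan(phase)


class TestFluorescence:
    def test_certain_conversion_switches_band(self):
        """With quantum efficiency 1 every packet that interacts converts,
        and all recorded exits on the emission band carry the full ledger."""
        props = {
            "excitation": OpticalProperties(0.01, 2.0, 0.5, 1.0),
            "emission": OpticalProperties(0.005, 1.0, 0.5, 1.0),
        }
        scene = Scene([Region("slab", make_cube_phantom(10.0), props)])
        src = SourceSpec(kind="beam", entry=(0.0, 0.0, 5.0), direction=(0, 0, -1),
                         band="excitation")
        res = run_simulation(
            scene, src,
            RunControls(n_photons=2000, seed=2, roulette_threshold=0.0),
            fluorophore=FluorophoreSpec("slab", 1.0),
        )
        n_interacted = int(res.totals["converted"])
        emitted = res.photon_band == 1
        assert n_interacted == emitted.sum()
        # exits recorded on the emission band only for converted packets
        assert res.triangle_record.data[1].sum() > 0
        assert abs(res.conservation_residual) < 1e-9

    def test_zero_efficiency_never_converts(self):
        props = {
            "excitation": OpticalProperties(0.01, 2.0, 0.5, 1.0),
            "emission": OpticalProperties(0.005, 1.0, 0.5, 1.0),
        }
        scene = Scene([Region("slab", make_cube_phantom(10.0), props)])
        src = SourceSpec(kind="beam", entry=(0.0, 0.0, 5.0), direction=(0, 0, -1),
                         band="excitation")
        res = run_simulation(
            scene, src,
            RunControls(n_photons=500, seed=2, roulette_threshold=0.0),
            fluorophore=FluorophoreSpec("slab", 0.0),
        )
        assert res.totals["converted"] == 0
        assert res.triangle_record.data[1].sum() == 0


class TestRunContract:
    def test_same_seed_bit_identical(self, cube_scene):
        src = SourceSpec(kind="internal", volume=("sphere", (0, 0, 2.0), 0.5))
        kwargs = dict(recorders=RecorderSpec(face_grid=(50, 50)))
        a = run_simulation(cube_scene, src, RunControls(n_photons=3000, seed=42), **kwargs)
        b = run_simulation(cube_scene, src, RunControls(n_photons=3000, seed=42), **kwargs)
        assert np.array_equal(a.face_record.data, b.face_record.data)
        assert np.array_equal(a.photon_exit_weight, b.photon_exit_weight)
        c = run_simulation(cube_scene, src, RunControls(n_photons=3000, seed=43), **kwargs)
        assert not np.array_equal(a.photon_exit_weight, c.photon_exit_weight)

    def test_zero_photons(self, cube_scene):
        src = SourceSpec(kind="internal", volume=("sphere", (0, 0, 0), 0.5))
        res = run_simulation(cube_scene, src, RunControls(n_photons=0, seed=1))
        assert res.totals["launched"] == 0.0
        assert res.triangle_record.total() == 0.0

    def test_step_cap_warns_and_accounts(self):
        scene = _slab_scene(OpticalProperties(1e-6, 50.0, 0.99, 1.0))
        src = SourceSpec(kind="internal", volume=("sphere", (0, 0, 0), 0.5))
        with pytest.warns(RuntimeWarning, match="step-count cap"):
            res = run_simulation(
                scene, src,
                RunControls(n_photons=50, seed=1, roulette_threshold=0.0, max_steps=10),
            )
        assert res.status_counts["step_cap"] == 50
        assert res.totals["step_cap"] > 0
        assert abs(res.conservation_residual) < 1e-9

    def test_propagate_single_packet(self, cube_scene):
        p = PhotonPacket((0.0, 0.0, 0.0), (1.0, 0.0, 0.0), 1.0, region="cube", band="single")
        out = propagate(p, cube_scene, seed=9)
        assert out["status"] in ("exited", "roulette_killed", "absorbed")
        t = out["totals"]
        balance = t["launched"] + t["roulette_injected"] - (
            t["deposited"] + t["exited"] + t["roulette_killed"]
        )
        assert abs(balance) < 1e-9

    def test_absorption_grid_covers_deposits(self, cube_scene):
        src = SourceSpec(kind="internal", volume=("sphere", (0, 0, 0), 0.5))
        res = run_simulation(
            cube_scene, src,
            RunControls(n_photons=2000, seed=4, roulette_threshold=0.0),
            recorders=RecorderSpec(absorption_voxel_mm=0.5),
        )
        assert res.absorption.data.sum() == pytest.approx(res.totals["deposited"], rel=1e-9)
        assert res.absorption.overflow.sum() == 0.0
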