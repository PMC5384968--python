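import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import chisquare

import dipolemc as d
from dipolemc import (
    LatticeSpec,
    MCState,
    MoveScale,
    PairPotentialParams,
    ProtocolSpec,
    Thermostat,
    metropolis_accept,
    propose_move,
    run_k_scan,
    run_sweeps,
    run_temperature_ramp,
)
from dipolemc.energetics import PairGeometry, pair_energy


class TestMoveScale:
    def test_dx_max_follows_mobility_relation(self):
        # k = (pi/l) <dx>/<dalpha> with uniform proposals
        scale = MoveScale.from_k(0.6, l=0.5, dalpha_max=math.pi / 2)
        assert scale.dx_max == pytest.approx(0.15)

    def test_pinned_freezes_translation(self):
        scale = MoveScale.from_k(2.0, l=0.5, pinned=True)
        assert scale.effective_dx_max == 0.0

    def test_k_zero_freezes_translation(self):
        scale = MoveScale.from_k(0.0, l=0.5)
        assert scale.dx_max == 0.0

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            MoveScale.from_k(-0.1, l=0.5)


class TestProposeMove:
    def test_empirical_displacement_rotation_ratio(self, square_15, reduced_params):
        """<|dx|>/<|dalpha|> = k l / pi over many proposals."""
        config = d.build_rectangular_lattice(square_15, seed=0)
        state = MCState(config=config, params=reduced_params, seed=0)
        scale = MoveScale.from_k(0.6, l=0.5)
        rng = np.random.default_rng(12)
        dxs, das = [], []
        for _ in range(100_000):
            idx, new_pos, new_ang = propose_move(state, scale, rng)
            dxs.append(np.hypot(*(new_pos - config.positions[idx])))
            das.append(abs(new_ang - config.angles[idx]))
        ratio = np.mean(dxs) / np.mean(das)
        assert ratio == pytest.approx(0.6 * 0.5 / math.pi, rel=0.01)

    def test_pinned_proposals_have_zero_displacement(self, square_15, reduced_params):
        config = d.build_rectangular_lattice(square_15, seed=0)
        state = MCState(config=config, params=reduced_params, seed=0)
        scale = MoveScale.from_k(0.7, l=0.5, pinned=True)
        rng = np.random.default_rng(0)
        for _ in range(100):
            idx, new_pos, _ = propose_move(state, scale, rng)
            np.testing.assert_array_equal(new_pos, config.positions[idx])


class TestMetropolisAccept:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        thermostat = Thermostat(T=0.5)
        assert all(
            metropolis_accept(-1.0, thermostat, rng) for _ in range(1000)
        )

    def test_core_clamp_sentinel_always_rejected(self):
        rng = np.random.default_rng(0)
        assert not any(
            metropolis_accept(math.inf, Thermostat(T=10.0), rng)
            for _ in range(1000)
        )

    def test_ln2_acceptance_is_half(self):
        rng = np.random.default_rng(1)
        thermostat = Thermostat(T=1.0)
        n = 100_000
        acc = sum(metropolis_accept(math.log(2.0), thermostat, rng) for _ in range(n))
        se = math.sqrt(0.25 / n)
        assert abs(acc / n - 0.5) < 3 * se

    def test_unit_delta_acceptance_is_inverse_e(self):
        rng = np.random.default_rng(2)
        thermostat = Thermostat(T=1.0)
        n = 100_000
        acc = sum(metropolis_accept(1.0, thermostat, rng) for _ in range(n))
        p = math.exp(-1.0)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(acc / n - p) < 3 * se


class TestRunSweeps:
    def test_zero_sweeps_is_noop(self, square_15, reduced_params):
        config = d.build_rectangular_lattice(square_15, seed=0)
        state = MCState(config=config, params=reduced_params, seed=0)
        before = config.angles.copy()
        trace = run_sweeps(state, MoveScale.from_k(0.1, 0.5), Thermostat(T=1.0), 0)
        assert trace.energy.size == 0
        np.testing.assert_array_equal(state.config.angles, before)

    def test_high_temperature_acceptance_approaches_one(self, reduced_params):
        spec = LatticeSpec("rectangular", 8, 8, 0.5)
        config = d.build_rectangular_lattice(spec, seed=1)
        state = MCState(config=config, params=reduced_params, seed=1)
        scale = MoveScale.from_k(0.0, 0.5, pinned=True)
        trace = run_sweeps(state, scale, Thermostat(T=1e6), 50, record_every=10)
        assert trace.acceptance.mean() > 0.99

    def test_energy_decreases_from_random_start_at_low_T(self, reduced_params):
        spec = LatticeSpec("rectangular", 15, 15, 0.5)
        decreased = 0
        for seed in range(20):
            config = d.build_rectangular_lattice(spec, seed=seed)
            state = MCState(config=config, params=reduced_params, seed=seed)
            e0 = state.E_p
            run_sweeps(state, MoveScale.from_k(0.0, 0.5, pinned=True),
                       Thermostat(T=0.05), 30, record_every=30)
            decreased += state.E_p < e0
        assert decreased == 20

    def test_identical_seeds_identical_traces(self, reduced_params):
        spec = LatticeSpec("hexagonal", 6, 6, 0.5)

        def run_once():
            config = d.build_hexagonal_lattice(spec, seed=4)
            state = MCState(config=config, params=reduced_params, seed=4)
            trace = run_sweeps(state, MoveScale.from_k(0.4, 0.5),
                               Thermostat(T=0.3), 100, record_every=10)
            return trace, state.config

        t1, c1 = run_once()
        t2, c2 = run_once()
        np.testing.assert_array_equal(t1.energy, t2.energy)
        np.testing.assert_array_equal(c1.positions, c2.positions)
        np.testing.assert_array_equal(c1.angles, c2.angles)

    def test_incremental_energy_matches_recompute(self, reduced_params):
        """Running-energy bookkeeping drift over 100 sweeps on 10x10."""
        spec = LatticeSpec("rectangular", 10, 10, 0.5)
        config = d.build_rectangular_lattice(spec, seed=7)
        state = MCState(config=config, params=reduced_params, seed=7)
        run_sweeps(state, MoveScale.from_k(0.5, 0.5), Thermostat(T=0.3),
                   100, record_every=100)
        full = state.recompute_energy()
        assert abs(state.E_p - full) / abs(full) < 1e-8

    def test_acceptance_monotone_in_temperature(self, reduced_params):
        spec = LatticeSpec("rectangular", 8, 8, 0.5)
        mean_acc = []
        for T in (0.05, 0.3, 2.0):
            accs = []
            for seed in range(10):
                config = d.build_rectangular_lattice(spec, seed=seed)
                state = MCState(config=config, params=reduced_params, seed=seed)
                trace = run_sweeps(state, MoveScale.from_k(0.0, 0.5, pinned=True),
                                   Thermostat(T=T), 60, record_every=20)
                accs.append(trace.acceptance[-1])
            mean_acc.append(np.mean(accs))
        assert mean_acc[0] <= mean_acc[1] <= mean_acc[2]


class TestBoltzmannSampling:
    def test_single_rotor_matches_boltzmann_density(self, coulomb_only):
        """Pinned two-dipole system, one rotor free: sampled angles follow
        exp(-U(alpha)/kT)/Z with Z from quadrature."""
        from dipolemc.lattice import DipoleConfiguration

        T = 0.5
        pos = np.array([[0.0, 0.0], [1.0, 0.0]])
        config = DipoleConfiguration(
            positions=pos, angles=np.array([0.0, 1.0]), l=0.5
        )
        state = MCState(config=config, params=coulomb_only, seed=123)
        scale = MoveScale.from_k(0.0, 0.5, pinned=True, dalpha_max=math.pi / 2)
        trace = run_sweeps(
            state, scale, Thermostat(T=T), 200_000,
            record_every=200_000, track_index=1, movable=np.array([1]),
        )
        samples = trace.tracked_angles[::10][1000:]

        def u(alpha):
            g = PairGeometry.from_angles(pos[0], pos[1], 0.0, alpha, 0.5)
            return pair_energy(g, coulomb_only)

        grid = np.linspace(0.0, 2 * math.pi, 721)
        dens = np.exp(-np.array([u(a) for a in grid]) / T)
        z = integrate.simpson(dens, x=grid)

        nbins = 36
        edges = np.linspace(0.0, 2 * math.pi, nbins + 1)
        observed, _ = np.histogram(samples, bins=edges)
        probs = np.empty(nbins)
        for i in range(nbins):
            sub = np.linspace(edges[i], edges[i + 1], 41)
            sub_d = np.exp(-np.array([u(a) for a in sub]) / T)
            probs[i] = integrate.simpson(sub_d, x=sub) / z
        expected = probs / probs.sum() * observed.sum()
        stat = chisquare(observed, expected)
        assert stat.pvalue > 0.01


class TestProtocols:
    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            ProtocolSpec(mode="bogus", schedule=(0.1,))
        with pytest.raises(ValueError):
            ProtocolSpec(mode="k_scan", schedule=())
        with pytest.raises(ValueError):
            ProtocolSpec(mode="k_scan", schedule=(0.1,), sweeps_per_point=0)

    def test_single_temperature_ramp_equals_run_sweeps(self, reduced_params):
        """A one-point schedule reduces to plain sweeps at that temperature."""
        spec = LatticeSpec("rectangular", 5, 5, 0.5)
        proto = ProtocolSpec(
            mode="temperature_ramp", schedule=(0.3,), sweeps_per_point=50,
            equilibration_sweeps=20, seed=5, record_every=10,
        )
        result = run_temperature_ramp(proto, spec, reduced_params)

        config = d.build_lattice(spec, seed=5)
        state = MCState(config=config, params=reduced_params, seed=5)
        scale = MoveScale.from_k(0.0, 0.5, pinned=True)
        run_sweeps(state, scale, Thermostat(T=0.3), 20, record_every=20)
        trace = run_sweeps(state, scale, Thermostat(T=0.3), 50, record_every=10)
        assert result.mean_Ep[0] == pytest.approx(trace.energy.mean())
        np.testing.assert_array_equal(result.final_config.angles,
                                      state.config.angles)

    def test_ramp_snapshots_and_trace_shape(self, reduced_params):
        spec = LatticeSpec("rectangular", 5, 5, 0.5)
        proto = ProtocolSpec(
            mode="temperature_ramp", schedule=(0.1, 0.2, 0.3),
            sweeps_per_point=40, equilibration_sweeps=10, seed=1,
            record_every=10, quench_schedule=(0.08, 0.05), quench_sweeps=20,
        )
        result = run_temperature_ramp(proto, spec, reduced_params)
        assert len(result.snapshots) == 3
        assert result.quench_mean_Ep is not None
        assert result.trace.shape[1] == 4
        # positions never move in pinned mode
        for snap in result.snapshots:
            np.testing.assert_array_equal(
                snap.positions, result.final_config.positions
            )

    def test_k_zero_scan_point_keeps_lattice_intact(self, reduced_params):
        """k = 0 freezes translation: final positions equal the lattice."""
        spec = LatticeSpec("rectangular", 6, 6, 0.5)
        proto = ProtocolSpec(
            mode="k_scan", schedule=(0.0,), sweeps_per_point=50,
            equilibration_sweeps=20, seed=3, record_every=10, temperature=0.2,
        )
        result = run_k_scan(proto, spec, reduced_params)
        lattice_positions = d.build_lattice(spec, seed=0).positions
        np.testing.assert_allclose(
            np.sort(result.final_configs[0][0].positions, axis=0),
            np.sort(lattice_positions, axis=0),
            atol=1e-12,
        )

    def test_k_scan_deterministic_and_shapes(self, reduced_params):
        spec = LatticeSpec("rectangular", 5, 5, 0.5)
        proto = ProtocolSpec(
            mode="k_scan", schedule=(0.1, 0.4), sweeps_per_point=30,
            equilibration_sweeps=10, seed=9, record_every=10,
            n_replicates=2, temperature=0.2,
        )
        r1 = run_k_scan(proto, spec, reduced_params)
        r2 = run_k_scan(proto, spec, reduced_params)
        np.testing.assert_array_equal(r1.mean_Ep, r2.mean_Ep)
        assert r1.mean_Ep.shape == (2, 2)
        assert r1.relative_Ep.shape == (2, 2)

    def test_mode_mismatch_rejected(self, reduced_params):
        spec = LatticeSpec("rectangular", 4, 4, 0.5)
        proto = ProtocolSpec(mode="k_scan", schedule=(0.1,))
        with pytest.raises(ValueError):
            run_temperature_ramp(proto, spec, reduced_params)
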