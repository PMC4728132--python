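import numpy as np
import pytest

import polarcomp as pc


class TestPeriodicLaplacian:
    def test_constant_field(self):
        lap = pc.periodic_laplacian(np.full((16, 16), 3.7), 0.1)
        assert np.max(np.abs(lap)) < 1e-12

    def test_sine_eigenfunction(self):
        L, N = 8.0, 128
        h = L / N
        x = (np.arange(N) + 0.5) * h
        f = np.sin(2 * np.pi * x / L)[:, None] * np.ones(N)
        lap = pc.periodic_laplacian(f, h)
        expected = -((2 * np.pi / L) ** 2) * f
        assert np.max(np.abs(lap - expected)) < 1e-3 * np.max(np.abs(expected))

    def test_zero_sum_on_torus(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0, 10, (32, 32))
        lap = pc.periodic_laplacian(f, 0.2)
        assert abs(lap.sum()) < 1e-9 * np.abs(lap).sum()

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            pc.periodic_laplacian(np.zeros((8, 10)), 0.1)


class TestStep:
    def test_fixed_point_noise_off(self, params, hss):
        cfg = pc.SimulationConfig(N=48, dt=0.01, noise=False)
        out = pc.step(hss, params, cfg, np.random.default_rng(0))
        assert np.max(np.abs(out.membrane.as_array()
                             - hss.membrane.as_array())) < 1e-10
        assert out.t == pytest.approx(hss.t + 0.01)

    def test_explicit_dt_bound_enforced(self, params):
        h = params.L / 48
        too_big = 1.01 * h * h / (4 * params.Dm)
        cfg = pc.SimulationConfig(N=48, dt=too_big, stepper="explicit")
        with pytest.raises(ValueError):
            cfg.validate(params)

    def test_explicit_matches_imex(self, params, hss):
        """Both steppers integrate the same semi-discretization: short
        noise-free runs from a perturbed state agree."""
        L = params.L
        st = pc.seed_perturbations(hss, params, [(L / 2, L / 2)],
                                   amplitude=10.0, width=0.8)
        ref = pc.simulate(st, params, pc.SimulationConfig(
            N=48, dt=2e-4, T=2.0, noise=False, cadence=2.0,
            stepper="explicit")).final
        got = pc.simulate(st, params, pc.SimulationConfig(
            N=48, dt=2e-3, T=2.0, noise=False, cadence=2.0)).final
        scale = np.max(np.abs(ref.membrane.as_array()))
        diff = np.max(np.abs(ref.membrane.as_array()
                             - got.membrane.as_array()))
        assert diff < 2e-3 * scale


class TestSimulate:
    def test_zero_duration(self, params, hss):
        traj = pc.simulate(hss, params, pc.SimulationConfig(N=48, dt=0.01,
                                                            T=0.0))
        assert len(traj) == 1
        assert traj.final is traj.states[0]

    def test_determinism(self, params, hss):
        cfg = pc.SimulationConfig(N=48, dt=0.01, T=2.0, seed=42, noise=True,
                                  cadence=1.0)
        a = pc.simulate(hss, params, cfg).final
        b = pc.simulate(hss, params, cfg).final
        assert np.array_equal(a.membrane.as_array(), b.membrane.as_array())
        assert a.cytosol.Cdc42Dc == b.cytosol.Cdc42Dc

    def test_conservation_with_noise(self, params, hss):
        cfg = pc.SimulationConfig(N=48, dt=0.01, T=30.0, seed=1, noise=True,
                                  cadence=5.0)
        traj = pc.simulate(hss, params, cfg)
        assert traj.max_total_drift() < 1e-3

    def test_times_strictly_increasing(self, params, hss):
        cfg = pc.SimulationConfig(N=48, dt=0.01, T=5.0, noise=False,
                                  cadence=1.0)
        traj = pc.simulate(hss, params, cfg)
        assert np.all(np.diff(traj.times) > 0)

    def test_symmetric_two_peak_stays_symmetric(self, params, two_peak_48):
        """Without noise the exact mirror symmetry of the two-peak state is
        preserved by the integrator."""
        cfg = pc.SimulationConfig(N=48, dt=0.01, T=50.0, noise=False,
                                  cadence=25.0)
        traj = pc.simulate(two_peak_48, params, cfg)
        for state in traj.states:
            f = state.membrane.total_membrane_cdc42()
            mirrored = np.roll(np.roll(f, 24, axis=0), 24, axis=1)
            assert np.max(np.abs(f - mirrored)) < 1e-9 * f.max()

    def test_turing_growth_from_noise_at_corrected_abundance(
            self, params_corrected):
        """At volume-corrected abundances the homogeneous state is linearly
        unstable: small zero-mean noise grows into a peak well above the
        homogeneous level within 600 s."""
        st = pc.make_noisy_homogeneous_state(params_corrected, 0.05, seed=3,
                                             N=48)
        hss_level = float(pc.homogeneous_steady_state(
            params_corrected).membrane.total_membrane_cdc42()[0, 0])
        cfg = pc.SimulationConfig(N=48, dt=0.01, T=600.0, seed=3, noise=True,
                                  cadence=600.0)
        final = pc.simulate(st, params_corrected, cfg).final
        assert final.membrane.total_membrane_cdc42().max() > 5.0 * hss_level


class TestSeedPerturbations:
    def test_empty_centers_identity(self, params, hss):
        out = pc.seed_perturbations(hss, params, [])
        assert np.array_equal(out.membrane.as_array(),
                              hss.membrane.as_array())

    def test_totals_preserved(self, params, hss):
        L = params.L
        out = pc.seed_perturbations(
            hss, params, [(L / 4, L / 4), (3 * L / 4, 3 * L / 4)],
            amplitude=30.0, width=0.6)
        assert pc.total_cdc42(out, params) == pytest.approx(
            pc.total_cdc42(hss, params), abs=1e-12)
        assert pc.total_bemgef(out, params) == pytest.approx(
            pc.total_bemgef(hss, params), abs=1e-14)

    def test_center_outside_domain_rejected(self, params, hss):
        with pytest.raises(ValueError):
            pc.seed_perturbations(hss, params, [(params.L + 1.0, 0.0)])

    def test_cytosol_depletion_rejected(self, params, hss):
        with pytest.raises(ValueError):
            pc.seed_perturbations(hss, params, [(4.0, 4.0)],
                                  amplitude=1e5, width=2.0)

    def test_two_peaks_persist_without_noise(self, params, two_peak_48):
        """The symmetric two-peak state is a genuine (unstable) stationary
        state: both peaks persist unchanged through continued noise-free
        integration."""
        f0 = two_peak_48.membrane.total_membrane_cdc42()
        cfg = pc.SimulationConfig(N=48, dt=0.01, T=300.0, noise=False,
                                  cadence=300.0)
        final = pc.simulate(two_peak_48, params, cfg).final
        f1 = final.membrane.total_membrane_cdc42()
        peaks = pc.detect_peaks(f1, params.L, min_height=100.0,
                                min_separation=1.0)
        assert len(peaks) == 2
        assert np.max(np.abs(f1 - f0)) < 0.02 * f0.max()


def test_grid_refinement_converges(params):
    """Halving the grid spacing changes the relaxed single-peak height by
    well under 5%."""
    L = params.L
    heights = {}
    for N in (48, 96):
        hss = pc.homogeneous_steady_state(params, N=N)
        st = pc.seed_perturbations(hss, params, [(L / 2, L / 2)],
                                   amplitude=30.0, width=0.6)
        cfg = pc.SimulationConfig(N=N, dt=0.01, T=200.0, noise=False,
                                  cadence=200.0)
        heights[N] = pc.simulate(st, params, cfg).final \
            .membrane.total_membrane_cdc42().max()
    assert abs(heights[96] - heights[48]) / heights[96] < 0.05


def test_trajectory_summary_table(params, hss):
    L = params.L
    st = pc.seed_perturbations(hss, params, [(L / 2, L / 2)],
                               amplitude=30.0, width=0.6)
    cfg = pc.SimulationConfig(N=48, dt=0.01, T=20.0, noise=False, cadence=10.0)
    traj = pc.simulate(st, params, cfg)
    df = traj.summary(params)
    assert list(df.columns) == ["t", "total_cdc42", "total_bemgef",
                                "n_peaks", "max_peak_height"]
    assert len(df) == len(traj)
    assert df["n_peaks"].iloc[-1] == 1
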