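import numpy as np
import pytest

import polarcomp as pc


@pytest.fixture(scope="session")
def params():
    return pc.default_parameters()


@pytest.fixture(scope="session")
def params_corrected(params):
    """Volume-corrected abundances (5.86x), where the homogeneous state is
    linearly unstable."""
    return params.scaled_abundance(258.0 / 44.0)


@pytest.fixture(scope="session")
def hss(params):
    return pc.homogeneous_steady_state(params, N=48)


@pytest.fixture(scope="session")
def two_peak_48(params):
    """Noise-free relaxed symmetric two-peak stationary state, N=48."""
    return pc.relax_two_peak_state(params, N=48, dt=0.01, T_relax=300.0)


@pytest.fixture(scope="session")
def single_peak_48(params):
    """Noise-free relaxed one-peak stationary state, N=48."""
    L = params.L
    hss = pc.homogeneous_steady_state(params, N=48)
    st = pc.seed_perturbations(hss, params, [(L / 2, L / 2)],
                               amplitude=30.0, width=0.6)
    cfg = pc.SimulationConfig(N=48, dt=0.01, T=300.0, noise=False, cadence=300.0)
    return pc.simulate(st, params, cfg).final


@pytest.fixture(scope="session")
def competition_runs(params):
    """Ten seeded competition runs at N=48, reusing one relaxed two-peak
    state (the noise-free relaxation is seed-independent)."""
    two = pc.relax_two_peak_state(params, N=48, dt=0.01, T_relax=300.0)
    cfg = pc.SimulationConfig(N=48, dt=0.01, T=2500.0, noise=True, cadence=20.0)
    return [pc.run_competition_experiment(params, cfg, seed=seed,
                                          two_peak_state=two)
            for seed in range(10)]
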