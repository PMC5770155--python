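import numpy as np
import pytest

import ratecorr as rc
from ratecorr.equilibria import equilibrium_at, reduced_drift


@pytest.fixture(scope="session")
def reference_network():
    """The reference 8E + 2I circuit."""
    return rc.default_network()


@pytest.fixture(scope="session")
def independent_noise():
    return rc.default_noise()


@pytest.fixture(scope="session")
def zero_weight_network():
    E = rc.PopulationParams("E", 3, 1.0, 1.0, 2.0, 2.0)
    I = rc.PopulationParams("I", 2, 1.0, 1.0, 2.0, 2.0)
    return rc.NetworkParams((E, I), np.zeros((2, 2)))


def stable_equilibrium(stim, net, seed=0):
    eqs = [e for e in rc.find_fixed_points(stim, net, seed=seed) if e.stable]
    assert eqs, f"no stable equilibrium at {stim}"
    return min(eqs, key=lambda e: e.spectral_abscissa)


@pytest.fixture(scope="session")
def asynchronous_equilibrium(reference_network):
    """Stable equilibrium in the asynchronous regime (strong E drive)."""
    return stable_equilibrium(rc.Stimulus.ei(14.0, -35.0), reference_network, seed=1)


def random_network(rng, max_size=12):
    """A random two-population network with valid signs and parameters."""
    NE = int(rng.integers(2, max_size + 1))
    NI = int(rng.integers(2, max_size + 1))
    vt = float(rng.uniform(-1.0, 3.0))
    E = rc.PopulationParams(
        "E",
        NE,
        float(rng.uniform(0.5, 2.0)),
        float(rng.uniform(0.5, 2.0)),
        float(rng.uniform(0.5, 4.0)),
        vt,
    )
    I = rc.PopulationParams(
        "I",
        NI,
        float(rng.uniform(0.5, 2.0)),
        float(rng.uniform(0.5, 2.0)),
        float(rng.uniform(0.5, 4.0)),
        vt,
    )
    W = np.array(
        [
            [rng.uniform(0.0, 30.0), -rng.uniform(0.1, 30.0)],
            [rng.uniform(0.1, 30.0), -rng.uniform(0.1, 30.0)],
        ]
    )
    return rc.NetworkParams((E, I), W)


def random_stable_setup(rng, max_size=12, require_nondegenerate_k=True, max_tries=500):
    """A random network with a stable homogeneous equilibrium.

    The membrane potentials are drawn first and the stimulus solved for
    (every state is stationary under exactly one stimulus), then stability
    of the full Jacobian is checked.
    """
    for _ in range(max_tries):
        net = random_network(rng, max_size=max_size)
        vt = net.populations[0].v_threshold
        mu = rng.uniform(vt - 3.0, vt + 3.0, 2)
        stim0 = rc.Stimulus.ei(0.0, 0.0)
        resid = reduced_drift(mu, stim0, net)
        stim = rc.Stimulus.ei(-resid[0], -resid[1])
        eq = equilibrium_at(mu, stim, net)
        if not eq.stable:
            continue
        if require_nondegenerate_k:
            spec = rc.spectrum_at(eq, net)
            K0, K1 = spec.K
            if not np.isfinite([K0.real, K0.imag, K1.real, K1.imag]).all():
                continue
            if abs(K1 - K0) < 1e-6 * max(abs(K0), abs(K1), 1.0):
                continue
        return net, eq
    raise RuntimeError("could not draw a stable configuration")


@pytest.fixture(scope="session")
def fold_scan(reference_network, independent_noise):
    """Bifurcations on the I_E segment crossing the fold at I_I = -35."""
    return rc.locate_on_segment(
        "I_E", (5.0, 20.0), -35.0, reference_network, independent_noise, step=0.01, seed=1
    )


@pytest.fixture(scope="session")
def hopf_bp_scan(reference_network, independent_noise):
    """Bifurcations on the I_I segment crossing Hopf and branching point at I_E = 1."""
    return rc.locate_on_segment(
        "I_I", (-30.0, 5.0), 1.0, reference_network, independent_noise, step=0.01, seed=1
    )
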