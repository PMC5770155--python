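"""Jacobian spectral decomposition at homogeneous equilibria.

For a fully-connected two-population network linearized at a homogeneous
equilibrium (mu_E, mu_I), the N x N Jacobian spectrum splits into

* *intra-population* eigenvalues lambda_E, lambda_I with multiplicities
  N_E - 1 and N_I - 1, generated by the all-to-all structure within each
  population, and
* two *inter-population* eigenvalues lambda_R_0, lambda_R_1 — the
  eigenvalues of the 2 x 2 collective-mode matrix coupling the
  population means.

The coupling coefficients K_x relate the E and I components of the
collective eigenmodes and enter the closed-form covariance.  Complex
arithmetic is used throughout so the Hopf neighbourhood (conjugate pair)
needs no special casing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkParams, activation_slope, build_connectivity, population_means

__all__ = [
    "SpectrumResult",
    "FullJacobian",
    "intra_eigenvalues",
    "inter_eigenvalues",
    "coupling_coefficients",
    "full_jacobian",
    "stability",
    "spectrum_at",
]

#: imaginary parts below this are dropped when reporting nominally real results
REALITY_TOL = 1e-10
#: a denominator in the K_x formulas smaller than this is treated as degenerate
K_DENOM_TOL = 1e-12


class DegenerateCouplingError(ValueError):
    """Both closed forms of the coupling coefficient are ill-conditioned.

    Signals that the closed-form covariance should fall back to the
    Lyapunov route.
    """


@dataclass(frozen=True)
class SpectrumResult:
    lambda_E: float
    lambda_I: float
    lambda_R: tuple[complex, complex]  # ordered: larger real part first
    XYZ: tuple[float, float, float]
    K: tuple[complex, complex]
    spectral_abscissa: float

    @property
    def stable(self) -> bool:
        return self.spectral_abscissa < 0


@dataclass(frozen=True)
class FullJacobian:
    matrix: np.ndarray
    equilibrium: object  # Equilibrium; kept loose to avoid an import cycle

    def __post_init__(self):
        m = np.array(self.matrix, dtype=float)
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)


def _ei_slopes(eq, net: NetworkParams):
    mu = population_means(eq.mu if hasattr(eq, "mu") else eq, net)
    return mu, np.array(
        [activation_slope(mu[a], net.populations[a]) for a in range(net.n_populations)]
    )


def intra_eigenvalues(eq, net: NetworkParams) -> tuple[float, float]:
    """(lambda_E, lambda_I): eigenvalues of the within-population modes.

    lambda_a = -(1/tau_a + J_aa A'_a(mu_a) / M_a); each appears with
    multiplicity N_a - 1 in the full spectrum.
    """
    _, slopes = _ei_slopes(eq, net)
    out = []
    for a, pop in enumerate(net.populations):
        out.append(-(1.0 / pop.tau + net.weights[a, a] * slopes[a] / pop.in_degree))
    return tuple(out)


def inter_eigenvalues(eq, net: NetworkParams):
    """Collective-mode pair lambda_R_{0,1} and the (X, Y, Z) coefficients.

    Y and Z are the diagonal entries of the 2 x 2 collective matrix, X
    the product of its off-diagonal entries; the pair is

        lambda_R = (Y + Z +/- sqrt((Y - Z)^2 + 4 X)) / 2,

    complex-conjugate when the radicand is negative.  lambda_R_0 is the
    root with the larger real part (larger imaginary part on ties).
    """
    if net.n_populations != 2:
        raise ValueError("inter_eigenvalues requires exactly two populations")
    mu, slopes = _ei_slopes(eq, net)
    (popE, popI) = net.populations
    NE, NI = popE.size, popI.size
    ME, MI = popE.in_degree, popI.in_degree
    X = (NE * NI / (ME * MI)) * net.weights[0, 1] * net.weights[1, 0] * slopes[0] * slopes[1]
    Y = -1.0 / popE.tau + (NE - 1) / ME * net.weights[0, 0] * slopes[0]
    Z = -1.0 / popI.tau + (NI - 1) / MI * net.weights[1, 1] * slopes[1]
    sq = np.sqrt(complex((Y - Z) ** 2 + 4.0 * X))
    r0 = 0.5 * (Y + Z + sq)
    r1 = 0.5 * (Y + Z - sq)
    if (r0.real, r0.imag) < (r1.real, r1.imag):
        r0, r1 = r1, r0
    return (r0, r1), (X, Y, Z)


def coupling_coefficients(lambda_R, eq, net: NetworkParams) -> tuple[complex, complex]:
    """Coupling coefficients K_0, K_1 of the collective eigenmodes.

    Two algebraically equivalent forms exist (one divides by the E->I
    pathway, one by the I->E pathway); the better-conditioned one is
    used, and both are cross-checked when both denominators are
    nondegenerate.
    """
    if net.n_populations != 2:
        raise ValueError("coupling_coefficients requires exactly two populations")
    mu, slopes = _ei_slopes(eq, net)
    popE, popI = net.populations
    NE, NI = popE.size, popI.size
    ME, MI = popE.in_degree, popI.in_degree
    JEE, JEI = net.weights[0]
    JIE, JII = net.weights[1]
    den1 = NI * JEI * slopes[1]
    out = []
    for lam in lambda_R:
        den2 = MI * (lam + 1.0 / popI.tau) - (NI - 1) * JII * slopes[1]
        num1 = ME * (lam + 1.0 / popE.tau) - (NE - 1) * JEE * slopes[0]
        num2 = NE * JIE * slopes[0]
        ok1 = abs(den1) > K_DENOM_TOL
        ok2 = abs(den2) > K_DENOM_TOL
        if not ok1 and not ok2:
            raise DegenerateCouplingError(
                "both coupling-coefficient denominators are degenerate"
            )
        k1 = num1 / den1 if ok1 else None
        k2 = num2 / den2 if ok2 else None
        k = k1 if (ok1 and (not ok2 or abs(den1) >= abs(den2))) else k2
        out.append(complex(k))
    return tuple(out)


def full_jacobian(eq, net: NetworkParams) -> FullJacobian:
    """N x N Jacobian of the drift at an equilibrium (reduced or full)."""
    mu = np.asarray(eq.mu, dtype=float)
    if mu.size == net.n_populations:
        v = np.repeat(mu, net.sizes)
    else:
        v = mu
    conn = build_connectivity(net)
    slopes = np.concatenate(
        [
            activation_slope(v[s], p) * np.ones(p.size)
            for s, p in zip(net.population_slices(), net.populations)
        ]
    )
    J = conn * slopes[None, :] / net.neuron_in_degrees()[:, None]
    J[np.diag_indices_from(J)] = -1.0 / net.neuron_taus()
    return FullJacobian(matrix=J, equilibrium=eq)


def stability(spec_or_jacobian) -> tuple[bool, float]:
    """(stable, spectral abscissa) from a SpectrumResult, FullJacobian or matrix.

    The abscissa (largest eigenvalue real part) also sets the slowest
    relaxation time 1/|abscissa|, the quantity that diverges under
    critical slowing down.
    """
    if isinstance(spec_or_jacobian, SpectrumResult):
        absc = spec_or_jacobian.spectral_abscissa
    else:
        m = (
            spec_or_jacobian.matrix
            if isinstance(spec_or_jacobian, FullJacobian)
            else np.asarray(spec_or_jacobian, dtype=float)
        )
        absc = float(np.max(np.linalg.eigvals(m).real))
    return absc < 0, absc


def spectrum_at(eq, net: NetworkParams) -> SpectrumResult:
    """Full spectral decomposition at a homogeneous equilibrium."""
    lam_E, lam_I = intra_eigenvalues(eq, net)
    lam_R, XYZ = inter_eigenvalues(eq, net)
    try:
        K = coupling_coefficients(lam_R, eq, net)
    except DegenerateCouplingError:
        K = (complex("nan"), complex("nan"))
    parts = [r.real for r in lam_R]
    # intra eigenvalues only present when the population holds >= 2 neurons
    for lam, pop in zip((lam_E, lam_I), net.populations):
        if pop.size >= 2:
            parts.append(lam)
    return SpectrumResult(
        lambda_E=float(lam_E),
        lambda_I=float(lam_I),
        lambda_R=lam_R,
        XYZ=tuple(float(x) for x in XYZ),
        K=K,
        spectral_abscissa=float(max(parts)),
    )
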