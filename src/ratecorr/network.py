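"""Model definition: populations, activation nonlinearity, structural matrices.

A network consists of homogeneous neural populations (excitatory or
inhibitory) coupled all-to-all.  Each neuron obeys a graded firing-rate
equation

    dV_i/dt = -V_i/tau_i + (1/M_i) sum_j J_ij A_j(V_j) + I_i + noise,

where the activation ``A`` is an algebraic sigmoid saturating at
``nu_max`` with slope parameter ``Lambda`` and threshold ``V_T``.  The
noise term is correlated white noise with population-block covariance
``Sigma_B``.  This module builds and validates all the structural pieces
(connectivity matrix, noise covariance) and the activation function and
its derivatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PopulationParams",
    "NetworkParams",
    "NoiseModel",
    "Stimulus",
    "NoiseValidityReport",
    "activation",
    "activation_slope",
    "activation_curvature",
    "curvature_radius",
    "build_connectivity",
    "build_noise_covariance",
    "weak_noise_check",
    "default_network",
    "default_noise",
    "EXCITATORY",
    "INHIBITORY",
]

EXCITATORY = "E"
INHIBITORY = "I"

#: relative tolerance on the minimum eigenvalue of the expanded noise
#: covariance; allows exactly singular cases (all noise correlations = 1).
PSD_RTOL = 1e-12


class SignConstraintError(ValueError):
    """A synaptic weight violates the excitatory/inhibitory sign convention."""


class NotPositiveSemidefiniteError(ValueError):
    """The expanded noise covariance is not positive semidefinite."""

    def __init__(self, min_eigenvalue: float):
        self.min_eigenvalue = min_eigenvalue
        super().__init__(
            f"noise covariance is not positive semidefinite "
            f"(minimum eigenvalue {min_eigenvalue:.3e})"
        )


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of one homogeneous population.

    Parameters
    ----------
    label:
        ``"E"`` (excitatory) or ``"I"`` (inhibitory); fixes the sign of
        outgoing synaptic weights.
    size:
        Number of neurons ``N_alpha`` (>= 1).
    tau:
        Membrane time constant (simulation time units, > 0).
    nu_max:
        Maximum firing rate (> 0).
    slope:
        Activation slope parameter ``Lambda`` (> 0).
    v_threshold:
        Activation threshold ``V_T`` (the sigmoid midpoint).
    in_degree:
        Incoming connections per neuron ``M_alpha``.  ``None`` means the
        fully-connected default ``N - 1``, filled in by the network.
    """

    label: str
    size: int
    tau: float
    nu_max: float
    slope: float
    v_threshold: float
    in_degree: int | None = None

    def __post_init__(self):
        if self.label not in (EXCITATORY, INHIBITORY):
            raise ValueError(f"label must be 'E' or 'I', got {self.label!r}")
        if self.size < 1:
            raise ValueError("population size must be >= 1")
        for name in ("tau", "nu_max", "slope"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not math.isfinite(self.v_threshold):
            raise ValueError("v_threshold must be finite")
        if self.in_degree is not None and self.in_degree < 1:
            raise ValueError("in_degree must be a positive integer")


@dataclass(frozen=True)
class NetworkParams:
    """A multi-population network: populations plus the weight matrix.

    ``weights[a, b]`` is the synaptic strength ``J_ab`` from population
    ``b`` (presynaptic) to population ``a`` (postsynaptic).  Columns
    belonging to excitatory populations must be non-negative, columns of
    inhibitory populations non-positive.
    """

    populations: tuple[PopulationParams, ...]
    weights: np.ndarray

    def __post_init__(self):
        pops = tuple(self.populations)
        object.__setattr__(self, "populations", pops)
        W = np.array(self.weights, dtype=float)
        P = len(pops)
        if P < 2:
            raise ValueError("at least two populations are required")
        if W.shape != (P, P):
            raise ValueError(f"weights must be {P}x{P}, got {W.shape}")
        for b, pop in enumerate(pops):
            col = W[:, b]
            if pop.label == EXCITATORY and np.any(col < 0):
                raise SignConstraintError(
                    f"weights from excitatory population {b} must be >= 0"
                )
            if pop.label == INHIBITORY and np.any(col > 0):
                raise SignConstraintError(
                    f"weights from inhibitory population {b} must be <= 0"
                )
        W.setflags(write=False)
        object.__setattr__(self, "weights", W)
        # default in-degree: fully connected without self-connections
        n = sum(p.size for p in pops)
        filled = tuple(
            replace(p, in_degree=n - 1) if p.in_degree is None else p for p in pops
        )
        object.__setattr__(self, "populations", filled)

    # -- convenience views -------------------------------------------------
    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([p.size for p in self.populations])

    @property
    def n_total(self) -> int:
        return int(self.sizes.sum())

    @property
    def taus(self) -> np.ndarray:
        return np.array([p.tau for p in self.populations])

    @property
    def in_degrees(self) -> np.ndarray:
        return np.array([p.in_degree for p in self.populations])

    def population_slices(self) -> list[slice]:
        """Index ranges of each population in the [all pop 0, pop 1, ...] layout."""
        edges = np.concatenate([[0], np.cumsum(self.sizes)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def neuron_taus(self) -> np.ndarray:
        return np.repeat(self.taus, self.sizes)

    def neuron_in_degrees(self) -> np.ndarray:
        return np.repeat(self.in_degrees, self.sizes)


@dataclass(frozen=True)
class NoiseModel:
    """Additive white-noise model: per-population amplitudes and correlations.

    ``sigma[a]`` is the noise standard deviation of every neuron in
    population ``a``; ``corr[a, b]`` the correlation between the Brownian
    inputs of a neuron in ``a`` and a *different* neuron in ``b`` (so the
    diagonal holds the within-population pairwise correlation, not 1).
    """

    sigma: np.ndarray
    corr: np.ndarray

    def __post_init__(self):
        s = np.atleast_1d(np.array(self.sigma, dtype=float))
        C = np.atleast_2d(np.array(self.corr, dtype=float))
        if np.any(s < 0):
            raise ValueError("noise amplitudes must be non-negative")
        if C.shape != (s.size, s.size):
            raise ValueError("corr must be P x P")
        if not np.allclose(C, C.T, atol=1e-14):
            raise ValueError("noise correlation matrix must be symmetric")
        if np.any(np.abs(C) > 1 + 1e-12):
            raise ValueError("noise correlations must lie in [-1, 1]")
        s.setflags(write=False)
        C.setflags(write=False)
        object.__setattr__(self, "sigma", s)
        object.__setattr__(self, "corr", C)


@dataclass(frozen=True)
class Stimulus:
    """Constant external currents, one value per population."""

    values: tuple[float, ...]

    def __post_init__(self):
        vals = tuple(float(v) for v in np.atleast_1d(self.values))
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("stimulus values must be finite")
        object.__setattr__(self, "values", vals)

    @classmethod
    def ei(cls, I_E: float, I_I: float) -> "Stimulus":
        return cls((I_E, I_I))

    @property
    def I_E(self) -> float:
        return self.values[0]

    @property
    def I_I(self) -> float:
        return self.values[1]

    def as_array(self) -> np.ndarray:
        return np.array(self.values)

    def with_value(self, index: int, value: float) -> "Stimulus":
        vals = list(self.values)
        vals[index] = float(value)
        return Stimulus(tuple(vals))


@dataclass(frozen=True)
class NoiseValidityReport:
    """Outcome of the weak-noise self-consistency check.

    The linear-response expansion is trusted when the stationary
    fluctuation scale of each population stays below the minimum radius
    of curvature of its activation function at the operating point.
    """

    curvature_radius: tuple[float, ...]
    sigma_v: tuple[float, ...]
    valid: bool


# ---------------------------------------------------------------------------
# activation function and derivatives
# ---------------------------------------------------------------------------

def _u(V, pop: PopulationParams):
    return 0.5 * pop.slope * (np.asarray(V, dtype=float) - pop.v_threshold)


def activation(V, pop: PopulationParams):
    """Algebraic sigmoid rate A(V) in (0, nu_max), equal to nu_max/2 at V_T."""
    u = _u(V, pop)
    return 0.5 * pop.nu_max * (1.0 + u / np.sqrt(1.0 + u * u))


def activation_slope(V, pop: PopulationParams):
    """First derivative A'(V); maximum nu_max*Lambda/4 exactly at V_T."""
    u = _u(V, pop)
    return 0.25 * pop.nu_max * pop.slope * (1.0 + u * u) ** -1.5


def activation_curvature(V, pop: PopulationParams):
    """Second derivative A''(V); zero at the inflection point V = V_T."""
    u = _u(V, pop)
    return -0.375 * pop.nu_max * pop.slope**2 * u * (1.0 + u * u) ** -2.5


def curvature_radius(mu, pop: PopulationParams):
    """Radius of curvature r(mu) = |(1 + A'(mu)^2)^(3/2) / A''(mu)|.

    Returns infinity where the curvature vanishes (at the inflection
    point and in the saturated tails).
    """
    ap = activation_slope(mu, pop)
    app = activation_curvature(mu, pop)
    with np.errstate(divide="ignore"):
        out = np.abs((1.0 + ap * ap) ** 1.5 / app)
    return np.where(app == 0.0, np.inf, out) if np.ndim(mu) else (
        math.inf if app == 0.0 else float(out)
    )


# ---------------------------------------------------------------------------
# structural matrices
# ---------------------------------------------------------------------------

def build_connectivity(net: NetworkParams) -> np.ndarray:
    """Expanded N x N synaptic matrix.

    Within-population blocks are ``J_aa (ones - Id)`` (no
    self-connections), between-population blocks are constant ``J_ab``.
    Neuron ordering is population-major: all neurons of population 0
    first, then population 1, and so on.
    """
    n = net.n_total
    J = np.zeros((n, n))
    sl = net.population_slices()
    for a in range(net.n_populations):
        for b in range(net.n_populations):
            block = np.full((net.sizes[a], net.sizes[b]), net.weights[a, b])
            if a == b:
                np.fill_diagonal(block, 0.0)
            J[sl[a], sl[b]] = block
    return J


def build_noise_covariance(net: NetworkParams, noise: NoiseModel) -> np.ndarray:
    """Expanded N x N white-noise covariance Sigma_B.

    Diagonal blocks ``sigma_a^2 [Id + C_aa (ones - Id)]``; off-diagonal
    blocks ``sigma_a sigma_b C_ab ones``.  Raises
    :class:`NotPositiveSemidefiniteError` if the result fails the PSD
    eigenvalue check.
    """
    if noise.sigma.size != net.n_populations:
        raise ValueError("noise model and network have different population counts")
    n = net.n_total
    S = np.zeros((n, n))
    sl = net.population_slices()
    for a in range(net.n_populations):
        for b in range(net.n_populations):
            if a == b:
                block = noise.sigma[a] ** 2 * (
                    np.eye(net.sizes[a])
                    + noise.corr[a, a] * (np.ones((net.sizes[a],) * 2) - np.eye(net.sizes[a]))
                )
            else:
                block = (
                    noise.sigma[a]
                    * noise.sigma[b]
                    * noise.corr[a, b]
                    * np.ones((net.sizes[a], net.sizes[b]))
                )
            S[sl[a], sl[b]] = block
    S = 0.5 * (S + S.T)
    if n:
        min_eig = float(np.linalg.eigvalsh(S)[0])
        tol = PSD_RTOL * max(float(np.max(np.diag(S))), 1e-300)
        if min_eig < -tol:
            raise NotPositiveSemidefiniteError(min_eig)
    return S


def weak_noise_check(eq, net: NetworkParams, noise: NoiseModel, cov) -> NoiseValidityReport:
    """Check the weak-noise assumption behind the linear-response covariance.

    Valid when each population's stationary membrane-potential standard
    deviation is below the radius of curvature of its activation at the
    equilibrium potential.
    """
    mu = population_means(eq.mu, net)
    radii = tuple(
        float(curvature_radius(m, p)) for m, p in zip(mu, net.populations)
    )
    sig_v = tuple(float(s) for s in cov.sigma_v)
    valid = all(s < r for s, r in zip(sig_v, radii))
    return NoiseValidityReport(curvature_radius=radii, sigma_v=sig_v, valid=valid)


def population_means(mu: np.ndarray, net: NetworkParams) -> np.ndarray:
    """Per-population mean of a state vector (identity on reduced states)."""
    mu = np.asarray(mu, dtype=float)
    if mu.size == net.n_populations:
        return mu
    if mu.size == net.n_total:
        return np.array([mu[s].mean() for s in net.population_slices()])
    raise ValueError(f"state vector has unexpected length {mu.size}")


# ---------------------------------------------------------------------------
# reference parameterization: the standard 8E + 2I circuit
# ---------------------------------------------------------------------------

def default_network(
    n_e: int = 8,
    n_i: int = 2,
    j_ee: float = 10.0,
    j_ei: float = -70.0,
    j_ie: float = 70.0,
    j_ii: float = -34.0,
    tau_e: float = 1.0,
    tau_i: float = 1.0,
    nu_max: float = 1.0,
    slope: float = 2.0,
    v_threshold: float = 2.0,
) -> NetworkParams:
    """The reference two-population circuit (8 excitatory, 2 inhibitory).

    The 4:1 E/I ratio matches the proportion of excitatory to inhibitory
    neurons in cortical circuits; weights put the circuit in a regime
    exhibiting fold, Hopf and branching-point bifurcations within
    moderate stimulus ranges.
    """
    E = PopulationParams(EXCITATORY, n_e, tau_e, nu_max, slope, v_threshold)
    I = PopulationParams(INHIBITORY, n_i, tau_i, nu_max, slope, v_threshold)
    return NetworkParams((E, I), np.array([[j_ee, j_ei], [j_ie, j_ii]]))


def default_noise(
    sigma: float | Sequence[float] = 1e-4,
    c_ee: float = 0.0,
    c_ii: float = 0.0,
    c_ei: float = 0.0,
) -> NoiseModel:
    """Reference noise model: weak independent noise (sigma = 1e-4)."""
    s = np.broadcast_to(np.atleast_1d(np.array(sigma, float)), (2,)).copy()
    return NoiseModel(s, np.array([[c_ee, c_ei], [c_ei, c_ii]]))
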