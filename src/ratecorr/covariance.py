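"""Stationary covariance and correlation of the membrane potentials.

Linear response around a stable equilibrium turns the network into
linearly coupled Ornstein-Uhlenbeck processes, whose stationary
covariance solves the algebraic Lyapunov relation

    J Sigma + Sigma J^T + Sigma_B = 0.

Two routes are provided:

* :func:`lyapunov_covariance` — a dense Lyapunov solve, valid for any
  stable Jacobian and any number of populations; the package's
  brute-force oracle.
* :func:`closed_form_covariance` — the explicit two-population block
  formulas in terms of the intra-/inter-population eigenvalues and the
  coupling coefficients K_x.  These expressions are evaluated in complex
  arithmetic (they remain valid across the Hopf neighbourhood, where the
  collective pair is complex conjugate) and the final result is checked
  to be real.

Because the populations are homogeneous, the full covariance has only
five distinct scalars: the two variances, the two within-population pair
covariances and the between-population pair covariance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm, solve_continuous_lyapunov

from .network import (
    NetworkParams,
    NoiseModel,
    activation,
    build_noise_covariance,
    population_means,
)
from .spectrum import (
    DegenerateCouplingError,
    FullJacobian,
    SpectrumResult,
    coupling_coefficients,
    full_jacobian,
    inter_eigenvalues,
    intra_eigenvalues,
    spectrum_at,
    stability,
)

__all__ = [
    "CovarianceResult",
    "RegimeThresholds",
    "closed_form_covariance",
    "lyapunov_covariance",
    "finite_time_covariance",
    "propagator",
    "correlation_from_covariance",
    "rate_statistics",
    "regime_classify",
    "expand_blocks",
]

logger = logging.getLogger(__name__)

#: |K_1 - K_0| below this (relative) threshold makes the closed form
#: ill-conditioned ((K_1 - K_0)^2 denominators) and triggers the
#: Lyapunov fallback; this happens in the decoupled/saturated limit.
K_DEGENERACY_RTOL = 1e-8
#: relative imaginary residue allowed when casting complex results to real
REALITY_RTOL = 1e-10
#: equilibria closer to marginality than this are rejected
MARGINAL_ABSCISSA = 1e-12


class UnstableEquilibriumError(ValueError):
    """The stationary covariance only exists at a strictly stable equilibrium."""


@dataclass(frozen=True)
class CovarianceResult:
    """Block stationary covariance of a two-population network.

    ``sigma_v[a]`` is the membrane-potential standard deviation in
    population ``a``; ``pair_cov`` holds the three distinct pair
    covariances (EE, II, EI) and ``corr`` the corresponding Pearson
    correlations.  ``upsilon``/``delta``/``theta`` expose the closed-form
    coefficients when that route was used (``None`` for the Lyapunov
    route).
    """

    sigma_v: tuple[float, float]
    pair_cov: dict[str, float]  # keys "EE", "II", "EI"
    corr: dict[str, float]
    upsilon: dict[str, complex] | None
    delta: tuple[float, float] | None
    theta: tuple[float, float] | None
    method: str  # "closed_form" | "lyapunov"

    @property
    def variances(self) -> tuple[float, float]:
        return tuple(s**2 for s in self.sigma_v)


def _check_stable(abscissa: float):
    if abscissa >= 0 or abs(abscissa) < MARGINAL_ABSCISSA:
        raise UnstableEquilibriumError(
            f"equilibrium is not strictly stable (spectral abscissa {abscissa:.3e})"
        )


def _real(x: complex, scale: float, what: str) -> float:
    if abs(x.imag) > REALITY_RTOL * max(abs(x.real), scale, 1e-300):
        raise ArithmeticError(
            f"{what} has non-negligible imaginary part {x.imag:.3e}"
        )
    return float(x.real)


# ---------------------------------------------------------------------------
# closed form (two populations)
# ---------------------------------------------------------------------------

def _upsilons(l0: complex, l1: complex, K0: complex, K1: complex) -> dict[str, complex]:
    d2 = (K1 - K0) ** 2
    s = l0 + l1
    return {
        "EE_EE": (2 * K0 * K1 / s - 0.5 * (K0**2 / l1 + K1**2 / l0)) / d2,
        "EE_II": (2 / s - 0.5 * (1 / l0 + 1 / l1)) / d2,
        "II_EE": K0**2 * K1**2 * (2 / s - 0.5 * (1 / l0 + 1 / l1)) / d2,
        "II_II": (2 * K0 * K1 / s - 0.5 * (K0**2 / l0 + K1**2 / l1)) / d2,
        "EE_EI": (0.5 * (K0 / l1 + K1 / l0) - (K0 + K1) / s) / d2,
        "II_EI": K0 * K1 * (0.5 * (K0 / l0 + K1 / l1) - (K0 + K1) / s) / d2,
        "EI_EE": K0 * K1 * ((K0 + K1) / s - 0.5 * (K0 / l1 + K1 / l0)) / d2,
        "EI_II": ((K0 + K1) / s - 0.5 * (K0 / l0 + K1 / l1)) / d2,
        "EI_EI": (K0 * K1 * (1 / l1 + 1 / l0 - 2 / s) - (K0**2 + K1**2) / s) / d2,
    }


def closed_form_covariance(
    eq, net: NetworkParams, noise: NoiseModel
) -> CovarianceResult:
    """Closed-form block covariance for a stable two-population equilibrium.

    Falls back to :func:`lyapunov_covariance` (with a logged notice) when
    the coupling coefficients are degenerate, i.e. when the closed form's
    ``(K_1 - K_0)^2`` denominators are ill-conditioned.
    """
    if net.n_populations != 2:
        raise ValueError("closed-form covariance requires exactly two populations")
    spec = spectrum_at(eq, net)
    _check_stable(spec.spectral_abscissa)

    l0, l1 = spec.lambda_R
    try:
        K0, K1 = coupling_coefficients(spec.lambda_R, eq, net)
    except DegenerateCouplingError:
        K0 = K1 = complex("nan")
    if not (
        np.isfinite([K0.real, K0.imag, K1.real, K1.imag]).all()
        and abs(K1 - K0) > K_DEGENERACY_RTOL * max(abs(K0), abs(K1), 1.0)
    ):
        logger.info(
            "coupling coefficients degenerate (|K1-K0| too small); "
            "falling back to the Lyapunov route"
        )
        return _lyapunov_blocks(eq, net, noise)

    NE, NI = net.sizes
    sE, sI = noise.sigma
    cEE, cII = noise.corr[0, 0], noise.corr[1, 1]
    cEI = noise.corr[0, 1]
    lam_E, lam_I = spec.lambda_E, spec.lambda_I
    if cII == 1.0 and abs(lam_I) < MARGINAL_ABSCISSA:
        raise ArithmeticError(
            "indeterminate 0/0: fully correlated inhibitory noise exactly at a "
            "branching point; the inhibitory variance is undefined here"
        )

    U = _upsilons(l0, l1, K0, K1)
    D_E = 1.0 / NE + cEE * (1.0 - 1.0 / NE)
    D_I = 1.0 / NI + cII * (1.0 - 1.0 / NI)
    Th_E = (1.0 - cEE) / (2.0 * lam_E)
    Th_I = (1.0 - cII) / (2.0 * lam_I)

    var_E = (
        sE**2 * (U["EE_EE"] * D_E - (1.0 - 1.0 / NE) * Th_E)
        + sI**2 * U["EE_II"] * D_I
        + 2.0 * sE * sI * U["EE_EI"] * cEI
    )
    var_I = (
        sI**2 * (U["II_II"] * D_I - (1.0 - 1.0 / NI) * Th_I)
        + sE**2 * U["II_EE"] * D_E
        + 2.0 * sE * sI * U["II_EI"] * cEI
    )
    cov_EE = (
        sE**2 * (U["EE_EE"] * D_E + Th_E / NE)
        + sI**2 * U["EE_II"] * D_I
        + 2.0 * sE * sI * U["EE_EI"] * cEI
    )
    cov_II = (
        sI**2 * (U["II_II"] * D_I + Th_I / NI)
        + sE**2 * U["II_EE"] * D_E
        + 2.0 * sE * sI * U["II_EI"] * cEI
    )
    cov_EI = (
        sE**2 * U["EI_EE"] * D_E
        + sI**2 * U["EI_II"] * D_I
        + sE * sI * U["EI_EI"] * cEI
    )

    scale = max(abs(var_E), abs(var_I))
    var_E = _real(var_E, scale, "excitatory variance")
    var_I = _real(var_I, scale, "inhibitory variance")
    cov_EE = _real(cov_EE, scale, "EE pair covariance")
    cov_II = _real(cov_II, scale, "II pair covariance")
    cov_EI = _real(cov_EI, scale, "EI pair covariance")

    sig_v = (math.sqrt(var_E), math.sqrt(var_I))
    pair = {"EE": cov_EE, "II": cov_II, "EI": cov_EI}
    corr = _block_correlations(sig_v, pair)
    return CovarianceResult(
        sigma_v=sig_v,
        pair_cov=pair,
        corr=corr,
        upsilon=U,
        delta=(D_E, D_I),
        theta=(Th_E, Th_I),
        method="closed_form",
    )


def _block_correlations(sig_v, pair) -> dict[str, float]:
    vE, vI = sig_v
    if vE <= 0 or vI <= 0:
        raise ZeroDivisionError("zero variance: correlations undefined")
    corr = {
        "EE": pair["EE"] / vE**2,
        "II": pair["II"] / vI**2,
        "EI": pair["EI"] / (vE * vI),
    }
    for k, c in corr.items():
        if abs(c) > 1.0 + 1e-10:
            raise ArithmeticError(f"correlation {k} = {c} exceeds [-1, 1]")
        corr[k] = min(1.0, max(-1.0, c))
    return corr


# ---------------------------------------------------------------------------
# Lyapunov route (any number of populations)
# ---------------------------------------------------------------------------

def lyapunov_covariance(jac, sigma_b: np.ndarray) -> np.ndarray:
    """Stationary N x N covariance from the algebraic Lyapunov relation.

    Requires a strictly stable Jacobian.  Serves as the independent
    oracle for the closed-form route and as the general-P fallback.
    """
    J = jac.matrix if isinstance(jac, FullJacobian) else np.asarray(jac, dtype=float)
    _, absc = stability(J)
    _check_stable(absc)
    S = solve_continuous_lyapunov(J, -np.asarray(sigma_b, dtype=float))
    return 0.5 * (S + S.T)


def _lyapunov_blocks(eq, net, noise) -> CovarianceResult:
    J = full_jacobian(eq, net)
    S = lyapunov_covariance(J, build_noise_covariance(net, noise))
    slE, slI = net.population_slices()
    NE, NI = net.sizes
    var_E = float(np.mean(np.diag(S)[slE]))
    var_I = float(np.mean(np.diag(S)[slI]))
    pair = {
        "EE": _offdiag_mean(S[slE, slE]) if NE >= 2 else math.nan,
        "II": _offdiag_mean(S[slI, slI]) if NI >= 2 else math.nan,
        "EI": float(np.mean(S[slE, slI])),
    }
    sig_v = (math.sqrt(var_E), math.sqrt(var_I))
    return CovarianceResult(
        sigma_v=sig_v,
        pair_cov=pair,
        corr=_block_correlations(sig_v, pair),
        upsilon=None,
        delta=None,
        theta=None,
        method="lyapunov",
    )


def _offdiag_mean(block: np.ndarray) -> float:
    n = block.shape[0]
    return float((block.sum() - np.trace(block)) / (n * (n - 1)))


def expand_blocks(cov: CovarianceResult, net: NetworkParams) -> np.ndarray:
    """Expand the five block scalars into the full N x N covariance matrix."""
    NE, NI = net.sizes
    vE, vI = cov.variances
    S = np.empty((net.n_total, net.n_total))
    slE, slI = net.population_slices()
    S[slE, slE] = cov.pair_cov["EE"]
    S[slI, slI] = cov.pair_cov["II"]
    S[slE, slI] = cov.pair_cov["EI"]
    S[slI, slE] = cov.pair_cov["EI"]
    d = np.concatenate([np.full(NE, vE), np.full(NI, vI)])
    S[np.diag_indices_from(S)] = d
    return S


# ---------------------------------------------------------------------------
# finite-time covariance and propagator
# ---------------------------------------------------------------------------

def propagator(jac, t: float) -> np.ndarray:
    """Fundamental matrix Phi(t) = exp(J t) of the linearized dynamics."""
    J = jac.matrix if isinstance(jac, FullJacobian) else np.asarray(jac, dtype=float)
    return expm(J * float(t))


def finite_time_covariance(
    jac, sigma_b: np.ndarray, t: float, rtol: float = 1e-10, atol: float = 1e-14
) -> np.ndarray:
    """Covariance at finite time from a deterministic initial condition.

    Integrates d Sigma/dt = J Sigma + Sigma J^T + Sigma_B from Sigma(0) = 0;
    converges to :func:`lyapunov_covariance` as t grows when J is stable.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    J = jac.matrix if isinstance(jac, FullJacobian) else np.asarray(jac, dtype=float)
    SB = np.asarray(sigma_b, dtype=float)
    n = J.shape[0]
    if t == 0:
        return np.zeros((n, n))

    def rhs(_, y):
        S = y.reshape(n, n)
        dS = J @ S + S @ J.T + SB
        return dS.ravel()

    sol = solve_ivp(
        rhs, (0.0, float(t)), np.zeros(n * n), method="RK45", rtol=rtol, atol=atol
    )
    if not sol.success:
        raise RuntimeError(f"finite-time covariance integration failed: {sol.message}")
    S = sol.y[:, -1].reshape(n, n)
    return 0.5 * (S + S.T)


# ---------------------------------------------------------------------------
# correlation, rates, regime
# ---------------------------------------------------------------------------

def correlation_from_covariance(S: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix from a covariance matrix.

    Entries overshooting [-1, 1] by less than 1e-10 are clipped; larger
    overshoots raise.
    """
    S = np.asarray(S, dtype=float)
    v = np.diag(S)
    if np.any(v <= 0):
        raise ZeroDivisionError("zero variance: correlation undefined")
    d = 1.0 / np.sqrt(v)
    C = S * d[:, None] * d[None, :]
    if np.any(np.abs(C) > 1.0 + 1e-10):
        raise ArithmeticError("correlation entries exceed [-1, 1] beyond tolerance")
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return 0.5 * (C + C.T)


@dataclass(frozen=True)
class RateStatistics:
    mean_rates: tuple[float, float]
    rate_corr: dict[str, float]
    geometric_mean_rates: dict[str, float]


def rate_statistics(eq, cov: CovarianceResult, net: NetworkParams) -> RateStatistics:
    """Mean firing rates and rate correlations at an equilibrium.

    At first perturbative order the rate correlations equal the membrane
    potential correlations; the geometric-mean rates sqrt(nu_a nu_b)
    provide the natural abscissa for correlation-vs-rate summaries.
    """
    mu = population_means(eq.mu, net)
    nu = tuple(
        float(activation(m, p)) for m, p in zip(mu, net.populations)
    )
    geo = {
        "EE": nu[0],
        "II": nu[1],
        "EI": math.sqrt(nu[0] * nu[1]),
    }
    return RateStatistics(mean_rates=nu, rate_corr=dict(cov.corr), geometric_mean_rates=geo)


@dataclass(frozen=True)
class RegimeThresholds:
    """Classification thresholds (dimensionless unless noted).

    ``c_low``/``c_high`` bound the block correlations; ``s_high`` caps the
    fluctuation scale relative to the decoupled Ornstein-Uhlenbeck value
    sigma_B/sqrt(2 tau); ``a_slow`` is the spectral-abscissa margin below
    which relaxation is considered critically slow (1/time units).
    """

    c_low: float = 0.1
    c_high: float = 0.9
    s_high: float = 2.0
    a_slow: float = 0.05


def regime_classify(
    cov: CovarianceResult,
    spec: SpectrumResult,
    net: NetworkParams,
    noise: NoiseModel,
    thresholds: RegimeThresholds = RegimeThresholds(),
) -> tuple[str, dict]:
    """Classify the operating regime as asynchronous / synchronous / intermediate.

    Asynchronous: all block correlations small and fluctuation scales
    close to the decoupled value.  Synchronous: strong correlations or
    critical slowing down (spectral abscissa near zero).
    """
    max_corr = max(abs(c) for c in cov.corr.values())
    ou_scale = noise.sigma / np.sqrt(2.0 * net.taus)
    ratios = np.array(cov.sigma_v) / ou_scale
    diag = {
        "max_abs_corr": max_corr,
        "sigma_ratio": tuple(float(r) for r in ratios),
        "spectral_abscissa": spec.spectral_abscissa,
    }
    if max_corr < thresholds.c_low and np.all(ratios < thresholds.s_high):
        return "asynchronous", diag
    if max_corr > thresholds.c_high or spec.spectral_abscissa > -thresholds.a_slow:
        return "synchronous", diag
    return "intermediate", diag
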