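"""Codimension-one local bifurcations: analytic conditions and localization.

Three kinds of local codimension-one bifurcation occur in the
two-population circuit, each signalled by a different eigenvalue of the
Jacobian crossing the imaginary axis:

* saddle-node (fold, LP): a real collective eigenvalue lambda_R crosses
  zero; the branch terminates and every block correlation tends to 1;
* Andronov-Hopf (H): the complex-conjugate collective pair crosses the
  axis (Re(lambda_R_0 + lambda_R_1) = 0 with nonzero imaginary part);
  within-population correlations tend to 1, the between-population one
  does not;
* branching point (BP, pitchfork): the intra-population inhibitory
  eigenvalue lambda_I crosses zero; the inhibitory population breaks
  symmetry and its pairwise correlation tends to 1/(1 - N_I) — maximal
  anti-correlation, a finite-size effect absent in the thermodynamic
  limit.

Necessary conditions on the weights for each kind are evaluated exactly;
locations along a stimulus segment are found by natural continuation of
the equilibrium branch plus bisection on the crossing eigenvalue (or on
branch existence, for folds, where the branch itself terminates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .equilibria import (
    AXIS_INDEX,
    JUMP_RADIUS,
    Equilibrium,
    _make_equilibrium,
    _select_start,
    _solve_reduced,
    find_fixed_points,
)
from .network import NetworkParams, NoiseModel, Stimulus, activation_slope, population_means
from .spectrum import intra_eigenvalues, inter_eigenvalues

__all__ = [
    "HopfConditionTerms",
    "BifurcationPoint",
    "saddle_node_condition",
    "hopf_condition",
    "branching_condition",
    "locate_on_segment",
    "limiting_correlations",
]

#: tolerance on the crossing-eigenvalue quantity at a reported location
RESIDUAL_TOL = 1e-6
#: imaginary parts below this classify the collective pair as real
REAL_PAIR_TOL = 1e-9


@dataclass(frozen=True)
class HopfConditionTerms:
    a: float
    b: float
    c: float
    z: float
    discriminant: float
    satisfied: bool


@dataclass(frozen=True)
class BifurcationPoint:
    kind: str  # "saddle_node" | "hopf" | "branching_point" | "other"
    axis: str
    location: float
    fixed_value: float
    eigen_signature: str
    localization_residual: float
    stable_side: bool  # branch is stable on (at least) one side of the point


# ---------------------------------------------------------------------------
# analytic necessary conditions
# ---------------------------------------------------------------------------

def _two_pop(net: NetworkParams):
    if net.n_populations != 2:
        raise ValueError("bifurcation conditions are defined for two populations")
    return net.populations


def saddle_node_condition(net: NetworkParams) -> tuple[float, bool]:
    """Fold necessary condition: strong enough recurrent excitation.

    quantity = ((N_E - 1)/(N - 1)) J_EE (nu_E_max Lambda_E / 4) tau_E;
    a fold requires quantity > 1 (strict).
    """
    popE, _ = _two_pop(net)
    N = net.n_total
    q = (
        (popE.size - 1)
        / (N - 1)
        * net.weights[0, 0]
        * popE.nu_max
        * popE.slope
        / 4.0
        * popE.tau
    )
    return float(q), bool(q > 1.0)


def hopf_condition(net: NetworkParams) -> HopfConditionTerms:
    """Hopf necessary condition on the weights.

    The quadratic a z^2 + b z + c (with c = 1/tau_E^2) must have real
    roots, and the selected root z = (-b - sqrt(b^2 - 4ac)) / (2a) must
    satisfy nu_E_max Lambda_E / (4 z) > 1.
    """
    popE, popI = _two_pop(net)
    JEE, JEI = net.weights[0]
    JIE, JII = net.weights[1]
    if JII == 0:
        raise ZeroDivisionError("hopf condition requires J_II != 0")
    if popI.size < 2:
        raise ZeroDivisionError("hopf condition requires N_I >= 2")
    N = net.n_total
    NE, NI = popE.size, popI.size
    a = ((NE - 1) / (N - 1) * JEE) ** 2 - (
        NE * NI * (NE - 1) / ((N - 1) ** 2 * (NI - 1))
    ) * (JEE * JEI * JIE / JII)
    b = -2.0 / popE.tau * (NE - 1) / (N - 1) * JEE + (
        NE * NI / ((N - 1) * (NI - 1))
    ) * (JEI * JIE / JII) * (1.0 / popE.tau + 1.0 / popI.tau)
    c = 1.0 / popE.tau**2
    disc = b * b - 4.0 * a * c
    if a == 0.0 or disc <= 0.0:
        return HopfConditionTerms(a, b, c, math.nan, disc, False)
    z = (-b - math.sqrt(disc)) / (2.0 * a)
    satisfied = z > 0 and popE.nu_max * popE.slope / (4.0 * z) > 1.0
    return HopfConditionTerms(a, b, c, z, disc, bool(satisfied))


def branching_condition(net: NetworkParams) -> tuple[float, bool]:
    """Branching-point necessary condition: strong enough self-inhibition.

    quantity = tau_I |J_II| nu_I_max Lambda_I / (4 (N - 1)); a branching
    point requires quantity > 1 (strict).  The quantity vanishes as
    N grows with fixed weights: symmetry breaking is a finite-size effect.
    """
    _, popI = _two_pop(net)
    N = net.n_total
    q = popI.tau * abs(net.weights[1, 1]) * popI.nu_max * popI.slope / (4.0 * (N - 1))
    return float(q), bool(q > 1.0)


# ---------------------------------------------------------------------------
# localization along a stimulus segment
# ---------------------------------------------------------------------------

def _indicators(mu, net):
    """Scalar crossing indicators of the three bifurcation kinds at mu.

    Returns (trace, product, min-|real| collective eigenvalue, lambda_E,
    lambda_I, pair_is_real): the real-part sum of the collective pair
    (Hopf indicator), the product of its real parts (fold indicator when
    the pair is real) and the two intra-population eigenvalues.
    """
    lam_E, lam_I = intra_eigenvalues(_Bare(mu), net)
    (r0, r1), _ = inter_eigenvalues(_Bare(mu), net)
    pair_real = abs(r0.imag) < REAL_PAIR_TOL and abs(r1.imag) < REAL_PAIR_TOL
    return (
        (r0 + r1).real,
        r0.real * r1.real,
        min(r0.real, r1.real, key=abs),
        lam_E,
        lam_I,
        pair_real,
    )


class _Bare:
    """Minimal state wrapper so spectrum helpers accept a raw mu vector."""

    def __init__(self, mu):
        self.mu = np.asarray(mu, dtype=float)


def _bisect_indicator(f, lo, hi, xtol=1e-10):
    return brentq(f, lo, hi, xtol=xtol)


def locate_on_segment(
    axis: str,
    scan_range: tuple[float, float],
    fixed_value: float,
    net: NetworkParams,
    noise: NoiseModel | None = None,
    step: float = 0.01,
    seed: int = 0,
) -> list[BifurcationPoint]:
    """Locate codimension-one bifurcations along one stimulus segment.

    The equilibrium branch is continued from each endpoint of the
    segment (warm-started Newton).  Along a branch, sign changes of the
    three scalar indicators — the real part of the collective-pair sum
    (Hopf, conjugate pair), the intra-population eigenvalues (branching
    point for lambda_I, unclassified for lambda_E) and termination of
    the branch with a real collective eigenvalue approaching zero
    (fold) — are refined by bisection.  Points found by both sweeps are
    deduplicated.
    """
    axis_idx = AXIS_INDEX.get(axis)
    if axis_idx is None:
        raise ValueError(f"axis must be one of {sorted(AXIS_INDEX)}")
    lo, hi = sorted(map(float, scan_range))
    base = Stimulus.ei(0.0, fixed_value) if axis_idx == 0 else Stimulus.ei(fixed_value, 0.0)

    points: list[BifurcationPoint] = []
    for start, stop in ((lo, hi), (hi, lo)):
        eq0 = _select_start(
            find_fixed_points(base.with_value(axis_idx, start), net, seed=seed)
        )
        if eq0 is None:
            continue
        points.extend(
            _sweep_and_locate(axis, axis_idx, start, stop, base, net, step, eq0)
        )

    # dedupe points located from both directions
    uniq: list[BifurcationPoint] = []
    for p in sorted(points, key=lambda p: p.location):
        dup = next(
            (
                i
                for i, q in enumerate(uniq)
                if q.kind == p.kind and abs(q.location - p.location) < 1e-4
            ),
            None,
        )
        if dup is None:
            uniq.append(p)
        elif p.stable_side and not uniq[dup].stable_side:
            uniq[dup] = p
    return uniq


def _sweep_and_locate(axis, axis_idx, start, stop, base, net, step, eq0):
    direction = 1.0 if stop >= start else -1.0
    value = float(start)
    mu = np.asarray(eq0.mu, dtype=float)
    prev = (value, mu) + _indicators(mu, net)
    out = []

    def solve_at(v, warm):
        return _solve_reduced(warm, base.with_value(axis_idx, v), net)

    while direction * (stop - value) > 1e-12:
        nxt_value = value + direction * min(step, abs(stop - value))
        nxt = solve_at(nxt_value, mu)
        if nxt is None or np.max(np.abs(nxt - mu)) > JUMP_RADIUS:
            p = _refine_fold(axis, axis_idx, value, nxt_value, base, net, mu)
            if p is not None:
                out.append(p)
            break
        ind2 = _indicators(nxt, net)
        tr2, prod2, _, lam_E2, lam_I2, pair_real2 = ind2
        v1, mu1, tr1, prod1, _, lam_E1, lam_I1, pair_real1 = prev

        def branch_indicator(pick):
            def f(v):
                m = solve_at(v, mu1 if abs(v - v1) < abs(v - nxt_value) else nxt)
                if m is None:
                    raise RuntimeError("branch lost during bisection")
                return pick(_indicators(m, net))

            return f

        lo_, hi_ = sorted((v1, nxt_value))
        crossings = []
        if tr1 * tr2 < 0 and not (pair_real1 and pair_real2):
            crossings.append(
                (
                    "hopf",
                    branch_indicator(lambda ind: ind[0]),
                    "collective conjugate pair crosses the imaginary axis",
                )
            )
        if pair_real1 and pair_real2 and prod1 * prod2 < 0:
            crossings.append(
                (
                    "saddle_node",
                    branch_indicator(lambda ind: ind[1]),
                    "real collective eigenvalue crosses zero",
                )
            )
        if lam_I1 * lam_I2 < 0:
            crossings.append(
                (
                    "branching_point",
                    branch_indicator(lambda ind: ind[4]),
                    "intra-population inhibitory eigenvalue lambda_I crosses zero",
                )
            )
        if lam_E1 * lam_E2 < 0:
            crossings.append(
                (
                    "other",
                    branch_indicator(lambda ind: ind[3]),
                    "intra-population excitatory eigenvalue lambda_E crosses zero",
                )
            )
        for kind, f, sig in crossings:
            loc = _bisect_indicator(f, lo_, hi_)
            out.append(_point(kind, axis, loc, base, axis_idx, net, mu, sig, f))
        value, mu = nxt_value, nxt
        prev = (value, mu) + ind2
    return out


def _point(kind, axis, loc, base, axis_idx, net, warm, signature, indicator):
    residual = indicator(loc)
    return BifurcationPoint(
        kind=kind,
        axis=axis,
        location=float(loc),
        fixed_value=float(base.values[1 - axis_idx]),
        eigen_signature=signature,
        localization_residual=float(residual),
        stable_side=_stable_nearby(axis_idx, loc, base, net, warm),
    )


def _stable_nearby(axis_idx, loc, base, net, warm, delta=1e-3):
    for sgn in (-1.0, 1.0):
        m = _solve_reduced(warm, base.with_value(axis_idx, loc + sgn * delta), net)
        if m is None:
            continue
        eq = _make_equilibrium(
            m, base.with_value(axis_idx, loc + sgn * delta), net, "reduced"
        )
        if eq.stable:
            return True
    return False


def _refine_fold(axis, axis_idx, good, bad, base, net, mu):
    """Bisect on branch existence where continuation terminated (fold)."""
    warm = mu.copy()
    lo, hi = good, bad
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        m = _solve_reduced(warm, base.with_value(axis_idx, mid), net)
        if m is not None and np.max(np.abs(m - warm)) < JUMP_RADIUS:
            lo, warm = mid, m
        else:
            hi = mid
    _, _, min_real, _, _, pair_real = _indicators(warm, net)
    if not pair_real or abs(min_real) > RESIDUAL_TOL:
        return None  # branch lost for another reason; not a clean fold
    return BifurcationPoint(
        kind="saddle_node",
        axis=axis,
        location=float(lo),
        fixed_value=float(base.values[1 - axis_idx]),
        eigen_signature="real collective eigenvalue reaches zero; branch terminates",
        localization_residual=float(min_real),
        stable_side=_stable_nearby(axis_idx, lo, base, net, warm),
    )


# ---------------------------------------------------------------------------
# limiting correlations at each bifurcation kind
# ---------------------------------------------------------------------------

def limiting_correlations(
    kind: str, net: NetworkParams, noise: NoiseModel, eq: Equilibrium | None = None
) -> dict:
    """Predicted limits of the block correlations approaching a bifurcation.

    fold: every block correlation tends to 1 and sigma_I/sigma_E tends to
    the (positive) fold coupling coefficient K.  hopf: within-population
    correlations tend to 1; the between-population correlation stays away
    from 1 (its limit is reported as computed, not asserted).  branching
    point: C_II tends to 1/(1 - N_I) when the inhibitory noise is not
    perfectly correlated; the excitatory statistics stay bounded.
    """
    popE, popI = _two_pop(net)
    if kind == "saddle_node":
        out = {"C_EE": 1.0, "C_II": 1.0, "C_EI": 1.0}
        if eq is not None:
            mu = population_means(eq.mu, net)
            apE = activation_slope(mu[0], popE)
            apI = activation_slope(mu[1], popI)
            K = (popE.size * net.weights[1, 0] * apE) / (
                popI.in_degree / popI.tau - (popI.size - 1) * net.weights[1, 1] * apI
            )
            out["sigma_ratio_I_over_E"] = float(K)
        return out
    if kind == "hopf":
        return {"C_EE": 1.0, "C_II": 1.0, "C_EI": None}
    if kind == "branching_point":
        if noise.corr[1, 1] >= 1.0:
            return {"C_II": 1.0, "note": "fully correlated inhibitory noise wins"}
        return {"C_II": 1.0 / (1.0 - popI.size), "excitatory": "bounded"}
    raise ValueError(f"unknown bifurcation kind {kind!r}")
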