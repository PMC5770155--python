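"""Stationary states of the noiseless dynamics and their continuation.

Two representations are used.  The *reduced* form exploits population
homogeneity: one membrane potential per population, with the recurrent
input of population ``a`` given by

    [(N_a - 1) J_aa A_a(mu_a) + sum_{b != a} N_b J_ab A_b(mu_b)] / M_a.

The *full* form keeps all N neuron potentials and is needed for the
symmetry-broken equilibria that appear beyond a branching point, where
neurons of one (inhibitory) population split onto distinct branches.

Stability is always judged on the full N-dimensional Jacobian, because
the intra-population eigenvalues (responsible for branching-point
instabilities) are invisible in the reduced system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    NetworkParams,
    Stimulus,
    activation,
    activation_slope,
    build_connectivity,
)

__all__ = [
    "Equilibrium",
    "BranchTable",
    "reduced_drift",
    "reduced_jacobian",
    "full_drift",
    "equilibrium_at",
    "find_fixed_points",
    "find_fixed_points_full",
    "continue_branch",
]

#: max-norm residual below which a root is accepted
DRIFT_TOL = 1e-12
#: max-norm radius within which two equilibria are considered the same
DEDUP_RADIUS = 1e-6
#: continuation: a warm-started solve that moves further than this is
#: treated as a jump onto another branch (branch terminated)
JUMP_RADIUS = 0.5


@dataclass(frozen=True)
class Equilibrium:
    """A stationary state of the deterministic system."""

    mu: np.ndarray
    stimulus: Stimulus
    stable: bool
    spectral_abscissa: float
    representation: str  # "reduced" | "full"

    def __post_init__(self):
        m = np.array(self.mu, dtype=float)
        m.setflags(write=False)
        object.__setattr__(self, "mu", m)
        if self.representation not in ("reduced", "full"):
            raise ValueError("representation must be 'reduced' or 'full'")


@dataclass
class BranchTable:
    """Equilibria along a one-parameter stimulus scan."""

    scan_axis: str  # "I_E" | "I_I"
    fixed_value: float
    points: list[tuple[float, Equilibrium]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for value, eq in self.points:
            row = {self.scan_axis: value}
            for k, m in enumerate(eq.mu):
                row[f"mu_{k}"] = m
            row["stable"] = eq.stable
            row["spectral_abscissa"] = eq.spectral_abscissa
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


AXIS_INDEX = {"I_E": 0, "I_I": 1}


# ---------------------------------------------------------------------------
# drift fields
# ---------------------------------------------------------------------------

def reduced_drift(mu, stim: Stimulus, net: NetworkParams) -> np.ndarray:
    """Drift of the homogeneous (one variable per population) reduction."""
    mu = np.asarray(mu, dtype=float)
    P = net.n_populations
    rates = np.array([activation(mu[a], net.populations[a]) for a in range(P)])
    sizes, M = net.sizes, net.in_degrees
    out = np.empty(P)
    for a in range(P):
        eff = sizes.astype(float).copy()
        eff[a] -= 1.0  # no self-connection
        rec = float(np.dot(net.weights[a] * eff, rates))
        out[a] = -mu[a] / net.populations[a].tau + rec / M[a] + stim.values[a]
    return out


def reduced_jacobian(mu, net: NetworkParams) -> np.ndarray:
    """Jacobian of :func:`reduced_drift` with respect to mu (P x P)."""
    mu = np.asarray(mu, dtype=float)
    P = net.n_populations
    slopes = np.array(
        [activation_slope(mu[a], net.populations[a]) for a in range(P)]
    )
    sizes, M = net.sizes, net.in_degrees
    J = np.empty((P, P))
    for a in range(P):
        eff = sizes.astype(float).copy()
        eff[a] -= 1.0
        J[a] = net.weights[a] * eff * slopes / M[a]
        J[a, a] -= 1.0 / net.populations[a].tau
    return J


def full_drift(v, stim: Stimulus, net: NetworkParams, conn: np.ndarray | None = None) -> np.ndarray:
    """Drift of the full N-dimensional system."""
    v = np.asarray(v, dtype=float)
    if conn is None:
        conn = build_connectivity(net)
    rates = np.concatenate(
        [activation(v[s], p) for s, p in zip(net.population_slices(), net.populations)]
    )
    I = np.repeat(np.asarray(stim.values), net.sizes)
    return -v / net.neuron_taus() + (conn @ rates) / net.neuron_in_degrees() + I


def _full_drift_jacobian(v, net: NetworkParams, conn: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    slopes = np.concatenate(
        [activation_slope(v[s], p) for s, p in zip(net.population_slices(), net.populations)]
    )
    J = conn * slopes[None, :] / net.neuron_in_degrees()[:, None]
    J[np.diag_indices_from(J)] -= 1.0 / net.neuron_taus()
    return J


# ---------------------------------------------------------------------------
# root finding
# ---------------------------------------------------------------------------

def _damped_newton(f, jac, x0, tol=DRIFT_TOL, maxit=200):
    """Newton iteration with backtracking on the residual max-norm."""
    x = np.array(x0, dtype=float)
    fx = f(x)
    for _ in range(maxit):
        nrm = np.max(np.abs(fx))
        if nrm < tol:
            return x
        try:
            step = np.linalg.solve(jac(x), fx)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(step)):
            return None
        lam = 1.0
        for _ in range(50):
            xn = x - lam * step
            fn = f(xn)
            if np.max(np.abs(fn)) < nrm:
                x, fx = xn, fn
                break
            lam *= 0.5
        else:
            return None
    return x if np.max(np.abs(f(x))) < tol else None


def _solve_reduced(mu0, stim, net, tol=DRIFT_TOL):
    return _damped_newton(
        lambda m: reduced_drift(m, stim, net),
        lambda m: reduced_jacobian(m, net),
        mu0,
        tol=tol,
    )


def _make_equilibrium(mu, stim, net, representation) -> Equilibrium:
    # stability from the full Jacobian: intra-population modes matter
    from .spectrum import full_jacobian, stability

    if representation == "reduced":
        v = np.repeat(np.asarray(mu, float), net.sizes)
    else:
        v = np.asarray(mu, float)
    conn = build_connectivity(net)
    J = _full_drift_jacobian(v, net, conn)
    stable, absc = stability(J)
    return Equilibrium(
        mu=np.asarray(mu, float),
        stimulus=stim,
        stable=stable,
        spectral_abscissa=absc,
        representation=representation,
    )


def equilibrium_at(
    mu, stim: Stimulus, net: NetworkParams, representation: str = "reduced"
) -> Equilibrium:
    """Wrap a known stationary state, verifying the drift residual.

    Useful when the stimulus was chosen to make a given state stationary
    (every state is an equilibrium for exactly one stimulus).
    """
    mu = np.asarray(mu, dtype=float)
    res = (
        reduced_drift(mu, stim, net)
        if representation == "reduced"
        else full_drift(mu, stim, net)
    )
    if np.max(np.abs(res)) > 1e-9:
        raise ValueError(
            f"state is not stationary (drift residual {np.max(np.abs(res)):.3e})"
        )
    return _make_equilibrium(mu, stim, net, representation)


def find_fixed_points(
    stim: Stimulus,
    net: NetworkParams,
    n_starts: int = 40,
    seed: int = 0,
    grid: int = 21,
    box_halfwidth: float = 10.0,
) -> list[Equilibrium]:
    """All reduced equilibria found by multi-start damped Newton.

    Starts on a deterministic grid over the box ``[V_T - w, V_T + w]^P``
    (the activation saturates, so equilibria are confined to a bounded
    region around threshold) plus ``n_starts`` seeded random points.
    """
    P = net.n_populations
    centers = np.array([p.v_threshold for p in net.populations])
    axes = [np.linspace(c - box_halfwidth, c + box_halfwidth, grid) for c in centers]
    if P == 2:
        starts = [np.array([a, b]) for a in axes[0] for b in axes[1]]
    else:
        # grid is exponential in P; fall back to axis-aligned + random starts
        starts = [centers + 0.0]
    rng = np.random.default_rng(seed)
    for _ in range(n_starts):
        starts.append(centers + rng.uniform(-box_halfwidth, box_halfwidth, P))

    found: list[np.ndarray] = []
    for s in starts:
        mu = _solve_reduced(s, stim, net)
        if mu is None:
            continue
        if not any(np.max(np.abs(mu - m)) < DEDUP_RADIUS for m in found):
            found.append(mu)
    found.sort(key=lambda m: tuple(m))
    return [_make_equilibrium(m, stim, net, "reduced") for m in found]


def find_fixed_points_full(
    stim: Stimulus, net: NetworkParams, starts
) -> list[Equilibrium]:
    """Equilibria of the full N-dimensional drift from user-supplied starts.

    Homogeneous equilibria embed the reduced ones; beyond a branching
    point, perturbed starts converge onto symmetry-broken equilibria in
    which neurons of the same population carry different potentials.
    """
    starts = [np.asarray(s, dtype=float) for s in starts]
    if not starts:
        raise ValueError("at least one start vector is required")
    conn = build_connectivity(net)
    f = lambda v: full_drift(v, stim, net, conn)
    jac = lambda v: _full_drift_jacobian(v, net, conn)
    found: list[np.ndarray] = []
    for s in starts:
        if s.size != net.n_total:
            raise ValueError("start vectors must have length N")
        v = _damped_newton(f, jac, s)
        if v is None:
            continue
        if not any(np.max(np.abs(v - w)) < DEDUP_RADIUS for w in found):
            found.append(v)
    found.sort(key=lambda m: tuple(m))
    return [_make_equilibrium(v, stim, net, "full") for v in found]


# ---------------------------------------------------------------------------
# natural-parameter continuation
# ---------------------------------------------------------------------------

def _select_start(eqs: list[Equilibrium]) -> Equilibrium | None:
    """Prefer a stable equilibrium; otherwise the least unstable one."""
    if not eqs:
        return None
    stable = [e for e in eqs if e.stable]
    pool = stable if stable else eqs
    return min(pool, key=lambda e: e.spectral_abscissa)


def _sweep(axis_idx, start_value, stop_value, base_stim, net, step, mu0, seed):
    """Warm-started natural continuation from one endpoint toward the other."""
    direction = 1.0 if stop_value >= start_value else -1.0
    value = start_value
    stim = base_stim.with_value(axis_idx, value)
    mu = _solve_reduced(mu0, stim, net)
    if mu is None:
        return []
    points = [(value, mu)]
    while direction * (stop_value - value) > 1e-12:
        nxt_value = value + direction * min(step, abs(stop_value - value))
        stim = base_stim.with_value(axis_idx, nxt_value)
        nxt = _solve_reduced(mu, stim, net)
        if nxt is None or np.max(np.abs(nxt - mu)) > JUMP_RADIUS:
            break  # fold passed: branch terminates here
        value, mu = nxt_value, nxt
        points.append((value, mu))
    return points


def continue_branch(
    axis: str,
    scan_range: tuple[float, float],
    fixed_value: float,
    net: NetworkParams,
    step: float = 1e-2,
    seed: int = 0,
) -> BranchTable:
    """Natural-parameter continuation over a stimulus interval.

    Continues from each endpoint toward the other, warm-starting every
    solve from the previous point; a branch halts where the solver fails
    or jumps (a fold has been passed), and the sweep from the other
    endpoint recovers coexisting branches.  Points from both sweeps are
    concatenated and sorted by stimulus value.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    axis_idx = AXIS_INDEX.get(axis)
    if axis_idx is None:
        raise ValueError(f"axis must be one of {sorted(AXIS_INDEX)}")
    lo, hi = sorted(map(float, scan_range))
    if axis_idx == 0:
        base = Stimulus.ei(0.0, fixed_value)
    else:
        base = Stimulus.ei(fixed_value, 0.0)

    all_points: list[tuple[float, np.ndarray]] = []
    for start, stop in ((lo, hi), (hi, lo)):
        stim0 = base.with_value(axis_idx, start)
        eq0 = _select_start(find_fixed_points(stim0, net, seed=seed))
        if eq0 is None:
            continue
        all_points.extend(_sweep(axis_idx, start, stop, base, net, step, eq0.mu, seed))
    if not all_points:
        raise RuntimeError("no equilibrium found at either endpoint of the scan")

    # drop duplicates where the two sweeps traced the same branch
    uniq: list[tuple[float, np.ndarray]] = []
    for v, m in sorted(all_points, key=lambda t: t[0]):
        if any(
            abs(v - v2) < 0.5 * step and np.max(np.abs(m - m2)) < DEDUP_RADIUS
            for v2, m2 in uniq
        ):
            continue
        uniq.append((v, m))

    points = [
        (v, _make_equilibrium(m, base.with_value(axis_idx, v), net, "reduced"))
        for v, m in uniq
    ]
    return BranchTable(scan_axis=axis, fixed_value=fixed_value, points=points)
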