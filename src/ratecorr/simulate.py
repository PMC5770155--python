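"""Euler-Maruyama Monte-Carlo simulation of the stochastic rate equations.

Provides the empirical counterpart of the analytic covariance: ensembles
of independent trials integrated with the Euler-Maruyama scheme

    V(t + dt) = V + dt * drift(V) + sqrt(dt) * L xi,     L L^T = Sigma_B,

started at a deterministic state (normally the stable equilibrium under
study) and sampled at fixed recording times.  Statistics are computed
across trials, so one recording time yields one sample of every neuron's
stationary law.

Reproducibility: each trial owns an independent generator seeded from
(seed, trial index), so any subset of trials is bit-reproducible
regardless of how many trials are run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkParams, NoiseModel, Stimulus, activation, build_connectivity, build_noise_covariance

__all__ = [
    "SimulationConfig",
    "Ensemble",
    "EnsembleStatistics",
    "simulate_paths",
    "noise_factor",
    "empirical_statistics",
]

#: negative Sigma_B eigenvalues above this (relative) are clipped to zero
FACTOR_CLIP_RTOL = 1e-12
#: steps processed per noise-buffer refill; bounds memory at
#: n_trials * chunk * N doubles without affecting per-trial streams
TIME_CHUNK = 500


class OverflowDetected(RuntimeError):
    def __init__(self, t: float):
        self.time = t
        super().__init__(f"trajectory overflow at t = {t:g}")


@dataclass(frozen=True)
class SimulationConfig:
    """Euler-Maruyama ensemble settings.

    Defaults follow the reference protocol: dt = 1e-3, integration over
    [0, 30] (long enough for the stationary regime away from
    bifurcations), recording at t = 30, 5000 trials.
    """

    dt: float = 1e-3
    t_end: float = 30.0
    n_trials: int = 5000
    seed: int = 0
    record_times: tuple[float, ...] = (30.0,)

    def __post_init__(self):
        if not 0 < self.dt < self.t_end:
            raise ValueError("need 0 < dt < t_end")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        rt = tuple(float(t) for t in self.record_times)
        if not rt or min(rt) < 0 or max(rt) > self.t_end + 1e-12:
            raise ValueError("record_times must lie within [0, t_end]")
        object.__setattr__(self, "record_times", rt)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    def record_steps(self) -> list[int]:
        return [int(round(t / self.dt)) for t in self.record_times]


@dataclass(frozen=True)
class Ensemble:
    """Recorded membrane potentials: shape (trial, recorded time, neuron)."""

    values: np.ndarray
    config: SimulationConfig
    initial_state: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape[1] != len(self.config.record_times):
            raise ValueError("values shape inconsistent with record_times")
        if not np.all(np.isfinite(v)):
            raise ValueError("ensemble contains non-finite values")


def noise_factor(sigma_b: np.ndarray) -> np.ndarray:
    """A factor L with L L^T = Sigma_B.

    Cholesky when positive definite; otherwise an eigenvalue factor with
    tiny negative eigenvalues clipped to zero (exactly singular noise,
    e.g. perfectly shared noise, is legitimate).  Indefinite input raises.
    """
    S = np.asarray(sigma_b, dtype=float)
    if not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("noise covariance must be symmetric")
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(S)
        tol = FACTOR_CLIP_RTOL * max(float(np.max(np.diag(S))), 1e-300)
        if np.min(w) < -tol:
            raise ValueError(
                f"noise covariance is indefinite (min eigenvalue {np.min(w):.3e})"
            )
        w = np.where(w < tol, 0.0, w)  # zero out numerically null directions
        return V * np.sqrt(w)


def simulate_paths(
    net: NetworkParams,
    noise: NoiseModel,
    stim: Stimulus,
    initial_state: np.ndarray,
    cfg: SimulationConfig,
) -> Ensemble:
    """Integrate an ensemble of independent trials.

    All trials share the deterministic initial state and differ only in
    their noise streams.  Fixed (seed, trial ordering) gives bit-identical
    output.
    """
    n = net.n_total
    v0 = np.asarray(initial_state, dtype=float)
    if v0.size == net.n_populations:
        v0 = np.repeat(v0, net.sizes)
    if v0.size != n:
        raise ValueError("initial state must have length N (or one value per population)")

    conn = build_connectivity(net)
    L = noise_factor(build_noise_covariance(net, noise))
    sqdt_Lt = math.sqrt(cfg.dt) * L.T
    taus = net.neuron_taus()
    in_deg = net.neuron_in_degrees()
    I = np.repeat(np.asarray(stim.values), net.sizes)
    sl = net.population_slices()
    pops = net.populations

    gens = [
        np.random.default_rng(np.random.SeedSequence((cfg.seed, k)))
        for k in range(cfg.n_trials)
    ]
    V = np.tile(v0, (cfg.n_trials, 1))
    rec_steps = cfg.record_steps()
    values = np.empty((cfg.n_trials, len(rec_steps), n))
    rec_map = {}
    for i, s in enumerate(rec_steps):
        rec_map.setdefault(s, []).append(i)
    for i in rec_map.get(0, []):
        values[:, i, :] = V

    rates = np.empty_like(V)
    step = 0
    n_steps = cfg.n_steps
    xi = np.empty((cfg.n_trials, TIME_CHUNK, n))
    while step < n_steps:
        m = min(TIME_CHUNK, n_steps - step)
        for k, g in enumerate(gens):
            xi[k, :m] = g.standard_normal((m, n))
        increments = xi[:, :m] @ sqdt_Lt
        for s in range(m):
            for a, p in enumerate(pops):
                rates[:, sl[a]] = activation(V[:, sl[a]], p)
            drift = -V / taus + (rates @ conn.T) / in_deg + I
            V += cfg.dt * drift + increments[:, s]
            step += 1
            if step % 1000 == 0 and not np.all(np.isfinite(V)):
                raise OverflowDetected(step * cfg.dt)
            for i in rec_map.get(step, []):
                values[:, i, :] = V
    if not np.all(np.isfinite(values)):
        raise OverflowDetected(cfg.t_end)
    return Ensemble(values=values, config=cfg, initial_state=v0)


@dataclass(frozen=True)
class EnsembleStatistics:
    """Across-trial statistics at one recorded time."""

    time: float
    std: tuple[float, float]  # per-population mean of per-neuron stds
    std_se: tuple[float, float]
    corr: dict[str, float]  # pooled pair correlations: EE, II, EI
    corr_se: dict[str, float]
    n_trials: int


def empirical_statistics(ens: Ensemble, net: NetworkParams) -> list[EnsembleStatistics]:
    """Across-trial std and pooled pair correlations at each recorded time.

    Pair correlations are averaged over all neuron pairs of each type
    (within-E, within-I, between).  Standard errors use the trial count:
    SE(std) ~ std / sqrt(2(n-1)), SE(corr) ~ (1 - r^2) / sqrt(n - 3).
    Degenerate (zero-variance) ensembles yield NaN correlations.
    """
    T = ens.values.shape[0]
    if T < 2:
        raise ValueError("at least two trials are required for statistics")
    slE, slI = net.population_slices()
    out = []
    for i, t in enumerate(ens.config.record_times):
        X = ens.values[:, i, :]  # (trials, neurons)
        stds = X.std(axis=0, ddof=1)
        std_pop = (float(stds[slE].mean()), float(stds[slI].mean()))
        std_se = tuple(s / math.sqrt(2.0 * (T - 1)) for s in std_pop)
        if np.any(stds == 0.0):
            corr = {"EE": math.nan, "II": math.nan, "EI": math.nan}
            corr_se = dict(corr)
        else:
            C = np.corrcoef(X.T)
            NE = net.sizes[0]
            iuE = np.triu_indices(NE, 1)
            iuI = np.triu_indices(net.sizes[1], 1)
            corr = {
                "EE": float(C[slE, slE][iuE].mean()) if NE >= 2 else math.nan,
                "II": float(C[slI, slI][iuI].mean()) if net.sizes[1] >= 2 else math.nan,
                "EI": float(C[slE, slI].mean()),
            }
            corr_se = {
                k: (1.0 - r * r) / math.sqrt(T - 3) if not math.isnan(r) else math.nan
                for k, r in corr.items()
            }
        out.append(
            EnsembleStatistics(
                time=float(t),
                std=std_pop,
                std_se=tuple(float(s) for s in std_se),
                corr=corr,
                corr_se=corr_se,
                n_trials=T,
            )
        )
    return out


def statistics_frame(stats: list[EnsembleStatistics]) -> pd.DataFrame:
    rows = []
    for s in stats:
        rows.append(
            {
                "time": s.time,
                "std_E": s.std[0],
                "std_I": s.std[1],
                "std_E_se": s.std_se[0],
                "std_I_se": s.std_se[1],
                "corr_EE": s.corr["EE"],
                "corr_II": s.corr["II"],
                "corr_EI": s.corr["EI"],
                "corr_EE_se": s.corr_se["EE"],
                "corr_II_se": s.corr_se["II"],
                "corr_EI_se": s.corr_se["EI"],
                "n_trials": s.n_trials,
            }
        )
    return pd.DataFrame(rows)
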