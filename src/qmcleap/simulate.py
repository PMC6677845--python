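"""Fixed-step sample-path generators driven by explicit uniform streams.

Two path simulators share the same time grid and the same input
convention.  The tau-leap method advances a discrete copy-number state by
firing each channel a Poisson(a_k(X) tau) number of times per step; the
chemical-Langevin (CLE) method takes the corresponding Euler-Maruyama
step of the diffusion approximation,

    X(t+tau) = X(t) + sum_k [a_k(X) tau + sqrt(a_k(X) tau) z_k] zeta_k,

with independent standard normals z_k.  Both draw their randomness by
*inverse transform* from a caller-supplied vector of uniforms with one
entry per (step, channel) pair, flat index ``j*K + k``.  That coupling is
what lets a low-discrepancy point drive a whole sample path: the path
functional becomes a deterministic function on the unit hypercube of
dimension ``K * ceil(T/tau)`` and a path ensemble becomes a quadrature
problem.

Both simulators are pure functions of their stream — identical uniforms
give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .network import ReactionNetwork, SystemState, problem_dimension, propensity_matrix

__all__ = [
    "Method",
    "NegativePolicy",
    "SimulationConfig",
    "Trajectory",
    "poisson_quantile",
    "normal_quantile",
    "tau_leap_path",
    "cle_em_path",
    "simulate_ensemble",
    "final_value",
    "species_observable",
]

# uniforms are clamped into this open interval before the normal quantile
_TINY = 1e-15
_BELOW_ONE = np.nextafter(1.0, 0.0)


class Method(str, Enum):
    TAU_LEAP = "tau_leap"
    CLE_EM = "cle_em"


class NegativePolicy(str, Enum):
    """What to do about negative copy numbers in the discrete simulator.

    ``clamp_propensity`` (default): propensities use the zero-combinations
    rule (a_k = 0 whenever a reactant is short) and any negative
    post-update copy number is clamped to zero — the stand-in for the
    usual guarded tau-leap treatments of near-extinct species.
    ``error``: raise on any negative copy number instead.
    """

    CLAMP_PROPENSITY = "clamp_propensity"
    ERROR = "error"


@dataclass(frozen=True)
class SimulationConfig:
    tau: float
    T: float
    method: Method = Method.TAU_LEAP
    negative_policy: NegativePolicy = NegativePolicy.CLAMP_PROPENSITY
    record_full_path: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.T <= 0:
            raise ValueError("tau and T must be positive")
        if self.tau > self.T:
            raise ValueError("tau must not exceed T")
        object.__setattr__(self, "method", Method(self.method))
        object.__setattr__(self, "negative_policy", NegativePolicy(self.negative_policy))

    @property
    def n_steps(self) -> int:
        return problem_dimension(1, self.T, self.tau)

    @property
    def step_sizes(self) -> np.ndarray:
        """Per-step durations; the final step is truncated when T % tau != 0."""
        n = self.n_steps
        steps = np.full(n, self.tau)
        steps[-1] = self.T - (n - 1) * self.tau
        return steps


@dataclass(frozen=True)
class Trajectory:
    """States on the grid 0, tau, 2*tau, ..., T (for one sample path)."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species); int for tau-leap, float for CLE

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.states)
        if t.ndim != 1 or x.ndim != 2 or x.shape[0] != t.shape[0]:
            raise ValueError("times and states are inconsistent")
        if (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", x)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def poisson_quantile(u, mean):
    """Smallest integer q with ``P(Poisson(mean) <= q) >= u`` (inverse CDF).

    Vectorised over both arguments; stable for means up to ~1e6 via the
    regularised incomplete-gamma inversion underlying ``scipy``'s Poisson
    percent-point function.
    """
    u = np.asarray(u, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if (u < 0).any() or (u >= 1).any():
        raise ValueError("u must lie in [0, 1)")
    if (mean < 0).any():
        raise ValueError("mean must be nonnegative")
    q = stats.poisson.ppf(u, mean)
    # ppf maps u=0 to -1 by convention; the smallest admissible count is 0
    out = np.maximum(q, 0.0).astype(np.int64)
    return out if out.ndim else int(out)


def normal_quantile(u):
    """Standard normal inverse CDF, accurate to ~1e-9 absolute or better."""
    u = np.asarray(u, dtype=float)
    if (u <= 0).any() or (u >= 1).any():
        raise ValueError("u must lie strictly inside (0, 1)")
    z = ndtri(u)
    return z if z.ndim else float(z)


def _check_stream(network: ReactionNetwork, cfg: SimulationConfig, U: np.ndarray) -> np.ndarray:
    U = np.atleast_2d(np.asarray(U, dtype=float))
    dim = problem_dimension(network.n_reactions, cfg.T, cfg.tau)
    if U.shape[1] != dim:
        raise ValueError(
            f"uniform stream has length {U.shape[1]} but the problem "
            f"dimension is {dim} (= K * ceil(T/tau))"
        )
    return U


def simulate_ensemble(
    network: ReactionNetwork,
    X0: SystemState,
    cfg: SimulationConfig,
    uniforms: np.ndarray,
) -> np.ndarray:
    """Simulate one path per row of ``uniforms``; returns final states.

    Parameters
    ----------
    uniforms : ndarray, shape (N, K*ceil(T/tau))
        One uniform stream per path (or a single flat stream for one path).

    Returns
    -------
    ndarray, shape (N, n_species)
        States at time T.  Integer-valued for tau-leap, real for CLE.
    """
    U = _check_stream(network, cfg, uniforms)
    if cfg.method is Method.TAU_LEAP:
        return _tau_leap_states(network, X0, cfg, U, record=None)
    return _cle_states(network, X0, cfg, U, record=None)


def _tau_leap_states(network, X0, cfg, U, record):
    K = network.n_reactions
    zeta = network.stoichiometry_matrix  # (K, n)
    frozen = network.frozen_mask
    x = np.broadcast_to(
        np.asarray(X0.copy_numbers, dtype=np.int64), (U.shape[0], network.n_species)
    ).copy()
    for j, tau_j in enumerate(cfg.step_sizes):
        a = propensity_matrix(x, network)  # (N, K)
        u = U[:, j * K : (j + 1) * K]
        p = poisson_quantile(u, a * tau_j)
        x = x + np.asarray(p) @ zeta
        if frozen.any():
            x[:, frozen] = np.asarray(X0.copy_numbers, dtype=np.int64)[frozen]
        if (x < 0).any():
            if cfg.negative_policy is NegativePolicy.ERROR:
                raise RuntimeError("negative copy number encountered")
            np.maximum(x, 0, out=x)
        if record is not None:
            record.append(x.copy())
    return x


def _cle_states(network, X0, cfg, U, record):
    K = network.n_reactions
    zeta = network.stoichiometry_matrix.astype(float)
    frozen = network.frozen_mask
    x = np.broadcast_to(
        np.asarray(X0.copy_numbers, dtype=float), (U.shape[0], network.n_species)
    ).copy()
    for j, tau_j in enumerate(cfg.step_sizes):
        a = propensity_matrix(x, network)
        u = np.clip(U[:, j * K : (j + 1) * K], _TINY, _BELOW_ONE)
        z = normal_quantile(u)
        incr = a * tau_j + np.sqrt(np.maximum(a, 0.0) * tau_j) * z
        x = x + incr @ zeta
        if frozen.any():
            x[:, frozen] = np.asarray(X0.copy_numbers, dtype=float)[frozen]
        if record is not None:
            record.append(x.copy())
    return x


def _single_path(network, X0, cfg, uniforms, kernel, dtype):
    U = _check_stream(network, cfg, uniforms)
    if U.shape[0] != 1:
        raise ValueError("a single path takes a single flat uniform stream")
    record: list = []
    kernel(network, X0, cfg, U, record)
    times = np.concatenate([[0.0], np.cumsum(cfg.step_sizes)])
    states = np.vstack(
        [np.asarray(X0.copy_numbers, dtype=dtype)[None, :]]
        + [s.astype(dtype) for s in record]
    )
    return Trajectory(times=times, states=states)


def tau_leap_path(
    network: ReactionNetwork, X0: SystemState, cfg: SimulationConfig, uniforms
) -> Trajectory:
    """One tau-leap trajectory driven by a flat uniform stream."""
    return _single_path(network, X0, cfg, uniforms, _tau_leap_states, np.int64)


def cle_em_path(
    network: ReactionNetwork, X0: SystemState, cfg: SimulationConfig, uniforms
) -> Trajectory:
    """One Euler-Maruyama trajectory of the chemical Langevin equation."""
    return _single_path(network, X0, cfg, uniforms, _cle_states, float)


def species_observable(network: ReactionNetwork, species, power: int = 1):
    """Observable g(X) = X_i ** power for a species given by name or index."""
    idx = network.species_index(species) if isinstance(species, str) else int(species)
    if not 0 <= idx < network.n_species:
        raise ValueError("species index out of range")

    def g(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        v = x[..., idx]
        return v if power == 1 else v ** power

    g.species_index = idx  # type: ignore[attr-defined]
    g.power = power  # type: ignore[attr-defined]
    return g


def final_value(traj: Trajectory, g) -> float:
    """Evaluate an observable on the end state g(X(T))."""
    return float(g(traj.final_state))


def trajectory_to_csv(traj: Trajectory, network: ReactionNetwork, path) -> None:
    """Write a trajectory as CSV with columns time, <species...>."""
    import pandas as pd

    df = pd.DataFrame(traj.states, columns=list(network.species_names))
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False, float_format="%.17g")
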