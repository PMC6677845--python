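"""Monte Carlo and randomised quasi-Monte Carlo estimation machinery.

The object of interest is an expectation E[g(X(T))] written as an
integral over the unit hypercube of path-stream uniforms.  An RQMC
estimate uses M independently randomised Sobol' point sets of N points
each; every randomisation m yields an unbiased estimate I_N^(m) (the mean
of g over its N paths) and the pooled estimator is their average,

    I_{M,RQMC} = (1/M) sum_m I_N^(m).

Because the M randomisations are i.i.d., the variance of the pooled mean
has the standard unbiased estimator

    sigma^2_{M,RQMC} = (1/(M(M-1))) sum_m (I_N^(m) - I_{M,RQMC})^2,

and the reported RMSE is its square root — a pure statistical error,
which is the right yardstick here because both estimator arms are
unbiased for the (method-specific) quantity they target; discretisation
bias of tau-leaping itself is deliberately out of scope.

The plain-MC comparison arm uses M*N pseudo-random paths partitioned
into M batches of N, so both arms consume the same number of sample
paths and are summarised by identical formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ReactionNetwork, SystemState, problem_dimension
from .points import GeneratorKind, pseudo_points, sobol_randomised
from .simulate import SimulationConfig, simulate_ensemble

__all__ = [
    "RQMCResult",
    "ConvergenceStudy",
    "mc_estimate",
    "rqmc_estimate",
    "sampler_experiment",
    "run_experiment",
    "convergence_study",
    "fit_decay_exponent",
    "local_slopes",
    "transition_sample_size",
    "spawn_child_seeds",
]


@dataclass(frozen=True)
class RQMCResult:
    """Pooled estimate over M randomisations of an N-point rule."""

    per_randomisation: np.ndarray  # I_N^(m), length M
    pooled_estimate: float
    variance_of_mean: float
    rmse: float
    N: int
    M: int
    seed: object = None


@dataclass(frozen=True)
class ConvergenceStudy:
    """(N, RMSE) table with a fitted decay exponent nu: RMSE ~ C N^-nu."""

    sample_sizes: np.ndarray
    rmse_values: np.ndarray
    fitted_exponent: float
    fit_range: tuple
    results: tuple = ()


def mc_estimate(values) -> float:
    """Arithmetic-mean Monte Carlo estimator."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot estimate from an empty sample")
    return float(v.mean())


def rqmc_estimate(per_randomisation_values, N=None, M=None, seed=None) -> RQMCResult:
    """Pool an M x N matrix of per-path values into an RQMC estimate.

    Row m holds the N observable values of randomisation m; row means are
    the I_N^(m), their mean is the pooled estimate, and the variance of
    the pooled mean is the unbiased between-randomisation estimator.
    """
    vals = np.atleast_2d(np.asarray(per_randomisation_values, dtype=float))
    m, n = vals.shape
    if m < 2:
        raise ValueError("need at least M=2 randomisations to estimate the variance")
    row_means = vals.mean(axis=1)
    pooled = row_means.mean()
    var_of_mean = float(np.sum((row_means - pooled) ** 2) / (m * (m - 1)))
    return RQMCResult(
        per_randomisation=row_means,
        pooled_estimate=float(pooled),
        variance_of_mean=var_of_mean,
        rmse=float(np.sqrt(var_of_mean)),
        N=int(N if N is not None else n),
        M=int(M if M is not None else m),
        seed=seed,
    )


def spawn_child_seeds(seed, count: int) -> list:
    """Derive ``count`` independent child seeds from a meta-seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(count)


def sampler_experiment(sampler, dim, N, M, generator_kind, seed) -> RQMCResult:
    """Run a generic estimator experiment over a row-wise sampler.

    ``sampler`` maps an (N, dim) matrix of uniforms to N observable
    values.  For RQMC, M independently seeded scrambled Sobol' sets of N
    points are drawn; for the MC arm a single pseudo-random stream of
    M*N points is partitioned into M batches so that both arms use MN
    sample points.
    """
    kind = GeneratorKind(generator_kind)
    if M < 2:
        raise ValueError("M must be at least 2")
    if kind is GeneratorKind.SOBOL_RANDOMISED:
        child_seeds = spawn_child_seeds(seed, M)
        rows = np.empty((M, N))
        for m in range(M):
            ps = sobol_randomised(N, dim, child_seeds[m])
            rows[m] = sampler(ps.values)
    else:
        ps = pseudo_points(M * N, dim, spawn_child_seeds(seed, 1)[0])
        rows = sampler(ps.values).reshape(M, N)
    return rqmc_estimate(rows, N=N, M=M, seed=seed)


def _path_sampler(network, X0, cfg, observable):
    def sampler(U: np.ndarray) -> np.ndarray:
        finals = simulate_ensemble(network, X0, cfg, U)
        return np.asarray(observable(finals), dtype=float)

    return sampler


def run_experiment(
    network: ReactionNetwork,
    observable,
    cfg: SimulationConfig,
    N: int,
    M: int,
    generator_kind,
    seed,
    X0: SystemState | None = None,
) -> RQMCResult:
    """Estimate E[g(X(T))] with N paths per randomisation and M randomisations.

    ``observable`` maps an (N, n_species) matrix of final states to N
    values (see :func:`qmcleap.simulate.species_observable`).  ``X0``
    defaults to the initial state bundled with built-in models; pass it
    explicitly for custom networks.
    """
    if X0 is None:
        raise ValueError("an initial state X0 is required")
    dim = problem_dimension(network.n_reactions, cfg.T, cfg.tau)
    sampler = _path_sampler(network, X0, cfg, observable)
    return sampler_experiment(sampler, dim, N, M, generator_kind, seed)


def _floor_rmse(r: np.ndarray) -> np.ndarray:
    """Keep log-log fits finite when an RMSE hits exact cancellation.

    An estimator that integrates its target exactly (possible for
    structured integrands on balanced nets) reports RMSE 0; such points
    are clipped to a value at the double-precision rounding floor of the
    largest RMSE in the study.
    """
    top = r.max() if r.size else 1.0
    return np.maximum(r, max(top, 1.0) * 2.0 ** -52)


def fit_decay_exponent(sample_sizes, rmse_values, fit_range=None) -> float:
    """Exponent nu from an unweighted least-squares fit of log2 RMSE vs log2 N.

    ``fit_range`` is an (start, stop) index pair into the size grid;
    default is the full grid.  Returns nu = -slope, so nu = 1/2 is the
    plain Monte Carlo rate.
    """
    n = np.asarray(sample_sizes, dtype=float)
    r = _floor_rmse(np.asarray(rmse_values, dtype=float))
    if fit_range is None:
        fit_range = (0, len(n))
    lo, hi = fit_range
    if hi - lo < 3:
        raise ValueError("the rate fit needs at least 3 points")
    slope = np.polyfit(np.log2(n[lo:hi]), np.log2(r[lo:hi]), 1)[0]
    return float(-slope)


def _check_sizes(sample_sizes) -> np.ndarray:
    sizes = np.asarray(sample_sizes, dtype=np.int64)
    if sizes.size < 3:
        raise ValueError("a convergence study needs at least 3 sample sizes")
    if (np.diff(sizes) <= 0).any():
        raise ValueError("sample sizes must be strictly increasing")
    return sizes


def study_from_sampler(
    sampler, dim, sample_sizes, M, generator_kind, seed, fit_range=None
) -> ConvergenceStudy:
    """Convergence study (RMSE vs N) for a generic sampler."""
    sizes = _check_sizes(sample_sizes)
    child = spawn_child_seeds(seed, len(sizes))
    results = tuple(
        sampler_experiment(sampler, dim, int(N), M, generator_kind, child[i])
        for i, N in enumerate(sizes)
    )
    rmse = np.array([r.rmse for r in results])
    fr = (0, len(sizes)) if fit_range is None else tuple(fit_range)
    nu = fit_decay_exponent(sizes, rmse, fr)
    return ConvergenceStudy(
        sample_sizes=sizes,
        rmse_values=rmse,
        fitted_exponent=nu,
        fit_range=fr,
        results=results,
    )


def convergence_study(
    network: ReactionNetwork,
    observable,
    cfg: SimulationConfig,
    sample_sizes,
    M: int,
    generator_kind,
    seed,
    X0: SystemState | None = None,
    fit_range=None,
) -> ConvergenceStudy:
    """RMSE-versus-N study for a path observable, with fitted rate exponent.

    Use ``fit_range`` to restrict the rate fit, e.g. to the upper half of
    the size grid when quoting a limiting (large-N) rate.
    """
    if X0 is None:
        raise ValueError("an initial state X0 is required")
    dim = problem_dimension(network.n_reactions, cfg.T, cfg.tau)
    sampler = _path_sampler(network, X0, cfg, observable)
    return study_from_sampler(
        sampler, dim, sample_sizes, M, generator_kind, seed, fit_range
    )


def local_slopes(study: ConvergenceStudy, window: int = 3) -> np.ndarray:
    """Sliding-window decay exponents along the size grid.

    Entry i is the exponent fitted over ``window`` consecutive sizes
    starting at i (length ``len(sizes) - window + 1``).
    """
    sizes = study.sample_sizes
    if window < 2 or window > sizes.size:
        raise ValueError("invalid window")
    rmse = _floor_rmse(study.rmse_values)
    out = np.empty(sizes.size - window + 1)
    for i in range(out.size):
        s = np.polyfit(
            np.log2(sizes[i : i + window].astype(float)),
            np.log2(rmse[i : i + window]),
            1,
        )[0]
        out[i] = -s
    return out


def transition_sample_size(
    study: ConvergenceStudy, threshold: float = 0.75, window: int = 3
):
    """First N at which the local decay exponent drops below ``threshold``.

    Detects the switch from the fast RQMC regime to Monte-Carlo-like
    convergence; returns None when the slope never drops within the grid
    (i.e. the transition lies beyond the largest N studied).
    """
    slopes = local_slopes(study, window=window)
    below = np.nonzero(slopes < threshold)[0]
    if below.size == 0:
        return None
    # attribute the windowed slope to the window's last (largest) size
    return int(study.sample_sizes[below[0] + window - 1])


def study_to_frame(study: ConvergenceStudy, **labels):
    """Convergence table as a pandas DataFrame (columns N, rmse, ...labels)."""
    import pandas as pd

    df = pd.DataFrame(
        {"N": study.sample_sizes, "rmse": study.rmse_values}
    )
    for key, val in labels.items():
        df[key] = val
    return df
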