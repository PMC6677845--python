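"""Quadrature testbed: smooth test integrands with tunable discontinuities.

The convergence-rate transitions seen when pairing randomised
quasi-Monte Carlo with the discrete tau-leap simulator can be replicated
in plain quadrature.  Two s-dimensional test families on [0,1)^s are
used, both with integral 0 and variance 1 for every s:

    additive:  f(x) = sqrt(12/s)   * sum_i (x_i - 1/2)
    product:   f(x) = sqrt(12^s)   * prod_i (x_i - 1/2)

The additive family has superposition effective dimension one and is
very easy for RQMC (RMSE ~ N^{-3/2} regardless of s); the product family
is hard at small N and reaches the fast rate only once enough points are
used.

Discreteness is injected by a staircase parameter eps > 0 in one of two
ways:

    input floor:   f_eps(x) = f(eps * floor(x / eps))
    output floor:  f_eps(x) = eps * floor(f(x) / eps)

The input floor creates discontinuities parallel to the coordinate axes
— the mild kind for digital nets, degrading the limiting RMSE rate to
~N^{-1}.  The output floor creates oblique discontinuity lines that a
digital net cannot align with, and the limiting rate collapses to the
Monte Carlo N^{-1/2}.  Writing f_eps = F + G with continuous F = f and
discontinuous remainder G = f_eps - f (so |G| <= eps for the output
floor) decomposes the estimator MSE into a fast term from F and a slow
term from G; the slow term takes over once N ~ 1/eps, which is the
switch point observed in the convergence curves.

Floors are mathematical floors (round toward -inf), so negative outputs
quantise downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .estimate import ConvergenceStudy, sampler_experiment, study_from_sampler
from .points import GeneratorKind, sobol_randomised

__all__ = [
    "Family",
    "Transform",
    "TestFunctionSpec",
    "evaluate",
    "true_moments",
    "grid_moments",
    "quad_experiment",
    "mse_decomposition_check",
]


class Family(str, Enum):
    ADDITIVE = "additive"
    PRODUCT = "product"


class Transform(str, Enum):
    NONE = "none"
    INPUT_FLOOR = "input_floor"
    OUTPUT_FLOOR = "output_floor"


@dataclass(frozen=True)
class TestFunctionSpec:
    __test__ = False  # not a pytest class despite the name

    family: Family
    dimension: int
    transform: Transform = Transform.NONE
    epsilon: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "transform", Transform(self.transform))
        if self.dimension < 1:
            raise ValueError("dimension must be at least 1")
        if self.transform is Transform.NONE:
            if self.epsilon is not None:
                raise ValueError("epsilon is only meaningful with a transform")
        else:
            if self.epsilon is None or self.epsilon <= 0:
                raise ValueError("a positive epsilon is required with a transform")
            if self.transform is Transform.INPUT_FLOOR and self.epsilon > 1:
                raise ValueError("input-floor epsilon must lie in (0, 1]")


def _base(family: Family, x: np.ndarray) -> np.ndarray:
    s = x.shape[1]
    centred = x - 0.5
    if family is Family.ADDITIVE:
        return np.sqrt(12.0 / s) * centred.sum(axis=1)
    return np.sqrt(12.0 ** s) * centred.prod(axis=1)


def evaluate(spec: TestFunctionSpec, x) -> np.ndarray:
    """Evaluate the (possibly discontinuity-transformed) test function.

    ``x`` is a single point of length s or an (N, s) matrix; points must
    lie componentwise in [0, 1).
    """
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != spec.dimension:
        raise ValueError(
            f"points have dimension {arr.shape[1]}, spec expects {spec.dimension}"
        )
    if (arr < 0).any() or (arr >= 1).any():
        raise ValueError("points must lie in [0, 1)^s")
    if spec.transform is Transform.INPUT_FLOOR:
        arr = spec.epsilon * np.floor(arr / spec.epsilon)
        out = _base(spec.family, arr)
    elif spec.transform is Transform.OUTPUT_FLOOR:
        out = spec.epsilon * np.floor(_base(spec.family, arr) / spec.epsilon)
    else:
        out = _base(spec.family, arr)
    return float(out[0]) if single else out


def continuous_part(spec: TestFunctionSpec):
    """The untransformed counterpart F = f of a transformed spec."""
    return TestFunctionSpec(spec.family, spec.dimension)


def true_moments(spec: TestFunctionSpec):
    """Analytic (integral, variance) of an untransformed test function.

    Both families are centred and normalised so the integral is 0 and the
    variance is 1 in every dimension.  Transformed functions have no
    closed form here; probe them numerically via :func:`grid_moments`.
    """
    if spec.transform is not Transform.NONE:
        raise ValueError("closed-form moments exist only for transform='none'")
    return 0.0, 1.0


def grid_moments(spec: TestFunctionSpec, points_per_axis: int, rule: str = "midpoint"):
    """Brute-force tensor-grid (integral, variance) oracle for small s.

    ``rule='midpoint'`` uses the composite midpoint rule (robust for the
    discontinuous transformed functions); ``rule='gauss'`` uses a
    tensor-product Gauss-Legendre rule, which integrates the polynomial
    untransformed families essentially exactly at a handful of nodes per
    axis.  Cost grows as ``points_per_axis ** s``.
    """
    s = spec.dimension
    if points_per_axis ** s > 4_000_000:
        raise ValueError("grid too large; reduce points_per_axis or dimension")
    if rule == "midpoint":
        nodes = (np.arange(points_per_axis) + 0.5) / points_per_axis
        weights = np.full(points_per_axis, 1.0 / points_per_axis)
    elif rule == "gauss":
        g, w = np.polynomial.legendre.leggauss(points_per_axis)
        nodes = 0.5 * (g + 1.0)
        weights = 0.5 * w
    else:
        raise ValueError("rule must be 'midpoint' or 'gauss'")
    grids = np.meshgrid(*([nodes] * s), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    wgrids = np.meshgrid(*([weights] * s), indexing="ij")
    wts = np.prod(np.stack([w.ravel() for w in wgrids], axis=1), axis=1)
    # Gauss nodes can touch 1 only through rounding; keep inside [0,1)
    np.minimum(pts, np.nextafter(1.0, 0.0), out=pts)
    f = evaluate(spec, pts)
    integral = float(np.dot(wts, f))
    second = float(np.dot(wts, f * f))
    return integral, second - integral ** 2


def quad_experiment(
    spec: TestFunctionSpec,
    sample_sizes,
    M: int,
    generator_kind,
    seed,
    fit_range=None,
) -> ConvergenceStudy:
    """Convergence study for estimating the integral of ``spec``."""

    def sampler(U: np.ndarray) -> np.ndarray:
        return evaluate(spec, U)

    return study_from_sampler(
        sampler, spec.dimension, sample_sizes, M, generator_kind, seed, fit_range
    )


def mse_decomposition_check(spec: TestFunctionSpec, sample_sizes, M, seed):
    """Split the estimator MSE into continuous and discontinuous parts.

    For a transformed function f_eps = F + G (F = f continuous,
    G = f_eps - f discontinuous), integrates F and G with *shared*
    randomised point sets at every N and reports the variance of the
    pooled mean for f_eps, F and G.  The returned DataFrame has columns
    N, mse_total, mse_continuous, mse_discontinuous; the attached
    ``switch_point`` attribute (in ``df.attrs``) is the first N at which
    the discontinuous part dominates.
    """
    import pandas as pd

    if spec.transform is Transform.NONE:
        raise ValueError("the decomposition needs a transformed spec")
    base = continuous_part(spec)
    sizes = np.asarray(sample_sizes, dtype=np.int64)
    child = np.random.SeedSequence(seed).spawn(len(sizes))
    rows = []
    for i, N in enumerate(sizes):
        seeds = child[i].spawn(M)
        means_tot = np.empty(M)
        means_f = np.empty(M)
        means_g = np.empty(M)
        for m in range(M):
            ps = sobol_randomised(int(N), spec.dimension, seeds[m])
            tot = evaluate(spec, ps.values)
            cont = evaluate(base, ps.values)
            means_tot[m] = tot.mean()
            means_f[m] = cont.mean()
            means_g[m] = (tot - cont).mean()

        def _var_of_mean(v):
            return float(np.sum((v - v.mean()) ** 2) / (M * (M - 1)))

        rows.append(
            {
                "N": int(N),
                "mse_total": _var_of_mean(means_tot),
                "mse_continuous": _var_of_mean(means_f),
                "mse_discontinuous": _var_of_mean(means_g),
            }
        )
    df = pd.DataFrame(rows)
    dominated = df.index[df["mse_discontinuous"] > df["mse_continuous"]]
    df.attrs["switch_point"] = (
        int(df.loc[dominated[0], "N"]) if len(dominated) else None
    )
    return df
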