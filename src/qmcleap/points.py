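"""Uniform input streams: pseudo-random and randomised Sobol' point sets.

Every fixed-step sample path of the simulators consumes a fixed number of
uniform variates, one per (time step, reaction channel) pair, so a batch
of N paths is driven by an N x s matrix of uniforms on [0,1)^s.  Plain
Monte Carlo fills that matrix with i.i.d. pseudo-random numbers; the
randomised quasi-Monte Carlo estimator instead uses a scrambled Sobol'
digital net, whose rows are individually uniform on [0,1)^s but jointly
much better spread than random points.

The randomisation is a linear matrix scramble combined with a random
digital shift (Matoušek), which preserves the base-2 digital-net
structure of the Sobol' construction while making each point marginally
uniform — the property that makes the pooled estimator unbiased and its
empirical variance meaningful.

A low-discrepancy point set must be generated with its full target
dimension up front: concatenating independent one-dimensional nets does
not yield a net in two dimensions (unlike pseudo-random columns, which
may be combined freely).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import qmc

__all__ = [
    "GeneratorKind",
    "PointSet",
    "pseudo_points",
    "sobol_randomised",
    "stream_chunk",
]

# largest double strictly below 1; quantile transforms require u < 1
_BELOW_ONE = np.nextafter(1.0, 0.0)


class GeneratorKind(str, Enum):
    PSEUDO = "pseudo"
    SOBOL_RANDOMISED = "sobol_randomised"


@dataclass(frozen=True)
class PointSet:
    """An N x s matrix of uniforms in [0,1) with generator metadata."""

    values: np.ndarray
    generator_kind: GeneratorKind
    dimension: int
    count: int
    seed: object

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.count, self.dimension):
            raise ValueError("values shape must be (count, dimension)")
        if (v < 0).any() or (v >= 1).any():
            raise ValueError("point-set entries must lie in [0, 1)")
        object.__setattr__(self, "values", v)


def _check_n_s(n: int, s: int) -> None:
    if n < 1:
        raise ValueError("point count must be positive")
    if s < 1:
        raise ValueError("dimension must be positive")


def pseudo_points(n: int, s: int, seed) -> PointSet:
    """I.i.d. uniform variates on [0,1)^s (the plain Monte Carlo stream)."""
    _check_n_s(n, s)
    rng = np.random.default_rng(seed)
    values = rng.random((n, s))
    return PointSet(values, GeneratorKind.PSEUDO, s, n, seed)


def sobol_randomised(n: int, s: int, seed, scramble: bool = True) -> PointSet:
    """The first ``n`` points of an ``s``-dimensional randomised Sobol' set.

    Parameters
    ----------
    n : int
        Number of points.  Powers of two preserve the digital-net balance
        properties; other counts are allowed but trigger a warning.
    s : int
        Dimension, fixed a priori (the full stream length of one path).
    seed : int or numpy seed-like
        Controls the scramble and digital shift; distinct seeds give
        independent randomisations of the same underlying net.
    scramble : bool
        Disable to obtain the raw deterministic Sobol' sequence (whose
        first point is the origin); used for structural checks only — the
        unscrambled set is biased and carries no error estimate.
    """
    _check_n_s(n, s)
    if n & (n - 1):
        warnings.warn(
            f"n={n} is not a power of two; the Sobol' balance properties "
            "only hold for power-of-two point counts",
            UserWarning,
            stacklevel=2,
        )
    engine = qmc.Sobol(d=s, scramble=scramble, seed=np.random.default_rng(seed))
    values = engine.random(n)
    # the digital shift works in fixed precision; guard the u < 1 contract
    np.minimum(values, _BELOW_ONE, out=values)
    return PointSet(values, GeneratorKind.SOBOL_RANDOMISED, s, n, seed)


def stream_chunk(ps: PointSet, path_index: int) -> np.ndarray:
    """The uniform stream driving one sample path (row ``path_index``).

    The caller maps coordinate (step j, reaction k) to flat index
    ``j*K + k``, so the earliest — best-distributed — Sobol' coordinates
    drive the earliest time steps.
    """
    if not 0 <= path_index < ps.count:
        raise IndexError(
            f"path_index {path_index} out of range for point set of size {ps.count}"
        )
    return ps.values[path_index]
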