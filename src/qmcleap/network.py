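"""Well-mixed chemical reaction networks and mass-action propensities.

A network consists of *n* chemical species and *K* reaction channels.
Channel :math:`R_k` converts reactant stoichiometries :math:`\\alpha_{i,k}`
into product stoichiometries :math:`\\beta_{i,k}` at rate constant
:math:`c_k`; its net effect on the copy-number state is the stoichiometric
vector :math:`\\zeta_k = \\beta_{\\cdot,k} - \\alpha_{\\cdot,k}`.

Propensities follow the combinatorial Law of Mass Action: channel ``k``
fires at rate :math:`a_k(X) = c_k \\prod_i \\binom{X_i}{\\alpha_{i,k}}`,
i.e. the rate constant times the number of distinct reactant combinations
that the current state can form.  The concentration-style monomial
:math:`c_k \\prod_i X_i^{\\alpha_{i,k}}` is deliberately *not* used; for
low-order channels the two conventions differ by falling-factorial
corrections which matter at small copy numbers.

Buffer species held at a constant, large copy number (such as the two
reservoir species of the Schlögl system) can be declared *frozen*: they
contribute to propensities at their fixed value and are never modified by
a state update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "SystemState",
    "propensities",
    "propensity_matrix",
    "apply_reactions",
    "problem_dimension",
    "builtin_model",
]


@dataclass(frozen=True)
class Reaction:
    """A single reaction channel.

    Parameters
    ----------
    reactant_stoich : array-like of int
        Reactant stoichiometry :math:`\\alpha_{\\cdot,k}`, one entry per species.
    product_stoich : array-like of int
        Product stoichiometry :math:`\\beta_{\\cdot,k}`, one entry per species.
    rate_constant : float
        Stochastic rate constant :math:`c_k \\ge 0`.
    """

    reactant_stoich: np.ndarray
    product_stoich: np.ndarray
    rate_constant: float

    def __post_init__(self) -> None:
        r = np.asarray(self.reactant_stoich, dtype=np.int64)
        p = np.asarray(self.product_stoich, dtype=np.int64)
        if r.ndim != 1 or p.ndim != 1 or r.shape != p.shape:
            raise ValueError("reactant and product stoichiometries must be 1-D and equal length")
        if (r < 0).any() or (p < 0).any():
            raise ValueError("stoichiometric coefficients must be nonnegative")
        if self.rate_constant < 0:
            raise ValueError("rate constant must be nonnegative")
        object.__setattr__(self, "reactant_stoich", r)
        object.__setattr__(self, "product_stoich", p)

    @property
    def stoichiometric_vector(self) -> np.ndarray:
        """Net copy-number change :math:`\\zeta_k` when this channel fires once."""
        return self.product_stoich - self.reactant_stoich


@dataclass(frozen=True)
class ReactionNetwork:
    species_names: tuple
    reactions: tuple
    frozen_species: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.species_names)
        reactions = tuple(self.reactions)
        if len(names) < 1:
            raise ValueError("a network needs at least one species")
        if len(reactions) < 1:
            raise ValueError("a network needs at least one reaction")
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        for rxn in reactions:
            if rxn.reactant_stoich.shape[0] != len(names):
                raise ValueError("reaction dimension does not match species count")
        for sp in self.frozen_species:
            if sp not in names:
                raise ValueError(f"frozen species {sp!r} is not in the network")
        object.__setattr__(self, "species_names", names)
        object.__setattr__(self, "reactions", reactions)
        object.__setattr__(self, "frozen_species", dict(self.frozen_species))

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def reactant_matrix(self) -> np.ndarray:
        """K x n matrix of reactant stoichiometries."""
        return np.stack([r.reactant_stoich for r in self.reactions])

    @property
    def stoichiometry_matrix(self) -> np.ndarray:
        """K x n matrix of net changes (one stoichiometric vector per row)."""
        return np.stack([r.stoichiometric_vector for r in self.reactions])

    @property
    def rate_constants(self) -> np.ndarray:
        return np.array([r.rate_constant for r in self.reactions], dtype=float)

    @property
    def frozen_mask(self) -> np.ndarray:
        return np.array([s in self.frozen_species for s in self.species_names])

    @property
    def frozen_values(self) -> np.ndarray:
        return np.array(
            [self.frozen_species.get(s, 0) for s in self.species_names], dtype=float
        )

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)


@dataclass(frozen=True)
class SystemState:
    """Copy-number state of a network at a given time.

    ``copy_numbers`` is integer-valued for the discrete simulators; the
    chemical-Langevin path generator carries real-valued states of the
    same shape internally.
    """

    copy_numbers: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.copy_numbers)
        if x.ndim != 1:
            raise ValueError("state must be a 1-D vector")
        if self.time < 0:
            raise ValueError("time must be nonnegative")
        object.__setattr__(self, "copy_numbers", x)


def _falling_factorial_combinations(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Number of reactant combinations, ``prod_i C(x_i, alpha_i)``, per state row.

    ``x`` has shape (N, n) and may be real valued (polynomial extension of the
    binomial coefficient); entries below the required stoichiometry yield zero.
    """
    out = np.ones(x.shape[0], dtype=float)
    for i, a in enumerate(alpha):
        if a == 0:
            continue
        xi = x[:, i]
        comb = np.ones_like(xi, dtype=float)
        for r in range(a):
            comb = comb * (xi - r)
        comb /= math.factorial(a)
        # integer states short of the stoichiometry form zero combinations;
        # the same guard keeps stray negative states from flipping the sign
        comb = np.where(xi < a, np.where(np.floor(xi) == xi, 0.0, comb), comb)
        out *= comb
    return out


def propensity_matrix(states: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Mass-action propensities for a batch of states.

    Parameters
    ----------
    states : ndarray, shape (N, n)
        One state per row; integer or real valued.
    network : ReactionNetwork

    Returns
    -------
    ndarray, shape (N, K)
        ``a_k`` evaluated at every state; frozen species contribute their
        fixed copy number regardless of the value stored in ``states``.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.shape[1] != network.n_species:
        raise ValueError(
            f"state dimension {states.shape[1]} does not match "
            f"network with {network.n_species} species"
        )
    mask = network.frozen_mask
    if mask.any():
        states = states.copy()
        states[:, mask] = network.frozen_values[mask]
    a = np.empty((states.shape[0], network.n_reactions), dtype=float)
    for k, rxn in enumerate(network.reactions):
        a[:, k] = rxn.rate_constant * _falling_factorial_combinations(
            states, rxn.reactant_stoich
        )
    return a


def propensities(state: SystemState, network: ReactionNetwork) -> np.ndarray:
    """Propensity vector ``a(X)`` of length K for a single state."""
    return propensity_matrix(state.copy_numbers[None, :], network)[0]


def apply_reactions(
    state: SystemState, firing_counts: np.ndarray, network: ReactionNetwork
) -> SystemState:
    """Advance a state by firing each channel a given number of times.

    Returns ``X + sum_k p_k zeta_k`` with frozen species pinned to their
    fixed values.  The result may contain negative copy numbers; policing
    those is the simulator's responsibility.
    """
    p = np.asarray(firing_counts)
    if p.shape != (network.n_reactions,):
        raise ValueError("firing_counts must have one entry per reaction")
    if (p < 0).any():
        raise ValueError("firing counts must be nonnegative")
    x = state.copy_numbers + p @ network.stoichiometry_matrix
    mask = network.frozen_mask
    if mask.any():
        x = np.where(mask, state.copy_numbers, x)
    return SystemState(copy_numbers=x, time=state.time)


def problem_dimension(K: int, T: float, tau: float) -> int:
    """Dimension of the uniform input stream for one fixed-step sample path.

    A path driven by K channels over ``ceil(T/tau)`` steps consumes one
    uniform variate per (step, channel) pair, so the integration problem
    posed by the path estimator lives on ``[0,1)^{K ceil(T/tau)}``.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    if T <= 0 or tau <= 0:
        raise ValueError("T and tau must be positive")
    if tau > T:
        raise ValueError("tau must not exceed T")
    return K * math.ceil(T / tau - 1e-12)


def _birth_death(params: dict):
    """Linear birth-death system: S1 -> 0 and S1 -> 2 S1, both at rate c.

    With equal rates the mean is stationary, E[X(t)] = X(0), and the
    variance grows linearly, V[X(t)] = 2 c t X(0).  ``epsilon`` sets the
    initial copy number X(0) = 1/epsilon; passing ``c0`` instead of ``c``
    rescales the rate as c = c0 * epsilon so the propensities stay O(c0)
    while the copy number grows.
    """
    eps = float(params.get("epsilon", 1e-3))
    if "c0" in params:
        c = float(params["c0"]) * eps
    else:
        c = float(params.get("c", 1.0))
    net = ReactionNetwork(
        species_names=("S1",),
        reactions=(
            Reaction([1], [0], c),  # degradation
            Reaction([1], [2], c),  # autocatalytic birth
        ),
    )
    x0 = int(round(1.0 / eps))
    return net, SystemState(np.array([x0], dtype=np.int64))


def _isomerisation(params: dict):
    """Closed reversible isomerisation: S1 -> S2 at c, S2 -> S1 at alpha*c.

    X1 + X2 is conserved.  The initial condition sits on the equilibrium
    ray, X(0) = (1/eps) * (1, 1/alpha), so there is no transient.
    """
    c = float(params.get("c", 1.0))
    alpha = float(params.get("alpha", 1e-4))
    eps = float(params.get("epsilon", 1e-2))
    net = ReactionNetwork(
        species_names=("S1", "S2"),
        reactions=(
            Reaction([1, 0], [0, 1], c),
            Reaction([0, 1], [1, 0], alpha * c),
        ),
    )
    x0 = np.array([round(1.0 / eps), round(1.0 / (alpha * eps))], dtype=np.int64)
    return net, SystemState(x0)


def _schlogl(params: dict):
    """Bistable Schlögl system with buffered reservoir species S2, S3.

    2 S1 + S2 -> 3 S1 (c1), 3 S1 -> 2 S1 + S2 (c2), S3 -> S1 (c3),
    S1 -> S3 (c4).  S2 and S3 are frozen at large constant copy numbers;
    with the default parameters S1 is bistable around roughly 100 and 550
    molecules, starting from 250.
    """
    c1 = float(params.get("c1", 3e-7))
    c2 = float(params.get("c2", 1e-4))
    c3 = float(params.get("c3", 1e-3))
    c4 = float(params.get("c4", 3.5))
    s2 = int(params.get("S2", 10**5))
    s3 = int(params.get("S3", 2 * 10**5))
    x1_0 = int(params.get("X1_0", 250))
    net = ReactionNetwork(
        species_names=("S1", "S2", "S3"),
        reactions=(
            Reaction([2, 1, 0], [3, 0, 0], c1),
            Reaction([3, 0, 0], [2, 1, 0], c2),
            Reaction([0, 0, 1], [1, 0, 0], c3),
            Reaction([1, 0, 0], [0, 0, 1], c4),
        ),
        frozen_species={"S2": s2, "S3": s3},
    )
    x0 = np.array([x1_0, s2, s3], dtype=np.int64)
    return net, SystemState(x0)


_BUILTINS = {
    "birth_death": _birth_death,
    "isomerisation": _isomerisation,
    "schlogl": _schlogl,
}


def builtin_model(name: str, params: dict | None = None):
    """Construct one of the built-in test systems.

    Parameters
    ----------
    name : {"birth_death", "isomerisation", "schlogl"}
    params : dict, optional
        Model-specific overrides (rate constants, ``epsilon`` scale, ...).

    Returns
    -------
    (ReactionNetwork, SystemState)
    """
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; available: {sorted(_BUILTINS)}"
        ) from None
    return factory(dict(params or {}))
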