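"""Experiment configuration: a flat YAML schema, validated before any compute.

Schema (all sections optional except ``network``)::

    network:
      model: birth_death            # builtin name, or give species/reactions
      params: {epsilon: 1.0e-3}     # builtin overrides
      # custom networks instead of `model`:
      # species: [S1, S2]
      # reactions:
      #   - {reactants: {S1: 1}, products: {S2: 1}, rate: 1.0}
      # frozen: {S2: 100000}
      # initial_state: {S1: 100, S2: 1000000}
    simulation:
      method: tau_leap              # or cle_em
      points: sobol                 # or pseudo
      tau: 0.2
      T: 1.6
      sample_sizes: [16, 32, 64]    # powers of two
      M: 32
      seed: 1
    observable:
      species: S1
      power: 1
    output: results.csv

Unknown keys and non-power-of-two sample sizes are rejected with a
descriptive error; invalid configs fail before any simulation starts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .network import Reaction, ReactionNetwork, SystemState, builtin_model
from .points import GeneratorKind
from .simulate import Method, SimulationConfig

__all__ = ["ConfigError", "ExperimentConfig", "parse_config", "serialise_config"]

_POINTS_ALIASES = {
    "sobol": GeneratorKind.SOBOL_RANDOMISED,
    "sobol_randomised": GeneratorKind.SOBOL_RANDOMISED,
    "pseudo": GeneratorKind.PSEUDO,
}


class ConfigError(ValueError):
    """A configuration document failed validation."""


@dataclass(frozen=True)
class ExperimentConfig:
    model: str | None
    model_params: dict
    species: tuple
    reactions: tuple  # tuples of (reactants dict, products dict, rate)
    frozen: dict
    initial_state: dict
    method: str
    points: str
    tau: float
    T: float
    sample_sizes: tuple
    M: int
    seed: int
    observable_species: str | None
    observable_power: int
    output_path: str | None = None

    def build_network(self):
        """Resolve (ReactionNetwork, SystemState) from the config."""
        if self.model is not None:
            return builtin_model(self.model, dict(self.model_params))
        species = tuple(self.species)
        rxns = tuple(
            Reaction(
                [reactants.get(s, 0) for s in species],
                [products.get(s, 0) for s in species],
                rate,
            )
            for reactants, products, rate in self.reactions
        )
        net = ReactionNetwork(species, rxns, dict(self.frozen))
        x0 = np.array([self.initial_state[s] for s in species], dtype=np.int64)
        return net, SystemState(x0)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(tau=self.tau, T=self.T, method=Method(self.method))

    def generator_kind(self) -> GeneratorKind:
        return _POINTS_ALIASES[self.points]


def _expect_mapping(obj, name):
    if not isinstance(obj, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    return obj


def _reject_unknown(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {name!r}: {sorted(unknown)}")


def parse_config(document) -> ExperimentConfig:
    """Parse and validate a YAML document (string, mapping, or file path)."""
    if isinstance(document, str):
        doc = yaml.safe_load(document)
        if isinstance(doc, str):
            raise ConfigError("config document is not a mapping")
    elif isinstance(document, dict):
        doc = document
    else:
        doc = yaml.safe_load(document.read_text())  # pathlib.Path
    doc = _expect_mapping(doc, "<root>")
    _reject_unknown(doc, {"network", "simulation", "observable", "output"}, "<root>")

    net = _expect_mapping(doc.get("network", {}), "network")
    _reject_unknown(
        net,
        {"model", "params", "species", "reactions", "frozen", "initial_state"},
        "network",
    )
    model = net.get("model")
    if model is None:
        for key in ("species", "reactions", "initial_state"):
            if key not in net:
                raise ConfigError(
                    f"network needs either 'model' or explicit '{key}'"
                )
        reactions = []
        for i, rxn in enumerate(net["reactions"]):
            _reject_unknown(
                _expect_mapping(rxn, f"reactions[{i}]"),
                {"reactants", "products", "rate"},
                f"reactions[{i}]",
            )
            if "rate" not in rxn:
                raise ConfigError(f"reactions[{i}] is missing 'rate'")
            reactions.append(
                (dict(rxn.get("reactants", {})), dict(rxn.get("products", {})), float(rxn["rate"]))
            )
        species = tuple(net["species"])
        initial_state = dict(net["initial_state"])
        missing = set(species) - set(initial_state)
        if missing:
            raise ConfigError(f"initial_state is missing species {sorted(missing)}")
    else:
        if not isinstance(model, str):
            raise ConfigError("network.model must be a string")
        reactions, species, initial_state = [], (), {}

    sim = _expect_mapping(doc.get("simulation", {}), "simulation")
    _reject_unknown(
        sim, {"method", "points", "tau", "T", "sample_sizes", "M", "seed"}, "simulation"
    )
    tau = float(sim.get("tau", 0.2))
    T = float(sim.get("T", 1.6))
    if tau <= 0 or T <= 0:
        raise ConfigError("tau and T must be positive")
    if tau > T:
        raise ConfigError("tau must not exceed T")
    method = str(sim.get("method", "tau_leap"))
    if method not in {m.value for m in Method}:
        raise ConfigError(f"unknown method {method!r}")
    points = str(sim.get("points", "sobol"))
    if points not in _POINTS_ALIASES:
        raise ConfigError(f"unknown point generator {points!r}")
    sizes = tuple(int(n) for n in sim.get("sample_sizes", (16, 32, 64, 128, 256)))
    for n in sizes:
        if n < 1 or n & (n - 1):
            raise ConfigError(f"sample size {n} is not a power of two")
    M = int(sim.get("M", 32))
    if M < 2:
        raise ConfigError("M must be at least 2")
    seed = int(sim.get("seed", 0))

    obs = _expect_mapping(doc.get("observable", {}), "observable")
    _reject_unknown(obs, {"species", "power"}, "observable")
    power = int(obs.get("power", 1))
    if power < 1:
        raise ConfigError("observable power must be a positive integer")

    return ExperimentConfig(
        model=model,
        model_params=dict(net.get("params", {})),
        species=species,
        reactions=tuple(reactions),
        frozen=dict(net.get("frozen", {})),
        initial_state=initial_state,
        method=method,
        points=points,
        tau=tau,
        T=T,
        sample_sizes=sizes,
        M=M,
        seed=seed,
        observable_species=obs.get("species"),
        observable_power=power,
        output_path=doc.get("output"),
    )


def serialise_config(cfg: ExperimentConfig) -> str:
    """Render a config back to YAML; parse(serialise(cfg)) == cfg."""
    network: dict = {}
    if cfg.model is not None:
        network["model"] = cfg.model
        if cfg.model_params:
            network["params"] = dict(cfg.model_params)
    else:
        network["species"] = list(cfg.species)
        network["reactions"] = [
            {"reactants": dict(r), "products": dict(p), "rate": rate}
            for r, p, rate in cfg.reactions
        ]
        if cfg.frozen:
            network["frozen"] = dict(cfg.frozen)
        network["initial_state"] = dict(cfg.initial_state)
    doc = {
        "network": network,
        "simulation": {
            "method": cfg.method,
            "points": cfg.points,
            "tau": cfg.tau,
            "T": cfg.T,
            "sample_sizes": list(cfg.sample_sizes),
            "M": cfg.M,
            "seed": cfg.seed,
        },
        "observable": {
            **({"species": cfg.observable_species} if cfg.observable_species else {}),
            "power": cfg.observable_power,
        },
    }
    if cfg.output_path:
        doc["output"] = cfg.output_path
    return yaml.safe_dump(doc, sort_keys=True)
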