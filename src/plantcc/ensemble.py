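"""Structure-matched random Boolean networks and ensemble robustness.

The comparison ensemble preserves only the template network's node count
and per-node in-degrees: each node receives ``k_i`` inputs drawn uniformly
without replacement from all nodes (self-inputs allowed) and a truth table
drawn uniformly from all ``2**(2**k_i)`` tables.  ``matched_wiring=True``
keeps the template's wiring and randomises tables only.

Also ships the toy fixture networks with analytically known synchronous
attractor structure used throughout the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import find_attractors
from .network import BooleanRule, LogicalNetwork, parse_network
from .robustness import (classify, find_attractors as _find,  # noqa: F401
                         flip_function_bit, transition_flip_trial)
from .dynamics import attractors_from_table, transition_table

__all__ = [
    "EnsembleSpec",
    "EnsembleSummary",
    "generate_matched_random_network",
    "ensemble_robustness",
    "fixture_networks",
]


@dataclass(frozen=True)
class EnsembleSpec:
    n_networks: int
    n_perturb: int
    seed: int
    matched_wiring: bool = False

    def __post_init__(self):
        if self.n_networks < 1:
            raise ValueError("ensemble needs at least one network")
        if self.n_perturb < 1:
            raise ValueError("need at least one perturbation per network")


@dataclass
class EnsembleSummary:
    kind: str
    spec: EnsembleSpec
    fractions: list[float] = field(default_factory=list)
    template_fraction: float | None = None

    @property
    def median(self) -> float:
        return float(np.median(self.fractions))

    @property
    def mean(self) -> float:
        return float(np.mean(self.fractions))

    @property
    def sd(self) -> float:
        return float(np.std(self.fractions, ddof=1))

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.fractions, q))


def generate_matched_random_network(
        template: LogicalNetwork,
        rng: np.random.Generator,
        matched_wiring: bool = False) -> LogicalNetwork:
    """A random network with the template's node count and in-degrees."""
    rules = {}
    for node in template.nodes:
        k = template.rules[node].k
        if matched_wiring:
            inputs = template.rules[node].inputs
        else:
            idx = rng.choice(template.n, size=k, replace=False)
            inputs = tuple(template.nodes[i] for i in sorted(idx))
        table = rng.integers(0, 2, size=1 << k)
        rules[node] = BooleanRule.from_table(node, inputs, table)
    return LogicalNetwork(template.nodes, rules)


def _network_recovery_fraction(net: LogicalNetwork, kind: str,
                               n_perturb: int,
                               rng: np.random.Generator) -> float:
    """Fraction of random perturbations after which the network recovers
    its *own* reference attractor set."""
    f = transition_table(net)
    reference = attractors_from_table(f, net.content_hash())
    recovered = 0
    if kind == "functions":
        bits = [(node, row) for node in net.nodes
                for row in range(1 << net.rules[node].k)]
        draws = rng.integers(0, len(bits), size=n_perturb)
        for d in draws:
            node, row = bits[d]
            patts = find_attractors(flip_function_bit(net, node, row))
            recovered += classify(reference, patts) != "altered"
    elif kind == "transitions":
        for _ in range(n_perturb):
            out = transition_flip_trial(net, rng, reference, f)
            recovered += out.recovered
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    return recovered / n_perturb


def ensemble_robustness(template: LogicalNetwork,
                        spec: EnsembleSpec,
                        kind: str = "functions",
                        include_template: bool = True) -> EnsembleSummary:
    """Robustness of an ensemble of structure-matched random networks.

    For every generated network the recovery fraction of its own attractor
    set under ``spec.n_perturb`` random perturbations of the chosen kind is
    recorded; the summary carries the per-network fractions plus the
    template network's own fraction for comparison.
    """
    rng = np.random.default_rng(spec.seed)
    fractions = []
    for _ in range(spec.n_networks):
        net = generate_matched_random_network(
            template, rng, matched_wiring=spec.matched_wiring)
        fractions.append(
            _network_recovery_fraction(net, kind, spec.n_perturb, rng))
    summary = EnsembleSummary(kind=kind, spec=spec, fractions=fractions)
    if include_template:
        summary.template_fraction = _network_recovery_fraction(
            template, kind, spec.n_perturb, rng)
    return summary


_FIXTURES = {
    # name: (rule text, expected {canonical cycle: basin size})
    "identity1": "targets, factors\nA, A\n",
    "constant2": "targets, factors\nA, 0\nB, 1\n",
    "mutual_negation": "targets, factors\nA, !B\nB, !A\n",
    "cyclic_negation3": "targets, factors\nA, !C\nB, !A\nC, !B\n",
}


def fixture_networks() -> dict[str, LogicalNetwork]:
    """Toy networks with hand-enumerated synchronous attractors.

    * ``identity1``: one node copying itself; both states are fixed points.
    * ``constant2``: constant rules; single fixed point (A=0, B=1) whose
      basin is the whole 4-state space.
    * ``mutual_negation``: A=!B, B=!A; fixed points (0,1) and (1,0), plus
      the period-2 cycle (0,0) <-> (1,1).
    * ``cyclic_negation3``: three-node negation ring; under synchronous
      update it has two period-2 cycles covering all 8 states
      ((0,0,0) <-> (1,1,1) and the 6 remaining states on one cycle of
      period 6 -- see the test-suite's brute-force enumeration).
    """
    return {name: parse_network(text) for name, text in _FIXTURES.items()}
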