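"""Perturbation robustness of the synchronous attractor landscape.

Two perturbation procedures:

* **Function bit flips** — flip one output entry of one node's truth table
  (``Sigma_i 2**k_i`` possible perturbations), either exhaustively or as a
  uniform random sample.
* **Transition bit flips** — flip one node's successor value at one
  specific global state in the full 2^N transition table, the ``bitflip``
  perturbation of state-transition robustness analyses.

Each perturbed system's attractors are recomputed exhaustively and compared
against the reference attractor set; the outcome is classified three ways:
the original attractor is the sole attractor (``recovered_only``), the
original is present alongside new attractors (``recovered_plus_new``), or
the original cycle is lost (``altered``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

from .dynamics import AttractorSet, attractors_from_table, find_attractors, \
    transition_table
from .network import BooleanRule, LogicalNetwork

__all__ = [
    "CATEGORIES",
    "PerturbationOutcome",
    "RobustnessSummary",
    "enumerate_function_flips",
    "flip_function_bit",
    "classify",
    "function_flip_robustness",
    "transition_flip_trial",
    "transition_flip_robustness",
]

CATEGORIES = ("recovered_only", "recovered_plus_new", "altered")

Category = Literal["recovered_only", "recovered_plus_new", "altered"]


@dataclass(frozen=True)
class PerturbationOutcome:
    category: Category
    descriptor: tuple
    perturbed_attractors: AttractorSet

    @property
    def recovered(self) -> bool:
        """Original attractor present (sole or with new ones)."""
        return self.category != "altered"


@dataclass
class RobustnessSummary:
    kind: str
    n_perturbations: int
    counts: dict[str, int]
    seed: int | None = None
    replicate_fractions: list[float] = field(default_factory=list)

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {c: self.counts[c] / total for c in CATEGORIES}

    @property
    def recovered_fraction(self) -> float:
        f = self.fractions
        return f["recovered_only"] + f["recovered_plus_new"]

    @property
    def replicate_mean(self) -> float:
        return float(np.mean(self.replicate_fractions))

    @property
    def replicate_sd(self) -> float:
        return float(np.std(self.replicate_fractions, ddof=1))


def flip_function_bit(net: LogicalNetwork, node: str,
                      row: int) -> LogicalNetwork:
    """A copy of ``net`` with one truth-table output bit of ``node``
    flipped.  Applying the same flip twice restores the original."""
    rule = net.rules[node]
    table = list(rule.table)
    table[row] ^= 1
    return net.with_rule(BooleanRule.from_table(node, rule.inputs, table))


def enumerate_function_flips(
        net: LogicalNetwork) -> Iterator[tuple[LogicalNetwork, tuple]]:
    """All single-bit truth-table perturbations, node by node, row by row.

    Yields ``(perturbed_network, (node, row))``; exactly
    ``net.n_function_bits()`` pairs in total.
    """
    for node in net.nodes:
        for row in range(1 << net.rules[node].k):
            yield flip_function_bit(net, node, row), (node, row)


def classify(reference: AttractorSet, perturbed: AttractorSet) -> Category:
    """Three-way outcome: is the original attractor set still there?

    'Original attractor recovered' means every reference cycle is present
    in the perturbed attractor set (canonicalized cycle equality).
    """
    ref = reference.cycles()
    new = perturbed.cycles()
    if ref <= new:
        return "recovered_only" if new == ref else "recovered_plus_new"
    return "altered"


def _classify_counts(outcomes: Sequence[Category]) -> dict[str, int]:
    return {c: sum(1 for o in outcomes if o == c) for c in CATEGORIES}


def function_flip_robustness(
        net: LogicalNetwork,
        mode: str = "exhaustive",
        n_samples: int | None = None,
        seed: int | None = None,
        weighting: str = "per-bit",
        reference: AttractorSet | None = None,
        collect: list | None = None) -> RobustnessSummary:
    """Classify single truth-table bit flips against the wild-type attractor.

    ``mode='exhaustive'`` walks every (node, row) pair; ``mode='sampled'``
    draws ``n_samples`` flips with replacement, uniformly over bits
    (``weighting='per-bit'``, node weight proportional to 2**k_i) or
    uniformly over nodes then rows (``weighting='per-node'``).
    """
    if reference is None:
        reference = find_attractors(net)
    outcomes: list[Category] = []
    if mode == "exhaustive":
        pairs = [(node, row) for node in net.nodes
                 for row in range(1 << net.rules[node].k)]
    elif mode == "sampled":
        if not n_samples or n_samples <= 0:
            raise ValueError("sampled mode requires n_samples >= 1")
        rng = np.random.default_rng(seed)
        pairs = []
        if weighting == "per-bit":
            all_bits = [(node, row) for node in net.nodes
                        for row in range(1 << net.rules[node].k)]
            idx = rng.integers(0, len(all_bits), size=n_samples)
            pairs = [all_bits[i] for i in idx]
        elif weighting == "per-node":
            for _ in range(n_samples):
                node = net.nodes[rng.integers(0, net.n)]
                row = int(rng.integers(0, 1 << net.rules[node].k))
                pairs.append((node, row))
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for node, row in pairs:
        pert = flip_function_bit(net, node, row)
        patts = find_attractors(pert)
        cat = classify(reference, patts)
        outcomes.append(cat)
        if collect is not None:
            collect.append(PerturbationOutcome(cat, (node, row), patts))
    return RobustnessSummary(
        kind=f"function-{mode}", n_perturbations=len(pairs),
        counts=_classify_counts(outcomes), seed=seed)


def transition_flip_trial(net: LogicalNetwork,
                          rng: np.random.Generator,
                          reference: AttractorSet | None = None,
                          f: np.ndarray | None = None) -> PerturbationOutcome:
    """One random state-transition bit flip.

    A state ``s`` and a node ``i`` are drawn uniformly; node *i*'s successor
    value at exactly state ``s`` is inverted in the full transition table,
    and the modified system's attractors are recomputed exhaustively.
    """
    if f is None:
        f = transition_table(net)
    if reference is None:
        reference = attractors_from_table(f, net.content_hash())
    s = int(rng.integers(0, len(f)))
    i = int(rng.integers(0, net.n))
    g = f.copy()
    g[s] ^= 1 << i
    patts = attractors_from_table(g)
    cat = classify(reference, patts)
    return PerturbationOutcome(cat, (s, net.nodes[i]), patts)


def transition_flip_robustness(net: LogicalNetwork,
                               n_trials: int,
                               n_replicates: int,
                               seed: int) -> RobustnessSummary:
    """Replicated transition-flip experiment.

    Each replicate performs ``n_trials`` independent single-transition
    flips; the per-replicate fraction of trials recovering the original
    attractor is recorded, and the summary reports their mean and SD.
    """
    if n_trials < 1 or n_replicates < 1:
        raise ValueError("n_trials and n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    f = transition_table(net)
    reference = attractors_from_table(f, net.content_hash())
    counts = {c: 0 for c in CATEGORIES}
    fractions = []
    for _ in range(n_replicates):
        rec = 0
        for _ in range(n_trials):
            out = transition_flip_trial(net, rng, reference, f)
            counts[out.category] += 1
            rec += out.recovered
        fractions.append(rec / n_trials)
    return RobustnessSummary(
        kind="transition", n_perturbations=n_trials * n_replicates,
        counts=counts, seed=seed, replicate_fractions=fractions)
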