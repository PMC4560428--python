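"""Synchronous Boolean dynamics: successors, attractors, basins, phases.

All nodes update simultaneously: bit *i* of the successor of state ``s`` is
node *i*'s rule evaluated on ``s`` (or its clamp value).  The state space of
an *N*-node network is the integer interval ``[0, 2**N)``; the full
transition function is materialised as an integer array ``f`` with
``f[s]`` the unique successor of ``s``, which makes exhaustive attractor
and basin enumeration exact and fast for the 2^14 = 16,384 states of the
cell-cycle model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import LogicalNetwork, decode_state

__all__ = [
    "Attractor",
    "AttractorSet",
    "transition_table",
    "successor",
    "find_attractors",
    "attractors_from_table",
    "sample_attractors",
    "PHASE_SCHEME_WT",
    "annotate_phases",
    "PhaseAnnotationError",
    "ExhaustiveLimitError",
]

#: Largest network size for which exhaustive enumeration is attempted.
EXHAUSTIVE_LIMIT = 24


class ExhaustiveLimitError(ValueError):
    """Network too large for exhaustive enumeration; use sampling mode."""


class PhaseAnnotationError(ValueError):
    """No rotation of the cycle matches the phase scheme's anchor."""


def transition_table(net: LogicalNetwork) -> np.ndarray:
    """Successor of every state: array ``f`` of length 2**N."""
    n = net.n
    if n > EXHAUSTIVE_LIMIT:
        raise ExhaustiveLimitError(
            f"{n}-node network exceeds the {EXHAUSTIVE_LIMIT}-node "
            "exhaustive limit; use sample_attractors instead")
    states = np.arange(1 << n, dtype=np.int64)
    bits = {node: ((states >> i) & 1).astype(np.int64)
            for i, node in enumerate(net.nodes)}
    f = np.zeros(1 << n, dtype=np.int64)
    for i, node in enumerate(net.nodes):
        if node in net.clamps:
            col = np.full(1 << n, int(net.clamps[node]), dtype=np.int64)
        else:
            rule = net.rules[node]
            code = np.zeros(1 << n, dtype=np.int64)
            for j, nm in enumerate(rule.inputs):
                code |= bits[nm] << j
            col = np.asarray(rule.table, dtype=np.int64)[code]
        f |= col << i
    return f


def successor(net: LogicalNetwork, state: int | Sequence[int]) -> int:
    """Synchronous successor of one state (integer code or bit vector)."""
    if not isinstance(state, (int, np.integer)):
        bits = list(state)
        if len(bits) != net.n:
            raise ValueError(
                f"state has {len(bits)} bits, network has {net.n} nodes")
        code = sum((1 if b else 0) << i for i, b in enumerate(bits))
    else:
        code = int(state)
        if not 0 <= code < (1 << net.n):
            raise ValueError(f"state code {code} out of range for "
                             f"{net.n}-node network")
    env = {node: (code >> i) & 1 for i, node in enumerate(net.nodes)}
    out = 0
    for i, node in enumerate(net.nodes):
        if node in net.clamps:
            v = int(net.clamps[node])
        else:
            v = net.rules[node](env)
        out |= v << i
    return out


@dataclass(frozen=True)
class Attractor:
    """A cyclic (or fixed-point) attractor with its basin.

    ``cycle`` is canonicalized: rotated so the smallest state code comes
    first, making attractor identity rotation-invariant.
    """

    cycle: tuple[int, ...]
    basin_size: int
    n_states: int

    @property
    def period(self) -> int:
        return len(self.cycle)

    @property
    def basin_fraction(self) -> float:
        return self.basin_size / self.n_states

    @staticmethod
    def canonical(cycle: Sequence[int]) -> tuple[int, ...]:
        cycle = list(cycle)
        m = cycle.index(min(cycle))
        return tuple(cycle[m:] + cycle[:m])

    def states_matrix(self, n_nodes: int) -> np.ndarray:
        """Cycle as an (n_nodes, period) 0/1 matrix (rows = nodes)."""
        return np.array([decode_state(s, n_nodes) for s in self.cycle]).T


@dataclass(frozen=True)
class AttractorSet:
    attractors: tuple[Attractor, ...]
    network_hash: str
    coverage: int

    def __len__(self):
        return len(self.attractors)

    def __iter__(self):
        return iter(self.attractors)

    def cycles(self) -> frozenset[tuple[int, ...]]:
        return frozenset(a.cycle for a in self.attractors)

    def periods(self) -> tuple[int, ...]:
        return tuple(sorted(a.period for a in self.attractors))

    def largest(self) -> Attractor:
        return max(self.attractors, key=lambda a: a.basin_size)


def attractors_from_table(f: np.ndarray,
                          network_hash: str = "") -> AttractorSet:
    """Exhaustive attractor enumeration from a materialised transition table.

    Pointer doubling composes ``f`` with itself ceil(log2(len(f))) times,
    which sends every state onto its terminal cycle; cycles are then walked
    explicitly and basins counted by a single bincount.
    """
    n = len(f)
    h = f
    steps = max(1, int(np.ceil(np.log2(n))))
    for _ in range(steps):
        h = h[h]
    reps = np.unique(h)
    cyc_id: dict[int, int] = {}
    cycles: list[tuple[int, ...]] = []
    for r in reps.tolist():
        if r in cyc_id:
            continue
        cyc = [r]
        t = int(f[r])
        while t != r:
            cyc.append(t)
            t = int(f[t])
        canon = Attractor.canonical(cyc)
        for c in canon:
            cyc_id[c] = len(cycles)
        cycles.append(canon)
    idmap = np.zeros(n, dtype=np.int64)
    for c, aid in cyc_id.items():
        idmap[c] = aid
    basins = np.bincount(idmap[h], minlength=len(cycles))
    atts = tuple(
        Attractor(cycle=cyc, basin_size=int(b), n_states=n)
        for cyc, b in zip(cycles, basins))
    atts = tuple(sorted(atts, key=lambda a: (-a.basin_size, a.cycle)))
    return AttractorSet(atts, network_hash, coverage=n)


def find_attractors(net: LogicalNetwork) -> AttractorSet:
    """All attractors, periods and basin sizes under synchronous update."""
    f = transition_table(net)
    return attractors_from_table(f, network_hash=net.content_hash())


def sample_attractors(net: LogicalNetwork, n_samples: int,
                      seed: int) -> AttractorSet:
    """Attractor search from random initial states (large networks).

    Basin sizes are sample counts (coverage = n_samples), not exact.
    """
    rng = np.random.default_rng(seed)
    found: dict[tuple[int, ...], int] = {}
    for _ in range(n_samples):
        s = int(rng.integers(0, 1 << net.n))
        seen: dict[int, int] = {}
        path = []
        while s not in seen:
            seen[s] = len(path)
            path.append(s)
            s = successor(net, s)
        cyc = Attractor.canonical(path[seen[s]:])
        found[cyc] = found.get(cyc, 0) + 1
    atts = tuple(
        Attractor(cycle=c, basin_size=k, n_states=1 << net.n)
        for c, k in sorted(found.items(), key=lambda kv: -kv[1]))
    return AttractorSet(atts, net.content_hash(), coverage=n_samples)


#: Cell-cycle phase labels for the wild-type period-11 attractor, in cycle
#: order starting from the first G1 configuration.
PHASE_SCHEME_WT = ("G1", "G1", "G1/S", "S", "S/G2", "S/G2", "G2", "G2/M",
                   "M", "M", "M-exit")


def _g1_anchor(net: LogicalNetwork, state: int) -> bool:
    """The G1 marker pattern anchoring the phase walkthrough: the
    CDKA;1-CYCD3;1 complex held inactive by KRP1, APC/C and RBR present,
    mitotic cyclins absent.  Requiring KRP1 distinguishes early G1 from
    the mitosis-exit configuration, which also carries RBR and APC/C."""
    bit = {node: (state >> i) & 1 for i, node in enumerate(net.nodes)}
    return bool(bit["KRP1"] and bit["APC/C"] and bit["RBR"]
                and not bit["CYCB1;1"] and not bit["CYCA2;3"])


def annotate_phases(net: LogicalNetwork, attractor: Attractor,
                    scheme: Sequence[str] = PHASE_SCHEME_WT,
                    ) -> list[tuple[int, str]]:
    """Label each cycle configuration with its cell-cycle phase.

    The cycle is rotated so that its first configuration matches the G1
    anchor pattern; the rotation must be unique up to consecutive G1
    states, otherwise an error is raised rather than guessing.
    """
    if attractor.period != len(scheme):
        raise PhaseAnnotationError(
            f"cycle period {attractor.period} does not match scheme "
            f"length {len(scheme)}")
    cyc = attractor.cycle
    anchors = [i for i, s in enumerate(cyc) if _g1_anchor(net, s)]
    if not anchors:
        raise PhaseAnnotationError("no configuration matches the G1 anchor")
    # earliest anchor of the maximal consecutive anchor run
    start = anchors[0]
    for i in anchors:
        if (i - 1) % len(cyc) not in anchors:
            start = i
            break
    rotated = cyc[start:] + cyc[:start]
    return [(state, phase) for state, phase in zip(rotated, scheme)]
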