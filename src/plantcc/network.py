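"""Logical (Boolean) gene regulatory networks.

A :class:`LogicalNetwork` is an ordered collection of nodes, each updated by
a Boolean rule over a subset of the nodes.  Rules are parsed from the
BoolNet-style ``targets, factors`` text dialect (operators ``!``, ``&``,
``|`` and parentheses; node names are taken verbatim, so ``;`` and ``/``
are legal name characters) and compiled to truth tables.

Node order is significant: it fixes the bit position of every node in the
integer encoding of a network state (bit *i* of the state code is the state
of node *i*).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "BooleanRule",
    "LogicalNetwork",
    "NetworkParseError",
    "parse_network",
    "serialize_network",
    "load_cc_model",
    "cc_metadata",
    "interaction_graph",
    "encode_state",
    "decode_state",
]


class NetworkParseError(ValueError):
    """Raised when a rule file cannot be parsed into a valid network."""


_TOKEN = re.compile(r"\s*(\(|\)|&|\||!|[^\s()&|!]+)")


def _tokenize(expr: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    if expr[pos:].strip():
        raise NetworkParseError(f"cannot tokenize {expr[pos:]!r}")
    return tokens


class _Parser:
    """Recursive-descent parser for !/&/| expressions.

    Grammar:  or := and ('|' and)* ;  and := unary ('&' unary)* ;
              unary := '!' unary | '(' or ')' | identifier | 0 | 1
    """

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise NetworkParseError(f"unexpected token {self.peek()!r}")
        return node

    def parse_or(self):
        terms = [self.parse_and()]
        while self.peek() == "|":
            self.take()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and(self):
        terms = [self.parse_unary()]
        while self.peek() == "&":
            self.take()
            terms.append(self.parse_unary())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_unary(self):
        tok = self.take()
        if tok == "!":
            return ("not", self.parse_unary())
        if tok == "(":
            inner = self.parse_or()
            if self.take() != ")":
                raise NetworkParseError("unbalanced parentheses")
            return inner
        if tok in (")", "&", "|", None):
            raise NetworkParseError(f"unexpected token {tok!r}")
        if tok in ("0", "1"):
            return ("const", int(tok))
        return ("var", tok)


def _ast_vars(ast, acc: list[str]) -> None:
    kind = ast[0]
    if kind == "var":
        if ast[1] not in acc:
            acc.append(ast[1])
    elif kind == "not":
        _ast_vars(ast[1], acc)
    elif kind in ("and", "or"):
        for child in ast[1]:
            _ast_vars(child, acc)


def _ast_eval(ast, env: Mapping[str, bool]) -> bool:
    kind = ast[0]
    if kind == "var":
        return env[ast[1]]
    if kind == "const":
        return bool(ast[1])
    if kind == "not":
        return not _ast_eval(ast[1], env)
    if kind == "and":
        return all(_ast_eval(c, env) for c in ast[1])
    return any(_ast_eval(c, env) for c in ast[1])


@dataclass(frozen=True)
class BooleanRule:
    """A Boolean update rule: expression plus its compiled truth table.

    ``inputs`` are the distinct identifiers in the expression, in order of
    first occurrence.  ``table[j]`` is the rule value on the *j*-th input
    assignment, with the low bit of *j* holding the first input.
    """

    target: str
    expression: str
    inputs: tuple[str, ...]
    table: tuple[int, ...]

    @classmethod
    def from_expression(cls, target: str, expression: str) -> "BooleanRule":
        ast = _Parser(_tokenize(expression)).parse()
        inputs: list[str] = []
        _ast_vars(ast, inputs)
        k = len(inputs)
        table = []
        for j in range(1 << k):
            env = {nm: bool((j >> i) & 1) for i, nm in enumerate(inputs)}
            table.append(int(_ast_eval(ast, env)))
        return cls(target, expression, tuple(inputs), tuple(table))

    @classmethod
    def from_table(cls, target: str, inputs: Sequence[str],
                   table: Sequence[int]) -> "BooleanRule":
        """Build a rule from an explicit truth table (expression in DNF)."""
        inputs = tuple(inputs)
        table = tuple(int(v) for v in table)
        if len(table) != 1 << len(inputs):
            raise ValueError("table length must be 2**len(inputs)")
        if not any(table):
            expr = "0"
        elif all(table):
            expr = "1"
        else:
            minterms = []
            for j, v in enumerate(table):
                if v:
                    lits = [nm if (j >> i) & 1 else "!" + nm
                            for i, nm in enumerate(inputs)]
                    minterms.append("(" + " & ".join(lits) + ")")
            expr = " | ".join(minterms)
        return cls(target, expr, inputs, table)

    @property
    def k(self) -> int:
        return len(self.inputs)

    def __call__(self, env: Mapping[str, int]) -> int:
        j = 0
        for i, nm in enumerate(self.inputs):
            j |= (1 if env[nm] else 0) << i
        return self.table[j]

    def constant(self) -> int | None:
        """The rule's value if it is constant, else None."""
        if all(self.table):
            return 1
        if not any(self.table):
            return 0
        return None


@dataclass(frozen=True)
class LogicalNetwork:
    """An ordered set of nodes with one Boolean update rule per node."""

    nodes: tuple[str, ...]
    rules: Mapping[str, BooleanRule]
    clamps: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkParseError("duplicate node names")
        known = set(self.nodes)
        for node in self.nodes:
            if node not in self.rules:
                raise NetworkParseError(f"no rule for node {node!r}")
            for dep in self.rules[node].inputs:
                if dep not in known:
                    raise NetworkParseError(
                        f"rule for {node!r} references unknown node {dep!r}")
        for node in self.clamps:
            if node not in known:
                raise NetworkParseError(f"clamp on unknown node {node!r}")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def in_degrees(self) -> dict[str, int]:
        return {node: self.rules[node].k for node in self.nodes}

    def in_degree_profile(self) -> tuple[int, ...]:
        """Multiset of in-degrees (sorted), in node order irrelevant."""
        return tuple(sorted(self.rules[n].k for n in self.nodes))

    def n_function_bits(self) -> int:
        """Total truth-table size Sigma_i 2**k_i across nodes."""
        return sum(1 << self.rules[n].k for n in self.nodes)

    def with_clamp(self, node: str, value: int) -> "LogicalNetwork":
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")
        clamps = dict(self.clamps)
        clamps[node] = int(value)
        return LogicalNetwork(self.nodes, self.rules, clamps)

    def with_rule(self, rule: BooleanRule) -> "LogicalNetwork":
        rules = dict(self.rules)
        rules[rule.target] = rule
        return LogicalNetwork(self.nodes, rules, dict(self.clamps))

    def content_hash(self) -> str:
        payload = json.dumps(
            [[n, list(self.rules[n].inputs), list(self.rules[n].table),
              self.clamps.get(n)] for n in self.nodes])
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def encode_state(bits: Iterable[int]) -> int:
    code = 0
    for i, b in enumerate(bits):
        code |= (1 if b else 0) << i
    return code


def decode_state(code: int, n: int) -> tuple[int, ...]:
    return tuple((code >> i) & 1 for i in range(n))


def parse_network(text: str) -> LogicalNetwork:
    """Parse BoolNet-style ``targets, factors`` rule text."""
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise NetworkParseError("empty rule file")
    header = lines[0].replace(" ", "").lower()
    if header != "targets,factors":
        raise NetworkParseError(
            f"expected header 'targets, factors', got {lines[0]!r}")
    if len(lines) == 1:
        raise NetworkParseError("empty rule file (header only)")
    order: list[str] = []
    exprs: dict[str, str] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        if "," not in ln:
            raise NetworkParseError(f"line {lineno}: missing comma in {ln!r}")
        target, expr = ln.split(",", 1)
        target = target.strip()
        if target in exprs:
            raise NetworkParseError(
                f"line {lineno}: duplicate target {target!r}")
        order.append(target)
        exprs[target] = expr.strip()
    declared = set(order)
    rules = {}
    for lineno, target in enumerate(order, start=2):
        try:
            rule = BooleanRule.from_expression(target, exprs[target])
        except NetworkParseError as err:
            raise NetworkParseError(f"line {lineno}: {err}") from None
        for dep in rule.inputs:
            if dep not in declared:
                raise NetworkParseError(
                    f"line {lineno}: rule for {target!r} references "
                    f"unknown node {dep!r}")
        rules[target] = rule
    net = LogicalNetwork(tuple(order), rules)
    return net


def serialize_network(net: LogicalNetwork) -> str:
    lines = ["targets, factors"]
    for node in net.nodes:
        lines.append(f"{node}, {net.rules[node].expression}")
    return "\n".join(lines) + "\n"


def _sign_of_input(rule: BooleanRule, j: int) -> str:
    """Monotonicity of the rule in its j-th input over all contexts."""
    table = np.asarray(rule.table)
    idx = np.arange(len(table))
    off = idx[(idx >> j) & 1 == 0]
    diff = table[off | (1 << j)] - table[off]
    pos = bool((diff > 0).any())
    neg = bool((diff < 0).any())
    if pos and neg:
        return "dual"
    if pos:
        return "activating"
    if neg:
        return "inhibiting"
    return "none"


def interaction_graph(net: LogicalNetwork) -> nx.DiGraph:
    """Signed interaction graph: one edge per essential (input, target) pair.

    Edge attribute ``sign`` is 'activating', 'inhibiting' or 'dual' by
    truth-table monotonicity.  Inputs the table does not actually depend on
    produce no edge.
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for node in net.nodes:
        rule = net.rules[node]
        for j, src in enumerate(rule.inputs):
            sign = _sign_of_input(rule, j)
            if sign != "none":
                g.add_edge(src, node, sign=sign)
    return g


def _data_text(name: str) -> str:
    return resources.files("plantcc.data").joinpath(name).read_text()


def cc_metadata() -> dict:
    """Metadata shipped with the cell-cycle model (node order, phases,
    per-rule provenance notes)."""
    return json.loads(_data_text("cc_metadata.json"))


def load_cc_model() -> LogicalNetwork:
    """The packaged 14-node Arabidopsis thaliana cell-cycle Boolean model."""
    text = _data_text("cc_model.txt")
    meta = cc_metadata()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != meta["rule_file_sha256"]:
        raise RuntimeError("packaged cell-cycle rule file failed its checksum")
    net = parse_network(text)
    if list(net.nodes) != meta["nodes"]:
        raise RuntimeError("packaged rule file disagrees with metadata")
    return net
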