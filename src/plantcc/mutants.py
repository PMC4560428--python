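"""In-silico loss- and gain-of-function mutants by node clamping.

A mutant fixes one node to 0 (loss of function) or 1 (gain of function):
the node's rule is skipped and its state held constant from t=0, while all
other rules are untouched.  Attractors of the clamped network are computed
over the full 2^N initial conditions, matching how mutant basin
percentages are quoted ("% of initial conditions").

Each attractor is assigned a dynamical class by explicit bit-pattern
predicates on the cell-cycle node set:

* ``wild-type-like``: the cycle equals the wild-type 11-cycle on all
  unclamped bits;
* ``fixed-point arrest``: period 1;
* ``endocycle-like``: a cycle with at least one S-phase configuration
  (E2Fa present, RBR absent) but no mitosis-onset configuration (CYCB1;1
  present with KRP1 and APC/C absent);
* ``other cycle`` otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .dynamics import Attractor, AttractorSet, find_attractors
from .network import LogicalNetwork

__all__ = [
    "MutantSpec",
    "MutantReport",
    "apply_mutation",
    "classify_attractor",
    "mutant_scan",
    "load_expectations",
    "compare_with_expectations",
]

CC_NODES = ("CYCD3;1", "CYCB1;1", "CYCA2;3", "CDKB1;1", "KRP1", "RBR",
            "E2Fa", "E2Fb", "E2Fc", "E2Fe", "MYB77", "MYB3R1/4", "SCF",
            "APC/C")


@dataclass(frozen=True)
class MutantSpec:
    node: str
    value: int  # 0 = loss of function, 1 = gain of function

    @property
    def label(self) -> str:
        return f"{self.node}{'+' if self.value else '-'}"


@dataclass
class MutantReport:
    spec: MutantSpec | None
    attractors: AttractorSet
    classes: list[str]

    @property
    def periods(self) -> tuple[int, ...]:
        return tuple(a.period for a in self.attractors)

    @property
    def basin_percents(self) -> tuple[float, ...]:
        return tuple(round(100 * a.basin_fraction, 2)
                     for a in self.attractors)


def apply_mutation(net: LogicalNetwork, spec: MutantSpec) -> LogicalNetwork:
    """Clamped copy of the network; the original is unmodified."""
    if spec.value not in (0, 1):
        raise ValueError("clamp value must be 0 or 1")
    return net.with_clamp(spec.node, spec.value)


def _bit(net: LogicalNetwork, state: int, node: str) -> int:
    return (state >> net.index(node)) & 1


def _mitosis_onset(net: LogicalNetwork, state: int) -> bool:
    """CYCB1;1 present with neither KRP1 nor APC/C opposing it: the
    mitosis-trigger pattern of the wild-type cycle's M configurations."""
    return bool(_bit(net, state, "CYCB1;1") and not _bit(net, state, "KRP1")
                and not _bit(net, state, "APC/C"))


def _s_phase(net: LogicalNetwork, state: int) -> bool:
    """E2Fa active with RBR absent: licensed DNA replication."""
    return bool(_bit(net, state, "E2Fa") and not _bit(net, state, "RBR"))


def _same_on_unclamped(net: LogicalNetwork, cycle: tuple[int, ...],
                       reference_cycle: tuple[int, ...],
                       clamped: str | None) -> bool:
    """Cycle equality ignoring the clamped node's bit (any rotation)."""
    mask = (1 << net.n) - 1
    if clamped is not None:
        mask &= ~(1 << net.index(clamped))
    a = [s & mask for s in cycle]
    b = [s & mask for s in reference_cycle]
    if len(a) != len(b):
        return False
    for shift in range(len(a)):
        if a[shift:] + a[:shift] == b:
            return True
    return False


def classify_attractor(net: LogicalNetwork, attractor: Attractor,
                       reference: Attractor | None = None,
                       clamped: str | None = None) -> str:
    if set(CC_NODES) - set(net.nodes):
        return "other"
    if reference is not None and _same_on_unclamped(
            net, attractor.cycle, reference.cycle, clamped):
        return "wild-type-like"
    if attractor.period == 1:
        return "fixed-point arrest"
    has_m = any(_mitosis_onset(net, s) for s in attractor.cycle)
    has_s = any(_s_phase(net, s) for s in attractor.cycle)
    if not has_m and has_s:
        return "endocycle-like"
    return "other"


def mutant_scan(net: LogicalNetwork,
                reference: AttractorSet | None = None) -> list[MutantReport]:
    """All 2N single-node clamps (and the wild type first, spec=None)."""
    if reference is None:
        reference = find_attractors(net)
    ref = reference.largest()
    reports = [MutantReport(None, reference,
                            [classify_attractor(net, a, ref)
                             for a in reference])]
    for node in net.nodes:
        for value in (0, 1):
            spec = MutantSpec(node, value)
            atts = find_attractors(apply_mutation(net, spec))
            classes = [classify_attractor(net, a, ref, clamped=node)
                       for a in atts]
            reports.append(MutantReport(spec, atts, classes))
    return reports


def load_expectations() -> list[dict]:
    """Published mutant phenotype expectations (transcribed summary table):
    periods and basin percentages where printed, qualitative class
    otherwise."""
    text = resources.files("plantcc.data").joinpath(
        "mutant_expectations.json").read_text()
    return json.loads(text)


def compare_with_expectations(reports: list[MutantReport]) -> list[dict]:
    """Join the scan against the expectations table.

    Numeric fields (periods, basin percentages) are compared exactly where
    the expectation records them; qualitative descriptions are carried
    through for reporting, not asserted.
    """
    expectations = load_expectations()
    by_key = {(r.spec.node, r.spec.value): r for r in reports
              if r.spec is not None}
    rows = []
    for exp in expectations:
        rep = by_key.get((exp["node"], exp["value"]))
        row = dict(exp)
        if rep is None:
            row["match"] = "not-run"
            rows.append(row)
            continue
        row["observed_periods"] = sorted(rep.periods)
        row["observed_basins"] = sorted(rep.basin_percents)
        row["observed_classes"] = rep.classes
        checks = []
        if exp.get("periods") is not None:
            checks.append(sorted(exp["periods"]) == sorted(rep.periods))
        if exp.get("basin_percents") is not None:
            checks.append(sorted(exp["basin_percents"])
                          == sorted(rep.basin_percents))
        if exp.get("n_attractors") is not None:
            checks.append(exp["n_attractors"] == len(rep.attractors))
        row["match"] = ("agree" if all(checks) else "disagree") if checks \
            else "qualitative"
        rows.append(row)
    return rows
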