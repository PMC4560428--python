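"""Continuous (fuzzy-logic) approximation of the Boolean model.

Each node's Boolean rule ``F_i`` is extended to a continuous input
function ``omega_i`` on the unit hypercube (AND -> min, OR -> max,
NOT -> 1-x under min-max semantics; AND -> product, OR -> probabilistic
sum under probabilistic semantics; both agree with ``F_i`` on binary
corners).  Node concentrations then follow

    dx_i/dt = g(omega_i(x); h) - gamma_i * x_i

where the production term is the sigmoid-normalised input

    g(w; h) = [-exp(0.5 h) + exp(-h w)] /
              [(1 - exp(0.5 h)) * (1 + exp(-h (w - 0.5)))]

with steepness ``h`` (straight line as h -> 0, step function for large h)
and per-node decay rate ``gamma_i``.  The wild-type system settles on a
limit cycle that mirrors the Boolean 11-cycle; mutants are integrated
with the clamped node held constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .network import BooleanRule, LogicalNetwork

__all__ = [
    "fuzzify",
    "production",
    "ContinuousModel",
    "Trajectory",
    "LimitCycleVerdict",
    "detect_limit_cycle",
    "parameter_sweep",
]


def fuzzify(rule: BooleanRule, semantics: str = "minmax"
            ) -> Callable[[Mapping[str, float]], float]:
    """Continuous extension of a Boolean rule.

    Returns a function of a mapping node -> level in [0, 1].  On binary
    corner inputs it coincides with the rule's truth table under either
    semantics.
    """
    if semantics not in ("minmax", "probabilistic"):
        raise ValueError(f"unknown semantics {semantics!r}")
    table = np.asarray(rule.table, dtype=float)
    inputs = rule.inputs
    k = len(inputs)

    def omega(env: Mapping[str, float]) -> float:
        x = [float(env[nm]) for nm in inputs]
        total = 0.0
        for j in range(1 << k):
            w = table[j]
            if w == 0.0:
                continue
            if semantics == "minmax":
                lit = min(((x[i] if (j >> i) & 1 else 1.0 - x[i])
                           for i in range(k)), default=1.0)
                total = max(total, lit)
            else:
                lit = 1.0
                for i in range(k):
                    lit *= x[i] if (j >> i) & 1 else 1.0 - x[i]
                total += lit
        return min(max(total, 0.0), 1.0)

    return omega


def production(omega_value: float | np.ndarray, h: float):
    """Sigmoid production term of the rate equation.

    Strictly increasing in ``omega_value``; evaluated in an algebraically
    stabilised form that cannot overflow for large ``h``:

        g(w) = (1 - e^{-h w}) / (1 - e^{-0.5 h})
                * 1 / (1 + e^{-h (w - 0.5)})  ... rearranged below.
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    w = np.asarray(omega_value, dtype=float)
    # numerator: -e^{0.5h} + e^{-hw} = -(e^{0.5h} - e^{-hw})
    # denominator: (1 - e^{0.5h})(1 + e^{-h(w-0.5)})
    # factor e^{0.5h} out of both: numerator = e^{0.5h}(e^{-hw-0.5h} - 1)
    # denominator = e^{0.5h}(e^{-0.5h} - 1)(1 + e^{-h(w-0.5)})
    a = np.expm1(-h * w - 0.5 * h)          # e^{-hw-0.5h} - 1, safe
    b = np.expm1(-0.5 * h)                  # e^{-0.5h} - 1
    c = 1.0 + np.exp(-np.clip(h * (w - 0.5), -700, 700))
    out = a / (b * c)
    return out if out.shape else float(out)


def production_raw(omega_value: float, h: float) -> float:
    """Literal textbook form of the production term (moderate h only);
    kept for cross-checking the stabilised evaluation."""
    w = float(omega_value)
    num = -np.exp(0.5 * h) + np.exp(-h * w)
    den = (1 - np.exp(0.5 * h)) * (1 + np.exp(-h * (w - 0.5)))
    return num / den


@dataclass
class Trajectory:
    t: np.ndarray
    x: np.ndarray                      # shape (n_nodes, n_times)
    nodes: tuple[str, ...]
    x0: np.ndarray
    solver: dict

    def node(self, name: str) -> np.ndarray:
        return self.x[self.nodes.index(name)]


@dataclass
class LimitCycleVerdict:
    is_cycle: bool
    period: float | None
    amplitudes: dict[str, float]
    diagnostics: dict = field(default_factory=dict)


class ContinuousModel:
    """ODE system derived from a logical network via fuzzy interpolation."""

    def __init__(self, net: LogicalNetwork, h: float = 20.0,
                 gamma: float | Mapping[str, float] = 0.5,
                 semantics: str = "minmax"):
        self.net = net
        self.h = float(h)
        if isinstance(gamma, (int, float)):
            self.gamma = {n: float(gamma) for n in net.nodes}
        else:
            self.gamma = {n: float(gamma[n]) for n in net.nodes}
        if any(g <= 0 for g in self.gamma.values()):
            raise ValueError("decay rates must be positive")
        self.semantics = semantics
        self._omega = {n: fuzzify(net.rules[n], semantics)
                       for n in net.nodes}

    def omega(self, name: str, env: Mapping[str, float]) -> float:
        return self._omega[name](env)

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        env = {n: x[i] for i, n in enumerate(self.net.nodes)}
        dx = np.empty_like(x)
        for i, n in enumerate(self.net.nodes):
            if n in self.net.clamps:
                dx[i] = 0.0
            else:
                dx[i] = production(self._omega[n](env), self.h) \
                    - self.gamma[n] * x[i]
        return dx

    def integrate(self, x0: Sequence[float], t_span: tuple[float, float],
                  n_points: int = 2000, rtol: float = 1e-6,
                  atol: float = 1e-8, method: str = "LSODA") -> Trajectory:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (self.net.n,):
            raise ValueError(f"x0 must have length {self.net.n}")
        for n, v in self.net.clamps.items():
            x0[self.net.index(n)] = float(v)
        t_eval = np.linspace(t_span[0], t_span[1], n_points)
        sol = solve_ivp(self.rhs, t_span, x0, t_eval=t_eval, rtol=rtol,
                        atol=atol, method=method)
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed ({sol.message}); settings: h={self.h}, "
                f"gamma={self.gamma}, rtol={rtol}, atol={atol}")
        return Trajectory(sol.t, sol.y, self.net.nodes, x0,
                          solver={"method": method, "rtol": rtol,
                                  "atol": atol, "h": self.h})


def detect_limit_cycle(traj: Trajectory, settle_fraction: float = 0.5,
                       tolerance: float = 0.05,
                       min_amplitude: float = 0.05) -> LimitCycleVerdict:
    """Sustained-oscillation test on the post-transient trajectory.

    A limit cycle requires at least one node with >= 3 successive peaks of
    near-constant amplitude and spacing (relative spread < ``tolerance``),
    and no node whose oscillation decays away during the analysis window.
    The period estimate is the mean inter-peak interval of the most
    regular oscillating node.
    """
    if not 0 < settle_fraction < 1:
        raise ValueError("settle_fraction must be in (0, 1)")
    n_skip = int(len(traj.t) * settle_fraction)
    if len(traj.t) - n_skip < 10:
        raise ValueError("trajectory too short after settling prefix")
    t = traj.t[n_skip:]
    periods = {}
    amplitudes = {}
    for i, node in enumerate(traj.nodes):
        y = traj.x[i, n_skip:]
        span = float(y.max() - y.min())
        amplitudes[node] = span
        if span < min_amplitude:
            continue
        peaks, props = find_peaks(y, prominence=min_amplitude / 2)
        if len(peaks) < 3:
            continue
        intervals = np.diff(t[peaks])
        heights = y[peaks]
        troughs = y.min()
        amp = heights - troughs
        rel_iv = intervals.std() / intervals.mean() if intervals.mean() else 1
        rel_amp = amp.std() / amp.mean() if amp.mean() else 1
        decaying = bool(amp[-1] < (1 - tolerance) * amp[0])
        if rel_iv < tolerance and rel_amp < tolerance and not decaying:
            periods[node] = float(intervals.mean())
    if periods:
        best = min(periods.items(), key=lambda kv: kv[1])
        return LimitCycleVerdict(True, best[1], amplitudes,
                                 {"oscillating_nodes": sorted(periods)})
    return LimitCycleVerdict(False, None, amplitudes,
                             {"oscillating_nodes": []})


def count_pulses_per_period(traj: Trajectory, node: str, period: float,
                            settle_fraction: float = 0.5,
                            min_amplitude: float = 0.05) -> float:
    """Mean number of activity pulses of ``node`` per limit-cycle period."""
    n_skip = int(len(traj.t) * settle_fraction)
    t = traj.t[n_skip:]
    y = traj.x[traj.nodes.index(node), n_skip:]
    peaks, _ = find_peaks(y, prominence=min_amplitude)
    window = t[-1] - t[0]
    return len(peaks) * period / window


def parameter_sweep(net: LogicalNetwork,
                    h_values: Sequence[float],
                    gamma_values: Sequence[float],
                    n_initial: int = 5,
                    seed: int = 0,
                    t_end: float = 160.0,
                    semantics: str = "minmax",
                    n_points: int = 4000) -> dict:
    """Limit-cycle survey over an h x gamma grid from random starts.

    Every grid cell integrates ``n_initial`` uniform-random initial
    conditions and applies :func:`detect_limit_cycle`; the cell verdict is
    'cycle' (all starts), 'mixed', or 'none'.  Returns the cell table and
    the overall fraction of cells whose every start reached the cycle.
    """
    if not len(h_values) or not len(gamma_values):
        raise ValueError("empty parameter grid")
    rng = np.random.default_rng(seed)
    cells = []
    n_cycle_cells = 0
    for h in h_values:
        for g in gamma_values:
            model = ContinuousModel(net, h=h, gamma=g, semantics=semantics)
            hits = 0
            for _ in range(n_initial):
                x0 = rng.uniform(0, 1, size=net.n)
                traj = model.integrate(x0, (0.0, t_end), n_points=n_points)
                if detect_limit_cycle(traj).is_cycle:
                    hits += 1
            verdict = ("cycle" if hits == n_initial
                       else "none" if hits == 0 else "mixed")
            n_cycle_cells += verdict == "cycle"
            cells.append({"h": h, "gamma": g, "n_cycle": hits,
                          "n_total": n_initial, "verdict": verdict})
    return {"cells": cells,
            "fraction_cycle": n_cycle_cells / len(cells),
            "seed": seed, "semantics": semantics, "t_end": t_end}
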