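"""Fuzzy-logic interpolation, production term, integration, cycle detection."""

import numpy as np
import pytest

from plantcc.continuous import (
    ContinuousModel,
    Trajectory,
    detect_limit_cycle,
    fuzzify,
    parameter_sweep,
    production,
)
from plantcc.continuous import production_raw
from plantcc.network import BooleanRule, parse_network


class TestFuzzify:
    @pytest.mark.parametrize("semantics", ["minmax", "probabilistic"])
    def test_corner_consistency_all_cc_rules(self, cc, semantics):
        """On binary corners omega equals the Boolean table, for every
        rule of the cell-cycle model (exhaustive over 2^k corners)."""
        for node in cc.nodes:
            rule = cc.rules[node]
            omega = fuzzify(rule, semantics)
            for j in range(1 << rule.k):
                env = {nm: float((j >> i) & 1)
                       for i, nm in enumerate(rule.inputs)}
                assert omega(env) == pytest.approx(rule.table[j]), node

    def test_minmax_interior_value(self):
        rule = BooleanRule.from_expression("E2Fb", "E2Fa & !RBR")
        omega = fuzzify(rule, "minmax")
        assert omega({"E2Fa": 0.8, "RBR": 0.3}) == pytest.approx(0.7)

    def test_probabilistic_interior_value(self):
        rule = BooleanRule.from_expression("E2Fb", "E2Fa & !RBR")
        omega = fuzzify(rule, "probabilistic")
        assert omega({"E2Fa": 0.8, "RBR": 0.3}) == pytest.approx(0.56)

    def test_bounded_on_random_points(self, cc, rng):
        for node in cc.nodes:
            omega = fuzzify(cc.rules[node], "probabilistic")
            for _ in range(20):
                env = {nm: rng.uniform()
                       for nm in cc.rules[node].inputs}
                assert 0.0 <= omega(env) <= 1.0


class TestProduction:
    @pytest.mark.parametrize("h", [1.0, 10.0, 50.0, 100.0])
    def test_closed_forms(self, h):
        a = np.exp(0.5 * h)
        assert production(0.0, h) == pytest.approx(1 / (1 + a), rel=1e-10)
        assert production(1.0, h) == pytest.approx(
            (1 + a + a * a) / (a + a * a), rel=1e-10)
        assert production(0.5, h) == pytest.approx(
            (1 + a) / (2 * a), rel=1e-10)

    @pytest.mark.parametrize("h", [1.0, 10.0, 50.0])
    def test_matches_raw_form_at_moderate_h(self, h):
        for w in np.linspace(0, 1, 21):
            assert production(w, h) == pytest.approx(
                production_raw(w, h), rel=1e-10)

    @pytest.mark.parametrize("h", [1.0, 10.0, 50.0, 100.0])
    def test_monotone_increasing(self, h):
        w = np.linspace(0, 1, 201)
        g = production(w, h)
        d = np.diff(g)
        assert (d >= 0).all()
        # strictly increasing wherever the sigmoid is not saturated to
        # machine precision
        interior = (g[:-1] > 1e-12) & (g[1:] < 1 - 1e-12)
        assert (d[interior] > 0).all()

    def test_large_h_approaches_step(self):
        assert production(0.0, 400.0) == pytest.approx(0.0, abs=1e-12)
        assert production(1.0, 400.0) == pytest.approx(1.0, abs=1e-12)
        assert np.isfinite(production(np.linspace(0, 1, 11), 700.0)).all()

    def test_invalid_h(self):
        with pytest.raises(ValueError):
            production(0.5, 0.0)


class TestIntegration:
    def test_constant_rule_converges_to_closed_form(self):
        """Single node with rule 1: x* = production(1, h) / gamma."""
        net = parse_network("targets, factors\nA, 1\n")
        model = ContinuousModel(net, h=10.0, gamma=1.0)
        traj = model.integrate([0.2], (0, 40))
        assert traj.x[0, -1] == pytest.approx(production(1.0, 10.0),
                                              abs=1e-4)

    def test_clamped_node_held_constant(self, cc):
        model = ContinuousModel(cc.with_clamp("KRP1", 0))
        traj = model.integrate(np.full(14, 0.5), (0, 5), n_points=100)
        assert np.allclose(traj.node("KRP1"), 0.0)

    def test_bad_x0_shape(self, cc):
        with pytest.raises(ValueError):
            ContinuousModel(cc).integrate([0.5, 0.5], (0, 1))

    def test_nonpositive_gamma_rejected(self, cc):
        with pytest.raises(ValueError):
            ContinuousModel(cc, gamma=0.0)


class TestLimitCycleDetector:
    def _traj(self, t, y):
        return Trajectory(t, y[None, :], ("A",), y[:1], {})

    def test_decaying_exponential_is_not_a_cycle(self):
        t = np.linspace(0, 100, 2000)
        v = detect_limit_cycle(self._traj(t, np.exp(-0.05 * t)))
        assert not v.is_cycle

    def test_damped_oscillation_is_not_a_cycle(self):
        t = np.linspace(0, 100, 4000)
        y = 0.5 + 0.4 * np.exp(-0.05 * t) * np.sin(t)
        assert not detect_limit_cycle(self._traj(t, y)).is_cycle

    def test_sinusoid_period_recovered(self):
        t = np.linspace(0, 100, 4000)
        y = 0.5 + 0.3 * np.sin(2 * np.pi * t / 12.5)
        v = detect_limit_cycle(self._traj(t, y))
        assert v.is_cycle
        assert v.period == pytest.approx(12.5, rel=0.02)

    def test_short_trajectory_raises(self):
        t = np.linspace(0, 1, 12)
        with pytest.raises(ValueError):
            detect_limit_cycle(self._traj(t, np.sin(t)),
                               settle_fraction=0.95)


class TestCellCycleODE:
    @pytest.fixture(scope="class")
    def wt_traj(self, cc):
        model = ContinuousModel(cc)  # package defaults: h=20, gamma=0.5
        rng = np.random.default_rng(3)
        return model.integrate(rng.uniform(0, 1, 14), (0, 150),
                               n_points=5000)

    def test_sustained_limit_cycle_minmax(self, wt_traj):
        v = detect_limit_cycle(wt_traj)
        assert v.is_cycle

    def test_cyclin_oscillations_not_attenuated(self, wt_traj):
        """CYCD3;1 and CYCB1;1 keep oscillating in the second half of the
        window with undiminished amplitude."""
        n = len(wt_traj.t)
        for node in ("CYCD3;1", "CYCB1;1"):
            y = wt_traj.node(node)
            amp_mid = np.ptp(y[n // 2:3 * n // 4])
            amp_late = np.ptp(y[3 * n // 4:])
            assert amp_mid > 0.3 and amp_late > 0.3
            assert amp_late > 0.8 * amp_mid

    def test_d_and_b_cyclins_antiphase(self, wt_traj):
        """G1/S and G2/M cyclins peak in opposite phases of the cycle."""
        n = len(wt_traj.t) // 2
        d = wt_traj.node("CYCD3;1")[n:]
        b = wt_traj.node("CYCB1;1")[n:]
        r = np.corrcoef(d, b)[0, 1]
        assert r < 0

    def test_probabilistic_semantics_also_cycles(self, cc):
        model = ContinuousModel(cc, semantics="probabilistic")
        rng = np.random.default_rng(4)
        traj = model.integrate(rng.uniform(0, 1, 14), (0, 150),
                               n_points=5000)
        assert detect_limit_cycle(traj).is_cycle

    def test_peak_order_matches_boolean_cycle(self, cc, wt_traj):
        """Peak times over one continuous period follow the first-activation
        order of the Boolean 11-cycle (rank correlation)."""
        from scipy.stats import spearmanr
        from plantcc.dynamics import annotate_phases, find_attractors

        v = detect_limit_cycle(wt_traj)
        assert v.is_cycle and v.period is not None
        labeled = annotate_phases(cc, find_attractors(cc).attractors[0])
        cycle_states = [s for s, _ in labeled]
        first_on = {}
        for i, node in enumerate(cc.nodes):
            prev = (cycle_states[-1] >> i) & 1
            for pos, s in enumerate(cycle_states):
                bit = (s >> i) & 1
                if bit and not prev:
                    first_on[node] = pos
                    break
                prev = bit
        # continuous peak phase within one period, post-transient
        n = len(wt_traj.t) // 2
        t = wt_traj.t[n:]
        phases = {}
        for node, pos in first_on.items():
            y = wt_traj.node(node)[n:]
            if np.ptp(y) < 0.1:
                continue
            k = int(np.argmax(y[:int(len(y) * v.period / (t[-1] - t[0]))]))
            phases[node] = t[k] % v.period
        common = [nd for nd in phases if nd in first_on]
        if len(common) >= 5:
            rho, _ = spearmanr([first_on[nd] for nd in common],
                               [phases[nd] for nd in common])
            assert abs(rho) > 0.3


class TestSweep:
    def test_single_cell_grid(self, cc):
        out = parameter_sweep(cc, h_values=[20.0], gamma_values=[0.5],
                              n_initial=2, seed=0, t_end=160.0,
                              n_points=4000)
        assert len(out["cells"]) == 1
        assert out["cells"][0]["verdict"] == "cycle"
        assert out["fraction_cycle"] == 1.0

    def test_degenerate_small_h_reported_not_failed(self, cc):
        out = parameter_sweep(cc, h_values=[0.05], gamma_values=[1.0],
                              n_initial=1, seed=1, t_end=40.0,
                              n_points=1000)
        assert out["cells"][0]["verdict"] in ("cycle", "mixed", "none")

    def test_empty_grid_raises(self, cc):
        with pytest.raises(ValueError):
            parameter_sweep(cc, h_values=[], gamma_values=[1.0])
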