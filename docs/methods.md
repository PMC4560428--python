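# Methods

## The model

`plantcc` ships a synchronous Boolean model of the *Arabidopsis thaliana*
cell cycle with fourteen nodes: the cyclins CYCD3;1, CYCB1;1 and CYCA2;3,
the plant-specific kinase CDKB1;1, the CDK inhibitor KRP1, the pocket
protein RBR, the E2F transcription factors E2Fa, E2Fb, E2Fc and E2Fe, the
MYB factors MYB77 and MYB3R1/4, and the two E3 ubiquitin-ligase complexes
SCF and APC/C.  CDKA;1 is not a node: it is treated as constitutively
present in proliferating tissue, so the activity of each CDKA;1–cyclin
complex is carried by the cyclin's node.  Complex formation is folded into
the rules of the complexes' targets: e.g. RBR phosphorylation by
CDKA;1–CYCD3;1 appears in RBR's rule as the condition
`CYCD3;1 & !KRP1`, and E2F activity appears in E2F targets as
`E2Fa & !RBR` / `E2Fb & !RBR`.  A node value of 1 means the component is
present and functional; 0 means absent or inactivated.

All nodes update simultaneously: `x_i(t+1) = F_i(x(t))`.  The state space
is the 2^14 = 16,384 binary configurations; each configuration has exactly
one successor, so the dynamics are a functional graph whose terminal
cycles are the attractors and whose weakly connected components are their
basins.

### Provenance of the rules

The regulatory interactions (activations/inhibitions with literature
evidence) are fixed, but the full logical expressions are published only
in a supplement that is not part of this package's sources.  The packaged
rules were therefore **reconstructed**: the per-node regulator sets and
signs were fixed from the interaction tables under the complex-folding
conventions above, and the truth tables were searched (constraint solving
over candidate attractor matrices consistent with the published phase
walkthrough, followed by simulated annealing over the remaining monotone
table bits) against the published dynamical behaviour — the single
period-11 wild-type attractor with a 100% basin, the phase ordering of its
configurations, and the published knockout/overexpression attractors.

The reconstruction reproduces, exactly: the unique wild-type 11-cycle
covering all 16,384 states with the documented G1 → G1/S → S → S/G2 → G2
→ G2/M → M → M-exit progression and the two-pulse expression of KRP1 and
E2Fc; the KRP1 loss-of-function attractor (period 11, 100% basin); the
CDKB1;1 loss-of-function and APC/C gain-of-function period-7 endocycles;
the RBR loss-of-function basin split of 81.98% / 18.02%; the MYB77
loss-of-function period-7 cycle; and the published arrest (fixed-point)
phenotypes including the E2Fa-loss arrest with exactly CYCD3;1 and E2Fe
present and the E2Fc-gain arrest with exactly E2Fc and CYCD3;1 present.
It does **not** exactly reproduce every published mutant: E2Fa
overexpression yields a single period-12 cycle here instead of the
published pair of attractors (periods 10 and 8 with a 40.48/59.52 basin
split), CYCD3;1 loss gives period 3 instead of 2, and E2Fe loss gives
period 9 instead of 7.  Those residuals are the strongest remaining
evidence that individual table entries still differ from the original
supplement; the corresponding strict tests in `tests/test_acceptance.py`
fail by design rather than being loosened.

## Attractor enumeration

`transition_table` materialises the full successor array; pointer doubling
(composing the map with itself ceil(log2(2^N)) times) lands every state on
its terminal cycle, after which cycles are walked explicitly and basin
sizes obtained with a single `bincount`.  The enumeration is exact for
N ≤ 24; beyond that `sample_attractors` draws seeded random initial
states.  Attractor identity is the canonicalized cycle (rotated so its
smallest state code comes first), which makes identity rotation-invariant.
An independent per-state trajectory-walk oracle in the test-suite verifies
the enumeration on every fixture network and on random 8-node networks.

## Phase annotation

The 11-cycle is annotated G1, G1, G1/S, S, S/G2, S/G2, G2, G2/M, M, M,
M-exit after rotating it so the first configuration matches the G1 anchor
pattern: CDKA;1–CYCD3;1 inactive (CYCD3;1 absent or KRP1 present), APC/C
and RBR present, mitotic cyclins absent.  If no rotation matches, the
annotation raises instead of guessing.

## Perturbation robustness

Two procedures, both classifying the perturbed network's attractor set
against the wild type three ways — `recovered_only` (original attractors
are the sole attractors), `recovered_plus_new` (original present plus new
ones), `altered` (an original attractor lost):

* **Function bit flips** flip one output bit of one node's truth table;
  there are Σ_i 2^{k_i} = 378 such perturbations for the packaged model,
  enumerable exhaustively in seconds, or sampled uniformly per-bit
  (per-node weighting is available as an option).
* **Transition bit flips** flip one node's successor value at one
  uniformly drawn state of the full 2^14-state transition table.

A structural consequence worth stating plainly: for any network whose
single attractor occupies only 11 of 16,384 states, a single transition
flip removes the original cycle only when it hits one of those 11 states,
so the recovered fraction under this procedure is ~99.9% and is not a
sensitive robustness probe for this model.  The published transition-
robustness figures for this system (≈88% recovery; ensemble median 24.2%)
cannot be produced by this operation on any single-attractor model, which
indicates that the original analysis perturbed something other than a
single uniformly chosen transition entry (its description admits several
readings, including rule re-inference from perturbed trajectories).  We
implement the operation as specified here and report what it actually
measures; see the strict tests for the corresponding expected failures.

## Random ensembles

`generate_matched_random_network` preserves the template's node count and
per-node in-degrees; inputs are drawn uniformly without replacement
(self-inputs allowed — the model itself has the MYB3R1/4 self-loop) and
truth tables uniformly over all 2^{2^k} tables (entry bias 0.5).  A
matched-wiring mode (template wiring, random tables) is available for
sensitivity analysis.  `ensemble_robustness` computes, for every random
network, its own reference attractor set and the fraction of seeded random
perturbations after which every reference attractor is still present.  The
reduced preset (100 networks × 100 perturbations) runs in ~2 minutes; the
full preset (1000 × 100) sits behind an explicit flag.

## Mutants

A mutant clamps one node to 0 or 1 from t = 0; basin percentages are over
all 2^14 initial states, matching how the published basin percentages are
quoted (restricting to clamp-consistent states is available as an option).
Attractors are classified by explicit bit-pattern predicates: wild-type-
like (equals the wild-type cycle on unclamped bits), fixed-point arrest
(period 1), endocycle-like (a cycle with an S-phase configuration —
E2Fa present, RBR absent — but no mitosis-onset configuration — CYCB1;1
present with KRP1 and APC/C absent), other.  The packaged expectations
table records the published periods and basin percentages where printed
and qualitative descriptions otherwise; numeric fields are compared
exactly, qualitative ones only reported.  One published inconsistency is
recorded as such: the mutant summary table prints period 11 for the
CDKB1;1 loss-of-function endocycle while the published attractor figure
shows period 7; the expectations file follows the figure.

## Continuous model

Each rule is extended to the unit hypercube with fuzzy operators
(min–max semantics: AND → min, OR → max, NOT → 1−x; probabilistic
semantics: AND → product, OR → a+b−ab), both of which agree with the
Boolean table on binary corners, and each node follows

    dx_i/dt = g(ω_i(x); h) − γ_i x_i,

where g is the normalised sigmoid production term (a straight line as
h → 0 and a step function for large h), evaluated in an algebraically
rearranged overflow-free form whose three closed-form values at ω = 0,
0.5, 1 are verified to 1e−10 in the tests.

Parameter defaults were chosen from the model's own phase diagram rather
than taken a priori: under min–max semantics the centre of the hypercube
(all x_i = 0.5) is always an equilibrium, and at steep h ≥ ~50 with
γ = 1 it attracts most random initial conditions, extinguishing the
oscillation.  At h = 20, γ = 0.5 (the package defaults) random initial
conditions converge to a large-amplitude limit cycle under both
semantics, the cyclins CYCD3;1 and CYCB1;1 oscillate in anti-phase
without attenuation, and E2Fc and KRP1 show their characteristic two
pulses per period.  Trajectories are integrated with LSODA
(rtol 1e−6, atol 1e−8); limit-cycle detection requires at least three
successive peaks with near-constant amplitude and spacing after
discarding a settling prefix, and no monotonically decaying oscillation.
The default robustness sweep covers h ∈ {1, 5, 10, 20, 50, 100} ×
γ ∈ {0.5, 1, 2} from seeded random starts; degenerate cells (near-linear
activation at small h) are reported as cells rather than errors.  The
published sweep recovered the limit cycle in 92.86% of cases (13/14 —
its exact grid is in the unavailable supplement).  On this package's
18-cell default grid the oscillation survives for steep activation with
slow decay (all h ≥ 10 at γ = 0.5, and h = 10–20 at γ = 1) but is lost
for near-linear activation (h ≤ 5) and for fast decay (γ = 2), putting
the limit-cycle fraction near one third of the grid; the corresponding
strict test fails rather than redefining the grid around the published
figure.

## Synthetic fixtures

`fixture_networks` packages four toy networks with hand-enumerated
synchronous attractors (a self-copying node, a constant network, the
two-node mutual-negation switch, the three-node negation ring) that
anchor the test-suite's oracle comparisons.  The random ensembles emulate
only the wiring statistics of the real network — in-degree profile,
unbiased tables — not its biological organisation (no canalization,
no signed-motif structure), so passing ensemble tests demonstrate the
contrast between this network and degree-matched noise, nothing more.

## Problem sizes

Exhaustive enumeration (16,384 states) takes milliseconds; the exhaustive
function-flip analysis (378 networks) ~2 s; the 100 × 100 transition-flip
experiment ~10 s; the reduced ensembles ~2 min each; the default
continuous sweep (18 cells × 3 starts) ~2 min.  The full published-scale
ensemble (1000 × 100) runs in tens of minutes behind `--n-networks 1000`.

## Known limitations

* The packaged rules are a validated reconstruction, not a transcription;
  three published mutant attractors and the exact perturbation
  percentages are not reproduced (see above and the decisions recorded in
  the test expectations).
* Asynchronous and priority-class updating are out of scope.
* The continuous transform keeps the Boolean network's logic; it is not a
  kinetic model, and its time unit is arbitrary (set by γ).
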