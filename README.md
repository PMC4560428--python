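# plantcc

Boolean and continuous dynamics of the *Arabidopsis thaliana* cell-cycle
gene regulatory network.

The plant cell cycle walks through G1 → S → G2 → M under the control of a
small regulatory core: CDK–cyclin complexes (CYCD3;1, CYCB1;1, CYCA2;3
with CDKA;1/CDKB1;1), the RBR–E2F transcriptional axis (RBR, E2Fa, E2Fb,
E2Fc, E2Fe), MYB transcription factors (MYB77, MYB3R1/4), the CDK
inhibitor KRP1 and the ubiquitin-ligase complexes SCF and APC/C.  This
package models that core as a 14-node synchronous Boolean network

    x_i(t+1) = F_i(x_{i1}(t), ..., x_{ik}(t)),      x_i ∈ {0, 1}

whose 2^14 = 16,384 configurations all converge to a single cyclic
attractor of period 11 — the cell cycle as a limit cycle — and provides
the analyses that make that claim testable:

* exhaustive attractor enumeration with exact basin sizes, and
  cell-cycle-phase annotation of the wild-type cycle;
* robustness to systematic truth-table bit flips and to random
  state-transition bit flips, with a three-way outcome classification;
* ensembles of in-degree-matched random networks for a null comparison;
* in-silico mutants (each node clamped to 0 or 1) classified as
  wild-type-like, endocycle-like, or arrest, with the published phenotype
  expectations packaged for comparison;
* a continuous (fuzzy-logic) transform: dx_i/dt = g(ω_i(x); h) − γ_i x_i,
  with limit-cycle detection and h × γ robustness sweeps.

The packaged rules are a reconstruction from the published interaction
tables validated against the published dynamics; see `docs/methods.md`
for exactly what is and is not reproduced.

## Worked example

```python
>>> import numpy as np
>>> from plantcc import load_cc_model, find_attractors, annotate_phases
>>> net = load_cc_model()
>>> atts = find_attractors(net)
>>> len(atts), atts.attractors[0].period, atts.attractors[0].basin_fraction
(1, 11, 1.0)
```

Every one of the 16,384 initial configurations reaches the same period-11
cycle: there is one attractor, its period is 11, and its basin fraction
is 1.0.  The cycle's configurations map onto cell-cycle phases:

```python
>>> for state, phase in annotate_phases(net, atts.attractors[0]):
...     on = [n for i, n in enumerate(net.nodes) if (state >> i) & 1]
...     print(f"{phase:6s} {'+'.join(on)}")
G1     CYCD3;1+KRP1+RBR+E2Fa+E2Fc+MYB3R1/4+APC/C
G1     CYCD3;1+KRP1+RBR+E2Fc+APC/C
G1/S   CYCD3;1+RBR
S      CYCD3;1+E2Fa
S/G2   CYCD3;1+E2Fa+E2Fb+E2Fc+E2Fe
S/G2   CYCD3;1+CDKB1;1+E2Fb+E2Fc+E2Fe+MYB77+SCF
G2     CYCB1;1+CYCA2;3+CDKB1;1+KRP1+E2Fe+MYB77+MYB3R1/4+SCF
G2/M   CYCB1;1+CYCA2;3+CDKB1;1+RBR+E2Fe+MYB3R1/4+SCF
M      CYCB1;1+CYCA2;3+RBR+MYB3R1/4+SCF
M      CYCB1;1+CYCA2;3+RBR+MYB3R1/4+SCF+APC/C
M-exit RBR+MYB3R1/4+APC/C
```

Reading it off: in G1 the CDKA;1–CYCD3;1 complex is held inactive by
KRP1, with RBR present and APC/C still on from mitotic exit; at G1/S
KRP1 is gone and the free complex phosphorylates RBR; S phase activates
E2Fa, then E2Fb and the second E2Fc pulse; MYB77 and MYB3R1/4 drive the
mitotic cyclins while KRP1 reappears in G2; CDKB1;1–CYCA2;3 eliminates
KRP1 at G2/M, CDKA;1–CYCB1;1 triggers mitosis, and returning APC/C
degrades the mitotic cyclins to close the loop.

Mutants are one clamp away:

```python
>>> from plantcc import MutantSpec, apply_mutation
>>> krp1_null = apply_mutation(net, MutantSpec("KRP1", 0))
>>> [(a.period, round(100 * a.basin_fraction, 2))
...  for a in find_attractors(krp1_null)]
[(11, 100.0)]
```

— the KRP1 knockout keeps a normal period-11 cycle with a full basin
(KRP1 loss has no overt cell-cycle phenotype), whereas

```python
>>> apc_on = apply_mutation(net, MutantSpec("APC/C", 1))
>>> [(a.period, round(100 * a.basin_fraction, 2))
...  for a in find_attractors(apc_on)]
[(7, 100.0)]
```

constitutively active APC/C collapses the dynamics onto a period-7
endocycle: Gap and S phases without a mitosis-onset configuration.

The same analyses are available from a shell:

```sh
plantcc attractors --out out/
plantcc robustness functions --exhaustive --out out/
plantcc robustness transitions --trials 100 --replicates 100 --seed 1 --out out/
plantcc ensemble --kind functions --n-networks 100 --seed 1 --reduced --out out/
plantcc mutant --scan --out out/
plantcc continuous --sweep --seed 1 --out out/
plantcc report --artifacts out/ --out figures/
```

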