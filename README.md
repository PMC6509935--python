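# fachkrec

Boolean network analysis of how Fanconi anemia (FA) cells divide despite
unrepaired DNA damage.

Cells hit by a DNA interstrand crosslink (ICL) normally activate the
FA/BRCA repair pathway and the G2 checkpoint, arrest, repair, and then use
the checkpoint-recovery (CHKREC) machinery — WIP1, PLK1, Aurora A, CDC25,
Cyclin B/CDK1 — to dismantle the checkpoint and re-enter the cell cycle.
FA-pathway-deficient cells cannot repair ICLs, yet many of them still
divide: *DNA damage adaptation* (DDA).  This package ships a 25-node
synchronous Boolean network coupling the FA pathway, the G2 checkpoint and
the CHKREC, and the tooling to interrogate it: exhaustive attractor
enumeration with basin sizes, damage-exposure protocols, single/double
in-silico knockout screens, interaction ablation, attractor phenotype
classification, and derivation of the signed regulatory graph from the
logic.

## The model

Each node `x_i ∈ {0,1}` is a protein, complex or lesion; all nodes update
simultaneously:

    x_i(t+1) = f_i(x_1(t), …, x_25(t))

with `f_i` a Boolean function over ¬, ∧, ∨ (e.g. `p21 ← p53`,
`ICL ← ICL ∧ ¬(NUC1 ∨ NUC2)`).  Because the map is deterministic on a
finite space, every trajectory ends in a cycle — an attractor (period 1 = a
fixed point).  Attractors are read as cell fates:

| category  | signature                                                               |
|-----------|-------------------------------------------------------------------------|
| `CCP`     | cell-cycle progression: CDK1-AurA, PLK1, CDC25, CycB-CDK1 always ON, everything else OFF |
| `CCP_DDA` | progression with damage adaptation: CycB-CDK1 active together with a damage node (ICL, DSB, R-DSB) |
| `CCA`     | cell-cycle arrest: CycB-CDK1 never ON, damage and checkpoint nodes (ATM, ATR, p53, p21, WEE1, MYT1) active |
| `OTHER`   | anything else                                                           |

Mutants are clamps (null = node fixed at 0, constitutive = fixed at 1);
persistent damage clamps ICL at 1; a damage pulse sets ICL = 1 at t = 0
only.  Removing an interaction substitutes the regulator by the constant 0
inside the target's rule.

## Worked example

```python
from fachkrec import build_fa_chkrec, enumerate_attractors, knockout, run_protocol, Protocol
from fachkrec.phenotype import classify_all

rs = build_fa_chkrec()

attractors = enumerate_attractors(rs)          # all 2^25 initial states
table = classify_all(attractors)
print(f"{len(attractors)} attractors; phenotype counts: {table.attrs['counts']}")
for att, row in zip(attractors, table.itertuples()):
    print(f"  period {att.period:2d}  basin {att.basin_size:8d}  {row.category}")

[(att, call)] = run_protocol(rs, knockout("FAcore"), Protocol("persistent"))
print("FAcore null mutant under persistent ICL ->", call.category,
      "| CycB-CDK1 active:", att.ever_on("CycB-CDK1"))
```

prints (about 15 s for the exhaustive enumeration):

```
8 attractors; phenotype counts: {'CCP': 1, 'CCP_DDA': 6, 'CCA': 1, 'OTHER': 0}
  period  2  basin     2240  CCA
  period  1  basin 24408843  CCP
  period  5  basin  8147366  CCP_DDA
  period  5  basin    23272  CCP_DDA
  period  1  basin   826552  CCP_DDA
  period  1  basin   132860  CCP_DDA
  period  2  basin     9859  CCP_DDA
  period  1  basin     3440  CCP_DDA
FAcore null mutant under persistent ICL -> CCP_DDA | CycB-CDK1 active: True
```

The wild-type network reaches 8 attractors.  Basin sizes count the initial
states flowing into each attractor and sum to 2^25 = 33,554,432.  The
dominant fixed point is strict cell-cycle progression; the `CCP_DDA`
attractors are reached only from initial states already carrying
self-sustaining damage or an active Cyclin B/CDK1.  The FAcore null mutant
(an FA patient cell) under persistent crosslinks reaches a fixed point in
which Cyclin B/CDK1 is ON next to unrepaired damage — division with damaged
DNA, the model's central prediction.

The same analyses are available from the shell:

```sh
fachkrec attractors --out-dir out/wt
fachkrec simulate --exposure persistent --ko FAcore --out-dir out/facore
fachkrec screen --background-ko FAcore --candidates WIP1,CDK1-AurA,PLK1,CDC25,CycB-CDK1 --out-dir out/fig3a
fachkrec edges --out-dir out/graph
fachkrec export --format sbml --out model.sbml
```

Knocking any CHKREC component out of the FAcore mutant (the `screen` call
above) turns every outcome into `CCA` — checkpoint recovery is what lets FA
cells divide, so its components are candidate therapeutic targets.

## Layout

- `fachkrec.rules` — Boolean expression trees, the two text dialects
  (unicode `∧ ∨ ¬` and BoolNet `& | !`), rule sets, state encoding.
- `fachkrec.model` — the built-in 25-node network, node annotations, the
  configurable inferred-interaction list.
- `fachkrec.dynamics` — synchronous stepping, trajectories, exhaustive
  attractor enumeration (bit-parallel bulk engine + naive oracle engine).
- `fachkrec.perturb` — knockouts, clamps, edge removal, damage protocols,
  double-mutant screens.
- `fachkrec.phenotype` — attractor phenotype classification.
- `fachkrec.interactions` — witness-based signed regulatory graph and edge
  statistics.
- `fachkrec.export` / `fachkrec.random_nets` / `fachkrec.cli` — BoolNet and
  SBML-qual export, reproducible random networks, command line.

See `docs/methods.md` for the modelling decisions and their rationale.
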