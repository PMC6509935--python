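# Methods

## Model

The package's core is a 25-node synchronous Boolean network coupling three
processes around a DNA interstrand crosslink (ICL): the FA/BRCA repair
pathway (FAcore, FANCD2I, NUC1, HRR, plus the alternative RNF4/PLK1 →
NUC2 unhooking route and the DSB machinery PARP-1, KU-53BP1, NHEJ,
gH2AX), the G2 checkpoint (ATM, ATR, p53, p21, WEE1, MYT1, PP2A-B55), and
checkpoint recovery (WIP1, CDK1-AurA, PLK1, CDC25, CycB-CDK1).  States are
complete 0/1 assignments; the update is synchronous and deterministic, so
the dynamics is a functional graph over 2^25 states whose cycles are the
attractors.  No asynchronous or probabilistic semantics are provided: the
modelled predictions are all statements about the synchronous map, and
mixing update schemes would change attractor structure silently.

Update rules are stored fully parenthesized.  Two rules are typographically
ambiguous when line-wrapped, and carry an explicit canonical grouping
derived from standard precedence (¬ > ∧ > ∨):

* `CDK1-AurA ← CycB-CDK1 ∨ CDC25 ∨ (¬(p21 ∧ PP2A-B55) ∧ ¬(WEE1 ∨ MYT1 ∨ ATM ∨ ATR))`
* `CycB-CDK1 ← CycB-CDK1 ∨ ((CDC25 ∧ PLK1 ∧ CDK1-AurA) ∧ ¬p21)`

FANCD2I's self-negation (`FAcore ∧ (ATM ∨ ATR) ∧ ¬FANCD2I`) forces an
active FANCD2I to oscillate.  It is kept as published: fidelity to the
source logic was preferred over biological plausibility, and the package's
behavioural checks (below) pass with it in place.

Node names: canonical names keep hyphens (`CycB-CDK1`, `KU-53BP1`,
`PARP-1`, `R-DSB`, `PP2A-B55`, `CDK1-AurA`); a bidirectional map to
identifier-safe forms (`CycB_CDK1`, `KU_53BP1`, `PARP1`, `RDSB`,
`PP2A_B55`, `CDK1_AurA`) is part of the public contract and is used by the
BoolNet and SBML-qual exports.  The one-off spelling `Plk1` inside the
CycB-CDK1 rule is normalized to `PLK1`.

## Dynamics engines

Exhaustive enumeration uses a bit-parallel bulk engine: the update map is
evaluated over the whole (clamp-reduced) state space as vectorized numpy
bit operations in 2^20-state chunks, producing a uint32 successor array.
Cycle states are found by pointer doubling (composing the successor map
with itself m times reaches `succ^(2^m)`, which lands every state on its
terminal cycle); cycles are then grouped by walking the successor map, and
basin sizes are a single `bincount` over the landing states.  Cost is
O(n·2^n) bit-ops plus m gathers of 2^m elements; the full 25-node run takes
on the order of ten seconds and ~400 MB.  Above 2^25 free states the engine
refuses rather than silently subsampling.

A deliberately simple per-state engine (follow each trajectory with
memoization) serves as the independent oracle; the test suite checks
bulk ≡ naive on random networks (n ≤ 10 exhaustively, including clamped and
pulse-restricted initial spaces) and that basins always partition the
initial space.

Attractor identity is the canonical rotation of the cycle (smallest
integer-encoded state first).  Clamps override rules at every step;
initial states conflicting with a clamp are projected onto it, so "all
initial states" under a clamp means all assignments of the free nodes —
basin sizes partition that reduced space.

## Protocols and perturbations

* Null / constitutive mutants: clamp to 0 / 1.  Gain-of-function of a
  damage node and persistent exposure are the same clamp and are not given
  two names.
* Pulse exposure: damage nodes set to 1 at t = 0 only; persistent exposure:
  damage nodes clamped at 1.
* Initial condition: the canonical start is the all-OFF state plus the
  pulsed/clamped nodes — a quiescent cell at damage onset, giving the
  single trajectory the published time-course panels show.  An ensemble
  mode over all initial assignments is available (`initial="all"`); it is
  not the default because self-sustaining nodes (notably CycB-CDK1, whose
  rule contains itself disjunctively) make ensemble summaries dominated by
  initial conditions rather than by the protocol under study.
* Interaction removal substitutes the source by constant 0 in the target's
  rule, then constant-folds.  Removals are grouped per target so deleting
  several regulators of one conjunction does not spuriously report a
  later edge as absent.

## Phenotype classification

The decision rule is ordered: strict CCP (division nodes always ON, all
else always OFF) before CCP_DDA (CycB-CDK1 active ∧ a damage node active)
before CCA (CycB-CDK1 never active ∧ damage active ∧ an arrest node
active), else OTHER.  Ordering matters because strict CCP also satisfies
the CCP_DDA CycB condition; testing it first resolves the overlap.
"Active" in a cycle means ON in at least one cycle state — arrest
attractors show recurrent, not constant, checkpoint activation.  The
damage set is {ICL, DSB, R-DSB} throughout; the arrest set is the
checkpoint nodes minus PP2A-B55 (a checkpoint-supporting phosphatase, not
an arrest effector); the division set is the CHKREC nodes minus WIP1 (a
phosphatase, not a mitosis driver).

## Signed interaction graph

Edges are semantic, not syntactic: `u → v` exists only with a witness
context (an assignment of v's other regulators in which flipping u changes
v's update value), positive/negative/dual by the direction(s) of change.
Inert literals are excluded from the edge list and reported separately.
Witness search enumerates all 2^(k−1) contexts per regulator and refuses
rules with more than 16 regulators.  On the built-in model this yields 121
edges (67 positive, 53 negative, 1 dual — ATR on PLK1, which both
activates the replication-stress route and is blocked by the
checkpoint-silencing route).  Published prose states two mutually
inconsistent count pairs for this graph; the package reports its derived,
witness-verified counts as the reproducible figure and pins no check to
either printed pair.  Dual edges are counted once in the total and shown in
their own column rather than split.

## The inferred-interaction list

Fifteen interactions in the network are model inferences with no direct
experimental report.  Twelve are named unambiguously in the model's
narrative (RNF4 → NUC2, PLK1 → NUC2; PLK1 ⊣ HRR, CycB-CDK1 ⊣ HRR, PLK1 ⊣
NHEJ, CycB-CDK1 ⊣ NHEJ; PLK1 ⊣ ATM, KU-53BP1 ⊣ ATM, PLK1 ⊣ ATR, KU-53BP1 ⊣
ATR; CycB-CDK1 ⊣ MYT1, CycB-CDK1 ⊣ WEE1).  The remaining three are not
named in prose and must be reconstructed.  This package ships
RNF4 ⊣ FAcore, PLK1 ⊣ FAcore and FAcore ⊣ FAcore (the displacement of the
FA core complex by the RNF4/PLK1 fork-takeover module, and the FA-core
self-limitation that makes the takeover stick), flagged
`confidence="figure"`, for two reasons: they belong to the same
hypothesized fork-collapse process as the two NUC2 activations, and they
are the unique tested completion under which ablating the full set
reproduces the published ablation outcome — with all fifteen edges
removed, every one of the 2^25 initial states reaches the strict CCP fixed
point (single attractor, basin 2^25).  Alternative completions that were
tested and rejected (each by exhaustive 2^25 enumeration): the NUC2/RNF4
silencing edges (R-DSB ⊣ NUC2, NUC1 ⊣ NUC2, FAcore ⊣ RNF4), the
replication-stress activation of PLK1 (ICL/ATR/¬FAcore → PLK1), and
self-loop-only variants; each leaves 0.3–0.5 % of the state space in
residual arrest or adaptation attractors sustained by an FAcore/ATR
antiphase oscillation.  The list is configuration
(`novel_interactions()`), not hard-coded truth, and the ablation
experiment accepts any edge set.

## Random networks

`generate_random_network(RandomNetworkSpec(n, k, seed))` draws k distinct
regulators per node and a uniform random truth table, rendered as DNF.
These are test fixtures for engine-vs-oracle and round-trip properties,
generated at test time from fixed seeds; they emulate nothing biological.
Consequently the engine equivalence they establish is a statement about
the simulator, not about the FA model's biology — the biological checks
are the wild-type and mutant behaviours above.

## Problem sizes and numerical choices

The test suite runs two exhaustive 2^25 enumerations (wild type and the
15-edge ablation) plus property tests on random networks up to n = 10
exhaustive; the whole suite completes in well under a minute on one core
after the two big runs (~15 s each).  Everything is integer/bit-exact —
there are no tolerances, no floating-point comparisons, no iterative
solvers.  The only randomness anywhere is the seeded random-network
generator and hypothesis's derandomized search; identical inputs give
byte-identical outputs, and the CLI embeds the model content hash,
perturbation label and library version in every report.

## Known limitations

* Synchronous updating only; attractors of asynchronous schemes may differ.
* The phenotype signature sets are the built-in model's; other models must
  supply their own `Signature` (the classifier takes the last division
  node as the commitment marker when `CycB-CDK1` is absent).
* The inferred-interaction list is a reconstruction (above); edge-ablation
  results depend on it and are flagged as such.
* Downstream fates (senescence vs. apoptosis after arrest) are biological
  interpretation outside the model's state space.
* SBML-qual export is a minimal writer (level 3 version 1, max level 1,
  one function term per transition); it does not import SBML.
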