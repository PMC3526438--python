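# Methods

## Data model

All trees are rooted, binary, uniquely leaf-labeled.  A gene tree
carries a total map `s(·)` from gene labels to species labels, read
from a two-column TSV or from the leaf-name convention (species = token
after the last underscore).  Polytomies are rejected rather than
resolved: every definition used here assumes binary phylogenies.
Branch lengths are parsed and discarded; all methods are topology-only.
Children keep their input order and every algorithm is tested to be
invariant to it.

A **history** is an event tree over a species tree *S*.  Each node has
a kind and a location (a node of *S*):

* speciation at *v*: children located at *v*'s two species children;
* duplication at *v*: both children located at *v* (duplications "on an
  edge" are located at the edge's lower endpoint; duplications at a
  species leaf model recent within-genome copies);
* gene leaf: at a species leaf;
* loss leaf: at any species node.  A loss at an internal node records
  the loss of a whole lineage copy before any further speciation and
  counts as **one** event — this convention is what makes the loss cost
  of a reconciliation equal the number of inserted loss leaves.

Duplication nodes may carry a retainer/mutant mark (which child
preserved the parental function).  Operations that need marks —
isorthogroups, surviving speciations, IRH validation — refuse unmarked
histories instead of guessing; a bare reconciliation is deliberately
unmarked because the LCA mapping carries no functional information.

Histories serialize to annotated Newick with per-node comments
`[&kind=...,loc=...,retainer=...]`; internal locations are written as
the `+`-joined species clade.  Round-tripping is exact and tested.

## Reconciliation

The LCA mapping is computed bottom-up with pairwise LCA by depth
walking (linear in practice on the trees this package targets; the
asymptotics of the LCA primitive are not the contract).  A node is a
duplication iff a child maps to the same species node.  The
reconciliation history is built by a recursive embedding that inserts a
speciation-with-loss-sibling at every species edge a lineage skips.
Losses are counted twice, independently: by the per-edge rule
(`dist − 1` below a speciation, `dist` below a duplication) and by
counting inserted loss leaves; the suite asserts the two agree on all
fixtures and simulations.

## The speciation forest and MIRH

A **speciation subtree** of *G* is a subtree whose internal nodes are
all labeled speciations.  The forest *F* of *maximal* speciation
subtrees is computed in three linear passes: label by the LCA mapping;
mark ancestors of duplications in postorder; collect unmarked
non-duplication nodes whose parent is a duplication or an ancestor of
one.  Leaves are trivial speciation subtrees; a duplication-free gene
tree yields *F* = {*G*}.

Joining *n* isorthogroups into one history requires exactly *n* − 1
duplications, and the coarsest admissible partition is *F*, so the
minimum duplication cost of an IRH is |*F*| − 1.  A brute-force oracle
(exhaustive enumeration of isorthology-respecting partitions, default
bound 10 leaves) cross-checks this on random instances in the suite.

**Construction.**  Each block is embedded at its anchor (the species
LCA of its species set), which forces exactly the losses of the species
tree restricted to the block's span.  The seed block is the one with
the shallowest anchor (ties: smallest leaf label); each remaining
block, in increasing anchor depth, attaches by one duplication onto an
existing lineage at the deepest already-realized point above its
anchor, chaining down with speciation/loss pairs only when the history
does not yet reach the anchor (and lifting the root with a stem
duplication when a block lies outside everything built so far).  The
host lineage is the retainer, the new block the mutant, so the built
history's isorthogroups are exactly the chosen blocks, and it validates
as an IRH by construction.

**Cost modes.**  `cost="duplication"` uses *F* and is provably optimal
for the duplication cost.  `cost="mutation"` also optimizes the
partition: keeping a block coarse saves duplications but pays one loss
for every species branch its over-wide copy spans without retaining a
gene.  A linear DP over *G* (keep a clean subtree whole, or cut at its
root) minimizes `(#blocks − 1) + Σ within-block losses`; since the DP
estimate ignores the (usually zero) cost of connecting block anchors,
the builder constructs both the DP partition and the coarse partition
and returns the history that is actually cheaper.  This is a search
over a structured family of candidate histories, not a proof of
mutation-optimality; the duplication-optimal partition provably does
not minimize the mutation cost in general — the interleukin-1 fixture
is the canonical case (8 vs 7).

**TRH validation** compares rooted triplet topologies (which pair forms
the cherry) between *G* and the loss-pruned history for every triplet
drawn from three distinct isorthogroups, after requiring the IRH
property.  Instances with fewer than three groups satisfy the triplet
clause vacuously — the definition quantifies over triplets from three
different groups, so two-group instances impose no constraint.  The
check is exhaustive and therefore cubic-ish; it is meant for the small
candidate histories users actually validate.

## Simulator

`simulate_history` starts one gene at the species root and walks the
tree edge by edge (stem included): each lineage entering an edge draws
`Poisson(dup_rate)` sequential duplications (each with a uniformly
chosen retainer), and every resulting copy is independently lost with
`loss_prob` at the edge's end; surviving copies speciate at species
nodes.  Defaults `dup_rate=0.3`, `loss_prob=0.2` keep simulated
families in the few-copies range typical of curated gene families while
exercising duplications and losses on most replicates.  With
`require_full_coverage` (default) runs are resampled until every
species retains a gene, mirroring the usual at-least-one-gene-per-
species assumption; a family that goes fully extinct is always
resampled.  All randomness flows from one integer seed, and identical
configs reproduce byte-identical serializations.

A per-edge Poisson model was chosen over a continuous-time birth–death
process deliberately: it realizes every event configuration the theory
quantifies over with trivially reproducible replication.  What it does
*not* emulate: sequence evolution (gene trees are derived, not
inferred), within-edge timing, population-level fixation dynamics, and
duplication modes that break the single-retainer hypothesis
(bifunctionalization, subfunctionalization).  Passing property tests
therefore demonstrate the combinatorial claims about histories, not
robustness to phylogenetic reconstruction error.

`derive_isolocalization_gene_tree` builds the gene tree sequence
clustering would produce if within-group divergence were negligible
next to between-group divergence (an infinite rate-ratio abstraction):
each isorthogroup's internal topology is the species tree restricted to
its species, and each mutant-born group attaches as an outgroup
directly above the smallest clade containing its parent group,
processing duplications oldest-first (age = depth of the duplication in
the event tree, ties by smallest mutant-side gene label) so that older
offshoots sit more basally.  The between-group nesting is a recorded
convention, not a claim: under the abstraction the data carry no signal
above the groups, and any nesting that keeps each group a clean clade
realizes the isolocalization property, which is asserted for every
replicate.

## The bundled interleukin-1 fixture

The gene and species trees are transcribed from the classic textbook
analysis of the mammalian interleukin-1 family.  The species tree uses
the rodents-basal arrangement common in the 1990s literature,
`((Mouse,Rat),(Rabbit,(Human,(Pig,(Sheep,Bovine)))))`; the gene tree
places the class-4 (sheep/bovine) clade sister to the slow-evolving
class-1 group and classes 2 and 3 together.  This transcription was
selected by exhaustively searching candidate species-tree and gene-tree
arrangements for the one reproducing *all* published event counts
simultaneously: three root duplications with 10 losses on the
contracted tree, four losses for the class-3/4 paralogy under
reconciliation, mutation 14 on the full tree, mutation 10 for the
triplet-respecting history, mutation 7 for the MIRH with six
isorthogroups (H2 and H3 split off).  Under this transcription each of
those numbers is forced, and the suite pins them.

Two subtleties are inherent to the example rather than to the
transcription.  First, the six-group, cost-7 analysis is the
*mutation*-cost MIRH: the maximal forest itself keeps the clean
{M2,Rt2,H2} and (contracted) {M3,H3} subtrees whole — which is exactly
what makes the four-group triplet-respecting history admissible as an
IRH.  Second, the drawn TRH is strictly valid only after contracting
the recent human duplication (H3p/H3pp → H3): on the full tree its
{M3,H3p} group is not a subtree of *G*.  Both behaviors are asserted in
the tests as features of the example, and the bundled TRH ships in
both full (for costing, mutation 10) and contracted (for validation)
forms.

## Numerical and degenerate-input choices

* Ties everywhere break on lexicographically smallest leaf label, so
  outputs are deterministic and child-order invariant.
* `(a);`-style Newick input collapses the unary root wrapper; unary
  internal nodes are otherwise rejected as non-binary.
* Species coverage ("every species has a gene") is available as a
  check and enforced by the simulator's coverage flag, but is not a
  precondition of the algorithms — reconciliation and the forest are
  well defined without it.
* `brute_force_mirh` refuses instances above its leaf bound rather
  than silently running exponentially.
* Contracting a tree whose leaves are all one species yields a single
  leaf; contraction is idempotent and logs every merge.

## Limitations

* No horizontal transfer, no probabilistic reconciliation, no
  finite rate-ratio model (the infinite-ratio abstraction is a stated
  hypothesis, not an inference).
* `build_mirh(cost="mutation")` is optimal within its candidate family
  but carries no global optimality proof; no mutation-cost-optimal TRH
  solver is provided — TRHs are validated and costed, and small
  instances can be explored with the brute-force oracle.
* The efficient-vs-oracle cross-checks run on small random instances;
  the linear-time claims are about algorithm structure, and the package
  targets trees of at most a few hundred leaves.
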