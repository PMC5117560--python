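# Methods

## Problem and model

A metabolic network with `m` metabolites and `n` reactions is described by
its total stoichiometric matrix `S = [N, B]`, where the `m x u` block `N`
holds the internal (mass- and charge-balanced) reactions and `B` the
exchange reactions that open the system.  Every quantity conserved by all
internal reactions is a vector `l` in the left null space of `N`
(`N' l = 0`); the biochemically meaningful subset are the *moiety
vectors*: nonnegative integer vectors whose `i`-th entry counts the
instances of a specific conserved group of atoms (a *moiety*) in
metabolite `i`.  Stoichiometry alone cannot distinguish moiety vectors
from other nonnegative integer conservation vectors; atom mappings can.

Given one atom mapping (a substrate-atom to product-atom bijection, per
element) for each internal reaction, the package builds the **atom
transition network** (ATN): a directed multigraph with one node per
metabolite atom and one edge per atom transition, with incidence matrix
`A` in `{-1, 0, 1}^(p x q)`.  The pipeline is then:

1. **Connected components** of the simple undirected graph underlying the
   ATN (edge directions ignored).  Each component `h` carries a mapping
   matrix `M(h)` from its atoms to metabolites and the atom conservation
   vector `a_h = M(h) 1` counting its atoms per metabolite.
2. **Isomorphism classes.**  Two components are isomorphic iff they have
   equal `a_h`.  Component nodes are labelled by metabolite and edges by
   reaction, and chemistry preserves all remaining structure along with
   those labels, so the count criterion is decisive on real data; a
   strict audit (per-reaction transition-pair multisets) runs by default
   and logs a warning if a hand-made pathological input violates it.
3. **Moiety graphs and the moiety matrix.**  Each class merges into a
   moiety graph whose nodes are moiety *instances*, each annotated with
   its constituent atoms (one per member component).  The class vector
   becomes a column of the moiety matrix `L`, with `N' L = 0` exactly.
4. **Classification.**  A moiety is *internal* if conserved in the open
   network (`S' l = 0`); metabolites supporting an internal moiety are
   secondary; moieties confined to primary metabolites are *transitive*
   and those spanning both are *integrative*.
5. **Decomposition.**  A composite vector `l` splits as `l = x + y` via
   the integer program `min 1'x` subject to `N'x = 0`, `0 <= x <= l`
   componentwise (integrality implied), and `1 <= 1'x <= 1'l - 1`;
   infeasibility certifies nondecomposability.  Iterating over all
   columns until every survivor is infeasible yields the fully decomposed
   matrix `D`.  The same routine factorises an elemental matrix or an
   electron vector (`e_i` = total electrons = sum of atomic numbers minus
   charge).

## Numerical choices

* **Exact arithmetic for rank and null-space decisions.**  Conservation
  vectors are integer objects; ranks are computed by exact rational
  elimination (sympy) and all conservation checks use integer matrix
  products.  Floating point appears only as a cross-check in tests.
* **MILP backend.**  `scipy.optimize.milp` (HiGHS) solves each split; the
  solution is rounded and re-verified exactly, and HiGHS' "infeasible"
  status is distinguished from other failure modes.  Because `min 1'x`
  does not pin `x` down, the split is canonicalised to the
  lexicographically smallest optimal `x` in metabolite order by
  sequential bound fixing (one extra solve per coordinate).  All
  reference comparisons are set-based regardless, since alternate optima
  are mathematically equivalent (for the DAS elemental matrix the oxygen
  column may legitimately return `l9 = l6 + 2(l2 - l1)` in place of
  `l6`).
* **Brute-force oracle.**  Nondecomposability is independently certified
  by exhaustive enumeration of `0 <= x <= l` (unit splits suffice: any
  decomposition with positive integer weights yields one).  The default
  cap of 64 on `1'l` bounds the search box; tests use sums <= 20.
* **Degenerate inputs.**  The zero vector is nondecomposable by
  convention (the strict sum window is empty).  Self-transitions are kept
  in the transition list but contribute a zero incidence column and never
  form simple-graph edges.  Massless placeholder metabolites (empty
  formulas) are excluded from ATNs and flagged in balance reports.
* **Determinism.**  Node order: metabolites in network order, elements in
  the fixed order C, H, O, N then alphabetical, atom index ascending.
  Transition order: reaction order, then mapping-table order.  Component
  order: by smallest node position.  Class order: descending atoms per
  instance, then lexicographic `a_h`.  Moieties are named `M01, M02, ...`
  in class order.  Outputs are byte-identical across reruns.

## Design choices that were genuinely open

* **Column convention.**  Internal reactions are moved ahead of exchange
  reactions on load, with the permutation recorded, so `[N, B]` indexing
  is uniform without mutating user input.  Internal coefficients must be
  integers (mappings act on whole molecules); fractional coefficients are
  accepted in `B` only.
* **Shared nodes for repeated metabolites.**  When a coefficient exceeds
  one, the mapping enumerates instance copies, but all copies attach to
  the same atom nodes: the ATN has one row per atom of the network, and
  atom conservation vectors count atoms per metabolite once.
* **Merging by representative.**  The merged incidence matrix is the
  class representative's matrix taken after verifying equality, rather
  than an average that would create fractional intermediates.
* **Graph-vs-hypergraph test** for moiety subnetworks
  (`S(k) = diag(l_k) S`) uses the pruned nonzero internal columns and
  ignores magnitudes: a column with exactly one negative and one positive
  entry is a graph edge whatever its coefficients.
* **Isotopomer counts** use Python's arbitrary-precision integers;
  genome-scale atom isotopomer counts overflow 64-bit floats.
* **RXN parsing** is strict by default (an unmapped atom in an internal
  reaction breaks the bijection the ATN needs); a permissive mode
  downgrades unmapped atoms to warnings for diagnostics.  Hydrogens must
  be explicit; none are inferred.

## Packaged data and the synthetic generator

The dopamine synthesis network (DAS: phenylalanine hydroxylase, tyrosine
hydroxylase, DOPA decarboxylase, and a composite pterin-regeneration /
formate-oxidation step, plus seven exchanges) ships with full
explicit-hydrogen atom mappings.  The oxygen of O2 entering water versus
the new hydroxyl group is symmetric, giving four mapping variants
(a/b/d/e); variants d and e send different O2 atoms to water in the two
hydroxylase reactions, which fuses the two single-oxygen moieties into
one composite moiety — the canonical test case for MILP decomposition.
The hydrogen-routing conventions in the hydroxylase and regeneration
steps (which pterin hydrogens leave to water; where the proton ends up)
are fixture conventions fixed by element/charge balance, not biochemical
claims; the aggregates they imply (170 atoms, 176 transitions, 57
components, the 7-column moiety matrix, isotopomer counts 2,820 / 22 /
11) are asserted by the tests.  A single-reaction DOPA decarboxylase
fixture covers the smallest nontrivial case.

`planted_moiety_generator(seed, n_moieties, size_range, n_metabolites,
n_reactions)` creates random networks with known ground truth.  Moiety
instances are indivisible "balls" with sampled element compositions
(`size_range` bounds atoms per moiety); metabolites are "bags"; each
internal reaction consumes one or two existing bags and repartitions
their balls into one or two new bags, and final bags receive exchange
sinks.  Formulas, stoichiometry, the atom-level mapping table and the
true moiety matrix all derive from one construction, so elemental
balance, mapping bijections and conservation hold by design.  Ground
truth columns whose metabolite support coincides are merged (atoms
following identical paths are by definition one moiety).  The generator
emulates connectivity and conservation structure, not chemistry: it does
not produce realistic formulas, reversible directions, coefficients
beyond +/-1, or mapping ambiguity, so recovery tests demonstrate
correctness of the pipeline mechanics rather than robustness to
noisy predicted mappings.

## Problem sizes and limitations

All packaged analyses are small (11 metabolites, 170 atoms; synthetic
networks of ~10 metabolites over 50 seeds), chosen so the whole suite
runs in seconds.  The pipeline is polynomial in the ATN size (components
are linear-time; isomorphism grouping is quadratic in the component count
at worst), but the decomposition MILP and the enumeration oracle are
exponential in the worst case and are intended for vectors with modest
entry sums.  Isomorphism by atom-count equality is justified for
chemically generated ATNs; adversarial hand-made inputs can violate it,
which is why the structural audit exists.  Electron conservation is
handled only via decomposition of the electron vector; no electron
mappings are modelled.  SBML input, mapping *prediction*, and
extreme-ray enumeration are out of scope.
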