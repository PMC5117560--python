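# conserved-moieties

Identification of conserved moieties in metabolic networks by graph
analysis of atom transition networks.

A conserved moiety is a group of atoms that stays intact through every
internal reaction of a metabolic network — think of the AMP core shared
by ATP/ADP/AMP, or the NAD scaffold of NAD/NADH.  Each moiety defines a
metabolite pool of constant total concentration, and its conservation
relation is a nonnegative integer vector `l` in the left null space of
the internal stoichiometric matrix `N` (`N' l = 0`), with `l_i` counting
the moiety's instances in metabolite `i`.  Computing such vectors from
stoichiometry alone is NP-hard and does not reveal *which* atoms form
the moiety.  Given per-reaction atom mappings, however, the problem
becomes polynomial-time graph analysis: atoms in the same moiety follow
identical paths, so moieties are exactly the isomorphism classes of
connected components of the **atom transition network** — the directed
multigraph whose nodes are individual metabolite atoms and whose edges
are substrate-to-product atom transitions.

The package is aimed at metabolic modellers who need conservation
relations for dynamic models, constant-pool analysis, network
decomposition, or moiety-resolution isotope labelling models.  It
provides:

- a network data model with exact rational rank/null-space operations,
  elemental matrices, electron vectors and balance checking
  (`network_core`);
- atom-mapping I/O: MDL RXN/MOL V2000 with atom-atom mapping numbers and
  a native TSV transition table (`atom_mapping_io`);
- atom transition network assembly with deterministic ordering
  (`atn_builder`);
- the identification pipeline: components, isomorphism classes, moiety
  graphs, moiety matrix, classification, compositions
  (`moiety_identification`);
- MILP decomposition of composite conservation vectors, elemental
  matrices and electron vectors, with an independent brute-force
  nondecomposability oracle (`moiety_decomposition`);
- moiety subnetworks and atom- vs moiety-resolution isotopomer counts
  (`applications`);
- packaged fixtures (dopamine synthesis network, DOPA decarboxylase) and
  a seeded random generator with planted ground-truth moieties
  (`fixtures`);
- a `moieties` command-line tool (`cli`).

## Worked example

The packaged dopamine synthesis network (DAS) has 11 metabolites, four
internal reactions and seven exchanges:

```python
from conserved_moieties import (
    das_fixture, build_atn, identify_moieties, split_matrices,
    left_nullspace_dim, moiety_isotopomer_count, atom_isotopomer_count,
)

fx = das_fixture("a")                      # network + atom mappings
N, B = split_matrices(fx.network)
print(left_nullspace_dim(N))               # 7 conservation relations

atn = build_atn(fx.network, fx.mappings)
print(atn.p, atn.q)                        # 170 atoms, 176 transitions

graphs, L = identify_moieties(atn)
for g, cls in zip(graphs, L.classes):
    print(g.name, g.composition_string(), cls)
print(atom_isotopomer_count(fx.network, "C"),
      moiety_isotopomer_count(L, "C"))
```

Output:

```
7
170 176
M01 C9H13N5O3 internal
M02 C8H11N transitive
M03 CO2 transitive
M04 O transitive
M05 H integrative
M06 H integrative
M07 O transitive
2820 22
```

The 170 atoms fall into 57 connected components that merge into seven
moieties: the biopterin core (internal — BH4 + BH2 form a constant
pool), the dopamine precursor skeleton, the decarboxylated CO2 unit, two
single-oxygen moieties and two single-hydrogen moieties.  `L.L` is the
11 x 7 moiety matrix with `N' L = 0`; its columns span the full
seven-dimensional left null space.  At carbon-tracer resolution the
2,820 atom isotopomers collapse to 22 moiety isotopomers.

Mapping variants `"d"`/`"e"` (the symmetric O2 atoms routed differently
in the two hydroxylase reactions) produce only six moieties, one of them
composite; `decompose_vector(N, l)` splits it back into the two
single-oxygen moieties by iterative integer programming.

The same pipeline is available from the shell:

```sh
moieties fixtures --name das --out-dir das/
moieties identify --network das/network.json --mappings das/mappings.tsv --out-dir out/
moieties isotopomers --network das/network.json --mappings das/mappings.tsv --element C
```

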