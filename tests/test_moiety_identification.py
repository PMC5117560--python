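import logging

import numpy as np
import pytest

from conserved_moieties import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    atom_conservation_vector,
    build_atn,
    classify_moieties,
    connected_components,
    elemental_matrix,
    group_isomorphic,
    identify_moieties,
    merge_to_moiety_graph,
    moiety_composition,
    parse_mapping_table,
    split_matrices,
    verify_isomorphism_strict,
)
from conserved_moieties.atom_mapping_io import AtomMappingSet, MappedAtom, ReactionAtomMap

from conftest import column_set


class TestComponents:
    def test_das_carbon_component_count(self, das):
        atn = build_atn(das.network, das.mappings, "C")
        assert len(connected_components(atn)) == 18

    def test_das_full_component_count(self, das_atn):
        assert len(connected_components(das_atn)) == 57

    def test_edgeless_atn_gives_singletons(self):
        net = MetabolicNetwork(
            [Metabolite("A", formula={"C": 3}, charge=0)],
            [Reaction("E1", "exchange", {"A": 1})],
        )
        comps = connected_components(build_atn(net, AtomMappingSet()))
        assert len(comps) == 3
        assert all(c.x == 1 and c.y == 0 for c in comps)
        for c in comps:
            assert atom_conservation_vector(c).tolist() == [1]

    def test_components_partition_nodes(self, das_atn):
        comps = connected_components(das_atn)
        rows = sorted(r for c in comps for r in (n.row for n in c.nodes))
        assert rows == list(range(das_atn.p))

    def test_component_matrices_consistent(self, das_atn):
        net = das_atn.network
        for c in connected_components(das_atn):
            assert c.M.shape == (net.m, c.x)
            assert np.all(np.asarray(c.M.sum(axis=0)).ravel() == 1)
            a = atom_conservation_vector(c)
            assert a.sum() == c.x
            # incidence columns have one -1 and one +1
            C = c.C.toarray()
            if c.y:
                assert np.all(np.abs(C).sum(axis=0) == 2)

    def test_chain_component_vector(self, das_atn):
        comps = connected_components(das_atn)
        phe_c1 = das_atn.node_row("Phe", "C", 1)
        comp = next(c for c in comps if any(n.row == phe_c1 for n in c.nodes))
        mets = {n.metabolite_id for n in comp.nodes}
        assert mets == {"Phe", "Tyr", "L-DOPA", "DA"}
        a = atom_conservation_vector(comp)
        idx = {m.id: i for i, m in enumerate(das_atn.network.metabolites)}
        assert all(a[idx[m]] == 1 for m in mets)
        assert a.sum() == 4

    def test_single_oxygen_component_has_two_dopa_atoms(self, das_atn, das):
        # O2:O2 travels to Tyr, then both L-DOPA hydroxyl oxygens, then DA
        comps = connected_components(das_atn)
        o2_row = das_atn.node_row("O2", "O", 2)
        comp = next(c for c in comps if any(n.row == o2_row for n in c.nodes))
        assert atom_conservation_vector(comp).tolist() == das.expected["l6"]


class TestIsomorphismGrouping:
    def test_carbon_classes(self, das):
        atn = build_atn(das.network, das.mappings, "C")
        classes = group_isomorphic(connected_components(atn))
        assert sorted(len(k) for k in classes) == [1, 8, 9]

    def test_full_network_classes(self, das_atn):
        classes = group_isomorphic(connected_components(das_atn))
        assert len(classes) == 7
        assert sorted(len(k) for k in classes) == [1, 1, 1, 1, 3, 20, 30]

    def test_single_component_single_class(self):
        net = MetabolicNetwork(
            [Metabolite("A", formula={"C": 1}, charge=0)],
            [Reaction("E1", "exchange", {"A": 1})],
        )
        comps = connected_components(build_atn(net, AtomMappingSet()))
        assert len(group_isomorphic(comps)) == 1

    def test_strict_verification_within_class(self, das):
        atn = build_atn(das.network, das.mappings, "C")
        classes = group_isomorphic(connected_components(atn))
        eight = next(k for k in classes if len(k) == 8)
        assert verify_isomorphism_strict(eight[0], eight[1])
        assert verify_isomorphism_strict(eight[0], eight[0])

    def test_strict_audit_warns_on_constructed_mismatch(self, caplog):
        """Components with equal a_h but different reaction edge multisets
        are reported, and merging still proceeds with a warning."""
        from conserved_moieties.moiety_identification import Component
        from scipy import sparse

        def fake_component(cid, reaction):
            # minimal hand-built component: 2 nodes, 1 transition
            from conserved_moieties.atn_builder import AtomNode, AtomTransition

            n1 = AtomNode("A", "C", 1, 0)
            n2 = AtomNode("B", "C", 1, 1)
            t = AtomTransition(reaction, n1, n2, 0)
            C = sparse.csc_matrix(np.array([[-1], [1]], dtype=np.int8))
            M = sparse.csc_matrix(np.eye(2, dtype=np.int8))
            return Component(cid, [n1, n2], [t], C, M, np.array([1, 1]))

        c1 = fake_component(0, "R1")
        c2 = fake_component(1, "R2")
        assert not verify_isomorphism_strict(c1, c2)
        with caplog.at_level(logging.WARNING):
            merge_to_moiety_graph([c1, c2], 0)
        assert "different transition structure" in caplog.text
        with pytest.raises(ValueError):
            merge_to_moiety_graph([c1, c2], 0, strict=True)


class TestMoietyGraphs:
    def test_dopamine_chain_moiety_graph(self, das_moieties):
        graphs, _ = das_moieties
        lam1 = next(g for g in graphs if g.composition == {"C": 8, "H": 11, "N": 1})
        assert lam1.node_metabolites == ["Phe", "Tyr", "L-DOPA", "DA"]
        assert lam1.G.shape == (4, 3)
        assert len(lam1.member_ids) == 20
        assert all(len(atoms) == 20 for atoms in lam1.instance_atoms)

    def test_biopterin_moiety_graph(self, das_moieties):
        graphs, _ = das_moieties
        lam3 = next(g for g in graphs if g.composition == {"C": 9, "H": 13, "N": 5, "O": 3})
        assert sorted(set(lam3.node_metabolites)) == ["BH2", "BH4"]
        assert lam3.G.shape == (2, 3)
        assert sorted(lam3.edge_reactions) == ["R1", "R2", "R4"]
        assert lam3.composition_string() == "C9H13N5O3"

    def test_singleton_class_graph_is_component(self, das_atn):
        comps = connected_components(das_atn)
        classes = group_isomorphic(comps)
        singleton = next(k for k in classes if len(k) == 1)
        g = merge_to_moiety_graph(singleton, 0)
        assert (g.G != singleton[0].C).nnz == 0
        assert np.array_equal(g.vector, singleton[0].a)


class TestIdentifyMoieties:
    def test_das_variant_a_matches_reference(self, das, das_moieties):
        _, matrix = das_moieties
        assert matrix.r == 7
        assert column_set(matrix.L) == column_set(
            np.array(list(das.expected["moiety_vectors"].values())).T
        )

    def test_das_variant_d_contains_composite(self, das_d):
        atn = build_atn(das_d.network, das_d.mappings)
        _, matrix = identify_moieties(atn)
        assert matrix.r == 6
        assert tuple(das_d.expected["l8"]) in column_set(matrix.L)

    def test_variants_a_and_b_give_identical_vectors(self, das):
        from conserved_moieties import das_fixture

        fb = das_fixture("b")
        atn_b = build_atn(fb.network, fb.mappings)
        _, mb = identify_moieties(atn_b)
        atn_a = build_atn(das.network, das.mappings)
        _, ma = identify_moieties(atn_a)
        # same vectors; only the atom assignment of the oxygen moieties differs
        assert column_set(ma.L) == column_set(mb.L)

    def test_dopa_decarboxylase_reference(self, dopa):
        atn = build_atn(dopa.network, dopa.mappings)
        graphs, matrix = identify_moieties(atn)
        assert column_set(matrix.L) == column_set(
            np.array(list(dopa.expected["moiety_vectors"].values())).T
        )
        comps = {g.composition_string() for g in graphs}
        assert comps == {"C8H11NO2", "CO2", "H"}

    def test_moiety_matrix_in_left_nullspace(self, das_N, das_moieties):
        _, matrix = das_moieties
        assert np.all(das_N.T @ matrix.L == 0)

    def test_rank_of_L_spans_nullspace_variant_a(self, das_N, das_moieties):
        from conserved_moieties import exact_rank, left_nullspace_dim

        _, matrix = das_moieties
        assert exact_rank(matrix.L) == left_nullspace_dim(das_N) == 7

    def test_rank_deficit_for_variant_d(self, das_d):
        from conserved_moieties import exact_rank

        atn = build_atn(das_d.network, das_d.mappings)
        _, matrix = identify_moieties(atn)
        assert exact_rank(matrix.L) == 6

    def test_partition_identity(self, das, das_moieties):
        """Moiety compositions weighted by L reproduce the elemental matrix."""
        graphs, matrix = das_moieties
        E = elemental_matrix(das.network)
        elements = das.network.elements
        recon = np.zeros_like(E)
        for k, g in enumerate(graphs):
            comp = g.composition
            for j, el in enumerate(elements):
                recon[:, j] += comp.get(el, 0) * matrix.L[:, k]
        assert np.array_equal(recon, E)

    def test_idempotence_on_reencoded_moiety_graph(self, das_moieties):
        """A moiety graph re-encoded as an ATN is its own single moiety."""
        graphs, _ = das_moieties
        for g in graphs:
            if g.G.shape[1] == 0:
                continue
            mets = sorted(set(g.node_metabolites))
            counts = {m: g.node_metabolites.count(m) for m in mets}
            net_mets = [Metabolite(m, formula={"C": counts[m]}, charge=0) for m in mets]
            G = g.G.toarray()
            per_rxn: dict[str, list[tuple[int, int]]] = {}
            for j, rid in enumerate(g.edge_reactions):
                src = int(np.flatnonzero(G[:, j] == -1)[0])
                dst = int(np.flatnonzero(G[:, j] == 1)[0])
                per_rxn.setdefault(rid, []).append((src, dst))
            instance_idx = {}
            seen: dict[str, int] = {}
            for i, m in enumerate(g.node_metabolites):
                seen[m] = seen.get(m, 0) + 1
                instance_idx[i] = seen[m]
            rxns, maps = [], {}
            for rid, edges in per_rxn.items():
                stoich: dict[str, float] = {}
                for src, dst in edges:
                    stoich[g.node_metabolites[src]] = -1
                    stoich[g.node_metabolites[dst]] = 1
                rxns.append(Reaction(rid, "internal", stoich))
                maps[rid] = ReactionAtomMap(rid, [
                    (MappedAtom(g.node_metabolites[s], 1, "C", instance_idx[s]),
                     MappedAtom(g.node_metabolites[d], 1, "C", instance_idx[d]))
                    for s, d in edges
                ])
            net = MetabolicNetwork(net_mets, rxns)
            atn = build_atn(net, AtomMappingSet(maps))
            new_graphs, matrix = identify_moieties(atn)
            assert matrix.r == 1
            assert matrix.L[:, 0].sum() == len(g.node_metabolites)


class TestClassification:
    def test_das_reference_classes(self, das, das_moieties):
        _, matrix = das_moieties
        expected = das.expected["classes"]
        vectors = das.expected["moiety_vectors"]
        by_vector = {tuple(v): expected[k] for k, v in vectors.items()}
        for k in range(matrix.r):
            assert matrix.classes[k] == by_vector[tuple(matrix.L[:, k])]

    def test_sink_for_every_metabolite_removes_internal(self, das, das_moieties):
        _, matrix = das_moieties
        mets = [Metabolite(m.id, m.name, dict(m.formula), m.charge)
                for m in das.network.metabolites]
        rxns = [r for r in das.network.reactions if r.kind == "internal"]
        rxns += [Reaction(f"S{i}", "exchange", {m.id: -1})
                 for i, m in enumerate(mets)]
        net = MetabolicNetwork(mets, rxns)
        labels = classify_moieties(matrix.L, net)
        assert "internal" not in labels


class TestComposition:
    def test_das_compositions(self, das_moieties):
        graphs, _ = das_moieties
        comps = sorted(g.composition_string() for g in graphs)
        assert comps == sorted(
            ["C8H11N", "CO2", "C9H13N5O3", "H", "H", "O", "O"]
        )

    def test_composition_total_atoms(self, das_moieties):
        graphs, matrix = das_moieties
        total = sum(
            sum(g.composition.values()) * int(matrix.L[:, k].sum())
            for k, g in enumerate(graphs)
        )
        assert total == 170

    def test_mismatch_raises(self, das_moieties):
        graphs, _ = das_moieties
        g = next(g for g in graphs if len(g.instance_atoms) > 1)
        import copy

        bad = copy.deepcopy(g)
        atom = bad.instance_atoms[0][0]
        bad.instance_atoms[0][0] = atom._replace(element="Zz")
        with pytest.raises(ValueError, match="compositions differ"):
            moiety_composition(bad)
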