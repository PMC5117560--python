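"""Assembly of atom transition networks.

An atom transition network (ATN) is a directed multigraph whose nodes are
the individual atoms of network metabolites and whose edges are the
substrate-to-product atom transitions of internal reactions.  Its
incidence matrix ``A`` lies in {-1, 0, 1}^(p x q): each column has one -1
(source atom) and one +1 (target atom).  Nodes are per metabolite atom:
repeated instances of a metabolite within one reaction attach their
transitions to the same nodes, so ``p`` equals the total atom count of the
included elements over included metabolites.

Node order is deterministic (metabolites in network order, elements in
canonical order, atom index ascending) and transition order follows
reaction order then mapping-table order, so ``A`` is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
from scipy import sparse

from .atom_mapping_io import AtomMappingSet, MappedAtom
from .network_core import MetabolicNetwork, NetworkError, element_sort_key

logger = logging.getLogger(__name__)

__all__ = [
    "AtomNode",
    "AtomTransition",
    "AtomTransitionNetwork",
    "build_atn",
    "underlying_simple_graph",
]


class AtomNode(NamedTuple):
    metabolite_id: str
    element: str
    index: int
    row: int


class AtomTransition(NamedTuple):
    reaction_id: str
    source: AtomNode
    target: AtomNode
    col: int


@dataclass
class AtomTransitionNetwork:
    nodes: list[AtomNode]
    transitions: list[AtomTransition]
    A: sparse.csc_matrix
    element_filter: str
    network: MetabolicNetwork
    self_loops: list[AtomTransition] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.nodes)

    @property
    def q(self) -> int:
        return len(self.transitions)

    def node_row(self, metabolite_id: str, element: str, index: int) -> int:
        return self._index[(metabolite_id, element, index)]

    def __post_init__(self) -> None:
        self._index = {
            (n.metabolite_id, n.element, n.index): n.row for n in self.nodes
        }

    def to_edge_table(self):
        """TSV-style edge list (reaction, substrate atom, product atom)."""
        import pandas as pd

        return pd.DataFrame(
            [
                (t.reaction_id, t.source.metabolite_id, t.source.element,
                 t.source.index, t.target.metabolite_id, t.target.index)
                for t in self.transitions
            ],
            columns=["reaction_id", "sub_met", "element", "sub_index",
                     "prod_met", "prod_index"],
        )

    def to_multigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for node in self.nodes:
            g.add_node(node.row, metabolite=node.metabolite_id,
                       element=node.element, index=node.index)
        for t in self.transitions:
            g.add_edge(t.source.row, t.target.row, reaction=t.reaction_id)
        return g


def _atom_key(net: MetabolicNetwork, atom: MappedAtom) -> tuple[str, str, int]:
    met = net.metabolite(atom.metabolite_id)
    count = met.atom_count(atom.element)
    if atom.index > count:
        raise NetworkError(
            f"atom index {atom.element}{atom.index} exceeds formula of "
            f"{atom.metabolite_id!r} ({atom.element} count {count})"
        )
    return (atom.metabolite_id, atom.element, atom.index)


def build_atn(
    net: MetabolicNetwork,
    maps: AtomMappingSet,
    element_filter: str = "all",
) -> AtomTransitionNetwork:
    """Build the ATN for a network and one atom mapping per internal reaction.

    ``element_filter`` restricts nodes and transitions to a single element
    symbol, or ``"all"`` for the full network.  Massless placeholder
    metabolites (empty formulas) carry no atoms and are excluded.
    Transition direction follows the designated forward direction of the
    parent reaction.  Self-transitions (an atom of a metabolite appearing
    on both sides) are retained in ``A`` but flagged in ``self_loops``.
    """
    for met in net.metabolites:
        if met.formula is None:
            raise NetworkError(f"metabolite {met.id!r} has no formula")
        if met.is_massless:
            logger.warning("massless metabolite %r excluded from ATN", met.id)

    def included(element: str) -> bool:
        return element_filter == "all" or element == element_filter

    # Nodes: metabolites in network order, elements in canonical order.
    nodes: list[AtomNode] = []
    for met in net.metabolites:
        for el in sorted((met.formula or {}), key=element_sort_key):
            if not included(el):
                continue
            for idx in range(1, met.atom_count(el) + 1):
                nodes.append(AtomNode(met.id, el, idx, len(nodes)))
    row_of = {(n.metabolite_id, n.element, n.index): n.row for n in nodes}

    transitions: list[AtomTransition] = []
    self_loops: list[AtomTransition] = []
    for rxn in net.internal_reactions:
        if rxn.id not in maps:
            raise NetworkError(f"internal reaction {rxn.id!r} missing from mapping set")
        rmap = maps[rxn.id]
        # Expected transition count per element from stoichiometry:
        # sum over substrates of |coefficient| * atom count.
        expected: dict[str, int] = {}
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                met = net.metabolite(met_id)
                for el, cnt in (met.formula or {}).items():
                    if included(el) and cnt > 0:
                        expected[el] = expected.get(el, 0) + int(-coeff) * cnt
        got: dict[str, int] = {}
        for sub, prod in rmap.transitions:
            if not included(sub.element):
                continue
            got[sub.element] = got.get(sub.element, 0) + 1
            src = row_of[_atom_key(net, sub)]
            dst = row_of[_atom_key(net, prod)]
            t = AtomTransition(rxn.id, nodes[src], nodes[dst], len(transitions))
            transitions.append(t)
            if src == dst:
                logger.warning(
                    "self-transition in %s: %s stays on %s %s%d",
                    rxn.id, sub.metabolite_id, sub.metabolite_id,
                    sub.element, sub.index,
                )
                self_loops.append(t)
        if got != expected:
            raise NetworkError(
                f"reaction {rxn.id!r}: mapped transitions per element {got} "
                f"do not match stoichiometry {expected} under filter "
                f"{element_filter!r}"
            )

    p, q = len(nodes), len(transitions)
    data, rows, cols = [], [], []
    for t in transitions:
        if t.source.row == t.target.row:
            continue  # self-loop: net incidence zero; kept in transition list
        rows.extend([t.source.row, t.target.row])
        cols.extend([t.col, t.col])
        data.extend([-1, 1])
    A = sparse.csc_matrix((data, (rows, cols)), shape=(p, q), dtype=np.int8)
    atn = AtomTransitionNetwork(nodes, transitions, A, element_filter, net, self_loops)
    logger.info("built ATN: p=%d atoms, q=%d transitions (filter=%s)",
                p, q, element_filter)
    return atn


def underlying_simple_graph(atn: AtomTransitionNetwork) -> nx.Graph:
    """Undirected simple graph over atom nodes.

    Parallel transitions collapse to a single edge and self-loops are
    dropped; every node is present even if isolated.
    """
    g = nx.Graph()
    g.add_nodes_from(n.row for n in atn.nodes)
    for t in atn.transitions:
        if t.source.row != t.target.row:
            g.add_edge(t.source.row, t.target.row)
    return g
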