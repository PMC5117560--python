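"""Identification of conserved moieties from an atom transition network.

The pipeline: find connected components of the ATN (edge directions
ignored); attach to each component ``h`` its incidence matrix ``C(h)``,
atom-to-metabolite mapping matrix ``M(h)`` and atom conservation vector
``a_h`` (atoms of the component per metabolite); group components into
isomorphism classes by exact equality of ``a_h``; merge each class into a
moiety graph whose nodes are moiety instances; and collect the class
vectors as columns of the moiety matrix ``L``, which satisfies
``N.T @ L = 0`` exactly.

Equality of ``a_h`` is the isomorphism criterion: because chemical
reactions preserve connectivity and reaction identity along with metabolic
identity, components with equal atom conservation vectors are structurally
identical in real atom transition networks.  A strict structural audit
(per-reaction transition multisets) is on by default and logs a warning if
a pathological input violates this.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse

from .atn_builder import AtomNode, AtomTransitionNetwork, underlying_simple_graph
from .network_core import MetabolicNetwork, element_sort_key

logger = logging.getLogger(__name__)

__all__ = [
    "Component",
    "MoietyGraph",
    "MoietyMatrix",
    "connected_components",
    "atom_conservation_vector",
    "group_isomorphic",
    "verify_isomorphism_strict",
    "merge_to_moiety_graph",
    "identify_moieties",
    "classify_moieties",
    "moiety_composition",
]


@dataclass
class Component:
    """A maximal connected subgraph of the ATN (directions ignored)."""

    id: int
    nodes: list[AtomNode]          # sorted by ATN row
    transitions: list              # AtomTransition, ATN column order
    C: sparse.csc_matrix           # local incidence, x nodes by y transitions
    M: sparse.csc_matrix           # metabolite-by-atom mapping matrix
    a: np.ndarray                  # atom conservation vector, length m

    @property
    def x(self) -> int:
        return len(self.nodes)

    @property
    def y(self) -> int:
        return len(self.transitions)


@dataclass
class MoietyGraph:
    """The common structure of one isomorphism class of components.

    Nodes represent moiety instances; ``instance_atoms[g]`` lists the
    constituent atoms of instance ``g``, one per member component.
    """

    id: int
    member_ids: list[int]
    G: sparse.csc_matrix
    node_metabolites: list[str]            # metabolite of each instance node
    node_instance_number: list[int]        # 1-based within metabolite
    instance_atoms: list[list[AtomNode]]
    edge_reactions: list[str]
    vector: np.ndarray                     # moiety vector l_k

    @property
    def name(self) -> str:
        return f"M{self.id + 1:02d}"

    @property
    def composition(self) -> dict[str, int]:
        return moiety_composition(self)

    def composition_string(self) -> str:
        """Hill-order formula string, e.g. ``C9H13N5O3``."""
        comp = self.composition
        hill = sorted(comp, key=lambda el: ({"C": 0, "H": 1}.get(el, 2), el))
        return "".join(
            f"{el}{comp[el]}" if comp[el] != 1 else el for el in hill
        )


@dataclass
class MoietyMatrix:
    """Moiety vectors as columns of ``L`` with names, classes, compositions."""

    L: np.ndarray                     # m x r, nonnegative integers
    names: list[str]
    compositions: list[dict[str, int]]
    network: MetabolicNetwork
    classes: list[str] | None = None  # transitive / internal / integrative

    @property
    def r(self) -> int:
        return self.L.shape[1]

    def column(self, k: int) -> np.ndarray:
        return self.L[:, k]

    def to_frame(self):
        import pandas as pd

        header = [
            f"{name}" for name in self.names
        ]
        df = pd.DataFrame(
            self.L,
            index=[m.id for m in self.network.metabolites],
            columns=header,
        )
        return df


def connected_components(atn: AtomTransitionNetwork) -> list[Component]:
    """Components of the underlying simple undirected graph.

    Deterministic order: components sorted by their smallest node row;
    nodes within a component sorted by row; transitions in ATN column
    order.  Each component carries ``C``, ``M`` and ``a``.
    """
    simple = underlying_simple_graph(atn)
    comps = sorted((sorted(c) for c in nx.connected_components(simple)), key=lambda c: c[0])
    net = atn.network
    m = net.m
    row_to_comp = {}
    for h, rows in enumerate(comps):
        for r in rows:
            row_to_comp[r] = h
    # transitions per component (both endpoints always lie in one component)
    comp_transitions: list[list] = [[] for _ in comps]
    for t in atn.transitions:
        comp_transitions[row_to_comp[t.source.row]].append(t)

    out = []
    for h, rows in enumerate(comps):
        nodes = [atn.nodes[r] for r in rows]
        local = {r: i for i, r in enumerate(rows)}
        ts = comp_transitions[h]
        data, ri, ci = [], [], []
        for j, t in enumerate(ts):
            if t.source.row == t.target.row:
                continue
            ri.extend([local[t.source.row], local[t.target.row]])
            ci.extend([j, j])
            data.extend([-1, 1])
        C = sparse.csc_matrix((data, (ri, ci)), shape=(len(rows), len(ts)), dtype=np.int8)
        mri = [net.metabolite_index(n.metabolite_id) for n in nodes]
        M = sparse.csc_matrix(
            (np.ones(len(nodes), dtype=np.int8), (mri, range(len(nodes)))),
            shape=(m, len(nodes)),
        )
        a = np.asarray(M.sum(axis=1), dtype=np.int64).ravel()
        out.append(Component(h, nodes, ts, C, M, a))
    return out


def atom_conservation_vector(component: Component) -> np.ndarray:
    """``a_h``: number of the component's atoms in each metabolite."""
    return component.a.copy()


def group_isomorphic(components: list[Component]) -> list[list[Component]]:
    """Partition components into isomorphism classes by equality of ``a_h``.

    Classes are ordered by descending atoms per instance (= class size),
    then lexicographically by ``a_h``, for reproducible moiety numbering.
    """
    groups: dict[tuple, list[Component]] = {}
    for comp in components:
        groups.setdefault(tuple(comp.a), []).append(comp)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [members for _, members in ordered]


def _transition_profile(component: Component) -> Counter:
    """Per-reaction multiset of (source metabolite, target metabolite) pairs."""
    return Counter(
        (t.reaction_id, t.source.metabolite_id, t.target.metabolite_id)
        for t in component.transitions
    )


def verify_isomorphism_strict(c1: Component, c2: Component) -> bool:
    """Audit of the ``a_h`` shortcut.

    True iff a bijection exists matching node metabolite identities and,
    per reaction, the multiset of (source, target) metabolite transition
    pairs.  For components of genuine chemical atom transition networks
    this always holds when ``a_h`` agrees.
    """
    if not np.array_equal(c1.a, c2.a):
        return False
    return _transition_profile(c1) == _transition_profile(c2)


def merge_to_moiety_graph(
    members: list[Component],
    moiety_id: int = 0,
    network: MetabolicNetwork | None = None,
    audit: bool = True,
    strict: bool = False,
) -> MoietyGraph:
    """Merge one isomorphism class into a moiety graph.

    The merged incidence structure is taken from the class representative
    after verifying equality (averaging identical matrices would only
    introduce fractional intermediates).  Each instance node is annotated
    with its constituent atoms, one per member component.  With ``audit``,
    members failing the strict structural check are reported via a logged
    warning, or raised when ``strict``.
    """
    if not members:
        raise ValueError("empty isomorphism class")
    rep = members[0]
    if audit:
        for other in members[1:]:
            if not verify_isomorphism_strict(rep, other):
                msg = (
                    f"components {rep.id} and {other.id} have equal atom "
                    "conservation vectors but different transition structure"
                )
                if strict:
                    raise ValueError(msg)
                logger.warning(msg)

    # Align nodes across members: within each (metabolite), order atoms by
    # ATN row; the g-th node of each member in that order is the same
    # moiety instance.
    def node_order(comp: Component) -> list[AtomNode]:
        return sorted(comp.nodes, key=lambda n: (n.row,))

    rep_nodes = node_order(rep)
    node_metabolites = [n.metabolite_id for n in rep_nodes]
    counters: Counter = Counter()
    node_instance_number = []
    for met in node_metabolites:
        counters[met] += 1
        node_instance_number.append(counters[met])
    instance_atoms: list[list[AtomNode]] = [[] for _ in rep_nodes]
    for comp in members:
        ordered = node_order(comp)
        if [n.metabolite_id for n in ordered] != node_metabolites:
            # Equal a_h guarantees equal per-metabolite counts; align by
            # grouping per metabolite instead of raw row order.
            by_met: dict[str, list[AtomNode]] = {}
            for n in ordered:
                by_met.setdefault(n.metabolite_id, []).append(n)
            ordered = []
            seen: Counter = Counter()
            for met in node_metabolites:
                ordered.append(by_met[met][seen[met]])
                seen[met] += 1
        for g, atom in enumerate(ordered):
            instance_atoms[g].append(atom)

    return MoietyGraph(
        id=moiety_id,
        member_ids=[c.id for c in members],
        G=rep.C.copy(),
        node_metabolites=node_metabolites,
        node_instance_number=node_instance_number,
        instance_atoms=instance_atoms,
        edge_reactions=[t.reaction_id for t in rep.transitions],
        vector=rep.a.copy(),
    )


def moiety_composition(graph: MoietyGraph) -> dict[str, int]:
    """Element counts of one moiety instance; asserted identical across
    instances (a mismatch signals a grouping bug)."""
    comps = [
        Counter(atom.element for atom in atoms) for atoms in graph.instance_atoms
    ]
    for other in comps[1:]:
        if other != comps[0]:
            raise ValueError(
                f"moiety {graph.name}: instance compositions differ "
                f"({dict(comps[0])} vs {dict(other)})"
            )
    return dict(comps[0]) if comps else {}


def identify_moieties(
    atn: AtomTransitionNetwork,
    audit: bool = True,
) -> tuple[list[MoietyGraph], MoietyMatrix]:
    """Full pipeline: components -> isomorphism classes -> moiety graphs/matrix."""
    comps = connected_components(atn)
    classes = group_isomorphic(comps)
    graphs = [
        merge_to_moiety_graph(members, k, atn.network, audit=audit)
        for k, members in enumerate(classes)
    ]
    L = (
        np.stack([g.vector for g in graphs], axis=1)
        if graphs
        else np.zeros((atn.network.m, 0), dtype=np.int64)
    )
    matrix = MoietyMatrix(
        L=L.astype(np.int64),
        names=[g.name for g in graphs],
        compositions=[g.composition for g in graphs],
        network=atn.network,
    )
    matrix.classes = classify_moieties(matrix, atn.network)
    logger.info(
        "identified %d moieties from %d components (p=%d, q=%d)",
        len(graphs), len(comps), atn.p, atn.q,
    )
    return graphs, matrix


def classify_moieties(L: MoietyMatrix | np.ndarray, net: MetabolicNetwork) -> list[str]:
    """Classify each moiety column as transitive, internal or integrative.

    A moiety is internal iff it is conserved in the open network
    (``S.T @ l = 0``).  Metabolites supporting an internal moiety are
    secondary; a moiety confined to primary metabolites is transitive and
    one spanning both is integrative.
    """
    mat = L.L if isinstance(L, MoietyMatrix) else np.asarray(L)
    S = net.S
    internal = [bool(np.all(S.T @ mat[:, k] == 0)) for k in range(mat.shape[1])]
    secondary = np.zeros(net.m, dtype=bool)
    for k, is_int in enumerate(internal):
        if is_int:
            secondary |= mat[:, k] > 0
    labels = []
    for k in range(mat.shape[1]):
        if internal[k]:
            labels.append("internal")
        elif np.any(secondary & (mat[:, k] > 0)):
            labels.append("integrative")
        else:
            labels.append("transitive")
    return labels
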