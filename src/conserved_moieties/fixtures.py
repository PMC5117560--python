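"""Packaged example networks and a synthetic planted-moiety generator.

``das_fixture`` builds the dopamine synthesis network DAS: 11 metabolites,
four internal reactions (phenylalanine hydroxylase, tyrosine hydroxylase,
DOPA decarboxylase, and a composite dihydropteridine reductase / formate
dehydrogenase step) and seven exchange reactions, together with a complete
explicit-hydrogen atom mapping for every internal reaction.  Because the
two oxygen atoms of O2 are symmetric, the O2 -> H2O mapping in the two
hydroxylase reactions admits four combinations (variants a, b, d, e);
variants d and e map a different O2 atom to water in the two reactions and
therefore fuse two oxygen moieties into one composite moiety.

The hydrogen conventions (which pterin hydrogens leave to water, and the
hydrogen ion entering the dopamine or regenerated pterin molecule) are
fixture conventions chosen for element and charge balance, not
biochemical claims; every aggregate they imply (atom and transition
counts, component counts, the moiety matrix) is checked by the test
suite.

``planted_moiety_generator`` builds random networks with known ground
truth: moiety instances are treated as indivisible balls, metabolites as
bags, and each internal reaction repartitions the balls of its substrate
bags into freshly created product bags.  Formulas, the stoichiometric
matrix, the atom-level mapping table and the true moiety matrix all
follow from the same construction, so balance, bijection and conservation
hold by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atom_mapping_io import AtomMappingSet, parse_mapping_table, write_mapping_table
from .network_core import Metabolite, MetabolicNetwork, Reaction, element_sort_key

__all__ = [
    "Fixture",
    "das_fixture",
    "dopa_decarboxylase_fixture",
    "planted_moiety_generator",
    "write_fixture",
    "DAS_METABOLITE_ORDER",
]


@dataclass
class Fixture:
    network: MetabolicNetwork
    mappings: AtomMappingSet
    expected: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# DAS

DAS_METABOLITE_ORDER = [
    "Phe", "Tyr", "L-DOPA", "DA", "CO2", "Formate", "BH4", "BH2", "O2", "H2O", "H+",
]

_DAS_FORMULAS = {
    "Phe": ({"C": 9, "H": 11, "N": 1, "O": 2}, 0),
    "Tyr": ({"C": 9, "H": 11, "N": 1, "O": 3}, 0),
    "L-DOPA": ({"C": 9, "H": 11, "N": 1, "O": 4}, 0),
    "DA": ({"C": 8, "H": 12, "N": 1, "O": 2}, 1),
    "CO2": ({"C": 1, "O": 2}, 0),
    "Formate": ({"C": 1, "H": 1, "O": 2}, -1),
    "BH4": ({"C": 9, "H": 15, "N": 5, "O": 3}, 0),
    "BH2": ({"C": 9, "H": 13, "N": 5, "O": 3}, 0),
    "O2": ({"O": 2}, 0),
    "H2O": ({"H": 2, "O": 1}, 0),
    "H+": ({"H": 1}, 1),
}

_DAS_NAMES = {
    "Phe": "L-phenylalanine", "Tyr": "L-tyrosine", "L-DOPA": "levodopa",
    "DA": "dopamine", "CO2": "carbon dioxide", "Formate": "formate",
    "BH4": "tetrahydrobiopterin", "BH2": "dihydrobiopterin",
    "O2": "oxygen", "H2O": "water", "H+": "hydrogen ion",
}


def _same_index_rows(rows, rid, sub, prod, element, count, prod_offset=0):
    for i in range(1, count + 1):
        rows.append((rid, sub, 1, element, i, prod, 1, i + prod_offset))


def _row(rows, rid, sub, element, si, prod, pi):
    rows.append((rid, sub, 1, element, si, prod, 1, pi))


def _pterin_reduction_block(rows, rid):
    """BH4 -> BH2 same-index block plus the two leaving hydrogens -> H2O."""
    _same_index_rows(rows, rid, "BH4", "BH2", "C", 9)
    _same_index_rows(rows, rid, "BH4", "BH2", "N", 5)
    _same_index_rows(rows, rid, "BH4", "BH2", "O", 3)
    _same_index_rows(rows, rid, "BH4", "BH2", "H", 13)
    _row(rows, rid, "BH4", "H", 14, "H2O", 1)
    _row(rows, rid, "BH4", "H", 15, "H2O", 2)


def _das_mapping_rows(oxygen_variant: str) -> list[tuple]:
    if oxygen_variant not in ("a", "b", "d", "e"):
        raise ValueError(f"unknown oxygen variant {oxygen_variant!r}")
    # Which O2 atom goes to water in R1 and in R2 under each variant.
    water_atom = {
        "a": (1, 1), "b": (2, 2), "d": (1, 2), "e": (2, 1),
    }[oxygen_variant]
    rows: list[tuple] = []

    # R1: Phe + BH4 + O2 -> Tyr + BH2 + H2O
    _same_index_rows(rows, "R1", "Phe", "Tyr", "C", 9)
    _same_index_rows(rows, "R1", "Phe", "Tyr", "H", 11)
    _same_index_rows(rows, "R1", "Phe", "Tyr", "N", 1)
    _same_index_rows(rows, "R1", "Phe", "Tyr", "O", 2)
    _pterin_reduction_block(rows, "R1")
    to_water, to_ring = (water_atom[0], 3 - water_atom[0])
    _row(rows, "R1", "O2", "O", to_water, "H2O", 1)
    _row(rows, "R1", "O2", "O", to_ring, "Tyr", 3)

    # R2: Tyr + BH4 + O2 -> L-DOPA + BH2 + H2O
    _same_index_rows(rows, "R2", "Tyr", "L-DOPA", "C", 9)
    _same_index_rows(rows, "R2", "Tyr", "L-DOPA", "H", 11)
    _same_index_rows(rows, "R2", "Tyr", "L-DOPA", "N", 1)
    _same_index_rows(rows, "R2", "Tyr", "L-DOPA", "O", 3)
    _pterin_reduction_block(rows, "R2")
    to_water, to_ring = (water_atom[1], 3 - water_atom[1])
    _row(rows, "R2", "O2", "O", to_water, "H2O", 1)
    _row(rows, "R2", "O2", "O", to_ring, "L-DOPA", 4)

    # R3: L-DOPA + H+ -> DA + CO2
    _same_index_rows(rows, "R3", "L-DOPA", "DA", "C", 8)
    _row(rows, "R3", "L-DOPA", "C", 9, "CO2", 1)
    _same_index_rows(rows, "R3", "L-DOPA", "DA", "H", 11)
    _same_index_rows(rows, "R3", "L-DOPA", "DA", "N", 1)
    _row(rows, "R3", "L-DOPA", "O", 1, "CO2", 1)
    _row(rows, "R3", "L-DOPA", "O", 2, "CO2", 2)
    _row(rows, "R3", "L-DOPA", "O", 3, "DA", 1)
    _row(rows, "R3", "L-DOPA", "O", 4, "DA", 2)
    _row(rows, "R3", "H+", "H", 1, "DA", 12)

    # R4: BH2 + Formate + H+ -> BH4 + CO2
    _same_index_rows(rows, "R4", "BH2", "BH4", "C", 9)
    _same_index_rows(rows, "R4", "BH2", "BH4", "N", 5)
    _same_index_rows(rows, "R4", "BH2", "BH4", "O", 3)
    _same_index_rows(rows, "R4", "BH2", "BH4", "H", 13)
    _row(rows, "R4", "Formate", "C", 1, "CO2", 1)
    _row(rows, "R4", "Formate", "O", 1, "CO2", 1)
    _row(rows, "R4", "Formate", "O", 2, "CO2", 2)
    _row(rows, "R4", "Formate", "H", 1, "BH4", 14)
    _row(rows, "R4", "H+", "H", 1, "BH4", 15)
    return rows


def _das_network() -> MetabolicNetwork:
    mets = [
        Metabolite(mid, _DAS_NAMES[mid], dict(_DAS_FORMULAS[mid][0]), _DAS_FORMULAS[mid][1])
        for mid in DAS_METABOLITE_ORDER
    ]
    rxns = [
        Reaction("R1", "internal",
                 {"Phe": -1, "BH4": -1, "O2": -1, "Tyr": 1, "BH2": 1, "H2O": 1}),
        Reaction("R2", "internal",
                 {"Tyr": -1, "BH4": -1, "O2": -1, "L-DOPA": 1, "BH2": 1, "H2O": 1}),
        Reaction("R3", "internal", {"L-DOPA": -1, "H+": -1, "DA": 1, "CO2": 1}),
        Reaction("R4", "internal", {"BH2": -1, "Formate": -1, "H+": -1, "BH4": 1, "CO2": 1}),
        Reaction("E1", "exchange", {"O2": 1}),
        Reaction("E2", "exchange", {"Phe": 1}),
        Reaction("E3", "exchange", {"H2O": -1}),
        Reaction("E4", "exchange", {"DA": -1}),
        Reaction("E5", "exchange", {"CO2": -1}),
        Reaction("E6", "exchange", {"Formate": 1}),
        Reaction("E7", "exchange", {"H+": 1}),
    ]
    return MetabolicNetwork(mets, rxns)


# Moiety vectors in DAS_METABOLITE_ORDER.
_DAS_L = {
    "l1": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
    "l2": [1, 1, 1, 0, 1, 1, 0, 0, 0, 0, 0],
    "l3": [0, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0],
    "l4": [0, 0, 0, 1, 0, 0, 1, 0, 0, 1, 1],
    "l5": [0, 0, 0, 0, 0, 1, 1, 0, 0, 1, 0],
    "l6": [0, 1, 2, 2, 0, 0, 0, 0, 1, 0, 0],
    "l7": [0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0],
    "l8": [0, 1, 2, 2, 0, 0, 0, 0, 2, 1, 0],
    "l9": [0, 1, 2, 0, 2, 2, 0, 0, 1, 0, 0],
}

_DAS_COMPOSITIONS = {
    "l1": {"C": 8, "H": 11, "N": 1},
    "l2": {"C": 1, "O": 2},
    "l3": {"C": 9, "H": 13, "N": 5, "O": 3},
    "l4": {"H": 1},
    "l5": {"H": 1},
    "l6": {"O": 1},
    "l7": {"O": 1},
    "l8": {"O": 2},
}

_DAS_CLASSES = {
    "l1": "transitive", "l2": "transitive", "l3": "internal",
    "l4": "integrative", "l5": "integrative", "l6": "transitive",
    "l7": "transitive",
}


def das_fixture(oxygen_variant: str = "a") -> Fixture:
    """The dopamine synthesis network with one of four oxygen mappings."""
    net = _das_network()
    df = pd.DataFrame(
        _das_mapping_rows(oxygen_variant),
        columns=["reaction_id", "sub_met", "sub_instance", "element",
                 "sub_index", "prod_met", "prod_instance", "prod_index"],
    )
    mappings = parse_mapping_table(df, network=net)
    if oxygen_variant in ("a", "b"):
        moiety_keys = ["l1", "l2", "l3", "l4", "l5", "l6", "l7"]
        n_components = 57
    else:
        moiety_keys = ["l1", "l2", "l3", "l4", "l5", "l8"]
        n_components = 56
    expected = {
        "p": 170,
        "q": 176,
        "components": n_components,
        "carbon_atoms": 55,
        "carbon_components": 18,
        "carbon_class_sizes": [9, 8, 1],
        "transitions_per_reaction": {"R1": 57, "R2": 58, "R3": 26, "R4": 35},
        "moiety_vectors": {k: list(_DAS_L[k]) for k in moiety_keys},
        "compositions": {k: dict(_DAS_COMPOSITIONS[k]) for k in moiety_keys},
        "classes": {k: _DAS_CLASSES[k] for k in moiety_keys if k in _DAS_CLASSES},
        "l6": list(_DAS_L["l6"]),
        "l7": list(_DAS_L["l7"]),
        "l8": list(_DAS_L["l8"]),
        "l9": list(_DAS_L["l9"]),
    }
    return Fixture(net, mappings, expected)


# ---------------------------------------------------------------------------
# DOPA decarboxylase example


def dopa_decarboxylase_fixture() -> Fixture:
    """One internal reaction (DOPA decarboxylase) with four exchanges."""
    order = ["L-DOPA", "H+", "DA", "CO2"]
    mets = [
        Metabolite(mid, _DAS_NAMES[mid], dict(_DAS_FORMULAS[mid][0]), _DAS_FORMULAS[mid][1])
        for mid in order
    ]
    rxns = [
        Reaction("R1", "internal", {"L-DOPA": -1, "H+": -1, "DA": 1, "CO2": 1}),
        Reaction("E1", "exchange", {"L-DOPA": 1}),
        Reaction("E2", "exchange", {"H+": 1}),
        Reaction("E3", "exchange", {"DA": -1}),
        Reaction("E4", "exchange", {"CO2": -1}),
    ]
    net = MetabolicNetwork(mets, rxns)
    rows = [r for r in _das_mapping_rows("a") if r[0] == "R3"]
    rows = [("R1",) + r[1:] for r in rows]
    df = pd.DataFrame(
        rows,
        columns=["reaction_id", "sub_met", "sub_instance", "element",
                 "sub_index", "prod_met", "prod_instance", "prod_index"],
    )
    mappings = parse_mapping_table(df, network=net)
    expected = {
        # moiety vectors in (L-DOPA, H+, DA, CO2) order
        "moiety_vectors": {
            "l1": [1, 0, 1, 0],   # dopamine moiety
            "l2": [1, 0, 0, 1],   # CO2 moiety
            "l3": [0, 1, 1, 0],   # hydrogen moiety
        },
        "compositions": {
            "l1": {"C": 8, "H": 11, "N": 1, "O": 2},
            "l2": {"C": 1, "O": 2},
            "l3": {"H": 1},
        },
        "elemental_matrix": [
            [9, 11, 4, 1],
            [0, 1, 0, 0],
            [8, 12, 2, 1],
            [1, 0, 2, 0],
        ],  # rows (C, H, O, N) per metabolite
    }
    return Fixture(net, mappings, expected)


# ---------------------------------------------------------------------------
# Planted-moiety generator

_GEN_ELEMENTS = ["C", "H", "O", "N", "P", "S"]


def planted_moiety_generator(
    seed: int,
    n_moieties: int = 3,
    size_range: tuple[int, int] = (1, 4),
    n_metabolites: int = 8,
    n_reactions: int = 5,
) -> Fixture:
    """Random network with planted conserved moieties and known moiety matrix.

    ``size_range`` bounds the atom count per moiety.  Deterministic under
    ``seed``.  Raises ``ValueError`` for parameter combinations that admit
    no construction (each reaction creates one or two product metabolites,
    so ``n_metabolites`` must fit between ``n_initial + n_reactions`` and
    ``n_initial + 2 * n_reactions``).
    """
    rng = np.random.default_rng(seed)
    if n_moieties < 1 or n_reactions < 1:
        raise ValueError("infeasible parameters: need at least one moiety and reaction")

    # Moiety compositions.
    compositions: list[dict[str, int]] = []
    for _ in range(n_moieties):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if size < 1:
            raise ValueError("infeasible parameters: moiety size must be >= 1")
        els = rng.choice(_GEN_ELEMENTS, size=size, replace=True)
        comp: dict[str, int] = {}
        for el in els:
            comp[el] = comp.get(el, 0) + 1
        compositions.append(comp)

    n_initial = n_metabolites - n_reactions - int(
        rng.integers(0, n_reactions + 1)
    )
    n_initial = max(1, min(n_initial, n_moieties, n_metabolites - n_reactions))
    total_products = n_metabolites - n_initial
    if not (n_reactions <= total_products <= 2 * n_reactions):
        raise ValueError(
            "infeasible parameters: n_metabolites must satisfy "
            "n_initial + n_reactions <= m <= n_initial + 2 * n_reactions"
        )

    # Bags: metabolite id -> tuple of moiety instance ids.
    bags: dict[str, tuple[int, ...]] = {}
    order: list[str] = []

    def new_bag(instances: tuple[int, ...]) -> str:
        mid = f"X{len(order) + 1:02d}"
        bags[mid] = tuple(sorted(instances))
        order.append(mid)
        return mid

    # Distribute the moiety instances over the initial bags, each nonempty.
    assignment = list(range(n_initial)) + [
        int(rng.integers(0, n_initial)) for _ in range(n_moieties - n_initial)
    ]
    rng.shuffle(assignment)
    for b in range(n_initial):
        new_bag(tuple(k for k, a in enumerate(assignment) if a == b))
    frontier = list(order)

    reactions: list[Reaction] = []
    moves: list[tuple[str, str, str, int]] = []  # (reaction, from_bag, to_bag, instance)
    remaining = total_products
    for j in range(n_reactions):
        left = n_reactions - j - 1
        p_min = max(1, remaining - 2 * left)
        p_max = min(2, remaining - left)
        n_sub = int(rng.integers(1, min(2, len(frontier)) + 1))
        subs = list(rng.choice(frontier, size=n_sub, replace=False))
        pool = [k for s in subs for k in bags[s]]
        if len(pool) < p_min:
            extra = [b for b in frontier if b not in subs]
            while extra and len(pool) < p_min:
                pick = extra.pop(int(rng.integers(0, len(extra))))
                subs.append(pick)
                pool = [k for s in subs for k in bags[s]]
        p_j = int(rng.integers(p_min, min(p_max, len(pool)) + 1)) if len(pool) >= p_min \
            else None
        if p_j is None:
            raise ValueError("infeasible parameters: not enough moiety instances to split")
        # Partition the pool into p_j nonempty product bags.
        rng.shuffle(pool)
        groups = [[pool[i]] for i in range(p_j)]
        for k in pool[p_j:]:
            groups[int(rng.integers(0, p_j))].append(k)
        prods = [new_bag(tuple(g)) for g in groups]
        stoich: dict[str, float] = {s: -1.0 for s in subs}
        stoich.update({p: 1.0 for p in prods})
        rid = f"R{j + 1:02d}"
        reactions.append(Reaction(rid, "internal", stoich))
        inst_to_prod = {k: p for g, p in zip(groups, prods) for k in g}
        for s in subs:
            for k in bags[s]:
                moves.append((rid, s, inst_to_prod[k], k))
        frontier = [b for b in frontier if b not in subs] + prods
        remaining -= p_j

    # Exchange sinks for the final frontier (opens the network).
    exchanges = [
        Reaction(f"E{i + 1:02d}", "exchange", {b: -1.0})
        for i, b in enumerate(sorted(frontier))
    ]

    mets = []
    for mid in order:
        formula: dict[str, int] = {}
        for k in bags[mid]:
            for el, cnt in compositions[k].items():
                formula[el] = formula.get(el, 0) + cnt
        mets.append(Metabolite(mid, formula=formula, charge=0))
    net = MetabolicNetwork(mets, reactions + exchanges)

    # Atom-level mapping rows: per bag, instance atoms are laid out in
    # ascending instance id, per element; indices are therefore reproducible.
    def atom_indices(bag: str, instance: int) -> dict[str, list[int]]:
        offsets: dict[str, int] = {}
        for k in bags[bag]:
            comp = compositions[k]
            if k == instance:
                return {
                    el: list(range(offsets.get(el, 0) + 1,
                                   offsets.get(el, 0) + cnt + 1))
                    for el, cnt in comp.items()
                }
            for el, cnt in comp.items():
                offsets[el] = offsets.get(el, 0) + cnt
        raise KeyError((bag, instance))

    rows = []
    for rid, src, dst, k in moves:
        src_idx = atom_indices(src, k)
        dst_idx = atom_indices(dst, k)
        for el in sorted(src_idx, key=element_sort_key):
            for si, di in zip(src_idx[el], dst_idx[el]):
                rows.append((rid, src, 1, el, si, dst, 1, di))
    df = pd.DataFrame(
        rows,
        columns=["reaction_id", "sub_met", "sub_instance", "element",
                 "sub_index", "prod_met", "prod_instance", "prod_index"],
    )
    mappings = parse_mapping_table(df, network=net)

    # Ground truth: instances with identical metabolite support are, by
    # definition, one conserved moiety; merge their compositions.
    support: dict[tuple, dict[str, int]] = {}
    for k in range(n_moieties):
        key = tuple(1 if k in bags[mid] else 0 for mid in order)
        comp = support.setdefault(key, {})
        for el, cnt in compositions[k].items():
            comp[el] = comp.get(el, 0) + cnt
    keys = sorted(support)
    L_true = np.array(keys, dtype=np.int64).T if keys else np.zeros((len(order), 0), int)
    expected = {
        "L": L_true,
        "compositions": [support[k] for k in keys],
        "n_moieties": len(keys),
    }
    return Fixture(net, mappings, expected)


# ---------------------------------------------------------------------------
# Serialisation


def network_to_dict(net: MetabolicNetwork) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "formula": m.formula, "charge": m.charge}
            for m in net.metabolites
        ],
        "reactions": [
            {"id": r.id, "kind": r.kind, "stoichiometry": r.stoichiometry}
            for r in net.reactions
        ],
    }


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write a fixture as network JSON + mapping TSV + expected-results JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "network.json", "w") as fh:
        json.dump(network_to_dict(fixture.network), fh, indent=1)
    write_mapping_table(fixture.mappings, outdir / "mappings.tsv")
    expected = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in fixture.expected.items()
    }
    with open(outdir / "expected.json", "w") as fh:
        json.dump(expected, fh, indent=1)
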