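"""Atom-mapping input/output.

Two interchange formats are supported:

* MDL RXN/MOL V2000 records carrying atom-atom mapping numbers in columns
  61-63 of each atom-block line (the format emitted by mapping predictors
  such as DREAM);
* a native tabular (TSV) transition format with one substrate-to-product
  atom pair per row.

Atoms are identified by ``(metabolite, instance, element, index)`` where
``index`` is the 1-based position of the atom among atoms of the *same
element* within the metabolite, in molfile atom-block order.  ``instance``
distinguishes copies of a metabolite when its stoichiometric coefficient
exceeds one.  Within a reaction the mapping must be a bijection: each
substrate atom maps to exactly one product atom of the same element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, NamedTuple

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MappedAtom",
    "ReactionAtomMap",
    "AtomMappingSet",
    "MappingError",
    "parse_rxn_v2000",
    "parse_rxn_directory",
    "parse_mapping_table",
    "write_mapping_table",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = [
    "reaction_id",
    "sub_met",
    "sub_instance",
    "element",
    "sub_index",
    "prod_met",
    "prod_instance",
    "prod_index",
]


class MappingError(ValueError):
    """Raised for malformed records or bijection violations."""


class MappedAtom(NamedTuple):
    metabolite_id: str
    instance: int
    element: str
    index: int


@dataclass
class ReactionAtomMap:
    """The atom bijection of one internal reaction."""

    reaction_id: str
    transitions: list[tuple[MappedAtom, MappedAtom]]

    def __post_init__(self) -> None:
        seen_sub: set[MappedAtom] = set()
        seen_prod: set[MappedAtom] = set()
        for sub, prod in self.transitions:
            if sub.element != prod.element:
                raise MappingError(
                    f"{self.reaction_id}: element mismatch {sub} -> {prod}"
                )
            if sub.index < 1 or prod.index < 1:
                raise MappingError(f"{self.reaction_id}: atom indices are 1-based")
            if sub in seen_sub:
                raise MappingError(
                    f"{self.reaction_id}: substrate atom {sub} mapped twice"
                )
            if prod in seen_prod:
                raise MappingError(
                    f"{self.reaction_id}: product atom {prod} mapped twice"
                )
            seen_sub.add(sub)
            seen_prod.add(prod)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionAtomMap):
            return NotImplemented
        return self.reaction_id == other.reaction_id and set(self.transitions) == set(
            other.transitions
        )


@dataclass
class AtomMappingSet:
    """One chosen :class:`ReactionAtomMap` per internal reaction."""

    maps: dict[str, ReactionAtomMap] = field(default_factory=dict)

    def __getitem__(self, reaction_id: str) -> ReactionAtomMap:
        return self.maps[reaction_id]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.maps

    def __len__(self) -> int:
        return len(self.maps)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AtomMappingSet):
            return NotImplemented
        return self.maps == other.maps

    def add(self, rmap: ReactionAtomMap) -> None:
        if rmap.reaction_id in self.maps:
            raise MappingError(f"duplicate map for reaction {rmap.reaction_id!r}")
        self.maps[rmap.reaction_id] = rmap


# ---------------------------------------------------------------------------
# MDL RXN V2000

RoleAssignment = Callable[[str, int], tuple[str, int]]
"""Callback ``(side, slot) -> (metabolite_id, instance)`` where ``side`` is
``"substrate"`` or ``"product"`` and ``slot`` is the 0-based molfile
position on that side.  Externalised because mapping predictors do not
agree on how molfile slots name metabolites."""


def _parse_molfile_atoms(lines: list[str], start: int) -> tuple[list[tuple[str, int]], int]:
    """Read one embedded molfile; return [(element, map_number)] and the
    index one past its ``M  END`` line.  Atom lines are fixed-width V2000:
    element in columns 32-34, atom-atom mapping number in columns 61-63."""
    counts_line = lines[start + 3]
    try:
        n_atoms = int(counts_line[0:3])
        n_bonds = int(counts_line[3:6])
    except (ValueError, IndexError) as exc:
        raise MappingError(f"malformed molfile counts line: {counts_line!r}") from exc
    atoms = []
    for ln in lines[start + 4 : start + 4 + n_atoms]:
        element = ln[31:34].strip()
        if not element:
            raise MappingError(f"malformed atom line: {ln!r}")
        aam_field = ln[60:63].strip() if len(ln) > 60 else ""
        aam = int(aam_field) if aam_field else 0
        atoms.append((element, aam))
    pos = start + 4 + n_atoms + n_bonds
    while pos < len(lines) and lines[pos].strip() != "M  END":
        pos += 1
    if pos >= len(lines):
        raise MappingError("molfile missing M  END")
    return atoms, pos + 1


def parse_rxn_v2000(
    text: str,
    reaction_id: str,
    role_assignment: RoleAssignment,
    permissive: bool = False,
) -> ReactionAtomMap:
    """Parse one RXN-format record into a :class:`ReactionAtomMap`.

    A substrate atom with nonzero mapping number ``k`` pairs with the
    product atom carrying the same ``k``.  Unmapped atoms (number 0 or
    blank) are an error unless ``permissive``, in which case they are
    reported with a warning and skipped.  Hydrogens are taken as written:
    the parser never infers implicit hydrogens, so molfiles used for
    full-element analysis must represent them explicitly.
    """
    lines = text.splitlines()
    if not lines or not lines[0].startswith("$RXN"):
        raise MappingError("record does not start with $RXN")
    counts_line = lines[4]
    try:
        n_sub = int(counts_line[0:3])
        n_prod = int(counts_line[3:6])
    except (ValueError, IndexError) as exc:
        raise MappingError(f"malformed RXN counts line: {counts_line!r}") from exc

    pos = 5
    sides: dict[str, list[list[tuple[str, int]]]] = {"substrate": [], "product": []}
    for side, count in (("substrate", n_sub), ("product", n_prod)):
        for _ in range(count):
            while pos < len(lines) and not lines[pos].startswith("$MOL"):
                pos += 1
            if pos >= len(lines):
                raise MappingError("fewer molfiles than the counts line declares")
            atoms, pos = _parse_molfile_atoms(lines, pos + 1)
            sides[side].append(atoms)

    def collect(side: str) -> dict[int, MappedAtom]:
        by_number: dict[int, MappedAtom] = {}
        unmapped = []
        for slot, atoms in enumerate(sides[side]):
            met_id, instance = role_assignment(side, slot)
            per_element: dict[str, int] = {}
            for element, aam in atoms:
                per_element[element] = per_element.get(element, 0) + 1
                atom = MappedAtom(met_id, instance, element, per_element[element])
                if aam == 0:
                    unmapped.append(atom)
                    continue
                if aam in by_number:
                    raise MappingError(
                        f"{reaction_id}: map number {aam} duplicated on {side} side"
                    )
                by_number[aam] = atom
        if unmapped:
            msg = f"{reaction_id}: {len(unmapped)} unmapped {side} atoms"
            if not permissive:
                raise MappingError(msg)
            logger.warning(msg)
        return by_number

    subs = collect("substrate")
    prods = collect("product")
    if set(subs) != set(prods):
        lonely = sorted(set(subs) ^ set(prods))
        raise MappingError(
            f"{reaction_id}: mapping numbers {lonely} present on only one side"
        )
    transitions = [(subs[k], prods[k]) for k in sorted(subs)]
    return ReactionAtomMap(reaction_id, transitions)


def parse_rxn_directory(
    directory: str | Path,
    role_assignments: dict[str, RoleAssignment],
    permissive: bool = False,
) -> AtomMappingSet:
    """Parse a directory of rxnfiles (filename stem = reaction id)."""
    out = AtomMappingSet()
    for path in sorted(Path(directory).glob("*.rxn")):
        rid = path.stem
        out.add(parse_rxn_v2000(path.read_text(), rid, role_assignments[rid], permissive))
    return out


# ---------------------------------------------------------------------------
# Native TSV format


def parse_mapping_table(source, network=None) -> AtomMappingSet:
    """Parse the native TSV transition format (or a matching DataFrame).

    When a network is supplied, reaction and metabolite ids are
    cross-validated against it.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        try:
            df = pd.read_csv(source, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            return AtomMappingSet()
    if df.empty:
        return AtomMappingSet()
    if list(df.columns) != TABLE_COLUMNS:
        raise MappingError(
            f"expected columns {TABLE_COLUMNS}, got {list(df.columns)}"
        )
    for col in ("sub_instance", "sub_index", "prod_instance", "prod_index"):
        df[col] = df[col].astype(int)
    out = AtomMappingSet()
    for rid, group in df.groupby("reaction_id", sort=False):
        if network is not None:
            known_rxns = {r.id for r in network.reactions}
            if rid not in known_rxns:
                raise MappingError(f"unknown reaction id {rid!r}")
            known_mets = {m.id for m in network.metabolites}
            for met in set(group["sub_met"]) | set(group["prod_met"]):
                if met not in known_mets:
                    raise MappingError(f"unknown metabolite id {met!r} in map for {rid!r}")
        transitions = [
            (
                MappedAtom(r.sub_met, r.sub_instance, r.element, r.sub_index),
                MappedAtom(r.prod_met, r.prod_instance, r.element, r.prod_index),
            )
            for r in group.itertuples()
        ]
        out.add(ReactionAtomMap(str(rid), transitions))
    return out


def write_mapping_table(mapping_set: AtomMappingSet, path: str | Path | None = None):
    """Serialise to the native TSV format.

    Rows are sorted by ``(reaction_id, element, sub_met, sub_index)`` so
    output is deterministic and ``parse(write(s)) == s``.  Returns the
    DataFrame; also writes it to ``path`` when given.
    """
    rows = []
    for rid in sorted(mapping_set.maps):
        for sub, prod in mapping_set.maps[rid].transitions:
            rows.append(
                (rid, sub.metabolite_id, sub.instance, sub.element, sub.index,
                 prod.metabolite_id, prod.instance, prod.index)
            )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df = df.sort_values(
        ["reaction_id", "element", "sub_met", "sub_index", "sub_instance"],
        kind="stable",
    ).reset_index(drop=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
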