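"""Data model for metabolic networks and exact linear algebra on stoichiometric matrices.

A metabolic network is represented by its total stoichiometric matrix
``S = [N, B]`` where ``N`` (m x u) holds the internal, mass- and
charge-balanced reactions and ``B`` holds the exchange reactions that open
the system to its environment.  Conservation analysis concerns the left
null space of ``N``: every quantity conserved by all internal reactions is
a vector ``l`` with ``N.T @ l = 0``.  Rank and null-space decisions are made
in exact rational arithmetic because conservation vectors are integer
objects and a floating tolerance could silently change dimension counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ConservationVector",
    "NetworkError",
    "load_network",
    "split_matrices",
    "exact_rank",
    "left_nullspace_dim",
    "is_conservation_vector",
    "elemental_matrix",
    "electron_vector",
    "check_elemental_balance",
    "element_sort_key",
    "ATOMIC_NUMBER",
]


class NetworkError(ValueError):
    """Raised for structurally invalid networks or inconsistent inputs."""


# Atomic numbers for elements that occur in metabolic reconstructions.
ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Cr": 24, "Mn": 25,
    "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29, "Zn": 30, "As": 33, "Se": 34,
    "Br": 35, "Mo": 42, "Cd": 48, "I": 53, "W": 74, "Hg": 80,
}

#: Fixed element order for reproducible output: C, H, O, N, then alphabetical.
_ELEMENT_PRIORITY = {"C": 0, "H": 1, "O": 2, "N": 3}


def element_sort_key(symbol: str) -> tuple[int, str]:
    return (_ELEMENT_PRIORITY.get(symbol, 4), symbol)


@dataclass
class Metabolite:
    """A network metabolite.

    ``formula`` maps element symbols to nonnegative atom counts; ``charge``
    is in elementary charges.  Both may be ``None`` for networks used
    without balance checking, but balance and electron operations require
    them.
    """

    id: str
    name: str = ""
    formula: dict[str, int] | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.formula is not None:
            for el, count in self.formula.items():
                if count < 0 or count != int(count):
                    raise NetworkError(
                        f"metabolite {self.id!r}: formula count {el}={count} "
                        "must be a nonnegative integer"
                    )

    def atom_count(self, element: str) -> int:
        if self.formula is None:
            return 0
        return int(self.formula.get(element, 0))

    @property
    def is_massless(self) -> bool:
        """True for placeholder species with an empty formula (photon-like)."""
        return self.formula is not None and sum(self.formula.values()) == 0


@dataclass
class Reaction:
    """A reaction column: ``kind`` is ``"internal"`` or ``"exchange"``.

    Stoichiometric coefficients are negative for substrates and positive
    for products in the designated forward direction.
    """

    id: str
    kind: str
    stoichiometry: dict[str, float]

    def __post_init__(self) -> None:
        if self.kind not in ("internal", "exchange"):
            raise NetworkError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id!r}: empty stoichiometry")
        if self.kind == "internal":
            subs = [m for m, c in self.stoichiometry.items() if c < 0]
            prods = [m for m, c in self.stoichiometry.items() if c > 0]
            if not subs or not prods:
                raise NetworkError(
                    f"internal reaction {self.id!r} needs at least one "
                    "substrate and one product"
                )
            for met, coeff in self.stoichiometry.items():
                if coeff != int(coeff):
                    raise NetworkError(
                        f"internal reaction {self.id!r}: coefficient for "
                        f"{met!r} must be an integer (atom mappings act on "
                        "whole molecules)"
                    )

    @property
    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class MetabolicNetwork:
    """Ordered metabolites (rows) and reactions (columns) of ``S = [N, B]``.

    Internal reactions are moved ahead of exchange reactions on
    construction; the applied column permutation relative to the input
    order is recorded in ``column_permutation``.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    column_permutation: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise NetworkError("duplicate metabolite id")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise NetworkError("duplicate reaction id")
        if not self.reactions:
            raise NetworkError("empty reaction list")
        known = set(met_ids)
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in known:
                    raise NetworkError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
        # Internal-before-exchange convention with a recorded permutation.
        order = sorted(
            range(len(self.reactions)),
            key=lambda j: (0 if self.reactions[j].kind == "internal" else 1, j),
        )
        if order != list(range(len(self.reactions))):
            self.reactions = [self.reactions[j] for j in order]
        self.column_permutation = order
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def m(self) -> int:
        return len(self.metabolites)

    @property
    def n(self) -> int:
        return len(self.reactions)

    @property
    def u(self) -> int:
        return sum(1 for r in self.reactions if r.kind == "internal")

    def metabolite_index(self, met_id: str) -> int:
        return self._met_index[met_id]

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    @property
    def internal_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "internal"]

    @property
    def S(self) -> np.ndarray:
        """Total stoichiometric matrix, metabolites x reactions."""
        S = np.zeros((self.m, self.n))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoichiometry.items():
                S[self._met_index[met], j] = coeff
        if np.all(S == S.astype(np.int64)):
            S = S.astype(np.int64)
        return S

    @property
    def elements(self) -> list[str]:
        """All element symbols in metabolite formulas, in canonical order."""
        symbols = set()
        for met in self.metabolites:
            if met.formula:
                symbols.update(k for k, v in met.formula.items() if v > 0)
        return sorted(symbols, key=element_sort_key)


@dataclass
class ConservationVector:
    """A nonnegative integer vector asserted to lie in the left null space."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if np.any(self.values < 0):
            raise NetworkError(f"conservation vector {self.label!r} has negative entries")


# ---------------------------------------------------------------------------
# Loading


def _network_from_dict(data: Mapping) -> MetabolicNetwork:
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            formula={k: int(v) for k, v in m["formula"].items()} if "formula" in m and m["formula"] is not None else None,
            charge=m.get("charge"),
        )
        for m in data["metabolites"]
    ]
    rxns = [
        Reaction(id=r["id"], kind=r["kind"], stoichiometry=dict(r["stoichiometry"]))
        for r in data["reactions"]
    ]
    return MetabolicNetwork(mets, rxns)


def _network_from_tsv(path: Path, internal_ids: Sequence[str]) -> MetabolicNetwork:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    internal = set(internal_ids)
    unknown = internal - set(df.columns)
    if unknown:
        raise NetworkError(f"internal reaction ids not in matrix: {sorted(unknown)}")
    mets = [Metabolite(id=str(i)) for i in df.index]
    rxns = [
        Reaction(
            id=str(col),
            kind="internal" if col in internal else "exchange",
            stoichiometry={
                str(i): float(v) for i, v in df[col].items() if v != 0
            },
        )
        for col in df.columns
    ]
    return MetabolicNetwork(mets, rxns)


def load_network(
    source: str | Path | Mapping,
    internal_ids: Sequence[str] | None = None,
) -> MetabolicNetwork:
    """Load a network from native JSON, an in-memory dict, or a TSV matrix.

    TSV input is a metabolite-by-reaction coefficient matrix with id
    labels; ``internal_ids`` names the internal columns (the sidecar list).
    """
    if isinstance(source, Mapping):
        return _network_from_dict(source)
    path = Path(source)
    if path.suffix.lower() in (".tsv", ".txt"):
        if internal_ids is None:
            sidecar = path.with_suffix(".internal.txt")
            if not sidecar.exists():
                raise NetworkError(
                    "TSV input requires internal reaction ids "
                    "(internal_ids argument or .internal.txt sidecar)"
                )
            internal_ids = [
                line.strip() for line in sidecar.read_text().splitlines() if line.strip()
            ]
        return _network_from_tsv(path, internal_ids)
    with open(path) as fh:
        return _network_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Linear algebra (exact)


def split_matrices(net: MetabolicNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(N, B)``: the internal and exchange blocks of ``S``."""
    S = net.S
    u = net.u
    N = np.asarray(S[:, :u], dtype=np.int64)
    B = S[:, u:]
    return N, B


def exact_rank(M: np.ndarray) -> int:
    """Rank of an integer/rational matrix by exact rational elimination."""
    M = np.atleast_2d(np.asarray(M))
    if M.size == 0:
        return 0
    return int(sympy.Matrix(M.tolist()).rank())


def left_nullspace_dim(M: np.ndarray) -> int:
    """Dimension of the left null space: ``m - rank(M)``."""
    M = np.atleast_2d(np.asarray(M))
    return M.shape[0] - exact_rank(M)


def is_conservation_vector(N: np.ndarray, v: Iterable) -> bool:
    """True iff ``N.T @ v == 0`` exactly in integer arithmetic."""
    N = np.asarray(N, dtype=np.int64)
    v = np.asarray(list(v) if not isinstance(v, np.ndarray) else v, dtype=np.int64)
    if v.shape[0] != N.shape[0]:
        raise NetworkError(
            f"dimension mismatch: vector has {v.shape[0]} entries, matrix {N.shape[0]} rows"
        )
    return bool(np.all(N.T @ v == 0))


def elemental_matrix(net: MetabolicNetwork, elements: Sequence[str] | None = None) -> np.ndarray:
    """Metabolite x element atom-count matrix ``E``.

    Columns follow the canonical element order (C, H, O, N, then
    alphabetical).  For a fully balanced network every column of ``E`` is a
    conservation vector of ``N``.
    """
    for met in net.metabolites:
        if met.formula is None:
            raise NetworkError(f"metabolite {met.id!r} has no formula")
    if elements is None:
        elements = net.elements
    E = np.zeros((net.m, len(elements)), dtype=np.int64)
    for i, met in enumerate(net.metabolites):
        for j, el in enumerate(elements):
            E[i, j] = met.atom_count(el)
    return E


def electron_vector(net: MetabolicNetwork) -> np.ndarray:
    """Total electrons per metabolite: sum of atomic numbers minus charge."""
    e = np.zeros(net.m, dtype=object)
    for i, met in enumerate(net.metabolites):
        if met.formula is None or met.charge is None:
            raise NetworkError(f"metabolite {met.id!r} needs formula and charge")
        total = 0
        for el, count in met.formula.items():
            if el not in ATOMIC_NUMBER:
                raise NetworkError(f"unknown element symbol {el!r} in {met.id!r}")
            total += ATOMIC_NUMBER[el] * count
        total -= met.charge
        if total < 0:
            raise NetworkError(
                f"metabolite {met.id!r}: negative electron count {total} "
                "(check formula/charge)"
            )
        e[i] = total
    return e.astype(np.int64)


@dataclass
class BalanceReport:
    """Per-internal-reaction element and charge balance."""

    reaction_id: str
    element_sums: dict[str, float]
    charge_sum: float | None
    balanced: bool
    massless_metabolites: list[str] = field(default_factory=list)


def check_elemental_balance(net: MetabolicNetwork) -> list[BalanceReport]:
    """Signed element/charge sums per internal reaction.

    Exchange reactions are exempt: they do not conserve mass or charge.
    Imbalance is reported, not raised.  Massless placeholder metabolites
    (empty formula) are flagged.
    """
    for met in net.metabolites:
        if met.formula is None:
            raise NetworkError(f"metabolite {met.id!r} has no formula")
    elements = net.elements
    reports = []
    for rxn in net.internal_reactions:
        sums = {el: 0.0 for el in elements}
        charge = 0.0
        have_charge = True
        massless = []
        for met_id, coeff in rxn.stoichiometry.items():
            met = net.metabolite(met_id)
            for el in elements:
                sums[el] += coeff * met.atom_count(el)
            if met.charge is None:
                have_charge = False
            else:
                charge += coeff * met.charge
            if met.is_massless:
                massless.append(met_id)
        charge_sum = charge if have_charge else None
        balanced = all(s == 0 for s in sums.values()) and (
            charge_sum is None or charge_sum == 0
        )
        reports.append(
            BalanceReport(rxn.id, sums, charge_sum, balanced, massless)
        )
    return reports
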