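"""Downstream uses of moiety vectors and moiety graphs.

Moiety subnetworks: a moiety vector ``l_k`` decomposes the open network's
stoichiometric matrix by row scaling, ``S(k) = diag(l_k) S``; the result is
mass balanced per internal reaction exactly when ``l_k`` is a conservation
vector of ``N``.  Isotopomer counting: for stable-isotope flux analysis a
metabolite with ``n`` atoms of a tracer element has ``2^n`` atom
isotopomers, while at moiety resolution (a moiety is labelled if any of
its atoms is) the count is ``2^(number of tracer-bearing moiety
instances)`` — typically a reduction by many orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .moiety_identification import MoietyMatrix
from .network_core import MetabolicNetwork

__all__ = [
    "MoietySubnetwork",
    "moiety_subnetwork",
    "subnetwork_mass_balance",
    "atom_isotopomer_count",
    "moiety_isotopomer_count",
    "moiety_instance_count",
]


@dataclass
class MoietySubnetwork:
    """Row-scaled stoichiometric matrix for one moiety's flow."""

    Sk: np.ndarray
    moiety_label: str
    u: int
    active_rows: np.ndarray      # metabolite indices with l_k > 0
    active_columns: np.ndarray   # reaction indices with a nonzero column
    is_graph: bool               # pruned internal part is a graph, not a hypergraph


def moiety_subnetwork(
    S: np.ndarray | MetabolicNetwork,
    l_k,
    u: int | None = None,
    label: str = "",
) -> MoietySubnetwork:
    """``S(k) = diag(l_k) S`` with a graph-vs-hypergraph report.

    The topology test uses the pruned nonzero internal columns only and
    ignores magnitudes: a column is a graph edge iff it has exactly one
    negative and one positive entry.
    """
    if isinstance(S, MetabolicNetwork):
        u = S.u
        S = S.S
    S = np.asarray(S)
    l_k = np.asarray(l_k, dtype=np.int64)
    if l_k.shape[0] != S.shape[0]:
        raise ValueError(
            f"dimension mismatch: vector length {l_k.shape[0]}, matrix rows {S.shape[0]}"
        )
    if np.any(l_k < 0):
        raise ValueError("moiety vector must be nonnegative")
    if u is None:
        u = S.shape[1]
    Sk = np.diag(l_k) @ S
    active_rows = np.flatnonzero(l_k > 0)
    active_columns = np.flatnonzero(np.any(Sk != 0, axis=0))
    is_graph = True
    for j in range(u):
        col = Sk[:, j]
        if np.all(col == 0):
            continue
        if np.sum(col < 0) != 1 or np.sum(col > 0) != 1:
            is_graph = False
            break
    return MoietySubnetwork(Sk, label, u, active_rows, active_columns, is_graph)


def subnetwork_mass_balance(sub: MoietySubnetwork, u: int | None = None) -> np.ndarray:
    """Column sums of the internal part of ``S(k)``.

    The ``j``-th entry equals ``l_k' N[:, j]``; all zeros iff ``l_k`` is a
    conservation vector of ``N``.
    """
    if u is None:
        u = sub.u
    return np.asarray(sub.Sk[:, :u].sum(axis=0))


def atom_isotopomer_count(net: MetabolicNetwork, element: str) -> int:
    """Sum of ``2^n_i`` over metabolites with ``n_i >= 1`` atoms of ``element``.

    Exact big-integer arithmetic: genome-scale counts exceed the float64
    integer range.
    """
    total = 0
    for met in net.metabolites:
        n = met.atom_count(element)
        if n >= 1:
            total += 2 ** n
    return total


def _element_columns(moieties: MoietyMatrix, element: str) -> list[int]:
    return [
        k for k, comp in enumerate(moieties.compositions) if comp.get(element, 0) > 0
    ]


def moiety_isotopomer_count(moieties: MoietyMatrix, element: str) -> int:
    """Isotopomer count at moiety resolution.

    Restricts to moiety columns whose composition contains ``element`` and
    sums ``2^(instances)`` per metabolite containing at least one such
    instance, counting multiplicity from the moiety matrix.
    """
    cols = _element_columns(moieties, element)
    total = 0
    for i in range(moieties.L.shape[0]):
        instances = int(sum(moieties.L[i, k] for k in cols))
        if instances >= 1:
            total += 2 ** instances
    return total


def moiety_instance_count(moieties: MoietyMatrix, element: str) -> int:
    """Total element-bearing moiety instances across all metabolites."""
    cols = _element_columns(moieties, element)
    return int(sum(moieties.L[:, k].sum() for k in cols))
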