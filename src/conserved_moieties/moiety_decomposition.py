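"""Integer-programming decomposition of composite conservation vectors.

A nonnegative integer conservation vector ``l`` of the internal
stoichiometric matrix ``N`` is *composite* if it splits as ``l = x + y``
with both parts nonzero nonnegative integer conservation vectors.  The
split is found by the mixed-integer program

    min 1'x  s.t.  N'x = 0,  x integer,  0 <= x <= l,  1 <= 1'x <= 1'l - 1,

which is infeasible exactly when ``l`` is nondecomposable.  Iterating the
split over all columns of a matrix until every survivor is infeasible
yields the fully decomposed matrix ``D``; the same procedure factorises an
elemental matrix or an electron vector into nondecomposable conservation
vectors.

The MILP is solved with HiGHS (``scipy.optimize.milp``); every solution is
rounded and re-verified in exact integer arithmetic.  Because the
objective does not pin ``x`` down uniquely, the returned split is
canonicalised to the lexicographically smallest optimal ``x`` in
metabolite order, found by sequential bound fixing.  A brute-force
enumeration over the box ``0 <= x <= l`` serves as an independent
nondecomposability oracle for small vectors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, milp

logger = logging.getLogger(__name__)

__all__ = [
    "DecompositionError",
    "SolverError",
    "DecomposedMatrix",
    "decompose_vector",
    "fully_decompose",
    "brute_force_nondecomposable",
    "decompose_matrix",
]


class DecompositionError(ValueError):
    """Input vector violates the conservation precondition."""


class SolverError(RuntimeError):
    """The MILP engine failed for a reason other than proven infeasibility."""


def _as_int_vector(v) -> np.ndarray:
    arr = np.asarray(v)
    out = np.asarray(np.rint(arr), dtype=np.int64)
    if not np.allclose(arr, out, atol=1e-6):
        raise DecompositionError("vector is not integer")
    return out


def _check_conservation(N: np.ndarray, l: np.ndarray, what: str = "input") -> None:
    if np.any(l < 0):
        raise DecompositionError(f"{what} vector has negative entries")
    if np.any(N.T @ l != 0):
        raise DecompositionError(f"{what} vector is not a conservation vector of N")


def _solve(N: np.ndarray, l: np.ndarray, extra_eq: list[tuple[np.ndarray, float]],
           objective: np.ndarray) -> np.ndarray | None:
    """One MILP solve; returns integer x, None if infeasible, raises on failure."""
    m = N.shape[0]
    total = int(l.sum())
    constraints = [
        LinearConstraint(N.T, 0, 0),
        LinearConstraint(np.ones((1, m)), 1, total - 1),
    ]
    for row, val in extra_eq:
        constraints.append(LinearConstraint(row.reshape(1, -1), val, val))
    res = milp(
        c=objective.astype(float),
        constraints=constraints,
        integrality=np.ones(m),
        bounds=(np.zeros(m), l.astype(float)),
    )
    if res.status == 2:  # proven infeasible
        return None
    if res.status != 0 or res.x is None:
        raise SolverError(f"MILP solver failure: status={res.status} ({res.message})")
    x = np.asarray(np.rint(res.x), dtype=np.int64)
    if not np.allclose(res.x, x, atol=1e-4):
        raise SolverError("MILP returned a non-integral solution")
    return x


def decompose_vector(
    N: np.ndarray,
    l,
    canonical: bool = True,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Split ``l`` into conservation vectors ``(x, y)``; None if nondecomposable.

    ``x`` minimises ``1'x``; with ``canonical`` it is additionally the
    lexicographically smallest minimiser in metabolite order.  The zero
    vector is nondecomposable by convention (the strict sum constraint is
    empty).  Both parts are re-verified exactly before returning.
    """
    N = np.asarray(N, dtype=np.int64)
    l = _as_int_vector(l)
    _check_conservation(N, l)
    m = N.shape[0]
    if l.sum() < 2:
        return None
    x = _solve(N, l, [], np.ones(m))
    if x is None:
        return None
    if canonical:
        fixed: list[tuple[np.ndarray, float]] = [
            (np.ones(m), float(x.sum()))  # stay on the optimal objective level
        ]
        for i in range(m):
            obj = np.zeros(m)
            obj[i] = 1.0
            xi = _solve(N, l, fixed, obj)
            if xi is None:  # cannot happen: current x satisfies the constraints
                raise SolverError("canonicalisation lost feasibility")
            unit = np.zeros(m)
            unit[i] = 1.0
            fixed.append((unit, float(xi[i])))
            x = xi
    y = l - x
    _check_conservation(N, x, "solution x")
    _check_conservation(N, y, "solution y")
    if x.sum() == 0 or y.sum() == 0:
        raise SolverError("MILP returned a trivial split")
    return x, y


@dataclass
class DecomposedMatrix:
    """Fully decomposed matrix with split provenance.

    ``D`` holds the distinct nondecomposable columns; ``multiplicity[j]``
    counts how many times column ``j`` was produced.  ``provenance`` is a
    tree per input column recording each split.
    """

    D: np.ndarray
    multiplicity: list[int]
    provenance: list[dict] = field(default_factory=list)

    @property
    def t(self) -> int:
        return self.D.shape[1]

    def column_set(self) -> set[tuple]:
        return {tuple(self.D[:, j]) for j in range(self.t)}


def _decompose_column(N: np.ndarray, l: np.ndarray, label: str) -> tuple[list[np.ndarray], dict]:
    """Iteratively split one column to nondecomposable parts (depth first)."""
    node: dict = {"label": label, "vector": l.tolist()}
    split = decompose_vector(N, l)
    if split is None:
        node["status"] = "nondecomposable"
        return [l], node
    x, y = split
    node["status"] = "split"
    parts_x, child_x = _decompose_column(N, x, label + ".x")
    parts_y, child_y = _decompose_column(N, y, label + ".y")
    node["children"] = [child_x, child_y]
    return parts_x + parts_y, node


def fully_decompose(N: np.ndarray, L) -> DecomposedMatrix:
    """Replace decomposable columns of ``L`` by their parts until none remain.

    Termination is guaranteed because each split strictly reduces the
    entry sum of both parts.  Identical output columns are collapsed in
    ``D``; their multiplicity and the split tree are kept in provenance.
    """
    N = np.asarray(N, dtype=np.int64)
    L = np.atleast_2d(np.asarray(L, dtype=np.int64))
    if L.shape[0] != N.shape[0]:
        L = L.T
    columns: list[np.ndarray] = []
    provenance: list[dict] = []
    for k in range(L.shape[1]):
        l = L[:, k]
        _check_conservation(N, l, f"column {k}")
        parts, tree = _decompose_column(N, l, f"L{k}")
        columns.extend(parts)
        provenance.append(tree)
        logger.info("column %d: %s into %d part(s)",
                    k, tree["status"], len(parts))
    seen: dict[tuple, int] = {}
    uniq: list[np.ndarray] = []
    multiplicity: list[int] = []
    for col in columns:
        key = tuple(col)
        if key in seen:
            multiplicity[seen[key]] += 1
        else:
            seen[key] = len(uniq)
            uniq.append(col)
            multiplicity.append(1)
    D = np.stack(uniq, axis=1) if uniq else np.zeros((N.shape[0], 0), dtype=np.int64)
    return DecomposedMatrix(D, multiplicity, provenance)


def brute_force_nondecomposable(
    N: np.ndarray,
    l,
    cap: int = 64,
) -> tuple[bool, tuple[np.ndarray, np.ndarray] | None]:
    """Exhaustive nondecomposability oracle over the box ``0 <= x <= l``.

    Enumerating unit splits ``x + y = l`` suffices to certify
    nondecomposability: any decomposition with positive integer weights
    yields such a split.  Returns ``(True, None)`` if no split exists,
    else ``(False, (x, y))`` with a witness.  Independent of the MILP
    path; intended for small vectors (``sum(l) <= cap``).
    """
    N = np.asarray(N, dtype=np.int64)
    l = _as_int_vector(l)
    _check_conservation(N, l)
    if int(l.sum()) > cap:
        raise ValueError(f"sum(l)={int(l.sum())} exceeds cap={cap}")
    ranges = [range(int(v) + 1) for v in l]
    for combo in itertools.product(*ranges):
        x = np.asarray(combo, dtype=np.int64)
        s = x.sum()
        if s == 0 or s == l.sum():
            continue
        if np.all(N.T @ x == 0):
            return False, (x, l - x)
    return True, None


def decompose_matrix(N: np.ndarray, M) -> DecomposedMatrix:
    """Fully decompose a matrix of conservation-vector columns.

    Applies to the moiety matrix, the elemental matrix of a balanced
    network, and (as a single column) the electron vector.  A column that
    is not a conservation vector of ``N`` (e.g. from an unbalanced
    network) raises :class:`DecompositionError`.
    """
    return fully_decompose(N, M)
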