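"""Interpretive Structural Modeling (ISM).

Turns expert pairwise influence judgments into a multi-level hierarchy:
relation codes V/A/X/O become a binary adjacency matrix A; the reachability
matrix M is the reflexive transitive closure (A + I)^k computed by Boolean
squaring to a fixed point; row/column reads of M give each factor's reachable
set R(Fi) and antecedent set Q(Fi); iterative extraction of factors with
R(Fi) ∩ Q(Fi) = R(Fi) partitions the system into levels; and the hierarchy
digraph is the transitive reduction of the strict reachability relation.

Level semantics: the extraction rule removes sinks first, so level 1 is the
*surface* (consequence) layer and the last level holds the root causes. Some
ISM literature numbers from the root end; this package does not.

Matrices are pandas DataFrames of 0/1 with factor ids as both index and
columns (plain arrays are accepted and labelled F1..Fn). Factor ids are
1-based in all I/O; positional indexing stays internal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "RELATION_CODES",
    "build_adjacency",
    "transitive_closure",
    "reachability_from_sets",
    "check_closure",
    "is_closed",
    "factor_sets",
    "LevelPartition",
    "partition_levels",
    "transitive_reduction_edges",
    "HierarchyDigraph",
    "hierarchy_digraph",
    "InterpretiveStructuralModel",
]

RELATION_CODES = ("V", "A", "X", "O")


def _to_frame(matrix, binary: bool = True) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        df = matrix.copy()
        if list(df.index) != list(df.columns):
            raise ValueError("matrix index and columns must carry the same factor ids")
    else:
        arr = np.asarray(matrix)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("matrix must be square")
        ids = [f"F{i + 1}" for i in range(arr.shape[0])]
        df = pd.DataFrame(arr, index=ids, columns=ids)
    if binary:
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        df = df.astype(int)
    return df


def build_adjacency(
    relations: Iterable[tuple[str, str, str]], factor_ids: Sequence[str]
) -> pd.DataFrame:
    """Build the binary adjacency matrix A from relation codes.

    Each relation is ``(Fi, Fj, code)`` with code V (i influences j → a_ij=1),
    A (j influences i → a_ji=1), X (both), O (neither). Unlisted pairs default
    to O; the diagonal is 0. A pair listed twice is an error (the two expert
    codings cannot be reconciled mechanically).
    """
    ids = list(factor_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("factor_ids contains duplicates")
    pos = {f: i for i, f in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)), dtype=int)
    seen: dict[frozenset, tuple] = {}
    for fi, fj, code in relations:
        if fi not in pos or fj not in pos:
            unknown = fi if fi not in pos else fj
            raise ValueError(f"unknown factor id {unknown!r}")
        if fi == fj:
            raise ValueError(f"self-relation on {fi!r} is not allowed (diagonal is 0)")
        if code not in RELATION_CODES:
            raise ValueError(f"invalid relation code {code!r} for pair ({fi}, {fj})")
        key = frozenset((fi, fj))
        if key in seen:
            raise ValueError(
                f"pair ({fi}, {fj}) listed more than once "
                f"(previously as {seen[key]})"
            )
        seen[key] = (fi, fj, code)
        i, j = pos[fi], pos[fj]
        if code == "V":
            A[i, j] = 1
        elif code == "A":
            A[j, i] = 1
        elif code == "X":
            A[i, j] = A[j, i] = 1
    return pd.DataFrame(A, index=ids, columns=ids)


def transitive_closure(adjacency) -> pd.DataFrame:
    """Reachability matrix M = (A + I)^k by Boolean squaring to a fixed point.

    The result is reflexive and transitively closed; at most ``ceil(log2 n)``
    squarings are needed.
    """
    A = _to_frame(adjacency)
    M = A.to_numpy().astype(bool) | np.eye(len(A), dtype=bool)
    while True:
        M2 = M @ M  # boolean matmul: OR of ANDs
        if np.array_equal(M2, M):
            break
        M = M2
    return pd.DataFrame(M.astype(int), index=A.index, columns=A.columns)


def reachability_from_sets(reachable_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Build M directly from per-factor reachable sets: M[i][j]=1 iff Fj ∈ R(Fi).

    Used when a published reachability table is available but the adjacency
    matrix behind it is not. The result is *not* assumed transitively closed
    — run :func:`check_closure` (the estimator does this automatically).
    Every factor must list itself (M is reflexive by definition).
    """
    ids = list(reachable_sets)
    known = set(ids)
    M = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for f, reach in reachable_sets.items():
        members = set(reach)
        if f not in members:
            raise ValueError(f"factor {f!r} missing from its own reachable set")
        stray = members - known
        if stray:
            raise ValueError(f"reachable set of {f!r} names unknown factors {sorted(stray)}")
        M.loc[f, sorted(members, key=ids.index)] = 1
    return M


def check_closure(M) -> list[tuple[str, str, str]]:
    """List transitivity violations (i, j, k) with M[i][j]=M[j][k]=1, M[i][k]=0.

    Empty list iff M is transitively closed.
    """
    df = _to_frame(M)
    vals = df.to_numpy(dtype=bool)
    two_step = vals @ vals
    viol_cells = two_step & ~vals
    out: list[tuple[str, str, str]] = []
    ids = list(df.index)
    for i, k in zip(*np.nonzero(viol_cells)):
        for j in np.nonzero(vals[i] & vals[:, k])[0]:
            out.append((ids[i], ids[j], ids[k]))
    return out


def is_closed(M) -> bool:
    df = _to_frame(M)
    vals = df.to_numpy(dtype=bool)
    return bool(np.array_equal(vals @ vals | vals, vals))


def factor_sets(M) -> pd.DataFrame:
    """Reachable, antecedent and intersection sets of every factor.

    Row reads of M give R(Fi), column reads give Q(Fi); both contain Fi
    itself. Returns a DataFrame indexed by factor with columns ``reachable``,
    ``antecedent`` and ``intersection`` holding frozensets.
    """
    df = _to_frame(M)
    if not (np.diag(df.to_numpy()) == 1).all():
        raise ValueError("reachability matrix must have a unit diagonal")
    ids = list(df.index)
    reach = {f: frozenset(df.columns[df.loc[f].to_numpy() == 1]) for f in ids}
    ante = {f: frozenset(df.index[df[f].to_numpy() == 1]) for f in ids}
    return pd.DataFrame(
        {
            "reachable": [reach[f] for f in ids],
            "antecedent": [ante[f] for f in ids],
            "intersection": [reach[f] & ante[f] for f in ids],
        },
        index=ids,
    )


@dataclass(frozen=True)
class LevelPartition:
    """Ordered disjoint levels, surface (level 1) first."""

    levels: tuple[tuple[str, ...], ...]
    level_of: Mapping[str, int]

    def __len__(self) -> int:
        return len(self.levels)


def partition_levels(M, reclose: bool = False) -> LevelPartition:
    """Partition factors into hierarchy levels by iterative extraction.

    In each round every remaining factor whose reachable set (on the
    remaining submatrix) is contained in its antecedent set — i.e.
    R(Fi) ∩ Q(Fi) = R(Fi) — is extracted into the current level, removed,
    and the sets recomputed. Level 1 therefore holds the surface
    (consequence) factors and the final level the roots.

    A non-closed M is processed as given, with a warning (published
    reachability tables are sometimes not perfectly closed yet still yield
    the published hierarchy under this rule); pass ``reclose=True`` to close
    it first. A round that extracts nothing (possible only on non-closed
    input) raises, naming the stuck factors.
    """
    df = _to_frame(M)
    if reclose:
        strict = df.copy()
        df = transitive_closure(strict)
    elif not is_closed(df):
        warnings.warn(
            "reachability matrix is not transitively closed; partitioning it "
            "as given (pass reclose=True to re-close first)",
            stacklevel=2,
        )
    order = {f: i for i, f in enumerate(df.index)}
    remaining = list(df.index)
    levels: list[tuple[str, ...]] = []
    level_of: dict[str, int] = {}
    while remaining:
        sub = df.loc[remaining, remaining]
        vals = sub.to_numpy(dtype=bool)
        extracted = [
            f
            for i, f in enumerate(remaining)
            if not np.any(vals[i] & ~vals[:, i])  # R(f) ⊆ Q(f)
        ]
        if not extracted:
            raise ValueError(
                "level extraction is stuck (no factor satisfies R∩Q=R); "
                f"remaining factors: {remaining} — the matrix is not "
                "transitively closed; consider reclose=True"
            )
        extracted.sort(key=order.__getitem__)
        levels.append(tuple(extracted))
        for f in extracted:
            level_of[f] = len(levels)
        remaining = [f for f in remaining if f not in level_of]
    return LevelPartition(levels=tuple(levels), level_of=level_of)


def transitive_reduction_edges(M) -> list[tuple[str, str]]:
    """Transitive reduction of the strict (off-diagonal) reachability relation.

    An edge (i, j) is kept iff there is no intermediate k with i→k and k→j.
    For a transitively closed acyclic relation this is the unique minimal
    edge set with the same closure. Mutually reachable pairs are rejected
    (the reduction of a cyclic relation is not unique). Edges are ordered by
    ascending (source, target) factor position.
    """
    df = _to_frame(M)
    vals = df.to_numpy(dtype=bool)
    strict = vals & ~np.eye(len(df), dtype=bool)
    if np.any(strict & strict.T):
        i, j = np.argwhere(strict & strict.T)[0]
        raise ValueError(
            f"mutual reachability between {df.index[i]!r} and {df.index[j]!r}; "
            "transitive reduction requires an acyclic relation"
        )
    two_step = strict @ strict
    keep = strict & ~two_step
    ids = list(df.index)
    return [(ids[i], ids[j]) for i, j in np.argwhere(keep)]


@dataclass(frozen=True)
class HierarchyDigraph:
    """Level-grouped hierarchy: nodes per level plus reduced edge set."""

    nodes_by_level: tuple[tuple[str, ...], ...]
    edges: tuple[tuple[str, str], ...]

    def to_dot(self, labels: Mapping[str, str] | None = None) -> str:
        """Emit Graphviz DOT with one ``rank=same`` group per level.

        Arrows point from influencing (deeper) factors toward the surface,
        mirroring stepwise risk transmission.
        """
        lines = ["digraph hierarchy {", "  rankdir=BT;", "  node [shape=box];"]
        for lvl, nodes in enumerate(self.nodes_by_level, start=1):
            decls = []
            for n in nodes:
                if labels and n in labels:
                    decls.append(f'"{n}" [label="{n}: {labels[n]}"];')
                else:
                    decls.append(f'"{n}";')
            lines.append(f"  subgraph level_{lvl} {{ rank=same; " + " ".join(decls) + " }")
        for src, tgt in self.edges:
            lines.append(f'  "{src}" -> "{tgt}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


def hierarchy_digraph(M, partition: LevelPartition | None = None) -> HierarchyDigraph:
    """Hierarchy digraph: levels from :func:`partition_levels`, edges from the
    transitive reduction of the strict reachability relation."""
    df = _to_frame(M)
    if partition is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            partition = partition_levels(df)
    missing = set(df.index) - set(partition.level_of)
    if missing:
        raise ValueError(f"partition does not cover factors {sorted(missing)}")
    return HierarchyDigraph(
        nodes_by_level=partition.levels,
        edges=tuple(transitive_reduction_edges(df)),
    )


class InterpretiveStructuralModel(BaseEstimator):
    """ISM as an estimator: fit on an influence matrix, read the hierarchy.

    Parameters
    ----------
    input : {"adjacency", "reachability"}
        Whether ``fit`` receives the direct-influence adjacency matrix A
        (closed internally) or an already-reachability matrix M (e.g. one
        reconstructed from published reachable sets).
    reclose : bool
        With ``input="reachability"``, re-close a non-closed M before
        partitioning instead of warning.

    Fitted attributes
    -----------------
    ``reachability_`` (DataFrame), ``closed_`` (bool), ``violations_``
    (transitivity violations of the *input* reachability, empty when closed),
    ``factor_sets_`` (DataFrame), ``partition_`` (:class:`LevelPartition`),
    ``levels_``, ``level_of_``, ``digraph_`` (:class:`HierarchyDigraph`).
    """

    def __init__(self, input: str = "adjacency", reclose: bool = False):
        self.input = input
        self.reclose = reclose

    def fit(self, X, y=None):
        df = _to_frame(X)
        if self.input == "adjacency":
            if not (np.diag(df.to_numpy()) == 0).all():
                raise ValueError("adjacency matrix must have a zero diagonal")
            self.adjacency_ = df
            M = transitive_closure(df)
        elif self.input == "reachability":
            M = df
        else:
            raise ValueError(f"unknown input kind {self.input!r}")
        self.violations_ = check_closure(M)
        self.closed_ = not self.violations_
        partition = partition_levels(M, reclose=self.reclose) if not self.closed_ else partition_levels(M)
        if self.reclose and not self.closed_:
            M = transitive_closure(M)
        self.reachability_ = M
        self.factor_sets_ = factor_sets(M)
        self.partition_ = partition
        self.levels_ = partition.levels
        self.level_of_ = partition.level_of
        self.digraph_ = hierarchy_digraph(M, partition)
        self.n_features_in_ = df.shape[1]
        return self
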