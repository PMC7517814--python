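"""Breeding pedigrees and additive genetic relationship matrices.

A pedigree records, for every individual, its sire (pollen donor), dam
(pollen receiver), generation and line/treatment label.  From a validated
pedigree the expected additive relationship matrix ``A`` is computed with
the tabular method

    A[j, j] = 1 + 0.5 * A[sire(j), dam(j)]
    A[i, j] = 0.5 * (A[i, sire(j)] + A[i, dam(j)])   for i preceding j,

with unknown parents contributing zero.  The diagonal equals 1 + F where F
is the individual's inbreeding coefficient.  Selfed offspring (sire == dam)
are handled by the same recursion (F = 0.5 * A[p, p]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "validate_pedigree",
    "build_a_matrix",
    "read_pedigree",
]

#: tokens normalized to "unknown parent" when reading pedigree files
UNKNOWN_TOKENS = {"", "0", "na", "nan", "none", None}


class PedigreeError(ValueError):
    """Raised when a pedigree violates its structural invariants."""


def _norm_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s.lower() in UNKNOWN_TOKENS:
        return None
    return s


@dataclass(frozen=True)
class Pedigree:
    """A validated, topologically ordered breeding pedigree.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``id, sire, dam, generation, line``; ``sire``/``dam`` hold
        ``None`` for unknown (founder) parents.  Rows are ordered parents
        before offspring after :func:`validate_pedigree`.
    """

    frame: pd.DataFrame = field(repr=False)

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build and validate from an iterable of
        ``(id, sire, dam, generation, line)`` tuples."""
        frame = pd.DataFrame(
            records, columns=["id", "sire", "dam", "generation", "line"]
        )
        return validate_pedigree(cls(frame))

    @property
    def ids(self) -> list:
        return list(self.frame["id"])

    @property
    def n(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return self.n

    @property
    def founders(self) -> list:
        f = self.frame
        mask = f["sire"].isna() & f["dam"].isna()
        return list(f.loc[mask, "id"])

    def subset_line(self, line, keep_ancestors: bool = True) -> "Pedigree":
        """Pedigree of one line, optionally with all its ancestors.

        The three artificial-selection lines may share the parental
        generation; ``keep_ancestors`` pulls shared founders in so that the
        relationship matrix of the line is complete.
        """
        f = self.frame
        keep = set(f.loc[f["line"] == line, "id"])
        if keep_ancestors:
            parent_of = {
                r.id: (r.sire, r.dam) for r in f.itertuples(index=False)
            }
            stack = list(keep)
            while stack:
                ind = stack.pop()
                for p in parent_of.get(ind, (None, None)):
                    if p is not None and not pd.isna(p) and p not in keep:
                        keep.add(p)
                        stack.append(p)
        sub = f[f["id"].isin(keep)].reset_index(drop=True)
        if not keep_ancestors:
            # parents outside the subset become unknown (treated as founders)
            for col in ("sire", "dam"):
                sub.loc[~sub[col].isin(keep), col] = None
        return validate_pedigree(Pedigree(sub))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["sire"] = out["sire"].fillna("")
        out["dam"] = out["dam"].fillna("")
        out.to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    """Read ``id,sire,dam,generation,line`` CSV; empty or "0" parent means
    unknown (founder)."""
    frame = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    missing = {"id", "sire", "dam", "generation", "line"} - set(frame.columns)
    if missing:
        raise PedigreeError(f"pedigree file lacks columns: {sorted(missing)}")
    return validate_pedigree(Pedigree(frame))


def validate_pedigree(pedigree: Pedigree) -> Pedigree:
    """Check invariants and return a topologically ordered pedigree.

    Raises
    ------
    PedigreeError
        On duplicate ids, unknown parent references, cycles (including an
        individual being its own ancestor), or a parent whose generation is
        not strictly below its offspring's.
    """
    f = pedigree.frame.copy()
    f["id"] = f["id"].astype(str).str.strip()
    for col in ("sire", "dam"):
        f[col] = f[col].map(_norm_parent)
    f["generation"] = f["generation"].astype(int)

    ids = f["id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise PedigreeError(f"duplicate individual id: {dup!r}")
    known = set(ids)
    gen = dict(zip(f["id"], f["generation"]))

    graph = nx.DiGraph()
    graph.add_nodes_from(ids)
    for row in f.itertuples(index=False):
        for parent in (row.sire, row.dam):
            if parent is None:
                continue
            if parent not in known:
                raise PedigreeError(
                    f"parent {parent!r} of {row.id!r} is not an individual "
                    "and not flagged unknown"
                )
            if parent == row.id:
                raise PedigreeError(f"{row.id!r} is its own parent")
            if gen[parent] >= row.generation:
                raise PedigreeError(
                    f"parent {parent!r} (generation {gen[parent]}) not "
                    f"before offspring {row.id!r} (generation {row.generation})"
                )
            graph.add_edge(parent, row.id)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise PedigreeError(f"pedigree contains a cycle: {cycle}")

    order = {ind: k for k, ind in enumerate(nx.topological_sort(graph))}
    f = f.iloc[np.argsort([order[i] for i in f["id"]], kind="stable")]
    return Pedigree(f.reset_index(drop=True))


@dataclass(frozen=True)
class RelationshipMatrix:
    """Expected additive relatedness ``A`` over an ordered set of ids.

    ``A`` is symmetric PSD; diagonal entries equal ``1 + F`` (F = inbreeding
    coefficient); founders are mutually unrelated (off-diagonal 0).
    """

    ids: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(
            self, "_index", {ind: k for k, ind in enumerate(self.ids)}
        )

    @property
    def n(self) -> int:
        return len(self.ids)

    def loc(self, i, j) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def inbreeding(self) -> pd.Series:
        """F per individual (diagonal minus one)."""
        return pd.Series(np.diag(self.values) - 1.0, index=list(self.ids))

    def restrict(self, ids) -> "RelationshipMatrix":
        """Submatrix over ``ids`` (a valid relatedness matrix itself)."""
        idx = [self._index[i] for i in ids]
        return RelationshipMatrix(tuple(ids), self.values[np.ix_(idx, idx)])


def build_a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Tabular (recursive) additive relationship matrix.

    The pedigree must be validated/topologically ordered; unknown parents
    contribute zero relatedness.
    """
    f = pedigree.frame
    ids = list(f["id"])
    index = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    sires = [None if pd.isna(s) else index[s] for s in f["sire"]]
    dams = [None if pd.isna(d) else index[d] for d in f["dam"]]
    for j in range(n):
        s, d = sires[j], dams[j]
        a[j, j] = 1.0 + (0.5 * a[s, d] if s is not None and d is not None else 0.0)
        for i in range(j):
            val = 0.0
            if s is not None:
                val += 0.5 * a[i, s]
            if d is not None:
                val += 0.5 * a[i, d]
            a[i, j] = a[j, i] = val
    return RelationshipMatrix(tuple(ids), a)
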