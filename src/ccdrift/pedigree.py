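"""Cells, pedigrees and census time series.

A pedigree is a forest of binary lineage trees: every division produces
exactly two progeny, and a cell is a member of the population on the
half-open interval ``[birth_time, division_time)`` so that counts are
unambiguous at division instants.  Family-relationship vocabulary follows
the usual convention for cell lineages: the two progeny of one parent are
a *sibling pair*; cells whose parents are siblings are *cousins*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Cell",
    "Pedigree",
    "CensusSeries",
    "RELATIONS",
    "extract_pairs",
    "census_from_pedigree",
    "progeny_fractions",
]

RELATIONS = ("parent_progeny", "sibling", "cousin", "grandparent")

#: columns of the on-disk pedigree table (External interface)
PEDIGREE_COLUMNS = [
    "cell_id",
    "parent_id",
    "birth_time",
    "t_g1",
    "t_sg2m",
    "c0",
    "g0",
    "c_end",
    "g_end",
]


@dataclass
class Cell:
    """One node of a pedigree.

    Phase durations are in hours; fluorescence amounts in arbitrary units.
    ``t_cycle`` is always ``t_g1 + t_sg2m`` and the division time is
    ``birth_time + t_cycle``.  ``ancestor_id`` is the id of the lineage
    root (roots carry their own id) so descendant fractions can be tallied
    per founding cell.
    """

    id: str
    parent_id: str | None
    birth_time: float
    t_g1: float
    t_sg2m: float
    ancestor_id: str | None = None
    c0: float = 0.0
    g0: float = 0.0
    c_end: float = 0.0
    g_end: float = 0.0
    p_c: float = 0.0
    p_g: float = 0.0

    @property
    def t_cycle(self) -> float:
        return self.t_g1 + self.t_sg2m

    @property
    def division_time(self) -> float:
        return self.birth_time + self.t_cycle


class PedigreeError(ValueError):
    pass


class Pedigree:
    """A forest of cells indexed by id, with binary divisions.

    Validity: acyclic parent links, every non-root's parent present, each
    parent has 0 or 2 progeny.  ``ancestor_id`` is filled in from the
    roots if the cells do not carry it.
    """

    def __init__(self, cells: Iterable[Cell], validate: bool = True):
        self._cells: dict[str, Cell] = {}
        for c in cells:
            if c.id in self._cells:
                raise PedigreeError(f"duplicate cell id {c.id!r}")
            self._cells[c.id] = c
        self._children: dict[str, list[str]] = {cid: [] for cid in self._cells}
        self.roots: list[str] = []
        for c in self._cells.values():
            if c.parent_id is None:
                self.roots.append(c.id)
            else:
                if c.parent_id not in self._cells:
                    raise PedigreeError(
                        f"cell {c.id!r} references missing parent {c.parent_id!r}"
                    )
                self._children[c.parent_id].append(c.id)
        for cid in self._children:
            self._children[cid].sort()
        self.roots.sort()
        if validate:
            self._validate()
        self._assign_ancestors()

    # -- construction / io ------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Pedigree":
        cells = []
        for row in df.itertuples(index=False):
            pid = getattr(row, "parent_id", None)
            if pid is None or (isinstance(pid, float) and np.isnan(pid)) or pid == "":
                pid = None
            else:
                pid = str(pid)
            cells.append(
                Cell(
                    id=str(row.cell_id),
                    parent_id=pid,
                    birth_time=float(row.birth_time),
                    t_g1=float(row.t_g1),
                    t_sg2m=float(row.t_sg2m),
                    c0=float(getattr(row, "c0", 0.0)),
                    g0=float(getattr(row, "g0", 0.0)),
                    c_end=float(getattr(row, "c_end", 0.0)),
                    g_end=float(getattr(row, "g_end", 0.0)),
                )
            )
        return cls(cells)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls.from_dataframe(pd.read_csv(path, dtype={"cell_id": str, "parent_id": str}))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells():
            rows.append(
                {
                    "cell_id": c.id,
                    "parent_id": "" if c.parent_id is None else c.parent_id,
                    "birth_time": c.birth_time,
                    "t_g1": c.t_g1,
                    "t_sg2m": c.t_sg2m,
                    "c0": c.c0,
                    "g0": c.g0,
                    "c_end": c.c_end,
                    "g_end": c.g_end,
                }
            )
        return pd.DataFrame(rows, columns=PEDIGREE_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self._cells)

    def __contains__(self, cid: str) -> bool:
        return cid in self._cells

    def __getitem__(self, cid: str) -> Cell:
        return self._cells[cid]

    def cells(self) -> list[Cell]:
        return [self._cells[cid] for cid in sorted(self._cells)]

    def children_of(self, cid: str) -> list[str]:
        return list(self._children[cid])

    def divided(self) -> list[Cell]:
        """Cells with (two) observed progeny."""
        return [self._cells[cid] for cid in sorted(self._cells) if self._children[cid]]

    # -- internals ---------------------------------------------------------
    def _validate(self) -> None:
        if not self._cells:
            raise PedigreeError("empty pedigree")
        for cid, kids in self._children.items():
            if len(kids) not in (0, 2):
                raise PedigreeError(
                    f"cell {cid!r} has {len(kids)} progeny; divisions are binary"
                )
        # acyclicity: walk to root, at most |cells| hops
        n = len(self._cells)
        for cid in self._cells:
            cur, hops = cid, 0
            while self._cells[cur].parent_id is not None:
                cur = self._cells[cur].parent_id
                hops += 1
                if hops > n:
                    raise PedigreeError("pedigree cycle detected")
        for c in self._cells.values():
            if c.t_g1 <= 0 or c.t_sg2m <= 0:
                raise PedigreeError(f"cell {c.id!r} has non-positive phase duration")
            if c.parent_id is not None:
                par = self._cells[c.parent_id]
                if not np.isclose(c.birth_time, par.division_time, atol=1e-9):
                    raise PedigreeError(
                        f"cell {c.id!r} birth time does not equal parent division time"
                    )

    def _assign_ancestors(self) -> None:
        for rid in self.roots:
            stack = [rid]
            while stack:
                cid = stack.pop()
                self._cells[cid].ancestor_id = rid if cid == rid else (
                    self._cells[self._cells[cid].parent_id].ancestor_id
                )
                stack.extend(self._children[cid])


# -- relationship extraction ----------------------------------------------

def _pair_ids(pedigree: Pedigree, relation: str) -> list[tuple[str, str]]:
    if relation == "parent_progeny":
        return [
            (p.id, kid)
            for p in pedigree.divided()
            for kid in pedigree.children_of(p.id)
        ]
    if relation == "sibling":
        return [tuple(pedigree.children_of(p.id)) for p in pedigree.divided()]
    if relation == "cousin":
        # all four cross pairs of the two sibling sets
        pairs = []
        for gp in pedigree.divided():
            k1, k2 = pedigree.children_of(gp.id)
            g1, g2 = pedigree.children_of(k1), pedigree.children_of(k2)
            pairs.extend(itertools.product(g1, g2))
        return pairs
    if relation == "grandparent":
        pairs = []
        for gp in pedigree.divided():
            for kid in pedigree.children_of(gp.id):
                for gkid in pedigree.children_of(kid):
                    pairs.append((gp.id, gkid))
        return pairs
    raise ValueError(f"unknown relation {relation!r}; expected one of {RELATIONS}")


def extract_pairs(
    pedigree: Pedigree,
    relation: str,
    value: str = "t_cycle",
) -> list[tuple[float, float]]:
    """Return (value_a, value_b) for every qualifying pair, once each.

    ``value`` names a :class:`Cell` attribute (``t_g1``, ``t_sg2m``,
    ``t_cycle``, ``p_c``, ...).  Sibling and cousin pairs are returned
    unordered (one orientation each); correlation estimators symmetrize
    them downstream.
    """
    pairs = _pair_ids(pedigree, relation)
    return [
        (getattr(pedigree[a], value), getattr(pedigree[b], value)) for a, b in pairs
    ]


# -- census ----------------------------------------------------------------

@dataclass
class CensusSeries:
    """Population counts on a time grid, total and per ancestor.

    ``counts[aid]`` is aligned with ``times``.  Counts use the half-open
    membership convention; with no cell death they are non-decreasing and
    the per-ancestor counts sum to the total.
    """

    times: np.ndarray
    total: np.ndarray
    per_ancestor: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"time": self.times, "total": self.total}
        for aid in sorted(self.per_ancestor):
            data[aid] = self.per_ancestor[aid]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CensusSeries":
        anc = {
            str(c): df[c].to_numpy(float)
            for c in df.columns
            if c not in ("time", "total")
        }
        return cls(df["time"].to_numpy(float), df["total"].to_numpy(float), anc)

    @classmethod
    def from_csv(cls, path) -> "CensusSeries":
        return cls.from_dataframe(pd.read_csv(path))


def _counts_on_grid(births: np.ndarray, divisions: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """#(cells with birth <= t < division) per grid point, O((n+m) log n).

    ``divisions`` may be +inf for cells still alive at the horizon.
    """
    b = np.sort(births)
    d = np.sort(divisions[np.isfinite(divisions)])
    return np.searchsorted(b, grid, side="right") - np.searchsorted(d, grid, side="right")


def census_from_pedigree(pedigree: Pedigree, time_grid: Sequence[float]) -> CensusSeries:
    """Tabulate total and per-ancestor cell counts on ``time_grid``.

    Leaves (cells with no recorded progeny) count as alive from their
    birth onward — their division lies beyond the observation horizon.
    """
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("time_grid must be a non-empty 1-d sequence")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    if len(pedigree) == 0:
        raise PedigreeError("empty pedigree")

    per_anc: dict[str, np.ndarray] = {}
    total = np.zeros_like(grid)
    for rid in pedigree.roots:
        births, divs = [], []
        stack = [rid]
        while stack:
            cid = stack.pop()
            cell = pedigree[cid]
            kids = pedigree.children_of(cid)
            births.append(cell.birth_time)
            divs.append(cell.division_time if kids else np.inf)
            stack.extend(kids)
        counts = _counts_on_grid(np.array(births), np.array(divs), grid)
        per_anc[rid] = counts.astype(float)
        total += counts
    return CensusSeries(grid, total, per_anc)


def progeny_fractions(census: CensusSeries, t: float) -> pd.Series:
    """Per-ancestor fractions of the population at time ``t``.

    ``t`` snaps to the last census point <= t.  Fractions are >= 0 and sum
    to 1 (within floating tolerance).
    """
    if t < census.times[0]:
        raise ValueError(f"t={t} precedes the census range start {census.times[0]}")
    idx = int(np.searchsorted(census.times, t, side="right") - 1)
    tot = census.total[idx]
    if tot <= 0:
        raise ValueError(f"total count at t={t} is not positive")
    keys = sorted(census.per_ancestor)
    vals = np.array([census.per_ancestor[k][idx] for k in keys], dtype=float)
    return pd.Series(vals / tot, index=keys, name=f"fraction@{t}")
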