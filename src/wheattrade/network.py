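"""Directed, unweighted trade-network state over a fixed world pool of countries.

The network is the model's central container: a set of directed edges
``(importer, exporter)`` over a fixed pool of ``N`` countries (default 244,
roughly the number of countries and territories in the world), with no
self-loops and no duplicate edges.  Reciprocal trade — ``i`` imports from
``j`` and ``j`` imports from ``i`` — is two distinct edges.

Degree bookkeeping is incremental: in-, out- and total degree are updated on
every edge addition/removal, because the preferential-attachment fitness of a
country is its total degree divided by the current edge count and is re-read
after every event.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import (
    DuplicateEdgeError,
    MissingEdgeError,
    SelfLoopError,
    UndefinedMetricError,
)

__all__ = [
    "CountryPool",
    "TradeNetwork",
    "write_edgelist_csv",
    "read_edgelist_csv",
    "to_networkx",
]

DEFAULT_POOL_SIZE = 244


@dataclass(frozen=True)
class CountryPool:
    """Immutable pool of country identifiers.

    Labels are ISO 3166-1 alpha-3 codes for empirical data, or synthetic IDs
    (``C001`` ...) for simulation-only runs.  Internally every country is a
    0-based integer index; labels appear only in file I/O.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("country labels must be unique")
        if len(self.labels) == 0:
            raise ValueError("country pool must be non-empty")

    @classmethod
    def default(cls, size: int = DEFAULT_POOL_SIZE) -> "CountryPool":
        """Synthetic pool ``C001 .. C{size}``."""
        if size < 1:
            raise ValueError("pool size must be positive")
        width = max(3, len(str(size)))
        return cls(tuple(f"C{i + 1:0{width}d}" for i in range(size)))

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "CountryPool":
        return cls(tuple(labels))

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __len__(self) -> int:
        return len(self.labels)


class TradeNetwork:
    """Directed unweighted graph with O(1) edge add/remove/sample.

    Edges are ordered pairs ``(i, j)`` meaning *i imports from j* (adjacency
    ``A[i, j] = 1``).  The edge list supports uniform random edge sampling for
    Maslov–Sneppen rewiring; the successor map supports out-edge removal for
    export-ban shocks.
    """

    __slots__ = ("pool", "_edge_pos", "_edge_list", "_succ",
                 "in_degree", "out_degree")

    def __init__(self, pool: CountryPool):
        self.pool = pool
        self._edge_pos: dict[tuple[int, int], int] = {}
        self._edge_list: list[tuple[int, int]] = []
        self._succ: dict[int, set[int]] = {}
        self.in_degree = np.zeros(pool.size, dtype=np.int64)
        self.out_degree = np.zeros(pool.size, dtype=np.int64)

    # -- basic accessors ---------------------------------------------------

    @property
    def m(self) -> int:
        """Number of directed edges."""
        return len(self._edge_list)

    @property
    def total_degree(self) -> np.ndarray:
        return self.in_degree + self.out_degree

    def has_edge(self, importer: int, exporter: int) -> bool:
        return (importer, exporter) in self._edge_pos

    def edges(self) -> list[tuple[int, int]]:
        """Snapshot copy of the edge list (importer, exporter)."""
        return list(self._edge_list)

    def edge_at(self, position: int) -> tuple[int, int]:
        """Edge at a list position; with a uniform position this is a
        uniform random edge."""
        return self._edge_list[position]

    def successors(self, exporter: int) -> set[int]:
        """Importers that ``exporter`` exports to (targets of its out-edges).

        Note out-edges of country ``x`` are the edges ``(i, x)``: ``x``
        exporting to ``i``.
        """
        return set(self._succ.get(exporter, ()))

    # -- mutation ----------------------------------------------------------

    def add_edge(self, importer: int, exporter: int) -> None:
        if importer == exporter:
            raise SelfLoopError(
                f"self-loop rejected: country index {importer}")
        key = (importer, exporter)
        if key in self._edge_pos:
            raise DuplicateEdgeError(f"edge already present: {key}")
        self._edge_pos[key] = len(self._edge_list)
        self._edge_list.append(key)
        self._succ.setdefault(exporter, set()).add(importer)
        self.in_degree[importer] += 1
        self.out_degree[exporter] += 1

    def remove_edge(self, importer: int, exporter: int) -> None:
        key = (importer, exporter)
        pos = self._edge_pos.pop(key, None)
        if pos is None:
            raise MissingEdgeError(f"edge not present: {key}")
        last = self._edge_list.pop()
        if last != key:  # swap-pop keeps the list compact
            self._edge_list[pos] = last
            self._edge_pos[last] = pos
        self._succ[exporter].discard(importer)
        self.in_degree[importer] -= 1
        self.out_degree[exporter] -= 1

    def copy(self) -> "TradeNetwork":
        clone = TradeNetwork(self.pool)
        clone._edge_pos = dict(self._edge_pos)
        clone._edge_list = list(self._edge_list)
        clone._succ = {k: set(v) for k, v in self._succ.items()}
        clone.in_degree = self.in_degree.copy()
        clone.out_degree = self.out_degree.copy()
        return clone

    # -- model quantities --------------------------------------------------

    def fitness(self, i: int) -> float:
        """Preferential-attachment fitness: total degree over edge count.

        Defined as 0 on the empty network so that the connection probability
        reduces to the baseline epsilon for the very first edge.
        """
        m = self.m
        if m == 0:
            return 0.0
        return float(self.in_degree[i] + self.out_degree[i]) / m

    def fitness_vector(self) -> np.ndarray:
        m = self.m
        if m == 0:
            return np.zeros(self.pool.size)
        return self.total_degree / m

    def active_nodes(self) -> set[int]:
        """Countries engaged in at least one trade partnership."""
        return set(np.nonzero(self.total_degree > 0)[0].tolist())

    def reciprocity(self) -> float:
        """Fraction of directed edges whose reverse edge also exists."""
        if self.m == 0:
            raise UndefinedMetricError("reciprocity undefined on empty network")
        pos = self._edge_pos
        reciprocated = sum(1 for (i, j) in self._edge_list if (j, i) in pos)
        return reciprocated / self.m

    def __repr__(self) -> str:  # pragma: no cover
        return (f"TradeNetwork(N={self.pool.size}, m={self.m}, "
                f"active={len(self.active_nodes())})")


# -- interoperability ------------------------------------------------------


def to_networkx(net: TradeNetwork, active_only: bool = True):
    """Convert to a :class:`networkx.DiGraph` (node ids are pool indices)."""
    import networkx as nx

    g = nx.DiGraph()
    if active_only:
        g.add_nodes_from(sorted(net.active_nodes()))
    else:
        g.add_nodes_from(range(net.pool.size))
    g.add_edges_from(net.edges())
    return g


def write_edgelist_csv(net: TradeNetwork, path) -> None:
    """Write ``importer,exporter`` label rows, sorted for reproducibility."""
    labels = net.pool.labels
    rows = sorted((labels[i], labels[j]) for (i, j) in net.edges())
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["importer", "exporter"])
        writer.writerows(rows)


def read_edgelist_csv(path, pool: CountryPool | None = None) -> TradeNetwork:
    """Read an edge-list CSV written by :func:`write_edgelist_csv`.

    If ``pool`` is omitted, a pool is built from the sorted set of labels in
    the file.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:2]] != ["importer", "exporter"]:
            raise ValueError(f"unexpected edge-list header: {header}")
        pairs = [(row[0], row[1]) for row in reader if row]
    if pool is None:
        pool = CountryPool.from_labels(sorted({c for p in pairs for c in p}))
    lookup = {lab: k for k, lab in enumerate(pool.labels)}
    net = TradeNetwork(pool)
    for imp, exp in pairs:
        net.add_edge(lookup[imp], lookup[exp])
    return net
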