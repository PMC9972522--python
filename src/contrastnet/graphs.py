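"""Node-labelled symmetric weighted networks and signed difference graphs.

Every network in this package is undirected, self-loop free and defined
over an ordered list of unique string node labels.  Two flavours exist:

* :class:`WeightedNetwork` — non-negative weights.  Coexpression networks
  are complete with weights in [0, 1]; protein–protein interaction
  networks are sparse with weights in {0, 1}.  Both use the same dense
  symmetric matrix contract.
* :class:`SignedDifferenceGraph` — the elementwise difference of two
  weighted networks on their shared nodes.  Weights may be negative; this
  is the substrate the contrast-subgraph miner operates on.

Node order is canonicalised by lexicographic sort at construction so that
all downstream tie-breaking is deterministic regardless of input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Collection, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: absolute tolerance for symmetry / diagonal / weight-range checks
ATOL = 1e-9


class _BaseNetwork:
    """Shared implementation of the symmetric labelled-matrix contract."""

    #: subclasses set this to forbid / allow negative weights
    _allow_negative = True

    def __init__(
        self,
        nodes: Iterable[str],
        weights: np.ndarray,
        meta: Mapping | None = None,
        *,
        _trusted: bool = False,
    ) -> None:
        nodes = [str(n) for n in nodes]
        w = np.asarray(weights, dtype=np.float64)
        if _trusted:
            self.nodes: tuple[str, ...] = tuple(nodes)
            self.weights: np.ndarray = w
        else:
            if len(set(nodes)) != len(nodes):
                dupes = sorted({n for n in nodes if nodes.count(n) > 1})
                raise ValueError(f"duplicate node labels: {dupes[:5]}")
            if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] != len(nodes):
                raise ValueError(
                    f"weight matrix shape {w.shape} does not match {len(nodes)} nodes"
                )
            if not np.allclose(w, w.T, atol=ATOL, rtol=0.0, equal_nan=False):
                raise ValueError("weight matrix is not symmetric within tolerance")
            if np.abs(np.diagonal(w)).max(initial=0.0) > ATOL:
                raise ValueError("nonzero diagonal: self-loops are not allowed")
            if not self._allow_negative and w.min(initial=0.0) < -ATOL:
                raise ValueError("negative weights are not allowed in this network")
            order = np.argsort(np.asarray(nodes, dtype=object))
            w = (w + w.T) / 2.0  # exact symmetry
            w = w[np.ix_(order, order)].copy()
            np.fill_diagonal(w, 0.0)
            if not self._allow_negative:
                np.clip(w, 0.0, None, out=w)
            self.nodes = tuple(nodes[i] for i in order)
            self.weights = w
        self.meta: dict = dict(meta or {})
        self._index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(n_nodes={self.n_nodes})"

    def indices(self, nodes: Collection[str]) -> np.ndarray:
        """Matrix indices for a collection of labels (sorted by label)."""
        missing = [n for n in nodes if n not in self._index]
        if missing:
            raise KeyError(f"node(s) not in graph: {sorted(missing)[:5]}")
        return np.array(sorted(self._index[n] for n in nodes), dtype=np.intp)

    def weight(self, u: str, v: str) -> float:
        return float(self.weights[self._index[u], self._index[v]])

    def induced_edge_sum(self, nodes: Collection[str]) -> float:
        """Sum of weights over unordered pairs within ``nodes``."""
        idx = self.indices(nodes)
        if idx.size < 2:
            return 0.0
        sub = self.weights[np.ix_(idx, idx)]
        return float(sub.sum() / 2.0)

    def degrees(self) -> pd.Series:
        """Weighted degree (signed, for difference graphs) per node."""
        return pd.Series(self.weights.sum(axis=1), index=list(self.nodes), name="degree")

    def subgraph(self, nodes: Collection[str]):
        idx = self.indices(nodes)
        labels = [self.nodes[i] for i in idx]
        return type(self)(labels, self.weights[np.ix_(idx, idx)], meta=self.meta, _trusted=True)

    def iter_edges(self, *, nonzero_only: bool = True) -> Iterator[tuple[str, str, float]]:
        """Yield unordered edges ``(u, v, w)`` with u < v."""
        n = self.n_nodes
        for i in range(n):
            row = self.weights[i]
            for j in range(i + 1, n):
                w = row[j]
                if nonzero_only and w == 0.0:
                    continue
                yield self.nodes[i], self.nodes[j], float(w)

    def __eq__(self, other) -> bool:
        return (
            type(other) is type(self)
            and self.nodes == other.nodes
            and np.array_equal(self.weights, other.weights)
        )

    __hash__ = None  # type: ignore[assignment]


class WeightedNetwork(_BaseNetwork):
    """Symmetric non-negative weighted network over named nodes."""

    _allow_negative = False

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float] | tuple[str, str]],
        nodes: Iterable[str] | None = None,
        default_weight: float = 1.0,
    ) -> "WeightedNetwork":
        """Build from an undirected edge list.

        Duplicate rows for the same unordered pair (including reciprocal
        rows) are collapsed to the maximum weight; conflicting duplicates
        are counted and logged.  Unweighted rows get ``default_weight``.
        """
        best: dict[tuple[str, str], float] = {}
        conflicts = 0
        labels: set[str] = set(nodes or ())
        for row in edges:
            if len(row) == 2:
                u, v = row  # type: ignore[misc]
                w = default_weight
            else:
                u, v, w = row  # type: ignore[misc]
            u, v = str(u), str(v)
            labels.update((u, v))
            if u == v:
                logger.warning("dropping self-loop on %r", u)
                continue
            key = (u, v) if u < v else (v, u)
            w = float(w)
            if key in best and best[key] != w:
                conflicts += 1
            best[key] = max(best.get(key, w), w)
        if conflicts:
            logger.warning("collapsed %d conflicting duplicate edges (kept max weight)", conflicts)
        ordered = sorted(labels)
        index = {n: i for i, n in enumerate(ordered)}
        w = np.zeros((len(ordered), len(ordered)))
        for (u, v), val in best.items():
            w[index[u], index[v]] = w[index[v], index[u]] = val
        return cls(ordered, w, _trusted=True)


class SignedDifferenceGraph(_BaseNetwork):
    """Symmetric network with weights of any sign (difference of two networks).

    Exposes the signed-degree bookkeeping the peeling algorithm needs:
    ``deg_plus`` (sum of positive incident weights), ``deg_minus`` (sum of
    negative incident weights, ≤ 0) and ``delta = max_v |deg_minus(v)|``.
    """

    _allow_negative = True

    @property
    def deg_plus(self) -> np.ndarray:
        return np.where(self.weights > 0, self.weights, 0.0).sum(axis=1)

    @property
    def deg_minus(self) -> np.ndarray:
        return np.where(self.weights < 0, self.weights, 0.0).sum(axis=1)

    @property
    def delta(self) -> float:
        """Maximum absolute negative degree, the Δ of the quality bound."""
        dm = self.deg_minus
        return float(-dm.min()) if dm.size else 0.0

    def negated(self) -> "SignedDifferenceGraph":
        return SignedDifferenceGraph(self.nodes, -self.weights, meta=self.meta, _trusted=True)


@dataclass(frozen=True)
class ContrastResult:
    """A mined contrast subgraph: the node set and how it was obtained.

    ``objective`` is the density f(S) = e(S)/|S| of ``node_set`` on the
    signed difference graph it was mined from; ``direction`` records which
    network plays the dense role (``A_over_B`` means dense in A, sparse
    in B).
    """

    node_set: frozenset[str]
    objective: float
    rank: int
    c_value: float
    direction: str

    def __post_init__(self) -> None:
        if not self.node_set:
            raise ValueError("contrast subgraph node set must be non-empty")
        if self.direction not in ("A_over_B", "B_over_A"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")

    @property
    def size(self) -> int:
        return len(self.node_set)

    def sorted_nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.node_set))


# -- module-level operations -------------------------------------------------


def difference_graph(net_a: _BaseNetwork, net_b: _BaseNetwork) -> SignedDifferenceGraph:
    """Signed difference A − B restricted to the shared nodes.

    Node alignment is by exact string label; the shared set is sorted so
    the result is independent of input node order.  Raises ``ValueError``
    when fewer than two nodes are shared (the networks are incomparable).
    """
    shared = sorted(set(net_a.nodes) & set(net_b.nodes))
    if len(shared) < 2:
        raise ValueError(
            f"networks share only {len(shared)} node(s); at least 2 are required "
            "for a difference graph"
        )
    if len(shared) < max(net_a.n_nodes, net_b.n_nodes):
        logger.info(
            "difference graph restricted to %d shared nodes (A: %d, B: %d)",
            len(shared), net_a.n_nodes, net_b.n_nodes,
        )
    ia = net_a.indices(shared)
    ib = net_b.indices(shared)
    w = net_a.weights[np.ix_(ia, ia)] - net_b.weights[np.ix_(ib, ib)]
    np.fill_diagonal(w, 0.0)
    return SignedDifferenceGraph(shared, w, _trusted=True)


def induced_edge_sum(g: _BaseNetwork, s: Collection[str]) -> float:
    """e(S): sum of edge weights over unordered pairs within ``s``."""
    return g.induced_edge_sum(s)


def signed_degrees(g: SignedDifferenceGraph) -> pd.DataFrame:
    """Per-node positive and negative degree of a signed graph.

    Returns a DataFrame indexed by node with columns ``deg_plus`` and
    ``deg_minus``; their sum is the total signed weighted degree.
    """
    return pd.DataFrame(
        {"deg_plus": g.deg_plus, "deg_minus": g.deg_minus}, index=list(g.nodes)
    )
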