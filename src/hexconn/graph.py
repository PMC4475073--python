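"""Dispersal kernel, habitat-availability indices and node importance.

The landscape is a graph whose nodes are habitat patches (or focal
landscapes) with attributes a_i, and whose links carry either a
dispersal probability p_ij (probabilistic mode) or plain adjacency
(binary mode). Two habitat-availability indices are computed over all
ordered node pairs, self-pairs included:

* PC (probability of connectivity)::

      PC = sum_i sum_j a_i * a_j * p*_ij / A_L**2

  where p*_ij is the maximum, over all paths between i and j, of the
  product of link probabilities (p*_ii = 1), and A_L is the landscape
  area in the same units as the attributes.

* IIC (integral index of connectivity), the binary counterpart::

      IIC = sum_i sum_j a_i * a_j / (1 + nl_ij) / A_L**2

  with nl_ij the number of links on the topological shortest path
  (nl_ii = 0); pairs in different components contribute nothing.

A node's importance is the percent drop of the index when the node is
removed, with A_L held fixed — habitat loss is simulated in the index,
not in the study area:

      dI_k = 100 * (I - I_without_k) / I
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra, shortest_path

__all__ = [
    "DispersalKernel",
    "calibrate_kernel",
    "PatchGraph",
    "IndexResult",
    "max_product_path_probabilities",
    "compute_pc",
    "compute_iic",
    "node_removal_importance",
    "write_node_file",
    "write_connection_file",
    "read_node_file",
    "read_connection_file",
]

# link probabilities marginally above 1 (floating point) are clipped; larger
# excursions are treated as data errors
_PROB_CLIP_TOL = 1e-9


@dataclass(frozen=True)
class DispersalKernel:
    """Negative-exponential dispersal kernel p(d) = exp(-k d).

    Calibrated from an anchor pair: the probability ``p0`` of a
    functional connection at distance ``d0`` (meters), giving
    k = -ln(p0) / d0. With k = 0 the kernel is flat (p = 1 everywhere).
    """

    k: float
    p0: float = 1.0
    d0: float = 1.0

    def probability(self, distance) -> np.ndarray | float:
        d = np.asarray(distance, dtype=float)
        if np.any(d < 0):
            raise ValueError("distance must be non-negative")
        p = np.exp(-self.k * d)
        return float(p) if p.ndim == 0 else p

    __call__ = probability

    def distance_at(self, p: float) -> float:
        """Distance at which the kernel drops to probability ``p``."""
        if not 0 < p <= 1:
            raise ValueError("p must be in (0, 1]")
        if self.k == 0:
            return math.inf if p < 1 else 0.0
        return -math.log(p) / self.k

    def cutoff_distance(self, negligible: float = 1e-4) -> float:
        """Distance beyond which connection probability is negligible."""
        return self.distance_at(negligible)


def calibrate_kernel(p0: float, d0: float) -> DispersalKernel:
    """Anchor a negative-exponential kernel so that p(d0) = p0."""
    if not 0 < p0 <= 1:
        raise ValueError("anchor probability p0 must be in (0, 1]")
    if d0 <= 0:
        raise ValueError("anchor distance d0 must be positive (meters)")
    return DispersalKernel(k=-math.log(p0) / d0, p0=p0, d0=d0)


@dataclass
class PatchGraph:
    """Nodes with attributes plus probabilistic or binary links.

    ``links`` is a symmetric sparse matrix: in ``"probability"`` mode its
    entries are direct link probabilities p_ij in [0, 1]; in ``"binary"``
    mode any stored entry means the pair is directly connected. No
    self-links are stored (the i = j terms are handled analytically).
    ``area`` is the landscape attribute ceiling A_L.
    """

    node_ids: np.ndarray
    attributes: np.ndarray
    links: csr_matrix
    mode: str = "probability"
    area: float = 1.0

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids)
        self.attributes = np.asarray(self.attributes, dtype=float)
        if self.mode not in ("probability", "binary"):
            raise ValueError("mode must be 'probability' or 'binary'")
        if self.attributes.shape != self.node_ids.shape:
            raise ValueError("node_ids and attributes must have equal length")
        if np.any(self.attributes < 0):
            raise ValueError("node attributes must be non-negative")
        n = len(self.node_ids)
        if self.links.shape != (n, n):
            raise ValueError("link matrix shape must be (n_nodes, n_nodes)")
        if self.mode == "probability" and self.links.nnz:
            p = self.links.data
            if np.any(p < 0):
                raise ValueError("link probabilities must be non-negative")
            if np.any(p > 1 + _PROB_CLIP_TOL):
                raise ValueError("link probabilities must not exceed 1")
            np.clip(p, 0.0, 1.0, out=self.links.data)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    # ------------------------------------------------------------ builders

    @classmethod
    def from_links(
        cls,
        node_ids,
        attributes,
        link_pairs,
        link_values=None,
        mode: str = "probability",
        area: float = 1.0,
    ) -> "PatchGraph":
        """Build from a list of (i, j) node-id pairs and optional values."""
        node_ids = np.asarray(node_ids)
        n = len(node_ids)
        index = {nid: k for k, nid in enumerate(node_ids)}
        rows, cols, vals = [], [], []
        link_pairs = list(link_pairs)
        if link_values is None:
            link_values = [1.0] * len(link_pairs)
        for (i, j), v in zip(link_pairs, link_values):
            a, b = index[i], index[j]
            if a == b:
                continue
            rows += [a, b]
            cols += [b, a]
            vals += [v, v]
        links = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        return cls(node_ids, attributes, links, mode=mode, area=area)

    @classmethod
    def from_distances(
        cls,
        node_ids,
        attributes,
        distances: pd.DataFrame,
        kernel: DispersalKernel,
        area: float = 1.0,
    ) -> "PatchGraph":
        """Build a probabilistic graph from an edge-distance table.

        ``distances`` columns: id_i, id_j, distance_m (one row per
        unordered pair); probabilities come from the kernel.
        """
        pairs = list(zip(distances["id_i"], distances["id_j"]))
        probs = kernel.probability(distances["distance_m"].to_numpy())
        return cls.from_links(
            node_ids, attributes, pairs, np.atleast_1d(probs), mode="probability",
            area=area,
        )


@dataclass
class IndexResult:
    """Value of a connectivity index and optional per-node importances."""

    index: str
    value: float
    numerator: float
    area: float
    importance: pd.Series | None = None


def _check_probability_mode(graph: PatchGraph) -> None:
    if graph.mode != "probability":
        raise ValueError("operation requires a probabilistic-mode graph")


def max_product_path_probabilities(graph: PatchGraph) -> np.ndarray:
    """Matrix of maximum product-path probabilities p*_ij.

    The best path maximizes the product of link probabilities, found as
    the shortest path under weights -ln(p_ij); zero-probability links
    are dropped beforehand. p*_ii = 1; unreachable pairs get 0.
    """
    _check_probability_mode(graph)
    n = graph.n_nodes
    if n == 0:
        return np.zeros((0, 0))
    links = graph.links.tocoo()
    keep = links.data > 0
    w = coo_matrix(
        (-np.log(links.data[keep]), (links.row[keep], links.col[keep])),
        shape=(n, n),
    ).tocsr()
    dist = dijkstra(w, directed=False)
    with np.errstate(over="ignore"):
        pstar = np.exp(-dist)
    np.fill_diagonal(pstar, 1.0)
    return pstar


def _pair_discount_binary(graph: PatchGraph) -> np.ndarray:
    """1 / (1 + nl_ij) for all pairs; 0 where disconnected."""
    n = graph.n_nodes
    adj = graph.links.copy()
    if adj.nnz:
        adj.data = np.ones_like(adj.data)
    nl = shortest_path(adj, method="D", directed=False, unweighted=True)
    with np.errstate(divide="ignore"):
        disc = 1.0 / (1.0 + nl)
    disc[~np.isfinite(nl)] = 0.0
    np.fill_diagonal(disc, 1.0)
    return disc


def _numerator(attributes: np.ndarray, pair_weight: np.ndarray) -> float:
    return float(attributes @ pair_weight @ attributes)


def compute_pc(graph: PatchGraph, importance: bool = False) -> IndexResult:
    """Probability of connectivity: PC = sum a_i a_j p*_ij / A_L^2.

    The double sum runs over ordered pairs including i = j (p*_ii = 1),
    so a lone patch contributes a_i^2. ``importance=True`` also computes
    per-node removal importances.
    """
    _check_probability_mode(graph)
    if graph.area <= 0:
        raise ValueError("landscape area A_L must be positive")
    pstar = max_product_path_probabilities(graph)
    num = _numerator(graph.attributes, pstar)
    res = IndexResult("PC", num / graph.area**2, num, graph.area)
    if importance:
        res.importance = node_removal_importance(graph, index="PC").importance
    return res


def compute_iic(graph: PatchGraph, importance: bool = False) -> IndexResult:
    """Integral index of connectivity, the binary counterpart of PC."""
    if graph.mode != "binary":
        raise ValueError("IIC requires a binary-mode graph")
    if graph.area <= 0:
        raise ValueError("landscape area A_L must be positive")
    disc = _pair_discount_binary(graph)
    num = _numerator(graph.attributes, disc)
    res = IndexResult("IIC", num / graph.area**2, num, graph.area)
    if importance:
        res.importance = node_removal_importance(graph, index="IIC").importance
    return res


def _subgraph_without(graph: PatchGraph, k: int) -> PatchGraph:
    keep = np.arange(graph.n_nodes) != k
    links = graph.links[keep][:, keep]
    return PatchGraph(
        graph.node_ids[keep], graph.attributes[keep], links.tocsr(),
        mode=graph.mode, area=graph.area,
    )


def node_removal_importance(graph: PatchGraph, index: str = "IIC") -> IndexResult:
    """Percent drop of PC or IIC when each node is removed in turn.

    A_L is held fixed across removals, so dI_k lies in [0, 100]: losing
    a node can only remove availability, never add it.
    """
    if graph.n_nodes == 0:
        raise ValueError("graph has no nodes")
    index = index.upper()
    compute = {"PC": compute_pc, "IIC": compute_iic}.get(index)
    if compute is None:
        raise ValueError("index must be 'PC' or 'IIC'")
    full = compute(graph)
    deltas = np.zeros(graph.n_nodes)
    if full.value == 0:
        warnings.warn(
            "index value is 0; node removal importance is undefined and "
            "reported as 0 for every node",
            stacklevel=2,
        )
    else:
        for k in range(graph.n_nodes):
            reduced = compute(_subgraph_without(graph, k))
            deltas[k] = 100.0 * (full.value - reduced.value) / full.value
        # removal can only lose availability; clamp float round-off
        np.clip(deltas, 0.0, 100.0, out=deltas)
    full.importance = pd.Series(deltas, index=pd.Index(graph.node_ids, name="node_id"),
                                name=f"d{index}_pct")
    return full


# ----------------------------------------------------------- text file I/O
# Node and connection files follow the widespread two/three-column dialect
# used by landscape-connectivity tools: "id attribute" and
# "id_i id_j distance|probability".

def write_node_file(graph: PatchGraph, path) -> None:
    with open(path, "w") as fh:
        for nid, a in zip(graph.node_ids, graph.attributes):
            fh.write(f"{nid} {a:.10g}\n")


def write_connection_file(graph: PatchGraph, path) -> None:
    links = graph.links.tocoo()
    with open(path, "w") as fh:
        for i, j, v in zip(links.row, links.col, links.data):
            if i < j:
                fh.write(f"{graph.node_ids[i]} {graph.node_ids[j]} {v:.10g}\n")


def read_node_file(path) -> tuple[np.ndarray, np.ndarray]:
    ids, attrs = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            a, b = line.split()
            ids.append(int(a))
            attrs.append(float(b))
    return np.asarray(ids), np.asarray(attrs)


def read_connection_file(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            i, j, v = line.split()
            rows.append((int(i), int(j), float(v)))
    return pd.DataFrame(rows, columns=["id_i", "id_j", "value"])
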