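"""Neighbourhood graphs and intrinsic CAR (ICAR) precision structure.

Cluster-level spatial dependence is modelled with the Besag intrinsic
conditional autoregression: given a neighbourhood graph, the improper
Gaussian prior on a field ``u`` has density

    p(u | tau) ∝ tau^((n - c)/2) * exp(-(tau/2) * sum_{i~j} (u_i - u_j)^2)

whose precision matrix is ``tau * Q`` with ``Q = D - A`` the graph
Laplacian (degree minus adjacency).  ``Q`` is rank ``n - c`` for a graph
with ``c`` connected components; identifiability is restored by a
sum-to-zero constraint within each component.

Survey clusters are points (village centroids), not polygons, so the
default neighbourhood is a symmetrised k-nearest-neighbour graph under
great-circle (haversine) distance; Delaunay triangulation and shared-
district adjacency are offered as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay

__all__ = [
    "AdjacencyGraph",
    "PrecisionMatrix",
    "build_adjacency",
    "icar_precision",
    "sample_icar",
    "haversine_km",
    "read_edge_list",
    "write_edge_list",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees (WGS84)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class AdjacencyGraph:
    """Undirected neighbourhood graph over site ids.

    ``nodes`` fixes the ordering used by all matrix representations;
    ``edges`` are unordered id pairs with no self-loops; ``components``
    partitions the nodes into connected components.
    """

    nodes: list
    edges: list = field(default_factory=list)
    components: list = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate site ids in adjacency graph")
        index = {v: i for i, v in enumerate(self.nodes)}
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a}")
            if a not in index or b not in index:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            canon.add((a, b) if index[a] < index[b] else (b, a))
        self.edges = sorted(canon, key=lambda e: (index[e[0]], index[e[1]]))
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        comps = [sorted(c, key=index.__getitem__) for c in nx.connected_components(g)]
        self.components = sorted(comps, key=lambda c: index[c[0]])
        self._index = index

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def index_of(self, node) -> int:
        return self._index[node]

    def edge_indices(self) -> np.ndarray:
        """Edges as an (m, 2) integer array of node positions."""
        if not self.edges:
            return np.empty((0, 2), dtype=int)
        return np.array([(self._index[a], self._index[b]) for a, b in self.edges], dtype=int)

    def component_indicator(self) -> np.ndarray:
        """Sparse-style (c, n) 0/1 matrix mapping components to nodes."""
        ind = np.zeros((self.n_components, self.n_nodes))
        for k, comp in enumerate(self.components):
            for v in comp:
                ind[k, self._index[v]] = 1.0
        return ind


def build_adjacency(sites: pd.DataFrame, method: str = "knn", k: int = 5) -> AdjacencyGraph:
    """Build a neighbourhood graph over survey sites.

    Parameters
    ----------
    sites : DataFrame
        Columns ``id``, ``lon``, ``lat`` (decimal degrees) and, for
        ``method="district-shared"``, ``district_id``.
    method : {"knn", "delaunay", "district-shared"}
        ``knn`` links each site to its ``k`` nearest neighbours by
        haversine distance and symmetrises (an edge is kept if either
        endpoint selects the other).  ``delaunay`` triangulates the
        lon/lat plane.  ``district-shared`` links all site pairs within
        the same district.
    k : int
        Neighbour count for ``knn``.
    """
    ids = list(sites["id"])
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate site ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 sites to build adjacency")
    lon = sites["lon"].to_numpy(dtype=float)
    lat = sites["lat"].to_numpy(dtype=float)
    n = len(ids)
    edges = set()
    if method == "knn":
        if k < 1:
            raise ValueError("k must be >= 1")
        k_eff = min(k, n - 1)
        # pairwise haversine; surveys have at most a few thousand sites so
        # the dense matrix is cheap and exact (a KD-tree on lon/lat would
        # mis-rank near the poles/antimeridian)
        d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
        np.fill_diagonal(d, np.inf)
        order = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
        for i in range(n):
            for j in order[i]:
                a, b = (i, int(j)) if i < j else (int(j), i)
                edges.add((a, b))
    elif method == "delaunay":
        pts = np.column_stack([lon, lat])
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for a, b in ((0, 1), (1, 2), (0, 2)):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((min(i, j), max(i, j)))
    elif method == "district-shared":
        if "district_id" not in sites.columns:
            raise ValueError("district-shared adjacency requires a district_id column")
        dist = sites["district_id"].to_numpy()
        for d_id in pd.unique(dist):
            members = np.flatnonzero(dist == d_id)
            for ii in range(len(members)):
                for jj in range(ii + 1, len(members)):
                    edges.add((int(members[ii]), int(members[jj])))
    else:
        raise ValueError(f"unknown adjacency method: {method!r}")
    return AdjacencyGraph(nodes=ids, edges=[(ids[i], ids[j]) for i, j in sorted(edges)])


@dataclass
class PrecisionMatrix:
    """ICAR precision structure ``tau * Q`` with ``Q`` the graph Laplacian."""

    Q: sp.csr_matrix
    graph: AdjacencyGraph
    tau: float = 1.0

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def rank(self) -> int:
        return self.n - self.graph.n_components

    def quadratic_form(self, x: np.ndarray) -> float:
        """x' Q x, equal to the sum of squared differences over edges."""
        x = np.asarray(x, dtype=float)
        return float(x @ (self.Q @ x))


def icar_precision(graph: AdjacencyGraph) -> PrecisionMatrix:
    """Structure matrix Q = D - A of the graph (unscaled ICAR precision)."""
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    eidx = graph.edge_indices()
    if len(eidx):
        i, j = eidx[:, 0], eidx[:, 1]
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate([-np.ones(2 * len(eidx)), np.ones(2 * len(eidx))])
        Q = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    else:
        Q = sp.csr_matrix((n, n))
    return PrecisionMatrix(Q=Q, graph=graph)


def sample_icar(precision: PrecisionMatrix, tau: float, seed=None, size: int = 1) -> np.ndarray:
    """Draw fields from the ICAR prior with precision ``tau * Q``.

    The draw lives on the subspace orthogonal to each component's constant
    vector (sum-to-zero per component), where the density is proper.
    Implemented by spectral decomposition of Q: coordinates along non-null
    eigenvectors are independent N(0, 1/(tau * lambda_k)).

    Returns an array of shape ``(n,)`` when ``size == 1`` else ``(size, n)``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    Q = precision.Q.toarray()
    lam, vec = np.linalg.eigh(Q)
    # null space dimension equals the number of connected components
    nullity = precision.graph.n_components
    lam_pos = lam[nullity:]
    vec_pos = vec[:, nullity:]
    z = rng.standard_normal((size, len(lam_pos)))
    draws = (vec_pos * (1.0 / np.sqrt(tau * lam_pos))) @ z.T
    draws = draws.T
    # enforce the constraint exactly against eigensolver round-off
    ind = precision.graph.component_indicator()
    sizes = ind.sum(axis=1)
    draws = draws - (draws @ ind.T / sizes) @ ind
    return draws[0] if size == 1 else draws


def write_edge_list(graph: AdjacencyGraph, path) -> None:
    """Write edges as whitespace-separated ``id_a id_b`` lines."""
    with open(path, "w") as fh:
        for a, b in graph.edges:
            fh.write(f"{a} {b}\n")


def read_edge_list(path, nodes=None) -> AdjacencyGraph:
    """Read a whitespace-separated edge list; ``nodes`` adds isolated sites."""
    edges = []
    seen = []
    seen_set = set()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {line!r}")
            a, b = parts
            edges.append((a, b))
            for v in (a, b):
                if v not in seen_set:
                    seen_set.add(v)
                    seen.append(v)
    if nodes is None:
        nodes = seen
    else:
        nodes = list(nodes)
    return AdjacencyGraph(nodes=nodes, edges=edges)
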