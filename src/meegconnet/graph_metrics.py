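"""Graph-theoretical characterization of brain networks.

A thresholded connectivity matrix becomes a :class:`BrainGraph`: an
undirected weighted graph whose nodes are electrodes or ROIs. Metrics
follow the standard topological definitions used for brain networks:

* global — density, characteristic path length, global efficiency,
  radius, diameter;
* per node — degree, strength, clustering coefficient, k-coreness,
  betweenness, participation coefficient;
* per edge — edge betweenness, shortcut flag (does removing the edge
  increase the characteristic path length?), neighbourhood overlap.

Path-based quantities use binary hop distances by default, matching the
topological definitions (``weighted_paths=True`` switches to 1/weight edge
lengths). Disconnected node pairs are excluded from the path-length mean
and contribute zero to efficiency; a disconnected graph has infinite
radius and diameter. Betweenness values are raw shortest-path counts with
fractional credit for multiplicities (``normalized=True`` rescales by the
number of pairs).

Module structure comes from weighted modularity maximization
(Louvain-style greedy, restarted), and node metrics can be aggregated per
ROI or per brain lobe and hemisphere for tabular export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import ConnectivityMatrix, ScoutAtlas
from .errors import AlignmentError, ParameterError, ShapeError, ValidationError
from .utils import spawn_seeds

logger = logging.getLogger("meegconnet")

__all__ = [
    "BrainGraph", "ModulePartition", "GlobalMetrics",
    "threshold_adjacency", "global_metrics", "node_metrics", "edge_metrics",
    "detect_modules", "aggregate_by_region",
]


@dataclass
class BrainGraph:
    """Weighted undirected graph with labelled, optionally positioned nodes."""

    adjacency: np.ndarray
    node_labels: list[str] | None = None
    node_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ShapeError("adjacency must be square")
        if not np.isfinite(self.adjacency).all():
            raise ValidationError("non-finite edge weight")
        if not np.allclose(self.adjacency, self.adjacency.T, atol=1e-10):
            raise ValidationError("adjacency must be symmetric")
        self.adjacency = 0.5 * (self.adjacency + self.adjacency.T)
        if self.adjacency.min() < 0:
            raise ValidationError("edge weights must be >= 0")
        if np.abs(np.diag(self.adjacency)).max(initial=0.0) > 0:
            raise ValidationError("self-loops are not allowed")
        if self.node_labels is None:
            self.node_labels = [f"n{i}" for i in range(n)]
        self.node_labels = [str(l) for l in self.node_labels]
        if len(self.node_labels) != n:
            raise ValidationError("node label count mismatch")
        if self.node_positions is not None:
            self.node_positions = np.asarray(self.node_positions, dtype=float)
            if self.node_positions.shape != (n, 3):
                raise ShapeError("node_positions must be (N, 3)")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def binary(self) -> np.ndarray:
        """Unweighted view: 1 where an edge is present."""
        return (self.adjacency > 0).astype(int)

    def to_networkx(self, partition: "ModulePartition | None" = None) -> nx.Graph:
        g = nx.Graph()
        strength = self.adjacency.sum(axis=1)
        for i, lab in enumerate(self.node_labels):
            attrs = {"label": lab, "strength": float(strength[i])}
            if self.node_positions is not None:
                attrs.update(
                    x=float(self.node_positions[i, 0]),
                    y=float(self.node_positions[i, 1]),
                    z=float(self.node_positions[i, 2]),
                )
            if partition is not None:
                attrs["module"] = int(partition.community_id[i])
            g.add_node(lab, **attrs)
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        for i, j in zip(iu, ju):
            g.add_edge(
                self.node_labels[i], self.node_labels[j],
                weight=float(self.adjacency[i, j]),
            )
        return g


@dataclass
class ModulePartition:
    """Community assignment per node plus its modularity score."""

    community_id: np.ndarray
    modularity_q: float

    def __post_init__(self) -> None:
        self.community_id = np.asarray(self.community_id, dtype=int)
        ids = np.unique(self.community_id)
        if ids.size and not np.array_equal(ids, np.arange(ids.size)):
            raise ValidationError("community ids must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return int(self.community_id.max() + 1) if self.community_id.size else 0


@dataclass
class GlobalMetrics:
    density: float
    char_path_length: float
    global_efficiency: float
    radius: float
    diameter: float


def threshold_adjacency(
    conn: ConnectivityMatrix | np.ndarray,
    mode: str = "proportional",
    value: float = 1.0,
    node_labels: list[str] | None = None,
    node_positions: np.ndarray | None = None,
) -> BrainGraph:
    """Threshold a connectivity matrix into a BrainGraph.

    ``absolute`` keeps edges with weight > value; ``proportional`` keeps
    the strongest ``value``-fraction of off-diagonal entries (ties at the
    cut broken by stable index order, with a log message). Kept edges
    retain their weights.
    """
    if isinstance(conn, ConnectivityMatrix):
        values = conn.values
        node_labels = node_labels or list(conn.node_labels)
    else:
        values = np.asarray(conn, dtype=float)
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    w = values[iu]
    if mode == "absolute":
        if value < 0:
            raise ParameterError("absolute threshold must be >= 0")
        keep = w > value
    elif mode == "proportional":
        if not 0 < value <= 1:
            raise ParameterError(
                f"proportional threshold must lie in (0, 1], got {value}"
            )
        k = int(round(value * w.size))
        order = np.argsort(-w, kind="stable")
        if 0 < k < w.size and w[order[k - 1]] == w[order[k]]:
            logger.info(
                "proportional threshold ties at the cut weight %g broken by "
                "index order", w[order[k]],
            )
        keep = np.zeros(w.size, dtype=bool)
        keep[order[:k]] = True
    else:
        raise ParameterError(
            f"mode must be 'absolute' or 'proportional', got {mode!r}"
        )
    adj = np.zeros_like(values)
    adj[iu[0][keep], iu[1][keep]] = w[keep]
    adj += adj.T
    return BrainGraph(adj, node_labels=node_labels, node_positions=node_positions)


def _distance_graph(g: BrainGraph, weighted_paths: bool) -> nx.Graph:
    gx = nx.from_numpy_array(g.binary if not weighted_paths else g.adjacency)
    if weighted_paths:
        for _, _, d in gx.edges(data=True):
            d["length"] = 1.0 / d["weight"]
    return gx


def _all_pairs_distances(
    g: BrainGraph, weighted_paths: bool = False
) -> np.ndarray:
    """Pairwise distance matrix; inf for disconnected pairs."""
    n = g.n_nodes
    gx = _distance_graph(g, weighted_paths)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    if weighted_paths:
        it = nx.all_pairs_dijkstra_path_length(gx, weight="length")
    else:
        it = nx.all_pairs_shortest_path_length(gx)
    for i, row in it:
        for j, d in row.items():
            dist[i, j] = d
    return dist


def _cpl_efficiency(dist: np.ndarray) -> tuple[float, float]:
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    finite = np.isfinite(d)
    cpl = float(d[finite].mean()) if finite.any() else float("inf")
    inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
    eff = float(inv.mean()) if d.size else 0.0
    return cpl, eff


def global_metrics(
    g: BrainGraph, weighted_paths: bool = False
) -> GlobalMetrics:
    """Density and the path-based global metrics (see module docstring)."""
    n = g.n_nodes
    if n < 2:
        raise ParameterError("need at least 2 nodes")
    density = 2.0 * g.n_edges / (n * (n - 1))
    dist = _all_pairs_distances(g, weighted_paths)
    cpl, eff = _cpl_efficiency(dist)
    ecc = dist.max(axis=1)  # inf when any pair is unreachable
    radius = float(ecc.min())
    diameter = float(ecc.max())
    return GlobalMetrics(
        density=density, char_path_length=cpl, global_efficiency=eff,
        radius=radius, diameter=diameter,
    )


def node_metrics(
    g: BrainGraph,
    partition: ModulePartition | None = None,
    weighted_paths: bool = False,
    normalized_betweenness: bool = False,
) -> pd.DataFrame:
    """Per-node metric table: degree, strength, clustering, coreness,
    betweenness, participation.

    ``partition`` feeds the participation coefficient; when omitted,
    modules are detected with the default seed. Betweenness is raw
    (pair counts) unless ``normalized_betweenness``.
    """
    n = g.n_nodes
    if partition is None:
        partition = detect_modules(g, seed=0)
    if partition.community_id.size != n:
        raise AlignmentError(
            f"partition covers {partition.community_id.size} nodes, graph "
            f"has {n}"
        )
    binary = g.binary
    degree = binary.sum(axis=1)
    strength = g.adjacency.sum(axis=1)
    gb = nx.from_numpy_array(binary)
    clustering = np.array([nx.clustering(gb, i) for i in range(n)])
    coreness = np.array([nx.core_number(gb)[i] for i in range(n)])
    gx = _distance_graph(g, weighted_paths)
    btw = nx.betweenness_centrality(
        gx, normalized=normalized_betweenness,
        weight="length" if weighted_paths else None,
    )
    betweenness = np.array([btw[i] for i in range(n)])
    participation = np.zeros(n)
    for i in range(n):
        k = degree[i]
        if k == 0:
            continue
        k_im = np.bincount(
            partition.community_id[binary[i] > 0],
            minlength=partition.n_communities,
        )
        participation[i] = 1.0 - float(np.sum((k_im / k) ** 2))
    return pd.DataFrame(
        {
            "degree": degree,
            "strength": strength,
            "clustering": clustering,
            "coreness": coreness,
            "betweenness": betweenness,
            "participation": participation,
        },
        index=pd.Index(g.node_labels, name="label"),
    )


def edge_metrics(
    g: BrainGraph, weighted_paths: bool = False
) -> pd.DataFrame:
    """Per-edge table: edge betweenness, neighbourhood overlap, and the
    shortcut flag with its characteristic-path-length increment.

    ``delta_cpl`` is CPL(graph without the edge) - CPL(graph); an edge is
    flagged a shortcut when its removal increases the CPL (disconnected
    pairs follow the same exclusion convention as :func:`global_metrics`).
    """
    if g.n_edges == 0:
        raise ParameterError("graph has no edges")
    gx = _distance_graph(g, weighted_paths)
    ebc = nx.edge_betweenness_centrality(
        gx, normalized=False, weight="length" if weighted_paths else None
    )
    binary = g.binary.astype(bool)
    cpl0, _ = _cpl_efficiency(_all_pairs_distances(g, weighted_paths))
    rows = []
    iu, ju = np.nonzero(np.triu(g.adjacency, k=1))
    for i, j in zip(iu, ju):
        overlap = int(np.sum(binary[i] & binary[j]))
        adj = g.adjacency.copy()
        adj[i, j] = adj[j, i] = 0.0
        sub = BrainGraph(adj, node_labels=g.node_labels)
        cpl1, _ = _cpl_efficiency(_all_pairs_distances(sub, weighted_paths))
        delta = cpl1 - cpl0
        if not np.isfinite(delta):
            delta = float("inf") if cpl1 > cpl0 else 0.0
        rows.append(
            {
                "u": g.node_labels[i],
                "v": g.node_labels[j],
                "edge_betweenness": float(ebc[(i, j) if (i, j) in ebc else (j, i)]),
                "neighborhood_overlap": overlap,
                "delta_cpl": float(delta),
                "is_shortcut": bool(delta > 1e-12),
            }
        )
    return pd.DataFrame(rows)


def detect_modules(g: BrainGraph, seed: int = 0, n_restarts: int = 20) -> ModulePartition:
    """Weighted modularity maximization (Louvain-style greedy moves).

    Restarted ``n_restarts`` times with seeds derived from ``seed``; the
    partition with the best modularity Q is kept. Deterministic given the
    seed. A graph with no edges yields one community per node and Q = 0.
    """
    if g.n_nodes < 1:
        raise ParameterError("empty graph")
    gx = nx.from_numpy_array(g.adjacency)
    if g.n_edges == 0:
        return ModulePartition(np.arange(g.n_nodes), 0.0)
    best_q, best_comms = -np.inf, None
    for s in spawn_seeds(seed, n_restarts):
        comms = nx.community.louvain_communities(
            gx, weight="weight", seed=int(s)
        )
        q = nx.community.modularity(gx, comms, weight="weight")
        if q > best_q:
            best_q, best_comms = q, comms
    ids = np.empty(g.n_nodes, dtype=int)
    # contiguous ids ordered by each community's smallest node index
    for cid, comm in enumerate(sorted(best_comms, key=min)):
        ids[list(comm)] = cid
    return ModulePartition(ids, float(best_q))


def aggregate_by_region(
    nm: pd.DataFrame, atlas: ScoutAtlas, level: str = "roi"
) -> pd.DataFrame:
    """Aggregate a node-metric table per ROI or per lobe and hemisphere.

    ``level='roi'`` passes the table through (after checking every node
    label maps to an atlas ROI); ``level='lobe'`` returns the unweighted
    mean of member-ROI values per (lobe, hemisphere).
    """
    labels = list(nm.index.astype(str))
    missing = sorted(set(labels) - set(atlas.roi_labels))
    if missing:
        raise AlignmentError(
            f"node label(s) not in atlas: {missing[:10]}"
        )
    if level == "roi":
        return nm.copy()
    if level != "lobe":
        raise ParameterError(f"level must be 'roi' or 'lobe', got {level!r}")
    lobe_of = dict(zip(atlas.roi_labels, atlas.lobes))
    hemi_of = dict(zip(atlas.roi_labels, atlas.hemispheres()))
    tagged = nm.copy()
    tagged["lobe"] = [lobe_of[l] for l in labels]
    tagged["hemisphere"] = [hemi_of[l] for l in labels]
    out = tagged.groupby(["lobe", "hemisphere"], sort=True).mean(
        numeric_only=True
    )
    return out
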