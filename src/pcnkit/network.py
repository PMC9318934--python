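"""Protein Contact Network construction and topological descriptors.

A contact network has one node per residue and an undirected edge wherever
the Cα-Cα distance falls inside a band, by default the closed interval
[4, 8] Å. The 4 Å lower cutoff removes the trivial covalent-neighbour
contacts (consecutive Cα pairs sit near 3.8 Å), so the network reflects
tertiary packing rather than chain connectivity.

Node-level descriptors: degree k_i (adjacency row sum), clustering
coefficient, unweighted shortest-path matrix (hop counts), unnormalized
shortest-path betweenness (Brandes accumulation: endpoints excluded, each
unordered pair counted once, fractional credit split over equally short
paths) and closeness as the reciprocal of farness (the sum of a node's
shortest paths, taken within its connected component).

Network-level descriptors: means of the above, graph energy (sum of the
absolute adjacency eigenvalues), degree- and hydropathy-based
assortativity (Pearson correlation of endpoint values over edges),
dyadicity and heterophilicity (observed over expected same-class /
cross-class edge counts under random mixing), plus the Jaccard contact
overlap between two networks and active-minus-inactive difference maps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp
from scipy.spatial.distance import pdist, squareform

from .constants import HYDROPHOBIC
from .structure_io import StructureFrame

logger = logging.getLogger(__name__)

__all__ = [
    "ContactNetwork",
    "NodeDescriptors",
    "NetworkSummary",
    "DifferenceMap",
    "build_pcn",
    "node_degrees",
    "clustering_coefficients",
    "shortest_path_matrix",
    "betweenness",
    "closeness",
    "graph_energy",
    "degree_assortativity",
    "value_assortativity",
    "dyadicity_heterophilicity",
    "jaccard_similarity",
    "node_descriptors",
    "network_summary",
    "difference_map",
    "threshold_nodes",
]


@dataclass
class ContactNetwork:
    """Symmetric binary adjacency over an ordered residue set."""

    adjacency: np.ndarray
    node_labels: list[str]
    cutoffs: tuple[float, float] = (4.0, 8.0)
    frame: StructureFrame | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if A.shape[0] != len(self.node_labels):
            raise ValueError("node_labels length mismatch")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = A.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_graph(self) -> nx.Graph:
        G = nx.from_numpy_array(self.adjacency)
        return G

    def edge_index_pairs(self) -> np.ndarray:
        """(m, 2) array of node-index pairs i < j with an edge."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu, ju] == 1
        return np.column_stack([iu[mask], ju[mask]])


def build_pcn(
    frame: StructureFrame,
    r_min: float = 4.0,
    r_max: float = 8.0,
) -> ContactNetwork:
    """Build the contact network of one frame.

    An edge joins residues i, j iff r_min <= d(Cα_i, Cα_j) <= r_max
    (closed interval at both ends).
    """
    if len(frame) < 2:
        raise ValueError("need at least 2 residues to build a network")
    if not r_min < r_max:
        raise ValueError("require r_min < r_max")
    d = squareform(pdist(frame.coords))
    A = ((d >= r_min) & (d <= r_max)).astype(np.int8)
    np.fill_diagonal(A, 0)
    return ContactNetwork(A, frame.keys, (float(r_min), float(r_max)), frame=frame)


def node_degrees(net: ContactNetwork) -> np.ndarray:
    """k_i: sum of the i-th adjacency row."""
    return net.adjacency.sum(axis=1).astype(int)


def clustering_coefficients(net: ContactNetwork) -> np.ndarray:
    """Fraction of a node's neighbour pairs that are themselves connected.

    Nodes with degree < 2 get 0.
    """
    cc = nx.clustering(net.to_graph())
    return np.array([cc[i] for i in range(net.n_nodes)], dtype=float)


def shortest_path_matrix(net: ContactNetwork) -> np.ndarray:
    """Unweighted hop-count matrix; unreachable pairs are ``inf``."""
    sp = _csgraph_sp(csr_matrix(net.adjacency), method="D", unweighted=True)
    if np.isinf(sp).any():
        logger.warning("contact network is disconnected; unreachable pairs flagged inf")
    return sp


def betweenness(net: ContactNetwork) -> np.ndarray:
    """Unnormalized shortest-path betweenness (Brandes accumulation).

    Endpoints excluded; each unordered pair counted once; paths tied for
    shortest share credit fractionally.
    """
    b = nx.betweenness_centrality(net.to_graph(), normalized=False)
    return np.array([b[i] for i in range(net.n_nodes)], dtype=float)


def closeness(net: ContactNetwork, sp: np.ndarray | None = None) -> np.ndarray:
    """1 / farness, with farness summed inside the node's component.

    Isolated nodes (no reachable partner) get NaN.
    """
    if sp is None:
        sp = shortest_path_matrix(net)
    finite = np.isfinite(sp)
    np.fill_diagonal(finite, False)
    farness = np.where(finite, sp, 0.0).sum(axis=1)
    out = np.full(net.n_nodes, np.nan)
    ok = farness > 0
    out[ok] = 1.0 / farness[ok]
    return out


def graph_energy(net: ContactNetwork) -> float:
    """Sum of absolute eigenvalues of the adjacency matrix."""
    lam = np.linalg.eigvalsh(net.adjacency.astype(float))
    return float(np.abs(lam).sum())


def _edge_endpoint_values(net: ContactNetwork, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pairs = net.edge_index_pairs()
    x = values[pairs[:, 0]]
    y = values[pairs[:, 1]]
    # both orientations, so the coefficient is symmetric in the endpoints
    return np.concatenate([x, y]), np.concatenate([y, x])


def value_assortativity(net: ContactNetwork, values: np.ndarray) -> float:
    """Pearson correlation of endpoint values over edges (both orientations).

    Returns NaN (flagged) when the endpoint values have zero variance,
    e.g. on a regular graph for degree-based assortativity.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (net.n_nodes,):
        raise ValueError("values must align with nodes")
    if net.n_edges == 0:
        return float("nan")
    x, y = _edge_endpoint_values(net, values)
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero-variance endpoint values; assortativity undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def degree_assortativity(net: ContactNetwork) -> float:
    """Degree-based assortativity (DBA)."""
    return value_assortativity(net, node_degrees(net).astype(float))


def dyadicity_heterophilicity(
    net: ContactNetwork, classes: np.ndarray
) -> tuple[float, float]:
    """Dyadicity and heterophilicity of a binary node labelling.

    Dy = observed hydrophobic-hydrophobic edges over the expectation under
    random mixing with the observed class counts and edge total,
    m * n1(n1-1) / (n(n-1)); H is the analogous ratio for mixed edges with
    expectation m * 2 n1 n0 / (n(n-1)).
    """
    classes = np.asarray(classes)
    if classes.shape != (net.n_nodes,):
        raise ValueError("classes must align with nodes")
    is_h = (classes == HYDROPHOBIC) | (classes == 1) | (classes == True)  # noqa: E712
    n = net.n_nodes
    n1 = int(is_h.sum())
    n0 = n - n1
    m = net.n_edges
    pairs = net.edge_index_pairs()
    hh = int((is_h[pairs[:, 0]] & is_h[pairs[:, 1]]).sum())
    hp = int((is_h[pairs[:, 0]] ^ is_h[pairs[:, 1]]).sum())
    exp_hh = m * n1 * (n1 - 1) / (n * (n - 1))
    exp_hp = m * 2 * n1 * n0 / (n * (n - 1))
    dy = hh / exp_hh if exp_hh > 0 else float("nan")
    h = hp / exp_hp if exp_hp > 0 else float("nan")
    return float(dy), float(h)


def jaccard_similarity(net_a: ContactNetwork, net_b: ContactNetwork) -> float:
    """Contact overlap M11 / (M10 + M01 + M11) over unordered pairs."""
    if net_a.node_labels != net_b.node_labels:
        raise ValueError("networks must share node set and order")
    iu = np.triu_indices(net_a.n_nodes, k=1)
    a = net_a.adjacency[iu].astype(bool)
    b = net_b.adjacency[iu].astype(bool)
    m11 = int((a & b).sum())
    m10 = int((a & ~b).sum())
    m01 = int((~a & b).sum())
    denom = m11 + m10 + m01
    return float(m11 / denom) if denom else 1.0


@dataclass
class NodeDescriptors:
    """Per-node topological descriptors of one contact network."""

    node_labels: list[str]
    k: np.ndarray
    cc: np.ndarray
    btw: np.ndarray
    close: np.ndarray
    sp: np.ndarray


def node_descriptors(net: ContactNetwork) -> NodeDescriptors:
    sp = shortest_path_matrix(net)
    return NodeDescriptors(
        node_labels=list(net.node_labels),
        k=node_degrees(net),
        cc=clustering_coefficients(net),
        btw=betweenness(net),
        close=closeness(net, sp),
        sp=sp,
    )


@dataclass
class NetworkSummary:
    """Whole-network descriptor block (the topology half of the MVA table)."""

    adeg: float
    acc: float
    abtw: float
    aclose: float
    asp: float
    E: float
    DBA: float
    HBAKD: float
    Dy: float
    H: float

    def as_dict(self) -> dict[str, float]:
        return {
            "adeg": self.adeg, "acc": self.acc, "abtw": self.abtw,
            "aclose": self.aclose, "asp": self.asp, "E": self.E,
            "DBA": self.DBA, "HBAKD": self.HBAKD, "Dy": self.Dy, "H": self.H,
        }


def network_summary(
    net: ContactNetwork,
    desc: NodeDescriptors | None = None,
    kd_values: np.ndarray | None = None,
    hp_classes: np.ndarray | None = None,
) -> NetworkSummary:
    """Aggregate node descriptors into the network-level block.

    Averages over shortest paths and closeness exclude unreachable pairs
    (component-wise convention for disconnected networks). ``kd_values``
    and ``hp_classes`` default to the annotations of the frame the network
    was built from.
    """
    if desc is None:
        desc = node_descriptors(net)
    if kd_values is None and net.frame is not None:
        kd_values = net.frame.kd_values
    if hp_classes is None and net.frame is not None:
        hp_classes = net.frame.hp_classes
    iu = np.triu_indices(net.n_nodes, k=1)
    sp_off = desc.sp[iu]
    sp_fin = sp_off[np.isfinite(sp_off)]
    return NetworkSummary(
        adeg=float(desc.k.mean()),
        acc=float(desc.cc.mean()),
        abtw=float(desc.btw.mean()),
        aclose=float(np.nanmean(desc.close)),
        asp=float(sp_fin.mean()) if sp_fin.size else float("nan"),
        E=graph_energy(net),
        DBA=degree_assortativity(net),
        HBAKD=value_assortativity(net, kd_values) if kd_values is not None else float("nan"),
        **dict(zip(("Dy", "H"), dyadicity_heterophilicity(net, hp_classes)
                   if hp_classes is not None else (float("nan"), float("nan")))),
    )


@dataclass
class DifferenceMap:
    """Active-minus-inactive node differences with threshold selections."""

    node_labels: list[str]
    delta_k: np.ndarray
    delta_btw: np.ndarray
    theta_k: float
    theta_btw: float
    selected_k: set[str] = field(default_factory=set)
    selected_btw: set[str] = field(default_factory=set)


def threshold_nodes(values: np.ndarray, theta: float,
                    labels: list[str] | None = None) -> set:
    """Nodes with value strictly greater than theta."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    idx = np.nonzero(values > theta)[0]
    if labels is None:
        return set(int(i) for i in idx)
    return {labels[i] for i in idx}


def difference_map(
    active: NodeDescriptors,
    inactive: NodeDescriptors,
    theta_k: float = 1.0,
    theta_btw: float = 500.0,
) -> DifferenceMap:
    """Δk_i and Δbtw_i (active − inactive) with strict |Δ| > θ selections."""
    if active.node_labels != inactive.node_labels:
        raise ValueError("descriptor sets are not residue-aligned")
    dk = active.k.astype(float) - inactive.k.astype(float)
    db = active.btw - inactive.btw
    labels = list(active.node_labels)
    return DifferenceMap(
        node_labels=labels,
        delta_k=dk,
        delta_btw=db,
        theta_k=theta_k,
        theta_btw=theta_btw,
        selected_k=threshold_nodes(np.abs(dk), theta_k, labels),
        selected_btw=threshold_nodes(np.abs(db), theta_btw, labels),
    )
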