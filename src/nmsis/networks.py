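"""Undirected simple networks: generation, edge-list IO, spectral threshold.

The dynamics run on a fixed undirected simple graph.  Internally nodes are
labelled 0..N-1 and each undirected edge is stored once as a sorted pair;
the event-driven simulator additionally views every undirected edge as two
directed edges (CSR layout with a reverse-edge map, see
:meth:`Network.directed_arrays`).

The quenched mean-field outbreak threshold is ``1 / Lambda_max`` with
``Lambda_max`` the leading eigenvalue of the adjacency matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._rng import generator

__all__ = [
    "Network",
    "erdos_renyi",
    "barabasi_albert",
    "powerlaw_configuration",
    "generate_network",
    "read_edge_list",
    "write_edge_list",
    "leading_eigenvalue",
    "epidemic_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class Network:
    """An undirected simple graph on nodes 0..n-1.

    ``edges`` is an (m, 2) int array with each undirected edge stored once,
    ``edges[:, 0] < edges[:, 1]``, sorted lexicographically.
    """

    n: int
    edges: np.ndarray
    #: optional original labels (index -> label) from an edge-list file
    labels: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            edges = np.sort(edges, axis=1)
            edges = np.unique(edges, axis=0)
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loops are not allowed in a simple graph")
            if edges.max() >= self.n or edges.min() < 0:
                raise ValueError("edge endpoints outside 0..n-1")
        self.edges = edges

    @property
    def m(self) -> int:
        """Number of undirected edges."""
        return int(self.edges.shape[0])

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 CSR adjacency matrix."""
        if "adj" not in self._cache:
            if self.m:
                u, v = self.edges[:, 0], self.edges[:, 1]
                rows = np.concatenate([u, v])
                cols = np.concatenate([v, u])
                data = np.ones(rows.shape[0])
                adj = sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))
            else:
                adj = sp.csr_matrix((self.n, self.n))
            self._cache["adj"] = adj
        return self._cache["adj"]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel().astype(np.int64)

    def mean_degree(self) -> float:
        return 2.0 * self.m / self.n if self.n else 0.0

    def directed_arrays(self):
        """CSR layout of the 2m directed edges plus the reverse-edge map.

        Returns ``(indptr, dst, src, pair)`` where directed edge ``e`` runs
        ``src[e] -> dst[e]``, edges with the same source are contiguous
        (``indptr`` indexes them), and ``pair[e]`` is the opposite
        orientation of the same undirected edge.
        """
        if "directed" not in self._cache:
            adj = self.adjacency().astype(np.int64)
            indptr = adj.indptr.astype(np.int64)
            dst = adj.indices.astype(np.int64)
            src = np.repeat(np.arange(self.n, dtype=np.int64), np.diff(indptr))
            order = {}
            pair = np.empty_like(dst)
            for e in range(dst.shape[0]):
                key = (dst[e], src[e])
                if key in order:
                    f = order.pop(key)
                    pair[e] = f
                    pair[f] = e
                else:
                    order[(src[e], dst[e])] = e
            assert not order
            self._cache["directed"] = (indptr, dst, src, pair)
        return self._cache["directed"]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        mapping = {node: i for i, node in enumerate(sorted(g.nodes()))}
        edges = np.array([(mapping[u], mapping[v]) for u, v in g.edges() if u != v],
                         dtype=np.int64).reshape(-1, 2)
        labels = np.array(sorted(g.nodes()))
        return cls(n=g.number_of_nodes(), edges=edges, labels=labels)


# ---------------------------------------------------------------------------
# generators


def erdos_renyi(n: int, mean_degree: float, seed: int) -> Network:
    """G(n, p) with p = mean_degree / (n - 1)."""
    if n < 2:
        raise ValueError("need at least two nodes")
    p = mean_degree / (n - 1)
    g = nx.fast_gnp_random_graph(n, p, seed=int(seed))
    return Network.from_networkx(g)


def barabasi_albert(n: int, m: int, seed: int) -> Network:
    """Preferential attachment with m edges per new node (mean degree -> 2m)."""
    g = nx.barabasi_albert_graph(n, int(m), seed=int(seed))
    return Network.from_networkx(g)


def powerlaw_configuration(n: int, exponent: float, k_min: int, seed: int,
                           k_max: int | None = None,
                           max_rewire_factor: int = 100) -> Network:
    """Simple configuration-model graph with P(k) ∝ k**(-exponent), k >= k_min.

    Stubs are matched uniformly at random; self-loops and multi-edges are then
    removed by degree-preserving edge swaps, with at most
    ``max_rewire_factor * E`` attempts before giving up.
    """
    if n < 2 or k_min < 1:
        raise ValueError("need n >= 2 and k_min >= 1")
    rng = generator(seed, "powerlaw-config")
    if k_max is None:
        k_max = min(n - 1, max(k_min + 1, int(round(np.sqrt(n) * k_min))))
    ks = np.arange(k_min, k_max + 1)
    pk = ks.astype(float) ** (-exponent)
    pk /= pk.sum()
    degrees = rng.choice(ks, size=n, p=pk)
    if degrees.sum() % 2:
        degrees[rng.integers(n)] += 1

    stubs = np.repeat(np.arange(n, dtype=np.int64), degrees)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)
    n_edges = pairs.shape[0]
    budget = max_rewire_factor * n_edges

    edge_set: set[tuple[int, int]] = set()
    bad: list[tuple[int, int]] = []
    for u, v in pairs:
        u, v = int(u), int(v)
        key = (min(u, v), max(u, v))
        if u == v or key in edge_set:
            bad.append((u, v))
        else:
            edge_set.add(key)
    attempts = 0
    edge_list = list(edge_set)
    while bad and attempts < budget:
        attempts += 1
        u, v = bad.pop()
        j = int(rng.integers(len(edge_list)))
        x, y = edge_list[j]
        # swap to (u, x) and (v, y)
        a = (min(u, x), max(u, x))
        b = (min(v, y), max(v, y))
        if u == x or v == y or a in edge_set or b in edge_set or a == b:
            bad.append((u, v))
            continue
        edge_set.discard((min(x, y), max(x, y)))
        edge_set.add(a)
        edge_set.add(b)
        edge_list[j] = a
        edge_list.append(b)
        # the (v, y) slot replaces the popped bad pair; nothing left to do
    if bad:
        raise RuntimeError(
            f"configuration model could not be made simple after {budget} swaps")
    edges = np.array(sorted(edge_set), dtype=np.int64)
    return Network(n=n, edges=edges)


_MODELS = {"er", "ba", "powerlaw_config", "file"}


def generate_network(model: str, seed: int = 0, **params) -> Network:
    """Dispatch on the model name (er / ba / powerlaw_config / file)."""
    model = model.lower()
    if model == "er":
        return erdos_renyi(params["n"], params["mean_degree"], seed)
    if model == "ba":
        return barabasi_albert(params["n"], params["m"], seed)
    if model == "powerlaw_config":
        return powerlaw_configuration(params["n"], params["exponent"],
                                      params["k_min"], seed,
                                      k_max=params.get("k_max"))
    if model == "file":
        return read_edge_list(params["path"])
    raise ValueError(f"unknown network model {model!r}; expected one of {_MODELS}")


# ---------------------------------------------------------------------------
# edge-list IO


def read_edge_list(path) -> Network:
    """Read a whitespace-separated integer edge list.

    Lines starting with '#' are ignored; duplicate and reversed pairs collapse
    to one undirected edge; self-loops are dropped with a warning.  Arbitrary
    integer labels are remapped to a dense 0-based index (kept in
    ``Network.labels``).
    """
    raw: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected two integers, got {line!r}")
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer token in {line!r}") from exc
            if u == v:
                logger.warning("%s:%d: dropping self-loop %d-%d", path, lineno, u, v)
                continue
            raw.append((u, v))
    if not raw:
        raise ValueError(f"{path}: no edges found")
    labels = np.unique(np.array(raw, dtype=np.int64))
    index = {int(lab): i for i, lab in enumerate(labels)}
    edges = np.array([(index[u], index[v]) for u, v in raw], dtype=np.int64)
    return Network(n=len(labels), edges=edges, labels=labels)


def write_edge_list(net: Network, path) -> None:
    """Write one undirected edge per line using internal 0-based ids."""
    with open(path, "w") as fh:
        for u, v in net.edges:
            fh.write(f"{u} {v}\n")


# ---------------------------------------------------------------------------
# spectral quantities


def leading_eigenvalue(net: Network, tol: float = 1e-10) -> float:
    """Largest adjacency eigenvalue (Perron root of the largest component)."""
    if net.n == 0 or net.m == 0:
        raise ValueError("leading eigenvalue of an empty graph is undefined")
    key = ("lam_max", tol)
    if key not in net._cache:
        adj = net.adjacency().astype(float)
        if net.n < 200:
            lam = float(np.linalg.eigvalsh(adj.toarray()).max())
        else:
            vals = spla.eigsh(adj, k=1, which="LA", tol=tol,
                              return_eigenvectors=False)
            lam = float(vals[0])
        net._cache[key] = lam
    return net._cache[key]


def epidemic_threshold(net: Network) -> float:
    """Quenched mean-field outbreak threshold 1 / Lambda_max."""
    lam = leading_eigenvalue(net)
    if lam <= 0:
        raise ValueError("non-positive leading eigenvalue")
    return 1.0 / lam
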