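"""Graph ensembles and their annealed (weighted fully-connected) view.

The generators produce the undirected, simple graphs on which the noisy
voter dynamics runs: Erdős–Rényi, Barabási–Albert, dichotomous (two-valued
degree sequence), complete, random-regular and periodic 2D lattice graphs.
All ensembles are parameterised so that a common mean degree can be held
fixed while the degree *heterogeneity* — the variance of the degree
distribution — varies, which is the structural property the annealed
theory singles out.

The annealed view replaces the adjacency matrix by connection
probabilities of the uncorrelated configuration ensemble,
``w_ij = k_i k_j / (N mu_k)``, which preserves every node's degree in the
row-sum sense and is accurate below the structural cutoff
``k_max <= sqrt(mu_k N)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "Graph",
    "DegreeStats",
    "AnnealedWeights",
    "make_network",
    "degree_stats",
    "annealed_weights",
    "check_uncorrelated",
    "read_edgelist",
    "write_edgelist",
]

_MAX_RETRIES = 100


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph with 0-based contiguous node ids.

    ``adjacency`` is a symmetric CSR boolean/0-1 matrix with zero diagonal;
    ``degrees`` its row sums. Every node has degree >= 1 (the dynamics
    divides by neighbour counts).
    """

    N: int
    adjacency: sp.csr_matrix
    degrees: np.ndarray
    kind_label: str = "custom"

    def __post_init__(self) -> None:
        A = self.adjacency
        if A.shape != (self.N, self.N):
            raise ValueError("adjacency shape does not match N")
        if (A != A.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().sum() != 0:
            raise ValueError("self-loops are not allowed")
        deg = np.asarray(A.sum(axis=1)).ravel()
        if not np.array_equal(deg.astype(np.int64), np.asarray(self.degrees, dtype=np.int64)):
            raise ValueError("degrees field inconsistent with adjacency")
        if int(deg.sum()) % 2 != 0:
            raise ValueError("total degree must be even")
        if deg.min() < 1:
            raise ValueError("isolated nodes (degree 0) are not allowed")

    @property
    def n_edges(self) -> int:
        return int(self.degrees.sum()) // 2

    @classmethod
    def from_networkx(cls, G: nx.Graph, kind_label: str = "custom") -> "Graph":
        G = nx.convert_node_labels_to_integers(G, ordering="sorted")
        A = nx.to_scipy_sparse_array(G, nodelist=range(G.number_of_nodes()), format="csr")
        A = sp.csr_matrix((np.ones(A.nnz, dtype=np.int8), A.indices, A.indptr), shape=A.shape)
        deg = np.asarray(A.sum(axis=1)).ravel().astype(np.int64)
        return cls(N=G.number_of_nodes(), adjacency=A, degrees=deg, kind_label=kind_label)

    def to_networkx(self) -> nx.Graph:
        G = nx.from_scipy_sparse_array(self.adjacency)
        G.remove_edges_from(nx.selfloop_edges(G))
        return G


@dataclass(frozen=True)
class DegreeStats:
    """Moments of a realized degree sequence.

    ``heterogeneity`` is the dimensionless ratio sigma_k^2 / mu_k^2 that
    controls every network-dependent prediction of the annealed theory.
    """

    mu_k: float
    var_k: float
    heterogeneity: float
    second_moment: float
    cutoff_ok: bool
    N: int = 0

    @classmethod
    def from_moments(cls, mu_k: float, var_k: float, N: int = 0, cutoff_ok: bool = True) -> "DegreeStats":
        """Build stats from nominal (design) moments rather than a graph."""
        if mu_k <= 0:
            raise ValueError("mu_k must be positive")
        if var_k < 0:
            raise ValueError("var_k must be nonnegative")
        return cls(
            mu_k=float(mu_k),
            var_k=float(var_k),
            heterogeneity=float(var_k) / float(mu_k) ** 2,
            second_moment=float(var_k) + float(mu_k) ** 2,
            cutoff_ok=bool(cutoff_ok),
            N=int(N),
        )


@dataclass(frozen=True)
class AnnealedWeights:
    """Pairwise connection weights w_ij = k_i k_j / (N mu_k), zero diagonal."""

    weights: np.ndarray
    degrees: np.ndarray = field(repr=False, default=None)

    def row_sum_error(self) -> np.ndarray:
        """Deviation of off-diagonal row sums from the degree sequence.

        With the zero-diagonal convention each row sum is short of k_i by
        exactly the excluded self-term k_i^2/(N mu_k); that is the
        tolerance within which the degree sequence is preserved.
        """
        return np.asarray(self.weights.sum(axis=1)).ravel() - self.degrees


def _graph_from_pairs(pairs: np.ndarray, N: int, kind_label: str) -> Graph:
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    A = sp.csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(N, N))
    deg = np.asarray(A.sum(axis=1)).ravel().astype(np.int64)
    return Graph(N=N, adjacency=A, degrees=deg, kind_label=kind_label)


def _configuration_pairs(seq: np.ndarray, rng: np.random.Generator, max_rounds: int = 500) -> np.ndarray:
    """Configuration-model stub matching with iterative rematching.

    Stubs are paired uniformly; invalid pairs (self-loops or duplicate
    edges) are broken together with an equal number of randomly chosen
    valid pairs and re-matched, until the pairing is simple. This samples
    the uncorrelated configuration ensemble with the degree sequence
    preserved exactly.
    """
    seq = np.asarray(seq, dtype=np.int64)
    N = len(seq)
    if seq.sum() % 2 != 0:
        raise ValueError("degree sequence has an odd number of stubs")
    if seq.max() >= N:
        raise ValueError(f"degree {seq.max()} >= N = {N} is infeasible for a simple graph")
    stubs = np.repeat(np.arange(N), seq)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2).copy()
    for _ in range(max_rounds):
        u, v = pairs[:, 0], pairs[:, 1]
        lo, hi = np.minimum(u, v), np.maximum(u, v)
        key = lo.astype(np.int64) * N + hi
        order = np.argsort(key, kind="stable")
        sk = key[order]
        dup = np.zeros(len(key), dtype=bool)
        dup[order] = np.concatenate([[False], sk[1:] == sk[:-1]])
        bad = dup | (u == v)
        if not bad.any():
            return pairs
        bad_idx = np.flatnonzero(bad)
        good_idx = np.flatnonzero(~bad)
        n_mix = min(len(good_idx), len(bad_idx))
        extra = rng.choice(good_idx, size=n_mix, replace=False) if n_mix else np.empty(0, dtype=int)
        sel = np.concatenate([bad_idx, extra])
        pool = pairs[sel].ravel()
        rng.shuffle(pool)
        pairs[sel] = pool.reshape(-1, 2)
    raise RuntimeError(
        "configuration-model stub matching failed to produce a simple graph "
        f"after {max_rounds} rematching rounds (degree sequence too dense?)"
    )


def make_network(kind: str, N: int, *, seed: int, mean_degree: float | None = None,
                 m: int | None = None, k1: int | None = None, k2: int | None = None,
                 k: int | None = None, side: int | None = None) -> Graph:
    """Generate one graph from a named ensemble.

    Parameters
    ----------
    kind
        One of ``er``, ``ba``, ``dichotomous``, ``complete``,
        ``random_regular``, ``lattice2d``.
    N
        Number of nodes (for ``lattice2d`` it may be omitted in favour of
        ``side``; if both are given they must agree, N = side**2).
    seed
        Seed for the generator; a fixed seed gives a fixed graph.
    mean_degree, m, k1, k2, k, side
        Ensemble parameters: ER needs ``mean_degree``; BA needs ``m``
        (attachment count, mean degree ~ 2m) or ``mean_degree`` (then
        m = round(mean_degree/2)); dichotomous needs ``k1 < k2`` assigned
        to equal halves; random_regular needs ``k``; lattice2d needs
        ``side`` (periodic square lattice, all degrees 4).
    """
    if kind != "lattice2d" and (N is None or N < 2):
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)

    if kind == "complete":
        G = nx.complete_graph(N)
        return Graph.from_networkx(G, "complete")

    if kind == "er":
        if mean_degree is None:
            raise ValueError("er requires mean_degree")
        p = mean_degree / (N - 1)
        if not 0 < p <= 1:
            raise ValueError(f"mean_degree {mean_degree} infeasible for N={N}")
        for _ in range(_MAX_RETRIES):
            G = nx.fast_gnp_random_graph(N, p, seed=int(rng.integers(2**31)))
            deg = np.array([d for _, d in G.degree()])
            if deg.min() >= 1:
                return Graph.from_networkx(G, "er")
        raise RuntimeError(
            f"er generation kept producing isolated nodes after {_MAX_RETRIES} tries "
            f"(mean_degree={mean_degree} too small for N={N}?)")

    if kind == "ba":
        if m is None:
            if mean_degree is None:
                raise ValueError("ba requires m or mean_degree")
            m = int(round(mean_degree / 2))
        if not 1 <= m < N:
            raise ValueError(f"ba attachment count m={m} infeasible for N={N}")
        G = nx.barabasi_albert_graph(N, m, seed=int(rng.integers(2**31)),
                                     initial_graph=nx.complete_graph(m + 1))
        return Graph.from_networkx(G, "ba")

    if kind == "dichotomous":
        if k1 is None or k2 is None:
            raise ValueError("dichotomous requires k1 and k2")
        if k1 < 1 or k2 < 1:
            raise ValueError("dichotomous degrees must be >= 1")
        n1 = (N + 1) // 2
        seq = np.array([k1] * n1 + [k2] * (N - n1), dtype=np.int64)
        if seq.sum() % 2 != 0:
            raise ValueError(
                f"dichotomous sequence with N={N}, k1={k1}, k2={k2} has an odd stub count")
        pairs = _configuration_pairs(seq, rng)
        return _graph_from_pairs(pairs, N, "dichotomous")

    if kind == "random_regular":
        if k is None:
            raise ValueError("random_regular requires k")
        if (N * k) % 2 != 0 or k >= N:
            raise ValueError(f"random_regular with N={N}, k={k} is infeasible")
        G = nx.random_regular_graph(k, N, seed=int(rng.integers(2**31)))
        return Graph.from_networkx(G, "random_regular")

    if kind == "lattice2d":
        if side is None:
            side = int(round(np.sqrt(N)))
        if N is not None and side * side != N:
            raise ValueError(f"lattice2d requires N = side**2 (got N={N}, side={side})")
        G = nx.grid_2d_graph(side, side, periodic=True)
        return Graph.from_networkx(G, "lattice2d")

    raise ValueError(f"unknown network kind {kind!r}")


def degree_stats(g: Graph) -> DegreeStats:
    """Moments of the realized degree sequence (not the nominal ensemble)."""
    k = np.asarray(g.degrees, dtype=float)
    mu = k.mean()
    var = k.var()
    return DegreeStats(
        mu_k=float(mu),
        var_k=float(var),
        heterogeneity=float(var / mu**2),
        second_moment=float((k**2).mean()),
        cutoff_ok=bool(k.max() <= np.sqrt(mu * g.N)),
        N=g.N,
    )


def annealed_weights(g: Graph) -> AnnealedWeights:
    """Uncorrelated-ensemble connection probabilities w_ij = k_i k_j/(N mu_k).

    The diagonal is set to zero; each off-diagonal row sum then equals
    k_i (1 - k_i/(N mu_k)), i.e. the degree sequence is preserved up to
    the excluded self-term. A warning is emitted when the structural
    cutoff is violated, in which case some weights exceed 1 and the
    probabilistic reading breaks down.
    """
    stats = degree_stats(g)
    k = np.asarray(g.degrees, dtype=float)
    W = np.outer(k, k) / (g.N * stats.mu_k)
    np.fill_diagonal(W, 0.0)
    if not stats.cutoff_ok:
        warnings.warn(
            "structural cutoff violated (max degree > sqrt(mu_k N)); "
            "annealed weights are not all valid probabilities",
            RuntimeWarning, stacklevel=2)
    return AnnealedWeights(weights=W, degrees=k)


def check_uncorrelated(g: Graph) -> dict:
    """Diagnostic report on degree correlations. Never raises.

    Returns the degree assortativity (0.0 by convention when undefined,
    e.g. regular graphs), the structural-cutoff status, and a verdict:
    ``pass`` when |assortativity| < 0.05 and the cutoff holds, else
    ``warn``.
    """
    stats = degree_stats(g)
    if stats.var_k == 0:
        assort = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assort = float(nx.degree_assortativity_coefficient(g.to_networkx()))
        if not np.isfinite(assort):
            assort = 0.0
    ok = abs(assort) < 0.05 and stats.cutoff_ok
    return {
        "assortativity": assort,
        "cutoff_ok": stats.cutoff_ok,
        "heterogeneity": stats.heterogeneity,
        "verdict": "pass" if ok else "warn",
    }


def write_edgelist(g: Graph, path) -> None:
    """Write 'u v' pairs, 0-based, one undirected edge per line."""
    A = sp.triu(g.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write(f"# N={g.N} kind={g.kind_label}\n")
        for u, v in zip(A.row, A.col):
            fh.write(f"{u} {v}\n")


def read_edgelist(path, kind_label: str = "file") -> Graph:
    """Read a whitespace-delimited edge list ('#' comments allowed)."""
    edges = []
    n_max = -1
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            u, v = (int(x) for x in line.split()[:2])
            if u == v:
                raise ValueError(f"self-loop {u}-{v} in edge list")
            edges.append((u, v))
            n_max = max(n_max, u, v)
    if not edges:
        raise ValueError("empty edge list")
    pairs = np.unique(np.sort(np.array(edges), axis=1), axis=0)
    return _graph_from_pairs(pairs, n_max + 1, kind_label)
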