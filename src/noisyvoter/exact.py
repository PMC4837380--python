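"""Brute-force ground truth for small systems.

Two solvers: the birth–death chain induced on n by the dynamics on a
complete graph (solvable by detailed balance for any N), and the full
2^N master equation on an arbitrary small graph. Both return stationary
distributions, moments, pairwise covariances and leading relaxation
rates, and are used to validate the transcribed rates and every closed
form of the annealed theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spl

from .dynamics import ModelParams, SystemState, flip_rate
from .networks import Graph

__all__ = ["ExactSolution", "birth_death_stationary", "ctmc_solve"]

_MAX_FULL_N = 12


@dataclass
class ExactSolution:
    """Exact stationary solution of a small system."""

    stationary: np.ndarray          # over n = 0..N (chain) or 2^N states (full)
    var_n: float
    mean_n: float
    cov: np.ndarray | None = None   # pairwise covariances sigma_ij (full solver)
    relaxation_rates: np.ndarray | None = None
    marginal_n: np.ndarray | None = None
    absorbing: bool = False
    meta: dict = field(default_factory=dict)


def birth_death_rates(N: int, p: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Up/down rates of the induced chain on n for the complete graph.

    A node in state 0 sees n disagreeing neighbours out of k = N−1, so
    W⁺(n) = (N−n)(a + h n/(N−1)) and W⁻(n) = n (a + h (N−n)/(N−1)).
    """
    n = np.arange(N + 1, dtype=float)
    k = N - 1
    up = (N - n) * (p.a + p.h * n / k)
    down = n * (p.a + p.h * (N - n) / k)
    return up, down


def birth_death_stationary(N: int, p: ModelParams) -> ExactSolution:
    """Exact stationary distribution of n on the complete graph.

    Detailed balance gives P(n) ∝ Π_{m=1}^{n} W⁺(m−1)/W⁻(m). The
    distribution is exactly uniform at a = h/(N−1), is bimodal below and
    unimodal above that value, and approaches Binomial(N, 1/2) as
    a/h → ∞. With a = 0 the chain is absorbing at n ∈ {0, N} and the
    returned distribution is the flagged two-point absorbing structure.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    up, down = birth_death_rates(N, p)
    if p.a == 0:
        pi = np.zeros(N + 1)
        pi[0] = pi[N] = 0.5
        var = (pi * np.arange(N + 1) ** 2).sum() - (N / 2) ** 2
        return ExactSolution(stationary=pi, var_n=float(var), mean_n=N / 2,
                             absorbing=True)
    log_pi = np.concatenate([[0.0], np.cumsum(np.log(up[:-1]) - np.log(down[1:]))])
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    pi /= pi.sum()
    n = np.arange(N + 1)
    mean = float(pi @ n)
    var = float(pi @ n**2 - mean**2)
    # slowest relaxation rate of the tridiagonal generator
    rates = None
    if N <= 400:
        Q = np.zeros((N + 1, N + 1))
        Q[n[:-1] + 1, n[:-1]] = up[:-1]
        Q[n[1:] - 1, n[1:]] = down[1:]
        Q[n, n] = -(up + down)
        ev = np.linalg.eigvals(Q)
        rates = np.sort(-np.real(ev))
        rates[np.abs(rates) < 1e-10] = 0.0
    return ExactSolution(stationary=pi, var_n=var, mean_n=mean,
                         relaxation_rates=rates)


def _build_generator(g: Graph, p: ModelParams):
    N = g.N
    ns = 2**N
    k = g.degrees.astype(np.int64)
    indptr, indices = g.adjacency.indptr, g.adjacency.indices
    rows = np.empty(ns * N, dtype=np.int64)
    cols = np.empty(ns * N, dtype=np.int64)
    vals = np.empty(ns * N, dtype=float)
    pos = 0
    for s_idx in range(ns):
        s = (s_idx >> np.arange(N)) & 1
        for i in range(N):
            nbrs = indices[indptr[i]:indptr[i + 1]]
            disagree = int(np.sum(s[nbrs] != s[i]))
            rows[pos] = s_idx ^ (1 << i)
            cols[pos] = s_idx
            vals[pos] = p.a + p.h * disagree / k[i]
            pos += 1
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(ns, ns)).tocsc()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=0)).ravel())
    return Q.tocsc()


def ctmc_solve(g: Graph, p: ModelParams, n_relaxation_rates: int = 4) -> ExactSolution:
    """Solve the full master equation over the 2^N configurations.

    States are bit-encoded with node 0 as the least significant bit. The
    stationary vector is the null space of the generator (solved with a
    normalization row replacing one balance row); pairwise covariances
    σ_ij and the leading relaxation rates are computed from it. Requires
    a > 0 for a unique stationary state; at a = 0 the two homogeneous
    configurations are absorbing and the flagged absorbing decomposition
    is returned.
    """
    if g.N > _MAX_FULL_N:
        raise ValueError(f"full solve limited to N <= {_MAX_FULL_N}")
    N = g.N
    ns = 2**N
    bits = ((np.arange(ns)[:, None] >> np.arange(N)[None, :]) & 1).astype(float)
    nv = bits.sum(axis=1)
    if p.a == 0:
        pi = np.zeros(ns)
        pi[0] = pi[ns - 1] = 0.5
        return ExactSolution(stationary=pi, var_n=float(N * N / 4), mean_n=N / 2,
                             absorbing=True)
    Q = _build_generator(g, p)
    M = sp.vstack([Q[:-1], sp.csr_matrix(np.ones((1, ns)))]).tocsc()
    b = np.zeros(ns)
    b[-1] = 1.0
    pi = spl.spsolve(M, b)
    pi = np.maximum(pi, 0)
    pi /= pi.sum()
    mean = float(pi @ nv)
    var = float(pi @ nv**2 - mean**2)
    mom1 = pi @ bits
    mom2 = bits.T @ (pi[:, None] * bits)
    cov = mom2 - np.outer(mom1, mom1)
    rates = None
    if n_relaxation_rates:
        kk = min(n_relaxation_rates + 1, ns - 2)
        ev = spl.eigs(Q, k=kk, sigma=1e-9, return_eigenvectors=False)
        rates = np.sort(-np.real(ev))
        rates[np.abs(rates) < 1e-9] = 0.0
    marg = np.bincount(nv.astype(int), weights=pi, minlength=N + 1)
    return ExactSolution(stationary=pi, var_n=var, mean_n=mean, cov=cov,
                         relaxation_rates=rates, marginal_n=marg)
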