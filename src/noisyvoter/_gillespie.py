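"""Event-driven kernel for the noisy voter process (numba-compiled).

Per-node flip rate: a + h * (disagreeing neighbours of i) / k_i.
A binary sum tree over the per-node rates gives O(log N) event draws and
updates; after a flip only the flipped node and its neighbourhood change
rate. Observables are read out on a fixed time grid with the last value
carried forward, which is exact for a piecewise-constant process.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_gillespie(indptr, indices, degrees, a, h, t_max, dt, s, seed):
    """Simulate from state ``s`` (modified in place) up to ``t_max``.

    Returns (n_series, active_series) sampled at times 0, dt, 2dt, ...;
    ``active_series`` counts edges whose endpoints disagree, so the
    interface density is active/E with E the total number of edges.
    """
    np.random.seed(seed)
    N = len(degrees)

    d = np.zeros(N, np.int64)  # disagreeing neighbours per node
    for i in range(N):
        for jj in range(indptr[i], indptr[i + 1]):
            if s[indices[jj]] != s[i]:
                d[i] += 1

    size = 1
    while size < N:
        size *= 2
    tree = np.zeros(2 * size)
    for i in range(N):
        tree[size + i] = a + h * d[i] / degrees[i]
    for p in range(size - 1, 0, -1):
        tree[p] = tree[2 * p] + tree[2 * p + 1]

    n = 0
    for i in range(N):
        n += s[i]
    act = 0  # number of active (disagreeing-endpoint) edges
    for i in range(N):
        act += d[i]
    act //= 2

    n_samp = int(t_max / dt) + 1
    n_series = np.empty(n_samp, np.int64)
    act_series = np.empty(n_samp, np.int64)
    n_series[0] = n
    act_series[0] = act
    isamp = 1
    t = 0.0
    while isamp < n_samp:
        total = tree[1]
        if total <= 0.0:  # frozen (a = 0 in a homogeneous state)
            while isamp < n_samp:
                n_series[isamp] = n
                act_series[isamp] = act
                isamp += 1
            break
        t += -np.log(np.random.random()) / total
        while isamp < n_samp and isamp * dt <= t:
            n_series[isamp] = n
            act_series[isamp] = act
            isamp += 1
        if isamp >= n_samp:
            break

        u = np.random.random() * total
        p = 1
        while p < size:
            if u <= tree[2 * p]:
                p = 2 * p
            else:
                u -= tree[2 * p]
                p = 2 * p + 1
        i = p - size

        old = s[i]
        s[i] = 1 - old
        n += 1 if old == 0 else -1
        # active edges incident to i go from d_old to k_i - d_old
        act += degrees[i] - 2 * d[i]
        d[i] = degrees[i] - d[i]
        q = size + i
        tree[q] = a + h * d[i] / degrees[i]
        q //= 2
        while q:
            tree[q] = tree[2 * q] + tree[2 * q + 1]
            q //= 2
        for jj in range(indptr[i], indptr[i + 1]):
            j = indices[jj]
            if s[j] != s[i]:
                d[j] += 1
            else:
                d[j] -= 1
            q = size + j
            tree[q] = a + h * d[j] / degrees[j]
            q //= 2
            while q:
                tree[q] = tree[2 * q] + tree[2 * q + 1]
                q //= 2
    return n_series, act_series
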