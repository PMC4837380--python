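"""Observables from simulated trajectories.

Stationary moments and histograms of n, bimodal/uniform/unimodal
classification against the uniform-distribution variance N(N+2)/12,
empirical location of the critical point, and the empirical stationary
autocorrelation of n. Averages are taken over time (on the uniform
sample grid, which time-weights the piecewise-constant process
correctly) and over realizations, after discarding an initial transient
of N time units by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ModelParams, Trajectory, simulate
from .theory import uniform_variance

__all__ = ["StationaryEstimate", "stationary_summary", "classify_distribution",
           "critical_a_empirical", "empirical_acf", "acf_ensemble"]


@dataclass
class StationaryEstimate:
    """Pooled time-and-ensemble stationary moments of n (and ρ)."""

    mean_n: float
    var_n: float
    hist_n: np.ndarray
    mean_rho: float | None
    n_transient_discarded: float
    n_realizations: int
    n_samples: int
    var_n_se: float


def _post_transient(traj: Trajectory, transient: float) -> slice:
    start = int(np.searchsorted(traj.times, transient, side="left"))
    if start >= len(traj.times):
        raise ValueError(
            f"trajectory of span {traj.times[-1]} has no samples after the "
            f"transient of {transient} time units")
    return slice(start, None)


def stationary_summary(trajs, transient: float | None = None) -> StationaryEstimate:
    """Moments of n pooled over time and realizations, transient discarded.

    ``transient`` defaults to N time units. The variance standard error
    reported is a correlation-blind estimate from the across-realization
    scatter when several realizations are given, else a plain i.i.d.
    approximation (useful only as an order of magnitude).
    """
    trajs = [trajs] if isinstance(trajs, Trajectory) else list(trajs)
    if not trajs:
        raise ValueError("no trajectories given")
    N = trajs[0].N
    if transient is None:
        transient = float(N)
    ns, rhos, per_var = [], [], []
    for tr in trajs:
        sl = _post_transient(tr, transient)
        x = tr.n_series[sl].astype(float)
        ns.append(x)
        per_var.append(x.var())
        if tr.rho_series is not None:
            rhos.append(tr.rho_series[sl])
    pooled = np.concatenate(ns)
    mean = float(pooled.mean())
    var = float(pooled.var())
    hist = np.bincount(np.concatenate(ns).astype(int), minlength=N + 1).astype(float)
    hist /= hist.sum()
    if len(trajs) > 1:
        se = float(np.std(per_var, ddof=1) / np.sqrt(len(per_var)))
    else:
        se = float(var * np.sqrt(2.0 / max(len(pooled) - 1, 1)))
    return StationaryEstimate(
        mean_n=mean, var_n=var, hist_n=hist,
        mean_rho=float(np.concatenate(rhos).mean()) if rhos else None,
        n_transient_discarded=float(transient),
        n_realizations=len(trajs), n_samples=len(pooled), var_n_se=se)


def classify_distribution(hist_n: np.ndarray, var_se: float | None = None) -> str:
    """Classify a normalized histogram of n as bimodal/uniform/unimodal.

    The variance of the histogram is compared to N(N+2)/12. The
    tolerance band is 3 × ``var_se`` when a standard error of the
    variance estimate is supplied, else 3% of the uniform value; values
    inside the band (including exact ties) classify as ``uniform``,
    above as ``bimodal``, below as ``unimodal``.
    """
    hist = np.asarray(hist_n, dtype=float)
    if not np.isclose(hist.sum(), 1.0, atol=1e-8):
        raise ValueError("histogram must be normalized")
    N = len(hist) - 1
    n = np.arange(N + 1)
    var = float(hist @ n**2 - (hist @ n) ** 2)
    target = uniform_variance(N)
    band = 3 * var_se if var_se is not None else 0.03 * target
    if abs(var - target) <= band:
        return "uniform"
    return "bimodal" if var > target else "unimodal"


def empirical_acf(trajs, max_lag: float, lag_step: float | None = None,
                  transient: float | None = None, known_mean: float | None = None):
    """Stationary autocorrelation K(τ) = ⟨n(t)n(t+τ)⟩ − ⟨n⟩² of n.

    Accepts one trajectory or several (pooled by averaging the
    autocovariances, normalizing with the pooled lag-0 value). The
    trajectories must be sampled on a uniform grid; ``lag_step``
    defaults to the grid spacing. Supplying ``known_mean`` (e.g. N/2 by
    symmetry) avoids the bias of subtracting a fitted mean.

    Returns (lags, K) with K(0) equal to the pooled sample variance.
    """
    trajs = [trajs] if isinstance(trajs, Trajectory) else list(trajs)
    dt = float(trajs[0].times[1] - trajs[0].times[0])
    if lag_step is None:
        lag_step = dt
    stride = int(round(lag_step / dt))
    if abs(stride * dt - lag_step) > 1e-9 * max(1.0, lag_step):
        raise ValueError("lag_step must be a multiple of the sample interval")
    N = trajs[0].N
    if transient is None:
        transient = float(N)
    n_lags = int(max_lag / lag_step)
    covs = []
    for tr in trajs:
        sl = _post_transient(tr, transient)
        x = tr.n_series[sl].astype(float)
        if max_lag >= (len(x) - 1) * dt:
            raise ValueError("max_lag must be smaller than the post-transient span")
        mu = x.mean() if known_mean is None else known_mean
        x = x - mu
        T = len(x)
        f = np.fft.rfft(x, n=2 * T)
        acov = np.fft.irfft(f * np.conj(f))[: n_lags * stride + 1]
        acov /= T - np.arange(len(acov))
        covs.append(acov[:: stride])
    K = np.mean(covs, axis=0)
    lags = np.arange(n_lags + 1) * lag_step
    return lags, K


def acf_ensemble(trajs, max_lag: float, lag_step: float | None = None,
                 transient: float | None = None, known_mean: float | None = None):
    """Per-realization autocovariances plus their pooled mean and SE.

    Returns (lags, K_mean, K_se, K_all); the standard error is the
    across-realization scatter of the per-realization estimates, which
    correctly reflects the strong correlation of autocovariance errors
    across lags within a realization.
    """
    trajs = [trajs] if isinstance(trajs, Trajectory) else list(trajs)
    rows = []
    lags = None
    for tr in trajs:
        lags, k = empirical_acf(tr, max_lag, lag_step, transient, known_mean)
        rows.append(k)
    K_all = np.array(rows)
    K = K_all.mean(axis=0)
    if len(rows) > 1:
        se = K_all.std(axis=0, ddof=1) / np.sqrt(len(rows))
    else:
        se = np.full_like(K, np.nan)
    return lags, K, se, K_all


def critical_a_empirical(graphs, h: float, a_grid, *, t_max: float,
                         sample_interval: float = 1.0, realizations: int = 1,
                         transient: float | None = None, seed: int = 0):
    """Empirical critical point from a variance sweep over a noise grid.

    Simulates every graph at each a, pools the stationary variance of n,
    and locates the crossing of N(N+2)/12 by linear interpolation of
    var(log a). Raises if the grid does not bracket the crossing.

    Returns (a_c_estimate, table) where table is a list of
    (a, var_n, mean_rho, classification) rows.
    """
    graphs = list(graphs)
    a_grid = np.asarray(a_grid, dtype=float)
    if np.any(np.diff(a_grid) <= 0):
        raise ValueError("a_grid must be strictly increasing")
    N = graphs[0].N
    target = uniform_variance(N)
    table = []
    rng = np.random.SeedSequence(seed)
    for a in a_grid:
        trajs = []
        for gi, g in enumerate(graphs):
            for r in range(realizations):
                sub = int(np.random.default_rng(rng.spawn(1)[0]).integers(2**31))
                trajs.append(simulate(g, ModelParams(a=float(a), h=h), t_max,
                                      sample_interval, "random", seed=sub))
        est = stationary_summary(trajs, transient)
        table.append((float(a), est.var_n, est.mean_rho,
                      classify_distribution(est.hist_n, est.var_n_se)))
    var = np.array([row[1] for row in table])
    above = var > target
    if above.all() or (~above).all():
        raise ValueError(
            "variance does not cross the uniform level on the given grid: "
            f"endpoints {var[0]:.6g} and {var[-1]:.6g} vs target {target:.6g}")
    i = int(np.flatnonzero(above[:-1] != above[1:])[0])
    la = np.log(a_grid)
    frac = (target - var[i]) / (var[i + 1] - var[i])
    a_c = float(np.exp(la[i] + frac * (la[i + 1] - la[i])))
    return a_c, table
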