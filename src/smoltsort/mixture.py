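"""Univariate Gaussian mixture fitting by EM with BIC model selection.

The analysis fits every metric (fork length on the raw millimetre scale,
maturation markers on the log10 scale) with k = 1, 2, 3 Gaussian
components and keeps the fit with the lowest Bayesian information
criterion, BIC = -2*loglik + p*ln(n) with p = 3k - 1 free parameters
(k means, k standard deviations, k - 1 independent weights).

Initialisation is deterministic: attempt 0 places the k component means at
evenly spaced sample quantiles with the pooled standard deviation and equal
weights; the R additional restarts draw candidate means from random data
points of a seeded stream, which lets EM latch onto small well-separated
modes.  The best final log-likelihood wins.  A variance floor (a fixed
fraction of the sample standard deviation) guards against single-point
component collapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EMOptions",
    "Component",
    "MixtureFit",
    "ModelSelection",
    "DegenerateDataError",
    "FitError",
    "bic",
    "fit_em",
    "select_model",
]


class DegenerateDataError(ValueError):
    """Data carry no spread a mixture could model (all values identical)."""


class FitError(RuntimeError):
    """No candidate model converged."""


@dataclass(frozen=True)
class EMOptions:
    """EM control parameters.

    tol
        Convergence when the relative log-likelihood change per iteration
        drops below this value.
    max_iter
        Iteration cap per EM run.
    n_restarts
        Random restarts in addition to the deterministic quantile start.
    seed
        Seed of the restart stream (the fit is deterministic given it).
    var_floor_frac
        Component sd floor as a fraction of the sample sd.
    """

    tol: float = 1e-8
    max_iter: int = 500
    n_restarts: int = 10
    seed: int = 0
    var_floor_frac: float = 1e-3


@dataclass(frozen=True)
class Component:
    weight: float
    mean: float
    sd: float


@dataclass(frozen=True)
class MixtureFit:
    """A fitted k-component Gaussian mixture (components sorted by mean)."""

    k: int
    components: tuple[Component, ...]
    loglik: float
    n: int
    bic: float
    converged: bool
    n_iter: int
    restarts_used: int
    loglik_trace: tuple[float, ...] = field(default=(), repr=False)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.sd for c in self.components])


@dataclass(frozen=True)
class ModelSelection:
    """BIC-ranked candidate fits for one metric within one treatment."""

    metric: str
    treatment: str
    fits: dict[int, MixtureFit]
    best_k: int

    @property
    def best(self) -> MixtureFit:
        return self.fits[self.best_k]


_LOG_2PI = math.log(2.0 * math.pi)


def bic(loglik: float, k: int, n: int) -> float:
    """BIC with the p = 3k - 1 univariate-Gaussian-mixture convention."""
    return -2.0 * loglik + (3 * k - 1) * math.log(n)


def _log_component_densities(x: np.ndarray, w: np.ndarray, mu: np.ndarray,
                             sd: np.ndarray) -> np.ndarray:
    """(n, k) matrix of log(w_j * phi(x_i; mu_j, sd_j))."""
    z = (x[:, None] - mu[None, :]) / sd[None, :]
    return np.log(w)[None, :] - np.log(sd)[None, :] - 0.5 * (_LOG_2PI + z * z)


def _loglik_and_resp(x, w, mu, sd):
    log_d = _log_component_densities(x, w, mu, sd)
    m = log_d.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_d - m).sum(axis=1))
    resp = np.exp(log_d - lse[:, None])
    return float(lse.sum()), resp


def _em_run_batch(x: np.ndarray, W: np.ndarray, MU: np.ndarray,
                  SD: np.ndarray, opts: EMOptions, floor: float):
    """Run R EM chains in parallel from the (R, k) start parameters.

    Each chain freezes once its relative log-likelihood change drops below
    tolerance, so results are identical to running the chains one by one.
    Returns per-chain final (ll, W, MU, SD, converged, n_iter) plus the
    full per-iteration log-likelihood history (n_steps, R).
    """
    R, k = W.shape
    n = x.size
    ll_cur = np.full(R, -np.inf)
    ll_prev = np.full(R, -np.inf)
    done = np.zeros(R, dtype=bool)
    n_iter = np.zeros(R, dtype=int)
    history: list[np.ndarray] = []
    x2 = x * x

    for it in range(1, opts.max_iter + 1):
        act = np.flatnonzero(~done)
        # E-step for the still-active chains only (frozen chains keep their
        # converged parameters and log-likelihood)
        z = (x[None, :, None] - MU[act][:, None, :]) / SD[act][:, None, :]
        log_d = (np.log(W[act])[:, None, :] - np.log(SD[act])[:, None, :]
                 - 0.5 * (_LOG_2PI + z * z))
        m = log_d.max(axis=2, keepdims=True)
        lse = m[:, :, 0] + np.log(np.exp(log_d - m).sum(axis=2))
        ll_cur[act] = lse.sum(axis=1)
        history.append(ll_cur.copy())

        conv_now = (np.isfinite(ll_prev[act])
                    & (np.abs(ll_cur[act] - ll_prev[act])
                       < opts.tol * np.maximum(1.0, np.abs(ll_prev[act]))))
        n_iter[act[conv_now]] = it
        done[act[conv_now]] = True
        if done.all():
            break
        ll_prev[act] = ll_cur[act]

        # M-step via sufficient statistics for chains still running
        run = act[~conv_now]
        sub = ~conv_now
        resp = np.exp(log_d[sub] - lse[sub][:, :, None])
        nk = np.maximum(resp.sum(axis=1), 1e-300)
        W[run] = nk / n
        mu = np.einsum("rnk,n->rk", resp, x) / nk
        var = np.einsum("rnk,n->rk", resp, x2) / nk - mu * mu
        MU[run] = mu
        SD[run] = np.maximum(np.sqrt(np.maximum(var, 0.0)), floor)

    n_iter[~done] = opts.max_iter
    hist = np.vstack(history)
    return hist[-1].copy(), W, MU, SD, done, n_iter, hist


def fit_em(values: Sequence[float], k: int,
           options: EMOptions | None = None) -> MixtureFit:
    """Fit a k-component univariate Gaussian mixture by EM.

    For k = 1 the closed-form maximum-likelihood estimate is returned
    without iteration.  For k >= 2 the best of the quantile start plus
    ``n_restarts`` seeded random starts is kept.
    """
    opts = options or EMOptions()
    x = np.asarray(values, dtype=float).ravel()
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.size
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} values to fit k={k}, got {n}")

    sample_sd = float(x.std())
    if sample_sd == 0.0:
        raise DegenerateDataError(
            f"all {n} values identical ({x[0]!r}); no mixture with k={k} is "
            "estimable (variance floor cannot rescue zero spread)")
    floor = opts.var_floor_frac * sample_sd

    if k == 1:
        mean = float(x.mean())
        sd = max(sample_sd, floor)
        ll = float(np.sum(-np.log(sd) - 0.5 * (_LOG_2PI + ((x - mean) / sd) ** 2)))
        comp = (Component(weight=1.0, mean=mean, sd=sd),)
        return MixtureFit(k=1, components=comp, loglik=ll, n=n,
                          bic=bic(ll, 1, n), converged=True, n_iter=0,
                          restarts_used=0, loglik_trace=(ll,))

    rng = np.random.default_rng(opts.seed)
    q = (2.0 * np.arange(k) + 1.0) / (2.0 * k)
    starts = [np.quantile(x, q)]
    for _ in range(opts.n_restarts):
        starts.append(np.sort(rng.choice(x, size=k, replace=False)))

    R = len(starts)
    W0 = np.full((R, k), 1.0 / k)
    MU0 = np.asarray(starts, dtype=float)
    SD0 = np.full((R, k), max(sample_sd, floor))
    ll_all, W, MU, SD, done, iters, hist = _em_run_batch(x, W0, MU0, SD0,
                                                         opts, floor)
    # best final log-likelihood; ties (within 1e-12) go to the earliest start
    best_i = 0
    for r in range(1, R):
        if ll_all[r] > ll_all[best_i] + 1e-12:
            best_i = r
    ll, w, mu, sd = ll_all[best_i], W[best_i], MU[best_i], SD[best_i]
    conv, it, restarts_used = bool(done[best_i]), int(iters[best_i]), best_i
    trace = [float(v) for v in hist[:it, best_i]]
    order = np.argsort(mu)
    comps = tuple(Component(weight=float(w[j]), mean=float(mu[j]), sd=float(sd[j]))
                  for j in order)
    # renormalise away floating-point drift so weights sum to 1 exactly
    total = sum(c.weight for c in comps)
    comps = tuple(Component(c.weight / total, c.mean, c.sd) for c in comps)
    return MixtureFit(k=k, components=comps, loglik=ll, n=n, bic=bic(ll, k, n),
                      converged=conv, n_iter=it, restarts_used=restarts_used,
                      loglik_trace=tuple(trace))


def select_model(values: Sequence[float], k_max: int = 3,
                 options: EMOptions | None = None, *,
                 metric: str = "", treatment: str = "") -> ModelSelection:
    """Fit k = 1..k_max and select the lowest-BIC converged fit.

    BIC ties (within 1e-9) resolve toward the smaller k (parsimony).
    """
    if not 1 <= k_max <= 3:
        raise ValueError("k_max must be in 1..3 (larger mixtures unsupported)")
    fits: dict[int, MixtureFit] = {}
    for k in range(1, k_max + 1):
        fits[k] = fit_em(values, k, options)
    converged = {k: f for k, f in fits.items() if f.converged}
    if not converged:
        raise FitError(f"no mixture fit converged for metric {metric!r}")
    best_k = min(converged)
    for k, f in sorted(converged.items()):
        if f.bic < converged[best_k].bic - 1e-9:
            best_k = k
    return ModelSelection(metric=metric, treatment=treatment, fits=fits,
                          best_k=best_k)
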