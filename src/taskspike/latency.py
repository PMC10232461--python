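"""Peak-latency extraction, GMM/BIC cluster-number selection, x-means
cross-check, and bootstrap pseudo-signal-flow.

The cluster count of a 1D peak-latency distribution is chosen by fitting a
Gaussian mixture with EM many times (default 1000 repeats, random
responsibilities each) for k = 1..5 and taking the k with the minimum mean
BIC, BIC = -2 ln L + k_params ln n.  The 1D EM is vectorized across repeats
so the full protocol stays cheap; the reported fit at the chosen k is the
single repeat with the best likelihood.  An x-means run (BIC-driven k-means
splitting) re-confirms the count with a non-GMM algorithm.

Pseudo-signal flow: each of B bootstrap repeats draws one neuron latency
per region (CA1, LECs, LECd) and forms the lag pair
(CA1 - LECs, CA1 - LECd); the 2D point cloud is clustered with a
full-covariance GMM (k by BIC) and every sample is labeled with the firing
order of the three regions implied by the lag signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from taskspike.peth import Peth

REGION_KEYS = ("CA1", "LECs", "LECd")
_ORDER_RANK = {"c": 0, "s": 1, "d": 2}


def peak_latency(peth: Peth, window: tuple[float, float]) -> tuple[float, bool]:
    """Time (ms) of the maximum smoothed rate within the window.

    Ties break to the earliest bin.  Returns ``(latency_ms, flat_flag)``;
    a flat PETH is flagged and its latency is NaN.
    """
    centers = peth.bin_centers
    mask = (centers >= window[0]) & (centers <= window[1])
    if not mask.any():
        raise ValueError("window outside PETH support")
    rates = peth.rates[mask]
    if np.ptp(rates) == 0:
        return float("nan"), True
    return float(centers[mask][int(np.argmax(rates))] * 1000.0), False


def bic(log_likelihood: float, k_params: int, n: int) -> float:
    """Bayesian information criterion, -2 ln(L) + k ln(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * log_likelihood + k_params * np.log(n)


# ---------------------------------------------------------------------------
# vectorized 1D EM


@dataclass
class Em1dResult:
    means: np.ndarray     # (repeats, k)
    variances: np.ndarray
    weights: np.ndarray
    loglik: np.ndarray    # (repeats,)
    n_floored: int        # repeats where a component hit the variance floor


def _em_1d(x: np.ndarray, k: int, repeats: int, rng: np.random.Generator,
           max_iter: int = 100, tol: float = 1e-3,
           var_floor: float = 1e-4) -> Em1dResult:
    """EM for a 1D free-variance Gaussian mixture, vectorized over repeats.

    Each repeat starts from its own short k-means pass seeded with random
    distinct data points (the initialization the standard EM
    implementations default to), so restarts explore genuine local optima
    rather than degenerate single-point components; repeats whose
    log-likelihood change falls below ``tol`` drop out of the working set.
    Components are kept proper with a variance floor (counted in
    ``n_floored``).
    """
    n = x.size
    xr = x[None, :, None]                       # (1, n, 1)
    total_var = max(float(np.var(x)), var_floor)

    # vectorized Lloyd iterations from random distinct data points
    mu = x[np.argsort(rng.random((repeats, n)), axis=1)[:, :k]]
    for _ in range(10):
        lab = np.abs(xr[:, :, 0, None] - mu[:, None, :]).argmin(axis=2)  # (R, n)
        onehot = lab[:, :, None] == np.arange(k)[None, None, :]
        nk0 = onehot.sum(axis=1)
        sums = (onehot * xr).sum(axis=1)
        mu = np.where(nk0 > 0, sums / np.maximum(nk0, 1), mu)
    var = (onehot * (xr - mu[:, None, :]) ** 2).sum(axis=1) / np.maximum(nk0, 1)
    var = np.where(nk0 > 1, np.maximum(var, var_floor), total_var)
    w = np.maximum(nk0, 1) / np.maximum(nk0, 1).sum(axis=1, keepdims=True)
    ll = np.full(repeats, -np.inf)
    floored = np.zeros(repeats, bool)
    idx = np.arange(repeats)                    # repeats still iterating
    mu_a, var_a, w_a = mu.copy(), var.copy(), w.copy()

    for _ in range(max_iter):
        # E-step (log-density accumulated in place)
        logp = xr - mu_a[:, None, :]
        logp *= logp
        logp /= -2.0 * var_a[:, None, :]
        logp += np.log(w_a / np.sqrt(2.0 * np.pi * var_a))[:, None, :]
        m = logp.max(axis=2)
        np.exp(logp - m[:, :, None], out=logp)
        s = logp.sum(axis=2)
        resp = logp / s[:, :, None]
        ll_a = (np.log(s) + m).sum(axis=1)

        # M-step
        nk = resp.sum(axis=1) + 1e-12           # (A, k)
        mu_a = (resp * xr).sum(axis=1) / nk
        var_a = (resp * (xr - mu_a[:, None, :]) ** 2).sum(axis=1) / nk
        hit = (var_a < var_floor).any(axis=1)
        if hit.any():
            floored[idx[hit]] = True
            np.maximum(var_a, var_floor, out=var_a)
        w_a = nk / n
        mu[idx], var[idx], w[idx] = mu_a, var_a, w_a

        done = np.abs(ll_a - ll[idx]) < tol
        ll[idx] = ll_a
        if done.all():
            break
        keep = ~done
        idx = idx[keep]
        mu_a, var_a, w_a = mu_a[keep], var_a[keep], w_a[keep]

    # refresh the log-likelihood at the final parameters of every repeat
    logp = xr - mu[:, None, :]
    logp *= logp
    logp /= -2.0 * var[:, None, :]
    logp += np.log(w / np.sqrt(2.0 * np.pi * var) + 1e-300)[:, None, :]
    m = logp.max(axis=2)
    ll = (np.log(np.exp(logp - m[:, :, None]).sum(axis=2)) + m).sum(axis=1)

    return Em1dResult(mu, var, w, ll, int(floored.sum()))


@dataclass
class GmmSelection:
    n: int
    k_range: tuple
    repeats: int
    mean_bic: dict          # k -> mean BIC over repeats
    best_loglik: dict       # k -> best (max) log-likelihood over repeats
    chosen_k: int
    means: np.ndarray       # components of the best fit at chosen_k, sorted
    sds: np.ndarray
    weights: np.ndarray
    n_floored: dict
    seed: int


def gmm_select(samples, k_range=range(1, 6), repeats: int = 1000,
               seed: int = 0, var_floor: float = 1e-4) -> GmmSelection:
    """Choose the 1D mixture component count by minimum mean BIC."""
    x = np.asarray(samples, float)
    k_range = tuple(k_range)
    if x.size < 2 * max(k_range):
        raise ValueError("need at least 2 x max(k_range) samples")
    rng = np.random.default_rng(seed)
    mean_bic, best_ll, n_floored, best_fits = {}, {}, {}, {}
    for k in k_range:
        res = _em_1d(x, k, repeats, rng, var_floor=var_floor)
        k_params = 3 * k - 1                    # means + variances + free weights
        bics = np.array([bic(ll, k_params, x.size) for ll in res.loglik])
        mean_bic[k] = float(bics.mean())
        j = int(np.argmax(res.loglik))
        best_ll[k] = float(res.loglik[j])
        n_floored[k] = res.n_floored
        best_fits[k] = (res.means[j], res.variances[j], res.weights[j])
    chosen_k = min(k_range, key=lambda k: mean_bic[k])
    mu, var, w = best_fits[chosen_k]
    order = np.argsort(mu)
    return GmmSelection(x.size, k_range, repeats, mean_bic, best_ll, chosen_k,
                        mu[order], np.sqrt(var[order]), w[order], n_floored, seed)


# ---------------------------------------------------------------------------
# x-means cross-check


def _gauss_ll(x: np.ndarray) -> float:
    var = max(float(np.var(x)), 1e-6)
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * var)
                        - (x - x.mean()) ** 2 / (2.0 * var)))


def xmeans_check(samples, k_max: int = 5, seed: int = 0) -> int:
    """BIC-driven k-means splitting (x-means); returns the cluster count."""
    x = np.asarray(samples, float).reshape(-1, 1)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    clusters = [x[:, 0]]
    improved = True
    while improved and len(clusters) < k_max:
        improved = False
        new_clusters: list[np.ndarray] = []
        for idx, c in enumerate(clusters):
            n_if_split = len(new_clusters) + (len(clusters) - idx) + 1
            if c.size < 4 or n_if_split > k_max:
                new_clusters.append(c)
                continue
            km = KMeans(n_clusters=2, n_init=5, random_state=seed).fit(c.reshape(-1, 1))
            parts = [c[km.labels_ == j] for j in (0, 1)]
            if min(p.size for p in parts) < 2:
                new_clusters.append(c)
                continue
            bic1 = bic(_gauss_ll(c), 2, c.size)
            ll2 = sum(_gauss_ll(p) + p.size * np.log(p.size / c.size) for p in parts)
            bic2 = bic(ll2, 5, c.size)
            if bic2 < bic1:
                new_clusters.extend(parts)
                improved = True
            else:
                new_clusters.append(c)
        clusters = new_clusters
    return len(clusters)


# ---------------------------------------------------------------------------
# bootstrap pseudo-signal flow


def order_label(lag_cs: float, lag_cd: float) -> str:
    """Firing order of CA1 (c), LECs (s), LECd (d) from the two lags.

    ``lag_cs = peak_c - peak_s`` and ``lag_cd = peak_c - peak_d``; the third
    comparison is their difference.  Exact-zero ties break toward the
    earlier-listed region in the order c, s, d.
    """
    t = {"c": 0.0, "s": -float(lag_cs), "d": -float(lag_cd)}
    letters = sorted(t, key=lambda r: (t[r], _ORDER_RANK[r]))
    return "->".join(letters)


@dataclass
class FlowResult:
    lag_cs: np.ndarray
    lag_cd: np.ndarray
    B: int
    mean_bic: dict
    chosen_k: int
    cluster_assignments: np.ndarray
    cluster_means: np.ndarray
    cluster_covariances: np.ndarray
    cluster_weights: np.ndarray
    order_labels: np.ndarray
    quadrant_fraction: float   # samples with lag_cs > 0 and lag_cd < 0 (s->c->d)
    seed: int


def bootstrap_flow(latencies_by_region: dict, B: int = 1000, seed: int = 0,
                   k_range=range(1, 6), repeats_2d: int = 20) -> FlowResult:
    """Bootstrap inter-region latency lags, cluster them, label firing orders."""
    for r in REGION_KEYS:
        if r not in latencies_by_region or len(latencies_by_region[r]) == 0:
            raise ValueError(f"region {r} is empty")
    rng = np.random.default_rng(seed)
    draws = {r: rng.choice(np.asarray(latencies_by_region[r], float), size=B,
                           replace=True) for r in REGION_KEYS}
    lag_cs = draws["CA1"] - draws["LECs"]
    lag_cd = draws["CA1"] - draws["LECd"]
    X = np.column_stack([lag_cs, lag_cd])

    jitter = 0.0
    if np.linalg.matrix_rank(np.cov(X.T)) < 2 or np.allclose(np.var(X, axis=0), 0):
        jitter = 1e-6  # degenerate cloud: regularize for the GMM only
    Xfit = X + rng.normal(0.0, jitter, X.shape) if jitter else X

    mean_bic, best = {}, {}
    for k in k_range:
        fits = []
        for _ in range(repeats_2d):
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 init_params="random", n_init=1, max_iter=500,
                                 tol=1e-6, reg_covar=1e-6,
                                 random_state=int(rng.integers(2**31 - 1)))
            gm.fit(Xfit)
            fits.append((gm.bic(Xfit), gm))
        mean_bic[k] = float(np.mean([b for b, _ in fits]))
        best[k] = min(fits, key=lambda t: t[0])[1]
    chosen_k = min(k_range, key=lambda k: mean_bic[k])
    gm = best[chosen_k]
    labels = np.array([order_label(a, b) for a, b in zip(lag_cs, lag_cd)])
    quad = float(np.mean((lag_cs > 0) & (lag_cd < 0)))
    return FlowResult(lag_cs, lag_cd, B, mean_bic, chosen_k, gm.predict(Xfit),
                      gm.means_, gm.covariances_, gm.weights_, labels, quad, seed)
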