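"""Batched EM for bivariate Gaussian mixtures with BIC model selection.

Every locus pair of the panel gets its own mixture of 1..4 full-covariance
bivariate Gaussians, fitted to the baseline cohort. Because a run needs tens
of thousands of independent small fits (C(k, 2) pairs, ~141 points each),
the EM here is vectorised across fits: all mixtures of a chunk, for every
restart of a given component count, advance together through the same E/M
steps, with converged fits dropped from the active set each iteration.

Initialisation is k-means++-style seeding driven by counter-based hashed
uniforms, so each fit is a pure function of its seed key and the data —
independent of chunking or execution order.

Model selection: each candidate component count 1..max_components is fitted
(``n_init`` restarts, best log-likelihood kept) and the count minimising the
Bayesian information criterion among converged candidates is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .utils import pair_uniforms

log = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)

__all__ = ["GMMSettings", "PairGMM", "fit_pair_gmm", "fit_gmm_batch", "BatchGMMResult"]


@dataclass(frozen=True)
class GMMSettings:
    """EM hyper-parameters for the per-pair mixtures."""

    max_components: int = 4
    n_init: int = 3            # k-means++ restarts per candidate count
    covariance_floor: float = 1e-6  # added to covariance diagonals
    tol: float = 1e-3          # convergence: |change in mean per-point log-lik|
    max_iter: int = 200
    chunk_size: int = 2048     # pairs fitted per vectorised chunk

    def n_uniforms(self) -> int:
        return self.n_init * sum(range(2, self.max_components + 1))


@dataclass
class PairGMM:
    """Fitted mixture for one locus pair (canonical order i < j).

    ``bic`` and ``converged`` record the selection metadata for every
    candidate component count that was attempted.
    """

    pair: tuple
    weights: np.ndarray        # (K,)
    means: np.ndarray          # (K, 2)
    covariances: np.ndarray    # (K, 2, 2)
    bic: dict
    converged: dict

    @property
    def n_components(self) -> int:
        return len(self.weights)


@dataclass
class BatchGMMResult:
    """Selected mixtures for a batch of fits, padded to ``kmax`` components."""

    n_components: np.ndarray   # (B,)
    weights: np.ndarray        # (B, kmax); zero beyond n_components
    means: np.ndarray          # (B, kmax, 2); NaN beyond n_components
    covariances: np.ndarray    # (B, kmax, 2, 2); NaN beyond n_components
    bic: np.ndarray            # (B, kmax); NaN where a count was not attempted
    converged: np.ndarray      # (B, kmax) bool


def _log_gauss(x: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Log density of points under each component; closed-form 2x2 algebra.

    x: (M, n, 2); means: (M, K, 2); covs: (M, K, 2, 2) -> (M, n, K).
    """
    a = covs[..., 0, 0]
    b = covs[..., 0, 1]
    d = covs[..., 1, 1]
    det = a * d - b * b
    dx = x[:, :, None, 0] - means[:, None, :, 0]
    dy = x[:, :, None, 1] - means[:, None, :, 1]
    q = (d[:, None, :] * dx * dx - 2.0 * b[:, None, :] * dx * dy
         + a[:, None, :] * dy * dy) / det[:, None, :]
    return -0.5 * (q + np.log(det)[:, None, :]) - _LOG_2PI


def _kmeanspp_means(x: np.ndarray, K: int, u: np.ndarray) -> np.ndarray:
    """k-means++ seeding for every fit of a batch from provided uniforms.

    x: (M, n, 2); u: (M, K) uniforms in [0, 1) -> initial means (M, K, 2).
    """
    M, n, _ = x.shape
    means = np.empty((M, K, 2))
    rows = np.arange(M)
    idx = np.minimum((u[:, 0] * n).astype(np.intp), n - 1)
    means[:, 0] = x[rows, idx]
    if K == 1:
        return means
    d2 = ((x - means[:, 0][:, None, :]) ** 2).sum(axis=2)
    for k in range(1, K):
        tot = d2.sum(axis=1)
        r = u[:, k] * tot
        idx = np.minimum((np.cumsum(d2, axis=1) < r[:, None]).sum(axis=1), n - 1)
        flat = tot <= 0.0  # all points identical to chosen centres
        if flat.any():
            idx[flat] = np.minimum((u[flat, k] * n).astype(np.intp), n - 1)
        means[:, k] = x[rows, idx]
        if k < K - 1:
            d2 = np.minimum(d2, ((x - means[:, k][:, None, :]) ** 2).sum(axis=2))
    return means


def _em_core(x, means, covs, logw, ll, converged, tol, floor, n_iter, drop_converged=True):
    """Advance EM on every fit of a batch, dropping converged fits.

    Arrays are updated in place; ``ll`` holds the E-step mean per-point
    log-likelihood of the final iteration (the returned parameters include
    the subsequent, never-worse, M-step).
    """
    M, n, _ = x.shape
    active = np.arange(M)
    for _ in range(n_iter):
        xa = x[active]
        lp = _log_gauss(xa, means[active], covs[active]) + logw[active][:, None, :]
        mx = lp.max(axis=2)
        s = np.exp(lp - mx[..., None])
        ssum = s.sum(axis=2)
        new_ll = (mx + np.log(ssum)).mean(axis=1)
        resp = s / ssum[..., None]

        nk = np.maximum(resp.sum(axis=1), 1e-12)
        mns = np.einsum("mnk,mnd->mkd", resp, xa) / nk[..., None]
        dxx = xa[:, :, None, :] - mns[:, None, :, :]
        cvs = np.einsum("mnkd,mnke->mkde", resp[..., None] * dxx, dxx) / nk[..., None, None]
        cvs[:, :, 0, 0] += floor
        cvs[:, :, 1, 1] += floor
        means[active] = mns
        covs[active] = cvs
        logw[active] = np.log(nk) - np.log(np.asarray(n, dtype=x.dtype))

        done = np.abs(new_ll - ll[active]) < tol
        ll[active] = new_ll
        if drop_converged:
            converged[active[done]] = True
            active = active[~done]
            if active.size == 0:
                break


_BURN_IN = 6  # iterations every restart runs before the best one continues


def _em_fixed_k(x, init_means, floor, tol, max_iter, n_init=1):
    """EM with restarts for a fixed component count on a batch of fits.

    ``x`` has shape (B, n, 2) and ``init_means`` (B * n_init, K, 2), the
    ``n_init`` restarts of each fit stored consecutively. All restarts are
    burned in for a few iterations; the restart with the best likelihood
    then continues to convergence (short-runs/long-runs EM). Returns
    (weights, means, covs, mean log-likelihood, converged), one per fit.
    """
    B, n, _ = x.shape
    K = init_means.shape[1]
    M = B * n_init
    xr = np.repeat(x, n_init, axis=0) if n_init > 1 else x
    means = init_means.astype(x.dtype, copy=True)
    mu = x.mean(axis=1)
    xc = x - mu[:, None, :]
    base_cov = np.einsum("mnd,mne->mde", xc, xc) / n
    base_cov[:, 0, 0] += floor
    base_cov[:, 1, 1] += floor
    covs = np.repeat(base_cov, n_init, axis=0)[:, None].repeat(K, axis=1) \
        if n_init > 1 else np.repeat(base_cov[:, None], K, axis=1)
    logw = np.full((M, K), -np.log(K), dtype=x.dtype)
    ll = np.full(M, -np.inf)
    converged = np.zeros(M, dtype=bool)

    burn = min(_BURN_IN, max_iter) if n_init > 1 else 0
    if burn:
        _em_core(xr, means, covs, logw, ll, converged, tol, floor, burn)
        best = ll.reshape(B, n_init).argmax(axis=1)
        rows = np.arange(B) * n_init + best
        means, covs, logw = means[rows], covs[rows], logw[rows]
        ll, converged = ll[rows], converged[rows]
    remaining = max_iter - burn
    if remaining > 0:
        pending = ~converged
        if pending.any():
            sub = np.where(pending)[0]
            m_s, c_s, w_s = means[sub], covs[sub], logw[sub]
            ll_s, cv_s = ll[sub], converged[sub]
            _em_core(x[sub] if burn else xr[sub], m_s, c_s, w_s, ll_s, cv_s,
                     tol, floor, remaining)
            means[sub], covs[sub], logw[sub] = m_s, c_s, w_s
            ll[sub], converged[sub] = ll_s, cv_s
    return np.exp(logw), means, covs, ll, converged


def _n_params(k: int) -> int:
    # k-1 mixing weights + 2k means + 3k free covariance entries
    return 6 * k - 1


def fit_gmm_batch(X: np.ndarray, uniforms: np.ndarray,
                  settings: GMMSettings = GMMSettings()) -> BatchGMMResult:
    """Fit and BIC-select mixtures for a batch of 2-D point sets.

    X: (B, n, 2); uniforms: (B, settings.n_uniforms()) initialisation
    uniforms (one stream per fit). Component counts exceeding the number of
    points are skipped. Non-converged candidates are never selected (the
    single-component fit is closed-form and always converged).
    """
    B, n, _ = X.shape
    kmax = min(settings.max_components, n)
    if kmax < settings.max_components:
        log.warning("only %d points: candidate component counts capped at %d", n, kmax)
    floor = settings.covariance_floor

    weights = np.zeros((B, kmax, kmax))
    means = np.full((B, kmax, kmax, 2), np.nan)
    covs = np.full((B, kmax, kmax, 2, 2), np.nan)
    lls = np.full((B, kmax), -np.inf)
    conv = np.zeros((B, kmax), dtype=bool)

    # K = 1: closed form
    mu = X.mean(axis=1)
    xc = X - mu[:, None, :]
    cov1 = np.einsum("mnd,mne->mde", xc, xc) / n
    cov1[:, 0, 0] += floor
    cov1[:, 1, 1] += floor
    lls[:, 0] = _log_gauss(X, mu[:, None, :], cov1[:, None]).mean(axis=1)[:, 0]
    weights[:, 0, 0] = 1.0
    means[:, 0, 0] = mu
    covs[:, 0, 0] = cov1
    conv[:, 0] = True

    # EM in single precision: the fits are bandwidth-bound and the tolerance
    # (1e-3 on the mean log-likelihood) is far above float32 noise.
    X32 = X.astype(np.float32)
    offset = 0
    n_init = settings.n_init
    for K in range(2, kmax + 1):
        u = uniforms[:, offset:offset + n_init * K].reshape(B * n_init, K)
        offset += n_init * K
        init = _kmeanspp_means(np.repeat(X32, n_init, axis=0), K, u)
        w_r, m_r, c_r, ll_r, cv_r = _em_fixed_k(
            X32, init, floor, settings.tol, settings.max_iter, n_init=n_init)
        lls[:, K - 1] = ll_r
        conv[:, K - 1] = cv_r
        weights[:, K - 1, :K] = w_r
        means[:, K - 1, :K] = m_r
        covs[:, K - 1, :K] = c_r

    ks = np.arange(1, kmax + 1)
    bic = -2.0 * lls * n + _n_params(ks)[None, :] * np.log(n)
    penalised = np.where(conv, bic, np.inf)
    choice = penalised.argmin(axis=1)  # ties resolve to the smaller count

    rows = np.arange(B)
    return BatchGMMResult(
        n_components=(choice + 1).astype(np.int64),
        weights=weights[rows, choice],
        means=means[rows, choice],
        covariances=covs[rows, choice],
        bic=bic,
        converged=conv,
    )


def fit_pair_gmm(points, max_components: int = 4, seed: int = 0,
                 n_init: int = 3, covariance_floor: float = 1e-6,
                 tol: float = 1e-3, max_iter: int = 200) -> PairGMM:
    """Fit a single pair's mixture; see :func:`fit_gmm_batch` for semantics."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"points must be (n, 2), got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValidationError("at least 2 points are required to fit a mixture")
    if not np.isfinite(pts).all():
        raise ValidationError("points contain non-finite values")
    settings = GMMSettings(max_components=max_components, n_init=n_init,
                           covariance_floor=covariance_floor, tol=tol,
                           max_iter=max_iter)
    u = pair_uniforms(seed, np.array([0]), np.array([0]), settings.n_uniforms())
    res = fit_gmm_batch(pts[None, :, :], u, settings)
    k = int(res.n_components[0])
    attempted = res.bic.shape[1]
    return PairGMM(
        pair=(0, 1),
        weights=res.weights[0, :k].copy(),
        means=res.means[0, :k].copy(),
        covariances=res.covariances[0, :k].copy(),
        bic={kk + 1: float(res.bic[0, kk]) for kk in range(attempted)},
        converged={kk + 1: bool(res.converged[0, kk]) for kk in range(attempted)},
    )
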