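"""Tweedie exponential-dispersion machinery.

The Tweedie family is parameterized by a mean ``mu``, a dispersion ``phi``
and a power parameter ``rho`` through the variance relation
``Var(Y) = phi * mu**rho``.  Special cases are the Gaussian (``rho = 0``),
Poisson (``rho = 1``), gamma (``rho = 2``) and inverse Gaussian (``rho = 3``)
distributions.  For ``1 < rho < 2`` the family is the compound
Poisson-gamma: a Poisson number of gamma jumps, which places positive
probability mass at exactly zero while remaining continuous on the positive
half line.  That mixed support is what makes it a natural single-component
model for zero-inflated, overdispersed microbiome abundances: no separate
zero-inflation component or pseudocount is needed.

This module provides the density (series evaluation of the normalizer),
variance and link functions, an IRLS fitter that exposes the *working*
quantities (working response, working residuals, IRLS weights) consumed by
the ASCA-style decomposition, profile-likelihood estimation of
``(rho, phi)``, and a compound Poisson-gamma sampler used in tests and
simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr
from scipy.special import gammaln

__all__ = [
    "TweedieParams",
    "UnivariateFit",
    "variance_function",
    "tweedie_log_density",
    "tweedie_deviance",
    "tweedie_rvs",
    "LogLink",
    "IdentityLink",
    "ConstantWeightLink",
    "constant_weight_link",
    "get_link",
    "irls_fit",
    "irls_fit_multi",
    "estimate_power_dispersion",
    "estimate_power_dispersion_multi",
    "DEFAULT_RHO_GRID",
]

#: default grid for profile-likelihood estimation of the power parameter
DEFAULT_RHO_GRID = np.round(np.arange(1.05, 1.9501, 0.05), 2)


@dataclass(frozen=True)
class TweedieParams:
    """Parameters of a Tweedie distribution with ``Var(Y) = phi * mu**rho``."""

    mu: float
    phi: float
    rho: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not self.phi > 0:
            raise ValueError(f"phi must be positive, got {self.phi}")
        r = self.rho
        if not (r in (0.0, 1.0, 2.0, 3.0) or 1.0 < r < 2.0):
            raise ValueError(
                f"unsupported power parameter rho={r}; supported: 0, 1, (1,2), 2, 3"
            )


def variance_function(mu, rho):
    """Tweedie variance function ``V(mu) = mu**rho`` (dispersion excluded)."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("variance function requires mu > 0")
    return mu**rho


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------


def _log_series_a(y, phi, rho, rtol=1e-12, k_cap=100_000):
    """log of the series normalizer a(y; phi, rho) for y > 0, 1 < rho < 2.

    The compound Poisson-gamma density is
    ``f(y) = a(y; phi, rho) * exp{(1/phi) * (y*mu**(1-rho)/(1-rho)
    - mu**(2-rho)/(2-rho))}`` and the normalizer is an infinite series over
    the latent Poisson count::

        a(y) = (1/y) * sum_{k>=1} W_k,
        log W_k = k*c(y, phi) - gammaln(k+1) - gammaln(k*alpha),
        alpha = (2-rho)/(rho-1),
        c = alpha*log(y) - alpha*log(rho-1) - (1+alpha)*log(phi) - log(2-rho).

    The summand is unimodal in k with mode near
    ``k* = exp((c - alpha*log(alpha)) / (1+alpha))``; the sum runs over an
    index window centred there and is widened until boundary terms fall below
    ``rtol`` of the running maximum.
    """
    y = np.asarray(y, dtype=float)
    shape = y.shape
    phi = np.broadcast_to(np.asarray(phi, dtype=float), shape).ravel()
    y = y.ravel()
    alpha = (2.0 - rho) / (rho - 1.0)
    c = (
        alpha * np.log(y)
        - alpha * np.log(rho - 1.0)
        - (1.0 + alpha) * np.log(phi)
        - np.log(2.0 - rho)
    )
    k_star = np.exp((c - alpha * np.log(alpha)) / (1.0 + alpha))
    log_rtol = np.log(rtol)

    def _accumulate(c_chunk, k_star_chunk):
        k_hi = int(np.ceil(np.max(k_star_chunk + 12.0 * np.sqrt(k_star_chunk + 1.0) + 20.0)))
        k_hi = min(k_hi, k_cap)
        while True:
            # stream over k blocks so memory stays bounded for extreme (y, phi)
            m = np.full(c_chunk.shape, -np.inf)
            acc = np.zeros(c_chunk.shape)
            last = np.full(c_chunk.shape, -np.inf)
            for k0 in range(1, k_hi + 1, 8192):
                k = np.arange(k0, min(k0 + 8192, k_hi + 1), dtype=float)
                log_w = c_chunk[:, None] * k - gammaln(k + 1.0) - gammaln(k * alpha)
                m_new = np.maximum(m, log_w.max(axis=1))
                acc = acc * np.exp(m - m_new) + np.exp(log_w - m_new[:, None]).sum(axis=1)
                m = m_new
                last = log_w[:, -1]
            tail_ok = np.all(last - m < log_rtol)
            if tail_ok or k_hi >= k_cap:
                if not tail_ok:
                    warnings.warn(
                        "Tweedie series truncated at the index cap; "
                        "density may lose precision for extreme (y, phi).",
                        RuntimeWarning,
                    )
                return m + np.log(acc)
            k_hi = min(2 * k_hi, k_cap)

    out = np.empty_like(c)
    chunk = 100_000
    for i0 in range(0, len(c), chunk):
        sl = slice(i0, i0 + chunk)
        out[sl] = _accumulate(c[sl], k_star[sl])
    return (out - np.log(y)).reshape(shape)


def tweedie_log_density(y, mu, phi, rho):
    """Log density/mass of the compound Poisson-gamma (1 < rho < 2).

    Supports scalar or array ``y``/``mu``/``phi`` (broadcast together).  At
    ``y = 0`` the point mass has the closed form
    ``log f(0) = -mu**(2-rho) / (phi*(2-rho))``; for ``y > 0`` the normalizer
    is evaluated by adaptive series summation.
    """
    if not 1.0 < rho < 2.0:
        raise ValueError(
            f"tweedie_log_density supports the compound Poisson-gamma range "
            f"1 < rho < 2 only, got rho={rho}"
        )
    y, mu, phi = np.broadcast_arrays(
        np.asarray(y, dtype=float), np.asarray(mu, dtype=float), np.asarray(phi, dtype=float)
    )
    if np.any(y < 0):
        raise ValueError("y must be nonnegative")
    if np.any(mu <= 0) or np.any(phi <= 0):
        raise ValueError("mu and phi must be positive")
    out = np.empty(y.shape, dtype=float)
    # exponential-family kernel (theta-form), valid for all y >= 0
    kernel = (
        y * mu ** (1.0 - rho) / (1.0 - rho) - mu ** (2.0 - rho) / (2.0 - rho)
    ) / phi
    zero = y == 0
    out[zero] = kernel[zero]
    if np.any(~zero):
        out[~zero] = kernel[~zero] + _log_series_a(y[~zero], phi[~zero], rho)
    if out.ndim == 0:
        return float(out)
    return out


def _unit_deviance(y, mu, rho):
    """Elementwise Tweedie unit deviance for scalar ``rho``."""
    if rho == 0:
        return (y - mu) ** 2
    if rho == 1:
        ylogy = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        return 2.0 * (ylogy - (y - mu))
    if rho == 2:
        return 2.0 * (-np.log(y / mu) + (y - mu) / mu)
    a = np.where(y > 0, y, 0.0) ** (2.0 - rho) / ((1.0 - rho) * (2.0 - rho))
    b = y * mu ** (1.0 - rho) / (1.0 - rho)
    c = mu ** (2.0 - rho) / (2.0 - rho)
    return 2.0 * (a - b + c)


def tweedie_deviance(y, mu, rho):
    """Summed unit deviance for a Tweedie family.

    Handles the special cases ``rho = 0`` (Gaussian), ``rho = 1`` (Poisson),
    ``rho = 2`` (gamma) and the generic power form elsewhere.  For
    ``1 < rho < 2`` the formula is defined at ``y = 0``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return np.sum(_unit_deviance(y, mu, rho), axis=0)


def _deviance_columns(Y, mu, rho):
    """Per-column summed deviance with a column-specific power parameter.

    ``Y``/``mu`` are n x p, ``rho`` length p; columns are grouped by the
    special cases so everything stays vectorized.
    """
    p = Y.shape[1]
    out = np.empty(p)
    for case in (0.0, 1.0, 2.0):
        idx = rho == case
        if np.any(idx):
            out[idx] = np.sum(_unit_deviance(Y[:, idx], mu[:, idx], case), axis=0)
    gen = ~np.isin(rho, (0.0, 1.0, 2.0))
    if np.any(gen):
        r = rho[gen]
        Yg, mg = Y[:, gen], mu[:, gen]
        a = np.where(Yg > 0, Yg, 0.0) ** (2.0 - r) / ((1.0 - r) * (2.0 - r))
        b = Yg * mg ** (1.0 - r) / (1.0 - r)
        c = mg ** (2.0 - r) / (2.0 - r)
        out[gen] = 2.0 * np.sum(a - b + c, axis=0)
    return out


def tweedie_rvs(mu, phi, rho, size=None, rng=None):
    """Draw Tweedie variates.

    ``rho = 0``: Gaussian; ``rho = 1``: Poisson; ``rho = 2``: gamma;
    ``1 < rho < 2``: compound Poisson-gamma, sampled as a Poisson number of
    gamma jumps with rate ``lam = mu**(2-rho)/(phi*(2-rho))``, shape
    ``alpha = (2-rho)/(rho-1)`` and scale ``phi*(rho-1)*mu**(rho-1)``.
    """
    rng = np.random.default_rng(rng)
    if rho == 0:
        return rng.normal(mu, np.sqrt(phi), size=size)
    if rho == 1:
        return rng.poisson(mu, size=size) * 1.0
    if rho == 2:
        return rng.gamma(1.0 / phi, phi * mu, size=size)
    if not 1.0 < rho < 2.0:
        raise ValueError(f"unsupported rho={rho} for sampling")
    lam = mu ** (2.0 - rho) / (phi * (2.0 - rho))
    alpha = (2.0 - rho) / (rho - 1.0)
    scale = phi * (rho - 1.0) * mu ** (rho - 1.0)
    n = rng.poisson(np.broadcast_to(lam, size) if size is not None else lam)
    n = np.asarray(n)
    return np.where(n > 0, rng.gamma(np.maximum(n, 1) * alpha, scale), 0.0) * (n > 0)


# ---------------------------------------------------------------------------
# links
# ---------------------------------------------------------------------------


class LogLink:
    """Canonical-style log link: eta = log(mu)."""

    name = "log"

    def g(self, mu):
        return np.log(mu)

    def g_inv(self, eta):
        return np.exp(np.clip(eta, -700.0, 700.0))

    def dmu_deta(self, mu):
        return mu


class IdentityLink:
    name = "identity"

    def g(self, mu):
        return np.asarray(mu, dtype=float)

    def g_inv(self, eta):
        return np.asarray(eta, dtype=float)

    def dmu_deta(self, mu):
        return np.ones_like(np.asarray(mu, dtype=float))


class ConstantWeightLink:
    """Link built so every IRLS weight equals a chosen constant ``w``.

    The IRLS weight is ``(dmu/deta)**2 / V(mu)``; solving
    ``g'(mu) = 1/(sqrt(w) * sqrt(V(mu)))`` gives
    ``g(mu) = mu**(1-rho/2) / ((1-rho/2)*sqrt(w))`` for ``rho != 2`` and
    ``g(mu) = log(mu)/sqrt(w)`` for ``rho = 2`` (gamma + log up to scale).
    Constant weights make the weighted hat matrix commute with the weights,
    which restores the orthogonal effect decomposition for any balanced
    design, saturated or not.
    """

    def __init__(self, rho, w=1.0):
        if w <= 0:
            raise ValueError(f"constant weight w must be positive, got {w}")
        self.rho = float(rho)
        self.w = float(w)
        self.name = f"constant-weight(rho={rho}, w={w})"

    def g(self, mu):
        mu = np.asarray(mu, dtype=float)
        if self.rho == 2:
            return np.log(mu) / np.sqrt(self.w)
        e = 1.0 - self.rho / 2.0
        return mu**e / (e * np.sqrt(self.w))

    def g_inv(self, eta):
        eta = np.asarray(eta, dtype=float)
        if self.rho == 2:
            return np.exp(np.sqrt(self.w) * eta)
        e = 1.0 - self.rho / 2.0
        base = e * np.sqrt(self.w) * eta
        return np.maximum(base, 1e-300) ** (1.0 / e)

    def dmu_deta(self, mu):
        # 1/g'(mu) = sqrt(w) * mu**(rho/2)
        mu = np.asarray(mu, dtype=float)
        return np.sqrt(self.w) * mu ** (self.rho / 2.0)


def constant_weight_link(rho, w=1.0):
    """Return the link whose induced IRLS weights are identically ``w``."""
    if rho == 0 and w == 1.0:
        return IdentityLink()
    return ConstantWeightLink(rho, w)


_LINKS = {"log": LogLink, "identity": IdentityLink}


def get_link(link):
    if isinstance(link, str):
        try:
            return _LINKS[link]()
        except KeyError:
            raise ValueError(f"unknown link {link!r}; choose from {sorted(_LINKS)}")
    return link


# ---------------------------------------------------------------------------
# IRLS
# ---------------------------------------------------------------------------


@dataclass
class UnivariateFit:
    """One feature's GLM fit with the working quantities used downstream."""

    beta: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    weights: np.ndarray
    working_response: np.ndarray
    working_residuals: np.ndarray
    phi: float
    rho: float
    converged: bool
    n_iter: int
    deviance: float = field(default=np.nan)


def _check_full_rank(X):
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, m) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < m:
        bad = sorted(piv[rank:].tolist())
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {m} columns); "
            f"offending columns (0-based): {bad}"
        )
    return X


def irls_fit_multi(Y, X, rho, link="log", tol=1e-8, max_iter=100, mu_floor=None):
    """Fit GLMs for every column of ``Y`` against a shared design by IRLS.

    Vectorized over features: each iteration solves the per-feature weighted
    least-squares system ``beta_j = (X' W_j X)^{-1} X' W_j z_j`` with working
    response ``z = eta + (y - mu)/ (dmu/deta)`` and weights
    ``w = (dmu/deta)**2 / V(mu)`` (for the log link and Tweedie variance,
    ``w = mu**(2-rho)``).  Convergence is declared per feature on the
    relative change in deviance; a few step-halvings guard against deviance
    increases.  The dispersion ``phi`` cancels from the weights for a fixed
    ``rho`` and therefore never enters the fit.

    Returns a dict of stacked arrays: ``beta`` (m x p), ``eta``, ``mu``,
    ``weights``, ``working_response``, ``working_residuals`` (all n x p),
    ``deviance``, ``converged``, ``n_iter`` (length p).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-d array (samples x features)")
    X = _check_full_rank(X)
    n, p = Y.shape
    m = X.shape[1]
    if np.any(Y < 0):
        raise ValueError("response values must be nonnegative")
    rho = np.broadcast_to(np.asarray(rho, dtype=float), (p,))
    link = get_link(link)
    if link.name == "log" and np.any(~np.any(Y > 0, axis=0)):
        bad = np.where(~np.any(Y > 0, axis=0))[0].tolist()
        raise ValueError(
            f"all-zero response column(s) {bad} cannot be fitted with a log link"
        )

    # Gaussian/identity fits may legitimately produce negative means; every
    # other supported family needs mu > 0 for its variance function.  A
    # design cell whose responses are all zero has its MLE on the boundary
    # (cell mean 0, log-link coefficient -inf); left alone the linear
    # predictor drifts without limit and the huge working responses swamp
    # the decomposition.  Fitted means are therefore floored at a
    # detection-limit value below which no cell mean is data-supported.
    # Callers that know the replicate count R pass min_positive/R (the
    # smallest mean any cell with a detection can have, so no interior MLE
    # is ever clipped); the fallback is min_positive/(2n).
    pos_min = np.where(
        np.any(Y > 0, axis=0), np.min(np.where(Y > 0, Y, np.inf), axis=0), 1.0
    )
    if mu_floor is None:
        mu_floor = 0.5 * pos_min / max(n, 1)
    else:
        mu_floor = np.broadcast_to(np.asarray(mu_floor, dtype=float), (p,))

    def _clip_mu(mu_raw):
        if link.name == "identity" and np.all(rho == 0):
            return mu_raw
        return np.clip(mu_raw, mu_floor[None, :], 1e12)

    # init: shrink each observation halfway toward its feature's positive mean
    pos_sum = np.where(Y > 0, Y, 0.0).sum(axis=0)
    pos_cnt = np.maximum((Y > 0).sum(axis=0), 1)
    pos_mean = np.where(pos_sum > 0, pos_sum / pos_cnt, 1.0)
    mu = np.maximum((Y + pos_mean) / 2.0, 1e-10)
    eta = link.g(mu)

    dev = _deviance_columns(Y, mu, rho)
    B = np.zeros((m, p))
    converged = np.zeros(p, dtype=bool)
    n_iter = np.zeros(p, dtype=int)
    XX = X[:, :, None] * X[:, None, :]  # n x m x m outer products, reused

    for it in range(1, max_iter + 1):
        d = link.dmu_deta(mu)
        V = mu**rho
        W = np.maximum(d**2 / V, 1e-300)
        Z = eta + (Y - mu) / d
        # per-feature weighted least squares, all features at once
        A = np.tensordot(W.T, XX, axes=(1, 0))  # p x m x m
        b = X.T @ (W * Z)  # m x p
        try:
            B_new = np.linalg.solve(A, b.T[:, :, None])[:, :, 0].T  # m x p
        except np.linalg.LinAlgError:
            # boundary fits can drive some weights to ~0; a relative ridge
            # keeps the solve defined without visibly moving interior fits
            tr = np.einsum("pii->p", A) / m
            A = A + (1e-10 * tr)[:, None, None] * np.eye(m)
            B_new = np.linalg.solve(A, b.T[:, :, None])[:, :, 0].T

        # step-halving where the deviance would increase
        step = np.ones(p)
        for _ in range(8):
            B_try = B * (1 - step) + B_new * step
            mu_try = _clip_mu(link.g_inv(X @ B_try))
            dev_try = _deviance_columns(Y, mu_try, rho)
            worse = (dev_try > dev * (1 + 1e-9)) & ~converged & (it > 1)
            if not np.any(worse):
                break
            step[worse] *= 0.5
        B_next = B * (1 - step) + B_new * step
        eta_next = X @ B_next
        mu_next = _clip_mu(link.g_inv(eta_next))
        dev_next = _deviance_columns(Y, mu_next, rho)

        rel = np.abs(dev - dev_next) / (np.abs(dev) + 0.1)
        newly = ~converged
        n_iter[newly] = it
        B, eta, mu, dev = B_next, eta_next, mu_next, dev_next
        converged = converged | (rel < tol)
        if np.all(converged):
            break

    if not np.all(converged):
        warnings.warn(
            f"{int(np.sum(~converged))} feature fit(s) did not converge within "
            f"{max_iter} IRLS iterations",
            RuntimeWarning,
        )
    # final-iteration working quantities
    d = link.dmu_deta(mu)
    V = mu**rho
    W = np.maximum(d**2 / V, 1e-300)
    Rw = (Y - mu) / d
    Z = eta + Rw
    return {
        "beta": B,
        "eta": eta,
        "mu": mu,
        "weights": W,
        "working_response": Z,
        "working_residuals": Rw,
        "deviance": dev,
        "converged": converged,
        "n_iter": n_iter,
        "rho": rho.copy(),
    }


def irls_fit(y, X, rho=1.5, link="log", tol=1e-8, max_iter=100, phi=1.0):
    """Fit a single-response GLM by IRLS; see :func:`irls_fit_multi`."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be 1-d; use irls_fit_multi for matrices")
    if get_link(link).name == "log" and not np.any(y > 0):
        raise ValueError("all-zero response cannot be fitted with a log link")
    res = irls_fit_multi(y[:, None], X, rho, link=link, tol=tol, max_iter=max_iter)
    return UnivariateFit(
        beta=res["beta"][:, 0],
        eta=res["eta"][:, 0],
        mu=res["mu"][:, 0],
        weights=res["weights"][:, 0],
        working_response=res["working_response"][:, 0],
        working_residuals=res["working_residuals"][:, 0],
        phi=float(phi),
        rho=float(np.atleast_1d(res["rho"])[0]),
        converged=bool(res["converged"][0]),
        n_iter=int(res["n_iter"][0]),
        deviance=float(res["deviance"][0]),
    )


# ---------------------------------------------------------------------------
# (rho, phi) estimation by profile likelihood
# ---------------------------------------------------------------------------


def _loglik_phi_vec(Y, mu, rho, log_phi):
    """Tweedie log likelihood per feature at feature-specific phi.

    ``Y``/``mu`` are n x p, ``log_phi`` length p, scalar ``rho`` in (1, 2).
    """
    phi = np.exp(log_phi)
    kernel = (
        Y * mu ** (1.0 - rho) / (1.0 - rho) - mu ** (2.0 - rho) / (2.0 - rho)
    ) / phi
    ll = kernel.sum(axis=0)
    pos = Y > 0
    if np.any(pos):
        i, j = np.nonzero(pos)
        ll += np.bincount(
            j, weights=_log_series_a(Y[i, j], phi[j], rho), minlength=Y.shape[1]
        )
    return ll


def _golden_max(f, lo, hi, iters=28):
    """Vectorized golden-section maximization on per-feature brackets.

    ``f`` maps a vector of abscissae (one per feature) to a vector of
    objective values; one new evaluation per iteration.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.asarray(lo, dtype=float).copy()
    b = np.broadcast_to(np.asarray(hi, dtype=float), a.shape).astype(float).copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        move = fc < fd  # maximum lies in [c, b]
        a = np.where(move, c, a)
        b = np.where(move, b, d)
        c_new = np.where(move, d, b - invphi * (b - a))
        d_new = np.where(move, a + invphi * (b - a), c)
        f_known = np.where(move, fd, fc)
        # one fresh evaluation per iteration at the unknown interior point
        x_new = np.where(move, d_new, c_new)
        f_new = f(x_new)
        c, d = c_new, d_new
        fc = np.where(move, f_known, f_new)
        fd = np.where(move, f_new, f_known)
    x = (a + b) / 2.0
    return x, f(x)


def estimate_power_dispersion_multi(
    Y, X, rho_grid=None, link="log", log_phi_bounds=(-7.0, 7.0), tol=1e-8, max_iter=100
):
    """Profile-likelihood estimation of (rho_j, phi_j) for every feature.

    For each grid value of ``rho`` all features are refitted by IRLS (the fit
    does not depend on ``phi``), then the dispersion maximizing the Tweedie
    log likelihood at the fitted means is found by golden-section search on
    ``log(phi)``, vectorized across features.  The search is bracketed three
    log-units either side of the Pearson moment estimate
    ``sum((y-mu)^2 / mu^rho) / (n-m)`` (a consistent estimator the maximum
    sits close to), intersected with ``log_phi_bounds``; this keeps the
    series summation away from pathologically small dispersions.  Each
    feature's ``rho_hat`` is the grid point with the largest profiled
    likelihood.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    if rho_grid is None:
        rho_grid = DEFAULT_RHO_GRID
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any((rho_grid <= 1.0) | (rho_grid >= 2.0)):
        raise ValueError("rho_grid must lie strictly inside (1, 2)")
    const = np.ptp(Y, axis=0) == 0
    if np.any(const):
        raise ValueError(
            f"constant response column(s) {np.where(const)[0].tolist()}: "
            "power/dispersion are not identifiable"
        )
    best_ll = np.full(p, -np.inf)
    rho_hat = np.full(p, np.nan)
    phi_hat = np.full(p, np.nan)
    any_conv = np.zeros(p, dtype=bool)
    dof = max(Y.shape[0] - X.shape[1], 1)
    for rho in rho_grid:
        fit = irls_fit_multi(Y, X, rho, link=link, tol=tol, max_iter=max_iter)
        mu = fit["mu"]
        pearson = np.sum((Y - mu) ** 2 / mu**rho, axis=0) / dof
        center = np.log(np.clip(pearson, 1e-6, 1e6))
        lo = np.clip(center - 3.0, log_phi_bounds[0], log_phi_bounds[1] - 0.1)
        hi = np.clip(center + 3.0, log_phi_bounds[0] + 0.1, log_phi_bounds[1])
        lp, ll = _golden_max(
            lambda lp_: _loglik_phi_vec(Y, mu, rho, lp_), lo, hi
        )
        any_conv |= fit["converged"]
        better = ll > best_ll
        best_ll = np.where(better, ll, best_ll)
        rho_hat = np.where(better, rho, rho_hat)
        phi_hat = np.where(better, np.exp(lp), phi_hat)
    if not np.all(any_conv):
        bad = np.where(~any_conv)[0].tolist()
        warnings.warn(
            f"feature(s) {bad} had no convergent IRLS fit on the rho grid",
            RuntimeWarning,
        )
    return rho_hat, phi_hat


def estimate_power_dispersion(y, X, rho_grid=None, link="log", **kw):
    """Single-feature profile-likelihood (rho, phi); see the multi version."""
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("y is constant; power/dispersion are not identifiable")
    rho_hat, phi_hat = estimate_power_dispersion_multi(
        y[:, None], X, rho_grid=rho_grid, link=link, **kw
    )
    return float(rho_hat[0]), float(phi_hat[0])
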