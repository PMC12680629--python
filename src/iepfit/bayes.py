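"""Bayesian estimation of the IEP parameters under squared-error loss.

Independent Gamma(shape, rate) priors are placed on alpha and lam.  The
Bayes estimator under squared-error loss is the posterior mean, which has
no closed form here; four routes to it are provided:

* :func:`lindley_estimates` -- Lindley's second-order expansion of the
  ratio of posterior integrals around the MLE (error O(1/n)),
* :func:`tk_estimates` -- the Tierney-Kadane Laplace approximation applied
  separately to numerator and denominator (error O(1/n^2)),
* :func:`mh_sample` + :func:`sel_estimate` -- random-walk Metropolis-
  Hastings on the log-parameters,
* :func:`posterior_mean_quadrature` -- brute-force two-dimensional
  quadrature, usable as an oracle at small n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize

from .distribution import _EXP_OVERFLOW, IEPParams, PositiveSample
from .likelihood import (
    LikelihoodOverflowError,
    _log_likelihood_safe,
    derivative_bundle,
    log_likelihood,
)
from .mle import FitError, FitResult, fit_mle

__all__ = [
    "GammaPriorPair",
    "MCChain",
    "log_prior",
    "prior_gradient",
    "log_posterior_kernel",
    "lindley_estimates",
    "lindley_adjustment",
    "tk_estimates",
    "mh_sample",
    "random_walk_metropolis",
    "sel_estimate",
    "posterior_mean_quadrature",
]


@dataclass(frozen=True)
class GammaPriorPair:
    """Independent Gamma priors, shape-rate parameterization.

    ``Gamma(gamma1, delta1)`` on alpha and ``Gamma(gamma2, delta2)`` on
    lam, with density proportional to theta**(shape-1) * exp(-rate*theta).
    The defaults are the informative priors used throughout the
    simulation study: shape 1, rate 2 on alpha (prior mean 0.5) and
    shape 2, rate 1 on lam (prior mean 2).
    """

    gamma1: float = 1.0
    delta1: float = 2.0
    gamma2: float = 2.0
    delta2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma1", "delta1", "gamma2", "delta2"):
            v = float(getattr(self, name))
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite real")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class MCChain:
    """Posterior draws with burn-in bookkeeping."""

    draws: np.ndarray = field(repr=False)  # (n_iter, 2) of (alpha, lam), burn-in included
    n_iter: int
    burn_in: int
    acceptance_rate: float
    seed: Optional[int] = None

    @property
    def retained(self) -> np.ndarray:
        return self.draws[self.burn_in:]


def log_prior(p: IEPParams, pr: GammaPriorPair) -> float:
    """Fully normalized joint log prior density."""
    return float(
        (pr.gamma1 - 1.0) * np.log(p.alpha)
        + (pr.gamma2 - 1.0) * np.log(p.lam)
        - pr.delta1 * p.alpha
        - pr.delta2 * p.lam
        + pr.gamma1 * np.log(pr.delta1)
        + pr.gamma2 * np.log(pr.delta2)
        - math.lgamma(pr.gamma1)
        - math.lgamma(pr.gamma2)
    )


def prior_gradient(p: IEPParams, pr: GammaPriorPair) -> np.ndarray:
    """(rho_1, rho_2) = gradient of the log prior."""
    return np.array(
        [
            (pr.gamma1 - 1.0) / p.alpha - pr.delta1,
            (pr.gamma2 - 1.0) / p.lam - pr.delta2,
        ]
    )


def _prior_hessian(p: IEPParams, pr: GammaPriorPair) -> np.ndarray:
    return np.diag(
        [
            -(pr.gamma1 - 1.0) / p.alpha**2,
            -(pr.gamma2 - 1.0) / p.lam**2,
        ]
    )


def log_posterior_kernel(s: PositiveSample, p: IEPParams, pr: GammaPriorPair) -> float:
    """log likelihood + log prior, i.e. the log posterior up to a constant."""
    return log_likelihood(s, p) + log_prior(p, pr)


def _log_kernel_safe(s: PositiveSample, p: IEPParams, pr: GammaPriorPair) -> float:
    val = _log_likelihood_safe(s, p)
    return val + log_prior(p, pr) if np.isfinite(val) else -np.inf


# ---------------------------------------------------------------------------
# Lindley's approximation

def lindley_adjustment(
    sigma: np.ndarray,
    rho: np.ndarray,
    third: Callable[[int, int, int], float],
    u_grad: np.ndarray,
    u_hess: Optional[np.ndarray] = None,
) -> float:
    """Second-order Lindley correction for E[u | data] around the MLE.

    ``sigma`` is the inverse negated log-likelihood Hessian, ``rho`` the
    log-prior gradient, ``third(i, j, k)`` the third log-likelihood
    partials (0-based indices), and ``u_grad``/``u_hess`` the derivatives
    of the function whose posterior mean is wanted.  With ``rho`` and all
    third partials zero the correction vanishes, so the estimate falls
    back to the plain plug-in value.
    """
    if u_hess is None:
        u_hess = np.zeros((2, 2))
    corr = 0.0
    for i in range(2):
        for j in range(2):
            corr += 0.5 * (u_hess[i, j] + 2.0 * u_grad[i] * rho[j]) * sigma[i, j]
    for i in range(2):
        for j in range(2):
            for k in range(2):
                for l in range(2):
                    corr += 0.5 * third(i, j, k) * sigma[i, j] * sigma[k, l] * u_grad[l]
    return float(corr)


def lindley_estimates(s: PositiveSample, fit: FitResult, pr: GammaPriorPair) -> IEPParams:
    """Lindley-approximate posterior means of alpha and lam.

    Everything is evaluated at the MLE: sigma from the observed
    information, the log-prior gradient, and the analytic third partials.
    """
    if not fit.converged or fit.info is None:
        raise FitError("Lindley approximation requires a converged fit")
    p = fit.params
    bundle = derivative_bundle(s, p)
    sigma = fit.info.covariance()
    rho = prior_gradient(p, pr)
    a_hat = p.alpha + lindley_adjustment(sigma, rho, bundle.third, np.array([1.0, 0.0]))
    l_hat = p.lam + lindley_adjustment(sigma, rho, bundle.third, np.array([0.0, 1.0]))
    if a_hat <= 0 or l_hat <= 0:
        raise FitError("Lindley correction drove an estimate non-positive; n too small")
    return IEPParams(a_hat, l_hat)


# ---------------------------------------------------------------------------
# Tierney-Kadane

def _penalized_newton(
    s: PositiveSample,
    pr: GammaPriorPair,
    extra_grad: Callable[[IEPParams], np.ndarray],
    extra_hess: Callable[[IEPParams], np.ndarray],
    value: Callable[[IEPParams], float],
    start: IEPParams,
    tol: float = 1e-10,
    max_iter: int = 80,
):
    """Maximize L + rho + extra over (alpha, lam) by Newton in log coordinates.

    Returns the maximizer, its objective value, and the (original-
    coordinate) negated Hessian of the objective there.
    """
    theta = np.log(start.as_array())

    def full_grad_hess(p: IEPParams):
        b = derivative_bundle(s, p)
        g = b.score() + prior_gradient(p, pr) + extra_grad(p)
        H = b.hessian() + _prior_hessian(p, pr) + extra_hess(p)
        return g, H

    for _ in range(max_iter):
        p = IEPParams(*np.exp(theta))
        try:
            g, H = full_grad_hess(p)
        except LikelihoodOverflowError:
            break
        if np.max(np.abs(g)) < tol:
            break
        a, lam = p.alpha, p.lam
        gu = np.array([a * g[0], lam * g[1]])
        Hu = np.array(
            [
                [a * a * H[0, 0] + a * g[0], a * lam * H[0, 1]],
                [a * lam * H[0, 1], lam * lam * H[1, 1] + lam * g[1]],
            ]
        )
        try:
            step = np.linalg.solve(Hu, -gu)
        except np.linalg.LinAlgError:
            break
        f0 = value(p)
        scale = 1.0
        cand = theta
        while scale > 1e-10:
            cand = np.clip(theta + scale * step, -200.0, 200.0)
            if value(IEPParams(*np.exp(cand))) > f0 - 1e-13:
                break
            scale /= 2.0
        theta = cand

    p = IEPParams(*np.exp(theta))
    g, H = full_grad_hess(p)
    if np.max(np.abs(g)) > 1e-5:
        # fall back to a derivative-free polish before giving up
        res = minimize(
            lambda th: -value(IEPParams(*np.exp(th))),
            theta,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000},
        )
        p = IEPParams(*np.exp(res.x))
        g, H = full_grad_hess(p)
        if np.max(np.abs(g)) > 1e-4:
            raise FitError("posterior-mode optimization failed to converge")
    return p, value(p), -H


def _tk_expectation(
    s: PositiveSample,
    pr: GammaPriorPair,
    logu_value: Callable[[IEPParams], float],
    logu_grad: Callable[[IEPParams], np.ndarray],
    logu_hess: Callable[[IEPParams], np.ndarray],
    start: IEPParams,
) -> float:
    """Tierney-Kadane posterior expectation of a positive function u.

    eta = (L + rho)/n is maximized once; eta* = (log u)/n + eta is
    maximized for the requested u; the estimate is
    sqrt(det Sigma* / det Sigma) * exp(n [eta*(mode*) - eta(mode)]),
    where Sigma and Sigma* are inverse negated Hessians of eta and eta*.
    """
    n = s.n
    zero_g = lambda p: np.zeros(2)
    zero_h = lambda p: np.zeros((2, 2))
    val = lambda p: _log_kernel_safe(s, p, pr)

    mode, f_mode, negH = _penalized_newton(s, pr, zero_g, zero_h, val, start)
    val_star = lambda p: (val(p) + logu_value(p)) if np.isfinite(val(p)) else -np.inf
    mode_s, f_mode_s, negH_s = _penalized_newton(
        s, pr, logu_grad, logu_hess, val_star, mode
    )

    # negH are Hessians of n*eta; Sigma = inv(negH)/... determinant ratio:
    # det Sigma* / det Sigma = det(negH) / det(negH*) (the n factors cancel)
    det, det_s = np.linalg.det(negH), np.linalg.det(negH_s)
    if det <= 0 or det_s <= 0:
        raise FitError("non-positive-definite Hessian in Tierney-Kadane approximation")
    # n(eta* - eta) = (f_mode_s - f_mode) since both values carry the same kernel
    return float(np.sqrt(det / det_s) * np.exp(f_mode_s - f_mode))


def tk_estimates(
    s: PositiveSample, pr: GammaPriorPair, fit: Optional[FitResult] = None
) -> IEPParams:
    """Tierney-Kadane posterior means of alpha and lam."""
    if s.n < 3:
        raise FitError("Tierney-Kadane approximation needs n >= 3")
    start = (fit.params if fit is not None else fit_mle(s).params)
    a_hat = _tk_expectation(
        s,
        pr,
        logu_value=lambda p: np.log(p.alpha),
        logu_grad=lambda p: np.array([1.0 / p.alpha, 0.0]),
        logu_hess=lambda p: np.diag([-1.0 / p.alpha**2, 0.0]),
        start=start,
    )
    l_hat = _tk_expectation(
        s,
        pr,
        logu_value=lambda p: np.log(p.lam),
        logu_grad=lambda p: np.array([0.0, 1.0 / p.lam]),
        logu_hess=lambda p: np.diag([0.0, -1.0 / p.lam**2]),
        start=start,
    )
    return IEPParams(a_hat, l_hat)


# ---------------------------------------------------------------------------
# Random-walk Metropolis-Hastings

def random_walk_metropolis(
    log_target: Callable[[np.ndarray], float],
    start: np.ndarray,
    proposal_cov: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
):
    """Generic Gaussian random-walk Metropolis sampler.

    Returns the full chain of states (n_iter, d) and the acceptance rate.
    """
    start = np.asarray(start, dtype=float)
    d = start.size
    cov = np.asarray(proposal_cov, dtype=float)
    if np.allclose(cov, 0.0):
        chol = np.zeros((d, d))
    else:
        chol = np.linalg.cholesky(cov)
    states = np.empty((n_iter, d))
    current = start
    f_current = log_target(current)
    accepted = 0
    noise = rng.standard_normal((n_iter, d))
    log_u = np.log(rng.uniform(size=n_iter))
    for i in range(n_iter):
        proposal = current + chol @ noise[i]
        f_prop = log_target(proposal)
        if log_u[i] < f_prop - f_current:
            current, f_current = proposal, f_prop
            accepted += 1
        states[i] = current
    return states, accepted / n_iter


def _transformed_mode_and_hessian(s: PositiveSample, pr: GammaPriorPair, start: IEPParams):
    """Mode of the (log alpha, log lam) posterior and its negated Hessian there.

    The transformed target is L + rho + log alpha + log lam (the last two
    terms are the Jacobian of the log transform).
    """
    jac_grad = lambda p: np.array([1.0 / p.alpha, 1.0 / p.lam])
    jac_hess = lambda p: np.diag([-1.0 / p.alpha**2, -1.0 / p.lam**2])
    val = lambda p: (
        _log_kernel_safe(s, p, pr) + np.log(p.alpha) + np.log(p.lam)
    )
    mode, _fval, negH = _penalized_newton(s, pr, jac_grad, jac_hess, val, start)
    # convert the original-coordinate negated Hessian to (u, v) = log coords;
    # the gradient term vanishes at the mode
    a, lam = mode.alpha, mode.lam
    H = -negH
    Hlog = np.array(
        [
            [a * a * H[0, 0], a * lam * H[0, 1]],
            [a * lam * H[0, 1], lam * lam * H[1, 1]],
        ]
    )
    return mode, -Hlog


def mh_sample(
    s: PositiveSample,
    pr: GammaPriorPair,
    n_iter: int = 10_000,
    burn_in: int = 2_000,
    scale: float = 2.4 / np.sqrt(2.0),
    seed=None,
) -> MCChain:
    """Random-walk Metropolis-Hastings for the IEP posterior.

    The chain runs on (log alpha, log lam); Gaussian proposals use
    covariance ``scale**2`` times the inverse negated Hessian of the
    transformed posterior at its mode, and the chain starts at that mode.
    The default scale 2.4/sqrt(2) is the usual optimal-scaling choice in
    two dimensions.
    """
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    if scale < 0:
        raise ValueError("scale must be non-negative")
    start = fit_mle(s).params
    mode, negH_log = _transformed_mode_and_hessian(s, pr, start)
    det = np.linalg.det(negH_log)
    if det <= 0 or negH_log[0, 0] <= 0:
        raise FitError("transformed posterior mode has non-PD Hessian")
    base_cov = np.linalg.inv(negH_log)

    def log_target(theta):
        p = IEPParams(*np.exp(theta))
        return _log_kernel_safe(s, p, pr) + theta[0] + theta[1]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states, rate = random_walk_metropolis(
        log_target, np.log(mode.as_array()), scale**2 * base_cov, n_iter, rng
    )
    if not 0.1 <= rate <= 0.6 and scale > 0:
        warnings.warn(
            f"Metropolis acceptance rate {rate:.3f} outside [0.1, 0.6]; "
            "consider adjusting the proposal scale",
            RuntimeWarning,
        )
    return MCChain(
        draws=np.exp(states),
        n_iter=n_iter,
        burn_in=burn_in,
        acceptance_rate=rate,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def sel_estimate(chain: MCChain) -> IEPParams:
    """Posterior mean of the retained draws (the SEL Bayes estimate)."""
    retained = chain.retained
    if retained.size == 0:
        raise ValueError("chain has no retained draws")
    mean = retained.mean(axis=0)
    return IEPParams(mean[0], mean[1])


# ---------------------------------------------------------------------------
# Quadrature oracle

def _log_kernel_grid(s: PositiveSample, pr: GammaPriorPair, A: np.ndarray, L: np.ndarray):
    """Vectorized log posterior kernel over parameter arrays of equal shape."""
    x = s.values
    n = s.n
    logx_sum = np.log(x).sum()
    A = np.asarray(A)[..., None]
    L = np.asarray(L)[..., None]
    with np.errstate(over="ignore"):
        t = np.power(L / x, A)
        ll = (
            n * np.log(A[..., 0])
            + n * A[..., 0] * np.log(L[..., 0])
            - (A[..., 0] + 1.0) * logx_sum
            + t.sum(axis=-1)
            + n
            - np.exp(np.minimum(t, _EXP_OVERFLOW + 1)).sum(axis=-1)
        )
        lp = (
            (pr.gamma1 - 1.0) * np.log(A[..., 0])
            + (pr.gamma2 - 1.0) * np.log(L[..., 0])
            - pr.delta1 * A[..., 0]
            - pr.delta2 * L[..., 0]
        )
    out = ll + lp
    return np.where(np.isfinite(out), out, -np.inf)


def posterior_mean_quadrature(
    s: PositiveSample,
    pr: GammaPriorPair,
    n_nodes: int = 160,
    half_width_sd: float = 10.0,
) -> IEPParams:
    """Posterior means by tensor-product Gauss-Legendre quadrature.

    Integration is performed in (log alpha, log lam) over a box of
    ``half_width_sd`` posterior standard deviations around the
    transformed-posterior mode, after centering the kernel by its value
    at the mode.  Intended as a brute-force reference for samples up to
    a few hundred observations, where the integrand is well localized.
    """
    start = fit_mle(s).params
    mode, negH_log = _transformed_mode_and_hessian(s, pr, start)
    cov = np.linalg.inv(negH_log)
    sd = np.sqrt(np.diag(cov))
    center = np.log(mode.as_array())
    k0 = _log_kernel_safe(s, mode, pr) + center.sum()

    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    lo, hi = center - half_width_sd * sd, center + half_width_sd * sd
    U = 0.5 * (hi[0] - lo[0]) * nodes + 0.5 * (hi[0] + lo[0])
    wu = 0.5 * (hi[0] - lo[0]) * weights
    V = 0.5 * (hi[1] - lo[1]) * nodes + 0.5 * (hi[1] + lo[1])
    wv = 0.5 * (hi[1] - lo[1]) * weights

    UU, VV = np.meshgrid(U, V, indexing="ij")
    A, L = np.exp(UU), np.exp(VV)
    logk = np.empty_like(UU)
    chunk = max(1, int(2e6 / (n_nodes * s.n)))
    for i in range(0, n_nodes, chunk):
        logk[i : i + chunk] = _log_kernel_grid(s, pr, A[i : i + chunk], L[i : i + chunk])
    W = np.exp(logk + UU + VV - k0)  # kernel times Jacobian, centered
    WW = wu[:, None] * wv[None, :] * W
    Z = WW.sum()
    if not np.isfinite(Z) or Z <= 0:
        raise FitError("quadrature mass vanished; posterior too diffuse for the box")
    return IEPParams(float((WW * A).sum() / Z), float((WW * L).sum() / Z))
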