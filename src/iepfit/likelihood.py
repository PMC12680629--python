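"""Log-likelihood of the IEP model and its analytic derivatives.

For a sample x_1..x_n the log-likelihood is

    L(alpha, lam) = n log alpha + n alpha log lam - (alpha+1) sum log x_i
                    + sum t_i + n - sum exp(t_i),      t_i = (lam/x_i)**alpha.

Writing u_i = log(lam/x_i), every derivative of L reduces to derivatives
of t_i (a power function, so t-derivatives are elementary) chained through
psi(t) = t - exp(t).  The score is

    dL/dalpha = n/alpha + sum u_i + sum t_i u_i (1 - exp t_i)
    dL/dlam   = (alpha/lam) [ n + sum t_i (1 - exp t_i) ]

Note the lam-derivative carries x_i**(-alpha) inside t_i.  All second and
third partials follow the same chain rule and are validated against
central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distribution import _EXP_OVERFLOW, IEPParams, PositiveSample

__all__ = [
    "LikelihoodOverflowError",
    "DerivativeBundle",
    "log_likelihood",
    "score",
    "derivative_bundle",
]


class LikelihoodOverflowError(FloatingPointError):
    """exp((lam/x_i)**alpha) exceeded the representable range."""


@dataclass(frozen=True)
class DerivativeBundle:
    """Score plus all second- and third-order partials of the log-likelihood.

    Index 1 is alpha, index 2 is lam; mixed partials are symmetric in
    their indices, so only one representative of each is stored.
    """

    L1: float
    L2: float
    L11: float
    L12: float
    L22: float
    L111: float
    L112: float
    L122: float
    L222: float

    def score(self) -> np.ndarray:
        return np.array([self.L1, self.L2])

    def hessian(self) -> np.ndarray:
        return np.array([[self.L11, self.L12], [self.L12, self.L22]])

    def third(self, i: int, j: int, k: int) -> float:
        """Third partial by 0-based indices, symmetric in (i, j, k)."""
        m = sum((i, j, k))
        return (self.L111, self.L112, self.L122, self.L222)[m]


def _t_terms(s: PositiveSample, p: IEPParams, check: bool = True):
    x = s.values
    u = np.log(p.lam) - np.log(x)
    with np.errstate(over="ignore"):
        t = np.exp(p.alpha * u)
    if check and np.any(t > _EXP_OVERFLOW):
        i = int(np.argmax(t))
        raise LikelihoodOverflowError(
            f"exp((lam/x)**alpha) overflows at observation index {i} "
            f"(x={x[i]!r}, (lam/x)**alpha={t[i]:.3g})"
        )
    return x, u, t


def log_likelihood(s: PositiveSample, p: IEPParams) -> float:
    """Exact sum of per-observation log-densities, in closed form."""
    x, _u, t = _t_terms(s, p)
    n = s.n
    return float(
        n * np.log(p.alpha)
        + n * p.alpha * np.log(p.lam)
        - (p.alpha + 1.0) * np.log(x).sum()
        + t.sum()
        + n
        - np.exp(t).sum()
    )


def score(s: PositiveSample, p: IEPParams) -> np.ndarray:
    """(dL/dalpha, dL/dlam) as a length-2 array."""
    _x, u, t = _t_terms(s, p)
    n, a, lam = s.n, p.alpha, p.lam
    w = t * (1.0 - np.exp(t))
    l1 = n / a + u.sum() + (w * u).sum()
    l2 = (a / lam) * (n + w.sum())
    return np.array([l1, l2])


def derivative_bundle(s: PositiveSample, p: IEPParams) -> DerivativeBundle:
    _x, u, t = _t_terms(s, p)
    n, a, lam = s.n, p.alpha, p.lam
    et = np.exp(t)
    p1 = 1.0 - et          # psi'(t)
    p2 = -et               # psi''(t) = psi'''(t)

    # derivatives of t = exp(alpha * u) wrt (alpha, lam)
    ta = t * u
    tl = a * t / lam
    taa = t * u * u
    tal = t * (a * u + 1.0) / lam
    tll = a * (a - 1.0) * t / lam**2
    taaa = t * u**3
    taal = t * u * (a * u + 2.0) / lam
    tall = t * ((a - 1.0) * (a * u + 1.0) + a) / lam**2
    tlll = a * (a - 1.0) * (a - 2.0) * t / lam**3

    l1 = n / a + u.sum() + (p1 * ta).sum()
    l2 = n * a / lam + (p1 * tl).sum()
    l11 = -n / a**2 + (p2 * ta * ta + p1 * taa).sum()
    l12 = n / lam + (p2 * ta * tl + p1 * tal).sum()
    l22 = -n * a / lam**2 + (p2 * tl * tl + p1 * tll).sum()
    l111 = 2.0 * n / a**3 + (p2 * ta**3 + 3.0 * p2 * ta * taa + p1 * taaa).sum()
    l112 = (p2 * ta * ta * tl + p2 * (taa * tl + 2.0 * ta * tal) + p1 * taal).sum()
    l122 = -n / lam**2 + (p2 * ta * tl * tl + p2 * (tll * ta + 2.0 * tl * tal) + p1 * tall).sum()
    l222 = 2.0 * n * a / lam**3 + (p2 * tl**3 + 3.0 * p2 * tl * tll + p1 * tlll).sum()

    vals = (l1, l2, l11, l12, l22, l111, l112, l122, l222)
    if not all(np.isfinite(v) for v in vals):
        raise LikelihoodOverflowError("a derivative term overflowed; parameters too extreme")
    return DerivativeBundle(*(float(v) for v in vals))


def _log_likelihood_safe(s: PositiveSample, p: IEPParams) -> float:
    """Like :func:`log_likelihood` but returns -inf instead of raising.

    Used by optimizers, which must be free to probe parameter values
    whose likelihood has underflowed.
    """
    x, _u, t = _t_terms(s, p, check=False)
    if np.any(t > _EXP_OVERFLOW):
        return -np.inf  # at least one observation's density underflowed to 0
    n = s.n
    val = (
        n * np.log(p.alpha)
        + n * p.alpha * np.log(p.lam)
        - (p.alpha + 1.0) * np.log(x).sum()
        + t.sum()
        + n
        - np.exp(t).sum()
    )
    return float(val) if np.isfinite(val) else -np.inf
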