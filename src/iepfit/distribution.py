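"""The inverse exponential power (IEP) distribution.

A strictly positive random variable X follows IEP(alpha, lam) when its
distribution function is

    F(x) = exp(1 - exp((lam / x)**alpha)),   x > 0,

i.e. the law of the reciprocal of an exponential-power variable.  Both
parameters are strictly positive; ``alpha`` is the power exponent
controlling the tail and hazard shape, ``lam`` sets the scale of x.
The density is

    f(x) = (alpha/lam) (lam/x)**(alpha+1) exp((lam/x)**alpha)
           * exp(1 - exp((lam/x)**alpha)).

All evaluation routes through a log-space form: the raw density contains
exp(exp(.)) and overflows for x well below lam, which is exactly the
region small case-fatality-rate observations live in.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IEPParams",
    "PositiveSample",
    "pdf",
    "log_pdf",
    "cdf",
    "survival",
    "hazard",
    "quantile",
    "sample",
]

# exp(t) overflows IEEE doubles just above t = 709.78; past this point the
# density has underflowed to an exact 0 anyway.
_EXP_OVERFLOW = 709.0


@dataclass(frozen=True)
class IEPParams:
    """Parameter pair (alpha, lam) of the IEP distribution, both > 0."""

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        alpha = float(self.alpha)
        lam = float(self.lam)
        if not (np.isfinite(alpha) and alpha > 0):
            raise ValueError(f"alpha must be a positive finite real, got {self.alpha!r}")
        if not (np.isfinite(lam) and lam > 0):
            raise ValueError(f"lam must be a positive finite real, got {self.lam!r}")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "lam", lam)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.lam])


@dataclass(frozen=True)
class PositiveSample:
    """An ordered collection of strictly positive observations.

    Order is preserved as read and duplicates are allowed; the container
    only guarantees positivity and non-emptiness.
    """

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("sample must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            bad = np.flatnonzero(~(np.isfinite(values) & (values > 0)))[0]
            raise ValueError(
                f"all observations must be positive finite reals; "
                f"offending value {values[bad]!r} at position {bad}"
            )
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    @classmethod
    def from_iterable(cls, values: Sequence[float]) -> "PositiveSample":
        return cls(np.asarray(list(values), dtype=float))

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.values)


def _check_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("x must be positive and finite")
    return x


def _t(x: np.ndarray, p: IEPParams) -> np.ndarray:
    """(lam/x)**alpha, the quantity every formula is built from."""
    return np.power(p.lam / x, p.alpha)


def log_pdf(x, p: IEPParams):
    """Log-density; returns -inf where the density underflows to zero."""
    x = _check_x(x)
    t = _t(x, p)
    with np.errstate(over="ignore"):
        out = (
            np.log(p.alpha)
            - np.log(p.lam)
            + (p.alpha + 1.0) * (np.log(p.lam) - np.log(x))
            + t
            + 1.0
            - np.exp(t)
        )
    out = np.where(t > _EXP_OVERFLOW, -np.inf, out)
    return out if out.ndim else float(out)


def pdf(x, p: IEPParams):
    """Density of IEP(alpha, lam); underflows to 0 rather than overflowing."""
    lp = np.asarray(log_pdf(x, p))
    out = np.where(np.isneginf(lp), 0.0, np.exp(lp))
    return out if out.ndim else float(out)


def cdf(x, p: IEPParams):
    """F(x) = exp(1 - exp((lam/x)**alpha)); 0 at 0+, 1 at infinity."""
    x = _check_x(x)
    t = _t(x, p)
    with np.errstate(over="ignore"):
        out = np.where(t > _EXP_OVERFLOW, 0.0, np.exp(1.0 - np.exp(np.minimum(t, _EXP_OVERFLOW))))
    return out if out.ndim else float(out)


def survival(x, p: IEPParams):
    """1 - F(x), computed through expm1 so the right tail keeps precision."""
    x = _check_x(x)
    t = _t(x, p)
    with np.errstate(over="ignore"):
        out = np.where(t > _EXP_OVERFLOW, 1.0, -np.expm1(1.0 - np.exp(np.minimum(t, _EXP_OVERFLOW))))
    return out if out.ndim else float(out)


def hazard(x, p: IEPParams):
    """Instantaneous failure rate pdf/survival.

    Where the survival function underflows to exact zero the hazard is
    reported as +inf with a warning.
    """
    f = np.asarray(pdf(x, p))
    s = np.asarray(survival(x, p))
    zero = s == 0.0
    if np.any(zero):
        warnings.warn("survival underflowed to 0; hazard reported as inf", RuntimeWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, np.inf, f / np.where(zero, 1.0, s))
    return out if out.ndim else float(out)


def quantile(u, p: IEPParams):
    """Closed-form inverse cdf: lam * [log(1 - log u)]**(-1/alpha)."""
    u = np.asarray(u, dtype=float)
    if np.any(~np.isfinite(u)) or np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("u must lie strictly inside (0, 1)")
    out = p.lam * np.power(np.log1p(-np.log(u)), -1.0 / p.alpha)
    return out if out.ndim else float(out)


def sample(n: int, p: IEPParams, seed) -> PositiveSample:
    """n i.i.d. draws by inverse-transform sampling.

    ``seed`` may be an integer or a ``numpy.random.Generator``; an integer
    seed makes the output bit-reproducible.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    # uniform() can return exactly 0.0 (open at 1); nudge into (0, 1)
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return PositiveSample(quantile(u, p))
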