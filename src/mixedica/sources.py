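"""Fixed source laws for mixed ICA/PCA.

Three unit-variance, zero-mean source distributions are modeled:

* ``SUB`` — a symmetric two-component Gaussian mixture, the components
  centered at ±1/√2 with variance 1/2, giving the light-tailed density
  ``p(x) = exp(-x²)·cosh(x·√2)/√(π·e)`` with excess kurtosis −1/2;
* ``SUPER`` — the heavy-tailed hyperbolic-secant law
  ``p(x) = 1/(2·cosh(π·x/2))`` with excess kurtosis 2;
* ``GAUSS`` — the standard normal.

Each law exposes its log-density, its score function (the derivative of
the log-density, which drives the likelihood gradient of the unmixing
matrix), and a seeded unit-variance sampler.  The particular non-Gaussian
shapes matter little for source separation — one light-tailed and one
heavy-tailed law suffice — but the three laws are fixed so that model
categories are comparable by likelihood.
"""

from __future__ import annotations

import enum
import math
from typing import Sequence

import numpy as np

__all__ = [
    "SourceKind",
    "log_density",
    "score",
    "sample",
    "excess_kurtosis",
    "multivariate_kurtosis",
]

_LOG_2 = math.log(2.0)
_LOG_2PI = math.log(2.0 * math.pi)
# normalizing constant of the Gaussian-mixture (sub-Gaussian) law: 1/sqrt(pi*e)
_SUB_CONST = -0.5 * (math.log(math.pi) + 1.0)
_SQRT2 = math.sqrt(2.0)


class SourceKind(enum.Enum):
    """The three modeled source laws."""

    SUB = "sub"
    SUPER = "super"
    GAUSS = "gauss"

    @classmethod
    def from_string(cls, name: str) -> "SourceKind":
        try:
            return cls(name.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown source kind {name!r}; expected one of "
                f"{[k.value for k in cls]}"
            ) from None


def _log_cosh(x: np.ndarray) -> np.ndarray:
    # overflow-safe: log cosh x = |x| + log1p(exp(-2|x|)) - log 2
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - _LOG_2


def log_density(x, kind: SourceKind):
    """Log-density ``log p(x)`` of the named unit-variance source law.

    Accepts scalars or arrays; raises on non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log_density requires finite input")
    if kind is SourceKind.GAUSS:
        out = -0.5 * _LOG_2PI - 0.5 * x * x
    elif kind is SourceKind.SUPER:
        out = -_LOG_2 - _log_cosh(0.5 * math.pi * x)
    elif kind is SourceKind.SUB:
        out = _SUB_CONST - x * x + _log_cosh(_SQRT2 * x)
    else:  # pragma: no cover - enum is exhaustive
        raise TypeError(f"not a SourceKind: {kind!r}")
    return out if out.ndim else float(out)


def score(x, kind: SourceKind):
    """Score function ``d log p / dx`` of the named law.

    For the heavy-tailed law this is ``−(π/2)·tanh(π·x/2)``, for the
    Gaussian-mixture law ``−2x + √2·tanh(√2·x)``, and for the Gaussian
    simply ``−x``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("score requires finite input")
    if kind is SourceKind.GAUSS:
        out = -x
    elif kind is SourceKind.SUPER:
        out = -0.5 * math.pi * np.tanh(0.5 * math.pi * x)
    elif kind is SourceKind.SUB:
        out = -2.0 * x + _SQRT2 * np.tanh(_SQRT2 * x)
    else:  # pragma: no cover
        raise TypeError(f"not a SourceKind: {kind!r}")
    return out if out.ndim else float(out)


def sample(kind: SourceKind, count: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``count`` i.i.d. unit-variance deviates from the named law.

    The Gaussian-mixture law is sampled by adding a random sign times
    1/√2 to a normal deviate of variance 1/2; the hyperbolic-secant law
    by the inverse-CDF transform ``v = (4/π)·artanh(tan((π/2)(u − ½)))``
    of a uniform deviate ``u``, clamped away from the endpoints where the
    transform diverges.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if kind is SourceKind.GAUSS:
        return rng.standard_normal(count)
    if kind is SourceKind.SUB:
        z = rng.standard_normal(count) / _SQRT2
        signs = rng.integers(0, 2, size=count) * 2 - 1
        return z + signs / _SQRT2
    if kind is SourceKind.SUPER:
        eps = np.finfo(float).eps
        u = np.clip(rng.random(count), eps, 1.0 - eps)
        return (4.0 / math.pi) * np.arctanh(np.tan(0.5 * math.pi * (u - 0.5)))
    raise TypeError(f"not a SourceKind: {kind!r}")  # pragma: no cover


def excess_kurtosis(kind: SourceKind) -> float:
    """Excess kurtosis E[x⁴] − 3 of the named unit-variance law.

    Closed forms: the Gaussian-mixture fourth moment is
    μ⁴ + 6μ²σ² + 3σ⁴ = 2.5 with μ² = σ² = 1/2, hence −1/2; the
    hyperbolic-secant law has fourth moment 5, hence +2.
    """
    if kind is SourceKind.SUB:
        return -0.5
    if kind is SourceKind.SUPER:
        return 2.0
    if kind is SourceKind.GAUSS:
        return 0.0
    raise TypeError(f"not a SourceKind: {kind!r}")  # pragma: no cover


def multivariate_kurtosis(kinds: Sequence[SourceKind]) -> float:
    """Multivariate (excess) kurtosis κ₄ of independent unit-variance components.

    For a product law of independent components, κ₄ is additive, so this
    is simply the sum of the per-component excess kurtoses.  Two
    components of the Gaussian-mixture law give −1; two of the
    hyperbolic-secant law give 4; any multivariate Gaussian gives 0.
    """
    kinds = list(kinds)
    if not kinds:
        raise ValueError("kinds must be non-empty")
    return float(sum(excess_kurtosis(k) for k in kinds))
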