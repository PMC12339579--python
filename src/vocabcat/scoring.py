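"""Vocabulary-size conversion and the attention (trustworthiness) index.

An ability estimate in logits is converted to a word count with the
logistic map ``y = a / (1 + exp(-b (x - c)))`` where ``a`` is the total
lexicon size (default 140,000 words, after a large orthographic
dictionary), ``b`` a positive slope, and ``c`` the ability at which the
estimate equals half the lexicon.  The coefficients (b, c) are obtained by
least-squares fitting the same logistic to item frequency rank versus item
difficulty; ``a`` is fixed, not estimated.

The attention index is ``100 * (x + y) / (ax + ay)`` where ``x`` of ``ax``
presented pseudowords were marked unknown and ``y`` of ``ay`` presented
multiple-choice words were defined correctly.  Sessions below the trust
threshold (default 70%) are flagged as not trustworthy; the index is never
used to penalize the vocabulary estimate itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = [
    "ConversionCoefficients",
    "ConversionFit",
    "AttentionCounts",
    "ConversionFitError",
    "UndefinedIndexError",
    "logits_to_words",
    "fit_conversion",
    "attention_index",
    "is_trustworthy",
    "DEFAULT_TRUST_THRESHOLD",
]

DEFAULT_TRUST_THRESHOLD = 70.0


class ConversionFitError(RuntimeError):
    """The logistic rank-vs-difficulty fit failed to converge."""


class UndefinedIndexError(ValueError):
    """The attention index is undefined (no control items presented)."""


@dataclass(frozen=True)
class ConversionCoefficients:
    """Coefficients of the logit-to-words logistic conversion."""

    a: int
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("lexicon size a must be positive")
        if self.b <= 0:
            raise ValueError("slope b must be positive (conversion increasing)")


@dataclass(frozen=True)
class ConversionFit:
    coefficients: ConversionCoefficients
    residual_rmse: float
    converged: bool
    n_pairs: int


@dataclass(frozen=True)
class AttentionCounts:
    """Control-item counts entering the attention index."""

    x: int   # pseudowords marked unknown
    ax: int  # pseudowords presented
    y: int   # multiple-choice words defined correctly
    ay: int  # multiple-choice words presented

    def __post_init__(self) -> None:
        for name, v in (("x", self.x), ("ax", self.ax), ("y", self.y), ("ay", self.ay)):
            if v < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.x > self.ax:
            raise ValueError("x cannot exceed ax")
        if self.y > self.ay:
            raise ValueError("y cannot exceed ay")


def logits_to_words(theta: float, coeffs: ConversionCoefficients) -> int:
    """Convert an ability in logits to an integer word count in [0, a]."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    raw = coeffs.a * expit(coeffs.b * (theta - coeffs.c))
    return int(round(min(max(raw, 0.0), float(coeffs.a))))


def fit_conversion(
    pairs: Sequence[tuple[float, float]], a: int = 140_000
) -> ConversionFit:
    """Fit (b, c) of the logistic rank-vs-difficulty relation with *a* fixed.

    *pairs* are (frequency rank, difficulty in logits).  The fit minimizes
    the sum of squared rank residuals with a multistart derivative-based
    nonlinear least-squares (logistic fits are prone to bad local optima).
    Requires at least 3 pairs with at least 2 distinct difficulties.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (rank, difficulty) pairs")
    ranks = np.array([p[0] for p in pairs], dtype=float)
    diffs = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(diffs).size < 2:
        raise ValueError("need at least 2 distinct difficulties")
    if a <= 0:
        raise ValueError("a must be positive")

    def residual(params: np.ndarray) -> np.ndarray:
        b, c = params
        return ranks - a * expit(b * (diffs - c))

    best = None
    for c0 in (-2.0, 0.0, 2.0):
        for b0 in (0.1, 0.5, 1.0):
            res = least_squares(
                residual,
                x0=np.array([b0, c0]),
                bounds=([1e-8, -np.inf], [np.inf, np.inf]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            if best is None or res.cost < best.cost:
                best = res
    assert best is not None
    if not best.success:
        raise ConversionFitError(
            f"logistic fit did not converge; last iterate b={best.x[0]:.6g}, "
            f"c={best.x[1]:.6g}, residual RMSE="
            f"{float(np.sqrt(np.mean(best.fun ** 2))):.6g}"
        )
    b_hat, c_hat = (float(v) for v in best.x)
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    return ConversionFit(
        coefficients=ConversionCoefficients(a=a, b=b_hat, c=c_hat),
        residual_rmse=rmse,
        converged=bool(best.success),
        n_pairs=len(pairs),
    )


def attention_index(counts: AttentionCounts) -> float:
    """Attention index in percent: ``100 (x + y) / (ax + ay)``."""
    total = counts.ax + counts.ay
    if total == 0:
        raise UndefinedIndexError("session presented no control items")
    return 100.0 * (counts.x + counts.y) / total


def is_trustworthy(index: float, threshold: float = DEFAULT_TRUST_THRESHOLD) -> bool:
    """True iff the attention index meets the trust threshold (``>=``)."""
    if not 0.0 <= index <= 100.0:
        raise ValueError("attention index must lie in [0, 100]")
    return index >= threshold
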