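"""Closed-form statistical kernel shared by every pipeline stage.

Correlation estimates and their Student-t p-values, the Fisher
z-transformation and the two-condition z-difference statistic for
differential co-expression, the one-sided hypergeometric
(over-representation) test, and Benjamini-Hochberg FDR adjustment.

The differential-correlation statistic compares a gene pair's Pearson
correlation between two conditions.  With ``z = atanh(r)`` approximately
``N(atanh(rho), 1/(n-3))``, the difference

    dz = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))

is approximately standard normal under the null of equal population
correlation, giving the asymptotic two-sided p-value ``2*Phi(-|dz|)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationEstimate",
    "ContingencyTable2x2",
    "UndefinedCorrelationError",
    "pearson_correlation",
    "correlation_pvalue",
    "fisher_z",
    "diff_correlation_z",
    "diff_correlation_pvalue_asymptotic",
    "fisher_exact_over",
    "bh_adjust",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested on a constant vector."""


@dataclass(frozen=True)
class CorrelationEstimate:
    """A Pearson correlation with its sample size and (optional) p-value.

    Attributes
    ----------
    r : float
        Pearson correlation coefficient, in [-1, 1].
    n : int
        Number of paired observations (>= 4).
    p : float or None
        Two-sided p-value; ``None`` until :func:`correlation_pvalue`
        has been applied.
    """

    r: float
    n: int
    p: float | None = None

    def with_pvalue(self) -> "CorrelationEstimate":
        return CorrelationEstimate(self.r, self.n, correlation_pvalue(self.r, self.n))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Overlap table for a one-sided over-representation test.

    k genes shared by a set of size K and a set of size n drawn from a
    universe of size N.
    """

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"overlap k={self.k} exceeds min(K={self.K}, n={self.n})")
        if self.K > self.N or self.n > self.N:
            raise ValueError(f"set sizes K={self.K}, n={self.n} exceed universe N={self.N}")
        if min(self.k, self.K, self.n, self.N) < 0:
            raise ValueError("negative table entry")


def pearson_correlation(x, y) -> CorrelationEstimate:
    """Pearson correlation of two equal-length vectors.

    The p-value is left unset; apply :func:`correlation_pvalue` (or
    ``.with_pvalue()``) when one is needed.

    Raises
    ------
    UndefinedCorrelationError
        If either vector is constant — the correlation is undefined and
        must never be silently reported as 0.
    ValueError
        On length mismatch or fewer than 4 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation of a constant vector is undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    # guard rounding drift outside [-1, 1]
    r = min(1.0, max(-1.0, r))
    return CorrelationEstimate(r=r, n=n)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the Student-t test.

    Uses ``t = r * sqrt(n-2) / sqrt(1-r^2)`` with ``n-2`` degrees of
    freedom.  ``|r| == 1`` returns exactly 0.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range: {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def fisher_z(r: float) -> float:
    """Fisher z-transformation ``z = atanh(r)``; requires ``|r| < 1``.

    Callers that must map a degenerate ``|r| = 1`` to a finite z clamp
    explicitly (e.g. at ``1 - 1e-12``) before calling.
    """
    if not -1.0 < r < 1.0:
        raise ValueError(f"fisher_z requires |r| < 1, got {r}")
    return float(np.arctanh(r))


def diff_correlation_z(r1: float, n1: int, r2: float, n2: int) -> float:
    """Standardized difference of Fisher-z-transformed correlations.

    Antisymmetric under swapping the two conditions.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("need at least 4 samples per condition")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float((fisher_z(r1) - fisher_z(r2)) / se)


def diff_correlation_pvalue_asymptotic(dz: float) -> float:
    """Two-sided normal p-value ``2*Phi(-|dz|)`` for the z-difference."""
    if not np.isfinite(dz):
        raise ValueError(f"dz must be finite, got {dz}")
    return float(2.0 * sps.norm.sf(abs(dz)))


def fisher_exact_over(table: ContingencyTable2x2) -> float:
    """One-sided (over-representation) p-value ``P(X >= k)``.

    X is hypergeometric: the overlap of a fixed set of size K with a
    random draw of size n from a universe of N.
    """
    # sf(k-1) == P(X >= k)
    return float(min(1.0, sps.hypergeom.sf(table.k - 1, table.N, table.K, table.n)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Returns q in the input order; monotone enforcement guarantees that
    sorting p ascending yields non-decreasing q and q >= p elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
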