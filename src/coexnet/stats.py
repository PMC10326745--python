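"""Shared statistical primitives.

Small, heavily-tested building blocks used by every pipeline stage:
Pearson correlation with an exact t-based p-value, the Fisher
Z-transformation test for a difference between two independent
correlations, multiple-testing adjustment (Benjamini-Hochberg and Holm),
binomial upper tails, and Fisher's exact test for 2x2 enrichment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationStat",
    "PValueVector",
    "ZeroVarianceError",
    "pearson_with_p",
    "fisher_z_diff_test",
    "adjust_pvalues",
    "bh_adjust",
    "binomial_tail",
    "fisher_exact_enrichment",
]


class ZeroVarianceError(ValueError):
    """A correlation was requested on a constant vector."""


@dataclass(frozen=True)
class CorrelationStat:
    """Pearson correlation of one variable pair.

    Attributes
    ----------
    r : correlation coefficient in [-1, 1].
    n : number of paired observations (>= 4 so that Fisher's Z has a
        positive variance 1/(n-3)).
    p : two-sided p-value for H0: r = 0, from the exact t transform.
    """

    r: float
    n: int
    p: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")
        if self.n < 4:
            raise ValueError("need at least 4 paired observations")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value out of range: {self.p}")


@dataclass
class PValueVector:
    """Raw p-values with their multiplicity-adjusted counterparts."""

    values: np.ndarray
    adjusted: np.ndarray
    method: str = field(default="BH")


def pearson_with_p(x, y) -> CorrelationStat:
    """Sample Pearson correlation with a two-sided p-value.

    The p-value comes from t = r * sqrt((n-2) / (1-r^2)) referred to a
    t-distribution with n-2 degrees of freedom, which is exact when the
    pair is bivariate normal.

    Raises
    ------
    ZeroVarianceError
        If either vector is constant; the caller must drop the pair.
    ValueError
        On length mismatch or fewer than 4 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("constant vector has undefined correlation")
    r, p = sps.pearsonr(x, y)
    return CorrelationStat(r=float(r), n=int(n), p=float(p))


def correlation_pvalue(r, n) -> np.ndarray:
    """Vectorized two-sided p-value of H0 r=0 via the t transform (n-2 df)."""
    r = np.asarray(r, dtype=float)
    rr = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt(df / (1.0 - rr * rr))
    t = np.where(np.abs(rr) >= 1.0, np.inf * np.sign(rr), t)
    return 2.0 * sps.t.sf(np.abs(t), df)


def fisher_z_diff_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Test equality of two independent Pearson correlations.

    Fisher's variance-stabilizing transform atanh(r) is approximately
    N(atanh(rho), 1/(n-3)); the difference statistic

        z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))

    is referred to the standard normal, two-sided.

    Returns
    -------
    (z, p)
    """
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("Fisher Z requires group sizes > 3")
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| = 1 transforms to infinity; drop the pair")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def fisher_z_diff_vectorized(r1, n1: int, r2, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Array form of :func:`fisher_z_diff_test`; |r| is clipped just inside 1."""
    eps = 1e-15
    a1 = np.arctanh(np.clip(r1, -1 + eps, 1 - eps))
    a2 = np.arctanh(np.clip(r2, -1 + eps, 1 - eps))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (a1 - a2) / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return z, p


def adjust_pvalues(values, method: str = "BH") -> PValueVector:
    """Adjust a p-value vector for multiplicity.

    method="BH" applies the Benjamini-Hochberg step-up (FDR control);
    method="Holm" applies the Holm step-down (FWER control). Adjusted
    values are capped at 1 and mapped back to the input order.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-d p-value vector")
    if values.size == 0:
        return PValueVector(values=values, adjusted=values.copy(), method=method)
    if np.any((values < 0) | (values > 1)) or np.any(np.isnan(values)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "Holm": "holm"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method: {method!r}")
    adjusted = multipletests(values, method=key)[1]
    return PValueVector(values=values, adjusted=adjusted, method=method)


def bh_adjust(values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (convenience wrapper)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    return multipletests(values, method="fdr_bh")[1]


def holm_adjust(values) -> np.ndarray:
    """Holm step-down adjusted p-values (convenience wrapper)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    return multipletests(values, method="holm")[1]


def binomial_tail(k: int, n: int, rate: float) -> float:
    """Upper tail P(X >= k) for X ~ Binomial(n, rate)."""
    if not 0 <= k <= n:
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be a probability, got {rate}")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, rate))


def fisher_exact_enrichment(
    a: int, b: int, c: int, d: int, alternative: str = "greater"
) -> float:
    """Fisher's exact test p-value on the 2x2 table [[a, b], [c, d]].

    With alternative="greater" this is the hypergeometric upper tail
    P(overlap >= a) given the table margins -- the standard one-sided
    enrichment test.
    """
    for cell in (a, b, c, d):
        if cell < 0:
            raise ValueError("contingency cells must be non-negative")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unsupported alternative: {alternative!r}")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(p)


def hypergeom_sf_vectorized(a, row1, col1, total) -> np.ndarray:
    """Vectorized one-sided (greater) Fisher p: P(X >= a) with X hypergeometric.

    ``row1`` is the first row margin (a+b), ``col1`` the first column margin
    (a+c) and ``total`` the table total.
    """
    return sps.hypergeom.sf(np.asarray(a) - 1, total, col1, row1)
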