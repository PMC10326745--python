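"""Moderated two-group differential expression.

Per protein, an ordinary two-group linear model (intercept + group
indicator, i.e. a difference of means) yields the effect beta = mean
difference and a residual variance s_g^2 on d_g = n - 2 degrees of
freedom. The residual variances are then shrunk toward a common prior by
empirical Bayes: assuming s_g^2 | sigma_g^2 ~ scaled chi-square and
1/sigma_g^2 ~ scaled chi-square with hyperparameters (d0, s0^2), the
hyperparameters are estimated in closed form by matching the mean and
variance of log s_g^2 (digamma/trigamma moment equations), the posterior
variance is

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g),

and the moderated statistic t~ = beta / (s~_g * sqrt(1/n1 + 1/n2)) is
referred to a t-distribution on d0 + d_g degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy import stats as sps

from .data import AbundanceTable
from .stats import bh_adjust

__all__ = ["EBPrior", "fit_moderated_t", "call_de"]


@dataclass(frozen=True)
class EBPrior:
    """Empirical-Bayes hyperparameters: prior df d0 (may be inf) and prior
    variance s0_sq."""

    d0: float
    s0_sq: float


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the asymptotic start y = 0.5 + 1/x and the monotone update on the
    reciprocal scale, which converges from any positive x.
    """
    if x <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> EBPrior:
    """Moment-matching estimate of (d0, s0^2) from residual variances.

    Works on e_g = log s_g^2 - digamma(d/2) + log(d/2), whose mean is
    log s0^2 + digamma(d0/2) - log(d0/2) and whose excess variance over
    trigamma(d/2) is trigamma(d0/2). A non-positive excess variance means
    no evidence of variance heterogeneity: d0 is set infinite and
    s0^2 = exp(mean e).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all residual variances are zero; prior is degenerate")
    z = np.log(s2[positive])
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    if n < 2:
        return EBPrior(d0=math.inf, s0_sq=math.exp(e_mean))
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1)) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = math.exp(e_mean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return EBPrior(d0=d0, s0_sq=s0_sq)


def fit_moderated_t(
    table: AbundanceTable,
    case: str = "case",
    control: str = "control",
    d0: float | None = None,
    s0_sq: float | None = None,
) -> tuple[pd.DataFrame, EBPrior]:
    """Moderated t-test of every protein between two sample groups.

    Parameters
    ----------
    d0, s0_sq : optional prior overrides. ``d0=0`` reproduces the ordinary
        pooled-variance two-sample t-test; a very large ``d0`` shrinks all
        variances to ``s0_sq``.

    Returns
    -------
    results : DataFrame indexed by protein with columns log2fc, s2, t_mod,
        df_total, p, fdr, status (status filled by :func:`call_de`).
    prior : the EBPrior actually used.
    """
    x1 = table.group_matrix(case).to_numpy(dtype=float)
    x2 = table.group_matrix(control).to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.isnan(x1).any() or np.isnan(x2).any():
        raise ValueError("missing values present; run preprocessing first")

    beta = x1.mean(axis=1) - x2.mean(axis=1)
    rss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = rss / df_resid

    if d0 is None:
        prior = estimate_prior(s2, df_resid)
    else:
        if s0_sq is None:
            s0_sq = float(estimate_prior(s2, df_resid).s0_sq) if d0 > 0 else 1.0
        prior = EBPrior(d0=float(d0), s0_sq=float(s0_sq))

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
    elif prior.d0 == 0:
        s2_post = s2
    else:
        s2_post = (prior.d0 * prior.s0_sq + df_resid * s2) / (prior.d0 + df_resid)

    stderr = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(stderr > 0, beta / stderr, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    df_total = prior.d0 + df_resid
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * sps.t.sf(np.abs(t_mod), df_total)
    results = pd.DataFrame(
        {
            "log2fc": beta,
            "s2": s2,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "fdr": bh_adjust(p),
            "status": "ns",
        },
        index=table.values.index,
    )
    return results, prior


def call_de(results: pd.DataFrame, fdr_cut: float = 0.1, fc_cut: float = 1.5) -> pd.DataFrame:
    """Assign up/down/ns status: significant means fdr < fdr_cut together
    with a case/control abundance ratio above fc_cut, i.e.
    |log2fc| > log2(fc_cut)."""
    out = results.copy()
    lfc_cut = math.log2(fc_cut)
    sig = out["fdr"] < fdr_cut
    out["status"] = "ns"
    out.loc[sig & (out["log2fc"] > lfc_cut), "status"] = "up"
    out.loc[sig & (out["log2fc"] < -lfc_cut), "status"] = "down"
    return out
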