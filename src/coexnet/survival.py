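"""Kaplan-Meier survival curves and the two-group log-rank test.

Thin, validated wrappers around lifelines, taking the pipeline's
survival table (sample, time, event, group)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["km_curve", "logrank_test"]


def _check(table: pd.DataFrame) -> None:
    if (table["time"] < 0).any():
        raise ValueError("negative survival times")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event must be binary")


def km_curve(table: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Product-limit survival estimate S(t) for one group.

    Returns a step function as a DataFrame (time, survival), starting at
    S(0) = 1 unless there is an event at time 0. Right-censored subjects
    leave the risk set without an event.
    """
    _check(table)
    sub = table if group is None else table[table["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"no subjects in group {group!r}")
    km = KaplanMeierFitter()
    km.fit(sub["time"], event_observed=sub["event"])
    sf = km.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(table: pd.DataFrame, groups: tuple[str, str] | None = None) -> tuple[float, float]:
    """Standard (unweighted) log-rank test between two groups.

    At each distinct event time the observed events in group 1 are
    compared with their hypergeometric expectation given the risk sets;
    the statistic (O-E)^2/V is referred to chi-square with 1 df.

    Returns (chi2, p).
    """
    _check(table)
    if groups is None:
        uniq = sorted(table["group"].unique())
        if len(uniq) != 2:
            raise ValueError(f"need exactly two groups, found {uniq}")
        groups = (uniq[0], uniq[1])
    g1 = table[table["group"] == groups[0]]
    g2 = table[table["group"] == groups[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be nonempty")
    if g1["event"].sum() + g2["event"].sum() == 0:
        raise ValueError("log-rank test undefined without any event")
    res = _ll_logrank(
        g1["time"], g2["time"], event_observed_A=g1["event"], event_observed_B=g2["event"]
    )
    return float(res.test_statistic), float(res.p_value)
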