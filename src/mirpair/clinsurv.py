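"""Survival and clinical-covariate associations.

Patients are split into expression tertiles (low / medium / high); the
Kaplan-Meier curves of the highest and lowest thirds are compared with an
unweighted log-rank test, the medium group being excluded to guarantee an
expression difference between the compared groups. Tumour-stage association
uses Spearman rank correlation, and the xenograft volume follows the
ellipsoid caliper formula V = length * width^2 / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

logger = logging.getLogger(__name__)

TERTILE_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time, event indicator, expression value and
    the tertile group assigned by :func:`tertile_split`."""

    time: float
    event: bool
    expression: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("negative follow-up time")
        if self.group and self.group not in TERTILE_LABELS:
            raise ValueError(f"unknown group {self.group!r}")


def tertile_split(expression) -> np.ndarray:
    """Assign low/medium/high labels by expression rank.

    Groups are as equal as possible; when n is not divisible by 3 the extra
    members go to the lower groups first (n=10 -> sizes 4/3/3). Ties are
    broken by stable input order.
    """
    x = np.asarray(expression, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least three patients for a tertile split")
    if np.all(x == x[0]):
        raise ValueError("all expression values identical; no ordering")
    order = np.argsort(x, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for size, lab in zip(sizes, TERTILE_LABELS):
        labels[order[start : start + size]] = lab
        start += size
    return labels


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns the step function as a DataFrame with columns ``time`` and
    ``survival``; right-censored records lower the risk set without an
    event. S(0) = 1 and S is non-increasing.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("no records")
    if (t < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_test(times_a, events_a, times_b, events_b) -> float:
    """Two-sided p of the unweighted log-rank test between two groups."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.p_value)


def survival_association(records: pd.DataFrame) -> dict:
    """High-vs-low tertile Kaplan-Meier comparison of a survival table.

    ``records`` needs columns time, event, expression; groups are assigned
    by :func:`tertile_split` and the medium tertile is excluded. Returns the
    log-rank p and the two KM step functions.
    """
    for col in ("time", "event", "expression"):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    group = tertile_split(records["expression"].to_numpy())
    high = records.loc[group == "high"]
    low = records.loc[group == "low"]
    p = logrank_test(high["time"], high["event"], low["time"], low["event"])
    return {
        "p_value": p,
        "n_high": len(high),
        "n_low": len(low),
        "km_high": km_estimate(high["time"], high["event"]),
        "km_low": km_estimate(low["time"], low["event"]),
    }


def spearman_stage_association(expression, pt_stage) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) of expression with
    ordinal tumour stage; returns (cc, two-sided p)."""
    x = np.asarray(expression, dtype=float)
    s = np.asarray(pt_stage, dtype=float)
    if x.size < 4:
        raise ValueError("need at least four patients")
    if np.all(x == x[0]) or np.all(s == s[0]):
        raise ValueError("constant input; correlation undefined")
    res = stats.spearmanr(x, s)
    return float(res.statistic), float(res.pvalue)


def tumour_volume(length: float, width: float) -> float:
    """Xenograft tumour volume V = length * width^2 / 2 (mm^3).

    If width exceeds length the two are swapped with a warning: by caliper
    convention length is the larger dimension.
    """
    if length < 0 or width < 0:
        raise ValueError("negative caliper measurement")
    if width > length:
        logger.warning("width %.3g exceeds length %.3g; swapping", width, length)
        length, width = width, length
    return length * width**2 / 2.0
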