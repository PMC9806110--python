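"""Kaplan–Meier estimation, g-sample log-rank testing and panel-score
dichotomization, implemented from first principles.

The product-limit estimator uses the standard tie convention: subjects
censored at an event time remain at risk for that event.  The log-rank
statistic accumulates, at every event time, the observed minus expected
events per group under the hypergeometric model, and forms a chi-square from
the variance–covariance of the O−E vector (dropping one group; df = g−1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import score_panels
from .exceptions import DegenerateCutError
from .markers import MarkerPanel

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank",
    "dichotomize_and_compare",
]


def _extract(table, time=None, event=None, group=None):
    if isinstance(table, pd.DataFrame):
        t = np.asarray(table["time"], dtype=float)
        e = np.asarray(table["event"], dtype=int)
        g = np.asarray(table["group"]) if "group" in table.columns else None
        return t, e, g
    return (
        np.asarray(table, dtype=float),
        np.asarray(event, dtype=int),
        None if group is None else np.asarray(group),
    )


@dataclass
class KMCurve:
    """Product-limit survival curve over the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    n_subjects: int
    label: str = ""

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous, S(0−) = 1)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.event_times.size == 0:
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(self.event_times, t, side="right") - 1
            out = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return out if out.size > 1 else out[0]

    def median_survival(self) -> float:
        """Smallest event time with S(t) <= 0.5 (inf if never reached)."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.event_times[below[0]]) if below.size else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.concatenate([[0.0], self.event_times])
        ys = np.concatenate([[1.0], self.survival])
        ax.step(xs, ys, where="post", label=self.label or None, **kwargs)
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        return ax


def km_estimate(table, event=None, label: str = "") -> KMCurve:
    """Kaplan–Meier estimate from a (time, event) table.

    Accepts a DataFrame with ``time``/``event`` columns or two arrays.
    S(t) = Π over event times u <= t of (1 − d_u / n_u), with censored
    subjects at an event time still counted at risk.
    """
    time, ev, _ = _extract(table, event=event)
    if time.size == 0:
        raise ValueError("empty survival table")
    if (time < 0).any():
        raise ValueError("negative follow-up time")
    if not np.isin(ev, (0, 1)).all():
        raise ValueError("event indicator must be 0 or 1")
    etimes = np.unique(time[ev == 1])
    at_risk = np.array([(time >= t).sum() for t in etimes], dtype=int)
    d = np.array([((time == t) & (ev == 1)).sum() for t in etimes], dtype=int)
    surv = np.cumprod(1.0 - d / at_risk) if etimes.size else np.array([])
    return KMCurve(
        event_times=etimes,
        at_risk=at_risk,
        events=d,
        survival=surv,
        n_subjects=int(time.size),
        label=label,
    )


@dataclass
class LogRankResult:
    """g-sample log-rank test output."""

    chi_square: float
    df: int
    p_value: float
    groups: list
    observed: np.ndarray
    expected: np.ndarray
    covariance: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"Log-rank test: chi2 = {self.chi_square:.4f}, df = {self.df}, "
            f"p = {self.p_value:.4g}",
            "  group    observed  expected",
        ]
        for g, o, e in zip(self.groups, self.observed, self.expected):
            lines.append(f"  {str(g):<8} {o:<9.0f} {e:.2f}")
        return "\n".join(lines)


def logrank_test(table, event=None, group=None) -> LogRankResult:
    """g-sample log-rank test of equal survival across groups.

    Accepts a DataFrame with ``time``/``event``/``group`` columns or three
    arrays.  At each event time the per-group expected events and the
    hypergeometric variance–covariance are accumulated; the chi-square uses
    the pseudo-inverse of the covariance of the first g−1 components.
    """
    time, ev, grp = _extract(table, event=event, group=group)
    if grp is None:
        raise ValueError("group labels are required")
    if (time < 0).any():
        raise ValueError("negative follow-up time")
    groups = sorted(pd.unique(grp).tolist())
    if len(groups) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    gidx = {g: i for i, g in enumerate(groups)}
    gi = np.array([gidx[g] for g in grp])
    ng = len(groups)

    O = np.zeros(ng)
    E = np.zeros(ng)
    V = np.zeros((ng, ng))
    for t in np.unique(time[ev == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n_i = np.bincount(gi[at_risk], minlength=ng).astype(float)
        dead = (time == t) & (ev == 1)
        d = int(dead.sum())
        d_i = np.bincount(gi[dead], minlength=ng).astype(float)
        O += d_i
        E += d * n_i / n
        if n > 1:
            V += d * (n - d) / (n - 1) * (np.diag(n_i / n) - np.outer(n_i, n_i) / n**2)

    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi = float(diff @ np.linalg.pinv(Vsub) @ diff) if diff.size else 0.0
    chi = max(chi, 0.0)
    df = ng - 1
    return LogRankResult(
        chi_square=chi,
        df=df,
        p_value=float(stats.chi2.sf(chi, df)),
        groups=groups,
        observed=O,
        expected=E,
        covariance=V,
    )


def pairwise_logrank(table, event=None, group=None, adjust: str = "fdr_bh") -> pd.DataFrame:
    """All pairwise two-group log-rank tests with multiplicity adjustment."""
    from itertools import combinations

    from .markers import bh_adjust

    time, ev, grp = _extract(table, event=event, group=group)
    groups = sorted(pd.unique(grp).tolist())
    rows = []
    for a, b in combinations(groups, 2):
        mask = np.isin(grp, [a, b])
        res = logrank_test(time[mask], ev[mask], grp[mask])
        rows.append({"group_a": a, "group_b": b, "chi_square": res.chi_square, "p_value": res.p_value})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy(), method=adjust)
    return out


def dichotomize_and_compare(
    bulk_expr: pd.DataFrame,
    panel: MarkerPanel | Mapping[str, Sequence[str]],
    group: str,
    survival: pd.DataFrame,
    cut: str = "median",
    normalization: str = "zscore_cohort",
) -> tuple[pd.Series, LogRankResult]:
    """Split samples at high/low panel-mean score of one group; log-rank compare.

    ``cut='median'``: high = score strictly above the median (balanced for an
    even number of distinct scores).  ``cut='tertile'``: upper vs lower
    tertile with the middle third dropped.  Constant scores (or any empty
    side) raise :class:`DegenerateCutError`.
    """
    scores = score_panels(bulk_expr, panel, mode="panel_mean", normalization=normalization)
    if group not in scores.columns:
        raise KeyError(f"group {group!r} not in panel")
    s = scores[group]
    samples = survival["sample_id"].astype(str)
    missing = [x for x in samples if x not in s.index]
    if missing:
        raise KeyError(f"samples without expression: {missing[:5]}")
    s = s.loc[samples].to_numpy()
    if np.allclose(s, s[0]):
        raise DegenerateCutError("panel scores are constant; no cut is possible")
    if cut == "median":
        thr = np.median(s)
        labels = np.where(s > thr, "high", "low")
    elif cut == "tertile":
        lo_t, hi_t = np.quantile(s, [1 / 3, 2 / 3])
        labels = np.where(s >= hi_t, "high", np.where(s <= lo_t, "low", "mid"))
    else:
        raise ValueError(f"unknown cut {cut!r}")
    keep = labels != "mid"
    kept_labels = labels[keep]
    if (kept_labels == "high").sum() == 0 or (kept_labels == "low").sum() == 0:
        raise DegenerateCutError(f"{cut} cut produced an empty group")
    res = logrank_test(
        np.asarray(survival["time"], dtype=float)[keep],
        np.asarray(survival["event"], dtype=int)[keep],
        kept_labels,
    )
    return pd.Series(labels, index=samples, name=f"{group}_panel_level"), res
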