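"""Kaplan-Meier estimation and the two-group log-rank test.

Samples are split into ALTERED (GAIN or LOSS in at least one gene of a
list) and UNALTERED groups; overall survival is compared with the
product-limit estimator and the standard log-rank chi-square on 1
degree of freedom.  Ties follow the usual convention: all deaths at a
time are processed before censorings at the same time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cnv import GAIN, LOSS, CnvCallMatrix

ALTERED = "ALTERED"
UNALTERED = "UNALTERED"


@dataclass
class KmCurve:
    """Product-limit survival curve over the distinct event times."""

    times: np.ndarray          # distinct death times, increasing
    survival: np.ndarray       # S(t) just after each death time
    at_risk: np.ndarray        # numbers at risk just before each death time
    n_events: np.ndarray       # deaths at each time

    @property
    def median(self) -> float | None:
        """Smallest time with S <= 0.5, or None if S never reaches it."""
        below = self.survival <= 0.5
        if not below.any():
            return None
        return float(self.times[int(np.argmax(below))])

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    n_altered: int
    n_unaltered: int
    events_altered: int
    events_unaltered: int
    median_altered: float | None
    median_unaltered: float | None


def assign_groups(
    cnv: CnvCallMatrix, genes, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Label clinical samples ALTERED/UNALTERED from the CNV calls.

    ``clinical`` needs columns ``sample``, ``os_months``, ``os_event``.
    Only samples present in both tables are kept; no overlap is an
    error.  A sample is ALTERED iff it carries GAIN or LOSS in >= 1
    listed gene.
    """
    genes = [g for g in dict.fromkeys(genes) if g in cnv.genes]
    clin = clinical.loc[:, ["sample", "os_months", "os_event"]].copy()
    clin = clin[clin["sample"].isin(cnv.samples)]
    if clin.empty:
        raise ValueError("no overlap between clinical samples and CNV samples")
    sub = cnv.calls.loc[genes, list(clin["sample"])]
    altered = sub.isin([GAIN, LOSS]).any(axis=0)
    clin["group"] = np.where(
        altered.loc[clin["sample"]].to_numpy(), ALTERED, UNALTERED
    )
    if (clin["os_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    clin["os_event"] = clin["os_event"].astype(bool)
    return clin.reset_index(drop=True)


def km_fit(times, events) -> KmCurve:
    """Product-limit estimator for one group.

    ``events`` is True where death was observed; censored times reduce
    the risk set only.  With no censoring the curve equals the
    empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one record")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]

    death_times = np.unique(times[events])
    n = times.size
    at_risk = np.empty(death_times.size, dtype=int)
    n_events = np.empty(death_times.size, dtype=int)
    surv = np.empty(death_times.size, dtype=float)
    s = 1.0
    for i, t in enumerate(death_times):
        r = int(np.count_nonzero(times >= t))
        d = int(np.count_nonzero((times == t) & events))
        s *= 1.0 - d / r
        at_risk[i], n_events[i], surv[i] = r, d, s
    return KmCurve(times=death_times, survival=surv, at_risk=at_risk,
                   n_events=n_events)


def log_rank(records: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test on a table with time/event/group columns.

    The statistic is (O - E)^2 / V accumulated over all distinct death
    times, with the hypergeometric variance of the group-1 death count
    at each time; p from chi-square with 1 df.  Both groups must be
    non-empty.
    """
    time = records["os_months"].to_numpy(dtype=float)
    event = records["os_event"].to_numpy(dtype=bool)
    group = records["group"].to_numpy()
    g1 = group == ALTERED
    if not g1.any() or g1.all():
        raise ValueError("log-rank needs non-empty ALTERED and UNALTERED groups")

    death_times = np.unique(time[event])
    o_minus_e = 0.0
    var = 0.0
    for t in death_times:
        at_risk = time >= t
        n_r = int(at_risk.sum())
        n1_r = int((at_risk & g1).sum())
        d = int((event & (time == t)).sum())
        d1 = int((event & (time == t) & g1).sum())
        if n_r < 2:
            continue
        e1 = d * n1_r / n_r
        v1 = d * (n1_r / n_r) * (1 - n1_r / n_r) * (n_r - d) / (n_r - 1)
        o_minus_e += d1 - e1
        var += v1
    statistic = (o_minus_e**2 / var) if var > 0 else 0.0
    p_value = float(stats.chi2.sf(statistic, df=1)) if var > 0 else 1.0

    km1 = km_fit(time[g1], event[g1])
    km0 = km_fit(time[~g1], event[~g1])
    return LogRankResult(
        statistic=float(statistic),
        p_value=p_value,
        n_altered=int(g1.sum()),
        n_unaltered=int((~g1).sum()),
        events_altered=int(event[g1].sum()),
        events_unaltered=int(event[~g1].sum()),
        median_altered=km1.median,
        median_unaltered=km0.median,
    )


def km_table(curve: KmCurve) -> pd.DataFrame:
    """KM curve as a tidy table (time, at-risk, deaths, survival)."""
    return pd.DataFrame(
        {
            "time": curve.times,
            "at_risk": curve.at_risk,
            "n_events": curve.n_events,
            "survival": curve.survival,
        }
    )
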