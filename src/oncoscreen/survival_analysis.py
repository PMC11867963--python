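"""Kaplan-Meier estimation, Mantel-Cox log-rank test, and best-cutoff splits.

The screening pipeline dichotomizes each gene's expression at the "better
cutoff": every distinct expression value inside a percentile window is
tried as a threshold and the split minimizing the log-rank p-value is
reported. The minimum p over the scan is reported unadjusted — as is usual
in optimal-cutpoint screening — with a logged warning carrying the number
of thresholds scanned, since the scan inflates the nominal type-I error.

Censored subjects remain at risk at their censoring time when it ties an
event time (the conventional product-limit bookkeeping).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NoValidCutoffError, UndefinedStatisticError
from .types import CohortAnnotation, ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "CutoffResult",
    "km_curve",
    "logrank_test",
    "best_cutoff_split",
    "survival_flag",
    "best_cutoff_table",
]


@dataclass(frozen=True)
class SurvivalCurve:
    event_times: np.ndarray  # distinct event times, ascending
    survival_prob: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk at each event time
    n_events: np.ndarray  # deaths at each event time


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    observed_events: tuple[float, float]
    expected_events: tuple[float, float]
    direction: int  # +1 if group2 has observed > expected deaths, -1 if group1, 0 tied


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    group_sizes: tuple[int, int]  # (low, high)
    logrank: LogRankResult
    n_thresholds_scanned: int
    thresholds: np.ndarray
    p_values: np.ndarray


def _check_surv(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise DataError("empty survival input")
    if np.any(times < 0):
        raise DataError("negative survival times")
    if not np.all(np.isin(events, (0.0, 1.0))):
        raise DataError("events must be 0 or 1")
    return times, events


def km_curve(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times, events = _check_surv(np.asarray(times), np.asarray(events))
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    event_times = np.unique(t[e == 1])
    n = t.size
    at_risk = np.array([(t >= et).sum() for et in event_times], dtype=float)
    d = np.array([((t == et) & (e == 1)).sum() for et in event_times], dtype=float)
    surv = np.cumprod(1.0 - d / at_risk) if event_times.size else np.array([])
    return SurvivalCurve(
        event_times=event_times, survival_prob=surv, at_risk=at_risk, n_events=d
    )


def logrank_test(
    group1: tuple[Sequence[float], Sequence[int]],
    group2: tuple[Sequence[float], Sequence[int]],
) -> LogRankResult:
    """Two-group Mantel-Cox log-rank test (1 df chi-square).

    ``direction`` reports which group died more than expected: +1 for
    group2, -1 for group1, 0 when observed equals expected.
    """
    t1, e1 = _check_surv(*map(np.asarray, group1))
    t2, e2 = _check_surv(*map(np.asarray, group2))
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.zeros(t1.size), np.ones(t2.size)])
    if e.sum() == 0:
        raise UndefinedStatisticError("log-rank test undefined with zero events")
    event_times = np.unique(t[e == 1])
    o1 = e1_exp = var = 0.0
    o2 = e2_exp = 0.0
    for et in event_times:
        at_risk = t >= et
        n_tot = at_risk.sum()
        n1 = (at_risk & (g == 0)).sum()
        n2 = n_tot - n1
        dying = (t == et) & (e == 1)
        d_tot = dying.sum()
        d1 = (dying & (g == 0)).sum()
        o1 += d1
        o2 += d_tot - d1
        e1_exp += d_tot * n1 / n_tot
        e2_exp += d_tot * n2 / n_tot
        if n_tot > 1:
            var += d_tot * (n1 / n_tot) * (n2 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    if var == 0:
        chi, p = 0.0, 1.0
    else:
        chi = (o1 - e1_exp) ** 2 / var
        p = float(stats.chi2.sf(chi, df=1))
    if o2 > e2_exp:
        direction = 1
    elif o1 > e1_exp:
        direction = -1
    else:
        direction = 0
    return LogRankResult(
        chi_square=float(chi),
        p_value=p,
        observed_events=(float(o1), float(o2)),
        expected_events=(float(e1_exp), float(e2_exp)),
        direction=direction,
    )


class _LogrankScan:
    """Vectorized log-rank over many high/low group assignments that share
    one set of survival records (used by the per-gene cutoff scan)."""

    def __init__(self, times: np.ndarray, events: np.ndarray):
        self.times, self.events = _check_surv(times, events)
        if self.events.sum() == 0:
            raise UndefinedStatisticError("cutoff scan undefined with zero events")
        self.event_times = np.unique(self.times[self.events == 1])
        # at-risk and death indicator matrices, samples x event-times
        self._at_risk = self.times[:, None] >= self.event_times[None, :]
        self._death = (self.times[:, None] == self.event_times[None, :]) & (
            self.events[:, None] == 1
        )
        self.n_tot = self._at_risk.sum(axis=0).astype(float)
        self.d_tot = self._death.sum(axis=0).astype(float)

    def chi_p(self, high: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """chi-square and p for each column of the boolean membership matrix
        ``high`` (samples x thresholds; True = high group)."""
        high = np.asarray(high, dtype=float)
        n_hi = self._at_risk.T @ high  # event-times x thresholds
        d_hi = self._death.T @ high
        nt = self.n_tot[:, None]
        dt = self.d_tot[:, None]
        e_hi = dt * n_hi / nt
        with np.errstate(invalid="ignore", divide="ignore"):
            var_t = dt * (n_hi / nt) * ((nt - n_hi) / nt) * (nt - dt) / (nt - 1)
        var_t = np.where(nt > 1, var_t, 0.0)
        o_minus_e = (d_hi - e_hi).sum(axis=0)
        var = var_t.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            chi = np.where(var > 0, o_minus_e**2 / var, 0.0)
        p = np.where(var > 0, stats.chi2.sf(chi, df=1), 1.0)
        return chi, p

    def observed_minus_expected_high(self, high: np.ndarray) -> np.ndarray:
        high = np.asarray(high, dtype=float)
        d_hi = self._death.T @ high
        e_hi = self.d_tot[:, None] * (self._at_risk.T @ high) / self.n_tot[:, None]
        return (d_hi - e_hi).sum(axis=0)


def _candidate_thresholds(
    values: np.ndarray, pct_range: tuple[float, float], min_group: int
) -> np.ndarray:
    lo, hi = np.percentile(values, pct_range)
    cands = np.unique(values)
    cands = cands[(cands >= lo) & (cands <= hi)]
    sizes_low = np.searchsorted(np.sort(values), cands, side="right")
    keep = (sizes_low >= min_group) & (values.size - sizes_low >= min_group)
    return cands[keep]


def best_cutoff_split(
    values: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    pct_range: tuple[float, float] = (10.0, 90.0),
    min_group: int = 10,
) -> CutoffResult:
    """Scan distinct values in the percentile window as thresholds
    (low: value <= t, high: value > t) and return the split minimizing the
    log-rank p-value.

    Ties in p are broken toward the more balanced split, then toward the
    smaller threshold. The reported minimum p is unadjusted for the scan.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if values.size != times.size or values.size != events.size:
        raise DataError("values/times/events length mismatch")
    if values.size < 2 * min_group:
        raise NoValidCutoffError(
            f"need at least {2 * min_group} samples with survival data, got {values.size}"
        )
    cands = _candidate_thresholds(values, pct_range, min_group)
    if cands.size == 0:
        raise NoValidCutoffError("no threshold satisfies the minimum group size")
    scan = _LogrankScan(times, events)
    high = values[:, None] > cands[None, :]
    _, p = scan.chi_p(high)
    best_p = p.min()
    tied = np.flatnonzero(p == best_p)
    n_high = high[:, tied].sum(axis=0)
    imbalance = np.abs(values.size - 2 * n_high)
    pick = tied[np.lexsort((cands[tied], imbalance))[0]]
    threshold = float(cands[pick])
    is_high = values > threshold
    lr = logrank_test(
        (times[~is_high], events[~is_high]), (times[is_high], events[is_high])
    )
    log.warning(
        "best-cutoff scan: minimum log-rank p=%.3g over %d thresholds is "
        "unadjusted for multiple testing",
        lr.p_value,
        cands.size,
    )
    return CutoffResult(
        threshold=threshold,
        group_sizes=(int((~is_high).sum()), int(is_high.sum())),
        logrank=lr,
        n_thresholds_scanned=int(cands.size),
        thresholds=cands,
        p_values=p,
    )


def survival_flag(cutoff: CutoffResult, p_cut: float = 0.05) -> str:
    """Classify a cutoff split: 'poor_survival' when the high-expression
    group dies more than expected at p < p_cut, 'good_survival' for the
    opposite direction, else 'none'."""
    lr = cutoff.logrank
    if lr.p_value >= p_cut or lr.direction == 0:
        return "none"
    return "poor_survival" if lr.direction > 0 else "good_survival"


def best_cutoff_table(
    expr: ExpressionMatrix,
    annotation: CohortAnnotation,
    sample_ids: Sequence[str] | None = None,
    pct_range: tuple[float, float] = (10.0, 90.0),
    min_group: int = 10,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-gene best-cutoff survival screen.

    Restricted to samples with survival data (samples lacking time or event
    are excluded). Returns one row per gene with the selected threshold,
    minimum log-rank p, direction, and flag; genes with no valid cutoff get
    flag 'none' and NaN statistics.
    """
    if sample_ids is None:
        sample_ids = annotation.tumors
    surv = annotation.survival_subset(sample_ids)
    if surv.shape[0] == 0:
        raise DataError("no samples with survival data")
    sub = expr.subset_samples(list(surv.index))
    times = surv["survival_time"].to_numpy(dtype=float)
    events = surv["survival_event"].to_numpy(dtype=float)
    scan = _LogrankScan(times, events)
    rows = []
    for gene, vals in zip(sub.feature_ids, sub.values):
        cands = _candidate_thresholds(vals, pct_range, min_group)
        if cands.size == 0:
            rows.append((gene, np.nan, np.nan, np.nan, 0, 0, "none"))
            continue
        high = vals[:, None] > cands[None, :]
        chi, p = scan.chi_p(high)
        best_p = p.min()
        tied = np.flatnonzero(p == best_p)
        n_high = high[:, tied].sum(axis=0)
        imbalance = np.abs(vals.size - 2 * n_high)
        pick = tied[np.lexsort((cands[tied], imbalance))[0]]
        ome = scan.observed_minus_expected_high(high[:, [pick]])[0]
        direction = 1 if ome > 0 else (-1 if ome < 0 else 0)
        flag = "none"
        if best_p < p_cut and direction != 0:
            flag = "poor_survival" if direction > 0 else "good_survival"
        rows.append(
            (gene, float(cands[pick]), float(chi[pick]), float(best_p), int(cands.size), direction, flag)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "threshold",
            "chi_square",
            "p_value",
            "n_thresholds",
            "direction",
            "flag",
        ],
    ).set_index("gene")
    log.warning(
        "best-cutoff screen: per-gene minimum p over up to %d thresholds is "
        "unadjusted for the scan",
        int(out["n_thresholds"].max()) if len(out) else 0,
    )
    return out
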