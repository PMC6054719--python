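"""Clinical-validation statistics.

qMSP normalization against control DNA, Mann-Whitney group comparison,
maximum-accuracy threshold classification (positive class = non-responder,
test-positive = methylation at or above threshold), Kaplan-Meier estimation
and the log-rank test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_qmsp",
    "MannWhitneyResult",
    "compare_groups",
    "ClassifierEval",
    "select_threshold",
    "confusion_metrics",
    "SurvivalCurve",
    "km_estimate",
    "LogRankResult",
    "logrank",
]


def normalize_qmsp(raw_level, control_level):
    """Methylation percent: 100 * raw / control, capped at 100."""
    raw = np.asarray(raw_level, dtype=float)
    control = np.asarray(control_level, dtype=float)
    if np.any(control <= 0):
        raise ValueError("control_level must be positive")
    pct = 100.0 * raw / control
    if np.any(pct > 100.0):
        warnings.warn("qMSP signal above control; capped at 100%", stacklevel=2)
    out = np.minimum(pct, 100.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # 'exact' | 'asymptotic'


def compare_groups(values, labels) -> MannWhitneyResult:
    """Two-sided Mann-Whitney comparison of responder vs non-responder values.

    ``labels`` is boolean (True = first group). The U statistic reported is
    that of the first group. For combined n <= 20 the p-value is exact, by
    enumeration of all label assignments on the pooled midranks (so ties are
    handled exactly); larger samples use the normal approximation with tie
    and continuity correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    x = values[labels]
    y = values[~labels]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = stats.rankdata(values)
    r1 = ranks[labels].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0

    if n <= 20:
        obs = abs(u1 - mean_u)
        count = total = 0
        base = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n), n1):
            u = ranks[list(combo)].sum() - base
            total += 1
            if abs(u - mean_u) >= obs - 1e-9:
                count += 1
        return MannWhitneyResult(u_statistic=float(u1), p_value=count / total,
                                 method="exact")

    # normal approximation with tie correction and continuity correction
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return MannWhitneyResult(u_statistic=float(u1), p_value=1.0,
                                 method="asymptotic")
    z = (abs(u1 - mean_u) - 0.5) / np.sqrt(var_u)
    p = float(min(2.0 * stats.norm.sf(max(z, 0.0)), 1.0))
    return MannWhitneyResult(u_statistic=float(u1), p_value=p, method="asymptotic")


@dataclass(frozen=True)
class ClassifierEval:
    """Threshold classifier confusion counts and exact rational metrics."""

    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: Fraction
    specificity: Fraction
    accuracy: Fraction

    @property
    def sensitivity_pct(self) -> int:
        return round(float(self.sensitivity) * 100)

    @property
    def specificity_pct(self) -> int:
        return round(float(self.specificity) * 100)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int,
                      threshold: float = float("nan")) -> ClassifierEval:
    """Exact sensitivity/specificity/accuracy from confusion counts."""
    for v in (tp, fn, tn, fp):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    tp, fn, tn, fp = int(tp), int(fn), int(tn), int(fp)
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be represented")
    return ClassifierEval(
        threshold=threshold,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=Fraction(tp, tp + fn),
        specificity=Fraction(tn, tn + fp),
        accuracy=Fraction(tp + tn, tp + fn + tn + fp),
    )


def select_threshold(values, is_nonresponder) -> ClassifierEval:
    """Maximum-accuracy methylation threshold.

    Positives are non-responders; a patient tests positive when the value is
    at or above the threshold. Candidate thresholds are the midpoints between
    consecutive distinct sorted values plus one below the minimum and one
    above the maximum (the everyone-negative rule can be optimal); accuracy
    ties are broken by the smallest threshold.
    """
    values = np.asarray(values, dtype=float)
    pos = np.asarray(is_nonresponder, dtype=bool)
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    distinct = np.unique(values)
    candidates = (
        [distinct[0] - 1.0]
        + list((distinct[:-1] + distinct[1:]) / 2.0)
        + [distinct[-1] + 1.0]
    )
    best = None
    for thr in candidates:
        pred = values >= thr
        tp = int((pred & pos).sum())
        fp = int((pred & ~pos).sum())
        fn = int((~pred & pos).sum())
        tn = int((~pred & ~pos).sum())
        ev = confusion_metrics(tp, fn, tn, fp, threshold=float(thr))
        if best is None or ev.accuracy > best.accuracy:
            best = ev
    return best


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous Kaplan-Meier product-limit estimate."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time

    def at(self, t: float) -> float:
        """S(t) for arbitrary t (step function, right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator; censored subjects leave the risk set after
    their recorded time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events])
    surv = []
    at_risk = []
    s = 1.0
    for t in event_times:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
    return SurvivalCurve(
        times=event_times, survival=np.asarray(surv), at_risk=np.asarray(at_risk)
    )


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    n_a: int
    n_b: int
    observed_a: float
    expected_a: float


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test (O - E with hypergeometric variance, df 1)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank test requires at least one event")
    all_event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_a = e_a = v = 0.0
    for t in all_event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        n = n1 + n2
        d1 = int(((ta == t) & ea).sum())
        d2 = int(((tb == t) & eb).sum())
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        o_a += d1
        e_a += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if v <= 0:
        chi2 = 0.0
    else:
        chi2 = (o_a - e_a) ** 2 / v
    return LogRankResult(
        chi_square=float(chi2),
        df=1,
        p_value=float(stats.chi2.sf(chi2, df=1)),
        n_a=len(ta),
        n_b=len(tb),
        observed_a=float(o_a),
        expected_a=float(e_a),
    )
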