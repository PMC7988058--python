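"""Survival-biomarker statistics for screened texture features.

Three stages mirror the usual univariate prognostic workflow:

1. ROC analysis of each feature against a binary outcome (here the
   progression label), with the AUC computed by the Mann-Whitney rank
   identity and an operating cut-off chosen by Youden's J.
2. Kaplan-Meier comparison of the groups obtained by dichotomising the
   feature, with the two-sample log-rank test; an "optimal" cut-point is
   found by grid search over candidate thresholds. Because the threshold is
   chosen to minimise the log-rank p-value, that p-value is anti-conservative
   and every cut-point result is flagged exploratory.
3. Univariate Cox proportional-hazards regression of the continuous feature,
   fitted by partial likelihood with Efron tie handling (via lifelines).

The log-rank statistic is computed by a vectorised risk-table implementation
in this module: the cut-point search evaluates the test at every candidate
threshold, so it needs to be cheap. Kaplan-Meier and Cox fits delegate to
lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats

from .errors import ValidationError

#: cap for |log-hazard coefficient| when the partial likelihood is monotone
COEF_CAP = 50.0


@dataclass(frozen=True)
class ROCResult:
    """ROC summary of one feature against a binary outcome.

    ``direction`` is 'low' when low feature values indicate the positive
    class (prediction rule: value <= cutoff) and 'high' otherwise
    (rule: value > cutoff). AUC is reported for the favourable direction,
    hence always >= 0.5.
    """

    auc: float
    direction: str
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "direction": self.direction,
            "cutoff": self.cutoff,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve."""

    event_times: np.ndarray  # ordered distinct times at which anything happens
    survival_probs: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival_probs[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    group_sizes: tuple[int, int]
    threshold: float | None = None
    exploratory: bool = False

    def as_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "group_sizes": list(self.group_sizes),
            "threshold": self.threshold,
            "exploratory": self.exploratory,
        }


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit: hazard ratio per unit of the feature."""

    coefficient: float
    se: float
    hr: float
    ci95: tuple[float, float]
    p_value: float
    converged: bool
    n: int
    n_events: int

    def as_dict(self) -> dict:
        return {
            "coefficient": self.coefficient,
            "se": self.se,
            "hr": self.hr,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "converged": self.converged,
            "n": self.n,
            "n_events": self.n_events,
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def _check_times_events(times, events, name: str = "") -> tuple[np.ndarray, np.ndarray]:
    t = _as_1d(times, f"{name}times")
    e = np.asarray(events).ravel()
    if t.size != e.size:
        raise ValidationError("times and events must have equal length")
    if (t < 0).any():
        raise ValidationError("survival times must be non-negative")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("event flags must be binary 0/1")
    return t, e.astype(np.int64)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_analysis(scores, labels) -> ROCResult:
    """ROC/AUC of a continuous score against a binary label.

    The AUC is the Mann-Whitney concordance probability (ties get half
    credit).  When the raw AUC is below 0.5 the direction flips so that low
    values indicate the positive class, and the reported AUC is 1 - raw.
    The cut-off maximises Youden's J = sensitivity + specificity - 1 over
    the observed values, breaking ties toward higher specificity; the
    p-value tests AUC = 0.5 via the normal approximation to Mann-Whitney.
    """
    s = _as_1d(scores, "scores")
    y = np.asarray(labels).ravel()
    if s.size != y.size:
        raise ValidationError("scores and labels must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    y = y.astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both outcome classes must be present")

    ranks = stats.rankdata(s)
    auc_raw = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    direction = "high" if auc_raw >= 0.5 else "low"
    auc = auc_raw if auc_raw >= 0.5 else 1.0 - auc_raw

    if np.all(s == s[0]):
        p_value = 1.0
    else:
        p_value = float(
            stats.mannwhitneyu(s[y], s[~y], alternative="two-sided", method="asymptotic").pvalue
        )

    pos, neg = s[y], s[~y]
    candidates = np.unique(s)
    if direction == "low":
        # predict positive when value <= c
        sens = (pos[:, None] <= candidates[None, :]).mean(axis=0)
        spec = (neg[:, None] > candidates[None, :]).mean(axis=0)
    else:
        # predict positive when value > c
        sens = (pos[:, None] > candidates[None, :]).mean(axis=0)
        spec = (neg[:, None] <= candidates[None, :]).mean(axis=0)
    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.flatnonzero(j >= best_j - 1e-12)
    best = tied[np.argmax(spec[tied])]
    return ROCResult(
        auc=float(auc),
        direction=direction,
        cutoff=float(candidates[best]),
        sensitivity_pct=float(100.0 * sens[best]),
        specificity_pct=float(100.0 * spec[best]),
        p_value=p_value,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(times, events) -> KMCurve:
    """Product-limit (Kaplan-Meier) survival estimate."""
    t, e = _check_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    # drop the artificial t=0 row lifelines prepends unless 0 is an observed time
    if len(table) and table.index[0] == 0.0 and (t > 0).all():
        table = table.iloc[1:]
    timeline = np.asarray(table.index, dtype=np.float64)
    probs = kmf.survival_function_.loc[timeline, "KM_estimate"].to_numpy()
    return KMCurve(
        event_times=timeline,
        survival_probs=probs,
        at_risk=table["at_risk"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _logrank_chi2(times: np.ndarray, events: np.ndarray, in_group_a: np.ndarray) -> float:
    """Two-group log-rank chi-square (1 df) from pooled risk tables."""
    event_times = np.unique(times[events == 1])
    order = np.argsort(times, kind="stable")
    ts = times[order]
    grp = in_group_a[order]
    # at risk at t: subjects with time >= t
    left = np.searchsorted(ts, event_times, side="left")
    n_total = ts.size
    cum_a = np.concatenate(([0], np.cumsum(grp)))
    at_risk_total = n_total - left
    at_risk_a = (cum_a[-1] - cum_a[left]).astype(np.float64)
    # deaths at t per group
    te = times[events == 1]
    ge = in_group_a[events == 1]
    order_e = np.argsort(te, kind="stable")
    te, ge = te[order_e], ge[order_e]
    lo = np.searchsorted(te, event_times, side="left")
    hi = np.searchsorted(te, event_times, side="right")
    cum_ge = np.concatenate(([0], np.cumsum(ge)))
    d_total = (hi - lo).astype(np.float64)
    d_a = (cum_ge[hi] - cum_ge[lo]).astype(np.float64)

    nj = at_risk_total.astype(np.float64)
    n1 = at_risk_a
    expected = d_total * n1 / nj
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d_total * (n1 / nj) * (1 - n1 / nj) * (nj - d_total) / (nj - 1)
    var = np.where(nj > 1, var, 0.0)
    o_minus_e = float((d_a - expected).sum())
    v = float(np.nansum(var))
    if v <= 0:
        return 0.0
    return o_minus_e**2 / v


def log_rank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-sample log-rank test (1 df) of equal survival distributions."""
    ta, ea = _check_times_events(times_a, events_a, "group A ")
    tb, eb = _check_times_events(times_b, events_b, "group B ")
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("log-rank requires at least one event")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    chi2 = _logrank_chi2(times, events, in_a)
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return LogRankResult(
        chi_square=float(chi2), p_value=p, group_sizes=(ta.size, tb.size)
    )


@dataclass(frozen=True)
class CutpointResult:
    """Outcome of the optimal-threshold Kaplan-Meier search.

    The threshold minimises the log-rank p-value over all candidate splits,
    so ``logrank.exploratory`` is always True: no multiplicity adjustment is
    applied and the p-value understates the type-I error of the search.
    """

    threshold: float
    logrank: LogRankResult
    km_low: KMCurve
    km_high: KMCurve
    n_candidates: int


def optimal_cutoff_km(feature, times, events, min_group_frac: float = 0.10) -> CutpointResult:
    """Grid-search the feature threshold best separating survival groups.

    Candidate thresholds are midpoints between consecutive sorted unique
    feature values; a subject whose feature equals the threshold goes to the
    LOW group (the "<= cut-off" convention). Splits leaving either group
    below ``min_group_frac`` of the cohort are skipped.
    """
    x = _as_1d(feature, "feature")
    t, e = _check_times_events(times, events)
    if x.size != t.size:
        raise ValidationError("feature and survival arrays must align")
    if x.size < 4:
        raise ValidationError("cut-point search needs at least 4 subjects")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValidationError("feature is constant; no split exists")
    if e.sum() == 0:
        raise ValidationError("cut-point search requires at least one event")

    floor = max(1, int(np.ceil(min_group_frac * x.size)))
    midpoints = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    n_cand = 0
    for thr in midpoints:
        low = x <= thr
        n_low = int(low.sum())
        if n_low < floor or (x.size - n_low) < floor:
            continue
        n_cand += 1
        chi2 = _logrank_chi2(t, e, low)
        if best is None or chi2 > best[1] + 1e-12:
            best = (thr, chi2)
    if best is None:
        raise ValidationError("no admissible split satisfies the group-size floor")
    thr, chi2 = best
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    low = x <= thr
    lr = LogRankResult(
        chi_square=float(chi2),
        p_value=p,
        group_sizes=(int(low.sum()), int((~low).sum())),
        threshold=float(thr),
        exploratory=True,
    )
    return CutpointResult(
        threshold=float(thr),
        logrank=lr,
        km_low=km_estimate(t[low], e[low]),
        km_high=km_estimate(t[~low], e[~low]),
        n_candidates=n_cand,
    )


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def cox_univariate(feature, times, events) -> CoxResult:
    """Univariate Cox proportional-hazards fit of a continuous feature.

    Partial-likelihood maximisation with Efron's correction for tied event
    times (lifelines). A monotone partial likelihood (perfect separation)
    yields a flagged, capped result with ``converged=False`` instead of a
    silently diverging coefficient.
    """
    x = _as_1d(feature, "feature")
    t, e = _check_times_events(times, events)
    if x.size != t.size:
        raise ValidationError("feature and survival arrays must align")
    n_events = int(e.sum())
    if n_events < 2:
        raise ValidationError("Cox regression needs at least 2 events")
    if np.std(x) == 0:
        raise ValidationError("feature has zero variance")

    df = pd.DataFrame({"x": x, "time": t, "event": e})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="time", event_col="event")
        failed = any(
            issubclass(w.category, ConvergenceWarning)
            and "failed to converge" in str(w.message)
            for w in caught
        )
        if failed:
            coef = float(cph.params_.iloc[0])
            coef = float(np.sign(coef) or 1.0) * min(abs(coef), COEF_CAP)
            return CoxResult(
                coefficient=coef,
                se=float("nan"),
                hr=float(np.exp(coef)),
                ci95=(float("nan"), float("nan")),
                p_value=float("nan"),
                converged=False,
                n=x.size,
                n_events=n_events,
            )
    except ConvergenceError:
        # monotone likelihood: report the direction with a capped coefficient
        sign = np.sign(np.corrcoef(x, t)[0, 1]) or 1.0
        coef = -float(sign) * COEF_CAP  # longer times with larger x => negative beta
        return CoxResult(
            coefficient=coef,
            se=float("nan"),
            hr=float(np.exp(coef)),
            ci95=(float("nan"), float("nan")),
            p_value=float("nan"),
            converged=False,
            n=x.size,
            n_events=n_events,
        )
    coef = float(cph.params_.iloc[0])
    se = float(cph.standard_errors_.iloc[0])
    lo, hi = coef - 1.96 * se, coef + 1.96 * se
    z = coef / se if se > 0 else float("inf")
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxResult(
        coefficient=coef,
        se=se,
        hr=float(np.exp(coef)),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        p_value=p,
        converged=True,
        n=x.size,
        n_events=n_events,
    )
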