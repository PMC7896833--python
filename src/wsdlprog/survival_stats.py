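"""Survival evaluation battery for the PSI biomarker.

Kaplan-Meier estimation, the two-group log-rank test, IPCW time-dependent
ROC/AUC, Cox proportional-hazards regression (Efron ties), Fisher's exact
test, binary classification metrics against the 2-year outcome, and
median-cutoff univariate log-rank screening.

Kaplan-Meier, log-rank, and Cox fits are delegated to lifelines; the
time-dependent ROC is implemented here with the cumulative-cases /
dynamic-controls definition and inverse-probability-of-censoring weights,
since per-threshold ROC coordinates are needed alongside the AUC.

Significance is read at 0.05 throughout and no multiplicity adjustment is
applied in the univariate screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KmCurve",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "time_dependent_auc",
    "cox_fit",
    "classification_metrics",
    "fisher_exact",
    "univariate_screen",
]


@dataclass
class SurvivalRecord:
    patient_id: str
    time: float   # months, > 0
    event: int    # 1 = event observed, 0 = censored

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"nonpositive survival time for {self.patient_id}")


def _to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        t = records["time"].to_numpy(float)
        e = records["event"].to_numpy(int)
    else:
        t = np.asarray([r.time for r in records], dtype=float)
        e = np.asarray([r.event for r in records], dtype=int)
    if len(t) == 0:
        raise ValueError("no survival records")
    if (t <= 0).any():
        raise ValueError("nonpositive survival times")
    return t, e


@dataclass
class KmCurve:
    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray
    greenwood_se: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous product-limit estimate S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    summary: pd.DataFrame      # per-covariate HR, CI bounds, p
    log_likelihood: float
    converged: bool

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])


# --------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# --------------------------------------------------------------------------

def km_estimate(records) -> KmCurve:
    """Product-limit estimator with Greenwood standard errors.

    Subjects censored at an event time t remain at risk for the event at t
    (the standard convention).
    """
    t, e = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(float)
    d = ev["observed"].to_numpy(float)
    n = ev["at_risk"].to_numpy(float)
    surv = np.cumprod(1.0 - d / n)
    gw = np.cumsum(d / (n * (n - d + (d == n))))  # guard the S=0 terminal term
    se = surv * np.sqrt(gw)
    return KmCurve(times=times, survival=surv, at_risk=n, greenwood_se=se)


def logrank_test(records_a, records_b) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi2, p)."""
    ta, ea = _to_arrays(records_a)
    tb, eb = _to_arrays(records_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test undefined: no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# --------------------------------------------------------------------------
# time-dependent ROC
# --------------------------------------------------------------------------

def time_dependent_auc(marker, records, t_eval: float) -> tuple[float, pd.DataFrame]:
    """Cumulative-cases / dynamic-controls AUC at ``t_eval`` with IPCW.

    Cases are subjects with an observed event at or before ``t_eval``
    (weighted by 1/G(T-), with G the Kaplan-Meier estimate of the censoring
    survival); controls are subjects still event-free beyond ``t_eval``
    (weighted by 1/G(t_eval)).  The AUC is the weighted probability of
    concordance with ties counted one half; ROC points are returned for
    every distinct marker threshold.
    """
    m = np.asarray(marker, dtype=float)
    t, e = _to_arrays(records)
    if len(m) != len(t):
        raise ValueError("marker and records length mismatch")
    if t_eval <= 0 or t_eval > t.max():
        raise ValueError(f"t_eval {t_eval} outside the observed time range")

    case = (t <= t_eval) & (e == 1)
    ctrl = t > t_eval
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError(f"no cases or no controls at t={t_eval}")

    # censoring survival G from the flipped-event Kaplan-Meier estimator
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=1 - e)
    eps = 1e-9
    G = lambda u: max(float(kmf.predict(u)), 1e-12)
    w = np.zeros(len(t))
    w[case] = 1.0 / np.array([G(ti - eps) for ti in t[case]])
    w[ctrl] = 1.0 / G(t_eval)

    mc, wc = m[case], w[case]
    mk, wk = m[ctrl], w[ctrl]
    # weighted concordance: cases should score higher than controls
    diff = mc[:, None] - mk[None, :]
    ww = wc[:, None] * wk[None, :]
    auc = float((ww * ((diff > 0) + 0.5 * (diff == 0))).sum() / ww.sum())

    thresholds = np.unique(m)[::-1]
    rows = []
    for thr in thresholds:
        tp = wc[mc >= thr].sum()
        fp = wk[mk >= thr].sum()
        rows.append(
            {"threshold": thr, "sensitivity": tp / wc.sum(), "one_minus_specificity": fp / wk.sum()}
        )
    return auc, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

def cox_fit(covariates: pd.DataFrame, records) -> CoxFit:
    """Multivariate Cox PH fit (Efron tie handling, Wald inference)."""
    t, e = _to_arrays(records)
    X = covariates.copy().reset_index(drop=True)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    if np.linalg.matrix_rank(X.to_numpy(float) - X.to_numpy(float).mean(0)) < X.shape[1]:
        raise ValueError("collinear covariates: singular information matrix")
    if e.sum() < X.shape[1]:
        import warnings

        warnings.warn("fewer events than covariates; estimates may be unstable")
    df = X.copy()
    df["time"] = t
    df["event"] = e
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # non-convergence / separation
        raise ValueError(f"Cox fit failed (possible separation): {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "hazard_ratio": np.exp(s["coef"]),
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
            "coef": s["coef"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
    )


# --------------------------------------------------------------------------
# classification metrics and Fisher's exact test
# --------------------------------------------------------------------------

def classification_metrics(predicted_pos, true_pos) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent.

    Positive means relapse; predicted positive means the high-PSI group.
    """
    yp = np.asarray(predicted_pos, dtype=int)
    yt = np.asarray(true_pos, dtype=int)
    if yp.shape != yt.shape:
        raise ValueError("prediction and truth length mismatch")
    if yt.sum() == 0:
        raise ValueError("sensitivity undefined: no true positives in the truth margin")
    if (1 - yt).sum() == 0:
        raise ValueError("specificity undefined: no true negatives in the truth margin")
    tp = int(((yp == 1) & (yt == 1)).sum())
    tn = int(((yp == 0) & (yt == 0)).sum())
    fp = int(((yp == 1) & (yt == 0)).sum())
    fn = int(((yp == 0) & (yt == 1)).sum())
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / len(yt)
    return sens, spec, acc


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Empty margins return p = 1 by convention (with a warning).
    """
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("empty margin in Fisher table; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(tab, alternative="two-sided")[1])


# --------------------------------------------------------------------------
# univariate screening
# --------------------------------------------------------------------------

def univariate_screen(
    table: pd.DataFrame,
    records,
    cutoffs: dict | None = None,
    continuous_threshold: int = 3,
) -> pd.DataFrame:
    """Per-variable log-rank screening after dichotomization.

    Continuous variables (more than ``continuous_threshold`` distinct
    values) are split at the supplied cutoff or, by default, at the median
    (group high = value > cutoff); variables with few levels are split as
    level > minimum.  Constant variables are skipped with a warning.
    Returns a table of (variable, cutoff, p).
    """
    import warnings

    t, e = _to_arrays(records)
    cutoffs = cutoffs or {}
    rows = []
    for col in table.columns:
        v = table[col]
        if v.dtype == object:
            codes = pd.factorize(v)[0].astype(float)
        else:
            codes = v.to_numpy(float)
        uniq = np.unique(codes[~np.isnan(codes)])
        if len(uniq) < 2:
            warnings.warn(f"variable {col!r} is constant; skipped")
            continue
        if col in cutoffs:
            cut = float(cutoffs[col])
        elif len(uniq) > continuous_threshold:
            cut = float(np.median(codes))
        else:
            cut = float(uniq[0])
        high = codes > cut
        if high.sum() == 0 or (~high).sum() == 0:
            warnings.warn(f"variable {col!r}: cutoff {cut} leaves an empty group; skipped")
            continue
        recs_a = pd.DataFrame({"time": t[high], "event": e[high]})
        recs_b = pd.DataFrame({"time": t[~high], "event": e[~high]})
        try:
            _, p = logrank_test(recs_a, recs_b)
        except ValueError:
            warnings.warn(f"variable {col!r}: log-rank undefined; skipped")
            continue
        rows.append({"variable": col, "cutoff": cut, "p": p})
    return pd.DataFrame(rows)
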