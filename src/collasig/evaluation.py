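"""Model evaluation: discrimination, calibration, decision curves and
classification metrics, plus Kaplan-Meier/log-rank/Cox support.

Discrimination for the competing-risks endpoint uses the
cumulative/dynamic convention at a horizon t*: cases are subjects with a
cause-1 event by t*, controls are subjects known to be cause-1-free at t*
(including those with an earlier competing event, whose cause-1-free
status is determined); subjects censored before t* are reweighted by
inverse probability of censoring (IPCW) where weights apply and excluded
from rank-based tests that need determinate labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .competing import censoring_survival, cif_aalen_johansen

# ---------------------------------------------------------------------------
# binary status at a horizon
# ---------------------------------------------------------------------------

def binary_status_at(
    time: np.ndarray, event: np.ndarray, t_star: float
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, determinate) at horizon ``t_star``.

    label 1: cause-1 event by t*; label 0: known cause-1-free at t*
    (followed up to t* or beyond, or competing event by t*);
    indeterminate: censored strictly before t*.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    case = (event == 1) & (time <= t_star)
    control = ~case & (
        (time >= t_star) | ((event == 2) & (time <= t_star))
    )
    determinate = case | control
    return case.astype(int), determinate


# ---------------------------------------------------------------------------
# time-truncated IPCW concordance
# ---------------------------------------------------------------------------

def _c_index_at(risk, time, event, tau, g_at_t_minus) -> tuple[float, float]:
    """Weighted (numerator, denominator) of C(tau) for cause 1."""
    cases = np.flatnonzero((event == 1) & (time <= tau))
    num = den = 0.0
    for i in cases:
        comparable = (time > time[i]) | ((time <= time[i]) & (event == 2))
        comparable[i] = False
        m = comparable.sum()
        if m == 0:
            continue
        w = 1.0 / g_at_t_minus[i] ** 2
        conc = np.sum(risk[i] > risk[comparable]) + 0.5 * np.sum(
            risk[i] == risk[comparable]
        )
        num += w * conc
        den += w * m
    return num, den


def averaged_c_index(
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    grid: np.ndarray | None = None,
    t_max: float = 3.0,
    n_grid: int = 20,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """IPCW time-truncated concordance averaged over a time grid.

    ``C(t)`` restricts to case subjects with a cause-1 event by ``t``;
    the average is the unweighted mean over the grid (default: 20 equally
    spaced times from the first cause-1 event to ``t_max``).  The CI is a
    seeded subject-level bootstrap percentile interval.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if grid is None:
        t1 = time[event == 1]
        if t1.size == 0:
            raise ValueError("no cause-1 events")
        grid = np.linspace(t1.min(), t_max, n_grid)
    grid = np.asarray(grid, dtype=float)

    def c_avg(r, t, e):
        G = censoring_survival(t, e)
        g = np.asarray(G.left_limit(t), dtype=float)
        g = np.maximum(g, 1e-8)
        cs = []
        for tau in grid:
            num, den = _c_index_at(r, t, e, tau, g)
            if den == 0:
                warnings.warn(f"no comparable pairs at t={tau:.3g}; dropped")
                continue
            cs.append(num / den)
        if not cs:
            raise ValueError("no usable grid times")
        return float(np.mean(cs))

    c0 = c_avg(risk, time, event)
    if n_boot <= 0:
        return c0, (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    n = len(risk)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boots.append(c_avg(risk[idx], time[idx], event[idx]))
        except ValueError:
            continue
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return c0, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    t_star: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    ci: tuple[float, float]
    n_cases: int
    n_controls: int


def time_dependent_roc(
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    t_star: float = 3.0,
) -> ROCResult:
    """Cumulative/dynamic ROC at ``t_star`` for the cause-1 endpoint.

    Cases: cause-1 event by t*.  Controls: cause-1-free at t* (competing
    events included).  Subjects censored before t* enter through IPCW
    weights: cases by 1/G(T-), controls by 1/G(t*).  The CI is a DeLong
    interval on the determinate-status subjects.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    labels, determinate = binary_status_at(time, event, t_star)
    case = labels == 1
    control = (labels == 0) & determinate
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError("need both cases and controls at t_star")

    G = censoring_survival(time, event)
    w = np.zeros(len(risk))
    w[case] = 1.0 / np.maximum(
        np.asarray(G.left_limit(time[case]), dtype=float), 1e-8
    )
    w[control] = 1.0 / max(float(G(t_star)), 1e-8)

    r_case, w_case = risk[case], w[case]
    r_ctrl, w_ctrl = risk[control], w[control]
    # weighted Mann-Whitney AUC
    diff = r_case[:, None] - r_ctrl[None, :]
    wmat = w_case[:, None] * w_ctrl[None, :]
    auc = float(
        np.sum(wmat * ((diff > 0) + 0.5 * (diff == 0))) / wmat.sum()
    )

    thresholds = np.concatenate(
        [[np.inf], np.unique(risk)[::-1]]
    )
    tpr = np.array(
        [np.sum(w_case[r_case >= c]) / w_case.sum() for c in thresholds]
    )
    fpr = np.array(
        [np.sum(w_ctrl[r_ctrl >= c]) / w_ctrl.sum() for c in thresholds]
    )

    auc_d, var_d = _delong_auc_variance(risk[determinate],
                                        labels[determinate])
    se = np.sqrt(var_d)
    ci = (max(auc_d - 1.96 * se, 0.0), min(auc_d + 1.96 * se, 1.0))
    return ROCResult(
        t_star=t_star,
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auroc=auc,
        ci=ci,
        n_cases=int(case.sum()),
        n_controls=int(control.sum()),
    )


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(risk: np.ndarray, labels: np.ndarray):
    pos = risk[labels == 1]
    neg = risk[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both classes")
    all_r = np.concatenate([pos, neg])
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(all_r)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # per-case structural components
    v10 = 1.0 - (tz[m:] - ty) / m  # per-control
    return auc, v01, v10


def _delong_auc_variance(risk, labels) -> tuple[float, float]:
    auc, v01, v10 = _delong_components(np.asarray(risk, float),
                                       np.asarray(labels))
    var = np.var(v01, ddof=1) / len(v01) + np.var(v10, ddof=1) / len(v10)
    return float(auc), float(var)


def delong_compare(
    risk_a: np.ndarray, risk_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Paired DeLong test of two AUROCs on the same subjects.

    Returns (AUROC_a - AUROC_b, two-sided p).  Identical or rank-identical
    risk vectors give delta 0 and p = 1.
    """
    risk_a = np.asarray(risk_a, dtype=float)
    risk_b = np.asarray(risk_b, dtype=float)
    labels = np.asarray(labels)
    auc_a, v01a, v10a = _delong_components(risk_a, labels)
    auc_b, v01b, v10b = _delong_components(risk_b, labels)
    delta = auc_a - auc_b
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    var = (
        (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / len(v01a)
        + (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / len(v10a)
    )
    if var <= 1e-16:
        return float(delta), 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / np.sqrt(var)
    return float(delta), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibration_curve(
    predicted_cif: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    t_star: float = 3.0,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Observed (Aalen-Johansen) vs predicted cause-1 CIF at ``t_star``
    within predicted-risk quantile bins.

    Empty bins (duplicate quantile edges) are merged with their neighbour.
    Returns one row per bin: n, mean predicted, observed CIF, 95% CI.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    predicted_cif = np.asarray(predicted_cif, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    edges = np.unique(np.quantile(predicted_cif,
                                  np.linspace(0, 1, n_bins + 1)))
    if len(edges) - 1 < n_bins:
        warnings.warn(
            f"duplicate quantile edges; using {len(edges) - 1} bins"
        )
    if len(edges) < 2:  # constant predictions: one bin holding everyone
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    idx = np.clip(np.searchsorted(edges, predicted_cif, side="right") - 1,
                  0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() == 0:
            continue
        est = cif_aalen_johansen(time[sel], event[sel])
        obs = est.at(t_star, cause=1)
        se = np.sqrt(est.var_at(t_star, cause=1))
        rows.append(
            {
                "bin": b,
                "n": int(sel.sum()),
                "predicted_mean": float(predicted_cif[sel].mean()),
                "observed_cif": obs,
                "ci_low": max(obs - 1.96 * se, 0.0),
                "ci_high": min(obs + 1.96 * se, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    assert out["n"].sum() == len(predicted_cif)
    return out


# ---------------------------------------------------------------------------
# decision curve
# ---------------------------------------------------------------------------

def decision_curve(
    predicted_prob: np.ndarray,
    outcome: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Net benefit NB(P_t) = TP/n - FP/n * P_t / (1 - P_t).

    ``outcome`` is the binary event status at the horizon.  Treat-all and
    treat-none reference curves are included; thresholds at 1 are
    excluded (division by zero).
    """
    predicted_prob = np.asarray(predicted_prob, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    thresholds = thresholds[(thresholds > 0) & (thresholds < 1)]
    n = len(outcome)
    prevalence = outcome.mean()
    rows = []
    for pt in thresholds:
        treat = predicted_prob >= pt
        tp = int(np.sum(treat & (outcome == 1)))
        fp = int(np.sum(treat & (outcome == 0)))
        odds = pt / (1.0 - pt)
        nb = tp / n - fp / n * odds
        nb_all = prevalence - (1.0 - prevalence) * odds
        rows.append(
            {
                "threshold": pt,
                "net_benefit": nb,
                "treat_all": nb_all,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classification report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def as_dict(self) -> dict[str, float]:
        return {
            "cutoff": self.cutoff,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "youden": self.youden,
        }


def report_from_counts(
    tp: int, fp: int, tn: int, fn: int, cutoff: float = np.nan
) -> ClassificationReport:
    return ClassificationReport(cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn)


def classification_report(
    risk: np.ndarray,
    labels: np.ndarray,
    cutoff: float | None = None,
) -> ClassificationReport:
    """Confusion counts and rates at a cutoff (positive = risk >= cutoff).

    When ``cutoff`` is omitted, the Youden index (sensitivity +
    specificity - 1) is maximized over the observed risk values.
    """
    risk = np.asarray(risk, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if cutoff is None:
        best = (-np.inf, None)
        for c in np.unique(risk):
            rep = classification_report(risk, labels, cutoff=float(c))
            if rep.youden > best[0] + 1e-12:
                best = (rep.youden, float(c))
        cutoff = best[1]
    pred = risk >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return ClassificationReport(cutoff=float(cutoff), tp=tp, fp=fp,
                                tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# KM / log-rank / Cox support (overall and disease-free survival)
# ---------------------------------------------------------------------------

def survival_support(
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Kaplan-Meier curves, two-group log-rank, and Cox PH hazard ratios
    for a standard right-censored endpoint (binary event indicator).

    Returns a dict with ``km`` (per-group survival tables), ``logrank``
    (statistic, p) when a group is given, and ``cox`` (HR table) when
    covariates are given.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    out: dict = {}
    km = {}
    if group is None:
        groups = {"all": np.ones(len(time), dtype=bool)}
    else:
        group = np.asarray(group)
        groups = {g: group == g for g in np.unique(group)}
    for name, sel in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        km[name] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", "KM_estimate": "survival"}
        )
    out["km"] = km
    if group is not None:
        if event.sum() == 0:
            raise ValueError("no events; log-rank undefined")
        res = multivariate_logrank_test(time, group, event)
        out["logrank"] = (float(res.test_statistic), float(res.p_value))
    if covariates is not None:
        if event.sum() == 0:
            raise ValueError("no events; Cox model undefined")
        df = covariates.copy()
        df["time"] = time
        df["event"] = event
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        summ = cph.summary
        out["cox"] = pd.DataFrame(
            {
                "term": summ.index,
                "HR": np.exp(summ["coef"].to_numpy()),
                "ci_low": np.exp(
                    summ["coef lower 95%"].to_numpy()
                ),
                "ci_high": np.exp(
                    summ["coef upper 95%"].to_numpy()
                ),
                "p": summ["p"].to_numpy(),
            }
        ).reset_index(drop=True)
    return out
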