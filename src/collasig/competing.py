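"""Competing-risks estimation: CIF, Gray-type test, Fine-Gray regression,
and nomogram construction.

The event of interest (cause 1) is analysed on the subdistribution-hazard
scale: subjects who experience the competing event (cause 2) are retained
in the risk set with inverse-probability-of-censoring weights (IPCW)
w_j(t) = G(t-)/G(T_j-), where G is the Kaplan-Meier estimate of the
censoring distribution evaluated at left limits.  This is the standard
Fine-Gray construction; the regression maximizes the weighted partial
likelihood by Newton-Raphson with Breslow handling of ties and reports
robust (sandwich) standard errors.  The k-sample comparison of cause-1
cumulative incidence ("Gray's test" in reports) is implemented as the
score test of this weighted partial likelihood at beta = 0, which reduces
exactly to the log-rank test when no competing events are present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Censoring-distribution Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function with value 1 before the first jump."""

    times: np.ndarray  # sorted jump times
    values: np.ndarray  # value on [times[i], times[i+1])

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float),
                              side="right") - 1
        vals = np.concatenate([[1.0], self.values])
        return vals[idx + 1]

    def left_limit(self, t: np.ndarray | float) -> np.ndarray:
        """Value at t-, i.e. just before t."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float),
                              side="left") - 1
        vals = np.concatenate([[1.0], self.values])
        return vals[idx + 1]


def censoring_survival(time: np.ndarray, event: np.ndarray) -> StepFunction:
    """Kaplan-Meier of the censoring distribution (event code 0 = event)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    order = np.argsort(time, kind="stable")
    t = time[order]
    cens = (event[order] == 0).astype(float)
    uniq, start = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - start
    d_c = np.add.reduceat(cens, start)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(at_risk > 0, 1.0 - d_c / at_risk, 1.0)
    surv = np.cumprod(frac)
    return StepFunction(times=uniq, values=surv)


# ---------------------------------------------------------------------------
# Aalen-Johansen cumulative incidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CIFEstimate:
    """Aalen-Johansen estimate of the cause-specific cumulative incidence.

    ``times`` are the distinct observed times; ``cif[c]`` and ``var[c]``
    hold the estimate and its pointwise variance for cause c in {1, 2};
    ``surv`` is the all-cause Kaplan-Meier, so cif1 + cif2 + surv = 1 at
    every event time.
    """

    times: np.ndarray
    cif: dict[int, np.ndarray]
    var: dict[int, np.ndarray]
    surv: np.ndarray

    def at(self, t: float, cause: int = 1) -> float:
        """CIF of ``cause`` at time ``t`` (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.cif[cause][idx])

    def var_at(self, t: float, cause: int = 1) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.var[cause][idx])


def cif_aalen_johansen(time: np.ndarray, event: np.ndarray) -> CIFEstimate:
    """Aalen-Johansen estimator of the cause-1 and cause-2 CIFs.

    The pointwise variance is the classical three-term estimator
    (Klein & Moeschberger) combining variability of the at-risk process,
    the cause-specific jumps and their covariance.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("empty input")
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    uniq, start = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - start
    d_all = np.add.reduceat((e > 0).astype(float), start)
    d1 = np.add.reduceat((e == 1).astype(float), start)
    d2 = np.add.reduceat((e == 2).astype(float), start)

    frac = 1.0 - d_all / at_risk
    surv = np.cumprod(frac)
    surv_prev = np.concatenate([[1.0], surv[:-1]])

    cif = {}
    var = {}
    for cause, d_c in ((1, d1), (2, d2)):
        jumps = surv_prev * d_c / at_risk
        F = np.cumsum(jumps)
        cif[cause] = F
        # Klein-Moeschberger pointwise variance of the CIF
        with np.errstate(divide="ignore", invalid="ignore"):
            term_a = np.where(
                at_risk - d_all > 0,
                d_all / (at_risk * (at_risk - d_all)),
                0.0,
            )
        term_b = surv_prev**2 * ((at_risk - d_c) / at_risk) * d_c / at_risk**2
        term_c = surv_prev * d_c / at_risk**2
        v = np.empty_like(F)
        for k in range(len(uniq)):
            diff = F[k] - F[: k + 1]
            v[k] = (
                np.sum(diff**2 * term_a[: k + 1])
                + np.sum(term_b[: k + 1])
                - 2.0 * np.sum(diff * term_c[: k + 1])
            )
        var[cause] = np.maximum(v, 0.0)

    if d1.sum() == 0 and d2.sum() == 0:
        import warnings

        warnings.warn("all subjects censored; CIF is identically zero")
    return CIFEstimate(times=uniq, cif=cif, var=var, surv=surv)


# ---------------------------------------------------------------------------
# Weighted partial-likelihood machinery (shared by the fit and the test)
# ---------------------------------------------------------------------------

class _FGData:
    """Sorted data and censoring weights for the Fine-Gray risk sets."""

    def __init__(self, time, event, X):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        X = np.asarray(X, dtype=float)
        order = np.argsort(time, kind="stable")
        self.t = time[order]
        self.e = event[order]
        self.X = X[order]
        self.n, self.p = self.X.shape
        G = censoring_survival(time, event)
        self.G_at_T_minus = np.asarray(G.left_limit(self.t), dtype=float)
        self.event_idx = np.flatnonzero(self.e == 1)
        self.event_times = self.t[self.event_idx]
        # weight of competing-event subjects at later event times t:
        # G(t-)/G(T_j-); censored subjects leave the risk set.
        self.is_comp = (self.e == 2).astype(float)
        self.G_ev_minus = np.asarray(G.left_limit(self.event_times),
                                     dtype=float)

    def sums(self, beta: np.ndarray):
        """S0, S1, S2 over the Fine-Gray risk set at each cause-1 event."""
        eta = self.X @ beta
        eta -= eta.max() if self.n else 0.0  # guard overflow; cancels in ratios
        w = np.exp(eta)
        Xw = self.X * w[:, None]
        XXw = np.einsum("ij,ik,i->ijk", self.X, self.X, w)

        # suffix sums over subjects still conventionally at risk (T_j >= t)
        suf0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        suf1 = np.concatenate([np.cumsum(Xw[::-1], axis=0)[::-1],
                               np.zeros((1, self.p))])
        suf2 = np.concatenate([np.cumsum(XXw[::-1], axis=0)[::-1],
                               np.zeros((1, self.p, self.p))])

        # prefix sums over competing-event subjects with T_j < t
        cw = self.is_comp * w / self.G_at_T_minus
        pre0 = np.concatenate([[0.0], np.cumsum(cw)])
        pre1 = np.concatenate([np.zeros((1, self.p)),
                               np.cumsum(cw[:, None] * self.X, axis=0)])
        pre2 = np.concatenate([
            np.zeros((1, self.p, self.p)),
            np.cumsum(XXw * (self.is_comp / self.G_at_T_minus)[:, None, None],
                      axis=0),
        ])

        lo = np.searchsorted(self.t, self.event_times, side="left")
        g = self.G_ev_minus
        S0 = suf0[lo] + g * pre0[lo]
        S1 = suf1[lo] + g[:, None] * pre1[lo]
        S2 = suf2[lo] + g[:, None, None] * pre2[lo]
        return eta, S0, S1, S2

    def loglik_score_info(self, beta: np.ndarray):
        eta, S0, S1, S2 = self.sums(beta)
        xbar = S1 / S0[:, None]
        ll = float(np.sum(eta[self.event_idx]) - np.sum(np.log(S0)))
        U = self.X[self.event_idx].sum(axis=0) - xbar.sum(axis=0)
        V = S2 / S0[:, None, None] - np.einsum("kj,kl->kjl", xbar, xbar)
        info = V.sum(axis=0)
        return ll, U, info

    def score_residuals(self, beta: np.ndarray) -> np.ndarray:
        """Per-subject score contributions for the sandwich variance."""
        eta, S0, S1, S2 = self.sums(beta)
        xbar = S1 / S0[:, None]
        m = len(self.event_times)
        r = np.zeros((self.n, self.p))
        # event term
        r[self.event_idx] += self.X[self.event_idx] - xbar
        # cumulative hazard terms for conventional at-risk (t_k <= T_i)
        a = 1.0 / S0
        b = xbar / S0[:, None]
        cumA = np.concatenate([[0.0], np.cumsum(a)])
        cumB = np.concatenate([np.zeros((1, self.p)), np.cumsum(b, axis=0)])
        k_le = np.searchsorted(self.event_times, self.t, side="right")
        w_exp = np.exp(eta)
        r -= w_exp[:, None] * (self.X * cumA[k_le][:, None] - cumB[k_le])
        # tail terms for competing-event subjects (t_k > T_i)
        g = self.G_ev_minus
        c = g / S0
        ecoef = (g / S0)[:, None] * xbar
        sufC = np.concatenate([np.cumsum(c[::-1])[::-1], [0.0]])
        sufE = np.concatenate([np.cumsum(ecoef[::-1], axis=0)[::-1],
                               np.zeros((1, self.p))])
        k_gt = np.searchsorted(self.event_times, self.t, side="right")
        comp = self.e == 2
        scale = np.where(comp, w_exp / self.G_at_T_minus, 0.0)
        r -= scale[:, None] * (self.X * sufC[k_gt][:, None] - sufE[k_gt])
        return r

    def baseline_cumhaz(self, beta: np.ndarray):
        """Breslow estimate of the baseline cumulative subdistribution
        hazard, at the distinct cause-1 event times."""
        _, S0, _, _ = self.sums(beta)
        # note: sums() shifts eta by its max; undo the shift for the baseline
        shift = (self.X @ beta).max() if self.n else 0.0
        jumps = np.exp(-shift) / S0
        uniq, inv = np.unique(self.event_times, return_inverse=True)
        acc = np.zeros(len(uniq))
        np.add.at(acc, inv, jumps)
        return uniq, np.cumsum(acc)


# ---------------------------------------------------------------------------
# Gray-type k-sample test
# ---------------------------------------------------------------------------

def grays_test(time, event, group) -> tuple[float, int, float]:
    """k-sample test for equality of cause-1 cumulative incidence curves.

    Implemented as the score test of the Fine-Gray weighted partial
    likelihood at beta = 0 with group indicators, asymptotically
    equivalent to Gray's rho = 0 test; without competing events it
    coincides with the log-rank test.

    Returns (chi-square statistic, degrees of freedom, p-value).
    """
    group = np.asarray(group)
    levels, counts = np.unique(group, return_counts=True)
    if len(levels) < 2:
        raise ValueError("grays_test needs at least 2 groups")
    if (counts == 0).any():
        raise ValueError("every group must contain at least one subject")
    X = (group[:, None] == levels[1:][None, :]).astype(float)
    data = _FGData(time, event, X)
    if len(data.event_times) == 0:
        raise ValueError("no cause-1 events; test undefined")
    _, U, info = data.loglik_score_info(np.zeros(X.shape[1]))
    try:
        stat = float(U @ np.linalg.solve(info, U))
    except np.linalg.LinAlgError:
        stat = float(U @ np.linalg.lstsq(info, U, rcond=None)[0])
    stat = max(stat, 0.0)
    df = len(levels) - 1
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Fine-Gray regression
# ---------------------------------------------------------------------------

class ConvergenceError(RuntimeError):
    pass


@dataclass
class FineGrayModel:
    """Fitted Fine-Gray subdistribution-hazard model.

    ``terms`` are design-matrix column names (dummy-coded categoricals as
    ``variable[level]``); SHR = exp(beta) with Wald CIs from robust SEs.
    """

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    variable_terms: dict[str, list[str]] = field(default_factory=dict)
    categorical_levels: dict[str, list[str]] = field(default_factory=dict)
    n_obs: int = 0
    n_events: int = 0

    @property
    def shr(self) -> np.ndarray:
        return np.exp(self.beta)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.exp(
            np.stack([self.beta - z * self.se, self.beta + z * self.se],
                     axis=1)
        )

    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def overall_wald_p(self, variable: str) -> float:
        """Joint Wald test over all terms of one (categorical) variable."""
        idx = [self.terms.index(t) for t in self.variable_terms[variable]]
        b = self.beta[idx]
        V = self.cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        return float(stats.chi2.sf(stat, len(idx)))

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.beta,
                "se": self.se,
                "SHR": self.shr,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.wald_p(),
            }
        )

    def linear_predictor(self, covariates: dict[str, float | str]) -> float:
        x = encode_row(covariates, self.variable_terms,
                       self.categorical_levels, self.terms)
        return float(x @ self.beta)

    def cumhaz_at(self, t: float) -> float:
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        return float(self.baseline_cumhaz[idx]) if idx >= 0 else 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "terms": self.terms,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "baseline_times": self.baseline_times.tolist(),
            "baseline_cumhaz": self.baseline_cumhaz.tolist(),
            "variable_terms": self.variable_terms,
            "categorical_levels": self.categorical_levels,
            "n_obs": self.n_obs,
            "n_events": self.n_events,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FineGrayModel":
        d = json.loads(Path(path).read_text())
        return cls(
            terms=d["terms"],
            beta=np.array(d["beta"]),
            se=np.array(d["se"]),
            cov=np.array(d["cov"]),
            loglik=d["loglik"],
            n_iter=d["n_iter"],
            baseline_times=np.array(d["baseline_times"]),
            baseline_cumhaz=np.array(d["baseline_cumhaz"]),
            variable_terms=d["variable_terms"],
            categorical_levels=d["categorical_levels"],
            n_obs=d["n_obs"],
            n_events=d["n_events"],
        )


def build_design(
    cohort: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[str]], dict[str, list[str]]]:
    """Dummy-code a covariate list (first observed/declared level is the
    reference).  Returns (X, terms, variable_terms, categorical_levels)."""
    cols = []
    terms: list[str] = []
    variable_terms: dict[str, list[str]] = {}
    categorical_levels: dict[str, list[str]] = {}
    for var in covariates:
        s = cohort[var]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            cols.append(s.to_numpy(dtype=float))
            terms.append(var)
            variable_terms[var] = [var]
        else:
            if isinstance(s.dtype, pd.CategoricalDtype):
                levels = list(s.cat.categories)
            else:
                levels = list(pd.unique(s.astype(str)))
            categorical_levels[var] = [str(x) for x in levels]
            variable_terms[var] = []
            vals = s.astype(str).to_numpy()
            for lev in levels[1:]:
                name = f"{var}[{lev}]"
                cols.append((vals == str(lev)).astype(float))
                terms.append(name)
                variable_terms[var].append(name)
    X = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    return X, terms, variable_terms, categorical_levels


def encode_row(
    covariates: dict[str, float | str],
    variable_terms: dict[str, list[str]],
    categorical_levels: dict[str, list[str]],
    terms: list[str],
) -> np.ndarray:
    x = np.zeros(len(terms))
    for var, var_terms in variable_terms.items():
        if var not in covariates:
            raise ValueError(f"missing covariate '{var}'")
        val = covariates[var]
        if var in categorical_levels:
            levels = categorical_levels[var]
            sval = str(val)
            if sval not in levels:
                raise ValueError(
                    f"unseen level '{sval}' for '{var}' (known: {levels})"
                )
            for term in var_terms:
                lev = term[term.index("[") + 1 : -1]
                x[terms.index(term)] = 1.0 if sval == lev else 0.0
        else:
            x[terms.index(var)] = float(val)
    return x


def fit_fine_gray(
    cohort: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time_yr",
    event_col: str = "event",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> FineGrayModel:
    """Fit the Fine-Gray subdistribution-hazard model.

    Competing-event subjects stay in the risk set with IPCW weights from
    the censoring Kaplan-Meier (left limits, Breslow ties); Newton-Raphson
    to a gradient infinity-norm <= ``tol``; robust sandwich SEs; baseline
    cumulative subdistribution hazard by weighted Breslow.
    """
    X, terms, variable_terms, categorical_levels = build_design(
        cohort, covariates
    )
    time = cohort[time_col].to_numpy(dtype=float)
    event = cohort[event_col].to_numpy()
    if not (event == 1).any():
        raise ValueError("no cause-1 events; cannot fit")
    # collinearity guard
    if X.shape[1] > 0:
        sd = X.std(axis=0)
        if (sd == 0).any():
            bad = [terms[j] for j in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant design columns: {bad}")
        cond = np.linalg.cond(X - X.mean(axis=0))
        if cond > 1e8:
            raise ValueError(
                f"design matrix ill-conditioned (condition number {cond:.3g})"
            )

    data = _FGData(time, event, X)
    beta = np.zeros(X.shape[1])
    trace = []
    ll, U, info = data.loglik_score_info(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}")
        # step halving to keep the partial likelihood increasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, U_new, info_new = data.loglik_score_info(cand)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, ll, U, info = cand, ll_new, U_new, info_new
        trace.append((it, ll, float(np.abs(U).max())))
        if np.abs(beta).max() > 15.0:
            raise ConvergenceError(
                "separation detected (|beta| > 15); trace: " + repr(trace)
            )
        if np.abs(U).max() <= tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations; "
            "trace: " + repr(trace)
        )

    info_inv = np.linalg.inv(info)
    resid = data.score_residuals(beta)
    meat = resid.T @ resid
    cov = info_inv @ meat @ info_inv
    se = np.sqrt(np.diag(cov))
    bt, bh = data.baseline_cumhaz(beta)
    return FineGrayModel(
        terms=terms,
        beta=beta,
        se=se,
        cov=cov,
        loglik=ll,
        n_iter=it,
        baseline_times=bt,
        baseline_cumhaz=bh,
        variable_terms=variable_terms,
        categorical_levels=categorical_levels,
        n_obs=len(cohort),
        n_events=int((event == 1).sum()),
    )


def predict_cif(
    model: FineGrayModel, covariates: dict[str, float | str], t: float
) -> float:
    """Predicted cause-1 CIF: F1(t|x) = 1 - exp(-Lambda10(t) * exp(x'beta))."""
    lp = model.linear_predictor(covariates)
    return float(1.0 - np.exp(-model.cumhaz_at(t) * np.exp(lp)))


def predict_cif_from_lp(model: FineGrayModel, lp: float, t: float) -> float:
    return float(1.0 - np.exp(-model.cumhaz_at(t) * np.exp(lp)))


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

def univariate_screen(
    cohort: pd.DataFrame,
    candidates: list[str],
    alpha: float = 0.05,
    time_col: str = "time_yr",
    event_col: str = "event",
) -> pd.DataFrame:
    """One single-variable Fine-Gray fit per candidate; flag p < alpha.

    For categorical variables the variable-level p is the joint Wald test
    over its dummy terms.  Variables whose fit fails are excluded with a
    warning and an ``error`` note in the table.
    """
    import warnings

    rows = []
    for var in candidates:
        try:
            m = fit_fine_gray(cohort, [var], time_col=time_col,
                              event_col=event_col)
            if len(m.terms) == 1:
                p_var = float(m.wald_p()[0])
            else:
                p_var = m.overall_wald_p(var)
            ci = m.conf_int()
            for j, term in enumerate(m.terms):
                rows.append(
                    {
                        "variable": var,
                        "term": term,
                        "SHR": float(m.shr[j]),
                        "ci_low": float(ci[j, 0]),
                        "ci_high": float(ci[j, 1]),
                        "p_term": float(m.wald_p()[j]),
                        "p_variable": p_var,
                        "selected": bool(p_var < alpha),
                        "error": "",
                    }
                )
        except Exception as err:  # noqa: BLE001 - per-variable isolation
            warnings.warn(f"univariate fit failed for '{var}': {err}")
            rows.append(
                {
                    "variable": var,
                    "term": var,
                    "SHR": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_term": np.nan,
                    "p_variable": np.nan,
                    "selected": False,
                    "error": str(err),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nomogram
# ---------------------------------------------------------------------------

@dataclass
class Nomogram:
    """Point-based rendering of a Fine-Gray model at horizon ``t_star``.

    Each variable's contribution beta_j * x_j is mapped to a 0-100 point
    scale; the variable with the widest contribution range spans exactly
    0-100.  Total points map back to the linear predictor and then to the
    predicted cause-1 CIF at ``t_star``.
    """

    model: FineGrayModel
    t_star: float
    var_min: dict[str, float]
    var_range: dict[str, float]
    max_range: float
    continuous_ranges: dict[str, tuple[float, float]]

    def points(self, variable: str, value: float | str) -> float:
        contrib = self._contribution(variable, value)
        return 100.0 * (contrib - self.var_min[variable]) / self.max_range

    def _contribution(self, variable: str, value: float | str) -> float:
        vt = self.model.variable_terms[variable]
        if variable in self.model.categorical_levels:
            levels = self.model.categorical_levels[variable]
            sval = str(value)
            if sval not in levels:
                raise ValueError(f"unseen level '{sval}' for '{variable}'")
            contrib = 0.0
            for term in vt:
                lev = term[term.index("[") + 1 : -1]
                if sval == lev:
                    contrib = self.model.beta[self.model.terms.index(term)]
            return float(contrib)
        j = self.model.terms.index(variable)
        return float(self.model.beta[j] * float(value))

    def total_points(self, covariates: dict[str, float | str]) -> float:
        return float(
            sum(self.points(v, covariates[v]) for v in self.var_min)
        )

    def total_points_to_lp(self, total: float) -> float:
        return float(sum(self.var_min.values())
                     + total * self.max_range / 100.0)

    def predict(self, covariates: dict[str, float | str]) -> float:
        """Predicted cause-1 CIF at ``t_star`` via the point scale."""
        lp = self.total_points_to_lp(self.total_points(covariates))
        return predict_cif_from_lp(self.model, lp, self.t_star)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "t_star": self.t_star,
            "var_min": self.var_min,
            "var_range": self.var_range,
            "max_range": self.max_range,
            "continuous_ranges": {
                k: list(v) for k, v in self.continuous_ranges.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def build_nomogram(
    model: FineGrayModel,
    cohort: pd.DataFrame | None = None,
    t_star: float = 3.0,
    continuous_ranges: dict[str, tuple[float, float]] | None = None,
) -> Nomogram:
    """Build the point-scale nomogram for a fitted Fine-Gray model.

    Continuous variables need an observed range, taken from ``cohort``
    when given, else from ``continuous_ranges``.
    """
    continuous_ranges = dict(continuous_ranges or {})
    var_min: dict[str, float] = {}
    var_range: dict[str, float] = {}
    for var, vt in model.variable_terms.items():
        if var in model.categorical_levels:
            contribs = [0.0] + [
                float(model.beta[model.terms.index(t)]) for t in vt
            ]
        else:
            if var not in continuous_ranges:
                if cohort is None or var not in cohort.columns:
                    raise ValueError(
                        f"need an observed range for continuous '{var}'"
                    )
                continuous_ranges[var] = (
                    float(cohort[var].min()),
                    float(cohort[var].max()),
                )
            lo, hi = continuous_ranges[var]
            b = float(model.beta[model.terms.index(var)])
            contribs = [b * lo, b * hi]
        var_min[var] = min(contribs)
        var_range[var] = max(contribs) - min(contribs)
    max_range = max(var_range.values())
    if max_range <= 0:
        raise ValueError("all variables have zero contribution range")
    return Nomogram(
        model=model,
        t_star=t_star,
        var_min=var_min,
        var_range=var_range,
        max_range=max_range,
        continuous_ranges=continuous_ranges,
    )
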