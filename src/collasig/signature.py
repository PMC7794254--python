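"""Collagen-signature construction: cross-validated LASSO and cutoff search.

The signature is a sparse linear score over the 146 standardized collagen
features.  Features are selected by L1-penalized regression along a
decreasing lambda grid with stratified 5-fold cross-validation; the
penalty is chosen by the one-standard-error rule (the largest lambda whose
mean CV deviance is within one SE of the minimum), which favours the
sparser model.  The default outcome is binomial (event of interest within
the study horizon); a gaussian option exposes the plain LASSO for
continuous responses.

Patients are dichotomized at the cutoff that maximizes the Gray-type
statistic for the cause-1 cumulative-incidence difference over candidate
splits between the 10th and 90th signature percentiles — an in-repo
surrogate for outcome-driven cutpoint software.  Because the cutoff is
chosen to maximize a test statistic it is optimistic, and reports flag it
as such.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .competing import grays_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LassoConfig:
    n_folds: int = 5
    rule: str = "lambda_1se"  # or "lambda_min"
    lambda_grid: tuple[float, ...] | None = None  # strictly decreasing
    outcome: str = "binomial_3yr"  # or "gaussian"
    n_lambda: int = 40
    lambda_min_ratio: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.rule not in ("lambda_1se", "lambda_min"):
            raise ValueError(f"unknown rule '{self.rule}'")
        if self.outcome not in ("binomial_3yr", "gaussian"):
            raise ValueError(f"unknown outcome '{self.outcome}'")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if g.size < 2 or not np.all(np.diff(g) < 0):
                raise ValueError("lambda_grid must be strictly decreasing")


@dataclass
class SignatureModel:
    """Sparse linear signature over standardized collagen features."""

    feature_names: list[str]
    coefficients: np.ndarray  # on the standardized scale
    means: np.ndarray  # training means of the selected features
    sds: np.ndarray  # training SDs of the selected features
    cutoff: float | None = None
    cutoff_min_group_fraction: float = 0.10
    lambda_selected: float | None = None
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "coefficients": np.asarray(self.coefficients).tolist(),
            "means": np.asarray(self.means).tolist(),
            "sds": np.asarray(self.sds).tolist(),
            "cutoff": self.cutoff,
            "cutoff_min_group_fraction": self.cutoff_min_group_fraction,
            "lambda_selected": self.lambda_selected,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            coefficients=np.array(d["coefficients"]),
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            cutoff=d["cutoff"],
            cutoff_min_group_fraction=d["cutoff_min_group_fraction"],
            lambda_selected=d["lambda_selected"],
        )


def _fit_at_lambda(Xs, y, lam, outcome, n):
    if outcome == "gaussian":
        model = Lasso(alpha=lam, fit_intercept=True, max_iter=50_000,
                      tol=1e-10)
        model.fit(Xs, y)
        return model.coef_.copy(), float(model.intercept_)
    C = 1.0 / (n * lam)
    model = LogisticRegression(
        C=C, l1_ratio=1.0, solver="liblinear", max_iter=5000, tol=1e-7,
        random_state=0,
    )
    model.fit(Xs, y)
    return model.coef_.ravel().copy(), float(model.intercept_[0])


def _held_out_deviance(Xs, y, coef, intercept, outcome):
    eta = Xs @ coef + intercept
    if outcome == "gaussian":
        return float(np.mean((y - eta) ** 2))
    # binomial deviance per observation
    eta = np.clip(eta, -30, 30)
    ll = y * eta - np.log1p(np.exp(eta))
    return float(-2.0 * np.mean(ll))


def default_lambda_grid(
    Xs: np.ndarray, y: np.ndarray, cfg: LassoConfig
) -> np.ndarray:
    n = len(y)
    # glmnet-style: the smallest penalty that zeroes every coefficient
    resid = y - y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ resid)) / n)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio,
                        cfg.n_lambda)


def lasso_select(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    cfg: LassoConfig | None = None,
) -> SignatureModel:
    """Cross-validated LASSO feature selection.

    Standardizes features (population SD), runs the penalty path with
    k-fold CV (stratified for the binomial outcome), picks lambda by the
    configured rule, refits on the full data and returns the nonzero
    coefficients with the training standardization constants.

    Constant feature columns are dropped with a logged warning; an
    all-constant matrix is an error.
    """
    cfg = cfg or LassoConfig()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"f{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    if np.isnan(Xa).any() or np.isnan(y).any():
        raise ValueError("missing values in X or y")
    n = len(y)
    if n < cfg.n_folds:
        raise ValueError("need at least n_folds observations")

    sds_all = Xa.std(axis=0)
    keep = sds_all > 0
    if not keep.any():
        raise ValueError("all feature columns are constant")
    if not keep.all():
        dropped = [names[j] for j in np.flatnonzero(~keep)]
        logger.warning("dropping constant feature columns: %s", dropped)
    Xa = Xa[:, keep]
    names = [nm for nm, k in zip(names, keep) if k]

    means = Xa.mean(axis=0)
    sds = Xa.std(axis=0)
    Xs = (Xa - means) / sds

    if cfg.lambda_grid is not None:
        grid = np.asarray(cfg.lambda_grid, dtype=float)
    else:
        grid = default_lambda_grid(Xs, y, cfg)

    if cfg.outcome == "gaussian":
        splitter = KFold(cfg.n_folds, shuffle=True, random_state=cfg.seed)
        splits = list(splitter.split(Xs))
    else:
        splitter = StratifiedKFold(cfg.n_folds, shuffle=True,
                                   random_state=cfg.seed)
        splits = list(splitter.split(Xs, y.astype(int)))

    dev = np.zeros((len(grid), cfg.n_folds))
    for f, (tr, te) in enumerate(splits):
        mu = Xa[tr].mean(axis=0)
        sd = Xa[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xa[tr] - mu) / sd
        Xte = (Xa[te] - mu) / sd
        for li, lam in enumerate(grid):
            coef, icpt = _fit_at_lambda(Xtr, y[tr], lam, cfg.outcome, len(tr))
            dev[li, f] = _held_out_deviance(Xte, y[te], coef, icpt,
                                            cfg.outcome)
    cv_mean = dev.mean(axis=1)
    cv_se = dev.std(axis=1, ddof=1) / np.sqrt(cfg.n_folds)
    i_min = int(np.argmin(cv_mean))
    if cfg.rule == "lambda_min":
        i_sel = i_min
    else:
        threshold = cv_mean[i_min] + cv_se[i_min]
        admissible = np.flatnonzero(cv_mean <= threshold)
        i_sel = int(admissible.min())  # grid is decreasing: largest lambda
    lam_sel = float(grid[i_sel])

    coef, _ = _fit_at_lambda(Xs, y, lam_sel, cfg.outcome, n)
    nz = np.flatnonzero(np.abs(coef) > 1e-10)
    cv_table = pd.DataFrame(
        {"lambda": grid, "cv_deviance": cv_mean, "cv_se": cv_se}
    )
    return SignatureModel(
        feature_names=[names[j] for j in nz],
        coefficients=coef[nz],
        means=means[nz],
        sds=sds[nz],
        lambda_selected=lam_sel,
        cv_table=cv_table,
    )


def compute_signature(
    features: pd.Series | pd.DataFrame, model: SignatureModel
) -> float | np.ndarray:
    """Signature score: sum_j beta_j (v_j - mean_j) / sd_j (no intercept)."""
    if isinstance(features, pd.DataFrame):
        missing = [f for f in model.feature_names
                   if f not in features.columns]
        if missing:
            raise ValueError(f"missing selected features: {missing}")
        V = features[model.feature_names].to_numpy(dtype=float)
        return (V - model.means) / model.sds @ model.coefficients
    missing = [f for f in model.feature_names if f not in features.index]
    if missing:
        raise ValueError(f"missing selected features: {missing}")
    v = features[model.feature_names].to_numpy(dtype=float)
    return float((v - model.means) / model.sds @ model.coefficients)


def optimal_cutoff(
    signature: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    min_group_fraction: float = 0.10,
) -> float:
    """Outcome-driven dichotomization cutoff for the signature.

    Scans candidate splits at observed signature values between the 10th
    and 90th percentiles, requires each side to hold at least
    ``min_group_fraction`` of patients, and returns the split (reported as the midpoint between the two flanking
    observed values) maximizing the Gray-type statistic for the cause-1
    CIF difference.  Deterministic given the data (ties broken toward the
    lowest cutoff).
    """
    signature = np.asarray(signature, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = len(signature)
    if n < 20:
        raise ValueError("need at least 20 patients for the cutoff search")
    lo, hi = np.percentile(signature, [10, 90])
    values = np.unique(signature)
    candidates = values[(values >= lo) & (values <= hi)]
    best_stat = -np.inf
    best_cut = None
    if (event == 1).sum() == 0:
        raise ValueError("no cause-1 events; cutoff search undefined")
    for c in candidates:
        high = signature > c
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_group_fraction * n:
            continue
        try:
            stat, _, _ = grays_test(time, event, high.astype(int))
        except ValueError:
            continue
        if stat > best_stat + 1e-12:
            best_stat = stat
            best_cut = c
    if best_cut is None:
        raise ValueError("no admissible cutoff candidate")
    above = values[values > best_cut]
    if above.size:
        return float(0.5 * (best_cut + above.min()))
    return float(best_cut)
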