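"""Simulated cohorts from a Fine-Gray subdistribution-hazard model.

Event-of-interest (cause 1, e.g. peritoneal metastasis) times follow a
proportional subdistribution-hazards model built on a unit-exponential
mixture: the lifetime cause-1 probability given covariates x is

    P(cause 1 | x) = 1 - (1 - p_base)^exp(x'b),

and, conditional on cause 1, event times are drawn from the subdistribution

    F1(t | x) = 1 - [1 - p_base (1 - e^{-t})]^{exp(x'b)},

so the true subdistribution log-hazard ratios equal ``beta_true`` exactly
and fitted coefficients are directly comparable to them.  Competing-event
(cause 2) times are exponential, censoring is independent exponential plus
administrative censoring at the study horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the competing-risks cohort generator.

    Times are in years.  ``p_base`` is the lifetime (uncensored) cause-1
    probability at covariates x = 0; ``competing_rate`` and ``censor_rate``
    are exponential rates per year.
    """

    n_patients: int = 200
    beta_true: tuple[float, ...] = (0.9,)
    p_base: float = 0.35
    competing_rate: float = 0.10
    censor_rate: float = 0.15
    horizon_yr: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not (0.0 < self.p_base < 1.0):
            raise ValueError("p_base must be in (0, 1)")
        if not (self.competing_rate > 0):
            raise ValueError("competing_rate must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if not (self.horizon_yr > 0):
            raise ValueError("horizon_yr must be positive")


def cause1_probability(lp: np.ndarray, p_base: float) -> np.ndarray:
    """Lifetime cause-1 probability 1 - (1 - p_base)^exp(lp)."""
    return 1.0 - (1.0 - p_base) ** np.exp(lp)


def true_cif1(t: np.ndarray | float, lp: float, p_base: float) -> np.ndarray:
    """True cause-1 CIF of the generator at linear predictor ``lp``."""
    t = np.asarray(t, dtype=float)
    return 1.0 - (1.0 - p_base * (1.0 - np.exp(-t))) ** np.exp(lp)


def generate_cohort(
    params: CohortParams,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a cohort from the Fine-Gray generator.

    Parameters
    ----------
    params
        Generator parameters; ``len(params.beta_true)`` must equal the
        number of covariate columns.
    covariates
        Optional design matrix (n_patients × k).  When omitted, covariates
        are i.i.d. standard normal named ``x1..xk``.

    Returns
    -------
    DataFrame with columns ``patient_id``, covariates, ``time_yr``,
    ``event`` (0 censored / 1 cause of interest / 2 competing) and
    ``true_lp`` (the linear predictor x'beta, for oracle tests).
    """
    rng = np.random.default_rng(params.seed)
    beta = np.asarray(params.beta_true, dtype=float)
    n = params.n_patients

    if covariates is None:
        X = rng.standard_normal((n, beta.size))
        names = [f"x{j + 1}" for j in range(beta.size)]
        cov_df = pd.DataFrame(X, columns=names)
    else:
        cov_df = pd.DataFrame(covariates).reset_index(drop=True)
        if len(cov_df) != n:
            raise ValueError(
                f"covariates have {len(cov_df)} rows, expected {n}"
            )
        X = cov_df.to_numpy(dtype=float)
    if X.shape[1] != beta.size:
        raise ValueError(
            f"beta_true has length {beta.size} but covariates have "
            f"{X.shape[1]} columns"
        )

    lp = X @ beta
    eta = np.exp(lp)
    p1 = cause1_probability(lp, params.p_base)

    is_cause1 = rng.uniform(size=n) < p1

    # Conditional cause-1 time: invert F1(t|x)/p1(x) at a uniform draw.
    v = rng.uniform(size=n)
    inner = 1.0 - (1.0 - v * p1) ** (1.0 / eta)
    t1 = -np.log1p(-(inner / params.p_base))

    t2 = rng.exponential(1.0 / params.competing_rate, size=n)
    latent_time = np.where(is_cause1, t1, t2)
    latent_cause = np.where(is_cause1, 1, 2)

    if params.censor_rate > 0:
        c = rng.exponential(1.0 / params.censor_rate, size=n)
    else:
        c = np.full(n, np.inf)
    c = np.minimum(c, params.horizon_yr)

    observed = latent_time <= c
    time = np.where(observed, latent_time, c)
    event = np.where(observed, latent_cause, 0)

    out = pd.DataFrame({"patient_id": np.arange(1, n + 1)})
    out = pd.concat([out, cov_df], axis=1)
    out["time_yr"] = np.maximum(time, 1e-9)
    out["event"] = event.astype(int)
    out["true_lp"] = lp
    return out


COHORT_SCHEMA_NOTE = (
    "cohort CSV columns: patient_id, <covariates...>, time_yr, "
    "event (0/1/2), true_lp"
)


def validate_cohort(df: pd.DataFrame, covariate_cols: list[str] | None = None
                    ) -> None:
    """Raise ValueError on schema violations (bad event codes, times <= 0)."""
    for col in ("time_yr", "event"):
        if col not in df.columns:
            raise ValueError(f"cohort table missing required column '{col}'")
    ev = df["event"].to_numpy()
    if not np.isin(ev, (0, 1, 2)).all():
        bad = sorted(set(ev) - {0, 1, 2})
        raise ValueError(f"invalid event codes {bad}; expected 0, 1 or 2")
    if (df["time_yr"].to_numpy() <= 0).any():
        raise ValueError("follow-up times must be positive")
    if covariate_cols is not None:
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing covariates {missing}")
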