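"""Discrimination, calibration, decision-curve and classification metrics."""

import numpy as np
import pandas as pd
import pytest

from collasig.cohorts import CohortParams, generate_cohort, true_cif1
from collasig.evaluation import (
    averaged_c_index,
    binary_status_at,
    calibration_curve,
    classification_report,
    decision_curve,
    delong_compare,
    report_from_counts,
    survival_support,
    time_dependent_roc,
)


# ------------------------------------------------------------ C-index

def test_c_index_equals_brute_force_without_censoring():
    rng = np.random.default_rng(0)
    n = 20
    risk = rng.standard_normal(n)
    time = rng.uniform(0.1, 3.0, n)
    event = np.ones(n, dtype=int)
    tau = 3.0
    c, _ = averaged_c_index(risk, time, event, grid=np.array([tau]),
                            n_boot=0)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j or not (event[i] == 1 and time[i] <= tau):
                continue
            if time[j] > time[i]:
                den += 1
                num += (risk[i] > risk[j]) + 0.5 * (risk[i] == risk[j])
    assert c == pytest.approx(num / den, abs=1e-12)


def test_c_index_near_one_for_noise_free_ordering():
    """Event times a deterministic decreasing function of risk: the risk
    ranking is perfect up to independent censoring."""
    rng = np.random.default_rng(3)
    n = 1500
    risk = rng.standard_normal(n)
    t_event = 3.5 * np.exp(-risk)  # strictly decreasing in risk
    censor = rng.exponential(8.0, n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    c, _ = averaged_c_index(risk, time, event, n_boot=0)
    assert c >= 0.95


def test_c_index_null_near_half():
    df = generate_cohort(CohortParams(n_patients=2000, beta_true=(0.0,),
                                      seed=4))
    rng = np.random.default_rng(5)
    c, _ = averaged_c_index(
        rng.standard_normal(2000), df["time_yr"].to_numpy(),
        df["event"].to_numpy(), n_boot=0,
    )
    assert 0.47 <= c <= 0.53


# ------------------------------------------------------------ ROC

def test_roc_perfect_separation():
    time = np.array([0.5] * 20 + [4.0] * 30)
    event = np.array([1] * 20 + [0] * 30)
    risk = np.array([2.0] * 20 + [1.0] * 30)
    roc = time_dependent_roc(risk, time, event, t_star=3.0)
    assert roc.auroc == pytest.approx(1.0)


def test_roc_equals_mann_whitney_without_censoring():
    rng = np.random.default_rng(6)
    n = 150
    risk = rng.standard_normal(n)
    time = rng.uniform(0.1, 6.0, n)
    event = np.where(time <= 5.9, 1, 1)  # all events observed
    roc = time_dependent_roc(risk, time, event, t_star=3.0)
    labels, _ = binary_status_at(time, event, 3.0)
    from scipy.stats import mannwhitneyu

    u = mannwhitneyu(risk[labels == 1], risk[labels == 0]).statistic
    auc_u = u / ((labels == 1).sum() * (labels == 0).sum())
    assert roc.auroc == pytest.approx(auc_u, abs=1e-12)


def test_roc_competing_events_are_controls():
    time = np.array([1.0, 1.5, 2.0, 4.0, 5.0, 2.5])
    event = np.array([1, 2, 1, 0, 0, 2])
    risk = np.array([5.0, 1.0, 4.0, 2.0, 1.5, 0.5])
    roc = time_dependent_roc(risk, time, event, t_star=3.0)
    assert roc.n_cases == 2 and roc.n_controls == 4


def test_roc_permutation_null_centers_at_half():
    rng = np.random.default_rng(7)
    df = generate_cohort(CohortParams(n_patients=400, beta_true=(0.0,),
                                      seed=8))
    time = df["time_yr"].to_numpy()
    event = df["event"].to_numpy()
    risk = rng.standard_normal(400)
    aucs = []
    for _ in range(300):
        aucs.append(
            time_dependent_roc(rng.permutation(risk), time, event).auroc
        )
    assert abs(np.mean(aucs) - 0.5) < 0.02


# ------------------------------------------------------------ DeLong

def test_delong_identical_risks():
    rng = np.random.default_rng(9)
    risk = rng.standard_normal(100)
    labels = (rng.uniform(size=100) < 0.4).astype(int)
    d, p = delong_compare(risk, risk, labels)
    assert d == 0.0 and p == 1.0


def test_delong_rank_invariance():
    rng = np.random.default_rng(10)
    risk = rng.standard_normal(100)
    labels = (rng.uniform(size=100) < 0.4).astype(int)
    d, p = delong_compare(risk, np.exp(2.0 * risk) + 5.0, labels)
    assert d == pytest.approx(0.0, abs=1e-12)
    assert p == 1.0


def test_delong_variance_close_to_bootstrap():
    rng = np.random.default_rng(11)
    n = 200
    labels = (rng.uniform(size=n) < 0.45).astype(int)
    risk = labels * 1.0 + rng.standard_normal(n)
    from collasig.evaluation import _delong_auc_variance

    auc, var = _delong_auc_variance(risk, labels)
    boots = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        if len(np.unique(labels[idx])) < 2:
            continue
        a, _ = _delong_auc_variance(risk[idx], labels[idx])
        boots.append(a)
    ratio = var / np.var(boots)
    assert 0.8 <= ratio <= 1.2


# ------------------------------------------------------------ calibration

def test_calibration_well_calibrated_simulation():
    params = CohortParams(n_patients=5000, beta_true=(0.8,), p_base=0.3,
                          censor_rate=0.1, seed=12)
    df = generate_cohort(params)
    pred = np.array([
        float(true_cif1(3.0, lp, 0.3)) for lp in df["true_lp"]
    ])
    tab = calibration_curve(pred, df["time_yr"], df["event"], t_star=3.0,
                            n_bins=5)
    assert tab["n"].sum() == 5000
    assert np.max(np.abs(tab["predicted_mean"] - tab["observed_cif"])) <= 0.05


def test_calibration_constant_predictions_single_bin():
    df = generate_cohort(CohortParams(n_patients=500, seed=13))
    with pytest.warns(UserWarning):
        tab = calibration_curve(np.full(500, 0.3), df["time_yr"],
                                df["event"], n_bins=5)
    assert len(tab) == 1
    from collasig.competing import cif_aalen_johansen

    overall = cif_aalen_johansen(df["time_yr"], df["event"]).at(3.0, 1)
    assert tab["observed_cif"].iloc[0] == pytest.approx(overall)


def test_calibration_requires_three_bins():
    with pytest.raises(ValueError):
        calibration_curve(np.zeros(10), np.ones(10), np.ones(10, int),
                          n_bins=2)


# ------------------------------------------------------------ decision curve

def test_decision_curve_hand_example():
    """TP=30, FP=10, n=100 at P_t=0.25: NB = 0.30 - 0.10*(0.25/0.75)."""
    pred = np.zeros(100)
    outcome = np.zeros(100, dtype=int)
    pred[:40] = 0.9  # treated
    outcome[:30] = 1  # 30 TP among treated
    outcome[95:] = 1  # 5 positives untreated (prevalence 35%)
    dc = decision_curve(pred, outcome, thresholds=np.array([0.25]))
    assert dc["net_benefit"].iloc[0] == pytest.approx(
        0.30 - 0.10 * (0.25 / 0.75), abs=1e-12
    )
    assert dc["treat_none"].iloc[0] == 0.0


def test_decision_curve_treat_all_limit():
    rng = np.random.default_rng(14)
    outcome = (rng.uniform(size=500) < 0.3).astype(int)
    pred = rng.uniform(size=500)
    dc = decision_curve(pred, outcome,
                        thresholds=np.array([0.001, 0.5, 1.0]))
    # P_t = 1 excluded
    assert len(dc) == 2
    prev = outcome.mean()
    assert dc["treat_all"].iloc[0] == pytest.approx(
        prev - (1 - prev) * 0.001 / 0.999
    )
    assert abs(dc["treat_all"].iloc[0] - prev) < 0.002
    # model never beats the perfect classifier (NB = prevalence)
    assert (dc["net_benefit"] <= prev + 1e-12).all()


# ------------------------------------------------------------ classification

def test_classification_reconstructed_training_counts():
    """Counts TP=65 FN=14 TN=98 FP=21 reproduce the published-style rates."""
    rep = report_from_counts(tp=65, fp=21, tn=98, fn=14)
    assert rep.sensitivity == pytest.approx(0.823, abs=5e-4)
    assert rep.specificity == pytest.approx(0.824, abs=5e-4)
    assert rep.accuracy == pytest.approx(0.823, abs=5e-4)
    assert rep.ppv == pytest.approx(0.756, abs=5e-4)
    assert rep.npv == pytest.approx(0.875, abs=5e-4)
    assert rep.youden == pytest.approx(rep.sensitivity + rep.specificity - 1)


def test_classification_perfect():
    risk = np.array([0.9] * 5 + [0.1] * 5)
    labels = np.array([1] * 5 + [0] * 5)
    rep = classification_report(risk, labels)
    assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0
    assert rep.youden == 1.0


def test_classification_label_swap_symmetry():
    rng = np.random.default_rng(15)
    risk = rng.uniform(size=80)
    labels = (rng.uniform(size=80) < 0.5).astype(int)
    cut = 0.5
    rep = classification_report(risk, labels, cutoff=cut)
    # swapping labels and negating risk swaps the roles
    rep_sw = classification_report(-risk, 1 - labels, cutoff=-cut + 1e-12)
    assert rep_sw.sensitivity == pytest.approx(rep.specificity, abs=0.05)
    assert rep_sw.ppv == pytest.approx(rep.npv, abs=0.05)


def test_classification_single_class_raises():
    with pytest.raises(ValueError):
        classification_report(np.arange(5.0), np.ones(5, int))


def test_classification_rates_reproduce_from_counts():
    rng = np.random.default_rng(16)
    risk = rng.uniform(size=120)
    labels = (rng.uniform(size=120) < risk).astype(int)
    rep = classification_report(risk, labels)
    assert rep.tp + rep.fp + rep.tn + rep.fn == 120
    assert rep.sensitivity == rep.tp / (rep.tp + rep.fn)
    assert rep.accuracy == (rep.tp + rep.tn) / 120


# ------------------------------------------------------------ KM / Cox

def test_km_matches_empirical_without_censoring():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    out = survival_support(t, np.ones(5, int))
    km = out["km"]["all"]
    # S(2) = 3/5 etc.
    s_at_2 = km.loc[km["time"] == 2.0, "survival"].iloc[0]
    assert s_at_2 == pytest.approx(3 / 5)


def test_logrank_identical_groups_zero():
    t = np.tile([1.0, 2.0, 3.0, 4.0], 2)
    e = np.tile([1, 0, 1, 1], 2)
    g = np.repeat([0, 1], 4)
    out = survival_support(t, e, group=g)
    assert out["logrank"][0] == pytest.approx(0.0, abs=1e-12)


def test_cox_recovers_true_hazard_ratio():
    rng = np.random.default_rng(17)
    n = 2000
    x = (rng.uniform(size=n) < 0.5).astype(float)
    t = rng.exponential(1.0 / np.exp(np.log(2.0) * x))
    c = rng.exponential(2.0, n)
    obs = np.minimum(t, c)
    e = (t <= c).astype(int)
    out = survival_support(obs, e, covariates=pd.DataFrame({"x": x}))
    hr = out["cox"]["HR"].iloc[0]
    assert 1.85 <= hr <= 2.15


def test_no_events_raises():
    with pytest.raises(ValueError):
        survival_support(np.ones(4), np.zeros(4, int),
                         group=np.array([0, 0, 1, 1]))
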