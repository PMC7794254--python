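"""Competing-risks stack: Aalen-Johansen, Gray-type test, Fine-Gray fit,
prediction, screening and nomogram."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from collasig.cohorts import CohortParams, generate_cohort
from collasig.competing import (
    ConvergenceError,
    build_nomogram,
    cif_aalen_johansen,
    censoring_survival,
    fit_fine_gray,
    grays_test,
    predict_cif,
    univariate_screen,
)


# ------------------------------------------------------------ Aalen-Johansen

def test_cif_golden_hand_values():
    """times (1,2,3,4), events (1,2,1,0): hand Aalen-Johansen."""
    est = cif_aalen_johansen([1, 2, 3, 4], [1, 2, 1, 0])
    assert est.at(1, 1) == pytest.approx(1 / 4)
    assert est.at(2, 2) == pytest.approx((3 / 4) * (1 / 3))
    assert est.at(3, 1) == pytest.approx(1 / 4 + (1 / 2) * (1 / 2))
    # survival after t=3 is 1 - 1/2 - 1/4 = 1/4
    assert est.surv[-1] == pytest.approx(1 / 4)


def test_cif_reduces_to_km_without_competing_events():
    rng = np.random.default_rng(0)
    t = rng.exponential(1.0, 300)
    e = (rng.uniform(size=300) < 0.7).astype(int)
    est = cif_aalen_johansen(t, e)
    assert np.allclose(est.cif[1], 1.0 - est.surv, atol=1e-12)
    assert np.all(est.cif[2] == 0)


def test_cif_additivity_and_monotonicity(medium_cohort):
    _, df = medium_cohort
    est = cif_aalen_johansen(df["time_yr"], df["event"])
    total = est.cif[1] + est.cif[2] + est.surv
    assert np.allclose(total, 1.0, atol=1e-9)
    assert np.all(np.diff(est.cif[1]) >= -1e-12)
    assert np.all(np.diff(est.cif[2]) >= -1e-12)
    assert est.at(-1.0, 1) == 0.0


def test_cif_all_censored_warns_and_is_zero():
    with pytest.warns(UserWarning, match="censored"):
        est = cif_aalen_johansen([1.0, 2.0, 3.0], [0, 0, 0])
    assert np.all(est.cif[1] == 0)


def test_cif_matches_lifelines_point_estimates(medium_cohort):
    """Dual route: same estimates as lifelines' Aalen-Johansen fitter."""
    from lifelines import AalenJohansenFitter

    _, df = medium_cohort
    ajf = AalenJohansenFitter(calculate_variance=False, seed=0)
    ajf.fit(df["time_yr"], df["event"], event_of_interest=1)
    est = cif_aalen_johansen(df["time_yr"], df["event"])
    for t in (0.5, 1.0, 2.0, 3.0):
        ours = est.at(t, 1)
        theirs = float(
            ajf.cumulative_density_.loc[: t + 1e-12].iloc[-1, 0]
        )
        assert ours == pytest.approx(theirs, abs=1e-6)


# ------------------------------------------------------------ Gray-type test

def test_grays_reduces_to_logrank_without_competing_events():
    rng = np.random.default_rng(1)
    n = 300
    group = (rng.uniform(size=n) < 0.5).astype(int)
    t = rng.exponential(np.where(group, 0.7, 1.0))
    e = (rng.uniform(size=n) < 0.8).astype(int)
    stat, df, p = grays_test(t, e, group)
    assert df == 1

    from lifelines.statistics import logrank_test

    res = logrank_test(t[group == 0], t[group == 1],
                       e[group == 0], e[group == 1])
    assert stat == pytest.approx(res.test_statistic, abs=1e-6)


def test_grays_identical_groups_zero():
    t = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
    e = np.array([1, 0, 2, 1, 1, 0, 2, 1])
    g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    stat, _, p = grays_test(t, e, g)
    assert stat == pytest.approx(0.0, abs=1e-12)


def test_grays_rejects_single_group():
    with pytest.raises(ValueError):
        grays_test([1, 2], [1, 1], [0, 0])


def test_grays_null_pvalues_uniform():
    """Permuting group labels on a no-effect cohort gives uniform p."""
    df = generate_cohort(
        CohortParams(n_patients=150, beta_true=(0.0,), seed=5)
    )
    t = df["time_yr"].to_numpy()
    e = df["event"].to_numpy()
    rng = np.random.default_rng(6)
    base_group = (np.arange(150) < 75).astype(int)
    ps = []
    for _ in range(400):
        g = rng.permutation(base_group)
        ps.append(grays_test(t, e, g)[2])
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


# ------------------------------------------------------------ Fine-Gray fit

def test_fine_gray_reduces_to_cox_without_competing_or_censoring():
    rng = np.random.default_rng(2)
    n = 400
    x = rng.standard_normal(n)
    t = rng.exponential(np.exp(-0.8 * x))
    df = pd.DataFrame({"x": x, "time_yr": t, "event": 1})
    m = fit_fine_gray(df, ["x"])

    from lifelines import CoxPHFitter

    cph = CoxPHFitter()
    cph.fit(df.rename(columns={"time_yr": "T", "event": "E"})[["x", "T", "E"]],
            duration_col="T", event_col="E",
            fit_options={"precision": 1e-10})
    assert m.beta[0] == pytest.approx(cph.params_["x"], abs=1e-6)


def test_fine_gray_matches_brute_force_likelihood():
    """n=30, one binary covariate: beta-hat equals the grid argmax of the
    IPCW-weighted partial likelihood."""
    df = generate_cohort(
        CohortParams(n_patients=30, beta_true=(0.8,), seed=9)
    )
    df["xbin"] = (df["x1"] > 0).astype(float)
    m = fit_fine_gray(df, ["xbin"])

    t = df["time_yr"].to_numpy()
    e = df["event"].to_numpy()
    x = df["xbin"].to_numpy()
    G = censoring_survival(t, e)

    def loglik(beta):
        ll = 0.0
        for i in np.flatnonzero(e == 1):
            ti = t[i]
            num = beta * x[i]
            conventional = t >= ti
            comp = (e == 2) & (t < ti)
            w = conventional.astype(float) + np.where(
                comp,
                float(G.left_limit(ti)) /
                np.asarray(G.left_limit(t), dtype=float),
                0.0,
            ) * comp
            ll += num - np.log(np.sum(w * np.exp(beta * x)))
        return ll

    grid = np.arange(-2.0, 3.0, 1e-3)
    lls = [loglik(b) for b in grid]
    best = grid[int(np.argmax(lls))]
    assert m.beta[0] == pytest.approx(best, abs=1e-3)


def test_fine_gray_matches_r_cmprsk(medium_cohort, tmp_path):
    """Independent oracle: coefficients of cmprsk::crr on the same data."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    _, df = medium_cohort
    csv = tmp_path / "cohort.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "crr.R"
    script.write_text(
        "suppressMessages(library(cmprsk))\n"
        f"d <- read.csv('{csv}')\n"
        "f <- crr(d$time_yr, d$event, cbind(d$x1, d$x2),"
        " failcode=1, cencode=0)\n"
        "cat(sprintf('%.10f %.10f\\n', f$coef[1], f$coef[2]))\n"
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    b1, b2 = map(float, out.stdout.split())
    m = fit_fine_gray(df, ["x1", "x2"])
    assert m.beta[0] == pytest.approx(b1, abs=1e-4)
    assert m.beta[1] == pytest.approx(b2, abs=1e-4)


def test_fine_gray_separation_raises():
    # covariate perfectly separates early events from the rest
    t = np.concatenate([np.linspace(0.1, 0.5, 10),
                        np.linspace(2.0, 3.0, 10)])
    e = np.array([1] * 10 + [0] * 10)
    x = np.array([1.0] * 10 + [0.0] * 10)
    df = pd.DataFrame({"x": x, "time_yr": t, "event": e})
    with pytest.raises((ConvergenceError, ValueError)):
        fit_fine_gray(df, ["x"])


def test_fine_gray_shr_ci_reproduces_from_beta_se(medium_cohort):
    _, df = medium_cohort
    m = fit_fine_gray(df, ["x1", "x2"])
    z = stats.norm.ppf(0.975)
    ci = m.conf_int()
    assert np.allclose(ci[:, 0], np.exp(m.beta - z * m.se), atol=1e-12)
    assert np.allclose(ci[:, 1], np.exp(m.beta + z * m.se), atol=1e-12)
    assert np.all((ci[:, 0] < m.shr) & (m.shr < ci[:, 1]))


@pytest.mark.parametrize("n", [250, 1000, 4000])
def test_fine_gray_bias_shrinks_with_n(n):
    """Parameter recovery: absolute bias decreases with sample size."""
    est = []
    for r in range(8):
        df = generate_cohort(
            CohortParams(n_patients=n, beta_true=(0.7,), p_base=0.35,
                         competing_rate=0.25, censor_rate=0.2,
                         horizon_yr=5.0, seed=300 + r)
        )
        est.append(fit_fine_gray(df, ["x1"]).beta[0])
    bias = abs(np.mean(est) - 0.7)
    assert bias < max(0.12, 2.0 / np.sqrt(n))


# ------------------------------------------------------------ prediction

def test_predict_cif_baseline_and_closed_form(medium_cohort):
    _, df = medium_cohort
    m = fit_fine_gray(df, ["x1", "x2"])
    t = 2.0
    base = predict_cif(m, {"x1": 0.0, "x2": 0.0}, t)
    assert base == pytest.approx(1.0 - np.exp(-m.cumhaz_at(t)))
    x = {"x1": 1.3, "x2": -0.4}
    lp = 1.3 * m.beta[0] - 0.4 * m.beta[1]
    assert predict_cif(m, x, t) == pytest.approx(
        1.0 - np.exp(-m.cumhaz_at(t) * np.exp(lp)), abs=1e-12
    )
    # monotone in t
    preds = [predict_cif(m, x, s) for s in (0.5, 1.0, 2.0, 3.0, 4.0)]
    assert np.all(np.diff(preds) >= 0)


def test_predict_cif_unseen_level_raises():
    df = generate_cohort(CohortParams(n_patients=200, seed=1))
    df["grp"] = pd.Categorical(
        np.where(df["x1"] > 0, "a", "b"), categories=["a", "b"]
    )
    m = fit_fine_gray(df, ["grp"])
    with pytest.raises(ValueError, match="unseen level"):
        predict_cif(m, {"grp": "c"}, 1.0)


# ------------------------------------------------------------ screening

def test_univariate_screen_deterministic_and_flags(medium_cohort):
    _, df = medium_cohort
    t1 = univariate_screen(df, ["x1", "x2"])
    t2 = univariate_screen(df, ["x1", "x2"])
    pd.testing.assert_frame_equal(t1, t2)
    assert t1.loc[t1["variable"] == "x1", "selected"].all()
    assert t1.loc[t1["variable"] == "x2", "selected"].all()


def test_univariate_screen_null_variable_rarely_selected():
    """A no-effect covariate is selected at about the nominal 5% rate."""
    hits = 0
    reps = 120
    for r in range(reps):
        df = generate_cohort(
            CohortParams(n_patients=300, beta_true=(0.0,), seed=900 + r)
        )
        tab = univariate_screen(df, ["x1"])
        hits += bool(tab["selected"].iloc[0])
    rate = hits / reps
    assert 0.01 <= rate <= 0.11


def test_univariate_screen_power_for_strong_effect():
    hits = 0
    for r in range(20):
        df = generate_cohort(
            CohortParams(n_patients=500, beta_true=(float(np.log(2.5)),),
                         seed=1500 + r)
        )
        tab = univariate_screen(df, ["x1"])
        hits += bool(tab["selected"].iloc[0])
    assert hits >= 19


# ------------------------------------------------------------ nomogram

@pytest.fixture(scope="module")
def nomogram_setup():
    rng = np.random.default_rng(3)
    df = generate_cohort(
        CohortParams(n_patients=600, beta_true=(0.8, 0.6), seed=21)
    )
    df["grp"] = pd.Categorical(
        np.where(rng.uniform(size=600) < 0.5, "ref", "alt"),
        categories=["ref", "alt"],
    )
    m = fit_fine_gray(df, ["x1", "grp"])
    nom = build_nomogram(m, cohort=df, t_star=3.0)
    return df, m, nom


def test_nomogram_widest_variable_spans_100(nomogram_setup):
    df, m, nom = nomogram_setup
    widest = max(nom.var_range, key=nom.var_range.get)
    assert nom.var_range[widest] == pytest.approx(nom.max_range)
    if widest == "x1":
        b = m.beta[m.terms.index("x1")]
        extreme = float(df["x1"].max() if b > 0 else df["x1"].min())
        assert nom.points("x1", extreme) == pytest.approx(100.0)


def test_nomogram_minimum_contribution_is_zero_points(nomogram_setup):
    df, m, nom = nomogram_setup
    b = m.beta[m.terms.index("x1")]
    x_min = float(df["x1"].min() if b > 0 else df["x1"].max())
    assert nom.points("x1", x_min) == pytest.approx(0.0)
    ref_level = "ref" if m.beta[m.terms.index("grp[alt]")] > 0 else "alt"
    assert nom.points("grp", ref_level) == pytest.approx(0.0, abs=1e-12)


def test_nomogram_round_trip_matches_predict(nomogram_setup):
    df, m, nom = nomogram_setup
    rng = np.random.default_rng(4)
    idx = rng.integers(0, len(df), 100)
    for i in idx:
        cov = {"x1": float(df["x1"].iloc[i]),
               "grp": str(df["grp"].iloc[i])}
        assert nom.predict(cov) == pytest.approx(
            predict_cif(m, cov, 3.0), abs=1e-6
        )


def test_nomogram_zero_range_raises():
    df = generate_cohort(CohortParams(n_patients=100, seed=2))
    m = fit_fine_gray(df, ["x1"])
    with pytest.raises(ValueError, match="range"):
        build_nomogram(m, continuous_ranges={"x1": (1.0, 1.0)})
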