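"""Preprocessing, likelihood construction, ML fitting and BIC selection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from socialddm import (
    Boundary,
    DDMParams,
    FitOptions,
    StimulusTable,
    fit_subject,
    fpt_density,
    get_model,
    neg_loglik,
    select_model,
)
from socialddm.fitting import FitResult, fits_frame, preprocess


def _trial_frame(rts, responses=None, stim_type=1, subject="s1", censored=None):
    n = len(rts)
    responses = responses or ["lower"] * n
    censored = censored if censored is not None else [False] * n
    s = StimulusTable(ingroup_A=95, ingroup_B=13, stim_type=stim_type)
    return pd.DataFrame(
        {
            "subject": subject,
            "trial": range(n),
            "stim_type": stim_type,
            "mirrored": 0,
            "ingroup_A": s.ingroup_A,
            "ingroup_B": s.ingroup_B,
            "outgroup_A": s.outgroup_A,
            "outgroup_B": s.outgroup_B,
            "compliant_option": s.compliant_option,
            "response": responses,
            "rt": rts,
            "censored": censored,
        }
    )


# ---------------------------------------------------------------------------
# preprocessing

def test_preprocess_zero_iqr_keeps_point_mass():
    df = _trial_frame([0.8] * 30)
    kept, report = preprocess(df)
    assert len(kept) == 30
    assert report.loc[report["subject"] == "s1", "n_iqr"].item() == 0


def test_preprocess_removes_fast_and_censored_trials():
    rts = [0.1] + [0.8] * 20 + [5.0]
    censored = [False] * 21 + [True]
    df = _trial_frame(rts, censored=censored)
    kept, report = preprocess(df)
    assert len(kept) == 20
    row = report[report["subject"] == "s1"].iloc[0]
    assert row["n_fast"] == 1 and row["n_censored"] == 1


def test_preprocess_removes_exactly_the_implanted_outliers(subject_trials):
    clean = subject_trials.copy()
    median = clean["rt"].median()
    outliers = clean.head(4).copy()
    outliers["trial"] = [900, 901, 902, 903]
    outliers["rt"] = 20 * median
    contaminated = pd.concat([clean, outliers], ignore_index=True)
    kept, report = preprocess(contaminated)
    assert len(kept) == len(clean)
    assert not kept["trial"].isin([900, 901, 902, 903]).any()
    assert report[report["subject"] == "s01"]["n_iqr"].item() == 4


def test_preprocess_empty_input_warns():
    with pytest.warns(UserWarning):
        kept, report = preprocess(_trial_frame([]).iloc[0:0])
    assert kept.empty


# ---------------------------------------------------------------------------
# likelihood

def test_neg_loglik_equals_sum_of_individual_log_densities():
    """Five-trial fixture: term-by-term oracle via the public density."""
    rts = [0.5, 0.7, 0.9, 1.4, 0.6]
    responses = ["lower", "lower", "upper", "lower", "upper"]
    df = _trial_frame(rts, responses)
    model = get_model(36)  # type-varying drift, z and sv both fixed
    a, t0, v = 1.8, 0.3, -1.2
    theta = [a, t0, v, v, v]
    params = DDMParams(a=a, z=0.5, t0=t0, v=v)
    expected = -sum(
        np.log(fpt_density(rt, Boundary.LOWER if r == "lower" else Boundary.UPPER, params))
        for rt, r in zip(rts, responses)
    )
    assert neg_loglik(model, theta, df) == pytest.approx(expected, rel=1e-10)


def test_equal_type_drifts_collapse_to_single_drift_model():
    """Model nesting: equal per-type drifts reproduce a shared-drift likelihood."""
    rts = [0.5, 0.7, 0.9, 1.1]
    df = pd.concat(
        [_trial_frame(rts[:2], stim_type=1), _trial_frame(rts[2:], stim_type=2)],
        ignore_index=True,
    )
    a, t0, v = 2.0, 0.25, -0.8
    # model 35 (v varies, z free) at equal drifts vs model 31 (a varies, sv free)
    # at equal separations and sv=0: identical likelihood
    ll35 = neg_loglik(get_model(35), [a, t0, v, v, v, 0.5], df)
    ll31 = neg_loglik(get_model(31), [a, a, a, t0, v, 0.0], df)
    assert ll35 == pytest.approx(ll31, rel=1e-12)


def test_neg_loglik_penalizes_rt_below_t0():
    df = _trial_frame([0.4, 0.5])
    model = get_model(36)
    bad = neg_loglik(model, [2.0, 0.45, -1.0, -1.0, -1.0], df)
    good = neg_loglik(model, [2.0, 0.2, -1.0, -1.0, -1.0], df)
    assert np.isfinite(bad) and bad > good


def test_trial_removal_decreases_neg_loglik(subject_trials):
    model = get_model(36)
    theta = [2.0, 0.3, -2.0, -1.5, -0.8]
    full = neg_loglik(model, theta, subject_trials)
    fewer = neg_loglik(model, theta, subject_trials.iloc[:-30])
    assert fewer < full


def test_duplicating_trials_doubles_loglik_magnitude():
    df = _trial_frame([0.5, 0.8, 1.1])
    model = get_model(36)
    theta = [1.8, 0.3, -1.0, -1.0, -1.0]
    single = neg_loglik(model, theta, df)
    doubled = neg_loglik(
        model, theta, pd.concat([df, df], ignore_index=True)
    )
    assert doubled == pytest.approx(2 * single, rel=1e-12)


def test_censored_trials_are_rejected_by_likelihood():
    df = _trial_frame([0.5, 5.0], censored=[False, True])
    with pytest.raises(ValueError):
        neg_loglik(get_model(36), [1.8, 0.3, -1, -1, -1], df)


# ---------------------------------------------------------------------------
# fitting and selection

def test_fit_is_deterministic(subject_trials):
    opts = FitOptions(restarts=2, seed=4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = fit_subject(get_model(36), subject_trials, opts)
        f2 = fit_subject(get_model(36), subject_trials, opts)
    assert f1.estimates == f2.estimates
    assert f1.loglik == f2.loglik


def test_bic_identity(fit35):
    assert fit35.bic == pytest.approx(fit35.k * np.log(fit35.n) - 2 * fit35.loglik, rel=1e-12)
    assert fit35.k == 6


def test_fixing_start_point_cannot_improve_loglik(subject_trials, fit35):
    """Model 36 (z and sv fixed) is nested in model 35 (z free), so its best
    log-likelihood cannot exceed model 35's beyond numerical slack."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f36 = fit_subject(get_model(36), subject_trials, FitOptions(restarts=3, seed=5))
    assert f36.loglik <= fit35.loglik + 1e-4


def test_fit_duplication_invariance(subject_trials):
    opts = FitOptions(restarts=2, seed=8)
    model = get_model(36)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = fit_subject(model, subject_trials, opts)
        doubled_trials = pd.concat([subject_trials, subject_trials], ignore_index=True)
        doubled = fit_subject(model, doubled_trials, opts)
    for name in model.param_names:
        assert doubled.estimates[name] == pytest.approx(base.estimates[name], abs=0.05)
    assert doubled.loglik == pytest.approx(2 * base.loglik, rel=0.01)


def _dummy_fit(model_id, bic, subject="s1", converged=True):
    model = get_model(model_id)
    n = 294
    loglik = (model.k * np.log(n) - bic) / 2.0
    return FitResult(
        subject=subject, model=model, estimates={}, loglik=loglik, k=model.k,
        n=n, bic=bic, converged=converged, n_restarts_used=1,
    )


def test_select_single_candidate_and_groups():
    fits = [_dummy_fit(35, 300.0), _dummy_fit(22, 290.0)]
    best = select_model(fits)
    assert {m.id for m in best.values()} == {35, 22}


def test_select_tie_breaks_by_parsimony_then_id():
    # model 36 has k=5, model 35 k=6: equal BIC resolves to 36
    best = select_model([_dummy_fit(35, 300.0), _dummy_fit(36, 300.0)])
    assert best[get_model(35).group].id == 36
    # equal BIC and k: lower id wins (34 and 35 both have k=6)
    best = select_model([_dummy_fit(35, 300.0), _dummy_fit(34, 300.0)])
    assert best[get_model(35).group].id == 34


def test_select_excludes_nonconverged():
    with pytest.warns(UserWarning):
        best = select_model([_dummy_fit(35, 250.0, converged=False), _dummy_fit(34, 300.0)])
    assert best[get_model(35).group].id == 34
    with pytest.raises(ValueError):
        select_model([_dummy_fit(35, 250.0, converged=False)])


def test_select_uses_subject_mean_bic():
    fits = [
        _dummy_fit(35, 200.0, subject="s1"),
        _dummy_fit(35, 400.0, subject="s2"),  # mean 300
        _dummy_fit(34, 280.0, subject="s1"),
        _dummy_fit(34, 290.0, subject="s2"),  # mean 285
    ]
    assert select_model(fits)[get_model(35).group].id == 34


def test_fits_frame_roundtrip(fit35):
    df = fits_frame([fit35])
    assert df.loc[0, "model"] == 35
    assert df.loc[0, "bic"] == pytest.approx(fit35.bic)
    assert {"a", "t0", "v_1", "v_2", "v_3", "z"} <= set(df.columns)
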