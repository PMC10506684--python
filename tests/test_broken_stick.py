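"""Broken-stick mixed-model fitting: hinge design, estimation against
independent oracles, standardized slopes, and sector-vs-global tests."""

import numpy as np
import pandas as pd
import pytest

from sectornorm import (
    ModelSpec,
    build_design,
    compare_sector_vs_global,
    fit_mixed,
    fit_model,
    generate_cohort,
    standardized_slope,
)
from sectornorm.broken_stick import SECTOR_ALPHA
from sectornorm.config import CohortConfig, GeneratingModel


def _one_eye_frame(**kw):
    row = dict(participant_id="P0", age=50.0, sex="female", se=0.0,
               al=23.7, dd=1.6, ssi_nflt=50.0, nflt_global=100.0)
    row.update(kw)
    return pd.DataFrame([row])


@pytest.mark.parametrize("kw, h_myo, h_hyp", [
    (dict(ametropia="SE", se=-3.0), -3.0, 0.0),
    (dict(ametropia="SE", se=0.0), 0.0, 0.0),      # breakpoint eye
    (dict(ametropia="AL", se=-7.9, al=26.7), 3.0, 0.0),
    (dict(ametropia="AL", se=2.0, al=23.2), 0.0, -0.5),
])
def test_hinge_terms(kw, h_myo, h_hyp):
    frame = _one_eye_frame(se=kw["se"], al=kw.get("al", 23.7))
    X, _, _ = build_design(frame, ModelSpec("nflt_global", kw["ametropia"]))
    assert X.loc[0, "myopic"] == pytest.approx(h_myo)
    assert X.loc[0, "hyperopic"] == pytest.approx(h_hyp)


def test_build_design_names_missing_field():
    frame = _one_eye_frame()
    frame.loc[0, "ssi_nflt"] = np.nan
    with pytest.raises(ValueError, match="ssi_nflt"):
        build_design(frame, ModelSpec("nflt_global", "AL"))


def _small_fit_cohort(sigma_u, sigma_e, seed=7, n=250):
    cfg = CohortConfig(
        n_participants=n,
        outcome_models={"nflt_global": GeneratingModel(
            100.0, -0.14, -0.82, 0.09, "AL", beta_myopic=-2.22)},
        random_intercept_sd={"nflt_global": sigma_u},
        residual_sd={"nflt_global": sigma_e},
        seed=seed)
    return generate_cohort(cfg)


def test_mixed_equals_ols_without_random_intercept():
    """With no between-participant variance the mixed model degenerates
    to ordinary least squares.  The REML variance estimate sits near the
    zero boundary rather than exactly on it, so agreement is to the
    resulting GLS-vs-OLS reweighting, far inside one coefficient SE."""
    rec = _small_fit_cohort(sigma_u=0.0, sigma_e=4.0)
    spec = ModelSpec("nflt_global", "AL")
    X, y, groups = build_design(rec, spec)
    fit = fit_mixed(X, y, groups, spec)
    beta, *_ = np.linalg.lstsq(X.to_numpy(), y.to_numpy(), rcond=None)
    for i, name in enumerate(X.columns):
        assert fit.params[name] == pytest.approx(
            beta[i], abs=0.05 * fit.bse[name] + 1e-8)
    # the null variance component stays small relative to the residual
    assert fit.sigma_u ** 2 < 0.15 * fit.sigma_e ** 2


def test_generating_slope_recovered_within_2se():
    rec = _small_fit_cohort(sigma_u=6.0, sigma_e=5.0, n=400)
    fit = fit_model(rec, ModelSpec("nflt_global", "AL"))
    assert abs(fit.params["myopic"] + 2.22) < 2 * fit.bse["myopic"]
    assert fit.n_participants <= fit.n_eyes
    assert 0 <= fit.interaction_p <= 1
    assert all(se > 0 for se in fit.bse.values())


def test_outcome_shift_moves_only_intercept():
    rec = _small_fit_cohort(sigma_u=3.0, sigma_e=3.0)
    spec = ModelSpec("nflt_global", "AL")
    fit0 = fit_model(rec, spec)
    shifted = rec.copy()
    shifted["nflt_global"] += 50.0
    fit1 = fit_model(shifted, spec)
    assert fit1.params["intercept"] == pytest.approx(
        fit0.params["intercept"] + 50.0, abs=1e-4)
    for name in ("age", "male", "ssi", "myopic", "hyperopic"):
        assert fit1.params[name] == pytest.approx(fit0.params[name],
                                                  abs=1e-4)


def test_hinge_and_interaction_parameterizations_agree():
    """Fitting (h_myo, h_hyp) or (a_centered, a_centered*I(myopic)) gives
    identical fitted values and the same segment-difference test."""
    rec = _small_fit_cohort(sigma_u=4.0, sigma_e=4.0)
    spec = ModelSpec("nflt_global", "AL")
    X, y, groups = build_design(rec, spec)
    fit_hinge = fit_mixed(X, y, groups, spec)

    X2 = X.copy()
    X2["centered"] = X["myopic"] + X["hyperopic"]
    X2["interaction"] = X["myopic"]
    X2 = X2.drop(columns=["myopic", "hyperopic"])
    fit_int = fit_mixed(X2, y, groups)

    # slopes map: myopic = centered + interaction; hyperopic = centered
    assert fit_int.params["centered"] == pytest.approx(
        fit_hinge.params["hyperopic"], abs=1e-5)
    assert fit_int.params["centered"] + fit_int.params["interaction"] == \
        pytest.approx(fit_hinge.params["myopic"], abs=1e-5)
    # the interaction coefficient's p equals the hinge-difference Wald p
    assert fit_int.pvalues["interaction"] == pytest.approx(
        fit_hinge.interaction_p, rel=1e-3)


def test_permuted_sex_coefficient_is_null():
    """Randomly permuting sex detaches it from the outcome: p-values are
    approximately uniform (type-I error near 5%)."""
    rng = np.random.default_rng(17)
    rec = _small_fit_cohort(sigma_u=0.0, sigma_e=4.0, n=150)
    hits = 0
    n_rep = 40
    for _ in range(n_rep):
        perm = rec.copy()
        perm["sex"] = rng.permutation(perm["sex"].to_numpy())
        fit = fit_model(perm, ModelSpec("nflt_global", "AL"))
        hits += fit.pvalues["male"] < 0.05
    # binomial(40, 0.05): observing more than 7 rejections is ~0.1% likely
    assert hits <= 7


def test_rank_deficiency_reported():
    rec = _small_fit_cohort(sigma_u=0.0, sigma_e=2.0)
    rec = rec[rec["se"] < 0].reset_index(drop=True)  # no hyperopic hinge
    with pytest.raises(ValueError, match="rank deficient"):
        fit_model(rec, ModelSpec("nflt_global", "AL"))


@pytest.mark.parametrize("raw, sd_x, sd_y, expected", [
    (-2.22, 1.4, 9.0, -0.345),   # global NFLT vs AL
    (1.02, 2.9, 9.0, 0.329),     # global NFLT vs SE
    (0.0, 2.0, 5.0, 0.0),
])
def test_standardized_slope(raw, sd_x, sd_y, expected):
    assert standardized_slope(raw, sd_x, sd_y) == pytest.approx(
        expected, abs=5e-4)


def test_standardized_slope_rejects_bad_sd():
    with pytest.raises(ValueError):
        standardized_slope(1.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        standardized_slope(1.0, 1.0, -2.0)


def _sector_cohort(tl_slope, seed=13, n=350):
    models = {
        "nflt_global": GeneratingModel(100.0, -0.14, 0.0, 0.09, "AL",
                                       beta_myopic=-2.22),
        "nflt_tl": GeneratingModel(75.0, -0.14, 0.0, 0.09, "AL",
                                   beta_myopic=tl_slope),
    }
    cfg = CohortConfig(
        n_participants=n, outcome_models=models,
        random_intercept_sd={k: 5.0 for k in models},
        residual_sd={k: 5.0 for k in models},
        seed=seed)
    return generate_cohort(cfg)


def test_sector_with_different_slope_detected():
    """A temporal sector generated with slope +0.84 against a global slope
    of -2.22 is flagged by the joint interaction F-test."""
    rec = _sector_cohort(tl_slope=0.84)
    res = compare_sector_vs_global(rec, "nflt", "AL",
                                   regions=["global", "tl"])
    assert res.loc["tl", "p"] < SECTOR_ALPHA
    assert res.loc["tl", "delta_slope"] > 0


def test_sector_with_equal_slope_not_flagged():
    rec = _sector_cohort(tl_slope=-2.22)
    res = compare_sector_vs_global(rec, "nflt", "AL",
                                   regions=["global", "tl"])
    assert res.loc["tl", "p"] > SECTOR_ALPHA
    assert abs(res.loc["tl", "delta_slope"]) < 1.0


def test_compare_requires_two_regions(small_cohort):
    with pytest.raises(ValueError):
        compare_sector_vs_global(small_cohort, "nflt", "AL",
                                 regions=["global"])


def test_parametric_bootstrap_coverage():
    """Refitting on data re-simulated from fitted coefficients covers the
    truth at roughly the nominal 95% rate."""
    rng = np.random.default_rng(29)
    true_slope = -2.22
    cover = 0
    n_rep = 60
    base = _small_fit_cohort(sigma_u=0.0, sigma_e=0.0, n=120)
    X, _, _ = build_design(base, ModelSpec("nflt_global", "AL"))
    lin_pred = base["nflt_global"].to_numpy()
    for _ in range(n_rep):
        sim = base.copy()
        sim["nflt_global"] = lin_pred + rng.normal(0, 4.0, len(base))
        fit = fit_model(sim, ModelSpec("nflt_global", "AL"))
        lo = fit.params["myopic"] - 1.96 * fit.bse["myopic"]
        hi = fit.params["myopic"] + 1.96 * fit.bse["myopic"]
        cover += lo <= true_slope <= hi
    # binomial(60, 0.95): fewer than 51 covers has probability < 0.2%
    assert cover >= 51
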