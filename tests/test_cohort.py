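"""Generator behavior: determinism, degenerate models, calibration,
clustering and the hinge decomposition."""

import numpy as np
import pandas as pd
import pytest

from sectornorm import (
    CohortConfig,
    GeneratingModel,
    generate_cohort,
    matched_truncnorm,
    summarize_cohort,
)
from sectornorm.config import DEFAULT_OUTCOME_MODELS


def _flat_config(**model_kw):
    """One-outcome config with all betas zero unless overridden."""
    model = GeneratingModel(
        intercept=model_kw.pop("intercept", 100.6),
        beta_age=model_kw.pop("beta_age", 0.0),
        beta_male=model_kw.pop("beta_male", 0.0),
        beta_ssi=model_kw.pop("beta_ssi", 0.0),
        ametropia_variable=model_kw.pop("ametropia_variable", "AL"),
        beta_myopic=model_kw.pop("beta_myopic", 0.0),
    )
    return CohortConfig(
        n_participants=model_kw.pop("n_participants", 120),
        outcome_models={"nflt_global": model},
        random_intercept_sd={"nflt_global": model_kw.pop("sigma_u", 0.0)},
        residual_sd={"nflt_global": model_kw.pop("sigma_e", 0.0)},
        seed=model_kw.pop("seed", 3),
    )


def test_noise_free_flat_model_is_constant():
    """With all betas and variances zero every eye equals the intercept."""
    rec = generate_cohort(_flat_config(intercept=100.6))
    assert np.allclose(rec["nflt_global"], 100.6)


def test_seed_determinism():
    cfg = _flat_config(sigma_e=3.0)
    a = generate_cohort(cfg, seed=42)
    b = generate_cohort(cfg, seed=42)
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(cfg, seed=43)
    assert not a["nflt_global"].equals(c["nflt_global"])


def test_noise_free_generating_slope_recovered_by_ols():
    """OLS refit of the generating equation on noise-free data returns the
    configured myopic-segment slope exactly (linear-algebra oracle)."""
    cfg = _flat_config(beta_myopic=-2.22, beta_age=-0.14, beta_ssi=0.09,
                      n_participants=150)
    rec = generate_cohort(cfg)
    a = rec["al"].to_numpy() - 23.7
    myo = rec["se"].to_numpy() < 0
    X = np.column_stack([
        np.ones(len(rec)),
        rec["age"].to_numpy() - 50.0,
        (rec["sex"] == "male").to_numpy(float),
        rec["ssi_nflt"].to_numpy() - 50.0,
        np.where(myo, a, 0.0),
        np.where(~myo, a, 0.0),
    ])
    beta, *_ = np.linalg.lstsq(X, rec["nflt_global"].to_numpy(), rcond=None)
    assert beta[4] == pytest.approx(-2.22, abs=1e-8)
    assert beta[1] == pytest.approx(-0.14, abs=1e-8)


def test_hinge_partition():
    """h_myo + h_hyp reconstructs a - a_ref for every eye."""
    rec = generate_cohort(seed=5)
    a = rec["al"].to_numpy() - 23.7
    myo = rec["se"].to_numpy() < 0
    h_myo = np.where(myo, a, 0.0)
    h_hyp = np.where(~myo, a, 0.0)
    assert np.allclose(h_myo + h_hyp, a)


def test_eyes_share_participant_age_and_sex():
    rec = generate_cohort(seed=5)
    per = rec.groupby("participant_id")[["age", "sex"]].nunique()
    assert (per <= 1).all().all()


def test_dd_consistent_with_disk_area():
    rec = generate_cohort(seed=5)
    assert np.allclose(rec["dd"],
                       2 * np.sqrt(rec["disk_area"] / np.pi), atol=1e-9)


def test_default_calibration_reproduces_stratum_structure():
    """Stratum means of SE, AL and eye counts match the calibration
    targets within Monte-Carlo error at the default cohort size."""
    rec = generate_cohort(seed=2)
    s = summarize_cohort(rec)
    # high-myopia SE: target -7.9, 2 MC-SE band
    n_hm = s.loc["high_myopia", "n_eyes"]
    assert s.loc["high_myopia", "se_mean"] == pytest.approx(
        -7.9, abs=2 * 1.6 / np.sqrt(n_hm))
    # emmetrope AL: target 23.7, half printed precision + 2 MC-SE
    n_em = s.loc["emmetropia", "n_eyes"]
    assert s.loc["emmetropia", "al_mean"] == pytest.approx(
        23.7, abs=0.05 + 2 * 0.8 / np.sqrt(n_em))
    # eye counts near the 117/590/480/152 proportions (4 MC-SD binomial)
    total = s.loc["all", "n_eyes"]
    for stratum, target in zip(
            ("high_myopia", "low_myopia", "emmetropia", "hyperopia"),
            (117, 590, 480, 152)):
        p = target / 1339
        band = 4 * np.sqrt(total * p * (1 - p))
        assert abs(s.loc[stratum, "n_eyes"] - p * total) < band
    # marginal SD of global NFLT within 15% of 9.0 um
    assert abs(s.loc["all", "nflt_global_sd"] - 9.0) / 9.0 < 0.15


def test_intraclass_correlation_recovered():
    """For a pure random-intercept outcome the two-eye ICC estimates
    sigma_u^2/(sigma_u^2+sigma_e^2)."""
    cfg = _flat_config(sigma_u=4.0, sigma_e=3.0, n_participants=600,
                      seed=9)
    cfg.two_eye_fraction = 1.0
    rec = generate_cohort(cfg)
    wide = rec.pivot_table(index="participant_id", columns="eye_side",
                           values="nflt_global")
    wide = wide.dropna()
    icc = np.corrcoef(wide["OD"], wide["OS"])[0, 1]
    expected = 16.0 / 25.0
    assert icc == pytest.approx(expected, abs=0.08)


def test_matched_truncnorm_hits_target_mean():
    rng = np.random.default_rng(0)
    draws = matched_truncnorm(-7.9, 1.6, -np.inf, -6.0, 40000, rng)
    assert draws.max() < -6.0
    assert draws.mean() == pytest.approx(-7.9, abs=0.03)


def test_summary_hand_example():
    """Two eyes with AL 23 and 24 -> mean 23.5 and sample SD."""
    rec = generate_cohort(_flat_config(n_participants=2, seed=1))
    rec = rec.iloc[:2].copy()
    rec["al"] = [23.0, 24.0]
    rec["stratum"] = "emmetropia"
    s = summarize_cohort(rec)
    assert s.loc["emmetropia", "al_mean"] == pytest.approx(23.5)
    assert s.loc["emmetropia", "al_sd"] == pytest.approx(
        np.std([23.0, 24.0], ddof=1))


def test_empty_stratum_is_flagged_not_fatal():
    cfg = _flat_config()
    cfg.stratum_proportions = {"high_myopia": 0.0, "low_myopia": 0.5,
                               "emmetropia": 0.5, "hyperopia": 0.0}
    s = summarize_cohort(generate_cohort(cfg))
    assert s.loc["high_myopia", "n_eyes"] == 0
    assert np.isnan(s.loc["high_myopia", "al_mean"])


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_participants=0).validate()
    cfg = CohortConfig()
    cfg.stratum_proportions = {s: 0.3 for s in cfg.stratum_proportions}
    with pytest.raises(ValueError):
        cfg.validate()
    with pytest.raises(ValueError):
        GeneratingModel(0, 0, 0, 0, ametropia_variable="XX")


def test_qc_failure_injection_rates():
    cfg = _flat_config(n_participants=400, seed=21)
    cfg.qc_failure_rates = {"low_ssi": 0.1, "high_iop": 0.05,
                            "high_cdr": 0.05, "missing": 0.05}
    rec = generate_cohort(cfg)
    n = len(rec)
    low_ssi = ((rec[["ssi_nflt", "ssi_gcct", "ssi_nflp"]] < 50)
               .any(axis=1)).mean()
    assert low_ssi == pytest.approx(0.1, abs=0.04)
    assert (rec["iop"] > 21).mean() == pytest.approx(0.05, abs=0.03)
    assert (rec["cdr"] > 0.7).mean() == pytest.approx(0.05, abs=0.03)
    assert rec["nflt_global"].isna().mean() == pytest.approx(0.05, abs=0.03)
    assert n > 400


def test_yaml_round_trip(tmp_path):
    cfg = CohortConfig(n_participants=50)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = CohortConfig.from_yaml(path)
    a = generate_cohort(cfg, seed=4)
    b = generate_cohort(back, seed=4)
    pd.testing.assert_frame_equal(a, b)
    assert back.outcome_models["nflt_global"].beta_myopic == \
        DEFAULT_OUTCOME_MODELS["nflt_global"].beta_myopic
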