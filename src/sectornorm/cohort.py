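"""Synthetic normative cohort generator.

Generates one row per eye with demographics, biometry, per-scan signal
strength and all diagnostic parameters (global + sectoral), with
within-participant clustering through shared random intercepts.  Stratum
covariates are drawn from truncated normals whose location is
moment-matched so the realized stratum mean equals the configured mean
despite truncation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import CohortConfig
from .regions import STRATA, family_columns, ssi_column

#: SE intervals defining the strata: high myopia < -6 D, low myopia
#: [-6, -1), emmetropia [-1, 1], hyperopia > 1 D.
_STRATUM_SE_BOUNDS = {
    "high_myopia": (-math.inf, -6.0),
    "low_myopia": (-6.0, -1.0 - 1e-12),
    "emmetropia": (-1.0, 1.0),
    "hyperopia": (1.0 + 1e-12, math.inf),
}

#: Columns of a cohort frame, in storage order.
COHORT_COLUMNS = (
    ["participant_id", "eye_side", "stratum", "age", "sex", "se", "al",
     "disk_area", "dd", "iop", "cdr", "ssi_nflt", "ssi_gcct", "ssi_nflp"]
    + family_columns("nflt") + family_columns("gcct") + family_columns("nflp")
)


def matched_truncnorm(mean: float, sd: float, low: float, high: float,
                      size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw from a normal truncated to [low, high] whose *truncated* mean
    equals ``mean`` (the location is solved numerically; the scale is kept).

    With plain rejection sampling the realized stratum means would be
    biased toward the interval center (e.g. a mean −7.9 D, SD 1.6 D
    high-myopia stratum truncated at −6 D would realize −8.3 D).
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0 or size == 0:
        return np.full(size, mean)
    lo_margin = mean - low if math.isfinite(low) else math.inf
    hi_margin = high - mean if math.isfinite(high) else math.inf
    if lo_margin < 0 or hi_margin < 0:
        raise ValueError(f"target mean {mean} outside [{low}, {high}]")

    def trunc_mean(mu: float) -> float:
        a, b = (low - mu) / sd, (high - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd)

    # Bracket the location; the truncated mean is monotone in mu.
    span = 10.0 * sd + 1.0
    mu = optimize.brentq(lambda m: trunc_mean(m) - mean,
                         mean - span, mean + span, xtol=1e-10)
    a, b = (low - mu) / sd, (high - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate a cohort of eyes under *config*.

    Returns a DataFrame with one row per eye (columns documented in
    :data:`COHORT_COLUMNS`).  Deterministic given (config, seed); ``seed``
    overrides ``config.seed`` when given.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    strata = list(config.stratum_proportions)
    probs = np.array([config.stratum_proportions[s] for s in strata])
    stratum_of = rng.choice(len(strata), size=config.n_participants, p=probs)
    two_eye_map = config._two_eye_map()

    rows: list[dict] = []
    participant_re: dict[str, np.ndarray] = {}
    for s_idx, stratum in enumerate(strata):
        pids = np.flatnonzero(stratum_of == s_idx)
        n = pids.size
        if n == 0:
            continue
        cov = config.covariates[stratum]
        lo_se, hi_se = _STRATUM_SE_BOUNDS[stratum]
        age = matched_truncnorm(cov.age_mean, cov.age_sd,
                                *config.age_range, n, rng)
        male = rng.random(n) < cov.male_fraction
        two_eyes = rng.random(n) < two_eye_map[stratum]
        n_eyes = n + int(two_eyes.sum())
        se = matched_truncnorm(cov.se_mean, cov.se_sd, lo_se, hi_se,
                               n_eyes, rng)
        al = (config.al_model.intercept + config.al_model.slope * se
              + rng.normal(0.0, config.al_model.sd, n_eyes))
        dd = (config.dd_model.intercept + config.dd_model.slope * se
              + rng.normal(0.0, config.dd_model.sd, n_eyes))
        dd = np.clip(dd, 0.8, None)  # apparent disk diameter stays physical
        disk_area = math.pi * (dd / 2.0) ** 2
        iop = matched_truncnorm(cov.iop_mean, cov.iop_sd, 5.0, 21.0,
                                n_eyes, rng)
        cdr = matched_truncnorm(config.cdr_mean, config.cdr_sd,
                                *config.cdr_range, n_eyes, rng)
        ssi = {
            "nflt": matched_truncnorm(cov.ssi_nflt_mean, cov.ssi_nflt_sd,
                                      50.0, 100.0, n_eyes, rng),
            "gcct": matched_truncnorm(cov.ssi_gcct_mean, cov.ssi_gcct_sd,
                                      50.0, 100.0, n_eyes, rng),
            "nflp": matched_truncnorm(cov.ssi_nflp_mean, cov.ssi_nflp_sd,
                                      50.0, 100.0, n_eyes, rng),
        }

        eye_ix = 0
        for j, pid_num in enumerate(pids):
            pid = f"P{pid_num:05d}"
            u = rng.normal(0.0, 1.0, size=len(config.outcome_models))
            participant_re[pid] = u
            sides = ("OD", "OS") if two_eyes[j] else (
                "OD" if rng.random() < 0.5 else "OS",)
            for side in sides:
                row = {
                    "participant_id": pid,
                    "eye_side": side,
                    "stratum": stratum,
                    "age": age[j],
                    "sex": "male" if male[j] else "female",
                    "se": se[eye_ix],
                    "al": al[eye_ix],
                    "disk_area": disk_area[eye_ix],
                    "dd": dd[eye_ix],
                    "iop": iop[eye_ix],
                    "cdr": cdr[eye_ix],
                    "ssi_nflt": ssi["nflt"][eye_ix],
                    "ssi_gcct": ssi["gcct"][eye_ix],
                    "ssi_nflp": ssi["nflp"][eye_ix],
                }
                for k, (name, model) in enumerate(
                        config.outcome_models.items()):
                    fam = name.split("_", 1)[0]
                    a = {"AL": row["al"], "SE": row["se"],
                         "DD": row["dd"]}[model.ametropia_variable]
                    hinge = a - model.reference
                    myopic = row["se"] < 0.0
                    sigma_u = config.random_intercept_sd.get(name, 0.0)
                    sigma_e = config.residual_sd.get(name, 0.0)
                    slope = (model.beta_myopic if myopic
                             else model.beta_hyperopic)
                    row[name] = (
                        model.intercept
                        + model.beta_age * (row["age"] - 50.0)
                        + model.beta_male * (row["sex"] == "male")
                        + model.beta_ssi * (row[ssi_column(fam)] - 50.0)
                        + slope * hinge
                        + sigma_u * u[k]
                        + rng.normal(0.0, sigma_e)
                    )
                rows.append(row)
                eye_ix += 1

    frame = pd.DataFrame(rows)
    frame = _inject_qc_failures(frame, config, rng)
    # outcomes not in the config are omitted entirely (not NaN-filled):
    # a missing column means "not measured", NaN means "measurement lost"
    cols = [c for c in COHORT_COLUMNS if c in frame.columns]
    return frame[cols].reset_index(drop=True)


def _inject_qc_failures(frame: pd.DataFrame, config: CohortConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Overwrite a configured fraction of eyes with QC-failing values."""
    rates = dict(config.qc_failure_rates)
    n = len(frame)
    if n == 0:
        return frame
    if rates.get("low_ssi", 0.0) > 0:
        hit = rng.random(n) < rates["low_ssi"]
        col = rng.choice(["ssi_nflt", "ssi_gcct", "ssi_nflp"], size=n)
        for c in ("ssi_nflt", "ssi_gcct", "ssi_nflp"):
            sel = hit & (col == c)
            frame.loc[sel, c] = rng.uniform(30.0, 50.0, int(sel.sum()))
    if rates.get("high_iop", 0.0) > 0:
        hit = rng.random(n) < rates["high_iop"]
        frame.loc[hit, "iop"] = rng.uniform(21.5, 30.0, int(hit.sum()))
    if rates.get("high_cdr", 0.0) > 0:
        hit = rng.random(n) < rates["high_cdr"]
        frame.loc[hit, "cdr"] = rng.uniform(0.71, 0.95, int(hit.sum()))
    if rates.get("missing", 0.0) > 0:
        hit = np.flatnonzero(rng.random(n) < rates["missing"])
        outcome_cols = list(config.outcome_models)
        for i in hit:
            frame.loc[frame.index[i],
                      rng.choice(outcome_cols)] = np.nan
    return frame


#: Covariate/outcome columns summarized per stratum.
_SUMMARY_COLUMNS = ("age", "se", "al", "dd", "iop",
                    "ssi_nflt", "ssi_gcct", "ssi_nflp",
                    "nflt_global", "gcct_global", "nflp_global")


def summarize_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum mean/SD table (plus an 'all' row) for the main
    covariates and global parameters, with participant and eye counts.

    Empty strata produce a flagged all-NaN row rather than an error.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty cohort")
    out = []
    groups = [("all", records)] + [
        (s, records[records["stratum"] == s]) for s in STRATA
    ]
    for name, grp in groups:
        row: dict = {
            "stratum": name,
            "n_participants": grp["participant_id"].nunique(),
            "n_eyes": len(grp),
            "male_pct": 100.0 * (grp["sex"] == "male").mean()
            if len(grp) else np.nan,
        }
        for col in _SUMMARY_COLUMNS:
            if col in grp.columns and len(grp):
                row[f"{col}_mean"] = grp[col].mean()
                row[f"{col}_sd"] = grp[col].std(ddof=1)
            else:
                row[f"{col}_mean"] = np.nan
                row[f"{col}_sd"] = np.nan
        out.append(row)
    return pd.DataFrame(out).set_index("stratum")


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort frame to CSV (one row per eye)."""
    records.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    return pd.read_csv(path)
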