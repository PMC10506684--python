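"""Broken-stick (piecewise-linear) mixed-effects regression.

Each diagnostic parameter is modeled as a linear function of age, sex and
signal strength plus a piecewise-linear term in one ametropia variable
(axial length, spherical equivalent, or apparent disk diameter) with the
breakpoint at emmetropia (SE = 0 D).  The two segments are parameterized
as hinge terms::

    h_myo = (a - a_ref) * I(SE < 0)      h_hyp = (a - a_ref) * I(SE >= 0)

so the myopic- and hyperopic-segment slopes are separate coefficients and
their difference is the usual segment-by-side interaction.  Within-
participant clustering of the two eyes is absorbed by a participant-level
random intercept; variance components are estimated by REML and
coefficient tests use large-sample normal theory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .regions import (
    AGE_REF,
    AMETROPIA_REFERENCE,
    AMETROPIA_VARIABLES,
    FAMILY_REGIONS,
    SSI_REF,
    region_column,
    ssi_column,
)

#: Significance threshold for sector-vs-global slope comparisons after
#: Bonferroni correction over the eight sectors: 0.05 / 8.
BONFERRONI_FACTOR = 8
SECTOR_ALPHA = 0.05 / BONFERRONI_FACTOR

_AMETROPIA_COLUMN = {"AL": "al", "SE": "se", "DD": "dd"}

FIXED_EFFECTS = ("intercept", "age", "male", "ssi", "myopic", "hyperopic")


@dataclass(frozen=True)
class ModelSpec:
    """Definition of one broken-stick model.

    ``outcome`` is a cohort column such as ``nflt_global``; the signal
    strength covariate is the SSI of that outcome's scan type.  Age, sex
    and SSI are always included; exactly one ametropia variable enters
    per model.
    """

    outcome: str
    ametropia_variable: str = "AL"
    ametropia_center: float | None = None

    def __post_init__(self) -> None:
        if self.ametropia_variable not in AMETROPIA_VARIABLES:
            raise ValueError(
                f"unknown ametropia variable: {self.ametropia_variable!r}")

    @property
    def family(self) -> str:
        return self.outcome.split("_", 1)[0]

    @property
    def center(self) -> float:
        if self.ametropia_center is not None:
            return self.ametropia_center
        return AMETROPIA_REFERENCE[self.ametropia_variable]


@dataclass
class FitResult:
    """Fitted coefficients and variance components of one model."""

    outcome: str
    ametropia_variable: str
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    interaction_p: float
    sigma_u: float
    sigma_e: float
    n_eyes: int
    n_participants: int
    converged: bool = True
    diagnostics: str = ""
    sd_x: float = field(default=np.nan)
    sd_y: float = field(default=np.nan)

    @property
    def standardized_myopic(self) -> float:
        return standardized_slope(self.params["myopic"], self.sd_x, self.sd_y)


def build_design(records: pd.DataFrame, spec: ModelSpec):
    """Build (X, y, groups) for one broken-stick model.

    X columns: intercept, age (centered at 50), male indicator, SSI
    (centered at 50), and the two hinge terms of the ametropia variable.
    Raises on missing fields, naming the offending eyes and field.
    """
    needed = ["participant_id", "age", "sex", "se",
              _AMETROPIA_COLUMN[spec.ametropia_variable],
              ssi_column(spec.family), spec.outcome]
    for col in needed:
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
        bad = records.index[records[col].isna()]
        if len(bad):
            raise ValueError(
                f"missing {col!r} for eye(s) at rows {list(bad[:5])}")
    a = records[_AMETROPIA_COLUMN[spec.ametropia_variable]].to_numpy(float)
    se_ref = records["se"].to_numpy(float)
    centered = a - spec.center
    myopic = se_ref < 0.0
    X = pd.DataFrame({
        "intercept": np.ones(len(records)),
        "age": records["age"].to_numpy(float) - AGE_REF,
        "male": (records["sex"] == "male").to_numpy(float),
        "ssi": records[ssi_column(spec.family)].to_numpy(float) - SSI_REF,
        "myopic": np.where(myopic, centered, 0.0),
        "hyperopic": np.where(~myopic, centered, 0.0),
    })
    y = records[spec.outcome].astype(float).rename(spec.outcome)
    groups = records["participant_id"]
    return X, y, groups


def fit_mixed(X: pd.DataFrame, y: pd.Series, groups: pd.Series,
              spec: ModelSpec | None = None) -> FitResult:
    """REML fit of the random-intercept model on a prepared design."""
    if groups.nunique() < 2:
        raise ValueError("need at least 2 participants (groups)")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"fixed-effects design is rank deficient ({rank} < {X.shape[1]}); "
            "check that both myopic and hyperopic eyes are present")
    with warnings.catch_warnings():
        # boundary variance estimates (sigma_u ~ 0) are legitimate here
        warnings.simplefilter("ignore")
        model = MixedLM(y.to_numpy(float), X, groups=groups)
        result = model.fit(reml=True)
    fe = result.fe_params
    params = {k: float(fe[k]) for k in X.columns}
    bse = {k: float(result.bse_fe[k]) for k in X.columns}
    pvals = {k: float(result.pvalues[k]) for k in X.columns}
    if {"myopic", "hyperopic"} <= set(X.columns):
        contrast = np.zeros(len(X.columns))
        contrast[list(X.columns).index("myopic")] = 1.0
        contrast[list(X.columns).index("hyperopic")] = -1.0
        _, interaction_p = _wald_contrast(result, X.columns, contrast)
    else:
        interaction_p = float("nan")
    sigma_u = float(np.sqrt(max(result.cov_re.to_numpy()[0, 0], 0.0)))
    sigma_e = float(np.sqrt(result.scale))
    diagnostics = "" if result.converged else "optimizer did not converge"
    if {"myopic", "hyperopic"} <= set(X.columns):
        ametropia = X["myopic"] + X["hyperopic"] + (spec.center if spec
                                                    else 0.0)
        sd_x = float(np.std(ametropia, ddof=1))
    else:
        sd_x = float("nan")
    return FitResult(
        outcome=spec.outcome if spec else str(y.name),
        ametropia_variable=spec.ametropia_variable if spec else "",
        params=params, bse=bse, pvalues=pvals,
        interaction_p=interaction_p,
        sigma_u=sigma_u, sigma_e=sigma_e,
        n_eyes=len(y), n_participants=int(groups.nunique()),
        converged=bool(result.converged), diagnostics=diagnostics,
        sd_x=sd_x,
        sd_y=float(np.std(y, ddof=1)),
    )


def _wald_contrast(result, fe_names, contrast: np.ndarray
                   ) -> tuple[float, float]:
    """Wald chi-square (1 df) of c'beta = 0 on the fixed effects.

    Returns (statistic, p).  Uses the fixed-effects block of the parameter
    covariance, so it is robust to how the variance parameters are packed.
    """
    from scipy import stats as _st

    fe_names = list(fe_names)
    est = np.array([result.fe_params[k] for k in fe_names])
    cov = np.asarray(result.cov_params())[:len(fe_names), :len(fe_names)]
    delta = float(contrast @ est)
    var = float(contrast @ cov @ contrast)
    if var <= 0:
        return np.nan, np.nan
    stat = delta * delta / var
    return stat, float(_st.chi2.sf(stat, 1))


def fit_model(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Convenience: build the design from a cohort frame and fit."""
    X, y, groups = build_design(records, spec)
    return fit_mixed(X, y, groups, spec)


def standardized_slope(raw_slope: float, sd_x: float, sd_y: float) -> float:
    """Slope rescaled to SD units: raw * SD(x) / SD(y).

    Expresses the change in outcome SDs per one-SD change of the
    covariate, making effect sizes comparable across covariates.
    """
    if sd_x <= 0 or sd_y <= 0:
        raise ValueError("standard deviations must be positive")
    return raw_slope * sd_x / sd_y


def fit_family(records: pd.DataFrame, family: str,
               ametropia_variable: str = "AL") -> dict[str, FitResult]:
    """Fit one broken-stick model per region of a parameter family."""
    return {
        region: fit_model(
            records, ModelSpec(region_column(family, region),
                               ametropia_variable))
        for region in FAMILY_REGIONS[family]
    }


def coefficient_frame(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Tabulate fits as rows=covariates, columns=regions (global first),
    with slope, standardized slope and p-value per cell — the layout used
    for coefficient CSV output."""
    rows = []
    for effect in ("age", "male", "ssi", "myopic", "hyperopic"):
        for stat in ("slope", "std_slope", "p"):
            row = {"effect": effect, "stat": stat}
            for region, fit in fits.items():
                if stat == "slope":
                    row[region] = fit.params[effect]
                elif stat == "p":
                    row[region] = fit.pvalues[effect]
                else:
                    row[region] = (fit.standardized_myopic
                                   if effect == "myopic" else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def compare_sector_vs_global(records: pd.DataFrame, family: str,
                             ametropia_variable: str = "AL",
                             regions: list[str] | None = None
                             ) -> pd.DataFrame:
    """Test each sector's myopic-segment slope against the global slope.

    Stacks the family's regions in long format (one row per eye x region),
    fits a joint mixed model with region main effects, shared covariates,
    hinge terms, and region-by-hinge interactions, with a participant
    random intercept; each sector's interaction contrast is Wald-F tested
    against zero.  Returns a frame with raw and Bonferroni-adjusted
    p-values (factor = number of sectors, threshold 0.05/8 for the
    eight-sector families).
    """
    regions = regions or list(FAMILY_REGIONS[family])
    if len(regions) < 2:
        raise ValueError("need at least 2 regions to compare")
    base, sectors = regions[0], regions[1:]

    frames = []
    for region in regions:
        X, y, groups = build_design(
            records, ModelSpec(region_column(family, region),
                               ametropia_variable))
        part = X.copy()
        part["y"] = y.to_numpy()
        part["region"] = region
        part["participant_id"] = groups.to_numpy()
        frames.append(part)
    long = pd.concat(frames, ignore_index=True)

    cols = {"intercept": long["intercept"], "age": long["age"],
            "male": long["male"], "ssi": long["ssi"],
            "myopic": long["myopic"], "hyperopic": long["hyperopic"]}
    for s in sectors:
        ind = (long["region"] == s).to_numpy(float)
        cols[f"region[{s}]"] = ind
        cols[f"myo_x_{s}"] = ind * long["myopic"].to_numpy()
        cols[f"hyp_x_{s}"] = ind * long["hyperopic"].to_numpy()
    Xl = pd.DataFrame(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(long["y"].to_numpy(float), Xl,
                        groups=long["participant_id"])
        result = model.fit(reml=True)

    out = []
    names = list(Xl.columns)
    for s in sectors:
        contrast = np.zeros(len(names))
        contrast[names.index(f"myo_x_{s}")] = 1.0
        stat, p = _wald_contrast(result, names, contrast)
        out.append({
            "sector": s,
            "delta_slope": float(result.fe_params[f"myo_x_{s}"]),
            "F": stat,
            "p": p,
            "p_bonferroni": min(1.0, p * len(sectors)),
            "significant": p < 0.05 / len(sectors),
        })
    return pd.DataFrame(out).set_index("sector")
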