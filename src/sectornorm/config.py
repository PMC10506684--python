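"""Cohort simulation configuration.

The default calibration emulates a population-based normative OCT/OCTA
cohort of healthy adult eyes stratified by spherical-equivalent
refraction: per-stratum demographics and biometry (age, sex, SE, IOP,
per-scan signal strength), axial length and apparent disk diameter as
linear functions of SE, and piecewise-linear ("broken-stick") generating
models with a breakpoint at SE = 0 D for every diagnostic parameter.
Outcomes are clustered within participant through a shared random
intercept, mirroring the two-eye structure of real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .regions import (
    AMETROPIA_REFERENCE,
    AMETROPIA_VARIABLES,
    FAMILY_REGIONS,
    STRATA,
    region_column,
)


@dataclass(frozen=True)
class GeneratingModel:
    """Piecewise-linear generating equation for one diagnostic parameter.

    The linear predictor is::

        intercept + beta_age*(age-50) + beta_male*I(male)
                  + beta_ssi*(SSI-50)
                  + beta_myopic   * (a - a_ref) * I(SE < 0)
                  + beta_hyperopic* (a - a_ref) * I(SE >= 0)

    where ``a`` is the configured ametropia variable (AL, SE or DD) and
    ``a_ref`` its emmetropic reference.  The hyperopic-segment slope
    defaults to 0: hyperopic-segment associations are weak/null in
    normative cohorts, so the default piecewise models are flat on the
    hyperopic side.
    """

    intercept: float
    beta_age: float
    beta_male: float
    beta_ssi: float
    ametropia_variable: str = "AL"
    beta_myopic: float = 0.0
    beta_hyperopic: float = 0.0
    ametropia_reference: float | None = None

    def __post_init__(self) -> None:
        if self.ametropia_variable not in AMETROPIA_VARIABLES:
            raise ValueError(
                f"unknown ametropia variable: {self.ametropia_variable!r}"
            )

    @property
    def reference(self) -> float:
        if self.ametropia_reference is not None:
            return self.ametropia_reference
        return AMETROPIA_REFERENCE[self.ametropia_variable]


@dataclass(frozen=True)
class StratumCovariates:
    """Per-stratum covariate distribution parameters (truncated normals)."""

    age_mean: float
    age_sd: float
    male_fraction: float
    se_mean: float
    se_sd: float
    iop_mean: float
    iop_sd: float
    ssi_nflt_mean: float
    ssi_nflt_sd: float
    ssi_gcct_mean: float
    ssi_gcct_sd: float
    ssi_nflp_mean: float
    ssi_nflp_sd: float


@dataclass(frozen=True)
class LinearLink:
    """y = intercept + slope * SE + Normal(0, sd) — AL|SE and DD|SE links."""

    intercept: float
    slope: float
    sd: float


@dataclass
class CohortConfig:
    """Full simulation configuration; defaults calibrated to a normative
    East Asian population-based adult cohort of ~789 participants / ~1339 eyes."""

    n_participants: int = 789
    #: Probability a participant contributes both eyes; scalar or map
    #: stratum -> proportion.
    two_eye_fraction: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TWO_EYE_FRACTION)
    )
    stratum_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_PROPORTIONS)
    )
    covariates: Mapping[str, StratumCovariates] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    al_model: LinearLink = field(
        default_factory=lambda: LinearLink(23.8, -0.34, 0.8)
    )
    dd_model: LinearLink = field(
        default_factory=lambda: LinearLink(1.64, 0.018, 0.15)
    )
    outcome_models: Mapping[str, GeneratingModel] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_MODELS)
    )
    random_intercept_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RANDOM_INTERCEPT_SD)
    )
    residual_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUAL_SD)
    )
    #: Fractions of eyes injected with QC-failing values (low SSI, high IOP,
    #: large cup-to-disk ratio) or a missing measurement.  Zero by default:
    #: the default calibration emulates the post-exclusion analysis cohort.
    qc_failure_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "low_ssi": 0.0, "high_iop": 0.0, "high_cdr": 0.0, "missing": 0.0,
        }
    )
    age_range: tuple[float, float] = (18.0, 78.0)
    cdr_mean: float = 0.35
    cdr_sd: float = 0.12
    cdr_range: tuple[float, float] = (0.05, 0.7)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        props = dict(self.stratum_proportions)
        if set(props) != set(STRATA):
            raise ValueError(f"stratum_proportions must cover {STRATA}")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum_proportions sum to {total}, not 1")
        for s, p in props.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion for {s} outside [0,1]: {p}")
        for s, f2 in self._two_eye_map().items():
            if not 0.0 <= f2 <= 1.0:
                raise ValueError(f"two_eye_fraction for {s} outside [0,1]")
        for name, model in self.outcome_models.items():
            fam = name.split("_", 1)[0]
            if fam not in FAMILY_REGIONS:
                raise ValueError(f"outcome {name!r} has unknown family")
            region_column(fam, name.split("_", 1)[1])
        for mapping, label in (
            (self.random_intercept_sd, "random_intercept_sd"),
            (self.residual_sd, "residual_sd"),
        ):
            for name, sd in mapping.items():
                if sd < 0:
                    raise ValueError(f"{label}[{name!r}] is negative")
        for rule, rate in self.qc_failure_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"qc_failure_rates[{rule!r}] outside [0,1]")

    def _two_eye_map(self) -> dict[str, float]:
        if isinstance(self.two_eye_fraction, Mapping):
            return dict(self.two_eye_fraction)
        return {s: float(self.two_eye_fraction) for s in STRATA}

    # -- serialization --------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["covariates"] = {
            s: asdict(c) if not isinstance(c, dict) else c
            for s, c in dict(self.covariates).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["covariates"] = {
            s: StratumCovariates(**c) for s, c in payload["covariates"].items()
        }
        for key in ("al_model", "dd_model"):
            payload[key] = LinearLink(**payload[key])
        payload["outcome_models"] = {
            name: GeneratingModel(**m)
            for name, m in payload["outcome_models"].items()
        }
        for key in ("age_range", "cdr_range"):
            if key in payload:
                payload[key] = tuple(payload[key])
        cfg = cls(**payload)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Default calibration
# ---------------------------------------------------------------------------

#: Stratum shares of *participants* (66/336/284/103 of 789).
DEFAULT_STRATUM_PROPORTIONS = {
    "high_myopia": 66 / 789,
    "low_myopia": 336 / 789,
    "emmetropia": 284 / 789,
    "hyperopia": 103 / 789,
}

#: Per-stratum probability of contributing both eyes, chosen so expected
#: eye counts match 117/590/480/152 given the participant counts above
#: (overall two-eye fraction ~0.70).
DEFAULT_TWO_EYE_FRACTION = {
    "high_myopia": 117 / 66 - 1.0,
    "low_myopia": 590 / 336 - 1.0,
    "emmetropia": 480 / 284 - 1.0,
    "hyperopia": 152 / 103 - 1.0,
}

DEFAULT_COVARIATES = {
    "high_myopia": StratumCovariates(40.3, 11.3, 0.44, -7.9, 1.6, 14.0, 2.5,
                                     64.6, 7.4, 68.3, 5.5, 63.1, 6.2),
    "low_myopia": StratumCovariates(42.0, 14.1, 0.43, -3.1, 1.4, 14.1, 2.8,
                                    67.3, 7.6, 71.3, 6.8, 66.6, 7.3),
    "emmetropia": StratumCovariates(50.3, 13.9, 0.42, 0.1, 0.6, 13.3, 2.7,
                                    66.8, 8.2, 73.3, 7.2, 68.0, 8.0),
    "hyperopia": StratumCovariates(58.2, 11.8, 0.39, 2.0, 1.4, 13.0, 2.6,
                                   64.0, 8.5, 71.4, 7.8, 65.9, 8.1),
}


def _al_model(intercept, b_age, b_male, b_ssi, b_al):
    return GeneratingModel(intercept, b_age, b_male, b_ssi, "AL", b_al)


#: Generating coefficients for the axial-length piecewise models.  Global
#: rows carry their own coefficients (globals are generated independently
#: of their sectors so global-row recovery is exact; internal
#: global-vs-sector-mean consistency is deliberately not enforced).
#: Sector intercepts follow the TSNIT double-hump profile (temporal thin,
#: superior/inferior thick) and are free parameters of the simulator.
DEFAULT_OUTCOME_MODELS: dict[str, GeneratingModel] = {
    # NFLT (um): age/male/SSI/AL-myopic slopes per sector
    "nflt_global": _al_model(101.8, -0.14, -0.82, 0.09, -2.22),
    "nflt_tu": _al_model(80.0, -0.15, -4.44, -0.01, 0.53),
    "nflt_st": _al_model(130.0, -0.26, 1.94, 0.13, -2.86),
    "nflt_sn": _al_model(115.0, -0.16, 1.88, 0.13, -4.31),
    "nflt_nu": _al_model(85.0, -0.01, 1.35, 0.09, -3.25),
    "nflt_nl": _al_model(72.0, -0.01, -0.12, 0.02, -2.59),
    "nflt_in": _al_model(120.0, -0.11, -1.32, 0.09, -5.55),
    "nflt_it": _al_model(140.0, -0.33, -3.97, 0.14, -1.27),
    "nflt_tl": _al_model(75.0, -0.10, -1.27, 0.03, 0.84),
    # GCCT (um)
    "gcct_global": _al_model(95.9, -0.05, 0.46, 0.06, -0.91),
    "gcct_superior": _al_model(95.6, -0.05, 0.21, 0.06, -0.78),
    "gcct_inferior": _al_model(96.2, -0.06, 0.74, 0.06, -1.04),
    # NFLP capillary density (% area)
    "nflp_global": _al_model(52.0, -0.02, -0.89, 0.17, -0.32),
    "nflp_tu": _al_model(52.5, -0.02, -1.25, 0.14, 0.11),
    "nflp_st": _al_model(54.5, -0.01, -0.09, 0.09, -0.52),
    "nflp_sn": _al_model(53.0, -0.01, -0.58, 0.13, -0.30),
    "nflp_nu": _al_model(49.5, 0.05, -0.44, 0.22, -0.39),
    "nflp_nl": _al_model(49.0, 0.03, -0.54, 0.23, -0.56),
    "nflp_in": _al_model(54.0, 0.01, -1.57, 0.13, -0.63),
    "nflp_it": _al_model(56.0, 0.02, -1.42, 0.14, -0.13),
    "nflp_tl": _al_model(54.0, -0.06, -0.39, 0.17, -0.07),
}

#: Between-participant (random intercept) SDs, outcome units.  Globals are
#: tuned with the residual SDs below so marginal SDs land near the cohort
#: values (NFLT 9.0 um, GCCT 6.8 um, NFLP-CD 2.8%); sectors are noisier.
DEFAULT_RANDOM_INTERCEPT_SD: dict[str, float] = {
    **{f"nflt_{r}": 9.0 for r in FAMILY_REGIONS["nflt"][1:]},
    **{f"gcct_{r}": 5.0 for r in FAMILY_REGIONS["gcct"][1:]},
    **{f"nflp_{r}": 2.5 for r in FAMILY_REGIONS["nflp"][1:]},
    "nflt_global": 6.0,
    "gcct_global": 4.8,
    "nflp_global": 1.7,
}

#: Within-participant residual SDs, outcome units.
DEFAULT_RESIDUAL_SD: dict[str, float] = {
    **{f"nflt_{r}": 8.0 for r in FAMILY_REGIONS["nflt"][1:]},
    **{f"gcct_{r}": 4.0 for r in FAMILY_REGIONS["gcct"][1:]},
    **{f"nflp_{r}": 2.5 for r in FAMILY_REGIONS["nflp"][1:]},
    "nflt_global": 5.0,
    "gcct_global": 4.0,
    "nflp_global": 1.7,
}
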