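"""Regression-based covariate adjustment of diagnostic parameters.

Each raw value is corrected back to a reference covariate profile
(age 50 y, female, SSI 50, emmetropic ametropia) by subtracting the
fitted covariate effects::

    adjusted = raw - (age-50)*b_age - I(male)*b_male - (SSI-50)*b_ssi
                   - (a - a_ref)*b_a

with a the ametropia variable: axial length (reference 23.7 mm),
spherical equivalent (uncentered, i.e. reference 0 D) or apparent disk
diameter (uncentered).  Global parameters use the global regression
slopes; sectors use their own sectoral slopes.  By default only eyes on
the myopic side of the breakpoint receive the myopic-segment ametropia
slope; hyperopic-side eyes receive the hyperopic-segment slope, which is
0 unless supplied (hyperopic slopes are typically non-significant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .broken_stick import FitResult, _AMETROPIA_COLUMN
from .regions import (
    AGE_REF,
    AMETROPIA_REFERENCE,
    AMETROPIA_VARIABLES,
    FAMILY_REGIONS,
    SSI_REF,
    region_column,
)


@dataclass
class CoefficientTable:
    """Per-region adjustment slopes for one family and ametropia variable.

    ``entries`` maps region -> {beta_age, beta_male, beta_ssi,
    beta_ametropia[, beta_hyperopic]} in outcome units per covariate unit.
    """

    family: str
    ametropia_variable: str
    entries: Mapping[str, Mapping[str, float]]
    ametropia_reference: float | None = None
    #: When False, the myopic-segment slope is applied to all eyes
    #: (single-slope, non-piecewise adjustment variant).
    piecewise: bool = True

    REQUIRED = ("beta_age", "beta_male", "beta_ssi", "beta_ametropia")

    def __post_init__(self) -> None:
        if self.family not in FAMILY_REGIONS:
            raise ValueError(f"unknown family: {self.family!r}")
        if self.ametropia_variable not in AMETROPIA_VARIABLES:
            raise ValueError(
                f"unknown ametropia variable: {self.ametropia_variable!r}")
        for region, coeffs in self.entries.items():
            region_column(self.family, region)
            missing = [k for k in self.REQUIRED if k not in coeffs]
            if missing:
                raise ValueError(
                    f"region {region!r} lacks coefficients {missing}")

    @property
    def reference(self) -> float:
        if self.ametropia_reference is not None:
            return self.ametropia_reference
        return AMETROPIA_REFERENCE[self.ametropia_variable]

    @classmethod
    def from_fits(cls, fits: Mapping[str, FitResult],
                  use_hyperopic: bool = True) -> "CoefficientTable":
        """Build a table from fitted broken-stick models (one per region)."""
        first = next(iter(fits.values()))
        family = first.outcome.split("_", 1)[0]
        entries = {}
        for region, fit in fits.items():
            entry = {
                "beta_age": fit.params["age"],
                "beta_male": fit.params["male"],
                "beta_ssi": fit.params["ssi"],
                "beta_ametropia": fit.params["myopic"],
            }
            if use_hyperopic:
                entry["beta_hyperopic"] = fit.params["hyperopic"]
            entries[region] = entry
        return cls(family, first.ametropia_variable, entries)

    # -- CSV round trip (rows = regions, columns = coefficients) --------

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame.from_dict(dict(self.entries), orient="index")
        frame.index.name = "region"
        frame.insert(0, "family", self.family)
        frame.insert(1, "ametropia", self.ametropia_variable)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CoefficientTable":
        frame = pd.read_csv(path, index_col="region")
        family = frame["family"].iloc[0]
        variable = frame["ametropia"].iloc[0]
        coeff_cols = [c for c in frame.columns
                      if c not in ("family", "ametropia")]
        entries = {
            region: {k: row[k] for k in coeff_cols if pd.notna(row[k])}
            for region, row in frame.iterrows()
        }
        return cls(family, variable, entries)


def adjust(record: Mapping, region: str, table: CoefficientTable) -> float:
    """Adjusted value of one region for one eye (a row mapping).

    Identity at the reference profile: a female eye aged 50 with SSI 50
    and the ametropia variable at its reference is returned unchanged.
    """
    if region not in table.entries:
        raise ValueError(
            f"table for {table.family!r} has no region {region!r}")
    coeffs = table.entries[region]
    col = region_column(table.family, region)
    ssi_col = f"ssi_{table.family}"
    for key in (col, "age", "sex", ssi_col,
                _AMETROPIA_COLUMN[table.ametropia_variable]):
        if key not in record or pd.isna(record[key]):
            raise ValueError(f"missing covariate or value {key!r}")
    a = record[_AMETROPIA_COLUMN[table.ametropia_variable]]
    if table.piecewise and record.get("se") is not None \
            and pd.notna(record.get("se")) and record["se"] >= 0:
        beta_a = coeffs.get("beta_hyperopic", 0.0)
    else:
        beta_a = coeffs["beta_ametropia"]
    return float(
        record[col]
        - (record["age"] - AGE_REF) * coeffs["beta_age"]
        - (record["sex"] == "male") * coeffs["beta_male"]
        - (record[ssi_col] - SSI_REF) * coeffs["beta_ssi"]
        - (a - table.reference) * beta_a
    )


def adjust_cohort(records: pd.DataFrame,
                  table: CoefficientTable) -> pd.DataFrame:
    """Vectorized adjustment of every region in *table*.

    Adds one column per region named ``<family>_<region>_adj<VAR>``;
    raw columns are untouched.
    """
    out = records.copy()
    ssi_col = f"ssi_{table.family}"
    a = out[_AMETROPIA_COLUMN[table.ametropia_variable]].to_numpy(float)
    age = out["age"].to_numpy(float)
    male = (out["sex"] == "male").to_numpy(float)
    ssi = out[ssi_col].to_numpy(float)
    myopic = out["se"].to_numpy(float) < 0.0
    for region, coeffs in table.entries.items():
        col = region_column(table.family, region)
        new = f"{col}_adj{table.ametropia_variable}"
        if new in out.columns:
            raise ValueError(f"output column {new!r} already exists")
        if table.piecewise:
            beta_a = np.where(myopic, coeffs["beta_ametropia"],
                              coeffs.get("beta_hyperopic", 0.0))
        else:
            beta_a = coeffs["beta_ametropia"]
        out[new] = (
            out[col].to_numpy(float)
            - (age - AGE_REF) * coeffs["beta_age"]
            - male * coeffs["beta_male"]
            - (ssi - SSI_REF) * coeffs["beta_ssi"]
            - (a - table.reference) * beta_a
        )
    return out
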