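"""Normative thresholds and false-positive-rate analysis.

All eyes in the cohort are healthy, so any eye flagged abnormal is a
false positive.  The abnormality threshold of each diagnostic parameter
is the empirical 5th percentile of the emmetropic eyes (the normative
reference stratum); eyes strictly below the threshold are flagged.
Per-stratum rates are contrasted against emmetropia with Pearson's
chi-square (no continuity correction), and the pre- vs post-adjustment
reduction within a stratum is tested with McNemar's test on the
discordant pairs (continuity-corrected).  Thresholds are re-derived from
the emmetropes after each adjustment, since the SE- and DD-based
adjustment formulas are uncentered and shift every value by a constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .adjustment import CoefficientTable, adjust_cohort
from .qc import single_eye_subset
from .regions import STRATA, region_column

_REFERENCE_STRATUM = "emmetropia"


def normative_threshold(values, *, interpolated: bool = False) -> float:
    """5th-percentile normative cutoff from emmetropic values.

    Default convention is the order statistic: the k-th smallest value
    with k = ceil(0.05 n), which guarantees at most 5% of the reference
    sample falls strictly below it and is reproducible across platforms.
    ``interpolated=True`` uses the linear-interpolation quantile instead.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n == 0:
        raise ValueError("cannot derive a threshold from no values")
    if n < 20:
        import warnings

        warnings.warn(
            f"only {n} reference eyes; 5th percentile is unstable",
            stacklevel=2)
    if interpolated:
        return float(np.quantile(arr, 0.05))
    k = math.ceil(0.05 * n)
    return float(np.sort(arr)[k - 1])


def classify(values, threshold: float) -> np.ndarray:
    """Flag values strictly below the threshold; NaN stays NaN (masked).

    Returns a float array of {0.0, 1.0, nan} so missing values can be
    excluded from rates downstream.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    arr = np.asarray(values, dtype=float)
    flags = np.where(np.isnan(arr), np.nan, (arr < threshold).astype(float))
    return flags


def fp_rates(flags, strata) -> pd.DataFrame:
    """Per-stratum false-positive counts and rates.

    Zero-eye strata are reported with rate NaN (undefined), never raised.
    """
    frame = pd.DataFrame({"flag": np.asarray(flags, dtype=float),
                          "stratum": np.asarray(strata, dtype=object)})
    frame = frame.dropna(subset=["flag"])
    rows = []
    for stratum in STRATA:
        grp = frame[frame["stratum"] == stratum]
        n = len(grp)
        flagged = int(grp["flag"].sum())
        rows.append({"stratum": stratum, "n_eyes": n, "n_flagged": flagged,
                     "fp_rate": flagged / n if n else np.nan})
    return pd.DataFrame(rows).set_index("stratum")


def chi_square_vs_emmetropia(stratum_counts: tuple[int, int],
                             emmetropia_counts: tuple[int, int]
                             ) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) comparing a
    stratum's (flagged, unflagged) counts with emmetropia's.

    Returns (statistic, p).  Identical proportions give statistic 0, p 1.
    """
    table = np.array([list(emmetropia_counts), list(stratum_counts)], float)
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("chi-square table has a zero marginal")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def mcnemar_pre_post(raw_flags, adjusted_flags) -> tuple[float, float]:
    """Continuity-corrected McNemar test on paired pre/post flags.

    Uses the discordant counts b (flagged only before adjustment) and c
    (flagged only after): statistic (|b-c|-1)^2/(b+c), 1 df.  With no
    discordant pairs the statistic is 0 and p = 1.
    """
    a = np.asarray(raw_flags, dtype=float)
    b = np.asarray(adjusted_flags, dtype=float)
    if a.shape != b.shape:
        raise ValueError("flag vectors must be paired (same length)")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep].astype(bool), b[keep].astype(bool)
    n01 = int((a & ~b).sum())  # flagged raw only
    n10 = int((~a & b).sum())  # flagged adjusted only
    if n01 + n10 == 0:
        return 0.0, 1.0
    table = [[int((a & b).sum()), n01], [n10, int((~a & ~b).sum())]]
    res = _sm_mcnemar(table, exact=False, correction=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class FPReport:
    """Long-format false-positive report.

    ``rates``: one row per region x stratum x adjustment state with
    counts, rate, threshold, chi-square vs emmetropia, and McNemar vs the
    raw state.  ``single_eye`` holds the same analysis on a random
    one-eye-per-participant subset (sensitivity check for two-eye
    clustering).
    """

    rates: pd.DataFrame
    single_eye: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.rates.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {"rates": self.rates.to_dict(orient="records")}
        if self.single_eye is not None:
            payload["single_eye"] = self.single_eye.to_dict(orient="records")
        pd.Series(payload).to_json(path)


def _analyze(records: pd.DataFrame, columns: Mapping[str, dict],
             interpolated: bool) -> pd.DataFrame:
    """Threshold/classify/rate/test sweep over prepared value columns.

    ``columns`` maps value-column -> dict(region=..., adjustment=...).
    """
    emm = records[records["stratum"] == _REFERENCE_STRATUM]
    rows = []
    raw_flag_cache: dict[str, np.ndarray] = {}
    for col, meta in columns.items():
        threshold = normative_threshold(emm[col], interpolated=interpolated)
        flags = classify(records[col], threshold)
        if meta["adjustment"] == "raw":
            raw_flag_cache[meta["region"]] = flags
        table = fp_rates(flags, records["stratum"])
        emm_counts = (int(table.loc[_REFERENCE_STRATUM, "n_flagged"]),
                      int(table.loc[_REFERENCE_STRATUM, "n_eyes"]
                          - table.loc[_REFERENCE_STRATUM, "n_flagged"]))
        for stratum, trow in table.iterrows():
            row = {
                "region": meta["region"],
                "adjustment": meta["adjustment"],
                "stratum": stratum,
                "n_eyes": int(trow["n_eyes"]),
                "n_flagged": int(trow["n_flagged"]),
                "fp_rate": trow["fp_rate"],
                "threshold": threshold,
                "chi2": np.nan, "chi2_p": np.nan,
                "mcnemar": np.nan, "mcnemar_p": np.nan,
            }
            if stratum != _REFERENCE_STRATUM and trow["n_eyes"] > 0:
                counts = (int(trow["n_flagged"]),
                          int(trow["n_eyes"] - trow["n_flagged"]))
                row["chi2"], row["chi2_p"] = chi_square_vs_emmetropia(
                    counts, emm_counts)
            if meta["adjustment"] != "raw":
                mask = (records["stratum"] == stratum).to_numpy()
                raw_flags = raw_flag_cache.get(meta["region"])
                if raw_flags is not None and mask.any():
                    row["mcnemar"], row["mcnemar_p"] = mcnemar_pre_post(
                        raw_flags[mask], flags[mask])
            rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(records: pd.DataFrame,
                      tables: Iterable[CoefficientTable],
                      seed: int = 0,
                      interpolated: bool = False,
                      single_eye: bool = True) -> FPReport:
    """End-to-end false-positive analysis for one or more families.

    For every region covered by the coefficient tables and every
    adjustment state (raw plus one per table's ametropia variable):
    derive the emmetrope threshold, classify all eyes, compute
    per-stratum rates, chi-square each stratum against emmetropia, and
    McNemar each adjusted state against raw.  The same sweep is repeated
    on a seeded single-eye-per-participant subset.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("at least one coefficient table is required")
    adjusted = records
    columns: dict[str, dict] = {}
    seen_families = []
    for table in tables:
        adjusted = adjust_cohort(adjusted, table)
        if table.family not in seen_families:
            seen_families.append(table.family)
            for region in table.entries:
                columns[region_column(table.family, region)] = {
                    "region": region_column(table.family, region),
                    "adjustment": "raw",
                }
    for table in tables:
        for region in table.entries:
            col = region_column(table.family, region)
            columns[f"{col}_adj{table.ametropia_variable}"] = {
                "region": col,
                "adjustment": table.ametropia_variable,
            }
    rates = _analyze(adjusted, columns, interpolated)
    single = None
    if single_eye:
        subset = single_eye_subset(adjusted, seed)
        single = _analyze(subset, columns, interpolated)
    return FPReport(rates=rates, single_eye=single)
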