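"""Quality control, disk-diameter derivation, refraction strata, and the
single-eye sensitivity subset.

Exclusion criteria for the normative analysis cohort: any scan with a
signal strength index below 50, intraocular pressure above 21 mmHg, a
cup-to-disk ratio above 0.7, and eyes with any missing measurement
(complete-case eyes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .regions import STRATA, family_columns

_SSI_COLUMNS = ("ssi_nflt", "ssi_gcct", "ssi_nflp")
_MEASUREMENT_COLUMNS = tuple(
    family_columns("nflt") + family_columns("gcct") + family_columns("nflp")
)


def compute_dd(disk_area) -> float | np.ndarray:
    """Apparent optic disk diameter (mm) from apparent disk area (mm²).

    DD = 2 * sqrt(area / pi): the diameter of the circle with the same
    area, used as a surrogate measure of transverse optical magnification.
    """
    area = np.asarray(disk_area, dtype=float)
    if np.any(~np.isfinite(area)) or np.any(area <= 0):
        raise ValueError("disk area must be positive and finite")
    dd = 2.0 * np.sqrt(area / math.pi)
    return float(dd) if np.isscalar(disk_area) else dd


@dataclass(frozen=True)
class QCRule:
    """One exclusion rule: drop the eye when ``predicate(row)`` is True."""

    name: str
    description: str
    predicate: Callable[[pd.Series], bool]


def _low_ssi(row: pd.Series) -> bool:
    vals = [row.get(c) for c in _SSI_COLUMNS]
    return any(pd.notna(v) and v < 50.0 for v in vals)


def _missing(row: pd.Series) -> bool:
    cols = [c for c in _SSI_COLUMNS + _MEASUREMENT_COLUMNS
            if c in row.index]
    return bool(pd.isna(row[cols]).any())


def default_rules(per_scan_ssi: bool = False) -> list[QCRule]:
    """The standard exclusion rule set.

    ``per_scan_ssi=False`` (default) drops an eye entirely when *any* scan
    type has SSI < 50, making downstream analyses complete-case over eyes.
    With ``per_scan_ssi=True`` the SSI rule is skipped here; callers can
    then mask per-family values themselves.
    """
    rules = [
        QCRule("IOP>21", "intraocular pressure above 21 mmHg",
               lambda r: pd.notna(r.get("iop")) and r["iop"] > 21.0),
        QCRule("CDR>0.7", "cup-to-disk ratio above 0.7",
               lambda r: pd.notna(r.get("cdr")) and r["cdr"] > 0.7),
        QCRule("missing", "any missing OCT/OCTA measurement", _missing),
    ]
    if not per_scan_ssi:
        rules.insert(0, QCRule("SSI<50", "any scan SSI below 50", _low_ssi))
    return rules


def apply_exclusions(
    records: pd.DataFrame,
    rules: Sequence[QCRule] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop eyes violating any rule; return (kept, per-rule counts).

    An eye violating several rules is counted once under each rule it
    violates; ``log['excluded']`` counts unique dropped eyes.  Idempotent:
    re-applying the same rules to the kept frame drops nothing.
    """
    if rules is None:
        rules = default_rules()
    log = {rule.name: 0 for rule in rules}
    drop = np.zeros(len(records), dtype=bool)
    for i, (_, row) in enumerate(records.iterrows()):
        for rule in rules:
            if rule.predicate(row):
                log[rule.name] += 1
                drop[i] = True
    log["excluded"] = int(drop.sum())
    log["kept"] = int((~drop).sum())
    return records.loc[~drop].reset_index(drop=True), log


def stratify(se) -> str | np.ndarray:
    """Assign the refraction stratum from spherical equivalent (D).

    Intervals: high myopia SE < −6; low myopia −6 ≤ SE < −1; emmetropia
    −1 ≤ SE ≤ 1 (closed, it is the reference group); hyperopia SE > 1.
    """
    arr = np.asarray(se, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("SE must be finite")
    out = np.where(
        arr < -6.0, "high_myopia",
        np.where(arr < -1.0, "low_myopia",
                 np.where(arr <= 1.0, "emmetropia", "hyperopia")))
    return str(out) if np.isscalar(se) else out.astype(object)


def assign_strata(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the ``stratum`` column (re)derived from SE."""
    out = records.copy()
    out["stratum"] = stratify(out["se"].to_numpy())
    out["stratum"] = pd.Categorical(out["stratum"], categories=STRATA)
    return out


def single_eye_subset(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep one uniformly chosen eye per participant (seeded)."""
    rng = np.random.default_rng(seed)
    parts = []
    for _, grp in records.groupby("participant_id", sort=True):
        parts.append(grp.iloc[rng.integers(len(grp))])
    return pd.DataFrame(parts).reset_index(drop=True)
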