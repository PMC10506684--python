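"""Region and parameter-family naming conventions.

Peripapillary parameters (NFLT thickness, NFLP capillary density) are
reported globally and in eight 45-degree TSNIT-derived sectors; macular
ganglion cell complex thickness (GCCT) is reported globally and by
superior/inferior hemisphere.  Stored columns are always in right-eye
orientation (left eyes are mirrored horizontally at ingest), so sector
labels are anatomically comparable across eyes.
"""

from __future__ import annotations

#: Eight 45-degree peripapillary sectors, clockwise for a right eye:
#: temporal upper, superior temporal, superior nasal, nasal upper,
#: nasal lower, inferior nasal, inferior temporal, temporal lower.
SECTORS_8 = ("tu", "st", "sn", "nu", "nl", "in", "it", "tl")

#: Macular hemispheres for the ganglion cell complex.
HEMISPHERES = ("superior", "inferior")

#: Parameter family -> tuple of region suffixes (global first).
FAMILY_REGIONS = {
    "nflt": ("global",) + SECTORS_8,
    "gcct": ("global",) + HEMISPHERES,
    "nflp": ("global",) + SECTORS_8,
}

FAMILIES = tuple(FAMILY_REGIONS)

#: Units of each parameter family.
FAMILY_UNITS = {"nflt": "um", "gcct": "um", "nflp": "%area"}

#: Refraction strata, defined on spherical equivalent (diopters).
STRATA = ("high_myopia", "low_myopia", "emmetropia", "hyperopia")

#: Ametropia variables accepted by the piecewise models.
AMETROPIA_VARIABLES = ("AL", "SE", "DD")

#: Reference (emmetropic) values used for centering and adjustment.
#: Age and SSI references are the emmetropic mean age and the scan-quality
#: cutoff; AL reference is the emmetropic mean axial length.  SE and DD are
#: adjusted without centering (reference 0), exactly as the adjustment
#: formulas are written.
AGE_REF = 50.0
SSI_REF = 50.0
AMETROPIA_REFERENCE = {"AL": 23.7, "SE": 0.0, "DD": 0.0}


def region_column(family: str, region: str) -> str:
    """Column name carrying the raw value of *family* in *region*."""
    if family not in FAMILY_REGIONS:
        raise ValueError(f"unknown parameter family: {family!r}")
    if region not in FAMILY_REGIONS[family]:
        raise ValueError(f"unknown region {region!r} for family {family!r}")
    return f"{family}_{region}"


def ssi_column(family: str) -> str:
    """Column with the signal strength index of the scan behind *family*."""
    if family not in FAMILY_REGIONS:
        raise ValueError(f"unknown parameter family: {family!r}")
    return f"ssi_{family}"


def family_columns(family: str) -> list[str]:
    """All raw outcome columns of a family, global first."""
    return [region_column(family, r) for r in FAMILY_REGIONS[family]]
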