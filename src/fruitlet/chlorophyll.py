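"""Spectrophotometric chlorophyll quantification from ethanol extracts.

Freeze-dried tissue is extracted in 95 % ethanol and absorbance read at
664.1, 648.6 and 750.0 nm (the 750 nm reading corrects for turbidity).
Chlorophyll a and b follow the standard two-wavelength equations

    chl_a = [13.36 (A664.1 - A750) - 5.19 (A648.6 - A750)] * DF
    chl_b = [27.43 (A648.6 - A750) - 5.19 (A664.1 - A750)] * DF

with the dilution factor DF the total solvent volume (1.45 mL), and total
chlorophyll their sum.  The equations are applied literally as stated (the
nominal unit is ug per g dry weight); a dimensional account would further
divide by the extracted subsample mass, available via ``mass_normalize``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "DEFAULT_DILUTION_FACTOR_ML",
    "DEFAULT_SUBSAMPLE_MASS_G",
    "AbsorbanceTriplet",
    "ChlorophyllResult",
    "chlorophyll_a",
    "chlorophyll_b",
    "total_chlorophyll",
    "quantify",
    "content_from_concentration",
    "water_content",
]

DEFAULT_DILUTION_FACTOR_ML = 1.45
DEFAULT_SUBSAMPLE_MASS_G = 0.02

# Coefficients of the two-wavelength chlorophyll equations.
A_664 = 13.36
A_648 = 5.19
B_648 = 27.43
B_664 = 5.19


@dataclass(frozen=True)
class AbsorbanceTriplet:
    """Spectrophotometer readings for one extract (dimensionless absorbances)."""

    abs_664_1: float
    abs_648_6: float
    abs_750_0: float
    dilution_factor: float = DEFAULT_DILUTION_FACTOR_ML

    def __post_init__(self) -> None:
        for name in ("abs_664_1", "abs_648_6", "abs_750_0"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite, got {v}")
        if not self.dilution_factor > 0:
            raise ValueError("dilution_factor must be positive")


@dataclass(frozen=True)
class ChlorophyllResult:
    chl_a: float
    chl_b: float
    chl_total: float
    content_total_ug: float | None = None


def _warn_if_negative(value: float, label: str) -> float:
    if value < 0:
        warnings.warn(
            f"negative {label} ({value:.4g}); check the absorbance readings",
            stacklevel=3,
        )
    return value


def chlorophyll_a(t: AbsorbanceTriplet, mass_normalize: bool = False,
                  subsample_mass_g: float = DEFAULT_SUBSAMPLE_MASS_G) -> float:
    """Chlorophyll a from one absorbance triplet."""
    x = t.abs_664_1 - t.abs_750_0
    y = t.abs_648_6 - t.abs_750_0
    value = (A_664 * x - A_648 * y) * t.dilution_factor
    if mass_normalize:
        value /= subsample_mass_g
    return _warn_if_negative(value, "chlorophyll a")


def chlorophyll_b(t: AbsorbanceTriplet, mass_normalize: bool = False,
                  subsample_mass_g: float = DEFAULT_SUBSAMPLE_MASS_G) -> float:
    """Chlorophyll b from one absorbance triplet."""
    x = t.abs_664_1 - t.abs_750_0
    y = t.abs_648_6 - t.abs_750_0
    value = (B_648 * y - B_664 * x) * t.dilution_factor
    if mass_normalize:
        value /= subsample_mass_g
    return _warn_if_negative(value, "chlorophyll b")


def total_chlorophyll(t: AbsorbanceTriplet, mass_normalize: bool = False,
                      subsample_mass_g: float = DEFAULT_SUBSAMPLE_MASS_G) -> float:
    """Total chlorophyll = chlorophyll a + chlorophyll b."""
    return chlorophyll_a(t, mass_normalize, subsample_mass_g) + chlorophyll_b(
        t, mass_normalize, subsample_mass_g
    )


def quantify(t: AbsorbanceTriplet, dry_mass_g: float | None = None,
             mass_normalize: bool = False,
             subsample_mass_g: float = DEFAULT_SUBSAMPLE_MASS_G) -> ChlorophyllResult:
    """Chlorophyll a, b, total, and (when dry mass is given) total content in ug."""
    a = chlorophyll_a(t, mass_normalize, subsample_mass_g)
    b = chlorophyll_b(t, mass_normalize, subsample_mass_g)
    content = None if dry_mass_g is None else content_from_concentration(a + b, dry_mass_g)
    return ChlorophyllResult(chl_a=a, chl_b=b, chl_total=a + b, content_total_ug=content)


def content_from_concentration(concentration_ug_per_g: float, dry_mass_g: float) -> float:
    """Whole-fruit chlorophyll amount (ug) from concentration (ug/g DW) and dry mass (g)."""
    return concentration_ug_per_g * dry_mass_g


def water_content(fresh_g: float, dry_g: float) -> float:
    """Percent water content, 100 * (fresh - dry) / fresh."""
    if not 0 < dry_g <= fresh_g:
        raise ValueError(
            f"dry weight must satisfy 0 < dry ({dry_g} g) <= fresh ({fresh_g} g)"
        )
    return 100.0 * (fresh_g - dry_g) / fresh_g
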