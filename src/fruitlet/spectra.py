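"""Reflectance spectra on the portable Vis/NIR spectrometer's wavelength grid.

The instrument samples diffuse reflectance (arbitrary units) at 266
wavelengths from 303 to 1098 nm in 3 nm steps.  Two band-ratio indices are
computed from each spectrum:

* CCI (chlorophyll concentration index) = R(522-579) / R(640-700)
* PWI (plant water index)               = R(950-970) / R(890-900)

where R(lo-hi) is the arithmetic mean reflectance over the grid points that
fall inside the closed interval [lo, hi] nm.  The PWI numerator sits on the
~975 nm water-absorption dip, so PWI < 1 indicates water absorption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRID_START",
    "GRID_STOP",
    "GRID_STEP",
    "GRID_LENGTH",
    "CCI_NUMERATOR",
    "CCI_DENOMINATOR",
    "PWI_NUMERATOR",
    "PWI_DENOMINATOR",
    "Band",
    "Spectrum",
    "SpectralIndices",
    "make_grid",
    "band_mean",
    "band_indices",
    "compute_cci",
    "compute_pwi",
    "standardize",
    "spectra_matrix",
    "summarize_group",
    "read_spectra_csv",
    "write_summary_csv",
]

GRID_START = 303.0
GRID_STOP = 1098.0
GRID_STEP = 3.0
GRID_LENGTH = 266


def make_grid() -> np.ndarray:
    """Return the canonical wavelength grid 303, 306, ..., 1098 nm (266 points)."""
    return GRID_START + GRID_STEP * np.arange(GRID_LENGTH)


@dataclass(frozen=True)
class Band:
    """Closed wavelength interval [lo, hi] in nm used for a band mean."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band lo must be < hi, got [{self.lo}, {self.hi}]")
        if self.lo < GRID_START or self.hi > GRID_STOP:
            raise ValueError(
                f"band [{self.lo}, {self.hi}] outside instrument range "
                f"[{GRID_START}, {GRID_STOP}] nm"
            )


CCI_NUMERATOR = Band(522.0, 579.0)
CCI_DENOMINATOR = Band(640.0, 700.0)
PWI_NUMERATOR = Band(950.0, 970.0)
PWI_DENOMINATOR = Band(890.0, 900.0)


@dataclass
class Spectrum:
    """One fruit's reflectance spectrum on the canonical grid.

    ``trichome_state`` records whether the fruit was measured intact or after
    trichome removal.  Input wavelengths that deviate from the canonical grid
    are linearly interpolated onto it (with a warning).
    """

    reflectance: np.ndarray
    label: str = ""
    trichome_state: str = "intact"
    wavelengths: np.ndarray = field(default_factory=make_grid)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.trichome_state not in ("intact", "removed"):
            raise ValueError(f"unknown trichome_state {self.trichome_state!r}")
        if self.reflectance.shape != self.wavelengths.shape:
            raise ValueError(
                f"reflectance length {self.reflectance.size} does not match "
                f"wavelength grid length {self.wavelengths.size}"
            )
        grid = make_grid()
        if not np.array_equal(self.wavelengths, grid):
            warnings.warn(
                f"spectrum {self.label!r}: wavelengths differ from the canonical "
                "303-1098 nm / 3 nm grid; interpolating",
                stacklevel=2,
            )
            self.reflectance = np.interp(grid, self.wavelengths, self.reflectance)
            self.wavelengths = grid
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError(f"spectrum {self.label!r} has non-finite reflectance")
        if np.any(self.reflectance < 0):
            raise ValueError(f"spectrum {self.label!r} has negative reflectance")


@dataclass(frozen=True)
class SpectralIndices:
    cci: float
    pwi: float


def band_indices(band: Band, wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Grid indices whose wavelength lies in the closed interval [lo, hi]."""
    wl = make_grid() if wavelengths is None else np.asarray(wavelengths)
    idx = np.flatnonzero((wl >= band.lo) & (wl <= band.hi))
    if idx.size == 0:
        raise ValueError(
            f"band [{band.lo}, {band.hi}] nm contains no grid points "
            f"(grid step {GRID_STEP} nm)"
        )
    return idx


def band_mean(spectrum: Spectrum, band: Band) -> float:
    """Mean reflectance over the grid points inside ``band`` (endpoints included)."""
    idx = band_indices(band, spectrum.wavelengths)
    return float(np.mean(spectrum.reflectance[idx]))


def _band_ratio(spectrum: Spectrum, numerator: Band, denominator: Band) -> float:
    den = band_mean(spectrum, denominator)
    if den == 0.0:
        raise ZeroDivisionError(
            f"zero mean reflectance in denominator band "
            f"[{denominator.lo}, {denominator.hi}] nm for {spectrum.label!r}"
        )
    return band_mean(spectrum, numerator) / den


def compute_cci(spectrum: Spectrum) -> float:
    """Chlorophyll concentration index R(522-579)/R(640-700)."""
    return _band_ratio(spectrum, CCI_NUMERATOR, CCI_DENOMINATOR)


def compute_pwi(spectrum: Spectrum) -> float:
    """Plant water index R(950-970)/R(890-900)."""
    return _band_ratio(spectrum, PWI_NUMERATOR, PWI_DENOMINATOR)


def compute_indices(spectrum: Spectrum) -> SpectralIndices:
    return SpectralIndices(cci=compute_cci(spectrum), pwi=compute_pwi(spectrum))


def spectra_matrix(spectra: Sequence[Spectrum] | np.ndarray) -> np.ndarray:
    """Stack spectra into an (n_fruit, 266) matrix."""
    if isinstance(spectra, np.ndarray):
        mat = np.asarray(spectra, dtype=float)
        if mat.ndim != 2:
            raise ValueError("expected a 2-D matrix of spectra")
        return mat
    return np.vstack([s.reflectance for s in spectra])


def standardize(spectra: Sequence[Spectrum] | np.ndarray) -> np.ndarray:
    """Per-wavelength z-scores (sample sd, n-1 denominator).

    Each column of the result has mean 0 and sample standard deviation 1.
    A zero-variance wavelength is an error: a constant column carries no
    information and would divide by zero.
    """
    mat = spectra_matrix(spectra)
    if mat.shape[0] < 2:
        raise ValueError("standardize requires at least 2 spectra")
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        wl = make_grid()
        bad = wl[zero[0]] if mat.shape[1] == GRID_LENGTH else zero[0]
        raise ValueError(f"zero variance at wavelength {bad} nm; cannot standardize")
    return (mat - mean) / sd


def summarize_group(spectra: Sequence[Spectrum] | np.ndarray) -> pd.DataFrame:
    """Per-wavelength mean, sample sd and standard error (sd/sqrt(n)) curves."""
    mat = spectra_matrix(spectra)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("summarize_group requires at least 2 spectra")
    sd = mat.std(axis=0, ddof=1)
    return pd.DataFrame(
        {
            "wavelength_nm": make_grid() if mat.shape[1] == GRID_LENGTH else np.arange(mat.shape[1]),
            "mean": mat.mean(axis=0),
            "sd": sd,
            "se": sd / np.sqrt(n),
        }
    )


def read_spectra_csv(path) -> list[Spectrum]:
    """Read spectra from CSV, wide or long format.

    Wide: header ``wavelength_nm,<fruit_id_1>,...``; one row per wavelength.
    Long: columns ``fruit_id,wavelength_nm,reflectance``.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"fruit_id", "wavelength_nm", "reflectance"} <= cols:
        out = []
        for fid, sub in df.groupby("fruit_id", sort=False):
            sub = sub.sort_values("wavelength_nm")
            out.append(
                Spectrum(
                    reflectance=sub["reflectance"].to_numpy(),
                    wavelengths=sub["wavelength_nm"].to_numpy(),
                    label=str(fid),
                )
            )
        return out
    if "wavelength_nm" not in cols:
        raise ValueError(f"{path}: expected a 'wavelength_nm' column")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    return [
        Spectrum(reflectance=df[c].to_numpy(dtype=float), wavelengths=wl, label=str(c))
        for c in df.columns
        if c != "wavelength_nm"
    ]


def write_spectra_csv(path, spectra: Iterable[Spectrum]) -> None:
    """Write spectra in the wide CSV layout (one column per fruit)."""
    data = {"wavelength_nm": make_grid()}
    for s in spectra:
        data[s.label] = s.reflectance
    pd.DataFrame(data).to_csv(path, index=False)


def write_summary_csv(path, summary: pd.DataFrame) -> None:
    summary.to_csv(path, index=False)
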