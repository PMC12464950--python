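"""Synthetic fruitlet cohorts: weights, chlorophyll, trichomes, spectra, images.

The generator emulates two apple cultivars ('Fuji', 'Honeycrisp') sampled on
two dates each during early fruit development (20-36 days after full bloom):

* fresh weights uniform on the per-date ranges observed in the field;
* dry weight linear in fresh weight (slopes 0.132 / 0.124 g/g), with the
  intercept solved so the expected water content is 85 %;
* chlorophyll concentration declining ~linearly with fresh weight, with a
  ~250 ug/g DW offset between cultivars and a shared slope;
* trichome percent coverage declining linearly with weight at each of three
  positions (calyx end steepest, crossing the pedicel line at ~6.5 g for
  Fuji and ~2.5 g for Honeycrisp);
* diffuse reflectance spectra from a lens-coverage mixture model: the
  measured spectrum is f * R_tissue + (1 - f) * R_background, where the
  coverage fraction f = min(1, (w / w_sat)^(2/3)) saturates once the fruit
  fully covers the fixed spectrometer lens (~5.0 g Fuji, ~2.25 g Honeycrisp).
  R_tissue is a smooth broadband template attenuated by Gaussian absorbers
  for chlorophyll (blue, green-orange trough and red chlorophyll-a band) and
  water (~975 nm);
* tape-strip micrographs rendered as random bright fiber segments (~1 mm) on
  a dark background, with an exact ground-truth mask;
* spectrophotometer absorbance triplets obtained by inverting the
  two-wavelength chlorophyll equations.

All functional forms beyond the linear trends are descriptive stand-ins
whose few free constants are calibrated once against the reference anchors
in ``REFERENCE_ANCHORS`` (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .chlorophyll import DEFAULT_DILUTION_FACTOR_ML, AbsorbanceTriplet, water_content
from .spectra import Spectrum, compute_cci, compute_pwi, make_grid
from .trichomes import Micrograph

__all__ = [
    "WATER_TARGET_PCT",
    "BACKGROUND_REFLECTANCE",
    "REFERENCE_ANCHORS",
    "TrichomeLine",
    "CultivarParams",
    "CohortConfig",
    "Cohort",
    "fuji_params",
    "honeycrisp_params",
    "default_cohort_configs",
    "cultivar_params",
    "coverage_fraction",
    "tissue_reflectance",
    "measured_spectrum",
    "generate_trichome_image",
    "absorbance_from_chlorophyll",
    "generate_cohort",
    "generate_default_cohorts",
    "default_pca_spectra",
    "solve_dry_intercept",
]

# Expected water content of young fruitlets (percent of fresh weight).
WATER_TARGET_PCT = 85.0

# Reflectance of the uncovered part of the lens / instrument background (a.u.).
BACKGROUND_REFLECTANCE = 0.35

# Smooth broadband tissue template: control points (nm, a.u.) interpolated
# monotonically.  Shape: rise from the UV edge to a ~425 nm peak, a trough
# through the green-orange region, an NIR plateau at ~750-900 nm, and a
# slight decline toward 1098 nm.
_TEMPLATE_POINTS = np.array(
    [
        (303.0, 0.12),
        (375.0, 0.15),
        (425.0, 0.55),
        (560.0, 0.45),
        (700.0, 0.55),
        (750.0, 0.85),
        (900.0, 0.85),
        (1098.0, 0.80),
    ]
)
_TEMPLATE = PchipInterpolator(_TEMPLATE_POINTS[:, 0], _TEMPLATE_POINTS[:, 1])

# Chlorophyll absorber: unit-height Gaussians in the blue (Soret region),
# the green-orange trough that forms the 560-640 nm reflectance minimum,
# and the red chlorophyll-a absorption band near 675 nm.  The red band is
# what makes the green/red band ratio (CCI) increase with chlorophyll.
_CHL_BANDS = ((430.0, 30.0, 1.0), (600.0, 45.0, 1.0), (675.0, 25.0, 1.0))
# Water absorber: the ~975 nm dip.
_WATER_BAND = (975.0, 25.0)

# Calibration anchors the generator's free constants target: value, tolerance.
REFERENCE_ANCHORS = {
    "fuji_dry_slope": (0.132, 0.01),
    "honeycrisp_dry_slope": (0.124, 0.01),
    "mean_water_pct": (85.0, 2.0),
    "fuji_cci_vertex_g": (5.0, 0.5),
    "honeycrisp_pwi_vertex_g": (2.5, 0.5),
    "fuji_chl_content_weight_r": (0.944, 0.05),
    "pc1_explained_pct": (86.56, 5.0),
}


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-(((wl - center) / sigma) ** 2))


@dataclass(frozen=True)
class TrichomeLine:
    """Linear trend of percent coverage vs fresh weight at one position."""

    intercept_pct: float
    slope_pct_per_g: float

    def __call__(self, fresh_g):
        return self.intercept_pct + self.slope_pct_per_g * np.asarray(fresh_g, dtype=float)


@dataclass(frozen=True)
class CultivarParams:
    """Generative parameters for one cultivar.

    ``dry_intercept_g`` of None means "solve so that expected water content
    is 85 % over the cultivar's default date cohorts".
    """

    name: str
    dry_slope: float
    w_sat_g: float
    chl_conc_intercept: float        # ug/g DW at zero weight
    chl_conc_slope: float            # ug/g DW per g fresh weight (shared)
    trichome_calyx: TrichomeLine
    trichome_centre: TrichomeLine
    trichome_pedicel: TrichomeLine
    dry_intercept_g: float | None = None
    dry_noise_rel: float = 0.05      # relative sd of dry weight
    chl_noise_rel: float = 0.10      # relative sd of chlorophyll concentration
    trichome_noise_sd: float = 8.0   # additive sd, percentage points
    chl_a_fraction: float = 0.74     # chlorophyll a share of total
    # Spectral model constants (shared defaults, calibrated once).
    chl_absorber_per_conc: float = 1.8e-3   # optical depth per ug/g DW
    water_absorber_max: float = 0.30        # optical depth at lens saturation
    water_decay_exponent: float = 1.5       # post-saturation dilution rate
    chl_depth_decay: float = 0.40           # post-saturation areal chl dilution
    trichome_reflectance_gain: float = 0.05 # broadband gain per unit mean coverage
    scatter_gain_exponent: float = 0.14     # tissue backscatter growth with size
    amplitude_jitter_sd: float = 0.005      # lognormal per-spectrum scale sd
    additive_noise_sd: float = 0.001        # white noise sd (a.u.)
    absorbance_noise_sd: float = 0.003      # spectrophotometer noise

    def __post_init__(self) -> None:
        if not 0 < self.dry_slope < 1:
            raise ValueError("dry_slope must lie in (0, 1)")
        if not self.w_sat_g > 0:
            raise ValueError("w_sat_g must be positive")
        if not self.chl_conc_slope < 0:
            raise ValueError("chl_conc_slope must be negative (declining with size)")


def fuji_params() -> CultivarParams:
    return CultivarParams(
        name="Fuji",
        dry_slope=0.132,
        w_sat_g=5.0,
        chl_conc_intercept=1100.0,
        chl_conc_slope=-60.0,
        trichome_calyx=TrichomeLine(45.0, -4.0),
        trichome_centre=TrichomeLine(26.0, -1.5),
        trichome_pedicel=TrichomeLine(32.0, -2.0),
        dry_noise_rel=0.056,
        trichome_noise_sd=10.0,
    )


def honeycrisp_params() -> CultivarParams:
    return CultivarParams(
        name="Honeycrisp",
        dry_slope=0.124,
        w_sat_g=2.25,
        chl_conc_intercept=850.0,
        chl_conc_slope=-60.0,
        trichome_calyx=TrichomeLine(50.0, -8.0),
        trichome_centre=TrichomeLine(30.0, -1.8),
        trichome_pedicel=TrichomeLine(35.0, -2.0),
        dry_noise_rel=0.10,
        trichome_noise_sd=5.0,
    )


def cultivar_params(name: str) -> CultivarParams:
    key = name.strip().lower()
    if key == "fuji":
        return fuji_params()
    if key == "honeycrisp":
        return honeycrisp_params()
    raise ValueError(f"unknown cultivar {name!r} (expected Fuji or Honeycrisp)")


@dataclass
class CohortConfig:
    """One cultivar x sampling-date cohort."""

    cultivar: str
    dafb: int
    n: int
    weight_range_g: tuple[float, float]
    seed: int | Sequence[int] = 0

    def __post_init__(self) -> None:
        lo, hi = self.weight_range_g
        if self.n <= 0:
            raise ValueError("cohort size n must be positive")
        if not 0 < lo < hi:
            raise ValueError(f"weight range must satisfy 0 < min < max, got {self.weight_range_g}")


def default_cohort_configs(seed: int = 0) -> list[CohortConfig]:
    """The four field cohorts: per-date sample sizes and fresh-weight ranges."""
    base = [
        CohortConfig("Fuji", 23, 47, (0.19, 1.65)),
        CohortConfig("Fuji", 36, 45, (2.10, 10.30)),
        CohortConfig("Honeycrisp", 20, 36, (0.17, 0.88)),
        CohortConfig("Honeycrisp", 29, 29, (0.48, 2.86)),
    ]
    for i, cfg in enumerate(base):
        cfg.seed = (int(seed) % (2**31), i)
    return base


def solve_dry_intercept(params: CultivarParams,
                        configs: Sequence[CohortConfig] | None = None) -> float:
    """Dry-weight intercept making expected water content equal 85 %.

    With dry = a + b*w and water% = 100*(1 - dry/w), the expectation over the
    cultivar's sampled weights requires b + a*E[1/w] = 1 - 0.85.  E[1/w] for a
    uniform weight on (lo, hi) is log(hi/lo)/(hi - lo); the cultivar's two
    date cohorts are mixed with their sample-size weights.
    """
    if configs is None:
        configs = [c for c in default_cohort_configs() if c.cultivar == params.name]
    if not configs:
        raise ValueError(f"no cohort configs for cultivar {params.name!r}")
    total_n = sum(c.n for c in configs)
    e_inv = sum(
        c.n * np.log(c.weight_range_g[1] / c.weight_range_g[0])
        / (c.weight_range_g[1] - c.weight_range_g[0])
        for c in configs
    ) / total_n
    a = (1.0 - WATER_TARGET_PCT / 100.0 - params.dry_slope) / e_inv
    if a <= 0:
        raise ValueError(
            f"dry_slope {params.dry_slope} already exceeds the dry-matter fraction "
            f"implied by {WATER_TARGET_PCT} % water"
        )
    return float(a)


def coverage_fraction(fresh_g: float, w_sat_g: float) -> float:
    """Fraction of the lens covered by a fruit of the given fresh weight.

    Cross-sectional area scales as weight^(2/3); coverage saturates at 1 once
    the fruit outgrows the lens (fresh weight >= w_sat).
    """
    if fresh_g <= 0:
        return 0.0
    return float(min(1.0, (fresh_g / w_sat_g) ** (2.0 / 3.0)))


def tissue_reflectance(wavelengths: np.ndarray, c_chl: float, c_wat: float,
                       trichome_term: float = 0.0) -> np.ndarray:
    """Reflectance of fully-covering tissue at the given optical depths.

    R(lambda) = B(lambda) * exp(-c_chl * A_chl) * exp(-c_wat * A_wat)
                * (1 + trichome_term)

    where B is the broadband template and A_chl / A_wat are the Gaussian
    absorber profiles defined at module level.
    """
    wl = np.asarray(wavelengths, dtype=float)
    a_chl = np.zeros_like(wl)
    for center, sigma, weight in _CHL_BANDS:
        a_chl += weight * _gauss(wl, center, sigma)
    a_wat = _gauss(wl, *_WATER_BAND)
    return (
        _TEMPLATE(wl)
        * np.exp(-c_chl * a_chl)
        * np.exp(-c_wat * a_wat)
        * (1.0 + trichome_term)
    )


def _water_depth(fresh_g: float, params: CultivarParams, f: float) -> float:
    # Unimodal in weight: grows with lens coverage pre-saturation, then
    # declines as tissue water per sensed area dilutes; minimum PWI at w_sat.
    ratio = params.w_sat_g / max(fresh_g, params.w_sat_g)
    return params.water_absorber_max * f * ratio**params.water_decay_exponent


def measured_spectrum(fresh_g: float, chl_conc: float, trichome_mean_pct: float,
                      params: CultivarParams, rng: np.random.Generator | None = None,
                      noise: bool = True, label: str = "",
                      trichome_state: str = "intact") -> Spectrum:
    """Simulate one instrument reading via the lens-coverage mixture model."""
    wl = make_grid()
    f = coverage_fraction(fresh_g, params.w_sat_g)
    # Sensed chlorophyll optical depth tracks concentration; past lens
    # saturation it falls off faster than per-dry-mass concentration as
    # expanding, water-filled cortex cells dilute chlorophyll along the
    # optical path.
    area_dilution = (params.w_sat_g / max(fresh_g, params.w_sat_g)) ** params.chl_depth_decay
    c_chl = params.chl_absorber_per_conc * max(chl_conc, 0.0) * area_dilution
    c_wat = _water_depth(fresh_g, params, f)
    term = 0.0
    if trichome_state == "intact":
        term = params.trichome_reflectance_gain * trichome_mean_pct / 100.0
    tissue = tissue_reflectance(wl, c_chl, c_wat, term)
    # Thicker tissue backscatters more NIR: the 750-900 nm plateau keeps
    # rising with fruit size, also beyond lens saturation, while the visible
    # region stays absorption-dominated.  The gain ramps in above ~750 nm,
    # so it never touches the CCI bands and scales both PWI bands equally
    # (the ratio is unaffected).
    gain = (max(fresh_g, 0.05)) ** params.scatter_gain_exponent
    nir_ramp = 1.0 / (1.0 + np.exp(-(wl - 760.0) / 15.0))
    tissue = tissue * (1.0 + (gain - 1.0) * nir_ramp)
    refl = f * tissue + (1.0 - f) * BACKGROUND_REFLECTANCE
    if noise:
        if rng is None:
            raise ValueError("noise=True requires an rng")
        refl = refl * rng.lognormal(0.0, params.amplitude_jitter_sd)
        refl = refl + rng.normal(0.0, params.additive_noise_sd, size=wl.size)
    return Spectrum(
        reflectance=np.clip(refl, 0.0, None),
        label=label,
        trichome_state=trichome_state,
        wavelengths=wl,
    )


# ---------------------------------------------------------------------------
# Tape-strip micrograph rendering
# ---------------------------------------------------------------------------

# Foreground/background intensity distributions; the clip ranges keep the two
# levels strictly separated so a midpoint threshold recovers the truth mask.
_FG_MEAN, _FG_SD, _FG_CLIP = 230.0, 10.0, (180, 255)
_BG_MEAN, _BG_SD, _BG_CLIP = 20.0, 5.0, (0, 80)
_TRICHOME_LENGTH_MM = 1.0
_MAX_COVERAGE_PCT = 95.0

DEFAULT_IMAGE_SHAPE = (480, 360)    # rows x cols; 1.33 long/short aspect
DEFAULT_MM_PER_PIXEL = 0.025


def _segment_pixels(rng: np.random.Generator, shape: tuple[int, int],
                    mm_per_pixel: float, row_range: tuple[float, float]):
    """Pixel indices of one randomly placed, randomly oriented fiber segment."""
    from skimage.draw import polygon

    length = _TRICHOME_LENGTH_MM / mm_per_pixel * rng.uniform(0.9, 1.1)
    width = rng.uniform(2.0, 3.0)
    theta = rng.uniform(0.0, np.pi)
    cr = rng.uniform(*row_range)
    cc = rng.uniform(0, shape[1])
    dr, dc = np.sin(theta) * length / 2, np.cos(theta) * length / 2
    # Perpendicular half-width offsets.
    pr, pc = np.cos(theta) * width / 2, -np.sin(theta) * width / 2
    rows = np.array([cr - dr - pr, cr - dr + pr, cr + dr + pr, cr + dr - pr])
    cols = np.array([cc - dc - pc, cc - dc + pc, cc + dc + pc, cc + dc - pc])
    return polygon(rows, cols, shape=shape)


def generate_trichome_image(target_pct, shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
                            mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
                            rng: np.random.Generator | None = None) -> Micrograph:
    """Render a synthetic tape-strip micrograph with known coverage.

    ``target_pct`` is either a single percent-coverage target for the whole
    strip, or a (calyx, centre, pedicel) triple realised as per-third targets
    along the strip's long axis.  Bright fiber segments (~1 mm long, 2-3 px
    wide) are added until each region reaches its target; the exact rendered
    foreground is returned as ``truth_mask``.
    """
    if rng is None:
        rng = np.random.default_rng()
    targets = np.atleast_1d(np.asarray(target_pct, dtype=float))
    if targets.size not in (1, 3):
        raise ValueError("target_pct must be a scalar or a (calyx, centre, pedicel) triple")
    if np.any(targets < 0) or np.any(targets > _MAX_COVERAGE_PCT):
        raise ValueError(f"coverage targets must lie in [0, {_MAX_COVERAGE_PCT}] %")

    nrow, ncol = shape
    if nrow < ncol:
        raise ValueError("strip images put the long axis on rows; expected rows >= cols")
    # Render on a canvas padded by one fiber length and crop: fiber centres
    # falling just outside the image still contribute partial fibers, so the
    # rendered density is stationary right up to the image border (no edge
    # depletion biasing the ROIs, which sit in the interior).
    pad = int(np.ceil(1.1 * _TRICHOME_LENGTH_MM / mm_per_pixel))
    pshape = (nrow + 2 * pad, ncol + 2 * pad)
    pmask = np.zeros(pshape, dtype=bool)
    crop = (slice(pad, pad + nrow), slice(pad, pad + ncol))
    if targets.size == 1:
        regions = [(0, nrow)]
    else:
        thirds = [0, nrow // 3, 2 * nrow // 3, nrow]
        regions = list(zip(thirds[:-1], thirds[1:]))

    for (r0, r1), target in zip(regions, targets):
        region = (slice(pad + r0, pad + r1), slice(pad, pad + ncol))
        region_px = (r1 - r0) * ncol
        goal = target / 100.0 * region_px
        covered = int(np.count_nonzero(pmask[region]))
        guard = 0
        while covered < goal:
            rr, cc = _segment_pixels(rng, pshape, mm_per_pixel, (r0, r1 + 2 * pad))
            pmask[rr, cc] = True
            covered = int(np.count_nonzero(pmask[region]))
            guard += 1
            if guard > 200_000:
                raise RuntimeError("coverage target appears unreachable")

    mask = pmask[crop]
    pixels = rng.normal(_BG_MEAN, _BG_SD, size=shape)
    pixels[mask] = rng.normal(_FG_MEAN, _FG_SD, size=int(mask.sum()))
    lo = np.where(mask, _FG_CLIP[0], _BG_CLIP[0])
    hi = np.where(mask, _FG_CLIP[1], _BG_CLIP[1])
    pixels = np.clip(pixels, lo, hi)
    return Micrograph(pixels=pixels.astype(np.uint8), mm_per_pixel=mm_per_pixel,
                      truth_mask=mask)


# ---------------------------------------------------------------------------
# Absorbance triplets (inverse of the chlorophyll equations)
# ---------------------------------------------------------------------------

# Matrix of the two-wavelength equations acting on the turbidity-corrected
# absorbance differences (x, y) = (A664.1 - A750, A648.6 - A750).
_CHL_MATRIX = np.array([[13.36, -5.19], [-5.19, 27.43]])


def absorbance_from_chlorophyll(chl_a_target: float, chl_b_target: float,
                                dilution_factor: float = DEFAULT_DILUTION_FACTOR_ML,
                                rng: np.random.Generator | None = None,
                                noise_sd: float = 0.0) -> AbsorbanceTriplet:
    """Absorbance triplet whose chlorophyll equations recover the targets.

    Solves the 2x2 linear system for the turbidity-corrected differences,
    places the 750 nm baseline near 0.01, and optionally adds Gaussian
    reading noise to each absorbance.
    """
    x, y = np.linalg.solve(_CHL_MATRIX,
                           np.array([chl_a_target, chl_b_target]) / dilution_factor)
    a750 = 0.01
    noise = np.zeros(3)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        noise = rng.normal(0.0, noise_sd, size=3)
    return AbsorbanceTriplet(
        abs_664_1=float(a750 + x + noise[0]),
        abs_648_6=float(a750 + y + noise[1]),
        abs_750_0=float(a750 + noise[2]),
        dilution_factor=dilution_factor,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """One generated cultivar x date cohort with all raw artefacts."""

    config: CohortConfig
    params: CultivarParams
    records: pd.DataFrame
    spectra: list[Spectrum]
    absorbance: pd.DataFrame
    micrographs: dict[str, Micrograph] = field(default_factory=dict)


def generate_cohort(config: CohortConfig, params: CultivarParams | None = None,
                    noise: bool = True, with_images: bool = False,
                    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
                    image_mm_per_pixel: float = DEFAULT_MM_PER_PIXEL) -> Cohort:
    """Generate one cohort of fruit records plus spectra, triplets and images.

    All randomness derives from ``config.seed``; independent child streams
    drive biology, spectra, micrographs and absorbance readings, so the
    record table is identical whether or not images are rendered.
    """
    if params is None:
        params = cultivar_params(config.cultivar)
    if params.dry_intercept_g is None:
        params = replace(params, dry_intercept_g=solve_dry_intercept(params))

    ss = np.random.SeedSequence(config.seed)
    rng_bio, rng_spec, rng_img, rng_abs = (np.random.default_rng(s) for s in ss.spawn(4))

    n = config.n
    lo, hi = config.weight_range_g
    fresh = rng_bio.uniform(lo, hi, size=n)
    dry_line = params.dry_intercept_g + params.dry_slope * fresh
    dry = dry_line * (1.0 + (rng_bio.normal(0.0, params.dry_noise_rel, n) if noise else 0.0))
    dry = np.clip(dry, 0.01 * fresh, 0.95 * fresh)

    conc_line = np.maximum(params.chl_conc_intercept + params.chl_conc_slope * fresh, 0.0)
    conc = conc_line * (1.0 + (rng_bio.normal(0.0, params.chl_noise_rel, n) if noise else 0.0))
    conc = np.maximum(conc, 0.0)
    chl_a = params.chl_a_fraction * conc
    chl_b = conc - chl_a
    content = conc * dry

    tri = {}
    for pos, line in (("calyx", params.trichome_calyx),
                      ("centre", params.trichome_centre),
                      ("pedicel", params.trichome_pedicel)):
        true = line(fresh)
        if noise:
            true = true + rng_bio.normal(0.0, params.trichome_noise_sd, n)
        tri[pos] = np.clip(true, 0.0, 100.0)

    prefix = f"{config.cultivar[:2].upper()}{config.dafb}"
    ids = [f"{prefix}_{i:03d}" for i in range(n)]

    spectra_list, cci, pwi, triplets = [], [], [], []
    for i in range(n):
        tri_mean = (tri["calyx"][i] + tri["centre"][i] + tri["pedicel"][i]) / 3.0
        s = measured_spectrum(fresh[i], conc[i], tri_mean, params,
                              rng=rng_spec if noise else None, noise=noise,
                              label=ids[i])
        spectra_list.append(s)
        cci.append(compute_cci(s))
        pwi.append(compute_pwi(s))
        t = absorbance_from_chlorophyll(
            chl_a[i], chl_b[i],
            rng=rng_abs if noise else None,
            noise_sd=params.absorbance_noise_sd if noise else 0.0,
        )
        triplets.append(t)

    micrographs: dict[str, Micrograph] = {}
    if with_images:
        for i, fid in enumerate(ids):
            target = np.clip(
                [tri["calyx"][i], tri["centre"][i], tri["pedicel"][i]], 0.0, 90.0
            )
            micrographs[fid] = generate_trichome_image(
                target, shape=image_shape, mm_per_pixel=image_mm_per_pixel, rng=rng_img
            )

    records = pd.DataFrame(
        {
            "fruit_id": ids,
            "cultivar": config.cultivar,
            "dafb": config.dafb,
            "fresh_g": fresh,
            "dry_g": dry,
            "water_pct": [water_content(f, d) for f, d in zip(fresh, dry)],
            "chl_conc": conc,
            "chl_a": chl_a,
            "chl_b": chl_b,
            "chl_content_ug": content,
            "trichome_calyx_pct": tri["calyx"],
            "trichome_centre_pct": tri["centre"],
            "trichome_pedicel_pct": tri["pedicel"],
            "cci": cci,
            "pwi": pwi,
        }
    )
    absorbance = pd.DataFrame(
        {
            "fruit_id": ids,
            "abs_664_1": [t.abs_664_1 for t in triplets],
            "abs_648_6": [t.abs_648_6 for t in triplets],
            "abs_750_0": [t.abs_750_0 for t in triplets],
            "dry_mass_g": dry,
        }
    )
    return Cohort(config=config, params=params, records=records,
                  spectra=spectra_list, absorbance=absorbance, micrographs=micrographs)


def generate_default_cohorts(seed: int = 0, noise: bool = True,
                             with_images: bool = False) -> list[Cohort]:
    """Generate the four default cultivar x date cohorts (157 fruit)."""
    return [
        generate_cohort(cfg, noise=noise, with_images=with_images)
        for cfg in default_cohort_configs(seed)
    ]


def default_pca_spectra(cohorts: Sequence[Cohort],
                        second_fuji_n: int = 43) -> list[Spectrum]:
    """The 155-spectrum subset used for the combined PCA.

    The second Fuji date contributes its first ``second_fuji_n`` fruit (43 by
    default), mirroring the field analysis in which two of that cohort's
    spectra were excluded.
    """
    out: list[Spectrum] = []
    for c in cohorts:
        spectra = c.spectra
        if c.config.cultivar == "Fuji" and c.config.dafb == 36:
            spectra = spectra[:second_fuji_n]
        out.extend(spectra)
    return out
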