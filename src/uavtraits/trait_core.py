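"""Trait formulas, canopy forward model and sensor spectral handling.

The quantities handled here are the three retrievable crop traits --
leaf area index (LAI, m2/m2), fractional vegetation cover (fCover, 0-1)
and canopy chlorophyll content (CCC, g/m2) -- together with the leaf-level
chlorophyll content (LCC, ug/cm2) and the vertical crown cover Cv that
link them:

    fCover = Cv * (1 - exp(-k * LAI))        (Lambert-Beer gap fraction)
    CCC    = 0.01 * LAI * LCC                (ug/cm2 -> g/m2)
    LCC    = 0.0913 * exp(0.0415 * SPAD)     (SPAD meter transfer function)

A bundled analytic "mini-RTM" maps a trait sample plus a fixed-parameter
ledger to a 1-nm canopy reflectance spectrum.  It is deliberately simple --
a soil line, a chlorophyll-controlled red edge and an LAI/Cv-controlled
vegetation fraction -- but honours the qualitative monotonicities a
physical soil-leaf-canopy model would show, so the inversion and
machine-learning stages can be exercised end to end.  Any external
PROSPECT/SAIL-class model can be plugged in behind the same callable
contract ``(traits, fixed, grid) -> reflectance``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DEFAULT_K_EXT",
    "TraitSample",
    "FixedCanopyParams",
    "MiniRTMConstants",
    "SensorModel",
    "Spectrum",
    "spad_to_lcc",
    "lcc_to_spad",
    "fcover_from",
    "ccc_from",
    "simulate_canopy",
    "simulate_canopy_batch",
    "resample_to_sensor",
    "resampling_matrix",
    "add_noise",
    "default_grid",
]

#: Vertical extinction coefficient of the gap-fraction model.
DEFAULT_K_EXT = 0.55

#: 1-nm wavelength grid (nm) supported by the bundled forward model.
MINI_RTM_RANGE = (400.0, 1000.0)


def default_grid() -> np.ndarray:
    """1-nm grid covering the bundled forward model's supported range."""
    lo, hi = MINI_RTM_RANGE
    return np.arange(lo, hi + 0.5, 1.0)


# ---------------------------------------------------------------------------
# Trait formulas
# ---------------------------------------------------------------------------

def spad_to_lcc(spad: float) -> float:
    """Convert a SPAD-502 reading to leaf chlorophyll content.

    Uses the exponential transfer function ``LCC = 0.0913 * e^(0.0415*SPAD)``
    in the units in which it was published.  Note this calibration is
    crop-specific; see the package documentation for caveats.
    """
    spad = float(spad)
    if not math.isfinite(spad) or spad < 0:
        raise ValueError(f"SPAD reading must be finite and >= 0, got {spad}")
    return 0.0913 * math.exp(0.0415 * spad)


def lcc_to_spad(lcc: float) -> float:
    """Inverse of :func:`spad_to_lcc` (for synthetic metadata only)."""
    lcc = float(lcc)
    if not math.isfinite(lcc) or lcc <= 0:
        raise ValueError(f"LCC must be finite and > 0, got {lcc}")
    return math.log(lcc / 0.0913) / 0.0415


def fcover_from(cv, lai, k: float = DEFAULT_K_EXT):
    """Fractional vegetation cover from crown cover and LAI.

    ``fCover = Cv * (1 - exp(-k*LAI))``: the vertically projected crown
    fraction times the within-crown interception following Lambert-Beer.
    Accepts scalars or arrays.
    """
    cv_a = np.asarray(cv, dtype=float)
    lai_a = np.asarray(lai, dtype=float)
    if k <= 0:
        raise ValueError(f"extinction coefficient k must be > 0, got {k}")
    if np.any(cv_a < 0) or np.any(cv_a > 1):
        raise ValueError("Cv must lie in [0, 1]")
    if np.any(lai_a < 0):
        raise ValueError("LAI must be >= 0")
    out = cv_a * (1.0 - np.exp(-k * lai_a))
    return float(out) if np.isscalar(cv) and np.isscalar(lai) else out


def ccc_from(lai, lcc):
    """Canopy chlorophyll content (g/m2) = LAI x leaf chlorophyll.

    LCC in ug/cm2 converts to g/m2 with the factor 0.01.
    """
    lai_a = np.asarray(lai, dtype=float)
    lcc_a = np.asarray(lcc, dtype=float)
    if np.any(lai_a < 0) or np.any(lcc_a < 0):
        raise ValueError("LAI and LCC must be >= 0")
    out = 0.01 * lai_a * lcc_a
    return float(out) if np.isscalar(lai) and np.isscalar(lcc) else out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TraitSample:
    """One canopy parameterisation: free traits plus derived quantities.

    ``fcover`` and ``ccc`` are derived deterministically from (cv, lai)
    and (lai, lcc); :meth:`derive` fills them in.
    """

    lai: float          # m2/m2
    lcc: float          # ug/cm2
    cv: float           # vertical crown cover fraction
    fcover: float | None = None
    ccc: float | None = None
    n_struct: float | None = None  # leaf structure parameter override

    def derive(self, k: float = DEFAULT_K_EXT) -> "TraitSample":
        return replace(
            self,
            fcover=fcover_from(self.cv, self.lai, k),
            ccc=ccc_from(self.lai, self.lcc),
        )


@dataclass
class FixedCanopyParams:
    """Fixed-parameter ledger of the forward model.

    Defaults follow common soil-leaf-canopy practice for a fully green
    potato canopy on a ploughed-soil background: no brown leaf area,
    no senescent material, spherical-ish leaf angle distribution.
    ``geometry`` carries (solar zenith, view zenith, relative azimuth)
    in degrees for external models; the bundled mini-RTM assumes nadir
    view and ignores it.
    """

    n_struct: float = 1.5          # leaf structure N (when not sampled)
    cw: float = 0.0317             # leaf water content, cm
    cm_dry: float = 0.005          # leaf dry matter, g/cm2
    cs: float = 0.0                # senescent material
    lidfa: float = 0.66            # leaf inclination distribution a
    lidfb: float = -0.04           # leaf inclination distribution b
    hot: float = 0.05              # hotspot, m/m
    zeta: float = 1.0              # tree shape factor
    d_factor: float = 1.0          # layer dissociation factor
    fb: float = 0.0                # fraction of brown canopy area
    sm: float = 15.0               # soil moisture index
    hapke_b: float = 0.84
    hapke_c: float = 0.68
    hapke_h: float = 0.23
    hapke_b0: float = 0.3
    k_ext: float = DEFAULT_K_EXT   # vertical extinction coefficient
    geometry: tuple = (30.0, 0.0, 0.0)  # (tts, tto, psi) degrees

    def __post_init__(self):
        for name in ("n_struct", "cw", "cm_dry", "cs", "lidfa", "lidfb",
                     "hot", "zeta", "d_factor", "fb", "sm", "hapke_b",
                     "hapke_c", "hapke_h", "hapke_b0", "k_ext"):
            if not math.isfinite(float(getattr(self, name))):
                raise ValueError(f"FixedCanopyParams.{name} must be finite")


@dataclass
class MiniRTMConstants:
    """Tunable constants of the bundled analytic forward model."""

    soil_base: float = 0.10        # soil reflectance at 400 nm
    soil_slope: float = 0.25       # soil brightening over 2100 nm
    soil_moisture_coef: float = 0.004
    red_edge_base: float = 700.0   # red-edge position at LCC = 0, nm
    red_edge_per_lcc: float = 0.25  # nm shift per ug/cm2 chlorophyll
    red_edge_width: float = 12.0   # logistic width, nm
    nir_base: float = 0.30         # NIR plateau at N = 1
    nir_per_n: float = 0.08        # plateau gain per unit leaf structure
    green_base: float = 0.04
    green_amp: float = 0.30
    green_center: float = 550.0
    green_width: float = 35.0
    green_lcc_decay: float = 0.012  # chlorophyll absorption strength


def _mini_rtm_components(lam, lcc, n_struct, sm, c: MiniRTMConstants):
    """Soil spectrum, red-edge sigmoid and dense-canopy reflectance."""
    soil = (c.soil_base + c.soil_slope * (lam - 400.0) / 2100.0) * (
        1.0 - c.soil_moisture_coef * sm
    )
    lam_e = c.red_edge_base + c.red_edge_per_lcc * lcc
    sig = 1.0 / (1.0 + np.exp(-(lam - lam_e) / c.red_edge_width))
    plateau = c.nir_base + c.nir_per_n * (n_struct - 1.0)
    green = c.green_base + c.green_amp * np.exp(
        -(((lam - c.green_center) / c.green_width) ** 2)
    ) * np.exp(-c.green_lcc_decay * lcc)
    dense = plateau * sig + green * (1.0 - sig)
    return soil, dense


def simulate_canopy(
    traits: TraitSample,
    fixed: FixedCanopyParams,
    grid: np.ndarray,
    constants: MiniRTMConstants | None = None,
) -> "Spectrum":
    """Top-of-canopy reflectance of one trait sample on a 1-nm grid.

    Scene reflectance is the fCover-weighted mixture of a dense-canopy
    spectrum and the bare-soil spectrum,

        r(lam) = fCover * Rinf(lam) + (1 - fCover) * r_s(lam),

    with fCover from the Lambert-Beer gap-fraction law, so r reduces to
    the soil spectrum exactly at LAI = 0 or Cv = 0.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = MINI_RTM_RANGE
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"grid must lie within [{lo}, {hi}] nm for the bundled model"
        )
    for v in (traits.lai, traits.lcc, traits.cv):
        if not math.isfinite(float(v)):
            raise ValueError("trait values must be finite")
    c = constants or MiniRTMConstants()
    n_struct = traits.n_struct if traits.n_struct is not None else fixed.n_struct
    soil, dense = _mini_rtm_components(grid, traits.lcc, n_struct, fixed.sm, c)
    fc = fcover_from(traits.cv, traits.lai, fixed.k_ext)
    refl = fc * dense + (1.0 - fc) * soil
    return Spectrum(grid, refl)


def simulate_canopy_batch(
    lai: np.ndarray,
    lcc: np.ndarray,
    cv: np.ndarray,
    n_struct: np.ndarray,
    fixed: FixedCanopyParams,
    grid: np.ndarray,
    constants: MiniRTMConstants | None = None,
) -> np.ndarray:
    """Vectorised mini-RTM: returns an (n_samples, n_wavelengths) array."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = MINI_RTM_RANGE
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(f"grid must lie within [{lo}, {hi}] nm")
    c = constants or MiniRTMConstants()
    lam = grid[None, :]
    lcc = np.asarray(lcc, dtype=float)[:, None]
    nst = np.asarray(n_struct, dtype=float)[:, None]
    soil, dense = _mini_rtm_components(lam, lcc, nst, fixed.sm, c)
    fc = fcover_from(np.asarray(cv, float), np.asarray(lai, float),
                     fixed.k_ext)[:, None]
    return fc * dense + (1.0 - fc) * soil


# ---------------------------------------------------------------------------
# Sensor model and spectral resampling
# ---------------------------------------------------------------------------

@dataclass
class SensorModel:
    """Multispectral band definition: Gaussian response per band."""

    centers: np.ndarray   # nm, non-decreasing
    fwhm: np.ndarray      # nm
    name: str = "sensor"

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.fwhm = np.asarray(self.fwhm, dtype=float)
        if self.centers.shape != self.fwhm.shape:
            raise ValueError("centers and fwhm must have equal length")
        if np.any(np.diff(self.centers) < 0):
            raise ValueError("band centers must be non-decreasing")

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def band_labels(self) -> list:
        # duplicate centers (overlapping camera bands) get a numeric suffix
        labels, seen = [], {}
        for c in self.centers:
            base = f"b{c:.1f}"
            seen[base] = seen.get(base, 0) + 1
            labels.append(base if seen[base] == 1 else f"{base}_{seen[base]}")
        return labels

    @classmethod
    def gamaya_oxi(cls) -> "SensorModel":
        """The 40-band VNIR snapshot sensor used by the campaign.

        25 VIS bands span 474-638 nm (FWHM 16-27 nm) and 16 NIR bands
        span 638-915 nm (FWHM 15-27 nm); the camera pair shares the
        638 nm band, and the last concatenated NIR band is dropped,
        leaving 40 bands.
        """
        vis_centers = np.linspace(474.0, 638.0, 25)
        nir_centers = np.linspace(638.0, 915.0, 16)
        vis_fwhm = np.linspace(16.0, 27.0, 25)
        nir_fwhm = np.linspace(15.0, 27.0, 16)
        centers = np.concatenate([vis_centers, nir_centers])[:-1]
        fwhm = np.concatenate([vis_fwhm, nir_fwhm])[:-1]
        return cls(centers=centers, fwhm=fwhm, name="gamaya-oxi-vnir40")

    @property
    def vis_band_mask(self) -> np.ndarray:
        """Bands recorded by the VIS camera (centers <= 638 nm)."""
        return self.centers <= 638.0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "centers": self.centers.tolist(),
            "fwhm": self.fwhm.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorModel":
        return cls(centers=np.array(d["centers"]), fwhm=np.array(d["fwhm"]),
                   name=d.get("name", "sensor"))


@dataclass
class Spectrum:
    """Reflectance sampled on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance must match in length")


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def resampling_matrix(grid: np.ndarray, sensor: SensorModel) -> np.ndarray:
    """Discrete Gaussian spectral-response weights, (n_grid, n_bands).

    Each column is a Gaussian centred at the band centre with the band's
    FWHM, normalised to unit sum on the grid so a constant input spectrum
    is reproduced exactly.
    """
    grid = np.asarray(grid, dtype=float)
    W = np.empty((grid.size, len(sensor)))
    for j, (c, f) in enumerate(zip(sensor.centers, sensor.fwhm)):
        if grid.min() > c - 2.0 * f or grid.max() < c + 2.0 * f:
            raise ValueError(
                f"input grid does not cover band {j} "
                f"(center {c} nm, FWHM {f} nm): need "
                f"[{c - 2 * f:.1f}, {c + 2 * f:.1f}] nm"
            )
        sigma = f * _FWHM_TO_SIGMA
        w = np.exp(-0.5 * ((grid - c) / sigma) ** 2)
        W[:, j] = w / w.sum()
    return W


def resample_to_sensor(spec: Spectrum, sensor: SensorModel) -> Spectrum:
    """Convolve a fine-grid spectrum with the sensor's band responses."""
    W = resampling_matrix(spec.wavelengths, sensor)
    return Spectrum(sensor.centers.copy(), spec.reflectance @ W)


def add_noise(
    spec: Spectrum,
    sigma: float = 0.005,
    mode: str = "additive",
    rng: np.random.Generator | int | None = None,
) -> Spectrum:
    """Inject i.i.d. Gaussian noise per band, clipped to [0, 1].

    ``additive`` (default) adds Normal(0, sigma) in reflectance units;
    ``multiplicative`` scales by (1 + Normal(0, sigma)).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if mode not in ("additive", "multiplicative"):
        raise ValueError(f"unknown noise mode {mode!r}")
    if sigma == 0:
        return Spectrum(spec.wavelengths.copy(), spec.reflectance.copy())
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    eps = gen.normal(0.0, sigma, size=spec.reflectance.shape)
    if mode == "additive":
        r = spec.reflectance + eps
    else:
        r = spec.reflectance * (1.0 + eps)
    return Spectrum(spec.wavelengths.copy(), np.clip(r, 0.0, 1.0))
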