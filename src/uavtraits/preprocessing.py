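"""Radiometric calibration and spectral band-position correction.

The empirical line method fits, per band, an ordinary least-squares line
from raw digital numbers (DN) to the known reflectance of grey reference
panels; applying the fitted gain/offset converts scene DN to surface
reflectance.  Because bright panels may saturate snapshot VIS cameras,
the VIS bands can be restricted to the darkest-k panels.

Band-position correction warps the wavelength axis so diagnostic spectral
features (green-peak maximum, red-edge inflection, green-red edge
inflection) line up with those of a trusted reference spectrum, using a
monotone spline through matched feature wavelengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .trait_core import Spectrum

__all__ = [
    "ELCModel",
    "PanelSet",
    "empirical_line_fit",
    "apply_elc",
    "band_shift_correct",
]


@dataclass
class PanelSet:
    """Reference panels: DN and known reflectance per panel per band."""

    panel_ids: list
    dn: np.ndarray                   # (n_panels, n_bands)
    reference_reflectance: np.ndarray  # (n_panels, n_bands), scaled 0-1
    saturated: np.ndarray | None = None  # (n_panels,) bool flags

    def __post_init__(self):
        self.dn = np.atleast_2d(np.asarray(self.dn, dtype=float))
        self.reference_reflectance = np.atleast_2d(
            np.asarray(self.reference_reflectance, dtype=float)
        )
        if self.dn.shape != self.reference_reflectance.shape:
            raise ValueError("dn and reference_reflectance shapes differ")
        if len(self.panel_ids) != self.dn.shape[0]:
            raise ValueError("panel_ids length mismatch")
        if np.any(self.reference_reflectance < 0) or np.any(
            self.reference_reflectance > 1
        ):
            raise ValueError("reference reflectances must be scaled 0-1")

    @property
    def n_panels(self) -> int:
        return self.dn.shape[0]

    def darkest(self, k: int) -> "PanelSet":
        """Subset of the k darkest panels by mean reference reflectance.

        Ties are broken by panel id so the selection is reproducible.
        """
        means = self.reference_reflectance.mean(axis=1)
        order = sorted(range(self.n_panels),
                       key=lambda i: (means[i], self.panel_ids[i]))
        idx = sorted(order[:k])
        return PanelSet(
            [self.panel_ids[i] for i in idx],
            self.dn[idx],
            self.reference_reflectance[idx],
            None if self.saturated is None else self.saturated[idx],
        )


@dataclass
class ELCModel:
    """Per-band affine DN-to-reflectance calibration with fit statistics."""

    gain: np.ndarray
    offset: np.ndarray
    r2: np.ndarray
    rmse: np.ndarray

    @property
    def n_bands(self) -> int:
        return self.gain.size


def _ols_per_band(dn: np.ndarray, refl: np.ndarray):
    """Least-squares reflectance = gain*DN + offset for one band block."""
    n_bands = dn.shape[1]
    gain = np.empty(n_bands)
    offset = np.empty(n_bands)
    r2 = np.empty(n_bands)
    rmse = np.empty(n_bands)
    for b in range(n_bands):
        x, y = dn[:, b], refl[:, b]
        if np.ptp(x) == 0:
            raise ValueError(f"zero DN variance in band {b}: cannot fit a line")
        g, o = np.polyfit(x, y, 1)
        pred = g * x + o
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        gain[b], offset[b] = g, o
        r2[b] = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        rmse[b] = np.sqrt(ss_res / len(y))
    return gain, offset, r2, rmse


def empirical_line_fit(
    panels: PanelSet,
    vis_bands: np.ndarray | None = None,
    n_darkest_vis: int | None = None,
) -> ELCModel:
    """Fit the per-band empirical line from reference panels.

    Parameters
    ----------
    panels
        DN / reference-reflectance pairs, one row per panel.
    vis_bands
        Boolean mask of the bands recorded by the VIS camera.  When given
        together with ``n_darkest_vis``, only the darkest panels enter the
        fit for those bands (bright panels saturate the VIS camera).
    n_darkest_vis
        Number of darkest panels used for the VIS bands.
    """
    if panels.n_panels < 2:
        raise ValueError("need at least 2 panels to fit a line")
    gain, offset, r2, rmse = _ols_per_band(
        panels.dn, panels.reference_reflectance
    )
    if vis_bands is not None and n_darkest_vis is not None:
        vis_bands = np.asarray(vis_bands, dtype=bool)
        if vis_bands.size != panels.dn.shape[1]:
            raise ValueError("vis_bands length must equal band count")
        if n_darkest_vis < 2:
            raise ValueError("need at least 2 panels in the VIS subset")
        sub = panels.darkest(n_darkest_vis)
        g, o, r, e = _ols_per_band(
            sub.dn[:, vis_bands], sub.reference_reflectance[:, vis_bands]
        )
        gain[vis_bands], offset[vis_bands] = g, o
        r2[vis_bands], rmse[vis_bands] = r, e
    return ELCModel(gain, offset, r2, rmse)


def apply_elc(dn_spectrum: np.ndarray, model: ELCModel) -> np.ndarray:
    """Convert a DN spectrum (or matrix of spectra) to reflectance.

    No clipping is applied: calibration artefacts outside [0, 1] are
    preserved; a warning is raised when values exceed [0, 1.5].
    """
    dn = np.asarray(dn_spectrum, dtype=float)
    if dn.shape[-1] != model.n_bands:
        raise ValueError(
            f"band count mismatch: spectrum has {dn.shape[-1]}, "
            f"model has {model.n_bands}"
        )
    refl = model.gain * dn + model.offset
    if np.any(refl < -0.05) or np.any(refl > 1.5):
        warnings.warn(
            "calibrated reflectance outside [0, 1.5]: check panel fits",
            stacklevel=2,
        )
    return refl


# ---------------------------------------------------------------------------
# Band-position correction
# ---------------------------------------------------------------------------

def _refine_extremum(lam: np.ndarray, y: np.ndarray, idx: int) -> float:
    """Quadratic interpolation of a discrete extremum for sub-band precision."""
    if idx <= 0 or idx >= len(lam) - 1:
        return float(lam[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(lam[idx])
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (lam[idx + 1] - lam[idx - 1])
    return float(lam[idx] + np.clip(delta, -1.0, 1.0) * step)


def _find_feature(spec: Spectrum, lo: float, hi: float, kind: str) -> float | None:
    """Locate a spectral feature wavelength in a window, or None.

    ``kind``: 'max' (reflectance maximum), 'd1max'/'d1min' (extremum of
    the first derivative, i.e. an inflection of the reflectance curve).
    Derivatives are central differences on the native grid; the discrete
    extremum is refined by quadratic interpolation.  An extremum on the
    window edge does not count (no interior feature).
    """
    lam, r = spec.wavelengths, spec.reflectance
    if kind == "max":
        y = r
    else:
        y = np.gradient(r, lam)
    m = (lam >= lo) & (lam <= hi)
    if m.sum() < 3:
        return None
    lam_w, y_w = lam[m], y[m]
    idx = int(np.argmin(y_w)) if kind == "d1min" else int(np.argmax(y_w))
    if idx == 0 or idx == len(lam_w) - 1:
        return None
    if np.ptp(y_w) == 0:
        return None
    return _refine_extremum(lam_w, y_w, idx)


#: (window low, window high, kind) for the default feature set:
#: green-peak maximum, red-edge inflection, green-red edge inflection.
DEFAULT_FEATURES = (
    (500.0, 600.0, "max"),
    (680.0, 760.0, "d1max"),
    (550.0, 680.0, "d1min"),
)


def band_shift_correct(
    spec: Spectrum,
    reference: Spectrum,
    features=DEFAULT_FEATURES,
) -> Spectrum:
    """Warp a spectrum's wavelength axis onto a reference's feature positions.

    Matched feature wavelengths (sensor -> reference) anchor a monotone
    spline, pinned to identity at the grid endpoints; the spectrum is then
    resampled onto the warped axis with a cubic spline.  Features whose
    window holds no interior extremum are skipped with a warning; with no
    usable feature the input is returned unchanged (with a warning).
    """
    pairs = []
    for lo, hi, kind in features:
        a = _find_feature(spec, lo, hi, kind)
        b = _find_feature(reference, lo, hi, kind)
        if a is None or b is None:
            warnings.warn(
                f"no interior {kind} feature in window [{lo}, {hi}] nm; "
                "feature skipped",
                stacklevel=2,
            )
            continue
        pairs.append((a, b))
    if not pairs:
        warnings.warn("no usable spectral feature: returning spectrum "
                      "unchanged", stacklevel=2)
        return Spectrum(spec.wavelengths.copy(), spec.reflectance.copy())

    lam = spec.wavelengths
    knots_x = [lam[0]] + [p[0] for p in sorted(pairs)] + [lam[-1]]
    knots_y = [lam[0]] + [p[1] for p in sorted(pairs)] + [lam[-1]]
    # drop knots that would break strict monotonicity of the warp
    xs, ys = [knots_x[0]], [knots_y[0]]
    for x, y in zip(knots_x[1:], knots_y[1:]):
        if x > xs[-1] and y > ys[-1]:
            xs.append(x)
            ys.append(y)
    if len(xs) < 3:
        warnings.warn("degenerate warp anchors: returning spectrum unchanged",
                      stacklevel=2)
        return Spectrum(spec.wavelengths.copy(), spec.reflectance.copy())
    warp = PchipInterpolator(xs, ys)
    new_lam = warp(lam)
    # the spectrum keeps its values but now sits at corrected wavelengths;
    # resample back onto the original grid
    interp = CubicSpline(new_lam, spec.reflectance)
    corrected = interp(np.clip(lam, new_lam[0], new_lam[-1]))
    return Spectrum(lam.copy(), corrected)
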