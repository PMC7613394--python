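"""LUT-based inversion: nearest-spectrum search with a median-of-best-q solution.

For each measured spectrum the RMSE against every simulated LUT spectrum
is computed, the table is sorted by ascending cost (stable, so cost ties
keep LUT row order), and the per-variable median (or mean) of the q
best-matching entries is returned as the trait estimate.  Aggregating
over a neighbourhood of q entries rather than taking the single best
match regularises the ill-posedness of the inverse problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lut_sampling import LUT
from .trait_core import Spectrum

__all__ = ["TraitEstimate", "spectral_rmse", "invert", "invert_batch"]

TRAIT_COLUMNS = ("lai", "cv", "lcc", "fcover", "ccc")


@dataclass
class TraitEstimate:
    """Point estimates of the retrievable traits for one spectrum."""

    lai: float
    cv: float
    lcc: float
    fcover: float
    ccc: float
    method: str = "lut"
    q: int = 300
    uncertainty: dict | None = None  # per-variable IQR of the best-q entries


def spectral_rmse(a, b) -> float:
    """Root-mean-square difference between two band-aligned spectra."""
    ra = a.reflectance if isinstance(a, Spectrum) else np.asarray(a, float)
    rb = b.reflectance if isinstance(b, Spectrum) else np.asarray(b, float)
    if ra.shape != rb.shape:
        raise ValueError(f"band count mismatch: {ra.shape} vs {rb.shape}")
    return float(np.sqrt(np.mean((ra - rb) ** 2)))


def _best_q_rows(costs: np.ndarray, q: int) -> np.ndarray:
    # stable sort keeps LUT row order among cost ties
    return np.argsort(costs, kind="stable")[:q]


def _aggregate(sub: pd.DataFrame, stat: str) -> dict:
    agg = sub.median() if stat == "median" else sub.mean()
    return {c: float(agg[c]) for c in TRAIT_COLUMNS}


def invert(
    spec,
    lut: LUT,
    q: int = 300,
    stat: str = "median",
    method: str = "lut",
) -> TraitEstimate:
    """Estimate traits for one spectrum by median-of-best-q LUT search.

    Derived variables (fCover, CCC) are aggregated from the per-entry
    derived values of the selected LUT rows, consistent with taking
    medians of nonlinear functions.
    """
    if len(lut) == 0:
        raise ValueError("empty LUT")
    if stat not in ("median", "mean"):
        raise ValueError(f"stat must be 'median' or 'mean', got {stat!r}")
    if not 1 <= q <= len(lut):
        raise ValueError(f"q must lie in [1, {len(lut)}], got {q}")
    r = spec.reflectance if isinstance(spec, Spectrum) else np.asarray(spec, float)
    if r.size != lut.n_bands:
        raise ValueError("spectrum band count does not match the LUT")
    costs = np.sqrt(np.mean((lut.spectra - r[None, :]) ** 2, axis=1))
    rows = _best_q_rows(costs, q)
    sub = lut.traits.iloc[rows][list(TRAIT_COLUMNS)]
    est = _aggregate(sub, stat)
    iqr = {c: float(sub[c].quantile(0.75) - sub[c].quantile(0.25))
           for c in TRAIT_COLUMNS}
    return TraitEstimate(**est, method=method, q=q, uncertainty=iqr)


def invert_batch(
    spectra,
    lut: LUT,
    q: int = 300,
    stat: str = "median",
    method: str = "lut",
) -> pd.DataFrame:
    """Invert many spectra at once; returns one row per input spectrum.

    Vectorised equivalent of element-wise :func:`invert` (order preserved).
    """
    if stat not in ("median", "mean"):
        raise ValueError(f"stat must be 'median' or 'mean', got {stat!r}")
    X = np.atleast_2d(np.asarray(
        [s.reflectance if isinstance(s, Spectrum) else s for s in spectra],
        dtype=float,
    ))
    if X.shape[1] != lut.n_bands:
        raise ValueError("spectrum band count does not match the LUT")
    if not 1 <= q <= len(lut):
        raise ValueError(f"q must lie in [1, {len(lut)}], got {q}")
    T = lut.traits[list(TRAIT_COLUMNS)].to_numpy()
    out = np.empty((X.shape[0], len(TRAIT_COLUMNS)))
    # chunk the cost matrix so memory stays modest for large LUTs
    chunk = max(1, int(2e7 // max(len(lut), 1)))
    for start in range(0, X.shape[0], chunk):
        xs = X[start:start + chunk]
        d2 = (
            (xs ** 2).sum(axis=1)[:, None]
            - 2.0 * xs @ lut.spectra.T
            + (lut.spectra ** 2).sum(axis=1)[None, :]
        )
        costs = np.sqrt(np.maximum(d2, 0.0) / lut.n_bands)
        for i, c in enumerate(costs):
            rows = _best_q_rows(c, q)
            sel = T[rows]
            out[start + i] = (np.median(sel, axis=0) if stat == "median"
                              else sel.mean(axis=0))
    df = pd.DataFrame(out, columns=list(TRAIT_COLUMNS))
    df.insert(0, "method", method)
    df["q"] = q
    return df
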