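"""Synthetic field campaign with the statistical structure of the study design.

The generator emulates a six-date potato fertilisation trial: 156 plots
(21 on the first date, 27 on each later date), three nitrogen levels
(80/180/280 kg/ha) balanced within dates, date-level trait trajectories
that rise to a maturity maximum and dip at senescence, strong
cross-correlations between LAI, fCover and CCC, and a per-date
illumination/exposure regime (sunny, partial or overcast skies with
correspondingly longer integration times).  Observed spectra are the
forward-modelled true spectra perturbed by a per-plot multiplicative gain
whose distribution depends on the date's illumination class and which
shares a date-level component, so exposure time is informative about the
perturbation -- the situation the in-situ RFexp strategy exploits.

All magnitudes are configurable; the defaults give measured-trait
summary statistics (means, dispersions, correlations) matching the
field campaign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lut_sampling import CorrelationModel, DistributionSpec, impose_correlation, lhs, transform_marginals
from .preprocessing import PanelSet
from .trait_core import (
    FixedCanopyParams,
    MiniRTMConstants,
    SensorModel,
    ccc_from,
    default_grid,
    fcover_from,
    lcc_to_spad,
    resampling_matrix,
    simulate_canopy_batch,
)

__all__ = [
    "DateSpec",
    "CampaignConfig",
    "generate_campaign",
    "generate_spectra",
    "generate_panels",
    "default_dates",
]


@dataclass
class DateSpec:
    """One observation date: design, illumination and trait statistics."""

    label: str
    illumination: str          # sunny | partial | overcast
    exposure_vis: float        # seconds
    exposure_nir: float        # seconds
    solar_zenith: float        # degrees
    n_plots: int
    lai_mean: float
    lai_sd: float
    fcover_mean: float
    fcover_sd: float
    ccc_mean: float
    ccc_sd: float


def default_dates() -> list:
    """The six-date campaign: design sizes, sky conditions, exposure times
    and per-date trait statistics of the field measurements."""
    rows = [
        # label, illum, exp_vis, exp_nir, sza, n, lai (m, sd), fcover (m, sd), ccc (m, sd)
        ("08-Jul", "partial", 1 / 840, 1 / 1135, 28, 21, 1.91, 0.62, 0.47, 0.17, 1.37, 0.47),
        ("14-Jul", "partial", 1 / 840, 1 / 1135, 29, 27, 2.19, 0.91, 0.58, 0.22, 1.48, 0.68),
        ("19-Jul", "sunny", 1 / 840, 1 / 1135, 30, 27, 2.22, 0.86, 0.62, 0.25, 1.66, 0.77),
        ("27-Jul", "partial", 1 / 496, 1 / 840, 31, 27, 2.98, 0.99, 0.77, 0.14, 1.93, 0.78),
        ("05-Aug", "overcast", 1 / 328, 1 / 716, 33, 27, 3.94, 1.05, 0.91, 0.12, 2.27, 0.69),
        ("10-Aug", "overcast", 1 / 328, 1 / 552, 35, 27, 3.69, 0.77, 0.88, 0.09, 2.22, 0.60),
    ]
    return [DateSpec(*r) for r in rows]


@dataclass
class CampaignConfig:
    """Design, effect sizes and noise settings of the synthetic campaign."""

    dates: list = field(default_factory=default_dates)
    nitrogen_levels: tuple = (80, 180, 280)
    #: correlation targets between (lai, cv, lcc) residuals
    correlation: CorrelationModel = field(default_factory=CorrelationModel)
    #: mean shift of N80 / N280 relative to N180, in units of the date sd
    nitrogen_effect_sd: float = 0.15
    #: multiplicative measurement error of LAI (coefficient of variation)
    lai_noise_cv: float = 0.08
    #: additive measurement noise of leaf chlorophyll, ug/cm2
    lcc_noise_sd: float = 4.0
    #: additive noise of visually estimated fCover before 5%-rounding
    fcover_noise_sd: float = 0.03
    #: per-plot spectral gain (mean, sd) per illumination class
    gain_params: dict = field(default_factory=lambda: {
        "sunny": (1.00, 0.01),
        "partial": (1.00, 0.05),
        "overcast": (0.92, 0.04),
    })
    #: fraction of the gain variance shared at date level
    gain_date_share: float = 0.5
    #: additive spectral noise after the gain, reflectance units
    spectral_noise_sigma: float = 0.005
    k_ext: float = 0.55

    @property
    def n_plots(self) -> int:
        return sum(d.n_plots for d in self.dates)


def _nitrogen_assignment(n_plots: int, levels: tuple) -> np.ndarray:
    """Balanced nitrogen labels within a date (counts differ by <= 1)."""
    reps = int(np.ceil(n_plots / len(levels)))
    return np.tile(np.asarray(levels), reps)[:n_plots]


def _date_trait_params(d: DateSpec, config: CampaignConfig):
    """Convert the (LAI, fCover, CCC) date statistics to (lai, cv, lcc) priors.

    Crown cover Cv follows by inverting the gap-fraction law at the date
    mean; leaf chlorophyll follows from CCC = 0.01*LAI*LCC at the mean,
    with its dispersion propagated from the CCC dispersion.
    """
    k = config.k_ext
    interception = 1.0 - np.exp(-k * d.lai_mean)
    cv_mean = min(d.fcover_mean / interception, 0.98)
    cv_sd = min(d.fcover_sd / interception, 0.3)
    lcc_mean = 100.0 * d.ccc_mean / d.lai_mean
    # first-order error propagation of ccc = lai*lcc/100 holding corr high
    lcc_sd = max(100.0 * d.ccc_sd / d.lai_mean - lcc_mean * d.lai_sd / d.lai_mean, 3.0)
    return {
        "lai": DistributionSpec("lai", "truncated-gaussian", 0.05, 7.0,
                                mu=d.lai_mean, sigma=d.lai_sd),
        "cv": DistributionSpec("cv", "truncated-gaussian", 0.05, 1.0,
                               mu=cv_mean, sigma=cv_sd),
        "lcc": DistributionSpec("lcc", "truncated-gaussian", 20.0, 110.0,
                                mu=lcc_mean, sigma=lcc_sd),
    }


def generate_campaign(
    config: CampaignConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw the plot-level true and measured traits of a campaign.

    Returns one row per plot with columns: plot_id, date, nitrogen,
    illumination, exposure_vis/nir, solar_zenith, true traits
    (lai_true, cv_true, lcc_true, fcover_true, ccc_true) and measured
    traits (lai, fcover, spad, lcc, ccc).  Measured fCover is rounded to
    the visual 5% classes; measured CCC is the product of measured LAI
    and LCC.
    """
    config = config or CampaignConfig()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    records = []
    plot_counter = 0
    for d in config.dates:
        n = d.n_plots
        specs = _date_trait_params(d, config)
        nitro = _nitrogen_assignment(n, config.nitrogen_levels)
        # correlated residual draws shared across the date
        Z = lhs(n, 3, gen)
        score = impose_correlation(Z, config.correlation)
        # nitrogen shifts the mean before the marginal transform:
        # transform each nitrogen stratum with its shifted prior
        vals = np.empty((n, 3))
        mid = config.nitrogen_levels[len(config.nitrogen_levels) // 2]
        for level in config.nitrogen_levels:
            mask = nitro == level
            if not mask.any():
                continue
            sign = float(np.sign(level - mid))
            shifted = []
            for name in ("lai", "cv", "lcc"):
                s = specs[name]
                shifted.append(replace(
                    s, mu=s.mu + sign * config.nitrogen_effect_sd * s.sigma
                ))
            vals[mask] = transform_marginals(score.Z1[mask], shifted)
        lai_t, cv_t, lcc_t = vals[:, 0], vals[:, 1], vals[:, 2]
        fcover_t = fcover_from(cv_t, lai_t, config.k_ext)
        ccc_t = ccc_from(lai_t, lcc_t)

        lai_m = np.maximum(lai_t * (1.0 + gen.normal(0, config.lai_noise_cv, n)),
                           0.01)
        lcc_m = np.maximum(lcc_t + gen.normal(0, config.lcc_noise_sd, n), 1.0)
        fc_raw = fcover_t + gen.normal(0, config.fcover_noise_sd, n)
        fcover_m = np.clip(np.round(fc_raw / 0.05) * 0.05, 0.0, 1.0)
        ccc_m = ccc_from(lai_m, lcc_m)
        spad_m = np.array([lcc_to_spad(v) for v in lcc_m])

        for i in range(n):
            records.append({
                "plot_id": f"P{plot_counter:03d}",
                "date": d.label,
                "nitrogen": int(nitro[i]),
                "illumination": d.illumination,
                "exposure_vis": d.exposure_vis,
                "exposure_nir": d.exposure_nir,
                "solar_zenith": d.solar_zenith,
                "lai_true": lai_t[i], "cv_true": cv_t[i],
                "lcc_true": lcc_t[i], "fcover_true": fcover_t[i],
                "ccc_true": ccc_t[i],
                "lai": lai_m[i], "fcover": fcover_m[i],
                "spad": spad_m[i], "lcc": lcc_m[i], "ccc": ccc_m[i],
            })
            plot_counter += 1
    return pd.DataFrame(records)


def generate_spectra(
    plots: pd.DataFrame,
    config: CampaignConfig | None = None,
    rng: np.random.Generator | int | None = None,
    fixed: FixedCanopyParams | None = None,
    sensor: SensorModel | None = None,
    forward_model=None,
    constants: MiniRTMConstants | None = None,
) -> pd.DataFrame:
    """Attach observed 40-band spectra to campaign plots.

    The true spectrum is the forward model evaluated on the true traits
    and resampled to the sensor; the observed spectrum applies a per-plot
    multiplicative gain drawn from the date's illumination class (with a
    shared date-level component) plus additive band noise.
    """
    config = config or CampaignConfig()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    fixed = fixed or FixedCanopyParams(k_ext=config.k_ext)
    sensor = sensor or SensorModel.gamaya_oxi()
    grid = default_grid()
    if forward_model is None:
        fine = simulate_canopy_batch(
            plots["lai_true"].to_numpy(), plots["lcc_true"].to_numpy(),
            plots["cv_true"].to_numpy(),
            np.full(len(plots), fixed.n_struct),
            fixed, grid, constants,
        )
    else:
        fine = np.asarray(forward_model(plots, fixed, grid), dtype=float)
    true_spectra = fine @ resampling_matrix(grid, sensor)

    share = config.gain_date_share
    date_shift = {}
    for d in plots["date"].unique():
        illum = plots.loc[plots["date"] == d, "illumination"].iloc[0]
        _, sd = config.gain_params[illum]
        date_shift[d] = gen.normal(0.0, np.sqrt(share) * sd)
    gains = np.empty(len(plots))
    for i, (_, row) in enumerate(plots.iterrows()):
        mu, sd = config.gain_params[row["illumination"]]
        gains[i] = (mu + date_shift[row["date"]]
                    + gen.normal(0.0, np.sqrt(max(1.0 - share, 0.0)) * sd))
    observed = true_spectra * gains[:, None]
    if config.spectral_noise_sigma > 0:
        observed = observed + gen.normal(
            0.0, config.spectral_noise_sigma, size=observed.shape
        )
    observed = np.clip(observed, 0.0, 1.5)

    out = plots.copy()
    out["gain"] = gains
    for j, label in enumerate(sensor.band_labels):
        out[label] = observed[:, j]
        out[f"true_{label}"] = true_spectra[:, j]
    return out


def generate_panels(
    n_bands: int = 40,
    rng: np.random.Generator | int | None = None,
    dn_gain: float = 2000.0,
    dn_offset: float = 100.0,
    dn_noise_sd: float = 0.0,
    saturation_dn: float | None = None,
) -> PanelSet:
    """Nine grey calibration panels from black to white.

    Reference reflectances are evenly spaced 0.03-0.95 and flat across
    bands; DN values follow a per-band affine map of reflectance with
    optional noise.  With ``saturation_dn`` set, DN values are capped and
    affected panels flagged, exercising the darkest-panel VIS rule.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    refl = np.linspace(0.03, 0.95, 9)
    reference = np.tile(refl[:, None], (1, n_bands))
    dn = dn_gain * reference + dn_offset
    if dn_noise_sd > 0:
        dn = dn + gen.normal(0.0, dn_noise_sd, size=dn.shape)
    saturated = np.zeros(9, dtype=bool)
    if saturation_dn is not None:
        saturated = (dn >= saturation_dn).any(axis=1)
        dn = np.minimum(dn, saturation_dn)
    return PanelSet(
        panel_ids=[f"panel{i + 1}" for i in range(9)],
        dn=dn,
        reference_reflectance=reference,
        saturated=saturated,
    )
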