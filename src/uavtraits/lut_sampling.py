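"""Look-up-table generation by (optionally correlated) Latin hypercube sampling.

Two LUT flavours drive the inversion study:

* ``std`` -- every canopy variable is drawn independently from its prior
  (truncated Gaussian or uniform) via Latin hypercube sampling (LHS);
* ``reg`` -- the free variables (LAI, Cv, LCC) additionally carry the
  cross-correlation structure observed between the measured traits,
  imposed with the Iman-Conover / Cholesky method:

  1.  draw LHS scores Z in (0,1)^d, one point per 1/n stratum per column;
  2.  map to standard-normal scores and standardise columns exactly;
  3.  Cholesky-factor the target correlation M = L L' and the empirical
      score correlation m = Q Q';
  4.  transform Z1 = Z (L Q^-1)', whose sample correlation equals M
      exactly (matrix identity: L Q^-1 m Q^-T L' = L L' = M);
  5.  push each column through the normal CDF and the inverse CDF of its
      marginal prior, which preserves the rank correlation.

  The classical presentation writes the transform as Z (L Q)'; with LHS
  scores m is close to the identity so the two nearly coincide, but only
  the Q^-1 form reproduces M exactly.  The literal form is available
  behind ``literal_eq6=True`` for comparison.

Each trait row is pushed through the forward model, resampled to the
sensor bands and noise-injected, yielding paired (traits, spectra) tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .trait_core import (
    FixedCanopyParams,
    MiniRTMConstants,
    SensorModel,
    Spectrum,
    ccc_from,
    default_grid,
    fcover_from,
    resampling_matrix,
    simulate_canopy_batch,
)

__all__ = [
    "DistributionSpec",
    "CorrelationModel",
    "ScoreMatrix",
    "LUT",
    "default_specs",
    "default_correlation",
    "lhs",
    "impose_correlation",
    "transform_marginals",
    "build_lut",
]

DEFAULT_LUT_SIZE = 17280


@dataclass
class DistributionSpec:
    """Marginal prior of one canopy variable."""

    name: str                      # lai | cv | lcc | n_struct
    law: str                       # "uniform" | "truncated-gaussian"
    min: float
    max: float
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self):
        if self.law not in ("uniform", "truncated-gaussian"):
            raise ValueError(f"unknown law {self.law!r}")
        if not self.min < self.max:
            raise ValueError(f"{self.name}: min must be < max")
        if self.law == "truncated-gaussian":
            if self.mu is None or self.sigma is None or self.sigma <= 0:
                raise ValueError(f"{self.name}: gaussian law needs mu, sigma>0")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF: uniform scores in (0,1) -> variable values."""
        u = np.asarray(u, dtype=float)
        if self.law == "uniform":
            return self.min + u * (self.max - self.min)
        a = (self.min - self.mu) / self.sigma
        b = (self.max - self.mu) / self.sigma
        return stats.truncnorm.ppf(u, a, b, loc=self.mu, scale=self.sigma)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.law == "uniform":
            return np.clip((x - self.min) / (self.max - self.min), 0, 1)
        a = (self.min - self.mu) / self.sigma
        b = (self.max - self.mu) / self.sigma
        return stats.truncnorm.cdf(x, a, b, loc=self.mu, scale=self.sigma)

    def to_dict(self) -> dict:
        return {"name": self.name, "law": self.law, "min": self.min,
                "max": self.max, "mu": self.mu, "sigma": self.sigma}


def default_specs() -> dict:
    """Field-campaign priors of the free canopy variables.

    LAI, Cv and LCC follow truncated Gaussians fitted to the field
    measurements; the leaf structure parameter is uniform.
    """
    return {
        "lai": DistributionSpec("lai", "truncated-gaussian", 0.05, 7.0,
                                mu=2.85, sigma=1.17),
        "cv": DistributionSpec("cv", "truncated-gaussian", 0.05, 1.0,
                               mu=0.71, sigma=0.23),
        "lcc": DistributionSpec("lcc", "truncated-gaussian", 40.0, 90.0,
                                mu=65.36, sigma=9.38),
        "n_struct": DistributionSpec("n_struct", "uniform", 1.0, 2.5),
    }


@dataclass
class CorrelationModel:
    """Target correlation of the free variables, with its Cholesky factor.

    The default matrix carries the measured trait correlations
    (LAI-fCover 0.83, LAI-CCC 0.97, fCover-CCC 0.79) mapped onto the
    model inputs as (LAI, fCover->Cv, CCC->LCC).
    """

    order: tuple = ("lai", "cv", "lcc")
    M: np.ndarray = field(default_factory=lambda: np.array(
        [[1.0, 0.83, 0.97],
         [0.83, 1.0, 0.79],
         [0.97, 0.79, 1.0]]))
    note: str = "measured trait correlations mapped (LAI, fCover->Cv, CCC->LCC)"

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        d = len(self.order)
        if self.M.shape != (d, d):
            raise ValueError("M shape must match variable order")
        if not np.allclose(self.M, self.M.T, atol=1e-12):
            raise ValueError("M must be symmetric")
        if not np.allclose(np.diag(self.M), 1.0, atol=1e-12):
            raise ValueError("M must have unit diagonal")
        try:
            self.L = np.linalg.cholesky(self.M)
        except np.linalg.LinAlgError as exc:
            minors = [np.linalg.det(self.M[:k, :k])
                      for k in range(1, d + 1)]
            raise ValueError(
                f"M is not positive definite (leading minors: {minors})"
            ) from exc


def default_correlation() -> CorrelationModel:
    return CorrelationModel()


@dataclass
class ScoreMatrix:
    """Intermediate arrays of the Iman-Conover transform."""

    Z: np.ndarray    # standardised normal LHS scores, n x d
    m: np.ndarray    # empirical correlation of Z
    Q: np.ndarray    # lower Cholesky factor of m
    Z1: np.ndarray   # correlated scores, sample correlation = target M


def lhs(n: int, d: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Latin hypercube scores in (0,1)^d: one draw per 1/n stratum per column."""
    if n < 2:
        raise ValueError("LHS needs n >= 2")
    if d < 1:
        raise ValueError("LHS needs d >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    Z = np.empty((n, d))
    for j in range(d):
        Z[:, j] = (gen.permutation(n) + gen.random(n)) / n
    return Z


def impose_correlation(
    Z: np.ndarray,
    target: CorrelationModel,
    literal_eq6: bool = False,
) -> ScoreMatrix:
    """Impose the target correlation on LHS scores (Iman-Conover).

    Returns the score matrices; ``Z1`` holds standardised normal scores
    whose sample Pearson correlation equals ``target.M`` to numerical
    precision (unless ``literal_eq6`` selects the uncorrected textbook
    transcription ``Z (L Q)'``, kept for comparison).
    """
    Z = np.asarray(Z, dtype=float)
    n, d = Z.shape
    if n < d + 1:
        raise ValueError("need more rows than variables to estimate m")
    if d != target.M.shape[0]:
        raise ValueError("column count must match the correlation model")
    Zs = stats.norm.ppf(np.clip(Z, 1e-12, 1 - 1e-12))
    Zs = (Zs - Zs.mean(axis=0)) / Zs.std(axis=0)
    m = np.corrcoef(Zs, rowvar=False)
    try:
        Q = np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise ValueError("score correlation matrix is singular") from exc
    L = target.L
    if literal_eq6:
        A = L @ Q
    else:
        A = L @ np.linalg.inv(Q)
    Z1 = Zs @ A.T
    return ScoreMatrix(Z=Zs, m=m, Q=Q, Z1=Z1)


def transform_marginals(Z1: np.ndarray, specs: list) -> np.ndarray:
    """Map correlated normal scores to the target marginals column-wise.

    Scores -> uniforms via the normal CDF, uniforms -> values via the
    inverse CDF of each column's prior, so bounds are respected exactly
    and rank correlations are preserved.
    """
    Z1 = np.asarray(Z1, dtype=float)
    if Z1.shape[1] != len(specs):
        raise ValueError(
            f"{Z1.shape[1]} columns but {len(specs)} distribution specs"
        )
    U = stats.norm.cdf(Z1)
    out = np.empty_like(Z1)
    for j, spec in enumerate(specs):
        out[:, j] = spec.ppf(U[:, j])
    return out


@dataclass
class LUT:
    """Paired trait table and simulated sensor spectra with provenance."""

    traits: pd.DataFrame        # columns lai, cv, lcc, n_struct, fcover, ccc
    spectra: np.ndarray         # (n, n_bands)
    mode: str                   # "std" | "reg"
    seed: int | None
    noise_sigma: float
    sensor: SensorModel

    def __post_init__(self):
        if len(self.traits) != self.spectra.shape[0]:
            raise ValueError("traits and spectra row counts differ")

    def __len__(self) -> int:
        return len(self.traits)

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.traits.to_csv(directory / "traits.csv", index=False)
        pd.DataFrame(self.spectra, columns=self.sensor.band_labels).to_csv(
            directory / "spectra.csv", index=False
        )
        meta = {
            "mode": self.mode,
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "sensor": self.sensor.to_dict(),
        }
        (directory / "lut.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "LUT":
        directory = Path(directory)
        meta = json.loads((directory / "lut.json").read_text())
        return cls(
            traits=pd.read_csv(directory / "traits.csv"),
            spectra=pd.read_csv(directory / "spectra.csv").to_numpy(),
            mode=meta["mode"],
            seed=meta["seed"],
            noise_sigma=meta["noise_sigma"],
            sensor=SensorModel.from_dict(meta["sensor"]),
        )


def build_lut(
    mode: str,
    n: int = DEFAULT_LUT_SIZE,
    specs: dict | None = None,
    corr: CorrelationModel | None = None,
    fixed: FixedCanopyParams | None = None,
    sensor: SensorModel | None = None,
    noise_sigma: float = 0.005,
    rng: np.random.Generator | int | None = None,
    forward_model=None,
    constants: MiniRTMConstants | None = None,
    literal_eq6: bool = False,
) -> LUT:
    """Generate a look-up table of canopy simulations.

    ``mode="std"`` draws every variable independently; ``mode="reg"``
    imposes the measured-trait correlation on (LAI, Cv, LCC).  The leaf
    structure parameter is always drawn independently.  Each trait row is
    run through the forward model on a 1-nm grid, resampled to the sensor
    bands, and perturbed with additive Gaussian noise.

    ``forward_model`` may be any callable ``(traits_df, fixed, grid) ->
    (n, len(grid)) array``; the default is the bundled mini-RTM.
    """
    if mode not in ("std", "reg"):
        raise ValueError(f"mode must be 'std' or 'reg', got {mode!r}")
    specs = specs or default_specs()
    fixed = fixed or FixedCanopyParams()
    sensor = sensor or SensorModel.gamaya_oxi()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    corr_names = list((corr or default_correlation()).order) if mode == "reg" \
        else ["lai", "cv", "lcc"]
    if mode == "reg":
        corr = corr or default_correlation()
        Z = lhs(n, len(corr_names), gen)
        score = impose_correlation(Z, corr, literal_eq6=literal_eq6)
        corr_values = transform_marginals(
            score.Z1, [specs[v] for v in corr_names]
        )
    else:
        Z = lhs(n, len(corr_names), gen)
        Zs = stats.norm.ppf(np.clip(Z, 1e-12, 1 - 1e-12))
        corr_values = transform_marginals(Zs, [specs[v] for v in corr_names])
    nst = specs["n_struct"].ppf(lhs(n, 1, gen)[:, 0])

    traits = pd.DataFrame(corr_values, columns=corr_names)
    traits["n_struct"] = nst
    traits["fcover"] = fcover_from(traits["cv"].to_numpy(),
                                   traits["lai"].to_numpy(), fixed.k_ext)
    traits["ccc"] = ccc_from(traits["lai"].to_numpy(),
                             traits["lcc"].to_numpy())
    traits = traits[["lai", "cv", "lcc", "n_struct", "fcover", "ccc"]]

    grid = default_grid()
    if forward_model is None:
        fine = simulate_canopy_batch(
            traits["lai"].to_numpy(), traits["lcc"].to_numpy(),
            traits["cv"].to_numpy(), traits["n_struct"].to_numpy(),
            fixed, grid, constants,
        )
    else:
        fine = np.asarray(forward_model(traits, fixed, grid), dtype=float)
    W = resampling_matrix(grid, sensor)
    spectra = fine @ W
    if noise_sigma > 0:
        spectra = np.clip(
            spectra + gen.normal(0.0, noise_sigma, size=spectra.shape),
            0.0, 1.0,
        )
    return LUT(traits=traits, spectra=spectra, mode=mode, seed=seed,
               noise_sigma=noise_sigma, sensor=sensor)
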