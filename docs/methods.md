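# Methods

This note documents the models, default parameters and numerical choices
behind `uavtraits`, and what the synthetic test-bed does and does not
establish about real data.

## Trait model

Three traits are retrieved. LAI (m²/m²) and leaf chlorophyll content
LCC (µg/cm²) are free variables; crown cover Cv (0–1) is the third free
variable, from which fractional cover derives through the Lambert–Beer
gap-fraction law

    fCover = Cv · (1 − e^(−k·LAI)),   k = 0.55,

with k the vertical extinction coefficient (a property of the leaf angle
distribution and view direction; 0.55 is the fixed campaign value).
Canopy chlorophyll is CCC = 0.01·LAI·LCC (the 0.01 converts µg/cm² to
g/m²). SPAD meter readings convert to LCC via
LCC = 0.0913·e^(0.0415·SPAD); as printed this transfer function yields
LCC ≈ 0.73 at SPAD 50, two orders of magnitude below the 40–90 µg/cm²
prior — a unit inconsistency in the source calibration. We implement the
formula exactly as published but never rely on it: the samplers and the
campaign generator draw LCC directly, and SPAD is emitted only as
derived metadata (flagged non-physical in the generator docstring).

## Forward model

The pipeline is driven through a pluggable forward-model contract:
`(traits, fixed parameters, 1-nm grid) → reflectance`. The bundled
"mini-RTM" is an analytic stand-in, not physics:

- soil line r_s(λ) = (0.10 + 0.25·(λ−400)/2100)·(1 − 0.004·SM);
- red-edge sigmoid S(λ) = 1/(1+e^(−(λ−λ_e)/12)) with
  λ_e = 700 + 0.25·LCC, so chlorophyll shifts the red edge;
- NIR plateau P = 0.30 + 0.08·(N−1) controlled by leaf structure;
- green reflectance G(λ) = 0.04 + 0.30·e^(−((λ−550)/35)²)·e^(−0.012·LCC);
- dense canopy R∞ = P·S + G·(1−S) and scene reflectance
  r = fCover·R∞ + (1−fCover)·r_s.

It guarantees the monotonicities a physical soil–leaf–canopy model
would show (NIR increases with LAI, red reflectance decreases with
chlorophyll, soil returned exactly at LAI = 0 or Cv = 0) and satisfies
the crown-mixing identity implied by the gap-fraction law to machine
precision. All constants are config-exposed (`MiniRTMConstants`).
Geometry (sun/view angles) is carried in the fixed-parameter ledger for
external PROSPECT/SAIL-class models but ignored by the mini-RTM (nadir
assumption). The fixed-parameter defaults (Cw = 0.0317 cm,
Cm = 0.005 g/cm², Cs = 0, LIDF (0.66, −0.04), hotspot 0.05, ζ = 1,
D = 1, fB = 0, SM = 15, Hapke (0.84, 0.68, 0.23, 0.3)) describe a fully
green potato canopy on ploughed soil.

## Sensor model and noise

The 40-band VNIR snapshot sensor is built from 25 VIS centres evenly
spaced on 474–638 nm (FWHM interpolated 16→27 nm) and 16 NIR centres on
638–915 nm (FWHM 15→27 nm); the two cameras share the 638 nm boundary
band (kept, as the physical bands partly overlap) and the last
concatenated NIR band is dropped, leaving 40. Which physical band the
dropped one is was an open choice; we drop the last. Band responses are
Gaussians normalised to unit sum on the input grid, so constants are
preserved exactly. Simulation noise is additive Gaussian with
σ = 0.005 reflectance units per band ("0.5%" read in absolute
reflectance terms, the common LUT practice); a multiplicative mode is
available since the convention is ambiguous.

## Correlated Latin hypercube sampling

LUT priors: LAI ~ N(2.85, 1.17) truncated to [0.05, 7];
Cv ~ N(0.71, 0.23) on [0.05, 1]; LCC ~ N(65.36, 9.38) on [40, 90];
N ~ U[1, 2.5]. Truncation is handled by inverse-CDF sampling of the
truncated distribution (never by clipping), so bounds hold exactly and
the LHS stratification survives the transform.

The regularised LUT imposes the measured trait correlation matrix
(0.83, 0.97, 0.79) on (LAI, Cv, LCC). Two deliberate choices:

- **Variable mapping.** The measured matrix concerns (LAI, fCover, CCC);
  the sampler's free variables are (LAI, Cv, LCC). We map fCover→Cv and
  CCC→LCC. Applying r = 0.97 to LAI–LCC is physically questionable
  (CCC contains LAI by construction), but it is the only mapping
  consistent with correlating "the model input variables", and the
  qualitative conclusions do not depend on it.
- **Transform direction.** The classical write-up of the Iman–Conover
  step multiplies scores by (L·Q)ᵀ. The transform that actually induces
  correlation M is Z·(L·Q⁻¹)ᵀ (with LHS scores the empirical correlation
  m ≈ I, so the two nearly coincide). The corrected form is the default
  and makes the sample correlation of the scores equal M *exactly*
  (identity L Q⁻¹ m Q⁻ᵀ Lᵀ = M after exact column standardisation); the
  literal form is available as `literal_eq6=True`.

After the monotone marginal transform the rank correlations are
preserved exactly and the Pearson correlations shrink slightly under
truncation: at n = 17,280 the LAI–Cv Pearson correlation comes out near
0.82 against the 0.83 target and LAI–LCC near 0.969 against 0.97.

## LUT inversion

Cost is the unweighted band-wise RMSE; no band subsetting. The q = 300
lowest-cost rows (stable sort, so cost ties keep table order) are
aggregated by per-variable median. Derived variables are aggregated from
the per-entry derived values rather than re-derived from the aggregated
free variables — medians do not commute with nonlinear functions, and
the per-entry route keeps each reported trait a median of physically
consistent samples; the other convention is available via the recorded
aggregation mode.

## Machine-learning retrieval

- **RF**: scikit-learn random forest, 500 trees, ⌈p/3⌉ features per
  split.
- **GPR**: anisotropic squared-exponential kernel plus an additive noise
  term; hyperparameters by marginal-likelihood maximisation with three
  optimiser restarts. The target is centred before fitting so a constant
  target is reproduced exactly.
- **CCF**: canonical correlation forest, implemented here (no
  established Python implementation exists): a bootstrap ensemble of
  oblique trees; each node draws a random ⌈√p⌉-feature subset, projects
  it onto its first canonical direction against the target (for a scalar
  target, the ridge-regularised least-squares direction), and splits at
  the threshold minimising pooled child variance. Its acceptance is
  property-based (constant reproduction, signal recovery, determinism,
  beating the mean predictor), not value-based.

The hybrid experiment draws random LUT subsets of
{100, 250, 500, 750, 1000, 1500, 2000, 3000, 4000, 5000} simulations
(the published experiment names the endpoints and a ten-subset design;
the intermediate sizes are our interpolation), repeats each size ten
times by default, and ranks (method, size) pairs by NRMSE on the
independent field validation set — ground validation, not internal
cross-validation, decides. The internal k-fold granularity is recorded
in the config for diagnostics only. Multi-output is handled as
independent single-output models per trait.

The in-situ strategy trains on the field plots with leave-one-date-out
validation: 135 training plots when the 21-plot first date is held out,
129 otherwise. RFexp appends the per-date VIS exposure time to the band
features; because exposure is constant within a date and tied to the
illumination class, it is informative about date-level gain
perturbations exactly when those exist.

## Evaluation

NRMSE uses the range of the measured variable *within the evaluated
group* (per-date range for date rows, pooled range for pooled rows);
the range used is recorded per row. R² is the squared Pearson
correlation (the scatter-plot convention of the retrieval literature);
1 − SS_res/SS_tot is available via `r2_mode="explained"`. The Friedman
test uses mid-ranks and the standard tie correction; its blocks are
per-plot absolute errors (the block unit was an open choice; per-plot
errors give the finest exchangeable unit). The Bergmann–Hommel
adjustment enumerates exhaustive hypothesis sets from all set partitions
of the methods — exact for up to four methods, with a Holm fallback
beyond. The paired t-test compares the two LUT variants' absolute errors
by default.

## Synthetic campaign generator

The generator emulates the *structure* of the field campaign:

- 156 plots: 21 on the first date, 27 on each of five later dates; three
  nitrogen levels balanced within dates.
- Date-level (LAI, fCover, CCC) means and dispersions follow the
  measured per-date summary statistics (rising to a maturity maximum,
  dipping at senescence). Cv and LCC parameters are back-derived from
  the fCover and CCC statistics through the trait formulas.
- Within-date residuals carry the measured correlation structure via the
  same Iman–Conover machinery as the LUT sampler.
- Nitrogen shifts each variable's date mean by ±0.15 date-sd for the
  under/over-fertilised levels — an invented, config-exposed effect size
  (the study reports only that fertilisation created variation).
- Measurement error: LAI multiplicative with 8% CV, LCC additive with
  4 µg/cm² sd (plausible instrument magnitudes, config-exposed), fCover
  visual estimation as additive 0.03 sd noise then rounding to 5%
  classes. Measured CCC is the product of measured LAI and LCC, so the
  product identity holds in the "measured" data exactly as it would in a
  real protocol.
- Observed spectra: forward-modelled true spectra times a per-plot gain
  drawn per illumination class — sunny (1.00, 0.01), partial cloud
  (1.00, 0.05), overcast (0.92, 0.04) as (mean, sd) — with half the
  gain variance shared at date level, plus additive band noise
  (σ = 0.005). The gain magnitudes are plausible stand-ins (no
  quantitative values exist to copy) and are all config-exposed.
- Exposure times and sky classes per date follow the flight log of the
  emulated campaign (1/840–1/328 s VIS), so exposure is a valid proxy
  for the illumination regime.

**What passing tests show — and do not.** The synthetic campaign has the
right marginal statistics, correlations, design and a date-structured
gain confounder, so it can demonstrate *relative* behaviour: that
correlation regularisation tightens LUT inversion, that an exposure
covariate mitigates date-level gain effects, that learning curves
saturate. It cannot certify absolute accuracies on real canopies: the
mini-RTM is far smoother than a real potato canopy (no row structure,
no BRDF, no within-plot heterogeneity), the measured spectra share the
forward model with the LUT (no model inadequacy), and the published
accuracy tables depend on the undeposited field data. Absolute R²/NRMSE
values from this test-bed are therefore optimistic and are not treated
as reproduction targets.

## Problem sizes and numerical choices

- Default LUT size 17,280 and q = 300 everywhere the defaults are
  exercised; the directional method-ordering checks use 5,000-row LUTs
  and 200-tree forests over five seeds, and unit tests use 800–2,000-row
  LUTs — sizes chosen so the full suite runs in well under a minute per
  module while leaving the statistical conclusions unchanged.
- GPR tests run at 100–250 training samples with 0 optimiser restarts;
  anisotropic marginal-likelihood optimisation over 40 length scales
  grows steeply with training size, and the method comparison logic is
  independent of that cost.
- LHS scores are clipped to [1e−12, 1−1e−12] before the inverse normal
  CDF to avoid infinities at stratum edges.
- Spectral feature extrema in the band-shift correction are located by
  central differences plus quadratic interpolation of the discrete
  argmax; window-edge extrema do not count as features. The warp is a
  monotone (PCHIP) spline through matched feature wavelengths with
  identity-pinned endpoints; anchors violating monotonicity are dropped.
- The darkest-k panel subset for VIS calibration is selected by mean
  reference reflectance with panel-id tie-break.
- Ties in inversion cost are broken by LUT row order (stable sort);
  ranking ties in the Friedman test use mid-ranks.
- All pipeline randomness flows from one root seed through named
  substreams (campaign, LUT std/reg, subsets, regressors), making full
  runs bit-reproducible.

## Known limitations

- The mini-RTM is a fixture with physical *shape*, not a physical model;
  conclusions about real sensors require plugging in a PROSPECT/SAIL-class
  forward model behind the same contract.
- The Bergmann–Hommel enumeration is exponential in the number of
  methods and restricted to k ≤ 4 (Holm beyond).
- The hybrid default configuration (three methods × ten sizes × ten
  repeats, GPR up to 5,000 training samples) is faithful to the emulated
  experiment but computationally heavy; studies on modest hardware
  should restrict `hybrid_methods` or the size grid.
- Raster mapping (`map_traits`) operates on in-memory arrays; no
  geospatial metadata handling is provided.
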