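# Methods

## The decomposition

The quantity of interest is the interannual variability (IAV) of net biome
production (NBP = GPP − ReD, where ReD collects autotrophic and
heterotrophic respiration plus disturbance releases) and how much of it is
controlled by soil moisture, directly and through land–atmosphere coupling
(LAC).

**Anomaly operator.** For each grid cell and calendar month the values over
the analysis years are reduced by their OLS line in the year index. This is
a linear projection: it removes the seasonal cycle and any month-wise
linear trend *exactly* (per-month mean and slope of the output are zero to
1e−10), it is idempotent, and the removed line is stored so the input can
be rebuilt exactly. Fitting mean and trend jointly also settles the
intercept question for the regression below: anomalies are exactly
zero-mean per month, so the regression carries no intercept.

**Month-wise sensitivity regression.** At each cell `s` and calendar month
`m`, NBP anomalies over the `N` years are regressed without intercept on
the driver anomalies (default set: soil moisture SM, 2-m temperature T,
VPD, downward shortwave R). Fitting per calendar month allows the
sensitivities to vary seasonally (soil-water stress matters in the dry
months only). The solver is batched SVD least squares:

- drivers with zero variance within a month (prescribed soil moisture,
  deserts, ice) are dropped — coefficient 0 and a flag;
- designs with condition number above 1e8 are solved by minimum-norm least
  squares and flagged;
- the residual is orthogonal to the retained drivers per (cell, month), so
  components + residual reconstruct NBP exactly.

T and VPD are deliberately left collinear (VPD is computed from T and
humidity, and the coupling drives both); no orthogonalization is applied,
and downstream results report their joint `T&VPD` component. Alternative
driver sets (SM/T/R only; relative humidity instead of VPD; a T×SM
interaction formed as the elementwise anomaly product) pass through the
same named-driver interface.

**LAC / non-LAC split.** ExpA's meteorology is, by construction of the
factorial design, the counterfactual without soil-moisture variability. The
non-coupled T&VPD component is therefore
`nonLAC = β_CTL^T·T_ExpA + β_CTL^VPD·VPD_ExpA`, and per cell
`σ²_LAC = σ²(T&VPD, CTL) − σ²(nonLAC)`, floored at zero (floored cells are
counted; the stored non-LAC variance is capped at the total so additivity
is exact). Using CTL sensitivities on both sides isolates the meteorology
change from any sensitivity change; a method switch applies ExpA betas
instead for sensitivity analysis. The exact split formula was a genuinely
open design point; this reconstruction is the one implied by the
counterfactual reading of the experiment.

**Scale ladder.** Component time *series* are aggregated first
(conservative, area-weighted, land-only means on integer block factors; a
`"global"` level collapses the grid), variances are computed per coarse
cell, the T&VPD variance is re-split by the same remainder rule at that
level, and the spatial average of variances is taken **area-weighted over
land** (an unweighted option exists; whether the reference procedure
weights this average is unstated, and area weighting is the physically
consistent choice for fluxes). Normalizing by the sum of the four averages
makes the fractions sum to one identically.

**Variance bookkeeping.** All σ/σ² values are sample statistics (N−1),
computed on annual means by default (monthly-anomaly option retained);
budgets carry all pairwise covariances so Var(Σ) = ΣVar + 2ΣCov holds to
machine precision; the factorial variance change per component telescopes
exactly into a driver-variance effect (CTL betas, ExpA vs CTL drivers) and
a sensitivity effect (ExpA vs CTL betas, ExpA drivers).

**Hotspot classes.** A cell is a T (VPD) hotspot when its Δσ lies strictly
below the negative threshold; ties are not hotspots. Default thresholds are
relative — 0.25 × the area-weighted land mean of the field's CTL σ — since
any absolute choice is arbitrary; the operation itself requires explicit
thresholds (no silent defaults).

## The synthetic stated world

The generator emulates the paired-experiment design in anomaly space on a
24×48 (~7.5°) grid over 46 years (monthly), with every stochastic draw
shared between CTL and ExpA (the role of identical prescribed SSTs):

- `K = 4` large-scale atmospheric modes, unit-variance AR(1) with lag-1
  correlation 0.6; the first mode has a spatially uniform loading (a global
  mode), the others are smoothed random patterns. Modes force soil-moisture
  supply (loading sd 0.5), temperature (0.4) and radiation (0.4).
- Soil moisture is a single bucket, AR(1) with persistence 0.7, forced by
  the modes plus local noise (sd 0.25); ExpA's soil-moisture anomaly is
  identically zero.
- Coupling maps γ_T, γ_V are sums of Gaussian hotspot bumps (5 bumps,
  width 4 cells, amplitudes 2.0 K and 0.5 kPa per SM unit; ~30% of cells
  above half maximum): `T = modes + η_T − γ_T·SM`,
  `VPD = 0.12·T − γ_V·SM + η_V`. Hence, exactly,
  `T_CTL − T_ExpA = −γ_T·SM` per time step.
- Fluxes: `GPP = b_SM g(SM) + b_T T + b_VPD VPD + b_R R + η_G`,
  `ReD = c_T T + c_SM SM + η_D`, with (b_SM, b_T, b_VPD, b_R) =
  (1.2, −0.4, −2.0, 0.6) and (c_T, c_SM) = (0.4, 0.3), i.e. net NBP
  sensitivities (0.9, −0.8, −2.0, 0.6). `g` is the identity by default; an
  optional ramp `min(SM, θ)` models soil-water stress saturation (the
  recorded net SM sensitivity is only exact in the linear case).
- Flux noise is small (sd 0.03 each for η_G, η_D). This is a deliberate
  power choice: the parameter-recovery checks bound the *per-cell* relative
  error of month-averaged sensitivities at 10%, and in strong-coupling
  cells SM is highly collinear with T and VPD, so the bound is only ≥4
  sampling standard deviations away when the regression residual is this
  small. Noisier worlds are one config field away; green recovery tests
  establish correctness of the estimator, not robustness to heavy noise.
- Optional seasonal cycle and per-month trend (default 0) are added
  identically to all fields purely to exercise the anomaly projection.

Under the defaults, suppressing soil moisture removes ~98% of global
annual NBP variance and the true native-grid partition is roughly
direct 29% / LAC 65% / non-LAC 4% / radiation 1% — a world firmly in the
coupling-dominated regime the factorial design is meant to detect.

`coherent_sm_config` is a second stated world for the scale-coherence
property: soil moisture rides almost entirely on the coherent modes
(precipitation teleconnections), coupling is broad and near-uniform
(one bump of width 50 cells), and T carries strong spatially independent
noise (sd 1.2). The LAC-mediated component is then spatially coherent while
the non-coupled component is noise-dominated, so the LAC fraction *rises*
under aggregation. Note that with localized coupling hotspots the LAC
component inherits γ's fine structure and this need not hold — the
coherence contrast is a property of the world, not of the estimator.

**What the generator does not emulate:** water-balance closure,
vegetation structure and memory (lagged NBP responses), fire dynamics,
daily weather (a daily mode exists only to exercise VPD averaging),
realistic flux magnitudes or observational error. Green tests therefore
establish the correctness of the estimators on linear, memoryless worlds
with known truth — not fidelity to any particular Earth-system model.

## Numerical choices

- Cell areas on a sphere (R = 6371 km) from midpoint bounds, poles
  clamped; explicit areas or CF bounds override. Conservative aggregation
  uses land-only weights where a block contains land (ocean carries no
  flux), making the global *land* mean invariant to 1e−12 relative.
- Tolerances: exact identities asserted at 1e−10 (absolute in field units
  or relative, as stated per check); aggregation conservation at 1e−12
  relative; OLS oracle equivalence at 1e−8.
- Randomness: one master seed, `numpy` `SeedSequence.spawn` substreams with
  a fixed name order per purpose (modes, each noise field, loadings,
  hotspot placement); CTL and ExpA consume the same streams in shared-noise
  mode, separate dedicated streams otherwise.
- Degenerate inputs: empty region masks, non-tiling block factors,
  non-contiguous calendars, out-of-range humidity and unknown units all
  raise specific errors rather than propagating NaNs.

## Known limitations

- The LAC split is a variance-level remainder: per cell it absorbs the
  covariance between coupled and non-coupled T&VPD parts into the LAC
  term, and sampling noise can drive the remainder negative (floored,
  flagged, and in practice confined to weakly coupled cells).
- Only regular lat/lon grids and integer-factor coarsening are supported;
  regridding from model-native grids is out of scope.
- The month-wise regression ignores lags and memory by design; its
  residual collects them, which the R² diagnostic makes visible.
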