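# Methods

This note documents the models implemented in `prcarbon`, their assumptions,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## 1. Light-use-efficiency photosynthesis

GPP (gC m⁻² month⁻¹) is computed as

GPP = φ₀ · I · (χc_a − Γ*)/(χc_a + 2Γ*) · 12.011,

the electron-transport-limited assimilation rate under the coordination
hypothesis: photosynthetic capacity acclimates so that Rubisco-limited and
light-limited rates coincide under typical daytime conditions, which makes the
light-limited form predictive on monthly timescales and absorbs V_cmax.  A
separate Rubisco-limited prediction is therefore deliberately not computed.
Nutrient limitation is assumed to act through foliage allocation and hence to
be contained in the observed fAPAR.

Parameters (all configurable through `PhotosynthesisParams`):

| symbol | meaning | default | units |
|---|---|---|---|
| φ₀ | intrinsic quantum efficiency | 0.085 | mol C (mol photon)⁻¹ |
| β | least-cost unit-cost ratio | 356.51 | – |
| Γ*₂₅, ΔH | compensation point at 25 °C, activation energy | 4.22 Pa, 37.83 kJ mol⁻¹ | |
| K_c25, ΔH | carboxylation coefficient | 39.97 Pa, 79.43 kJ mol⁻¹ | |
| K_o25, ΔH | oxygenation coefficient | 27,480 Pa, 36.38 kJ mol⁻¹ | |
| P_o | O₂ partial pressure | 0.21 × 101,325 Pa | Pa |
| P_surf | surface pressure for ppm↔Pa | 101,325 | Pa |

φ₀ has no single canonical value in the LUE literature; 0.085 is a common
field-calibrated choice.  Because φ₀ multiplies GPP linearly it cancels from
every relative diagnostic in this package (β_CO2, attribution deltas relative
to their own baseline, equilibrium R₀ closure), so no result here depends on
it.

Temperature kinetics use the Arrhenius form x(T) = x₂₅·exp[ΔH(T−298.15)/
(298.15·R·T)], exactly x₂₅ at 25 °C.  Temperatures are °C at all I/O
boundaries (forcing files, vapour-pressure helpers) and K inside the kernels;
each function documents which it takes, and the Kelvin kernels reject values
outside (200, 350) K to catch unit mistakes loudly.

Saturation vapour pressure uses the Magnus form
e_s = 610.94·exp(17.625T/(T+243.04)) Pa (Alduchov–Eskridge coefficients;
e_s(0 °C) = 610.94 Pa).  VPD from daily extremes is the mean of e_s(T_min)
and e_s(T_max) minus actual vapour pressure, floored at zero.

The relative water viscosity η* is the ratio of a Vogel–Fulcher–Tammann
correlation η(T) = 0.02939·exp[507.88/(T_K − 149.3)] mPa·s to its 25 °C
value; it is exactly 1 at 25 °C and ≈ 2.0 at 0 °C, matching tabulated water
viscosities to ~0.1 % over 0–50 °C.

### Optimal χ and the cost parameter β

The least-cost hypothesis gives χ = ξ/(ξ+√D) with ξ = √(βK/(1.6η*)), all
pressures in Pa.  Two numerical choices:

- **D = 0 is rejected** (the optimum degenerates to χ→1); gridded
  evaluation floors D at 10 Pa so saturated cells remain evaluable.
- **η\* outside 0–50 °C** is held at its boundary value, so sub-zero months
  (where GPP is effectively light/temperature-limited anyway) do not abort a
  global run; `water_viscosity_rel` itself keeps its strict domain.

With the constants above, inverting the model at the calibration point
(χ = 0.8, T = 298.15 K, D = 1 kPa) yields β ≈ 361.0.  The widely used
calibration value β = 356.51 is nevertheless adopted as the default because
it is the established reference figure and reproduces χ = 0.799 ≈ 0.80 at
the calibration point; the ~1.2 % gap between 356.51 and the consistent-unit
inversion is sensitive to the assumed O₂ partial pressure and to unit
conventions in the inversion (e.g. expressing pressures in bar instead of Pa
rescales the result by 1.013) and is documented rather than hidden:
`invert_beta_cost` always reports the value implied by its stated
assumptions.

### Units of Γ* in ppm

The flux code carries Γ* in Pa and converts to ppm with the single
configurable surface pressure (4.22 Pa ↔ 41.6 ppm at 101,325 Pa).  The
sensitivity module instead takes Γ* = 43 ppm as its reference input — the
conventional rounded value at 25 °C — because the published sensitivity
figures (37 %/19 %) are defined with it.  The two conventions are documented,
not reconciled; the difference moves β_CO2 at 400 ppm by < 1 percentage
point.

## 2. Ecosystem respiration and the R₀ solve

R_eco = (R₀ + k·GPP) · f(T) · α, with the Lloyd–Taylor scalar
f(T) = exp[E₀(1/(T_ref−T₀) − 1/(T−T₀))], T_ref = 15 °C, T₀ = −46.02 °C.

The placement of the moisture scalar α (which terms it multiplies) is a
genuine design point: here both the basal and the GPP-coupled term are
modulated by f(T)·α, so ∂R_eco/∂GPP = k·f(T)·α and R_eco = R₀ exactly at
(GPP = 0, T = T_ref, α = 1).  This choice is frozen by a golden regression
test.  Conceptually the k·GPP term is autotrophic plus fast labile
heterotrophic respiration; R₀ stands for the slow heterotrophic pools.

Per-PFT (E₀, k) are supplied as a table (`pft,E0,k` CSV).  The shipped
default table is a **synthetic stand-in** spanning plausible ranges
(E₀ 120–350 K, k 0.1–0.5 across PFT bands); site-calibrated values should
replace it for any real-data use.  No acceptance-level result depends on the
specific values.

R₀ is solved per cell from the linearity of R_eco in R₀:
R₀ = (Σ_m GPP_m − k Σ_m GPP_m s_m)/Σ_m s_m with s_m = f(T_m)·α_m over a
preindustrial climatology (default: the first 15 years of forcing,
configurable).  "Equilibrium under preindustrial conditions" is interpreted
as mean annual NEP = 0 over that window.  The solve verifies itself by
re-running the respiration model (per-cell |annual NEP| < 10⁻⁸ gC m⁻²).  A
negative solution (possible only when k·⟨s⟩ approaches 1) is floored at zero
and excluded from the verification; the default parameter ranges keep
k·⟨s⟩ < 1 everywhere on the synthetic grids.

## 3. CO₂ sensitivity

β_CO2 = (∂GPP/∂c_a)(c_a/GPP) = 3χc_aΓ*/[(χc_a−Γ*)(χc_a+2Γ*)], with the
analytic derivative ∂β_CO2/∂c_a = −3χΓ*(χ²c_a²+2Γ*²)/[(χc_a−Γ*)²(χc_a+2Γ*)²].
χ is held fixed at 0.8 in these evaluations — the weak dependence of χ on
c_a through the least-cost model is deliberately excluded, as the standard
derivation does, so the closed form matches the reference figures.  Both
forms are continuously verified against central-difference differentiation
(10⁻⁸ relative).

## 4. Growth-rate diagnostics

The sink model is fitted as G = c₀ + F_anthro − B·M by OLS (statsmodels),
with the emissions coefficient fixed at 1; a free-coefficient design is
available behind a flag.  M₀ and F₀ are not separately identifiable from an
intercept, so the composite c₀ = B·M₀ − F₀ is reported (F₀ is derived when
the caller supplies M₀).  Residuals are always reported for the full series,
not only the fit window.

**Growth-rate convention.**  G(t) is the forward annual increment
M(t+1) − M(t) (ppm via the fixed conversion 1 ppm = 2.124 PgC).  A centred
difference is available as an option, but forward differencing is the
default because it makes the generator/fitter round trip exact: a noise-free
synthetic series refits to its generating (B, F₀) at machine precision,
which anchors the whole recovery test hierarchy.

**Structural-break test.**  A two-sided one-sample t-test of the post-
candidate-year residuals against zero (α = 0.05).  Its type-I error is the
nominal 5 % when the residuals fed to it are independent draws around zero —
the test's actual null, and how the calibration is measured.  Two pipeline
caveats, quantified by simulation and worth knowing before interpreting a
rejection:

- residuals *extrapolated* beyond a 30-year fit window are strongly
  anticonservative (≈ 50 % false positives at α = 0.05 for a 56-year series:
  far outside the fit range the slope-estimation error dominates and is
  common to all post-window residuals);
- residuals of a *full-series* fit on model-generated data are strongly
  conservative (≈ 0.4 %: the regressor M integrates the same noise the
  residuals contain, so the fit absorbs it).

Power, measured with the published design (30-year fit window, 30 % step in
B at year 43 of 56, noise s.d. 0.2 PgC yr⁻¹), is ≈ 100 % for a negative
residual mean at p < 0.05.

**Mann–Kendall/Sen.**  S = Σ_{i<j} sign(x_j−x_i); variance with the standard
tie correction; two-sided p from a continuity-corrected normal
approximation; τ is tau-b; the Sen slope is the median pairwise slope.  The
implementation is cross-checked against both exhaustive enumeration (n ≤ 10)
and scipy's `kendalltau`/`theilslopes`.

**Deseasonalisation** subtracts the calendar-month climatology.  Note that
group-mean removal converts a linear ramp into annual steps: the trend is
preserved exactly within each calendar-month series and to a few percent in
a full-series OLS.

## 5. SSA and IAAFT surrogates

SSA embeds the series in an L×K Hankel trajectory matrix (default
L = ⌊n/2⌋, configurable), takes the SVD and diagonally averages each
rank-one term into an elementary component.  Completeness (components sum to
the series) and the Parseval identity (eigenvalues sum to the trajectory
matrix's squared norm) are asserted in tests.

Each component's characteristic frequency is its periodogram argmax (the
assignment rule is not canonical; argmax is simple and reproducible).  The
"≥ 5-year" subsignal X5 sums all components with dominant period ≥ 5 samples;
a flag switches to the alternative reading (only the component(s) nearest a
5-year period).  Band extraction is exactly idempotent for band-limited
signals; for an X5 distilled from noise, re-extraction differs by the small
boundary-leakage energy (sub-percent of variance, a known property of SSA
mode mixing), which is why the uncertainty procedure perturbs the residual
rather than re-extracting blindly.

IAAFT surrogates iterate (spectrum step, rank-order amplitude step) from a
random permutation; amplitude last, so the surrogate's sorted values equal
the original's exactly while the spectrum converges (cap 1000 iterations,
stop when the spectrum changes by < 10⁻⁸ relative).  Surrogates are built
from the residual after X5 removal (the subsignal is treated as signal, the
remainder as exchangeable noise); X5 is added back, re-decomposed and
re-extracted 100 times, and the pointwise standard deviation across
re-extractions is the extraction uncertainty.

## 6. Attribution experiments

Detrending is per cell and per calendar month: the OLS slope over the full
record is removed and the series re-anchored to its baseline-period
(default 1901–1915) mean, so all experiments agree in the baseline period by
construction; physical bounds are re-clipped afterwards with counted
warnings.  "Climate" bundles temperature and VPD into one driver
(T-only/D-only runs are possible but not default).  A pre-1981 fAPAR
climatology operation emulates the satellite-era observability constraint.
Every experiment solves R₀ on its own preindustrial forcing, so each is in
equilibrium with its own baseline state.  Zonal profiles are native-grid
latitude rows; no smoothing is applied.

The additivity check quantifies the interaction remainder between the sum of
single-driver deltas and the full run; for the default synthetic trends it
is < 10 % of the full NEP change (first-order regime).

## 7. What the synthetic generator emulates — and what it does not

`make_forcing` builds each driver as latitude climatology + hemisphere-aware
seasonal cycle + linear trend + AR(1) noise (lag-1 correlation 0.3 by
default; interannual persistence of real climate is not otherwise
parameterised), on an 18×36 (10°) grid by default (0.5° is supported but not
required).  Default trends emulate the 20th-century study period: CO₂ from
290 ppm (1900) to 400 ppm (2013), ~0.9 °C century⁻¹ warming, a small
greening trend.  Monthly light I₀ spans ~300–1200 mol photon m⁻² month⁻¹
from poles to equator.  fAPAR/α are clipped to [0,1] (a trend that would
push > 5 % of cell-months out of bounds is rejected as unphysical).  PFTs
are contiguous latitude bands.

Deliberate non-realism: the synthetic planet is fully vegetated (no ocean or
barren mask), so global totals (GPP ~ 65–77 PgC yr⁻¹ over the century on the
default grid) are not calibrated to the real land biosphere; there is no
ENSO-like mode, no land-use flux, no soil-carbon pool dynamics, and no
spatial noise correlation.  Passing tests therefore demonstrate the
*structural* correctness of the methods (recovery of known truths, correct
signs and nulls, exact identities), not agreement with observed magnitudes.
Real-data quantities (observed airborne-fraction trends, the observed
growth-rate history, satellite greening contributions, real attribution
magnitudes) require the external CRU/GIMMS/MODIS/GCP/NOAA archives and are
out of scope.

`make_budget_series` integrates the sink model itself forward
(explicit annual Euler) with optional Gaussian noise and an optional step
change in B, so growth-diagnostic recoveries are exact at zero noise by
construction.  Default sink parameters (B = 0.02 yr⁻¹, M₀ = 280 ppm
equivalent, emissions ~ e^{0.0205(t−1900)} + 0.8 PgC yr⁻¹) give late-period
airborne fractions near 0.5, in the realistic range.

## 8. Problem sizes and determinism

Default test/acceptance problem sizes — 18×36 or smaller grids, 56-year
budget series, 500-seed recovery ensembles, 1000-seed calibration, 100 IAAFT
surrogates — were chosen so the full suite runs in seconds on one CPU while
keeping Monte-Carlo standard errors well below the asserted tolerances.  All
randomness flows from explicit seeds (`numpy.random.default_rng`); the
pipeline splits one root seed per stage via `SeedSequence`, and identical
configs reproduce byte-identical CSV/JSON outputs.

## 9. Known limitations

- The β inversion / 356.51 unit question (§1) is documented, not resolved.
- The respiration parameter table is a stand-in; absolute R_eco magnitudes
  are not meaningful until calibrated.
- The break test is a screening device; its size is only nominal under the
  i.i.d.-residual null (§4), so pipeline p-values should be read with the
  quantified caveats.
- SSA band membership is decided by periodogram argmax on short series,
  which can flip for components whose energy straddles the 5-year boundary;
  the surrogate s.d. quantifies exactly this instability.
- NetCDF I/O uses the NetCDF3 (scipy engine) format: portable and
  dependency-light, but without compression or groups.
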