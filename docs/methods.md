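# Methods

## Scope and model

All computations assume steady state in one spatial dimension. A solute
with molecular diffusion coefficient D (cm² s⁻¹) in sediment of porosity
φ obeys

    φ D d²C/dz² − R(z) = 0,

where R(z) is the net volumetric reaction rate (µmol cm⁻³ h⁻¹ at the
interface, converted to per-second internally), **consumption positive,
production negative** — the microsensor community's sign convention.
Positions are distances in cm from a named reference interface (sediment
surface for vertical transects, root surface for radial ones),
increasing away from it. Concentrations are carried internally in
µmol cm⁻³ (≡ mM); file I/O speaks µm / µM.

Fluxes follow Fick's first law, J = −φ D (dC/dz) · 3600, in
µmol cm⁻² h⁻¹ positive toward increasing position. Geometry is planar
throughout by default — the per-cm² flux arithmetic used for both
sediment and root interfaces — with a cylindrical solver mode available
behind a flag for radial scenarios around a root of given radius.

No porosity/tortuosity correction is applied by default (φ = 1,
free-water D at 20 °C: O₂ 2.06×10⁻⁵, NH₄⁺ 1.93×10⁻⁵, NO₃⁻
1.89×10⁻⁵ cm² s⁻¹). No temperature correction of D is attempted; users
working away from 20 °C supply their own coefficients.

## Forward solver (synthetic data generator)

The boundary-value problem is discretised with a node-centred
finite-volume scheme on the uniform measurement grid (default step 50 µm,
the instrument-typical increment): diffusive face fluxes by central
differences, the rate field integrated exactly over each control volume
(rates are piecewise constant, so cell integrals are exact), Dirichlet
or flux conditions at either end (at least one end must fix the
concentration or the level is undetermined). The system is tridiagonal
and solved directly.

Properties that the tests pin down:

* second-order convergence against exact piecewise-parabolic solutions,
  and *nodal exactness* when rate jumps coincide with grid nodes — the
  usual case, since zone boundaries live on the measurement grid;
* exact discrete conservation: the boundary-flux difference equals the
  zone-integrated rate to rounding, where the boundary flux is the
  one-sided face flux corrected by the adjacent half-cell rate integral.
  `ZoneRateResults.boundary_fluxes()` uses the same definition, which is
  why the conservation identity holds at 1e-8 and better. A plain OLS
  window slope at the boundary would estimate the gradient half a window
  inside the domain and cannot satisfy the identity on curved profiles.

Negative steady-state solutions are never clipped: they mean the rates
are inconsistent with the boundary values, and the solver raises an
infeasible-scenario error instead.

Measurement noise is additive homoscedastic Gaussian with a mandatory
seed, truncated at zero for solutes (a sensor reports nothing below its
floor). The default σ = 1 µM is a detection-limit-scale noise typical of
needle microsensors; the study's instruments have no published noise
figure, so this is a package choice.

### Presets

`fig5_o2` emulates a layered rhizosphere transect 25 mm from a root
apex: 1.9 mm from the sediment surface (55 µM O₂) to the root surface
(80 µM), with an anoxic gap between a consuming surface layer and a
consuming rhizosphere shell. Zone rates are derived in closed form from
parabolic pieces that meet an anoxic plateau with zero slope. Two
deliberate choices:

* the plateau sits at 0.1 µM rather than exactly zero, keeping the
  discrete solution strictly feasible without clipping;
* the parabola vertices (1.25 / 1.35 mm) are placed so that what a
  1 µM-threshold detector *sees* matches the emulated observation: O₂
  reads depleted from ≈1.1 mm depth and reappears ≈0.5 mm above the
  root, an oxic shell of ≈0.49 mm. The implied root-surface flux is
  0.215 µmol O₂ cm⁻² h⁻¹ and the rhizosphere shell consumes O₂ about
  seven times faster per volume than the surface layer.

`fig5_nh4` is the NH₄⁺ analogue (consumption in the top 0.5 mm and in
the rhizosphere shell, inert in the anoxic gap). `uniform_consumption`
(one zone, zero-flux bottom) and `two_zone` (consumption 0.4 then
production −0.2 µmol cm⁻³ h⁻¹ over 2 mm) are the parameter-recovery
workhorses; at the default σ the two-zone noise is 1% of full scale.

What the generator does *not* emulate: drift and calibration error,
position-registration error at the interface, heteroscedastic or
correlated sensor noise, 2-D/3-D geometry, advection, and transients.
Passing recovery tests therefore demonstrate correctness of the
inversion under the stated noise model, not robustness to every field
artefact.

## Zone-rate inversion

For fixed zone boundaries the steady-state solution is linear in the
zone rates, so the observed profile is fitted by ordinary least squares
with design columns:

* a constant and a linear ramp — the homogeneous (zero-rate) solutions,
  which estimate the effective boundary concentrations. Pinning the two
  measured end points as exact Dirichlet values instead correlates every
  residual with those two noisy readings; in replicate simulations that
  choice produced ~60% coverage for nominal-95% intervals, while the
  free baseline restores the calibrated ~94%;
* one forward-solver response per zone (solved once per grid interval
  with unit rate and zero Dirichlet ends; zone columns are contiguous
  sums via prefix sums, so the boundary search costs one small lstsq per
  candidate).

Zone boundaries are restricted to measurement grid points and found by
exhaustive search for k ≤ 3 zones, and by greedy insertion plus one
local refinement sweep for k > 3 (default k_max = 5).

The zone count is the smallest k whose nested F-test against k+1 zones
is non-significant (default α = 0.05, Δp = 2: one rate, one boundary).
Because the added boundary is the *best* of ~n candidate grid
placements, the raw improvement is a best-of-m statistic; the p-value is
Bonferroni-adjusted by the number of candidate placements. Without the
adjustment the procedure overfits noticeably (the true two-zone preset
was split into three zones in about a third of noisy replicates); with
it, selection is essentially exact at the tested noise level. An RSS
floor near machine precision short-circuits the test on noise-free data,
where the F statistic is numerically meaningless.

Rate standard errors come from the least-squares covariance at the
selected layout. `conf_int()` additionally (by default) widens intervals
to the envelope over all boundary layouts whose RSS lies within a
profile-likelihood cutoff of the optimum, because the boundary location
is estimated, not known; measured empirical coverage of the 95%
intervals on the two-zone preset is 0.94 with the true boundary fixed
and 0.98 with the search included (conditional-only intervals: 0.62).

Depth-integrating the fitted rates (Σ Rᵢhᵢ) converts volumetric zone
rates to the areal interface rates used in budgets, and equals the
fitted boundary-flux difference exactly (conservation).

## Flux, ROL, and oxic geometry estimators

`estimate_flux` fits an OLS line over a window of points on the inner
side of an interface (default 3 points = 100 µm at a 50 µm step) and is
exact on linear profiles for any window; the flux SE is propagated from
the slope SE. On curved profiles the window slope estimates the gradient
at the window centre, so for a model-consistent interface flux the
fitted `boundary_fluxes()` is preferred. `estimate_rol` applies this at
position 0 of a radial O₂ profile, planar form, outward positive; an
inward (negative) flux is reported with a flag rather than hidden.

`oxic_metrics` reports the penetration depth (first crossing below a
1 µM default threshold, linearly interpolated; flagged "not reached"
when the transect stays oxic) and the thickness of the contiguous
above-threshold region adjacent to the root side of the transect
(geometry-inferred: the start for radial profiles, the end for vertical
transects onto a buried root). A transect that never rises above the
threshold returns zero-extent metrics with a flag.

## Budget upscaling

Active root area treats releasing tips as open cylinders (lateral area
only; reproducing the census arithmetic exactly): π·d·L_active·count,
in cm² per 100 cm² of sediment. Areal O₂ release is ROL × area; the
gram conversion uses 32.00 g mol⁻¹ O₂ (×100 to m², ×24 to day, ×32e-6
µmol→g). The ammonia-oxidation split uses 1.5 mol O₂ per mol NH₄⁺
(NH₄⁺ + 1.5 O₂ → NO₂⁻), configurable; fractions above 1 are flagged as
stoichiometrically impossible rather than truncated. The reactor mass
balance is (c_in − c_out)·Q/A with production negative. No attempt is
made to partition NH₄⁺/NO₃⁻ consumption between nitrification,
denitrification, assimilation and plant uptake — the profile data alone
cannot separate them.

## qPCR

Calibration is an OLS line of Cq on log₁₀(copies) over ≥3 distinct
dilution levels; a non-negative slope invalidates the assay. Efficiency
ε = 10^(−1/S) − 1 (S = −3.32 is perfect doubling), and the
quantification inverse is copies = 10^((Cq − intercept)/S), flagged when
extrapolating outside the calibrated dynamic range. Detection limits are
per-assay (defaults 27, 160, 54 copies per well for the AOB,
*Nitrospira*-like and *Nitrobacter*-like assays), compared
boundary-inclusively — the limit is defined as the lowest quantifiable
standard — and below-limit results carry the limit, never zero.
Per-volume/per-mass conversion factors depend on elution volume,
template volume per well and sample mass and are therefore always
explicit configuration, never inferred. Gene copies convert to cells
assuming one 16S rRNA gene copy per genome by default.

## Numerical choices and problem sizes

Tolerances asserted in the tests: solver vs closed forms ≤1e-6 (machine
precision in the nodally-exact cases), conservation 1e-8 relative,
CSV round-trip 1e-12 relative, qPCR round trip 1e-9, efficiency/slope
inverse pair 1e-12. The replicate studies use 200 seeded realisations of
the two-zone preset (41 points each) for bias/coverage and 50 in the
acceptance script; the acceptance script averages 5 replicate transects
before profile analysis, mirroring the standard practice of repeating a
microsensor path and averaging. These sizes keep every result stable to
well under the tolerances above while the full suite runs in seconds.

## Known limitations

Steady-state only; uniform grids only; planar flux arithmetic for the
radial ROL (the cylindrical correction exists in the solver but is off
by default to match the per-cm² convention); piecewise-constant rates
(no smooth R(z)); single-transect inversion (no 2-D reconstruction);
homoscedastic noise model; qPCR handles Cq tables, not raw fluorescence
or melt curves.
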