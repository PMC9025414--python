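# Methods

This note documents the models implemented in `maizesail`, the choices
made where the design was genuinely open, and what the synthetic
campaigns do and do not establish about real data.

## Leaf model (PROSPECT-4)

The generalized plate model: a leaf is N homogeneous layers (N
continuous, ≥ 1) separated by air gaps. Per-layer absorption is
k(λ) = (C_ab·k_cab(λ) + C_w·k_cw(λ) + C_m·k_cm(λ)) / N. The
transmissivity of an elementary layer under isotropic internal
illumination is τ(k) = (1−k)e^(−k) + k²E₁(k); E₁ is evaluated with
`scipy.special.exp1` (accurate to machine precision, including the
sensitive k → 0 regime). Interface transmittances come from the
average-transmissivity integral tav(θ, n): the top surface uses the
standard 40° incidence cone of the plate-model family, internal
interfaces the 90° (isotropic) value; tav below 0.1° falls back to the
normal-incidence Fresnel limit to avoid catastrophic cancellation. The
N-layer stack is solved with the Stokes similarity solution; at
conservative wavelengths (r + t → 1) the degenerate algebra is replaced
by the classical pile-of-plates limit, which keeps R + T = 1 to better
than 10⁻¹² there.

Unit tests validate the solver against an independent oracle that sums
the multiple-reflection series explicitly and stacks integer numbers of
layers by iterative adding (agreement to 10⁻⁸), plus conservation,
monotonicity and continuity properties over the leaf parameter ranges.

### Synthetic leaf optical constants

No measured coefficient table is shipped; all tests and synthetic
campaigns use a documented analytic surrogate:

* n(λ) = 1.45 − 10⁻⁴·(λ − 400) — a gently falling refractive index;
* k_cab(λ) = 0.06·G(430, 30) + 0.10·G(662, 25) per µg/cm², two
  unit-peak Gaussians for the blue and red chlorophyll absorptions;
* k_cw(λ) = 0 below 850 nm (liquid water absorbs further into the
  infrared);
* k_cm(λ) = 4 per g/cm², flat.

The dry-matter coefficient is sized so that at the fixed content
C_m = 0.005 g/cm² a typical leaf keeps a near-infrared single-scattering
albedo of ≈ 0.92, as real leaves do. This is load-bearing: with a
strongly NIR-absorbing leaf the canopy NIR reflectance would be flat in
LAI and the entire retrieval mechanism (NIR brightening with leaf area)
would disappear. With these constants canopy NIR rises 0.18 → 0.46
over LAI 0.5–7, in the range hyperspectral maize campaigns report.

Known surrogate gaps, relevant when interpreting index behaviour: there
is **no chlorophyll absorption near 560 nm** (the two Gaussians vanish
there), so GNDVI carries almost no chlorophyll signal and the green
band behaves like a NIR band; the red edge is present but weaker than
in measured spectra, so NDRE is less informative than it is on real
maize. A measured table restores these features via
`prospect4.read_constants` (columns: wavelength_nm, n, k_cab, k_cw,
k_cm).

## Canopy model (4-SAIL)

Classical four-stream theory for a homogeneous turbid layer of
arbitrarily inclined leaves: SUITS geometric factors per inclination
class (the `volscatt` construction), averaged over the standard
13-class quadrature (10° classes to 80°, then 2° classes to 90°); exact
two-stream solutions for the diffuse fluxes with the J-function
singularity handled by series expansion; the hot-spot correction
integrates the joint sun–view gap probability in 20 exponential steps;
the canopy layer is coupled to a Lambertian soil lower boundary. The
returned quantity is the direct-sun directional reflectance factor;
a diffuse-sky fraction `skyl` (default 0, appropriate for imagery
corrected to surface reflectance under clear sky) blends in the
hemispherical-directional factor.

**Leaf inclination distribution.** The ellipsoidal distribution is
parameterized by its mean inclination ALIA. The excentricity is
calibrated numerically — a one-time table maps excentricity to the
continuous distribution's mean on a 0.05° quadrature and is inverted by
interpolation — so the continuous mean equals ALIA to well under 0.5°
across the whole range. The widely used cubic-polynomial calibration
was measured to miss by up to 1.3° (57 → 55.8°, 75 → 76.3°) and was
therefore not used.

**Geometry convention.** View zenith may be signed (θ_v ∈ (−90°, 90°))
with relative azimuth φ_SV ∈ [0°, 180°]; (−θ_v, φ) is folded to
(θ_v, 180° − φ) internally, making the convention check
BRF(−θ_v, 0°) = BRF(θ_v, 180°) exact.

**Soil.** One packaged reference spectrum, the analytic ramp
r(λ) = 0.12 + 0.00035·(λ − 400) clipped to [0, 1], scaled linearly by
the brightness parameter α_soil ∈ [0, 1]. Whether a field study's soil
variability is better captured by scaling one spectrum or mixing
wet/dry endmembers is not decidable here; linear scaling is the
convention, and a user soil file can be substituted.

With no reference PROSAIL implementation available in this environment,
the canopy solver is validated by closed-form invariants instead:
spherical-distribution extinction k_s·cos θ_s = 0.5 and mean squared
cosine 1/3; exact soil reproduction at LAI = 0; hot-spot maximum at
θ_v = θ_s in the principal plane; saturation and soil-decoupling
monotonicities; energy bounds over random parameter draws.

## Band model

Bands are Gaussian with a shared FWHM (7.5 nm default, σ = FWHM/2.3548),
truncated at ±2 FWHM and renormalized (< 0.1 % mass loss). The default
grid is 400–850 nm inclusive (61 centres); the printed exclusion
wavelengths (751, 759, 766, 773, 810, 818 nm) do not sit exactly on a
7.5-nm grid and are matched to the nearest centre within ±4 nm, leaving
55 active bands. Edge bands keep truncated, renormalized kernels: the
400 and 850 nm bands must exist even though their support is clipped by
the spectral range, at the price of a small quadrature bias (~10⁻³)
relative to an untruncated kernel — interior bands agree with a 0.1-nm
quadrature oracle to better than 10⁻⁷. Band values for vegetation
indices are taken from the nearest *active* centre to the nominal
wavelength (832 → 835, 663 → 662.5, 560 → 557.5, 722 → 722.5 nm), ties
resolved toward the shorter wavelength.

## Look-up-table inversion

The default design replicates the study configuration: 60 750 records;
free parameters i.i.d. uniform; LAI stratified by a one-dimensional
latin hypercube (exactly one sample per equal-width stratum); fixed
C_w/C_m/θ_s. The exact factorization behind the 60 750 figure is not
derivable from the record count alone; i.i.d. uniform + LHS is the most
literal reading and is the packaged default. The LSE cost is the plain
sum of squared band differences; the best ceil(0.10·n) records (ties
broken by record index, deterministically) are averaged per free
parameter — unweighted mean by default, 1/cost weighting behind a flag.
View geometry is a free LUT dimension; `LUT.subset_geometry` restricts
the table to a window around a known observation geometry before
inversion.

**What best-10 % averaging costs.** Averaging 10 % of a large LUT
shrinks retrievals toward the prior mean: in a noise-free self-closure
over the full prior (100 observations, 20 000-record table) the
retrieved-vs-true LAI reaches R² = 0.68 / RMSE = 1.14 m²/m², with low
LAI over- and high LAI under-estimated — the same over/under pattern
field validations of this method report. The identical experiment
retaining 0.1 % gives R² = 0.88 / RMSE = 0.65, so the limitation is the
retained-fraction convention (and the ALIA–LAI trade-off in the NIR:
at fixed LAI = 3, NIR varies 0.47 → 0.07 over ALIA 35–90°), not the
machinery. Over the realistic field range of LAI (≈ 0.6–5, as in the
synthetic campaigns) the same best-10 % inversion closes at R² ≈ 0.91 /
RMSE ≈ 0.74, because the saturated upper prior tail is absent. The 10 %
convention is kept as the default because it is the method's standard
and is robust under real measurement noise.

## Global sensitivity analysis

First-order indices by binning: S_i(band) = Var(E[R | bin of
parameter i]) / Var(R) from a single Monte-Carlo sample of the prior
(equal-width bins over each parameter's range; requires
n_mc ≥ 50·bins; fixed parameters and zero-variance bands have index 0
by convention). Freeing C_w over [0, 0.05] cm yields indices below 0.02
at every band — pure estimator noise, since k_cw ≡ 0 below 850 nm —
which is the null-sensitivity argument for fixing C_w (and likewise
C_m) in the retrieval. Note that under the surrogate constants the
LAI index is largest in the red (soil darkening, ≈ 0.6) and diluted in
the NIR (≈ 0.35) where the leaf-inclination interaction absorbs
variance; directional claims about per-band sensitivity depend on the
constants used.

## Synthetic field campaigns

The generator emulates a two-field maize study: F1 (26 points, 12
calibration points carrying ground LAI at 40/53/74/107/123 days after
sowing) and F2 (25 points, harvest only), harvest footprint 2 rows ×
5 m × 0.8 m = 8 m², 51 yield points of which 39 are held out for
cross-validation.

* **Growth.** Green LAI(t) = L_max·logistic(rate 0.055 d⁻¹, midpoint
  57 DAS)·senescence(rate 0.1 d⁻¹, onset 145/148 DAS, per-point jitter
  σ = 8 d, independent of yield). The per-point plateau is
  L_max = 5.8 − Exp(scale): the hybrid's potential minus an
  exponentially distributed stress deficit (scale 1.1 m²/m² for
  furrow-irrigated F1, 0.4 for pivot-irrigated F2). The left-skewed
  plateau distribution is what lets a field combine a wide yield range
  with a biologically capped LAI; it gives field-mean LAI ≈ 1.3 at
  40 DAS and a seasonal maximum ≈ 4.9 at 123 DAS.
* **Yield.** biomass = 2.5 (F1) / 3.8 (F2) t·ha⁻¹ per m²/m² of plateau
  LAI plus Gaussian noise; grain yield = 0.47 × biomass plus noise,
  clipped to [0, biomass] so biomass ≥ yield holds structurally.
  Generated values sit inside the campaign's reported ranges
  (F1 biomass 4.4–20, yield 1.4–9.2; F2 biomass 14.8–26.7, yield
  8–12 t/ha) for ≥ 95 % of points across seeds.
* **Spectra.** True LAI from the same seeded trajectories; nuisance
  parameters from within-field distributions much narrower than the
  retrieval prior (a single hybrid on one date does not span the
  literature range): N ~ N(1.5, 0.08), ALIA ~ N(60°, 5°),
  hot ~ N(0.15, 0.03) per point; C_ab ~ N(55 + 4·(L_max − L̄), 3) µg/cm²
  — chlorophyll weakly coupled to vigour; soil brightness one draw per
  acquisition date (surface moisture) with σ = 0.05 per-point jitter;
  view geometry uniform over the acquisition ranges per observation.
  All draws are clipped to the retrieval prior. Noise: multiplicative
  Gaussian σ = 2 % plus additive σ = 0.005, clipped to [0, 1].
* **Senescence and stage structure.** Because senescence timing is
  independent of yield, index–yield correlations peak in the late
  vegetative window and decay toward harvest, so the stage-selection
  machinery has a real optimum to find.

**What passing tests show — and do not.** The campaigns close the loop
between the generator and the retrieval under *matched physics*: the
same forward model, constants and soil on both sides. They establish
internal consistency, determinism, the design arithmetic, and the
qualitative behaviour of the method (saturation, stage structure,
field contrasts). They do not establish accuracy on real imagery,
which adds row structure and shading (not modelled — the canopy is a
homogeneous turbid medium), atmospheric residuals, mixed pixels,
registration error and model-constant mismatch. Pixel-level buffering
and aggregation are likewise not emulated.

## Pipeline and reproducibility

`maizesail run` executes synth → build-lut → invert → vi → fit-yield →
evaluate from one YAML config. Stage selection uses the per-date R² of
the configured family per predictor (retrieved LAI, GNDVI, NDRE linear;
NDVI exponential — the standard choice against NDVI saturation), ties
toward the earliest date; the best F1 date is mapped to the other field
by growth-stage label (V16 ↔ 74 DAS in F1, 67 DAS in F2), falling back
to nearest DAS. Fit R² is the coefficient of determination on the
calibration points; cross-validation R² is the squared Pearson
correlation of estimated vs ground values — both are reported under
those distinct names. Exponential and power fits minimise squared error
on the original response scale (Levenberg–Marquardt seeded by the
log-linearised closed form), so printed coefficients are recovered
exactly from noise-free data. Every random draw flows from explicit
seeds; the run manifest records the config hash and a SHA-256 per
output, and re-running a config reproduces every checksum.

Default problem sizes used by the test suite: 300–1000-record LUTs for
unit tests, 8000 for the campaign closure, 20 000 for the full-prior
recovery experiment, and the full 60 750 default build exercised once —
sizes chosen so the whole suite completes in a couple of minutes while
each experiment stays in the regime its conclusion needs (a 20 000-
record table already has mean best-match spectral distances far below
the noise model's floor).
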