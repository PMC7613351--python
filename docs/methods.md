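# Methods

`toasense` studies a question from quantitative vegetation remote sensing:
which leaf, canopy and atmospheric state variables drive the top-of-atmosphere
(TOA) radiance that an optical satellite measures over a vegetated surface,
and can leaf biophysics (chlorophyll content Cab, water content Cw, leaf area
index LAI) therefore be retrieved *directly* from TOA radiance, skipping
atmospheric correction?  The package answers it on a self-contained simulated
testbed: built-in surrogate radiative-transfer models generate the data, a
Gaussian-process emulator accelerates a variance-based global sensitivity
analysis (GSA), and hybrid Gaussian-process regressors perform the retrieval.

## Surrogate forward models

The surrogates are *normative* for this package: they are not reimplementations
of any particular leaf/canopy or atmospheric code, but compact models with the
correct qualitative spectroscopy, exposed behind pluggable interfaces
(`TwoFluxCanopyModel`; the transfer-function simulator) so genuine RTMs can be
substituted.

**Leaf and canopy (`toasense.surface`).**  Leaf single-scattering albedo
follows Beer-law extinction, `omega = 0.95 * exp(-A)` with
`A = Cab*alpha_cab + Cw*alpha_w + Cm*alpha_m`.  The constituent absorption
spectra are Gaussian fixtures: chlorophyll bands at 450/670 nm over a broad
visible shoulder (centre 550 nm, width 80 nm); water bands at
970/1200/1450/1940/2400 nm; a dry-matter continuum that is gated by a
logistic red-edge switch (centre 750 nm, width 25 nm) so dry matter absorbs
only above the red edge, plus a 2100 nm feature.  The gating and the visible
chlorophyll shoulder are deliberate: real cellulose/lignin absorption is
negligible in the visible while chlorophyll absorbs throughout it, and these
two features are what make chlorophyll the dominant driver of visible-range
variance and dry matter a NIR driver — the sensitivity fingerprint the
analysis is designed to resolve.  A leaf structure index N in [1.3, 2.5]
partitions `omega` into reflectance and transmittance.  The canopy is a
finite two-flux (Kubelka–Munk) layer over a parametric soil background with
per-unit-LAI absorption `k = 2*G_L*(1-omega)` and scattering `s = G_L*omega`,
where the projection factor `G_L` depends on mean leaf angle and sun angle;
the closed-form slab solution interpolates between the soil spectrum at
LAI = 0 and the infinite-canopy reflectance `a - b` at large LAI.
Directionality is collapsed to bi-hemispherical reflectance, consistent with
the Lambertian coupling below.  Native grid: 400–2500 nm at 1 nm.

**Atmosphere (`toasense.atmosphere`).**  Six transfer functions (path
radiance L0, direct/diffuse at-surface irradiance Edir/Edif, direct/diffuse
upward transmittance Tdir/Tdif, spherical albedo S) are produced from six
drivers: ozone column, columnar water vapour (CWV), aerosol optical thickness
at 550 nm, Henyey–Greenstein asymmetry G, Angstrom exponent and aerosol
single-scattering albedo.  Physics: Rayleigh + power-law aerosol extinction,
plane-parallel airmass factors, single-scattering path radiance with a
Rayleigh/HG phase mix, and a rational-form spherical albedo.  Water-vapour
band absorption uses a curve-of-growth exponent of 0.6, chosen so the 1380
and 1870 nm bands saturate across the CWV range [0.4, 4.5] g cm^-2 — this is
what confines CWV's sensitivity to its absorption bands.  The solar spectrum
is a 5800 K Planck shape scaled to 1.9 W m^-2 nm^-1 at 500 nm.  S excludes
gaseous absorption (a second-order effect).  Nine named aerosol presets
(rural, urban, three maritime, three continental, one urban-industrial) fix
(G, alpha, SSA) triples inside the sampled ranges.

**Coupling (`toasense.coupling`).**  TOA radiance over a Lambertian,
homogeneous surface:

    L = L0 + (Edir*cos(sza) + Edif) * (Tdir + Tdif) * rho / (pi * (1 - S*rho))

Surface spectra are cubic-spline resampled from the 1 nm grid to the
atmospheric grid (uniform 15 cm^-1 in wavenumber, 1401 points over
400–2500 nm, spacing 0.24–9.3 nm) before coupling.  `Edir` is defined as
per-beam irradiance so the explicit illumination cosine in the coupling is
coherent with the formula above.  A guard raises at `S*rho -> 1` rather than
clipping silently.

## Study datasets

Six LUT scenarios derive from one master experiment (defaults in
`RunConfig`): 10000 Latin-hypercube surface samples over the leaf/canopy box
(N [1.3,2.5], Cab [1,70] ug cm^-2, Cw [0.002,0.05] cm, Cm [0.002,0.05]
g cm^-2, LAI [0.1,7], mean leaf angle [0,90] deg) and 10000 LHS atmospheres
(ranges above), paired one-to-one by a seeded permutation and coupled to TOA
radiance (`analysis`).  A seeded permutation splits the surface samples into
two disjoint 5000-sample halves: `reference_toc` / `reference_toa` /
`reference_atm` (validation) and `retrieval_toc` / `retrieval_toa`
(training).  TOA subsets draw fresh atmospheres — all nine aerosol presets
for the reference set, rural only for the retrieval set, so retrieval from
TOA radiance carries aerosol-model error.  `reference_atm` perturbs
reference reflectance by a wavelength-dependent atmospheric-correction
residual `eps(lambda) = 0.010 + 0.015*exp(-(lambda-400)/300)` (declining
from ~0.025 in the blue), applied by default as seeded zero-mean Gaussian
noise (a deterministic bias mode is available; which the operational error
resembles more is genuinely open).  Geometry is fixed: sun zenith 30 deg,
nadir view.  The LUT soil background is fixed at brightness 1.0, wetness 0.3
(a mid-range assumption recorded in the config).

## Sensitivity analysis

First-order (Si) and total-order (STi) Sobol indices come from the radial
Saltelli design: one LHS of size N x 2k split into P | Q, plus k
column-substituted matrices, N(k+2) model evaluations in total (14000 at the
study scale N = 1000, k = 12).  The estimators are

    V(y) = mean(f(P)^2) - f0^2
    Si   = mean( f(Q) * (f(PQ_i) - f(P)) ) / V(y)
    STi  = mean( (f(P) - f(PQ_i))^2 ) / (2 V(y))

applied per wavelength.  Outputs with variance below 1e-12 are flagged
undefined (NaN) instead of divided.  Negative small-magnitude estimates are
reported as-is — they are Monte Carlo noise and useful for convergence
diagnostics; normalized shares (`sti_shares`) clip at zero for display.  A
Jansen-form first-order estimator is available behind a flag purely as a
cross-check; the radial form above is primary.  Estimator validation uses
the Ishigami function and the Sobol g-function, whose closed-form indices
are recomputed analytically in `toasense.gsa`.  Because substituted design
columns differ per variable, permuting the variable order reproduces index
rows only up to Monte Carlo noise, and single-seed errors at N = 4096 can
reach ~0.035; the test suite therefore checks medians over a fixed seed
batch against the +-0.03 expectation.

## Emulation

The spectral emulator (`SpectralEmulator`) compresses training spectra with
mean-centred PCA to 20 components, trains one ARD Gaussian-process regressor
per component on the unit-scaled 12-dimensional inputs, and reconstructs
predictions through the basis.  The GP kernel is the scaled anisotropic
squared exponential with a noise term on the training diagonal; per-dimension
length-scales sigma_b provide automatic relevance determination.
Hyperparameters maximize the exact marginal log-likelihood by L-BFGS in log
space with analytic gradients (1e-8 diagonal jitter; stop at gradient norm
1e-6 or 200 iterations).  Exact deterministic optimization is preferred
over stochastic gradients at these problem sizes.  The likelihood surface
has two relevant basins, so the multi-start design is structural rather
than random: start 0 is the near-interpolation heuristic (sigma_b =
per-dimension std of the scaled inputs, nu = var(y), sigma_n^2 =
1e-6 var(y)), which wins on clean, injective targets; start 1 scales the
length-scales by sqrt(d) (keeping the typical scaled distance O(1) in d
dimensions) and starts the noise at 10% of the target variance, which is
required on non-injective inverse problems — from the near-interpolation
start alone, a band-to-LAI regression collapses into the degenerate
noise-only optimum (sigma_b -> 0, constant prediction).  Further restarts
jitter start 1; the best marginal likelihood decides.  The emulator uses
start 0 only, since the extra starts converged to identical optima on its
smooth PCA-score targets and triple the cost.  For training sets beyond
1000 rows, hyperparameters are optimized on a seeded 1000-row subsample
while the weights `w = (K + sigma_n^2 I)^-1 y` and the predictive
factorization use all rows.

Accuracy is reported as R^2 (squared Pearson correlation — offset- and
scale-invariant by construction), RMSE, and NRMSE = 100*RMSE/mean(reference)
(the normalizer choice is recorded in the metrics; range normalization is
available).  On a 1000-sample coupled LUT with a 70/30 split the emulator
reaches a held-out NRMSE of ~2.1–2.4% depending on the seed: PCA truncation
contributes only ~0.12%, so the error is almost entirely the leading
component's GP regression error — the statistical limit of a 700-sample
squared-exponential GP on this 12-dimensional multiplicative response, with
errors concentrated in the water-vapour bands.

## Hybrid retrieval

Per-variable GP regressors map nine band values (Gaussian spectral-response
fixtures at 490/560/665/705/740/783/865/1610/2190 nm; FWHMs are package
defaults, overridable from a delimited SRF table) to Cab, Cw or LAI.
Training bands receive 2% multiplicative Gaussian noise (seeded; additive
mode available), and 20 bare-soil rows labelled with target 0 are appended —
bare soil has no canopy, and the labels stop the model hallucinating
vegetation over soil.  Band convolution happens before noise injection.
Validation bands stay clean except for the `reference_atm` perturbation.
The TOC-trained model serves both the TOC and imperfect-correction
scenarios; the TOA-trained model serves the TOA scenario.  `band_relevance`
ranks bands by ascending sigma_b (small length-scale = informative band);
`retrieve` returns the GP predictive standard deviation per sample, and
`apply_to_cube` maps both over raster arrays with NaN propagation.

## What the testbed does and does not show

The generator emulates the *structure* of the real problem — nonlinear
surface/atmosphere coupling, band saturation, aerosol-type uncertainty,
correction residuals — with smooth low-dimensional surrogates.  Passing
tests show the estimators, emulator and retrieval machinery behave correctly
and that the qualitative sensitivity pattern (chlorophyll dominant in the
visible, water vapour confined to its absorption bands, LAI strong in the
SWIR) is reproduced.  They do not certify accuracy on real sensor data: the
surrogates lack directional effects, adjacency, rugged terrain, non-soil
backgrounds, sensor noise beyond the injected 2%, and the fine spectral
structure of real gas absorption.  Retrieval R^2 on the surrogate testbed is
optimistic relative to field conditions, most visibly for LAI.

Two testbed-specific behaviours deserve note.  First, LAI retrieval error
is not monotone in LAI: the inverse is precise near the soil limit
(LAI < 1, where the soil-to-canopy transition is steep and the background
is fixed), degrades in the mid-range where LAI and leaf angle enter the
two-flux optical depth nearly as a product, and is worst in the saturated
deep-canopy regime (LAI > 5) — the saturation property tested is deep
versus sparse.  Second, the surrogate atmosphere's aerosol influence in
the visible is much weaker than a full atmospheric code's, so retrieving
chlorophyll from TOA radiance costs essentially nothing relative to ideal
surface reflectance; the expected TOC-over-TOA accuracy margin appears for
Cw and LAI but not for Cab, where the two scenarios tie to ~0.002 in R².

## Problem sizes and numerical choices

Full-scale runs (acceptance script): 1000-sample emulator LUT, N = 1000
spectral GSA (14000 direct-simulator evaluations), 5000/5000
retrieval/reference split with 3500 noisy training rows.  The test suite
uses reduced sizes for unit and property tests (n of a few hundred,
max_iter 40–80) and full scale only in the acceptance tests.  Degenerate
inputs are handled explicitly: LAI = 0 returns the soil spectrum exactly;
zero-variance GSA outputs are flagged, not divided; reflectance outputs are
clipped to [0, 1] after spline resampling; predictive variances are floored
at zero; the two-flux `b` and scattering coefficient are floored at 1e-6.
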