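# toasense

Global sensitivity analysis and hybrid retrieval of vegetation biophysics
from simulated top-of-atmosphere (TOA) radiance.

Optical satellites measure at-sensor radiance, not surface reflectance.
Operational retrieval of vegetation variables — leaf chlorophyll content
(Cab, ug/cm^2), leaf water content (Cw, cm) and leaf area index (LAI,
m^2/m^2) — usually runs an atmospheric correction first and inverts the
surface signal, inheriting whatever error the correction made.  `toasense`
is a testbed for the alternative: quantify which leaf, canopy and
atmospheric variables actually drive TOA radiance across 400–2500 nm, and
train retrieval models that work on TOA radiance directly.  It is aimed at
researchers in quantitative remote sensing who want a self-contained,
seedable simulation framework for sensitivity and retrieval experiments —
with built-in surrogate radiative-transfer models, so no external RTM is
needed (and pluggable interfaces where a real one is available).

## What it computes

**Coupled simulation.**  A two-flux leaf/canopy model maps six surface
variables (leaf structure N, Cab, Cw, dry matter Cm, LAI, mean leaf angle)
to top-of-canopy reflectance rho; an atmospheric simulator maps six drivers
(ozone, columnar water vapour, aerosol optical thickness, asymmetry G,
Angstrom exponent, single-scattering albedo) to the transfer functions
L0, Edir, Edif, Tdir, Tdif, S; Lambertian coupling gives at-sensor radiance

    L = L0 + (Edir cos(theta_s) + Edif)(Tdir + Tdif) rho / (pi (1 - S rho)).

**Variance-based GSA.**  First-order and total-order Sobol indices per
wavelength from the radial Saltelli design (N(k+2) model evaluations),

    Si  = mean(f(Q)(f(PQ_i) - f(P))) / V(y),
    STi = mean((f(P) - f(PQ_i))^2) / (2 V(y)),

run either directly on the coupled simulator or through an emulator.

**Emulation.**  Spectra are compressed to 20 principal components; one
Gaussian-process regressor with an anisotropic squared-exponential (ARD)
kernel, k(x, x') = nu exp(-sum_b (x_b - x'_b)^2 / 2 sigma_b^2) + delta
sigma_n^2, is trained per component by exact marginal-likelihood
maximization.

**Hybrid retrieval.**  Per-variable GP regressors on nine sensor-like band
values (centres 490–2190 nm), trained on simulated data with 2%
multiplicative noise and bare-soil augmentation; the fitted length-scales
sigma_b rank band relevance and the GP returns per-sample retrieval
uncertainty.

## Worked example

```python
import numpy as np
from toasense import (
    build_lut, coupled_toa_model, gsa_spectral, emulator_train,
    train_retrieval, retrieve, validate, band_relevance, make_s2_bandset,
    make_wavenumber_grid,
)
from toasense.coupling import ALL_RANGES

# 1. Spectral Sobol analysis of the coupled simulator (N=1000 -> 14000 runs)
grid = make_wavenumber_grid(400, 2500, 15)
res = gsa_spectral(coupled_toa_model(grid=grid), ALL_RANGES, N=1000, seed=1,
                   wavelengths_nm=grid.wavelengths_nm)
print("model evaluations:", res.n_evaluations)
print("Cab STi, 450-750 nm: %.2f" % res.mean_sti("Cab", 450, 750))
print("CWV STi, 1350-1450 nm: %.2f" % res.mean_sti("CWV", 1350, 1450))

# 2. Emulate the simulator from a 1000-sample LUT (PCA-20 + per-component GP)
lut = build_lut("analysis", n=1000, seed=1)
emulator, metrics = emulator_train(lut, p=20, split=0.7, seed=1)
print("emulator held-out NRMSE: %.2f%%" % metrics.nrmse_percent)

# 3. Train a chlorophyll retrieval on noisy TOC bands, validate on the
#    disjoint reference half
bands = make_s2_bandset()
ret = build_lut("retrieval_toc", n=5000, seed=1, bands=bands)
ref = build_lut("reference_toc", n=5000, seed=1, bands=bands)
model = train_retrieval(ret, "Cab", noise=0.02, soils=20, seed=1)
est, unc = retrieve(model, ref.Y)
m = validate(ref.column("Cab"), est)
print("Cab retrieval R2 vs reference: %.3f (RMSE %.2f ug/cm2)" % (m.r2, m.rmse))
print("most relevant band:", band_relevance(model)[0][0])
```

Output:

```
model evaluations: 14000
Cab STi, 450-750 nm: 0.94
CWV STi, 1350-1450 nm: 1.07
emulator held-out NRMSE: 2.40%
Cab retrieval R2 vs reference: 0.994 (RMSE 1.52 ug/cm2)
most relevant band: B12
```

Reading: chlorophyll explains ~94% of TOA radiance variance across the
visible on average, water vapour dominates inside its 1350–1450 nm
absorption band (total-order indices are Monte Carlo estimates and may
slightly exceed 1 where the band saturates and the local variance is tiny),
the emulator reproduces the simulator to ~2.4% relative error, and the
TOC-band retrieval recovers chlorophyll almost perfectly on the clean
reference set.  A SWIR band topping the relevance ranking for a visible-
range pigment is not a mistake: chlorophyll absorbs only where leaves are
present, so leaf-area-sensitive SWIR bands carry indirect information the
regressor exploits alongside the directly sensitive visible bands.

A command-line interface mirrors the pipeline
(`toasense build-lut | train-emulator | run-gsa | train-retrieval |
evaluate | apply`); each subcommand writes its outputs plus a JSON run
manifest with the resolved configuration and seeds.

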