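"""Lambertian surface–atmosphere coupling and LUT scenario construction.

Top-of-atmosphere radiance over a Lambertian, homogeneous surface is

    L = L0 + E_tot * T_tot * rho / (pi * (1 - S * rho))

with E_tot = Edir*cos(sza) + Edif the total at-surface irradiance and
T_tot = Tdir + Tdif the total target-to-sensor transmittance.  The
denominator accounts for multiple surface–atmosphere reflections through
the spherical albedo S.

Six LUT scenarios are built around one master experiment:

* ``analysis``       n surface x n atmosphere samples, paired one-to-one,
                     coupled to TOA radiance (the sensitivity/emulation set);
* ``reference_toc``  a seeded half of the analysis surface samples, kept as
                     TOC reflectance (ideal atmospheric correction);
* ``reference_toa``  the same surface samples under fresh atmospheres with
                     aerosol climatologies drawn from nine presets;
* ``reference_atm``  reference_toc perturbed by a wavelength-dependent
                     atmospheric-correction residual (imperfect correction);
* ``retrieval_toc``  the disjoint other half of the analysis surface samples;
* ``retrieval_toa``  retrieval_toc under fresh rural-aerosol atmospheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import atmosphere as atm
from . import surface as srf
from .spectral import (
    BandSet,
    Geometry,
    SpectralGrid,
    Spectrum,
    _band_convolve_matrix,
    _resample_matrix,
    make_wavenumber_grid,
)

__all__ = [
    "SpectrumLUT",
    "Sen2CorErrorModel",
    "toa_radiance",
    "sen2cor_perturb",
    "build_lut",
    "coupled_toa_model",
    "SCENARIOS",
    "ALL_VARIABLES",
]

SCENARIOS = (
    "analysis",
    "reference_toc",
    "reference_toa",
    "reference_atm",
    "retrieval_toc",
    "retrieval_toa",
)

#: the 12 coupled-model inputs, surface first then atmosphere
ALL_VARIABLES = srf.SURFACE_VARIABLES + atm.ATMOSPHERE_VARIABLES
ALL_RANGES = {**srf.TABLE_SURFACE_RANGES, **atm.TABLE_ATMOSPHERE_RANGES}


@dataclass
class SpectrumLUT:
    """Paired input records and spectra; the central exchange object."""

    input_names: list[str]
    ranges: dict[str, tuple[float, float]]
    X: np.ndarray                      # (n, k) input records
    Y: np.ndarray                      # (n, m) spectra or band values
    grid: SpectralGrid | None          # None at band level
    level: str                         # toc_reflectance | toa_radiance | band_*
    scenario: str = ""
    seed: int | None = None
    band_ids: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.Y = np.atleast_2d(np.asarray(self.Y, float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        if self.X.shape[1] != len(self.input_names):
            raise ValueError("X column count does not match input_names")
        if self.grid is not None and self.Y.shape[1] != self.grid.n:
            raise ValueError("Y column count does not match grid length")
        for j, name in enumerate(self.input_names):
            lo, hi = self.ranges[name]
            col = self.X[:, j]
            if np.any(col < lo - 1e-9) or np.any(col > hi + 1e-9):
                raise ValueError(f"input {name} outside declared range [{lo}, {hi}]")
        if self.level.endswith("reflectance") and (
            self.Y.min() < -1e-9 or self.Y.max() > 1 + 1e-9
        ):
            raise ValueError("reflectance LUT values must lie in [0, 1]")
        if self.level.endswith("radiance") and self.Y.min() < -1e-9:
            raise ValueError("radiance LUT values must be non-negative")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.input_names.index(name)]

    def subset(self, idx: np.ndarray, scenario: str | None = None) -> "SpectrumLUT":
        return SpectrumLUT(
            self.input_names,
            self.ranges,
            self.X[idx],
            self.Y[idx],
            self.grid,
            self.level,
            scenario or self.scenario,
            self.seed,
            self.band_ids,
            dict(self.meta),
        )

    def to_bands(self, bands: BandSet) -> "SpectrumLUT":
        """Convolve every spectrum into the given band set."""
        if self.grid is None:
            raise ValueError("LUT is already at band level")
        Yb = _band_convolve_matrix(self.grid, self.Y, bands)
        level = "band_" + self.level.split("_", 1)[1]
        return SpectrumLUT(
            self.input_names, self.ranges, self.X, Yb, None, level,
            self.scenario, self.seed, bands.ids, dict(self.meta),
        )


@dataclass
class Sen2CorErrorModel:
    """Wavelength-dependent surface-reflectance error after atmospheric correction.

    ``mode='bias'`` adds eps(lambda); ``mode='gaussian'`` adds seeded
    zero-mean noise with std eps(lambda).  The default magnitude declines
    from ~0.025 in the blue to ~0.010 in the SWIR.
    """

    eps: Callable[[np.ndarray], np.ndarray] | None = None
    mode: str = "gaussian"

    def __post_init__(self):
        if self.mode not in ("bias", "gaussian"):
            raise ValueError("mode must be 'bias' or 'gaussian'")
        if self.eps is None:
            self.eps = lambda lam: 0.010 + 0.015 * np.exp(-(lam - 400.0) / 300.0)

    @classmethod
    def from_table(cls, wavelengths_nm, eps_values, mode: str = "gaussian"):
        wl = np.asarray(wavelengths_nm, float)
        ev = np.asarray(eps_values, float)
        if np.any(ev < 0):
            raise ValueError("error magnitudes must be non-negative")
        return cls(eps=lambda lam: np.interp(lam, wl, ev), mode=mode)


def toa_radiance(rho: Spectrum, tf: atm.TransferFunctions, geom: Geometry) -> Spectrum:
    """Propagate TOC reflectance to at-sensor radiance (Lambertian coupling)."""
    if rho.grid != tf.grid:
        raise ValueError("reflectance must be resampled to the transfer-function grid")
    L = _toa_matrix(
        rho.values[None, :],
        {k: getattr(tf, k)[None, :] for k in ("L0", "Edir", "Edif", "Tdir", "Tdif", "S")},
        geom.mu_s,
    )[0]
    return Spectrum(tf.grid, L, "radiance")


def _toa_matrix(rho: np.ndarray, tf: dict[str, np.ndarray], mu_s: float) -> np.ndarray:
    Srho = tf["S"] * rho
    if np.any(Srho >= 1.0 - 1e-6):
        raise ValueError("coupling singularity: S * rho reaches 1")
    E_tot = tf["Edir"] * mu_s + tf["Edif"]
    T_tot = tf["Tdir"] + tf["Tdif"]
    return tf["L0"] + E_tot * T_tot * rho / (np.pi * (1.0 - Srho))


def sen2cor_perturb(
    rho: Spectrum | np.ndarray,
    model: Sen2CorErrorModel | None = None,
    seed: int = 0,
    wavelengths_nm: np.ndarray | None = None,
):
    """Apply the correction-residual model to a spectrum or an (n, m) matrix."""
    model = model or Sen2CorErrorModel()
    if isinstance(rho, Spectrum):
        lam = rho.wavelengths_nm
        out = _perturb_matrix(rho.values[None, :], lam, model, seed)[0]
        return Spectrum(rho.grid, out, rho.quantity)
    if wavelengths_nm is None:
        raise ValueError("wavelengths_nm required for matrix input")
    return _perturb_matrix(np.atleast_2d(rho), wavelengths_nm, model, seed)


def _perturb_matrix(R, lam, model, seed):
    eps = model.eps(np.asarray(lam, float))
    if np.any(eps < 0):
        raise ValueError("error magnitudes must be non-negative")
    if model.mode == "bias":
        out = R + eps
    else:
        rng = np.random.default_rng(seed)
        out = R + rng.standard_normal(R.shape) * eps
    return np.clip(out, 0.0, 1.0)


def coupled_toa_model(
    grid: SpectralGrid | None = None,
    geom: Geometry | None = None,
    surface_model: srf.TwoFluxCanopyModel | None = None,
    chunk: int = 2000,
) -> Callable[[np.ndarray], np.ndarray]:
    """Direct coupled simulator: (n, 12) parameter rows -> (n, m) TOA radiance.

    Columns follow :data:`ALL_VARIABLES` (surface then atmosphere).  Spectra
    are produced on the 1 nm surface grid, cubic-spline resampled to the
    wavenumber grid and coupled per row; evaluation is chunked to bound
    memory.
    """
    grid = grid or make_wavenumber_grid(400.0, 2500.0, 15.0)
    geom = geom or Geometry()
    surface_model = surface_model or srf.TwoFluxCanopyModel(geometry=geom)
    E0 = atm.solar_irradiance(grid).values

    def model(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != 12:
            raise ValueError("expected 12 input columns (6 surface + 6 atmosphere)")
        out = np.empty((X.shape[0], grid.n))
        for i0 in range(0, X.shape[0], chunk):
            sl = slice(i0, min(i0 + chunk, X.shape[0]))
            rho = surface_model.reflectance_matrix(X[sl, :6])
            rho = np.clip(_resample_matrix(surface_model.grid, rho, grid), 0.0, 1.0)
            tf = atm._transfer_matrix(X[sl, 6:], geom, grid, E0=E0)
            out[sl] = _toa_matrix(rho, tf, geom.mu_s)
        return out

    return model


def _lhs_physical(n: int, ranges: dict[str, tuple[float, float]], seed: int) -> np.ndarray:
    from .gsa import lhs_sample

    U = lhs_sample(n, len(ranges), seed)
    lo = np.array([r[0] for r in ranges.values()])
    hi = np.array([r[1] for r in ranges.values()])
    return lo + U * (hi - lo)


def build_lut(
    scenario: str,
    n: int | None = None,
    seed: int = 0,
    config=None,
    bands: BandSet | None = None,
    keep_intermediates: bool = False,
) -> SpectrumLUT:
    """Build one of the six study LUT scenarios.

    ``n`` is the scenario's own sample count (defaults: 10000 for analysis,
    half the analysis size for the subsets).  All randomness derives from
    ``seed``; the reference/retrieval TOC subsets partition the analysis
    surface samples disjointly for any fixed (seed, analysis size).  When
    ``bands`` is given the result is convolved to band level.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")

    geom = Geometry(cfg.sza_deg, cfg.vza_deg)
    wngrid = make_wavenumber_grid(*cfg.wavenumber_grid)
    surface_model = srf.TwoFluxCanopyModel(
        soil=srf.SoilParams(cfg.soil_brightness, cfg.soil_wetness), geometry=geom
    )
    sgrid = surface_model.grid
    E0 = atm.solar_irradiance(wngrid).values

    # independent child seeds for every stochastic step
    ss = np.random.SeedSequence(seed)
    seeds = dict(
        zip(
            ("surface", "atmosphere", "pairing", "partition", "ref_atm",
             "ret_atm", "perturb"),
            (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(7)),
        )
    )

    if scenario == "analysis":
        n = n or cfg.n_analysis
        Xs = _lhs_physical(n, srf.TABLE_SURFACE_RANGES, seeds["surface"])
        Xa = _lhs_physical(n, atm.TABLE_ATMOSPHERE_RANGES, seeds["atmosphere"])
        perm = np.random.default_rng(seeds["pairing"]).permutation(n)
        Xa = Xa[perm]
        rho = surface_model.reflectance_matrix(Xs)
        rho_w = np.clip(_resample_matrix(sgrid, rho, wngrid), 0.0, 1.0)
        tf = atm._transfer_matrix(Xa, geom, wngrid, E0=E0)
        Y = _toa_matrix(rho_w, tf, geom.mu_s)
        lut = SpectrumLUT(
            ALL_VARIABLES, ALL_RANGES, np.hstack([Xs, Xa]), Y, wngrid,
            "toa_radiance", scenario, seed,
        )
        if keep_intermediates:
            lut.meta["rho"] = rho_w
            lut.meta["tf"] = tf
        return lut.to_bands(bands) if bands is not None else lut

    # subset scenarios share the analysis surface experiment
    n_parent = cfg.n_analysis
    n = n or n_parent // 2
    if 2 * n > n_parent:
        raise ValueError(
            f"subset size {n} exceeds half the analysis size {n_parent}"
        )
    Xs_all = _lhs_physical(n_parent, srf.TABLE_SURFACE_RANGES, seeds["surface"])
    part = np.random.default_rng(seeds["partition"]).permutation(n_parent)
    idx = part[:n] if scenario.startswith("reference") else part[n : 2 * n]
    Xs = Xs_all[idx]
    rho = surface_model.reflectance_matrix(Xs)

    if scenario in ("reference_toc", "retrieval_toc"):
        lut = SpectrumLUT(
            srf.SURFACE_VARIABLES, srf.TABLE_SURFACE_RANGES, Xs, rho, sgrid,
            "toc_reflectance", scenario, seed, meta={"parent_indices": idx},
        )
        return lut.to_bands(bands) if bands is not None else lut

    if scenario == "reference_atm":
        Ratm = _perturb_matrix(
            rho, sgrid.wavelengths_nm, cfg.sen2cor_model(), seeds["perturb"]
        )
        lut = SpectrumLUT(
            srf.SURFACE_VARIABLES, srf.TABLE_SURFACE_RANGES, Xs, Ratm, sgrid,
            "toc_reflectance", scenario, seed, meta={"parent_indices": idx},
        )
        return lut.to_bands(bands) if bands is not None else lut

    # TOA subsets: fresh atmospheres over the reference ranges
    aseed = seeds["ref_atm"] if scenario == "reference_toa" else seeds["ret_atm"]
    gas_ranges = {k: atm.TABLE_ATMOSPHERE_RANGES[k] for k in ("O3C", "CWV", "AOT550")}
    Xgas = _lhs_physical(n, gas_ranges, aseed)
    rng = np.random.default_rng(aseed)
    if scenario == "reference_toa":
        types = rng.choice(sorted(atm.AEROSOL_PRESETS), size=n)
    else:  # retrieval_toa: rural aerosol only
        types = np.array(["rural"] * n)
    aero = np.array([atm.aerosol_preset(t) for t in types])
    Xa = np.hstack([Xgas, aero])
    rho_w = np.clip(_resample_matrix(sgrid, rho, wngrid), 0.0, 1.0)
    tf = atm._transfer_matrix(Xa, geom, wngrid, E0=E0)
    Y = _toa_matrix(rho_w, tf, geom.mu_s)
    lut = SpectrumLUT(
        ALL_VARIABLES, ALL_RANGES, np.hstack([Xs, Xa]), Y, wngrid,
        "toa_radiance", scenario, seed,
        meta={"parent_indices": idx, "aerosol_types": types.tolist()},
    )
    return lut.to_bands(bands) if bands is not None else lut
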