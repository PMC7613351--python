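"""Stylized leaf + canopy reflectance model and soil spectra.

A self-contained two-flux (Kubelka–Munk) canopy over a parametric soil
background stands in for a full leaf/canopy radiative-transfer code.  Leaf
single-scattering albedo follows Beer-law extinction of three constituent
absorbers (chlorophyll, water, dry matter) with Gaussian absorption fixtures;
the canopy solution is the finite-layer two-flux reflectance over a soil
boundary.  The model is deliberately simple but reproduces the qualitative
spectral fingerprints that matter for sensitivity and retrieval studies:
chlorophyll dominates the visible, water the SWIR, and leaf area drives the
transition from soil-like to closed-canopy reflectance.

All operations have vectorized cores (parameter matrices in, spectra
matrices out) used by the LUT builders and the sensitivity driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import Geometry, SpectralGrid, Spectrum, make_uniform_grid

__all__ = [
    "TABLE_SURFACE_RANGES",
    "SURFACE_VARIABLES",
    "LeafCanopyParams",
    "SoilParams",
    "leaf_optics",
    "canopy_reflectance",
    "soil_spectrum",
    "generate_soil_library",
    "TwoFluxCanopyModel",
    "default_surface_grid",
]

#: LUT sampling ranges for the six leaf/canopy variables
TABLE_SURFACE_RANGES: dict[str, tuple[float, float]] = {
    "N": (1.3, 2.5),       # leaf structure index [-]
    "Cab": (1.0, 70.0),    # leaf chlorophyll content [ug/cm2]
    "Cw": (0.002, 0.05),   # leaf water content (EWT) [cm]
    "Cm": (0.002, 0.05),   # leaf dry matter content [g/cm2]
    "LAI": (0.1, 7.0),     # leaf area index [m2/m2]
    "LAD": (0.0, 90.0),    # mean leaf angle [deg]
}
SURFACE_VARIABLES = list(TABLE_SURFACE_RANGES)


def default_surface_grid() -> SpectralGrid:
    """Native surface grid: 400–2500 nm at 1 nm."""
    return make_uniform_grid(400.0, 2500.0, 1.0)


@dataclass(frozen=True)
class LeafCanopyParams:
    N: float = 1.5
    Cab: float = 40.0
    Cw: float = 0.02
    Cm: float = 0.01
    LAI: float = 3.0
    LAD: float = 45.0

    def __post_init__(self):
        # zero absorber contents are allowed (limit cases); negatives are not
        for name in ("N", "Cab", "Cw", "Cm", "LAI", "LAD"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.N, self.Cab, self.Cw, self.Cm, self.LAI, self.LAD])


@dataclass(frozen=True)
class SoilParams:
    brightness: float = 1.0  # B in [0.5, 1.5]
    wetness: float = 0.3     # W in [0, 1]

    def __post_init__(self):
        if not 0.5 <= self.brightness <= 1.5:
            raise ValueError("soil brightness must lie in [0.5, 1.5]")
        if not 0.0 <= self.wetness <= 1.0:
            raise ValueError("soil wetness must lie in [0, 1]")


def _g(lam: np.ndarray, c: float, s: float) -> np.ndarray:
    return np.exp(-((lam - c) ** 2) / (2.0 * s**2))


def constituent_absorption(lam: np.ndarray) -> dict[str, np.ndarray]:
    """Specific absorption fixtures for the three leaf constituents.

    alpha_cab [cm2/ug]: blue + red chlorophyll bands over a broad visible
        shoulder (chlorophyll absorbs throughout the visible, weakest in
        the green).
    alpha_w   [1/cm]:   the 970/1200/1450/1940/2400 nm water bands.
    alpha_m   [cm2/g]:  a declining continuum that switches on above the
        red edge (dry matter absorbs negligibly in the visible) plus a
        2100 nm feature.
    """
    lam = np.asarray(lam, dtype=float)
    alpha_cab = (
        0.12 * _g(lam, 450, 35)
        + 0.10 * _g(lam, 670, 25)
        + 0.025 * _g(lam, 550, 80)
    )
    alpha_w = (
        35 * _g(lam, 970, 40)
        + 120 * _g(lam, 1200, 50)
        + 900 * _g(lam, 1450, 60)
        + 1400 * _g(lam, 1940, 70)
        + 600 * _g(lam, 2400, 100)
    )
    red_edge = 1.0 / (1.0 + np.exp(-(lam - 750.0) / 25.0))
    alpha_m = red_edge * 40 * (1 - 0.5 * (lam - 400) / 2100) + 60 * _g(lam, 2100, 80)
    return {"alpha_cab": alpha_cab, "alpha_w": alpha_w, "alpha_m": alpha_m}


def _leaf_matrix(lam: np.ndarray, N, Cab, Cw, Cm):
    """Vectorized leaf optics: parameter columns broadcast against wavelength."""
    ab = constituent_absorption(lam)
    N, Cab, Cw, Cm = (np.atleast_1d(np.asarray(v, float))[:, None] for v in (N, Cab, Cw, Cm))
    A = Cab * ab["alpha_cab"] + Cw * ab["alpha_w"] + Cm * ab["alpha_m"]
    omega = np.clip(0.95 * np.exp(-A), 1e-4, 0.9999)
    r_N = 0.30 + 0.10 * (N - 1.3) / 1.2
    return omega * r_N, omega * (1 - r_N), omega


def leaf_optics(p: LeafCanopyParams, grid: SpectralGrid):
    """Leaf reflectance, transmittance and single-scattering albedo."""
    R, T, omega = _leaf_matrix(grid.wavelengths_nm, p.N, p.Cab, p.Cw, p.Cm)
    mk = lambda v: Spectrum(grid, v, "reflectance")
    return mk(R[0]), mk(T[0]), Spectrum(grid, omega[0], "albedo")


def _canopy_matrix(
    lam: np.ndarray,
    omega: np.ndarray,
    LAI,
    LAD,
    soil: np.ndarray,
    sza_deg: float,
) -> np.ndarray:
    """Two-flux finite-layer reflectance over a soil boundary (vectorized).

    omega: (n, m) leaf albedo; LAI/LAD: length-n; soil: (m,) or (n, m).
    """
    LAI = np.atleast_1d(np.asarray(LAI, float))[:, None]
    LAD = np.atleast_1d(np.asarray(LAD, float))[:, None]
    Rg = np.broadcast_to(np.asarray(soil, float), omega.shape)

    gL = 0.5 + 0.5 * np.cos(np.deg2rad(LAD)) * np.cos(np.deg2rad(sza_deg))
    k = 2.0 * gL * (1.0 - omega)
    s = np.maximum(gL * omega, 1e-6)
    a = (s + k) / s
    b = np.maximum(np.sqrt(np.maximum(a**2 - 1.0, 0.0)), 1e-6)
    y = np.maximum(b * s * LAI, 1e-30)  # LAI=0 rows handled exactly below
    coth = 1.0 / np.tanh(np.minimum(y, 50.0))
    rho = (1.0 - Rg * (a - b * coth)) / (a - Rg + b * coth)
    rho = np.where(LAI <= 0.0, Rg, rho)
    return np.clip(rho, 0.0, 1.0)


def canopy_reflectance(
    p: LeafCanopyParams,
    soil: Spectrum,
    geom: Geometry,
    grid: SpectralGrid,
) -> Spectrum:
    """Top-of-canopy directional-hemispherical reflectance."""
    if soil.grid != grid:
        raise ValueError("soil spectrum must be sampled on the requested grid")
    _, _, omega = _leaf_matrix(grid.wavelengths_nm, p.N, p.Cab, p.Cw, p.Cm)
    rho = _canopy_matrix(
        grid.wavelengths_nm, omega, p.LAI, p.LAD, soil.values, geom.sza_deg
    )[0]
    return Spectrum(grid, rho, "reflectance")


def _soil_matrix(lam: np.ndarray, B, W) -> np.ndarray:
    B = np.atleast_1d(np.asarray(B, float))[:, None]
    W = np.atleast_1d(np.asarray(W, float))[:, None]
    base = 0.12 + 0.18 * (lam - 400.0) / 2100.0
    dips = 1.0 - 0.35 * W * (_g(lam, 1450, 80) + _g(lam, 1940, 90))
    return np.clip(B * base * dips, 0.0, 1.0)


def soil_spectrum(sp: SoilParams, grid: SpectralGrid) -> Spectrum:
    """Bright/wet parametric bare-soil reflectance with 1450/1940 nm dips."""
    return Spectrum(
        grid,
        _soil_matrix(grid.wavelengths_nm, sp.brightness, sp.wetness)[0],
        "reflectance",
    )


def generate_soil_library(
    n: int = 20, seed: int = 0, grid: SpectralGrid | None = None
) -> list[Spectrum]:
    """Seeded library of bare-soil spectra, (B, W) uniform on their ranges."""
    grid = grid or default_surface_grid()
    rng = np.random.default_rng(seed)
    B = rng.uniform(0.5, 1.5, size=n)
    W = rng.uniform(0.0, 1.0, size=n)
    M = _soil_matrix(grid.wavelengths_nm, B, W)
    return [Spectrum(grid, row, "reflectance") for row in M]


class TwoFluxCanopyModel:
    """Surface reflectance model: parameter vectors -> TOC spectra.

    Implements the pluggable surface interface used by the LUT builders: any
    object with the same ``grid``/``variable_names`` attributes and a
    ``reflectance_matrix`` method (rows of [N, Cab, Cw, Cm, LAI, LAD] in,
    (n, m) reflectance out) can replace it, e.g. a genuine leaf/canopy RTM.
    """

    variable_names = SURFACE_VARIABLES

    def __init__(
        self,
        grid: SpectralGrid | None = None,
        soil: SoilParams | Spectrum | None = None,
        geometry: Geometry | None = None,
    ):
        self.grid = grid or default_surface_grid()
        self.geometry = geometry or Geometry()
        if soil is None:
            soil = SoilParams()  # default LUT background: B=1, W=0.3
        if isinstance(soil, SoilParams):
            soil = soil_spectrum(soil, self.grid)
        elif soil.grid != self.grid:
            raise ValueError("soil spectrum must be on the model grid")
        self.soil = soil

    def reflectance_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n, 6) parameter rows [N, Cab, Cw, Cm, LAI, LAD] -> (n, m) TOC."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != 6:
            raise ValueError("expected 6 surface parameter columns")
        _, _, omega = _leaf_matrix(
            self.grid.wavelengths_nm, X[:, 0], X[:, 1], X[:, 2], X[:, 3]
        )
        return _canopy_matrix(
            self.grid.wavelengths_nm,
            omega,
            X[:, 4],
            X[:, 5],
            self.soil.values,
            self.geometry.sza_deg,
        )

    def reflectance(self, p: LeafCanopyParams) -> Spectrum:
        return Spectrum(
            self.grid, self.reflectance_matrix(p.as_array()[None, :])[0], "reflectance"
        )
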