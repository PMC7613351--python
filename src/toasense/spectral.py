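"""Spectral grids, resampling, and sensor-band convolution.

Conventions used throughout the package:

* wavelengths are vacuum nanometres, stored strictly ascending;
* grids generated uniformly in wavenumber (cm^-1) are still stored as
  ascending wavelengths, with the generating step recorded;
* radiance is W m^-2 sr^-1 nm^-1, irradiance W m^-2 nm^-1; reflectance,
  transmittance and albedo are unitless in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SpectralGrid",
    "Spectrum",
    "Band",
    "BandSet",
    "Geometry",
    "make_wavenumber_grid",
    "make_uniform_grid",
    "resample_spectrum",
    "band_convolve",
    "make_s2_bandset",
]

#: quantities whose values are bounded to [0, 1]
_UNIT_QUANTITIES = frozenset({"reflectance", "transmittance", "albedo"})
#: quantities that only need to be non-negative
_FLUX_QUANTITIES = frozenset({"radiance", "irradiance"})

_WL_MIN, _WL_MAX = 380.0, 2600.0


@dataclass(frozen=True)
class SpectralGrid:
    """A strictly increasing wavelength sampling in [380, 2600] nm."""

    wavelengths_nm: np.ndarray
    origin: str = "uniform_nm"  # or "uniform_wavenumber"
    step: float = float("nan")  # nm or cm^-1, matching ``origin``

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("grid must be a non-empty 1-D wavelength array")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("grid wavelengths must be strictly increasing")
        if wl[0] < _WL_MIN - 1e-9 or wl[-1] > _WL_MAX + 1e-9:
            raise ValueError(
                f"grid must lie within [{_WL_MIN}, {_WL_MAX}] nm, got "
                f"[{wl[0]:.3f}, {wl[-1]:.3f}]"
            )
        if self.origin not in ("uniform_nm", "uniform_wavenumber"):
            raise ValueError(f"unknown grid origin {self.origin!r}")
        if self.origin == "uniform_wavenumber" and wl.size > 1:
            dnu = np.abs(np.diff(1e7 / wl))
            if np.any(np.abs(dnu - self.step) / self.step > 1e-6):
                raise ValueError("wavenumber spacing deviates from stated step")

    @property
    def n(self) -> int:
        return self.wavelengths_nm.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpectralGrid)
            and self.wavelengths_nm.shape == other.wavelengths_nm.shape
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
        )

    def __len__(self) -> int:
        return self.n


@dataclass
class Spectrum:
    """Values sampled on a :class:`SpectralGrid`, tagged with a quantity."""

    grid: SpectralGrid
    values: np.ndarray
    quantity: str = "reflectance"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n,):
            raise ValueError(
                f"values shape {v.shape} does not match grid length {self.grid.n}"
            )
        if self.quantity in _UNIT_QUANTITIES:
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
                raise ValueError(f"{self.quantity} values must lie in [0, 1]")
        elif self.quantity in _FLUX_QUANTITIES:
            if np.any(v < -1e-9):
                raise ValueError(f"{self.quantity} values must be >= 0")
        else:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        self.values = v

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.grid.wavelengths_nm


@dataclass(frozen=True)
class Geometry:
    """Sun/view zenith geometry; defaults are the fixed LUT acquisition angles."""

    sza_deg: float = 30.0
    vza_deg: float = 0.0

    def __post_init__(self):
        for name in ("sza_deg", "vza_deg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 89.0:
                raise ValueError(f"{name}={v} outside [0, 89] degrees")

    @property
    def mu_s(self) -> float:
        return float(np.cos(np.deg2rad(self.sza_deg)))

    @property
    def mu_v(self) -> float:
        return float(np.cos(np.deg2rad(self.vza_deg)))


@dataclass
class Band:
    id: str
    center_nm: float
    fwhm_nm: float
    wavelengths_nm: np.ndarray
    response: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if wl.shape != r.shape or wl.ndim != 1:
            raise ValueError(f"band {self.id}: response/wavelength shape mismatch")
        if np.any(r < 0):
            raise ValueError(f"band {self.id}: response must be non-negative")
        if np.trapezoid(r, wl) <= 0:
            raise ValueError(f"band {self.id}: response integrates to zero")
        self.wavelengths_nm, self.response = wl, r


@dataclass
class BandSet:
    bands: list[Band] = field(default_factory=list)

    def __post_init__(self):
        centers = [b.center_nm for b in self.bands]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("band centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def ids(self) -> list[str]:
        return [b.id for b in self.bands]

    @property
    def centers_nm(self) -> np.ndarray:
        return np.array([b.center_nm for b in self.bands])


def make_wavenumber_grid(
    lambda_min_nm: float, lambda_max_nm: float, step_cm1: float
) -> SpectralGrid:
    """Uniform wavenumber grid between two wavelengths, reported in nm.

    The grid runs from 1e7/lambda_max upward in steps of ``step_cm1``; the
    short-wavelength endpoint is included only when the interval is an exact
    multiple of the step.
    """
    if lambda_min_nm <= 0 or lambda_max_nm <= 0 or lambda_min_nm >= lambda_max_nm:
        raise ValueError(
            f"need 0 < lambda_min < lambda_max, got ({lambda_min_nm}, {lambda_max_nm})"
        )
    if step_cm1 <= 0:
        raise ValueError(f"step_cm1 must be positive, got {step_cm1}")
    nu_min = 1e7 / lambda_max_nm
    nu_max = 1e7 / lambda_min_nm
    n = int(np.floor((nu_max - nu_min) / step_cm1 + 1e-9)) + 1
    nu = nu_min + step_cm1 * np.arange(n)
    wl = (1e7 / nu)[::-1]
    return SpectralGrid(wl, origin="uniform_wavenumber", step=float(step_cm1))


def make_uniform_grid(
    lambda_min_nm: float, lambda_max_nm: float, step_nm: float = 1.0
) -> SpectralGrid:
    """Uniform wavelength grid (endpoint included when representable)."""
    n = int(np.floor((lambda_max_nm - lambda_min_nm) / step_nm + 1e-9)) + 1
    wl = lambda_min_nm + step_nm * np.arange(n)
    return SpectralGrid(wl, origin="uniform_nm", step=float(step_nm))


def resample_spectrum(s: Spectrum, target: SpectralGrid) -> Spectrum:
    """Cubic-spline interpolation onto ``target``; extrapolation is refused."""
    lo, hi = s.grid.span
    twl = target.wavelengths_nm
    if twl[0] < lo - 1e-9 or twl[-1] > hi + 1e-9:
        bad = twl[0] if twl[0] < lo - 1e-9 else twl[-1]
        raise ValueError(
            f"target wavelength {bad:.3f} nm outside source span [{lo:.3f}, {hi:.3f}]"
        )
    out = _resample_matrix(s.grid, s.values[None, :], target)[0]
    out = _clip_for_quantity(out, s.quantity)
    return Spectrum(target, out, s.quantity)


def _resample_matrix(
    grid: SpectralGrid, Y: np.ndarray, target: SpectralGrid
) -> np.ndarray:
    """Row-wise cubic-spline resampling of an (n, m) value matrix."""
    if grid == target:
        return Y.copy()
    cs = CubicSpline(grid.wavelengths_nm, Y, axis=1)
    return cs(target.wavelengths_nm)


def _clip_for_quantity(values: np.ndarray, quantity: str) -> np.ndarray:
    if quantity in _UNIT_QUANTITIES:
        return np.clip(values, 0.0, 1.0)
    if quantity in _FLUX_QUANTITIES:
        return np.maximum(values, 0.0)
    return values


def band_convolve(s: Spectrum, bands: BandSet) -> np.ndarray:
    """Band-average a spectrum through each response function.

    Per band the value is the trapezoidal ratio  ∫ s·f dλ / ∫ f dλ  with the
    response linearly resampled onto the spectrum's grid (zero outside its
    own support).  Units follow the input spectrum.
    """
    return _band_convolve_matrix(s.grid, s.values[None, :], bands)[0]


def _band_convolve_matrix(
    grid: SpectralGrid, Y: np.ndarray, bands: BandSet
) -> np.ndarray:
    wl = grid.wavelengths_nm
    lo, hi = grid.span
    out = np.empty((Y.shape[0], len(bands)))
    for j, band in enumerate(bands):
        bwl = band.wavelengths_nm
        if bwl[0] < lo - 1e-9 or bwl[-1] > hi + 1e-9:
            raise ValueError(
                f"band {band.id} response support [{bwl[0]:.1f}, {bwl[-1]:.1f}] nm "
                f"extends beyond spectrum span [{lo:.1f}, {hi:.1f}] nm"
            )
        resp = np.interp(wl, bwl, band.response, left=0.0, right=0.0)
        den = np.trapezoid(resp, wl)
        if den <= 0:
            raise ValueError(f"band {band.id}: resampled response integrates to zero")
        out[:, j] = np.trapezoid(Y * resp, wl, axis=1) / den
    return out


# 20 m band fixture: ids / centers from the 9-band (no B8) configuration;
# Gaussian FWHMs are package defaults, overridable from an SRF table.
_S2_BANDS = (
    ("B2", 490.0, 65.0),
    ("B3", 560.0, 35.0),
    ("B4", 665.0, 30.0),
    ("B5", 705.0, 15.0),
    ("B6", 740.0, 15.0),
    ("B7", 783.0, 20.0),
    ("B8A", 865.0, 20.0),
    ("B11", 1610.0, 90.0),
    ("B12", 2190.0, 180.0),
)


def make_s2_bandset() -> BandSet:
    """Nine Gaussian 20 m band responses (B2–B12, broadband B8 omitted).

    Each response is sampled at 0.5 nm over ±3σ, which keeps every band's
    support inside the 400–2500 nm simulation range.
    """
    bands = []
    for bid, center, fwhm in _S2_BANDS:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        wl = np.arange(center - 3 * sigma, center + 3 * sigma + 0.25, 0.5)
        resp = np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        bands.append(Band(bid, center, fwhm, wl, resp))
    return BandSet(bands)


def bandset_from_table(wavelengths_nm, responses: dict[str, np.ndarray]) -> BandSet:
    """Build a BandSet from a tabulated SRF (columns: one response per band)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    bands = []
    for bid, resp in responses.items():
        resp = np.asarray(resp, dtype=float)
        mask = resp > 0
        if not mask.any():
            raise ValueError(f"band {bid}: response is identically zero")
        i0, i1 = np.flatnonzero(mask)[[0, -1]]
        sl = slice(max(i0 - 1, 0), min(i1 + 2, wl.size))
        w, r = wl[sl], resp[sl]
        center = float(np.trapezoid(w * r, w) / np.trapezoid(r, w))
        half = r.max() / 2.0
        above = w[r >= half]
        fwhm = float(above[-1] - above[0]) if above.size > 1 else float(w[1] - w[0])
        bands.append(Band(bid, center, fwhm, w, r))
    bands.sort(key=lambda b: b.center_nm)
    return BandSet(bands)
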