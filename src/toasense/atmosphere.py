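"""Stylized clear-sky atmospheric transfer-function simulator.

Maps six atmospheric state variables — ozone column, columnar water vapour,
aerosol optical thickness at 550 nm, Henyey–Greenstein asymmetry, Angstrom
exponent and aerosol single-scattering albedo — to the six transfer
functions needed for Lambertian surface–atmosphere coupling:

* ``L0``    path radiance [W m-2 sr-1 nm-1]
* ``Edir``  direct at-surface irradiance [W m-2 nm-1]
* ``Edif``  diffuse at-surface irradiance [W m-2 nm-1]
* ``Tdir``  direct target-to-sensor transmittance [-]
* ``Tdif``  diffuse target-to-sensor transmittance [-]
* ``S``     atmospheric spherical albedo [-]

The physics is single-scattering with plane-parallel airmass factors and a
curve-of-growth water-vapour band model (exponent 0.6) so that the 1380 and
1870 nm bands saturate across the columnar-water-vapour range.  Multiple
scattering is collapsed into a rational-form spherical albedo.  The model is
monotone in each driver in the physically expected direction, which is what
sensitivity and retrieval experiments on it rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import Geometry, SpectralGrid, Spectrum

__all__ = [
    "TABLE_ATMOSPHERE_RANGES",
    "ATMOSPHERE_VARIABLES",
    "AEROSOL_PRESETS",
    "AtmosphereParams",
    "TransferFunctions",
    "solar_irradiance",
    "aerosol_preset",
    "transfer_functions",
]

#: sampling ranges of the six atmospheric variables for the analysis LUT
TABLE_ATMOSPHERE_RANGES: dict[str, tuple[float, float]] = {
    "O3C": (0.25, 0.35),     # ozone column [atm-cm]
    "CWV": (0.4, 4.5),       # columnar water vapour [g/cm2]
    "AOT550": (0.05, 0.5),   # aerosol optical thickness at 550 nm [-]
    "G": (0.6, 1.0),         # HG asymmetry parameter [-]
    "alpha": (0.05, 2.0),    # Angstrom exponent [-]
    "SSA": (0.85, 1.0),      # aerosol single-scattering albedo [-]
}
ATMOSPHERE_VARIABLES = list(TABLE_ATMOSPHERE_RANGES)

#: fixed (G, alpha, SSA) triples for the nine named aerosol climatologies
AEROSOL_PRESETS: dict[str, tuple[float, float, float]] = {
    "rural": (0.65, 1.3, 0.94),
    "urban": (0.70, 1.4, 0.88),
    "maritime-1": (0.72, 0.3, 0.99),
    "maritime-2": (0.75, 0.5, 0.985),
    "maritime-3": (0.78, 0.8, 0.98),
    "continental-clean": (0.64, 1.1, 0.97),
    "continental-average": (0.66, 1.25, 0.93),
    "continental-polluted": (0.69, 1.4, 0.89),
    "opac-urban": (0.71, 1.5, 0.86),
}


@dataclass(frozen=True)
class AtmosphereParams:
    O3C: float = 0.3
    CWV: float = 2.0
    AOT550: float = 0.2
    G: float = 0.65
    alpha: float = 1.3
    SSA: float = 0.94
    aerosol_type: str | None = None

    @classmethod
    def from_preset(cls, name: str, O3C: float = 0.3, CWV: float = 2.0,
                    AOT550: float = 0.2) -> "AtmosphereParams":
        G, alpha, SSA = aerosol_preset(name)
        return cls(O3C, CWV, AOT550, G, alpha, SSA, aerosol_type=name)

    def as_array(self) -> np.ndarray:
        return np.array([self.O3C, self.CWV, self.AOT550, self.G, self.alpha, self.SSA])


@dataclass
class TransferFunctions:
    grid: SpectralGrid
    L0: np.ndarray
    Edir: np.ndarray
    Edif: np.ndarray
    Tdir: np.ndarray
    Tdif: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        m = self.grid.n
        for name in ("L0", "Edir", "Edif", "Tdir", "Tdif", "S"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (m,):
                raise ValueError(f"{name} length {v.shape} != grid length {m}")
            if np.any(v < -1e-12):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, v)
        for name in ("Tdir", "Tdif", "S"):
            if np.any(getattr(self, name) > 1 + 1e-12):
                raise ValueError(f"{name} must not exceed 1")


_H = 6.62607015e-34
_C = 2.99792458e8
_KB = 1.380649e-23
_T_SUN = 5800.0


def _planck_shape(lam_nm: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam_nm, float) * 1e-9
    return lam**-5 / np.expm1(_H * _C / (lam * _KB * _T_SUN))


#: scale such that E0(500 nm) = 1.9 W m-2 nm-1
_E0_SCALE = 1.9 / _planck_shape(np.array([500.0]))[0]


def solar_irradiance(grid: SpectralGrid) -> Spectrum:
    """Smooth solar-style irradiance: 5800 K Planck shape, E0(500 nm) = 1.9."""
    return Spectrum(grid, _E0_SCALE * _planck_shape(grid.wavelengths_nm), "irradiance")


def aerosol_preset(name: str) -> tuple[float, float, float]:
    """(G, alpha, SSA) for one of the nine named aerosol models."""
    try:
        return AEROSOL_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown aerosol preset {name!r}; valid names: "
            f"{', '.join(sorted(AEROSOL_PRESETS))}"
        ) from None


def _check_ranges(X: np.ndarray) -> None:
    for j, (name, (lo, hi)) in enumerate(TABLE_ATMOSPHERE_RANGES.items()):
        col = X[:, j]
        if np.any(col < lo - 1e-9) or np.any(col > hi + 1e-9):
            raise ValueError(
                f"atmospheric parameter {name} outside valid range [{lo}, {hi}]"
            )


def _transfer_matrix(
    X: np.ndarray,
    geom: Geometry,
    grid: SpectralGrid,
    E0: np.ndarray | None = None,
    validate_ranges: bool = True,
) -> dict[str, np.ndarray]:
    """Vectorized transfer functions for (n, 6) parameter rows.

    Columns: [O3C, CWV, AOT550, G, alpha, SSA].  Returns (n, m) arrays.
    ``validate_ranges=False`` admits analytic limit cases (e.g. a gas- and
    aerosol-free sky) outside the LUT sampling box.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if validate_ranges:
        _check_ranges(X)
    lam = grid.wavelengths_nm
    if E0 is None:
        E0 = solar_irradiance(grid).values
    mu_s, mu_v = geom.mu_s, geom.mu_v
    if mu_s <= 0 or mu_v <= 0:
        raise ValueError("sun and view cosines must be positive")

    O3C, CWV, AOT, G, alpha, SSA = (X[:, j][:, None] for j in range(6))
    lam_um = lam / 1000.0

    tau_R = 0.008735 * lam_um**-4.08                 # Rayleigh optical depth
    tau_A = AOT * (lam / 550.0) ** (-alpha)          # aerosol extinction
    tau_R = np.broadcast_to(tau_R, tau_A.shape)
    tau_sc = tau_R + SSA * tau_A                     # scattering-only depth
    tau_ext = tau_R + tau_A

    # vertical-column gas transmittances, then plane-parallel airmass powers
    k_w = (
        0.02 * _gauss(lam, 720, 10)
        + 0.03 * _gauss(lam, 820, 12)
        + 0.2 * _gauss(lam, 940, 18)
        + 0.35 * _gauss(lam, 1130, 25)
        + 3.0 * _gauss(lam, 1380, 40)
        + 4.0 * _gauss(lam, 1870, 50)
        + 1.0 * _gauss(lam, 2500, 100)
    )
    T_w = np.exp(-((CWV * k_w) ** 0.6))              # curve-of-growth saturation
    T_O3 = np.exp(-O3C * 0.08 * _gauss(lam, 600, 60))
    T_gas = T_w * T_O3
    T_gas_s = T_gas ** (1.0 / mu_s)
    T_gas_v = T_gas ** (1.0 / mu_v)

    w_R = tau_R / tau_sc
    w_A = SSA * tau_A / tau_sc
    f_dif = 0.5 * w_R + ((1.0 + G) / 2.0) * w_A      # forward-scattered fraction

    Edir = E0 * mu_s * np.exp(-tau_ext / mu_s) * T_gas_s
    Edif = E0 * mu_s * T_gas_s * f_dif * (1.0 - np.exp(-tau_sc / mu_s))
    Tdir = np.exp(-tau_ext / mu_v) * T_gas_v
    Tdif = T_gas_v * f_dif * (1.0 - np.exp(-tau_sc / mu_v))

    # single-scattering path radiance at scattering angle 180 deg - sza
    cos_theta = -np.cos(np.deg2rad(geom.sza_deg))
    P_ray = 0.75 * (1.0 + cos_theta**2)
    P_hg = (1.0 - G**2) / (1.0 + G**2 - 2.0 * G * cos_theta) ** 1.5
    P = (tau_R * P_ray + SSA * tau_A * P_hg) / tau_sc
    L0 = (
        (E0 * mu_s / np.pi)
        * T_gas_s
        * T_gas_v
        * (P / (4.0 * (mu_s + mu_v)))
        * (1.0 - np.exp(-tau_sc * (1.0 / mu_s + 1.0 / mu_v)))
    )

    x = 0.92 * tau_R + (1.0 - G) * SSA * tau_A
    S = x / (1.0 + x)

    return {"L0": L0, "Edir": Edir, "Edif": Edif, "Tdir": Tdir, "Tdif": Tdif, "S": S}


def _gauss(lam: np.ndarray, c: float, s: float) -> np.ndarray:
    return np.exp(-((lam - c) ** 2) / (2.0 * s**2))


def transfer_functions(
    a: AtmosphereParams,
    geom: Geometry,
    grid: SpectralGrid,
    validate_ranges: bool = True,
) -> TransferFunctions:
    """Six atmospheric transfer functions for one atmospheric state."""
    tf = _transfer_matrix(
        a.as_array()[None, :], geom, grid, validate_ranges=validate_ranges
    )
    return TransferFunctions(grid, **{k: v[0] for k, v in tf.items()})
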