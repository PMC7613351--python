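"""Hybrid GP retrieval of leaf biophysics from band-convolved spectra.

One ARD GP regressor per target variable (Cab, Cw or LAI) is trained on
simulated band values — top-of-canopy reflectance or top-of-atmosphere
radiance convolved to a sensor band set — with multiplicative Gaussian
noise injected into the training bands and a small library of bare-soil
rows (target value 0) appended so the models do not hallucinate vegetation
over soil.  The fitted length-scales sigma_b rank band relevance (small
sigma_b = informative band) and the GP predictive variance provides a
per-sample retrieval uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import atmosphere as atm
from . import surface as srf
from .coupling import SpectrumLUT, _resample_matrix, _toa_matrix
from .emulator import Metrics, validate
from .gpr import GaussianProcessRegressorARD
from .spectral import BandSet, Geometry, _band_convolve_matrix, make_wavenumber_grid

__all__ = [
    "RetrievalModel",
    "ScenarioReport",
    "add_noise",
    "soil_band_rows",
    "train_retrieval",
    "band_relevance",
    "retrieve",
    "evaluate_scenarios",
    "apply_to_cube",
    "RETRIEVABLE_VARIABLES",
]

RETRIEVABLE_VARIABLES = ("Cab", "Cw", "LAI")


def add_noise(
    band_matrix: np.ndarray,
    level: float = 0.02,
    mode: str = "multiplicative",
    seed: int = 0,
    quantity: str = "radiance",
) -> np.ndarray:
    """Seeded Gaussian noise injection on band values.

    multiplicative: x * (1 + level * z); additive: x + level * scale(x) * z.
    Reflectance outputs are clipped to [0, 1], radiance floored at 0.
    """
    X = np.asarray(band_matrix, float)
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if level == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(X.shape)
    if mode == "multiplicative":
        out = X * (1.0 + level * z)
    elif mode == "additive":
        out = X + level * X.std() * z
    else:
        raise ValueError("mode must be 'multiplicative' or 'additive'")
    if quantity == "reflectance":
        return np.clip(out, 0.0, 1.0)
    return np.maximum(out, 0.0)


@dataclass
class RetrievalModel:
    """A trained per-variable retrieval model over band space."""

    variable: str
    model: GaussianProcessRegressorARD
    band_ids: list[str]
    level: str                     # "toc" or "toa"
    noise_level: float
    seed: int
    validation: Metrics | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if hasattr(self.model, "n_features_in_") and len(self.band_ids) != self.model.n_features_in_:
            raise ValueError("band count does not match model input dimension")


def soil_band_rows(
    bands: BandSet,
    level: str = "toc",
    n: int = 20,
    seed: int = 0,
    config=None,
) -> np.ndarray:
    """Band values of a seeded bare-soil library at TOC or TOA level.

    TOC rows are soil reflectance convolved to bands; TOA rows couple each
    soil spectrum through a seeded rural-aerosol atmosphere first.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    soils = srf.generate_soil_library(n=n, seed=seed)
    grid = soils[0].grid
    R = np.stack([s.values for s in soils])
    if level == "toc":
        return _band_convolve_matrix(grid, R, bands)
    if level != "toa":
        raise ValueError("level must be 'toc' or 'toa'")
    geom = Geometry(cfg.sza_deg, cfg.vza_deg)
    wngrid = make_wavenumber_grid(*cfg.wavenumber_grid)
    rng = np.random.default_rng(seed)
    gas = np.column_stack(
        [
            rng.uniform(*atm.TABLE_ATMOSPHERE_RANGES[k], size=n)
            for k in ("O3C", "CWV", "AOT550")
        ]
    )
    aero = np.tile(atm.aerosol_preset("rural"), (n, 1))
    tf = atm._transfer_matrix(np.hstack([gas, aero]), geom, wngrid)
    Rw = np.clip(_resample_matrix(grid, R, wngrid), 0.0, 1.0)
    L = _toa_matrix(Rw, tf, geom.mu_s)
    return _band_convolve_matrix(wngrid, L, bands)


def train_retrieval(
    lut: SpectrumLUT,
    variable: str,
    split: float = 0.7,
    noise: float = 0.02,
    soils: int = 20,
    seed: int = 0,
    config=None,
    **gpr_opts,
) -> RetrievalModel:
    """Train one GP retrieval model from a band-level LUT.

    A seeded ``split`` fraction of the LUT trains the GP (bands noised,
    soil rows appended with target 0); the remainder provides the internal
    validation Metrics stored on the returned model.
    """
    if lut.band_ids is None:
        raise ValueError("LUT must be at band level (convolve with a BandSet first)")
    if variable not in lut.input_names:
        raise ValueError(f"variable {variable!r} not among LUT inputs {lut.input_names}")
    level = "toa" if lut.level.endswith("radiance") else "toc"
    quantity = "radiance" if level == "toa" else "reflectance"
    y = lut.column(variable)
    B = lut.Y

    rng = np.random.default_rng(seed)
    perm = rng.permutation(lut.n)
    n_train = int(round(split * lut.n))
    tr, te = perm[:n_train], perm[n_train:]
    if n_train < 50:
        raise ValueError(f"need at least 50 training rows, got {n_train}")

    Xtr, ytr = B[tr], y[tr]
    if soils:
        bands = _bandset_for(lut)
        Xsoil = soil_band_rows(bands, level=level, n=soils, seed=seed, config=config)
        Xtr = np.vstack([Xtr, Xsoil])
        ytr = np.concatenate([ytr, np.zeros(Xsoil.shape[0])])
    Xtr = add_noise(Xtr, level=noise, seed=seed, quantity=quantity)

    gp = GaussianProcessRegressorARD(random_state=seed, **gpr_opts)
    gp.fit(Xtr, ytr)
    est = gp.predict(B[te])
    metrics = validate(y[te], est)
    metrics.meta.update({"n_train": int(Xtr.shape[0]), "n_validation": int(te.size)})
    return RetrievalModel(
        variable, gp, list(lut.band_ids), level, noise, seed, validation=metrics,
        meta={"scenario": lut.scenario},
    )


def _bandset_for(lut: SpectrumLUT) -> BandSet:
    from .spectral import make_s2_bandset

    bands = make_s2_bandset()
    if lut.band_ids != bands.ids:
        raise ValueError(
            "LUT band ids do not match the built-in band set; pass soil rows "
            "explicitly via soil_band_rows for custom band sets"
        )
    return bands


def band_relevance(model: RetrievalModel) -> list[tuple[str, float]]:
    """Bands ranked most-relevant first (ascending length-scale sigma_b)."""
    sig = model.model.length_scales_
    order = np.argsort(sig)
    return [(model.band_ids[i], float(sig[i])) for i in order]


def retrieve(model: RetrievalModel, band_matrix: np.ndarray):
    """Estimates and predictive std for rows of band values."""
    B = np.atleast_2d(np.asarray(band_matrix, float))
    return model.model.predict(B, return_std=True)


@dataclass
class ScenarioReport:
    """Per-variable, per-scenario retrieval accuracy (table + histograms)."""

    entries: dict = field(default_factory=dict)  # (variable, scenario) -> Metrics
    errors: dict = field(default_factory=dict)   # (variable, scenario) -> residuals

    def to_frame(self):
        import pandas as pd

        scenarios = sorted({s for _, s in self.entries})
        rows = {}
        for stat in ("r2", "rmse"):
            for var in sorted({v for v, _ in self.entries}):
                rows[(stat.upper(), var)] = [
                    getattr(self.entries[(var, s)], stat)
                    if (var, s) in self.entries
                    else np.nan
                    for s in scenarios
                ]
        return pd.DataFrame(rows, index=scenarios).T

    def error_histogram(self, variable: str, scenario: str, bins: int = 50):
        return np.histogram(self.errors[(variable, scenario)], bins=bins)


def evaluate_scenarios(
    models: dict[tuple[str, str], RetrievalModel],
    references: dict[str, SpectrumLUT],
) -> ScenarioReport:
    """Validate retrieval models against the reference band-level LUTs.

    ``models`` maps (variable, "toc"|"toa") to trained models; ``references``
    maps scenario labels "TOC" / "TOA" / "TOC-ATM" to band-level LUTs.  The
    TOC-trained model is applied to the TOC and TOC-ATM scenarios, the
    TOA-trained model to the TOA scenario.
    """
    report = ScenarioReport()
    for scen, lut in references.items():
        if scen not in ("TOC", "TOA", "TOC-ATM"):
            raise ValueError(f"unknown scenario label {scen!r}")
        level = "toa" if scen == "TOA" else "toc"
        for (var, lvl), model in models.items():
            if lvl != level:
                continue
            y = lut.column(var)
            est, _ = retrieve(model, lut.Y)
            report.entries[(var, scen)] = validate(y, est)
            report.errors[(var, scen)] = est - y
    return report


def apply_to_cube(
    model: RetrievalModel, cube: np.ndarray, band_order: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel retrieval over a (rows, cols, bands) array.

    ``band_order`` names the cube's band axis; it must contain the model's
    bands (any order).  Non-finite pixels propagate as NaN in both maps.
    """
    cube = np.asarray(cube, float)
    if cube.ndim != 3:
        raise ValueError("cube must be rows x cols x bands")
    missing = [b for b in model.band_ids if b not in band_order]
    if missing:
        raise ValueError(f"cube lacks required bands: {', '.join(missing)}")
    sel = [band_order.index(b) for b in model.band_ids]
    nr, nc, _ = cube.shape
    flat = cube[:, :, sel].reshape(nr * nc, len(sel))
    ok = np.all(np.isfinite(flat), axis=1)
    est = np.full(nr * nc, np.nan)
    std = np.full(nr * nc, np.nan)
    if ok.any():
        est[ok], std[ok] = retrieve(model, flat[ok])
    return est.reshape(nr, nc), std.reshape(nr, nc)
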