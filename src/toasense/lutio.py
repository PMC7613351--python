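"""Serialization: LUT container files, delimited-text tables, SRF tables.

The LUT container is a single ``.npz`` archive holding the input matrix,
the spectra matrix, the grid and a JSON metadata record (scenario, seed,
ranges, level) — self-describing and lossless for floats.  Delimited-text
exports (one row per sample: inputs then spectra) serve interchange.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .coupling import SpectrumLUT
from .spectral import SpectralGrid, Spectrum, bandset_from_table

__all__ = [
    "write_lut",
    "read_lut",
    "export_lut_csv",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_srf_table",
    "write_sensitivity_table",
]


def write_lut(lut: SpectrumLUT, path) -> None:
    meta = {
        "input_names": lut.input_names,
        "ranges": {k: list(v) for k, v in lut.ranges.items()},
        "level": lut.level,
        "scenario": lut.scenario,
        "seed": lut.seed,
        "band_ids": lut.band_ids,
        "grid_origin": None if lut.grid is None else lut.grid.origin,
        "grid_step": None if lut.grid is None else lut.grid.step,
    }
    arrays = {"X": lut.X, "Y": lut.Y, "meta_json": np.array(json.dumps(meta))}
    if lut.grid is not None:
        arrays["grid"] = lut.grid.wavelengths_nm
    np.savez(path, **arrays)


def read_lut(path) -> SpectrumLUT:
    with np.load(path, allow_pickle=False) as z:
        names = set(z.files)
        for req in ("X", "Y", "meta_json"):
            if req not in names:
                raise ValueError(f"LUT file is missing required entry {req!r}")
        meta = json.loads(str(z["meta_json"]))
        grid = None
        if meta["level"].startswith(("toc", "toa")):
            if "grid" not in names:
                raise ValueError("LUT file is missing required entry 'grid'")
            grid = SpectralGrid(
                z["grid"],
                origin=meta["grid_origin"] or "uniform_nm",
                step=meta["grid_step"] or float("nan"),
            )
        return SpectrumLUT(
            meta["input_names"],
            {k: tuple(v) for k, v in meta["ranges"].items()},
            z["X"],
            z["Y"],
            grid,
            meta["level"],
            meta["scenario"],
            meta["seed"],
            meta["band_ids"],
        )


def export_lut_csv(lut: SpectrumLUT, path) -> None:
    """One row per sample: input columns then spectral/band columns."""
    if lut.grid is not None:
        ycols = [f"wl_{w:.3f}" for w in lut.grid.wavelengths_nm]
    else:
        ycols = list(lut.band_ids)
    df = pd.DataFrame(
        np.hstack([lut.X, lut.Y]), columns=lut.input_names + ycols
    )
    df.to_csv(path, index=False)


def write_spectrum_table(s: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": s.wavelengths_nm, "value": s.values}
    ).to_csv(path, index=False)


def read_spectrum_table(path, quantity: str = "reflectance") -> Spectrum:
    df = pd.read_csv(path)
    grid = SpectralGrid(df["wavelength_nm"].to_numpy())
    return Spectrum(grid, df["value"].to_numpy(), quantity)


def read_srf_table(path):
    """Delimited SRF table (header: wavelength_nm,B2,B3,...) -> BandSet."""
    df = pd.read_csv(path)
    wl = df["wavelength_nm"].to_numpy()
    responses = {c: df[c].to_numpy() for c in df.columns if c != "wavelength_nm"}
    return bandset_from_table(wl, responses)


def write_sensitivity_table(result, path) -> None:
    """Rows = wavelengths, columns = Si and STi per variable."""
    result.to_frame().to_csv(path)
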