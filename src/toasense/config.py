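"""Run configuration: study defaults, YAML round-trip, seeding."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults of the simulation study.

    Sizes are the full experiment sizes; the CLI offers reduced smoke-test
    sizes behind the same fields.  Every stochastic step derives its own
    child seed from ``seed``.
    """

    seed: int = 0

    # dataset sizes
    n_analysis: int = 10000
    n_subset: int = 5000
    n_emulator_train: int = 1000

    # spectral configuration
    wavenumber_grid: tuple[float, float, float] = (400.0, 2500.0, 15.0)
    surface_step_nm: float = 1.0

    # fixed acquisition geometry
    sza_deg: float = 30.0
    vza_deg: float = 0.0

    # default LUT soil background
    soil_brightness: float = 1.0
    soil_wetness: float = 0.3

    # emulator
    pca_components: int = 20
    train_split: float = 0.7

    # GSA
    gsa_N: int = 1000

    # retrieval
    noise_level: float = 0.02
    noise_mode: str = "multiplicative"
    n_soils: int = 20
    sen2cor_mode: str = "gaussian"

    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumber_grid = tuple(self.wavenumber_grid)
        if self.n_subset * 2 > self.n_analysis:
            raise ValueError("n_subset must not exceed half of n_analysis")
        if not 0 < self.train_split < 1:
            raise ValueError("train_split must lie in (0, 1)")

    def sen2cor_model(self):
        from .coupling import Sen2CorErrorModel

        return Sen2CorErrorModel(mode=self.sen2cor_mode)

    # ------------------------------------------------------------- io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wavenumber_grid"] = list(self.wavenumber_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        """Stable hash of the resolved configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
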