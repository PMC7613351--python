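"""Spectral emulation: PCA compression + one GP regressor per component.

An emulator replaces the expensive coupled simulator inside sensitivity
studies: spectra are compressed to a small number of principal components
(20 by default), one ARD GP is trained per retained component over the
unit-scaled simulator inputs, and predictions are reconstructed through the
PCA basis.  Accuracy is reported as R^2 (squared Pearson correlation),
RMSE, and NRMSE = 100 * RMSE / mean(reference) on a held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .gpr import GaussianProcessRegressorARD

__all__ = [
    "PCABasis",
    "pca_fit",
    "pca_project",
    "pca_reconstruct",
    "Metrics",
    "validate",
    "SpectralEmulator",
    "emulator_train",
    "emulator_predict",
]


@dataclass
class PCABasis:
    """Mean spectrum plus an orthonormal component basis."""

    mean: np.ndarray               # (m,)
    components: np.ndarray         # (p, m), orthonormal rows
    explained_variance_ratio: np.ndarray
    p: int

    def __post_init__(self):
        G = self.components @ self.components.T
        if not np.allclose(G, np.eye(self.p), atol=1e-8):
            raise ValueError("components are not orthonormal")


def pca_fit(Y: np.ndarray, p: int) -> PCABasis:
    """Mean-centred PCA of an (n, m) spectra matrix, p retained components."""
    Y = np.atleast_2d(np.asarray(Y, float))
    p_max = min(Y.shape[0] - 1, Y.shape[1])
    if not 1 <= p <= p_max:
        raise ValueError(f"p must lie in [1, {p_max}], got {p}")
    pca = PCA(n_components=p, svd_solver="full").fit(Y)
    return PCABasis(pca.mean_, pca.components_, pca.explained_variance_ratio_, p)


def pca_project(basis: PCABasis, Y: np.ndarray) -> np.ndarray:
    return (np.atleast_2d(Y) - basis.mean) @ basis.components.T


def pca_reconstruct(basis: PCABasis, scores: np.ndarray) -> np.ndarray:
    return basis.mean + np.atleast_2d(scores) @ basis.components


@dataclass
class Metrics:
    """Goodness-of-fit of reconstructed vs reference values."""

    r2: float
    rmse: float
    nrmse_percent: float
    n: int
    normalizer: str = "mean"
    per_spectrum_rmse: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def validate(ref: np.ndarray, est: np.ndarray, normalizer: str = "mean") -> Metrics:
    """R^2 (squared Pearson correlation), RMSE and NRMSE over all entries.

    NRMSE is normalized by the mean of the reference values by default, or
    by their range with ``normalizer='range'``.
    """
    ref = np.asarray(ref, float)
    est = np.asarray(est, float)
    if ref.shape != est.shape:
        raise ValueError("reference and estimate shapes differ")
    r, e = ref.ravel(), est.ravel()
    rmse = float(np.sqrt(np.mean((r - e) ** 2)))
    if r.std() == 0 or e.std() == 0:
        r2 = 1.0 if rmse == 0 else 0.0
    else:
        r2 = float(np.corrcoef(r, e)[0, 1] ** 2)
    denom = float(r.mean()) if normalizer == "mean" else float(r.max() - r.min())
    nrmse = 100.0 * rmse / denom if denom != 0 else float("inf")
    per = (
        np.sqrt(np.mean((ref - est) ** 2, axis=1)) if ref.ndim == 2 else None
    )
    return Metrics(r2, rmse, nrmse, r.size, normalizer, per)


class SpectralEmulator(BaseEstimator, RegressorMixin):
    """PCA-compressed multi-output GP emulator of a spectral simulator.

    fit(X, Y) takes simulator inputs (n, k) and spectra (n, m); predict(X)
    returns reconstructed spectra.  One independent
    :class:`GaussianProcessRegressorARD` is trained per retained component.
    """

    def __init__(
        self,
        n_components: int = 20,
        input_ranges: np.ndarray | None = None,
        n_restarts: int = 1,
        max_iter: int = 200,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.input_ranges = input_ranges
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "SpectralEmulator":
        X = np.atleast_2d(np.asarray(X, float))
        Y = np.atleast_2d(np.asarray(Y, float))
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        self.basis_ = pca_fit(Y, min(self.n_components, X.shape[0] - 1, Y.shape[1]))
        scores = pca_project(self.basis_, Y)
        ranges = self.input_ranges
        if ranges is None:
            ranges = np.column_stack([X.min(axis=0), X.max(axis=0)])
        self.models_ = []
        for c in range(self.basis_.p):
            gp = GaussianProcessRegressorARD(
                n_restarts=self.n_restarts,
                max_iter=self.max_iter,
                input_ranges=ranges,
                random_state=None
                if self.random_state is None
                else self.random_state + c,
            )
            self.models_.append(gp.fit(X, scores[:, c]))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray, return_component_std: bool = False):
        check_is_fitted(self, "models_")
        X = np.atleast_2d(np.asarray(X, float))
        scores = np.empty((X.shape[0], self.basis_.p))
        stds = np.empty_like(scores) if return_component_std else None
        for c, gp in enumerate(self.models_):
            if return_component_std:
                scores[:, c], stds[:, c] = gp.predict(X, return_std=True)
            else:
                scores[:, c] = gp.predict(X)
        Yhat = pca_reconstruct(self.basis_, scores)
        return (Yhat, stds) if return_component_std else Yhat


def emulator_train(
    lut,
    p: int = 20,
    split: float = 0.7,
    seed: int = 0,
    n_restarts: int = 1,
    max_iter: int = 200,
) -> tuple[SpectralEmulator, Metrics]:
    """Train an emulator on a seeded train/validation split of a LUT.

    Returns the fitted emulator and held-out Metrics (R^2, RMSE, NRMSE).
    """
    n = lut.n
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(split * n))
    tr, te = perm[:n_train], perm[n_train:]
    ranges = np.array([lut.ranges[v] for v in lut.input_names])
    em = SpectralEmulator(
        n_components=p,
        input_ranges=ranges,
        n_restarts=n_restarts,
        max_iter=max_iter,
        random_state=seed,
    )
    em.fit(lut.X[tr], lut.Y[tr])
    metrics = validate(lut.Y[te], em.predict(lut.X[te]))
    metrics.meta.update(
        {"n_train": int(n_train), "n_validation": int(n - n_train), "p": em.basis_.p,
         "seed": seed}
    )
    return em, metrics


def emulator_predict(em: SpectralEmulator, X: np.ndarray, **kw) -> np.ndarray:
    """Stateless prediction wrapper (no re-fitting)."""
    return em.predict(X, **kw)
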