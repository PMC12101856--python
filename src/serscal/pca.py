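"""Mean-centered principal component analysis of spectra.

Channels share intensity units, so spectra are mean-centered but not variance
scaled.  The decomposition is a thin SVD of the centered intensity matrix;
score matrices feed the neural calibration and loading extrema identify the
bands driving group separation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from .dataset import SpectrumSet


@dataclasses.dataclass
class PCAModel:
    """Fitted PCA: mean spectrum, unit-norm loadings and variance ratios.

    ``loadings`` has shape (components, channels) with orthonormal rows; the
    sign convention makes each loading's largest-magnitude element positive so
    fits are reproducible.  ``explained_variance_ratio`` is per retained
    component relative to the total variance of the training set.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    wavenumbers: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "mean_spectrum": self.mean_spectrum.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "wavenumbers": None
            if self.wavenumbers is None
            else self.wavenumbers.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            np.asarray(payload["mean_spectrum"], dtype=float),
            np.asarray(payload["loadings"], dtype=float),
            np.asarray(payload["explained_variance_ratio"], dtype=float),
            None
            if payload["wavenumbers"] is None
            else np.asarray(payload["wavenumbers"], dtype=float),
        )


def _as_matrix(data) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(data, SpectrumSet):
        return data.intensities, data.wavenumbers
    return np.atleast_2d(np.asarray(data, dtype=float)), None


def fit_pca(data, n_components: int) -> PCAModel:
    """Thin SVD of the column-mean-centered matrix.

    ``explained_variance_ratio_i = sigma_i^2 / sum_j sigma_j^2`` over *all*
    singular values, so the retained ratios sum to at most 1.
    """
    X, wavenumbers = _as_matrix(data)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two spectra")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}] for a {n}x{p} matrix"
        )
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    ratios = s**2 / np.sum(s**2)
    loadings = vt[:n_components].copy()
    # deterministic sign: largest-magnitude element of each loading positive
    flip = np.sign(loadings[np.arange(n_components),
                            np.abs(loadings).argmax(axis=1)])
    loadings *= flip[:, None]
    return PCAModel(mean, loadings, ratios[:n_components], wavenumbers)


def project(model: PCAModel, data) -> np.ndarray:
    """Score matrix ``(X - mean) @ loadings.T`` (spectra x components)."""
    X, _ = _as_matrix(data)
    if X.shape[1] != model.mean_spectrum.size:
        raise ValueError(
            f"spectra have {X.shape[1]} channels, model expects "
            f"{model.mean_spectrum.size}"
        )
    return (X - model.mean_spectrum) @ model.loadings.T


def reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Back-project scores to spectra: ``mean + scores @ loadings``."""
    return model.mean_spectrum + np.atleast_2d(scores) @ model.loadings


def loading_peaks(
    model: PCAModel, component: int, top_k: int = 5
) -> list[tuple[float, float]]:
    """Band centers driving one component, ranked by |loading|.

    Local extrema of the absolute loading are ranked by magnitude; ties break
    toward the lower wavenumber.  Returns ``(wavenumber, signed loading)``
    pairs; if fewer extrema exist than ``top_k``, all are returned with a
    warning.  Requires the model to carry its wavenumber grid.
    """
    if model.wavenumbers is None:
        raise ValueError("model carries no wavenumber grid")
    if not 0 <= component < model.n_components:
        raise IndexError(f"component {component} out of range")
    v = model.loadings[component]
    mag = np.abs(v)
    left = np.r_[True, mag[1:] >= mag[:-1]]
    right = np.r_[mag[:-1] >= mag[1:], True]
    candidates = np.flatnonzero(left & right & (mag > 0))
    order = np.lexsort((model.wavenumbers[candidates], -mag[candidates]))
    peaks = [
        (float(model.wavenumbers[candidates[i]]), float(v[candidates[i]]))
        for i in order
    ]
    if top_k > len(peaks):
        warnings.warn(
            f"requested {top_k} peaks but only {len(peaks)} extrema exist",
            stacklevel=2,
        )
        return peaks
    return peaks[:top_k]
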