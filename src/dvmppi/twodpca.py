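"""Two-dimensional PCA over 20 x 20 evolution matrices.

Classic PCA would vectorise each 20 x 20 matrix into a 400-vector before
eigen-analysis.  2DPCA instead builds the image scatter matrix

    G_t = (1/M) sum_j (A_j - Abar)' (A_j - Abar)

directly from the sample matrices A_j and projects each matrix onto the top-d
eigenvectors X_1..X_d of G_t (the maximisers of the scatter criterion
J(X) = X' G_t X under orthonormality).  Each projection Y_k = A X_k is a
20-vector; concatenating Y_1..Y_d gives the 20*d-dimensional protein feature
(60 for the default d = 3), and concatenating the two protein features of a
pair gives the 40*d-dimensional pair feature (120 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .pssm import EvolutionMatrix

__all__ = [
    "Basis",
    "TwoDPCA",
    "scatter_matrix",
    "fit_basis",
    "project",
    "pair_feature",
]

_ORTHO_TOL = 1e-8


def _as_matrix_array(samples) -> np.ndarray:
    """Stack EvolutionMatrix objects / raw arrays into an (n, 20, 20) array."""
    mats = [
        s.values if isinstance(s, EvolutionMatrix) else np.asarray(s, dtype=float)
        for s in samples
    ]
    if not mats:
        raise ValueError("need at least one sample matrix")
    arr = np.stack(mats).astype(float)
    if arr.shape[-2:] != (20, 20):
        raise ValueError(f"expected 20 x 20 matrices, got {arr.shape[-2:]}")
    return arr


@dataclass
class Basis:
    """A fitted 2DPCA projection basis.

    Attributes
    ----------
    axes : numpy.ndarray
        20 x d matrix whose columns are the orthonormal projection axes,
        ordered by decreasing eigenvalue.
    eigenvalues : numpy.ndarray
        The d attained values of the scatter criterion J(X), non-increasing.
    mean_matrix : numpy.ndarray
        The 20 x 20 mean Abar of the training matrices.
    """

    axes: np.ndarray
    eigenvalues: np.ndarray
    mean_matrix: np.ndarray

    @property
    def d(self) -> int:
        return self.axes.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "d": self.d,
            "axes": self.axes.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "mean_matrix": self.mean_matrix.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Basis":
        payload = json.loads(Path(path).read_text())
        return cls(
            axes=np.asarray(payload["axes"], dtype=float),
            eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
            mean_matrix=np.asarray(payload["mean_matrix"], dtype=float),
        )


def scatter_matrix(samples) -> tuple[np.ndarray, np.ndarray]:
    """Image scatter matrix G_t and mean matrix Abar of the samples.

    Returns ``(G_t, mean_matrix)`` with
    G_t = (1/M) sum_j (A_j - Abar)'(A_j - Abar); G_t is symmetric PSD.
    """
    arr = _as_matrix_array(samples)
    mean = arr.mean(axis=0)
    centered = arr - mean
    gt = np.einsum("jik,jil->kl", centered, centered) / arr.shape[0]
    gt = (gt + gt.T) / 2.0  # enforce exact symmetry against roundoff
    return gt, mean


def fit_basis(samples, d: int = 3) -> Basis:
    """Fit the top-d 2DPCA axes from training evolution matrices.

    The axes are the orthonormal eigenvectors of G_t for the d largest
    eigenvalues.  Sign convention: the largest-magnitude component of each
    axis is made positive, so the basis is reproducible across eigensolvers.

    Raises
    ------
    ValueError
        If ``d`` is outside 1..20, or all samples are identical (zero
        scatter: no informative axes).
    """
    if not 1 <= d <= 20:
        raise ValueError(f"d must be in 1..20, got {d}")
    gt, mean = scatter_matrix(samples)
    if not np.any(gt):
        raise ValueError("degenerate scatter: all sample matrices identical")
    eigvals, eigvecs = np.linalg.eigh(gt)  # ascending
    order = np.argsort(eigvals)[::-1][:d]
    axes = eigvecs[:, order]
    eigenvalues = eigvals[order]
    for k in range(axes.shape[1]):
        j = np.argmax(np.abs(axes[:, k]))
        if axes[j, k] < 0:
            axes[:, k] = -axes[:, k]
    return Basis(axes=axes, eigenvalues=eigenvalues, mean_matrix=mean)


def project(a, basis: Basis) -> np.ndarray:
    """Project one 20 x 20 matrix onto the basis: Y_k = A X_k, k = 1..d.

    The sample matrix itself is projected (no mean-centering before the
    product).  Output is the axis-major concatenation [Y_1; ...; Y_d],
    length 20*d.
    """
    mat = a.values if isinstance(a, EvolutionMatrix) else np.asarray(a, dtype=float)
    return (mat @ basis.axes).flatten(order="F")


def pair_feature(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Concatenate two protein features into the pair feature [fa || fb]."""
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if fa.shape != fb.shape:
        raise ValueError(
            f"feature length mismatch: {fa.shape[0]} vs {fb.shape[0]}"
        )
    return np.concatenate([fa, fb])


class TwoDPCA(TransformerMixin, BaseEstimator):
    """2DPCA feature extractor for single matrices or matrix pairs.

    Accepts ``X`` of shape (n, 20, 20) — one matrix per sample — or
    (n, 2, 20, 20) — a protein pair per sample.  ``fit`` estimates the scatter
    basis from every matrix seen in the training samples (both members of each
    pair), so using this transformer inside a cross-validation pipeline
    automatically refits the basis on training-fold proteins only.
    ``transform`` maps each sample to its 20*d (single) or 40*d (pair)
    feature vector.

    Parameters
    ----------
    n_components : int, default 3
        Number of projection axes d.  The default reproduces the standard
        60-dim protein / 120-dim pair features on 20-row matrices.

    Attributes
    ----------
    axes_ : ndarray of shape (20, n_components)
    eigenvalues_ : ndarray of shape (n_components,)
    mean_matrix_ : ndarray of shape (20, 20)
    basis_ : Basis
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def _matrices(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3 and X.shape[1:] == (20, 20):
            return X
        if X.ndim == 4 and X.shape[1] == 2 and X.shape[2:] == (20, 20):
            return X
        raise ValueError(
            "X must have shape (n, 20, 20) or (n, 2, 20, 20); "
            f"got {X.shape}"
        )

    def fit(self, X, y=None):
        mats = self._matrices(X)
        self._pair_input_ = mats.ndim == 4
        pool = mats.reshape(-1, 20, 20)
        self.basis_ = fit_basis(list(pool), d=self.n_components)
        self.axes_ = self.basis_.axes
        self.eigenvalues_ = self.basis_.eigenvalues
        self.mean_matrix_ = self.basis_.mean_matrix
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "basis_")
        mats = self._matrices(X)
        # (..., 20, 20) @ (20, d) -> (..., 20, d); axis-major flatten per matrix
        proj = np.swapaxes(mats @ self.axes_, -1, -2).reshape(mats.shape[0], -1)
        return proj

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "basis_")
        width = 20 * self.n_components
        n = width * 2 if getattr(self, "_pair_input_", False) else width
        return np.array([f"f{i + 1}" for i in range(n)])
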