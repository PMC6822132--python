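"""Principal coordinates analysis (classical metric MDS) of dissimilarity matrices.

The squared dissimilarity matrix is Gower double-centred, B = -1/2 J D^2 J
with J = I - 11'/n, and eigendecomposed; coordinates on axis k are
eigenvector_k * sqrt(lambda_k) for positive eigenvalues. Sørensen-family
dissimilarities are generally non-Euclidean, so negative eigenvalues are
expected; by default they are only reported (as a share of total absolute
eigenvalue mass), with the Lingoes additive-constant correction available
on request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .beta_partition import DissimilarityMatrix

EIG_TOL = 1e-10


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray  # areas x retained axes
    eigenvalues: np.ndarray  # full spectrum, descending
    variance_explained: np.ndarray  # fraction of positive eigenvalue mass per retained axis
    correction: str
    negative_eigenvalue_share: float

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ d2 @ j


def pcoa(
    d: DissimilarityMatrix | np.ndarray,
    correction: str = "none",
    n_axes: int = 2,
    labels: list[str] | None = None,
) -> OrdinationResult:
    """Embed a dissimilarity matrix into Euclidean principal coordinates.

    Parameters
    ----------
    d : DissimilarityMatrix or square ndarray
    correction : 'none' or 'lingoes'
        Lingoes adds the smallest constant c to all squared off-diagonal
        dissimilarities that removes negative eigenvalues.
    n_axes : number of leading positive axes to retain.

    Axis signs are canonicalized (the largest-magnitude loading on each
    axis is made positive) so repeated runs and different eigensolvers
    agree.
    """
    if isinstance(d, DissimilarityMatrix):
        labels = d.labels
        mat = d.values
    else:
        mat = np.asarray(d, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or mat.shape[0] < 2:
        raise ValueError("need a square matrix of size >= 2")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(mat < -1e-12):
        raise ValueError("dissimilarities must be non-negative")
    if correction not in ("none", "lingoes"):
        raise ValueError("correction must be 'none' or 'lingoes'")

    n = mat.shape[0]
    b = _gower_center(mat**2)
    eigvals = eigh(b, eigvals_only=True)
    applied = "none"
    if correction == "lingoes" and eigvals.min() < -EIG_TOL:
        c = -float(eigvals.min())
        d2 = mat**2 + 2.0 * c * (1.0 - np.eye(n))
        b = _gower_center(d2)
        applied = "lingoes"

    vals, vecs = eigh(b)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]

    pos = vals > EIG_TOL
    pos_mass = vals[pos].sum() if pos.any() else 0.0
    neg_mass = float(np.abs(vals[vals < -EIG_TOL]).sum())
    total_abs = float(np.abs(vals).sum())
    neg_share = neg_mass / total_abs if total_abs > 0 else 0.0

    k = min(n_axes, int(pos.sum()))
    coords = vecs[:, :k] * np.sqrt(vals[:k]) if k else np.zeros((n, 0))
    # canonical signs: largest-|loading| entry positive on each axis
    for ax in range(k):
        pivot = np.argmax(np.abs(coords[:, ax]))
        if coords[pivot, ax] < 0:
            coords[:, ax] *= -1
    var = vals[:k] / pos_mass if pos_mass > 0 else np.zeros(k)

    return OrdinationResult(
        labels=list(labels),
        coordinates=coords,
        eigenvalues=vals,
        variance_explained=var,
        correction=applied,
        negative_eigenvalue_share=neg_share,
    )


def reconstructed_distances(result: OrdinationResult, full: bool = False) -> np.ndarray:
    """Pairwise Euclidean distances among the embedded points."""
    x = result.coordinates
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))
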