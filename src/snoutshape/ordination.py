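"""Covariance-based PCA of superimposed coordinates, raw and phylogenetic.

The ordinary fit eigendecomposes the sample covariance (divisor n - 1) of
the flattened aligned coordinates; scores are the centred data projected
onto the eigenvectors, which preserves the partial Procrustes distances
among specimens.  The phylogenetic variant replaces the arithmetic mean
and covariance with their generalized least-squares counterparts under a
Brownian-motion tree covariance C: the mean is the GLS estimate of the
root state and the evolutionary covariance is
(X - 1 a')' C^-1 (X - 1 a') / (n - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .procrustes import AlignedDataset
from .trees import tree_vcv


@dataclass
class PcaModel:
    """Eigenstructure of shape covariance.

    ``eigenvectors`` has one orthonormal column per retained axis;
    ``variance_fraction`` is each eigenvalue over the total variance
    (trace of the full covariance), so it sums to <= 1 for a truncated
    fit and to 1 when all axes are retained.
    """

    ids: list
    mean_vector: np.ndarray        # (2p,)
    eigenvectors: np.ndarray       # (2p, k)
    eigenvalues: np.ndarray        # (k,)
    scores: np.ndarray             # (n, k)
    variance_fraction: np.ndarray  # (k,)
    total_variance: float

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class PhyloPcaModel(PcaModel):
    gls_root_mean: np.ndarray = None  # (2p,)
    tree_covariance: np.ndarray = None  # (n, n)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    # deterministic orientation: largest-|loading| entry of each axis positive
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def pca_fit(aligned: AlignedDataset, k: int | None = None) -> PcaModel:
    """Covariance PCA of flattened aligned coordinates.

    Parameters
    ----------
    aligned
        Superimposed dataset (n >= 2 specimens).
    k
        Number of axes to retain; ``None`` keeps every axis with a
        nonzero eigenvalue (up to min(n - 1, 2p)).
    """
    x = aligned.flattened()
    n = x.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 specimens")
    mean = x.mean(axis=0)
    centred = x - mean
    cov = centred.T @ centred / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    total = float(np.trace(cov))
    kmax = min(n - 1, x.shape[1])
    keep = kmax if k is None else min(int(k), kmax)
    eigvals, eigvecs = eigvals[:keep], eigvecs[:, :keep]
    return PcaModel(
        ids=list(aligned.ids),
        mean_vector=mean,
        eigenvectors=eigvecs,
        eigenvalues=eigvals,
        scores=centred @ eigvecs,
        variance_fraction=eigvals / total if total > 0 else eigvals * 0.0,
        total_variance=total,
    )


def pca_project(model: PcaModel, new_configs: np.ndarray) -> np.ndarray:
    """Project configurations (already in the model's consensus frame).

    ``new_configs`` may be (m, p, 2) configurations or (m, 2p) flattened
    rows; returns (m, k) scores relative to the model's mean vector.
    """
    x = np.asarray(new_configs, dtype=float)
    if x.ndim == 3:
        x = x.reshape(x.shape[0], -1)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.mean_vector.shape[0]:
        raise ValueError(
            f"dimension mismatch: got {x.shape[1]} variables, "
            f"model has {model.mean_vector.shape[0]}"
        )
    return (x - model.mean_vector) @ model.eigenvectors


def pca_reconstruct(model: PcaModel, scores: np.ndarray) -> np.ndarray:
    """Back-project scores to flattened coordinate space."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return model.mean_vector + scores @ model.eigenvectors.T


def phylo_pca_fit(
    aligned: AlignedDataset,
    tree: dendropy.Tree,
    k: int | None = None,
) -> PhyloPcaModel:
    """Phylogenetic PCA under Brownian motion.

    The specimen ids of ``aligned`` must match the tree's tip labels
    exactly.  Eigendecomposes the evolutionary covariance
    E = (X - 1 a')' C^-1 (X - 1 a') / (n - 1) where a is the GLS root
    mean; scores are the root-centred data on E's eigenvectors.
    """
    x = aligned.flattened()
    n = x.shape[0]
    c = tree_vcv(tree, list(aligned.ids))
    try:
        cinv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular tree covariance (duplicate zero-length tips?); "
            "jitter terminal branch lengths"
        ) from exc
    ones = np.ones(n)
    denom = ones @ cinv @ ones
    a = (ones @ cinv @ x) / denom
    centred = x - a
    evol_cov = centred.T @ cinv @ centred / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(evol_cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    total = float(np.trace(evol_cov))
    kmax = min(n - 1, x.shape[1])
    keep = kmax if k is None else min(int(k), kmax)
    eigvals, eigvecs = eigvals[:keep], eigvecs[:, :keep]
    return PhyloPcaModel(
        ids=list(aligned.ids),
        mean_vector=a,
        eigenvectors=eigvecs,
        eigenvalues=eigvals,
        scores=centred @ eigvecs,
        variance_fraction=eigvals / total if total > 0 else eigvals * 0.0,
        total_variance=total,
        gls_root_mean=a,
        tree_covariance=c,
    )
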