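"""Generalized least-squares Procrustes superimposition (GPA).

Configurations are translated to a common centroid, scaled once to unit
centroid size, and iteratively rotated to the running consensus until the
partial Procrustes distance between successive consensus shapes falls
below a tolerance (default 1e-4).  Only proper rotations are allowed:
every specimen is digitised in the same ventral view, so a reflection
would fabricate a left/right inversion.  The analysis proceeds in shape
space (size removed), not form space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .outline import SemilandmarkSet


@dataclass
class AlignedDataset:
    """Procrustes-superimposed configurations plus their consensus shape.

    Attributes
    ----------
    ids : list of specimen identifiers, in input order.
    configs : (n, p, 2) aligned configurations; each is centred at the
        origin with unit centroid size.
    consensus : (p, 2) mean shape, unit centroid size.
    centroid_sizes : (n,) original (pre-scaling) centroid sizes.
    iterations : number of consensus updates performed.
    final_change : partial Procrustes distance between the last two
        consensus estimates.
    """

    ids: list
    configs: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    final_change: float

    @property
    def n(self) -> int:
        return self.configs.shape[0]

    @property
    def p(self) -> int:
        return self.configs.shape[1]

    def flattened(self) -> np.ndarray:
        """(n, 2p) row-major flattening: x0, y0, x1, y1, ..."""
        return self.configs.reshape(self.n, -1)

    def subset(self, ids: list) -> "AlignedDataset":
        """Restrict to the given specimen ids (order follows `ids`)."""
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in ids]
        return AlignedDataset(
            ids=list(ids),
            configs=self.configs[rows],
            consensus=self.consensus,
            centroid_sizes=self.centroid_sizes[rows],
            iterations=self.iterations,
            final_change=self.final_change,
        )


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared distances to the centroid."""
    config = np.asarray(config, dtype=float)
    if config.shape[0] < 3:
        raise ValueError("need at least 3 points")
    centred = config - config.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred**2)))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points coincident")
    return cs


def optimal_rotation(config_a: np.ndarray, config_b: np.ndarray) -> np.ndarray:
    """Proper 2x2 rotation R minimising ||A R - B||^2 for centred A, B.

    Reflections are excluded (det(R) = +1).
    """
    a = np.asarray(config_a, dtype=float)
    b = np.asarray(config_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must share dimensions")
    h = a.T @ b
    if np.allclose(h, 0.0):
        raise ValueError("degenerate configuration (zero cross-covariance)")
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    return u @ np.diag([1.0, d]) @ vt


def procrustes_distance(config_a: np.ndarray, config_b: np.ndarray) -> float:
    """Partial Procrustes distance between two centred, unit-size shapes.

    Square root of the minimised sum of squared coordinate differences
    after optimal proper rotation of A onto B.
    """
    a = np.asarray(config_a, dtype=float)
    b = np.asarray(config_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must share the same number of points")
    r = optimal_rotation(a, b)
    return float(np.sqrt(np.sum((a @ r - b) ** 2)))


def _centre_and_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    cs = centroid_size(config)
    return (config - config.mean(axis=0)) / cs, cs


def gpa(
    dataset: list[SemilandmarkSet],
    tolerance: float = 1e-4,
    max_iter: int = 1000,
) -> AlignedDataset:
    """Generalized Procrustes superimposition of a set of configurations.

    Each configuration is centred and scaled to unit centroid size, then
    all are rotated to the first specimen; thereafter the consensus is
    recomputed (and rescaled to unit centroid size) and all specimens are
    rotated to it, until the partial Procrustes distance between
    successive consensus shapes drops below ``tolerance``.
    """
    if len(dataset) < 2:
        raise ValueError("GPA needs at least 2 specimens")
    p = dataset[0].p
    for s in dataset:
        if s.p != p:
            raise ValueError(
                f"specimen {s.species_id!r} has {s.p} points, expected {p}"
            )
    ids = [s.species_id for s in dataset]
    configs = np.empty((len(dataset), p, 2))
    sizes = np.empty(len(dataset))
    for i, s in enumerate(dataset):
        configs[i], sizes[i] = _centre_and_scale(s.points)

    reference = configs[0]
    for i in range(len(configs)):
        configs[i] = configs[i] @ optimal_rotation(configs[i], reference)

    mean = configs.mean(axis=0)
    mean /= centroid_size(mean)
    change = np.inf
    iterations = 0
    while change >= tolerance:
        if iterations >= max_iter:
            raise RuntimeError(
                f"GPA did not converge in {max_iter} iterations "
                f"(last consensus change {change:.3e})"
            )
        for i in range(len(configs)):
            configs[i] = configs[i] @ optimal_rotation(configs[i], mean)
        new_mean = configs.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        new_mean /= centroid_size(new_mean)
        change = procrustes_distance(mean, new_mean)
        mean = new_mean
        iterations += 1

    return AlignedDataset(
        ids=ids,
        configs=configs,
        consensus=mean,
        centroid_sizes=sizes,
        iterations=iterations,
        final_change=float(change),
    )


def align_to_consensus(
    specimens: list[SemilandmarkSet], consensus: np.ndarray
) -> AlignedDataset:
    """Superimpose specimens onto a fixed consensus frame (no iteration).

    Used to bring held-out or unknown specimens into the shape space of a
    previously fitted alignment.
    """
    p = consensus.shape[0]
    configs = np.empty((len(specimens), p, 2))
    sizes = np.empty(len(specimens))
    for i, s in enumerate(specimens):
        if s.p != p:
            raise ValueError(f"specimen {s.species_id!r} point count mismatch")
        c, sizes[i] = _centre_and_scale(s.points)
        configs[i] = c @ optimal_rotation(c, consensus)
    return AlignedDataset(
        ids=[s.species_id for s in specimens],
        configs=configs,
        consensus=np.asarray(consensus, dtype=float),
        centroid_sizes=sizes,
        iterations=0,
        final_change=0.0,
    )
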