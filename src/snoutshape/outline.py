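"""Equal arc-length resampling of digitised outlines.

An outline is an ordered polyline of (x, y) vertices starting at a fixed
homologous landmark (for the ruminant premaxilla: the point where the
maxilla-premaxilla suture meets the left-lateral margin).  Resampling
places ``p`` semilandmarks at equal arc-length intervals along the
polyline, interpolating linearly between input vertices.  No semilandmark
sliding is performed at any stage of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SemilandmarkSet:
    """An ordered p x 2 semilandmark configuration for one specimen."""

    species_id: str
    points: np.ndarray  # (p, 2) float array

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"{self.species_id}: points must be (p, 2)")
        if self.points.shape[0] < 3:
            raise ValueError(f"{self.species_id}: need at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"{self.species_id}: non-finite coordinate")

    @property
    def p(self) -> int:
        return self.points.shape[0]


def _cumulative_arc_length(vertices: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def arc_length(vertices: np.ndarray) -> float:
    """Total polyline arc length."""
    return float(_cumulative_arc_length(np.asarray(vertices, dtype=float))[-1])


def points_at_arc_positions(vertices: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Linear interpolation of polyline points at given arc-length positions."""
    vertices = np.asarray(vertices, dtype=float)
    cum = _cumulative_arc_length(vertices)
    x = np.interp(positions, cum, vertices[:, 0])
    y = np.interp(positions, cum, vertices[:, 1])
    return np.column_stack([x, y])


def resample(
    outline: np.ndarray,
    p: int = 100,
    closed: bool = False,
    species_id: str = "",
) -> SemilandmarkSet:
    """Resample an ordered outline to ``p`` equally spaced semilandmarks.

    Open curves keep both endpoints: semilandmark ``k`` sits at arc-length
    position ``k * L / (p - 1)``.  Closed curves are sampled at
    ``k * L / p`` starting from vertex 0, with the closing segment back to
    vertex 0 appended before measuring arc length.

    Parameters
    ----------
    outline
        (m, 2) ordered vertices, m >= 2, not all coincident.
    p
        Number of semilandmarks, >= 3.
    closed
        Treat the outline as a closed contour.
    """
    outline = np.asarray(outline, dtype=float)
    if p < 3:
        raise ValueError("p must be >= 3")
    if outline.ndim != 2 or outline.shape[1] != 2 or outline.shape[0] < 2:
        raise ValueError("outline must be an (m, 2) array with m >= 2")
    if not np.all(np.isfinite(outline)):
        raise ValueError("outline contains non-finite coordinates")
    vertices = outline
    if closed:
        vertices = np.vstack([outline, outline[:1]])
    L = arc_length(vertices)
    if L <= 0.0:
        raise ValueError("outline has zero arc length")
    if closed:
        positions = np.arange(p) * (L / p)
    else:
        positions = np.arange(p) * (L / (p - 1))
    pts = points_at_arc_positions(vertices, positions)
    return SemilandmarkSet(species_id=species_id, points=pts)
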