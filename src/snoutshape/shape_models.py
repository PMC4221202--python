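"""Back-projection of ordination-axis positions into landmark space.

Each retained axis is modelled at five positions: the two observed score
extremes, the two medial interpolations (half-extremes), and zero.  A
position s on PC axis j maps to the configuration
reshape(mean_vector + s * eigenvector_j); a canonical-axis position is
first mapped back into PC space along the discriminant direction and then
through the eigenvectors.  The resulting five-shape series is drawn as a
"strobe" overlay, colour-graded by position.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "snoutshape"  # reproducible SVG ids
import matplotlib.pyplot as plt
import numpy as np

from .discriminant import CvaModel
from .ordination import PcaModel


@dataclass
class AxisModelSeries:
    axis_id: str
    positions: np.ndarray      # (5,) ordered
    model_shapes: np.ndarray   # (5, p, 2)


def _five_positions(scores_on_axis: np.ndarray) -> np.ndarray:
    s_min = float(np.min(scores_on_axis))
    s_max = float(np.max(scores_on_axis))
    return np.array([s_min, s_min / 2.0, 0.0, s_max / 2.0, s_max])


def model_pc_axis(
    pca: PcaModel, axis: int, scores: np.ndarray | None = None
) -> AxisModelSeries:
    """Five-shape model series along one PC axis (0-based index)."""
    if axis < 0 or axis >= pca.k:
        raise ValueError(f"axis {axis} out of range (model retains {pca.k})")
    scores_axis = (pca.scores if scores is None else np.asarray(scores))[..., axis]
    positions = _five_positions(np.ravel(scores_axis))
    p2 = pca.mean_vector.shape[0]
    shapes = np.empty((5, p2 // 2, 2))
    for i, s in enumerate(positions):
        vec = pca.mean_vector + s * pca.eigenvectors[:, axis]
        shapes[i] = vec.reshape(-1, 2)
    return AxisModelSeries(f"PC{axis + 1}", positions, shapes)


def cv_position_to_pc(cva: CvaModel, position: float | np.ndarray) -> np.ndarray:
    """Map canonical-axis positions back to PC-space offsets from the grand mean."""
    v = cva.discriminant_vector
    return np.atleast_1d(np.asarray(position, dtype=float))[:, None] * v / (v @ v)


def model_cv_axis(
    cva: CvaModel, pca: PcaModel, cv_scores: np.ndarray | None = None
) -> AxisModelSeries:
    """Five-shape model series along the canonical (discriminant) axis."""
    if cva.k > pca.k:
        raise ValueError("CVA uses more axes than the PCA model retains")
    positions = _five_positions(
        np.ravel(cva.cv_scores if cv_scores is None else cv_scores)
    )
    # offsets are taken about the consensus: canonical scores are centred
    # on the PC grand mean, which is the consensus when the CVA is fitted
    # on the PCA's own training scores
    pc_offsets = cv_position_to_pc(cva, positions)
    p2 = pca.mean_vector.shape[0]
    shapes = np.empty((5, p2 // 2, 2))
    for i in range(5):
        vec = pca.mean_vector + pca.eigenvectors[:, : cva.k] @ pc_offsets[i]
        shapes[i] = vec.reshape(-1, 2)
    return AxisModelSeries("CV1", positions, shapes)


def strobe_plot(series: AxisModelSeries, path) -> None:
    """Write an overlay ("strobe") plot of the model series as SVG/PNG.

    One large overlay panel, colour-graded from the negative to the
    positive axis extreme, plus one small panel per model shape.
    """
    cmap = plt.get_cmap("viridis")
    npos = len(series.positions)
    fig = plt.figure(figsize=(10, 4))
    gs = fig.add_gridspec(2, max(npos, 2), height_ratios=[2.2, 1])
    ax = fig.add_subplot(gs[0, :])
    span = np.ptp(series.positions) or 1.0
    for i, (pos, shape) in enumerate(zip(series.positions, series.model_shapes)):
        colour = cmap((pos - series.positions.min()) / span)
        ax.plot(shape[:, 0], shape[:, 1], color=colour, lw=1.4,
                label=f"{series.axis_id} = {pos:+.4f}")
    ax.set_aspect("equal")
    ax.legend(fontsize=6, loc="upper right")
    ax.set_title(f"Strobe plot: {series.axis_id} model series")
    for i, (pos, shape) in enumerate(zip(series.positions, series.model_shapes)):
        sub = fig.add_subplot(gs[1, i])
        sub.plot(shape[:, 0], shape[:, 1], color=cmap(i / (npos - 1)), lw=1.0)
        sub.set_aspect("equal")
        sub.set_xticks([])
        sub.set_yticks([])
        sub.set_title(f"{pos:+.3f}", fontsize=6)
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
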