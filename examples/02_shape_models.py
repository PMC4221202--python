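"""Back-project ordination axes into landmark space ("strobe" plots).

Fits the PCA and CVA on a simulated study, models each retained axis at
five positions (extremes, half-extremes, centre), and writes overlay
plots. The centre model is exactly the consensus shape.
"""

from pathlib import Path

import numpy as np

from snoutshape import (
    GroupedScores, OutlineGenConfig, cva_fit, generate_study, gpa,
    model_cv_axis, model_pc_axis, pca_fit, resample, strobe_plot,
)

study = generate_study(OutlineGenConfig(n_browser=20, n_grazer=20,
                                        n_unknown=0, seed=2))
aligned = gpa([resample(s.points, p=100, species_id=s.species_id)
               for s in study.coordinates])
pca = pca_fit(aligned, k=3)
labels = study.traits.loc[aligned.ids, "feeding_class"].to_numpy()
cva = cva_fit(GroupedScores(aligned.ids, pca.scores, labels))

out = Path("scratch/models")
out.mkdir(parents=True, exist_ok=True)
for axis in range(3):
    series = model_pc_axis(pca, axis)
    strobe_plot(series, out / f"{series.axis_id}_strobe.svg")
    print(f"{series.axis_id}: positions {np.round(series.positions, 3)} "
          f"({pca.variance_fraction[axis] * 100:.1f}% of variance)")
cv_series = model_cv_axis(cva, pca)
strobe_plot(cv_series, out / "CV1_strobe.svg")
print(f"CV1: positions {np.round(cv_series.positions, 3)}; "
      f"centre model == consensus: "
      f"{bool(np.array_equal(cv_series.model_shapes[2].reshape(-1), pca.mean_vector))}")
print(f"plots written to {out}/")

# Each strobe plot overlays the five modelled outlines along one axis,
# showing the blunt-to-pointed deformation the axis encodes.
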