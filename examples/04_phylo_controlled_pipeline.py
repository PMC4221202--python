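"""Raw versus phylogenetically controlled discriminant analysis.

Runs the pipeline twice on the same simulated study: once with ordinary
covariance PCA and once with phylogenetic PCA (GLS root mean and
tree-weighted evolutionary covariance), and compares the resulting
classification performance.
"""

from snoutshape import OutlineGenConfig, generate_study, run_study

study = generate_study(OutlineGenConfig(
    n_browser=30, n_grazer=30, n_unknown=20, seed=4))

raw = run_study(study.coordinates, study.traits, study.tree,
                replicates=500, seed=4, phylo=False, write_plots=False)
phylo = run_study(study.coordinates, study.traits, study.tree,
                  replicates=500, seed=4, phylo=True, write_plots=False)

for name, s in (("raw", raw), ("phylogenetic", phylo)):
    print(f"{name:>13}: phi = {s['phi']:8.2f}  "
          f"resubstitution = {s['pct_correct']:6.2f}%  "
          f"jackknife = {s['pct_correct_jackknife']:6.2f}%  "
          f"unknowns = {s['unknown_assignments']}")
print("PC1 signal (raw run):", raw["phylo_signal"]["PC1"])

# Similar accuracy in both runs indicates the guild separation is not an
# artefact of shared ancestry; the signal block reports K and lambda for
# the mass-residualised PC scores plus contrast correlations with mass.
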