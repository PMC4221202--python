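"""Simulate a two-guild study and classify snout profiles.

Builds a synthetic browser/grazer outline dataset, runs the full
pipeline (resample -> Procrustes -> PCA -> CVA -> randomized phi nulls
-> classification -> unknown projection), and prints the headline
statistics.
"""

from snoutshape import OutlineGenConfig, generate_study, run_study

study = generate_study(OutlineGenConfig(
    n_browser=34, n_grazer=34, n_unknown=57, seed=1))
summary = run_study(study.coordinates, study.traits, study.tree,
                    replicates=1000, seed=1, write_plots=False)

print(f"3 PC axes carry {summary['variance_pct_retained']:.2f}% of shape variance")
print(f"Wilks' Lambda = {summary['wilks_lambda']:.4f}, phi = {summary['phi']:.2f}")
print(f"p (chi2) = {summary['p_chi2']:.3g}; "
      f"p (Monte Carlo) = {summary['p_mc']}; p (bootstrap) = {summary['p_boot']}")
print(f"resubstitution accuracy = {summary['pct_correct']:.2f}%, "
      f"jackknife = {summary['pct_correct_jackknife']:.2f}%")
print(f"unknown assignments: {summary['unknown_assignments']}")

# phi far above every null replicate means the browser/grazer centroid
# separation cannot be explained by sampling error or dimensionality;
# the unknown split shows which guild each unclassified species resembles.
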