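"""Robustness of the reconstruction to taxon sampling and tree uncertainty.

Builds family sampling fractions for a synthetic specimen table, repeats
the stochastic-mapping summary on family-weighted 90/80/70% subsamples of
the species, and again over a pseudo-posterior set of perturbed trees.
"""

from bristlephylo import mk, sensitivity, synthdata

tree = synthdata.simulate_tree(120, seed=20, root_age_myr=1.0)
data, truth = synthdata.simulate_ecological_dataset(tree, seed=21,
                                                    n_families=12)
states, _ = synthdata.simulate_binary_trait(
    tree, mk.QMatrix.from_params("ER", 2, [0.8]), seed=22)

fractions = sensitivity.family_fractions(data, truth.extras["family_known"])
print(fractions.table.head().to_string(index=False))

reports = sensitivity.downsample_analysis(
    tree, states, data, fractions, targets=(1.0, 0.9, 0.8, 0.7),
    reps=50, maps_per_rep=4, seed=23, refit_q=False)

trees = synthdata.simulate_tree_posterior(tree, n=25, seed=24)
reports.append(sensitivity.tree_uncertainty_analysis(
    trees, states, n_trees=25, maps_per_tree=8, seed=25))

print()
print(sensitivity.reports_to_frame(reports).round(3).to_string(index=False))
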