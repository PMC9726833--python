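#!/usr/bin/env bash
# The full pipeline from the shell: generate a small synthetic study with
# the library, then run every subcommand on the resulting files.
set -euo pipefail
work=$(mktemp -d)

python - "$work" <<'PY'
import sys
from pathlib import Path
import pandas as pd
from bristlephylo import mk, synthdata

work = Path(sys.argv[1])
tree = synthdata.simulate_tree(60, seed=50)
(work / "tree.nwk").write_text(tree.to_newick())
trees = synthdata.simulate_tree_posterior(tree, n=10, seed=51)
(work / "trees.nwk").write_text("\n".join(t.to_newick() for t in trees))

q = mk.QMatrix.from_params("ER", 2, [0.02])
cols = {ch: synthdata.simulate_binary_trait(tree, q, seed=52 + i)[0]
        for i, ch in enumerate(("rictal", "lower_rictal", "narial",
                                "interramal"))}
eco, truth = synthdata.simulate_ecological_dataset(tree, seed=56,
                                                   n_families=6)
fam = eco.drop_duplicates("species").set_index("species")["family"]
species = sorted(tree.tip_labels)
pd.DataFrame({"species": species, "family": [fam[s] for s in species],
              **{c: [v[s] for s in species] for c, v in cols.items()}}
             ).to_csv(work / "traits.csv", index=False)
eco.to_csv(work / "specimens.csv", index=False)
pd.DataFrame([{"family": f, "known": k}
              for f, k in truth.extras["family_known"].items()]
             ).to_csv(work / "richness.csv", index=False)
PY

bristlephylo asr --tree "$work/tree.nwk" --traits "$work/traits.csv" \
    --nsim 200 --seed 1 --out "$work/asr"
bristlephylo signal --tree "$work/tree.nwk" --traits "$work/traits.csv" \
    --characters rictal,narial --out "$work/signal"
bristlephylo sensitivity --tree "$work/tree.nwk" --trees "$work/trees.nwk" \
    --traits "$work/traits.csv" --richness "$work/richness.csv" \
    --reps 20 --n-trees 5 --maps-per-tree 10 --out "$work/sens"
bristlephylo glmm --tree "$work/tree.nwk" --traits "$work/specimens.csv" \
    --response presence --iterations 2000 --burnin 400 --chains 2 \
    --out "$work/glmm"

echo "--- sensitivity table ---"
cat "$work/sens/sensitivity_table.csv"
echo "artifacts under $work"
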