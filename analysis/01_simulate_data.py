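#!/usr/bin/env python
"""Generate the synthetic study inputs: stand-in phylogeny + population table.

Writes results/data/tree.nwk, populations.csv and truth.json (the generating
parameters, for later comparison against what the analysis recovers).
"""

import json
from pathlib import Path

from hylocomp.phylo import write_newick
from hylocomp.simulate import SyntheticSpec, reference_tree, simulate_population_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tree = reference_tree()
    write_newick(tree, OUT / "tree.nwk")
    spec = SyntheticSpec(seed=SEED)
    table, truth = simulate_population_dataset(spec, tree)
    table.to_csv(OUT / "populations.csv", index=False)
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2, default=float))
    n_multi = (table.species.value_counts() >= 2).sum()
    print(f"tree: {tree.n_tips} tips (19 gibbon species + 2 outgroup), depth 20 my")
    print(f"table: {len(table)} populations over {table.species.nunique()} species; "
          f"{n_multi} species with >1 population")
    print(f"responses: HR {table.HR.min():.2f}-{table.HR.max():.1f} km2, "
          f"GS {table.GS.min():.1f}-{table.GS.max():.1f}, "
          f"MS {({k: int(v) for k, v in table.MS.value_counts().items()})}")
    print(f"wrote {OUT}/tree.nwk, populations.csv, truth.json")


if __name__ == "__main__":
    main()
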