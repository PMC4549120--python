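#!/usr/bin/env python
"""Predictive kinship mixed models with AICc multimodel inference.

Per response (HR, GS): 13 single-predictor screens (11 predictors + 2
co-responses), a global model of the significant terms, all-subsets AICc
ranking, the Delta-AICc < 7 confidence set, model-averaged coefficients
with relative importance, and the variance partition of the best model.
The binary mating system gets an exploratory all-candidate global model.
Writes screen_/models_/averaged_ CSVs under results/.
"""

import warnings
from pathlib import Path

import pandas as pd

from hylocomp import preprocess
from hylocomp.kinship import fit_kinship_lmm, variance_partition
from hylocomp.model_selection import (
    averaged_to_frame,
    fit_all_subsets,
    model_average,
    single_predictor_screen,
)
from hylocomp.phylo import population_kinship, read_newick, vcv_from_tree

ROOT = Path(__file__).resolve().parents[1] / "results"
RESPONSES = ("HR", "GS", "MS01")


def main() -> None:
    tree = read_newick(ROOT / "data" / "tree.nwk")
    raw = pd.read_csv(ROOT / "data" / "populations.csv")
    table, _ = preprocess.transform_variables(raw)
    table = preprocess.code_mating_system(table)
    cov = vcv_from_tree(tree)
    kin = population_kinship(cov, dict(zip(table.population_id, table.species)))
    predictors = list(preprocess.PREDICTOR_COLUMNS)

    warnings.filterwarnings("ignore")
    for response in RESPONSES:
        others = [r for r in RESPONSES if r != response]
        significant, report = single_predictor_screen(
            table, response, predictors, others, kin
        )
        report.to_csv(ROOT / f"screen_{response}.csv", index=False)
        print(f"\n{response}: {len(report)} single-predictor models, "
              f"significant at 0.05: {significant or 'none'}")

        if response == "MS01":
            gfit = fit_kinship_lmm(table, response, predictors + others, kin)
            gfit.to_frame().to_csv(ROOT / "global_MS01.csv", index=False)
            sig = gfit.to_frame().query("p_value < 0.05 and coefficient != '(Intercept)'")
            print(f"  exploratory global model (13 candidates): "
                  f"{len(sig)} significant terms")
            continue
        if not significant:
            print("  no global model assembled")
            continue

        mset = fit_all_subsets(table, response, significant, kin)
        mset.to_frame().to_csv(ROOT / f"models_{response}.csv", index=False)
        avg = averaged_to_frame(model_average(mset))
        avg.to_csv(ROOT / f"averaged_{response}.csv", index=False)
        best = mset.records[0]
        vp = variance_partition(best.fit)
        print(f"  {len(mset.records)} candidate models; "
              f"{len(mset.confidence_set)} in the Delta-AICc<7 set "
              f"(cumulative weight {mset.cumulative_weight:.3f})")
        print(f"  best model: {' + '.join(best.predictor_subset)} "
              f"(AICc {best.AICc:.2f})")
        if vp.fraction_phylo is not None:
            print(f"  random-effect variance: {vp.fraction_phylo:.1f}% phylogenetic, "
                  f"{vp.fraction_species:.1f}% within-species "
                  f"(residual {vp.sigma2_resid:.4f})")


if __name__ == "__main__":
    main()
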