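"""End-to-end orchestration: signal -> outliers -> screen -> selection -> report.

`run_full_analysis` drives the whole procedure for a tree + population table
pair, writing per-stage CSV/JSON artifacts and a markdown report into the
output directory, deterministically for a given seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess
from ._version import __version__
from .kinship import fit_kinship_lmm, variance_partition
from .model_selection import (
    averaged_to_frame,
    fit_all_subsets,
    model_average,
    single_predictor_screen,
)
from .outliers import observed_vs_expected_tests
from .phylo import read_newick, population_kinship, vcv_from_tree
from .signal import classify_d, estimate_D, fit_lambda

__all__ = ["AnalysisConfig", "run_full_analysis", "render_report"]

#: traits tested for phylogenetic signal / outliers at the species level
SIGNAL_TRAITS = ("HR", "GS", "body_mass")


@dataclass
class AnalysisConfig:
    tree_path: str
    table_path: str
    output_dir: str
    responses: tuple[str, ...] = ("HR", "GS", "MS01")
    predictors: tuple[str, ...] = preprocess.PREDICTOR_COLUMNS
    alpha: float = 0.05
    delta_threshold: float = 7.0
    n_sim_d: int = 1000
    seed: int = 1
    arcsine_variant: str = "asin-sqrt"
    refit_loo_per_fold: bool = False
    #: optional alternative values for a focal population's HR (the analysis
    #: re-runs once per variant), keyed by population_id
    hr_variants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.delta_threshold <= 0 or self.n_sim_d <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _species_means(table: pd.DataFrame, trait: str, tip_order: list[str]) -> np.ndarray:
    means = table.groupby("species")[trait].mean()
    missing = [sp for sp in tip_order if sp not in means.index]
    if missing:
        raise ValueError(f"no data for tree species: {missing}")
    return means.reindex(tip_order).to_numpy(float)


def _predominant_state(table: pd.DataFrame, tip_order: list[str]) -> np.ndarray:
    mode = table.groupby("species")["MS01"].agg(lambda s: int(round(s.mean())))
    return mode.reindex(tip_order).to_numpy(int)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the complete comparative analysis; returns the report bundle.

    Stage order is fixed: preprocessing, phylogenetic signal (lambda per
    continuous trait, D for mating system), species outlier tables
    (continuous traits only), then per response the single-predictor screen,
    all-subsets AICc ranking, model averaging and variance partitioning.
    Every artifact is also written under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": asdict(config), "version": __version__}

    stage = "input"
    try:
        tree = read_newick(config.tree_path)
        raw = pd.read_csv(config.table_path)
        if config.hr_variants:
            for pop, value in config.hr_variants.items():
                raw.loc[raw["population_id"] == pop, "HR"] = value
        preprocess.validate_population_table(raw)

        stage = "preprocess"
        table, tlog = preprocess.transform_variables(
            raw, arcsine_variant=config.arcsine_variant
        )
        table = preprocess.code_mating_system(table)
        tlog.to_frame().to_csv(out / "transform_log.csv", index=False)

        cov = vcv_from_tree(tree)
        kin = population_kinship(
            cov, dict(zip(table["population_id"], table["species"]))
        )

        stage = "signal"
        rng = np.random.SeedSequence(config.seed)
        d_seed = int(rng.generate_state(1)[0] % (2**31))
        lambda_rows = []
        lambda_fits = {}
        traits = [t for t in SIGNAL_TRAITS if t in table.columns]
        for trait in traits:
            y = _species_means(table, trait, cov.tip_order)
            fit = fit_lambda(y, cov)
            lambda_fits[trait] = (y, fit)
            lambda_rows.extend(
                [
                    {"variable": trait, "ml_lambda": fit.lambda_ml,
                     "test": "lambda = 0", "chi2": fit.chi2_vs_0,
                     "p_value": fit.p_vs_0},
                    {"variable": trait, "ml_lambda": fit.lambda_ml,
                     "test": "lambda = 1", "chi2": fit.chi2_vs_1,
                     "p_value": fit.p_vs_1},
                ]
            )
        lambda_table = pd.DataFrame(lambda_rows)
        lambda_table.to_csv(out / "signal_lambda.csv", index=False)
        bundle["signal_lambda"] = lambda_table

        ms_states = _predominant_state(table, cov.tip_order)
        d_res = estimate_D(tree, ms_states, n_sim=config.n_sim_d, seed=d_seed)
        d_payload = {
            "D": d_res.D, "sum_d_obs": d_res.sum_d_obs,
            "mean_sum_d_random": d_res.mean_sum_d_random,
            "mean_sum_d_brownian": d_res.mean_sum_d_brownian,
            "p_random": d_res.p_random, "p_brownian": d_res.p_brownian,
            "n_sim": d_res.n_sim, "seed": d_res.seed,
            "interpretation": classify_d(d_res, alpha=config.alpha),
        }
        (out / "signal_D.json").write_text(json.dumps(d_payload, indent=2))
        bundle["signal_D"] = d_payload

        stage = "outliers"
        outlier_tables = {}
        for trait in traits:
            y, fit = lambda_fits[trait]
            tab = observed_vs_expected_tests(
                y, cov, fit, alpha=config.alpha,
                refit_per_fold=config.refit_loo_per_fold,
            )
            tab.to_csv(out / f"outliers_{trait}.csv", index=False)
            outlier_tables[trait] = tab
        bundle["outliers"] = outlier_tables

        stage = "screen"
        screens = {}
        selections = {}
        averaged = {}
        variance = {}
        for response in config.responses:
            others = [r for r in config.responses if r != response]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                significant, report = single_predictor_screen(
                    table, response, list(config.predictors), others, kin,
                    alpha=config.alpha,
                )
            report.to_csv(out / f"screen_{response}.csv", index=False)
            screens[response] = {"significant": significant, "report": report}

            if response == "MS01":
                # exploratory global model: every candidate at once
                global_predictors = list(config.predictors) + others
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gfit = fit_kinship_lmm(table, response, global_predictors, kin)
                gframe = gfit.to_frame()
                gframe.to_csv(out / "global_MS01.csv", index=False)
                selections[response] = {"global_model": gframe,
                                        "predictors": global_predictors}
                variance[response] = asdict(variance_partition(gfit))
                continue

            if not significant:
                selections[response] = {"note": "no significant single predictors"}
                continue

            stage = f"selection[{response}]"
            mset = fit_all_subsets(
                table, response, significant, kin,
                delta_threshold=config.delta_threshold,
            )
            mset.to_frame().to_csv(out / f"models_{response}.csv", index=False)
            avg = averaged_to_frame(model_average(mset))
            avg.to_csv(out / f"averaged_{response}.csv", index=False)
            best = mset.records[0]
            variance[response] = asdict(variance_partition(best.fit))
            selections[response] = {
                "model_set": mset,
                "best": best.fit.to_frame(),
                "n_confidence": len(mset.confidence_set),
                "cumulative_weight": mset.cumulative_weight,
            }
            averaged[response] = avg
        bundle["screens"] = screens
        bundle["selections"] = selections
        bundle["averaged"] = averaged
        bundle["variance_components"] = variance
        (out / "variance_components.json").write_text(
            json.dumps(variance, indent=2, default=float)
        )

        stage = "report"
        manifest = {
            "config": asdict(config),
            "seed": config.seed,
            "version": __version__,
            "stages": ["input", "preprocess", "signal", "outliers", "screen",
                       "selection", "report"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        report_md = render_report(bundle)
        (out / "report.md").write_text(report_md)
        bundle["report"] = report_md
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc
    return bundle


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    def fmt(v):
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    rows = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *rows])


def render_report(bundle: dict) -> str:
    """Human-readable markdown summary of a report bundle."""
    missing = [
        key for key in ("signal_lambda", "signal_D", "outliers", "selections")
        if key not in bundle
    ]
    if missing:
        return "# Analysis report (incomplete)\n\nMissing artifacts: " + ", ".join(missing)

    lines = ["# Comparative analysis report", ""]
    lam = bundle["signal_lambda"].copy()
    lam = lam.rename(
        columns={"variable": "Variable", "ml_lambda": "ML-lambda",
                 "test": "Test", "chi2": "chi2", "p_value": "P-value"}
    )
    lam["significant"] = lam["P-value"] < bundle["config"]["alpha"]
    lines += ["## Phylogenetic signal (continuous traits)", "", _md_table(lam), ""]

    d = bundle["signal_D"]
    lines += [
        "## Phylogenetic signal (binary mating system)",
        "",
        f"D = {d['D']:.3f} (sum of sister differences {d['sum_d_obs']:.3f}; "
        f"random-null mean {d['mean_sum_d_random']:.3f}, Brownian-null mean "
        f"{d['mean_sum_d_brownian']:.3f})",
        f"P vs random structure = {d['p_random']:.3g}; "
        f"P vs Brownian structure = {d['p_brownian']:.3g} "
        f"(n_sim = {d['n_sim']})",
        f"Interpretation: {d['interpretation']}",
        "",
    ]

    for trait, tab in bundle["outliers"].items():
        show = tab.copy()
        show["significant"] = show["flagged"]
        lines += [f"## Observed vs expected species values: {trait}", "",
                  _md_table(show.drop(columns=["flagged"])), ""]

    for response, sel in bundle["selections"].items():
        lines.append(f"## Predictive models: {response}")
        lines.append("")
        if "note" in sel:
            lines += [sel["note"], ""]
            continue
        if "global_model" in sel:
            lines += ["Exploratory global model (all candidates):", "",
                      _md_table(sel["global_model"]), ""]
            continue
        mset = sel["model_set"]
        frame = mset.to_frame()
        if not len(mset.confidence_set):
            lines += ["No models under the Delta-AICc threshold.", ""]
        lines += [
            f"{sel['n_confidence']} models with Delta-AICc < "
            f"{bundle['config']['delta_threshold']} "
            f"(cumulative weight {sel['cumulative_weight']:.3f})",
            "", _md_table(frame.head(15)), "",
            "Model-averaged coefficients:", "",
            _md_table(bundle["averaged"][response]), "",
        ]
    return "\n".join(lines)
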