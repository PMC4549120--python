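"""Information-theoretic multimodel inference over kinship mixed models.

Single-predictor screening, all-subsets candidate generation from a global
model, AICc ranking with Akaike weights, a Delta-AICc confidence set, and
conditional model averaging with relative importance (RI) per parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import KinshipLMMFit, fit_kinship_lmm
from .phylo import KinshipMatrix

__all__ = [
    "ModelRecord",
    "ModelSet",
    "AveragedCoefficient",
    "single_predictor_screen",
    "enumerate_candidate_models",
    "aicc",
    "rank_and_weigh",
    "model_average",
    "fit_all_subsets",
]


@dataclass
class ModelRecord:
    predictor_subset: tuple[str, ...]
    fit: KinshipLMMFit | None
    k: int
    lnL: float
    AICc: float
    delta_AICc: float = np.nan
    akaike_weight: float = np.nan


@dataclass
class ModelSet:
    response: str
    records: list[ModelRecord]
    confidence_set: list[ModelRecord]
    cumulative_weight: float
    delta_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "predictors": "+".join(r.predictor_subset),
                    "k": r.k,
                    "lnL": r.lnL,
                    "AICc": r.AICc,
                    "delta_AICc": r.delta_AICc,
                    "akaike_weight": r.akaike_weight,
                    "in_confidence_set": r.delta_AICc < self.delta_threshold,
                }
                for r in self.records
            ]
        )


@dataclass
class AveragedCoefficient:
    name: str
    averaged_beta: float
    unconditional_se: float
    z_value: float
    p_value: float
    relative_importance: float


def single_predictor_screen(
    table: pd.DataFrame,
    response: str,
    candidate_predictors: list[str],
    co_responses: list[str],
    kinship: KinshipMatrix,
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[list[str], pd.DataFrame]:
    """One single-predictor kinship LMM per candidate.

    Candidates are the predictor roster plus the co-response variables (the
    responses not currently modelled).  Returns the names whose slope is
    significant at ``alpha``, plus the full per-candidate report; a fit
    failure for one candidate is recorded and does not abort the screen.
    """
    candidates = list(candidate_predictors) + list(co_responses)
    overlap = set(candidates) & {response}
    if overlap:
        raise ValueError(f"response cannot be its own predictor: {overlap}")
    rows = []
    significant: list[str] = []
    for cand in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_kinship_lmm(table, response, [cand], kinship, **fit_kwargs)
            c = fit.coefficient(cand)
            passed = bool(c.p_value < alpha and fit.converged)
            rows.append(
                {"candidate": cand, "estimate": c.beta, "se": c.se,
                 "z_value": c.z_value, "p_value": c.p_value,
                 "significant": passed, "error": ""}
            )
            if passed:
                significant.append(cand)
        except Exception as exc:  # noqa: BLE001 - screen must not abort
            rows.append(
                {"candidate": cand, "estimate": np.nan, "se": np.nan,
                 "z_value": np.nan, "p_value": np.nan,
                 "significant": False, "error": str(exc)}
            )
    return significant, pd.DataFrame(rows)


def enumerate_candidate_models(global_predictors: list[str]) -> list[tuple[str, ...]]:
    """All non-empty predictor subsets of the global model.

    The intercept is implicit in every model; the intercept-only model is
    excluded.  Order is deterministic: by subset size, then by position in
    the supplied roster.
    """
    preds = list(global_predictors)
    if not preds:
        raise ValueError("global model must contain at least one predictor")
    if len(preds) > 12:
        raise ValueError("all-subsets enumeration limited to 12 predictors")
    out: list[tuple[str, ...]] = []
    for size in range(1, len(preds) + 1):
        out.extend(combinations(preds, size))
    return out


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (needs n > k + 1)")
    aic = -2.0 * lnL + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def rank_and_weigh(
    records: list[ModelRecord],
    response: str = "",
    delta_threshold: float = 7.0,
) -> ModelSet:
    """Delta-AICc, Akaike weights and the confidence set for a model list.

    Ties in AICc are broken towards fewer predictors, then lexicographic
    subset order (stable sort).
    """
    if not records:
        raise ValueError("no models to rank")
    ordered = sorted(
        records, key=lambda r: (r.AICc, len(r.predictor_subset), r.predictor_subset)
    )
    best = ordered[0].AICc
    deltas = np.array([r.AICc - best for r in ordered])
    w = np.exp(-deltas / 2.0)
    w /= w.sum()
    for rec, d, wi in zip(ordered, deltas, w):
        rec.delta_AICc = float(d)
        rec.akaike_weight = float(wi)
    conf = [r for r in ordered if r.delta_AICc < delta_threshold]
    return ModelSet(
        response=response,
        records=ordered,
        confidence_set=conf,
        cumulative_weight=float(sum(r.akaike_weight for r in conf)),
        delta_threshold=delta_threshold,
    )


def model_average(model_set: ModelSet) -> list[AveragedCoefficient]:
    """Conditional model averaging over the confidence set.

    Weights are renormalised within the confidence set.  For each parameter,
    the averaged estimate is the weight-normalised mean over the models that
    contain it; the unconditional SE follows the revised multimodel-variance
    formula sqrt(sum_i w~_i (se_i^2 + (beta_i - beta_bar)^2)); RI is the sum
    of (set-renormalised) weights of the containing models.
    """
    conf = model_set.confidence_set
    if not conf:
        raise ValueError("confidence set is empty; nothing to average")
    wsum = sum(r.akaike_weight for r in conf)
    weights = {id(r): r.akaike_weight / wsum for r in conf}

    names: list[str] = []
    for rec in conf:
        for c in rec.fit.coefficients:
            if c.name not in names:
                names.append(c.name)

    out: list[AveragedCoefficient] = []
    for name in names:
        members = [
            (weights[id(rec)], rec.fit.coefficient(name))
            for rec in conf
            if any(c.name == name for c in rec.fit.coefficients)
        ]
        ri = sum(w for w, _ in members)
        wnorm = [(w / ri, c) for w, c in members]
        beta_bar = sum(w * c.beta for w, c in wnorm)
        var = sum(w * (c.se**2 + (c.beta - beta_bar) ** 2) for w, c in wnorm)
        se = float(np.sqrt(var))
        z = beta_bar / se if se > 0 else np.inf
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append(
            AveragedCoefficient(
                name=name,
                averaged_beta=float(beta_bar),
                unconditional_se=se,
                z_value=float(z),
                p_value=p,
                relative_importance=float(min(ri, 1.0)),
            )
        )
    return out


def averaged_to_frame(averaged: list[AveragedCoefficient]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"coefficient": a.name, "averaged_estimate": a.averaged_beta,
             "se": a.unconditional_se, "z_value": a.z_value,
             "p_value": a.p_value,
             "RI": np.nan if a.name == "(Intercept)" else a.relative_importance}
            for a in averaged
        ]
    )


def fit_all_subsets(
    table: pd.DataFrame,
    response: str,
    global_predictors: list[str],
    kinship: KinshipMatrix,
    delta_threshold: float = 7.0,
    **fit_kwargs,
) -> ModelSet:
    """Fit every candidate subset of the global model and rank by AICc.

    k counts the fixed effects (including intercept) plus the three
    variance parameters.  Warns when the global model exceeds the
    5-observations-per-predictor guideline but never hard-fails.
    """
    n = len(table)
    if len(global_predictors) > n / 5:
        warnings.warn(
            f"global model has {len(global_predictors)} predictors for {n} "
            "observations (> n/5); candidate fits are exploratory",
            stacklevel=2,
        )
    records = []
    for subset in enumerate_candidate_models(global_predictors):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_kinship_lmm(table, response, list(subset), kinship, **fit_kwargs)
        k = fit.n_params
        records.append(
            ModelRecord(
                predictor_subset=subset,
                fit=fit,
                k=k,
                lnL=fit.lnL,
                AICc=aicc(fit.lnL, k, n),
            )
        )
    return rank_and_weigh(records, response=response, delta_threshold=delta_threshold)
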