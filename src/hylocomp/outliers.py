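"""Observed-versus-expected species trait tests under the fitted PGLS model.

For each species in turn, the trait value expected from all *other* species
is the conditional mean of the fitted multivariate-normal model
(mu + V_f,- V_--^-1 (y_- - mu)), with the conditional standard deviation as
its prediction error.  Observed minus expected, scaled by that error, is
referred to a Student's t distribution and Bonferroni-corrected across the
species tested — the procedure that asks whether any species' trait is
anomalous given the phylogenetic signal alone.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .phylo import PhyloCov, lambda_transform
from .signal import LambdaFit, fit_lambda

__all__ = ["loo_expected_value", "observed_vs_expected_tests"]


def _model_cov(cov: PhyloCov, fit: LambdaFit) -> np.ndarray:
    return fit.sigma2 * lambda_transform(cov, fit.lambda_ml).C


def loo_expected_value(
    y: np.ndarray,
    cov: PhyloCov,
    fit: LambdaFit,
    focal: int,
    include_mean_uncertainty: bool = False,
) -> tuple[float, float]:
    """Conditional expectation and prediction SE for one left-out species.

    ``include_mean_uncertainty`` adds the GLS-mean estimation variance to
    the prediction variance; the default reports the pure conditional
    (partitioned-Gaussian) standard deviation.
    """
    y = np.asarray(y, dtype=float)
    n = len(cov.tip_order)
    if n < 4:
        raise ValueError("need at least 4 species for leave-one-out prediction")
    V = _model_cov(cov, fit)
    rest = [i for i in range(n) if i != focal]
    Vrr = V[np.ix_(rest, rest)]
    vfr = V[focal, rest]
    try:
        cho = linalg.cho_factor(Vrr, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular leave-one-out covariance") from exc
    one = np.ones(n - 1)
    y_rest = y[rest]
    sol = linalg.cho_solve(cho, np.column_stack([one, y_rest, vfr]), check_finite=False)
    vi1, viy, vivf = sol.T
    mu = (one @ viy) / (one @ vi1)
    expected = mu + vfr @ linalg.cho_solve(cho, y_rest - mu, check_finite=False)
    var = V[focal, focal] - vfr @ vivf
    if include_mean_uncertainty:
        w = 1.0 - vfr @ vi1
        var = var + w * w / (one @ vi1)
    var = max(var, 0.0)
    return float(expected), float(np.sqrt(var))


def observed_vs_expected_tests(
    y: np.ndarray,
    cov: PhyloCov,
    fit: LambdaFit | None = None,
    alpha: float = 0.05,
    refit_per_fold: bool = False,
    include_mean_uncertainty: bool = False,
) -> pd.DataFrame:
    """Per-species observed-vs-expected t-tests with Bonferroni correction.

    ``t = (observed - expected) / prediction_se`` on ``n - 2`` degrees of
    freedom (one mean and one variance estimated); the per-test threshold is
    ``alpha / n`` over the ``n`` species tested.  With ``refit_per_fold``
    the lambda/sigma2 fit is re-estimated on each leave-one-out subset
    (externally studentised prediction), so the focal value cannot inflate
    the variance against which it is judged.
    """
    y = np.asarray(y, dtype=float)
    n = len(cov.tip_order)
    if fit is None and not refit_per_fold:
        fit = fit_lambda(y, cov)
    df = n - 2
    threshold = alpha / n
    rows = []
    for focal in range(n):
        if refit_per_fold:
            rest = [i for i in range(n) if i != focal]
            fold_fit = fit_lambda(y[rest], cov.submatrix(rest))
            # classical external studentisation uses the unbiased variance
            # (the fold's ML estimate divides by m rather than m - 1)
            m = n - 1
            fold_fit = replace(fold_fit, sigma2=fold_fit.sigma2 * m / (m - 1))
            expected, se = loo_expected_value(
                y, cov, fold_fit, focal,
                include_mean_uncertainty=include_mean_uncertainty,
            )
        else:
            expected, se = loo_expected_value(
                y, cov, fit, focal,
                include_mean_uncertainty=include_mean_uncertainty,
            )
        t = (y[focal] - expected) / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append(
            {
                "species": cov.tip_order[focal],
                "observed": float(y[focal]),
                "expected": expected,
                "prediction_se": se,
                "t_statistic": float(t),
                "df": df,
                "p_value": p,
                "p_threshold_adjusted": threshold,
                "flagged": bool(p < threshold),
            }
        )
    return pd.DataFrame(rows)
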