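"""Linear mixed models with phylogenetic kinship covariance.

The model for a population-level response is

    y = X beta + u_phylo + u_species + eps,
    cov(y) = s2_phylo * A + s2_species * Z Z' + s2_resid * I,

where ``A`` is the population-expanded phylogenetic correlation matrix and
``Z`` maps populations to species.  Fitting is by maximum likelihood with
the two variance ratios optimised on the log scale (multi-start
Nelder-Mead) and beta / the residual scale profiled out in closed form.
Wald z statistics with a normal reference are reported per coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import KinshipMatrix

__all__ = [
    "CoefficientEstimate",
    "VarianceComponents",
    "KinshipLMMFit",
    "ConvergenceError",
    "fit_kinship_lmm",
    "variance_partition",
]

_LOG_GAMMA_BOUND = 16.0  # variance ratios confined to e^(+-16)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CoefficientEstimate:
    name: str
    beta: float
    se: float
    z_value: float
    p_value: float


@dataclass
class VarianceComponents:
    sigma2_phylo: float
    sigma2_species: float
    sigma2_resid: float
    fraction_phylo: float | None
    fraction_species: float | None

    @property
    def total_random(self) -> float:
        return self.sigma2_phylo + self.sigma2_species


@dataclass
class KinshipLMMFit:
    response: str
    predictors: list[str]
    coefficients: list[CoefficientEstimate]
    variance: VarianceComponents
    lnL: float
    n_obs: int
    n_params: int
    converged: bool
    _gls: dict = field(default_factory=dict, repr=False)

    def coefficient(self, name: str) -> CoefficientEstimate:
        for c in self.coefficients:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"coefficient": c.name, "estimate": c.beta, "se": c.se,
                 "z_value": c.z_value, "p_value": c.p_value}
                for c in self.coefficients
            ]
        )


def _align_kinship(table: pd.DataFrame, kinship: KinshipMatrix) -> np.ndarray:
    pops = list(table["population_id"])
    missing = [p for p in pops if p not in kinship.species_of]
    if missing:
        raise KeyError(f"populations absent from kinship matrix: {missing}")
    idx = [kinship.population_order.index(p) for p in pops]
    return kinship.A[np.ix_(idx, idx)]


def _profile_neg_lnl(
    log_g: np.ndarray,
    A: np.ndarray,
    S: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
) -> float:
    g1, g2 = np.exp(np.clip(log_g, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND))
    n = len(y)
    V0 = g1 * A + g2 * S
    V0[np.diag_indices_from(V0)] += 1.0
    try:
        cho = linalg.cho_factor(V0, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf
    sol = linalg.cho_solve(cho, np.column_stack([X, y]), check_finite=False)
    ViX, Viy = sol[:, :-1], sol[:, -1]
    XtViX = X.T @ ViX
    try:
        beta = linalg.solve(XtViX, X.T @ Viy, assume_a="pos")
    except linalg.LinAlgError:
        return np.inf
    r = y - X @ beta
    q = r @ linalg.cho_solve(cho, r, check_finite=False)
    if q <= 0:
        return np.inf
    s2 = q / n
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def fit_kinship_lmm(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    kinship: KinshipMatrix,
    fix_gamma: tuple[float, float] | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> KinshipLMMFit:
    """ML fit of the phylogenetic kinship mixed model.

    Parameters
    ----------
    table
        Transformed population table with ``population_id``, ``species``,
        the response and predictor columns.
    fix_gamma
        Optional fixed variance ratios ``(s2_phylo/s2_resid,
        s2_species/s2_resid)``; ``(0, 0)`` collapses the model to OLS.
    """
    y = table[response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"response {response!r} contains non-finite values")
    n = len(y)
    X = np.column_stack(
        [np.ones(n)] + [table[p].to_numpy(float) for p in predictors]
    )
    names = ["(Intercept)"] + list(predictors)
    if n < 5 * X.shape[1]:
        warnings.warn(
            f"only {n} observations for {X.shape[1]} fixed-effect parameters "
            "(< 5 per parameter); treat the fit as exploratory",
            stacklevel=2,
        )
    A = _align_kinship(table, kinship)
    sp = pd.Categorical(table["species"]).codes
    S = (sp[:, None] == sp[None, :]).astype(float)

    if fix_gamma is not None:
        g = np.array(fix_gamma, dtype=float)
        if np.any(g < 0):
            raise ValueError("variance ratios must be >= 0")
        log_g = np.log(np.maximum(g, np.exp(-_LOG_GAMMA_BOUND)))
        nll = _profile_neg_lnl(log_g, A, S, X, y)
        best_g = np.exp(np.clip(log_g, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND))
        if np.any(g == 0):
            best_g = np.where(g == 0, 0.0, best_g)
            V0 = best_g[0] * A + best_g[1] * S + np.eye(n)
            nll = _neg_lnl_at(V0, X, y)
        converged = np.isfinite(nll)
    else:
        rng = np.random.default_rng(seed)
        starts = [np.array([0.0, 0.0]), np.array([2.0, -2.0]), np.array([-2.0, 2.0])]
        while len(starts) < n_restarts:
            starts.append(rng.uniform(-4, 4, size=2))
        best = None
        converged = False
        for s0 in starts[: max(n_restarts, 1)]:
            res = optimize.minimize(
                _profile_neg_lnl,
                s0,
                args=(A, S, X, y),
                method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 600},
            )
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("kinship LMM likelihood could not be evaluated")
        nll = float(best.fun)
        best_g = np.exp(np.clip(best.x, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND))
        # ratios at the numerical floor are genuinely zero components
        best_g = np.where(best_g <= np.exp(-_LOG_GAMMA_BOUND) * 1.01, 0.0, best_g)

    V0 = best_g[0] * A + best_g[1] * S + np.eye(n)
    cho = linalg.cho_factor(V0, lower=True, check_finite=False)
    sol = linalg.cho_solve(cho, np.column_stack([X, y]), check_finite=False)
    ViX, Viy = sol[:, :-1], sol[:, -1]
    XtViX = X.T @ ViX
    beta = linalg.solve(XtViX, X.T @ Viy, assume_a="pos")
    r = y - X @ beta
    s2_resid = float(r @ linalg.cho_solve(cho, r, check_finite=False) / n)
    cov_beta = s2_resid * linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    coeffs = [
        CoefficientEstimate(nm, float(b), float(s), float(zz), float(pp))
        for nm, b, s, zz, pp in zip(names, beta, se, z, p)
    ]
    s2_phylo = float(best_g[0] * s2_resid)
    s2_species = float(best_g[1] * s2_resid)
    total = s2_phylo + s2_species
    if total > 0:
        frac_p = 100.0 * s2_phylo / total
        frac_s = 100.0 * s2_species / total
    else:
        frac_p = frac_s = None
    variance = VarianceComponents(s2_phylo, s2_species, s2_resid, frac_p, frac_s)
    lnL = float(-nll)
    return KinshipLMMFit(
        response=response,
        predictors=list(predictors),
        coefficients=coeffs,
        variance=variance,
        lnL=lnL,
        n_obs=n,
        n_params=len(coeffs) + 3,
        converged=bool(converged),
        _gls={"gamma": tuple(best_g), "cov_beta": cov_beta},
    )


def _neg_lnl_at(V0: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    cho = linalg.cho_factor(V0, lower=True, check_finite=False)
    sol = linalg.cho_solve(cho, np.column_stack([X, y]), check_finite=False)
    ViX, Viy = sol[:, :-1], sol[:, -1]
    beta = linalg.solve(X.T @ ViX, X.T @ Viy, assume_a="pos")
    r = y - X @ beta
    s2 = r @ linalg.cho_solve(cho, r, check_finite=False) / n
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def variance_partition(fit: KinshipLMMFit) -> VarianceComponents:
    """Percent split of the random-effect variance (phylo vs species).

    The residual component is reported alongside but excluded from the
    percentages; when both random components are zero the fractions are
    not applicable (None).
    """
    if not fit.converged:
        raise ConvergenceError("variance partition requires a converged fit")
    v = fit.variance
    total = v.sigma2_phylo + v.sigma2_species
    if total <= 0:
        return VarianceComponents(
            v.sigma2_phylo, v.sigma2_species, v.sigma2_resid, None, None
        )
    return VarianceComponents(
        v.sigma2_phylo,
        v.sigma2_species,
        v.sigma2_resid,
        100.0 * v.sigma2_phylo / total,
        100.0 * v.sigma2_species / total,
    )
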