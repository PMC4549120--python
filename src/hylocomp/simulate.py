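"""Synthetic data generation with known ground truth.

Everything the analysis consumes — trees, species traits, binary characters,
and multi-population datasets — can be generated here under known parameter
values, so each pipeline stage is testable without any external download.
Trait generators draw from the lambda-scaled Brownian model; binary traits
use the threshold (liability) model; population responses are fixed effects
plus phylogenetic, species-level and residual variance components.

The fixture tree :func:`reference_tree` is a synthetic stand-in for the
study system (19 gibbon species in four genera plus a two-species orang-utan
outgroup) with invented node ages; it is NOT the deposited study tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .phylo import PhyloTree, PhyloCov, KinshipMatrix, vcv_from_tree, lambda_transform

__all__ = [
    "SyntheticSpec",
    "reference_tree",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_binary_threshold",
    "simulate_lmm_response",
    "simulate_regression_table",
    "simulate_population_dataset",
    "count_cherries",
]

# Synthetic stand-in phylogeny: real 2015 gibbon taxonomy (genus sizes
# Hoolock 2 / Hylobates 9 / Symphalangus 1 / Nomascus 7) plus Pongo
# outgroup, with invented ultrametric node ages in my (depth 20).
_REFERENCE_NEWICK = (
    "((Pongo_abelii:5.0,Pongo_pygmaeus:5.0):15.0,"
    "((((Nomascus_hainanus:2.0,Nomascus_nasutus:2.0):2.0,Nomascus_concolor:4.0):3.0,"
    "((Nomascus_leucogenys:2.5,Nomascus_siki:2.5):1.5,"
    "(Nomascus_annamensis:0.7,Nomascus_gabriellae:0.7):3.3):3.0):1.0,"
    "(Symphalangus_syndactylus:7.0,"
    "((Hoolock_hoolock:2.0,Hoolock_leuconedys:2.0):4.5,"
    "((Hylobates_moloch:3.0,Hylobates_klossii:3.0):1.0,"
    "(Hylobates_pileatus:3.5,(Hylobates_lar:3.0,(Hylobates_agilis:2.5,"
    "(Hylobates_albibarbis:2.0,(Hylobates_muelleri:1.0,"
    "(Hylobates_abbotti:0.5,Hylobates_funereus:0.5):0.5):1.0):0.5):0.5):0.5):0.5)"
    ":2.5):0.5):1.0):12.0);"
)

OUTGROUP_SPECIES = ("Pongo_abelii", "Pongo_pygmaeus")


def reference_tree() -> PhyloTree:
    """The packaged synthetic stand-in tree (21 tips, ultrametric, depth 20 my)."""
    return PhyloTree.from_newick_string(_REFERENCE_NEWICK)


def simulate_tree(n_tips: int, seed: int, depth: float = 1.0) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree rescaled to the given depth.

    Lineages split at rate 1 each; at every event a uniformly random active
    lineage bifurcates, which is the Yule process.  Deterministic given
    ``seed``.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)
    parent = [-1]
    origin = [0.0]  # time at which the branch subtending this node starts
    # active lineages: (node index, origin time)
    active = []
    for _ in range(2):
        parent.append(0)
        origin.append(0.0)
        active.append(len(parent) - 1)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        j = int(rng.integers(k))
        nd = active.pop(j)
        for _ in range(2):
            parent.append(nd)
            origin.append(t)
            active.append(len(parent) - 1)
        origin[nd] = (origin[nd], t)  # mark split time
    t_end = t + rng.exponential(1.0 / n_tips)
    length = np.zeros(len(parent))
    labels: list[str | None] = [None] * len(parent)
    tip_no = 0
    for i in range(1, len(parent)):
        if isinstance(origin[i], tuple):
            start, split = origin[i]
            length[i] = split - start
        else:
            length[i] = t_end - origin[i]
            tip_no += 1
            labels[i] = f"s{tip_no:03d}"
    length *= depth / t_end
    return PhyloTree(parent, length, labels)


def count_cherries(tree: PhyloTree) -> int:
    """Number of internal nodes whose children are both tips."""
    tipset = set(tree.tips)
    return sum(
        1
        for i in range(tree.n_nodes)
        if len(tree.children[i]) == 2 and all(c in tipset for c in tree.children[i])
    )


def _as_cov(tree_or_cov: PhyloTree | PhyloCov) -> PhyloCov:
    if isinstance(tree_or_cov, PhyloCov):
        return tree_or_cov
    return vcv_from_tree(tree_or_cov)


def simulate_bm_traits(
    tree_or_cov: PhyloTree | PhyloCov,
    lam: float,
    sigma2: float,
    mu: float,
    seed: int,
    size: int = 1,
) -> np.ndarray:
    """Draw trait vectors from MVN(mu * 1, sigma2 * C(lambda)).

    Returns shape ``(n_tips,)`` when ``size == 1`` else ``(size, n_tips)``,
    aligned with the covariance's ``tip_order``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    cov = _as_cov(tree_or_cov)
    V = lambda_transform(cov, lam).C * sigma2
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("lambda-transformed covariance is not PSD") from exc
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((V.shape[0], size))
    out = mu + (L @ Z).T
    return out[0] if size == 1 else out


def simulate_binary_threshold(
    tree_or_cov: PhyloTree | PhyloCov,
    prevalence: float,
    seed: int,
) -> np.ndarray:
    """Binary states from a Brownian liability cut at a prevalence quantile.

    The top ``round(prevalence * n)`` tips by liability get state 1, so the
    realised count of ones is exact, not merely expected.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    cov = _as_cov(tree_or_cov)
    n = len(cov.tip_order)
    k = int(round(prevalence * n))
    if k in (0, n):
        raise ValueError(
            f"prevalence {prevalence} with n={n} yields a constant trait"
        )
    liab = simulate_bm_traits(cov, 1.0, 1.0, 0.0, seed)
    states = np.zeros(n, dtype=int)
    states[np.argsort(liab)[-k:]] = 1
    return states


def simulate_lmm_response(
    X: np.ndarray,
    beta: np.ndarray,
    A: np.ndarray,
    species_index: np.ndarray,
    sigma2_phylo: float,
    sigma2_species: float,
    sigma2_resid: float,
    seed: int,
) -> np.ndarray:
    """One draw of y = X beta + u_phylo + u_species + eps.

    ``A`` is the population-level kinship correlation matrix and
    ``species_index`` maps each population (row) to a species code; the
    species random effect is i.i.d. across species and shared within them.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    y = X @ beta
    if sigma2_phylo > 0:
        L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        y = y + np.sqrt(sigma2_phylo) * (L @ rng.standard_normal(n))
    n_sp = int(species_index.max()) + 1
    if sigma2_species > 0:
        u = np.sqrt(sigma2_species) * rng.standard_normal(n_sp)
        y = y + u[species_index]
    if sigma2_resid > 0:
        y = y + np.sqrt(sigma2_resid) * rng.standard_normal(n)
    return y


@dataclass
class SyntheticSpec:
    """Generating parameters for a study-structured synthetic dataset.

    Defaults emulate the study conditions: 39 populations over 19 gibbon
    species plus a 2-species outgroup (>= 1 population each, 58% of species
    with more than one), responses on their modelling (log10) scale driven
    by fixed effects plus phylogenetic / species / residual variance
    components, and a phylogenetically clumped binary mating system.
    """

    n_populations: int = 39
    multi_population_fraction: float = 0.58
    lambda_true: float = 1.0
    #: Brownian rate used for species-level traits, per unit branch length
    sigma2_trait: float = 0.005
    binary_prevalence: float = 1 / 3
    #: fixed effects on the transformed (modelling) scale
    beta_hr: Mapping[str, float] = field(
        default_factory=lambda: {
            "(Intercept)": 0.1,
            "GS": 0.5,
            "MS01": 0.3,
            "group_density": -0.15,
        }
    )
    beta_gs: Mapping[str, float] = field(
        default_factory=lambda: {
            "(Intercept)": 0.8,
            "MS01": 0.2,
            "annual_precipitation": -0.15,
        }
    )
    sigma2_phylo: float = 0.02
    sigma2_species: float = 0.01
    sigma2_resid: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_trait", "sigma2_phylo", "sigma2_species", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.binary_prevalence < 1.0):
            raise ValueError("binary_prevalence must lie in (0, 1)")


# raw-scale sampling ranges loosely emulating the field predictor roster
_PREDICTOR_RANGES = {
    "group_density": ("loguniform", 0.05, 6.0),     # groups / km^2
    "latitude": ("uniform", -9.0, 28.0),            # decimal degrees
    "longitude": ("uniform", 92.0, 117.0),          # decimal degrees
    "altitude": ("loguniform", 60.0, 2600.0),       # m asl
    "annual_mean_temperature": ("uniform", 12.0, 27.0),  # degC
    "annual_precipitation": ("loguniform", 1100.0, 4000.0),  # mm
    "precipitation_seasonality": ("uniform", 20.0, 110.0),   # CV
    "NDVI": ("uniform", 0.4, 0.9),                  # ratio
    "GHF": ("uniform", 5.0, 60.0),                  # percent
    "reserve_area": ("loguniform", 20.0, 3000.0),   # km^2
}


def _allocate_populations(
    species: list[str], n_populations: int, multi_fraction: float, rng: np.random.Generator
) -> list[str]:
    n_sp = len(species)
    if n_populations < n_sp:
        raise ValueError(
            f"cannot place >= 1 population in each of {n_sp} species with "
            f"only {n_populations} populations"
        )
    counts = {sp: 1 for sp in species}
    extras = n_populations - n_sp
    n_multi = min(int(round(multi_fraction * n_sp)), extras)
    multi = list(rng.choice(species, size=n_multi, replace=False))
    for sp in multi:
        counts[sp] += 1
    extras -= n_multi
    if extras > 0:
        if multi:
            for sp in rng.choice(multi, size=extras, replace=True):
                counts[sp] += 1
        else:
            for sp in rng.choice(species, size=extras, replace=True):
                counts[sp] += 1
    out = []
    for sp in species:
        out.extend([sp] * counts[sp])
    return out


def simulate_population_dataset(
    spec: SyntheticSpec, tree: PhyloTree | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate a raw-scale population table plus its generating-truth record.

    Responses are built on the modelling scale (log10 for HR and GS) from the
    transformed predictors — exactly the design the downstream analysis sees —
    then back-transformed to raw units for the table.  Mating system is a
    species-level threshold character, uniform across populations of a
    species; outgroup species are recorded as 'solitary'.
    """
    from . import preprocess  # local import to avoid cycle

    if tree is None:
        tree = reference_tree()
    cov = vcv_from_tree(tree)
    species = list(cov.tip_order)
    root = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(8)]
    rng = np.random.default_rng(seeds[0])

    sp_of_pop = _allocate_populations(
        species, spec.n_populations, spec.multi_population_fraction, rng
    )
    n = len(sp_of_pop)
    pop_ids = [f"P{i+1:02d}" for i in range(n)]
    sites = [f"site_{i+1:02d}" for i in range(n)]

    table = pd.DataFrame({"population_id": pop_ids, "species": sp_of_pop, "site": sites})
    for name, (kind, lo, hi) in _PREDICTOR_RANGES.items():
        if kind == "loguniform":
            table[name] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        else:
            table[name] = rng.uniform(lo, hi, size=n)

    # species-level traits: log10 body mass is a Brownian control trait
    log_mass = simulate_bm_traits(cov, spec.lambda_true, spec.sigma2_trait,
                                  np.log10(6.0), seeds[1])
    mass_of = dict(zip(species, 10.0 ** log_mass))
    table["body_mass"] = [mass_of[sp] for sp in sp_of_pop]

    # mating system: species-level threshold character, uniform within species
    ms_states = simulate_binary_threshold(cov, spec.binary_prevalence, seeds[2])
    ms_of = {
        sp: ("polygyny" if st == 1 else "monogamy")
        for sp, st in zip(species, ms_states)
    }
    for sp in OUTGROUP_SPECIES:
        if sp in ms_of:
            ms_of[sp] = "solitary"
    table["MS"] = [ms_of[sp] for sp in sp_of_pop]

    # transformed predictor design, as the analysis will reconstruct it
    design, _ = preprocess.transform_variables(table.copy())
    design = preprocess.code_mating_system(design)
    sp_codes = pd.Categorical(design["species"], categories=species).codes
    A = cov.C[np.ix_(
        [cov.index_of(sp) for sp in sp_of_pop],
        [cov.index_of(sp) for sp in sp_of_pop],
    )] / cov.depth

    def lin(beta: Mapping[str, float], frame: pd.DataFrame) -> tuple[np.ndarray, dict]:
        # continuous predictors enter standardised, so SyntheticSpec betas are
        # per-SD (standardised) effects whatever the raw units; the implied
        # raw-scale slopes are recorded in the truth record
        y = np.full(n, float(beta.get("(Intercept)", 0.0)))
        effective = {"(Intercept)": float(beta.get("(Intercept)", 0.0))}
        for name, b in beta.items():
            if name == "(Intercept)":
                continue
            x = frame[name].to_numpy(float)
            if name == "MS01":  # binary stays on its natural 0/1 scale
                y = y + b * x
                effective[name] = float(b)
                continue
            m, s = x.mean(), x.std(ddof=0)
            y = y + b * (x - m) / s
            effective[name] = float(b / s)
            effective["(Intercept)"] -= float(b * m / s)
        return y, effective

    # GS first (HR depends on it)
    y_gs, eff_gs = lin(spec.beta_gs, design)
    y_gs = y_gs + _random_effects(A, sp_codes, spec, seeds[3])
    # solitary outgroup species live in units of 1-2 individuals
    out_rows = np.array([sp in OUTGROUP_SPECIES for sp in sp_of_pop])
    if out_rows.any():
        y_gs[out_rows] = np.log10(
            np.random.default_rng(seeds[5]).uniform(1.0, 2.0, out_rows.sum())
        )
    design["GS"] = y_gs
    y_hr, eff_hr = lin(spec.beta_hr, design)
    y_hr = y_hr + _random_effects(A, sp_codes, spec, seeds[4])
    table["GS"] = np.maximum(10.0 ** y_gs, 1.0)
    table["HR"] = 10.0 ** y_hr

    truth = {
        "spec": asdict(spec),
        "species_of": dict(zip(pop_ids, sp_of_pop)),
        "ms_of_species": ms_of,
        "log10_body_mass": dict(zip(species, log_mass)),
        "y_gs_model_scale": y_gs.tolist(),
        "y_hr_model_scale": y_hr.tolist(),
        "beta_hr_standardised": dict(spec.beta_hr),
        "beta_gs_standardised": dict(spec.beta_gs),
        "beta_hr_effective": eff_hr,
        "beta_gs_effective": eff_gs,
        "variance_components": {
            "sigma2_phylo": spec.sigma2_phylo,
            "sigma2_species": spec.sigma2_species,
            "sigma2_resid": spec.sigma2_resid,
        },
    }
    cols = ["population_id", "species", "site", "HR", "GS", "MS", "body_mass"] + list(
        _PREDICTOR_RANGES
    )
    return table[cols], truth


def _random_effects(
    A: np.ndarray, sp_codes: np.ndarray, spec: SyntheticSpec, seed: int
) -> np.ndarray:
    return simulate_lmm_response(
        np.zeros((len(sp_codes), 1)),
        np.zeros(1),
        A,
        np.asarray(sp_codes),
        spec.sigma2_phylo,
        spec.sigma2_species,
        spec.sigma2_resid,
        seed,
    )


def simulate_regression_table(
    n_species: int,
    n_populations: int,
    beta: Mapping[str, float],
    sigma2_phylo: float,
    sigma2_species: float,
    sigma2_resid: float,
    seed: int,
    n_predictors: int | None = None,
    tree: PhyloTree | None = None,
) -> tuple[pd.DataFrame, "KinshipMatrix", dict]:
    """Ready-to-model table with standard-normal predictors and known effects.

    Convenience generator for recovery experiments: predictors ``x1..xk`` are
    i.i.d. N(0, 1) at the population level (so coefficients are standardized
    effects), the response ``y`` follows the kinship mixed model.  Returns
    the table, the kinship matrix and a truth record.
    """
    from .phylo import population_kinship

    rng_master = np.random.SeedSequence(seed)
    s_tree, s_x, s_y, s_alloc = (
        int(s.generate_state(1)[0] % (2**31)) for s in rng_master.spawn(4)
    )
    if tree is None:
        tree = simulate_tree(n_species, s_tree)
    cov = vcv_from_tree(tree)
    rng = np.random.default_rng(s_alloc)
    sp_of_pop = _allocate_populations(
        list(cov.tip_order), n_populations, 0.58, rng
    )
    pops = [f"P{i+1:02d}" for i in range(len(sp_of_pop))]
    kin = population_kinship(cov, dict(zip(pops, sp_of_pop)))

    names = sorted({k for k in beta if k != "(Intercept)"})
    if n_predictors is not None:
        names = sorted(set(names) | {f"x{i+1}" for i in range(n_predictors)})
    rng_x = np.random.default_rng(s_x)
    table = pd.DataFrame({"population_id": pops, "species": sp_of_pop})
    for nm in names:
        table[nm] = rng_x.standard_normal(len(pops))
    X = np.column_stack(
        [np.ones(len(pops))] + [table[nm].to_numpy() for nm in names]
    )
    b = np.array([beta.get("(Intercept)", 0.0)] + [beta.get(nm, 0.0) for nm in names])
    sp_codes = pd.Categorical(table["species"], categories=list(cov.tip_order)).codes
    table["y"] = simulate_lmm_response(
        X, b, kin.A, np.asarray(sp_codes), sigma2_phylo, sigma2_species,
        sigma2_resid, s_y,
    )
    truth = {
        "beta": {"(Intercept)": b[0], **dict(zip(names, b[1:]))},
        "sigma2_phylo": sigma2_phylo,
        "sigma2_species": sigma2_species,
        "sigma2_resid": sigma2_resid,
        "predictors": names,
    }
    return table, kin, truth
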