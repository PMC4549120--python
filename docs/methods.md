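# Methods

This note records the models implemented in `hylocomp`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Trees and covariance

A rooted tree with branch lengths implies, under Brownian trait evolution,
the among-tip covariance `C[i, j]` = path length from the root to the MRCA
of tips i and j (diagonal = root-to-tip distance). Trees need not be
ultrametric for `C` to be well defined, but two guarantees are stated only
for ultrametric trees: positive semi-definiteness of the λ-transform for
all λ ∈ [0, 1], and same-species population kinship of exactly 1. A tree
whose tip depths differ by more than 1e-6 × depth is treated as
non-ultrametric; kinship construction then warns and applies the same
correlation normalisation `A[p, q] = C[s(p), s(q)] / √(C_ss C_tt)`.
Polytomies are kept as-is for covariance (well defined); only the
sister-difference statistic needs a bifurcating tree and resolves
polytomies into zero-length bifurcations, with a warning. Branch lengths
are carried through in their input units (the fixture tree uses millions
of years, depth 20); no quantity depends on the unit except the raw scale
of σ².

Newick parsing/serialisation is delegated to dendropy; strictness added on
top: mandatory terminating semicolon, mandatory branch lengths (covariance
is undefined without them), unique non-empty tip labels, ≥ 3 tips.

## Variable transformations

* Log rule: a continuous variable is log10-transformed when its pooled
  max/min ratio is ≥ 10 ("varies by an order of magnitude",
  operationalised mechanically). Log base does not affect model structure,
  only coefficient scale. Candidates are the inherently positive variables
  (HR, GS, body mass, group density, altitude, precipitation, its
  seasonality, reserve area); temperature (can be ≤ 0 °C), coordinates and
  bounded indices are never log candidates.
* Human-footprint percentages are divided by 100 and arcsine-square-root
  transformed (the standard variance-stabilising form). A plain-arcsine
  variant is available (`arcsine_variant="asin"`) because either reading
  of "arcsine transformed" is defensible; the default is asin(√p).
* Latitude enters as its absolute value; mating system is coded
  polygyny = 1, monogamy = 0, solitary = 0.
* Idempotence: a second pass over an in-memory transformed table applies
  no further rules (an attribute marker records what was transformed; a
  data-scale guard backs it up for GHF). After a CSV round trip the marker
  is lost and only the data-based guards remain — re-transforming a table
  read back from disk is not supported for log-scale columns whose logged
  range happens to trigger the rule again.

## Pagel's λ and the D statistic

λ is estimated by ML on the profile likelihood (GLS mean and σ² profiled
out in closed form), searched on [0, 1] only: the endpoints are exactly the
hypotheses tested, and values above the PSD-maximal λ > 1 are out of scope.
A 26-point grid locates the likelihood basin before bounded scalar
refinement (tolerance 1e-7); the reported optimum never falls below either
endpoint's likelihood. LRT statistics ≤ 0 (optimum at a bound) are
reported as computed with P = 1. A flat-likelihood flag is set when the
λ-grid range of lnL is < 1e-6 (e.g. star trees, where λ is inert).
Constant traits are an error, not lnL = -∞: σ̂² = 0 makes every λ equally
"perfect" and no signal question is answerable.

D is computed from the sum of sister differences Σd: node values estimated
tips-to-root (each internal node the mean of its two daughters), Σd = Σ
|daughter₁ − daughter₂|. Two simulated nulls with `n_sim` draws each:
tip permutations of the observed states, and Brownian liabilities
thresholded so the count of ones exactly equals the observed count
(rank thresholding avoids prevalence drift). Then
`D = (Σd_obs − mean Σd_B) / (mean Σd_R − mean Σd_B)`. Tail conventions:
`p_random` = fraction of permutation Σd ≤ observed (small for a clumped
trait); `p_brownian` = fraction of Brownian Σd ≥ observed (large when
clumping is at least Brownian). These definitions are validated by
calibration — mean D ≈ 0 on Brownian-threshold data and ≈ 1 on shuffled
data — rather than by matching any particular empirical value, which would
require the original data. Given a seed, results are bit-reproducible.

## Species outlier tests

With the fitted model `V = σ̂² C(λ̂)`, each species' expected value is the
conditional (partitioned-Gaussian) mean given all other species, and its
prediction SE the conditional SD. `t = (obs − exp)/SE` on n − 2 degrees of
freedom (one mean and one variance estimated — the df is a documented
choice, not given by the source analyses), two-tailed, against a
Bonferroni-adjusted threshold α/n over the n species tested (0.05/21 =
0.0024 at 4 d.p.).

Two switches, both off by default:

* `include_mean_uncertainty` adds the GLS-mean estimation variance
  `(1 − V_f,- V_--⁻¹ 1)² / (1ᵀ V_--⁻¹ 1)` to the prediction variance.
* `refit_per_fold` re-estimates λ̂ and σ̂² on each leave-one-out subset
  (external studentisation) and applies the classical unbiased-variance
  correction m/(m−1). The default single-fit mode mirrors the convention
  of deriving one PGLS model per trait and holding it fixed; but for
  *outlier detection* it is internally studentised and therefore masks
  large spikes — a 6-SD outlier inflates the full-data σ̂² by roughly
  (n−1+36)/n, shrinking its own t statistic to ~3.7 and its detection
  probability to ~50% at the Bonferroni threshold. The injection/recovery
  harness therefore uses `refit_per_fold=True`, where measured power is
  ~100% with family-wise false-flag rates at the nominal 5% (with some
  tree-shape dependence: trees with very short terminal branches run a
  point or two above nominal because the conditional SD is then itself
  poorly estimated).

Flag decisions are invariant to affine rescaling of the trait.

## Kinship mixed model

`y = Xβ + u_phylo + u_species + ε` with
`cov(y) = σ²_p A + σ²_s ZZᵀ + σ²_r I`. The random-effects structure — a
phylogenetic species effect, an i.i.d. species effect, and a population
residual — is the identifiable standard decomposition when species hold
replicate populations; components are labelled explicitly in all output so
users can map them onto other conventions (with a single population per
species the i.i.d. species term and the residual are confounded, and the
fit simply splits that variance arbitrarily between them without affecting
β̂ or lnL). Fitting is ML: for fixed variance ratios γ = (σ²_p/σ²_r,
σ²_s/σ²_r), β̂ is GLS and σ̂²_r closed-form; the 2-D profile likelihood is
maximised by Nelder-Mead on log γ (bounds e±16, three starts by default —
the origin and two asymmetric points — plus seeded random restarts if more
are requested). Wald z with a normal reference per coefficient (not t with
adjusted df). Binary mating system is fitted as a linear 0/1 response;
a logistic variant is out of scope. A capacity warning (never an error)
fires below 5 observations per fixed-effect parameter, since the
all-candidate mating-system model intentionally violates the guideline.
Variance partitioning reports each random component as a percentage of
σ²_p + σ²_s, with the residual alongside; both components at zero makes
the percentages not applicable.

Calibration note: Wald tests with ML variance components at n ≈ 39 run
mildly anticonservative (empirical single-predictor type-I rate ≈ 5-8% at
nominal 5%); the screening step therefore behaves like any ML-based
mixed-model screen at this sample size.

## Multimodel inference

Candidate models are every non-empty predictor subset of the global model
(intercept always included; intercept-only excluded), capped at 12
predictors. k counts fixed effects including the intercept plus the three
variance parameters. AICc ranking, ΔAICc, softmax Akaike weights; the
confidence set is ΔAICc < 7; ties break toward fewer predictors then
lexicographic subset order. Averaging is conditional (subset-based):
weights renormalised within the confidence set, β̄ the weight-normalised
mean over models containing the term, unconditional SE =
√(Σ w̃ᵢ (se²ᵢ + (βᵢ − β̄)²)), RI the sum of set-renormalised weights of
containing models. Conditional rather than zero-substitution averaging
matches the convention where averaged estimates remain close to
best-model estimates; a full-model average is deliberately not provided.
Main effects only — no interactions.

## Synthetic data

The generator emulates the study's structure, with all conditions fixed as
defaults: 21 species (19 ingroup across four genera + 2 outgroup,
real species names on a synthetic ultrametric tree with invented node ages,
depth 20 my), 39 populations with ≥ 1 per species and 58% of species
holding > 1; body mass a pure Brownian trait constant across a species'
populations; mating system a species-level threshold character (prevalence
1/3, uniform within species, outgroup recorded solitary with group sizes
of 1–2 individuals); environmental predictors drawn independently over
field-realistic ranges (e.g. precipitation 1,100–4,000 mm, altitude
60–2,600 m, human footprint 5–60%). Responses are built on the modelling
(log10) scale from the *transformed* predictors — continuous predictors
standardised so the default effect sizes (e.g. 0.5 per SD of log group
size on log home range) are per-SD effects whatever the raw units — plus
phylogenetic/species/residual components (0.02/0.01/0.01 on the log10
scale, i.e. random-effect SDs of ~0.1–0.14, chosen to leave visible but
not dominant relatedness structure). The implied raw-scale coefficients
are stored in the truth record. Random trees are forward-simulated Yule
processes (uniform lineage splitting), rescaled to depth 1, and checked
against the analytic mean cherry count n/3.

What the generator does **not** emulate: real climatic covariance between
predictors (they are independent by construction, which is also what the
collinearity screen should then confirm), measurement error, sampling
effort differences between sites, or the actual trait values of any
species. Passing tests therefore demonstrate that the estimators recover
known structure under the model's own assumptions — not that the model is
correct for real field data.

## Problem sizes used in validation

Simulation-based checks use: λ recovery on 100-tip trees (200 replicates
per regime) with a 0.001-step grid oracle on 20 datasets; D calibration on
a 50-tip tree, 300 replicate datasets per regime at 1,000 null draws each;
mixed-model β recovery over 600 datasets of 39 populations / 19 species
(600 rather than 200 because three coefficients each held to ±2 Monte-Carlo
SEs give a perfectly unbiased estimator a ~12% chance of a chance failure
at 200 replicates); relative-importance recovery over 100 end-to-end
replicates with two true effects of 0.8 SD among five candidates; outlier
injection at 6 conditional SDs over 200 replicates on a 21-tip tree.

## Known limitations

* λ is restricted to [0, 1]; traits with anti-signal (λ > 1 regions or
  negative covariance) are not modelled.
* The D implementation follows the published construction of the
  statistic but is validated by calibration, not against the original
  software; exact numerical agreement with other implementations'
  node-estimation conventions is not guaranteed.
* Wald inference in the mixed model is asymptotic; at n ≈ 39 its type-I
  rate is a little above nominal (documented above), and variance
  components are ML (not REML), hence biased low in small samples.
* The default outlier mode (single full-data fit) should not be used to
  hunt for single extreme outliers; use `refit_per_fold=True` for that
  purpose (rationale above).
* Binary responses use a linear probability mixed model by design choice;
  predicted values are not constrained to [0, 1].
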