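# Methods

## Model

The extended limiting-pathway (LP) model specifies an observed quantitative
trait as the maximum (equivalently, with `combine="min"`, the minimum) of
`k` latent pathway phenotypes. Pathway `j` of individual `i` is

    P_ij = mu_j + A_ij + C_ij + U_ij        (siblings)
    P_ij = mu_j + A_ij + E_ij               (parents)

with additive genetic values `A_i ~ MVN(0, Sigma_A)`,
`Sigma_A[i,j] = R[i,j] * sqrt(h2_i sigma2_i h2_j sigma2_j)`, where `R` is a
structured pathway correlation matrix, `h2_j` the pathway heritability and
`sigma2_j` the pathway phenotypic variance. Environmental effects are
independent across pathways and between parents; for siblings the pathway
environmental variance `(1 − h2_j) sigma2_j` is split into a family-common
part `C` (fraction `c2_path`, one scalar for all pathways, identical for
all siblings of a family) and a unique part `U`. Each pathway is an
infinitesimal additive trait, yet for `k > 1` the max induces
additive-by-additive epistatic variance in the final phenotype; no
dominance variance arises.

The basic LP model is the special case `mu = 0`, `sigma2 = 1`, equal
`h2_path`, uncorrelated pathways.

### Correlation structures

All three supported structures are rank-one sign perturbations of the
identity, `R = (1 − rho) I + rho s s'`:

- `uniform`: `s = 1` — every pair correlated `rho`;
- `two_block`: `s = (1,…,1,−1,…,−1)` with blocks of `ceil(k/2)` and
  `floor(k/2)` — `+rho` within blocks, `−rho` across;
- `one_vs_rest`: `s = (−1,1,…,1)` — pathway 1 correlated `−rho` with each
  of the rest, which are mutually `+rho`.

They share the eigenvalues `1 + (k−1) rho` and `1 − rho`, hence the common
feasibility bound `rho ≥ −1/(k−1)`; infeasible requests raise an error
naming the bound. The PSD check tolerates a minimum eigenvalue of `−1e−10`
(eigen-decomposition noise). The correlation applies to additive values
only; environments are always pathway-independent. Both negative-structure
variants are provided because "negative correlation between pathways" can
mean either a balanced two-set split or a single antagonistic pathway, and
the two behave differently as `k` grows.

## Family simulation

Each simulated family holds two parents, an offspring, its MZ co-twin and
its DZ co-twin. Parents are drawn independently (random mating) with the
full environmental variance, unsplit, since parental common environment
plays no role in the twin statistics. Offspring additive values follow the
infinitesimal-model recursion

    A_off = (A_mother + A_father)/2 + M,   M ~ MVN(0, Sigma_A / 2),

the Mendelian-sampling deviation `M` drawn independently per child (the DZ
co-twin gets its own draw; the MZ co-twin copies `A_off`). This preserves
`Var(A) = Sigma_A` across generations and gives parent-offspring and DZ
additive covariances of `Sigma_A / 2`. Siblings share `C` and receive
independent `U`. Final phenotypes are not re-standardized after the max:
every reported quantity is a variance ratio and therefore scale-free
(verified exactly in the tests by the scaling invariance of correlations).

One `numpy` generator per cohort is consumed in a fixed documented stream
order, so cohorts are bit-reproducible given `(params, n_families, seed)`;
replicates receive independent `SeedSequence`-spawned children of the root
seed.

## Estimators

- **Twin correlations**: Pearson correlations of ordered
  (offspring, co-twin) phenotype pairs. At the cohort sizes used
  (≥ 20,000 pairs) the difference from the intraclass correlation is below
  Monte-Carlo noise.
- **ACE components** (Falconer): `h2_ACE = 2(rMZ − rDZ)`,
  `c2_ACE = 2 rDZ − rMZ`, `e2 = 1 − rMZ`. Not truncated to [0, 1]:
  negative `c2_ACE` is the signature of epistasis and truncation would
  bias replicate means.
- **Narrow-sense h²**: OLS regression of `Y` on the `k` additive-value
  columns plus intercept; `h2 = Var(sum_j beta_j A_j) / Var(Y)` on centered
  genetic columns. Rank-deficient designs (perfectly collinear pathways at
  `rho = 1`) fall back to the minimum-norm solution with a warning.
- **Final-level common-environment proportion c²**: the default estimator
  is `rMZ − H²`, with `H²` the covariance ratio of pairs sharing the whole
  genome but nothing else (broad-sense genetic variance) — i.e. the
  classical MZ identity `rMZ = H² + c²` solved for `c²`, which assigns
  genome-by-common-environment interaction variance to the common
  component. Two alternatives are selectable: the covariance of pairs
  sharing only `C` ("adopted sibling" contrast, `method="pair"`) and a
  regression of `Y` on the `C` columns mirroring the h² estimator
  (`method="regression"`). The estimators agree exactly in the linear
  `k = 1` limit but differ under epistasis; the default is the one whose
  output matches the published three-trait table.
- **Phantom heritability**: `pi = 1 − h2 / h2_ACE`, undefined (error) for
  `h2_ACE ≤ 0`. Replicate aggregation applies the identity to the
  replicate *means* of `h2` and `h2_ACE` (ratio of means), which keeps the
  aggregate consistent with its components and avoids the Jensen bias of
  averaging ratios when `h2_ACE` is small; per-replicate ratios and their
  spread are still reported.

`run_replicates` reports means, medians and Monte-Carlo standard errors of
all quantities across independent replicates; the reference experiment
scale is 50 replicates of 100,000 families, with a desk scale of 10 × 20,000
(`--fast`) whose tolerances are correspondingly wider.

## Calibration

Observed twin correlations `(rMZ, rDZ)` (requiring
`0 ≤ rDZ ≤ rMZ ≤ 1`) are matched by solving for the shared pathway
heritability `h2_path` and common-environment fraction `c2_path` at fixed
`(k, R, mu, sigma2)`. Matching `(rMZ, rDZ)` is equivalent to matching
`(h2_ACE, c2_ACE)`, which nearly decouples the two unknowns: a nested
bisection solves `h2_path` against `h2_ACE` (inner) for each candidate
`c2_path` against `c2_ACE` (outer). Both maps are monotone increasing
(checked numerically on a grid in the tests). Every candidate evaluation
reuses one fixed set of standard-normal draws (**common random numbers**),
rescaled to the candidate parameters, so the Monte-Carlo objective is
smooth and the search deterministic given the seed; the median across the
CRN replicates is the search statistic. Targets outside the attainable
region of `[0,1]²` raise an error reporting the attainable boundary.
The returned summary is recomputed at the solution with fresh independent
seeds. The default matching tolerance is 0.005 per correlation; the
acceptance script tightens it to 0.002 because the phantom heritability of
low-heritability traits divides by a small `h2_ACE` and amplifies any
matching error roughly five-fold.

## Disease extension

Disease status is assigned when any standardized pathway phenotype
(model mean and sd divided out, making the threshold scale-free) exceeds
`t = Phi^{-1}(1 − mu_path)`. For independent equal pathways the prevalence
is `1 − (1 − mu_path)^k`; a `convention="total"` flag instead back-solves
`mu_path` from a requested overall prevalence. Reported: sample prevalence,
casewise MZ/DZ concordances, and recurrence-risk ratios
(concordance/prevalence). As `rho → 1` with fully heritable pathways the
model degenerates to the single-pathway liability-threshold model.

## Numerical choices and defaults

- PSD factorization uses Cholesky with an eigen-decomposition fallback
  (negative eigenvalues clipped at 0) for the singular `rho → 1` boundary.
- Sensitivity-sweep defaults where the design was open: two pathways,
  `h2_path = 0.5`, no common environment, uncorrelated pathways unless the
  swept parameter says otherwise; the "10% common environment" sweep
  variant sets `c2_path = 0.1/(1 − h2_path)` so common environment is 10%
  of each pathway's phenotypic variance. These are this package's choices,
  config-exposed.
- Bisection: parameter resolution `5e−4`, at most 24 iterations per level;
  the total number of CRN evaluations per calibration is typically 40–80.
- Seeds: all derived seeds are kept below 2³¹.

## What the simulator does and does not emulate

The generator realizes the LP model's own idealizations: infinitesimal
purely additive pathways, multivariate-normal components, random mating, no
assortment, no dominance, no parent-offspring environmental transmission,
a single shared `c2_path` across pathways, and exchangeable siblings. Tests
passing therefore validate the implementation of this model — its internal
identities, closed-form limits and published table — not the biological
adequacy of limiting-pathway epistasis for real traits. In particular,
real twin data cannot distinguish epistatic from common-environment
variance; the model quantifies the trade-off rather than resolving it.

## Known limitations

- Calibration assumes equal pathway heritabilities and a shared
  `c2_path`; per-pathway calibration is out of scope.
- Monte-Carlo precision of phantom heritability degrades as
  `h2_ACE → 0` (ratio estimator); desk-scale runs of low-correlation
  traits carry errors of a few hundredths.
- The maximum-likelihood / SEM route to ACE estimation is not implemented;
  estimates are moment-based (Falconer) by design.
- Disease-scale heritability transformations and ascertainment bias are
  not modeled.
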