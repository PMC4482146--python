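# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the synthetic data generator, and the numerical conventions.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Phylogenies and weight matrices

A phylogeny is a rooted tree with unique tip labels, non-negative branch
lengths and polytomies allowed (polytomy support is required because the
robustness re-analysis collapses poorly supported subclades into star
groups). Missing branch lengths default to 1 with a warning: the Abouheif
analyses are topology-only, but the eigenvector regression needs distances.
Species matching between tree and tables is by exact label string and a
mismatch is fatal, never silently dropped; species order in every output
follows the tree's tip order.

Two matrices are derived:

- **Patristic distances** `d_ij` = sum of branch lengths on the tip-to-tip
  path, computed as `depth_i + depth_j − 2·depth(MRCA)`.
- **Abouheif proximities** `a_ij = 1 / prod(ddf)` over the internal nodes
  on the path (both tips' ancestors up to and including the MRCA), where
  `ddf` is a node's direct-descendant count. At a polytomy the `ddf` is the
  full child count — no arbitrary resolution. The diagonal is zero; the
  diagonal-corrected variant used by some software is deliberately not the
  default, because the statistic is interpreted as Moran's I, which ignores
  the diagonal.

Row normalization divides each row by its sum (zero row sums are an error
naming the species); the symmetrized form `(W + W')/2` of the
row-normalized matrix is used wherever a symmetric operator is needed.
Both normalizations preserve the total weight `S0 = n`, which is what makes
the phylogenetic PCA eigenvalue identity below exact.

## Phylogenetic signal

Moran's I is `I = (n/S0)·(z'Wz)/(z'z)` with `z = x − mean(x)`. A constant
trait raises an error (the statistic is undefined, not zero). Significance
comes from `B` random permutations of trait values across tips, with the
add-one estimator `p = (1 + #{null ≥ obs}) / (B + 1)` — conservative and
never zero. Trait signal tests are upper-tailed by default (positive
autocorrelation is the hypothesis of interest); the two-sided p doubles the
smaller tail and caps at 1. `B = 1000` permutations is the pipeline
default. The Abouheif test is this test run on the row-normalized Abouheif
proximity. Whether raw or row-normalized proximities were used in the
original analyses is not documented anywhere we could check; row
normalization is the default here and the raw matrix remains available
through `normalize_weights(..., "raw")`.

Congruence among several distance matrices uses Kendall's W of concordance
over the midranked upper triangles (tie-corrected), with a null built by
independently permuting the species labels of all matrices but the first.
W = 1 means perfect rank agreement; under independence E[W] ≈ 1/m.

## Trait preparation

The analysis matrix has 11 fixed columns: % lipid, % carbohydrate,
% protein, caloric concentration (cal/g), dormancy (days of cold
stratification), then natural logs of hardness (kg), shell thickness (µm),
the hardness × thickness interaction, kernel mass (g), shell mass (g) and
tannin (% TAE). Moisture is measured but excluded. The choice of which
columns to log is a fixed list, not a data-driven skew test, so the design
matrix is exactly reproducible. Before logging, exact zeros in the tannin
column are floored at 0.35 % TAE.

One consequence of this design is worth stating plainly: the log
interaction equals the sum of the two log main effects, so the 11-column
matrix has rank 10. Least-squares software that aliases collinear columns
(e.g. R's `lm`) fits it silently; here the variance-partition fits use the
projection onto the column space (rank-deficiency-tolerant least squares),
which leaves every R² well-defined, while the eigenvector-selection
regressions keep a strict full-rank check because collinearity among
selected eigenvectors would indicate a bug.

Standardization uses divisor `n` (not `n − 1`) so that the phylogenetic
PCA eigenvalues decompose exactly the trait variance entering the score
identities.

## Eigenvector regression and variance partitioning

Squared patristic distances are double-centered in the principal-
coordinates sense, `G = −½ C D⁽²⁾ C`; centering raw distances is available
as a switch. Eigenvectors with eigenvalues above `1e-8 × max` are kept,
ordered by descending eigenvalue — the leading vectors contrast deep
clades, later ones structure near the tips. Selection is greedy forward:
starting from the empty set, the candidate whose inclusion most reduces
the absolute residual Moran's I is added, with ties going to the lower
index (coarser phylogenetic scale first); the search stops when a
permutation test finds no significant residual autocorrelation at `alpha`,
when no candidate reduces |I|, or at `n − 3` vectors. The stopping test is
run two-sided, consistent with the sign-free |I| objective. The residual
weight matrix defaults to row-normalized inverse patristic distances
(1/d, zero diagonal); Abouheif proximities are available by config and are
noticeably more sensitive to clade-level structure in our simulations.

The partition of each response is the classical partial-regression
decomposition into traits-alone, shared, phylogeny-alone and unexplained
fractions (formulas in the README); the four always sum to 1 and R² is
the ordinary, unadjusted coefficient of determination. The shared fraction
can be slightly negative under suppression; values below −1e-6 trigger a
warning rather than silent clipping.

## Phylogenetic PCA

The decomposition is of `H = (1/n) X' W_s X` with `X` standardized
(divisor n) and `W_s` the symmetrized row-normalized Abouheif proximity.
Standardization is the default because the 11 traits mix units (%, g, kg,
µm, days); covariance-matrix analysis of the raw columns is one flag away.
Axes are ordered positive-descending (global) then most-negative-first
(local); each axis's sign is fixed by making its largest-magnitude loading
positive, so biplots are deterministic. Because `S0 = n`, every axis
satisfies `eigenvalue = var_n(score) · I(score)` exactly (checked to 1e-8
on every fit in the test suite). With identity weights the procedure
reduces to ordinary PCA of the correlation matrix, which the tests verify
against an independent eigendecomposition.

Variance shares are reported under two conventions — `|λ| / Σ|λ|` and
`|λ| / p` (share of total trait variance) — because shares of a signed
spectrum are quoted inconsistently in the literature. Retention keeps the
`k_global` largest-positive and `k_local` most-negative axes (pipeline
default 2 + 1). Per-axis signal uses the Abouheif test, upper-tailed for
global axes and lower-tailed for local ones. Loadings above the 75th
percentile of absolute loadings are flagged as dominant per axis.

## Regressions

Behaviors are regressed on the retained axis scores by OLS; inference
permutes the response vector `B` times and compares `|t*|` against the
observed `|t|` with the add-one rule (two-sided). Permuting the raw
response is the default scheme; Freedman–Lane (permuting residuals of the
intercept-only null) is available but changes little under the global
null. Slope p-values are invariant to affine rescaling of the response;
the intercept's is not, and the permutation null for intercepts is
implementation-defined — we report it but attach no interpretation.

Interference counts are fitted by a log-link Poisson regression via IRLS
(convergence `max|Δβ| < 1e-8`, cap 100 iterations, divergence reported
with the iteration trace; all-zero counts are rejected since the MLE is
−∞). No over-dispersion correction is applied. The paired t-test on
handling times with and without interference is the classical two-sided
test on differences.

## Synthetic data

The generator defines the study conditions: 23 species, 11 traits, 4
behaviors.

- **Trees**: pure-birth (Yule) simulation with exponential waiting times
  (rate `k·birth_rate` for `k` lineages) and a final waiting interval so
  the tree is strictly ultrametric with no zero-length tip branches.
  The "paperlike" tree nests three clades of 8/10/5 species (family-like
  structure), each an independent Yule subtree rescaled to depth 0.6 under
  stems completing a total depth of 1.
- **Traits**: multivariate normal with covariance `σ²·V(λ)`, where `V`
  holds shared root-to-MRCA path lengths. λ attenuates off-diagonals only
  (the standard Pagel construction — equivalent to branch-length
  stretching for simulation purposes and simpler): λ = 1 is Brownian
  motion, λ = 0 independent tips. The paperlike preset evolves the
  nutrition, shell and dormancy traits with λ = 1 and kernel mass, tannin
  and moisture with λ = 0, then maps the Gaussians onto natural scales
  (logistic for percentages, log-normal for masses/hardness/thickness,
  affine for calories). The three lowest tannin values are set to exactly
  zero so the flooring path is exercised.
- **Behaviors**: `intercept + scores·β + N(0, noise_sd)` on the fitted
  pPCA axes of the prepared traits, with effect sizes patterned after the
  motivating analysis (the first global and the local axis drive all four
  behaviors, the second global axis only consumption time; default
  β ≈ ±0.5–8 on behavior scales, noise_sd = 1). Interference counts are
  Poisson(0.6) per species, independent of the axes — the null the
  post-hoc model probes; 0.6/species matches roughly 14 interference
  trials across 23 species.

What the generator does **not** emulate: within-species trial-to-trial
variation (behaviors are species means by construction), measurement error
in trait assays, correlated trait evolution beyond what the shared tree
induces, and non-Gaussian trait distributions beyond the monotone
rescalings above. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
feature of field data.

## Problem sizes and numerical conventions

The test suite and acceptance script use 20–23 species for calibration and
power runs (200–1000 replicates, 999 permutations — sizes at which the
permutation statistics are fully vectorized), 50 species for the
variance-partition null, and n ≤ 7 for exhaustive permutation
enumeration. Eigendecompositions use symmetric solvers (`eigh`);
eigenvalue sign classification uses a relative tolerance of 1e-10 so that
numerically-zero eigenvalues of a positive semidefinite operator are not
mislabeled as local axes. Permutation p-values use the add-one rule
everywhere. All randomness flows from a single seed; pipeline stages draw
from substreams derived by hashing the stage name (CRC32 mod 2³¹), so
adding a stage never perturbs another stage's draws.

## Known limitations

- Eigenvector selection is greedy; it can miss a jointly-optimal pair of
  vectors that neither helps alone. The stopping rule depends on the
  chosen residual weight matrix, and the inverse-distance default is less
  sensitive than Abouheif weights to clade-level residual structure.
- The four-way partition inherits the usual caveats of partial regression:
  with few species and many predictors the trait block can absorb nearly
  all variance, and shared fractions are bounded by the traits' own
  phylogenetic structure.
- The Poisson interference model assumes equal observation effort per
  species and no over-dispersion.
- The per-species foraging means of the motivating study were published
  only as PDF supplements; analyses of those data require a manual
  transcription (see `tests/test_acceptance.py`).
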