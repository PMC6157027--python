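# Methods

This note records the model, the conventions, and the design choices behind
`methvc`, in the spirit of a statistical methods appendix.

## Model

For a quantitative trait `y` measured on `n` pedigree members,

```
y ~ MVN( X beta ,  Omega ),
Omega = sigma2_Total * ( 2*Phi * h_r^2  +  E * h_meth^2  +  I * e^2 ),
e^2 = 1 - h_r^2 - h_meth^2,   h_r^2, h_meth^2 >= 0.
```

- `X` holds the fixed effects: intercept, sex (female indicator), age, and
  optionally methylation PCs or user covariates.
- `2*Phi` is the additive relationship matrix; `Phi` is computed exactly by
  the recursive tabular method over a topological ordering of the pedigree
  (`phi(i,i) = (1 + phi(f,m))/2`, `phi(i,j) = (phi(f,j) + phi(m,j))/2`,
  founders unrelated, missing parents contributing zero).  The method is
  O(n^2) memory, adequate for family-cohort sizes.
- `E` is the gene-specific methylation kernel (below).

The **null (polygenic) model** drops the `E` term.  The per-gene test is
`LRT = 2 (ll_full - ll_null)`; since `h_meth^2` is tested on the boundary of
its space, LRT is referred to a 50:50 mixture of a point mass at zero and
chi-square(1).  This reference is known to be slightly conservative.

### The `E` vs `2E` weighting

The natural printed form of the covariance uses `2E` by analogy with
`2*Phi`.  `E` is built with unit diagonal, however, so under `2E` the trait
variance would decompose as `sigma2 (h_r^2 + 2 h_meth^2 + e^2)` and the
fractions would no longer be proportions of variance.  The default therefore
enters `E` with coefficient 1, preserving the proportion interpretation of
`h_meth^2` (the fraction of phenotypic variance attributable to the gene's
methylation covariance); `strict_omega=True` (CLI `--strict-omega`)
reproduces the literal `2E` weighting.  The LRT is essentially unaffected
because the factor is absorbed by rescaling `h_meth^2`.

## Kernel construction

For each gene with at least `min_sites = 5` annotated CpG sites (inclusive
threshold; genes with fewer sites produce spuriously extreme pairwise
correlations and are excluded):

1. take the inverse-normalized (and, by default, PC-residualized) site
   rows; drop sites that are constant or exceed 20% missingness; if fewer
   than `min_sites` usable sites remain the gene goes to the skip report;
2. standardize each site to mean 0, variance 1 (sample `n-1` convention;
   configurable, and irrelevant after step 4) over its observed samples;
   missing entries are imputed to 0, the standardized mean, which keeps the
   cross-product a valid Gram matrix;
3. form `R = Z Z'` over samples (`Z` is samples x sites);
4. scale to exact unit diagonal: `K_ij = R_ij / sqrt(R_ii R_jj)`.

Step 4 is the only transformation that guarantees every diagonal element
equals 1 exactly; it makes `K` the pairwise sample correlation of
methylation state and bounds all entries by 1.  A sample whose sites are all
missing would give `R_ii = 0`; kernel construction fails loudly naming that
sample rather than emitting a defective kernel.

## Inverse-normal transform

Each site row is mapped to `Qnorm((rank - c) / (n - 2c + 1))` with the Blom
offset `c = 3/8` (the common default in genetic epidemiology; `c` is
exposed), average ranks for ties, missing values excluded from ranking.
Sites with fewer than 3 observed values are dropped.  Normalization is
always within the supplied matrix; nothing is pooled across files.

## PC batch correction

PCs are estimated with samples as observations and a seed-selected random
10% of sites as variables (the only orientation in which scores can serve
as per-sample covariates), variables centered, no rescaling beyond the
prior inverse-normalization.  The first 20 PCs are retained by default;
both knobs are configurable and the seed is mandatory.  Two consumption
routes exist, because both are legitimate:

- **residualize** each site on `[1, scores]` before kernel construction
  (default for kernels);
- carry the scores as **fixed covariates** in per-site heritability models.

Residualization is idempotent and leaves rows orthogonal to every score.

## Maximum-likelihood fitting

The likelihood is the exact multivariate-normal density.  Internally the
fractions are optimized on the simplex `{f_k >= 0, sum f <= 1}` with
`e^2 = 1 - sum f`; at every covariance evaluation the fixed effects are
profiled by GLS and `sigma2_Total` in closed form, so the optimizer works in
1–2 dimensions with analytic envelope gradients.  Implementation details
that matter:

- **Factorizations.**  Dense Cholesky; single-kernel models instead use one
  symmetric eigendecomposition and rotate, making per-site scans cheap.
- **Boundaries.**  The simplex is handled directly (L-BFGS-B in 1-D, SLSQP
  with the sum constraint in 2-D) so `h_meth^2 = 0` is exactly reachable —
  this is what produces the LRT's point mass at zero.  Fractions below 1e-6
  are snapped to 0.
- **Multi-start.**  Default starts `(0.5, 0), (0.25, 0.25), (0, 0.5),
  (0.1, 0.1)` plus a warm start at the null solution; every start point and
  optimizer endpoint is evaluated and the best kept, which enforces
  `ll_full >= ll_null` by construction (the genome-wide scan uses the
  lighter start set `(0.25, 0.25), (0, 0.5)` + warm start).  In the rare
  case cross-path rounding leaves the full fit a hair below the null, the
  null point itself — which lies inside the full model — is returned.
- **Degeneracies.**  A ridge of 1e-8 is added to the diagonal only when a
  factorization fails (logged at debug level).  If `E` aliases `2*Phi`
  exactly, the profile is flat along `h_r^2 + h_meth^2` and the fit
  converges to the null likelihood, as it should.
- **ML vs REML.**  ML is used throughout (`sigma2 = r' V^-1 r / n`), so
  LRTs between nested mean-identical models are valid; variance fractions
  carry the usual small downward ML bias, negligible at the sample sizes
  the experiments use.
- Convergence: successive log-likelihood change below 1e-8.  Non-converged
  fits are returned flagged, and the association layer reports them.

## P-values, thresholds, plots

- `p = 0.5 * P(chi2_1 >= LRT)` for `LRT > 0`.  At `LRT = 0` conventions
  differ (1 vs 0.5); the default reports `p = 1` so boundary genes can never
  look significant (configurable).  Negative statistics beyond -1e-6 raise;
  within rounding they clamp to zero.
- Multiple testing: Bonferroni `alpha / n_tests` over converged tests.
- Q-Q expectations come from the mixture null, under which the p-value law
  is uniform on (0, 0.5) with mass 0.5 plus a point mass at 1; a uniform
  reference would fake deflation because half the null statistics are
  exactly zero.

## Synthetic data

The generator's defaults define the desk-scale study conditions used by all
experiments: 40 nuclear families of 5 (200 samples), 1000 sites, 50 genes
with 5–30 sites each, site heritability 0.2, trait `h_r^2 = 0.3`.

- Site model: `z = g + lam * b + eps` with `g ~ MVN(0, site_h2 * 2*Phi)`
  per site, `eps ~ N(0, 1 - site_h2)`, loadings `lam ~ U(0.5, 1)`, and a
  batch value `b` shared by all members of a family (families are grouped
  into 8 batches; scale `batch_sd`, default 0).  Assigning batches at the
  family level mirrors how relatives are processed on shared plates and is
  what makes the batch factor masquerade as heritability; a batch factor
  independent of family would only add noise.
- Beta scale: `beta = ndtr(z)`.  The normal CDF maps to (0, 1) monotonically
  per site, so the rank-based inverse-normal transform recovers the Gaussian
  scale and the simulated pipeline is self-consistent.
- Trait: `y = 0.5 * female + 0.01 * age + u_poly + sum_g u_g + eps` with
  `u_poly ~ MVN(0, h_r^2 * 2*Phi)`, `u_g ~ MVN(0, (h_meth^2/|causal|) K_g)`
  using the kernels actually built from the simulated methylation, and unit
  total variance.

What the generator does **not** emulate: realistic genome coordinates or
CpG-island structure, array-specific noise, probe QC artifacts, cell-type
composition, or longitudinal treatment effects.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every failure mode of real arrays.

## Experiment scales

The replicated studies in `methvc.experiments` (used by the test suite and
the acceptance script) run at sizes chosen to finish in minutes on one CPU
while keeping Monte-Carlo error well inside the asserted margins: 500 null
replicates at n = 200 for LRT calibration, with the tested gene cycling
through the simulated genes — the boundary mass of any single gene is
sensitive to its kernel's site count at this sample size (small kernels
sit a few points above 50%, large ones below), while the mixture claim
concerns the pooled distribution over a genome-wide scan; 50 replicates at n = 600 for
parameter recovery (truth `h_r^2 = 0.4`, `h_meth^2 = 0.2`, tolerance
±0.05 on the means); 20 replicates of 20-gene scans at n = 400 for causal
ranking; 500 sites at n = 200 for the batch-correction contrast, paired so
the with/without-batch arms share every draw except the batch term.

## Known limitations

- Kinship is autosomal-additive only; no dominance, no X-linkage, and no
  genotype-based (realized) relatedness.
- One methylation kernel at a time; no joint or conditional multi-gene
  models, no score-test (SKAT-style) alternative, no bivariate/longitudinal
  extension across timepoints.
- The boundary-mixture reference is asymptotic; at small n the zero-mass
  fraction can drift a few points from 50% and tail p-values are
  approximate (the calibration experiment quantifies this).
- Kernels are dense; thousands of genes at thousands of samples would need
  out-of-core or low-rank handling that desk scale does not.
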