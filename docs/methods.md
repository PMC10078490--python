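# Methods

This note documents the statistical model behind `metapart`, the defaults
and the reasoning for the genuinely open design choices, what the synthetic
generator does and does not emulate, and the numerical details that affect
reproducibility.

## The analysis chain

### Latent-variable response (binomial GLLVM)

Occurrence of taxon *j* at site *i* is Bernoulli with
`logit p_ij = α_j + u_i'λ_j`, `u_i ~ N(0, I_d)`. The latent site scores
absorb the common, unmeasured covariation among taxa; regressing their
fitted probabilities (rather than raw zeros/ones) on environment and space
concentrates the downstream models on shared structure and removes binomial
sampling noise.

The scores are integrated out with a variational Gaussian approximation —
per-site `q(u_i) = N(m_i, V_i)` and the Jaakkola–Jordan quadratic bound on
the Bernoulli-logit likelihood. All updates (variational tilts ξ_ij, taxon
coefficients, site posteriors) are closed-form and increase the evidence
lower bound monotonically, which makes the fit fast and deterministic. We
chose this over a Laplace-at-joint-mode scheme after observing that the
joint-mode alternation is not monotone in the Laplace objective (the
loading update ignores the log-determinant term) and can return d > 0
"optima" whose approximate likelihood falls below the exact d = 0 closed
form; the variational route is also the default in the widely used GLLVM
software this model class comes from.

- The ELBO stands in for the marginal log-likelihood in
  `AIC = 2k − 2·loglik`, with `k = m + d·m_var − d(d−1)/2` (intercepts,
  loadings, minus rotational constraints; latent scores are integrated out
  and not counted). At d = 0 the likelihood is exact.
- Candidate dimensions default to {0, 1, 2, 3}: ~30-site surveys cannot
  support more; ties break toward the smaller dimension.
- Identification: the likelihood is rotation-invariant, so loadings are
  canonicalized post hoc (Λ'Λ diagonal, decreasing; largest-|loading|
  positive per factor). This canonicalization is equivariant under taxon
  permutation, which a triangular constraint anchored to the first d taxa
  would not be.
- Invariant taxa (all-absent/all-present) are retained as clamped
  intercept-only columns with zero loadings; their degenerate likelihood
  contribution is 0 by the 0·log 0 convention.
- Three seeded restarts (jittered score initialization from an SVD of the
  centered matrix); the best ELBO is kept. Predicted probabilities are
  clamped to [1e-6, 1 − 1e-6].

### Environment processing

Raw variables mix units and distributions, so transforms precede any
multivariate step: `arcsin(√p)` for proportions (percent-scale values
divided by 100 first), `log10(x + c)` with `c = 1` only when zeros are
present, for non-negative right-skewed quantities (sample skewness > 1
under auto-assignment). The PCA is on the correlation matrix — with
conductivities, precipitations and percentages in one table, covariance PCA
would be dominated by units. Three components are kept, matching the GAM
variable budget; component signs are fixed (largest-|loading| positive) so
downstream selection is reproducible across LAPACK builds. The shoreline
development index is implemented as `DL = L/(2√(πA))`, the standard form in
which a circle scores exactly 1.

### Community GAMs

Each taxon column of the predicted-probability matrix is regressed on the
same smooth terms with a quasibinomial family (logit link, free dispersion
estimated from Pearson residuals). Smooths are penalized B-splines: nine
cubic basis functions with a second-difference penalty per univariate term,
and a 4×4 tensor-product surface (16 functions ≤ the 18-function cap) when
longitude and latitude are selected together. Penalized B-splines were
preferred to thin-plate bases as the smoother family: same penalized-spline
class and effective degrees of freedom, simpler and numerically robust at
n ≈ 30–60, and directly comparable to mgcv's `bs='ps'` smooths, which serve
as the independent oracle in the test suite. The total budget is 27 basis
functions (3 variables × 9), enforced; each block absorbs a sum-to-zero
constraint (B-splines sum to one, so the constant must be removed for the
intercept to stay identifiable).

A single smoothing parameter shared across terms is selected per taxon by
GCV on the working penalized least-squares problem (grid `10^-4 … 10^7`,
14 points, Demmler–Reinsch reparameterization, re-converged after
selection). Community-level summaries pool over taxa on the response scale:

```
R² = 1 − Σ_j RSS_j / Σ_j TSS_j
adjR² = 1 − (1 − R²)(n − 1)/(n − 1 − EDF)
```

with EDF the average per-taxon effective degrees of freedom (trace of the
hat matrix, intercept excluded) — an Ezekiel-type adjustment in which EDF
replaces the parameter count, so that irrelevant smooths contribute ≈ 0 in
expectation (verified by null simulation). A deviance-based pooling switch
exists for sensitivity analyses.

### Forward selection

Candidates are the three environmental PCs, or longitude and latitude
(selected separately, per predictor set). The double-stopping procedure:

1. **Global gate.** The whole-candidate-set model must be significant at α;
   otherwise nothing is selected. This gate is what controls the family
   type-I error of selection (without it, the best of three candidates
   passes α = 0.05 by chance ~14% of the time).
2. **Stepwise.** Add the candidate with the largest adjusted-R² gain among
   those whose addition is significant, stopping when none qualifies or
   when the cumulative adjusted R² would exceed the global model's.
3. **Fallback.** If the stepwise pass selects nothing despite a significant
   global model, the single most significant candidate is kept if it passes α.
4. **Cap.** If environment + space together exceed three variables, the
   weakest contributors (by single-variable adjusted R²) are dropped.

Significance uses a pooled F statistic on response-scale residual sums of
squares. The numerator degrees of freedom are the *added basis rank* (not
the fitted EDF): a reference-df test that is conservative for GCV-selected
smooths, because a penalized fit cannot reduce the RSS more than the
unpenalized basis regression the df describe. EDF-based df are available
for diagnostics but are anti-conservative under smoothness selection
(measured: ~16% null selection rate vs. ≤ 5% with reference df). When both
coordinates are in a model they are fitted as one 2-D surface, reconciling
separate candidacy with a joint spatial trend.

### Variation partitioning and the spectral-randomization correction

Fractions follow the standard identity from the three community fits
(E-only, S-only, E+S); an empty side contributes adjR² = 0, so all explained
variation loads on the other pure component. The identity holds to 1e-10 by
construction and is asserted in the tests.

Spatially autocorrelated environments can explain spatially autocorrelated
communities with no causal link. The correction replaces the Ezekiel
penalty for the environmental component with a Moran-spectral-randomization
null: each selected environmental predictor is decomposed on the complete
(n−1)-column MEM basis and rebuilt with randomized coefficient signs, and

```
adjR²_MSR(E) = 1 − (1 − R²(E)) / (1 − mean_r R²(E_r))
```

The E+S model is corrected the same way (surrogate environment + observed
space); S-only keeps its classical adjustment; corrected fractions follow
the partition identity on the corrected quantities. Three implementation
points matter and were established by simulation on the `confounded` preset
(spatialized environment, env-independent spatialized species):

- **One sign per eigenvector, shared across the predictor block.** This
  preserves each variable's spatial power spectrum (hence its Moran's I)
  *exactly* and the block's cross-product structure (PC scores stay
  orthogonal). Independent per-variable flips decorrelate the block and
  understate the null R² by the lost joint-fit efficiency.
- **Surrogate refits re-run GCV.** Freezing the smoothing parameter at the
  observed fit's value understates the null (the observed flexibility is
  tuned to the observed alignment); with GCV re-run the corrected
  environmental component is unbiased on the confounded null
  (mean ≈ 0.01 ± 0.03 at 40 sites, 100 replicates, against an uncorrected
  mean ≈ 0.31).
- **No within-spectrum rotation.** A spectral-window rotation null was
  evaluated and rejected: it smears the concentration that genuine
  broad-scale variables share with broad-scale community structure and
  over-corrects.

Default 199 surrogates (≥ 19 required); the calibration tests use 39 to
keep their replicate counts affordable.

### MEM basis

Distance-based Moran eigenvector maps: binary connectivity (pairs closer
than the longest minimum-spanning-tree edge), doubly centered,
eigendecomposed on the centered subspace via a Helmert basis so all n−1
columns are exactly centered and orthonormal even with degenerate spectra.
All n−1 eigenvectors are kept, ordered by decreasing eigenvalue —
broad-scale, positively autocorrelated patterns first. Keeping the full
spectrum (not only positive eigenvalues) is required for the
spectral-randomization step, which must reconstruct arbitrary centered
variables exactly; the simulator draws only from the broad-scale
(positive-eigenvalue) subset. Geographic coordinates use great-circle
distances (sphere radius 6371 km); planar coordinates use Euclidean.

### PERMDISP

Gower-centered principal-coordinate embedding of the (Euclidean) distance
matrix with negative-eigenvalue axes tracked separately; distance of a site
to its group centroid is `√(max(d²_real − d²_imag, 0))`. The test statistic
is the one-way ANOVA F on those distances, with a permutation p-value from
reshuffling distances across groups, `p = (1 + #{F_perm ≥ F_obs})/(1 +
n_perm)` (default 999 permutations). Centroids, not spatial medians;
variables should be transformed and jointly standardized first
(`standardize_jointly`). Type-I error is calibrated (0.04–0.07 at α = 0.05
in 500-simulation checks); the scikit-bio centroid PERMDISP statistic
matches to numerical precision.

## The synthetic generator

The generator emulates the structure of a two-region temporary-pond survey:
~30 sites scattered over a square extent, an environment table whose
variables measure a few latent gradients (spatial gradients are
combinations of broad-scale MEMs; nonspatial ones white noise; observation
noise sd 0.5 relative to the unit-variance gradient), and species whose
logit-occurrence responds to those gradients, to independent broad-scale
spatial gradients, and to a shared latent site effect, with intercepts
solved by bisection so each species hits the target mean prevalence (0.35
by default, giving realistic sparsity without mass degeneracy).

The variable-level correlation structure is deliberate: PCA reduction to
three components is only informative when many variables reflect few
gradients, as in real environmental tables (where three components carry
roughly half the variance of ~49 variables). Without it, a three-component
reduction of independent variables dilutes any signal.

Presets fix the study conditions used in calibration:

| preset | environment effect | spatial effect | notes |
|---|---|---|---|
| `null` | 0 | 0 | latent site effect only (σ = 1) |
| `env_only` | β = 2 on 2 nonspatial gradients | 0 | |
| `space_only` | 0 | β = 2 on 2 broad-scale gradients | environment pure noise |
| `mixed` | β = 2.5, half the taxa | β = 2, other half | one gradient per process |
| `confounded` | 0 | β = 2 | spatialized environment, env-independent spatialized species |

Effect sizes are logit-scale per gradient standard deviation; β = 2 is a
strong but realistic niche response (odds ratio ≈ 7.4 across one gradient
SD). What the generator does **not** emulate: temporal/hydroperiod
dynamics, species interactions, abundance information, observation error in
the community matrix, non-Gaussian environmental gradients, and anisotropic
or network-structured (stream-like) spatial processes. Passing tests
therefore demonstrate calibration and recovery under species-independent
Bernoulli sampling with smooth monotone responses — not robustness to
interaction-driven or temporally autocorrelated structure.

## Numerical details

- Degenerate inputs: all-0/all-1 taxa retained and flagged; constant
  environmental variables dropped from PCA with a warning; constant
  response columns contribute zero to pooled sums and force `p = 1` in the
  F test; groups with a single site are rejected by PERMDISP.
- PIRLS: weights floored at 1e-8, convergence at 1e-9 on the linear
  predictor, 60 iterations max; a 1e-9 ridge keeps penalized systems
  positive definite at λ → 0.
- GLLVM: convergence at relative ELBO change < 1e-8, 500 iterations; a
  1e-8 ridge conditions the taxon updates.
- Every stochastic stage takes an explicit seed; the pipeline derives
  per-(group, stage) seeds from the master seed by CRC hashing (all below
  2^31), so multi-group runs are bit-reproducible and groups are
  independent of each other's presence.
- Per-group isolation: an error in one group marks it failed in the summary
  without aborting the rest.
- Problem sizes in the shipped calibration tests (60 sites × 40 taxa × 200
  replicates for null calibration; 40 × 15 × 100 for the confounded
  correction; 500 simulations for PERMDISP) were chosen as the smallest
  sizes at which the binomial Monte-Carlo error is well inside the asserted
  bands.

## Known limitations

- The adaptation of the spectral-randomization adjustment from the linear
  redundancy-analysis setting to smooth GAM fits is this package's own
  defined procedure; its unbiasedness is established here by simulation,
  not by published theory.
- The pooled F tests are pragmatic surrogates for smooth-term inference;
  they are calibrated empirically (conservative by design), and their power
  against weak multi-gradient signal is limited — diffuse environmental
  effects split across many latent axes can go unselected.
- The variational bound underestimates the marginal likelihood; AIC
  comparisons inherit whatever bias differs across dimensions (in practice
  rank recovery is exact in the shipped checks).
- With ~30 sites, a three-variable cap and nine basis functions per
  variable are hard constraints, not tuning choices; analyses of richer
  designs should revisit both.
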