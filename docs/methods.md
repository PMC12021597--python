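# Methods

`commdyn` packages the statistical machinery used to analyse long-running,
monthly-sampled, multi-domain microbial community surveys (the motivating
system is activated sludge monitored over more than a decade): coverage
normalization and filtering, alpha diversity, Bray–Curtis ordination,
Procrustes congruence, association screens, and — centrally — regularized
S-map inference of time-varying interaction strengths. Every stage is
exercised against a synthetic community generator with known ground truth,
so all recovery claims are testable without any sequencing data.

## Synthetic community model

The generator is a discrete-time (Ricker-form) generalized Lotka–Volterra
map on the monthly grid:

    x_i(t+1) = x_i(t) · exp( r_i + s_i sin(2πt/P + φ_i) + Σ_j a_ij x_j(t) + ε_i(t) )

with intrinsic rates `r_i` (1/month), seasonal amplitude `s_i`
(dimensionless) and phase `φ_i`, period `P = 12` months, per-capita
interaction coefficients `a_ij` (1/abundance/month, diagonal ≤ 0 for
self-limitation), and Gaussian log-scale process noise. A discrete map was
chosen over a continuous ODE because the downstream S-map operates on the
same monthly transition structure; no integrator is needed and the map's
Jacobian is available in closed form,

    J_ij = x_i(t+1)·a_ij + δ_ij·x_i(t+1)/x_i(t),

which is the ground truth for all interaction-recovery tests (verified
against central finite differences to 1e-6 relative error).

Random parameter draws are kept inside a stability envelope: `a_ii` uniform
in [−0.2, −0.05], sparse Gaussian off-diagonals rescaled until the
linearization at the all-ones equilibrium has spectral radius below 0.8,
and growth rates set to `r = −A·1` so that all-ones is an equilibrium. The
simulator never emits zeros; divergence (non-finite or > 1e12) raises an
error naming the first offending taxon and step.

Around the deterministic skeleton the module emulates features of a real
monitoring campaign:

- **Transient intervention** — a one-step multiplicative mortality pulse
  (survival fraction in (0, 1]) emulating a bleach dosing event; duration
  and strength are user parameters because no dose–response is assumed.
- **Finite-depth sampling** — per-sample multinomial read counts with
  probabilities ∝ abundance × feature length, so TPM normalization of the
  counts is unbiased for the underlying composition as the library grows.
  Column sums equal the library size exactly; zero counts are possible and
  tolerated downstream.
- **Operational metadata** — salinity around 1.2% with a sustained
  11-month dip, an annual temperature sinusoid, an autocorrelated MCRT
  random walk, and one covariate constructed as
  `ρ·z(taxon) + sqrt(1−ρ²)·N(0,1)` so its population correlation with the
  chosen taxon is exactly ρ (default 0.7, checked by Monte Carlo to ±0.05
  over 500 replicates).

What the generator does **not** emulate: sequence-level artifacts (no
FASTQ), compositional closure effects of real mapping pipelines, RNA
viruses, phage–host infection mechanics, or the magnitudes of any
particular historical event. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not field accuracy on
real metagenomes.

## Normalization and filtering

- **TPM-like coverage normalization**: per-feature counts are divided by
  feature length and each sample rescaled to sum to 1e6. Invariant to
  uniform rescaling of lengths and of any one sample's counts; all-zero
  samples are an error. Normalization is applied *after* multi-mapped read
  removal (the order is otherwise unconstrained by the protocol the package
  mirrors).
- **Multi-mapping filter**: a read is assigned to a domain iff all its
  maximum-score alignments fall in that domain; reads whose top score is
  shared across domains are "unclassified". Ties *within* a domain do not
  unclassify — the unclassified category is defined across domains. The
  interface is a minimal 4-column alignment digest (read, target, domain,
  score); SAM/BAM parsing is deliberately out of scope.
- **rRNA gene-equivalents**: aligned base pairs divided by the mean SSU
  gene length, 1408 bp (16S) or 1705 bp (18S); read counts are converted at
  a configurable read length (default 150 bp).
- **Occurrence filter**: keep features present (> 0, no epsilon — TPM zeros
  are structural) in strictly more than 10% of samples; at 143 samples this
  keeps 15/143 and drops 14/143. Idempotent.

## Diversity

Shannon entropy in nats (natural log), richness as strict-positive count,
Pielou's evenness `H/ln(S)` (undefined flag, NaN, when S < 2). No
rarefaction is applied.

## Ordination

Bray–Curtis is computed pairwise with contiguous 1-D reductions so results
are bit-identical to the naive double-loop definition. PCoA Gower-centers
−d²/2 and eigendecomposes; negative eigenvalues are reported and their axes
dropped (no Cailliez/Lingoes correction). NMDS minimizes Kruskal stress-1
by alternating isotonic regression of configuration distances on the
dissimilarities (ties averaged within blocks, the primary approach) with a
Guttman/SMACOF configuration update; 20 random starts plus one PCoA start
by default, all threaded from one seed. The recorded stress sequence is
non-increasing by construction: an iteration that would raise stress-1
(possible because the normalization term changes between iterations) ends
the run on the previous configuration.

## Procrustes and protest

Symmetric protocol matching the protest convention: both configurations
centered and scaled to unit total sum of squares, rotation from the SVD of
YᵀX, M² = 1 − (Σσ)² ∈ [0, 1], symmetric in its arguments. Configurations of
unequal dimensionality are zero-padded with a warning. The permutation test
reorders rows of one configuration (999 permutations by default) and uses
the add-one p estimator, so p is never exactly 0; permuted M² values are
computed in a single batched SVD because centering and total sum of squares
are permutation-invariant.

## Regularized S-map

For each target time n\* and each target taxon i, the package solves

    ĉ = argmin_c (1/N) Σ_n w_n (y_{n+1} − X_n c)² + λ(α‖c‖₂² + (1−α)|c|₁)
    w_n = exp( −θ‖X_n − X_n*‖ / mean_n‖X_n − X_n*‖ )

and stores the coefficient of taxon j as the Jacobian element J[i, j, n\*].
Numerical and interpretive choices:

- **Penalty orientation**: α multiplies the *squared*-norm term — the
  mirror image of the glmnet convention (glmnet's mixing parameter equals
  1 − α here). The form is kept as stated above and the mapping documented
  rather than silently reparameterized.
- **Weights**: training transitions are the N−1 state pairs with a
  successor. The denominator of the weight formula is the mean distance
  over training states and by default includes the target's own zero
  self-distance when the target is a training state (`include_target_in_mean`
  flips this; the formula's sum is ambiguous on the point). θ = 0 gives
  uniform weights; the target transition, when included, has weight 1.
- **Normalization factor**: the 1/N factor keeps N = series length even
  though only N−1 transitions train — it only rescales λ, and keeping it
  as written makes reported λ values comparable.
- **Solver**: cyclic coordinate descent on weighted-centered data with
  soft-thresholding for the absolute-norm part, unpenalized intercept,
  convergence when the largest coefficient change in a sweep < 1e-8 (cap
  1e5 sweeps, non-convergence returns the last iterate with a warning).
  The objective is non-increasing across sweeps. When the L1 weight
  λ(1−α) is exactly 0 the problem is a pure weighted ridge/OLS and is
  solved in closed form — this makes the unregularized limit exact rather
  than iteratively approximate.
- **Standardization**: series are z-scored per taxon (zero-variance taxa
  removed with a log message); Jacobians are reported in standardized units
  with an optional back-transform `J_raw[i,j] = J_std[i,j]·sd_i/sd_j`. The
  target transition is retained in its own local regression (weight 1) but
  held out during leave-one-out tuning.
- **Tuning**: grid search minimizing leave-one-out forecast RMSE across
  taxa (standard empirical-dynamic-modeling practice); default grids
  θ ∈ {0, 0.1, 0.5, 1, 2, 4, 8}, λ ∈ 10^{−4..0} (7 points), α = 0.5.
  Ties break toward smaller θ, then larger λ. LOO tuning costs
  grid × taxa × (N−1) fits; use reduced grids for long series.
- **Summaries**: per ordered pair, median and IQR of J over time. Pairs
  whose two directed IQRs both exclude zero are classified: opposite-signed
  medians → "exploitation" with the predator being the taxon whose growth
  benefits (positive incoming median); both positive → "mutualistic-like";
  both negative → "competition-like".

## Association statistics

Pearson screens use the t transform with n−2 df and a Bonferroni multiplier
equal to the number of tests actually performed (zero-variance pairs are
skipped and logged); a Benjamini–Hochberg mode is available because
family-wise control is often stricter than needed. The Mantel statistic is
the Pearson correlation of upper-triangle entries with simultaneous
row/column permutation of one matrix. PERMANOVA is the standard one-factor
distance partition (pseudo-F with g−1 and n−g df, R² = SS_between/SS_total,
label permutation). Cross-correlation z-scores both series and reports
r(ℓ) for ℓ ∈ [−max_lag, max_lag] with a ±1.96/√(N−|ℓ|) envelope; positive
lag means y lags x (y's later values are compared with x now).

## Benchmarks used by the acceptance checks

- **Linear system**: x(t+1) = A x(t) + ε with ε sd 0.01, N = 200, 8 taxa;
  A is 0.95 × a seeded random orthogonal matrix. The rotation-like A keeps
  the trajectory persistent and the regression design well conditioned, so
  identification error measures solver correctness rather than
  collinearity; a generic decaying random A conflates the two.
- **gLV benchmark**: a fixed 8-taxon cross-domain web (four prokaryotes,
  three eukaryotes, one phage-like virus) with three predator–prey pairs,
  one host–phage pair, one competitive and one mutualistic pair; effect
  floor |a_ij| ≥ 0.05, equilibrium at all-ones, noise sd 0.05, seasonal
  amplitude 0.05, N = 150; inference protocol θ = 1, λ = 1e-4, α = 0.5.
  The designated exploitation pair for the asymmetry-flag check is
  E1 → P1 (a[E1,P1] = +0.10, a[P1,E1] = −0.12).

## Problem sizes and defaults

The demo pipeline simulates 12 taxa × 143 monthly samples, library size
1e5, pulse at month 30, NMDS with 10 starts, 999 permutations for all
tests, and S-map at θ = 1, λ = 0.01, α = 0.5 — a size chosen so the whole
run, including two-run determinism checks, completes in well under five
minutes on one CPU while exercising every stage at realistic dimensions.
All pipeline randomness expands from one root seed via
`SeedSequence([root, stage_index])`, recorded in the run manifest.

## Known limitations

- The S-map reports standardized coefficients by default; raw-scale
  back-transforms assume the standardization was estimated on the same
  window being analysed.
- PERMANOVA is one-factor only; no strata/two-factor designs.
- NMDS stress comparisons across different dissimilarity matrices are not
  meaningful (stress-1 is scale-free only within a matrix).
- The multinomial sampling model ignores mapping ambiguity; the
  multi-mapping filter is tested on digest fixtures, not on real aligner
  output.
- Compositional effects (closure) are not corrected anywhere; correlations
  on TPM values share the usual caveats of relative-abundance data.
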