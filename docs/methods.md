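# Methods

## The microbial mixed linear model

For each trait and each sample subset (gut section × sample type) the model
is

    y = Xb + m + e

- `y` — trait records, one per animal. Behavioral traits are non-negative
  counts over an observation period; when raw counts are supplied the
  pipeline Box-Cox transforms them first (see below). The synthetic
  generator emits traits directly on the transformed (Gaussian) scale, so
  the Box-Cox step is optional there.
- `Xb` — fixed effects: an intercept, the selection line (reference-level
  dummy coding, first level alphabetically as reference), and optionally the
  run × pen combination. The combination enters only "if significant": a
  joint F-test of its dummies in the fixed-effects-only OLS model at
  α = 0.05 (per trait; the decision and its p-value are recorded in the
  output). Levels confounded with line are dropped with a warning.
- `m ~ N(0, M σ²ₘ)` — the random microbial animal effect. `M = XXᵀ/N` where
  `X` (n × N) holds standardized, log-transformed OTU relative abundances.
- `e` — residuals, heterogeneous across lines: `Var(e_i) = σ²ₑ,ₗ(i)`. A
  single-line subset reduces to one residual variance; the same fitting code
  serves the per-line analyses (no line fixed effect in that case).

Microbiability per line is `m²ₗ = σ²ₘ/(σ²ₘ + σ²ₑ,ₗ)` — the denominator is
the phenotypic variance within a line after fixed effects, which is what the
two variance components sum to under this model. Variance attributable to
fixed effects is deliberately not in the denominator; the worked-example
arithmetic of the published component table is consistent with this
definition.

## Preprocessing contract

1. **Filter**: keep OTUs whose mean per-sample relative abundance strictly
   exceeds 10⁻⁶ (0.0001%). Filtering is idempotent.
2. **Transform**: total-sum scale each sample; add a pseudocount; take
   natural logs. Neither the source analyses nor standard practice fix the
   pseudocount, so the default is half the smallest nonzero relative
   abundance in the filtered table (scale-aware, conventional), overridable.
3. **Standardize**: center each OTU column and divide by its population
   (÷n) standard deviation, so each column satisfies Σx² = n exactly.
   This makes trace(M) = n, which keeps σ²ₘ interpretable on the phenotypic
   scale and gives a clean test invariant. Constant columns are dropped with
   a warning.
4. Standardization is applied within each analyzed subset (the model is run
   separately per gut section × sample type), not across all samples
   jointly; whether the original analysis did the former or the latter is
   not documented, and within-subset is the choice consistent with fitting
   each subset as a self-contained model.

**Box-Cox**: y(λ) = (yᵒ − 1)/λ, log y at λ = 0, with λ estimated by profile
maximum likelihood (scipy's Brent-based optimizer). Traits are counts with
zeros, so +1 is added before the transform (overridable); no shift value is
documented for the original analysis and +1 is the minimal standard choice.

**Diversity**: Shannon H = −Σ p ln p (natural log) and Pielou J = H/ln S,
with J reported missing for single-OTU samples; both computed via
scikit-bio.

## REML estimation

θ = (σ²ₘ, σ²ₑ,HFP, σ²ₑ,LFP) maximizes the restricted likelihood

    ℓ_R(θ) = −½ [ log|V| + log|XᵀV⁻¹X| + yᵀPy ] − (n−p)/2 log 2π,

V = σ²ₘM + Σₗ σ²ₑ,ₗ Dₗ. Updates are average-information (AI) steps with
step-halving; when no damped AI step improves ℓ_R (or the proposal leaves
the parameter space) an EM-REML step is taken instead, which is ascent by
construction. Convergence: |Δℓ_R| < 10⁻⁸ and relative parameter change
< 10⁻⁶; at most 200 iterations, then a convergence error carrying the full
trajectory.

- **Bounds and boundary fixing**: components are constrained to
  ε_b = 10⁻⁶ · var(y). A component sitting at ε_b for 3 consecutive
  iterations is flagged "fixed at the boundary", held there, excluded from
  further AI updates, and its standard error reported as missing (NA).
- **Standard errors**: square roots of the diagonal of the inverse AI matrix
  over free components at the optimum (observed average information; no
  sandwich correction).
- **Starting values**: σ²ₘ = 0.1·var(y), σ²ₑ,ₗ = 0.9·var(yₗ).
- **Degenerate kernels**: with M = I and homogeneous residuals only
  σ²ₘ + σ²ₑ is identifiable; the AI matrix is singular and the solver falls
  back to least-squares/EM steps, converging in the identifiable direction
  (tested against the closed-form OLS REML variance).

**Likelihood-ratio test**: D = 2(logL_full − logL_reduced), clipped at 0,
referred to χ²₁ — the convention of the ASReml-style analyses this package
mirrors. Because the null hypothesis places σ²ₘ on the boundary, χ²₁ is
conservative; the asymptotically correct 50:50 χ²₀:χ²₁ mixture p-value is
reported alongside as `p_value_mixture`. When σ²ₘ is fixed at the boundary
the full and reduced models coincide, so D = 0 and p = 1 by construction.

## Community statistics

- **Bray-Curtis** on total-standardized abundances, stored as dissimilarity
  in [0, 1] (PRIMER's 0–100 similarity is a reported conversion, not the
  storage format).
- **PERMANOVA**: Gower-centered matrix G = −½ JD²J partitioned sequentially
  over the declared terms (type-I SS, so the partition sums to the total
  SS). The p-value for each term comes from permuting the residuals of the
  model reduced to the preceding terms (G residualized by the reduced-model
  projector, rows/columns permuted, pseudo-F recomputed with the full-model
  residual). All n! arrangements are enumerated when n! ≤ 10⁵, otherwise
  B = 999 (default) Monte-Carlo permutations with p = (#{F* ≥ F} + 1)/(B+1).
  The exact tie-handling and permutation scheme of PRIMER's implementation
  is not fully documented; p-values on the same data may differ in the third
  decimal.
- **NMDS**: non-metric SMACOF (scikit-learn) minimizing Kruskal stress-1;
  defaults k = 2, 20 restarts, 300 iterations, best restart reported with a
  convergence flag.
- **SIMPER**: per-OTU averages of |x_ij − x_kj| / Σ_j(x_ij + x_kj) over all
  between-group pairs, so contributions sum exactly to the mean
  between-group Bray-Curtis dissimilarity. Two-group designs only.

## Synthetic data generator

The generator emulates the features of the study design that the analysis
depends on, with every parameter recorded as ground truth:

- **Design**: two lines (HFP, LFP) of 96 and 73 animals (the ileum-mucosa
  subset sizes), two experimental runs, pens assigned round-robin within
  line; pen effects default to 0 but can be drawn with a configurable SD.
- **Compositions**: OTU log-abundance means are N(0, 1.5²) (log-normal
  rank-abundance curve); line divergence adds a fixed shift to a random 20%
  of OTU log-means for the second line. Per-sample composition is
  Dirichlet(c·p_line) with concentration c = 50 (strong overdispersion and
  zero inflation at the default 200 OTUs); counts are multinomial with a
  Poisson library size, default 44 240 reads (the study's mean per sample).
- **Traits**: m is drawn once per dataset from N(0, σ²ₘM) using the M built
  from the simulated table by the same preprocessing the analysis applies —
  so the generative kernel and the fitted kernel coincide and microbiability
  is identifiable by construction. A single m vector is shared by the three
  traits (each gets independent line-heteroscedastic residuals). Defaults:
  σ²ₘ = 0.1, σ²ₑ = {HFP: 0.8, LFP: 0.4}, line effect 1.0 — the scale of the
  reported component estimates.
- **Factorization jitter**: M is rank-deficient whenever N < n, so the
  Cholesky factor is computed with diagonal jitter δ = 10⁻⁸·mean(diag M),
  doubled at most 10 times before a numerical error is raised.
- **Determinism**: each operation derives its own seed stream from the
  config seed, so `simulate_otu_counts` and `simulate_traits` are
  individually reproducible and independent of call order.

What the generator does **not** emulate: phylogenetic correlation between
OTUs, sequencing-depth artifacts beyond Poisson library-size variation,
taxonomic structure, true count-scale (zero-inflated) behavior traits, or
any real causal pathway from microbiome to behavior — the trait model is an
assumption for testing estimator behavior, not a biological claim. Passing
recovery tests therefore show that the estimator is consistent under its own
model, not that real behavioral data carry microbial signal.

## Problem sizes used in the validation suite

Chosen as the smallest sizes at which the statistical claims are sharp:
parameter recovery uses 200 replicates of n = 400 animals with 120 OTUs and
library size 5000 (well-spread M, tight Monte-Carlo SEs); the REML-vs-grid
oracle uses n = 12 with a three-stage coarsened exhaustive grid (50 points
per axis per stage, two zooms — effective per-axis resolution far finer than
a single 200-point sweep); PERMANOVA calibration uses 500 null datasets of
24 samples at B = 199; LRT null calibration uses 120 datasets of 30 animals.

## Pipeline and reproducibility

Each analysis cell (subset × trait) is isolated: an error is recorded in the
report and other cells proceed. Every randomized stage (simulation,
permutation tests, NMDS restarts) receives a sub-seed spawned from the run
seed and a stage key, so adding or reordering stages does not perturb the
others. The report JSON is byte-identical across runs with the same config
and seed; wall-clock timestamps are written to `run.log` only, and the
report's provenance block carries the config hash, seed, and package
version. The relationship matrix serializes to TSV at 17 significant digits
and round-trips exactly (reads use pandas' round-trip float parser).

## Known limitations

- The AI-REML SEs are asymptotic; at n ≈ 100–200 the sampling distribution
  of σ̂²ₘ is markedly skewed and single-dataset m² estimates are noisy (the
  README example shows this honestly).
- PERMANOVA terms are sequential (order matters in unbalanced designs),
  matching the reduced-model permutation scheme; marginal (type-III) tests
  are not implemented.
- No UniFrac or other phylogeny-aware kernels; no rarefaction; one random
  microbial kernel only (no multi-kernel or genomic relationship models).
- BIOM-format input is not implemented; OTU tables are TSV.
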