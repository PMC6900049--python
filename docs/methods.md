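# Methods

This note records the statistical models implemented in `gpcattle`, the
defaults and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the design decisions that were
genuinely open.

## Animal model and GBLUP

All analyses use the mixed model `y = Xb + Zg + e`. Fixed effects are an
intercept, treatment-coded gender/farm/year factors (first level as
reference; constant factors contribute no columns; aliased columns are
dropped with a warning) and a centred slaughter-age covariate — omitted
for average daily gain, which is itself a rate over the rearing period.

The genomic relationship matrix is VanRaden's method 1,
`G = WW′/Σ 2pⱼ(1−pⱼ)` with `wᵢⱼ = zᵢⱼ − 2pⱼ` and observed allele
frequencies (no base-population frequencies exist for this design; method 1
is also what makes GBLUP exactly equivalent to SNP-BLUP ridge regression,
which the test suite exploits as an algebraic oracle). A ridge of
`10⁻⁶ × mean(diag G)` may be added when a factorization requires strict
positive definiteness; it is part of the documented solver policy so runs
are bit-reproducible.

REML maximizes the restricted likelihood of `y ~ N(Xb, Gσa² + Iσe²)`
profiled over `λ = σa²/σe²`: after one eigendecomposition `G = UDU′`, the
rotated model has diagonal covariance and each profile evaluation is
`O(np²)`. `λ` is searched in log-space on `[10⁻⁶, 10⁶]` by bounded Brent
(tolerance 10⁻¹⁰ in log λ); estimates at the search edge are flagged, not
errored. `σe²` then has a closed form. This is exact and derivative-free
for one genomic component; AI-REML iteration would add nothing at n ~ 10³.
The SE of `h²` comes from the inverse average-information matrix at the
optimum via the delta method, computed in the rotated basis. A GRM that is
numerically a multiple of the identity is rejected as non-identifiable
(only the total variance is then estimable).

GBLUP solves the mixed-model equations on the reference animals via a
Cholesky factorization of `V = σa²G_rr + σe²I` and predicts masked animals
through the conditional mean `ĝ_val = G_vr G_rr⁻¹ ĝ_ref` — algebraically
identical to solving the MME with empty records, cheaper, and it makes the
phenotype masking explicit. Variance components are re-estimated on each
training fold by default (no leakage); a switch reuses the full-data fit.

## Bayesian whole-genome regression

Priors are as in the README table. Numerical and algorithmic choices:

* **Slab scale.** `Sa² = (v−2)·E(σⱼ²)/v` with `v = 4.2`. `E(σⱼ²)` spreads a
  prior genetic variance (by default the REML `σ̂a²`) over the expected
  non-null heterozygosity: `E(σⱼ²) = σ̂a² / ((1−π) Σ 2pⱼqⱼ)`, with π = 0
  for BayesA, the fixed π for BayesB (default 0.95 — the model treats
  BayesB's π as known, and 0.95 is the conventional choice), and the
  initial π = 0.5 for BayesCπ.
* **Spike sampling.** Inclusion indicators are drawn with the marker effect
  analytically integrated out (the marginal likelihood of the single-site
  right-hand side under slab vs spike), replacing the historical
  Metropolis–Hastings step with a plain Gibbs update that has the same
  stationary distribution. Variances of excluded markers are refreshed
  from the prior — their exact conditional when the effect is pinned at
  zero.
* **BayesR.** Component variances are `(0, 10⁻⁴, 10⁻³, 10⁻²) × σg²` with
  `σg²` fixed at the REML estimate by default; an option re-draws it from
  the current effects each sweep (both conventions circulate). Mixture
  proportions get a `Dirichlet(counts + 1)` update.
* **Residual variance** uses a scaled-inverse-χ² prior with df = −2 and
  scale 0, i.e. flat on σe²; draws are `r′r / χ²_{n−2}` and are positive by
  construction.
* **Mechanics.** Markers are updated in fixed ascending order (bit
  reproducibility beats the marginal mixing gain of random scans); dosage
  columns are centred internally, which shifts only the intercept and
  leaves `α` unchanged; chains default to 50 000 cycles with 10 000
  burn-in; posterior means of `α` use every post-burn-in draw while the
  thinning interval (10) applies only to stored scalar traces. Kernels are
  numba-compiled with the residual-update trick, so one marker update
  costs two length-n passes.

## Quality control

Filters use strict inequalities — keep MAF > 0.05, missing proportion
< 0.05, HWE p > 10⁻⁶ (1-df χ² goodness of fit; monomorphic markers return
p = 1 by convention) — applied missingness → MAF → HWE, with telescoping
per-stage counts reported. LD pruning scans greedily left-to-right within
each chromosome: a marker is dropped when its r² with any already-kept
marker in the trailing 100-marker window exceeds 0.995, so the left
(lower-position) member of a correlated pair survives and the procedure is
idempotent. Pruning runs before imputation by default; missing dosages are
then mean-imputed (2pⱼ, real-valued) — a deliberately simple stand-in for
haplotype-based imputation, adequate at the <5% missingness the filters
guarantee.

## Evaluation

`n` animals are partitioned into k = 5 balanced folds (sizes differ by at
most one; at n = 1217 this gives the 974/243 reference/validation split),
repeated 10 times. Corrected phenotypes use fixed-effect estimates from
the full-data REML fit (per-fold correction is available by flag), and the
accuracy denominator `√h²` likewise uses the full-data estimate, matching
the usual pairing of published heritability and accuracy tables.
Aggregation is the unweighted mean of per-fold statistics, then of
per-trait means; rounding happens only at presentation. The MSE criterion
is the mean of squared differences `Σ(GEBVᵢ − ŷᵢ)²/N`; undefined
correlations (zero variance) are reported as NaN, never silently as 0.

## Synthetic data

The generator emulates exactly the structure the models assume:

* **Genotypes.** Two haplotypes per animal, each a first-order
  haplotype-copying chain: the allele at marker j+1 copies marker j's
  allele with probability `ld_decay`, else is drawn fresh at that marker's
  frequency (uniform on `maf_range`, default (0.05, 0.5)). One parameter
  gives monotone adjacent-marker r²; the induced marginal frequencies are
  the geometric smoothing `f_{j+1} = ld·f_j + (1−ld)·p_{j+1}`, available in
  closed form for tests. Default `ld_decay = 0.9` (adjacent r² ≈ 0.8),
  the dense-LD regime of a high-density array — the setting in which
  marker-based relationships carry real information at herd-scale n.
  Missingness is completely at random.
* **Effects** come from the normal, point-normal or four-component
  architecture; realized effects are rescaled so `var(Zα)` equals the
  requested genetic variance exactly, which makes recovery tests sharp.
  (The rescaling changes component variances by the factor
  `1/(M Σ pₖcₖ)`; the mixture-recovery study therefore skips it and draws
  effects at the exact component variances.)
* **Phenotypes.** `y = Xb + g + e` with σe² set from the realized `var(g)`
  and the target h², so the realized heritability is exact. Fixed-effect
  level values are drawn once per level with spread equal to the
  phenotypic SD, and the age slope is a small fixed constant (0.1
  phenotypic SD per age-SD) — the magnitudes are conventions, since only
  the factor structure is prescribed.

Not emulated: pedigree/family structure, selection, coalescent-realistic
LD, genotyping error, non-random missingness. Passing recovery tests
therefore show correctness of the estimators under their own assumptions,
not robustness to real-data violations of them.

## Validation studies and their sizing

* REML recovery runs 200 replicate phenotypes per truth (h² = 0.10, 0.47)
  on one 500 × 5000 dense-LD panel, re-drawing effects, fixed effects and
  noise each replicate after a single eigendecomposition. With weakly
  related individuals instead, the sampling SD of ĥ² at this n is ~0.14
  (GREML information scales as N/√(2 M_eff)) and the bounded, skewed
  finite-sample distribution shifts the replicate mean — a property of the
  estimator, not the implementation, and the reason the study is run in
  the dense-LD regime.
* The BayesCπ study (M = 1000, n = 800, h² = 0.5, 20 000 cycles) recovers
  π = 0.95 within ±0.05.
* The BayesR mixture study is sized by a non-centrality argument:
  component 3 (variance 10⁻³σg²) becomes detectable when
  `n·2p̄q̄·10⁻³·σg²/σe² ≈ 2`, i.e. n = 2000 at h² = 0.8, while component 2
  (10⁻⁴σg²) is confounded with the spike at any desk scale — the posterior
  is flat along the p₁/p₂ direction, so the study's truth places equal
  mass there (0.425/0.425/0.10/0.05, near the self-consistency constraint
  `M Σ pₖcₖ ≈ 1`) and element-wise recovery within ±0.1 over 10 seeds is a
  meaningful check of everything the data can identify.
* The cross-validation benchmark (n = 500, M = 2000, h² = 0.5, 5 folds ×
  10 repeats × 5 methods) uses 800-cycle chains: posterior-mean GEBVs
  stabilize far faster than scalar posteriors, and the benchmark scores
  only GEBVs.

## Known limitations

* Single-trait, single-variance-component models only; no pedigree or
  single-step matrices.
* Mean imputation ignores haplotype information; with >5% missingness a
  dedicated imputation tool should precede this package.
* BayesB's π is fixed, not estimated; BayesR's σg² update option uses a
  flat prior and requires >2 non-null markers per sweep.
* The per-draw "genetic variance" trace includes Monte-Carlo noise from
  small-component effects and overstates the signal on null data; the
  variance of the posterior-mean GEBVs is the sharper point summary.
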