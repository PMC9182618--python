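# Methods

## Models and estimators

### Per-location RCBD analysis

Each location is a randomized complete block design analysed under the
additive two-way model `y_ij = μ + t_i + r_j + e_ij` with genotypes `t_i`
and replicates (blocks) `r_j` fixed, `e_ij` i.i.d. normal. Sums of squares
are the definitional marginal-mean forms (genotype SS = r·Σ(ḡ_i − ȳ)², and
so on), error by subtraction, the genotype F-test against the error mean
square with an upper-tail p-value. Replicates are a blocking factor; no F
is reported for them. LSD = t(1 − α/2, df_e)·√(2·MSE/r); CV% =
100·√MSE/x̄.

Variance components come from the expected mean squares of this layout:
σ²g = (MSG − MSE)/r, σ²e = MSE, σ²p = σ²g + σ²e. A negative raw σ²g is
truncated to zero and flagged; heritability and GCV then report zero as
well. Note the estimand: within one location the genotype effect contains
any genotype×location deviation, so per-location σ²g estimates
Var(g) + Var(gl). The combined-ANOVA estimators (below) separate the two.

Derived parameters: GCV/PCV/ECV = 100·√σ²/x̄; h² = σ²g/σ²p (broad sense,
plot basis); GA = K·h²·σp with K = 2.06, the standardized selection
differential when the best 5% of a normal population is retained;
GAM = 100·GA/x̄. An alternative `mode="variance"` computes K·h²·σ²p (the
variance rather than SD scale), matching the GA columns of some published
trial reports; the default remains the textbook SD form.

Descriptive bands follow the conventional cutpoints — GCV/PCV: <10 low,
10–20 medium, >20 high; GAM likewise; heritability either 40/80
("results"-style, the default) or 30/60 ("methods"-style) on the percent
scale. A value exactly on a cutpoint joins the higher-named band
([10, 20] is medium, >20 high); the choice is arbitrary and configurable
only by editing the scheme table.

### Trait association

For a trait pair the RCBD cross-product decomposition mirrors the sums of
squares with products replacing squares, giving genotype and error mean
cross-products; cov_g = (MCPG − MCPE)/r, cov_e = MCPE, cov_p = their sum.
Then r_g = cov_g/√(σ²g_x·σ²g_y) and r_p = cov_p/√(σ²p_x·σ²p_y). r_g is
undefined (reported as NaN / dash) when either genotypic variance is
truncated to zero, and moment estimates can exceed 1 in magnitude; such
cells are clamped to ±1 and flagged rather than silently accepted.
Significance for both r_p and r_g uses the two-sided t-test
t = r·√(n − 2)/√(1 − r²) with n = genotype count. For r_g this is an
approximation — genotypic correlations have no exact small-sample test in
this moment framework — and is marked as such here.

Regression of grain yield on the component traits runs on per-location
genotype means (one observation per genotype), not plots, so block
structure cannot leak into the slopes. Stepwise selection is bidirectional
on p-values from the empty model (α = 0.05 to enter and to stay; ties by
smallest p then earlier trait order; an AIC criterion is available). A
visited-state guard terminates the search if degenerate fits (zero
residual) make p-values oscillate. Per-trait "contribution" is the squared
semi-partial correlation against the final model, i.e. the r² drop when
the trait is removed.

### Diversity

D² between genotypes is the squared generalized distance of their
across-location mean vectors under the pooled error variance–covariance
matrix W (per-location two-way residual SSCP matrices summed and divided
by pooled error df). W weights trait differences by experimental precision
and residual trait correlation; D² is invariant to any invertible linear
re-expression of the traits. A singular W (duplicate or constant trait)
raises unless a pseudo-inverse is explicitly allowed, in which case the
result is flagged.

Tocher clustering seeds each cluster with the closest unassigned pair and
admits the genotype with the smallest mean D² to current members while
that mean stays at or below the threshold; the default threshold is the
classical convention, the maximum over genotypes of the minimum
off-diagonal D². Ties break by genotype order, so results are
deterministic. Note the threshold convention makes Tocher deliberately
conservative about diffuse groups: for an i.i.d. Gaussian cloud the mean
pairwise D² exceeds the largest nearest-neighbour D² (a scale-invariant
property of the configuration), so such clouds are split. Hierarchical
clustering runs on √D² with ward/average/complete linkage, cut at k
clusters (default 4), with Newick export of the dendrogram.

PCA operates on the genotype × trait means, default on the correlation
matrix (standardized traits); covariance mode is available and is what
produces a dominant PC1 when one large-scale trait (e.g. kernels per ear)
dwarfs the rest. Trait grouping uses average linkage on 1 − |Pearson r|.

### Genotype × location analysis

The combined model `y_ijk = μ + g_i + l_j + (gl)_ij + ε_ijk` is decomposed
from cell and marginal means scaled by the replicate count; by default
replicates within locations are pooled into the residual (the common
presentation of MET tables), and a `rep_within_location` flag adds the
block stratum, which keeps the genotype and G×L F-tests exact when block
effects are real — with pooling those tests are conservative. The
percent-of-SS column covers the three structural rows (Location, Genotype,
G×L) with their own sum as denominator, so the three percentages add to
100; this is stated prominently because the more common convention divides
by the total SS.

Combined-ANOVA variance components: σ²e = MS_res, σ²gl = (MS_GL − MS_res)/r,
σ²g = (MS_G − MS_GL)/(r·l), each clamped at zero; h² on this basis is
σ²g/(σ²g + σ²e). These are the estimators used for parameter recovery
because they are unbiased for the generating values, unlike the
per-location σ²g (see above).

Adaptation indices: Pi = genotype mean over locations − grand mean;
Li = location mean − grand mean; both exactly zero-sum under balance.
Top performers are the k largest means per location and overall (ties by
input order); locations rank by Li.

## Synthetic data generator

`simulate_met` realises
`y_ijkt = μ_t + g_it + l_jt + (gl)_ijt + r_jkt + e_ijkt` with genotype
effects multivariate normal (full genetic covariance across traits),
location effects as **fixed** per-location offsets (so locational indices
are exactly recoverable; default zero), interaction and block effects
independent normals with per-trait variances, and residuals multivariate
normal. All draws come from one `numpy` Generator seeded by the config, in
the fixed order genotype → interaction → block → residual; standard-normal
draws are scaled through Cholesky factors, so a common rescaling of μ and
all SDs rescales the data exactly for a matched seed. Genotype effects are
drawn i.i.d., not centered: estimators must be unbiased without that help.

The default configuration is the standard trial size of this package's
reference setting: 45 genotypes × 3 locations × 3 replicates, one generic
trait with σ²g = 4, σ²e = 2, σ²gl = 1 (h² = 2/3 at the genotype level).

What the generator does **not** emulate: spatial field trend, non-Gaussian
or heteroscedastic errors, missing plots, outliers, or year effects.
Passing recovery tests therefore demonstrates estimator correctness under
the model's own assumptions, not robustness to field pathologies.

## Simulation studies (problem sizes)

The calibration studies run at sizes chosen to keep the whole suite and
the acceptance script within a couple of minutes on one CPU while leaving
Monte-Carlo error well inside the asserted margins:

- ANOVA oracle equivalence: 100 random datasets (3–8 genotypes, 2–4
  replicates, 2–3 locations), relative SS agreement ≤ 1e-8 against
  plot-wise effect-mean-subtraction oracles.
- Parameter recovery: 500 replicates of the default trial; mean σ̂²g
  within 5% of 4, mean ĥ² within 0.05 of 2/3.
- Correlation duality: 200 replicates of a two-trait trial with genetic
  correlation 0.9 and uncorrelated residuals; mean r̂g exceeds mean r̂p and
  lands in [0.8, 0.97].
- Null F-test calibration: 1000 replicates with σ²g = σ²gl = 0 and block
  variance 0.3; genotype (per-location RCBD) and G×L (combined, block
  stratum separated) rejection rates within ±1.5 points of 5%.

## Numerical choices and degenerate inputs

- Negative error SS from floating-point cancellation is clamped at zero
  with a warning; negative variance components truncate to zero with a
  flag.
- A constant trait yields zero SS everywhere, an absent (NaN) F and "ns";
  CV%/GCV require a positive mean and otherwise raise.
- D² is computed by linear solve, never an explicit inverse; condition
  number above 1e12 counts as singular.
- Stepwise, Tocher and top-k tie-breaks all follow input order, making
  every procedure deterministic.
- Missing plot values are a hard error for all variance-component
  operations — the moment formulas assume balance. (Listwise dropping of a
  genotype within a location is intentionally not silently applied.)

## Known limitations

- Broad-sense, plot-basis heritability only; no REML/mixed-model
  components, no entry-mean h².
- LSD is the only mean-separation statistic (no Tukey/Duncan).
- Pi/Li are descriptive indices; no regression-based stability statistics
  (Eberhart–Russell, AMMI, GGE) are computed.
- Correlation/regression analyses are per-location; no pooled
  multi-location correlation is offered.
- The unbalanced case is out of scope by design: the estimators here are
  the balanced-data moment estimators.
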