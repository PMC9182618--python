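# metvar

Quantitative-genetic analysis of multi-environment plant breeding trials
(METs): the classical battery a maize or field-crop breeder runs on a
balanced randomized-complete-block trial repeated over locations.

## Who this is for

Breeders and biometricians evaluating a set of genotypes (hybrids, lines)
for yield and yield-component traits across several sites, who need to know
(i) how much of the observed trait variation is genetic and hence
selectable, (ii) which component traits drive yield, (iii) how diverse the
germplasm is, and (iv) which genotypes perform well everywhere versus at
particular sites.

## What it computes

For plot data `y_ij = μ + t_i + r_j + e_ij` (genotype *i*, replicate *j*)
at each location:

- **RCBD ANOVA** with the genotype F-test, LSD and CV%.
- **Variance components** from expected mean squares:
  σ²g = (MSG − MSE)/r, σ²e = MSE, σ²p = σ²g + σ²e (negative estimates
  truncated at 0).
- **Coefficients of variation** GCV/PCV/ECV = 100·σ/x̄, **broad-sense
  heritability** h² = σ²g/σ²p, and **genetic advance** GA = K·h²·σp with
  selection intensity K = 2.06 (top 5%), plus GAM = 100·GA/x̄ and the
  conventional low/medium/high bands for each.
- **Genotypic and phenotypic correlations** r_g, r_p for every trait pair
  from the ANCOVA cross-product decomposition (cov_g = (MCPG − MCPE)/r),
  with significance stars.
- **Multiple and stepwise regression** of grain yield on the component
  traits over genotype means, with per-trait contribution statistics
  (squared semi-partial correlations).
- **Mahalanobis-D² diversity**: D²_ij = (m_i − m_j)ᵀ W⁻¹ (m_i − m_j) over
  genotype mean vectors with the pooled error covariance W; Tocher and
  hierarchical clustering with intra/inter-cluster distances; PCA with
  variance partition and a trait dendrogram.
- **Genotype × location analysis** for
  `y_ijk = μ + g_i + l_j + (gl)_ij + ε_ijk`: the combined ANOVA with %SS
  partition, combined-ANOVA variance components (σ²g, σ²gl, σ²e), the
  phenotypic index Pi (genotype mean − grand mean) and locational index Li
  (location mean − grand mean), and top-performer flags.
- A **synthetic MET generator** with known genetic covariance, G×L
  variance, block effects and residual covariance, returning ground truth
  for parameter-recovery studies.

## Worked example

Simulate a 45-genotype × 3-location × 3-replicate trial with four traits
and run the genetic-parameter report for one location:

```python
import numpy as np
import metvar as mv
from metvar.trial_data import STANDARD_MAIZE_TRAITS

cfg = mv.SimulationConfig(
    traits=STANDARD_MAIZE_TRAITS[:3] + (STANDARD_MAIZE_TRAITS[-1],),
    mu=(92.0, 93.5, 1.2, 11.0),               # AD, SD, ASI, GY
    sigma_g=np.diag([6.0, 6.5, 0.3, 1.2]),    # genetic variances
    sigma_e=np.diag([1.0, 1.2, 0.35, 0.8]),   # plot residual variances
    sigma_gl=(0.5, 0.5, 0.05, 0.4),           # G x L variances
    sigma_rep=(0.2, 0.2, 0.02, 0.1),          # block variances
    seed=42,
)
ds, truth = mv.simulate_met(cfg)
rep = mv.variability_report(ds, locations=["Ishwardi"])
```

which prints (rounded):

```
trait  mean   CV%  sigma2_g  sigma2_p   GCV   PCV   h2   GA   GAM gcv_band h2_band gam_band sig
   AD 91.94  1.05      4.81      5.74  2.38  2.61 0.84 4.14  4.50      low    high      low  **
   SD 93.10  1.21      3.45      4.73  2.00  2.34 0.73 3.27  3.51      low  medium      low  **
  ASI  1.14 56.42      0.32      0.74 50.05 75.42 0.44 0.78 68.42     high  medium     high  **
   GY 10.54  8.03      1.70      2.42 12.39 14.76 0.70 2.26 21.42   medium  medium     high  **
```

Flowering dates (AD, SD) have low GCV but high heritability — typical for
strongly inherited, low-variability traits — while grain yield shows medium
GCV/PCV with h² ≈ 0.70 against a generating h² of 1.2/2.0 = 0.6 plus the
within-location G×L share. The combined genotype × location ANOVA for
yield on the same data:

```
>>> mv.combined_anova(ds, "GY").rows.round(3)
                      df       SS      MS       F    p  pct_total_SS
location               2   23.628  11.814  13.564  0.0         3.375
genotype              44  509.925  11.589  13.306  0.0        72.841
genotype_x_location   88  166.496   1.892   2.172  0.0        23.783
residual             270  235.160   0.871     NaN  NaN           NaN
```

shows most structural variation is genotypic (72.8% of the structural SS)
with a significant but smaller G×L share — good news for broad selection.

The same analyses are available from the shell: `metvar simulate`,
`metvar validate`, `metvar anova`, `metvar variability`,
`metvar correlate`, `metvar regress`, `metvar gxe`, `metvar diversity`.

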