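# gwlct

**Geographically weighted linear combination test for gene-set analysis
of continuous spatial phenotypes.**

Spatial transcriptomics assays (e.g. 10x Visium) measure a genes × cells
expression matrix together with planar coordinates for every cell.
Classical gene-set analysis (GSA) asks whether an *a priori* set of
genes is associated with a phenotype, but returns a single global
answer — useless for intratumor heterogeneity, where an association may
hold in one tissue region and not another.  `gwlct` localizes the linear
combination test (LCT): at **every** cell it tests the gene set against
a continuous per-cell phenotype (e.g. a CAF marker gene's expression)
using only spatially nearby cells, kernel-downweighted by distance.

## The statistic

At calibration location \((u_l, v_l)\), cells \(l'\) receive bisquare
(or tricube) kernel weights

$$w_{ll'} = \bigl(1 - (d_{ll'}/h_l)^2\bigr)^2 \quad (d_{ll'} < h_l),$$

with bandwidth \(h_l\) either a fixed radius or the adaptive k-nearest
neighbour distance (selectable by leave-one-out cross-validation).  With
\(\widehat{\Sigma}_{XX}\) the kernel-weighted, shrinkage-regularized
(Schäfer–Strimmer, toward the diagonal) covariance of the set's genes
and \(\hat{s}_{XY}\) the weighted gene–phenotype covariances, the local
test statistic is the maximal weighted association over linear scores
\(\beta' X\):

$$\rho_l = \sqrt{\hat s_{XY}' \widehat\Sigma_{XX}^{-1} \hat s_{XY} \,/\, \hat s_{YY}},
\qquad \beta^* \propto \widehat\Sigma_{XX}^{-1}\hat s_{XY},$$

i.e. \(\beta^*\) is the principal eigenvector of
\(\widehat\Sigma_{XX}^{-1}\hat s_{XY}\hat s_{XY}'\).  Significance comes
from permuting the phenotype across cells: \(p = (1 + \#\{\rho^{perm}
\ge \rho^{obs}\})/(1 + B)\).  Per location the K per-set p-values are
combined by Fisher's method (\(X^2 = -2\sum_k \log p_k \sim
\chi^2_{2K}\)), mapped as \(CS = -\log CP\), and the per-location counts
of significant sets are scanned for spatial clusters with Openshaw's
Poisson GAM.  A variogram-parameterized Gaussian-field simulator
reproduces the 144-scenario factorial power study, with the aspatial
(all weights = 1) LCT as baseline.

## Worked example

```python
from gwlct import KernelSpec, run_gwlct
from gwlct.simulate import ScenarioSpec, simulate_scenario_dataset

scenario = ScenarioSpec(bandwidth=20, grid_side=10, n_genes=30, geneset_prob=0.4,
                        gene_assoc_variance=5.0, pheno_assoc_variance=0.1)
dataset, genesets, _ = simulate_scenario_dataset(scenario, seed=11)
results = run_gwlct(dataset, genesets,
                    spec=KernelSpec("bisquare", "adaptive", 20), B=199, seed=0)
print(results.nsmallest(3, "p_value")[["location_index", "gene_set", "rho", "p_value"]])
```

prints

```
 location_index gene_set      rho  p_value
              0     set1 1.246625    0.005
              1     set1 1.261887    0.005
              2     set1 1.394334    0.005
```

`rho` is the local association score (it can exceed 1 when the set size
is large relative to the kernel window — see `docs/methods.md`), and
`p_value = 0.005 = 1/200` is the permutation floor at B = 199: these
cells reject as strongly as 199 permutations can resolve.  On this
dataset 92% of locations are significant for `set1` (the set that
generated the phenotype) at α = 0.05.

The `examples/` directory walks through each capability: the local test
(`01`), Fisher significance maps and phenotype-level stratification
(`02`), the Poisson cluster scan (`03`), cross-validated bandwidth
selection (`04`) and the simulation power study (`05`).  The same
pipeline is available from the shell:

```bash
gwlct run --expression matrix.mtx --features features.tsv --barcodes barcodes.tsv \
          --coords positions.csv --gmt hallmarks.gmt --phenotype COL11A1 \
          --kernel bisquare --mode adaptive --bandwidth 16 \
          --permutations 500 --seed 1 --out results.tsv
gwlct maps --results results.tsv --out-dir maps/
gwlct scan --counts maps/set_counts.tsv --out-dir scan/
```

Real 10x-style inputs (MTX triplet or dense CSV, coordinate CSV, GMT
gene sets) are read and preprocessed with the standard recipe: keep
genes with mean expression > 1, jitter exact zeros, then rank-based
inverse-normal transform per gene.  When a marker gene serves as the
phenotype it is excluded from every tested set (self-association guard).

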