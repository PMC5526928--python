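# phylogs

Phylogenetic comparative analysis of nuclear genome-size (GS) evolution,
built for genus-scale studies of plants with large genomes (the motivating
system is *Lilium*, 2C ≈ 45–170 pg, 2n = 2x = 24). The package answers the
standard questions of such a study with tested, reusable code:

* **How big are the genomes?** 2C DNA amounts from flow-cytometry
  histograms by the internal-standard ratio equation
  `2C = (sample G1 peak mean / standard G1 peak mean) × standard 2C`,
  with peak detection, QC flags, and monoploid values `1Cx = 2C / ploidy`.
* **What do the karyotypes look like?** Haploid complement length (HCL),
  karyotype asymmetry index (AsK% = Σ long arms / HCL × 100), centromeric
  indices, and the inter/intrachromosomal asymmetry coefficients CV_CL and
  CV_CI.
* **Is GS phylogenetically conserved?** Pagel's λ by maximum likelihood on
  [0, 1], with a likelihood-ratio test against λ = 0 (χ²₁ reference).
* **What predicts GS?** PGLS regression of 1Cx on karyotype and climate
  predictors under Brownian-motion (`V_ij = t_MRCA`) and Ornstein–Uhlenbeck
  (`corr_ij = e^{−α d_ij}`) residual structures, ranked by AIC = 2k − 2 logL.
* **Do regions/sections differ?** One-way ANOVA, Tukey-HSD (Tukey–Kramer
  when unbalanced), and "homogeneous groups" compact-letter display.
* **Can I test all of it without data in hand?** A synthetic-data module
  generates every input — Yule trees, BM/λ/OU traits, coupled environmental
  covariates, karyotypes, and two-peak flow-cytometry histograms — with a
  machine-readable truth ledger for recovery checks.

## Worked example

Generate a 71-species synthetic study and run the whole pipeline:

```sh
phylogs simulate --out demo/bundle --seed 42 --n-tips 71
phylogs run-all --tree demo/bundle/tree.nwk --traits demo/bundle/traits.tsv \
    --karyotypes demo/bundle/karyotypes.tsv --histograms demo/bundle/histograms \
    --out demo/out
```

The run log summarizes each stage:

```
phylogs 0.1.0
seed 0
karyotype: 71 species summarized
genome_size: 71 species estimated
alignment: 71 species analyzed, dropped: none
signal: lambda=0.686 p=1.43e-07
pgls: 14 fits over 7 predictors
groups[region]: F=2.226 p=0.0932 letters=a,a,a,a
groups[section]: F=3.529 p=0.00696 letters=ab,ab,ab,b,a,ab
```

`signal.tsv` holds the phylogenetic-signal estimate — here λ̂ = 0.686
(LRT = 27.69, p = 1.4e-07, n = 71), recovering the simulation's true
λ = 0.6: the genome-size trait is strongly phylogenetically structured, so
ordinary regression would overstate significance. `pgls.tsv` holds one row
per predictor × model; for the karyotype predictor HCL the BM and OU fits
give slopes 0.490 and 0.487 with AIC 486.0 vs 419.1, so OU describes the
residuals better for this pair, while for annual mean temperature BM wins
(AIC 126.2 vs 128.7) — the slope ≈ 0.665 is the attenuated inverse of the
generative temperature↦trait coupling. `groups_region.tsv` letters all four
regions "a" (ANOVA p = 0.093): with a λ = 0.6 trait these contiguous-block
regions do not separate, whereas the finer sections do (p = 0.007).

Every stage is also importable directly, e.g.:

```python
from phylogs import parse_newick, bm_covariance, estimate_lambda
tree = parse_newick(open("demo/bundle/tree.nwk").read())
res = estimate_lambda(y, bm_covariance(tree))   # y conformed to tree.tip_labels
```

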