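# Methods

## Scope and model

`phylogs` implements the comparative-methods core of a genus-scale
genome-size (GS) study: trait measurement (flow cytometry, karyotype
morphometry), phylogenetic signal, phylogenetically corrected regression,
and group comparison. The phylogeny is an *input* (rooted Newick with branch
lengths); tree inference is out of scope. Branch-length units are taken as
given — λ and α are interpreted on the scale of the input tree and not
converted to absolute time.

### Trait-evolution covariance structures

For a rooted tree with tips 1..n, three residual structures are built
(`phylogs.tree`):

* **Brownian motion (BM).** `V_ij = t_MRCA(i,j)` (shared root-to-MRCA path
  length); diagonal = root-to-tip depth. On an ultrametric tree the diagonal
  is constant. The rate σ² scales V externally and is estimated by GLS.
* **Pagel's λ.** Off-diagonal entries of the BM matrix multiplied by
  λ ∈ [0, 1]; diagonal unchanged. The upper bound is fixed at 1.0 (not the
  largest PSD-feasible λ): conventional, always PSD, and matches the
  reported [0, 1] scale of published λ values.
* **Ornstein–Uhlenbeck (OU).** The *stationary-OU correlation*
  `R_ij = exp(−α d_ij)` with `d_ij` the patristic distance, unit diagonal.
  The stationary variance σ²/(2α) is absorbed into the GLS scale, and no
  per-regime optimum θ is modelled — a single-optimum OU is what a
  two-variable PGLS supports. This is the correlation form used by the R
  comparative-methods ecosystem, chosen so results are comparable with the
  software lineage most studies of this kind use.

Non-ultrametric trees are accepted with a warning for BM/λ. For OU the
stationary-correlation form assumes contemporaneous tips;
`pgls_ou(require_ultrametric=True)` rejects trees whose tip-depth range
exceeds 1% of the maximum depth. Duplicate covariance rows (zero-length
terminal branches) are handled by retrying the Cholesky factorization with
1e-10 added to the diagonal.

### Genome-size estimation

`2C = (sample G1 peak mean / standard G1 peak mean) × standard 2C` assumes
fluorescence–DNA linearity with no channel offset, which is exactly what
the ratio equation presumes; no GC or fluorochrome bias correction is
attempted. Peaks are located on a moving-average-smoothed histogram
(default width 5 bins, noise floor 3× the median smoothed count), then
refined by an intensity-weighted centroid over ±2×FWHM around the mode;
peak CV = (FWHM/2.355)/mean × 100. Centroid refinement was preferred over a
Gaussian least-squares fit as simpler and adequate at histogram scale; a
Gaussian-fit mode (`gaussian_fit=True`) exists as a cross-check. Nuclei per
peak are the events inside the refined region, which excludes the
low-channel debris continuum by construction. Species 2C is the unweighted
mean over individuals (the aggregation used when a protocol reports only
"individuals were analyzed"); QC raises flags — never failures — for
< 5 individuals, < 5,000 nuclei per run, peak CV > 5%, or replicate runs
differing by > 2% relative. `1Cx = 2C / ploidy`.

### Karyotype metrics

Computed on the haploid complement of x chromosomes after normalization
(arms swapped so long ≥ short; chromosomes arranged by decreasing short-arm
then total length). Somatic tables (x·ploidy rows) are collapsed to one
representative per homologous group by size-rank averaging before metric
computation — HCL is defined as a haploid quantity, and this choice (not
dictated by any published formula) also covers the occasional triploid.
CI uses the short-arm convention, (0, 50]. CVs use the sample SD
(n−1 denominator), the usual choice when the source method does not restate
the denominator; a population-SD mode exists for cross-checks. Metrics are
scale-invariant, so µm and relative lengths are interchangeable. Output
TSVs carry 4 decimals so metrics round-trip through the writer; full
precision is kept internally.

### Pagel's λ and PGLS estimation

Everything is maximum likelihood (not REML) so log-likelihoods and AIC are
comparable across BM, OU and the λ module; REML would make AIC values
non-comparable across mean structures. For fixed covariance V the ML
solutions are closed-form: β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, σ̂² = rᵀV⁻¹r/n,
logL = −½[n ln(2πσ̂²) + ln det V + n]. Coefficient SEs use the unbiased
scale rᵀV⁻¹r/(n−p) with t tests on n−p df. Computation goes through the
Cholesky factor (whitening), never an explicit inverse.

λ is profiled on [0, 1]: a 21-point grid seeds a bounded scalar optimizer
(xatol 1e-8); boundary optima within 1e-8 of an interior candidate resolve
to the interior. The LRT against λ = 0 uses χ²₁ without the ½-point-mass
boundary correction — the convention of the widely used R implementations —
which makes the test conservative (confirmed by the null-calibration test:
≤ 8% rejections at the 5% level); `boundary_correction=True` halves p.
On a star phylogeny λ is unidentifiable and the result is flagged, with
λ̂ = 0 and p = 1. Traits are analyzed as-is (no automatic log transform).

OU's α is profiled over log α in [1e-4/T, 50/T] (T = max tip depth),
11-point log grid plus bounded optimization; fits pinned at a bound are
flagged `alpha_at_boundary`. AIC counts all free parameters: k = p + 1
(coefficients + σ²) under BM and k = p + 2 (… + α) under OU. This counting
convention matters — AIC magnitudes are not comparable with software that
omits σ² — and is stated here for that reason. Predictors are centered and
scaled internally for optimizer stability; coefficients, SEs and tests are
reported on the original scale (slope tests are invariant to this).

### Group comparison

Classical one-way fixed-effects ANOVA; all-pairs Tukey-HSD in the
Tukey–Kramer form `q = |m_i − m_j| / sqrt(MSW/2 (1/n_i + 1/n_j))` (reduces
to plain Tukey when balanced; the variant choice is the artifact's, made
because published tables rarely state it), with adjusted p from the
studentized-range distribution (k, df_within). Letters come from an
insert-and-absorb pass over the significance matrix; assignment follows the
input group order — not mean order — so a published table's letter pattern
is reproducible given its row order. Every lettering is audited against the
matrix before being returned: groups share a letter iff not significantly
different. Default α = 0.05, configurable. Group tests run on species-level
values (one observation per species), not individual-level replicates.

## Pipeline conventions

The response for signal and PGLS defaults to 1Cx (monoploid GS), the scale
on which GS–karyotype and GS–climate relationships are usually plotted.
Each response–predictor pair is fitted independently (pairwise
relationships, not a joint model); per-regression raw p-values are reported,
with an optional Holm-adjusted column off by default. Geographic region is
a grouping factor for ANOVA/Tukey only, never a PGLS predictor — a
categorical predictor treatment is not part of the two-variable PGLS.
Species dropped at tree/table alignment are dropped once, before all
analysis stages. The PGLS stage requires ≥ 5 analyzed species (OU has four
free parameters); smaller runs abort at that stage with earlier outputs
left in place. TSV outputs are tab-separated UTF-8 with mandatory headers
and "." decimals.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the estimators assume:
Yule (pure-birth) ultrametric trees; traits by exact preorder recursion
(BM, OU) or a single MVN draw (λ); environment = intercept + slope·trait +
BM residual on the same tree, so PGLS assumptions hold *exactly*;
karyotypes with log-normal lengths and Beta-distributed centromeric indices
moment-matched to CV targets; histograms as multinomial draws from a
two-Gaussian + exponential-debris mixture. Default condition values are the
study design the package targets: 71 species, λ = 0.6 signal, 2C in
45–170 pg, x = 12, internal standard 30.9 pg, 10,000 events at 3% peak CV,
two replicate runs per species, 5% debris.

Deliberately not emulated: extinction (no birth–death), trait-dependent
diversification, measurement error in arm lengths, cytometer nonlinearity,
S/G2-phase populations, and real spatial climate structure (covariates are
phylogenetically coupled to the trait by construction). Passing recovery
tests therefore show the estimators are correct *under their own
assumptions* — they do not certify behavior on real data that violates
them. Every generator is a pure function of (config, seed); bundle
generation derives one child seed per operation via `SeedSequence.spawn`,
so adding a generator never perturbs existing streams.

## Numerical choices and problem sizes

Tolerances: covariance symmetry 1e-12; PSD eigenvalue floor −1e-10;
Cholesky jitter 1e-10; λ/α optimizer xatol 1e-8; boundary-tie window 1e-8;
AIC tie window 1e-6. Degenerate inputs error early with named exceptions
(constant trait, constant predictor, zero within-group variance, flat
histogram). Simulation-based checks in the test suite use the sizes their
claims state: λ recovery at n = 200 × 100 replicates, PGLS slope/coverage
and AIC selection at n = 100 × 100 replicates, null LRT calibration at
n = 50 × 500 replicates, 2C recovery over 20 histograms — sizes at which
the whole suite completes in about a minute on one core.

## Known limitations

* λ-PGLS hybrids, multi-predictor model selection, phylogenetic ANOVA,
  measurement-error models, and Blomberg's K are not implemented.
* The OU fit estimates α jointly with the regression by profile likelihood;
  with n ≲ 20 α is weakly identified and often lands at a bound (flagged).
* FCS binary files are not parsed; histograms enter as channel/count CSVs.
* The compact-letter algorithm is exact but can in principle need many
  letters for adversarial significance patterns (> 26 raises).
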