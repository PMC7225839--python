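# Methods

## The prediction model

`maizegs` fits the standard additive genomic mixed model. With one
adjusted phenotype per line,

    y = 1μ + Zu + ε,   u ~ N(0, I σ²_u),   ε ~ N(0, I σ²_ε),

where `Z` (n × m) holds marker dosages centered at observed allele
frequencies: `M − 2p̂` for codominant 0/1/2 SNPs, `M − p̂` for dominant
0/1 presence tags. The dual GBLUP form replaces `Zu` with
`g ~ N(0, K σ²_A)` where `K = WW′/c` is the VanRaden method-1 genomic
relationship matrix with `c = Σ 2p̂(1−p̂)` (codominant) or
`Σ p̂(1−p̂)` (dominant). Dominant markers pass through the same
machinery with presence-frequency centering; no dominance variance is
modeled — the genetic model is purely additive throughout.

### REML

Variance components maximize the restricted likelihood via error
contrasts: a Helmert basis `H` of the orthogonal complement of the
intercept gives `HKH′ = VΘV′`, and the rotated data
`η = V′Hy` are independent with `Var(η_i) = σ²_K θ_i + σ²_ε`. The
explicit contrast basis (rather than the projection matrix `P = I −
11′/n`) matters when `K` is rank-deficient: the null space of `PKP`
then mixes the intercept with genuine zero-variance directions and a
naive "drop the smallest eigenvalue" rule contaminates the contrasts
with the sample mean.

One scalar parameter — the log variance ratio — is then optimized by
Brent's method on `[−10, 10]` (convergence tolerance 1e-10, boundary
candidates checked explicitly), with the genetic variance profiled out
in closed form. A single eigendecomposition per fit keeps REML at
O(n³) + O(grid-free scalar search).

### Variance scales and heritability for inbred lines

For fully homozygous lines the VanRaden matrix has diagonal ≈ 1 + F ≈ 2,
so the per-unit-K variance parameter `σ²_K` is about half the realized
genetic variance. All populations handled here (DH lines, inbred
panels) are fully homozygous, so this is not a corner case. The
estimator therefore normalizes `K` internally to the realized scale
`tr(HKH′)/(n−1) = 1` and reports

- `V_A = σ²_K · tr(HKH′)/(n−1)` — the expected sample variance of the
  genetic values, i.e. additive variance on the phenotype scale;
- `h² = V_A / (V_A + V_e)` exactly;
- `lambda_ = V_e / V_A` — the optimized ratio on the realized scale;
- `sigma2_K` — the raw per-K-unit parameter, from which the
  marker-space ridge parameter is `λ_ridge = V_e / σ²_u` with
  `σ²_u = σ²_K` when REML is run on `K = ZZ′` (as `fit_rrblup` does),
  or `σ²_u = σ²_K(grm)/c` when run on the normalized GRM.

The internal normalization also makes REML exactly scale-invariant in
`K`, so the RR-BLUP (`ZZ′`) and GBLUP (`WW′/c`) routes return identical
`h²` and identical BLUPs (checked to 1e-8 in the suite). Without the
realized-scale reporting, `h²` on simulated inbred panels is biased low
by roughly 0.15.

### RR-BLUP solution

Marker effects solve `(Z′Z + λI)û = Z′(y − μ̂1)`. The intercept is the
GLS estimate `μ̂ = (1′V⁻¹1)⁻¹1′V⁻¹y` with `V = ZZ′ + λI`; for exactly
column-centered `Z` the vector `1` is an eigenvector of `V` and `μ̂`
reduces to the sample mean. The solver works in line space
(`n ≤ m`, the usual genomic case) or marker space (`n > m`), whichever
is smaller. Validation lines are centered with the **training**
frequencies: `GEBV = μ̂ + Z_new û`.

## The synthetic populations

The generator reproduces the population designs the evaluation battery
needs, not maize genomes in general:

- **Panel** (`simulate_panel`): each marker's allele frequency is drawn
  from Beta(0.158, 0.158). The shape was solved analytically so the
  prior-predictive fraction of markers with MAF < 0.05 is 64.8% and the
  mean MAF ≈ 0.085, the regime of unfiltered GBS calls on tropical
  maize panels. Lines are fully homozygous (dosage 0 or 2); loci are
  independent — there is deliberately no LD in the default panel, since
  most experiments don't need it and no LD model is uniquely implied.
- **Block-LD panel** (`simulate_panel_blocks`): a haplotype-block
  variant (two haplotypes per block, default 5–20 markers) for the
  experiments whose logic rests on LD — marker-density plateaus and
  reduced-tag platform contrasts. With independent loci a random marker
  subset simply loses the QTL; with blocks, nearby markers tag them.
- **DH populations** (`simulate_dh`): each line is a doubled F1 gamete.
  Crossovers per chromosome are Poisson(L/100) under Haldane
  (no interference), positions uniform on the genetic map, phase
  initialized by a fair coin. Output lines are fully homozygous and
  carry only parental alleles.
- **Dominant collapse** (`to_dominant`): per marker one allele is
  designated tag-present (fair coin), carriers of ≥ 1 copy score 1.
  On fully homozygous input this is a per-marker relabeling and loses
  no information — a property the suite asserts. The real platform
  difference (far fewer tags) is modeled by subsampling the collapsed
  markers, not by the collapse itself. The allele-calling rule of real
  repeat-amplicon assays from read counts is not modeled.
- **Phenotypes** (`simulate_phenotypes`): QTL sampled without
  replacement from the markers (monomorphic picks swapped for
  polymorphic ones when available), effects iid N(0, 1) per allele
  dose, true breeding value = centered QTL dosages × effects. One
  record per genotype × environment (× replicate); environment main
  effects ~ N(0, 2²) mg/kg drawn once per environment; baseline
  26 mg/kg. The plot residual SD is set **analytically** so that at the
  genotype-mean level Var(TBV)/(Var(TBV) + σ²/(n_env·n_rep)) equals the
  `h2_target`, using the realized Var(TBV) — no trial-and-error
  calibration. With `n_qtl = 0` (null trait) the residual SD falls back
  to 3.5·√(n_env·n_rep) mg/kg, a typical kernel-Zn phenotypic SD.
- **Missingness** (`inject_missing`): iid Bernoulli masking per cell.

Defaults (3 environments, 1 replicate, h² at the genotype-mean level)
imply between-location genotype correlations of `1/(1 + (1/h² − 1)·3)`,
i.e. 0.35–0.64 for h² in 0.62–0.84 — consistent with the moderate
between-location correlations such trials report, without a separate
dial.

What the generator does **not** emulate: linkage disequilibrium decay
with physical distance, population structure and kinship within panels,
genotyping error beyond missingness, dominance/epistasis, and
genotype-by-environment interaction (environment effects are shared by
all genotypes). Passing tests therefore demonstrate correctness of the
machinery and the direction of design effects, not real-data accuracy
levels.

## Phenotype adjustment

`ls_means` fits the two-way additive fixed-effects model
`value ~ genotype + environment` by OLS with sum-to-zero environment
contrasts, after averaging replicates within genotype × environment
cells, and reports each genotype's prediction at the average
environment. Environment is treated as fixed here even though
multi-environment analyses often call it random: with the additive
model and genotype-mean reporting the rankings coincide in balanced
designs, and no variance component for environments is needed
downstream. Disconnected genotype × environment designs are rejected
(connectivity checked on the bipartite incidence graph) because the
model is then not estimable. Incomplete-block (lattice) adjustments
within locations are out of scope.

## Experiment designs

All designs share one engine: center training markers, REML per
training split (never a global λ), fit RR-BLUP, score Pearson accuracy
on the validation set.

- **k-fold CV**: per replicate a fresh random partition into k
  near-equal folds; replicate accuracy is the mean of per-fold
  accuracies (per-fold correlation, not pooled-prediction correlation —
  the two differ slightly and the choice is documented here). Folds
  smaller than 3 are rejected since a correlation needs ≥ 3 points.
- **Training-size sweep**: single random split per replicate at each
  fraction (10–90%); training sets under 10 lines are flagged.
- **Density sweep**: a fresh random marker subset per replicate feeds a
  full k-fold CV replicate; oversized counts are recorded as skipped.
- **Quality grid**: filter (strict `maf > t₁`, `missing < t₂`, per the
  "greater than"/"less than" reading of the thresholds), impute, CV;
  cells report marker count and accuracy; empty cells are flagged.
- **Scenario training**: training sets picked by lsmean rank — random,
  top, bottom, middle (central band around the median), two tails
  (half from each extreme, the odd line going to the top tail). The
  validation set is the **whole population including the training
  lines**, deliberately; a held-out mode
  (`whole_population_validation=False`) is available but off by
  default. Deterministic scenarios run once; only `random` replicates.
- **Cross-population**: markers intersected by id, centering from the
  training population, single fit, accuracy on the full validation
  population; fewer than 50 shared markers is an error.
- **MAS**: the CV machinery restricted to a named marker list.
- **Comparisons**: Welch two-sample t-test on replicate accuracy lists.

Seed policy: each experiment takes one integer seed; child generators
derive via `SeedSequence.spawn` (or `SeedSequence((seed, cell_index))`
for sweeps), so any cell is bit-reproducible independently of which
other cells run.

## Numerical choices and edge cases

- Markers monomorphic in a training split are dropped from that fit
  (they carry no information and would zero-divide the centering).
- All-missing markers make imputation fail loudly rather than silently
  filling; QC flags their MAF as undefined.
- Mean imputation can produce fractional dosages; the 0/1/2 domain
  invariant applies to called data.
- Accuracy is NaN (flagged, not raised) when either side of the
  correlation has zero variance.
- REML rejects constant phenotype vectors and non-PSD relationship
  matrices (tolerance −1e-6 on the projected spectrum, relative to the
  largest eigenvalue).

## Problem sizes in the shipped experiments

The test-suite and acceptance-script experiments use panels of 200–300
lines with 1000–5000 markers, DH populations of 108–143 lines with 500
markers, 30–250 replicates per cell, and 20–50 seeds per Monte-Carlo
contrast — sizes chosen to give stable qualitative contrasts (paired
Monte-Carlo SEs comfortably below the effect sizes) on a single CPU.
The training-size sweep uses 250 replicates per fraction because the
strict monotone ordering of nine means demands an MC standard error
below the ~0.02 gaps between the top fractions.

## Known limitations

- Heritability estimates at n = 300 with a sparse 40-QTL architecture
  and unlinked markers carry a per-seed SD of ~0.10–0.13; the estimator
  is unbiased but individual estimates scatter accordingly. This is an
  information limit of the design, not an optimizer artifact — an
  oracle relationship matrix built from the true QTL does worse, since
  a single fixed draw of sparse effects misaligns with the QTL
  principal directions.
- The independent-loci default panel cannot express marker-density
  plateaus or tag-count effects; use the block-LD variant for those.
- Dominant-marker "MAF" is defined on the presence class, the only
  frequency observable without dosage information.
- VCF input reads the GT field only; no phasing, no multi-allelic
  handling beyond the first ALT.
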