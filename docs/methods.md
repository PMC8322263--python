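# Methods

This note documents the statistical models, numerical choices and the
synthetic study design behind `pleiogene`, in the spirit of the model
documentation shipped with simulation and statistics packages.

## Problem setting

Given per-trait GWAS summary statistics (marginal β, SE, p, effect-allele
frequency, N, imputation INFO per SNP), an LD reference panel of diploid
genotypes, and a gene annotation, the pipeline asks: which genes carry more
than one independent association, and do those associations belong to one
trait (allelic heterogeneity), to several traits through LD-independent
variants (gene-level pleiotropy), or to several traits through the same or
LD-dependent variants (SNP-level pleiotropy)? Loci carrying both dependent
and independent cross-trait associations are "mixed".

## Quality control and harmonization

Filters: INFO < 0.9 (records with no INFO column are treated as genotyped
and pass), MAF < 0.1, strand-ambiguous pairs {A/T, T/A, C/G, G/C},
non-single-base alleles (indels, I/D codes), non-autosomal chromosomes, and
duplicated ids (all copies removed — the ambiguity is unresolvable from
summary data). Filters are predicate conjunctions, so the retained set is
order-independent; removal *counts* are attributed to the first failing
filter in a fixed order. Harmonization matches records to panel markers by
id (positions are used only for windows and binning), flips β and the
frequency when the alleles are reported in reverse order, and drops
records absent from the panel, with incompatible alleles, or with
|freq − panel freq| > 0.2 (configurable; the frequency-consistency check is
standard practice for conditional analysis and guards against mismatched
populations or mislabelled alleles).

## Conditional and joint analysis from summary statistics

The joint model is reconstructed from marginal statistics with the panel as
the LD oracle. With HWE dosage variance d_j = 2 f_j (1 − f_j):

- normal-equation matrix: B_jj = n_j d_j,
  B_jk = r_jk √(d_j d_k) · min(n_j, n_k) for j ≠ k — the conservative
  choice when per-SNP sample sizes differ; pairs on different chromosomes
  or farther apart than 10 Mb are treated as uncorrelated;
- joint effects: β_J = B⁻¹ D β_marginal with D = diag(n_j d_j);
- the phenotypic variance is estimated per SNP as d_j(n_j se_j² + β_j²)
  and pooled by the median; the residual variance after the joint fit,
  σ² = (n·var_y − β_J'Dβ)/(n − k), prices the joint standard errors
  se_J² = σ² [B⁻¹]_jj; p-values are two-sided normal.

Stepwise selection seeds with the genome-wide smallest marginal p (if
< 1e-5), repeatedly adds the candidate with the smallest conditional p
below the threshold (ties: smaller p, then position), refits jointly after
each addition and drops any signal whose joint p rises above the threshold.
Candidates with r² > 0.9 against a selected signal are excluded as
collinear; systems with condition number above 1e10 raise an error naming
the offending pair. Ties and ordering are fully deterministic. Selection
runs per chromosome, which is equivalent to a genome-wide run under the
10 Mb horizon. Internally the selected block of B is factorized once per
iteration and every candidate is handled through its Schur complement —
algebraically identical to refitting the (k+1)-SNP model per candidate.

Validation: on 10-SNP regions simulated with individual-level genotypes
(n = 5,000), summary-level joint effects track exact least squares to
within 0.005 absolute (tolerance 0.05), and stepwise selection equals
exhaustive best-subset search (same threshold and collinearity cap,
largest valid subset, RSS tie-break) on 97/100 regions. These fixtures use
a rich ancestral haplotype pool (25 haplotypes, 2% mutation) so that the
maximum pairwise r² stays below the collinearity cap: with near-duplicate
markers the joint model is ill-conditioned and "the" best subset is not
identifiable, which would test tie-breaking luck rather than equivalence.

## Gene binning

Signals are assigned to every gene whose boundaries ± 10 kb cover them
(1-based inclusive coordinates throughout, matching the marker map
convention; the BED-like gene table is read with the same convention).
Genes whose assigned marker sets are identical — fully overlapping or
antisense pairs — merge into gene_blocks keyed on exact marker-set
identity, not mere positional overlap; the block spans min start to max
end. Region SNP sets (inputs to pruning and Brown scores) take every QC'd
SNP within the *block* boundaries ± 10 kb.

## Scenario classification

Signals with joint p below the experiment-wide threshold are compared
pairwise; a pair is dependent iff panel r² ≥ 0.2 (the same SNP selected
for two traits has r² = 1 by definition). With T = number of distinct
traits, D = any *cross-trait* dependent pair, I = any independent pair of
distinct markers: ≤ 1 signal → "single"; T = 1 → Scenario II if any
independent pair, else "none" (purely dependent within-trait signals are
redundant rather than heterogeneous, and cross-trait dependence is what
SNP-level pleiotropy means — within-trait dependent pairs therefore never
create Scenario III, but remain in the evidence list); T ≥ 2 → mixed if D
and I, Scenario III if D only, Scenario I otherwise. The experiment-wide
threshold is 0.05 divided by the number of markers surviving pairwise
pruning (10 Mb window, r² 0.2, smaller-MAF member removed, deterministic
position tie-break) over all SNPs mapped to multi-signal regions; with the
marker counts of the motivating 27-GWAS application this is
0.05/8772 = 5.70e-6, and it is data-dependent here.

## Brown gene scores

Fisher's statistic X = −2 Σ ln p over the SNPs of a gene is moment-matched
to c·χ²_f with E[X] = 2k and Var[X] = 4k + 2 Σ cov_ij. The covariance of
(−2 ln p_i, −2 ln p_j) uses the Kost–McDermott polynomial
cov(a) = 3.263a + 0.710a² + 0.027a³. GWAS p-values are two-sided —
functions of z² — and cor(z_i², z_j²) = ρ², so the polynomial is evaluated
at a = ρ² by default; the classical one-sided form a = |ρ| is available as
an option but measured markedly conservative on two-sided inputs
(empirical type-I ≈ 0.03 vs ≈ 0.055 for the default at nominal 0.05 under
strong LD; the package requires calibration within [0.035, 0.065]). Both
forms give cov = 4 exactly at |ρ| = 1 (duplicate-test identity: c = 2,
f = 2, p_brown = p) and reduce to Fisher's method at ρ = 0. Genotype
correlation from the panel proxies ρ. p-values are floored at 1e-300
before logs. Scores are FDR-adjusted (Benjamini–Hochberg — the named
method's standard step-up variant) within each trait; the study threshold
is 0.05/n_traits truncated to four decimals (0.05/27 → 0.0018), applied
per trait with ≥ 2 qualifying traits required. Survivors whose minimal SNP
p across qualifying traits exceeds the experiment-wide marker threshold
are set aside (`minp_fail`); the rest are categorized as
`marker_confirmed` (already classified by the marker-based analysis) or by
the LD between per-trait top SNPs (`independent_markers`,
`dependent_markers`, `mixed`).

## Haplotype analysis

Haploblocks follow the four-gamete rule: adjacent markers join while at
most three of the four two-locus haplotypes reach frequency ≥ 0.01 (the
conventional cutoff of the tool family that popularized the rule) and the
block span stays ≤ 500 kb, interpreted as a block-span cap. Within a block
(≤ 25 SNPs), haplotype frequencies are EM maximum-likelihood estimates
from unphased genotypes: each individual's genotype vector is expanded
into its compatible haplotype pairs (missing sites sum over all four
configurations; an ambiguity guard bounds the enumeration), and the E/M
iteration stops when the largest frequency change is < 1e-6 or after 500
iterations. The report keeps haplotypes with frequency > 10%, places each
trait's risk allele (from the harmonized β sign) on them, and flags focal
pairs whose alleles sit on disjoint haplotype sets — the configuration in
which two traits' associations ride on different haplotypes of one block.

## Synthetic study generator

The generator emulates the study design the pipeline targets, not human
demography:

- **Panel** — each LD block has a pool of ancestral haplotypes (default 8)
  with Dirichlet(3) population weights; per-site target frequencies are
  drawn in the MAF band (default 0.15–0.5, kept above the 0.1 QC cut so
  only labelled decoys fail QC) and resampled until the pooled frequency
  lands in band; every chromosome copy of every individual picks one pool
  member per block independently (mosaic), with 0.5% per-site mutation.
  This produces strong within-block LD, ≈ 0 between-block LD, and HWE.
- **Summary statistics** — per block, z ~ MVN(Rλ, R) with R the panel
  correlation (eigenvalue-floored at 1e-6) and λ the planted noncentrality
  vector; SE = 1/√(2f(1−f)n) with a small binomial perturbation of f;
  β = z·SE; two-sided normal p; INFO ~ U(0.9, 1). Simulating directly on
  the z scale matches exactly the model the conditional-selection stage
  assumes, making parameter-recovery tests sharp. Optional decoy rows each
  violate exactly one QC filter and are labelled in the truth output, so
  QC removals can be asserted exactly.
- **Genes** — each gene covers three consecutive blocks (~66 kb, the size
  scale on which multi-block genes show these phenomena); one fully
  overlapping antisense duplicate exercises gene_block merging; genes sit
  20 Mb apart; leftover blocks stay unannotated.
- **Benchmark** — 30 regions on 3 traits with λ = 6 and n = 50,000 per
  trait: 6 Scenario I loci (three LD-independent variants, one per trait),
  6 Scenario II (three independent variants, one trait), 6 Scenario III
  (one variant shared by all traits), 4 mixed (a shared variant plus two
  independent ones), 8 null. Per-signal detection power at λ = 6 and the
  1e-5 selection threshold is Φ(6 − 4.417) ≈ 0.94, so the loci use the
  redundancy their scenario definitions allow (multi-variant, multi-trait
  archetypes of the kind reported for large pleiotropic genes) to keep the
  class label identifiable under single-signal dropout; with minimal
  two-variant loci the benchmark would measure detection power, not
  classification. Measured recovery is 97–100% per class over 20 seeds.

What the generator does **not** emulate: realistic demography or
coalescent LD decay, imputation error structure, related individuals,
sample overlap between cohorts, and effect-size distributions of real
traits (λ is a free parameter, uncalibrated to any study). Passing tests
therefore demonstrate correctness of the statistical machinery under its
own model assumptions, not performance on real consortium data.

## Numerical choices and degenerate inputs

- Correlation matrices are eigenvalue-floored (1e-6) and rescaled to unit
  diagonal before Cholesky sampling or inversion.
- Monomorphic markers: LD is undefined and signalled by a dedicated
  exception; pruning retains them (no LD evidence); the generator does not
  report them in summary statistics; gene scoring drops them with logging.
- Missing genotypes: pairwise deletion for correlations; EM sums over
  compatible genotype configurations.
- Pruning resolves the first violating pair in position order and removes
  the smaller-MAF member (tie: larger position). The named tool family's
  exact behaviour is version-dependent; a fixed, documented, deterministic
  rule was preferred over bug-for-bug fidelity.
- All randomness flows from a single seed through named child streams;
  reruns are byte-identical (asserted in the test suite). The run manifest
  records parameters and counts but no timestamps.
- Problem sizes in the test and acceptance suites (panel of 2,000
  individuals, 1,472 markers, 100 oracle regions, 20 benchmark seeds,
  10,000 calibration replicates) were chosen as the smallest sizes at
  which the estimated quantities are stable to well within the asserted
  tolerances.

## Known limitations

- The conditional machinery assumes the panel LD matches the GWAS
  population; mismatched LD inflates both false selections and spurious
  "independence" calls — the same caveat that applies to any
  summary-statistics conditional analysis.
- Brown's moment-matching is approximate in the extreme tail; the
  two-sided covariance polynomial is itself a fit, slightly anticonservative
  (~0.055 at nominal 0.05 under strong LD).
- EM phasing is exact maximum likelihood only up to local optima; blocks
  are capped at 25 SNPs and the enumeration guard rejects individuals with
  extreme ambiguity.
- Genome builds are assumed consistent across inputs; chromosome X is out
  of scope.
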