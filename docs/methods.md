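# Methods

This note documents the models implemented in `poolburden`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter
for reproducing results.

## Pooled allele-frequency estimation (`poolcall`)

**Read model.** A pool of N diploid individuals has true minor-allele
frequency p = (Σ genotypes)/(2N). Each read independently shows the
minor allele with probability

    φ(p) = p(1 − ε) + (1 − p)ε,

a symmetric two-allele miscall model with a single per-read error rate
ε. This is the minimal identifiable model that is closed-form and
reduces to naive counting at ε = 0; per-base or per-cycle error
profiles are out of scope. The MLE inverts the read fraction:

    p̂ = (k/n − ε) / (1 − 2ε),  clamped to [0, 1],

requiring ε < 0.5 for identifiability. An optional flag snaps p̂ to the
nearest multiple of 1/(2N), the granularity a finite pool can realise
(off by default, since downstream stages average over pools).

**Error-rate estimation.** At a biallelic site, miscalls land uniformly
on the three non-template bases; reads at the two bases that are
neither ref nor alt therefore observe 2/3 of the miscall mass, giving
ε̂ = 3/2 · Σk_other/Σn pooled over all sites and pools (clamped to
[0, 0.25]). One shared ε per run is the default; a user-supplied ε
overrides estimation. Consequently the simulator draws third-allele
reads with probability (2/3)ε so that the estimator is consistent.

**Monomorphism LRT.** Λ = 2[ℓ(p̂) − ℓ(0)] with
ℓ(p) = k ln φ(p) + (n−k) ln(1−φ(p)). Because p = 0 lies on the boundary
of the parameter space, the exact null distribution of Λ is a 50:50
mixture of a point mass at zero and χ²₁; we report the plain χ²₁ tail
probability, which is conservative (roughly a factor 2 at small Λ).
Convention: with ε = 0 and k > 0 the null likelihood vanishes, so
Λ = +∞ and p = 0.

**Pool combination.** The default rule sums read counts across a
cohort's pools before estimating — equivalent to one large pool — which
is the efficient choice when ε is shared. A depth-weighted average of
per-pool estimates is available by flag. Pools under a configurable
depth floor (default 50 reads) are dropped as low-coverage.

**Detection limit.** Near-certain detection of a rare signal needs
about 10 minor alleles among the 2n sampled chromosomes;
`min_detectable_cmaf(n) = min(10/(2n), 1)` — 0.01 for n = 500.

## Prioritization (`prioritize`)

A variant qualifies as rare and damaging iff its consequence is
missense or stop-gain, max(MAF_ctrl, MAF_case) < `maf_max`, and scaled
CADD ≥ `cadd_min`. Defaults: `maf_max = 0.01`, `cadd_min = 10`. The MAF
gate uses the maximum across cohorts — the strictest reading of
"rare" — because a variant common in either cohort is not a rare-burden
candidate. Missing CADD scores exclude the variant with a warning
rather than failing the run. `filter_table` drops only *fully
identical* duplicate rows; rows that share a (chrom, pos, ref, alt) key
but differ elsewhere (the packaged table contains two such repeated
sites, each printed once per cohort context) are kept and flagged,
because published variant lists count printed rows. Region assignment
maps genes to named (possibly composite) regions through an explicit
map; genes marked "." form a drop-list whose variants are excluded
with a log line — in the packaged map these are the five genes
(GP1BA, RAF1, FERMT3, GP9, GP5) that have qualifying variants but no
tested region, e.g. because downstream genotyping-assay design failed
for them.

## Burden tests (`burden`)

**cMAF convention.** cMAF = carriers / cohort size (carrier-based).
This is forced by the packaged carrier table's internal arithmetic
(10/500 = 0.02, 32/500 = 0.064, 1/500 = 0.002). The allele-based
convention carriers/(2n) — natural in power calculations — is available
via `allele_based=True`.

**CMAT.** Region variants are collapsed per individual into weighted
minor/major allele counts (weights default to 1; no weighting scheme is
asserted), summed per cohort, and the statistic is the Pearson X² of
the resulting 2×2 allele table. The null is obtained by permuting
case/control labels over *individuals* — preserving within-individual
multi-variant structure — with the add-one estimator
p = (1 + #{permuted ≥ observed − 10⁻¹²})/(1 + n_perm). Ties count
against the observed statistic, so the test is conservative
(super-uniform under the null); with very sparse carriers the
attainable p-values are coarse. Default n_perm = 10 000.

**Method routing.** Per region: CMAT when both cohorts have ≥ 1
carrier; Fisher's exact test on the carrier 2×2 when exactly one cohort
has carriers (a permutation test is then dominated by ties); NA when
neither. The totals row sums carrier counts over regions (an individual
carrying variants in two regions counts twice, matching how published
totals are tabulated) and uses Pearson's chi-squared without continuity
correction — the variant that reproduces the fixture's totals p to the
printed precision — plus a carrier odds ratio with Woolf CI,
Haldane–Anscombe +0.5 on all cells when any cell is zero.

**Multiple testing.** Raw p-values are reported with the Bonferroni
threshold α/m, m = number of regions supplied; no FDR procedure.

**Missing genotypes** count as reference with a logged missingness
rate; a per-variant complete-case mode (missing contributes neither
minor nor major alleles) is available.

**Subset re-analysis.** `subset_analysis` removes every individual
whose comorbidity flag is set (in both cohorts) and reruns the full
analysis, erroring if a cohort empties.

## Synthetic cohorts (`synth`)

The generator reproduces the statistical structure the analysis
assumes. Defaults mirror the study design the package targets:

| parameter | default | rationale |
|---|---|---|
| cohort sizes | 500 + 500 | pooled re-sequencing design |
| pools | 5 × 100 per cohort | pooling layout |
| per-individual depth | 120× (pool depth Poisson, mean 12 000×) | reported mean coverage |
| regions | 10 × 4 variants | ~40 rare variants over 10 tested regions |
| carrier frequencies | 1/500 … 10/500 per variant | rare-variant regime |
| error rate ε | 0.001 | typical short-read miscall rate after QC |
| comorbidity prevalence | 0.49 (ctrl) / 0.30 (case) | leaves ≈ 605/1000 after exclusion, controls enriched for cardiac disease |

Carriers are drawn independently per variant (no linkage
disequilibrium) and are heterozygous below carrier frequency 0.1;
above it, or with `allow_homozygotes`, genotypes come from
Hardy–Weinberg proportions. A causal region transforms the control
carrier probability through a carrier odds ratio:
odds_case = OR · odds_ctrl. Depth is Poisson by default; a negative
binomial with configurable dispersion reproduces the wide per-sample
coverage ranges (tens to hundreds×) seen in capture data. Reads per
pool-site are multinomial over (minor, third-allele, major) with
probabilities (φ(p), (2/3)ε, remainder), so counts always sum to the
depth. Pool assignment is by contiguous index blocks (randomizable by
flag).

What the generator does **not** emulate — and hence what passing tests
do not show about real data: linkage disequilibrium and haplotype
structure, capture-efficiency and GC-coverage bias, batch effects
between pools, context-dependent or strand-asymmetric sequencing
error, population stratification, and genotyping error in the
individual-verification stage.

## Packaged fixtures (`fixtures`)

Three small TSVs ship with the package: the 38-row rare-damaging
variant table, per-region carrier counts for the full and
comorbidity-excluded panels, and the gene-to-region map. Individual
genotypes were never published, so `build_carrier_genotypes`
constructs a *synthetic* matrix consistent with the printed counts:
each carrier is a distinct individual with exactly one heterozygous
genotype at one region variant (round-robin over the region's
variants) — the single-variant-per-carrier assumption, flagged as an
assumption rather than fact. Comorbidity flags are placed so the
excluded subset reproduces the subset panel's carrier counts with 400
controls and 205 cases remaining; that split is the only one
consistent with the subset panel's control-side cMAFs (5/400 = 0.0125,
1/400 = 0.0025, 2/400 = 0.005). The subset panel's case-side cMAFs are
not internally consistent under any split and are not reproduced —
only carrier counts are.

## Numerical choices and conventions

- All randomness flows from one root seed through
  `numpy.random.SeedSequence` spawning; per-region permutation streams
  are derived deterministically, so cached stages rerun identically.
- Permutation tie tolerance 10⁻¹² on statistic comparison; add-one
  estimator makes p = 0 impossible.
- Coordinates are 1-based inclusive internally (VCF convention); BED's
  0-based half-open intervals convert at the boundary
  ([s, e) → s+1 … e).
- Degenerate 2×2 tables: chi-squared refuses zero margins and directs
  the caller to Fisher; Fisher returns 1 for degenerate tables; the
  CMAT statistic is 0 when a margin vanishes.
- Fisher's exact two-sided p sums hypergeometric probabilities no more
  likely than the observed table with a 10⁻⁷ relative tie tolerance
  (scipy's convention, matched by the enumeration oracle in the tests).

## Test problem sizes

The statistical property checks are sized for a desktop run: type-I
error over 500 region-level null tests (50 simulated cohorts × 10
regions, n_perm = 399); permutation-vs-enumeration agreement at
n_perm = 10⁶ on 4+4-individual cohorts; odds-ratio CI coverage over
200 replicates of the 1-vs-10-carriers design; estimator recovery over
300 draws per true frequency. The measured type-I error at α = 0.05
(~0.03–0.04) sits below nominal, as expected for a conservative
discrete permutation test.

## Known limitations

- The CMAT permutation p for very sparse regions is coarse and
  conservative; exact conditional tests would be preferable below ~5
  total carriers (the Fisher fallback covers the one-sided-carrier
  case only).
- The chi-squared LRT reference for monomorphism is conservative at
  the boundary (mixture null not implemented).
- The error model is a single symmetric ε; real miscall rates vary by
  base context and cycle.
- The totals row double-counts individuals carrying variants in more
  than one region, matching tabulation practice rather than a strict
  unique-carrier count.
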