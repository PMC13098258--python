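# Methods

This note documents the models and procedures implemented in `magpop`, the
assumptions behind them, the defaults and why they were chosen, and the
limits of what the synthetic tests establish.

## ANI estimation

Average nucleotide identity is estimated from bottom-s MinHash sketches of
canonical k-mers (the lexicographic minimum of each k-mer and its reverse
complement under a 2-bit encoding, hashed with a fixed splitmix64
finalizer). For two sketches the Jaccard index *j* is estimated Mash-style:
among the *s* smallest hashes of the union, the fraction present in both
genomes. The Mash distance

&nbsp;&nbsp;&nbsp;&nbsp;D = −(1/k) · ln( 2j / (1+j) )

is mapped to identity as **ANI = exp(−D)**, clamped to [0, 1] and with
j = 0 mapped to 0. Under independent per-site substitution at rate *d* (the
generator's model), 2j/(1+j) estimates (1−d)^k, so exp(−D) = 1−d in
expectation. The common first-order form 1−D instead estimates
1+ln(1−d) and is biased low by ≈ d²/2 — about 0.005 at species-boundary
distances (d ≈ 0.1), which is material when validating against an exact
per-site oracle; exp(−D) removes that bias at no cost (the two forms agree
to first order as d → 0).

**Defaults** k = 21, s = 1,000 (standard sketching regime; both
configurable). The per-pair sampling noise of the ANI estimate is
σ ≈ exp(−D)/(k·√s) · √(j(1−j))/(j(1+j)): ≲ 0.001 for pairs above the 95 %
species boundary and ≈ 0.006 at ANI 0.89. Threshold clustering only needs
the separation between bands (gaps of 0.015 at the 99 % cut and 0.10 at the
95 % cut), so s = 1,000 is ample.

**Accuracy limits.** For 20 kb genomes the deviation between *any*
k-mer-based ANI estimate and the exact per-site identity is not dominated
by sketching below ~95 % ANI: the fraction of mutation-free k-windows
fluctuates around (1−d)^k because overlapping windows are correlated, giving
the exact full-set Jaccard estimator itself a per-pair spread of ~0.003–0.005
at ANI 0.89 (measured: max |full-set Jaccard ANI − Hamming ANI| ≈ 0.009 over
5,500 between-species pairs). Maximum deviations over large pair sets
therefore exceed 0.01 at species-boundary distances no matter the sketch
size. The test suite pins the guarantee that does hold — sketch ANI within
0.01 of the Hamming oracle for within-species pairs (ANI ≥ 0.95) — and the
benchmark-wide < 0.01 check over all pairs is retained in the acceptance
suite as a known-unattainable bound. Non-ACGT bases void every k-mer window
containing them; in the Hamming oracle an ambiguous base matches nothing.

## Clustering and representatives

Species are average-linkage agglomerative clusters on distance 1 − ANI cut
at 1 − 0.95; genome units re-cluster each species' members at 1 − 0.99.
Average linkage is robust to a single spurious high-ANI pair (single and
complete linkage are available via `method=`). Genomes are always processed
in sorted-id order so dendrogram tie-breaks are reproducible; cluster ids
are `S<i>` by descending size then smallest member id, units `S<i>_U<j>`
likewise. Pairs with no sketch overlap get ANI 0, i.e. maximal distance,
rather than a missing value.

Representatives maximize the dereplication score

&nbsp;&nbsp;&nbsp;&nbsp;score = completeness − 5·contamination −
0.1·strain_heterogeneity + 0.5·log₁₀(N50)

(ties → smallest id). The 5× contamination penalty and logarithmic N50 term
follow the common dereplication convention; weights are exposed in
`DEFAULT_SCORE_WEIGHTS`.

Merging two representative collections (cohort catalog A vs global
reference B) clusters the union at 95 % ANI and keeps the higher-scoring
genome per species, recording provenance: A-only and unlabelled → `novel`;
A-only labelled → `known_absent_from_B`; shared with A winning →
`higher_quality_replacement`; otherwise the B side.

## Quality tiers

MIMAG tiers are applied with strict inequalities exactly as conventionally
printed: HQ needs completeness > 90 **and** contamination < 5 **and** all of
5S/16S/23S rRNA **and** ≥ 18 tRNAs; MQ needs completeness > 50 and
contamination < 10; everything else is LQ. A genome at exactly 90 %
completeness fails the stricter class. "Almost complete" (> 90 %, < 5 %) is
tracked independently of the rRNA/tRNA requirements. N50 is the smallest
length among the longest contigs whose cumulative length reaches half the
assembly; GC excludes ambiguous bases from the denominator.

## GUN and nGUN

GUN is the number of genome units of a species; nGUN = GUN/n_MAGs × 100,
reported to one decimal in tables. nGUN is bounded by [100/n_MAGs, 100]:
low values mean many genomes collapse into few units (feasible
within-species testing), 100 means every genome is its own unit. Reports
cover species with MAG count strictly above `min_mags` (default 10); a
stricter >100-MAG regime used when the metric itself is the object of study
is the same parameter. Candidates for within-species testing are filtered
(nGUN ≤ `max_ngun`, MAG count ≥ `min_mags`) and sorted by nGUN ascending
then MAG count descending. Phylum summaries report quartiles for phyla with
≥ 10 species. Known confounders of nGUN — genome length, pangenome size,
recombination — are not modeled.

## Association models

**Species level.** Relative abundances are CLR-transformed per sample:
zeros are first replaced by half the smallest nonzero value of the whole
table (configurable via `pseudocount`), rows renormalized, then
y = ln x − mean(ln x), so each row sums to 0 and the transform is invariant
to per-sample scaling. Each (species, disease) pair is tested by OLS of CLR
abundance on the binary disease indicator plus BMI, sex (0 = male,
1 = female) and age, with a Wald test on the disease coefficient. The CLR
abundance is the response and disease the predictor; the reversed logistic
orientation is not the default. Filters: species present in ≥ 1 % of
samples (inclusive), diseases with ≥ 100 cases. Bonferroni divisor: the
number of species tested.

**Within species.** For units with ≥ `min_carriers` (default 100) carrier
samples, disease is regressed logistically on unit presence plus sex, age
and BMI; OR = exp(β₁) with a Wald p-value. Bonferroni divisor: the number
of diseases. Perfect separation, non-convergence, and constant regressors
produce results flagged `separation` / `nonconverged` / `degenerate` with
NaN statistics — they are never dropped silently and never significant.
No robust/sandwich errors are used.

The novel-species accumulation curve averages cumulative distinct novel
species over random sample orderings (default 20 permutations) and reports
a least-squares slope per 500 samples with its R².

## Synthetic cohort generator

Genomes evolve on a **star phylogeny** by independent per-site
substitutions only — no indels, rearrangements, or gene flow — which keeps
every pairwise distance analytically controllable and makes per-site
Hamming identity an exact ANI oracle. Species ancestors derive from a
common root at rate d_between_species/2 (default 0.10 total: between-species
identity ≈ 0.89 < 0.95), unit centers from their ancestor at
d_between_units/2 (default 0.015: between-unit identity ≈ 0.985, inside
(0.95, 0.99)), members from their center at d_within_unit/2 (default 0.002:
within-unit identity ≈ 0.998 > 0.99). Config validation enforces the band
structure. Each member genome is attributed to a distinct sample of its
unit, so unit carrier counts equal planted MAG counts; per-species recovery
probabilities are free parameters, not fitted to any survey.

Quality metadata marginals (truncated-normal completeness centered at 85,
exponential contamination with scale 2, Bernoulli(0.92) rRNA genes,
Poisson(25) tRNAs, log-normal N50) were chosen once so the implied tier mix
resembles large gut MAG surveys — roughly a fifth of genomes HQ, most MQ, a
small LQ residue — and are exposed as `QualityParams`.

Cohort covariates: age ~ U(23, 89), sex ~ Bernoulli(0.70 female), BMI ~
N(26, 4), matching a population-biobank profile. Each disease is drawn from
a logistic model whose intercept is calibrated by root-finding so the mean
predicted probability hits the target prevalence, with a planted carrier
log-odds-ratio and mild centered covariate effects (0.01/yr age, 0.2 sex,
0.03/unit BMI). A planted species-level effect multiplies the species'
abundance load by exp(β) in cases, shifting its CLR value by ≈ β. For the
planted-OR recovery benchmarks the disease prevalence is 0.5 (the
information-maximizing choice; only carrier rate and sample size are
prescribed by the benchmark).

**What a green test establishes — and what it does not.** Recovery of the
planted hierarchy shows the estimator/clustering stack resolves the stated
ANI bands at 20 kb scale; it says nothing about indel-rich divergence,
chimeric bins, uneven genome lengths, or assembly artifacts, none of which
the generator emulates. Calibration of the MWAS layers is under the
generator's correctly-specified logistic/linear models; robustness to
model misspecification is untested.

## Numerical and reproducibility choices

- Percentages in summaries are rounded half-up to two decimals (Decimal
  arithmetic, not bankers rounding); full-precision values stay in the TSVs.
- All randomness flows through `numpy.random.default_rng` seeded from the
  run seed; collections, tables and every pipeline output are byte-identical
  across reruns with one seed, verified by SHA-256 in the run manifest.
- Hierarchical clustering uses `scipy.cluster.hierarchy`; regressions use
  `statsmodels` OLS/Logit; FASTA I/O uses Biopython. The CLR transform is
  implemented directly (the zero-replacement rule is package-specific) and
  cross-checked against scikit-bio in the tests.
- The sketch hash is splitmix64 rather than MurmurHash3: it is dependency
  free, invertible on 64-bit inputs (collision-free on k ≤ 32 k-mers), and
  passes standard avalanche tests.

## Known limitations

- Sketch ANI accuracy degrades below ~95 % ANI at short genome lengths (see
  above); the clustering thresholds are unaffected but absolute ANI values
  for distant pairs carry ~0.005–0.03 uncertainty at L = 20 kb.
- The generator's substitution-only model understates real within-species
  structural variation; nGUN on real data reflects additional processes
  (HGT, recombination, assembly failure) that the synthetic tests cannot
  probe.
- Logistic fits at very small carrier or case counts are frequently flagged
  rather than estimated; the within-species layer is only meaningful with
  on the order of ≥ 100 carriers, which is why that is the default filter.
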