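# Methods

This note documents the models, default parameters and design choices
behind `bulkmap`, in the order data flows through the package.

## 1. The generative model (`bulkmap.sim`)

**Cross.** Two fully homozygous, fully divergent inbred parents carry the
reference and alternate allele respectively at every marker (one marker
per `marker_spacing`, default 20 kb). The F₁ is selfed to F₂; for an F₃
population each individual is one selfed seed of an *independent* F₂
plant, so unlinked markers segregate 3/8 : 1/4 : 3/8 (AA : Aa : aa) and
heterozygosity is 1/4. `n_f2_families` optionally caps the number of
distinct F₂ plants (round-robin assignment) for designs where F₃
individuals share families; the default models one seed per plant.

**Meiosis.** Haldane model: the crossover count per chromosome is
Poisson(L<sub>Mb</sub> · cM/Mb / 100) with breakpoints uniform in
physical position; the starting haplotype is fair-coin. The map is
uniform at 4 cM/Mb, a typical rice-scale rate; there is no interference,
no dominance and no epistasis.

**Phenotype.** Purely additive: y = Σ a<sub>j</sub>(d<sub>j</sub> − 1) + ε
with d the alt-allele dosage and ε Gaussian. The noise SD is set from the
*realised* genetic variance of the simulated population,
σ² = var(g)(1 − h²)/h², so the in-sample heritability equals the target
even when QTLs are linked. h² = 0 (or no QTLs) gives pure unit-variance
noise; h² = 1 requires nonzero genetic variance. For a single F₃ locus
the dosage variance is 3/4, so an effect of s phenotypic SDs corresponds
to h² = 0.75 s²/(1 + 0.75 s²) — the helper
`study.heritability_for_effect_sd` does this conversion (0.48 for
s = 0.8).

**Pooling.** Pool size is round-half-up of `pool_fraction · n` (299
plants at 10% → 30 per pool); ties in the phenotype are broken by
individual index, a documented stable rule.

**Sequencing.** Per site and sample, total depth ~ Poisson(mean depth:
50X bulks, 31X parents) and alt reads ~ Binomial(depth, p′), where p′ is
the pooled alt frequency moved toward 1/2 by a symmetric per-read error
(default 0.001). Genotypes are *called from the reads* (allele fraction
< 0.1 hom-ref, > 0.9 hom-alt, else het; zero depth missing), so parents
can occasionally miscall and the parent-consistency filter is exercised
honestly. Ref/alt bases are uniform draws, which fixes the expected
Ts/Tv of simulated data at 0.5 (one transition vs two transversion
classes per reference base) — a deliberate anchor showing tests exercise
the statistic, not a substitution model. QUAL ∈ [600, 3000] and QD ∈
[20, 35] are synthetic plumbing drawn from the seeded generator, above
typical hard-filter defaults. All randomness flows from `CrossConfig.seed`;
output VCFs are byte-identical under a fixed seed.

**What the generator does not emulate.** Real read alignment (mapping
bias, paralogs), InDel discovery (the simulator emits SNP sites only;
InDel handling is exercised by hand-written fixtures), non-uniform
recombination, dominance/epistasis, genotyping-error structure beyond a
symmetric flip, and a realistic substitution spectrum. Passing tests
therefore demonstrate correctness of the statistics and their
calibration under a clean additive model — not robustness to alignment
artifacts or non-additive genetics.

## 2. Variant model and filters (`bulkmap.vario`, `bulkmap.filters`)

Sites are classified by allele lengths: SNP (all alleles 1 bp), small
InDel (length difference 1–50 bp), Other (oversize differences are
retained but flagged and excluded from the InDel marker class).
Multi-allelic rows are kept at read time and removed only by the
biallelic filter so per-pass accounting is explicit. Coordinates are
1-based at VCF ingestion; all region math is half-open 0-based.

The filter chain runs in a fixed, logged order — quality (QUAL ≥ 30 and
QD ≥ 2.0; strictly-below removed, missing QD passes and is counted),
proximity (SNPs within 5 bp of an InDel dropped; both members of InDel
pairs within 10 bp dropped), clusters (every member of a run of > 2
variants chained by ≤ 5 bp gaps dropped — removing the whole run is the
conservative reading), biallelic, bulk depth (each bulk ≥ 4 reads), and
parent consistency. The last pass keeps sites where both parents are
called homozygous for different alleles — the M/P parental attribution
of the ΔSNP-index is undefined otherwise — and where any bulk allele
above an error floor of 2 × the sequencing error rate is carried by a
parent; rarer alleles are treated as sequencing noise. Each pass is
idempotent, and on clean simulated data the passes commute.

## 3. ED scan (`bulkmap.ed`)

Raw statistic: D = √Σ(N<sub>mut</sub> − N<sub>wt</sub>)² over per-base
frequencies (high bulk as "mutant", low as "wild-type"; D is symmetric so
the labeling cannot affect calls), raised to the 5th power (`power`
configurable). Smoothing is a tricube-kernel weighted local mean over
physical distance, w = (1 − (d/h)³)³ for d < h, bandwidth h = 2 Mb by
default; a single-site chromosome passes through with a warning. The
genome-wide threshold is median + 3 sample SDs (n − 1 denominator) of
the fitted values, pooled across chromosomes per marker class. Sites
strictly above threshold are snapped to 10-kb bins
(floor(pos/10 kb)·10 kb) and bins merge when their gap is at most one
grid unit — with ≤ 20 kb marker spacing, consecutive exceeding sites
chain into contiguous regions. The bin grid reflects the 10-kb-aligned
convention of published candidate-region bounds.

## 4. ΔSNP-index scan (`bulkmap.snpindex`)

After the parent-consistency filter, the female parent's allele defines
the M read counts and the male parent's the P counts; the per-bulk index
is M/(M+P) (zero-depth sites are skipped) and Δ = index<sub>low</sub> −
index<sub>high</sub>. Tracks are sliding-window means (2 Mb windows on a
10-kb step grid clipped to each chromosome's observed sites; empty
windows are absent, never zero), carrying each window's mean
minimum-bulk-depth.

Null bounds: pools of `pool_size` genotypes are drawn from the
generation's segregation ratios (genotype-class counts are multinomial —
identical to per-individual draws but O(1) in pool size), pooled allele
frequencies formed for two independent bulks, and read counts drawn
binomially at each depth of a grid ({4, 6, …, 200} by default); the
symmetric quantiles at confidence 0.99 give (lower, upper) per depth,
keyed by minimum bulk depth and linearly interpolated (clamped at the
grid ends). 10,000 simulations by default; bounds are deterministic
under a seed. Windows whose mean Δ escapes the bounds at their mean
depth are binned and merged exactly as in the ED caller, and each region
records the sign of its mean Δ — the direction of parental contribution.

## 5. Region algebra (`bulkmap.regions`)

Regions are half-open [start, end); sizes in Mb are exact from the
bounds. Union merges touching intervals and pools provenance;
intersection across tracks is the set intersection of each input's
union; exclusion drops whole chromosomes or subtracts intervals
(splitting as needed). Gene counting uses any-overlap (≥ 1 bp) by
default — a gene spanning two regions counts once per region, while
set-level totals deduplicate by gene id — with midpoint-containment
available as an alternative. The algebra is property-tested against a
brute-force bitmap oracle. The bundled dataset
(`bulkmap.datasets.rice_candidate_regions`) carries a published rice
candidate-region table; all study-level aggregates are recomputed from
its bounds, and gene totals of derived region sets transfer the
published per-interval counts by exact interval identity.

## 6. Reference study design and calibration (`bulkmap.study`)

The reference design is 5 chromosomes × 30 Mb, markers every 20 kb, 299
F₃ individuals, pools of 30, 50X bulks, 31X parents. The null arm (no
QTL, pure-noise phenotype) and the QTL arm (one additive locus of 0.8
phenotypic SD at Chr3:15 Mb) each run 20 seeds; these sizes keep a full
calibration run under a minute on one CPU while giving stable medians.
Recovery is scored by whether a called region contains the true QTL
position; localisation by the midpoint of the final reported region (the
intersection of the ED and ΔSNP-index region sets) against the true
position — the per-algorithm ΔSNP-index regions are deliberately wide,
and the intersected region is what the pipeline reports.

**Known limitation — the median+3SD rule is anti-conservative for small
pools.** With 30-plant pools, the between-pool allele-frequency
difference has a drift SD of ≈ 0.11 with a correlation length of several
Mb (Haldane, 4 cM/Mb), so a 150 Mb genome contains only a few dozen
independent drift blocks. The fitted ED⁵ field is strongly right-skewed,
and its largest drift excursion — a blob of a few Mb — typically exceeds
the genome-wide median + 3 SD even with no QTL present. The acceptance
script measures this false-call burden (`ed_null_called_genome_pct`)
alongside the ΔSNP-index null calibration, whose depth- and
pool-size-aware simulated bounds absorb drift correctly
(`idx_null_windows_outside_pct`). Practical consequence: ED regions
should be interpreted jointly with the ΔSNP-index CI regions — the
pipeline's default final report intersects them, which is also what
drives the null burden of the end-to-end run to near zero.

## 7. Numerical conventions

Strict inequalities at thresholds (above-threshold means `>`); filter
boundaries keep the boundary value (QUAL 30 and QD 2.0 survive);
quantiles are numpy's linear-interpolation default; SDs use the sample
(n − 1) estimator; pool-size rounding is round-half-up; tie-breaks are
stable by individual index; degenerate inputs (single-site chromosomes,
empty windows, zero-depth sites, empty region lists) pass through with
warnings or sentinels rather than zeros, so absence is never conflated
with signal.
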