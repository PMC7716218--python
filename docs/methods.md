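# Methods

## The experimental design being modeled

A reporter line in the Col background is EMS-mutagenized; a recessive mutant
is recovered and outcrossed to the Ler accession; the selfed F1 yields an F2
in which the mutant phenotype segregates 1:3. Three complementary analyses
locate the causal gene: a χ² test establishes single-locus recessive
inheritance; SSLP markers genotyped in phenotypically mutant F2 plants give
crude map positions; and pooled whole-genome sequencing of mutant and normal
F2 bulks (plus the parent line, the original mutant and Ler) localizes the
mutation by SNP-index and identifies EMS-signature candidate variants.

## Segregation and allelism

`chi_square_ratio` is the plain Pearson statistic Σ(obs−exp)²/exp against an
integer ratio, df = k−1, **without** Yates continuity correction: the
continuity-corrected statistic for 18:60 vs 1:3 is 0.068, while the plain
statistic 0.1538 matches the published 0.155 to printed precision.
Decisions use the df = 1 critical value 3.841 at α = 0.05 (the convention of
the source tables); p-values from `scipy.stats.chi2` are carried along as
supplementary output. Note that a 16:48 split fits 1:3 exactly and yields
χ² = 0 — the corresponding published entry prints 0.004, which no variant of
the statistic reproduces; we return 0 and do not attempt to match it.

Complementation verdicts are categorical: a uniformly wild-type F1 from a
mutant × mutant cross means the mutations complement (different genes), a
uniformly mutant F1 means allelism, anything else (including an empty F1) is
inconclusive.

## Marker distances

Distance to the causal locus is the raw recombinant-chromosome fraction
× 100. No Haldane/Kosambi correction is applied — the published tables are
exact ratios of small integers (5/72 = 6.94, 3/96 = 3.13, 16/62 = 25.8), so
none was applied there either. Missing genotypes drop out of the marker's
denominator. Printed values use half-up rounding with trailing zeros
dropped, mimicking the tables (3.125 → 3.13, 19.05 → 19 at integer
precision). The linked interval is the span of the outermost markers tied at
the minimum distance; a unique minimum is bracketed by its immediate
neighbors.

## SNP-index cascade

Per pool, SNP-index = alt/(ref+alt), undefined below `min_depth` (default 5
reads). Filter rules in order: low depth in any required pool; Ler-pool
index > 0.5 (mapping-parent variant); F2-normal index > 0.5; F2-mutant index
< 1−ε. The fixation rule derives from recessive selection: every chromosome
of the mutant bulk carries the causal allele, so the causal SNP must be
(near-)fixed. The bare `filter_cascade` defaults to the literal strict rule
(ε = 0); the simulation and pipeline configs default to **ε = 0.05** because
under the sequencing-error model a strictly fixed site shows a non-alt read
with probability ≈ 1−exp(−depth·e) (≈ 5% at 50X, e = 0.001), so the strict
rule would discard a truly causal site for a single error read. ε = 0.05
tolerates ~2 error reads at 50X while remaining far above the ~0.5 index of
any heterozygous site. The 20X parent-line/original-mutant pools can be
enabled as extra filters (`use_line_pools`), requiring fixation in the
original mutant and near-absence in the parent line; off by default.

Pool roles for either a sequenced Ler sample or a precomputed Ler-variant
list are equivalent here: a Ler exclusion list can be expressed as a LER
pool fixed for those alleles.

## Localization profile

ΔSNP-index (mutant bulk − normal bulk) is averaged in sliding windows
(default 1 Mb window, 200 kb step; half-open `[start, start+window)`;
empty windows are reported as empty, not zero). The profile is computed on
records that survive the Ler and low-depth rules: with alt alleles called
against the Col reference, Col/Ler diagnostic variants near the causal locus
have Δ ≈ −2/3 (the normal bulk is enriched for Ler) and would cancel the
+2/3 signal of EMS variants inside a window mean; removing Ler-pool-positive
records first — the same operation the cascade performs — leaves a clean
one-sided peak. `call_peak_region` reports the argmax window (ties broken by
chromosome name, then start, and flagged). Because EMS variants are sparse
(~5 per window at the default load), the argmax alone is noisy; the
candidate interval used downstream is the contiguous run of windows whose
mean Δ reaches half the peak mean (`peak_support_region`), extended by
`interval_margin_bp` (default 1 Mb, the scale of a crude-mapping interval).

## Effect annotation

Candidates are retained variants inside the interval that are G→A or C→T on
the reference strand (the EMS G:C→A:T signature; C→T is G→A on the other
strand) and fall in a CDS with a missense or nonsense consequence. The
spliced CDS honors strand and multi-exon structure; codons translate with
the standard genetic code (Biopython); amino-acid numbering is 1-based from
the initiator methionine; stop gains use `*` as the alternate residue.
"Coding region" means CDS only — UTR and intron hits are NONCODING. One
gene model per gene (no isoforms); a SNP in overlapping genes is annotated
against each. Every excluded record is listed with a drop reason
(out-of-interval, non-EMS, synonymous, noncoding) for auditability.

## Simulator

* **Genome.** Default two-chromosome toy genome, 8 Mb/40 cM and 6 Mb/30 cM
  (≈ 5 cM/Mb, Arabidopsis-like), four SSLP markers per chromosome anchoring a
  piecewise-linear genetic↔physical map, and genes every ~0.9 Mb (single- and
  two-exon, both strands). The reference sequence is uniform random.
* **Mutagenesis.** Default 70 point mutations (~5/Mb, the scale of a typical
  Arabidopsis EMS M2 line), each an EMS-signature transition with probability
  `transition_fraction` = 0.99. Exactly one mutation is causal; by default it
  is placed at a random CDS position where the transition is missense, so
  the phenotype has a protein-level basis.
* **Meiosis.** Crossover count per chromosome ~ Poisson(L_cM/100), positions
  uniform on the genetic map, no interference (Haldane) — the simplest model
  consistent with treating recombinant fractions as map distances. An F2
  plant is the fusion of two independent gametes; phenotype is MUTANT iff
  both haplotypes are Col-origin at the causal position.
* **Pools.** Defaults: 300 F2 plants, 30-plant mutant and normal bulks at
  50X, single-genotype parent-line / original-mutant / Ler pools at 20X.
  Col/Ler diagnostic SNPs are thinned to one per 50 kb (a representative
  panel; real Col/Ler divergence is far denser, which only strengthens the
  Ler filter). Per site and pool, depth ~ Poisson(mean), alt reads ~
  Binomial(depth, p′) with p′ = p(1−e) + (1−p)e, e = 0.001 (a typical
  post-filter short-read substitution rate); p is the exact mean over member
  haplotypes. No read-level artifacts (mapping bias, indel noise, base
  qualities) are modeled, so passing tests demonstrate correctness of the
  analysis logic under idealized counts, not robustness to alignment
  artifacts.
* **Seeding.** One integer seed drives a `numpy.random.SeedSequence` spawn
  (reference, mutagenesis, population, diagnostic panel, sequencing), so
  outputs are bit-identical across runs and sub-simulations are
  independently reproducible.
* **Coordinates** are 1-based inclusive throughout (VCF/GFF3 convention).

## Problem sizes

Statistical checks run the full default design over 50 seeded replicates
(each: 14 Mb genome, 300 plants, ~350 sites × 5 pools), which completes in
well under a minute; estimator-consistency checks use a 2 Mb single
chromosome with populations of 160–4000 plants.

## Known limitations

* The distance estimator is the raw recombinant fraction, downward-biased
  relative to true map distance beyond ~15 cM (no mapping function); this is
  intentional, matching how the reference tables were computed.
* ΔSNP-index confidence intervals / significance thresholds (QTL-seq style)
  are not computed; localization is by peak support only.
* Variant calling and alignment are out of scope — the pipeline consumes
  allele depths (VCF with AD fields, or TSV).
* InDels are treated identically to SNPs by the index logic and are assumed
  normalized; no left-alignment is performed.
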