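# ewemap

Forward-genetics mapping of recessive EMS-induced mutants in an
Arabidopsis-style Col × Ler cross, as one reusable, tested pipeline:

1. **Segregation analysis** — Pearson χ² goodness of fit of F2
   mutant/wild-type counts to a Mendelian ratio (default 1:3), inheritance-mode
   inference, and complementation (allelism) test verdicts.
2. **Marker-assisted crude mapping** — map distances from SSLP marker
   genotypes of phenotypically mutant F2 plants, estimated as
   `cM = 100 · n_recombinant / n_scored` chromosomes (a heterozygote
   contributes one recombinant chromosome, a mapping-parent homozygote two),
   and selection of the linked marker interval.
3. **Bulked-segregant SNP-index analysis** — per-pool SNP-index
   `alt/(ref+alt)`, ΔSNP-index between the mutant and normal F2 bulks, a
   three-rule filter cascade (drop Ler-pool index > 0.5, drop F2-normal
   index > 0.5, require the F2-mutant bulk fixed for the variant), and a
   sliding-window Manhattan-style profile that localizes the causal region.
4. **EMS candidate annotation** — retained variants that are G→A / C→T
   transitions (the EMS signature) inside a CDS and change the protein,
   reported with `P113L`-style amino-acid change strings.
5. **A simulator of the whole experiment** — EMS mutagenesis with a
   transition-biased spectrum, a recessive causal locus, F2 meiosis with
   Poisson crossovers (Haldane, no interference), phenotype-based bulk
   selection, and pooled sequencing depths (Poisson coverage, binomial allele
   sampling with a symmetric error rate) — so every stage can be verified
   against a known truth table without external data.

Why a marker in a recessive-selected bulk measures map distance: every
chromosome of a selected mutant plant carries the causal allele, so the
marker shows the mapping parent's allele with probability equal to the
recombination fraction *r*; the recombinant-chromosome fraction estimates
*r* directly, and `100·r` is reported as centimorgans with no map-function
correction. At the causal SNP the mutant-bulk index is 1 while the
normal-bulk expectation is 1/3 (normal plants are 1 homozygous wild type : 2
heterozygotes), giving an expected ΔSNP-index of 2/3 against 0 genome-wide.

## Worked example

```python
>>> from ewemap import chi_square_ratio, marker_distance, MarkerGenotypeTable
>>> from ewemap.markers import Marker
>>> res = chi_square_ratio(18, 60)          # 18 mutant : 60 wild type vs 1:3
>>> round(res.chi2, 4), res.significant_at_0_05
(0.1538, False)
>>> table = MarkerGenotypeTable.from_counts(Marker("CIW2", "2", 1_000_000),
...                                         n_hom_mut_bg=13, n_het=8, n_hom_map_parent=0)
>>> d = marker_distance(table, "CIW2")      # 8 recombinant of 42 chromosomes
>>> d.n_recombinant_chromosomes, d.n_scored_chromosomes, round(d.distance_cm, 2)
(8, 42, 19.05)
```

The χ² of 0.1538 is far below the df = 1 critical value 3.841, so the 1:3
recessive hypothesis stands; the marker sits ≈ 19 cM from the mutation.

The full pipeline on a simulated experiment (two-chromosome toy genome,
70 EMS mutations, one causal missense transition, 300 F2 plants, 30-plant
bulks at 50X):

```
$ ewemap -v run-all --seed 2 --out out/
ewemap INFO simulated experiment: 70 mutations, causal chr1:7401047, 300 F2 plants
ewemap INFO segregation: tested 1 cross(es) against 1:3
ewemap INFO marker mapping: 8 markers, best M1-4 (chr1, 5.19 cM)
ewemap INFO snp-index: 350 records, 5 retained, peak chr1:7400001-8400001 (mean delta 0.771)
ewemap INFO candidates: 1 EMS-type protein-changing candidate(s) in chr1:2800001-9400000
```

`out/candidates.tsv` then names the planted causal mutation and nothing else:

```
gene_id  chrom  pos      change  change_string  consequence  codon_number
C1G09    chr1   7401047  G>A     S283N          MISSENSE     283
```

i.e. the crude marker scan, the ΔSNP-index peak and the EMS/coding filter all
converge on the gene that actually carries the planted mutation.
`ewemap simulate|segregation|map-markers|snp-index|candidates` expose the
individual stages; every stage also has a plain Python API (see
`docs/methods.md`).

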