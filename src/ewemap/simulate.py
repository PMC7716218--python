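"""Simulation of the full forward-genetics experiment.

The simulated design mirrors the mapping study: an EMS-mutagenized line in
the Col background carrying one recessive causal point mutation plus a load
of passenger mutations (overwhelmingly G:C -> A:T transitions), an outcross
to the Ler mapping parent, an F2 generated by meiosis with Poisson crossover
counts and no interference (Haldane model), phenotype-based selection of
mutant and normal bulks, and pooled sequencing summarized as per-site allele
depths: total depth Poisson around the pool mean, alt reads binomial at the
pool allele frequency folded with a symmetric error rate.

A single seed drives a hierarchical `numpy.random.SeedSequence` scheme so
the reference, the mutagenesis, the population and the sequencing stages
are independently reproducible.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from . import annotate
from .bsa import (
    ALL_POOLS,
    F2_MUTANT,
    F2_NORMAL,
    LER_POOL,
    ORIG_MUTANT,
    PARENT_LINE,
    SnpRecord,
)
from .genome import COL, LER, ChromosomeModel, GenomeModel, default_toy_genome
from .markers import (
    HET,
    HOM_MAP_PARENT,
    HOM_MUT_BG,
    Marker,
    MarkerGenotypeTable,
)

MUTANT = "MUTANT"
NORMAL = "NORMAL"

INDUCED = "INDUCED"   # EMS-induced mutation: alt allele rides on Col-origin chromatin
NATURAL = "NATURAL"   # Col/Ler diagnostic SNP: alt (non-reference) allele is Ler's

_BASES = "ACGT"
_BYTE_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class InducedMutation:
    chrom: str
    pos: int
    ref: str
    alt: str
    is_causal: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError("bases must be ACGT")


@dataclass(frozen=True)
class Haplotype:
    """A gamete as COL/LER segments; ``starts`` are the 1-based segment starts."""

    starts: tuple[int, ...]
    origins: tuple[str, ...]

    def origin_at(self, pos: int) -> str:
        return self.origins[bisect.bisect_right(self.starts, pos) - 1]

    def segments(self, length_bp: int) -> list[tuple[int, int, str]]:
        out = []
        for i, (start, origin) in enumerate(zip(self.starts, self.origins)):
            end = self.starts[i + 1] - 1 if i + 1 < len(self.starts) else length_bp
            out.append((start, end, origin))
        return out


@dataclass
class F2Plant:
    plant_id: str
    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    phenotype: str

    def genotype_at(self, chrom: str, pos: int) -> tuple[str, str]:
        h1, h2 = self.haplotypes[chrom]
        return h1.origin_at(pos), h2.origin_at(pos)


@dataclass(frozen=True)
class Line:
    """A non-segregating line contributing fixed haplotypes to a pool."""

    name: str
    background: str            # COL or LER
    carries_induced: bool      # True only for the EMS mutant line


@dataclass(frozen=True)
class Site:
    """A segregating site with a defined carrier origin for the alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str                  # INDUCED or NATURAL
    is_causal: bool = False

    @property
    def origin_of_alt(self) -> str:
        return COL if self.kind == INDUCED else LER


@dataclass
class PoolSpec:
    pool_id: str
    members: list
    mean_depth: float

    def __post_init__(self) -> None:
        if self.pool_id not in ALL_POOLS:
            raise ValueError(f"unknown pool id {self.pool_id!r}")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be > 0")
        if self.pool_id == F2_MUTANT:
            bad = [m for m in self.members if getattr(m, "phenotype", MUTANT) != MUTANT]
            if bad:
                raise ValueError("F2_MUTANT pool must contain only MUTANT plants")
        if self.pool_id == F2_NORMAL:
            bad = [m for m in self.members if getattr(m, "phenotype", NORMAL) != NORMAL]
            if bad:
                raise ValueError("F2_NORMAL pool must contain only NORMAL plants")


def random_reference(genome: GenomeModel, seed=None) -> dict[str, str]:
    """Uniform-random nucleotide sequence for every chromosome."""
    rng = np.random.default_rng(seed)
    return {
        c.name: _BYTE_BASES[
            rng.integers(0, 4, size=c.length_bp, dtype=np.uint8)
        ].tobytes().decode("ascii")
        for c in genome.chromosomes
    }


def _pick_causal_missense(
    genome: GenomeModel, reference: dict[str, str], rng: np.random.Generator
) -> InducedMutation:
    """Plant the causal mutation as a missense EMS transition inside a CDS."""
    genes = genome.all_genes()
    for _ in range(10_000):
        gene = genes[int(rng.integers(len(genes)))]
        seg = gene.cds_segments[int(rng.integers(len(gene.cds_segments)))]
        pos = int(rng.integers(seg[0], seg[1] + 1))
        ref = reference[gene.chrom][pos - 1]
        if ref not in "GC":
            continue
        alt = "A" if ref == "G" else "T"
        snp = SnpRecord(gene.chrom, pos, ref, alt)
        ann = annotate.annotate_effect(snp, [gene], reference)[0]
        if ann.consequence == annotate.MISSENSE:
            return InducedMutation(gene.chrom, pos, ref, alt, is_causal=True)
    raise RuntimeError("could not place a missense causal mutation")


def simulate_ems_line(
    genome: GenomeModel,
    reference: dict[str, str],
    n_mutations: int,
    transition_fraction: float = 0.99,
    seed=None,
    causal_site: tuple[str, int] | None = None,
) -> list[InducedMutation]:
    """Induce ``n_mutations`` point mutations, exactly one flagged causal.

    Each mutation is an EMS-signature transition (G->A or C->T on the
    reference strand) with probability ``transition_fraction``, otherwise
    any other substitution.  The causal mutation is placed at ``causal_site``
    if given, else at a random CDS position where the EMS transition is
    missense (so the phenotype has a protein-level basis).
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    if not (0.0 <= transition_fraction <= 1.0):
        raise ValueError("transition_fraction must be in [0, 1]")
    if n_mutations > genome.total_bp:
        raise ValueError("n_mutations exceeds available positions")
    rng = np.random.default_rng(seed)
    if causal_site is not None:
        chrom, pos = causal_site
        cm = genome.chromosome(chrom)
        if not (1 <= pos <= cm.length_bp):
            raise ValueError(f"causal position {pos} outside {chrom}")
        ref = reference[chrom][pos - 1]
        if ref in "GC":
            alt = "A" if ref == "G" else "T"
        else:
            alt = _BASES[(_BASES.index(ref) + 1) % 4]
        causal = InducedMutation(chrom, pos, ref, alt, is_causal=True)
    else:
        causal = _pick_causal_missense(genome, reference, rng)
    used = {(causal.chrom, causal.pos)}
    muts = [causal]
    weights = np.array([c.length_bp for c in genome.chromosomes], dtype=float)
    weights /= weights.sum()
    while len(muts) < n_mutations:
        is_signature = rng.random() < transition_fraction
        for _ in range(100_000):
            ci = int(rng.choice(len(genome.chromosomes), p=weights))
            chrom = genome.chromosomes[ci]
            pos = int(rng.integers(1, chrom.length_bp + 1))
            if (chrom.name, pos) in used:
                continue
            ref = reference[chrom.name][pos - 1]
            if is_signature:
                if ref not in "GC":
                    continue
                alt = "A" if ref == "G" else "T"
            else:
                options = [
                    b
                    for b in _BASES
                    if b != ref and (ref, b) not in (("G", "A"), ("C", "T"))
                ]
                alt = options[int(rng.integers(len(options)))]
            used.add((chrom.name, pos))
            muts.append(InducedMutation(chrom.name, pos, ref, alt))
            break
        else:
            raise RuntimeError("failed to place mutation")
    muts.sort(key=lambda m: (m.chrom, m.pos))
    return muts


def _other(origin: str) -> str:
    return LER if origin == COL else COL


def _gamete(chrom: ChromosomeModel, rng: np.random.Generator) -> Haplotype:
    """One meiotic product: Poisson(L/100) crossovers, uniform on the cM map."""
    n_xo = int(rng.poisson(chrom.length_cm / 100.0)) if chrom.length_cm > 0 else 0
    starts = [1]
    origins = [COL if rng.random() < 0.5 else LER]
    if n_xo:
        cm_pos = np.sort(rng.uniform(0.0, chrom.length_cm, size=n_xo))
        for cm in cm_pos:
            bp = int(round(chrom.cm_to_bp(float(cm))))
            bp = min(max(bp, 2), chrom.length_bp)
            if bp == starts[-1]:
                # two crossovers collapsing onto one bp cancel pairwise
                origins[-1] = _other(origins[-1])
            else:
                starts.append(bp)
                origins.append(_other(origins[-1]))
    return Haplotype(tuple(starts), tuple(origins))


def simulate_f2_population(
    genome: GenomeModel,
    causal: InducedMutation,
    n_plants: int,
    seed=None,
) -> list[F2Plant]:
    """F2 of (Col-background mutant) x Ler, phenotyped at the recessive locus."""
    cm = genome.chromosome(causal.chrom)
    if not (1 <= causal.pos <= cm.length_bp):
        raise ValueError("causal position outside genome")
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    rng = np.random.default_rng(seed)
    plants = []
    for i in range(n_plants):
        haps = {
            c.name: (_gamete(c, rng), _gamete(c, rng)) for c in genome.chromosomes
        }
        g1, g2 = (h.origin_at(causal.pos) for h in haps[causal.chrom])
        phenotype = MUTANT if (g1 == COL and g2 == COL) else NORMAL
        plants.append(F2Plant(f"F2-{i + 1:05d}", haps, phenotype))
    return plants


def genotype_table(plants: list[F2Plant], genome: GenomeModel) -> MarkerGenotypeTable:
    """Score every genome marker in the given plants (A/H/B codes)."""
    import pandas as pd

    markers = [Marker(m.name, cname, m.pos_bp) for cname, m in genome.all_markers()]
    data = {}
    for mk in markers:
        col = []
        for p in plants:
            g = p.genotype_at(mk.chrom, mk.pos_bp)
            if g == (COL, COL):
                col.append(HOM_MUT_BG)
            elif g == (LER, LER):
                col.append(HOM_MAP_PARENT)
            else:
                col.append(HET)
        data[mk.name] = col
    df = pd.DataFrame(data, index=[p.plant_id for p in plants])
    return MarkerGenotypeTable(markers, df)


def mutation_sites(mutations: list[InducedMutation]) -> list[Site]:
    return [Site(m.chrom, m.pos, m.ref, m.alt, INDUCED, m.is_causal) for m in mutations]


def natural_snp_sites(
    genome: GenomeModel,
    reference: dict[str, str],
    spacing_bp: int = 50_000,
    seed=None,
    exclude: set[tuple[str, int]] | None = None,
) -> list[Site]:
    """Evenly spaced Col/Ler diagnostic SNPs (a thinned divergence panel)."""
    rng = np.random.default_rng(seed)
    exclude = exclude or set()
    sites = []
    for c in genome.chromosomes:
        pos = spacing_bp // 2
        while pos <= c.length_bp:
            if (c.name, pos) not in exclude:
                ref = reference[c.name][pos - 1]
                options = [b for b in _BASES if b != ref]
                alt = options[int(rng.integers(3))]
                sites.append(Site(c.name, pos, ref, alt, NATURAL))
            pos += spacing_bp
    return sites


def _member_alt_freq(member, site: Site) -> float:
    if isinstance(member, Line):
        if site.kind == INDUCED:
            return 1.0 if member.carries_induced else 0.0
        return 1.0 if member.background == LER else 0.0
    g1, g2 = member.genotype_at(site.chrom, site.pos)
    want = site.origin_of_alt
    return ((g1 == want) + (g2 == want)) / 2.0


def simulate_pool_counts(
    sites: list[Site],
    pools: list[PoolSpec],
    error_rate: float = 0.001,
    seed=None,
) -> list[SnpRecord]:
    """Pooled-sequencing allele depths at every site for every pool.

    Per site and pool: depth ~ Poisson(mean depth); alt reads ~
    Binomial(depth, p') with p' = p(1-e) + (1-p)e where p is the exact mean
    alt-allele frequency over member haplotypes and e the error rate.
    """
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    for pool in pools:
        if not pool.members:
            raise ValueError(f"pool {pool.pool_id} is empty")
    rng = np.random.default_rng(seed)
    records = []
    for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
        depths = {}
        for pool in pools:
            p = float(
                np.mean([_member_alt_freq(m, site) for m in pool.members])
            )
            p_eff = p * (1.0 - error_rate) + (1.0 - p) * error_rate
            depth = int(rng.poisson(pool.mean_depth))
            alt = int(rng.binomial(depth, p_eff)) if depth > 0 else 0
            depths[pool.pool_id] = (depth - alt, alt)
        records.append(SnpRecord(site.chrom, site.pos, site.ref, site.alt, depths))
    return records


@dataclass
class SimulationConfig:
    """Study-condition defaults for the simulated experiment.

    Bulks are sequenced at 50X and the fixed lines at 20X; the EMS load and
    its transition bias, the F2 size, the bulk size and the diagnostic-SNP
    spacing are the remaining knobs of the design.
    """

    n_f2_plants: int = 300
    bulk_size: int = 30
    depth_bulk: float = 50.0
    depth_line: float = 20.0
    n_mutations: int = 70
    transition_fraction: float = 0.99
    error_rate: float = 0.001
    natural_snp_spacing_bp: int = 50_000
    min_depth: int = 5
    window_size_bp: int = 1_000_000
    step_bp: int = 200_000
    epsilon: float = 0.05
    use_line_pools: bool = False


@dataclass
class SimulatedExperiment:
    genome: GenomeModel
    reference: dict[str, str]
    mutations: list[InducedMutation]
    causal: InducedMutation
    sites: list[Site]
    plants: list[F2Plant]
    pools: list[PoolSpec]
    snp_records: list[SnpRecord]
    mutant_table: MarkerGenotypeTable = None
    config: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int | None = None


def simulate_experiment(
    config: SimulationConfig | None = None,
    genome: GenomeModel | None = None,
    seed: int | None = 0,
) -> SimulatedExperiment:
    """Run the whole design: mutagenesis, F2, bulk selection, pooled counts."""
    cfg = config or SimulationConfig()
    genome = genome or default_toy_genome()
    ss = np.random.SeedSequence(seed)
    ref_ss, ems_ss, pop_ss, nat_ss, seq_ss = ss.spawn(5)
    reference = random_reference(genome, ref_ss)
    mutations = simulate_ems_line(
        genome, reference, cfg.n_mutations, cfg.transition_fraction, seed=ems_ss
    )
    causal = next(m for m in mutations if m.is_causal)
    plants = simulate_f2_population(genome, causal, cfg.n_f2_plants, seed=pop_ss)
    mutants = [p for p in plants if p.phenotype == MUTANT]
    normals = [p for p in plants if p.phenotype == NORMAL]
    if not mutants or not normals:
        raise RuntimeError("F2 population lacks one phenotype class; enlarge it")
    mut_bulk = mutants[: cfg.bulk_size]
    norm_bulk = normals[: cfg.bulk_size]
    pools = [
        PoolSpec(PARENT_LINE, [Line("parent", COL, carries_induced=False)], cfg.depth_line),
        PoolSpec(ORIG_MUTANT, [Line("mutant", COL, carries_induced=True)], cfg.depth_line),
        PoolSpec(LER_POOL, [Line("ler", LER, carries_induced=False)], cfg.depth_line),
        PoolSpec(F2_MUTANT, mut_bulk, cfg.depth_bulk),
        PoolSpec(F2_NORMAL, norm_bulk, cfg.depth_bulk),
    ]
    sites = mutation_sites(mutations) + natural_snp_sites(
        genome,
        reference,
        cfg.natural_snp_spacing_bp,
        seed=nat_ss,
        exclude={(m.chrom, m.pos) for m in mutations},
    )
    snp_records = simulate_pool_counts(sites, pools, cfg.error_rate, seed=seq_ss)
    table = genotype_table(mutants, genome)
    return SimulatedExperiment(
        genome=genome,
        reference=reference,
        mutations=mutations,
        causal=causal,
        sites=sites,
        plants=plants,
        pools=pools,
        snp_records=snp_records,
        mutant_table=table,
        config=cfg,
        seed=seed,
    )
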