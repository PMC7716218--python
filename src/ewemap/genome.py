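"""Genome model: chromosomes with genetic maps, SSLP marker loci and gene models.

The genetic map of each chromosome is piecewise linear between anchor loci:
the chromosome ends plus any markers with known genetic positions.  Physical
coordinates are 1-based inclusive throughout (VCF/GFF3 convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COL = "COL"
LER = "LER"


@dataclass(frozen=True)
class MarkerLocus:
    """An SSLP marker anchored both physically (bp) and genetically (cM)."""

    name: str
    pos_bp: int
    pos_cm: float


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform protein-coding gene.

    ``cds_segments`` are 1-based inclusive (start, end) pairs sorted by start;
    translation begins at spliced position 1 and the spliced CDS length must
    be a multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_segments:
            raise ValueError(f"{self.gene_id}: gene needs at least one CDS segment")
        prev_end = 0
        for start, end in self.cds_segments:
            if start <= prev_end:
                raise ValueError(
                    f"{self.gene_id}: CDS segments must be sorted and non-overlapping"
                )
            if end < start:
                raise ValueError(f"{self.gene_id}: CDS segment end < start")
            prev_end = end
        if self.spliced_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: spliced CDS length {self.spliced_length} "
                "is not a multiple of 3"
            )

    @property
    def spliced_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)

    @property
    def start(self) -> int:
        return self.cds_segments[0][0]

    @property
    def end(self) -> int:
        return self.cds_segments[-1][1]

    def contains(self, pos: int) -> bool:
        """True if ``pos`` falls inside any CDS segment."""
        return any(start <= pos <= end for start, end in self.cds_segments)


@dataclass
class ChromosomeModel:
    name: str
    length_bp: int
    length_cm: float
    markers: list[MarkerLocus] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"{self.name}: length_bp must be >= 1")
        if self.length_cm < 0:
            raise ValueError(f"{self.name}: length_cm must be >= 0")
        self.markers = sorted(self.markers, key=lambda m: m.pos_bp)
        for m in self.markers:
            if not (1 <= m.pos_bp <= self.length_bp):
                raise ValueError(f"marker {m.name} outside chromosome {self.name}")
        cms = [m.pos_cm for m in self.markers]
        if any(b < a for a, b in zip(cms, cms[1:])):
            raise ValueError(
                f"{self.name}: genetic positions must be nondecreasing in bp"
            )
        if cms and (cms[0] < 0 or cms[-1] > self.length_cm):
            raise ValueError(f"{self.name}: marker cM positions outside [0, length_cm]")
        for g in self.genes:
            if g.chrom != self.name:
                raise ValueError(f"gene {g.gene_id} assigned to wrong chromosome")
            if g.start < 1 or g.end > self.length_bp:
                raise ValueError(f"gene {g.gene_id} outside chromosome {self.name}")
        self._anchors_bp = np.array(
            [1] + [m.pos_bp for m in self.markers] + [self.length_bp], dtype=float
        )
        self._anchors_cm = np.array(
            [0.0] + [m.pos_cm for m in self.markers] + [self.length_cm], dtype=float
        )

    def bp_to_cm(self, pos_bp: float) -> float:
        return float(np.interp(pos_bp, self._anchors_bp, self._anchors_cm))

    def cm_to_bp(self, pos_cm: float) -> float:
        # np.interp needs strictly increasing x only for uniqueness; plateaus
        # (zero-recombination stretches) resolve to their left edge.
        return float(np.interp(pos_cm, self._anchors_cm, self._anchors_bp))


@dataclass
class GenomeModel:
    chromosomes: list[ChromosomeModel]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        marker_names = [m.name for c in self.chromosomes for m in c.markers]
        if len(set(marker_names)) != len(marker_names):
            raise ValueError("marker names must be unique genome-wide")
        self._by_name = {c.name: c for c in self.chromosomes}

    def chromosome(self, name: str) -> ChromosomeModel:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    def all_markers(self) -> list[tuple[str, MarkerLocus]]:
        return [(c.name, m) for c in self.chromosomes for m in c.markers]

    def all_genes(self) -> list[GeneModel]:
        return [g for c in self.chromosomes for g in c.genes]


def _toy_genes(chrom: str, length_bp: int, prefix: str) -> list[GeneModel]:
    """Genes every ~900 kb; alternating strand, every third gene two-exon."""
    genes = []
    start = 200_000
    i = 1
    while start + 2_000 < length_bp - 200_000:
        strand = "+" if i % 2 else "-"
        if i % 3 == 0:
            segs = ((start, start + 599), (start + 800, start + 1099))  # 600 + 300
        else:
            segs = ((start, start + 899),)
        genes.append(GeneModel(f"{prefix}G{i:02d}", chrom, strand, segs))
        start += 900_000
        i += 1
    return genes


def default_toy_genome() -> GenomeModel:
    """Two-chromosome toy genome at an Arabidopsis-like 5 cM/Mb map density.

    Four SSLP markers per chromosome anchor the (here uniform) genetic map,
    and protein-coding genes are spaced along each chromosome so a causal
    point mutation can be planted in a CDS anywhere in the genome.
    """
    chr1 = ChromosomeModel(
        "chr1",
        8_000_000,
        40.0,
        markers=[
            MarkerLocus("M1-1", 1_000_000, 5.0),
            MarkerLocus("M1-2", 3_000_000, 15.0),
            MarkerLocus("M1-3", 5_000_000, 25.0),
            MarkerLocus("M1-4", 7_000_000, 35.0),
        ],
        genes=_toy_genes("chr1", 8_000_000, "C1"),
    )
    chr2 = ChromosomeModel(
        "chr2",
        6_000_000,
        30.0,
        markers=[
            MarkerLocus("M2-1", 1_000_000, 5.0),
            MarkerLocus("M2-2", 2_500_000, 12.5),
            MarkerLocus("M2-3", 4_000_000, 20.0),
            MarkerLocus("M2-4", 5_500_000, 27.5),
        ],
        genes=_toy_genes("chr2", 6_000_000, "C2"),
    )
    return GenomeModel([chr1, chr2])
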