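"""Marker-assisted crude mapping from phenotypically mutant F2 plants.

In an F2 of (mutant, Col background) x Ler selected for a recessive mutant
phenotype, every chromosome of a selected plant carries the causal allele,
so at a linked marker each chromosome shows the mapping parent's (Ler)
allele with probability equal to the recombination fraction r.  The map
distance to a marker is therefore estimated as

    distance_cM = 100 * (mapping-parent allele chromosomes) / (scored chromosomes)

with a heterozygote contributing one recombinant chromosome, a homozygote
for the mapping-parent allele two, and missing genotypes dropped from the
denominator.  No map-function (Haldane/Kosambi) correction is applied.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

# Genotype codes: A = homozygous mutant background (Col), H = heterozygous,
# B = homozygous mapping parent (Ler), - = missing.
HOM_MUT_BG = "A"
HET = "H"
HOM_MAP_PARENT = "B"
MISSING = "-"
VALID_CODES = frozenset({HOM_MUT_BG, HET, HOM_MAP_PARENT, MISSING})

_RECOMBINANT_CHROMS = {HOM_MUT_BG: 0, HET: 1, HOM_MAP_PARENT: 2}


@dataclass(frozen=True)
class Marker:
    name: str
    chrom: str
    pos_bp: int


@dataclass
class MarkerGenotypeTable:
    """Genotypes of phenotypically mutant F2 plants at SSLP markers.

    ``genotypes`` is a DataFrame indexed by plant id with one column per
    marker name, cells drawn from {A, H, B, -}.
    """

    markers: list[Marker]
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names")
        if list(self.genotypes.columns) != names:
            raise ValueError("genotype columns must match marker names, in order")
        bad = set(self.genotypes.values.ravel()) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"unknown marker {name!r}")

    @classmethod
    def from_counts(
        cls,
        marker: Marker,
        n_hom_mut_bg: int,
        n_het: int,
        n_hom_map_parent: int,
        n_missing: int = 0,
    ) -> "MarkerGenotypeTable":
        """Single-marker table from genotype class counts (worked-example helper)."""
        codes = (
            [HOM_MUT_BG] * n_hom_mut_bg
            + [HET] * n_het
            + [HOM_MAP_PARENT] * n_hom_map_parent
            + [MISSING] * n_missing
        )
        df = pd.DataFrame(
            {marker.name: codes},
            index=[f"plant{i + 1}" for i in range(len(codes))],
        )
        return cls([marker], df)


@dataclass(frozen=True)
class MarkerDistance:
    marker_name: str
    chrom: str
    pos_bp: int
    n_scored_chromosomes: int
    n_recombinant_chromosomes: int
    distance_cm: float


def marker_distance(table: MarkerGenotypeTable, marker_name: str) -> MarkerDistance:
    """Recombinant-chromosome distance between one marker and the causal locus."""
    marker = table.marker(marker_name)
    codes = table.genotypes[marker_name]
    scored = codes[codes != MISSING]
    if scored.empty:
        raise ValueError(f"marker {marker_name} has no scored genotypes")
    n_scored = 2 * len(scored)
    n_rec = int(sum(_RECOMBINANT_CHROMS[c] for c in scored))
    return MarkerDistance(
        marker_name=marker.name,
        chrom=marker.chrom,
        pos_bp=marker.pos_bp,
        n_scored_chromosomes=n_scored,
        n_recombinant_chromosomes=n_rec,
        distance_cm=100.0 * n_rec / n_scored,
    )


def scan_markers(table: MarkerGenotypeTable) -> list[MarkerDistance]:
    """Distances for every marker, ascending; ties broken by chromosome, position."""
    if len(table.markers) < 2:
        # a single-marker scan is a degenerate but valid request
        pass
    dists = [marker_distance(table, m.name) for m in table.markers]
    return sorted(dists, key=lambda d: (d.distance_cm, d.chrom, d.pos_bp))


def linked_interval(
    distances: list[MarkerDistance], chromosome: str, tol: float = 1e-9
) -> tuple[str, str]:
    """Flanking-marker interval around the minimum-distance marker(s).

    When several markers tie at the minimum the interval spans the outermost
    tied markers; a unique minimum is bracketed by its immediate neighbours
    (or by itself at a chromosome-end position).
    """
    on_chrom = sorted(
        (d for d in distances if d.chrom == chromosome), key=lambda d: d.pos_bp
    )
    if len(on_chrom) < 2:
        raise ValueError(f"need >= 2 markers on chromosome {chromosome}")
    dmin = min(d.distance_cm for d in on_chrom)
    tied_idx = [i for i, d in enumerate(on_chrom) if abs(d.distance_cm - dmin) <= tol]
    if len(tied_idx) > 1:
        left, right = tied_idx[0], tied_idx[-1]
    else:
        i = tied_idx[0]
        left = max(i - 1, 0)
        right = min(i + 1, len(on_chrom) - 1)
    return on_chrom[left].marker_name, on_chrom[right].marker_name


def format_cm(distance_cm: float, decimals: int = 2) -> str:
    """Render a distance the way the mapping tables print it.

    Half-up rounding to ``decimals`` places, then trailing zeros (and a bare
    decimal point) dropped: 19.047 -> "19.05" -> with decimals=0 "19";
    3.125 -> "3.13"; 40.0 -> "40".
    """
    q = Decimal(1).scaleb(-decimals) if decimals > 0 else Decimal(1)
    s = str(Decimal(repr(distance_cm)).quantize(q, rounding=ROUND_HALF_UP))
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s


def round_cm(distance_cm: float, decimals: int = 2) -> float:
    """Half-up numeric rounding used for printed-precision comparisons."""
    q = Decimal(1).scaleb(-decimals) if decimals > 0 else Decimal(1)
    return float(Decimal(repr(distance_cm)).quantize(q, rounding=ROUND_HALF_UP))
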