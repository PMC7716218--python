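"""Candidate-mutation annotation.

EMS (ethyl methanesulfonate) produces almost exclusively G:C -> A:T
transitions, so candidate causal variants are retained variants that are
G->A or C->T on the reference strand, fall inside a CDS, and change the
encoded protein.  Effects are computed on the spliced CDS honoring strand,
with amino-acid numbering 1-based from the initiator methionine (``P113L``
style change strings; stop gains use ``*`` as the alternate residue).
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .bsa import SnpIndexRecord, SnpRecord
from .genome import GeneModel

MISSENSE = "MISSENSE"
SYNONYMOUS = "SYNONYMOUS"
NONSENSE = "NONSENSE"
NONCODING = "NONCODING"

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class CandidateMutation:
    record: SnpRecord
    gene_id: str | None
    is_ems_type: bool
    consequence: str
    codon_number: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def change_string(self) -> str | None:
        """``P113L``-style string; defined only for MISSENSE and NONSENSE."""
        if self.consequence in (MISSENSE, NONSENSE):
            return f"{self.ref_aa}{self.codon_number}{self.alt_aa}"
        return None


def is_ems_transition(ref_base: str, alt_base: str) -> bool:
    """True for the EMS signature: G->A, or C->T (= G->A on the other strand)."""
    if ref_base not in _NUCLEOTIDES or alt_base not in _NUCLEOTIDES:
        raise ValueError(f"non-ACGT base in ({ref_base!r}, {alt_base!r})")
    return (ref_base, alt_base) in (("G", "A"), ("C", "T"))


def _spliced_cds(gene: GeneModel, chrom_seq: str) -> str:
    parts = [chrom_seq[start - 1 : end] for start, end in gene.cds_segments]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _coding_offset(gene: GeneModel, pos: int) -> int:
    """0-based position of ``pos`` in the spliced CDS, honoring strand."""
    offset = 0
    for start, end in gene.cds_segments:
        if start <= pos <= end:
            offset += pos - start
            break
        offset += end - start + 1
    else:
        raise ValueError(f"{pos} not in CDS of {gene.gene_id}")
    if gene.strand == "-":
        offset = gene.spliced_length - 1 - offset
    return offset


def annotate_effect(
    snp: SnpRecord, genes: list[GeneModel], reference: dict[str, str]
) -> list[CandidateMutation]:
    """Annotate a SNP against every overlapping gene model.

    Returns one CandidateMutation per gene whose CDS contains the SNP, or a
    single NONCODING record when no CDS overlaps.  The reference base at the
    SNP position must match ``snp.ref``.
    """
    chrom_seq = reference[snp.chrom]
    ref_base = chrom_seq[snp.pos - 1]
    if ref_base != snp.ref:
        raise ValueError(
            f"reference mismatch at {snp.chrom}:{snp.pos}: "
            f"sequence has {ref_base}, record says {snp.ref}"
        )
    ems = is_ems_transition(snp.ref, snp.alt)
    hits = [g for g in genes if g.chrom == snp.chrom and g.contains(snp.pos)]
    if not hits:
        return [CandidateMutation(snp, None, ems, NONCODING)]
    out = []
    for gene in hits:
        cds = _spliced_cds(gene, chrom_seq)
        offset = _coding_offset(gene, snp.pos)
        ref_in_cds = snp.ref if gene.strand == "+" else _COMPLEMENT[snp.ref]
        alt_in_cds = snp.alt if gene.strand == "+" else _COMPLEMENT[snp.alt]
        assert cds[offset] == ref_in_cds
        codon_number = offset // 3 + 1
        codon_start = (codon_number - 1) * 3
        ref_codon = cds[codon_start : codon_start + 3]
        alt_codon = (
            ref_codon[: offset - codon_start]
            + alt_in_cds
            + ref_codon[offset - codon_start + 1 :]
        )
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if ref_aa == alt_aa:
            consequence = SYNONYMOUS
        elif alt_aa == "*":
            consequence = NONSENSE
        else:
            consequence = MISSENSE
        out.append(
            CandidateMutation(snp, gene.gene_id, ems, consequence, codon_number, ref_aa, alt_aa)
        )
    return out


@dataclass(frozen=True)
class DroppedRecord:
    record: SnpRecord
    gene_id: str | None
    reason: str


@dataclass
class CandidateReport:
    candidates: list[CandidateMutation]
    dropped: list[DroppedRecord]


def candidate_report(
    retained: list[SnpIndexRecord],
    interval: tuple[str, int, int],
    genes: list[GeneModel],
    reference: dict[str, str],
) -> CandidateReport:
    """EMS-signature protein-changing candidates inside a mapping interval.

    Keeps retained records within ``interval`` (chrom, start, end inclusive)
    that are EMS-type transitions with a MISSENSE or NONSENSE consequence;
    every excluded record is listed with its drop reason for auditability.
    """
    chrom, start, end = interval
    if start > end:
        raise ValueError("malformed interval: start > end")
    candidates: list[CandidateMutation] = []
    dropped: list[DroppedRecord] = []
    for rec in sorted(retained, key=lambda r: (r.record.chrom, r.record.pos)):
        snp = rec.record
        if snp.chrom != chrom or not (start <= snp.pos <= end):
            dropped.append(DroppedRecord(snp, None, "OUT_OF_INTERVAL"))
            continue
        for ann in annotate_effect(snp, genes, reference):
            if not ann.is_ems_type:
                dropped.append(DroppedRecord(snp, ann.gene_id, "NOT_EMS_TYPE"))
            elif ann.consequence in (MISSENSE, NONSENSE):
                candidates.append(ann)
            else:
                dropped.append(DroppedRecord(snp, ann.gene_id, ann.consequence))
    candidates.sort(key=lambda c: c.record.pos)
    return CandidateReport(candidates, dropped)
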