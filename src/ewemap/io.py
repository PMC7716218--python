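"""File formats: FASTA, GFF3, minimal VCF 4.2 and the pipeline's TSV tables.

All TSVs are tab-separated with a header row; lines starting with '#' are
comments.  The VCF writer emits a minimal VCF 4.2 with one sample column
per pool and AD-style allele depths; reading goes through pysam so any
AD-bearing VCF with samples named after the pools is accepted.
"""
from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import CandidateMutation, CandidateReport
from .bsa import ALL_POOLS, SnpIndexRecord, SnpRecord
from .genome import GeneModel, GenomeModel
from .markers import Marker, MarkerDistance, MarkerGenotypeTable, format_cm
from .segregation import SegregationResult
from .simulate import F2Plant, InducedMutation


# ---------------------------------------------------------------- FASTA

def write_fasta(reference: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------- GFF3

def _cds_phases(gene: GeneModel) -> list[int]:
    """Phase per CDS segment (file order = ascending start), honoring strand."""
    segs = list(gene.cds_segments)
    order = segs if gene.strand == "+" else segs[::-1]
    phases, cum = {}, 0
    for seg in order:
        phases[seg] = (3 - cum % 3) % 3
        cum += seg[1] - seg[0] + 1
    return [phases[s] for s in segs]


def write_gff3(genes: Iterable[GeneModel], path: str, genome: GenomeModel | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if genome is not None:
            for c in genome.chromosomes:
                fh.write(f"##sequence-region {c.name} 1 {c.length_bp}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tewemap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID=gene:{g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tewemap\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID=tx:{g.gene_id};Parent=gene:{g.gene_id}\n"
            )
            for (start, end), phase in zip(g.cds_segments, _cds_phases(g)):
                fh.write(
                    f"{g.chrom}\tewemap\tCDS\t{start}\t{end}\t.\t{g.strand}\t{phase}\t"
                    f"ID=cds:{g.gene_id};Parent=tx:{g.gene_id}\n"
                )


def read_gff3(path: str) -> list[GeneModel]:
    """Gene models from a GFF3: CDS features grouped by gene via Parent links."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        segs = sorted(
            (cds.start, cds.end)
            for cds in db.children(gene, featuretype="CDS")
        )
        gene_id = gene.id.removeprefix("gene:")
        genes.append(GeneModel(gene_id, gene.seqid, gene.strand, tuple(segs)))
    return genes


# ---------------------------------------------------------------- VCF

def write_snp_vcf(
    records: list[SnpRecord],
    path: str,
    pools: list[str] | None = None,
    genome: GenomeModel | None = None,
) -> None:
    if pools is None:
        seen = {p for r in records for p in r.depths}
        pools = [p for p in ALL_POOLS if p in seen]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ewemap\n")
        if genome is not None:
            for c in genome.chromosomes:
                fh.write(f"##contig=<ID={c.name},length={c.length_bp}>\n")
        else:
            for name in sorted({r.chrom for r in records}):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(pools)
            + "\n"
        )
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            samples = []
            for p in pools:
                if p in r.depths:
                    ref_d, alt_d = r.depths[p]
                    samples.append(f"{ref_d},{alt_d}")
                else:
                    samples.append(".")
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\tAD\t"
                + "\t".join(samples)
                + "\n"
            )


def read_snp_vcf(path: str, pool_map: dict[str, str] | None = None) -> list[SnpRecord]:
    """Read a VCF with per-sample AD depths.

    ``pool_map`` maps VCF sample names to pool ids; by default samples are
    assumed to already be named after pools.
    """
    records = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        pool_map = pool_map or {s: s for s in samples}
        for rec in vf:
            if not rec.alts or len(rec.alts) != 1:
                raise ValueError(f"{path}: expected biallelic records ({rec.chrom}:{rec.pos})")
            depths = {}
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or all(v is None for v in ad):
                    continue
                depths[pool_map.get(s, s)] = (int(ad[0]), int(ad[1]))
            records.append(SnpRecord(rec.chrom, rec.pos, rec.ref, rec.alts[0], depths))
    return records


# ---------------------------------------------------------------- TSV tables

def _read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")


def write_genotype_tsv(table: MarkerGenotypeTable, path: str) -> None:
    df = table.genotypes.copy()
    df.insert(0, "plant", df.index)
    df.to_csv(path, sep="\t", index=False)


def write_marker_map_tsv(markers: list[Marker], path: str) -> None:
    pd.DataFrame(
        {
            "marker": [m.name for m in markers],
            "chromosome": [m.chrom for m in markers],
            "pos_bp": [m.pos_bp for m in markers],
        }
    ).to_csv(path, sep="\t", index=False)


def read_genotype_tsv(genotype_path: str, marker_map_path: str) -> MarkerGenotypeTable:
    gdf = _read_tsv(genotype_path).set_index("plant")
    mdf = _read_tsv(marker_map_path)
    markers = [
        Marker(row["marker"], row["chromosome"], int(row["pos_bp"]))
        for _, row in mdf.iterrows()
    ]
    order = [m.name for m in markers if m.name in gdf.columns]
    markers = [m for m in markers if m.name in gdf.columns]
    return MarkerGenotypeTable(markers, gdf[order])


def distances_to_df(distances: list[MarkerDistance]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [d.chrom for d in distances],
            "marker": [d.marker_name for d in distances],
            "n_scored_chromosomes": [d.n_scored_chromosomes for d in distances],
            "n_recombinant_chromosomes": [d.n_recombinant_chromosomes for d in distances],
            "distance_cm": [round(d.distance_cm, 4) for d in distances],
            "distance_printed": [format_cm(d.distance_cm) for d in distances],
        }
    )


def read_crosses_tsv(path: str) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"cross_id", "generation", "n_total", "n_mutant", "n_wildtype", "ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def segregation_results_to_df(
    results: list[tuple[str, str, SegregationResult]]
) -> pd.DataFrame:
    rows = []
    for cross_id, generation, res in results:
        rows.append(
            {
                "cross_id": cross_id,
                "generation": generation,
                "n_total": res.n_total,
                "n_mutant": res.n_mutant,
                "n_wildtype": res.n_wildtype,
                "ratio": f"{res.expected_ratio[0]}:{res.expected_ratio[1]}",
                "chi2": round(res.chi2, 4),
                "df": res.df,
                "p_value": round(res.p_value, 4),
                "significant_at_0_05": res.significant_at_0_05,
            }
        )
    return pd.DataFrame(rows)


def index_records_to_df(records: list[SnpIndexRecord]) -> pd.DataFrame:
    pools = [p for p in ALL_POOLS if any(p in r.record.depths for r in records)]
    rows = []
    for r in records:
        row = {"chrom": r.record.chrom, "pos": r.record.pos, "ref": r.record.ref, "alt": r.record.alt}
        for p in pools:
            rd, ad = r.record.depths.get(p, ("", ""))
            row[f"{p}_ref"] = rd
            row[f"{p}_alt"] = ad
            idx = r.indices.get(p)
            row[f"{p}_index"] = "" if idx is None else round(idx, 4)
        row["delta_snp_index"] = "" if r.delta is None else round(r.delta, 4)
        row["filter_status"] = r.filter_status or ""
        rows.append(row)
    return pd.DataFrame(rows)


def read_snp_tsv(path: str) -> list[SnpRecord]:
    """Flat-TSV alternative to VCF: chrom, pos, ref, alt, <pool>_ref, <pool>_alt."""
    df = _read_tsv(path)
    pools = [p for p in ALL_POOLS if f"{p}_ref" in df.columns and f"{p}_alt" in df.columns]
    records = []
    for _, row in df.iterrows():
        depths = {}
        for p in pools:
            r_, a_ = row[f"{p}_ref"], row[f"{p}_alt"]
            if r_ != "" and a_ != "":
                depths[p] = (int(r_), int(a_))
        records.append(SnpRecord(row["chrom"], int(row["pos"]), row["ref"], row["alt"], depths))
    return records


def candidates_to_df(report: CandidateReport) -> pd.DataFrame:
    rows = []
    for c in report.candidates:
        rows.append(
            {
                "gene_id": c.gene_id,
                "chrom": c.record.chrom,
                "pos": c.record.pos,
                "change": f"{c.record.ref}>{c.record.alt}",
                "change_string": c.change_string or "",
                "consequence": c.consequence,
                "codon_number": c.codon_number,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "pos", "change", "change_string", "consequence", "codon_number"],
    )


def dropped_to_df(report: CandidateReport) -> pd.DataFrame:
    rows = [
        {
            "chrom": d.record.chrom,
            "pos": d.record.pos,
            "change": f"{d.record.ref}>{d.record.alt}",
            "gene_id": d.gene_id or "",
            "reason": d.reason,
        }
        for d in report.dropped
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "change", "gene_id", "reason"])


def write_truth_tsv(mutations: list[InducedMutation], path: str) -> None:
    pd.DataFrame(
        {
            "chrom": [m.chrom for m in mutations],
            "pos": [m.pos for m in mutations],
            "ref": [m.ref for m in mutations],
            "alt": [m.alt for m in mutations],
            "is_causal": [int(m.is_causal) for m in mutations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str) -> list[InducedMutation]:
    df = _read_tsv(path)
    return [
        InducedMutation(r["chrom"], int(r["pos"]), r["ref"], r["alt"], bool(int(r["is_causal"])))
        for _, r in df.iterrows()
    ]


def write_plants_tsv(plants: list[F2Plant], path: str) -> None:
    pd.DataFrame(
        {
            "plant": [p.plant_id for p in plants],
            "phenotype": [p.phenotype for p in plants],
        }
    ).to_csv(path, sep="\t", index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
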