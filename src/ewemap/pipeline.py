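"""End-to-end pipeline: simulation (or real inputs) to candidate report.

Stages run in order — segregation, marker mapping, SNP-index, candidate
annotation — each skipped with a logged notice when its inputs are absent.
A JSON report bundles the stage outputs together with a snapshot of the
configuration actually used, so a run is auditable and reproducible.

Exit codes: 0 success, 2 input error, 3 pipeline ran but found no candidate.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import annotate, bsa, io, markers, segregation, simulate
from .bsa import REMOVED_LER, REMOVED_LOW_DEPTH
from .genome import default_toy_genome
from .simulate import SimulationConfig

log = logging.getLogger("ewemap")

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_NO_CANDIDATES = 3


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # real-data inputs (used when simulate=False; any may be omitted)
    crosses_tsv: str | None = None
    genotype_tsv: str | None = None
    marker_map_tsv: str | None = None
    snp_vcf: str | None = None
    snp_tsv: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    interval: tuple[str, int, int] | None = None
    # stage parameters
    ratio_mutant: int = 1
    ratio_wildtype: int = 3
    min_depth: int = 5
    window_size_bp: int = 1_000_000
    step_bp: int = 200_000
    epsilon: float = 0.05
    use_line_pools: bool = False
    interval_margin_bp: int = 1_000_000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        if self.interval is not None:
            d["interval"] = list(self.interval)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_d = d.pop("sim", {}) or {}
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.sim = SimulationConfig(**sim_d)
        if cfg.interval is not None:
            chrom, start, end = cfg.interval
            cfg.interval = (str(chrom), int(start), int(end))
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    exit_code: int
    report: dict
    outdir: str


def _simulate_stage(config: PipelineConfig, outdir: str) -> simulate.SimulatedExperiment:
    exp = simulate.simulate_experiment(config.sim, genome=default_toy_genome(), seed=config.seed)
    io.write_fasta(exp.reference, os.path.join(outdir, "genome.fasta"))
    io.write_gff3(exp.genome.all_genes(), os.path.join(outdir, "genes.gff3"), exp.genome)
    io.write_snp_vcf(exp.snp_records, os.path.join(outdir, "pools.vcf"), genome=exp.genome)
    io.write_truth_tsv(exp.mutations, os.path.join(outdir, "truth.tsv"))
    io.write_plants_tsv(exp.plants, os.path.join(outdir, "plants.tsv"))
    io.write_genotype_tsv(exp.mutant_table, os.path.join(outdir, "genotypes.tsv"))
    io.write_marker_map_tsv(exp.mutant_table.markers, os.path.join(outdir, "marker_map.tsv"))
    log.info(
        "simulated experiment: %d mutations, causal %s:%d, %d F2 plants",
        len(exp.mutations), exp.causal.chrom, exp.causal.pos, len(exp.plants),
    )
    return exp


def run_pipeline(config: PipelineConfig, outdir: str) -> PipelineResult:
    io.ensure_dir(outdir)
    report: dict = {"config": config.to_dict(), "stages": {}}

    exp = None
    crosses = genotable = snp_records = genes = reference = None
    if config.simulate:
        exp = _simulate_stage(config, outdir)
        genotable = exp.mutant_table
        snp_records = exp.snp_records
        genes = exp.genome.all_genes()
        reference = exp.reference
        n_mut = sum(p.phenotype == simulate.MUTANT for p in exp.plants)
        crosses = [("simulated-F2", "F2", len(exp.plants) - n_mut, n_mut)]
    else:
        if config.crosses_tsv:
            df = io.read_crosses_tsv(config.crosses_tsv)
            crosses = [
                (r["cross_id"], r["generation"], int(r["n_wildtype"]), int(r["n_mutant"]))
                for _, r in df.iterrows()
            ]
        if config.genotype_tsv and config.marker_map_tsv:
            genotable = io.read_genotype_tsv(config.genotype_tsv, config.marker_map_tsv)
        if config.snp_vcf:
            snp_records = io.read_snp_vcf(config.snp_vcf)
        elif config.snp_tsv:
            snp_records = io.read_snp_tsv(config.snp_tsv)
        if config.gff3:
            genes = io.read_gff3(config.gff3)
        if config.fasta:
            reference = io.read_fasta(config.fasta)

    # ---- segregation ----
    if crosses is not None:
        results = []
        for cross_id, generation, n_wt, n_mut in crosses:
            res = segregation.chi_square_ratio(
                n_mut, n_wt, config.ratio_mutant, config.ratio_wildtype
            )
            mode = segregation.infer_inheritance(True, res)
            results.append((cross_id, generation, res))
            report["stages"].setdefault("segregation", []).append(
                {
                    "cross_id": cross_id,
                    "chi2": round(res.chi2, 4),
                    "significant_at_0_05": res.significant_at_0_05,
                    "inferred_mode_if_f1_uniform": mode,
                }
            )
        io.segregation_results_to_df(results).to_csv(
            os.path.join(outdir, "segregation.tsv"), sep="\t", index=False
        )
        log.info("segregation: tested %d cross(es) against %d:%d",
                 len(results), config.ratio_mutant, config.ratio_wildtype)
    else:
        log.info("segregation: no cross counts supplied, stage skipped")

    # ---- marker mapping ----
    interval = config.interval
    if genotable is not None:
        dists = markers.scan_markers(genotable)
        io.distances_to_df(dists).to_csv(
            os.path.join(outdir, "marker_distances.tsv"), sep="\t", index=False
        )
        best = dists[0]
        report["stages"]["marker_mapping"] = {
            "best_marker": best.marker_name,
            "best_chromosome": best.chrom,
            "best_distance_cm": round(best.distance_cm, 4),
        }
        n_on_chrom = sum(d.chrom == best.chrom for d in dists)
        if n_on_chrom >= 2:
            left, right = markers.linked_interval(dists, best.chrom)
            report["stages"]["marker_mapping"]["linked_interval"] = [left, right]
        log.info("marker mapping: %d markers, best %s (%s, %.2f cM)",
                 len(dists), best.marker_name, best.chrom, best.distance_cm)
    else:
        log.info("marker mapping: no genotype table supplied, stage skipped")

    # ---- SNP-index ----
    indexed = None
    if snp_records is not None:
        indexed = bsa.compute_indices(snp_records, min_depth=config.min_depth)
        indexed = bsa.filter_cascade(
            indexed, epsilon=config.epsilon, use_line_pools=config.use_line_pools
        )
        io.index_records_to_df(indexed).to_csv(
            os.path.join(outdir, "snp_index.tsv"), sep="\t", index=False
        )
        # Ler-derived variants carry negative deltas around the causal locus
        # and would cancel the EMS-variant peak inside a window mean, so the
        # localization profile uses records surviving the Ler/low-depth rules.
        profiled = [
            r for r in indexed
            if r.filter_status not in (REMOVED_LER, REMOVED_LOW_DEPTH)
        ]
        chrom_lengths = None
        if exp is not None:
            chrom_lengths = {c.name: c.length_bp for c in exp.genome.chromosomes}
        profile = bsa.delta_index_profile(
            profiled, config.window_size_bp, config.step_bp, chrom_lengths
        )
        profile.to_csv(os.path.join(outdir, "delta_profile.tsv"), sep="\t", index=False)
        peak = bsa.call_peak_region(profile)
        report["stages"]["snp_index"] = {
            "n_records": len(indexed),
            "n_retained": len(bsa.retained(indexed)),
            "peak": {
                "chrom": peak.chrom, "start": peak.start, "end": peak.end,
                "mean_delta": round(peak.mean_delta, 4), "tied": peak.tied,
            },
        }
        log.info("snp-index: %d records, %d retained, peak %s:%d-%d (mean delta %.3f)",
                 len(indexed), len(bsa.retained(indexed)), peak.chrom, peak.start,
                 peak.end, peak.mean_delta)
        if interval is None:
            chrom, start, end = bsa.peak_support_region(profile)
            interval = (
                chrom,
                max(1, start - config.interval_margin_bp),
                end + config.interval_margin_bp,
            )
    else:
        log.info("snp-index: no allele counts supplied, stage skipped")

    # ---- candidate annotation ----
    exit_code = EXIT_OK
    if indexed is not None and genes is not None and reference is not None and interval:
        rep = annotate.candidate_report(bsa.retained(indexed), interval, genes, reference)
        io.candidates_to_df(rep).to_csv(
            os.path.join(outdir, "candidates.tsv"), sep="\t", index=False
        )
        io.dropped_to_df(rep).to_csv(
            os.path.join(outdir, "dropped.tsv"), sep="\t", index=False
        )
        report["stages"]["candidates"] = {
            "interval": list(interval),
            "n_candidates": len(rep.candidates),
            "candidates": [
                {
                    "gene_id": c.gene_id,
                    "chrom": c.record.chrom,
                    "pos": c.record.pos,
                    "change": f"{c.record.ref}>{c.record.alt}",
                    "change_string": c.change_string,
                    "consequence": c.consequence,
                }
                for c in rep.candidates
            ],
        }
        log.info("candidates: %d EMS-type protein-changing candidate(s) in %s:%d-%d",
                 len(rep.candidates), *interval)
        if not rep.candidates:
            exit_code = EXIT_NO_CANDIDATES
    else:
        log.info("candidates: missing SNP records, gene models, reference or interval; stage skipped")

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    config.to_yaml(os.path.join(outdir, "config_used.yaml"))
    return PipelineResult(exit_code, report, outdir)
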