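"""End-to-end orchestration: simulate -> pooled mapping -> linkage
refinement -> variant annotation -> candidate filter.

Every intermediate is written as plain text (TSV/BED/GFF3/FASTA) under the
output directory, each stage logs its parameters, and the whole run is a
pure function of (config, seed): re-running with the same seed reproduces
every output byte for byte.
"""

from __future__ import annotations

import sys
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import bsa, cross, effects, linkage, scenario
from .genome import (GenomicInterval, load_gene_models, load_genome,
                     load_marker_map, write_bed, write_gene_models,
                     write_genome, write_marker_map)


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 1
    # stage selection: simulate a full scenario or load tables from files
    simulate: bool = True
    genome_path: str | None = None
    markers_path: str | None = None
    genes_path: str | None = None
    depths_path: str | None = None
    genotypes_path: str | None = None
    snvs_path: str | None = None
    # cross parameters (simulate mode)
    n_progeny: int = 192
    n_bulk: int = 48
    coverage: float = 50.0
    error_rate: float = 0.01
    penetrance: float = 1.0
    undetermined_rate: float = 0.0
    # pooled-mapping parameters
    window: int = bsa.DEFAULT_WINDOW
    step: int = bsa.DEFAULT_STEP
    min_markers: int = bsa.DEFAULT_MIN_MARKERS
    threshold: float = bsa.DEFAULT_THRESHOLD
    min_run: int = 1
    # refinement + filter
    refine: bool = True
    refine_segregants: int | None = None
    include_splice: bool = False
    write_fasta: bool = False

    def __post_init__(self) -> None:
        if self.simulate and any(
            p is not None for p in (self.depths_path, self.genotypes_path)
        ):
            raise ValueError("choose either simulate or load-from-files, not both")
        if not self.simulate and self.depths_path is None:
            raise ValueError("load-from-files mode needs depths_path")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"{path}: unknown config keys {sorted(bad)}")
        return cls(**data)


def _log(msg: str, lines: list[str]) -> None:
    lines.append(msg)
    print(msg, file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a dict of key results.

    Result keys: ``peaks`` (list of MappingPeak), ``interval`` (the mapped
    interval used for filtering), ``candidates`` (retained VariantCalls,
    report-ranked), ``report_path``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            _log(f"[simulate] seed={config.seed} n_progeny={config.n_progeny} "
                 f"n_bulk={config.n_bulk} coverage={config.coverage} "
                 f"error_rate={config.error_rate}", log)
            cfg, genes, snvs = scenario.mapping_scenario(config.seed)
            cfg = cross.CrossConfig(
                genome=cfg.genome, markers=cfg.markers,
                causal_locus=cfg.causal_locus, seed=config.seed,
                n_progeny=config.n_progeny, n_bulk=config.n_bulk,
                coverage=config.coverage, error_rate=config.error_rate,
                penetrance=config.penetrance,
                undetermined_rate=config.undetermined_rate)
            genome, markers = cfg.genome, cfg.markers
            segregants = cross.simulate_cross(cfg)
            import numpy as np
            rng = np.random.default_rng(cfg.seed + 1)
            bulk = cross.make_bulk(segregants, "down", cfg.n_bulk)
            depths = cross.simulate_pool_depths(
                bulk, markers, cfg.coverage, cfg.error_rate, rng)
            geno = cross.genotype_table(segregants, markers)
            write_marker_map(markers, out / "markers.tsv")
            cross.write_depth_table(depths, out / "bulk_depths.tsv")
            cross.write_genotype_table(geno, out / "genotypes.tsv")
            write_gene_models(genes, out / "genes.gff3")
            pd.DataFrame(snvs, columns=["chrom", "pos_bp", "ref", "alt"]).to_csv(
                out / "snvs.tsv", sep="\t", index=False)
            if config.write_fasta:
                write_genome(genome, out / "genome.fa")
            _log(f"[simulate] {len(segregants)} segregants, "
                 f"{sum(s.phenotype == 'down' for s in segregants)} down, "
                 f"bulk of {len(bulk)}; {len(depths)} marker depths", log)
        else:
            stage = "load"
            genome = load_genome(config.genome_path)
            markers = load_marker_map(config.markers_path)
            depths = cross.load_depth_table(config.depths_path)
            genes = (load_gene_models(config.genes_path)
                     if config.genes_path else [])
            snvs = (effects.load_snv_table(config.snvs_path)
                    if config.snvs_path else [])
            geno = (cross.load_genotype_table(config.genotypes_path)
                    if config.genotypes_path else None)
            _log(f"[load] {len(markers)} markers, {len(depths)} depth rows, "
                 f"{len(genes)} genes, {len(snvs)} SNVs", log)

        stage = "bsa"
        ratios = bsa.ratio_track(depths)
        windows = bsa.window_means(ratios, genome, config.window, config.step,
                                   config.min_markers)
        peaks = bsa.detect_peaks(windows, config.threshold, config.min_run)
        ratios.to_csv(out / "ratios.tsv", sep="\t", index=False)
        bsa.write_windows(windows, out / "windows.tsv")
        write_bed([p.interval for p in peaks], out / "peaks.bed",
                  [f"peak_{i+1}" for i in range(len(peaks))])
        _log(f"[bsa] window={config.window} step={config.step} "
             f"threshold={config.threshold}: {len(peaks)} peak(s)", log)
        interval: GenomicInterval | None = peaks[0].interval if peaks else None

        if config.refine and interval is not None:
            stage = "refine"
            geno_df = geno if not config.simulate else cross.genotype_table(
                segregants[: config.refine_segregants]
                if config.refine_segregants else segregants, markers)
            if geno_df is not None:
                refined, link = linkage.two_round_refine(
                    geno_df, markers.to_frame(), interval.chrom,
                    genome.length(interval.chrom))
                link.to_csv(out / "linkage.tsv", sep="\t", index=False,
                            na_rep="NA")
                write_bed([refined], out / "refined_interval.bed", ["refined"])
                _log(f"[refine] interval {refined.chrom}:{refined.start}-"
                     f"{refined.end} ({refined.length_kb} kb)", log)
                interval = refined

        stage = "annotate"
        candidates: list[effects.VariantCall] = []
        if snvs and genome.chromosomes[0].sequence is not None:
            calls = effects.classify_variants(genome, genes, snvs)
            effects.variants_to_frame(calls, interval).to_csv(
                out / "variants_annotated.tsv", sep="\t", index=False)
            if interval is not None:
                candidates = effects.rank_for_report(effects.filter_candidates(
                    calls, interval, config.include_splice))
                effects.variants_to_frame(candidates).to_csv(
                    out / "candidates.tsv", sep="\t", index=False)
            _log(f"[annotate] {len(snvs)} SNVs classified, "
                 f"{len(candidates)} candidate(s) retained", log)

        stage = "report"
        report = out / "report.txt"
        with open(report, "w") as fh:
            fh.write("# mossmap pipeline report\n")
            fh.write(f"seed\t{config.seed}\n")
            if interval is not None:
                fh.write(f"mapped_interval\t{interval.chrom}:{interval.start}-"
                         f"{interval.end}\t{interval.length_kb} kb\n")
            else:
                fh.write("mapped_interval\tnone (no peak above threshold)\n")
            if candidates:
                fh.write("candidates (stop_gained ranked first):\n")
                for v in candidates:
                    fh.write(f"\t{v.gene_id}\t{v.chrom}:{v.pos_bp}\t"
                             f"{v.ref_base}>{v.alt_base}\t{v.effect}\t"
                             f"{v.protein_change}\n")
                fh.write(f"top_candidate\t{candidates[0].gene_id}\t"
                         f"{candidates[0].protein_change}\n")
            else:
                fh.write("candidates\tnone\n")
            fh.write("\n# log\n")
            for line in log:
                fh.write(line + "\n")
        return {"peaks": peaks, "interval": interval,
                "candidates": candidates, "report_path": report}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
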