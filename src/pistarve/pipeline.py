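"""Pipeline orchestration: structured config, staged runs, output manifest.

Each subcommand (simulate, srna, diffexp, degradome, quant, motifs, enrich,
all) is reproducible from its declared inputs alone; every produced file is
recorded in a manifest with a SHA-256 content hash so reruns under the same
seed and config can be audited for byte identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import annotation, degradome, diffexp, motifs, quant, simulate
from .io import (
    read_fastq,
    read_transcript_models,
    write_count_table,
    write_fasta,
    write_transcript_models,
)

log = logging.getLogger("pistarve")


@dataclass
class PipelineConfig:
    """All thresholds and paths of the pipeline, in their documented domains."""

    outdir: str = "pistarve_out"
    seed: int = 0
    alpha: float = 0.05
    min_srna_len: int = 18
    max_srna_len: int = 25
    quality_limit: float = 0.02
    min_degradome_tag_len: int = 15
    mfe_ratio_min: float = 0.6
    allen_threshold: float = 4.0
    n_permutations: int = 100
    track: str = "allen"
    promoter_window: int = 2000
    motif_bin: int = 500
    motif_names: tuple = ("P1BS", "PHO")
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.quality_limit < 1:
            raise ValueError("quality_limit must be in (0, 1)")
        if not 0 < self.min_srna_len <= self.max_srna_len:
            raise ValueError("invalid sRNA length window")
        if self.min_degradome_tag_len < 1:
            raise ValueError("min_degradome_tag_len must be positive")
        if not 0 <= self.mfe_ratio_min <= 1:
            raise ValueError("mfe_ratio_min must be in [0, 1]")
        if self.allen_threshold < 0:
            raise ValueError("allen_threshold must be non-negative")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be non-negative")
        if self.track not in ("allen", "targetseek"):
            raise ValueError(f"unknown track {self.track!r}")
        if self.promoter_window % self.motif_bin != 0:
            raise ValueError("promoter_window must be a multiple of motif_bin")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**data)
        config.validate()
        return config

    def simulation_config(self) -> simulate.SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        if "planted_log2fc_range" in sim:
            sim["planted_log2fc_range"] = tuple(sim["planted_log2fc_range"])
        return simulate.SimulationConfig(**sim)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


class Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.entries: dict[str, str] = {}

    def add(self, path: Path) -> Path:
        self.entries[str(path.relative_to(self.outdir))] = _sha256(path)
        return path

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as handle:
            json.dump(dict(sorted(self.entries.items())), handle, indent=2)
        return path


STAGES = ("simulate", "srna", "diffexp", "degradome", "quant", "motifs", "enrich")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path.name}: run the {stage!r} stage first"
        )
    return path


def run_pipeline(config: PipelineConfig, stages: Optional[list] = None) -> Path:
    """Run the requested stages in dependency order; returns the manifest path."""
    config.validate()
    stages = list(STAGES) if stages is None else stages
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir)
    sim_config = config.simulation_config()

    if "simulate" in stages:
        log.info("simulate: generating reference bundle and reads (seed=%d)", sim_config.seed)
        bundle, truth = simulate.generate_reference(sim_config)
        write_fasta(bundle.mature_mirnas, outdir / "mature.fasta")
        write_fasta(bundle.precursor_mirnas, outdir / "precursor.fasta")
        write_transcript_models(
            bundle.transcripts.values(), outdir / "transcripts.fasta", outdir / "transcripts.tsv"
        )
        write_fasta(bundle.promoters, outdir / "promoters.fasta")
        with open(outdir / "go_annotation.tsv", "w") as handle:
            handle.write("term\tgene\n")
            for term in sorted(bundle.go_annotation):
                for gene in sorted(bundle.go_annotation[term]):
                    handle.write(f"{term}\t{gene}\n")
        fastqs, true_counts = simulate.simulate_srna_reads(bundle, truth, sim_config, outdir)
        write_count_table(true_counts, outdir / "srna_true_counts.tsv", "sequence")
        simulate.simulate_degradome_reads(bundle, truth, sim_config, outdir / "degradome.fastq")
        mrna = simulate.simulate_mrna_counts(bundle, truth, sim_config)
        write_count_table(mrna, outdir / "mrna_counts.tsv", "transcript")
        with open(outdir / "planted_truth.json", "w") as handle:
            json.dump(
                {
                    "de_srnas": truth.de_srnas,
                    "de_genes": truth.de_genes,
                    "target_pairs": [list(t) for t in truth.target_pairs],
                    "motif_positions": truth.motif_positions,
                },
                handle,
                indent=1,
            )
        sheet = pd.DataFrame(
            {
                "sample": sim_config.sample_names,
                "group": sim_config.group_labels,
                "organ": "shoot",
                # paths are relative to the output directory so reruns in
                # different locations produce byte-identical sheets
                "path": [fastqs[s].name for s in sim_config.sample_names],
            }
        )
        sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        for name in (
            "mature.fasta", "precursor.fasta", "transcripts.fasta", "transcripts.tsv",
            "promoters.fasta", "go_annotation.tsv", "srna_true_counts.tsv",
            "degradome.fastq", "mrna_counts.tsv", "planted_truth.json", "samples.tsv",
        ):
            manifest.add(outdir / name)
        for path in fastqs.values():
            manifest.add(path)

    from .io import read_count_table, read_fasta, read_sample_sheet

    if "srna" in stages:
        sheet = read_sample_sheet(_require(outdir / "samples.tsv", "simulate"))
        per_sample = {}
        stats = {}
        for row in sheet.itertuples(index=False):
            fastq_path = Path(row.path)
            if not fastq_path.is_absolute():
                fastq_path = outdir / fastq_path
            kept, st = annotation.preprocess_reads(
                read_fastq(fastq_path),
                adapter=sim_config.adapter,
                quality_limit=config.quality_limit,
                min_len=config.min_srna_len,
                max_len=config.max_srna_len,
            )
            per_sample[row.sample] = kept
            stats[row.sample] = dict(st)
            log.info("srna %s: %s", row.sample, dict(st))
        unique = annotation.collapse_and_count(per_sample)
        cpm = annotation.cpm_normalize(unique)
        mature = read_fasta(outdir / "mature.fasta")
        precursor = read_fasta(outdir / "precursor.fasta")
        transcripts = read_transcript_models(outdir / "transcripts.fasta", outdir / "transcripts.tsv")
        layered = annotation.annotate_layered(unique, mature, precursor, transcripts)
        report = unique.join(cpm, rsuffix="_cpm").join(layered.drop(columns=["id"]))
        report.to_csv(outdir / "srna_report.tsv", sep="\t", index_label="sequence")
        with open(outdir / "srna_preprocess_stats.json", "w") as handle:
            json.dump(stats, handle, indent=1)
        manifest.add(outdir / "srna_report.tsv")
        manifest.add(outdir / "srna_preprocess_stats.json")

    if "diffexp" in stages:
        report = pd.read_csv(
            _require(outdir / "srna_report.tsv", "srna"), sep="\t", index_col="sequence"
        )
        sheet = read_sample_sheet(outdir / "samples.tsv")
        design = diffexp.TwoGroupDesign(
            tuple(sheet["sample"]), tuple(sheet["group"]),
            treated=sim_config.groups[0], control=sim_config.groups[1],
        )
        counts = report[list(sheet["sample"])].astype(int)
        results = diffexp.run_two_group(counts, design)
        dems, dess = diffexp.select_dems_dess(results, report["layer"], alpha=config.alpha)
        results.join(report[["id", "layer"]]).to_csv(
            outdir / "differential_srnas.tsv", sep="\t", index_label="sequence"
        )
        dems.to_csv(outdir / "dems.tsv", sep="\t", index_label="sequence")
        dess.to_csv(outdir / "dess.tsv", sep="\t", index_label="sequence")
        des_annot = pd.read_csv(outdir / "srna_report.tsv", sep="\t", index_col="sequence")
        length_table, class_table = annotation.summarize_distributions(
            des_annot.loc[dess.index]
        )
        length_table.to_csv(outdir / "des_length_distribution.tsv", sep="\t")
        class_table.to_csv(outdir / "des_class_distribution.tsv", sep="\t")
        log.info("diffexp: %d DEMs, %d DESs at Bonferroni alpha=%.3g",
                 len(dems), len(dess), config.alpha)
        for name in ("differential_srnas.tsv", "dems.tsv", "dess.tsv",
                     "des_length_distribution.tsv", "des_class_distribution.tsv"):
            manifest.add(outdir / name)

    if "degradome" in stages:
        transcripts = read_transcript_models(outdir / "transcripts.fasta", outdir / "transcripts.tsv")
        profiles, stats = degradome.build_cleavage_profile(
            read_fastq(_require(outdir / "degradome.fastq", "simulate")),
            transcripts,
            min_tag_len=config.min_degradome_tag_len,
        )
        log.info("degradome: %s", stats)
        rows = []
        for tid, profile in sorted(profiles.items()):
            import numpy as np

            for pos in (np.nonzero(profile.raw_counts)[0] + 1):
                rows.append(
                    (tid, int(pos), profile.raw(pos),
                     float(profile.depth_normalized[pos - 1]),
                     float(profile.fraction_of_transcript_signal[pos - 1]))
                )
        pd.DataFrame(
            rows, columns=["transcript", "position", "raw", "depth_normalized", "fraction"]
        ).to_csv(outdir / "cleavage_profiles.tsv", sep="\t", index=False)
        dems = pd.read_csv(_require(outdir / "dems.tsv", "diffexp"), sep="\t", index_col="sequence")
        dess = pd.read_csv(outdir / "dess.tsv", sep="\t", index_col="sequence")
        report = pd.read_csv(outdir / "srna_report.tsv", sep="\t", index_col="sequence")
        guides = {}
        for seq in list(dems.index) + list(dess.index):
            if seq in report.index:
                guides[f"sRNA_{int(report.loc[seq, 'id'])}"] = seq
        predictions = degradome.predict_targets(
            guides, profiles, transcripts,
            track=config.track,
            allen_threshold=config.allen_threshold,
            ts_kwargs={"mfe_ratio_min": config.mfe_ratio_min},
            n_perm=config.n_permutations,
            seed=config.seed,
        )
        pred_rows = [
            (p.srna_id, p.transcript_id, p.cleavage_coordinate, p.category,
             p.score, p.p_value, p.track, p.duplex.n_mismatch, p.duplex.n_gu,
             p.duplex.n_bulge_nt, round(p.duplex.mfe, 2), round(p.duplex.mfe_ratio, 3))
            for p in predictions
        ]
        pd.DataFrame(
            pred_rows,
            columns=["srna", "transcript", "cleavage_coordinate", "category", "score",
                     "p_value", "track", "n_mismatch", "n_gu", "n_bulge_nt", "mfe", "mfe_ratio"],
        ).to_csv(outdir / "target_predictions.tsv", sep="\t", index=False)
        if predictions:
            best = predictions[0]
            degradome.export_tplot(
                profiles[best.transcript_id], best,
                outdir / "tplot_best.tsv", outdir / "tplot_best.png",
            )
            manifest.add(outdir / "tplot_best.tsv")
        manifest.add(outdir / "cleavage_profiles.tsv")
        manifest.add(outdir / "target_predictions.tsv")

    if "quant" in stages:
        counts = read_count_table(_require(outdir / "mrna_counts.tsv", "simulate"))
        transcripts = read_transcript_models(outdir / "transcripts.fasta", outdir / "transcripts.tsv")
        lengths = pd.Series({t: m.exon_length for t, m in transcripts.items()})
        rpkm, tpm = quant.compute_rpkm_tpm(counts, lengths)
        write_count_table(rpkm.round(4), outdir / "rpkm.tsv", "transcript")
        write_count_table(tpm.round(4), outdir / "tpm.tsv", "transcript")
        sheet = read_sample_sheet(outdir / "samples.tsv")
        design = diffexp.TwoGroupDesign(
            tuple(sheet["sample"]), tuple(sheet["group"]),
            treated=sim_config.groups[0], control=sim_config.groups[1],
        )
        degs = quant.test_deg(counts, design, transcripts=transcripts, alpha=config.alpha)
        degs.to_csv(outdir / "degs.tsv", sep="\t", index_label="gene")
        quant.chromosome_distribution(degs, transcripts).to_csv(
            outdir / "chromosome_distribution.tsv", sep="\t"
        )
        log.info("quant: %d DEGs at Bonferroni alpha=%.3g", len(degs), config.alpha)
        for name in ("rpkm.tsv", "tpm.tsv", "degs.tsv", "chromosome_distribution.tsv"):
            manifest.add(outdir / name)

    if "motifs" in stages:
        promoters = read_fasta(_require(outdir / "promoters.fasta", "simulate"))
        degs = pd.read_csv(_require(outdir / "degs.tsv", "quant"), sep="\t", index_col="gene")
        deg_promoters = {g: promoters[g] for g in degs.index if g in promoters}
        specs = [m for m in motifs.DEFAULT_MOTIFS if m.name in config.motif_names]
        hits = motifs.scan_promoters(deg_promoters, specs)
        pd.DataFrame(
            [(h.gene, h.motif, h.strand, h.start, h.matched) for h in hits],
            columns=["gene", "motif", "strand", "start", "matched"],
        ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
        bins = motifs.bin_motif_positions(
            hits, gene_log2fc=degs["log2fc"].to_dict(),
            bin_size=config.motif_bin, window=config.promoter_window,
        )
        bins.to_csv(outdir / "motif_bins.tsv", sep="\t")
        gene_counts = motifs.count_genes_with_motifs(hits, deg_promoters)
        with open(outdir / "motif_gene_counts.json", "w") as handle:
            json.dump(gene_counts, handle, indent=1)
        log.info("motifs: gene counts %s", gene_counts)
        for name in ("motif_hits.tsv", "motif_bins.tsv", "motif_gene_counts.json"):
            manifest.add(outdir / name)

    if "enrich" in stages:
        degs = pd.read_csv(_require(outdir / "degs.tsv", "quant"), sep="\t", index_col="gene")
        go = pd.read_csv(_require(outdir / "go_annotation.tsv", "simulate"), sep="\t")
        annotation_map: dict[str, set] = {}
        for row in go.itertuples(index=False):
            annotation_map.setdefault(row.term, set()).add(row.gene)
        transcripts = read_transcript_models(outdir / "transcripts.fasta", outdir / "transcripts.tsv")
        background = [t for t, m in transcripts.items() if m.cdna_class == "protein-coding"]
        input_genes = [g for g in degs.index if g in set(background)]
        enrichment = motifs.go_overrepresentation(
            input_genes, annotation_map, background, alpha=config.alpha
        )
        enrichment.to_csv(outdir / "go_enrichment.tsv", sep="\t")
        manifest.add(outdir / "go_enrichment.tsv")

    path = manifest.write()
    log.info("manifest: %d files -> %s", len(manifest.entries), path)
    return path
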