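"""Synthetic reference bundles and sequencing datasets with planted truth.

The generator emulates the statistical structure of a phosphate-starvation
study design: two conditions (low-Pi vs. control) with three biological
replicates, negative-binomial counts with planted log2 fold changes, small
RNAs of 18-25 nt (miRBase-exact sequences, isomiR end-shift variants,
cDNA-derived fragments, and unannotatable sequences), degradome (PARE) tags
whose 5' ends pile up at the transcript position paired to small-RNA
nucleotide 10 of a planted target, and 2-kb promoters carrying planted
P1BS (GNATATNC) and PHO-element (ATGCCAT) instances.

Everything is deterministic under a fixed seed: the same SimulationConfig
reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    CDNA_CLASSES,
    FastqRead,
    TranscriptModel,
    reverse_complement,
    write_fastq,
)

# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

DNA = np.array(list("ACGT"))

DEFAULT_MOTIFS = {"P1BS": "GNATATNC", "PHO": "ATGCCAT"}

_IUPAC_CHOICES = {"N": "ACGT", "A": "A", "C": "C", "G": "G", "T": "T"}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA[rng.integers(0, 4, size=length)])


@dataclass
class SimulationConfig:
    """Parameters of one simulated study.

    Count parameters follow an NB(mean, dispersion) parameterization with
    variance ``mean + dispersion * mean**2``; ``nb_dispersion`` is the
    squared biological coefficient of variation (0.1 is a typical value for
    replicated bulk libraries; the default is a free parameter, not a
    measured one).  ``planted_log2fc_range`` bounds the absolute planted
    log2 fold change; the sign is drawn at random per feature.
    """

    seed: int = 0
    n_mirnas: int = 30
    n_transcripts_per_class: dict = field(
        default_factory=lambda: {
            "non-translating": 10,
            "protein-coding": 40,
            "pseudogene": 4,
            "rRNA": 8,
            "snoRNA": 4,
            "snRNA": 4,
            "SRP-RNA": 3,
            "tRNA": 6,
        }
    )
    n_replicates_per_group: int = 3
    mean_library_size: int = 50_000
    nb_dispersion: float = 0.1
    planted_dem_fraction: float = 0.2
    planted_des_fraction: float = 0.05
    planted_deg_fraction: float = 0.15
    planted_log2fc_range: tuple = (3.0, 4.0)
    n_planted_targets: int = 10
    degradome_signal_to_noise: float = 50.0
    degradome_background_per_position: float = 0.2
    promoter_length: int = 2000
    planted_motif_counts: dict = field(default_factory=lambda: {"P1BS": 1, "PHO": 1})
    adapter: str = DEFAULT_ADAPTER
    low_quality_tail: bool = False
    groups: tuple = ("low-Pi", "control")

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name, n in self.n_transcripts_per_class.items():
            if name not in CDNA_CLASSES:
                raise ValueError(f"unknown cDNA class {name!r}")
            if n <= 0:
                raise ValueError(f"zero transcripts requested in class {name!r}")
        for name in CDNA_CLASSES:
            if name not in self.n_transcripts_per_class:
                raise ValueError(f"missing cDNA class {name!r} in n_transcripts_per_class")
        for frac in (
            self.planted_dem_fraction,
            self.planted_des_fraction,
            self.planted_deg_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("planted fractions must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.n_replicates_per_group < 1:
            raise ValueError("need at least one replicate per group")
        if self.degradome_signal_to_noise < 0:
            raise ValueError("degradome_signal_to_noise must be non-negative")
        lo, hi = self.planted_log2fc_range
        if not (0 < lo <= hi):
            raise ValueError("planted_log2fc_range must satisfy 0 < low <= high")
        for motif, count in self.planted_motif_counts.items():
            consensus = DEFAULT_MOTIFS.get(motif, motif)
            if len(consensus) > self.promoter_length:
                raise ValueError(f"motif {motif!r} longer than promoter")
            if count < 0:
                raise ValueError("planted motif counts must be non-negative")

    @property
    def sample_names(self) -> list[str]:
        out = []
        for group in self.groups:
            tag = group.replace("-", "")
            out += [f"{tag}_{i + 1}" for i in range(self.n_replicates_per_group)]
        return out

    @property
    def group_labels(self) -> list[str]:
        return [g for g in self.groups for _ in range(self.n_replicates_per_group)]


@dataclass
class ReferenceBundle:
    mature_mirnas: dict[str, str]
    precursor_mirnas: dict[str, str]
    transcripts: dict[str, TranscriptModel]
    promoters: dict[str, str]
    go_annotation: dict[str, set]
    # sRNA population: sequence -> (baseline control mean count, origin label)
    srna_population: dict[str, tuple]
    mature_positions: dict[str, tuple]  # mature id -> (start, end) 1-based in precursor


@dataclass
class PlantedTruth:
    de_srnas: dict[str, float]          # sequence -> true log2fc (low-Pi vs control)
    de_genes: dict[str, float]          # transcript id -> true log2fc
    target_pairs: list[tuple]           # (srna id, transcript id, cleavage coord, srna seq)
    motif_positions: dict[str, list]    # gene -> [(motif name, strand, TSS-relative start)]


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def _instantiate_consensus(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        bases[rng.integers(0, len(bases))] if len(bases := _IUPAC_CHOICES.get(c, c)) > 1 else bases
        for c in consensus
    )


def generate_reference(config: SimulationConfig) -> tuple[ReferenceBundle, PlantedTruth]:
    """Build a self-consistent reference bundle plus the planted truth.

    Planted target sites are exact reverse complements of the guide small
    RNA, so every planted pair has full contiguous complementarity spanning
    small-RNA positions 9-11; the recorded cleavage coordinate is the
    transcript position paired to small-RNA nucleotide 10.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- miRNAs: 21-nt matures embedded in stem-loop-sized precursors
    matures: dict[str, str] = {}
    precursors: dict[str, str] = {}
    mature_positions: dict[str, tuple] = {}
    for i in range(config.n_mirnas):
        mid = f"sim-miR{i + 1:03d}"
        mature = _random_seq(rng, 21)
        left = _random_seq(rng, int(rng.integers(15, 31)))
        right = _random_seq(rng, int(rng.integers(15, 31)))
        matures[mid] = mature
        precursors[f"{mid}-pre"] = left + mature + right
        mature_positions[mid] = (len(left) + 1, len(left) + 21)

    # --- transcripts per cDNA class
    transcripts: dict[str, TranscriptModel] = {}
    for cls in CDNA_CLASSES:
        n = config.n_transcripts_per_class[cls]
        for k in range(n):
            if cls == "protein-coding":
                length = int(rng.integers(600, 1501))
            elif cls == "rRNA":
                length = int(rng.integers(300, 1001))
            else:
                length = int(rng.integers(120, 501))
            tid = f"SIM_{cls.replace('-', '_')}_{k + 1:03d}"
            chrom = f"{rng.integers(1, 8)}H"
            seq = _random_seq(rng, length)
            transcripts[tid] = TranscriptModel(tid, cls, chrom, length, seq)

    # --- planted differential expression among miRNAs and other sRNAs
    lo, hi = config.planted_log2fc_range

    def draw_lfc() -> float:
        sign = 1.0 if rng.random() < 0.8 else -1.0  # Pi starvation mostly induces
        return float(sign * rng.uniform(lo, hi))

    mature_ids = list(matures)
    n_dem = max(1, round(config.planted_dem_fraction * config.n_mirnas))
    dem_ids = list(rng.choice(mature_ids, size=n_dem, replace=False))

    # --- planted cleavage targets: up-regulated DEM guides vs protein-coding mRNAs
    coding_ids = [t for t, m in transcripts.items() if m.cdna_class == "protein-coding"]
    if config.n_planted_targets > len(coding_ids):
        raise ValueError("more planted targets than protein-coding transcripts")
    guide_ids = [dem_ids[i % len(dem_ids)] for i in range(config.n_planted_targets)]
    target_ids = list(rng.choice(coding_ids, size=config.n_planted_targets, replace=False))
    target_pairs = []
    for gid, tid in zip(guide_ids, target_ids):
        model = transcripts[tid]
        guide = matures[gid]
        L = len(guide)
        site = reverse_complement(guide)
        start = int(rng.integers(30, model.exon_length - L - 30))  # 0-based
        seq = model.sequence[:start] + site + model.sequence[start + L:]
        transcripts[tid] = TranscriptModel(
            tid, model.cdna_class, model.chromosome, model.exon_length, seq
        )
        # site occupies 1-based [start+1, start+L]; sRNA nt k pairs position start+L+1-k
        coord = start + L + 1 - 10
        target_pairs.append((gid, tid, coord, guide))

    # --- sRNA population with baseline control-condition mean counts
    population: dict[str, tuple] = {}

    def add(seq: str, mean: float, origin: str) -> None:
        if 18 <= len(seq) <= 25 and seq not in population:
            population[seq] = (mean, origin)

    for mid, mature in matures.items():
        base = float(rng.uniform(60, 400)) if mid in dem_ids else float(rng.uniform(20, 200))
        add(mature, base, f"mature:{mid}")
        # isomiRs: templated end shifts of +/- 1-2 nt within the precursor
        pre = precursors[f"{mid}-pre"]
        ms, me = mature_positions[mid]
        for d5, d3 in ((1, 0), (-1, 0), (0, 1), (0, -1), (-1, 1), (1, -2)):
            if rng.random() < 0.5:
                continue
            s, e = ms - d5, me + d3
            iso = pre[s - 1: e]
            add(iso, float(rng.uniform(10, 80)), f"isomir:{mid}")
    for tid, model in transcripts.items():
        n_frag = 2 if model.cdna_class in ("rRNA", "protein-coding", "non-translating") else 1
        for _ in range(n_frag):
            L = int(rng.integers(18, 26))
            pos = int(rng.integers(0, model.exon_length - L + 1))
            frag = model.sequence[pos: pos + L]
            if rng.random() < 0.4:
                frag = reverse_complement(frag)
            add(frag, float(rng.uniform(5, 120)), f"cdna:{tid}")
    for j in range(40):
        add(_random_seq(rng, int(rng.integers(18, 26))), float(rng.uniform(5, 80)), "random")

    # --- DE truth for sRNAs: all DEM matures plus a fraction of other sRNAs
    de_srnas: dict[str, float] = {}
    for mid in dem_ids:
        de_srnas[matures[mid]] = draw_lfc()
    for gid, _, _, guide in target_pairs:
        # cleavage guides must be induced for the biology to make sense
        de_srnas[guide] = abs(de_srnas.get(guide, draw_lfc()))
    other = [s for s, (_, origin) in population.items() if not origin.startswith("mature:")]
    n_des = round(config.planted_des_fraction * len(other))
    for seq in rng.choice(other, size=n_des, replace=False):
        de_srnas[str(seq)] = draw_lfc()

    # --- DEGs among protein-coding transcripts
    de_genes: dict[str, float] = {}
    n_deg = max(1, round(config.planted_deg_fraction * len(coding_ids)))
    for tid in rng.choice(coding_ids, size=n_deg, replace=False):
        de_genes[str(tid)] = draw_lfc()

    # --- promoters for protein-coding genes, with planted motifs
    promoters: dict[str, str] = {}
    motif_positions: dict[str, list] = {}
    W = config.promoter_length
    for tid in coding_ids:
        promoter = list(_random_seq(rng, W))
        placed: list[tuple] = []
        occupied: set[int] = set()
        for motif, count in config.planted_motif_counts.items():
            consensus = DEFAULT_MOTIFS.get(motif, motif)
            m = len(consensus)
            for _ in range(count):
                for _attempt in range(200):
                    start = int(rng.integers(0, W - m + 1))
                    if not occupied.intersection(range(start, start + m)):
                        break
                else:  # pragma: no cover - dense planting only
                    raise RuntimeError("could not place motif without overlap")
                occupied.update(range(start, start + m))
                instance = _instantiate_consensus(rng, consensus)
                strand = "+" if rng.random() < 0.5 else "-"
                embedded = instance if strand == "+" else reverse_complement(instance)
                promoter[start: start + m] = list(embedded)
                placed.append((motif, strand, start - W))
        promoters[tid] = "".join(promoter)
        motif_positions[tid] = sorted(placed, key=lambda h: h[2])

    # --- GO annotation: random term memberships over protein-coding genes
    go_annotation: dict[str, set] = {}
    for t in range(20):
        term = f"GO:SIM{t + 1:04d}"
        size = int(rng.integers(3, max(4, len(coding_ids) // 2)))
        go_annotation[term] = set(rng.choice(coding_ids, size=size, replace=False))

    bundle = ReferenceBundle(
        mature_mirnas=matures,
        precursor_mirnas=precursors,
        transcripts=transcripts,
        promoters=promoters,
        go_annotation=go_annotation,
        srna_population=population,
        mature_positions=mature_positions,
    )
    truth = PlantedTruth(
        de_srnas=de_srnas,
        de_genes=de_genes,
        target_pairs=target_pairs,
        motif_positions=motif_positions,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Count and read simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with variance mean + dispersion*mean^2; Poisson at 0."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 1e-12:
        out[pos] = rng.poisson(mean[pos])
    else:
        r = 1.0 / dispersion
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    baseline_means: pd.Series,
    log2fc: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """NB count table (features x samples); treated-group means offset by log2fc."""
    features = baseline_means.index
    fold = np.array([2.0 ** log2fc.get(f, 0.0) for f in features])
    treated_means = baseline_means.to_numpy() * fold
    columns = {}
    for sample, group in zip(config.sample_names, config.group_labels):
        means = treated_means if group == config.groups[0] else baseline_means.to_numpy()
        columns[sample] = _nb_draw(rng, means, config.nb_dispersion)
    return pd.DataFrame(columns, index=features)


def simulate_srna_counts(
    ref: ReferenceBundle, truth: PlantedTruth, config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """True per-sample counts of every unique small RNA in the population."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    base = pd.Series({seq: mean for seq, (mean, _) in ref.srna_population.items()})
    base = base * (config.mean_library_size / base.sum())
    return simulate_counts(base, truth.de_srnas, config, rng)


def srna_counts_to_fastq(
    counts: pd.DataFrame, config: SimulationConfig, outdir
) -> dict[str, Path]:
    """Write one FASTQ per sample: read = sRNA + 3' adapter, constant high quality."""
    if not config.adapter:
        raise ValueError("adapter must be non-empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in counts.columns:
        if counts[sample].sum() == 0:
            raise ValueError(f"library size 0 for sample {sample!r}")
        path = outdir / f"srna_{sample}.fastq"

        def reads(sample=sample):
            for i, (seq, n) in enumerate(counts[sample].items()):
                full = seq + config.adapter
                qual = "I" * len(seq) + ("#" if config.low_quality_tail else "I") * len(config.adapter)
                for copy in range(int(n)):
                    yield FastqRead(f"{sample}:s{i}:c{copy}", full, qual)

        write_fastq(reads(), path)
        paths[sample] = path
    return paths


def simulate_srna_reads(
    ref: ReferenceBundle, truth: PlantedTruth, config: SimulationConfig, outdir
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Simulate small-RNA FASTQ files plus the true count table."""
    counts = simulate_srna_counts(ref, truth, config)
    paths = srna_counts_to_fastq(counts, config, outdir)
    return paths, counts


def simulate_degradome_reads(
    ref: ReferenceBundle,
    truth: PlantedTruth,
    config: SimulationConfig,
    out_path,
    tag_length: int = 20,
) -> Path:
    """Simulate degradome (PARE) 5'-end tags.

    Background tags start uniformly along each transcript at a mean density
    of ``degradome_background_per_position``; each planted target adds tags
    whose 5' end is exactly the planted cleavage coordinate, with mean
    abundance ``signal_to_noise`` times the per-position background mean.
    Every tag is an exact sense-strand substring of its source transcript.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    out_path = Path(out_path)
    reads: list[FastqRead] = []
    density = config.degradome_background_per_position
    for tid, model in sorted(ref.transcripts.items()):
        n_positions = model.exon_length - tag_length + 1
        if n_positions < 1:
            continue
        n_bg = rng.poisson(density * n_positions)
        starts = rng.integers(1, n_positions + 1, size=n_bg)  # 1-based 5' ends
        for j, s in enumerate(sorted(starts.tolist())):
            tag = model.sequence[s - 1: s - 1 + tag_length]
            reads.append(FastqRead(f"bg:{tid}:{j}", tag, "I" * len(tag)))
    for k, (sid, tid, coord, _guide) in enumerate(truth.target_pairs):
        model = ref.transcripts[tid]
        n_sig = rng.poisson(config.degradome_signal_to_noise * density)
        length = min(tag_length, model.exon_length - coord + 1)
        tag = model.sequence[coord - 1: coord - 1 + length]
        for j in range(n_sig):
            reads.append(FastqRead(f"sig:{sid}:{tid}:{k}:{j}", tag, "I" * len(tag)))
    write_fastq(reads, out_path)
    return out_path


def simulate_mrna_counts(
    ref: ReferenceBundle, truth: PlantedTruth, config: SimulationConfig
) -> pd.DataFrame:
    """NB mRNA count table (all transcripts x samples) with planted DEGs."""
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    tids = sorted(ref.transcripts)
    base = pd.Series(
        np.exp(rng.normal(np.log(150.0), 0.8, size=len(tids))), index=tids
    )
    # planted DEGs get a comfortable baseline so the fold change is estimable
    for tid in truth.de_genes:
        base[tid] = float(rng.uniform(80, 400))
    return simulate_counts(base, truth.de_genes, config, rng)
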