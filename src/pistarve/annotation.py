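"""Small-RNA preprocessing, collapsing, normalization and layered annotation.

Raw reads are adapter- and quality-trimmed (modified-Mott running-sum rule
with an error-probability limit, 0.02 by default), restricted to 18-25 nt,
collapsed to unique sequences with per-sample raw counts and counts per
million, and annotated in layers:

1. ``mirbase_exact``    - exact sense-strand substring of a mature or
                          precursor miRNA reference,
2. ``cdna_class``       - exact substring (either strand) of a reference
                          transcript, labelled with its cDNA class,
3. ``mirbase_mismatch`` - sense-strand substring of a miRNA reference with
                          1-3 substitutions,
4. ``unannotated``      - everything else.

The layering is a partition: each unique sequence gets exactly one layer in
the combined report.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import FastqRead, reverse_complement

CLASS_PRIORITY = (
    "rRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "SRP-RNA",
    "non-translating",
    "protein-coding",
    "pseudogene",
)

LAYERS = ("mirbase_exact", "cdna_class", "mirbase_mismatch", "unannotated")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _phred_error_probs(quality: str) -> np.ndarray:
    q = np.frombuffer(quality.encode(), dtype=np.uint8).astype(float) - 33.0
    return 10.0 ** (-q / 10.0)


def mott_trim(sequence: str, quality: str, limit: float) -> str:
    """Keep the maximal-scoring segment under the running-sum rule.

    Each base contributes ``limit - P_error``; the retained segment is the
    contiguous stretch maximizing the sum (first such stretch on ties).
    """
    values = limit - _phred_error_probs(quality)
    best, best_start, best_end = 0.0, 0, 0
    running, start = 0.0, 0
    for i, v in enumerate(values):
        running += v
        if running <= 0:
            running, start = 0.0, i + 1
        elif running > best + 1e-15:
            best, best_start, best_end = running, start, i + 1
    return sequence[best_start:best_end]


def trim_adapter(sequence: str, adapter: str, min_overlap: int = 3) -> str:
    """Remove a 3' adapter: the longest read suffix matching an adapter
    prefix with at most one mismatch per 10 aligned bases."""
    n = len(sequence)
    for j in range(n - min_overlap + 1):
        k = min(n - j, len(adapter))
        allowed = k // 10
        mismatches = 0
        for a, b in zip(sequence[j: j + k], adapter[:k]):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return sequence[:j]
    return sequence


def preprocess_reads(
    reads: Iterable[FastqRead],
    adapter: str,
    quality_limit: float = 0.02,
    min_len: int = 18,
    max_len: int = 25,
    min_adapter_overlap: int = 3,
) -> tuple[list[str], Counter]:
    """Adapter- and quality-trim reads, then apply the length filter.

    Returns the retained insert sequences and a tally of discarded reads by
    reason (``too_short`` / ``too_long``).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 0 < quality_limit < 1:
        raise ValueError("quality_limit must be an error probability in (0, 1)")
    kept: list[str] = []
    stats: Counter = Counter()
    for read in reads:
        stats["input"] += 1
        trimmed = trim_adapter(read.sequence, adapter, min_adapter_overlap)
        trimmed = mott_trim(trimmed, read.quality[: len(trimmed)], quality_limit)
        if len(trimmed) < min_len:
            stats["too_short"] += 1
        elif len(trimmed) > max_len:
            stats["too_long"] += 1
        else:
            stats["retained"] += 1
            kept.append(trimmed)
    return kept, stats


# ---------------------------------------------------------------------------
# Collapse, count, normalize
# ---------------------------------------------------------------------------

def collapse_and_count(per_sample_sequences: dict[str, Iterable[str]]) -> pd.DataFrame:
    """One row per distinct sequence with exact per-sample raw counts.

    Rows are ordered by descending total count then lexicographically, and
    an ``id`` column assigns stable 1-based internal identifiers in that
    order.
    """
    if not per_sample_sequences:
        raise ValueError("need at least one sample")
    counters = {s: Counter(seqs) for s, seqs in per_sample_sequences.items()}
    universe = sorted(set().union(*[set(c) for c in counters.values()]))
    table = pd.DataFrame(
        {s: [counters[s].get(seq, 0) for seq in universe] for s in counters},
        index=pd.Index(universe, name="sequence"),
        dtype=np.int64,
    )
    total = table.sum(axis=1)
    order = sorted(table.index, key=lambda s: (-total[s], s))
    table = table.loc[order]
    table.insert(0, "id", np.arange(1, len(table) + 1))
    return table


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million over the retained sequences, per sample.

    A zero-total sample yields an all-zero column with a warning.
    """
    samples = [c for c in counts.columns if c != "id"]
    raw = counts[samples].astype(float)
    totals = raw.sum(axis=0)
    cpm = raw.copy()
    for s in samples:
        if totals[s] == 0:
            import warnings

            warnings.warn(f"zero-total sample {s!r}: CPM set to 0", stacklevel=2)
            cpm[s] = 0.0
        else:
            cpm[s] = raw[s] * 1e6 / totals[s]
    return cpm


# ---------------------------------------------------------------------------
# Annotation layers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationRecord:
    srna_id: int
    sequence: str
    layer: str
    reference_id: Optional[str]
    reference_type: Optional[str]  # mature / precursor / cdna class
    cdna_class: Optional[str]
    mismatches: int
    match_strand: str  # sense / antisense / none
    assigned_name: str


_BASE_CODES = {c: i for i, c in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_CODES.get(c, 4) for c in seq), dtype=np.uint8, count=len(seq))


def hamming_substring_hits(query: str, reference: str, max_mismatch: int) -> list[tuple]:
    """(start, mismatches) for every ungapped occurrence of ``query`` in
    ``reference`` with at most ``max_mismatch`` substitutions (1-based starts)."""
    m, n = len(query), len(reference)
    if m > n:
        return []
    q = _encode(query)
    r = _encode(reference)
    windows = np.lib.stride_tricks.sliding_window_view(r, m)
    mm = (windows != q).sum(axis=1)
    return [(int(i) + 1, int(mm[i])) for i in np.nonzero(mm <= max_mismatch)[0]]


def annotate_mirbase(
    unique: pd.DataFrame,
    mature: dict[str, str],
    precursor: dict[str, str],
    max_mismatch: int = 0,
) -> list[AnnotationRecord]:
    """Strand-specific (sense only), ungapped miRBase-style annotation.

    A sequence matches if it occurs as a substring of a mature or precursor
    reference with at most ``max_mismatch`` substitutions.  All matching
    references are reported; the assigned name follows the reference miRNA.
    """
    if not mature and not precursor:
        raise ValueError("references must be non-empty")
    if not 0 <= max_mismatch <= 3:
        raise ValueError("max_mismatch must be in 0..3")
    records: list[AnnotationRecord] = []
    refs = [(rid, seq, "mature") for rid, seq in mature.items()] + [
        (rid, seq, "precursor") for rid, seq in precursor.items()
    ]
    for seq, row in zip(unique.index, unique.itertuples()):
        for rid, rseq, rtype in refs:
            hits = hamming_substring_hits(seq, rseq, max_mismatch)
            if not hits:
                continue
            best_mm = min(mm for _, mm in hits)
            layer = "mirbase_exact" if best_mm == 0 else "mirbase_mismatch"
            records.append(
                AnnotationRecord(
                    srna_id=int(row.id),
                    sequence=seq,
                    layer=layer,
                    reference_id=rid,
                    reference_type=rtype,
                    cdna_class=None,
                    mismatches=best_mm,
                    match_strand="sense",
                    assigned_name=rid.removesuffix("-pre"),
                )
            )
    return records


@dataclass(frozen=True)
class IsomiRCall:
    reference_mature_id: str
    five_prime_offset: int   # + = extension (super), - = shortening (sub)
    three_prime_offset: int
    kind: str                # exact | isomiR


def classify_isomir(
    srna: str,
    mature_id: str,
    precursor_seq: str,
    mature_position: tuple[int, int],
) -> Optional[IsomiRCall]:
    """Classify an sRNA mapping within a precursor relative to its mature arm.

    ``mature_position`` is the 1-based closed span of the annotated mature
    sequence within the precursor.  Returns ``None`` when the sRNA is not a
    substring of the precursor.
    """
    start0 = precursor_seq.find(srna)
    if start0 < 0:
        return None
    ss, se = start0 + 1, start0 + len(srna)
    ms, me = mature_position
    five = ms - ss
    three = se - me
    kind = "exact" if five == 0 and three == 0 else "isomiR"
    return IsomiRCall(mature_id, five, three, kind)


def annotate_cdna_classes(
    unique: pd.DataFrame,
    transcripts: dict,
    mode: str = "combined",
    priority: Sequence[str] = CLASS_PRIORITY,
) -> pd.DataFrame:
    """Annotate sequences by exact substring match against class-labelled cDNAs.

    ``per-class`` mode reports every class with at least one match (strand
    recorded); ``combined`` mode assigns a single class by the fixed
    priority order.  Sequences with no match anywhere are ``unannotated``.
    """
    if mode not in ("combined", "per-class"):
        raise ValueError(f"unknown mode {mode!r}")
    by_class: dict[str, list] = {}
    for model in transcripts.values():
        by_class.setdefault(model.cdna_class, []).append(model)
    rows = []
    for seq, row in zip(unique.index, unique.itertuples()):
        rc = reverse_complement(seq)
        hits: dict[str, str] = {}
        for cls, models in by_class.items():
            for model in models:
                if seq in model.sequence:
                    hits[cls] = "sense"
                    break
                if rc in model.sequence and cls not in hits:
                    hits[cls] = "antisense"
        if mode == "per-class":
            for cls in sorted(hits):
                rows.append((int(row.id), seq, cls, hits[cls]))
        else:
            assigned = next((cls for cls in priority if cls in hits), None)
            rows.append(
                (int(row.id), seq, assigned, hits.get(assigned, "none"))
                if assigned
                else (int(row.id), seq, None, "none")
            )
    return pd.DataFrame(rows, columns=["id", "sequence", "cdna_class", "strand"])


def annotate_layered(
    unique: pd.DataFrame,
    mature: dict[str, str],
    precursor: dict[str, str],
    transcripts: dict,
    max_mirbase_mismatch: int = 3,
    priority: Sequence[str] = CLASS_PRIORITY,
) -> pd.DataFrame:
    """Partition unique sequences into the four annotation layers.

    mirbase_exact beats cdna_class beats mirbase_mismatch beats unannotated.
    Returns one row per sequence with layer, assigned name/class, mismatch
    count and strand.
    """
    exact = {
        r.sequence: r for r in annotate_mirbase(unique, mature, precursor, max_mismatch=0)
    }
    relaxed: dict[str, AnnotationRecord] = {}
    if max_mirbase_mismatch > 0:
        for r in annotate_mirbase(unique, mature, precursor, max_mismatch=max_mirbase_mismatch):
            prev = relaxed.get(r.sequence)
            if prev is None or r.mismatches < prev.mismatches:
                relaxed[r.sequence] = r
    cdna = annotate_cdna_classes(unique, transcripts, mode="combined", priority=priority)
    cdna_map = dict(zip(cdna["sequence"], zip(cdna["cdna_class"], cdna["strand"])))
    rows = []
    for seq, row in zip(unique.index, unique.itertuples()):
        if seq in exact:
            r = exact[seq]
            rows.append((int(row.id), seq, "mirbase_exact", r.assigned_name, None, 0, "sense"))
            continue
        cls, strand = cdna_map.get(seq, (None, "none"))
        if cls is not None:
            rows.append((int(row.id), seq, "cdna_class", None, cls, 0, strand))
            continue
        if seq in relaxed and relaxed[seq].mismatches >= 1:
            r = relaxed[seq]
            rows.append(
                (int(row.id), seq, "mirbase_mismatch", r.assigned_name, None, r.mismatches, "sense")
            )
            continue
        rows.append((int(row.id), seq, "unannotated", None, None, 0, "none"))
    return pd.DataFrame(
        rows,
        columns=["id", "sequence", "layer", "assigned_name", "cdna_class", "mismatches", "strand"],
    ).set_index("sequence")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_distributions(des_annotation: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Length-percentage (18-25 nt) and class-percentage tables for a DES set.

    Percentages are 100 * n / n_total rounded to two decimals; class
    percentages are computed over combined-mode annotated sequences only.
    """
    if des_annotation.empty:
        return pd.DataFrame(columns=["n", "percent"]), pd.DataFrame(columns=["n", "percent"])
    lengths = des_annotation.index.str.len()
    length_counts = pd.Series(lengths).value_counts().sort_index()
    length_table = pd.DataFrame(
        {
            "n": length_counts,
            "percent": (100.0 * length_counts / length_counts.sum()).round(2),
        }
    )
    length_table.index.name = "length"
    annotated = des_annotation[des_annotation["cdna_class"].notna()]
    if annotated.empty:
        class_table = pd.DataFrame(columns=["n", "percent"])
    else:
        class_counts = annotated["cdna_class"].value_counts()
        class_table = pd.DataFrame(
            {
                "n": class_counts,
                "percent": (100.0 * class_counts / class_counts.sum()).round(2),
            }
        )
        class_table.index.name = "cdna_class"
    return length_table, class_table
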