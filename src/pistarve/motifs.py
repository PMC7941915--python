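"""Promoter motif scanning and GO over-representation.

Phosphate-responsive promoters carry two characteristic cis-regulatory
elements: the P1BS (PHR1-binding sequence, IUPAC consensus GNATATNC) and
the PHO element (ATGCCAT).  Promoter sequences are the 2000 bp upstream of
the transcription start site; hit coordinates are reported TSS-relative in
[-2000, -1] (the base immediately upstream of the TSS is -1).

GO over-representation uses an upper-tail binomial test with success
probability term_size / background_size, Bonferroni-adjusted over tested
terms, and the fold-enrichment ratio
(annotated_in_input / term_size) / (input_size / background_size).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifSpec:
    name: str
    consensus: str
    scan_both_strands: bool = True

    def __post_init__(self):
        bad = [c for c in self.consensus.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"non-IUPAC character(s) {bad} in consensus {self.consensus!r}")


P1BS = MotifSpec("P1BS", "GNATATNC")
PHO_ELEMENT = MotifSpec("PHO", "ATGCCAT")
DEFAULT_MOTIFS = (P1BS, PHO_ELEMENT)


@dataclass(frozen=True)
class MotifHit:
    gene: str
    motif: str
    strand: str            # + / -
    start: int             # TSS-relative start of the plus-strand footprint
    matched: str           # plus-strand footprint sequence


def _consensus_regex(consensus: str) -> re.Pattern:
    # ambiguous reference bases (N in the sequence) never match: character
    # classes contain concrete bases only
    body = "".join(
        IUPAC[c] if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in consensus.upper()
    )
    return re.compile(f"(?=({body}))")  # lookahead: overlapping occurrences included


def scan_iupac_motif(sequence: str, spec: MotifSpec, gene: str = "") -> list[MotifHit]:
    """All occurrences of an IUPAC consensus in an upstream sequence.

    Overlapping occurrences are included.  Minus-strand hits are found by
    scanning the reverse complement and reported at the TSS-relative
    coordinate of their plus-strand footprint.
    """
    sequence = sequence.upper()
    window = len(sequence)
    m = len(spec.consensus)
    pattern = _consensus_regex(spec.consensus)
    hits: list[MotifHit] = []
    for match in pattern.finditer(sequence):
        i = match.start()
        hits.append(MotifHit(gene, spec.name, "+", i - window, sequence[i: i + m]))
    if spec.scan_both_strands:
        plus_starts = {h.start for h in hits}
        rc = reverse_complement(sequence)
        for match in pattern.finditer(rc):
            j = match.start()
            i = window - j - m  # plus-strand footprint start
            # a palindromic consensus matches both strands at the same
            # footprint; report that footprint once (plus strand)
            if i - window not in plus_starts:
                hits.append(MotifHit(gene, spec.name, "-", i - window, sequence[i: i + m]))
    return sorted(hits, key=lambda h: (h.start, h.strand))


def scan_promoters(
    promoters: dict[str, str], specs: Sequence[MotifSpec] = DEFAULT_MOTIFS
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for gene in sorted(promoters):
        for spec in specs:
            hits.extend(scan_iupac_motif(promoters[gene], spec, gene=gene))
    return hits


def bin_motif_positions(
    hits: Iterable[MotifHit],
    gene_log2fc: Optional[dict] = None,
    bin_size: int = 500,
    window: int = 2000,
) -> pd.DataFrame:
    """Count hits in TSS-proximal bins, split by motif and regulation sign.

    Bin 1 = [-bin_size, -1], bin 2 = [-2*bin_size, -bin_size-1], ...; a
    hit's bin is determined by its start coordinate.  When ``gene_log2fc``
    is given, hits are split into induced (log2fc > 0) and repressed rows.
    """
    n_bins = window // bin_size
    rows: dict[tuple, np.ndarray] = {}
    for hit in hits:
        if not -window <= hit.start <= -1:
            raise ValueError(f"hit start {hit.start} outside [-{window}, -1]")
        b = (-hit.start - 1) // bin_size  # 0-based bin index
        regulation = "all"
        if gene_log2fc is not None:
            lfc = gene_log2fc.get(hit.gene, 0.0)
            regulation = "induced" if lfc > 0 else "repressed"
        key = (hit.motif, regulation)
        rows.setdefault(key, np.zeros(n_bins, dtype=int))[b] += 1
    table = pd.DataFrame(
        {f"bin_{i + 1} [{-(i + 1) * bin_size}..{-i * bin_size - 1}]":
             {k: v[i] for k, v in rows.items()} for i in range(n_bins)}
    )
    table.index = pd.MultiIndex.from_tuples(table.index, names=["motif", "regulation"])
    return table.fillna(0).astype(int)


def count_genes_with_motifs(
    hits: Iterable[MotifHit], gene_universe: Optional[Iterable[str]] = None
) -> dict[str, int]:
    """Per-motif gene counts plus the any-motif union (genes count once per
    motif regardless of hit multiplicity)."""
    per_motif: dict[str, set] = {}
    union: set = set()
    for hit in hits:
        per_motif.setdefault(hit.motif, set()).add(hit.gene)
        union.add(hit.gene)
    if gene_universe is not None:
        universe = set(gene_universe)
        per_motif = {m: g & universe for m, g in per_motif.items()}
        union &= universe
    out = {motif: len(genes) for motif, genes in sorted(per_motif.items())}
    out["any"] = len(union)
    return out


# ---------------------------------------------------------------------------
# GO over-representation
# ---------------------------------------------------------------------------

def go_overrepresentation(
    input_genes: Iterable[str],
    annotation: dict[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Binomial over-representation of GO terms in an input gene set.

    For each term, k = genes of the input annotated to the term, n = input
    size, success probability = term_size / background_size; p is the
    upper-tail binomial probability P(X >= k).  Fold enrichment is
    (k / term_size) / (n / background_size).  Terms of size zero are
    skipped with a warning; Bonferroni correction runs over tested terms.
    """
    background = set(background)
    input_set = set(input_genes)
    if not input_set <= background:
        raise ValueError("input genes must be a subset of the background")
    n = len(input_set)
    N = len(background)
    rows = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & background
        size = len(term_genes)
        if size == 0:
            warnings.warn(f"term {term!r} has size 0; skipped", stacklevel=2)
            continue
        k = len(term_genes & input_set)
        prob = size / N
        p = float(stats.binom.sf(k - 1, n, prob)) if k > 0 else 1.0
        fold = (k / size) / (n / N) if n else float("nan")
        rows.append((term, size, k, n, N, fold, min(p, 1.0)))
    table = pd.DataFrame(
        rows,
        columns=[
            "term", "term_size", "annotated_in_input", "input_size",
            "background_size", "fold_enrichment", "p_binomial",
        ],
    ).set_index("term")
    table["p_bonferroni"] = adjusted = np.minimum(table["p_binomial"] * len(table), 1.0)
    table["significant"] = adjusted < alpha
    return table
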