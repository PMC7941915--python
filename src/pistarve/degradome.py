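"""Degradome (PARE) cleavage profiles and small-RNA target prediction.

Degradome tags mark the 5' ends of uncapped cleavage fragments.  Guided
slicing occurs between the target nucleotides paired to small-RNA positions
10 and 11 (counted from the sRNA 5' end), so the 5' end of the 3' cleavage
fragment sits at the position paired to nucleotide 10 — the predicted
cleavage coordinate throughout this module.

Two scoring tracks are provided:

* ``allen`` — the classic plant-target alignment penalty (mismatch 1,
  gap/bulged nucleotide 1, G:U wobble 0.5, doubled within sRNA positions
  2-13), optionally relaxed so that a single mismatch or G:U exactly at
  position 10 is not doubled.
* ``targetseek`` — a minimum-free-energy track: duplexes are filtered by
  the ratio of duplex MFE to the perfect-complement MFE, bulge and
  overhang limits, then scored by a configurable penalty schema for
  mismatches, G:U pairs, bulges and loops.

The MFE uses a simplified built-in nearest-neighbour RNA/RNA stacking table
(documented below); absolute energies are therefore package-specific and
only ratios and orderings are meaningful.

Degradome positions are ranked into five peak categories: 0 = unique
transcript maximum (> 1 read), 1 = shared maximum, 2 = above the mean of
positions with signal, 3 = at or below that mean, 4 = single read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import FastqRead, reverse_complement

# ---------------------------------------------------------------------------
# Base-pair bookkeeping (DNA letters; T stands for U)
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def pair_state(srna_base: str, target_base: str) -> str:
    """'match' (Watson-Crick), 'gu' (G:U wobble) or 'mismatch'."""
    if _COMPLEMENT.get(srna_base) == target_base:
        return "match"
    if (srna_base, target_base) in (("G", "T"), ("T", "G")):
        return "gu"
    return "mismatch"


# Simplified nearest-neighbour RNA/RNA stacking free energies (kcal/mol).
# Pair strengths reflect hydrogen bonding (G:C > A:U > G:U); stacking two
# pairs contributes the mean of their strengths plus a constant stacking
# bonus.  Duplex initiation is taken as zero.
_PAIR_STRENGTH = {"GC": 2.4, "CG": 2.4, "AT": 1.1, "TA": 1.1, "GT": 0.5, "TG": 0.5}
_STACK_BONUS = 0.8
BULGE_OPEN = 3.0
BULGE_PER_NT = 0.5
LOOP_OPEN = 1.5
LOOP_PER_NT = 0.5


def stack_energy(pair1: str, pair2: str) -> float:
    """Free energy of stacking two adjacent base pairs (each 'XY' =
    sRNA base + target base)."""
    return -(_PAIR_STRENGTH[pair1] + _PAIR_STRENGTH[pair2]) / 2.0 - _STACK_BONUS


# ---------------------------------------------------------------------------
# Cleavage profiles
# ---------------------------------------------------------------------------

@dataclass
class CleavageProfile:
    """Per-transcript degradome 5'-end counts (1-based positions)."""

    transcript_id: str
    length: int
    raw_counts: np.ndarray            # shape (length,), raw_counts[p-1]
    depth_normalized: np.ndarray      # per 1e7 total mapped tags
    fraction_of_transcript_signal: np.ndarray

    def raw(self, position: int) -> int:
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside transcript bounds")
        return int(self.raw_counts[position - 1])

    @property
    def total(self) -> int:
        return int(self.raw_counts.sum())

    def argmax_position(self) -> int:
        return int(np.argmax(self.raw_counts)) + 1


def build_cleavage_profile(
    tags: Iterable[FastqRead],
    transcripts: dict,
    min_tag_len: int = 15,
    adapter: Optional[str] = None,
    quality_limit: float = 0.02,
    depth_scale: float = 1e7,
) -> tuple[dict[str, CleavageProfile], dict]:
    """Map degradome tags to transcripts and count 5'-end cleavage sites.

    Tags are optionally adapter/quality trimmed (as in small-RNA
    preprocessing), filtered at ``min_tag_len``, and each tag's 5' end is
    counted at every transcript position where the tag matches exactly on
    the sense strand (multimapping tags count at all loci; multiplicities
    are logged in the returned stats).
    """
    from .annotation import mott_trim, trim_adapter

    unique: dict[str, int] = {}
    stats = {"input": 0, "too_short": 0, "mapped_tags": 0, "unmapped_tags": 0,
             "multimapped_tags": 0, "placements": 0}
    for read in tags:
        stats["input"] += 1
        seq = read.sequence
        if adapter:
            seq = trim_adapter(seq, adapter)
            seq = mott_trim(seq, read.quality[: len(seq)], quality_limit)
        if len(seq) < min_tag_len:
            stats["too_short"] += 1
            continue
        unique[seq] = unique.get(seq, 0) + 1

    raw = {tid: np.zeros(m.exon_length, dtype=np.int64) for tid, m in transcripts.items()}
    for seq, count in unique.items():
        placements = []
        for tid, model in transcripts.items():
            start = model.sequence.find(seq)
            while start >= 0:
                placements.append((tid, start + 1))
                start = model.sequence.find(seq, start + 1)
        if not placements:
            stats["unmapped_tags"] += count
            continue
        stats["mapped_tags"] += count
        if len(placements) > 1:
            stats["multimapped_tags"] += count
        stats["placements"] += count * len(placements)
        for tid, pos in placements:
            raw[tid][pos - 1] += count

    total_mapped = sum(arr.sum() for arr in raw.values())
    if total_mapped == 0:
        import warnings

        warnings.warn("no degradome tags mapped to any transcript", stacklevel=2)
    profiles = {}
    for tid, arr in raw.items():
        t_total = arr.sum()
        depth = arr * (depth_scale / total_mapped) if total_mapped else arr.astype(float)
        frac = arr / t_total if t_total else arr.astype(float)
        profiles[tid] = CleavageProfile(tid, len(arr), arr, depth, frac)
    return profiles, stats


def assign_peak_category(profile: CleavageProfile, position: int) -> int:
    """Five-level ranking of a degradome position within its transcript.

    0: unique maximum with count > 1; 1: shared maximum (> 1); 2: above the
    mean of positions with >= 1 read; 3: > 1 but at or below that mean;
    4: exactly one read.  Positions with zero signal are not scorable.
    """
    c = profile.raw(position)
    if c == 0:
        raise ValueError(f"no signal at position {position} of {profile.transcript_id}")
    if c == 1:
        return 4
    signal = profile.raw_counts[profile.raw_counts > 0]
    maximum = int(signal.max())
    mean = float(signal.mean())
    if c == maximum:
        return 0 if int((profile.raw_counts == maximum).sum()) == 1 else 1
    return 2 if c > mean else 3


# ---------------------------------------------------------------------------
# Duplex enumeration
# ---------------------------------------------------------------------------

@dataclass
class DuplexAlignment:
    srna_id: str
    transcript_id: str
    srna_seq: str
    site_start: int                 # 1-based, closed, sense strand
    site_end: int
    # alignment columns 5'->3' along the sRNA: (srna_pos or None,
    # transcript_pos or None); both None never occurs
    columns: tuple
    n_mismatch: int = 0
    n_gu: int = 0
    n_bulge_nt: int = 0
    n_loop: int = 0
    overhang_5p: int = 0
    overhang_3p: int = 0
    mfe: float = 0.0
    perfect_mfe: float = 0.0
    mfe_ratio: float = 0.0
    allen_score: float = 0.0
    targetseek_score: Optional[float] = None
    # per-sRNA-position pair states plus target-bulge attributions
    pair_states: dict = field(default_factory=dict)

    def paired_position(self, srna_pos: int) -> Optional[int]:
        for i, j in self.columns:
            if i == srna_pos and j is not None:
                return j
        return None


_ENC = {c: i for i, c in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC.get(c, 0) for c in seq), dtype=np.int8, count=len(seq))


def _prescreen_offsets(srna: str, transcript: str, min_score: float) -> np.ndarray:
    """0-based site starts whose ungapped antiparallel complementarity
    (match 1, G:U 0.5) reaches ``min_score``."""
    L = len(srna)
    if len(transcript) < L:
        return np.array([], dtype=int)
    pattern = _encode(reverse_complement(srna))
    t = _encode(transcript)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    match = windows == pattern
    # pattern C against target T <=> sRNA G : target U; pattern A against
    # target G <=> sRNA U : target G
    wobble = ((pattern == _ENC["C"]) & (windows == _ENC["T"])) | (
        (pattern == _ENC["A"]) & (windows == _ENC["G"])
    )
    score = match.sum(axis=1) + 0.5 * wobble.sum(axis=1)
    return np.nonzero(score >= min_score)[0]


def _pair_score(x: str, y: str) -> float:
    state = pair_state(x, _COMPLEMENT[y])  # y is complement-space
    if state == "match":
        return 1.0
    if state == "gu":
        return 0.5
    return 0.0


def _align_window(srna: str, window: str, gap: float = -2.0) -> list[tuple]:
    """Global alignment with free end gaps of the sRNA against the window's
    reverse complement (match +1, G:U +0.5, mismatch 0, gap -2).

    Returns alignment columns as (srna_index, window_rc_index) pairs with
    None marking gaps, 5'->3' along the sRNA.
    """
    x = srna
    y = reverse_complement(window)
    m, n = len(x), len(y)
    NEG = -1e9
    S = [[0.0] * (n + 1) for _ in range(m + 1)]
    P = [[0] * (n + 1) for _ in range(m + 1)]  # 1 diag, 2 up (gap in y), 3 left
    for i in range(1, m + 1):
        P[i][0] = 2
    for j in range(1, n + 1):
        P[0][j] = 3
    for i in range(1, m + 1):
        xi = x[i - 1]
        row, prev = S[i], S[i - 1]
        prow = P[i]
        for j in range(1, n + 1):
            diag = prev[j - 1] + _pair_score(xi, y[j - 1])
            up = prev[j] + gap
            left = row[j - 1] + gap
            best, ptr = diag, 1
            if up > best:
                best, ptr = up, 2
            if left > best:
                best, ptr = left, 3
            row[j], prow[j] = best, ptr
    # free trailing gaps: best cell in the last row or column, preferring
    # the fullest extension on ties
    best, bi, bj = NEG, m, n
    for j in range(n + 1):
        if S[m][j] >= best:
            best, bi, bj = S[m][j], m, j
    for i in range(m + 1):
        if S[i][n] >= best:
            best, bi, bj = S[i][n], i, n
    columns: list[tuple] = []
    # unaligned tails (free end gaps)
    for i in range(m, bi, -1):
        columns.append((i - 1, None))
    for j in range(n, bj, -1):
        columns.append((None, j - 1))
    i, j = bi, bj
    while i > 0 or j > 0:
        ptr = P[i][j]
        if ptr == 1 and i > 0 and j > 0:
            columns.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif ptr == 2 or (j == 0 and i > 0):
            columns.append((i - 1, None))
            i -= 1
        else:
            columns.append((None, j - 1))
            j -= 1
    columns.reverse()
    return columns


def _build_duplex(
    srna_id: str,
    srna: str,
    transcript_id: str,
    transcript: str,
    win_start0: int,
    window: str,
    columns: list[tuple],
) -> Optional[DuplexAlignment]:
    """Translate alignment columns into a DuplexAlignment with a full
    mismatch/G:U/bulge/loop inventory."""
    n = len(window)

    def t_pos(j: int) -> int:  # window-rc index -> 1-based transcript position
        return win_start0 + (n - 1 - j) + 1

    cols: list[tuple] = []
    states: dict = {}
    aligned = []
    for i, j in columns:
        sp = None if i is None else i + 1
        tp = None if j is None else t_pos(j)
        cols.append((sp, tp))
        if sp is not None and tp is not None:
            state = pair_state(srna[i], transcript[tp - 1])
            states[sp] = state
            aligned.append((sp, tp, state))
    if not aligned:
        return None
    # trim flanking window bases (target-side terminal gaps are not bulges)
    first = next(k for k, (sp, tp) in enumerate(cols) if sp is not None)
    last = len(cols) - 1 - next(
        k for k, (sp, tp) in enumerate(reversed(cols)) if sp is not None
    )
    cols = cols[first: last + 1]

    site_positions = [tp for sp, tp in cols if tp is not None]
    site_start, site_end = min(site_positions), max(site_positions)

    n_mismatch = sum(1 for s in states.values() if s == "mismatch")
    n_gu = sum(1 for s in states.values() if s == "gu")
    # bulges: internal gap runs; loops: internal mismatch runs
    n_bulge_nt = 0
    bulge_runs = 0
    in_gap = False
    bulge_anchor: dict = {}
    last_sp = 0
    for sp, tp in cols:
        if sp is None or tp is None:
            n_bulge_nt += 1
            if not in_gap:
                bulge_runs += 1
                in_gap = True
            if tp is not None:  # bulged target nucleotide: attribute to the
                bulge_anchor[len(bulge_anchor)] = max(last_sp, 1)  # 5'-adjacent sRNA pos
        else:
            last_sp = sp
            in_gap = False
    loop_runs = 0
    in_loop = False
    for sp, tp in cols:
        if sp is not None and tp is not None and states[sp] == "mismatch":
            if not in_loop:
                loop_runs += 1
                in_loop = True
        else:
            in_loop = False
    srna_positions = [sp for sp, tp in cols if sp is not None]
    overhang_5p = min(srna_positions) - 1
    overhang_3p = len(srna) - max(srna_positions)

    duplex = DuplexAlignment(
        srna_id=srna_id,
        transcript_id=transcript_id,
        srna_seq=srna,
        site_start=site_start,
        site_end=site_end,
        columns=tuple(cols),
        n_mismatch=n_mismatch,
        n_gu=n_gu,
        n_bulge_nt=n_bulge_nt,
        n_loop=loop_runs,
        overhang_5p=overhang_5p,
        overhang_3p=overhang_3p,
        pair_states={"states": states, "bulges": n_bulge_nt, "bulge_anchors": bulge_anchor},
    )
    duplex.mfe = duplex_mfe(duplex, transcript)
    duplex.perfect_mfe = perfect_mfe(srna)
    duplex.mfe_ratio = (
        min(max(duplex.mfe / duplex.perfect_mfe, 0.0), 1.0) if duplex.perfect_mfe < 0 else 0.0
    )
    duplex.allen_score = score_alignment_allen(duplex)
    return duplex


def enumerate_candidate_duplexes(
    srna_id: str,
    srna: str,
    transcript_id: str,
    transcript: str,
    max_bulge: int = 2,
    prescreen_min_score: Optional[float] = None,
) -> list[DuplexAlignment]:
    """Enumerate plausible antiparallel sRNA:transcript duplexes.

    Candidate sites are located by an ungapped complementarity prescreen
    (threshold ``prescreen_min_score``, default ``max(10, 0.55 * len)``);
    each is refined by global alignment against the reverse complement of a
    window padded by ``max_bulge`` on both sides.  Every returned duplex
    carries a complete pairing inventory.
    """
    if not 18 <= len(srna) <= 25:
        raise ValueError("sRNA must be 18-25 nt")
    if len(transcript) < len(srna):
        return []
    L = len(srna)
    if prescreen_min_score is None:
        prescreen_min_score = max(10.0, 0.55 * L)
    duplexes: dict[tuple, DuplexAlignment] = {}
    for offset in _prescreen_offsets(srna, transcript, prescreen_min_score):
        ws = max(0, int(offset) - max_bulge)
        we = min(len(transcript), int(offset) + L + max_bulge)
        window = transcript[ws:we]
        columns = _align_window(srna, window)
        duplex = _build_duplex(srna_id, srna, transcript_id, transcript, ws, window, columns)
        if duplex is None:
            continue
        key = (duplex.site_start, duplex.site_end, duplex.columns)
        if key not in duplexes:
            duplexes[key] = duplex
    return sorted(duplexes.values(), key=lambda d: (d.allen_score, d.site_start))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

CORE_POSITIONS = range(2, 14)  # sRNA positions 2-13 (5' count), doubled region


def score_alignment_allen(
    duplex: DuplexAlignment, permit_pos10_relaxation: bool = True
) -> float:
    """Plant-target alignment penalty score (lower = better pairing).

    Mismatch 1, bulged/gapped nucleotide 1, G:U wobble 0.5; each doubled
    within sRNA positions 2-13.  With the position-10 relaxation a single
    mismatch or G:U exactly at position 10 incurs the undoubled penalty.
    Unaligned sRNA end positions are penalized as mismatches.
    """
    states: dict = duplex.pair_states["states"]
    srna_gap_positions = {sp for sp, tp in duplex.columns if sp is not None and tp is None}
    score = 0.0
    for pos in range(1, len(duplex.srna_seq) + 1):
        state = states.get(pos)
        if state == "match" or pos in srna_gap_positions:
            continue  # gapped sRNA positions are charged in the bulge pass
        penalty = 0.5 if state == "gu" else 1.0  # mismatch or unaligned end
        if pos in CORE_POSITIONS and not (
            permit_pos10_relaxation and pos == 10 and state in ("gu", "mismatch")
        ):
            penalty *= 2.0
        score += penalty
    # bulged target nucleotides, attributed to the 5'-adjacent sRNA position
    for anchor in duplex.pair_states["bulge_anchors"].values():
        score += 2.0 if anchor in CORE_POSITIONS else 1.0
    # bulged sRNA nucleotides (aligned to a target gap)
    for sp in srna_gap_positions:
        score += 2.0 if sp in CORE_POSITIONS else 1.0
    return score


def duplex_mfe(duplex: DuplexAlignment, transcript: str) -> float:
    """Nearest-neighbour stacking-energy sum plus loop/bulge penalties."""
    pairs = []  # (srna_pos, transcript_pos, pair string)
    for sp, tp in duplex.columns:
        if sp is None or tp is None:
            continue
        state = duplex.pair_states["states"][sp]
        if state in ("match", "gu"):
            pairs.append((sp, tp, duplex.srna_seq[sp - 1] + transcript[tp - 1]))
    if len(pairs) < 2:
        return 0.0
    energy = 0.0
    for (s1, t1, p1), (s2, t2, p2) in zip(pairs, pairs[1:]):
        if s2 == s1 + 1 and t2 == t1 - 1:  # stacked (antiparallel: target descends)
            energy += stack_energy(p1, p2)
        else:
            interior = (s2 - s1 - 1) + abs(t1 - t2 - 1)
            if (s2 - s1 - 1) == 0 or (t1 - t2 - 1) == 0:
                energy += BULGE_OPEN + BULGE_PER_NT * interior
            else:
                energy += LOOP_OPEN + LOOP_PER_NT * interior
    return float(energy)


def perfect_mfe(srna: str) -> float:
    """MFE of the sRNA paired with its exact complement."""
    pairs = [srna[i] + _COMPLEMENT[srna[i]] for i in range(len(srna))]
    return float(sum(stack_energy(a, b) for a, b in zip(pairs, pairs[1:])))


DEFAULT_TS_WEIGHTS = {"mismatch": 2.0, "gu": 1.0, "bulge": 3.0, "loop": 1.0}


def targetseek_score_filter(
    duplex: DuplexAlignment,
    weights: Optional[dict] = None,
    mfe_ratio_min: float = 0.6,
    max_bulge_nt: int = 3,
    max_overhang: int = 2,
) -> Optional[float]:
    """MFE-track filter and penalty score; returns None when rejected.

    A duplex passes when its MFE reaches ``mfe_ratio_min`` of the
    perfect-complement MFE, has at most ``max_bulge_nt`` bulged nucleotides
    and overhangs of at most ``max_overhang``; the score is the weighted sum
    of mismatches, G:U pairs, bulged nucleotides and loops (lower = better).
    """
    w = dict(DEFAULT_TS_WEIGHTS)
    if weights:
        w.update(weights)
    if any(v < 0 for v in w.values()):
        raise ValueError("weights must be non-negative")
    if duplex.mfe_ratio < mfe_ratio_min:
        return None
    if duplex.n_bulge_nt > max_bulge_nt:
        return None
    if max(duplex.overhang_5p, duplex.overhang_3p) > max_overhang:
        return None
    return (
        w["mismatch"] * duplex.n_mismatch
        + w["gu"] * duplex.n_gu
        + w["bulge"] * duplex.n_bulge_nt
        + w["loop"] * duplex.n_loop
    )


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

@dataclass
class TargetPrediction:
    srna_id: str
    transcript_id: str
    cleavage_coordinate: int  # transcript position paired to sRNA nucleotide 10
    category: int
    score: float
    p_value: float
    track: str
    duplex: DuplexAlignment


def _candidates_for_track(
    srna_id: str,
    srna: str,
    transcript_id: str,
    transcript: str,
    track: str,
    allen_threshold: float,
    ts_kwargs: dict,
    max_bulge: int,
    prescreen_min_score: Optional[float],
) -> list[tuple[DuplexAlignment, float]]:
    out = []
    for duplex in enumerate_candidate_duplexes(
        srna_id, srna, transcript_id, transcript, max_bulge=max_bulge,
        prescreen_min_score=prescreen_min_score,
    ):
        if track == "allen":
            if duplex.allen_score <= allen_threshold:
                out.append((duplex, duplex.allen_score))
        elif track == "targetseek":
            score = targetseek_score_filter(duplex, **ts_kwargs)
            if score is not None:
                duplex.targetseek_score = score
                out.append((duplex, score))
        else:
            raise ValueError(f"unknown track {track!r}")
    return out


def site_pvalue_permutation(
    profile: CleavageProfile,
    srna: str,
    transcript: str,
    observed_score: float,
    observed_category: int,
    n_perm: int = 1000,
    seed: int = 0,
    track: str = "allen",
    allen_threshold: float = 4.0,
    ts_kwargs: Optional[dict] = None,
    shuffle: str = "mononucleotide",
    max_bulge: int = 2,
) -> float:
    """Permutation p-value for one predicted site.

    The null shuffles the sRNA (mononucleotide by default, dinucleotide by
    flag) and asks how often a shuffled guide achieves a score at most the
    observed one at a degradome site of category at most the observed one on
    this transcript.  p = (1 + hits) / (n_perm + 1); a fixed seed gives an
    identical p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(srna))
    hits = 0
    for _ in range(n_perm):
        if shuffle == "dinucleotide":
            shuffled = _dinucleotide_shuffle(srna, rng)
        else:
            shuffled = "".join(rng.permutation(letters))
        found = False
        for duplex, score in _candidates_for_track(
            "perm", shuffled, profile.transcript_id, transcript, track,
            allen_threshold, ts_kwargs or {}, max_bulge, None,
        ):
            if score > observed_score:
                continue
            coord = duplex.paired_position(10)
            if coord is None or not 1 <= coord <= profile.length:
                continue
            if profile.raw(coord) == 0:
                continue
            if assign_peak_category(profile, coord) <= observed_category:
                found = True
                break
        hits += found
    return (1 + hits) / (n_perm + 1)


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Eulerian-walk shuffle preserving dinucleotide composition (simple
    retry variant adequate for short sRNAs)."""
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for _ in range(50):
        pools = {k: list(rng.permutation(v)) for k, v in edges.items()}
        out = [seq[0]]
        ok = True
        for _ in range(len(seq) - 1):
            pool = pools.get(out[-1])
            if not pool:
                ok = False
                break
            out.append(pool.pop())
        if ok:
            return "".join(out)
    return "".join(rng.permutation(list(seq)))


def predict_targets(
    srnas: dict[str, str],
    profiles: dict[str, CleavageProfile],
    transcripts: dict,
    track: str = "allen",
    allen_threshold: float = 4.0,
    permit_pos10_relaxation: bool = True,
    ts_kwargs: Optional[dict] = None,
    category_max: int = 4,
    coordinate_tolerance: int = 1,
    n_perm: int = 100,
    seed: int = 0,
    max_bulge: int = 2,
) -> list[TargetPrediction]:
    """Predict cleavage targets for a set of small RNAs.

    For each sRNA x transcript pair, candidate duplexes of the chosen track
    are evaluated; the predicted cleavage coordinate is the transcript
    position paired to sRNA nucleotide 10.  A prediction is kept when the
    coordinate carries degradome signal of category <= ``category_max`` and
    lies within ``coordinate_tolerance`` of the transcript's maximal peak.
    Results are sorted by (score, p).
    """
    ts_kwargs = ts_kwargs or {}
    predictions: list[TargetPrediction] = []
    for sid, seq in srnas.items():
        for tid, profile in profiles.items():
            if profile.total == 0:
                continue
            model = transcripts[tid]
            for duplex, score in _candidates_for_track(
                sid, seq, tid, model.sequence, track, allen_threshold,
                ts_kwargs, max_bulge, None,
            ):
                if not permit_pos10_relaxation and track == "allen":
                    score = score_alignment_allen(duplex, permit_pos10_relaxation=False)
                    if score > allen_threshold:
                        continue
                coord = duplex.paired_position(10)
                if coord is None or not 1 <= coord <= profile.length:
                    continue
                if profile.raw(coord) == 0:
                    continue
                category = assign_peak_category(profile, coord)
                if category > category_max:
                    continue
                if abs(profile.argmax_position() - coord) > coordinate_tolerance:
                    continue
                p = (
                    site_pvalue_permutation(
                        profile, seq, model.sequence, score, category,
                        n_perm=n_perm, seed=seed, track=track,
                        allen_threshold=allen_threshold, ts_kwargs=ts_kwargs,
                        max_bulge=max_bulge,
                    )
                    if n_perm > 0
                    else float("nan")
                )
                predictions.append(
                    TargetPrediction(sid, tid, coord, category, score, p, track, duplex)
                )
    predictions.sort(key=lambda x: (x.score, x.p_value if x.p_value == x.p_value else 1.0))
    return predictions


# ---------------------------------------------------------------------------
# t-plot export
# ---------------------------------------------------------------------------

def export_tplot(
    profile: CleavageProfile,
    prediction: TargetPrediction,
    tsv_path,
    figure_path=None,
) -> None:
    """Write per-position abundance TSV (positions with signal only) and an
    optional rendered figure marking the predicted cleavage coordinate."""
    positions = np.nonzero(profile.raw_counts)[0] + 1
    table = pd.DataFrame(
        {
            "position": positions,
            "raw": profile.raw_counts[positions - 1],
            "depth_normalized": profile.depth_normalized[positions - 1],
            "fraction": profile.fraction_of_transcript_signal[positions - 1],
            "predicted_cleavage": positions == prediction.cleavage_coordinate,
        }
    )
    table.to_csv(tsv_path, sep="\t", index=False)
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3))
        ax.vlines(positions, 0, profile.raw_counts[positions - 1], color="black", lw=1)
        coord = prediction.cleavage_coordinate
        ax.vlines([coord], 0, max(profile.raw(coord), 1), color="red", lw=2)
        ax.set_xlabel(f"{profile.transcript_id} position (nt)")
        ax.set_ylabel("fragment abundance")
        ax.set_title(
            f"{prediction.srna_id} -> {profile.transcript_id} "
            f"(cleavage {coord}, category {prediction.category})"
        )
        fig.tight_layout()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
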