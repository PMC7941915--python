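"""Cleavage profiles, duplex scoring oracles and target-prediction recovery."""

import dataclasses

import numpy as np
import pytest

from pistarve import degradome as dg
from pistarve import simulate
from pistarve.io import FastqRead, TranscriptModel, read_fastq, reverse_complement

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_transcript(seq, tid="t", cls="protein-coding"):
    return TranscriptModel(tid, cls, "1H", len(seq), seq)


def recount_inventory(duplex):
    """Independent brute-force recount of the pairing inventory from the
    alignment columns and raw sequences."""
    n_mismatch = n_gu = n_bulge = 0
    srna = duplex.srna_seq
    # transcript bases are recoverable from pair states + matched letters via
    # the stored columns; recount against the duplex's own bookkeeping inputs
    states = duplex.pair_states["states"]
    for sp, tp in duplex.columns:
        if sp is None or tp is None:
            n_bulge += 1
    for sp, state in states.items():
        if state == "mismatch":
            n_mismatch += 1
        elif state == "gu":
            n_gu += 1
    return n_mismatch, n_gu, n_bulge


def brute_force_inventory(duplex, transcript_seq):
    """Recount mismatches/G:U/bulges directly from the two sequences."""
    n_mismatch = n_gu = n_bulge = 0
    for sp, tp in duplex.columns:
        if sp is None or tp is None:
            n_bulge += 1
            continue
        a, b = duplex.srna_seq[sp - 1], transcript_seq[tp - 1]
        if COMPLEMENT[a] == b:
            continue
        if (a, b) in (("G", "T"), ("T", "G")):
            n_gu += 1
        else:
            n_mismatch += 1
    return n_mismatch, n_gu, n_bulge


class TestProfiles:
    def test_single_tag_counts_at_five_prime_end(self, rng):
        t = make_transcript(random_seq(rng, 300))
        tag = t.sequence[99:119]  # starts at position 100
        profiles, stats = dg.build_cleavage_profile(
            [FastqRead("r", tag, "I" * 20)], {"t": t}
        )
        profile = profiles["t"]
        assert profile.raw(100) == 1
        assert profile.fraction_of_transcript_signal[99] == 1.0
        assert stats["mapped_tags"] == 1

    def test_short_tag_excluded(self, rng):
        t = make_transcript(random_seq(rng, 300))
        tag = t.sequence[99:113]  # 14 nt
        profiles, stats = dg.build_cleavage_profile(
            [FastqRead("r", tag, "I" * 14)], {"t": t}
        )
        assert stats["too_short"] == 1
        assert profiles["t"].total == 0

    def test_unmapped_tags_warn(self, rng):
        t = make_transcript(random_seq(rng, 100))
        with pytest.warns(UserWarning, match="no degradome tags"):
            dg.build_cleavage_profile([FastqRead("r", "T" * 20, "I" * 20)], {"t": t})

    def test_planted_peak_is_argmax(self, small_config, bundle_truth, tmp_path):
        bundle, truth = bundle_truth
        path = simulate.simulate_degradome_reads(
            bundle, truth, small_config, tmp_path / "d.fastq"
        )
        profiles, _ = dg.build_cleavage_profile(read_fastq(path), bundle.transcripts)
        hits = sum(
            profiles[tid].argmax_position() == coord
            for _, tid, coord, _ in truth.target_pairs
        )
        assert hits >= 0.9 * len(truth.target_pairs)

    def test_fraction_sums_to_one_where_signal(self, rng):
        t = make_transcript(random_seq(rng, 300))
        tags = [FastqRead(f"r{i}", t.sequence[i: i + 20], "I" * 20) for i in (0, 50, 50, 99)]
        profiles, _ = dg.build_cleavage_profile(tags, {"t": t})
        assert profiles["t"].fraction_of_transcript_signal.sum() == pytest.approx(1.0)


class TestDuplexEnumeration:
    def test_perfect_complement_site(self, rng):
        srna = random_seq(rng, 21)
        t = random_seq(rng, 300)
        t = t[:100] + reverse_complement(srna) + t[121:]
        duplexes = dg.enumerate_candidate_duplexes("s", srna, "t", t)
        best = duplexes[0]
        assert (best.n_mismatch, best.n_gu, best.n_bulge_nt) == (0, 0, 0)
        assert best.site_end - best.site_start + 1 == len(srna)
        assert best.allen_score == 0.0
        assert best.mfe_ratio == pytest.approx(1.0)

    def test_transcript_shorter_than_srna_gives_empty(self, rng):
        assert dg.enumerate_candidate_duplexes("s", random_seq(rng, 21), "t", "ACGT") == []

    def test_inventories_match_brute_force_recount(self, rng):
        """Every returned duplex's (mismatch, G:U, bulge) inventory equals an
        independent recount from its paired positions and raw sequences."""
        checked = 0
        for _ in range(60):
            srna = random_seq(rng, int(rng.integers(18, 26)))
            t = random_seq(rng, 600)
            # implant a corrupted site so candidates exist
            site = list(reverse_complement(srna))
            for _ in range(int(rng.integers(0, 4))):
                pos = int(rng.integers(0, len(site)))
                site[pos] = "ACGT"[int(rng.integers(0, 4))]
            t = t[:200] + "".join(site) + t[200 + len(site):]
            for duplex in dg.enumerate_candidate_duplexes("s", srna, "t", t):
                assert brute_force_inventory(duplex, t) == (
                    duplex.n_mismatch, duplex.n_gu, duplex.n_bulge_nt
                )
                checked += 1
        assert checked >= 60

    def test_predicted_coordinate_pairs_nucleotide_ten(self, rng):
        srna = random_seq(rng, 21)
        t = random_seq(rng, 300)
        t = t[:100] + reverse_complement(srna) + t[121:]
        duplex = dg.enumerate_candidate_duplexes("s", srna, "t", t)[0]
        coord = duplex.paired_position(10)
        assert t[coord - 1] == COMPLEMENT[srna[9]]


class TestAllenScore:
    def _perfect(self, rng, srna=None):
        srna = srna or random_seq(rng, 21)
        t = reverse_complement(srna)
        t = "ACGTACGTAC" + t + "ACGTACGTAC"
        return srna, t

    def test_perfect_complement_scores_zero(self, rng):
        srna, t = self._perfect(rng)
        duplex = dg.enumerate_candidate_duplexes("s", srna, "t", t)[0]
        assert dg.score_alignment_allen(duplex) == 0.0

    def test_single_gu_at_position_fifteen_scores_half(self, rng):
        srna = "A" * 14 + "G" + "A" * 6  # position 15 is G
        t = list(reverse_complement(srna))
        # target base paired to sRNA position 15 sits at site index L-15
        t[21 - 15] = "T"  # G:U wobble
        t = "CCCCCCCCCC" + "".join(t) + "CCCCCCCCCC"
        duplex = dg.enumerate_candidate_duplexes("s", srna, "t", t)[0]
        assert duplex.n_gu == 1
        assert dg.score_alignment_allen(duplex) == 0.5

    def test_single_mismatch_at_position_five_scores_two(self, rng):
        srna = random_seq(rng, 21)
        site = list(reverse_complement(srna))
        idx = 21 - 5  # paired to sRNA position 5
        current = site[idx]
        # substitute so the pair is neither Watson-Crick nor G:U
        for base in "ACGT":
            s = srna[4]
            if base != current and not (
                COMPLEMENT[s] == base or (s, base) in (("G", "T"), ("T", "G"))
            ):
                site[idx] = base
                break
        t = "GGGGGGGGGG" + "".join(site) + "GGGGGGGGGG"
        duplex = dg.enumerate_candidate_duplexes("s", srna, "t", t)[0]
        assert duplex.n_mismatch == 1
        assert dg.score_alignment_allen(duplex) == 2.0

    def test_position_ten_relaxation_halves_core_penalty(self, rng):
        srna = random_seq(rng, 21)
        site = list(reverse_complement(srna))
        idx = 21 - 10
        for base in "ACGT":
            s = srna[9]
            if base != site[idx] and not (
                COMPLEMENT[s] == base or (s, base) in (("G", "T"), ("T", "G"))
            ):
                site[idx] = base
                break
        t = "GGGGGGGGGG" + "".join(site) + "GGGGGGGGGG"
        duplex = dg.enumerate_candidate_duplexes("s", srna, "t", t)[0]
        assert dg.score_alignment_allen(duplex, permit_pos10_relaxation=True) == 1.0
        assert dg.score_alignment_allen(duplex, permit_pos10_relaxation=False) == 2.0

    def test_score_invariant_under_coordinate_shift(self, rng):
        srna = random_seq(rng, 21)
        site = reverse_complement(srna)
        for pad in (10, 200):
            t = random_seq(rng, pad) + site + random_seq(rng, 50)
            duplex = dg.enumerate_candidate_duplexes("s", srna, "t", t)[0]
            assert dg.score_alignment_allen(duplex) == 0.0


class TestMfe:
    def test_perfect_duplex_ratio_one(self, rng):
        srna, t = TestAllenScore()._perfect(rng)
        duplex = dg.enumerate_candidate_duplexes("s", srna, "t", t)[0]
        assert duplex.mfe == pytest.approx(duplex.perfect_mfe)
        assert duplex.mfe_ratio == pytest.approx(1.0)

    def test_removing_pairs_raises_mfe(self, rng):
        """Corrupting base pairs makes the energy strictly less negative."""
        srna = random_seq(rng, 21)
        site = list(reverse_complement(srna))
        perfect_t = "GGGGGGGGGG" + "".join(site) + "GGGGGGGGGG"
        perfect = dg.enumerate_candidate_duplexes("s", srna, "t", perfect_t)[0]
        for idx in (5, 6):
            s = srna[21 - 1 - idx]
            for base in "ACGT":
                if base != site[idx] and not (
                    COMPLEMENT[s] == base or (s, base) in (("G", "T"), ("T", "G"))
                ):
                    site[idx] = base
                    break
        damaged_t = "GGGGGGGGGG" + "".join(site) + "GGGGGGGGGG"
        damaged = dg.enumerate_candidate_duplexes("s", srna, "t", damaged_t)[0]
        assert damaged.mfe > perfect.mfe

    def test_gc_duplex_more_stable_than_au(self):
        gc = "GC" * 10 + "G"
        au = "AT" * 10 + "A"
        assert dg.perfect_mfe(gc) < dg.perfect_mfe(au)

    def test_mfe_nonpositive_with_stacked_pairs(self, rng):
        srna, t = TestAllenScore()._perfect(rng)
        duplex = dg.enumerate_candidate_duplexes("s", srna, "t", t)[0]
        assert duplex.mfe <= 0


class TestTargetSeekFilter:
    def _duplex(self, rng, **overrides):
        srna, t = TestAllenScore()._perfect(rng)
        duplex = dg.enumerate_candidate_duplexes("s", srna, "t", t)[0]
        return dataclasses.replace(duplex, **overrides)

    def test_perfect_complement_accepted_with_score_zero(self, rng):
        assert dg.targetseek_score_filter(self._duplex(rng)) == 0.0

    def test_low_mfe_ratio_rejected(self, rng):
        assert dg.targetseek_score_filter(self._duplex(rng, mfe_ratio=0.5)) is None

    def test_weight_arithmetic(self, rng):
        duplex = self._duplex(rng, n_gu=1, n_mismatch=1)
        assert dg.targetseek_score_filter(duplex) == 3.0

    def test_negative_weights_rejected(self, rng):
        with pytest.raises(ValueError):
            dg.targetseek_score_filter(self._duplex(rng), weights={"gu": -1})


class TestPeakCategory:
    def _profile(self, counts):
        arr = np.zeros(50, dtype=np.int64)
        for pos, c in counts.items():
            arr[pos - 1] = c
        frac = arr / arr.sum() if arr.sum() else arr.astype(float)
        return dg.CleavageProfile("t", 50, arr, arr.astype(float), frac)

    def test_unique_maximum_is_category_zero(self):
        assert dg.assign_peak_category(self._profile({1: 10, 4: 2}), 1) == 0

    def test_below_mean_is_category_three(self):
        assert dg.assign_peak_category(self._profile({1: 10, 4: 2}), 4) == 3

    def test_single_read_is_category_four(self):
        assert dg.assign_peak_category(self._profile({1: 1}), 1) == 4

    def test_shared_maximum_is_category_one(self):
        assert dg.assign_peak_category(self._profile({1: 5, 9: 5, 20: 2}), 9) == 1

    def test_above_mean_nonmax_is_category_two(self):
        profile = self._profile({1: 100, 5: 50, 9: 2, 10: 2, 11: 2})
        assert dg.assign_peak_category(profile, 5) == 2

    def test_zero_signal_not_scorable(self):
        with pytest.raises(ValueError, match="no signal"):
            dg.assign_peak_category(self._profile({1: 5}), 2)


class TestPermutationPvalue:
    def test_identical_seed_identical_p(self, rng):
        srna = random_seq(rng, 21)
        t = random_seq(rng, 200) + reverse_complement(srna) + random_seq(rng, 50)
        arr = np.zeros(len(t), dtype=np.int64)
        arr[200 + 21 - 10] = 30
        profile = dg.CleavageProfile("t", len(t), arr, arr.astype(float), arr / arr.sum())
        args = (profile, srna, t, 0.0, 0)
        p1 = dg.site_pvalue_permutation(*args, n_perm=30, seed=5)
        p2 = dg.site_pvalue_permutation(*args, n_perm=30, seed=5)
        assert p1 == p2

    def test_planted_strong_target_significant(self, rng):
        srna = random_seq(rng, 21)
        t = random_seq(rng, 300) + reverse_complement(srna) + random_seq(rng, 100)
        arr = np.zeros(len(t), dtype=np.int64)
        coord = 300 + 21 + 1 - 10
        arr[coord - 1] = 30
        profile = dg.CleavageProfile("t", len(t), arr, arr.astype(float), arr / arr.sum())
        p = dg.site_pvalue_permutation(profile, srna, t, 0.0, 0, n_perm=99, seed=1)
        assert p <= 0.05

    def test_invalid_n_perm(self, rng):
        srna = random_seq(rng, 21)
        profile = dg.CleavageProfile("t", 10, np.ones(10, dtype=np.int64),
                                     np.ones(10), np.full(10, 0.1))
        with pytest.raises(ValueError):
            dg.site_pvalue_permutation(profile, srna, "A" * 30, 0.0, 0, n_perm=0)


class TestPredictTargets:
    def test_planted_pairs_recovered_with_exact_coordinate(
        self, small_config, bundle_truth, tmp_path
    ):
        bundle, truth = bundle_truth
        path = simulate.simulate_degradome_reads(
            bundle, truth, small_config, tmp_path / "d.fastq"
        )
        profiles, _ = dg.build_cleavage_profile(read_fastq(path), bundle.transcripts)
        guides = {sid: bundle.mature_mirnas[sid] for sid, _, _, _ in truth.target_pairs}
        predictions = dg.predict_targets(guides, profiles, bundle.transcripts, n_perm=0)
        found = {(p.srna_id, p.transcript_id, p.cleavage_coordinate) for p in predictions}
        wanted = {(sid, tid, coord) for sid, tid, coord, _ in truth.target_pairs}
        assert len(found & wanted) >= 0.9 * len(wanted)

    def test_unrelated_srna_gives_no_predictions(self, rng):
        t = make_transcript(random_seq(rng, 400))
        arr = np.zeros(400, dtype=np.int64)
        arr[100] = 20
        profile = dg.CleavageProfile("t", 400, arr, arr.astype(float), arr / arr.sum())
        predictions = dg.predict_targets(
            {"s": random_seq(rng, 21)}, {"t": profile}, {"t": t}, n_perm=0
        )
        assert predictions == []

    def test_perfect_site_without_signal_not_predicted(self, rng):
        srna = random_seq(rng, 21)
        seq = random_seq(rng, 200) + reverse_complement(srna) + random_seq(rng, 100)
        t = make_transcript(seq)
        arr = np.zeros(len(seq), dtype=np.int64)
        arr[10] = 5  # signal far from the site
        profile = dg.CleavageProfile("t", len(seq), arr, arr.astype(float), arr / arr.sum())
        predictions = dg.predict_targets({"s": srna}, {"t": profile}, {"t": t}, n_perm=0)
        assert predictions == []


class TestTplot:
    def test_export_rows_and_mark(self, rng, tmp_path):
        import pandas as pd

        srna = random_seq(rng, 21)
        seq = random_seq(rng, 100) + reverse_complement(srna) + random_seq(rng, 50)
        t = make_transcript(seq)
        arr = np.zeros(len(seq), dtype=np.int64)
        coord = 100 + 21 + 1 - 10
        arr[coord - 1] = 25
        arr[5] = 1
        profile = dg.CleavageProfile("t", len(seq), arr, arr.astype(float), arr / arr.sum())
        prediction = dg.predict_targets({"s": srna}, {"t": profile}, {"t": t}, n_perm=0)[0]
        tsv = tmp_path / "tplot.tsv"
        fig = tmp_path / "tplot.png"
        dg.export_tplot(profile, prediction, tsv, fig)
        table = pd.read_csv(tsv, sep="\t")
        assert len(table) == int((arr > 0).sum())
        assert table.loc[table["predicted_cleavage"], "position"].tolist() == [coord]
        assert fig.exists()
        # deterministic re-export
        tsv2 = tmp_path / "tplot2.tsv"
        dg.export_tplot(profile, prediction, tsv2)
        assert tsv.read_text() == tsv2.read_text()
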