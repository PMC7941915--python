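"""Preprocessing, collapsing, CPM and layered annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pistarve import annotation, simulate
from pistarve.io import FastqRead, TranscriptModel, read_fastq

ADAPTER = simulate.DEFAULT_ADAPTER


def _read(seq, qual=None):
    return FastqRead("r", seq, qual or "I" * len(seq))


class TestPreprocess:
    def test_insert_with_full_adapter_retained(self, rng):
        insert = "ACGTACGTACGTACGTACGTA"  # 21 nt
        kept, stats = annotation.preprocess_reads([_read(insert + ADAPTER)], ADAPTER)
        assert kept == [insert]
        assert stats["retained"] == 1

    def test_short_insert_discarded(self):
        insert = "ACGTACGTACGTACGTA"  # 17 nt, below minimum
        kept, stats = annotation.preprocess_reads([_read(insert + ADAPTER)], ADAPTER)
        assert kept == []
        assert stats["too_short"] == 1

    def test_low_quality_tail_trimmed_then_length_filtered(self):
        # 21-nt insert whose last 5 bases are unreliable: quality trimming
        # keeps the 16-nt high-quality segment, which then fails the filter
        insert = "ACGTACGTACGTACGTACGTA"
        qual = "I" * 16 + "#" * 5
        kept, stats = annotation.preprocess_reads([_read(insert, qual)], "TGGAATTCTC")
        assert kept == []
        assert stats["too_short"] == 1

    def test_mott_trim_keeps_max_scoring_segment(self):
        seq = "AAAACCCCGGGG"
        qual = "##" + "I" * 8 + "##"
        assert annotation.mott_trim(seq, qual, 0.02) == seq[2:10]

    def test_adapter_with_one_mismatch_per_ten_bases_trimmed(self):
        insert = "ACGTACGTACGTACGTACGTA"
        mutated = ADAPTER[:10] + ("A" if ADAPTER[10] != "A" else "C") + ADAPTER[11:]
        kept, _ = annotation.preprocess_reads([_read(insert + mutated)], ADAPTER)
        assert kept == [insert]

    def test_invalid_quality_limit_rejected(self):
        with pytest.raises(ValueError, match="quality_limit"):
            annotation.preprocess_reads([], ADAPTER, quality_limit=1.5)


class TestCollapseAndCpm:
    def test_truth_counts_recovered_exactly(self, small_config, bundle_truth, tmp_path):
        """Simulated error-free reads collapse back to the generator's truth."""
        bundle, truth = bundle_truth
        paths, truth_counts = simulate.simulate_srna_reads(bundle, truth, small_config, tmp_path)
        per_sample = {}
        for sample, path in paths.items():
            kept, _ = annotation.preprocess_reads(read_fastq(path), small_config.adapter)
            per_sample[sample] = kept
        unique = annotation.collapse_and_count(per_sample)
        samples = list(paths)
        recovered = unique[samples].reindex(truth_counts.index).fillna(0).astype(np.int64)
        pd.testing.assert_frame_equal(recovered, truth_counts.loc[recovered.index])
        assert set(unique.index) <= set(truth_counts.index)

    def test_union_with_zero_columns(self):
        unique = annotation.collapse_and_count({"a": ["ACGT" * 5], "b": ["TTTT" * 5]})
        assert unique.loc["ACGT" * 5, "b"] == 0
        assert unique.loc["TTTT" * 5, "a"] == 0

    def test_empty_sample_gives_zero_column(self):
        unique = annotation.collapse_and_count({"a": ["ACGT" * 5], "b": []})
        assert (unique["b"] == 0).all()

    def test_ids_ordered_by_total_then_lexicographic(self):
        unique = annotation.collapse_and_count({"a": ["CCCC" * 5] * 3 + ["AAAA" * 5, "TTTT" * 5]})
        assert list(unique.index) == ["CCCC" * 5, "AAAA" * 5, "TTTT" * 5]
        assert list(unique["id"]) == [1, 2, 3]

    def test_cpm_simple_case(self):
        unique = annotation.collapse_and_count({"a": ["ACGT" * 5] * 5 + ["TTTT" * 5] * 5})
        cpm = annotation.cpm_normalize(unique)
        assert (cpm["a"] == 500_000.0).all()

    def test_cpm_sums_to_one_million(self, srna_counts):
        table = srna_counts.copy()
        table.insert(0, "id", range(1, len(table) + 1))
        cpm = annotation.cpm_normalize(table)
        assert np.allclose(cpm.sum(axis=0), 1e6)

    @given(scale=st.integers(min_value=2, max_value=50))
    @settings(max_examples=20, deadline=None)
    def test_cpm_scale_invariance(self, scale):
        table = pd.DataFrame({"id": [1, 2], "a": [30, 70]}, index=["AAAA" * 5, "TTTT" * 5])
        doubled = table.copy()
        doubled["a"] *= scale
        pd.testing.assert_frame_equal(
            annotation.cpm_normalize(table), annotation.cpm_normalize(doubled)
        )

    def test_zero_total_sample_warns(self):
        table = pd.DataFrame({"id": [1], "a": [0]}, index=["AAAA" * 5])
        with pytest.warns(UserWarning, match="zero-total"):
            cpm = annotation.cpm_normalize(table)
        assert (cpm["a"] == 0).all()


def _unique_frame(seqs):
    return pd.DataFrame({"id": range(1, len(seqs) + 1)}, index=pd.Index(seqs, name="sequence"))


class TestMirbaseAnnotation:
    MATURE = {"miR-x": "ACGTACGTACGTACGTACGTA"}
    PRECURSOR = {"miR-x-pre": "GGGGG" + "ACGTACGTACGTACGTACGTA" + "CCCCC"}

    def test_exact_match_is_layer_exact(self):
        records = annotation.annotate_mirbase(
            _unique_frame([self.MATURE["miR-x"]]), self.MATURE, self.PRECURSOR
        )
        assert {r.layer for r in records} == {"mirbase_exact"}
        assert all(r.mismatches == 0 and r.match_strand == "sense" for r in records)

    def test_single_substitution_needs_mismatch_budget(self):
        variant = "TCGTACGTACGTACGTACGTA"
        frame = _unique_frame([variant])
        assert annotation.annotate_mirbase(frame, self.MATURE, self.PRECURSOR, 0) == []
        records = annotation.annotate_mirbase(frame, self.MATURE, self.PRECURSOR, 1)
        assert records and all(r.mismatches == 1 for r in records)

    def test_antisense_only_match_rejected(self):
        from pistarve.io import reverse_complement

        anti = reverse_complement(self.MATURE["miR-x"])
        assert annotation.annotate_mirbase(_unique_frame([anti]), self.MATURE, {}) == []


class TestIsomir:
    PRE = "GGGGG" + "ACGTACGTACGTACGTACGTA" + "CCCCC"
    POS = (6, 26)

    def test_exact_mature(self):
        call = annotation.classify_isomir("ACGTACGTACGTACGTACGTA", "m", self.PRE, self.POS)
        assert (call.five_prime_offset, call.three_prime_offset, call.kind) == (0, 0, "exact")

    def test_templated_three_prime_extension(self):
        call = annotation.classify_isomir("ACGTACGTACGTACGTACGTAC", "m", self.PRE, self.POS)
        assert (call.five_prime_offset, call.three_prime_offset, call.kind) == (0, 1, "isomiR")

    def test_missing_first_base(self):
        call = annotation.classify_isomir("CGTACGTACGTACGTACGTA", "m", self.PRE, self.POS)
        assert (call.five_prime_offset, call.three_prime_offset, call.kind) == (-1, 0, "isomiR")

    def test_not_in_precursor_gives_no_call(self):
        assert annotation.classify_isomir("T" * 21, "m", self.PRE, self.POS) is None


class TestCdnaClasses:
    @pytest.fixture()
    def transcripts(self):
        r = "ACGT" * 30
        return {
            "rrna1": TranscriptModel("rrna1", "rRNA", "1H", 120, r),
            "pc1": TranscriptModel("pc1", "protein-coding", "2H", 120, "TTGG" + r[:116]),
        }

    def test_fragment_assigned_to_class(self, transcripts):
        frag = transcripts["rrna1"].sequence[10:31]
        out = annotation.annotate_cdna_classes(_unique_frame([frag]), transcripts)
        assert list(out["cdna_class"]) == ["rRNA"]

    def test_shared_fragment_resolved_by_priority(self, transcripts):
        frag = transcripts["rrna1"].sequence[0:20]  # also inside pc1
        assert frag in transcripts["pc1"].sequence
        combined = annotation.annotate_cdna_classes(_unique_frame([frag]), transcripts)
        assert list(combined["cdna_class"]) == ["rRNA"]
        per_class = annotation.annotate_cdna_classes(
            _unique_frame([frag]), transcripts, mode="per-class"
        )
        assert set(per_class["cdna_class"]) == {"rRNA", "protein-coding"}

    def test_unmatched_sequence_unannotated(self, transcripts):
        out = annotation.annotate_cdna_classes(_unique_frame(["T" * 21]), transcripts)
        assert out["cdna_class"].isna().all()

    def test_combined_assignment_order_invariant(self, transcripts):
        frag = transcripts["rrna1"].sequence[0:20]
        reordered = dict(reversed(list(transcripts.items())))
        a = annotation.annotate_cdna_classes(_unique_frame([frag]), transcripts)
        b = annotation.annotate_cdna_classes(_unique_frame([frag]), reordered)
        pd.testing.assert_frame_equal(a, b)


class TestLayering:
    def test_layers_partition_every_sequence(self, small_config, bundle_truth, srna_counts):
        bundle, _ = bundle_truth
        unique = srna_counts.copy()
        unique.insert(0, "id", range(1, len(unique) + 1))
        layered = annotation.annotate_layered(
            unique, bundle.mature_mirnas, bundle.precursor_mirnas, bundle.transcripts
        )
        assert len(layered) == len(unique)
        assert set(layered["layer"]) <= set(annotation.LAYERS)
        # every mature sequence lands in the exact layer
        for mature in bundle.mature_mirnas.values():
            if mature in layered.index:
                assert layered.loc[mature, "layer"] == "mirbase_exact"
        # mismatch layer only carries 1-3 substitutions
        mm = layered[layered["layer"] == "mirbase_mismatch"]
        assert mm.empty or mm["mismatches"].between(1, 3).all()


class TestSummaries:
    def test_root_des_length_distribution_fraction(self):
        """274 sequences of length 18 among 1796 report as 15.26%."""
        seqs = ["A" * 18 + str(i).zfill(3)[:0] for i in range(274)]
        # build 1796 distinct sequences: 274 of length 18, rest spread 19-25
        seqs = [f"{'A' * 17}{chr(65 + i % 4)}" for i in range(274)]
        seqs = []
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        while len(seqs) < 274:
            s = "".join(bases[rng.integers(0, 4, 18)])
            if s not in seqs:
                seqs.append(s)
        remaining = 1796 - 274
        lengths = [19 + i % 7 for i in range(remaining)]
        seen = set(seqs)
        for L in lengths:
            while True:
                s = "".join(bases[rng.integers(0, 4, L)])
                if s not in seen:
                    seen.add(s)
                    seqs.append(s)
                    break
        frame = pd.DataFrame(
            {"cdna_class": [None] * len(seqs)}, index=pd.Index(seqs, name="sequence")
        )
        length_table, _ = annotation.summarize_distributions(frame)
        assert length_table.loc[18, "n"] == 274
        assert length_table.loc[18, "percent"] == 15.26

    def test_single_length_is_hundred_percent(self):
        frame = pd.DataFrame({"cdna_class": ["rRNA"]}, index=pd.Index(["A" * 20]))
        length_table, class_table = annotation.summarize_distributions(frame)
        assert length_table["percent"].tolist() == [100.0]
        assert class_table["percent"].tolist() == [100.0]

    def test_percentages_sum_to_hundred(self, bundle_truth, srna_counts):
        frame = pd.DataFrame(
            {"cdna_class": [None] * len(srna_counts)},
            index=srna_counts.index,
        )
        length_table, _ = annotation.summarize_distributions(frame)
        assert abs(length_table["percent"].sum() - 100.0) < 0.1

    def test_empty_set_gives_empty_tables(self):
        frame = pd.DataFrame({"cdna_class": []}, index=pd.Index([]))
        length_table, class_table = annotation.summarize_distributions(frame)
        assert length_table.empty and class_table.empty
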