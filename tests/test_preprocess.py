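"""Read cleaning: quality decoding, the seven rules, collapsing, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spidmir import preprocess
from spidmir.preprocess import (
    EncodingError,
    FilterParams,
    RawRead,
    classify_read,
    collapse_tags,
    decode_quality,
    filter_reads,
    find_adapter3,
    length_distribution,
    base_profiles,
    summarize_totals,
    tag_totals,
)

A3 = "TGGAATTCTCGGGTGCCAAGG"
A5 = "GTTCAGAGTTCTACAGTCCGACGATC"
HI = "h"  # phred64 quality 40


def _read(seq: str, qual: str | None = None, rid: str = "r1") -> RawRead:
    return RawRead(rid, seq, qual if qual is not None else HI * len(seq))


class TestDecodeQuality:
    @pytest.mark.parametrize(
        "char,encoding,expected",
        [("h", "phred64", 40), ("@", "phred64", 0), ("J", "phred64", 10),
         ("I", "phred33", 40), ("!", "phred33", 0)],
    )
    def test_offset_arithmetic(self, char, encoding, expected):
        assert decode_quality(char, encoding) == [expected]

    def test_out_of_range_suggests_other_encoding(self):
        with pytest.raises(EncodingError, match="phred33"):
            decode_quality("!", "phred64")  # decodes to -31
        with pytest.raises(EncodingError, match="phred64"):
            decode_quality("h", "phred33")  # decodes to 71

    def test_empty_quality_rejected(self):
        with pytest.raises(EncodingError):
            decode_quality("")


class TestFilterRules:
    def test_four_low_quality_bases_removed_three_kept(self):
        insert = "ACGTACGTACGTACGTACGT"
        seq = insert + A3
        bad4 = "I" * 4 + HI * (len(seq) - 4)  # 'I' = phred64 score 9
        bad3 = "I" * 3 + HI * (len(seq) - 3)
        params = FilterParams()
        assert classify_read(_read(seq, bad4), A3, A5, params)[0] == "low_quality"
        assert classify_read(_read(seq, bad3), A3, A5, params) == (None, insert)

    def test_n_fraction_strictly_greater_than_ten_percent(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTA"  # 29 nt
        seq = insert + A3  # 50 nt total
        five_n = "N" * 5 + seq[5:]  # exactly 10 %
        six_n = "N" * 6 + seq[6:]
        params = FilterParams()
        cat5, ins5 = classify_read(_read(five_n), A3, A5, params)
        assert cat5 is None and len(ins5) == 29
        assert classify_read(_read(six_n), A3, A5, params)[0] == "high_N"

    def test_rule_order_is_first_match(self):
        # a read that is low quality AND carries the 5' adapter is charged
        # to the earlier rule
        seq = (A5 + "ACGTACGTACGTACGTACGT" + A3)[:49]
        qual = "I" * 5 + HI * (len(seq) - 5)
        assert classify_read(_read(seq, qual), A3, A5, FilterParams())[0] == "low_quality"
        assert classify_read(_read(seq), A3, A5, FilterParams())[0] == "adapter5_contaminant"

    def test_insert_length_boundary(self):
        params = FilterParams()
        seq17 = "ACGTACGTACGTACGTC" + A3
        seq18 = "ACGTACGTACGTACGTCA" + A3
        assert classify_read(_read(seq17), A3, A5, params)[0] == "shorter_than_18nt"
        assert classify_read(_read(seq18), A3, A5, params) == (None, "ACGTACGTACGTACGTCA")

    def test_adapter_categories(self):
        params = FilterParams()
        assert classify_read(_read((A3 + "CGTATGCCG")[:30]), A3, A5, params)[0] == "insert_null"
        no_adapter = "ACGTC" * 10  # no adapter seed anywhere
        assert classify_read(_read(no_adapter), A3, A5, params)[0] == "adapter3_null"
        polya = "A" * 22 + A3
        assert classify_read(_read(polya), A3, A5, params)[0] == "polyA"

    def test_truncated_terminal_adapter_match(self):
        insert = "ACGTACGTACGTACGTACGT"
        seq = insert + A3[:8]  # adapter truncated by the read end, seed >= 6
        assert find_adapter3(seq, A3) == len(insert)
        assert classify_read(_read(seq), A3, A5, FilterParams()) == (None, insert)

    def test_false_seed_at_junction_is_skipped(self):
        # insert ends with a prefix of the adapter seed; the seed match that
        # spans the junction fails extension and the true position is found
        insert = "CCGTACGTACGTACGTGGAA"
        seq = insert + A3
        assert find_adapter3(seq, A3) == len(insert)

    def test_truncated_record_raises(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nhh\n")
        with pytest.raises(Exception):
            list(preprocess.read_fastq(path))


class TestAccountingClosure:
    def test_fuzzed_category_accounting_closes(self, rng):
        reads = []
        alphabet = np.array(list("ACGTN"))
        for i in range(400):
            n = int(rng.integers(20, 60))
            seq = "".join(rng.choice(alphabet, n, p=[0.23, 0.23, 0.23, 0.23, 0.08]))
            if rng.random() < 0.5:  # half get a real adapter at a random point
                cut = int(rng.integers(0, n))
                seq = seq[:cut] + A3 + seq[cut:]
            qual = "".join(
                chr(int(q) + 64) for q in rng.integers(0, 42, len(seq))
            )
            reads.append(RawRead(f"r{i}", seq, qual))
        _, report = filter_reads(reads, A3, A5)
        assert report.total_reads == 400
        assert report.high_quality == (
            report.total_reads
            - report.removed["low_quality"]
            - report.removed["high_N"]
        )
        structural = sum(
            report.removed[c]
            for c in preprocess.CATEGORIES
            if c not in ("low_quality", "high_N")
        )
        assert report.clean_reads == report.high_quality - structural
        assert report.clean_reads >= 0

    def test_synthetic_library_counts_match_manifest_exactly(
        self, small_cfg, filtered, manifest
    ):
        _, reports = filtered
        for lib in small_cfg.libraries:
            want = manifest["class_counts"][lib]
            rep = reports[lib]
            for cat in preprocess.CATEGORIES:
                assert rep.removed[cat] == want[cat], (lib, cat)
            assert rep.clean_reads == want["clean"]
            assert rep.total_reads == small_cfg.n_reads_per_library


class TestCollapseAndTotals:
    def test_collapse_counts(self):
        tags = collapse_tags({"CW": ["AAA"] * 3 + ["CCC"] * 2})
        assert tags.loc["AAA", "CW"] == 3
        assert tags.loc["CCC", "CW"] == 2
        totals = tag_totals(tags)
        assert totals.loc["CW", "total_reads"] == 5
        assert totals.loc["CW", "unique_reads"] == 2

    def test_grand_totals_and_mean_reads_per_unique(self):
        # clean totals of the four published cucumber libraries
        clean = {"CW": 10_865_804, "CS": 12_215_270, "HW": 10_854_344, "HS": 10_884_228}
        got = summarize_totals(clean, unique_total=3_882_844)
        assert got["total_reads"] == 44_819_646
        assert got["mean_reads_per_unique"] == 12

    def test_collapse_column_sums_equal_clean_totals(self, filtered, tags):
        inserts, reports = filtered
        for lib in tags.columns:
            assert int(tags[lib].sum()) == reports[lib].clean_reads


class TestLengthDistribution:
    def test_single_tag(self):
        tags = collapse_tags({"CW": ["A" * 21] * 10})
        dist = length_distribution(tags)
        assert dist.loc[21, "CW"] == 100.0

    def test_read_order_invariance(self, rng):
        inserts = ["ACGTACGTACGTACGTAC", "ACGTACGTACGTACGTACGTA"] * 30
        shuffled = list(inserts)
        rng.shuffle(shuffled)
        d1 = length_distribution(collapse_tags({"CW": inserts}))
        d2 = length_distribution(collapse_tags({"CW": shuffled}))
        pd.testing.assert_frame_equal(d1, d2)

    def test_percentages_sum_to_100(self, tags):
        sums = length_distribution(tags).sum(axis=0)
        assert np.allclose(sums, 100.0)

    def test_planted_21nt_share_within_binomial_error(self, tags, manifest):
        dist = length_distribution(tags)
        for lib in tags.columns:
            p = manifest["true_length_dist"][lib]["21"]
            n = int(tags[lib].sum())
            sd = 100.0 * np.sqrt(p * (1 - p) / n)
            assert abs(dist.loc[21, lib] - 100.0 * p) <= 3 * sd

    def test_empty_library_rejected(self):
        tags = collapse_tags({"CW": ["ACGTACGTACGTACGTAC"], "CS": []})
        with pytest.raises(Exception):
            length_distribution(tags)


class TestBaseProfiles:
    def test_homogeneous_reads(self):
        reads = [_read("AAAA")] * 5
        comp, quals = base_profiles(reads)
        assert (comp["A"] == 1.0).all()
        assert np.allclose(quals, 40.0)  # constant quality -> flat profile

    def test_uniform_composition_within_binomial_error(self, rng):
        n = 3000
        reads = [
            _read("".join(rng.choice(list("ACGT"), 30))) for _ in range(n)
        ]
        comp, _ = base_profiles(reads)
        sd = np.sqrt(0.25 * 0.75 / n)
        assert (abs(comp[list("ACGT")] - 0.25) <= 3.5 * sd).all().all()

    def test_fractions_sum_to_one(self, rng):
        reads = [_read("".join(rng.choice(list("ACGTN"), 25))) for _ in range(50)]
        comp, _ = base_profiles(reads)
        assert np.allclose(comp.sum(axis=1), 1.0)
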