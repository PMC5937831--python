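"""Genome mapping, category priority, known-miRNA matching, base bias."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spidmir import annotate
from spidmir._util import revcomp
from spidmir.annotate import (
    CATEGORY_PRIORITY,
    Feature,
    KnownMiRNA,
    base_bias,
    classify,
    map_to_genome,
    match_known_mirna,
    read_features_bed,
    read_features_gff3,
    write_features_bed,
    write_features_gff3,
)
from ._oracles import oracle_scan_genome


def _hits_as_tuples(hits):
    return sorted((h.chrom, h.start, h.end, h.strand) for h in hits)


class TestMapToGenome:
    def test_unique_plus_strand_hit(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 500))}
        tag = genome["chr1"][100:121]
        hits = map_to_genome([tag], genome)[tag]
        assert _hits_as_tuples(hits) == [("chr1", 100, 121, "+")] or (
            ("chr1", 100, 121, "+") in _hits_as_tuples(hits)
        )

    def test_reverse_complement_maps_minus_strand(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 500))}
        tag = revcomp(genome["chr1"][200:221])
        hits = map_to_genome([tag], genome)[tag]
        assert ("chr1", 200, 221, "-") in _hits_as_tuples(hits)

    def test_matches_naive_scan_on_random_genomes(self, rng):
        for _ in range(3):
            genome = {"chr1": "".join(rng.choice(list("ACGT"), 1000))}
            tags = set()
            for _ in range(30):  # planted (some as reverse complements)
                s = int(rng.integers(0, 980))
                t = genome["chr1"][s : s + 20]
                tags.add(t if rng.random() < 0.5 else revcomp(t))
            for _ in range(30):  # random, mostly absent
                tags.add("".join(rng.choice(list("ACGT"), 30)))
            hits = map_to_genome(sorted(tags), genome)
            for tag in tags:
                assert _hits_as_tuples(hits[tag]) == oracle_scan_genome(tag, genome)

    def test_invalid_characters_rejected(self):
        with pytest.raises(Exception, match="non-ACGTN"):
            map_to_genome(["ACGU"], {"chr1": "ACGT"})


class TestKnownMiRNAMatching:
    def setup_method(self):
        mature = "ACGTGCATGCTAGCTAGGCTA"  # 21 nt
        loop = "TTTTTTTTTTTT"
        self.mir = KnownMiRNA("miR-x", "miR-x", mature + loop + revcomp(mature), mature)

    def test_exact_mature_hits_with_full_overlap(self):
        hit = match_known_mirna(self.mir.mature, [self.mir])
        assert hit is not None
        assert hit.mature_overlap == 21
        assert hit.precursor_offset == 0

    def test_sixteen_nt_overlap_boundary(self):
        prec = self.mir.precursor
        # tag shifted so that it overlaps the mature region by exactly 15/16 nt
        tag15 = prec[6:27]  # overlap with [0, 21) is 15
        tag16 = prec[5:26]
        assert match_known_mirna(tag15, [self.mir]) is None
        hit = match_known_mirna(tag16, [self.mir])
        assert hit is not None and hit.mature_overlap == 16

    def test_single_mismatch_disqualifies(self):
        tag = "T" + self.mir.mature[1:]
        if tag != self.mir.mature:
            assert match_known_mirna(tag, [self.mir]) is None

    def test_result_independent_of_reference_order(self):
        other = KnownMiRNA(
            "miR-a", "miR-a",
            "GACCTAGGCTAGCTAGCATGC" + "AAAACCCC" + revcomp("GACCTAGGCTAGCTAGCATGC"),
            "GACCTAGGCTAGCTAGCATGC",
        )
        tag = self.mir.mature
        h1 = match_known_mirna(tag, [self.mir, other])
        h2 = match_known_mirna(tag, [other, self.mir])
        assert h1 == h2


class TestClassify:
    def _toy(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 300))}
        tag = genome["chr1"][50:71]
        tags = pd.DataFrame({"CW": [5], "CS": [3], "HW": [0], "HS": [1]},
                            index=pd.Index([tag], name="tag"))
        hits = map_to_genome([tag], genome)
        return genome, tag, tags, hits

    def test_priority_rrna_beats_exon(self, rng):
        genome, tag, tags, hits = self._toy(rng)
        features = [
            Feature("chr1", 40, 90, "+", "exon", "exon1"),
            Feature("chr1", 45, 80, "+", "rRNA", "rrna1"),
        ]
        assignments, _ = classify(tags, hits, features, [], genome)
        assert assignments[tag].category == "rRNA"

    def test_antisense_relative_to_feature_strand(self, rng):
        genome, tag, tags, hits = self._toy(rng)
        features = [Feature("chr1", 40, 90, "-", "exon", "exon1")]
        assignments, _ = classify(tags, hits, features, [], genome)
        assert assignments[tag].category == "exon_antisense"

    def test_feature_outside_genome_rejected(self, rng):
        genome, tag, tags, hits = self._toy(rng)
        bad = [Feature("chr1", 250, 400, "+", "exon", "exon1")]
        with pytest.raises(Exception):
            classify(tags, hits, bad, [], genome)

    def test_manifest_confusion_matrix_is_diagonal(self, annotated, manifest):
        _, assignments, _ = annotated
        truth = manifest["tag_sources"]
        mismatches = {
            t: (truth[t]["category"], a.category)
            for t, a in assignments.items()
            if truth[t]["category"] != a.category
        }
        assert mismatches == {}

    def test_summary_closure(self, tags, annotated, filtered):
        _, _, summary = annotated
        _, reports = filtered
        for lib in tags.columns:
            block = summary[lib]
            cat_reads = block.loc[list(CATEGORY_PRIORITY), "reads"].sum()
            cat_unique = block.loc[list(CATEGORY_PRIORITY), "unique"].sum()
            assert cat_reads == reports[lib].clean_reads
            assert cat_reads == block.loc["total", "reads"]
            assert cat_unique == block.loc["total", "unique"]
            assert cat_unique == int((tags[lib] > 0).sum())


class TestBaseBias:
    def test_uniform_first_base(self):
        counts = {"TACGTACGTACGTACGTACGT": 7, "TTTTACGTACGTACGTACGTA": 3}
        bias = base_bias(counts, "first_position_by_length")
        assert bias.loc[21, "T"] == 1.0

    def test_per_position_width_is_max_length(self):
        counts = {"ACGTACGTACGTACGTAC": 1, "ACGTACGTACGTACGTACGTACGTA": 1}
        table = base_bias(counts, "per_position")
        assert len(table) == 25
        assert np.allclose(table.sum(axis=1), 1.0)

    def test_planted_first_position_bias_recovered(self, rng):
        n = 2000
        counts = {}
        for i in range(n):
            first = "T" if rng.random() < 0.9 else "A"
            counts[first + "".join(rng.choice(list("ACGT"), 20))] = 1
        bias = base_bias(counts, "first_position_by_length", weighted=False)
        sd = np.sqrt(0.9 * 0.1 / n)
        assert abs(bias.loc[21, "T"] - 0.9) <= 3 * sd


class TestFeatureIO:
    def test_gff3_and_bed_round_trip(self, tmp_path):
        features = [
            Feature("chr1", 10, 50, "+", "rRNA", "r1"),
            Feature("chr1", 100, 150, "-", "exon", "e1"),
        ]
        gff = tmp_path / "f.gff3"
        bed = tmp_path / "f.bed"
        write_features_gff3(features, gff)
        write_features_bed(features, bed)
        assert read_features_gff3(gff) == features
        assert read_features_bed(bed) == features
        # conventions: GFF3 is 1-based closed, BED 0-based half-open
        gff_line = [l for l in gff.read_text().splitlines() if not l.startswith("#")][0]
        bed_line = bed.read_text().splitlines()[0]
        assert gff_line.split("\t")[3:5] == ["11", "50"]
        assert bed_line.split("\t")[1:3] == ["10", "50"]
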