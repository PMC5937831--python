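"""Target complementarity scoring, preset intersection, enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spidmir._util import revcomp
from spidmir.targets import (
    RELAXED,
    STRICT,
    hypergeom_enrich,
    predict_targets,
    score_target,
)
from ._oracles import oracle_hypergeom_upper, oracle_target_penalty

MIRNA = "TCGGACCAGGCTTCATTCCCC"  # 21 nt


def _window_with_state(mirna: str, position: int, state: str) -> str:
    """Perfect-complement window modified at one miRNA position (1-based)."""
    window = list(revcomp(mirna))
    idx = len(mirna) - position  # transcript partner of miRNA position
    m = mirna[position - 1]
    if state == "wobble":
        # miRNA G : target T, or miRNA T : target G
        assert m in "GT", "wobble requires G or U on the miRNA side"
        window[idx] = "T" if m == "G" else "G"
    elif state == "mismatch":
        window[idx] = m  # same base never pairs
    return "".join(window)


class TestScoreTarget:
    def test_perfect_complement_scores_zero(self):
        penalty, states = score_target(MIRNA, revcomp(MIRNA))
        assert penalty == 0.0
        assert set(states) == {"match"}

    def test_wobble_position_weighting(self):
        # position 20 (outside the 2-13 core): G:U costs 0.5
        pen20, _ = score_target("G" * 21, _window_with_state("G" * 21, 20, "wobble"))
        assert pen20 == 0.5
        # position 5 (inside the core): same wobble costs 1.0
        pen5, _ = score_target("G" * 21, _window_with_state("G" * 21, 5, "wobble"))
        assert pen5 == 1.0

    def test_mismatch_weighting(self):
        pen1, _ = score_target(MIRNA, _window_with_state(MIRNA, 1, "mismatch"))
        assert pen1 == 1.0
        pen10, _ = score_target(MIRNA, _window_with_state(MIRNA, 10, "mismatch"))
        assert pen10 == 2.0

    def test_matches_per_position_recount_on_random_pairs(self, rng):
        for _ in range(50):
            L = int(rng.integers(19, 24))
            m = "".join(rng.choice(list("ACGT"), L))
            w = "".join(rng.choice(list("ACGT"), L))
            penalty, _ = score_target(m, w)
            assert penalty == oracle_target_penalty(m, w)

    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception):
            score_target(MIRNA, "ACGT")


class TestPredictTargets:
    def _transcriptome(self, rng, site: str | None, n_extra: int = 5):
        tx = {
            f"gene{i:03d}": "".join(rng.choice(list("ACGT"), 200))
            for i in range(1, n_extra + 1)
        }
        if site is not None:
            seq = tx["gene001"]
            tx["gene001"] = seq[:80] + site + seq[80 + len(site):]
        return tx

    def test_planted_perfect_site_found_under_both_presets(self, rng):
        tx = self._transcriptome(rng, revcomp(MIRNA))
        hits = predict_targets({"mir": MIRNA}, tx)
        assert list(hits["gene"]) == ["gene001"]
        assert hits.iloc[0]["penalty"] == 0.0
        assert hits.iloc[0]["start"] == 81

    def test_site_passing_only_relaxed_is_dropped_by_intersection(self, rng):
        # penalty 4.5: one wobble at position 20 (0.5) plus four mismatches
        # outside the core -> relaxed (<=5.0) yes, strict (<=4.0) no
        mirna = "G" * 13 + "ACGTTGGA"  # core (2-13) is all G, matched below
        window = list(revcomp(mirna))
        L = len(mirna)
        for p in (14, 15, 16, 17):
            window[L - p] = mirna[p - 1]
        m19 = mirna[18]  # position 19 outside the core; make it a wobble
        window[L - 19] = "T" if m19 == "G" else "G"
        assert m19 in "GT"
        site = "".join(window)
        penalty, _ = score_target(mirna, site)
        assert penalty == 4.5
        tx = self._transcriptome(rng, site)
        only_relaxed = predict_targets({"mir": mirna}, tx, presets=(RELAXED,))
        both = predict_targets({"mir": mirna}, tx)
        assert list(only_relaxed["gene"]) == ["gene001"]
        assert both.empty

    def test_strict_forbids_slice_site_mismatch(self, rng):
        site = _window_with_state(MIRNA, 10, "mismatch")  # penalty 2.0 only
        tx = self._transcriptome(rng, site)
        strict_only = predict_targets({"mir": MIRNA}, tx, presets=(STRICT,))
        relaxed_only = predict_targets({"mir": MIRNA}, tx, presets=(RELAXED,))
        assert strict_only.empty
        assert list(relaxed_only["gene"]) == ["gene001"]

    def test_preset_order_does_not_matter(self, rng):
        tx = self._transcriptome(rng, revcomp(MIRNA))
        h1 = predict_targets({"mir": MIRNA}, tx, presets=(STRICT, RELAXED))
        h2 = predict_targets({"mir": MIRNA}, tx, presets=(RELAXED, STRICT))
        pd.testing.assert_frame_equal(h1, h2)

    def test_intersection_never_exceeds_single_presets(self, rng):
        tx = self._transcriptome(rng, revcomp(MIRNA), n_extra=8)
        inter = set(predict_targets({"mir": MIRNA}, tx)["gene"])
        for preset in (STRICT, RELAXED):
            single = set(predict_targets({"mir": MIRNA}, tx, presets=(preset,))["gene"])
            assert inter <= single

    def test_mirna_without_complementary_site_has_no_targets(self, rng):
        tx = self._transcriptome(rng, None)
        assert predict_targets({"mir": MIRNA}, tx).empty

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(Exception):
            predict_targets({"mir": MIRNA}, {})

    def test_planted_reference_sites_recovered(self, reference):
        mirnas = {
            m.name: m.mature
            for m in reference.known
            if m.name in reference.target_truth
        }
        hits = predict_targets(mirnas, reference.transcripts)
        got = {
            mir: sorted(hits.loc[hits["miRNA"] == mir, "gene"])
            for mir in mirnas
        }
        assert got == reference.target_truth


class TestHypergeomEnrich:
    def _setup(self, N, K, target):
        genes = [f"g{i}" for i in range(N)]
        term_map = pd.DataFrame(
            {"gene": genes[:K], "term": "T1", "term_class": "mf"}
        )
        return set(target), set(genes), term_map

    def test_exact_small_case(self):
        # N=10, K=4, n=5, k=4 -> C(4,4)*C(6,1)/C(10,5) = 6/252
        target, background, tm = self._setup(10, 4, [f"g{i}" for i in range(4)] + ["g9"])
        res = hypergeom_enrich(target, background, tm)
        assert res.iloc[0]["pvalue"] == pytest.approx(6 / 252, rel=1e-12)

    def test_matches_enumeration_oracle_for_small_backgrounds(self, rng):
        for N, K, n in [(8, 3, 4), (10, 4, 5), (12, 6, 5), (11, 2, 7)]:
            genes = [f"g{i}" for i in range(N)]
            target = set(rng.choice(genes, size=n, replace=False))
            tm = pd.DataFrame({"gene": genes[:K], "term": "T", "term_class": "c"})
            res = hypergeom_enrich(target, set(genes), tm)
            k = res.iloc[0]["k"]
            assert res.iloc[0]["pvalue"] == pytest.approx(
                oracle_hypergeom_upper(int(k), N, K, n), rel=1e-10
            )

    def test_zero_hits_gives_p_one(self):
        target, background, tm = self._setup(10, 4, ["g8", "g9"])
        res = hypergeom_enrich(target, background, tm)
        assert res.iloc[0]["k"] == 0
        assert res.iloc[0]["pvalue"] == 1.0

    def test_saturated_target_set(self):
        target, background, tm = self._setup(10, 4, [f"g{i}" for i in range(10)])
        res = hypergeom_enrich(target, background, tm)
        assert res.iloc[0]["k"] == res.iloc[0]["K"]
        assert res.iloc[0]["pvalue"] == 1.0

    def test_target_outside_background_rejected(self):
        with pytest.raises(Exception):
            hypergeom_enrich({"x"}, {"a"}, pd.DataFrame(
                {"gene": ["a"], "term": ["T"], "term_class": ["c"]}
            ))

    def test_bonferroni_is_not_more_permissive_than_bh(self, rng):
        genes = [f"g{i}" for i in range(40)]
        rows = []
        for t in range(6):
            members = rng.choice(genes, size=int(rng.integers(5, 15)), replace=False)
            rows += [{"gene": g, "term": f"T{t}", "term_class": "c"} for g in members]
        tm = pd.DataFrame(rows)
        target = set(genes[:10])
        bh = hypergeom_enrich(target, set(genes), tm, correction="fdr_bh")
        bonf = hypergeom_enrich(target, set(genes), tm, correction="bonferroni")
        assert set(bonf.loc[bonf["enriched"], "term"]) <= set(bh.loc[bh["enriched"], "term"])
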