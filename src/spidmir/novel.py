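"""Novel miRNA candidate prediction from unannotated genome-mapped tags.

A candidate precursor is a genomic window around an unannotated tag that
folds into a stem-loop.  Folding here is a deliberately simple,
deterministic hairpin model: the best *contiguous* antiparallel stem,
scored as -(Watson-Crick pairs + 0.5 * G:U wobble pairs), found by
exhaustive search over all pairings (i, j) with a loop of at least 3 nt
between the arms.  The score is a dimensionless stand-in for a minimum
folding free energy; an external thermodynamic folding engine can be
plugged in through the ``fold`` argument of :func:`call_candidates`.

A tag becomes a candidate mature miRNA when
  * at least ``min_pairs`` stem pairs fall inside the tag,
  * the loop is at least ``min_loop`` nt,
  * the pairing score is at or below ``score_max``, and
  * a tag boundary lies within ``max_end_distance`` nt of a stem end
    (a proxy for a Dicer cleavage site at the duplex end).

Candidates supported in only one library are discarded, and candidates
on overlapping loci are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from ._util import DataError
from .annotate import GenomeHit
from ._util import revcomp

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


@dataclass
class NovelParams:
    flank: int = 100  # nt of genomic context beyond the tag on one side
    min_window: int = 50
    min_loop: int = 3
    min_pairs: int = 14  # stem pairs required inside the mature tag
    score_max: float = -14.0
    max_end_distance: int = 3
    min_support: int = 5  # total reads across libraries to attempt folding


@dataclass
class Window:
    """A candidate precursor window (0-based half-open genome coords)."""

    chrom: str
    start: int
    end: int
    strand: str
    seq: str
    tag_offset: int  # tag position within seq
    tag_len: int
    truncated: bool = False


@dataclass
class StemFold:
    """Best contiguous stem of a window.

    ``outer5``/``outer3`` are window positions of the outermost pair;
    the stem pairs positions (outer5 + k) with (outer3 - k) for
    k in [0, length).
    """

    score: float
    paired: int
    outer5: int
    outer3: int
    length: int


@dataclass
class HairpinCandidate:
    cand_id: str
    chrom: str
    start: int
    end: int
    strand: str
    precursor: str
    mature: str
    mature_span: tuple[int, int]  # genome coords
    star_span: tuple[int, int]
    paired: int
    score: float
    counts: dict[str, int] = field(default_factory=dict)
    support_tags: tuple[str, ...] = ()


def _pair_weight(a: str, b: str) -> float:
    if (a, b) in _WC:
        return 1.0
    if (a, b) in _GU:
        return 0.5
    return 0.0


def extract_precursor_windows(
    hit: GenomeHit, genome: Mapping[str, str], flank: int = 100
) -> list[Window]:
    """Windows extending the tag by ``flank`` nt up- or downstream.

    Two variants are produced so that the tag may sit on either hairpin
    arm.  Windows truncated at a contig edge are shrunk and flagged.
    For minus-strand hits the window sequence is the reverse complement,
    so the tag always reads 5'->3' inside the window.
    """
    seq = genome[hit.chrom]
    out = []
    for lo, hi in ((hit.start - flank, hit.end), (hit.start, hit.end + flank)):
        trunc = lo < 0 or hi > len(seq)
        lo_c, hi_c = max(lo, 0), min(hi, len(seq))
        wseq = seq[lo_c:hi_c]
        if hit.strand == "+":
            tag_offset = hit.start - lo_c
        else:
            wseq = revcomp(wseq)
            tag_offset = hi_c - hit.end
        out.append(
            Window(
                hit.chrom, lo_c, hi_c, hit.strand, wseq,
                tag_offset, hit.end - hit.start, trunc,
            )
        )
    return out


def fold_and_score(seq: str, min_loop: int = 3) -> StemFold:
    """Best contiguous antiparallel stem by exhaustive pairing search.

    Considers every pairing of position ``a`` with position ``b`` (a < b,
    b - a - 1 >= min_loop) and every maximal run of consecutive pairs
    (a+k, b-k).  Watson-Crick pairs weigh 1, G:U wobbles 0.5, and any
    non-pairing position terminates the stem.  Returns the stem with the
    most negative score; ties prefer the longer stem, then the leftmost.
    """
    n = len(seq)
    best = StemFold(0.0, 0, 0, 0, 0)
    for d in range(min_loop + 1, 2 * n - 3):  # d = a + b
        a_lo = max(0, d - n + 1)
        a_hi = (d - min_loop - 1) // 2  # innermost a with loop >= min_loop
        run_w, run_n, run_start = 0.0, 0, a_lo
        for a in range(a_lo, a_hi + 1):
            b = d - a
            w = _pair_weight(seq[a], seq[b])
            if w == 0.0:
                run_w, run_n, run_start = 0.0, 0, a + 1
                continue
            if run_n == 0:
                run_start = a
            run_w += w
            run_n += 1
            cand = StemFold(-run_w, run_n, run_start, d - run_start, run_n)
            if (cand.score, -cand.length, cand.outer5) < (
                best.score, -best.length, best.outer5
            ):
                best = cand
    return best


def _stem_positions(fold: StemFold) -> tuple[set[int], set[int]]:
    """Window positions of the 5' and 3' stem arms."""
    arm5 = set(range(fold.outer5, fold.outer5 + fold.length))
    arm3 = set(range(fold.outer3 - fold.length + 1, fold.outer3 + 1))
    return arm5, arm3


def evaluate_window(
    window: Window,
    params: NovelParams,
    fold: Callable[[str], StemFold] | None = None,
) -> tuple[StemFold, int, int] | None:
    """Fold one window and test the candidate criteria.

    Returns ``(fold, pairs_in_tag, end_distance)`` when the window
    qualifies, else None.  Windows shorter than ``min_window`` are
    skipped.
    """
    if len(window.seq) < params.min_window:
        return None
    folder = fold or (lambda s: fold_and_score(s, params.min_loop))
    sf = folder(window.seq)
    if sf.length == 0 or sf.score > params.score_max:
        return None
    arm5, arm3 = _stem_positions(sf)
    tag_pos = set(range(window.tag_offset, window.tag_offset + window.tag_len))
    pairs_in_tag = max(len(tag_pos & arm5), len(tag_pos & arm3))
    if pairs_in_tag < params.min_pairs:
        return None
    end_distance = min(
        abs(window.tag_offset - sf.outer5),
        abs((window.tag_offset + window.tag_len - 1) - sf.outer3),
    )
    if end_distance > params.max_end_distance:
        return None
    return sf, pairs_in_tag, end_distance


def call_candidates(
    tag_hits: Mapping[str, Sequence[GenomeHit]],
    tag_counts: pd.DataFrame,
    genome: Mapping[str, str],
    params: NovelParams | None = None,
    fold: Callable[[str], StemFold] | None = None,
) -> list[HairpinCandidate]:
    """Predict hairpin candidates from unannotated mapped tags.

    ``tag_hits`` should contain only tags classified as unannotated that
    have at least one genome hit.  Candidates expressed in fewer than
    two libraries are removed, and candidates whose precursor loci
    overlap are merged (support summed over distinct tags, best-scoring
    locus kept as representative).
    """
    params = params or NovelParams()
    raw: list[HairpinCandidate] = []
    for tag in sorted(tag_hits):
        counts = tag_counts.loc[tag] if tag in tag_counts.index else None
        if counts is None or int(counts.sum()) < params.min_support:
            continue
        for hit in tag_hits[tag]:
            for window in extract_precursor_windows(hit, genome, params.flank):
                res = evaluate_window(window, params, fold)
                if res is None:
                    continue
                sf, pairs_in_tag, _ = res
                # genome coordinates of the folded hairpin
                if window.strand == "+":
                    g5 = window.start + sf.outer5
                    g3 = window.start + sf.outer3
                else:
                    g5 = window.end - 1 - sf.outer3
                    g3 = window.end - 1 - sf.outer5
                lo, hi = min(g5, g3), max(g5, g3) + 1
                arm5, arm3 = _stem_positions(sf)
                tag_pos = set(
                    range(window.tag_offset, window.tag_offset + window.tag_len)
                )
                mature_arm = arm5 if len(tag_pos & arm5) >= len(tag_pos & arm3) else arm3
                star_arm = arm3 if mature_arm is arm5 else arm5
                star_lo, star_hi = min(star_arm), max(star_arm) + 1
                if window.strand == "+":
                    star_span = (window.start + star_lo, window.start + star_hi)
                else:
                    star_span = (window.end - star_hi, window.end - star_lo)
                raw.append(
                    HairpinCandidate(
                        cand_id="",
                        chrom=hit.chrom,
                        start=lo,
                        end=hi,
                        strand=hit.strand,
                        precursor=window.seq[sf.outer5 : sf.outer3 + 1],
                        mature=tag,
                        mature_span=(hit.start, hit.end),
                        star_span=star_span,
                        paired=sf.length,
                        score=sf.score,
                        counts={
                            lib: int(counts[lib]) for lib in tag_counts.columns
                        },
                        support_tags=(tag,),
                    )
                )
                break  # one qualifying window per hit is enough
    merged = _merge_overlapping(raw)
    kept = [
        c for c in merged if sum(1 for v in c.counts.values() if v > 0) >= 2
    ]
    for i, c in enumerate(sorted(kept, key=lambda c: (c.chrom, c.start)), start=1):
        c.cand_id = f"novel-mir-{i}"
    return sorted(kept, key=lambda c: (c.chrom, c.start))


def _merge_overlapping(cands: list[HairpinCandidate]) -> list[HairpinCandidate]:
    """Merge candidates whose loci overlap on the same contig.

    The best-scoring (then longest-stem) candidate represents the merged
    locus; read counts are summed over the distinct supporting tags.
    """
    by_chrom: dict[str, list[HairpinCandidate]] = {}
    for c in cands:
        by_chrom.setdefault(c.chrom, []).append(c)
    out: list[HairpinCandidate] = []
    for chrom in sorted(by_chrom):
        group: list[HairpinCandidate] = []
        hi = -1
        for c in sorted(by_chrom[chrom], key=lambda c: c.start):
            if group and c.start >= hi:
                out.append(_merge_group(group))
                group = []
                hi = -1
            group.append(c)
            hi = max(hi, c.end)
        if group:
            out.append(_merge_group(group))
    return out


def _merge_group(group: list[HairpinCandidate]) -> HairpinCandidate:
    rep = min(group, key=lambda c: (c.score, -c.paired, c.start))
    tags: dict[str, dict[str, int]] = {}
    for c in group:
        for t in c.support_tags:
            tags[t] = c.counts
    counts: dict[str, int] = {}
    for t in sorted(tags):
        for lib, n in tags[t].items():
            counts[lib] = counts.get(lib, 0) + n
    rep.counts = counts
    rep.support_tags = tuple(sorted(tags))
    rep.start = min(c.start for c in group)
    rep.end = max(c.end for c in group)
    return rep


def candidate_counts(cands: Sequence[HairpinCandidate], libraries) -> pd.DataFrame:
    """Expression matrix rows for novel candidates."""
    data = {
        c.cand_id: [c.counts.get(lib, 0) for lib in libraries] for c in cands
    }
    out = pd.DataFrame(data, index=list(libraries)).T
    out.index.name = "miRNA"
    return out


def candidates_to_frame(cands: Sequence[HairpinCandidate]) -> pd.DataFrame:
    rows = []
    for c in cands:
        row = {
            "id": c.cand_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "score": c.score,
            "paired": c.paired,
            "mature": c.mature,
        }
        row.update(c.counts)
        rows.append(row)
    return pd.DataFrame(rows)
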