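"""Raw small-RNA read filtering, tag collapsing and library summaries.

Raw HiSeq-era small RNA reads are an 18-30 nt insert followed by the 3'
sequencing adapter.  Cleaning applies seven rules in a fixed order, each
read being charged to the *first* rule it fails, so the removal categories
partition the input exactly:

  (1) low quality    : >= 4 bases with quality < 10
  (2) high N         : > 10 % of bases undetermined (N)
  (3) 5' contaminant : the 5' adapter occurs in the read
  (4) insert null    : the 3' adapter starts at position 0 (no insert)
  (5) 3' adapter null: no 3' adapter match anywhere in the read
  (6) poly(A)        : trimmed insert is >= 80 % adenine
  (7) too short      : trimmed insert shorter than 18 nt

Survivors are emitted as trimmed inserts ("clean reads") and collapsed
into unique tags with per-library read counts, the unit every downstream
stage works on.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import DataError, percent, round_half_up

#: removal categories in rule order; also the row order of the cleaning report
CATEGORIES = (
    "low_quality",
    "high_N",
    "adapter5_contaminant",
    "insert_null",
    "adapter3_null",
    "polyA",
    "shorter_than_18nt",
)

#: human-readable row labels for the cleaning report table
CATEGORY_LABELS = {
    "low_quality": "Low quality",
    "high_N": "High N",
    "adapter5_contaminant": "5'adapter contaminants",
    "insert_null": "Insert null",
    "adapter3_null": "3'adapter null",
    "polyA": "Poly(A)",
    "shorter_than_18nt": "Smaller than 18 nt",
}

QUALITY_OFFSETS = {"phred64": 64, "phred33": 33}
QUALITY_MAX = 41


class EncodingError(DataError):
    """Quality string inconsistent with the declared encoding."""


def decode_quality(quality: str, encoding: str = "phred64") -> list[int]:
    """Decode a FASTQ quality string into integer phred scores.

    The score of each base is the ASCII value of its character minus the
    encoding offset (64 for phred64, 33 for phred33).  HiSeq qualities
    range from 0 to 41; a value outside that range raises
    :class:`EncodingError` suggesting the other encoding.
    """
    if not quality:
        raise EncodingError("empty quality string")
    try:
        offset = QUALITY_OFFSETS[encoding]
    except KeyError:
        raise EncodingError(f"unknown quality encoding {encoding!r}") from None
    other = "phred33" if encoding == "phred64" else "phred64"
    scores = [ord(c) - offset for c in quality]
    for c, q in zip(quality, scores):
        if q < 0 or q > QUALITY_MAX:
            raise EncodingError(
                f"quality character {c!r} decodes to {q} under {encoding} "
                f"(valid range 0-{QUALITY_MAX}); is the file {other}?"
            )
    return scores


@dataclass
class RawRead:
    """One FASTQ record: id, nucleotide sequence and quality string."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise DataError(
                f"read {self.id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass
class FilterParams:
    """Thresholds for the seven cleaning rules."""

    encoding: str = "phred64"
    low_quality_threshold: int = 10  # a base is "low quality" below this score
    max_low_quality_bases: int = 3  # 4 or more such bases remove the read
    max_n_fraction: float = 0.10  # strictly more than 10 % N removes the read
    adapter3_seed: int = 6  # minimum terminal adapter match length
    polya_fraction: float = 0.80  # insert with >= 80 % A is poly(A)
    min_insert_length: int = 18


@dataclass
class FilterReport:
    """Removal accounting for one library, mirroring published cleaning tables.

    ``high_quality`` reads are those surviving the two per-base quality
    rules; the adapter/structure categories and the clean total are
    reported as percentages of ``high_quality`` (which is itself the
    100 % row of the table).
    """

    total_reads: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CATEGORIES}
    )

    @property
    def high_quality(self) -> int:
        return (
            self.total_reads
            - self.removed["low_quality"]
            - self.removed["high_N"]
        )

    @property
    def clean_reads(self) -> int:
        structural = sum(
            self.removed[c] for c in CATEGORIES if c not in ("low_quality", "high_N")
        )
        return self.high_quality - structural

    @classmethod
    def from_counts(
        cls, total_reads: int, removed: Mapping[str, int]
    ) -> "FilterReport":
        """Build a report from already-tallied per-category counts."""
        rep = cls(total_reads=total_reads)
        for cat, n in removed.items():
            if cat not in rep.removed:
                raise DataError(f"unknown removal category {cat!r}")
            rep.removed[cat] = int(n)
        return rep

    def percentages(self) -> dict[str, float]:
        """Category percentages of high-quality reads, half-up to 2 decimals."""
        hq = self.high_quality
        out = {"high_quality": percent(hq, hq)}
        for cat in CATEGORIES:
            if cat in ("low_quality", "high_N"):
                continue
            out[cat] = percent(self.removed[cat], hq)
        out["clean_reads"] = percent(self.clean_reads, hq)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Cleaning table: one row per category with count and percent."""
        pct = self.percentages()
        rows = [("Total reads", self.total_reads, float("nan"))]
        rows.append(("High quality", self.high_quality, pct["high_quality"]))
        for cat in (
            "adapter3_null",
            "insert_null",
            "adapter5_contaminant",
            "shorter_than_18nt",
            "polyA",
        ):
            rows.append((CATEGORY_LABELS[cat], self.removed[cat], pct[cat]))
        rows.append(("Clean reads", self.clean_reads, pct["clean_reads"]))
        return pd.DataFrame(rows, columns=["type", "count", "percent"])


def read_fastq(path) -> Iterator[RawRead]:
    """Stream FASTQ records without quality validation (done by the filter)."""
    with open(path) as handle:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
            if len(seq) != len(qual):
                raise DataError(f"truncated FASTQ record at index {i} ({title})")
            yield RawRead(title.split()[0], seq.upper(), qual)


def find_adapter3(sequence: str, adapter3: str, seed: int = 6) -> int:
    """Leftmost position where the 3' adapter starts, or -1.

    A match is an exact prefix of the adapter, allowed to be truncated by
    the end of the read as long as at least ``seed`` nucleotides match.
    """
    if not adapter3:
        raise DataError("empty 3' adapter")
    probe = adapter3[: min(seed, len(adapter3))]
    start = 0
    while True:
        j = sequence.find(probe, start)
        if j < 0:
            return -1
        k = min(len(adapter3), len(sequence) - j)
        if k >= len(probe) and sequence[j : j + k] == adapter3[:k]:
            return j
        start = j + 1


def classify_read(
    read: RawRead,
    adapter3: str,
    adapter5: str,
    params: FilterParams,
) -> tuple[str | None, str | None]:
    """Apply the seven rules in order.

    Returns ``(category, None)`` for a removed read or ``(None, insert)``
    for a clean read with its trimmed insert.
    """
    seq = read.sequence
    # (1) low quality
    scores = decode_quality(read.quality, params.encoding)
    n_low = sum(q < params.low_quality_threshold for q in scores)
    if n_low > params.max_low_quality_bases:
        return "low_quality", None
    # (2) proportion of N
    if seq.count("N") / len(seq) > params.max_n_fraction:
        return "high_N", None
    # (3) 5' primer contamination
    if adapter5 and adapter5 in seq:
        return "adapter5_contaminant", None
    # (4)/(5) insert and 3' adapter presence
    pos = find_adapter3(seq, adapter3, params.adapter3_seed)
    if pos == 0:
        return "insert_null", None
    if pos < 0:
        return "adapter3_null", None
    insert = seq[:pos]
    # (6) poly(A)
    if insert.count("A") / len(insert) >= params.polya_fraction:
        return "polyA", None
    # (7) length
    if len(insert) < params.min_insert_length:
        return "shorter_than_18nt", None
    return None, insert


def filter_reads(
    reads: Iterable[RawRead],
    adapter3: str,
    adapter5: str = "",
    params: FilterParams | None = None,
) -> tuple[list[str], FilterReport]:
    """Run the cleaning rules over a library.

    Returns the clean trimmed inserts (in input order) and the
    :class:`FilterReport` whose category accounting closes exactly.
    """
    params = params or FilterParams()
    report = FilterReport()
    inserts: list[str] = []
    for read in reads:
        report.total_reads += 1
        category, insert = classify_read(read, adapter3, adapter5, params)
        if category is None:
            inserts.append(insert)  # type: ignore[arg-type]
        else:
            report.removed[category] += 1
    return inserts, report


def collapse_tags(inserts_per_library: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Collapse identical inserts into unique tags with per-library counts.

    Returns a DataFrame indexed by tag sequence with one integer column
    per library; column sums equal the clean-read totals.
    """
    libraries = list(inserts_per_library)
    counters = {
        lib: collections.Counter(inserts_per_library[lib]) for lib in libraries
    }
    tags = sorted(set().union(*(c.keys() for c in counters.values())))
    data = {
        lib: np.array([counters[lib].get(t, 0) for t in tags], dtype=np.int64)
        for lib in libraries
    }
    return pd.DataFrame(data, index=pd.Index(tags, name="tag"))


def tag_totals(tags: pd.DataFrame) -> pd.DataFrame:
    """Per-library totals: clean reads, unique tags, mean reads per tag."""
    rows = []
    for lib in tags.columns:
        total = int(tags[lib].sum())
        unique = int((tags[lib] > 0).sum())
        mean = int(round_half_up(total / unique, 0)) if unique else 0
        rows.append((lib, total, unique, mean))
    return pd.DataFrame(
        rows, columns=["library", "total_reads", "unique_reads", "mean_reads_per_tag"]
    ).set_index("library")


def summarize_totals(
    clean_totals: Mapping[str, int], unique_total: int
) -> dict[str, int]:
    """Grand totals over libraries: total sRNA reads and mean reads per
    unique sequence (rounded to the nearest integer, half up)."""
    grand = int(sum(clean_totals.values()))
    if unique_total <= 0:
        raise DataError("unique_total must be positive")
    return {
        "total_reads": grand,
        "unique_reads": int(unique_total),
        "mean_reads_per_unique": int(round_half_up(grand / unique_total, 0)),
    }


def length_distribution(tags: pd.DataFrame) -> pd.DataFrame:
    """Per-library percentage of clean *reads* by insert length.

    Percentages are over read counts, not unique tags, and sum to 100
    per library up to rounding.
    """
    if tags.empty:
        raise DataError("no tags: cannot compute a length distribution")
    lengths = tags.index.str.len()
    by_len = tags.groupby(lengths).sum()
    by_len.index.name = "length"
    totals = tags.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise DataError(f"empty libraries: {empty}")
    return 100.0 * by_len / totals


def base_profiles(
    reads: Sequence[RawRead], encoding: str = "phred64"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-position base composition and mean quality over a read set.

    Returns ``(composition, mean_quality)`` where composition rows are
    positions (0-based) with fractional columns A/C/G/T/N summing to 1,
    and ``mean_quality`` is the positionwise mean phred score.  Reads may
    have unequal lengths; each position averages over the reads covering it.
    """
    if not reads:
        raise DataError("no reads")
    maxlen = max(len(r.sequence) for r in reads)
    bases = "ACGTN"
    counts = np.zeros((maxlen, len(bases)), dtype=np.int64)
    qual_sum = np.zeros(maxlen)
    depth = np.zeros(maxlen, dtype=np.int64)
    lut = {b: i for i, b in enumerate(bases)}
    for r in reads:
        scores = decode_quality(r.quality, encoding)
        for pos, (b, q) in enumerate(zip(r.sequence, scores)):
            counts[pos, lut.get(b, lut["N"])] += 1
            qual_sum[pos] += q
            depth[pos] += 1
    comp = pd.DataFrame(
        counts / depth[:, None], columns=list(bases)
    )
    comp.index.name = "position"
    return comp, qual_sum / depth
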