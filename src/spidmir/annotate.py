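"""Hierarchical classification of unique tags against genome and references.

Tags are mapped to the genome exactly (no mismatches, both strands), then
assigned a single category by priority:

    rRNA > snRNA > snoRNA > tRNA > repeat
         > exon (sense, antisense) > intron (sense, antisense)
         > known miRNA > unannotated

The priority mirrors the usual small-RNA annotation order in which
structural RNA, repeat and mRNA-degradation matches are removed before
miRNA identification.  A tag counts as a known miRNA when it is a perfect
substring of a reference precursor and overlaps the annotated mature
sequence by at least 16 nt.

Coordinates are 0-based half-open internally; GFF3 (1-based closed) and
BED (0-based half-open) conventions are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

from ._util import DataError, percent, revcomp

CATEGORY_PRIORITY = (
    "rRNA",
    "snRNA",
    "snoRNA",
    "tRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "miRNA_known",
    "unannotated",
)

#: feature types that ignore strand when classifying
_UNSTRANDED = {"rRNA", "snRNA", "snoRNA", "tRNA", "repeat"}
#: feature types classified relative to the feature strand
_STRANDED = {"exon", "intron"}


@dataclass(frozen=True)
class Feature:
    """A genomic feature interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    ftype: str
    fid: str


@dataclass(frozen=True)
class GenomeHit:
    """An exact occurrence of a tag in the genome.

    The interval is always given on the plus strand; ``strand`` is '-'
    when the reverse complement of the tag matches there.
    """

    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class KnownMiRNA:
    name: str
    family: str
    precursor: str
    mature: str
    mature_offset: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.mature_offset < 0:
            self.mature_offset = self.precursor.find(self.mature)
        if self.mature_offset < 0:
            raise DataError(
                f"{self.name}: mature sequence is not a substring of precursor"
            )


@dataclass(frozen=True)
class KnownMiRNAHit:
    tag: str
    name: str
    family: str
    precursor_offset: int
    mature_overlap: int


@dataclass
class CategoryAssignment:
    tag: str
    category: str
    hits: tuple[GenomeHit, ...] = ()
    ref_id: str | None = None


# ---------------------------------------------------------------------------
# genome mapping


def map_to_genome(
    tags: Iterable[str], genome: Mapping[str, str]
) -> dict[str, list[GenomeHit]]:
    """Exact mapping of tags to both genome strands.

    Every zero-mismatch occurrence is reported.  Reverse-strand hits are
    found by searching the reverse complement of the tag on the plus
    strand.  Tags containing characters outside ACGTN are rejected.
    """
    hits: dict[str, list[GenomeHit]] = {}
    for tag in tags:
        if set(tag) - set("ACGTN"):
            raise DataError(f"tag {tag!r} contains non-ACGTN characters")
        found: list[GenomeHit] = []
        for chrom, seq in genome.items():
            for strand, probe in (("+", tag), ("-", revcomp(tag))):
                start = seq.find(probe)
                while start >= 0:
                    found.append(GenomeHit(chrom, start, start + len(tag), strand))
                    start = seq.find(probe, start + 1)
        found.sort(key=lambda h: (h.chrom, h.start, h.strand))
        hits[tag] = found
    return hits


def mapping_summary(
    tags: pd.DataFrame, hits: Mapping[str, list[GenomeHit]]
) -> pd.DataFrame:
    """Mapped reads/types counts and percentages per library."""
    mapped = tags.index.to_series().map(lambda t: len(hits.get(t, [])) > 0)
    rows = []
    for lib in tags.columns:
        counts = tags[lib]
        total_reads = int(counts.sum())
        total_types = int((counts > 0).sum())
        mapped_reads = int(counts[mapped].sum())
        mapped_types = int(((counts > 0) & mapped).sum())
        rows.append(
            (
                lib,
                mapped_reads,
                percent(mapped_reads, total_reads) if total_reads else 0.0,
                mapped_types,
                percent(mapped_types, total_types) if total_types else 0.0,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["library", "mapped_reads", "mapped_reads_pct",
                 "mapped_types", "mapped_types_pct"],
    ).set_index("library")


# ---------------------------------------------------------------------------
# known miRNA matching

MIN_MATURE_OVERLAP = 16


def match_known_mirna(
    tag: str, known: Sequence[KnownMiRNA], min_overlap: int = MIN_MATURE_OVERLAP
) -> KnownMiRNAHit | None:
    """Perfect-substring match of a tag to a reference precursor.

    A hit requires the tag to occur verbatim in the precursor and to
    overlap the annotated mature sequence by at least ``min_overlap`` nt.
    Ties are broken by longest mature overlap, then miRNA name.
    """
    best: KnownMiRNAHit | None = None
    for m in known:
        start = m.precursor.find(tag)
        while start >= 0:
            mat_lo, mat_hi = m.mature_offset, m.mature_offset + len(m.mature)
            overlap = min(start + len(tag), mat_hi) - max(start, mat_lo)
            if overlap >= min_overlap:
                cand = KnownMiRNAHit(tag, m.name, m.family, start, overlap)
                if (
                    best is None
                    or cand.mature_overlap > best.mature_overlap
                    or (
                        cand.mature_overlap == best.mature_overlap
                        and cand.name < best.name
                    )
                ):
                    best = cand
            start = m.precursor.find(tag, start + 1)
    return best


# ---------------------------------------------------------------------------
# classification


def _feature_trees(
    features: Sequence[Feature], genome: Mapping[str, str]
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        if f.chrom not in genome:
            raise DataError(f"feature {f.fid} on unknown contig {f.chrom}")
        if f.start < 0 or f.end > len(genome[f.chrom]) or f.start >= f.end:
            raise DataError(
                f"feature {f.fid} interval [{f.start},{f.end}) outside "
                f"{f.chrom} (length {len(genome[f.chrom])})"
            )
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return trees


def classify(
    tags: pd.DataFrame,
    hits: Mapping[str, list[GenomeHit]],
    features: Sequence[Feature],
    known: Sequence[KnownMiRNA],
    genome: Mapping[str, str],
) -> tuple[dict[str, CategoryAssignment], pd.DataFrame]:
    """Assign every tag to exactly one category.

    Returns the per-tag assignments and a classification summary in the
    shape of the usual annotation table: per library, unique-tag and
    read counts with percentages of the library totals, including a
    total row.  Category totals close exactly against the clean totals.
    """
    trees = _feature_trees(features, genome)
    assignments: dict[str, CategoryAssignment] = {}
    for tag in tags.index:
        tag_hits = tuple(hits.get(tag, ()))
        best_rank = CATEGORY_PRIORITY.index("unannotated")
        ref_id = None
        for h in tag_hits:
            tree = trees.get(h.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(h.start, h.end):
                f: Feature = iv.data
                if f.ftype in _UNSTRANDED:
                    cat = f.ftype
                elif f.ftype in _STRANDED:
                    rel = "sense" if h.strand == f.strand else "antisense"
                    cat = f"{f.ftype}_{rel}"
                else:
                    continue  # e.g. miRNA precursor annotations: not a bucket
                rank = CATEGORY_PRIORITY.index(cat)
                if rank < best_rank:
                    best_rank, ref_id = rank, f.fid
        if best_rank == CATEGORY_PRIORITY.index("unannotated"):
            mhit = match_known_mirna(tag, known)
            if mhit is not None:
                best_rank = CATEGORY_PRIORITY.index("miRNA_known")
                ref_id = mhit.name
        assignments[tag] = CategoryAssignment(
            tag, CATEGORY_PRIORITY[best_rank], tag_hits, ref_id
        )
    return assignments, category_summary(tags, assignments)


def category_summary(
    tags: pd.DataFrame, assignments: Mapping[str, CategoryAssignment]
) -> pd.DataFrame:
    """Per-library category table with unique/read counts and percentages."""
    cats = pd.Series({t: a.category for t, a in assignments.items()})
    cats = cats.reindex(tags.index)
    blocks = {}
    for lib in tags.columns:
        counts = tags[lib]
        lib_reads = int(counts.sum())
        lib_unique = int((counts > 0).sum())
        reads_by_cat = counts.groupby(cats).sum()
        unique_by_cat = (counts > 0).groupby(cats).sum()
        rows = []
        for cat in CATEGORY_PRIORITY:
            r = int(reads_by_cat.get(cat, 0))
            u = int(unique_by_cat.get(cat, 0))
            rows.append(
                (
                    u,
                    percent(u, lib_unique) if lib_unique else 0.0,
                    r,
                    percent(r, lib_reads) if lib_reads else 0.0,
                )
            )
        rows.append((lib_unique, 100.0, lib_reads, 100.0))
        blocks[lib] = pd.DataFrame(
            rows,
            index=list(CATEGORY_PRIORITY) + ["total"],
            columns=["unique", "unique_pct", "reads", "reads_pct"],
        )
    out = pd.concat(blocks, axis=1)
    out.index.name = "category"
    return out


def mirna_counts(
    tags: pd.DataFrame, assignments: Mapping[str, CategoryAssignment]
) -> pd.DataFrame:
    """Read counts per known miRNA: sum over all tags assigned to it."""
    rows = {}
    for tag, a in assignments.items():
        if a.category == "miRNA_known" and a.ref_id:
            if a.ref_id not in rows:
                rows[a.ref_id] = tags.loc[tag].copy()
            else:
                rows[a.ref_id] += tags.loc[tag]
    if not rows:
        return pd.DataFrame(columns=tags.columns, dtype=np.int64)
    out = pd.DataFrame(rows).T.sort_index()
    out.index.name = "miRNA"
    return out


# ---------------------------------------------------------------------------
# base bias


def base_bias(
    tag_counts: Mapping[str, int] | pd.Series,
    which: str = "first_position_by_length",
    weighted: bool = True,
) -> pd.DataFrame:
    """Base-composition bias tables for a tag category.

    ``first_position_by_length``: rows are tag lengths, columns are the
    fraction of each base at the first (5') position.  ``per_position``:
    rows are positions (1-based), columns base fractions; the table is as
    wide as the longest tag.  Fractions sum to 1 per row.  With
    ``weighted`` the contribution of a tag is its read count, otherwise
    each unique tag counts once.
    """
    items = list(pd.Series(tag_counts).items())
    if not items:
        raise DataError("empty tag set")
    bases = "ACGTN"
    if which == "first_position_by_length":
        acc: dict[int, dict[str, float]] = {}
        for seq, n in items:
            w = n if weighted else 1
            row = acc.setdefault(len(seq), {b: 0.0 for b in bases})
            row[seq[0] if seq[0] in bases else "N"] += w
        df = pd.DataFrame(acc).T.sort_index()
        df.index.name = "length"
    elif which == "per_position":
        maxlen = max(len(s) for s, _ in items)
        df = pd.DataFrame(
            0.0, index=pd.RangeIndex(1, maxlen + 1, name="position"),
            columns=list(bases),
        )
        for seq, n in items:
            w = n if weighted else 1
            for pos, b in enumerate(seq, start=1):
                df.at[pos, b if b in bases else "N"] += w
    else:
        raise DataError(f"unknown base-bias mode {which!r}")
    return df.div(df.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# reference I/O


def load_known_mirnas(mature_fasta, precursor_fasta) -> list[KnownMiRNA]:
    """Pair mature and precursor FASTA records by name.

    The FASTA description may carry a ``family=...`` token; otherwise the
    family defaults to the record name.
    """
    matures = {r.id: r for r in SeqIO.parse(str(mature_fasta), "fasta")}
    known = []
    for rec in SeqIO.parse(str(precursor_fasta), "fasta"):
        if rec.id not in matures:
            raise DataError(f"precursor {rec.id} has no mature record")
        family = rec.id
        for token in rec.description.split():
            if token.startswith("family="):
                family = token.split("=", 1)[1]
        known.append(
            KnownMiRNA(
                name=rec.id,
                family=family,
                precursor=str(rec.seq).upper(),
                mature=str(matures[rec.id].seq).upper(),
            )
        )
    return known


def load_genome(fasta_path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def write_features_gff3(features: Sequence[Feature], path) -> None:
    """Write features as GFF3 (1-based, closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chrom}\tspidmir\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.fid}\n"
            )


def read_features_gff3(path) -> list[Feature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise DataError(f"malformed GFF3 line: {line.strip()!r}")
            fid = ""
            for kv in cols[8].split(";"):
                if kv.startswith("ID="):
                    fid = kv[3:]
            features.append(
                Feature(
                    chrom=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    ftype=cols[2],
                    fid=fid,
                )
            )
    return features


def write_features_bed(features: Sequence[Feature], path) -> None:
    """Write features as BED6 (0-based, half-open)."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.ftype}:{f.fid}\t0\t{f.strand}\n"
            )


def read_features_bed(path) -> list[Feature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            ftype, _, fid = name.partition(":")
            features.append(
                Feature(chrom, int(start), int(end), strand.strip(), ftype, fid)
            )
    return features
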