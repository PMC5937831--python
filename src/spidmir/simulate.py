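"""Synthetic small-RNA libraries with ground truth.

Generates a desk-scale stand-in for a four-condition cucumber small-RNA
sequencing experiment: a ~100 kb toy genome carrying known miRNA
precursors, structural-RNA/repeat/exon/intron features and planted novel
hairpin loci; a transcriptome with planted miRNA target sites; a
term-to-gene map with planted enrichment structure; and four FASTQ
libraries (CW, CS, HW, HS: water/spermidine at control/high temperature)
whose reads are insert + 3' adapter with phred64 qualities.

Contaminant reads of each removal class are injected at configured
rates, each built to fail exactly its intended cleaning rule.  Clean
reads are drawn multinomially from a per-library template distribution:
fixed weights for non-miRNA tags and log-normal baseline abundances for
known miRNAs, multiplied by per-library differential-expression effects.
Fourteen miRNAs are planted as responsive — eight differentially
expressed in all four comparison pairs (five consistently down, two
down except up in HS/HW, one up except down in HS/HW), three
heat-responsive and three spermidine-responsive — so the screening
stage has a known answer.  Everything emitted is recorded in a ground
truth manifest.

A fixed seed yields byte-identical FASTQ, reference and manifest files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import ConfigError, DataError, revcomp
from .annotate import Feature, KnownMiRNA
from .preprocess import CATEGORIES

LIBRARIES = ("CW", "CS", "HW", "HS")
PAIRS = (("CS", "CW"), ("HW", "CW"), ("HS", "CW"), ("HS", "HW"))

CLASS_ORDER = CATEGORIES + ("clean",)

#: insert length distribution of clean tags, peaked at 21 nt
LENGTH_DIST = {
    18: 0.03, 19: 0.06, 20: 0.12, 21: 0.36, 22: 0.14, 23: 0.08, 24: 0.08,
    25: 0.04, 26: 0.03, 27: 0.02, 28: 0.02, 29: 0.01, 30: 0.01,
}

#: total clean-read weight per non-miRNA category and number of distinct tags
CATEGORY_PLAN = {
    "rRNA": (10_000.0, 40),
    "tRNA": (1_000.0, 20),
    "snRNA": (200.0, 8),
    "snoRNA": (150.0, 8),
    "repeat": (600.0, 15),
    "exon_sense": (600.0, 25),
    "exon_antisense": (150.0, 10),
    "intron_sense": (450.0, 20),
    "intron_antisense": (120.0, 8),
    "unannotated": (35_000.0, 800),
}

#: feature loci planted in the genome: (type, count, length)
FEATURE_PLAN = (
    ("rRNA", 3, 400),
    ("tRNA", 5, 80),
    ("snRNA", 4, 150),
    ("snoRNA", 4, 150),
    ("repeat", 5, 200),
    ("exon", 6, 250),
    ("intron", 6, 250),
)

#: sequence appended after the 3' adapter when the read is longer
POST_ADAPTER = "CGTATGCCGTCTTCTGCTTG"

#: planted target-gene counts per responsive miRNA (others target nothing)
TARGET_PLAN = {
    "miR101a": 2, "miR102a": 1, "miR103a": 3, "miR106a": 6, "miR107a": 4,
}


def default_contaminant_rates() -> dict[str, float]:
    """Removal-class rates of the same order as real HiSeq sRNA libraries."""
    return {
        "low_quality": 0.0006,
        "high_N": 0.0003,
        "adapter5_contaminant": 0.0009,
        "insert_null": 0.0001,
        "adapter3_null": 0.0032,
        "polyA": 0.0001,
        "shorter_than_18nt": 0.0280,
    }


def default_de_effects() -> dict[str, dict[str, float]]:
    """Planted per-library expression multipliers (CW is the 1.0 baseline).

    Eight miRNAs respond in all four comparison pairs: five down
    everywhere, two down except up in HS/HW (spermidine induction under
    heat), one up except down in HS/HW.  Three respond to heat only and
    three to spermidine only.  Every planted contrast is at least a
    4-fold effect.
    """
    effects: dict[str, dict[str, float]] = {}
    for name in ("miR101a", "miR102a", "miR103a", "miR104a", "miR105a"):
        effects[name] = {"CW": 1.0, "CS": 0.25, "HW": 0.25, "HS": 0.0625}
    for name in ("miR106a", "miR107a"):
        effects[name] = {"CW": 1.0, "CS": 0.25, "HW": 0.0625, "HS": 0.25}
    effects["miR108a"] = {"CW": 1.0, "CS": 4.0, "HW": 16.0, "HS": 4.0}
    for name in ("miR109a", "miR110a", "miR111a"):  # heat only
        effects[name] = {"CW": 1.0, "CS": 1.0, "HW": 0.2, "HS": 0.2}
    for name in ("miR112a", "miR113a", "miR114a"):  # spermidine only
        effects[name] = {"CW": 1.0, "CS": 0.2, "HW": 1.0, "HS": 0.2}
    return effects


BOTH_SET = ("miR101a", "miR102a", "miR103a", "miR104a", "miR105a",
            "miR106a", "miR107a", "miR108a")
HEAT_SET = ("miR109a", "miR110a", "miR111a")
SPD_SET = ("miR112a", "miR113a", "miR114a")


@dataclass
class SimulationConfig:
    seed: int = 20180424
    n_reads_per_library: int = 100_000
    libraries: tuple[str, ...] = LIBRARIES
    read_length: int = 49
    encoding: str = "phred64"
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    genome_length: int = 100_000
    n_known_mirnas: int = 50
    n_families: int = 20
    novel_hairpin_count: int = 6
    novel_mature_weight: float = 120.0
    n_transcripts: int = 60
    transcript_length: int = 300
    baseline_logmean: float = 5.0
    baseline_logsd: float = 1.2
    responsive_weight: float = 1500.0
    contaminant_rates: dict[str, float] = field(
        default_factory=default_contaminant_rates
    )
    de_effects: dict[str, dict[str, float]] | None = None

    def validate(self) -> None:
        if len(self.libraries) != 4 or len(set(self.libraries)) != 4:
            raise ConfigError("exactly four distinct library labels are required")
        rates = self.contaminant_rates
        unknown = set(rates) - set(CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown contaminant classes: {sorted(unknown)}")
        for k, v in rates.items():
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"contaminant rate {k}={v} outside [0, 1)")
        if sum(rates.values()) >= 1.0:
            raise ConfigError("contaminant rates must sum to < 1")
        if self.novel_hairpin_count < 0:
            raise ConfigError("novel_hairpin_count must be >= 0")
        if not self.adapter3 or not self.adapter5:
            raise ConfigError("adapters must be non-empty")
        if self.adapter5 in POST_ADAPTER or self.adapter5 in self.adapter3:
            raise ConfigError("5' adapter collides with read tail sequence")
        if self.encoding not in ("phred64", "phred33"):
            raise ConfigError(f"unknown encoding {self.encoding!r}")


@dataclass
class ReferenceBundle:
    """Toy reference: genome, features, miRNA/transcript sequences, term map,
    plus the simulation internals (template tags and abundance weights)."""

    genome: dict[str, str]
    features: list[Feature]
    known: list[KnownMiRNA]
    novel_hairpins: list[dict]
    transcripts: dict[str, str]
    term_map: pd.DataFrame
    base_weights: dict[str, float]
    de_effects: dict[str, dict[str, float]]
    category_templates: list[dict]
    novel_mature_weight: float
    target_truth: dict[str, list[str]]
    enriched_terms_truth: list[str]

    # -- persistence --------------------------------------------------------

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(outdir / "genome.fa", self.genome.items())
        from .annotate import write_features_bed, write_features_gff3

        write_features_gff3(self.features, outdir / "features.gff3")
        write_features_bed(self.features, outdir / "features.bed")
        _write_fasta(
            outdir / "mirna_mature.fa",
            ((f"{m.name} family={m.family}", m.mature) for m in self.known),
        )
        _write_fasta(
            outdir / "mirna_precursor.fa",
            ((f"{m.name} family={m.family}", m.precursor) for m in self.known),
        )
        _write_fasta(outdir / "transcripts.fa", sorted(self.transcripts.items()))
        self.term_map.to_csv(outdir / "term_map.tsv", sep="\t", index=False)
        internals = {
            "novel_hairpins": self.novel_hairpins,
            "base_weights": self.base_weights,
            "de_effects": self.de_effects,
            "category_templates": self.category_templates,
            "novel_mature_weight": self.novel_mature_weight,
            "target_truth": self.target_truth,
            "enriched_terms_truth": self.enriched_terms_truth,
        }
        with open(outdir / "simulation.json", "w") as fh:
            json.dump(internals, fh, sort_keys=True, indent=1)

    @classmethod
    def load(cls, refdir) -> "ReferenceBundle":
        refdir = Path(refdir)
        from .annotate import load_genome, load_known_mirnas, read_features_gff3

        with open(refdir / "simulation.json") as fh:
            internals = json.load(fh)
        return cls(
            genome=load_genome(refdir / "genome.fa"),
            features=read_features_gff3(refdir / "features.gff3"),
            known=load_known_mirnas(
                refdir / "mirna_mature.fa", refdir / "mirna_precursor.fa"
            ),
            novel_hairpins=internals["novel_hairpins"],
            transcripts=load_genome(refdir / "transcripts.fa"),
            term_map=pd.read_csv(refdir / "term_map.tsv", sep="\t"),
            base_weights=internals["base_weights"],
            de_effects=internals["de_effects"],
            category_templates=internals["category_templates"],
            novel_mature_weight=internals["novel_mature_weight"],
            target_truth=internals["target_truth"],
            enriched_terms_truth=internals["enriched_terms_truth"],
        )

    # -- derived helpers ----------------------------------------------------

    def clean_templates(self) -> list[dict]:
        """All clean-read tag templates: category tags, novel matures,
        known matures.  Order is fixed and deterministic."""
        out = list(self.category_templates)
        for h in self.novel_hairpins:
            out.append(
                {
                    "seq": h["mature"],
                    "category": "unannotated",
                    "source": "novel_mature",
                    "name": h["id"],
                    "weight": self.novel_mature_weight,
                }
            )
        for m in self.known:
            out.append(
                {
                    "seq": m.mature,
                    "category": "miRNA_known",
                    "source": "known_mirna",
                    "name": m.name,
                    "weight": self.base_weights[m.name],
                }
            )
        return out

    def library_weights(self, library: str) -> np.ndarray:
        """Template weight vector for one library (DE effects applied)."""
        weights = []
        for t in self.clean_templates():
            w = t["weight"]
            if t["source"] == "known_mirna":
                eff = self.de_effects.get(t["name"], {})
                w *= eff.get(library, 1.0)
            weights.append(w)
        return np.array(weights, dtype=float)


def _write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


# ---------------------------------------------------------------------------
# reference construction


class _SeqFactory:
    """Random sequence generation under the simulator's tag constraints."""

    def __init__(self, rng: np.random.Generator, config: SimulationConfig):
        self.rng = rng
        self.forbidden = (config.adapter3[:6], config.adapter5)
        self.seen: set[str] = set()

    def random(self, n: int) -> str:
        return "".join("ACGT"[i] for i in self.rng.integers(0, 4, n))

    def ok(self, seq: str, check_polya: bool = True) -> bool:
        if any(f in seq for f in self.forbidden):
            return False
        if check_polya and seq.count("A") / len(seq) >= 0.8:
            return False
        return True

    def fresh(self, n: int, check_polya: bool = True, tries: int = 500) -> str:
        for _ in range(tries):
            s = self.random(n)
            if self.ok(s, check_polya) and s not in self.seen:
                self.seen.add(s)
                return s
        raise DataError("could not generate a sequence under the tag constraints")


def _mirna_names(config: SimulationConfig) -> list[tuple[str, str]]:
    """(name, family) pairs: members spread round-robin over families."""
    sizes = [0] * config.n_families
    for i in range(config.n_known_mirnas):
        sizes[i % config.n_families] += 1
    out = []
    for fam_idx, size in enumerate(sizes, start=1):
        family = f"miR{100 + fam_idx}"
        for j in range(size):
            out.append((f"{family}{'abcdefgh'[j]}", family))
    return out


def _draw_length(rng: np.random.Generator, max_len: int | None = None) -> int:
    lens = np.array(list(LENGTH_DIST))
    probs = np.array(list(LENGTH_DIST.values()))
    if max_len is not None:
        mask = lens <= max_len
        lens, probs = lens[mask], probs[mask]
        probs = probs / probs.sum()
    return int(rng.choice(lens, p=probs))


def build_reference(config: SimulationConfig) -> ReferenceBundle:
    """Build the toy reference bundle.

    Postconditions: every mature miRNA is a perfect substring of its
    precursor; every precursor occurs exactly once in the genome; novel
    hairpins lie in unannotated space; all feature intervals are within
    genome bounds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fac = _SeqFactory(rng, config)

    # -- hairpin sequences --------------------------------------------------
    known: list[KnownMiRNA] = []
    precursors: list[str] = []
    for name, family in _mirna_names(config):
        for _ in range(200):
            mature = fac.fresh(int(rng.choice([20, 21, 22], p=[0.25, 0.5, 0.25])))
            loop = fac.random(int(rng.integers(12, 19)))
            prec = mature + loop + revcomp(mature)
            if fac.ok(prec, check_polya=False) and prec.count(mature) == 1:
                break
        else:  # pragma: no cover
            raise DataError("could not build a precursor")
        known.append(KnownMiRNA(name, family, prec, mature))
        precursors.append(prec)

    novel_seqs: list[tuple[str, str]] = []  # (hairpin, mature arm)
    for _ in range(config.novel_hairpin_count):
        arm = fac.fresh(21)
        loop = fac.random(int(rng.integers(12, 19)))
        novel_seqs.append((arm + loop + revcomp(arm), arm))

    # -- genome assembly ----------------------------------------------------
    chrom = "chr1"
    genome_arr = np.array(list("ACGT"))[rng.integers(0, 4, config.genome_length)]
    occupied: list[tuple[int, int]] = []
    features: list[Feature] = []
    precursor_loci: dict[str, tuple[int, int]] = {}
    novel_hairpins: list[dict] = []

    cursor = int(rng.integers(300, 600))

    def place(length: int) -> int:
        nonlocal cursor
        start = cursor
        cursor += length + int(rng.integers(500, 900))
        if cursor > config.genome_length:
            raise DataError(
                "genome too small for the requested elements (generation error)"
            )
        occupied.append((start, start + length))
        return start

    for m, prec in zip(known, precursors):
        start = place(len(prec))
        genome_arr[start : start + len(prec)] = list(prec)
        precursor_loci[m.name] = (start, start + len(prec))
        features.append(
            Feature(chrom, start, start + len(prec), "+", "miRNA_primary_transcript", m.name)
        )
    for i, (hairpin, arm) in enumerate(novel_seqs, start=1):
        start = place(len(hairpin))
        genome_arr[start : start + len(hairpin)] = list(hairpin)
        novel_hairpins.append(
            {
                "id": f"hairpin{i:02d}",
                "chrom": chrom,
                "start": start,
                "end": start + len(hairpin),
                "strand": "+",
                "mature": arm,
                "mature_start": start,
                "mature_end": start + len(arm),
            }
        )
    feature_count = 0
    for ftype, count, length in FEATURE_PLAN:
        for _ in range(count):
            start = place(length)
            feature_count += 1
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                Feature(chrom, start, start + length, strand, ftype, f"{ftype}{feature_count:03d}")
            )
    genome = {chrom: "".join(genome_arr)}

    for m in known:
        if genome[chrom].count(m.precursor) != 1:
            raise DataError(f"precursor {m.name} not unique in genome (generation error)")

    # -- clean-read tag templates ------------------------------------------
    category_templates: list[dict] = []
    by_type: dict[str, list[Feature]] = {}
    for f in features:
        by_type.setdefault(f.ftype, []).append(f)

    def fragment(feature: Feature, orientation: str) -> str | None:
        flen = _draw_length(rng, feature.end - feature.start)
        s = int(rng.integers(feature.start, feature.end - flen + 1))
        seq = genome[chrom][s : s + flen]
        if feature.strand == "-":
            seq = revcomp(seq)  # sense strand of the feature
        if orientation == "antisense":
            seq = revcomp(seq)
        if fac.ok(seq) and seq not in fac.seen:
            fac.seen.add(seq)
            return seq
        return None

    for category, (total_weight, n_tags) in CATEGORY_PLAN.items():
        if category == "unannotated":
            continue
        base_type = category.split("_")[0]
        orientation = "antisense" if category.endswith("antisense") else "sense"
        pool = by_type[base_type]
        splits = rng.dirichlet(np.full(n_tags, 5.0)) * total_weight
        made = 0
        attempts = 0
        while made < n_tags:
            attempts += 1
            if attempts > 200 * n_tags:  # pragma: no cover
                raise DataError(f"could not draw tags for category {category}")
            feat = pool[int(rng.integers(0, len(pool)))]
            seq = fragment(feat, orientation)
            if seq is None:
                continue
            category_templates.append(
                {
                    "seq": seq,
                    "category": category,
                    "source": "feature_fragment",
                    "name": feat.fid,
                    "weight": float(splits[made]),
                }
            )
            made += 1

    # unannotated tags come from the gaps between placed elements
    gaps = []
    prev = 0
    for s, e in sorted(occupied):
        if s - prev > 80:
            gaps.append((prev + 20, s - 20))
        prev = e
    if config.genome_length - prev > 80:
        gaps.append((prev + 20, config.genome_length - 20))
    gap_lens = np.array([e - s for s, e in gaps], dtype=float)
    gap_p = gap_lens / gap_lens.sum()
    total_weight, n_tags = CATEGORY_PLAN["unannotated"]
    splits = rng.dirichlet(np.full(n_tags, 5.0)) * total_weight
    made = 0
    attempts = 0
    while made < n_tags:
        attempts += 1
        if attempts > 200 * n_tags:  # pragma: no cover
            raise DataError("could not draw unannotated tags")
        gi = int(rng.choice(len(gaps), p=gap_p))
        lo, hi = gaps[gi]
        flen = _draw_length(rng)
        if hi - lo < flen:
            continue
        s = int(rng.integers(lo, hi - flen + 1))
        seq = genome[chrom][s : s + flen]
        if not fac.ok(seq) or seq in fac.seen:
            continue
        fac.seen.add(seq)
        category_templates.append(
            {
                "seq": seq,
                "category": "unannotated",
                "source": "unannotated",
                "name": f"intergenic{made + 1:04d}",
                "weight": float(splits[made]),
            }
        )
        made += 1

    # -- transcriptome with planted target sites ---------------------------
    matures = {m.name: m.mature for m in known}
    transcripts = {
        f"gene{i:03d}": fac.random(config.transcript_length)
        for i in range(1, config.n_transcripts + 1)
    }
    target_truth: dict[str, list[str]] = {}
    plan = {k: v for k, v in TARGET_PLAN.items() if k in matures}
    n_target_genes = sum(plan.values())
    gene_pool = [
        str(g)
        for g in rng.choice(sorted(transcripts), size=n_target_genes, replace=False)
    ]
    for mir, n_genes in plan.items():
        site = revcomp(matures[mir])
        genes = []
        for _ in range(n_genes):
            gene = gene_pool.pop()
            pos = int(rng.integers(30, config.transcript_length - 30 - len(site)))
            seq = transcripts[gene]
            transcripts[gene] = seq[:pos] + site + seq[pos + len(site) :]
            genes.append(gene)
        target_truth[mir] = sorted(genes)

    # -- term map with planted enrichment ----------------------------------
    term_classes = {
        "biological_process": [f"GO:10000{i:02d}" for i in range(1, 5)],
        "cellular_component": [f"GO:10000{i:02d}" for i in range(5, 9)],
        "molecular_function": [f"GO:10000{i:02d}" for i in range(9, 13)],
        "kegg_pathway": [f"ko100{i:02d}" for i in range(1, 7)],
    }
    enriched_mf, enriched_ko = "GO:1000009", "ko10001"
    rows = []
    hot_genes = set(target_truth.get("miR106a", []))
    for gene in sorted(transcripts):
        for tclass in ("biological_process", "cellular_component", "molecular_function"):
            choices = term_classes[tclass]
            if tclass == "molecular_function" and gene in hot_genes:
                term = enriched_mf
            elif tclass == "molecular_function":
                # the planted term stays specific to the planted target set
                term = choices[int(rng.integers(1, len(choices)))]
            else:
                term = choices[int(rng.integers(0, len(choices)))]
            rows.append({"gene": gene, "term": term, "term_class": tclass})
        if gene in hot_genes:
            rows.append({"gene": gene, "term": enriched_ko, "term_class": "kegg_pathway"})
        elif rng.random() < 0.5:
            term = term_classes["kegg_pathway"][int(rng.integers(1, 6))]
            rows.append({"gene": gene, "term": term, "term_class": "kegg_pathway"})
    term_map = pd.DataFrame(rows, columns=["gene", "term", "term_class"])

    # -- abundance weights and effects --------------------------------------
    de_effects = config.de_effects if config.de_effects is not None else default_de_effects()
    de_effects = {k: dict(v) for k, v in de_effects.items() if k in matures}
    base_weights = {}
    for m in known:
        if m.name in de_effects:
            base_weights[m.name] = float(config.responsive_weight)
        else:
            base_weights[m.name] = float(
                np.exp(rng.normal(config.baseline_logmean, config.baseline_logsd))
            )

    return ReferenceBundle(
        genome=genome,
        features=features,
        known=known,
        novel_hairpins=novel_hairpins,
        transcripts=transcripts,
        term_map=term_map,
        base_weights=base_weights,
        de_effects=de_effects,
        category_templates=category_templates,
        novel_mature_weight=float(config.novel_mature_weight),
        target_truth=target_truth,
        enriched_terms_truth=[enriched_mf, enriched_ko],
    )


# ---------------------------------------------------------------------------
# library simulation


def simulate_libraries(
    config: SimulationConfig, ref: ReferenceBundle
) -> tuple[dict[str, list[tuple[str, str, str]]], dict]:
    """Draw the four FASTQ libraries and the ground-truth manifest.

    Returns ``(reads, manifest)`` where ``reads[lib]`` is a list of
    (read id, sequence, phred64 quality string) triples.  Use
    :func:`write_libraries` to put them on disk.
    """
    config.validate()
    for m in ref.known:
        if m.mature in (config.adapter3, config.adapter5):
            raise ConfigError(
                f"adapter identical to mature sequence of {m.name}; "
                "this would confound adapter trimming"
            )
    rng = np.random.default_rng([config.seed, 1])
    templates = ref.clean_templates()
    template_seqs = [t["seq"] for t in templates]
    L = config.read_length
    a3, a5 = config.adapter3, config.adapter5
    tail = POST_ADAPTER * ((2 * L) // len(POST_ADAPTER) + 1)
    if a5 in (a3 + tail):
        raise ConfigError("5' adapter occurs in the post-insert sequence")

    def read_of(insert: str) -> str:
        return (insert + a3 + tail)[:L]

    fac = _SeqFactory(rng, config)

    rates = [config.contaminant_rates.get(c, 0.0) for c in CATEGORIES]
    probs = rates + [1.0 - sum(rates)]

    reads: dict[str, list[tuple[str, str, str]]] = {}
    manifest: dict = {
        "libraries": list(config.libraries),
        "n_reads_per_library": config.n_reads_per_library,
        "read_classes": {},
        "class_counts": {},
        "tag_sources": {
            t["seq"]: {
                "category": t["category"],
                "source": t["source"],
                "name": t["name"],
            }
            for t in templates
        },
        "mature_offsets": {m.name: m.precursor.find(m.mature) for m in ref.known},
        "novel_hairpins": ref.novel_hairpins,
        "true_tpm": {},
        "true_log2fc": {},
        "true_length_dist": {},
        "responsive": _responsive_patterns(ref),
        "target_truth": ref.target_truth,
        "enriched_terms_truth": ref.enriched_terms_truth,
    }

    tpm: dict[str, dict[str, float]] = {}
    for lib in config.libraries:
        n = config.n_reads_per_library
        weights = ref.library_weights(lib)
        p = weights / weights.sum()

        # expected expression in this library
        for t, pi in zip(templates, p):
            if t["source"] in ("known_mirna", "novel_mature"):
                tpm.setdefault(t["name"], {})[lib] = float(pi * 1e6)
        ldist: dict[int, float] = {}
        for t, pi in zip(templates, p):
            ldist[len(t["seq"])] = ldist.get(len(t["seq"]), 0.0) + float(pi)
        manifest["true_length_dist"][lib] = {str(k): v for k, v in sorted(ldist.items())}

        class_counts = rng.multinomial(n, probs)
        seqs: list[str] = []
        # clean reads, grouped by template
        tmpl_counts = rng.multinomial(class_counts[-1], p)
        for t, k in zip(templates, tmpl_counts):
            seqs.extend([read_of(t["seq"])] * int(k))
        # contaminants, each constructed to fail exactly its rule
        cont: list[str] = []
        for ci, cat in enumerate(CATEGORIES):
            k = int(class_counts[ci])
            if k == 0:
                continue
            if cat in ("low_quality", "high_N"):
                picks = rng.choice(len(templates), size=k, p=p)
                built = [read_of(template_seqs[int(i)]) for i in picks]
                if cat == "high_N":
                    built = [_with_ns(s, rng) for s in built]
                cont.extend(built)
            elif cat == "adapter5_contaminant":
                picks = rng.choice(len(templates), size=k, p=p)
                cont.extend(
                    (a5 + template_seqs[int(i)] + a3 + tail)[:L] for i in picks
                )
            elif cat == "insert_null":
                cont.extend([(a3 + tail)[:L]] * k)
            elif cat == "adapter3_null":
                for _ in range(k):
                    while True:
                        s = fac.random(L)
                        if fac.ok(s, check_polya=False):
                            cont.append(s)
                            break
            elif cat == "polyA":
                for _ in range(k):
                    ilen = int(rng.integers(20, 28))
                    ins = "".join(
                        "A" if rng.random() < 0.95
                        else "CGT"[int(rng.integers(0, 3))]
                        for _ in range(ilen)
                    )
                    if ins.count("A") / len(ins) < 0.8 or not fac.ok(ins, False):
                        ins = "A" * ilen
                    cont.append(read_of(ins))
            elif cat == "shorter_than_18nt":
                for _ in range(k):
                    while True:
                        ins = fac.random(int(rng.integers(8, 18)))
                        if fac.ok(ins):
                            cont.append(read_of(ins))
                            break
        # contaminants were built in CATEGORIES order; align class codes
        all_seqs = cont + seqs
        all_classes = np.concatenate(
            [
                np.repeat(np.arange(len(CATEGORIES)), class_counts[:-1]),
                np.full(int(class_counts[-1]), len(CLASS_ORDER) - 1),
            ]
        )
        perm = rng.permutation(n)
        all_seqs = [all_seqs[i] for i in perm]
        all_classes = all_classes[perm]

        # qualities: high for everything, then low-quality rows degraded
        qual = rng.integers(30, 42, size=(n, L), dtype=np.int64)
        low_idx = np.nonzero(all_classes == CLASS_ORDER.index("low_quality"))[0]
        for i in low_idx:
            npos = int(rng.integers(4, 7))
            pos = rng.choice(L, size=npos, replace=False)
            qual[i, pos] = rng.integers(0, 10, size=npos)
        offset = 64 if config.encoding == "phred64" else 33
        qual_bytes = (qual + offset).astype(np.uint8)

        lib_reads = [
            (
                f"{lib}_{i + 1:06d}",
                all_seqs[i],
                qual_bytes[i].tobytes().decode("ascii"),
            )
            for i in range(n)
        ]
        reads[lib] = lib_reads
        classes = [CLASS_ORDER[c] for c in all_classes]
        manifest["read_classes"][lib] = classes
        manifest["class_counts"][lib] = {
            c: int(k) for c, k in zip(CLASS_ORDER, class_counts)
        }

    manifest["true_tpm"] = tpm
    manifest["true_log2fc"] = {
        name: {
            f"{t}/{c}": float(np.log2(vals[t] / vals[c]))
            for t, c in PAIRS
        }
        for name, vals in tpm.items()
    }
    return reads, manifest


def _with_ns(seq: str, rng: np.random.Generator) -> str:
    """Replace enough positions with N to exceed the 10 % threshold."""
    n_ns = int(rng.integers(6, 11))
    pos = rng.choice(len(seq), size=n_ns, replace=False)
    arr = list(seq)
    for i in pos:
        arr[i] = "N"
    return "".join(arr)


def _responsive_patterns(ref: ReferenceBundle) -> dict:
    """Planted responsive sets with their expected direction patterns."""
    both: dict[str, dict[str, str]] = {}
    heat: list[str] = []
    spd: list[str] = []
    for name, eff in sorted(ref.de_effects.items()):
        ratios = {f"{t}/{c}": eff[t] / eff[c] for t, c in PAIRS}
        member = {pair: abs(np.log2(r)) > 1.0 for pair, r in ratios.items()}
        if all(member.values()):
            both[name] = {
                pair: ("up" if r > 1 else "down") for pair, r in ratios.items()
            }
        elif member["HW/CW"] and member["HS/CW"]:
            heat.append(name)
        elif member["CS/CW"] and member["HS/CW"] and member["HS/HW"]:
            spd.append(name)
    return {"both": both, "heat": sorted(heat), "spd": sorted(spd)}


def write_libraries(
    reads: Mapping[str, list[tuple[str, str, str]]], manifest: dict, outdir
) -> dict[str, Path]:
    """Write FASTQ files (one per library) and the manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lib, lib_reads in reads.items():
        path = outdir / f"{lib}.fastq"
        with open(path, "w") as fh:
            for rid, seq, qual in lib_reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        paths[lib] = path
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return paths
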