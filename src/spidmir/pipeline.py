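"""End-to-end orchestration: simulate -> preprocess -> annotate -> novel
-> differential expression -> screen -> targets -> enrichment.

Every stage is a pure function of its inputs and the run configuration;
all randomness flows from the single seed, so identical configurations
produce identical outputs (including the summary JSON byte for byte).
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from ._util import DataError
from . import annotate, diffexpr, novel, preprocess, screen, simulate, targets


@dataclass
class RunConfig:
    seed: int = 20180424
    outdir: str = "spidmir_run"
    n_reads_per_library: int = 100_000
    encoding: str = "phred64"
    simulation: simulate.SimulationConfig | None = None
    filter_params: preprocess.FilterParams = field(
        default_factory=preprocess.FilterParams
    )
    novel_params: novel.NovelParams = field(default_factory=novel.NovelParams)

    def resolve_simulation(self) -> simulate.SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return simulate.SimulationConfig(
            seed=self.seed,
            n_reads_per_library=self.n_reads_per_library,
            encoding=self.encoding,
        )


def _log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic experiment; returns the run summary.

    All stage outputs (reference bundle, FASTQ, cleaning/annotation
    tables, DE results, screen report, targets, enrichment) are written
    under ``config.outdir``; the summary is also written as
    ``summary.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "tool": "spidmir",
        "version": __version__,
        "seed": config.seed,
    }

    sim_cfg = config.resolve_simulation()
    # one encoding governs the whole run: the simulator writes it and the
    # filter decodes it
    config.filter_params.encoding = sim_cfg.encoding
    _log("simulate", f"building reference (seed={sim_cfg.seed})")
    ref = simulate.build_reference(sim_cfg)
    ref.write(out / "reference")
    reads, manifest = simulate.simulate_libraries(sim_cfg, ref)
    simulate.write_libraries(reads, manifest, out / "libraries")
    libraries = list(sim_cfg.libraries)

    _log("preprocess", "filtering and collapsing reads")
    inserts: dict[str, list[str]] = {}
    clean_totals: dict[str, int] = {}
    filter_tables = []
    for lib in libraries:
        raw = (preprocess.RawRead(rid, s, q) for rid, s, q in reads[lib])
        lib_inserts, report = preprocess.filter_reads(
            raw, sim_cfg.adapter3, sim_cfg.adapter5, config.filter_params
        )
        inserts[lib] = lib_inserts
        clean_totals[lib] = report.clean_reads
        tbl = report.to_frame()
        tbl.insert(0, "library", lib)
        filter_tables.append(tbl)
    pd.concat(filter_tables).to_csv(out / "cleaning_report.tsv", sep="\t", index=False)
    tags = preprocess.collapse_tags(inserts)
    lengths = preprocess.length_distribution(tags)
    lengths.to_csv(out / "length_distribution.tsv", sep="\t")
    summary["clean_reads"] = clean_totals
    summary["unique_tags"] = int(len(tags))

    _log("annotate", f"mapping {len(tags)} tags to the genome")
    hits = annotate.map_to_genome(tags.index, ref.genome)
    assignments, cat_summary = annotate.classify(
        tags, hits, ref.features, ref.known, ref.genome
    )
    cat_summary.to_csv(out / "annotation_summary.tsv", sep="\t")
    known_counts = annotate.mirna_counts(tags, assignments)
    summary["known_mirnas_detected"] = int(len(known_counts))

    _log("novel", "folding candidate precursor windows")
    unannotated_hits = {
        t: a.hits
        for t, a in assignments.items()
        if a.category == "unannotated" and a.hits
    }
    candidates = novel.call_candidates(
        unannotated_hits, tags, ref.genome, config.novel_params
    )
    novel.candidates_to_frame(candidates).to_csv(
        out / "novel_candidates.tsv", sep="\t", index=False
    )
    novel_counts = novel.candidate_counts(candidates, libraries)
    summary["novel_candidates"] = int(len(candidates))

    _log("de", "testing the four comparison pairs")
    all_counts = pd.concat([known_counts, novel_counts])
    matrix = diffexpr.normalize(all_counts, clean_totals).drop_single_library()
    matrix.normalized.to_csv(out / "expression_tpm.tsv", sep="\t")
    de = diffexpr.call_de(matrix)
    de.to_csv(out / "de_results.tsv", sep="\t", index=False)
    kind = pd.Series(
        ["novel" if m in novel_counts.index else "known" for m in de["miRNA"]],
        index=de.index,
    )
    summary["de_counts"] = {
        pair: {
            "known": int(((de["pair"] == pair) & de["significant"] & (kind == "known")).sum()),
            "novel": int(((de["pair"] == pair) & de["significant"] & (kind == "novel")).sum()),
        }
        for pair in sorted(de["pair"].unique())
    }

    _log("screen", "Venn screening of responsive miRNAs")
    report = screen.classify_responsiveness(de)
    report.to_csv(out / "screen_report.tsv", sep="\t", index=False)
    venn = screen.venn_counts(screen.de_sets_by_pair(de))
    with open(out / "venn_regions.json", "w") as fh:
        json.dump(
            {"|".join(sorted(k)): v for k, v in venn.items()}, fh, sort_keys=True, indent=1
        )
    sets = screen.responsive_sets(report)
    summary["responsive"] = {k: sorted(v) for k, v in sets.items()}

    _log("targets", "predicting targets of the both-responsive set")
    both_mirnas = {
        m.name: m.mature for m in ref.known if m.name in sets["both"]
    }
    hits_df = targets.predict_targets(both_mirnas, ref.transcripts)
    hits_df.to_csv(out / "targets.tsv", sep="\t", index=False)
    summary["target_genes"] = {
        mir: sorted(hits_df.loc[hits_df["miRNA"] == mir, "gene"])
        for mir in sorted(both_mirnas)
    }

    _log("enrich", "hypergeometric term enrichment")
    target_genes = set(hits_df["gene"])
    background = set(ref.transcripts)
    if target_genes:
        enrich = targets.hypergeom_enrich(target_genes, background, ref.term_map)
    else:
        enrich = pd.DataFrame(
            columns=["term", "term_class", "k", "K", "n", "N", "pvalue",
                     "genes", "p_corrected", "enriched"]
        )
    enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    summary["enriched_terms"] = sorted(enrich.loc[enrich.get("enriched", pd.Series(dtype=bool)).fillna(False), "term"]) if len(enrich) else []

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    _log("done", f"outputs written to {out}")
    return summary
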