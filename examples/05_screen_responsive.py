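"""Venn screening of responsive miRNAs across the four comparison pairs.

heat-responsive  : DE in HW/CW and HS/CW
spd-responsive   : DE in CS/CW, HS/CW and HS/HW
both-responsive  : DE in all four pairs (takes precedence)
"""

import pandas as pd

from spidmir import annotate, diffexpr, preprocess, screen
from spidmir.simulate import SimulationConfig, build_reference, simulate_libraries

cfg = SimulationConfig(seed=42, n_reads_per_library=50_000)
ref = build_reference(cfg)
reads, manifest = simulate_libraries(cfg, ref)

inserts, totals = {}, {}
for lib in cfg.libraries:
    raw = (preprocess.RawRead(i, s, q) for i, s, q in reads[lib])
    inserts[lib], rep = preprocess.filter_reads(raw, cfg.adapter3, cfg.adapter5)
    totals[lib] = rep.clean_reads
tags = preprocess.collapse_tags(inserts)
hits = annotate.map_to_genome(tags.index, ref.genome)
assignments, _ = annotate.classify(tags, hits, ref.features, ref.known, ref.genome)
counts = annotate.mirna_counts(tags, assignments)

matrix = diffexpr.normalize(counts, totals).drop_single_library()
de = diffexpr.call_de(matrix)
report = screen.classify_responsiveness(de)

print("responsiveness classes (planted truth in brackets):")
truth = manifest["responsive"]
for cls in ("both", "heat", "spd"):
    found = sorted(report.loc[report["class"] == cls, "miRNA"])
    planted = sorted(truth[cls]) if cls != "both" else sorted(truth["both"])
    print(f"  {cls:5s}: {found}  [planted: {planted}]")

flips = report[report["pattern"] == "down,down,down,up"]
print("\nsign-flip miRNAs (down in three pairs, up in HS/HW — repressed by")
print("heat, induced by spermidine under heat):")
print(flips[["miRNA", "pattern", "consistency"]].to_string(index=False))

regions = screen.venn_counts(screen.de_sets_by_pair(de))
four_way = regions[frozenset(screen.PAIR_NAMES)]
print(f"\nfour-way Venn region holds {four_way} miRNAs (the 'both' set)")
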