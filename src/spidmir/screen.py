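"""Venn screening of differentially expressed miRNAs across the four pairs.

The four comparison pairs carry the experimental semantics:

  CS/CW : response to spermidine at normal temperature
  HW/CW : response to high temperature
  HS/CW : response to the combined treatment
  HS/HW : response to spermidine under high temperature

A miRNA differentially expressed in HW/CW and HS/CW is called
heat-responsive; one differentially expressed in CS/CW, HS/CW and HS/HW
is spermidine-responsive; one differentially expressed in all four pairs
responds to both (the headline set), with "both" taking precedence.
Direction patterns record the sign of the log2 fold-change in the pairs
where the miRNA is significant.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from ._util import DataError
from .diffexpr import DEFAULT_PAIRS

PAIR_NAMES = tuple(f"{t}/{c}" for t, c in DEFAULT_PAIRS)

HEAT_PAIRS = ("HW/CW", "HS/CW")
SPD_PAIRS = ("CS/CW", "HS/CW", "HS/HW")


def venn_counts(de_sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Counts of every exclusive (disjoint) Venn region of the input sets.

    Keys are frozensets of set names; the value for key K is the number
    of elements belonging to exactly the sets in K.  Only nonempty
    combinations are keyed (regions may have zero counts).  The region
    counts sum to the size of the union.
    """
    names = sorted(de_sets)
    regions = {
        frozenset(combo): 0
        for k in range(1, len(names) + 1)
        for combo in combinations(names, k)
    }
    universe = set().union(*de_sets.values()) if de_sets else set()
    for el in universe:
        membership = frozenset(n for n in names if el in de_sets[n])
        regions[membership] += 1
    return regions


def classify_responsiveness(
    de_results: pd.DataFrame, pair_names: Sequence[str] = PAIR_NAMES
) -> pd.DataFrame:
    """Per-miRNA membership vector, responsiveness class and pattern.

    ``de_results`` is the output of :func:`spidmir.diffexpr.call_de`.
    The returned frame has one row per miRNA with boolean membership
    columns per pair, a class in {both, heat, spd, other}, a direction
    pattern over the member pairs (e.g. "down,down,down,up") and a
    consistency flag in {all-down, all-up, inconsistent}.
    """
    required = {"miRNA", "pair", "log2fc", "significant"}
    if not required <= set(de_results.columns):
        raise DataError(f"DE table missing columns {sorted(required - set(de_results.columns))}")
    rows = []
    for mirna, grp in de_results.groupby("miRNA", sort=True):
        by_pair = grp.set_index("pair")
        member = {p: bool(by_pair.at[p, "significant"]) if p in by_pair.index else False
                  for p in pair_names}
        if all(member.values()):
            cls = "both"
        elif all(member[p] for p in HEAT_PAIRS):
            cls = "heat"
        elif all(member[p] for p in SPD_PAIRS):
            cls = "spd"
        else:
            cls = "other"
        directions = {
            p: ("up" if by_pair.at[p, "log2fc"] > 0 else "down")
            for p in pair_names
            if member[p]
        }
        pattern = ",".join(directions[p] for p in pair_names if p in directions)
        if directions and all(d == "down" for d in directions.values()):
            consistency = "all-down"
        elif directions and all(d == "up" for d in directions.values()):
            consistency = "all-up"
        else:
            consistency = "inconsistent" if directions else ""
        row = {"miRNA": mirna, "class": cls, "pattern": pattern,
               "consistency": consistency}
        row.update({p: member[p] for p in pair_names})
        rows.append(row)
    cols = ["miRNA", *pair_names, "class", "pattern", "consistency"]
    return pd.DataFrame(rows, columns=cols).sort_values("miRNA").reset_index(drop=True)


def responsive_sets(report: pd.DataFrame) -> dict[str, set]:
    """Convenience: miRNA id sets by responsiveness class.

    The "both" set is contained in the heat and spermidine sets: a
    miRNA significant in all four pairs satisfies both rules.
    """
    both = set(report.loc[report["class"] == "both", "miRNA"])
    heat = set(report.loc[report["class"] == "heat", "miRNA"]) | both
    spd = set(report.loc[report["class"] == "spd", "miRNA"]) | both
    return {"both": both, "heat": heat, "spd": spd}


def de_sets_by_pair(
    de_results: pd.DataFrame, pair_names: Sequence[str] = PAIR_NAMES
) -> dict[str, set]:
    """Significant miRNA id set per comparison pair (Venn input)."""
    sig = de_results[de_results["significant"]]
    return {
        p: set(sig.loc[sig["pair"] == p, "miRNA"]) for p in pair_names
    }
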