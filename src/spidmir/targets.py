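"""Plant miRNA target prediction and hypergeometric term enrichment.

Targets are found by complementarity between the miRNA (5'->3') and a
transcript window, scored with the classic plant penalty scheme:
mismatches cost 1, G:U wobbles 0.5, and penalties within positions 2-13
from the miRNA 5' end (the seed-to-cleavage core) are doubled.  Two rule
presets are applied and only genes found under *both* are reported, the
usual way two prediction engines are reconciled by intersection:

  strict  : total penalty <= 4.0, no mismatch at positions 10-11
            (the slicing site), no bulges
  relaxed : total penalty <= 5.0, at most one single-nucleotide bulge
            on the transcript side (penalty 1, doubled in the core)

Term enrichment of the predicted target genes against a background gene
set uses the upper-tail hypergeometric test with Benjamini-Hochberg
correction within each ontology class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import DataError

CORE_START, CORE_END = 2, 13  # 1-based inclusive, doubled-penalty region
SLICE_POSITIONS = (10, 11)  # no mismatch here under the strict preset

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class TargetPreset:
    name: str
    max_penalty: float
    forbid_slice_mismatch: bool
    max_bulges: int


STRICT = TargetPreset("strict", 4.0, True, 0)
RELAXED = TargetPreset("relaxed", 5.0, False, 1)


@dataclass
class TargetHit:
    mirna: str
    transcript: str
    start: int  # 1-based on transcript
    end: int  # inclusive
    penalty: float
    mismatches: int
    wobbles: int
    bulges: int
    violation_positions: tuple[int, ...]  # 1-based from miRNA 5' end


def _position_weights(length: int) -> np.ndarray:
    pos = np.arange(1, length + 1)
    return np.where((pos >= CORE_START) & (pos <= CORE_END), 2.0, 1.0)


def _states(mirna: str, window: str) -> list[str]:
    """Per-miRNA-position pairing state vs an equal-length target window.

    Position p of the miRNA (1-based from its 5' end) faces transcript
    window position L - p (0-based), i.e. the duplex is antiparallel.
    States are 'match', 'wobble' (G:U) or 'mismatch'.
    """
    L = len(mirna)
    if len(window) != L:
        raise DataError("window length must equal miRNA length")
    states = []
    for p in range(L):
        m = mirna[p]
        t = window[L - 1 - p]
        c = _COMP.get(t, "N")
        if m == c and m != "N":
            states.append("match")
        elif (m == "G" and c == "A") or (m == "T" and c == "C"):
            # miRNA G with target T, or miRNA U with target G
            states.append("wobble")
        else:
            states.append("mismatch")
    return states


def score_target(mirna: str, window: str) -> tuple[float, list[str]]:
    """Penalty of an ungapped miRNA:target duplex and per-position states."""
    states = _states(mirna, window)
    weights = _position_weights(len(mirna))
    penalty = 0.0
    for p, s in enumerate(states):
        if s == "mismatch":
            penalty += 1.0 * weights[p]
        elif s == "wobble":
            penalty += 0.5 * weights[p]
    return penalty, states


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in _COMP.items():
    _COMP_LUT[ord(_a)] = ord(_b)


def _scan_penalties(mirna_b: np.ndarray, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized penalties for a stack of equal-length windows.

    Returns (penalty per window, slice-site mismatch flag per window).
    """
    L = mirna_b.size
    comp = _COMP_LUT[windows[:, ::-1]]  # complement of reversed window
    match = comp == mirna_b
    wobble = ((mirna_b == ord("G")) & (comp == ord("A"))) | (
        (mirna_b == ord("T")) & (comp == ord("C"))
    )
    wobble &= ~match
    mism = ~match & ~wobble
    w = _position_weights(L)
    pen = (mism * 1.0 + wobble * 0.5) @ w
    slice_idx = [p - 1 for p in SLICE_POSITIONS if p <= L]
    slice_mism = mism[:, slice_idx].any(axis=1)
    return pen, slice_mism


def _find_sites(
    mirna: str, transcript: str, preset: TargetPreset
) -> list[TargetHit]:
    """All windows of one transcript passing a preset for one miRNA."""
    L = len(mirna)
    T = len(transcript)
    hits: list[TargetHit] = []
    mirna_b = _encode(mirna)
    tr_b = _encode(transcript)
    if T >= L:
        wins = np.lib.stride_tricks.sliding_window_view(tr_b, L)
        pen, slice_mism = _scan_penalties(mirna_b, wins)
        ok = pen <= preset.max_penalty
        if preset.forbid_slice_mismatch:
            ok &= ~slice_mism
        for s in np.nonzero(ok)[0]:
            penalty, states = score_target(mirna, transcript[s : s + L])
            hits.append(
                TargetHit(
                    mirna="",
                    transcript="",
                    start=int(s) + 1,
                    end=int(s) + L,
                    penalty=float(penalty),
                    mismatches=states.count("mismatch"),
                    wobbles=states.count("wobble"),
                    bulges=0,
                    violation_positions=tuple(
                        p + 1 for p, st in enumerate(states) if st != "match"
                    ),
                )
            )
    if preset.max_bulges >= 1 and T >= L + 1:
        wins = np.lib.stride_tricks.sliding_window_view(tr_b, L + 1)
        for k in range(1, L):  # bulged transcript position inside the window
            eff = np.concatenate([wins[:, :k], wins[:, k + 1 :]], axis=1)
            pen, slice_mism = _scan_penalties(mirna_b, eff)
            # bulge faces the gap between miRNA positions L-k and L-k+1
            p_bulge = L - k
            bulge_pen = 2.0 if CORE_START <= p_bulge <= CORE_END else 1.0
            pen = pen + bulge_pen
            ok = pen <= preset.max_penalty
            if preset.forbid_slice_mismatch:
                ok &= ~slice_mism
            for s in np.nonzero(ok)[0]:
                window = transcript[s : s + L + 1]
                eff_win = window[:k] + window[k + 1 :]
                penalty, states = score_target(mirna, eff_win)
                hits.append(
                    TargetHit(
                        mirna="",
                        transcript="",
                        start=int(s) + 1,
                        end=int(s) + L + 1,
                        penalty=float(penalty + bulge_pen),
                        mismatches=states.count("mismatch"),
                        wobbles=states.count("wobble"),
                        bulges=1,
                        violation_positions=tuple(
                            sorted(
                                {p_bulge}
                                | {p + 1 for p, st in enumerate(states) if st != "match"}
                            )
                        ),
                    )
                )
    return hits


def predict_targets(
    mirnas: Mapping[str, str],
    transcriptome: Mapping[str, str],
    presets: Sequence[TargetPreset] = (STRICT, RELAXED),
) -> pd.DataFrame:
    """Intersection target prediction over a transcriptome.

    For each miRNA, a gene is reported only if it has a qualifying site
    under *every* preset; the reported site is the best strict-preset
    site (lowest penalty, then leftmost).  Returns a frame with one row
    per (miRNA, gene).
    """
    if not transcriptome:
        raise DataError("empty transcriptome")
    report_preset = min(presets, key=lambda p: (p.max_penalty, p.max_bulges))
    rows = []
    for name in sorted(mirnas):
        seq = mirnas[name].upper().replace("U", "T")
        gene_sets = []
        per_gene_hits: dict[str, list[TargetHit]] = {}
        for preset in presets:
            genes = set()
            for gene in transcriptome:
                hits = _find_sites(seq, transcriptome[gene].upper(), preset)
                if hits:
                    genes.add(gene)
                    if preset is report_preset:
                        per_gene_hits[gene] = hits
            gene_sets.append(genes)
        common = set.intersection(*gene_sets) if gene_sets else set()
        for gene in sorted(common):
            best = min(per_gene_hits[gene], key=lambda h: (h.penalty, h.start))
            rows.append(
                {
                    "miRNA": name,
                    "gene": gene,
                    "start": best.start,
                    "end": best.end,
                    "penalty": best.penalty,
                    "mismatches": best.mismatches,
                    "wobbles": best.wobbles,
                    "bulges": best.bulges,
                    "violations": ",".join(map(str, best.violation_positions)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "miRNA", "gene", "start", "end", "penalty",
            "mismatches", "wobbles", "bulges", "violations",
        ],
    )


# ---------------------------------------------------------------------------
# enrichment


def hypergeom_enrich(
    target_genes: set,
    background_genes: set,
    term_map: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms in a gene set.

    ``term_map`` needs columns gene, term and term_class; multiple
    ontology classes (e.g. the three GO categories and pathways) are
    corrected separately.  Terms with no background annotation are
    skipped with a warning.  Returns one row per term with k (hits in
    target set), K (background hits), n, N, raw and corrected p, and the
    enriched flag (corrected p < alpha).
    """
    if not target_genes <= background_genes:
        raise DataError("target genes must be a subset of the background")
    required = {"gene", "term", "term_class"}
    if not required <= set(term_map.columns):
        raise DataError(f"term map missing columns {sorted(required - set(term_map.columns))}")
    tm = term_map[term_map["gene"].isin(background_genes)]
    N = len(background_genes)
    n = len(target_genes)
    rows = []
    for (term, tclass), grp in tm.groupby(["term", "term_class"], sort=True):
        genes = set(grp["gene"])
        K = len(genes)
        if K == 0:
            warnings.warn(f"term {term} has no background annotation; skipped")
            continue
        hit_genes = sorted(genes & target_genes)
        k = len(hit_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "term_class": tclass,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": min(p, 1.0),
                "genes": ",".join(hit_genes),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "term_class", "k", "K", "n", "N", "pvalue", "genes"]
    )
    if out.empty:
        out["p_corrected"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
        return out
    corrected = np.ones(len(out))
    for tclass, idx in out.groupby("term_class").groups.items():
        _, padj, _, _ = multipletests(out.loc[idx, "pvalue"], method=correction)
        corrected[out.index.get_indexer(idx)] = padj
    out["p_corrected"] = corrected
    out["enriched"] = out["p_corrected"] < alpha
    return out.sort_values(["term_class", "pvalue", "term"]).reset_index(drop=True)
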