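"""Normalization, exact tag-count differential expression, and ANOVA.

Expression is normalized to transcripts per million of clean reads:

    normalized = count / clean_total * 1,000,000

Zeros are imputed to 0.01 only when ratios are formed, and miRNAs
expressed in only one of the four libraries are excluded before testing.
A miRNA is significantly differentially expressed in a comparison pair
when |log2 fold-change| > 1 and p < 0.05 (strict inequalities).

The p-value comes from the classic exact test for a tag observed x times
in a library of depth N1 and y times in a library of depth N2.  Under a
flat prior on the unknown concentration, the count in the second library
conditioned on the first is negative binomial,

    P(y | x) = C(x+y, y) * q**y * (1-q)**(x+1),   q = N2 / (N1 + N2),

and the two-sided p-value is twice the smaller of the two "at least as
extreme" tails, computed once in each conditioning direction so the test
is symmetric under swapping the libraries:

    p = min(1, 2 * min( P(Y >= y | x; N1, N2), P(X >= x | y; N2, N1) )).

Tails are evaluated by direct summation of the probability mass (log-
gamma recurrences, all-positive terms), which keeps full relative
accuracy even for very small p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import DataError

#: the four condition contrasts, written treatment/control
DEFAULT_PAIRS = (("CS", "CW"), ("HW", "CW"), ("HS", "CW"), ("HS", "HW"))

ZERO_IMPUTATION = 0.01
TPM_SCALE = 1_000_000.0


@dataclass
class ExpressionMatrix:
    """miRNA x library counts with clean-read totals.

    ``normalized`` is the exact per-million value (zeros stay zero);
    ``ratio_values`` applies the 0 -> 0.01 imputation used for fold
    changes.
    """

    counts: pd.DataFrame
    clean_totals: pd.Series

    def __post_init__(self) -> None:
        self.clean_totals = pd.Series(self.clean_totals).astype(float)
        missing = set(self.counts.columns) - set(self.clean_totals.index)
        if missing:
            raise DataError(f"clean totals missing for libraries {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("negative counts")
        if (self.clean_totals <= 0).any():
            raise DataError("clean totals must be positive")

    @property
    def normalized(self) -> pd.DataFrame:
        return self.counts / self.clean_totals[self.counts.columns] * TPM_SCALE

    @property
    def ratio_values(self) -> pd.DataFrame:
        norm = self.normalized
        return norm.mask(norm == 0.0, ZERO_IMPUTATION)

    def drop_single_library(self) -> "ExpressionMatrix":
        """Remove miRNAs expressed in fewer than two libraries."""
        expressed = (self.counts > 0).sum(axis=1)
        return ExpressionMatrix(self.counts[expressed >= 2].copy(), self.clean_totals)


def normalize(
    counts: pd.DataFrame, clean_totals: Mapping[str, float] | pd.Series
) -> ExpressionMatrix:
    """Per-million normalization against clean-read library totals."""
    return ExpressionMatrix(counts.astype(np.int64), pd.Series(clean_totals))


def fold_change(expr_treat: float, expr_ctrl: float) -> float:
    """log2 ratio of (imputation-adjusted) normalized expression values."""
    if expr_treat <= 0 or expr_ctrl <= 0:
        raise DataError("fold change requires positive (imputed) values")
    # difference of logs keeps the swap antisymmetry exact in floating point
    return math.log2(expr_treat) - math.log2(expr_ctrl)


# ---------------------------------------------------------------------------
# exact tag-count test


def _log_pmf0(x: int, y: int, log_q: float, log_omq: float) -> float:
    """log P(y | x) of the conditional negative binomial."""
    return (
        math.lgamma(x + y + 1)
        - math.lgamma(x + 1)
        - math.lgamma(y + 1)
        + y * log_q
        + (x + 1) * log_omq
    )


def _upper_tail(x: int, y: int, q: float, omq: float) -> float:
    """P(Y >= y | x) for the conditional negative binomial (q = N2/(N1+N2)).

    Below the distribution mode the tail is of order one, so the short
    complementary lower sum is safe; at or above the mode the tail terms
    decrease and direct summation of all-positive terms keeps full
    relative precision for arbitrarily small p-values.  Terms come from
    log-gamma and partial sums from math.fsum, so no cancellation or
    accumulation error enters.
    """
    if y <= 0:
        return 1.0
    log_q, log_omq = math.log(q), math.log(omq)
    mode = q * (x + 1) / omq
    if y <= mode:
        lower = math.fsum(
            math.exp(_log_pmf0(x, k, log_q, log_omq)) for k in range(y)
        )
        return min(max(1.0 - lower, 0.0), 1.0)
    term = math.exp(_log_pmf0(x, y, log_q, log_omq))
    terms = [term]
    total = term
    k = y
    while term > 0.0:
        k += 1
        term *= (x + k) / k * q
        terms.append(term)
        total += term
        ratio = q * (x + k + 1) / (k + 1)  # next-term ratio, decreasing to q
        if ratio < 1.0 and term * ratio / (1.0 - ratio) <= total * 1e-17:
            break
    return min(math.fsum(terms), 1.0)


def tagcount_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided exact p-value for counts x (depth n1) vs y (depth n2).

    Symmetric in the two libraries: p(x, y, N1, N2) == p(y, x, N2, N1).
    Equal counts at equal depths give the least significant value for
    the given x.
    """
    if x < 0 or y < 0 or int(x) != x or int(y) != y:
        raise DataError("counts must be non-negative integers")
    if n1 <= 0 or n2 <= 0:
        raise DataError("library depths must be positive")
    x, y = int(x), int(y)
    q12 = n2 / (n1 + n2)  # conditioning on x
    q21 = n1 / (n1 + n2)  # conditioning on y
    tail_up = _upper_tail(x, y, q12, q21)  # P(Y >= y | x)
    tail_down = _upper_tail(y, x, q21, q12)  # P(X >= x | y)
    return min(1.0, 2.0 * min(tail_up, tail_down))


# ---------------------------------------------------------------------------
# per-pair DE calls

FC_THRESHOLD = 1.0
P_THRESHOLD = 0.05
STARS_THRESHOLD = 0.01


def call_de(
    matrix: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
) -> pd.DataFrame:
    """Fold change, p-value and significance for each comparison pair.

    The second library of each pair is the control.  Input should
    already have single-library miRNAs removed (see
    :meth:`ExpressionMatrix.drop_single_library`).  Output is sorted by
    miRNA then pair and is deterministic.
    """
    ratio = matrix.ratio_values
    totals = matrix.clean_totals
    rows = []
    for mirna in matrix.counts.index:
        for treat, ctrl in pairs:
            lfc = fold_change(ratio.at[mirna, treat], ratio.at[mirna, ctrl])
            p = tagcount_pvalue(
                int(matrix.counts.at[mirna, treat]),
                int(matrix.counts.at[mirna, ctrl]),
                totals[treat],
                totals[ctrl],
            )
            sig = abs(lfc) > FC_THRESHOLD and p < P_THRESHOLD
            rows.append(
                {
                    "miRNA": mirna,
                    "pair": f"{treat}/{ctrl}",
                    "log2fc": lfc,
                    "pvalue": p,
                    "significant": sig,
                    "stars": "**" if (sig and p < STARS_THRESHOLD) else ("*" if sig else ""),
                }
            )
    out = pd.DataFrame(
        rows, columns=["miRNA", "pair", "log2fc", "pvalue", "significant", "stars"]
    )
    return out.sort_values(["miRNA", "pair"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# two-way ANOVA (2 x 2 fixed effects, balanced)


@dataclass
class AnovaResult:
    """F and p for temperature, spermidine and their interaction."""

    f_temperature: float
    p_temperature: float
    f_spd: float
    p_spd: float
    f_interaction: float
    p_interaction: float
    df_error: int
    degenerate: bool = False


def twoway_anova(values: np.ndarray) -> AnovaResult:
    """Balanced fixed-effects two-way ANOVA of a 2 x 2 x r array.

    ``values[i, j, k]`` is replicate k at temperature level i and
    spermidine level j.  The sums of squares partition the total
    exactly.  If all residual variation is zero the F ratios are
    undefined and the result is flagged degenerate.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 3 or arr.shape[0] != 2 or arr.shape[1] != 2:
        raise DataError("expected a 2 x 2 x r array (unbalanced designs unsupported)")
    r = arr.shape[2]
    if r < 2:
        raise DataError("at least 2 replicates per cell are required")
    f_t, f_s, f_i, df_err, msel = _anova_fstats(arr)
    degenerate = not np.isfinite([f_t, f_s, f_i]).all()
    if degenerate:
        return AnovaResult(
            math.nan, math.nan, math.nan, math.nan, math.nan, math.nan,
            df_err, degenerate=True,
        )
    p = lambda f: float(stats.f.sf(f, 1, df_err))  # noqa: E731
    return AnovaResult(
        float(f_t), p(f_t), float(f_s), p(f_s), float(f_i), p(f_i), df_err
    )


def _anova_fstats(arr: np.ndarray):
    """Vectorized core: accepts (..., 2, 2, r), returns F arrays."""
    r = arr.shape[-1]
    cell = arr.mean(axis=-1)  # (..., 2, 2)
    grand = cell.mean(axis=(-1, -2))
    row = cell.mean(axis=-1)  # temperature means (..., 2)
    col = cell.mean(axis=-2)  # spd means (..., 2)
    ss_t = 2 * r * ((row - grand[..., None]) ** 2).sum(axis=-1)
    ss_s = 2 * r * ((col - grand[..., None]) ** 2).sum(axis=-1)
    inter = cell - row[..., :, None] - col[..., None, :] + grand[..., None, None]
    ss_i = r * (inter**2).sum(axis=(-1, -2))
    ss_e = ((arr - cell[..., None]) ** 2).sum(axis=(-1, -2, -3))
    df_err = 4 * (r - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_e = ss_e / df_err
        f_t = ss_t / ms_e
        f_s = ss_s / ms_e
        f_i = ss_i / ms_e
    return f_t, f_s, f_i, df_err, ms_e


def interaction_pvalues(batch: np.ndarray) -> np.ndarray:
    """Interaction p-values for a batch of 2 x 2 x r designs.

    ``batch`` has shape (n_sims, 2, 2, r); used for simulation-based
    calibration of the test.
    """
    arr = np.asarray(batch, dtype=float)
    f_t, f_s, f_i, df_err, _ = _anova_fstats(arr)
    return stats.f.sf(f_i, 1, df_err)
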