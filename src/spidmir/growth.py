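"""Growth-trait summaries and percent-change contrasts.

The growth table holds mean +/- SD per treatment (CW, CS, HW, HS) and
trait (plant height, stem diameter, leaf area, shoot fresh/dry weight).
Percent changes between treatments are reported half-up to two
decimals, the convention that reproduces published contrast tables.
Post-hoc grouping letters are preserved as opaque annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import DataError, round_half_up

TREATMENTS = ("CW", "CS", "HW", "HS")


def percent_change(value_a: float, value_b: float) -> float:
    """Percent change of b relative to a: 100 * (b - a) / a, half-up 2 dp."""
    if value_a <= 0:
        raise DataError("reference value must be positive")
    return round_half_up(100.0 * (value_b - value_a) / value_a, 2)


@dataclass
class GrowthTable:
    """Long-form table: treatment, trait, mean, sd, n, letter."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"treatment", "trait", "mean", "sd"}
        if not required <= set(self.data.columns):
            raise DataError(
                f"growth table missing columns {sorted(required - set(self.data.columns))}"
            )
        if (self.data["sd"] < 0).any():
            raise DataError("negative SD")
        present = set(self.data["treatment"])
        missing = set(TREATMENTS) - present
        if missing:
            raise DataError(f"missing treatments: {sorted(missing)}")

    def mean(self, treatment: str, trait: str) -> float:
        sel = self.data[
            (self.data["treatment"] == treatment) & (self.data["trait"] == trait)
        ]
        if sel.empty:
            raise DataError(f"no entry for ({treatment}, {trait})")
        return float(sel["mean"].iloc[0])

    def contrast(self, treatment_a: str, treatment_b: str) -> pd.Series:
        """Percent change of every trait, b relative to a."""
        traits = self.data.loc[self.data["treatment"] == treatment_a, "trait"]
        return pd.Series(
            {
                t: percent_change(self.mean(treatment_a, t), self.mean(treatment_b, t))
                for t in traits
            },
            name=f"{treatment_a}->{treatment_b} (%)",
        )

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GrowthTable":
        # keep_default_na so empty grouping-letter annotations stay strings
        return cls(pd.read_csv(path, sep="\t", keep_default_na=False))


def summarize(replicates: pd.DataFrame) -> GrowthTable:
    """Mean and sample SD per (treatment, trait) from replicate rows.

    ``replicates`` has columns treatment, trait, value; each cell needs
    at least two replicates.
    """
    required = {"treatment", "trait", "value"}
    if not required <= set(replicates.columns):
        raise DataError(
            f"replicate table missing columns {sorted(required - set(replicates.columns))}"
        )
    rows = []
    for (treatment, trait), grp in replicates.groupby(
        ["treatment", "trait"], sort=True
    ):
        vals = grp["value"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise DataError(f"cell ({treatment}, {trait}) has fewer than 2 replicates")
        rows.append(
            {
                "treatment": treatment,
                "trait": trait,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)),
                "n": len(vals),
                "letter": "",
            }
        )
    return GrowthTable(pd.DataFrame(rows))
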