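"""Small shared helpers: sequence arithmetic, reporting-grade rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_RC = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (U treated as T)."""
    return seq.translate(_RC)[::-1]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed summary tables do.

    Python's built-in round() is banker's rounding, which does not
    reproduce the half-up convention of most published tables.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """part/whole as a percentage, half-up rounded to `ndigits` decimals."""
    if whole == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * part / whole, ndigits)


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""
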