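"""Summary arithmetic and formatting for the paper-style report tables.

Shares and ratios are rounded half-up at a configurable precision (one
decimal for percentage shares, integers for bound ratios), which is the
convention every printed value in the study follows.
"""

from __future__ import annotations

import decimal

import pandas as pd


class ReportError(ValueError):
    pass


def round_half_up(x: float, decimals: int = 1) -> str:
    """Decimal round-half-up, returned as a fixed-precision string."""
    q = decimal.Decimal(1).scaleb(-decimals) if decimals > 0 else decimal.Decimal(1)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return f"{d}"


def share_percent(numerator: float, denominator: float, decimals: int = 1) -> str:
    """Percentage share formatted like "59.0%"."""
    if denominator == 0:
        raise ReportError("zero denominator in share")
    return f"{round_half_up(100.0 * numerator / denominator, decimals)}%"


def plain_ratio(numerator: float, denominator: float, decimals: int = 1) -> str:
    """Plain ratio formatted like "3.5"."""
    if denominator == 0:
        raise ReportError("zero denominator in ratio")
    return round_half_up(numerator / denominator, decimals)


def summary_ratios(numbers: dict[str, float],
                   extra: list[tuple[str, str, str, int, str]] | None = None) -> pd.DataFrame:
    """Standard summary table from named death totals.

    ``numbers`` may contain any of: total, anthropogenic, extra_regional,
    residual, within_domain, low, mid, high; every ratio whose operands are
    present is emitted.  ``extra`` adds arbitrary rows as tuples
    (name, numerator_key, denominator_key, decimals, mode) with mode
    ``percent`` or ``ratio``.
    """
    specs = [
        ("anthro_over_total", "anthropogenic", "total", 1, "percent"),
        ("anthro_over_within_domain", "anthropogenic", "within_domain", 1, "percent"),
        ("extra_over_total", "extra_regional", "total", 1, "percent"),
        ("residual_over_total", "residual", "total", 1, "percent"),
        ("residual_over_within_domain", "residual", "within_domain", 1, "percent"),
        ("low_over_mid", "low", "mid", 0, "percent"),
        ("high_over_mid", "high", "mid", 0, "percent"),
    ]
    if extra:
        specs += list(extra)
    rows = []
    for name, num_k, den_k, decimals, mode in specs:
        if num_k not in numbers or den_k not in numbers:
            continue
        num, den = numbers[num_k], numbers[den_k]
        if den == 0:
            raise ReportError(f"zero denominator for {name}")
        value = (share_percent if mode == "percent" else plain_ratio)(num, den, decimals)
        rows.append({"name": name, "numerator": num, "denominator": den,
                     "value": value})
    return pd.DataFrame(rows)
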