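"""Small formatting helpers shared by the reports and the CLI."""

from __future__ import annotations


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Share as a percentage, e.g. percent(25, 39) -> 64.1."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def percent_increase(value: float, baseline: float, decimals: int = 1) -> float:
    """Relative excess as a percentage, e.g. percent_increase(773, 449) -> 72.2."""
    if baseline == 0:
        raise ValueError("zero baseline")
    return round(100.0 * (value - baseline) / baseline, decimals)


def fmt(value: float | None, decimals: int = 4) -> str:
    return "NA" if value is None else f"{value:.{decimals}f}"
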