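"""Small reporting helpers shared by summary tables and scripts."""

from __future__ import annotations


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage rounded to the table-printing precision (one decimal by
    default), e.g. percent(7962, 33323) == 23.9."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return float(f"{100.0 * numerator / denominator:.{digits}f}")


def ratio_summary(counts: dict[str, tuple[float, float]],
                  digits: int = 1) -> dict[str, float]:
    """Apply :func:`percent` to a named {name: (numerator, denominator)}
    mapping."""
    return {name: percent(n, d, digits) for name, (n, d) in counts.items()}
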