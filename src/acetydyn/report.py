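"""Small reporting helpers: printed-style percentages and run summaries."""

from __future__ import annotations


def percent(part: float, whole: float, decimals: int = 1) -> float:
    """Percentage of ``part`` in ``whole``, rounded to ``decimals``
    (half-away-from-zero, matching how such figures are printed)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    x = 100.0 * part / whole
    scale = 10**decimals
    import math

    return math.floor(x * scale + 0.5) / scale


def fraction_of_classes(counts: dict, decimals: int = 1) -> dict:
    """Per-class percentage breakdown of a label->count mapping."""
    total = sum(counts.values())
    return {k: percent(v, total, decimals) for k, v in counts.items()}
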