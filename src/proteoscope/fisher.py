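"""Shared 2x2 contingency-table primitives (Fisher exact p, odds ratio)."""

from __future__ import annotations

from scipy import stats


def fisher_p(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher's exact p for the table [[a, b], [c, d]].

    ``alternative="greater"`` is the enrichment (upper-tail hypergeometric)
    test; ``"two-sided"`` sums all tables with probability <= that observed.
    """
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def odds_ratio(a: int, b: int, c: int, d: int, *, zero_rule: str = "haldane") -> float:
    """Sample odds ratio ad/bc.

    ``zero_rule="haldane"`` adds 0.5 to every cell when any cell is zero;
    ``zero_rule="zero"`` returns 0.0 when a == 0 (no overlap can never count
    as enriched) and inf when only the denominator vanishes.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if zero_rule == "haldane":
        if min(a, b, c, d) == 0:
            a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
            return (a2 * d2) / (b2 * c2)
        return (a * d) / (b * c)
    if zero_rule == "zero":
        if a == 0:
            return 0.0
        if b == 0 or c == 0:
            return float("inf")
        return (a * d) / (b * c)
    raise ValueError(f"unknown zero_rule {zero_rule!r}")
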