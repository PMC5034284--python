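"""Threshold Fisher gene-set enrichment and category roll-up.

A term counts as enriched only if it clears BOTH a Benjamini-Hochberg
q-value cut and a strict odds-ratio floor (default OR > 2); the OR floor
suppresses marginally enriched very large terms.  With a zero overlap
(a = 0) the odds ratio is defined as 0, so such terms can never be
enriched regardless of p.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .fisher import fisher_p, odds_ratio
from .io_formats import GeneSetCollection, ValidationError, logger


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    a: int  # query ∩ term
    b: int  # query \ term
    c: int  # term \ query
    d: int  # neither
    odds_ratio: float
    p: float
    q: float
    enriched: bool
    category: str | None = None


def threshold_fisher(query: set[str], sets: GeneSetCollection,
                     universe: set[str], or_min: float = 2.0,
                     q_max: float = 0.05) -> list[EnrichmentResult]:
    """One-sided Fisher enrichment per term with BH correction and OR floor.

    Every term is intersected with ``universe`` before counting; terms with
    empty intersection are skipped.  ``enriched`` requires q <= q_max AND
    odds_ratio > or_min (strict).
    """
    if not query:
        raise ValidationError("empty query gene list")
    if not universe:
        raise ValidationError("empty universe")
    if not query <= universe:
        raise ValidationError(f"query genes outside universe: "
                              f"{sorted(query - universe)[:5]}")
    rows = []
    for term, (name, genes) in sets.sets.items():
        term_genes = genes & universe
        if not term_genes:
            logger.info("threshold_fisher: term %s has no overlap with universe; skipped", term)
            continue
        a = len(query & term_genes)
        b = len(query) - a
        c = len(term_genes) - a
        d = len(universe) - a - b - c
        rows.append((term, name, a, b, c, d))
    if not rows:
        return []
    p_values = [fisher_p(a, b, c, d, alternative="greater")
                for _, _, a, b, c, d in rows]
    q_values = multipletests(p_values, method="fdr_bh")[1]
    out = []
    for (term, name, a, b, c, d), p, q in zip(rows, p_values, q_values):
        orr = odds_ratio(a, b, c, d, zero_rule="zero")
        out.append(EnrichmentResult(
            term_id=term, term_name=name, a=a, b=b, c=c, d=d,
            odds_ratio=orr, p=float(p), q=float(q),
            enriched=bool(q <= q_max and orr > or_min)))
    return out


def categorize(results: list[EnrichmentResult],
               category_map: dict[str, str]) -> pd.Series:
    """Percentage of enriched terms per general category.

    Terms missing from ``category_map`` fall into ``"other"``.  Percentages
    sum to 100 over all categories; any display flooring (e.g. hiding
    categories under 10%) is a rendering concern, not applied here.
    """
    enriched = [r for r in results if r.enriched]
    if not enriched:
        logger.warning("categorize: zero enriched terms")
        return pd.Series(dtype=float, name="percent")
    cats = pd.Series([category_map.get(r.term_id, "other") for r in enriched])
    pct = 100.0 * cats.value_counts() / len(enriched)
    pct.name = "percent"
    return pct.sort_values(ascending=False)


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
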