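#!/usr/bin/env python
"""Threshold Fisher enrichment of the IP-correlate gene lists.

Takes the per-layer IP correlate lists from step 05, tests them against
the fixture gene sets with the threshold Fisher test (one-sided, BH FDR
<= 0.05 AND odds ratio > 2), and rolls enriched terms up into general
categories.  Expected outcome: the non-M5 correlates enrich the immune
term, the M5 correlates the metabolic term.
"""

import json
from pathlib import Path

import proteoscope as ps
from proteoscope.enrichment import results_frame

IN = Path("results/conet")
OUT = Path("results/enrichment")
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec, tags = ps.dichotomy_network_spec(n_samples=200, seed=SEED)
    sets, category_map = ps.dichotomy_gene_sets(tags)
    universe = set(spec.gene_ids)
    correlates = json.loads((IN / "ip_correlates.json").read_text())

    for layer, per_ip in correlates.items():
        query = {g for genes in per_ip.values() for g in genes} - set(ps.IP_GENES)
        if not query:
            print(f"{layer}: no IP correlates; skipped")
            continue
        res = ps.threshold_fisher(query, sets, universe)
        results_frame(res).to_csv(OUT / f"{layer}_enrichment.tsv", sep="\t",
                                  index=False)
        enriched = [r.term_id for r in res if r.enriched]
        pct = ps.categorize(res, category_map)
        print(f"{layer}: query of {len(query)} genes; enriched terms: {enriched}")
        if not pct.empty:
            summary = ", ".join(f"{c} {v:.0f}%" for c, v in pct.items())
            print(f"  category distribution: {summary}")
            pct.to_csv(OUT / f"{layer}_categories.tsv", sep="\t")


if __name__ == "__main__":
    main()
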