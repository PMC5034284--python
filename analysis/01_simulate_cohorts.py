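#!/usr/bin/env python
"""Simulate the two study cohorts.

Generates a "breast-like" cohort, where a latent TIL/IFN infiltration
factor drives both immunoproteasome (IP) genes and lymphocyte markers and
high IP expression is protective, and an "AML-like" cohort, where IP
expression is cell-intrinsic, shifted up in FAB M5 and down in M3, and
carries a mild adverse trend.  Writes the expression and clinical TSVs
that the later steps read back.
"""

import logging
from pathlib import Path

import proteoscope as ps
from proteoscope.io_formats import write_clinical, write_expression

logging.basicConfig(level=logging.INFO, format="%(message)s")

OUT = Path("results/cohorts")
SEED = 2026
N = 500

SPECS = {
    "breast_like": ps.CohortSpec(mode="breast_like", n_samples=N,
                                 til_loading=0.9, beta_surv=-0.3, seed=SEED),
    "aml_like": ps.CohortSpec(mode="aml_like", n_samples=N, til_loading=0.9,
                              beta_surv=0.2, seed=SEED + 1),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, spec in SPECS.items():
        expr, clin = ps.generate_cohort(spec)
        write_expression(expr, OUT / f"{name}_expression_log10p.tsv")
        write_clinical(clin, OUT / f"{name}_clinical.tsv")
        n_events = (clin.vital_status == "expired").sum()
        print(f"{name}: {expr.n_genes} genes x {expr.n_samples} samples, "
              f"{n_events} deaths ({100 * n_events / N:.0f}%)")
    ps.write_manifest(OUT / "manifest.json", config=ps.load_config(), seed=SEED,
                      extra={"n_samples": N})
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
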