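import numpy as np
import pandas as pd
import pytest

import proteoscope as ps


@pytest.fixture(scope="session")
def breast_cohort():
    """High TIL coupling, n = 500: the infiltration-driven regime."""
    spec = ps.CohortSpec(mode="breast_like", til_loading=0.9, n_samples=500, seed=11)
    return ps.generate_cohort(spec)


@pytest.fixture(scope="session")
def aml_cohort():
    """Cell-intrinsic IP expression, markers decoupled."""
    spec = ps.CohortSpec(mode="aml_like", til_loading=0.9, n_samples=500, seed=11)
    return ps.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_log_expr():
    """Deterministic 6-gene x 8-sample log-scale matrix."""
    rng = np.random.default_rng(5)
    genes = ["PSMB8", "PSMB9", "PSMB10", "BG000", "BG001", "BG002"]
    vals = np.abs(rng.normal(2.5, 0.5, size=(6, 8)))
    df = pd.DataFrame(vals, index=genes, columns=[f"S{i}" for i in range(8)])
    return ps.ExpressionMatrix(df, "log10p")


@pytest.fixture(scope="session")
def toy_two_layer():
    """Hand-built 2-layer toy: 4 nodes per layer, fully alignable."""
    genes = ["G1", "G2", "G3", "G4"]
    net_a = ps.LayeredNetwork(
        layer="A", nodes=list(genes),
        edges=[("G1", "G2", 0.9), ("G2", "G3", 0.8), ("G3", "G4", 0.7)],
        tau=0.7)
    net_b = ps.LayeredNetwork(
        layer="B", nodes=list(genes),
        edges=[("G1", "G2", 0.95), ("G3", "G4", 0.85)],
        tau=0.85)
    alignment = ps.AlignmentMap(
        p_values={g: 1.0 for g in genes},
        aligned=frozenset(genes), rule="similar", alpha=0.05)
    return net_a, net_b, alignment
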