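"""Expression scoring: log transform, z-scores, global CP/IP signature scores,
cohort stratification, lineage means and extreme-decile drug-response contrast.

The global CP (constitutive proteasome) score of a sample is the sum of the
gene-wise z-scores of PSMB5/6/7; the IP (immunoproteasome) score sums
PSMB8/9/10.  Cohorts are split into k equal-size groups by score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    CP_GENES,
    IP_GENES,
    SCALE_LOG10P,
    SCALE_RPKM,
    DrugResponseTable,
    ExpressionMatrix,
    ValidationError,
    logger,
)

GROUP_NAMES = {2: ("low", "high"), 3: ("low", "mid", "high")}


@dataclass
class ScoreTable:
    """Per-sample CP/IP scores with 2- and 3-group stratification labels."""

    scores: pd.DataFrame  # index sample_id; columns cp_score, ip_score
    groups: dict[tuple[str, int], pd.Series]  # (score_name, k) -> labels

    def group(self, score: str = "ip", k: int = 2) -> pd.Series:
        return self.groups[(score, k)]


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Map raw RPKM v to log10(1000*v + 1) and retag the scale."""
    if expr.scale != SCALE_RPKM:
        raise ValidationError("log_transform requires scale=rpkm (double-transform guard)")
    values = np.log10(1000.0 * expr.values + 1.0)
    return ExpressionMatrix(values, SCALE_LOG10P)


def zscore(expr: ExpressionMatrix) -> pd.DataFrame:
    """Gene-wise z-scores (sample SD, n-1 denominator); zero-variance genes dropped.

    Returns a gene x sample DataFrame with per-gene mean 0 and SD 1.
    """
    if expr.n_samples < 3:
        raise ValidationError("zscore requires at least 3 samples")
    values = expr.values
    sd = values.std(axis=1, ddof=1)
    constant = (values.max(axis=1) - values.min(axis=1)) == 0
    if constant.any():
        dropped = list(values.index[constant])
        logger.warning("zscore: dropping %d zero-variance genes: %s", len(dropped), dropped)
        values = values.loc[~constant]
        sd = sd.loc[~constant]
    return values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)


def proteasome_score(z: pd.DataFrame, genes: tuple[str, ...]) -> pd.Series:
    """Per-sample sum of z-scores over a 3-gene catalytic-subunit set."""
    missing = [g for g in genes if g not in z.index]
    if missing:
        raise ValidationError(f"score genes missing from z matrix: {missing}")
    return z.loc[list(genes)].sum(axis=0)


def stratify(scores: pd.Series, k: int) -> pd.Series:
    """Split samples into k contiguous score-ordered groups of near-equal size.

    Samples are ordered by (score, sample_id) ascending; sizes differ by at
    most one, with remainders assigned to the lower groups.  Deterministic
    under ties via the secondary sort on sample id.
    """
    if k not in GROUP_NAMES:
        raise ValidationError(f"k must be in {sorted(GROUP_NAMES)}, got {k}")
    n = len(scores)
    if n < k:
        raise ValidationError(f"cannot split {n} samples into {k} groups")
    order = scores.to_frame("score").reset_index()
    order.columns = ["sample_id", "score"]
    order = order.sort_values(["score", "sample_id"], kind="mergesort")
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    labels = np.repeat(GROUP_NAMES[k], sizes)
    out = pd.Series(labels, index=order["sample_id"].to_numpy(), name=f"group_k{k}")
    return out.reindex(scores.index)


def score_table(expr: ExpressionMatrix,
                cp_genes: tuple[str, ...] = CP_GENES,
                ip_genes: tuple[str, ...] = IP_GENES) -> ScoreTable:
    """Compute CP/IP scores on a log-scale matrix and stratify for k in {2, 3}."""
    if expr.scale != SCALE_LOG10P:
        raise ValidationError("score_table expects log-transformed expression")
    z = zscore(expr)
    scores = pd.DataFrame(
        {
            "cp_score": proteasome_score(z, cp_genes),
            "ip_score": proteasome_score(z, ip_genes),
        }
    )
    groups = {
        (name, k): stratify(scores[f"{name}_score"], k)
        for name in ("cp", "ip")
        for k in (2, 3)
    }
    return ScoreTable(scores, groups)


def lineage_mean_expression(expr: ExpressionMatrix, genes: tuple[str, ...],
                            lineages: pd.Series) -> pd.Series:
    """Mean expression of a gene set per cell lineage.

    ``lineages`` maps sample id -> lineage label for every sample in the
    matrix; empty lineages are excluded with a warning.
    """
    missing = [s for s in expr.sample_ids if s not in lineages.index]
    if missing:
        raise ValidationError(f"samples without lineage label: {missing}")
    sub = expr.subset_genes(list(genes))
    per_sample = sub.values.mean(axis=0)
    out = per_sample.groupby(lineages.reindex(expr.sample_ids)).mean()
    empty = [lin for lin in lineages.unique() if lin not in out.index]
    if empty:
        logger.warning("lineage_mean_expression: empty lineages excluded: %s", empty)
    return out


@dataclass(frozen=True)
class DecileComparison:
    n_high: int
    n_low: int
    u_statistic: float
    p_value: float
    median_high: float
    median_low: float


def extreme_decile_response(expr: ExpressionMatrix, genes: tuple[str, ...],
                            drug: DrugResponseTable, drug_name: str,
                            pct: float = 0.10) -> DecileComparison:
    """Compare log-IC50 of the top vs bottom ``pct`` of cell lines by gene-set
    expression, with a two-sided rank-sum (Mann-Whitney U) test.

    Lines are ranked by mean expression of ``genes``; the top and bottom
    ``floor(pct * n)`` lines form the high/low groups.
    """
    ic50 = drug.for_drug(drug_name)
    shared = [s for s in expr.sample_ids if s in ic50.index]
    if len(shared) < 20:
        raise ValidationError(
            f"need >= 20 cell lines with expression and {drug_name} response, got {len(shared)}"
        )
    mean_expr = expr.subset_genes(list(genes)).values[shared].mean(axis=0)
    m = int(np.floor(pct * len(shared)))
    if m == 0:
        raise ValidationError(f"pct={pct} selects zero lines from n={len(shared)}")
    ranked = mean_expr.sort_values(kind="mergesort")
    low_lines = ranked.index[:m]
    high_lines = ranked.index[-m:]
    high = ic50[high_lines].to_numpy(dtype=float)
    low = ic50[low_lines].to_numpy(dtype=float)
    res = stats.mannwhitneyu(high, low, alternative="two-sided", method="auto")
    return DecileComparison(
        n_high=m, n_low=m, u_statistic=float(res.statistic), p_value=float(res.pvalue),
        median_high=float(np.median(high)), median_low=float(np.median(low)),
    )
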