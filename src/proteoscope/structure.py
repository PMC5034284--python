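"""Co-expression structure of the proteasome subunits.

PCA of the eight catalytic + regulatory subunit genes, marker correlations
against the IP score, hierarchical clustering of samples on the three IP
genes with Fisher enrichment of categorical labels per cluster, and the
CpG methylation-expression correlation filter (|r| > 0.2 within 10 kb of
the TSS, both inequalities strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .fisher import fisher_p, odds_ratio
from .io_formats import (
    CP_GENES,
    IP_GENES,
    REGULATORY_GENES,
    CpGAnnotation,
    ExpressionMatrix,
    MethylationMatrix,
    ValidationError,
    logger,
)

SUBUNIT_GENES = tuple(sorted(CP_GENES + IP_GENES + REGULATORY_GENES))


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # gene x [PC1, PC2], orthonormal columns
    projections: pd.DataFrame  # sample x [PC1, PC2]
    variance_fractions: np.ndarray  # all components, non-increasing


@dataclass
class SampleClustering:
    labels: pd.Series  # sample -> cluster id in 1..k
    merge_heights: np.ndarray
    linkage_name: str


@dataclass(frozen=True)
class MethylationCorrelation:
    cpg_id: str
    gene_id: str
    r: float
    signed_distance: int
    kept: bool


def pca_subunits(z: pd.DataFrame, genes: tuple[str, ...] = SUBUNIT_GENES) -> PCAResult:
    """PCA of the gene-gene covariance of z-scored subunit expression.

    Operating on z-scores makes this a correlation PCA.  Sign convention:
    the alphabetically first gene has a non-negative PC1 loading (and PC2
    loading), so results are reproducible across eigensolvers.
    """
    missing = [g for g in genes if g not in z.index]
    if missing:
        raise ValidationError(f"subunit genes missing from z matrix: {missing}")
    sub = z.loc[list(genes)]
    cov = np.cov(sub.to_numpy(), ddof=1)  # gene x gene
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    if (evals > 1e-12).sum() < 2:
        raise ValidationError("subunit covariance has rank < 2; PCA in 2D undefined")
    first = genes.index(min(genes))  # alphabetically first gene anchors the sign
    for j in range(evecs.shape[1]):
        if evecs[first, j] < 0:
            evecs[:, j] = -evecs[:, j]
    var_frac = evals / evals.sum()
    loadings = pd.DataFrame(evecs[:, :2], index=list(genes), columns=["PC1", "PC2"])
    proj = pd.DataFrame(sub.to_numpy().T @ evecs[:, :2], index=sub.columns,
                        columns=["PC1", "PC2"])
    return PCAResult(loadings, proj, var_frac)


def marker_correlation(score: pd.Series, marker: pd.Series) -> float:
    """Pearson r between a per-sample signature score and one marker gene."""
    shared = score.index.intersection(marker.index)
    if len(shared) < 3:
        raise ValidationError("marker correlation needs >= 3 shared samples")
    x = score[shared].to_numpy(dtype=float)
    y = marker[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: Pearson r undefined")
    return float(stats.pearsonr(x, y)[0])


def hcluster_samples(expr: ExpressionMatrix, k: int,
                     genes: tuple[str, ...] = IP_GENES,
                     method: str = "complete") -> SampleClustering:
    """Agglomerative clustering of samples on Euclidean distance over the
    3-gene IP profiles, cut into k clusters."""
    if k > expr.n_samples:
        raise ValidationError(f"k={k} exceeds n_samples={expr.n_samples}")
    profiles = expr.subset_genes(list(genes)).values.T.to_numpy()  # sample x gene
    Z = linkage(profiles, method=method, metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber clusters by first appearance for determinism
    remap: dict[int, int] = {}
    for c in raw:
        if c not in remap:
            remap[c] = len(remap) + 1
    labels = pd.Series([remap[c] for c in raw], index=expr.sample_ids, name="cluster")
    return SampleClustering(labels=labels, merge_heights=Z[:, 2], linkage_name=method)


def cluster_enrichment(clustering: SampleClustering,
                       categories: pd.Series) -> pd.DataFrame:
    """Per-(cluster, category) two-sided Fisher exact test.

    The 2x2 table counts in-cluster/in-category membership against the rest
    of the cohort.  The odds ratio is ad/bc with a Haldane 0.5 correction
    only when a zero cell occurs.
    """
    cats = categories.reindex(clustering.labels.index)
    if cats.isna().any():
        raise ValidationError("every sample needs a category label")
    if cats.nunique() < 2:
        raise ValidationError("cluster_enrichment needs >= 2 categories")
    rows = []
    for cl in sorted(clustering.labels.unique()):
        in_cl = clustering.labels == cl
        for cat in sorted(cats.unique()):
            in_cat = cats == cat
            a = int((in_cl & in_cat).sum())
            b = int((in_cl & ~in_cat).sum())
            c = int((~in_cl & in_cat).sum())
            d = int((~in_cl & ~in_cat).sum())
            rows.append(
                {"cluster": cl, "category": cat, "a": a, "b": b, "c": c, "d": d,
                 "odds_ratio": odds_ratio(a, b, c, d, zero_rule="haldane"),
                 "p": fisher_p(a, b, c, d, alternative="two-sided")}
            )
    return pd.DataFrame(rows)


def methylation_filter(meth: MethylationMatrix, annotations: list[CpGAnnotation],
                       expr: ExpressionMatrix, gene: str,
                       r_meth: float = 0.2,
                       window_bp: int = 10_000) -> list[MethylationCorrelation]:
    """Score every annotated CpG against one IP gene's log expression.

    A site is *kept* iff |Pearson r| > ``r_meth`` AND |signed distance to the
    TSS| < ``window_bp`` — both strict, matching the printed filter.  All
    annotated sites are scored and returned so the window-vs-threshold
    contributions stay auditable.
    """
    if gene not in expr.values.index:
        raise ValidationError(f"gene {gene} absent from expression matrix")
    shared = [s for s in meth.sample_ids if s in expr.values.columns]
    if len(shared) < 10:
        raise ValidationError(f"need >= 10 shared samples, got {len(shared)}")
    expr_vec = expr.values.loc[gene, shared].to_numpy(dtype=float)
    out: list[MethylationCorrelation] = []
    for ann in annotations:
        if ann.cpg_id not in meth.beta_values.index:
            continue
        beta = meth.beta_values.loc[ann.cpg_id, shared]
        mask = beta.notna().to_numpy()
        if mask.sum() < 3:
            continue
        b = beta.to_numpy(dtype=float)[mask]
        e = expr_vec[mask]
        if np.ptp(b) == 0 or np.ptp(e) == 0:
            r = 0.0
        else:
            r = float(stats.pearsonr(b, e)[0])
        kept = (abs(r) > r_meth) and (abs(ann.signed_distance) < window_bp)
        out.append(MethylationCorrelation(
            cpg_id=ann.cpg_id, gene_id=ann.gene_id, r=r,
            signed_distance=ann.signed_distance, kept=kept))
    logger.info("methylation_filter: %s — %d sites scored, %d kept "
                "(|r|>%g and |dist|<%d)", gene, len(out),
                sum(m.kept for m in out), r_meth, window_bp)
    return out
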