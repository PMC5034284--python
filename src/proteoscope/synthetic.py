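"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators, all pure functions of (spec, seed):

* :func:`generate_cohort` — log-scale expression for the proteasome genes,
  TIL/IFN markers and background genes, with a latent immune-infiltration
  factor coupled to the immunoproteasome (IP) genes ("breast_like" mode) or
  decoupled from them ("aml_like" mode), FAB-label-dependent IP shifts, and
  exponential proportional-hazards survival tied to the IP score.
* :func:`generate_methylation` — CpG beta values anti-correlated with the
  expression of chosen genes, planted near a synthetic TSS, plus decoy
  sites outside the window.
* :func:`generate_two_layer_networks` — two expression layers drawn from
  block-correlation Gaussians honouring per-layer module memberships, the
  fixture for co-clustering.

Expression is generated directly on the log10(1000*RPKM + 1) scale
(Gaussian, clipped at 0); raw-RPKM views are derived by the inverse
transform where needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io_formats import (
    CP_GENES,
    IP_GENES,
    MARKER_GENES,
    REGULATORY_GENES,
    SCALE_LOG10P,
    ClinicalTable,
    CpGAnnotation,
    ExpressionMatrix,
    GeneSetCollection,
    MethylationMatrix,
    ValidationError,
    logger,
)

REQUIRED_GENES = CP_GENES + IP_GENES + REGULATORY_GENES + MARKER_GENES

#: FAB-subtype mix resembling an adult AML cohort (M3 = APL, M5 = monocytic)
DEFAULT_FAB_FRACTIONS = {
    "M0": 0.08, "M1": 0.23, "M2": 0.22, "M3": 0.09,
    "M4": 0.19, "M5": 0.12, "M6": 0.07,
}


def default_gene_roster(n_background: int = 40) -> list[str]:
    background = [f"BG{i:03d}" for i in range(n_background)]
    return list(REQUIRED_GENES) + background


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``til_loading`` is the weight of the latent TIL/IFN factor on IP genes
    and markers (breast_like) or of the cell-intrinsic factor on IP genes
    (aml_like).  ``ip_fab_shift`` is added to IP-gene log expression in
    M5 samples and subtracted in M3 samples.  ``beta_surv`` is the true
    log hazard ratio per unit standardised IP score.
    """

    n_samples: int = 200
    genes: list[str] = field(default_factory=default_gene_roster)
    mode: str = "breast_like"
    til_loading: float = 0.7
    ip_fab_shift: float = 0.5
    fab_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAB_FRACTIONS))
    beta_surv: float = -0.3
    censoring_frac: float = 0.5
    noise_sd: float = 0.5
    baseline_hazard: float = math.log(2) / 1500.0  # per day; median ~4 years
    cp_loading: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("breast_like", "aml_like"):
            raise ValidationError(f"mode must be breast_like or aml_like, got {self.mode!r}")
        missing = [g for g in REQUIRED_GENES if g not in self.genes]
        if missing:
            raise ValidationError(f"gene roster missing required symbols: {missing}")
        if not (0 <= self.til_loading <= 1):
            raise ValidationError("til_loading must lie in [0, 1]")
        if not (0 <= self.censoring_frac < 1):
            raise ValidationError("censoring_frac must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        total = sum(self.fab_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"fab_fractions must sum to 1, got {total}")


# mean log10p levels; RPKM ~ 10**(mu)/1000.  Kept well above 0 so the
# clip-at-zero of the log scale stays in the far tail of every gene.
GENE_MEANS = {"proteasome": 3.0, "marker": 2.5, "background": 2.5}


def _gene_mean(gene: str) -> float:
    if gene in CP_GENES + IP_GENES + REGULATORY_GENES:
        return GENE_MEANS["proteasome"]
    if gene in MARKER_GENES:
        return GENE_MEANS["marker"]
    return GENE_MEANS["background"]


def expected_marker_correlation(lam: float, sigma: float) -> float:
    """Closed-form Pearson r between the summed 3-gene IP z-score and a
    marker gene when both load with weight ``lam`` on one latent factor
    against independent noise of SD ``sigma``."""
    num = 3 * lam * lam
    den = math.sqrt(9 * lam * lam + 3 * sigma * sigma) * math.sqrt(lam * lam + sigma * sigma)
    return num / den if den > 0 else 0.0


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Draw one cohort; deterministic given ``spec`` (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    genes = list(spec.genes)
    samples = [f"S{i:04d}" for i in range(n)]
    lam, sd = spec.til_loading, spec.noise_sd

    til_factor = rng.standard_normal(n)       # immune infiltration / IFN tone
    intrinsic_factor = rng.standard_normal(n)  # cell-autonomous programme
    cp_factor = rng.standard_normal(n)

    ip_driver = til_factor if spec.mode == "breast_like" else intrinsic_factor

    values = np.empty((len(genes), n))
    for gi, g in enumerate(genes):
        mu = _gene_mean(g)
        noise = sd * rng.standard_normal(n)
        if g in IP_GENES + REGULATORY_GENES:
            values[gi] = mu + lam * ip_driver + noise
        elif g in MARKER_GENES:
            values[gi] = mu + lam * til_factor + noise
        elif g in CP_GENES:
            values[gi] = mu + spec.cp_loading * cp_factor + noise
        else:
            values[gi] = mu + noise

    # FAB labels with the +/- shift of IP expression in M5/M3 samples;
    # the shift is a myeloid-subtype effect, so it applies in aml_like mode only
    fabs = list(spec.fab_fractions)
    probs = np.array([spec.fab_fractions[f] for f in fabs])
    fab = rng.choice(fabs, size=n, p=probs / probs.sum())
    ip_rows = [genes.index(g) for g in IP_GENES]
    if spec.mode == "aml_like":
        shift = np.where(fab == "M5", spec.ip_fab_shift,
                         np.where(fab == "M3", -spec.ip_fab_shift, 0.0))
        for gi in ip_rows:
            values[gi] += shift

    values = np.clip(values, 0.0, None)
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            SCALE_LOG10P)

    # survival: exponential proportional hazards on the standardised IP score
    ip_score = values[ip_rows].sum(axis=0)
    z_ip = (ip_score - ip_score.mean()) / ip_score.std(ddof=1)
    rates = spec.baseline_hazard * np.exp(spec.beta_surv * z_ip)
    event_time = rng.exponential(1.0 / rates)

    if spec.censoring_frac > 0:
        horizon = _censoring_horizon(rates, spec.censoring_frac)
        censor_time = rng.uniform(0.0, horizon, size=n)
        observed = np.minimum(event_time, censor_time)
        event = event_time <= censor_time
    else:
        observed = event_time
        event = np.ones(n, dtype=bool)

    idx = pd.Index(samples, name="sample_id")
    clinical = ClinicalTable(
        sample_ids=samples,
        vital_status=pd.Series(np.where(event, "expired", "living"), index=idx),
        days_to_death=pd.Series(np.where(event, np.round(observed, 1), np.nan), index=idx),
        days_to_last_followup=pd.Series(
            np.where(event, np.nan, np.round(observed, 1)), index=idx),
        labels={"FAB": pd.Series(fab, index=idx)},
    )
    logger.info("generate_cohort: mode=%s n=%d lambda=%.2f events=%d/%d",
                spec.mode, n, lam, int(event.sum()), n)
    return expr, clinical


def _censoring_horizon(rates: np.ndarray, frac: float) -> float:
    """Horizon h of administrative Uniform(0, h) censoring such that the
    expected censored fraction, averaged over the sample hazards, is frac."""

    def censored_frac(h: float) -> float:
        rh = rates * h
        return float(np.mean((1.0 - np.exp(-rh)) / rh))

    lo, hi = 1e-6, 1e8
    return brentq(lambda h: censored_frac(h) - frac, lo, hi, xtol=1e-6)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def generate_methylation(expr: ExpressionMatrix, target_genes: list[str],
                         rho_m: float = -0.9, n_cpg_per_gene: int = 10,
                         window_bp: int = 10_000, seed: int = 0,
                         slope: float = 1.0,
                         n_decoy_per_gene: int = 10
                         ) -> tuple[MethylationMatrix, list[CpGAnnotation]]:
    """CpG beta values coupled to expression via a latent Gaussian.

    For each target gene, ``n_cpg_per_gene`` sites are placed uniformly
    strictly within ``window_bp`` of a synthetic TSS with
    ``beta = logistic(slope * (rho_m * z_expr + sqrt(1 - rho_m^2) * eps))``;
    ``n_decoy_per_gene`` decoys are placed outside the window with beta
    independent of expression.  ``rho_m`` must be in [-1, 0]: promoter
    methylation represses transcription, so only anti-correlation is modelled.
    """
    if not (-1.0 <= rho_m <= 0.0):
        raise ValidationError(f"rho_m must lie in [-1, 0], got {rho_m}")
    missing = [g for g in target_genes if g not in expr.values.index]
    if missing:
        raise ValidationError(f"target genes absent from expression: {missing}")
    rng = np.random.default_rng(seed)
    n = expr.n_samples
    betas: dict[str, np.ndarray] = {}
    annots: list[CpGAnnotation] = []
    comp = math.sqrt(1.0 - rho_m * rho_m)
    for k, gene in enumerate(target_genes):
        x = expr.values.loc[gene].to_numpy(dtype=float)
        z = (x - x.mean()) / x.std(ddof=1)
        tss = 1_000_000 + 100_000 * k
        strand = "+" if k % 2 == 0 else "-"
        offsets = rng.integers(-(window_bp - 1), window_bp, size=n_cpg_per_gene)
        for j, off in enumerate(offsets):
            eps = rng.standard_normal(n)
            beta = expit(slope * (rho_m * z + comp * eps))
            cpg_id = f"cg_{gene}_{j:03d}"
            betas[cpg_id] = beta
            pos = tss + (int(off) if strand == "+" else -int(off))
            annots.append(CpGAnnotation(cpg_id=cpg_id, chromosome="chr6",
                                        position=pos, gene_id=gene,
                                        tss_position=tss, strand=strand))
        decoy_off = rng.integers(window_bp, 5 * window_bp, size=n_decoy_per_gene)
        decoy_sign = rng.choice([-1, 1], size=n_decoy_per_gene)
        for j, (off, sg) in enumerate(zip(decoy_off, decoy_sign)):
            beta = expit(slope * rng.standard_normal(n))
            cpg_id = f"cg_{gene}_decoy_{j:03d}"
            betas[cpg_id] = beta
            pos = tss + (int(off) * int(sg) if strand == "+" else -int(off) * int(sg))
            annots.append(CpGAnnotation(cpg_id=cpg_id, chromosome="chr6",
                                        position=max(pos, 0), gene_id=gene,
                                        tss_position=tss, strand=strand))
    meth = MethylationMatrix(pd.DataFrame(betas, index=expr.sample_ids).T)
    return meth, annots


# ---------------------------------------------------------------------------
# two-layer block-correlation networks
# ---------------------------------------------------------------------------


@dataclass
class NetworkSpec:
    """Block-correlation Gaussian layers for co-clustering fixtures.

    ``memberships`` maps each layer label to a module id per gene (aligned
    with ``gene_ids``).  Within-module pairs correlate at ``rho_in``,
    between-module pairs at ``rho_out``.
    """

    gene_ids: list[str]
    memberships: dict[str, list[int]]
    rho_in: float = 0.9
    rho_out: float = 0.0
    n_samples: int = 200
    gene_sd: float = 0.5
    gene_mean: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho_out < self.rho_in <= 1):
            raise ValidationError(
                f"require 0 <= rho_out < rho_in <= 1, got ({self.rho_out}, {self.rho_in})")
        if len(self.memberships) != 2:
            raise ValidationError("exactly two layers required")
        for layer, mem in self.memberships.items():
            if len(mem) != len(self.gene_ids):
                raise ValidationError(f"memberships[{layer}] length mismatch")


def _block_covariance(membership: list[int], rho_in: float, rho_out: float,
                      sd: float) -> np.ndarray:
    mem = np.asarray(membership)
    same = mem[:, None] == mem[None, :]
    corr = np.where(same, rho_in, rho_out)
    np.fill_diagonal(corr, 1.0)
    evals = np.linalg.eigvalsh(corr)
    if evals.min() < -1e-8:
        raise ValidationError("implied covariance is not positive semi-definite")
    return corr * sd * sd


def generate_two_layer_networks(spec: NetworkSpec
                                ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                           dict[str, list[int]]]:
    """Draw the two expression layers; returns (layer1, layer2, true labels).

    Layer order follows ``spec.memberships`` insertion order; the returned
    truth dict is the memberships map itself.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[ExpressionMatrix] = []
    for layer, mem in spec.memberships.items():
        cov = _block_covariance(mem, spec.rho_in, spec.rho_out, spec.gene_sd)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(mem)))
        draws = rng.standard_normal((spec.n_samples, len(mem))) @ chol.T
        values = np.clip(spec.gene_mean + draws.T, 0.0, None)
        samples = [f"{layer}_S{i:04d}" for i in range(spec.n_samples)]
        out.append(ExpressionMatrix(
            pd.DataFrame(values, index=list(spec.gene_ids), columns=samples),
            SCALE_LOG10P))
    return out[0], out[1], dict(spec.memberships)


def dichotomy_network_spec(n_immune: int = 12, n_metabolic: int = 12,
                           n_other: int = 10, rho_in: float = 0.9,
                           rho_out: float = 0.0, n_samples: int = 200,
                           seed: int = 0) -> tuple[NetworkSpec, dict[str, str]]:
    """Two-layer spec mirroring the AML dichotomy: IP genes share a module
    with immune companions in the non-M5 layer and with metabolic / cell
    cycle companions in the M5 layer.

    Returns the spec and a gene -> tag map ("immune" / "metabolic" /
    "other" / "ip").
    """
    immune = [f"IMM{i:03d}" for i in range(n_immune)]
    metabolic = [f"MET{i:03d}" for i in range(n_metabolic)]
    other = [f"OTH{i:03d}" for i in range(n_other)]
    genes = list(IP_GENES) + immune + metabolic + other
    tags = {g: "ip" for g in IP_GENES}
    tags.update({g: "immune" for g in immune})
    tags.update({g: "metabolic" for g in metabolic})
    tags.update({g: "other" for g in other})

    def mem(companions: list[str]) -> list[int]:
        labels = []
        for g in genes:
            if g in IP_GENES or g in companions:
                labels.append(0)
            elif g in other:
                labels.append(2)
            else:
                labels.append(1)
        return labels

    spec = NetworkSpec(
        gene_ids=genes,
        memberships={"non_m5": mem(immune), "m5": mem(metabolic)},
        rho_in=rho_in, rho_out=rho_out, n_samples=n_samples, seed=seed)
    return spec, tags


def dichotomy_gene_sets(tags: dict[str, str]) -> tuple[GeneSetCollection,
                                                       dict[str, str]]:
    """GMT-style gene sets and a term -> category map for the dichotomy
    fixture: one immune term, one metabolic term, plus split decoy terms."""
    immune = frozenset(g for g, t in tags.items() if t == "immune")
    metabolic = frozenset(g for g, t in tags.items() if t == "metabolic")
    other = sorted(g for g, t in tags.items() if t == "other")
    half = max(1, len(other) // 2)
    sets = {
        "TERM:IMMUNE": ("immune response", immune),
        "TERM:METABOLIC": ("metabolic and cell cycle process", metabolic),
        "TERM:OTHER_A": ("housekeeping A", frozenset(other[:half])),
        "TERM:OTHER_B": ("housekeeping B", frozenset(other[half:]) or
                         frozenset(other[:1])),
    }
    category_map = {
        "TERM:IMMUNE": "immune",
        "TERM:METABOLIC": "metabolic",
        "TERM:OTHER_A": "other",
        "TERM:OTHER_B": "other",
    }
    return GeneSetCollection(sets), category_map
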