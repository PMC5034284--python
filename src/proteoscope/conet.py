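"""Two-condition co-expression networks and coupled co-clustering.

Each condition (layer) yields an undirected network whose edges are the
gene pairs whose absolute Pearson correlation falls in the top centile.
Layers are aligned gene-by-gene by distribution similarity (two-sided
Mann-Whitney-Wilcoxon), and the two networks are co-clustered by simulated
annealing of a coupled objective:

    H = Q(layer A) + Q(layer B) + kappa * (1/|aligned|) * #{aligned genes
        assigned to the same cluster in both layers}

where Q is Newman-Girvan modularity of the unweighted thresholded graph.
Cluster labels live in one shared namespace across layers, so the coupling
term rewards consistent placement of aligned genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, ValidationError, logger

IP_GENES = ("PSMB8", "PSMB9", "PSMB10")


@dataclass
class LayeredNetwork:
    """Thresholded correlation network for one condition."""

    layer: str
    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (gene_a, gene_b, r) with gene_a < gene_b
    tau: float  # |r| of the weakest retained edge

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for a, b, r in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a}")
            if a not in node_set or b not in node_set:
                raise ValidationError(f"edge endpoint outside node set: {(a, b)}")
            if abs(r) < self.tau - 1e-12:
                raise ValidationError(f"edge {(a, b)} below threshold tau={self.tau}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, gene: str) -> set[str]:
        out = set()
        for a, b, _ in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out


@dataclass
class AlignmentMap:
    """Same-gene cross-layer alignment with the MWW p-value per gene."""

    p_values: dict[str, float]
    aligned: frozenset[str]
    rule: str
    alpha: float


@dataclass
class AnnealSchedule:
    """Geometric cooling: T starts at t0, multiplied by ``cooling`` after
    ``sweeps_per_temp`` full sweeps, until T < t_min."""

    t0: float = 1.0
    cooling: float = 0.99
    sweeps_per_temp: int = 20
    t_min: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 < self.cooling < 1):
            raise ValidationError("cooling ratio must lie in (0, 1): temperature must decrease")
        if self.t0 <= 0 or self.t_min <= 0 or self.t_min > self.t0:
            raise ValidationError("require 0 < t_min <= t0")


@dataclass
class CoClusterAssignment:
    """Joint cluster labels over (layer, gene) nodes with the achieved H."""

    labels: dict[tuple[str, str], int]
    kappa: float
    objective: float
    seed: int
    schedule: AnnealSchedule
    per_layer_q: dict[str, float] = field(default_factory=dict)

    def layer_labels(self, layer: str) -> dict[str, int]:
        return {g: c for (lay, g), c in self.labels.items() if lay == layer}


# ---------------------------------------------------------------------------
# network construction and alignment
# ---------------------------------------------------------------------------


def build_network(expr: ExpressionMatrix, centile: float = 0.01,
                  layer: str = "") -> LayeredNetwork:
    """Retain the gene pairs whose |Pearson r| lies in the top ``centile``.

    Exactly ``ceil(centile * n_pairs)`` edges are kept, counting pairs among
    the genes with nonzero variance; ties at the threshold are resolved by
    lexicographic (gene_a, gene_b) order so the edge set is reproducible.
    Zero-variance genes stay in the node set but receive no edges.
    """
    if not (0 < centile <= 0.5):
        raise ValidationError(f"centile must lie in (0, 0.5], got {centile}")
    if expr.n_samples < 3:
        raise ValidationError("build_network needs >= 3 samples")
    values = expr.values
    span = values.max(axis=1) - values.min(axis=1)  # exact-zero for constants
    live = list(values.index[span > 0])
    if len(live) < 2:
        raise ValidationError("need >= 2 genes with nonzero variance")
    sub = values.loc[live].to_numpy()
    corr = np.corrcoef(sub)
    iu = np.triu_indices(len(live), k=1)
    absr = np.abs(corr[iu])
    n_pairs = len(absr)
    m = math.ceil(centile * n_pairs)
    # stable ranking: descending |r|, then lexicographic pair order
    pairs = sorted(
        ((live[i], live[j]) if live[i] < live[j] else (live[j], live[i]),
         corr[i, j])
        for i, j in zip(*iu)
    )
    ranked = sorted(pairs, key=lambda pr: (-abs(pr[1]), pr[0]))
    kept = ranked[:m]
    tau = abs(kept[-1][1])
    edges = sorted(((a, b, float(r)) for (a, b), r in kept))
    logger.info("build_network[%s]: %d genes (%d degenerate), %d/%d pairs kept, tau=%.4f",
                layer, expr.n_genes, expr.n_genes - len(live), m, n_pairs, tau)
    return LayeredNetwork(layer=layer, nodes=list(values.index), edges=edges, tau=tau)


def align_layers(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix,
                 alpha: float = 0.05, rule: str = "similar") -> AlignmentMap:
    """Per-gene two-sided MWW test between the two layers' expression values.

    Under ``rule="similar"`` (default) a gene is aligned iff p >= alpha —
    its distribution is *not* detectably different between conditions.
    ``rule="different"`` inverts this (aligned iff p < alpha); both are kept
    because the source protocol is ambiguous on the direction.
    """
    if rule not in ("similar", "different"):
        raise ValidationError(f"rule must be 'similar' or 'different', got {rule!r}")
    shared = [g for g in expr_a.gene_ids if g in set(expr_b.gene_ids)]
    if not shared:
        raise ValidationError("layers share no genes")
    p_values: dict[str, float] = {}
    for g in shared:
        xa = expr_a.values.loc[g].to_numpy(dtype=float)
        xb = expr_b.values.loc[g].to_numpy(dtype=float)
        if len(xa) < 3 or len(xb) < 3:
            logger.warning("align_layers: gene %s has < 3 samples in a layer; skipped", g)
            continue
        if np.ptp(np.concatenate([xa, xb])) == 0:
            p = 1.0  # identical constants: indistinguishable by construction
        else:
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        p_values[g] = p
    if rule == "similar":
        aligned = frozenset(g for g, p in p_values.items() if p >= alpha)
    else:
        aligned = frozenset(g for g, p in p_values.items() if p < alpha)
    logger.info("align_layers: %d/%d genes aligned (rule=%s, alpha=%g)",
                len(aligned), len(p_values), rule, alpha)
    return AlignmentMap(p_values=p_values, aligned=aligned, rule=rule, alpha=alpha)


# ---------------------------------------------------------------------------
# coupled modularity
# ---------------------------------------------------------------------------


def modularity(net: LayeredNetwork, labels: dict[str, int]) -> float:
    """Newman-Girvan modularity of the unweighted thresholded graph."""
    m = net.n_edges
    if m == 0:
        return 0.0
    deg: dict[str, int] = {g: 0 for g in net.nodes}
    intra: dict[int, int] = {}
    for a, b, _ in net.edges:
        deg[a] += 1
        deg[b] += 1
        if labels[a] == labels[b]:
            intra[labels[a]] = intra.get(labels[a], 0) + 1
    dsum: dict[int, int] = {}
    for g in net.nodes:
        dsum[labels[g]] = dsum.get(labels[g], 0) + deg[g]
    q = 0.0
    for c, d in dsum.items():
        q += intra.get(c, 0) / m - (d / (2 * m)) ** 2
    return q


def coupled_modularity(net_a: LayeredNetwork, net_b: LayeredNetwork,
                       alignment: AlignmentMap,
                       labels: dict[tuple[str, str], int],
                       kappa: float = 1.0) -> float:
    """H = Q_A + Q_B + kappa * mean same-cluster indicator over aligned genes."""
    for net in (net_a, net_b):
        missing = [g for g in net.nodes if (net.layer, g) not in labels]
        if missing:
            raise ValidationError(f"assignment misses nodes in layer {net.layer}: {missing[:5]}")
    qa = modularity(net_a, {g: labels[(net_a.layer, g)] for g in net_a.nodes})
    qb = modularity(net_b, {g: labels[(net_b.layer, g)] for g in net_b.nodes})
    usable = [g for g in alignment.aligned
              if (net_a.layer, g) in labels and (net_b.layer, g) in labels]
    if not usable:
        if kappa > 0:
            logger.warning("coupled_modularity: empty alignment; coupling term = 0")
        coupling = 0.0
    else:
        same = sum(labels[(net_a.layer, g)] == labels[(net_b.layer, g)] for g in usable)
        coupling = kappa * same / len(usable)
    return qa + qb + coupling


# ---------------------------------------------------------------------------
# simulated-annealing co-clustering
# ---------------------------------------------------------------------------


def cocluster(net_a: LayeredNetwork, net_b: LayeredNetwork,
              alignment: AlignmentMap, kappa: float = 1.0,
              seed: int = 0, schedule: AnnealSchedule | None = None,
              n_init_clusters: int | None = None) -> CoClusterAssignment:
    """Maximise the coupled-modularity objective by simulated annealing.

    Moves are single-node reassignments, including moves to a fresh cluster;
    a zero-temperature greedy pass polishes the annealed state.  Cluster ids
    are canonicalised by decreasing cluster size.  Deterministic given seed.
    """
    if schedule is None:
        schedule = AnnealSchedule()
    if not net_a.nodes or not net_b.nodes:
        raise ValidationError("cocluster requires non-empty networks")
    if net_a.layer == net_b.layer:
        raise ValidationError("the two layers must carry distinct labels")
    rng = np.random.default_rng(seed)

    node_keys = [(net_a.layer, g) for g in net_a.nodes] + \
                [(net_b.layer, g) for g in net_b.nodes]
    index = {k: i for i, k in enumerate(node_keys)}
    n = len(node_keys)
    layer_of = np.array([0] * len(net_a.nodes) + [1] * len(net_b.nodes))

    adj: list[list[int]] = [[] for _ in range(n)]
    deg = np.zeros(n, dtype=np.int64)
    m_layer = [max(net_a.n_edges, 1), max(net_b.n_edges, 1)]
    has_edges = [net_a.n_edges > 0, net_b.n_edges > 0]
    for li, net in enumerate((net_a, net_b)):
        for a, b, _ in net.edges:
            ia, ib = index[(net.layer, a)], index[(net.layer, b)]
            adj[ia].append(ib)
            adj[ib].append(ia)
            deg[ia] += 1
            deg[ib] += 1

    # aligned partner (same gene, other layer), -1 if none
    partner = np.full(n, -1, dtype=np.int64)
    usable_aligned = [g for g in alignment.aligned
                      if (net_a.layer, g) in index and (net_b.layer, g) in index]
    for g in usable_aligned:
        ia, ib = index[(net_a.layer, g)], index[(net_b.layer, g)]
        partner[ia] = ib
        partner[ib] = ia
    coup_w = kappa / len(usable_aligned) if usable_aligned else 0.0

    # initial state: random labels over a modest palette
    n_init = n_init_clusters or max(2, int(np.sqrt(n)))
    labels = list(rng.integers(0, n_init, size=n))
    max_label = n_init
    dsum = [dict(), dict()]  # per layer: label -> degree sum
    for i in range(n):
        li = layer_of[i]
        dsum[li][labels[i]] = dsum[li].get(labels[i], 0) + int(deg[i])
    size: dict[int, int] = {}
    for lab in labels:
        size[lab] = size.get(lab, 0) + 1

    def delta(i: int, new: int) -> float:
        old = labels[i]
        if new == old:
            return 0.0
        li = int(layer_of[i])
        d = 0.0
        if has_edges[li]:
            m = m_layer[li]
            e_old = e_new = 0
            for j in adj[i]:
                if labels[j] == old:
                    e_old += 1
                elif labels[j] == new:
                    e_new += 1
            ki = int(deg[i])
            d_old = dsum[li].get(old, 0)
            d_new = dsum[li].get(new, 0)
            d += (e_new - e_old) / m - ki * (d_new - d_old + ki) / (2.0 * m * m)
        p = partner[i]
        if p >= 0 and coup_w:
            cp = labels[p]
            d += coup_w * ((1.0 if new == cp else 0.0) - (1.0 if old == cp else 0.0))
        return d

    def apply_move(i: int, new: int) -> None:
        nonlocal max_label
        old = labels[i]
        li = int(layer_of[i])
        labels[i] = new
        dsum[li][old] -= int(deg[i])
        dsum[li][new] = dsum[li].get(new, 0) + int(deg[i])
        size[old] -= 1
        if size[old] == 0:
            del size[old]
        size[new] = size.get(new, 0) + 1
        if new >= max_label:
            max_label = new + 1

    t = schedule.t0
    while t >= schedule.t_min:
        for _ in range(schedule.sweeps_per_temp):
            order = rng.permutation(n)
            cluster_draws = rng.random(n)
            accept_draws = rng.random(n)
            for idx, i in enumerate(order):
                active = list(size.keys())
                k = int(cluster_draws[idx] * (len(active) + 1))
                new = max_label if k == len(active) else active[k]
                dH = delta(int(i), new)
                if dH >= 0 or accept_draws[idx] < math.exp(dH / t):
                    apply_move(int(i), new)
        t *= schedule.cooling

    # zero-temperature greedy polish to a local optimum
    improved = True
    while improved:
        improved = False
        for i in range(n):
            active = sorted(size.keys()) + [max_label]
            best, best_d = labels[i], 0.0
            for new in active:
                dH = delta(i, new)
                if dH > best_d + 1e-15:
                    best, best_d = new, dH
            if best != labels[i]:
                apply_move(i, best)
                improved = True

    # canonicalise: renumber clusters by decreasing size, ties by first node
    first_seen = {}
    for i, lab in enumerate(labels):
        first_seen.setdefault(lab, i)
    order = sorted(size.keys(), key=lambda c: (-size[c], first_seen[c]))
    remap = {c: r + 1 for r, c in enumerate(order)}
    final = {node_keys[i]: remap[labels[i]] for i in range(n)}

    h = coupled_modularity(net_a, net_b, alignment, final, kappa)
    qa = modularity(net_a, {g: final[(net_a.layer, g)] for g in net_a.nodes})
    qb = modularity(net_b, {g: final[(net_b.layer, g)] for g in net_b.nodes})
    logger.info("cocluster: %d nodes -> %d clusters, H=%.4f (Q_%s=%.4f, Q_%s=%.4f)",
                n, len(size), h, net_a.layer, qa, net_b.layer, qb)
    return CoClusterAssignment(labels=final, kappa=kappa, objective=h, seed=seed,
                               schedule=schedule,
                               per_layer_q={net_a.layer: qa, net_b.layer: qb})


def extract_ip_correlates(net: LayeredNetwork, assignment: CoClusterAssignment,
                          ip_genes: tuple[str, ...] = IP_GENES) -> dict[str, list[str]]:
    """Genes sharing both the cluster AND a network edge with each IP gene."""
    layer_labels = assignment.layer_labels(net.layer)
    out: dict[str, list[str]] = {}
    for ip in ip_genes:
        if ip not in layer_labels or ip not in set(net.nodes):
            logger.warning("extract_ip_correlates: %s absent from layer %s", ip, net.layer)
            out[ip] = []
            continue
        cluster = layer_labels[ip]
        out[ip] = sorted(
            g for g in net.neighbors(ip) if layer_labels.get(g) == cluster
        )
    return out
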