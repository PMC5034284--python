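import itertools
import math

import numpy as np
import pandas as pd
import pytest

import proteoscope as ps
from oracles import naive_coupled_h, set_partitions, adjusted_rand_index


def _expr(values, genes=None, prefix="S"):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(arr.shape[0])]
    cols = [f"{prefix}{i:03d}" for i in range(arr.shape[1])]
    return ps.ExpressionMatrix(pd.DataFrame(np.abs(arr), index=genes, columns=cols),
                               "log10p")


class TestBuildNetwork:
    def test_edge_count_is_ceil_of_centile(self):
        rng = np.random.default_rng(0)
        mat = _expr(rng.normal(2.5, 0.5, size=(15, 40)))
        net = ps.build_network(mat, centile=0.01)
        assert net.n_edges == math.ceil(0.01 * 105) == 2

    @pytest.mark.parametrize("n_genes,centile", [(50, 0.01), (50, 0.1), (20, 0.25)])
    def test_edges_match_brute_force_ranking(self, n_genes, centile):
        rng = np.random.default_rng(n_genes)
        mat = _expr(rng.normal(2.5, 0.5, size=(n_genes, 60)))
        net = ps.build_network(mat, centile=centile)
        n_pairs = n_genes * (n_genes - 1) // 2
        m = math.ceil(centile * n_pairs)
        assert net.n_edges == m
        # brute-force: rank all pairs by |r| desc then lexicographic
        vals = mat.values
        scored = []
        for a, b in itertools.combinations(sorted(mat.gene_ids), 2):
            r = np.corrcoef(vals.loc[a], vals.loc[b])[0, 1]
            scored.append(((a, b), r))
        scored.sort(key=lambda pr: (-abs(pr[1]), pr[0]))
        expected = sorted((a, b) for (a, b), _ in scored[:m])
        assert [(a, b) for a, b, _ in net.edges] == expected
        assert all(abs(r) >= net.tau for _, _, r in net.edges)

    def test_planted_modules_dominate_edges(self):
        spec = ps.NetworkSpec(
            gene_ids=[f"G{i:03d}" for i in range(20)],
            memberships={"l1": [0] * 10 + [1] * 10, "l2": [0] * 10 + [1] * 10},
            rho_in=0.9, rho_out=0.0, n_samples=200, seed=2)
        la, _, truth = ps.generate_two_layer_networks(spec)
        net = ps.build_network(la, centile=0.25)
        mem = dict(zip(spec.gene_ids, truth["l1"]))
        within = sum(mem[a] == mem[b] for a, b, _ in net.edges)
        assert within / net.n_edges >= 0.95

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        mat = _expr(rng.normal(2.5, 0.5, size=(12, 30)))
        net1 = ps.build_network(mat, centile=0.1)
        perm = mat.values[list(np.array(mat.sample_ids)[rng.permutation(30)])]
        net2 = ps.build_network(ps.ExpressionMatrix(perm, "log10p"), centile=0.1)
        assert [(a, b) for a, b, _ in net1.edges] == [(a, b) for a, b, _ in net2.edges]

    def test_zero_variance_genes_isolated_but_retained(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(2.5, 0.5, size=(10, 30))
        vals[0] = 1.7  # constant gene
        mat = _expr(vals)
        net = ps.build_network(mat, centile=0.1)
        assert "G000" in net.nodes
        assert all("G000" not in (a, b) for a, b, _ in net.edges)
        # centile counted over the 36 live pairs
        assert net.n_edges == math.ceil(0.1 * 36)

    def test_centile_bounds(self):
        rng = np.random.default_rng(5)
        mat = _expr(rng.normal(2.5, 0.5, size=(5, 10)))
        for bad in (0.0, 0.6, -0.1):
            with pytest.raises(ps.ValidationError):
                ps.build_network(mat, centile=bad)


class TestAlignLayers:
    def test_identical_layers_fully_aligned(self):
        rng = np.random.default_rng(6)
        mat = _expr(rng.normal(2.5, 0.5, size=(8, 50)))
        al = ps.align_layers(mat, mat)
        assert al.aligned == frozenset(mat.gene_ids)
        assert all(p == pytest.approx(1.0) for p in al.p_values.values())

    def test_large_shift_breaks_alignment(self):
        rng = np.random.default_rng(7)
        mat = _expr(rng.normal(2.5, 0.5, size=(8, 100)))
        shifted = ps.ExpressionMatrix(mat.values + 10.0, "log10p")
        al = ps.align_layers(mat, shifted)
        assert al.aligned == frozenset()
        assert all(p < 1e-10 for p in al.p_values.values())

    def test_alpha_boundaries(self):
        rng = np.random.default_rng(8)
        mat_a = _expr(rng.normal(2.5, 0.5, size=(6, 40)))
        mat_b = _expr(rng.normal(2.5, 0.5, size=(6, 40)))
        # alpha = 0: p >= 0 always, every tested gene aligned
        assert len(ps.align_layers(mat_a, mat_b, alpha=0.0).aligned) == 6
        # alpha slightly above 1: only p = 1 genes could align
        al = ps.align_layers(mat_a, mat_b, alpha=1.0)
        assert al.aligned == frozenset(g for g, p in al.p_values.items() if p >= 1.0)

    def test_different_rule_inverts(self):
        rng = np.random.default_rng(9)
        mat_a = _expr(rng.normal(2.5, 0.5, size=(6, 40)))
        mat_b = ps.ExpressionMatrix(mat_a.values + 10.0, "log10p")
        assert len(ps.align_layers(mat_a, mat_b, rule="different").aligned) == 6


class TestCoupledModularity:
    def test_duplicated_layer_full_alignment_coupling_term(self, toy_two_layer):
        net_a, _, alignment = toy_two_layer
        net_b = ps.LayeredNetwork(layer="B", nodes=list(net_a.nodes),
                                  edges=list(net_a.edges), tau=net_a.tau)
        labels = {("A", g): i for i, g in enumerate(net_a.nodes)}
        labels.update({("B", g): labels[("A", g)] for g in net_a.nodes})
        kappa = 2.5
        h = ps.coupled_modularity(net_a, net_b, alignment, labels, kappa)
        qa = ps.modularity(net_a, {g: labels[("A", g)] for g in net_a.nodes})
        assert h == pytest.approx(2 * qa + kappa)  # all indicators are 1

    def test_random_assignment_on_er_graphs_near_zero_q(self):
        rng = np.random.default_rng(10)
        genes = [f"G{i:03d}" for i in range(30)]
        edges = []
        for a, b in itertools.combinations(genes, 2):
            if rng.random() < 0.15:
                edges.append((a, b, 0.9))
        net = ps.LayeredNetwork(layer="A", nodes=genes, edges=edges, tau=0.5)
        qs = []
        for s in range(40):
            rr = np.random.default_rng(s)
            labels = {g: int(rr.integers(0, 3)) for g in genes}
            qs.append(ps.modularity(net, labels))
        # random partitions have expected Q near zero (small negative O(1/m) bias)
        assert abs(np.mean(qs)) < 0.05

    def test_agrees_with_naive_evaluation_on_every_partition(self, toy_two_layer):
        net_a, net_b, alignment = toy_two_layer
        nodes = [("A", g) for g in net_a.nodes] + [("B", g) for g in net_b.nodes]
        count = 0
        for part in set_partitions(nodes):
            labels = {}
            for ci, block in enumerate(part):
                for node in block:
                    labels[node] = ci
            ours = ps.coupled_modularity(net_a, net_b, alignment, labels, 1.0)
            oracle = naive_coupled_h(net_a, net_b, set(alignment.aligned), labels, 1.0)
            assert ours == pytest.approx(oracle, abs=1e-12)
            count += 1
        assert count == 4140  # Bell(8)

    def test_empty_alignment_coupling_zero(self, toy_two_layer):
        net_a, net_b, _ = toy_two_layer
        empty = ps.AlignmentMap(p_values={}, aligned=frozenset(),
                                rule="similar", alpha=0.05)
        labels = {(l, g): 0 for l in ("A", "B") for g in net_a.nodes}
        h = ps.coupled_modularity(net_a, net_b, empty, labels, kappa=5.0)
        qa = ps.modularity(net_a, {g: 0 for g in net_a.nodes})
        qb = ps.modularity(net_b, {g: 0 for g in net_b.nodes})
        assert h == pytest.approx(qa + qb)


class TestCocluster:
    def test_stored_objective_self_consistent(self, toy_two_layer):
        net_a, net_b, alignment = toy_two_layer
        asg = ps.cocluster(net_a, net_b, alignment, kappa=1.0, seed=1)
        recomputed = ps.coupled_modularity(net_a, net_b, alignment,
                                           asg.labels, asg.kappa)
        assert asg.objective == pytest.approx(recomputed, abs=1e-12)

    def test_deterministic_given_seed(self, toy_two_layer):
        net_a, net_b, alignment = toy_two_layer
        a1 = ps.cocluster(net_a, net_b, alignment, seed=3)
        a2 = ps.cocluster(net_a, net_b, alignment, seed=3)
        assert a1.labels == a2.labels and a1.objective == a2.objective

    def test_kappa_zero_matches_single_layer_optimum(self, toy_two_layer):
        net_a, net_b, alignment = toy_two_layer
        asg = ps.cocluster(net_a, net_b, alignment, kappa=0.0, seed=5)
        # exhaustive per-layer optimum over partitions of 4 nodes
        best = {}
        for net in (net_a, net_b):
            vals = []
            for part in set_partitions(list(net.nodes)):
                labels = {g: ci for ci, block in enumerate(part) for g in block}
                vals.append(ps.modularity(net, labels))
            best[net.layer] = max(vals)
        assert asg.per_layer_q["A"] == pytest.approx(best["A"], abs=1e-9)
        assert asg.per_layer_q["B"] == pytest.approx(best["B"], abs=1e-9)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ps.ValidationError, match="cooling"):
            ps.AnnealSchedule(cooling=1.1)

    def test_kappa_monotonically_couples_toy(self, toy_two_layer):
        """On an exhaustively solved toy, raising kappa never decreases the
        number of aligned genes sharing a cluster in the optimal partition."""
        net_a, net_b, alignment = toy_two_layer
        nodes = [("A", g) for g in net_a.nodes] + [("B", g) for g in net_b.nodes]
        prev_best_same = -1
        for kappa in (0.0, 0.5, 1.0, 2.0):
            best_h, best_same = -np.inf, 0
            for part in set_partitions(nodes):
                labels = {node: ci for ci, block in enumerate(part)
                          for node in block}
                h = ps.coupled_modularity(net_a, net_b, alignment, labels, kappa)
                same = sum(labels[("A", g)] == labels[("B", g)]
                           for g in alignment.aligned)
                if h > best_h + 1e-12 or (abs(h - best_h) <= 1e-12
                                          and same > best_same):
                    best_h, best_same = h, same
            assert best_same >= prev_best_same
            prev_best_same = best_same


class TestExtractIpCorrelates:
    @staticmethod
    def _setup():
        nodes = ["PSMB8", "PSMB9", "PSMB10", "X1", "X2", "X3"]
        edges = [("PSMB8", "X1", 0.9), ("PSMB8", "X2", 0.8), ("PSMB8", "PSMB9", 0.85)]
        net = ps.LayeredNetwork(layer="L", nodes=nodes, edges=edges, tau=0.8)
        labels = {("L", n): 1 for n in nodes}
        labels[("L", "X2")] = 2  # edged to PSMB8 but in another cluster
        labels[("L", "X3")] = 1  # same cluster, no edge
        asg = ps.CoClusterAssignment(labels=labels, kappa=1.0, objective=0.0,
                                     seed=0, schedule=ps.AnnealSchedule())
        return net, asg

    def test_definition_edge_and_cluster_required(self):
        net, asg = self._setup()
        out = ps.extract_ip_correlates(net, asg)
        assert out["PSMB8"] == ["PSMB9", "X1"]  # X2 wrong cluster, X3 no edge
        assert out["PSMB9"] == ["PSMB8"]

    def test_absent_ip_gene_empty_list(self):
        net, asg = self._setup()
        out = ps.extract_ip_correlates(net, asg, ip_genes=("PSMB8", "NOPE"))
        assert out["NOPE"] == []
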