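import itertools
import math

import numpy as np
import pytest
from scipy import stats

from paracne.core import (
    aggregate_to_protein,
    annotate_spearman,
    apply_dpi,
    bootstrap_consolidate,
    consolidate_support,
    infer_candidate_edges,
    negative_correlation_summary,
    tk_tk_bias_test,
)
from paracne.networks import Edge, ProteinEdge, ProteinNetwork, SignalingNetwork
from paracne.phospho_io import KinaseList, PeptideID
from paracne.synthetic import (
    SimulationConfig,
    gene_level_performance,
    simulate_dataset,
)

from conftest import make_matrix


def pep(name, site=1):
    return PeptideID(name, (site,))


def dpi_bruteforce(net, tolerance):
    """Exhaustive all-triples DPI oracle on the undirected MI graph."""
    mi = {}
    for e in net.edges:
        mi[frozenset((e.regulator, e.substrate))] = e.mi
    nodes = sorted({p for e in net.edges for p in (e.regulator, e.substrate)})
    marked = set()
    for trio in itertools.combinations(nodes, 3):
        keys = [frozenset(pair) for pair in itertools.combinations(trio, 2)]
        if not all(k in mi for k in keys):
            continue
        vals = sorted(keys, key=lambda k: mi[k])
        if mi[vals[0]] < (1 - tolerance) * mi[vals[1]]:
            marked.add(vals[0])
    return {
        (e.regulator, e.substrate)
        for e in net.edges
        if frozenset((e.regulator, e.substrate)) not in marked
    }


def random_regulator_network(rng, n_nodes=30, n_kinases=8, density=0.35):
    nodes = [pep(f"TK{i}") for i in range(n_kinases)] + [
        pep(f"S{i}") for i in range(n_nodes - n_kinases)
    ]
    edges = []
    for i in range(n_kinases):
        for j in range(n_nodes):
            if j == i:
                continue
            if j < n_kinases and j < i:
                continue  # one edge per kinase pair
            if rng.random() < density:
                edges.append(Edge(nodes[i], nodes[j], float(rng.uniform(0.05, 1))))
    return SignalingNetwork(edges)


class TestDPI:
    def test_weakest_edge_removed(self):
        a, b, c = pep("TKA"), pep("TKB"), pep("C")
        net = SignalingNetwork(
            [Edge(a, b, 0.9), Edge(b, c, 0.8), Edge(a, c, 0.3)]
        )
        out = apply_dpi(net, 0.0)
        assert {(e.regulator, e.substrate) for e in out.edges} == {(a, b), (b, c)}

    def test_tied_minimum_is_kept(self):
        a, b, c = pep("TKA"), pep("TKB"), pep("C")
        net = SignalingNetwork(
            [Edge(a, b, 0.9), Edge(b, c, 0.8), Edge(a, c, 0.8)]
        )
        assert len(apply_dpi(net, 0.0)) == 3

    def test_never_removes_edge_maximal_in_all_its_triangles(self, rng):
        # an edge can only be pruned by a triangle in which it is weakest, so
        # an edge that is the unique maximum of every triangle containing it
        # must always survive
        for _ in range(30):
            net = random_regulator_network(rng, n_nodes=12, n_kinases=5)
            kept = {(e.regulator, e.substrate) for e in apply_dpi(net, 0.0).edges}
            mi = {frozenset((e.regulator, e.substrate)): e.mi for e in net.edges}
            in_triangle: dict[frozenset, list] = {}
            for trio in itertools.combinations(sorted(net.peptides), 3):
                keys = [frozenset(p) for p in itertools.combinations(trio, 2)]
                if all(k in mi for k in keys):
                    for k in keys:
                        in_triangle.setdefault(k, []).append(keys)
            for key, triangles in in_triangle.items():
                if all(
                    mi[key] > max(mi[k] for k in tri if k != key)
                    for tri in triangles
                ):
                    a, b = tuple(key)
                    assert (a, b) in kept or (b, a) in kept

    @pytest.mark.parametrize("tolerance", [0.0, 0.1])
    def test_matches_bruteforce_oracle(self, tolerance):
        rng = np.random.default_rng(7)
        for _ in range(40):
            net = random_regulator_network(rng)
            kept = {(e.regulator, e.substrate) for e in apply_dpi(net, tolerance).edges}
            assert kept == dpi_bruteforce(net, tolerance)

    def test_monotone_sparsification(self, rng):
        net = random_regulator_network(rng)
        assert len(apply_dpi(net, 0.0)) <= len(net)

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            apply_dpi(SignalingNetwork([]), 1.0)


class TestInfer:
    def test_planted_edges_recovered_before_dpi(self):
        # clean construction — single-parent topology, strong coupling and
        # abundances mostly above the detection floor — so that candidate
        # inference alone recovers nearly all planted edges
        hits, total = 0, 0
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed, n_tk=5, n_substrates=50, n_tumor=150, n_cell_line=50,
                n_normal=50, edges_per_tk=8, n_tk_tk_edges=0,
                multi_peptide_fraction=0, n_synergistic_pairs=0,
                coupling_strength=0.9, zero_inflation=0.4,
            )
            matrix, truth, kinases = simulate_dataset(cfg)
            net = infer_candidate_edges(matrix, kinases, m=10)
            pred = {(e.regulator.gene, e.substrate.gene) for e in net.edges}
            for sub, parents in truth.gene_parents.items():
                for tk, _ in parents:
                    total += 1
                    hits += (tk, sub) in pred
        assert hits / total >= 0.9

    def test_independent_rows_give_no_edges(self, rng):
        counts = rng.poisson(2.0, size=(40, 200))
        matrix = make_matrix(counts, kinase_genes={0, 1, 2})
        kin = KinaseList.from_symbols(["K0", "K1", "K2"])
        net = infer_candidate_edges(matrix, kin, m=8)
        assert len(net) <= 2  # Bonferroni keeps the false-edge count near zero

    def test_missing_kinases_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="kinase"):
            infer_candidate_edges(tiny_matrix, KinaseList.from_symbols(["ZZZ"]), m=2)


class TestBootstrapConsolidate:
    def test_overwhelming_edge_retained_with_full_support(self):
        cfg = SimulationConfig(
            seed=3, n_tk=2, n_substrates=10, n_tumor=100, n_cell_line=40,
            n_normal=40, edges_per_tk=3, coupling_strength=0.95,
            n_tk_tk_edges=0, multi_peptide_fraction=0, n_synergistic_pairs=0,
        )
        matrix, truth, kinases = simulate_dataset(cfg)
        b = 25
        net = bootstrap_consolidate(matrix, kinases, m=8, b=b, seed=5)
        assert len(net) > 0
        assert max(e.support for e in net.edges) == b

    def test_poisson_tail_oracle(self):
        # one sporadic edge among well-supported ones: mean support ~ 50,
        # support 1 has Poisson upper tail ~ 1 and must be dropped
        counts = np.array([50] * 99 + [1])
        keep = consolidate_support(counts, b=100, consolidation="poisson")
        mu = counts.mean()
        for s, k in [(50, keep[0]), (1, keep[-1])]:
            expected = stats.poisson.sf(s - 1, mu) * 100 < 0.05
            assert k == expected
        assert not keep[-1]

    def test_majority_vote_option(self):
        keep = consolidate_support(np.array([60, 40, 51]), b=100,
                                   consolidation="majority")
        assert list(keep) == [True, False, True]

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(
            seed=4, n_tk=3, n_substrates=15, n_tumor=60, n_cell_line=20,
            n_normal=20, edges_per_tk=4, n_synergistic_pairs=1,
        )
        matrix, _, kinases = simulate_dataset(cfg)
        n1 = bootstrap_consolidate(matrix, kinases, m=6, b=10, seed=9)
        n2 = bootstrap_consolidate(matrix, kinases, m=6, b=10, seed=9)
        assert [(e.key, e.mi, e.support) for e in n1.edges] == [
            (e.key, e.mi, e.support) for e in n2.edges
        ]

    def test_too_few_bootstraps_rejected(self, tiny_matrix, kinase_k0):
        with pytest.raises(ValueError):
            bootstrap_consolidate(tiny_matrix, kinase_k0, b=1)


class TestSpearmanAnnotation:
    def test_rank_reverse_gives_minus_one(self):
        counts = np.array([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]])
        m = make_matrix(counts, kinase_genes={0})
        net = SignalingNetwork([Edge(m.peptides[0], m.peptides[1], 0.5)])
        out = annotate_spearman(net, m)
        assert out.edges[0].rho == pytest.approx(-1.0)

    def test_constant_row_flagged_and_excluded(self):
        counts = np.array([[1, 2, 3, 4, 5], [2, 2, 2, 2, 2]])
        m = make_matrix(counts, kinase_genes={0})
        net = SignalingNetwork([Edge(m.peptides[0], m.peptides[1], 0.5)])
        out = annotate_spearman(net, m)
        assert math.isnan(out.edges[0].rho)
        n_neg, frac = negative_correlation_summary(out)
        assert n_neg == 0 and math.isnan(frac)

    def test_missing_peptide_rejected(self, tiny_matrix):
        net = SignalingNetwork([Edge(pep("NOPE"), pep("ALSO"), 0.5)])
        with pytest.raises(Exception, match="not in matrix"):
            annotate_spearman(net, tiny_matrix)


class TestProteinAggregation:
    def test_max_mi_wins(self):
        net = SignalingNetwork(
            [
                Edge(PeptideID("EGFR", (1197,)), PeptideID("X", (5,)), 0.4),
                Edge(PeptideID("EGFR", (1069,)), PeptideID("X", (12,)), 0.7),
            ]
        )
        pn = aggregate_to_protein(net)
        assert pn.edges == [ProteinEdge("EGFR", "X", 0.7)]

    def test_idempotent_on_protein_unique_networks(self):
        net = SignalingNetwork(
            [Edge(pep("TKA"), pep("S1"), 0.3), Edge(pep("TKB"), pep("S2"), 0.6)]
        )
        pn = aggregate_to_protein(net)
        assert {(e.kinase, e.substrate, e.mi_max) for e in pn.edges} == {
            ("TKA", "S1", 0.3),
            ("TKB", "S2", 0.6),
        }

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            aggregate_to_protein(SignalingNetwork([]))


class TestTkTkBias:
    def test_all_tk_targets_extreme(self):
        kin = KinaseList.from_symbols([f"TK{i}" for i in range(20)])
        edges = [
            ProteinEdge(f"TK{i}", f"TK{(i + 1) % 20}", 0.5) for i in range(20)
        ] + [ProteinEdge(f"TK{i}", f"TK{(i + 2) % 20}", 0.5) for i in range(20)]
        p = tk_tk_bias_test(ProteinNetwork(edges), kin, n_total_targets=1000)
        assert p < 1e-10

    def test_zero_tk_tk_edges_near_one(self):
        kin = KinaseList.from_symbols(["TKA"])
        pn = ProteinNetwork([ProteinEdge("TKA", "S1", 0.5)])
        assert tk_tk_bias_test(pn, kin, n_total_targets=100) == pytest.approx(1.0)

    def test_uniform_under_null_targets(self, rng):
        kin = KinaseList.from_symbols([f"TK{i}" for i in range(10)])
        universe = [f"TK{i}" for i in range(10)] + [f"S{i}" for i in range(90)]
        pvals = []
        for _ in range(300):
            targets = rng.choice(universe, size=15, replace=False)
            pn = ProteinNetwork(
                [ProteinEdge("R", t, 0.5) for t in targets]
            )
            pvals.append(tk_tk_bias_test(pn, kin, n_total_targets=100))
        # discrete p-values are super-uniform; check the right-tail behaviour
        pvals = np.array(pvals)
        assert np.mean(pvals <= 0.05) <= 0.10
        assert np.mean(pvals <= 0.5) <= 0.65


class TestPipelineRecovery:
    def test_recovery_beats_degree_matched_random(self):
        rng = np.random.default_rng(11)
        ratios = []
        for seed in (0, 1, 2):
            cfg = SimulationConfig(seed=seed)
            matrix, truth, kinases = simulate_dataset(cfg)
            net = bootstrap_consolidate(matrix, kinases, m=10, b=30, seed=seed)
            precision, recall = gene_level_performance(net, truth)
            # degree-matched random baseline: same regulators and edge counts,
            # targets drawn uniformly
            genes = sorted({p.gene for p in matrix.peptides})
            rand_edges = []
            for i, e in enumerate(net.edges):
                g = genes[rng.integers(len(genes))]
                rand_edges.append(Edge(e.regulator, PeptideID(g, (9000 + i,)), e.mi))
            rand_net = SignalingNetwork(rand_edges)
            rand_precision, _ = gene_level_performance(rand_net, truth)
            ratios.append(precision / max(rand_precision, 1e-3))
        assert np.mean(ratios) >= 3.0
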