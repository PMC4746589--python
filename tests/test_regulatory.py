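"""Motif scanning, target prediction, network topology and enrichment."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from madskit import regulatory, simulate
from madskit.io import GeneModel
from madskit.simulate import SimConfig


def naive_scan(seq, pattern, both_strands=True):
    """Character-by-character all-offsets oracle for degenerate matching."""
    seq = seq.upper()
    variants = [("+", pattern.upper())]
    if both_strands:
        variants.append(("-", regulatory.reverse_complement(pattern)))
    hits = []
    for strand, pat in variants:
        for i in range(len(seq) - len(pat) + 1):
            if all(seq[i + j] in regulatory.IUPAC[c] for j, c in enumerate(pat)):
                hits.append((i, strand))
    return sorted(hits)


class TestScanMotifs:
    def test_forward_hit_position(self):
        assert regulatory.scan_motifs("AAACCGACAA", ["CCGAC"]) == {"CCGAC": [(3, "+")]}

    def test_reverse_complement_hit(self):
        assert regulatory.scan_motifs("GTCGG", ["CCGAC"]) == {"CCGAC": [(0, "-")]}

    def test_iupac_degeneracy_semantics(self):
        assert regulatory.count_motifs("ACCGAC", ["RCCGAC"], both_strands=False) == {"RCCGAC": 1}
        assert regulatory.count_motifs("GCCGAC", ["RCCGAC"], both_strands=False) == {"RCCGAC": 1}
        assert regulatory.count_motifs("TCCGAC", ["RCCGAC"], both_strands=False) == {"RCCGAC": 0}

    def test_overlapping_occurrences_all_counted(self):
        assert regulatory.count_motifs("AAAA", ["AA"], both_strands=False) == {"AA": 3}

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            regulatory.scan_motifs("ACGT", ["CXGA"])

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=0, max_size=60),
        pattern=st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=8),
        both=st.booleans(),
    )
    def test_matches_naive_all_offsets_oracle(self, seq, pattern, both):
        assert regulatory.scan_motifs(seq, [pattern], both)[pattern] == naive_scan(
            seq, pattern, both
        )


class TestExtractUpstream:
    GENOME = {"c1": "".join("ACGT"[i % 4] for i in range(300))}

    def test_plus_strand_window(self):
        g = GeneModel("g", "c1", 101, 160, "+")  # TSS at 0-based 100
        (region,) = regulatory.extract_upstream([g], self.GENOME, 50)
        assert region.sequence == self.GENOME["c1"][50:100]
        assert not region.truncated

    def test_minus_strand_window_is_reverse_complement(self):
        g = GeneModel("g", "c1", 101, 160, "-")
        (region,) = regulatory.extract_upstream([g], self.GENOME, 50)
        assert region.sequence == regulatory.reverse_complement(self.GENOME["c1"][160:210])

    def test_truncation_at_chromosome_edge(self):
        g = GeneModel("g", "c1", 31, 90, "+")
        (region,) = regulatory.extract_upstream([g], self.GENOME, 2000)
        assert len(region) == 30 and region.truncated

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chrX"):
            regulatory.extract_upstream([GeneModel("g", "chrX", 10, 20)], self.GENOME, 5)


class TestPhaseFilteringAndTargets:
    def test_pattern_spanning_peak_boundary_not_counted(self):
        genome = {"c": "TTTTTTCCGACTTTTT"}
        # peak covers only the first three bases of the CCGAC occurrence
        peaks = [("c", 0, 9, "p1")]
        got = regulatory.filter_phase_motifs(["CCGAC"], peaks, genome, "veg")
        assert got.retained == []
        whole = regulatory.filter_phase_motifs(["CCGAC"], [("c", 0, 16, "p")], genome, "veg")
        assert whole.retained == ["CCGAC"]

    def test_empty_peak_set_retains_nothing(self):
        got = regulatory.filter_phase_motifs(["CCGAC"], [], {"c": "ACGT"}, "veg")
        assert got.retained == []

    def test_planted_subset_and_targets_recovered(self):
        cfg = SimConfig(seed=27)
        sim = simulate.gen_promoters_and_peaks(cfg)
        phase = regulatory.filter_phase_motifs(
            cfg.motif_library, sim.peaks, sim.peak_genome, "reproductive"
        )
        assert sorted(phase.retained) == sim.truth.peak_motif_subset
        regions = [
            regulatory.UpstreamRegion(g, seq, cfg.promoter_length)
            for g, seq in sim.regions.items()
        ]
        targets, present, _ = regulatory.predict_targets(phase, regions)
        assert sorted(targets) == sim.truth.true_targets
        planted_present = {
            p
            for counts in sim.truth.true_motif_counts.values()
            for p in counts
            if p in set(phase.retained)
        }
        assert present == planted_present

    def test_empty_motif_set_predicts_no_targets(self):
        regions = [regulatory.UpstreamRegion("g", "ACGT" * 100, 400)]
        targets, present, _ = regulatory.predict_targets([], regions)
        assert targets == set() and present == set()


class TestNetwork:
    def test_duplicate_edges_merge_and_self_loops_drop(self):
        net = regulatory.map_and_build_network(
            {"t"},
            {"t": "T"},
            [("T", "a"), ("a", "T"), ("T", "T"), ("b", "c")],
        )
        assert set(net.graph.edges()) == {("T", "a")} or set(net.graph.edges()) == {("a", "T")}
        assert net.seeds == {"T"}

    def test_seed_without_partners_is_eliminated(self):
        net = regulatory.map_and_build_network(
            {"lonely", "t"}, {}, [("t", "x"), ("lonely2", "y")]
        )
        assert "lonely" not in net.graph

    def test_counts_match_direct_construction_on_random_graphs(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            g = nx.gnp_random_graph(25, 0.12, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            seeds = {f"n{i}" for i in rng.choice(25, 6, replace=False)}
            net = regulatory.map_and_build_network(seeds, {}, g)
            expected_edges = {
                frozenset(e) for e in g.edges() if (e[0] in seeds or e[1] in seeds) and e[0] != e[1]
            }
            assert {frozenset(e) for e in net.graph.edges()} == expected_edges

    def test_empty_interactome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            regulatory.map_and_build_network({"t"}, {}, [])


class TestPowerLaw:
    def test_star_graph_degree_distribution(self):
        star = nx.star_graph(9)
        degs = sorted(d for _, d in star.degree())
        assert degs == [1] * 9 + [9]
        fit = regulatory.degree_and_powerlaw(star)
        assert fit.n == 10

    def test_mle_equals_grid_search_on_small_multisets(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            degs = list(rng.zipf(2.2, 40))
            alpha = regulatory.powerlaw_mle(degs)
            slogk = sum(math.log(k) for k in degs)

            def nll(a):
                return a * slogk + len(degs) * math.log(special.zeta(a, 1))

            grid = np.arange(1.01, 8.0, 1e-3)
            best = grid[int(np.argmin([nll(a) for a in grid]))]
            for _zoom in range(3):
                grid = np.linspace(best - 2e-3, best + 2e-3, 4001)
                best = grid[int(np.argmin([nll(a) for a in grid]))]
            assert alpha == pytest.approx(best, abs=1e-6)

    def test_degenerate_degrees_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            regulatory.degree_and_powerlaw([3] * 20)

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            regulatory.degree_and_powerlaw([1, 2, 3])


class TestHubs:
    def _net(self, graph):
        return regulatory.TargetNetwork(
            graph, set(graph.nodes), set(max(nx.connected_components(graph), key=len))
        )

    def test_star_center_is_the_single_hub(self):
        net = self._net(nx.star_graph(6))
        hubs, _ = regulatory.find_hubs(net, k=1)
        assert hubs == [0]

    def test_five_hubs_in_125_component_is_four_percent(self):
        g = nx.path_graph(125)
        net = self._net(g)
        hubs, pct = regulatory.find_hubs(net, k=5)
        assert len(hubs) == 5 and pct == pytest.approx(4.0)

    def test_oversized_k_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            regulatory.find_hubs(self._net(nx.path_graph(3)), k=10)


class TestEnrichment:
    def test_universe_wide_term_has_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        ann = {g: {"T"} for g in universe}
        (res,) = regulatory.go_enrichment({"g0", "g1"}, ann, universe)
        assert res.p == pytest.approx(1.0)

    def test_exact_combinatorial_value(self):
        # N=10, K=4, n=5, k=4: p = C(4,4)C(6,1)/C(10,5) = 6/252
        universe = {f"g{i}" for i in range(10)}
        ann = {f"g{i}": {"T"} for i in range(4)}
        gene_set = {"g0", "g1", "g2", "g3", "g9"}
        (res,) = regulatory.go_enrichment(gene_set, ann, universe)
        assert res.overlap == 4 and res.term_size == 4
        assert res.p == pytest.approx(6 / 252)

    def test_bh_is_monotone_and_dominates_raw_p(self):
        rng = np.random.default_rng(17)
        universe = {f"g{i}" for i in range(60)}
        ann = {}
        for g in universe:
            terms = {f"T{j}" for j in range(8) if rng.random() < 0.25}
            if terms:
                ann[g] = terms
        gene_set = set(rng.choice(sorted(universe), 15, replace=False))
        results = regulatory.go_enrichment(gene_set, ann, universe)
        assert all(r.fdr >= r.p for r in results)
        ordered = sorted(results, key=lambda r: r.p)
        for a, b in zip(ordered, ordered[1:]):
            assert a.fdr <= b.fdr + 1e-12

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="alien"):
            regulatory.go_enrichment({"alien"}, {}, {"g1"})
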