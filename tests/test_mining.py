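"""Profile mining, local alignment and naming against independent oracles."""

import math
from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from madskit import mining, simulate
from madskit.io import GeneModel
from madskit.simulate import SimConfig

B62 = substitution_matrices.load("BLOSUM62")


def brute_force_local(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0):
    """Independent Smith-Waterman oracle: best global score over all
    substring pairs, by plain memoized recursion (affine gaps; a gap of
    length k costs open + k * extend)."""
    first = gap_open + gap_extend

    def global_score(x, y):
        @lru_cache(maxsize=None)
        def rec(i, j, prev):
            if i == len(x) and j == len(y):
                return 0.0
            best = -math.inf
            if i < len(x) and j < len(y):
                best = max(best, B62[x[i], y[j]] + rec(i + 1, j + 1, "M"))
            if i < len(x):
                best = max(best, -(gap_extend if prev == "X" else first) + rec(i + 1, j, "X"))
            if j < len(y):
                best = max(best, -(gap_extend if prev == "Y" else first) + rec(i, j + 1, "Y"))
            return best

        return rec(0, 0, "M")

    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, global_score(a[i1:i2], b[j1:j2]))
    return best


class TestBuildProfile:
    def test_conserved_column_approaches_log2_twenty_bits(self):
        prof = mining.build_profile(["M", "M", "M"], pseudocount=1e-9)
        assert prof.matrix[0, mining._INDEX["M"]] == pytest.approx(math.log2(20), abs=1e-6)

    def test_background_matching_column_scores_zero(self):
        # one of each residue -> column frequency equals uniform background
        prof = mining.build_profile(list(mining.ALPHABET), pseudocount=0.5)
        assert np.allclose(prof.matrix[:, :20], 0.0, atol=1e-12)

    def test_matrix_matches_hand_computed_counts_formula(self):
        seqs = ["MAD", "MAE", "MSD"]
        pc, bg = 0.5, 1 / 20
        prof = mining.build_profile(seqs, pseudocount=pc)
        for j in range(3):
            for a_i, aa in enumerate(mining.ALPHABET):
                count = sum(1 for s in seqs if s[j] == aa)
                expected = math.log2(((count + pc * bg) / (3 + pc)) / bg)
                assert prof.matrix[j, a_i] == pytest.approx(expected)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            mining.build_profile(["MAD", "MA"])


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(seed=17, n_family_genes=3, n_background_genes=3, domain_divergence=0.0)
    sim = simulate.gen_proteome(cfg)
    profile = mining.build_profile(
        simulate.seed_alignment(sim.consensus, n=6, divergence=0.05, seed=1)
    )
    return sim, profile


class TestScanProfile:

    def test_hit_spans_the_planted_window(self, planted):
        sim, profile = planted
        for gene, (s, e) in sim.domain_spans.items():
            (hit,) = mining.scan_profile(gene, sim.proteins[gene], profile, n_decoys=200, seed=2)
            assert (hit.start, hit.end) == (s, e)
            assert hit.evalue <= 1e-4

    def test_background_proteins_score_no_hit(self, planted):
        sim, profile = planted
        for gene in (g for g in sim.proteins if g.startswith("BG")):
            assert mining.scan_profile(gene, sim.proteins[gene], profile, n_decoys=200, seed=2) == []

    def test_best_window_equals_exhaustive_window_max(self):
        rng = np.random.default_rng(5)
        profile = mining.build_profile(
            [simulate._random_protein(rng, 10) for _ in range(3)]
        )
        protein = simulate._random_protein(rng, 60)
        score, start = mining.best_window(protein, profile)
        brute = max(
            (profile.score_sequence(protein[i : i + 10]), i)
            for i in range(len(protein) - 9)
        )
        assert (score, start) == (pytest.approx(brute[0]), brute[1])

    def test_best_score_invariant_under_flank_reversal(self, planted):
        sim, profile = planted
        gene = next(iter(sim.domain_spans))
        s, e = sim.domain_spans[gene]
        seq = sim.proteins[gene]
        flipped = seq[:s][::-1] + seq[s:e] + seq[e:][::-1]
        assert mining.best_window(seq, profile)[0] == pytest.approx(
            mining.best_window(flipped, profile)[0]
        )

    def test_short_protein_yields_empty_result(self, planted):
        _, profile = planted
        assert mining.scan_profile("x", "MKV", profile, n_decoys=10, seed=0) == []


class TestConfirmMembers:
    @pytest.mark.parametrize("divergence,min_recall", [(0.15, 1.0), (0.2, 0.9)])
    def test_confirmation_recovers_diverged_family(self, divergence, min_recall):
        cfg = SimConfig(
            seed=19, n_family_genes=10, n_background_genes=30, domain_divergence=divergence
        )
        sim = simulate.gen_proteome(cfg)
        seed_aln = simulate.seed_alignment(sim.consensus, n=8, divergence=0.05, seed=3)
        profile = mining.build_profile(seed_aln)
        confirmed = mining.confirm_members(sim.proteins, profile, seed_aln, n_decoys=200, seed=4)
        family = {g for g, fam in sim.truth.family_membership.items() if fam}
        assert not (confirmed - family)  # no background leaks through
        assert len(confirmed & family) / len(family) >= min_recall

    def test_empty_input_gives_empty_confirmed_set(self):
        profile = mining.build_profile(["MADS" * 4, "MADS" * 4])
        assert mining.confirm_members({}, profile) == set()

    def test_stricter_threshold_shrinks_confirmed_set(self):
        cfg = SimConfig(seed=19, n_family_genes=6, n_background_genes=6, domain_divergence=0.1)
        sim = simulate.gen_proteome(cfg)
        seed_aln = simulate.seed_alignment(sim.consensus, n=6, divergence=0.05, seed=3)
        profile = mining.build_profile(seed_aln)
        loose = mining.confirm_members(sim.proteins, profile, seed_aln, n_decoys=100, seed=4)
        strict = mining.confirm_members(
            sim.proteins, profile, seed_aln, n_decoys=100, seed=4, evalue_threshold=1e-6
        )
        assert strict <= loose


class TestAlignLocal:
    def test_identical_sequences_are_fully_similar(self):
        score, sim_pct, cov = mining.align_local("MKVLAW", "MKVLAW")
        assert score > 0 and sim_pct == 100.0 and cov == 100.0

    def test_nonmatching_alphabets_give_empty_alignment(self):
        score, sim_pct, cov = mining.align_local("AAAA", "WWWW")
        assert (score, sim_pct, cov) == (0.0, 0.0, 0.0)

    def test_score_matches_brute_force_on_short_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = simulate._random_protein(rng, rng.integers(2, 8))
            b = simulate._random_protein(rng, rng.integers(2, 8))
            score, _, _ = mining.align_local(a, b)
            assert score == pytest.approx(brute_force_local(a, b))

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="'J'"):
            mining.align_local("MKJ", "MKV")


class TestCallOrthologs:
    def test_identical_query_maps_to_itself_as_regular(self):
        rng = np.random.default_rng(2)
        ref = {f"R{i}": simulate._random_protein(rng, 80) for i in range(5)}
        (call,) = mining.call_orthologs({"q": ref["R3"]}, ref)
        assert call.subject_id == "R3" and call.regular

    def test_coverage_exactly_fifty_is_not_regular(self):
        # aligned span covers exactly half the query: strict > 50 rule
        (call,) = mining.call_orthologs({"q": "WWWWDDDD"}, {"r": "WWWW"})
        assert call.query_coverage == 50.0
        assert not call.regular

    def test_diverged_orthologs_recover_best_hits(self):
        rng = np.random.default_rng(29)
        ref = {f"R{i:02d}": simulate._random_protein(rng, 100) for i in range(20)}
        queries = {
            f"q{i:02d}": simulate.mutate_protein(ref[f"R{i:02d}"], 0.2, rng)
            for i in range(20)
        }
        calls = mining.call_orthologs(queries, ref)
        correct = sum(1 for c in calls if c.subject_id == "R" + c.query_id[1:])
        assert correct / len(calls) >= 0.95

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            mining.call_orthologs({"q": "MKV"}, {})


class TestAssignNames:
    MODELS = [
        GeneModel("a", "chr1", 100, 200, "+", 0),
        GeneModel("b", "chr1", 500, 600, "-", 1),
        GeneModel("c", "chr2", 50, 80, "+", 0),
    ]

    def test_top_to_bottom_naming_rule(self):
        named = mining.assign_names(["c", "a", "b"], self.MODELS, prefix="MdMADS")
        assert {m.gene_id: m.assigned_name for m in named} == {
            "a": "MdMADS001",
            "b": "MdMADS002",
            "c": "MdMADS003",
        }

    def test_single_member(self):
        named = mining.assign_names(["a"], self.MODELS, prefix="X")
        assert named[0].assigned_name == "X001"

    def test_order_invariance_and_density(self):
        fwd = mining.assign_names(["a", "b", "c"], self.MODELS)
        rev = mining.assign_names(["c", "b", "a"], self.MODELS)
        assert {m.gene_id: m.assigned_name for m in fwd} == {
            m.gene_id: m.assigned_name for m in rev
        }
        assert sorted(m.assigned_name for m in fwd) == [
            "MdMADS001", "MdMADS002", "MdMADS003",
        ]

    def test_unplaced_members_named_last_in_input_order(self):
        named = mining.assign_names(["z2", "a", "z1"], self.MODELS)
        names = {m.gene_id: m.assigned_name for m in named}
        assert names["a"] == "MdMADS001"
        assert names["z2"] == "MdMADS002" and names["z1"] == "MdMADS003"

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            mining.assign_names(["a", "a"], self.MODELS)
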