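"""Synthetic datasets with machine-readable ground truth.

Every input the pipeline consumes can be generated here at desk scale with
the statistical structure the downstream analysis assumes: proteomes with a
planted ~58-residue conserved domain at tunable divergence, multi-chromosome
gene layouts with planted tandem/proximal/segmental/dispersed duplication
events, protein alignments evolved along a known tree, stage-structured FPKM
matrices with anti-correlated repressor/activator gene pairs, promoters with
exactly-known degenerate-motif counts, ChIP-style peak sets carrying a chosen
subset of a motif library, and scale-free interactomes with planted hubs and
one planted enriched GO term.  Generators are byte-deterministic under a
fixed seed; each draws from its own substream so adding one stage never
perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import io as mio
from .io import GeneModel
from .regulatory import (
    count_motifs,
    filter_phase_motifs,
    reverse_complement,
    scan_motifs,
    IUPAC,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"

# default degenerate-motif library: pairwise non-nested, none self-complementary,
# so planted occurrence counts are exact under both-strand scanning
DEFAULT_MOTIF_LIBRARY = [
    "CCGAC",        # LTRE / CRT core
    "CCWWWWWWAG",   # CArG-like box
    "TTGACY",       # W-box
    "GATAAG",       # GATA / I-box core
    "TGTCTC",       # AuxRE
    "ACGTGKC",      # ABRE-like
    "CAATKATTG",    # MADS-adjacent A/T-rich element
    "AGATCCAA",     # GT1-like
]

DEFAULT_PHASE_DESIGN = (
    ("apical_bud", 3),
    ("spur_bud", 5),
    ("flower", 6),
    ("fruit", 7),
)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _random_protein(rng, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, int(n)))


def _random_dna(rng, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, int(n)))


def mutate_protein(seq: str, p: float, rng) -> str:
    """Substitute each site with probability ``p`` (uniform over other 19)."""
    chars = list(seq)
    for i, c in enumerate(chars):
        if rng.random() < p:
            pool = AMINO_ACIDS.replace(c, "")
            chars[i] = pool[rng.integers(len(pool))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Configuration and ground truth


@dataclass
class SimConfig:
    """Knobs for every generator; defaults are the study conditions.

    The family size / expression split (142 genes, 63 expressed) and the
    21-sample phenological design (3 apical-bud, 5 spur-bud, 6 flower, 7
    fruit stages) mirror the apple MADS-box study design the pipeline
    targets.
    """

    seed: int = 0
    # proteome
    n_family_genes: int = 50
    n_background_genes: int = 500
    domain_length: int = 58
    domain_divergence: float = 0.15
    flank_length: tuple[int, int] = (40, 80)
    background_length: tuple[int, int] = (120, 250)
    # genome layout
    n_chromosomes: int = 5
    genes_per_chromosome: int = 60
    duplication_events: list[tuple[str, int]] = field(default_factory=list)
    n_singleton_family: int = 10
    duplicate_divergence: float = 0.05
    proximal_window: int = 20
    gene_length: int = 300
    # expression
    phase_design: tuple = DEFAULT_PHASE_DESIGN
    n_expression_pairs: int = 10
    n_bystander_genes: int = 43
    n_silent_genes: int = 79
    expression_noise: float = 0.2
    reciprocal_window: int = 10
    # promoters / peaks
    motif_library: list[str] = field(default_factory=lambda: list(DEFAULT_MOTIF_LIBRARY))
    planted_motif_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    promoter_length: int = 2000
    n_promoter_genes: int = 20
    n_peaks: int = 12
    peak_width: int = 200
    peak_subset_size: int = 5
    # interactome / GO
    interactome_size: int = 1000
    powerlaw_exponent: float = 2.5
    n_hubs: int = 0
    n_true_targets: int = 30
    n_go_terms: int = 15
    enriched_term_fraction: float = 0.8
    go_background_rate: float = 0.02

    def validate(self) -> None:
        if not (0.0 <= self.domain_divergence < 1.0):
            raise ValueError("domain_divergence must lie in [0, 1)")
        if self.domain_length < 10:
            raise ValueError("domain_length must be >= 10")
        for gene, counts in self.planted_motif_counts.items():
            for motif, n in counts.items():
                if n < 0:
                    raise ValueError(f"planted count for {gene}/{motif} is negative")
        if len(self.phase_design) and sum(n for _, n in self.phase_design) < 2:
            raise ValueError("need at least 2 stages")


@dataclass
class GroundTruth:
    """What the generators planted, keyed by emitted entity IDs."""

    family_membership: dict[str, bool] = field(default_factory=dict)
    duplication_class: dict[str, str] = field(default_factory=dict)
    duplication_events: list[tuple[str, list[str]]] = field(default_factory=list)
    true_tree: str | None = None
    archetype: dict[str, str] = field(default_factory=dict)
    expression_pairs: list[tuple[str, str]] = field(default_factory=list)
    true_motif_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    peak_motif_subset: list[str] = field(default_factory=list)
    true_targets: list[str] = field(default_factory=list)
    hub_nodes: list[str] = field(default_factory=list)
    enriched_terms: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Proteome


@dataclass
class ProteomeSim:
    proteins: dict[str, str]
    consensus: str
    domain_spans: dict[str, tuple[int, int]]
    truth: GroundTruth


def gen_proteome(config: SimConfig) -> ProteomeSim:
    """Family proteins with one planted domain instance; i.i.d. background.

    Each family protein is random flank + (consensus mutated per-site with
    probability ``domain_divergence``) + random flank; background proteins
    are i.i.d. uniform draws over the 20 amino acids.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    consensus = _random_protein(rng, config.domain_length)
    proteins: dict[str, str] = {}
    spans: dict[str, tuple[int, int]] = {}
    truth = GroundTruth()
    lo, hi = config.flank_length
    for i in range(config.n_family_genes):
        name = f"FAM{i + 1:04d}"
        nflank = _random_protein(rng, rng.integers(lo, hi + 1))
        cflank = _random_protein(rng, rng.integers(lo, hi + 1))
        domain = mutate_protein(consensus, config.domain_divergence, rng)
        proteins[name] = nflank + domain + cflank
        spans[name] = (len(nflank), len(nflank) + config.domain_length)
        truth.family_membership[name] = True
    blo, bhi = config.background_length
    for i in range(config.n_background_genes):
        name = f"BG{i + 1:04d}"
        proteins[name] = _random_protein(rng, rng.integers(blo, bhi + 1))
        truth.family_membership[name] = False
    return ProteomeSim(proteins, consensus, spans, truth)


def seed_alignment(
    consensus: str, n: int = 10, divergence: float = 0.05, seed: int = 0
) -> dict[str, str]:
    """Gap-free alignment of diverged consensus copies, for profile building."""
    rng = _rng(seed, 11)
    return {
        f"SEED{i + 1:02d}": mutate_protein(consensus, divergence, rng)
        for i in range(n)
    }


# ---------------------------------------------------------------------------
# Genome layout with planted duplication events


@dataclass
class GenomeSim:
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    family_proteins: dict[str, str]
    truth: GroundTruth


def gen_genome_layout(config: SimConfig) -> GenomeSim:
    """Ordered non-overlapping gene models with planted duplication events.

    Tandem events place the duplicate at the adjacent gene-order position,
    proximal within <= ``proximal_window`` positions, segmental as a block of
    >= 5 consecutive homologous gene pairs copied to another chromosome, and
    dispersed as a homolog pair on different chromosomes.  Infeasible
    placements raise rather than truncating silently.
    """
    config.validate()
    rng = _rng(config.seed, 2)
    chroms = [f"Chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    gpc = config.genes_per_chromosome
    free: dict[str, set[int]] = {c: set(range(gpc)) for c in chroms}
    assigned: dict[tuple[str, int], str] = {}  # (chrom, slot) -> protein
    truth = GroundTruth()
    family_slots: dict[str, tuple[str, int]] = {}

    def claim(chrom, slots, proteins, gene_ids, mode):
        for s, p, gid in zip(slots, proteins, gene_ids):
            free[chrom].discard(s)
            assigned[(chrom, s)] = p
            family_slots[gid] = (chrom, s)
            truth.duplication_class[gid] = mode
            truth.family_membership[gid] = True

    def find_run(chrom, k, max_tries=500):
        """A run of k consecutive free slots on ``chrom``, or None."""
        if k > gpc:
            return None
        for _ in range(max_tries):
            i = int(rng.integers(0, gpc - k + 1))
            if all(i + j in free[chrom] for j in range(k)):
                return i
        return None

    gene_counter = [0]
    segmental_pairs: set[frozenset] = set()
    dispersed_pair_load: dict[frozenset, int] = {}

    def new_id():
        gene_counter[0] += 1
        return f"FG{gene_counter[0]:04d}"

    for ev_idx, (mode, size) in enumerate(config.duplication_events):
        placed = False
        for _ in range(200):
            if mode == "tandem":
                chrom = chroms[rng.integers(len(chroms))]
                i = find_run(chrom, 2)
                if i is None:
                    continue
                src = _random_protein(rng, rng.integers(100, 161))
                dup = mutate_protein(src, config.duplicate_divergence, rng)
                ids = [new_id(), new_id()]
                claim(chrom, [i, i + 1], [src, dup], ids, "tandem")
            elif mode == "proximal":
                chrom = chroms[rng.integers(len(chroms))]
                delta = int(rng.integers(2, config.proximal_window + 1))
                i = int(rng.integers(0, gpc - delta))
                if i not in free[chrom] or i + delta not in free[chrom]:
                    continue
                src = _random_protein(rng, rng.integers(100, 161))
                dup = mutate_protein(src, config.duplicate_divergence, rng)
                ids = [new_id(), new_id()]
                claim(chrom, [i, i + delta], [src, dup], ids, "proximal")
            elif mode == "segmental":
                if size < 5:
                    raise ValueError("segmental event size must be >= 5")
                ca, cb = rng.choice(len(chroms), 2, replace=False)
                ca, cb = chroms[ca], chroms[cb]
                i = find_run(ca, size)
                j = find_run(cb, size)
                if i is None or j is None:
                    continue
                srcs = [
                    _random_protein(rng, rng.integers(100, 161)) for _ in range(size)
                ]
                dups = [
                    mutate_protein(s, config.duplicate_divergence, rng) for s in srcs
                ]
                ids_a = [new_id() for _ in range(size)]
                ids_b = [new_id() for _ in range(size)]
                claim(ca, range(i, i + size), srcs, ids_a, "segmental")
                claim(cb, range(j, j + size), dups, ids_b, "segmental")
                segmental_pairs.add(frozenset((ca, cb)))
            elif mode == "dispersed":
                ca, cb = rng.choice(len(chroms), 2, replace=False)
                ca, cb = chroms[ca], chroms[cb]
                key = frozenset((ca, cb))
                # keep dispersed pairs off chromosome pairs hosting a
                # segmental block (and < min_block per pair) so a dispersed
                # anchor can never be chained into a collinear block
                if key in segmental_pairs or dispersed_pair_load.get(key, 0) >= 4:
                    continue
                i, j = find_run(ca, 1), find_run(cb, 1)
                if i is None or j is None:
                    continue
                dispersed_pair_load[key] = dispersed_pair_load.get(key, 0) + 1
                src = _random_protein(rng, rng.integers(100, 161))
                dup = mutate_protein(src, config.duplicate_divergence, rng)
                ids = [new_id(), new_id()]
                claim(ca, [i], [src], [ids[0]], "dispersed")
                claim(cb, [j], [dup], [ids[1]], "dispersed")
            else:
                raise ValueError(f"unknown duplication class {mode!r}")
            members = [
                g for g, cls in truth.duplication_class.items()
                if g.startswith("FG")
            ][-(2 * size if mode == "segmental" else 2):]
            truth.duplication_events.append((mode, members))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"infeasible placement for duplication event #{ev_idx} ({mode}, {size})"
            )

    for _ in range(config.n_singleton_family):
        chrom = chroms[rng.integers(len(chroms))]
        i = find_run(chrom, 1)
        if i is None:
            raise ValueError("infeasible placement for singleton family gene")
        gid = new_id()
        claim(chrom, [i], [_random_protein(rng, rng.integers(100, 161))], [gid], "singleton")

    # lay out coordinates: every slot becomes a gene; family slots keep their ids
    genes: list[GeneModel] = []
    chrom_seqs: dict[str, str] = {}
    family_proteins: dict[str, str] = {}
    slot_to_gene = {v: k for k, v in family_slots.items()}
    for chrom in chroms:
        pos = 1
        for slot in range(gpc):
            pos += int(rng.integers(200, 801))
            start, end = pos, pos + config.gene_length - 1
            gid = slot_to_gene.get((chrom, slot), f"{chrom}.bg{slot + 1:03d}")
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gid, chrom, start, end, strand, slot))
            if (chrom, slot) in assigned:
                family_proteins[gid] = assigned[(chrom, slot)]
            pos = end
        chrom_seqs[chrom] = _random_dna(rng, pos + 500)
    return GenomeSim(chrom_seqs, genes, family_proteins, truth)


# ---------------------------------------------------------------------------
# Sequence evolution along a tree


def random_tree(
    n_taxa: int, seed: int = 0, branch_range: tuple[float, float] = (0.1, 1.0)
) -> str:
    """Random binary tree (newick) by sequential joining; positive lengths."""
    rng = _rng(seed, 3)
    lo, hi = branch_range
    clusters = [f"T{i + 1}" for i in range(n_taxa)]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        a, b = clusters[i], clusters[j]
        la, lb = rng.uniform(lo, hi), rng.uniform(lo, hi)
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return clusters[0] + ";"


def tree_distance_matrix(newick: str):
    """Leaf-to-leaf path-length matrix of a newick tree (dendropy-backed)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    names = [t.label for t in taxa]
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return names, d


def gen_alignment_on_tree(
    tree, root_sequence: str, seed: int = 0, rate: float = 1.0
) -> dict[str, str]:
    """Evolve a gap-free protein alignment along a tree (Poisson model).

    On a branch of length b, the number of substitution events is
    Poisson(b * rate * L); each event hits a uniform site and replaces the
    residue with a uniform draw over the other 19.  Returns leaf -> sequence.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = _rng(seed, 4)
    L = len(root_sequence)
    seqs: dict[int, str] = {}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = root_sequence
        else:
            bl = node.edge.length or 0.0
            if bl < 0:
                raise ValueError(f"negative branch length {bl} on edge to {node}")
            seq = seqs[id(node.parent_node)]
            chars = list(seq)
            for _ in range(rng.poisson(bl * rate * L)):
                site = int(rng.integers(L))
                pool = AMINO_ACIDS.replace(chars[site], "")
                chars[site] = pool[rng.integers(len(pool))]
            seq = "".join(chars)
        seqs[id(node)] = seq
        if node.is_leaf():
            out[node.taxon.label] = seq
    return out


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionSim:
    matrix: pd.DataFrame
    phases: dict[str, str]
    samples: list[str]
    truth: GroundTruth


def gen_expression(config: SimConfig) -> ExpressionSim:
    """Stage-structured FPKM matrix with planted expression archetypes.

    Repressor genes decline linearly across the dormancy-to-bloom window
    (first ``reciprocal_window`` samples) while their paired activators rise
    mirror-symmetrically, so at zero noise each pair is exactly
    anti-correlated; bystander genes are expressed at random levels; silent
    genes stay below FPKM 1 in every sample.  Noise is multiplicative
    log-normal.
    """
    config.validate()
    rng = _rng(config.seed, 5)
    samples = [
        f"{phase}_{i + 1}"
        for phase, count in config.phase_design
        for i in range(count)
    ]
    phases = {
        f"{phase}_{i + 1}": phase
        for phase, count in config.phase_design
        for i in range(count)
    }
    w = min(config.reciprocal_window, len(samples))
    # profiles are linear on the log2(FPKM + 1) scale, so a planted pair is
    # exactly anti-correlated there at zero noise
    lhi, llo = 5.0, 1.0
    ldecline = np.linspace(lhi, llo, w)
    truth = GroundTruth()
    rows, index = [], []

    def noisy(base):
        if config.expression_noise == 0:
            return base
        return base * np.exp(rng.normal(0.0, config.expression_noise, base.size))

    for i in range(config.n_expression_pairs):
        rep, act = f"REP{i + 1:03d}", f"ACT{i + 1:03d}"
        lrep = np.concatenate([ldecline, np.full(len(samples) - w, llo)])
        rep_base = 2.0**lrep - 1.0
        act_base = 2.0 ** ((lhi + llo) - lrep) - 1.0
        rows.append(noisy(rep_base))
        index.append(rep)
        rows.append(noisy(act_base))
        index.append(act)
        truth.archetype[rep] = "repressor"
        truth.archetype[act] = "activator"
        truth.expression_pairs.append((rep, act))
    for i in range(config.n_bystander_genes):
        gid = f"EXP{i + 1:03d}"
        base = rng.uniform(2.0, 50.0, len(samples))
        rows.append(noisy(base))
        index.append(gid)
        truth.archetype[gid] = "expressed"
    for i in range(config.n_silent_genes):
        gid = f"SIL{i + 1:03d}"
        rows.append(rng.uniform(0.0, 0.5, len(samples)))
        index.append(gid)
        truth.archetype[gid] = "silent"
    matrix = pd.DataFrame(np.vstack(rows), index=index, columns=samples)
    return ExpressionSim(matrix, phases, samples, truth)


# ---------------------------------------------------------------------------
# Promoters and ChIP-style peaks


def _realize(pattern: str, rng) -> str:
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in pattern.upper())


def _plant_region(
    rng, length: int, wanted: dict[str, int], library: list[str], max_tries: int = 200
) -> str:
    """A random sequence containing exactly the wanted motif occurrences.

    Background occurrences of any library pattern are removed by resampling
    the offending window; the finished region is re-scanned and rebuilt if
    planting junctions ever created an accidental hit.
    """
    total = sum(wanted.values())
    longest = max((len(p) for p in library), default=0)
    if any(len(p) > length for p in wanted if wanted[p] > 0):
        raise ValueError("motif longer than region")
    if total * (longest + 2) > length:
        raise ValueError("planted counts inconsistent with region length")
    for _ in range(max_tries):
        seq = list(_random_dna(rng, length))
        placements: list[tuple[int, int]] = []  # (start, end) occupied windows
        ok = True
        for motif, count in wanted.items():
            for _ in range(count):
                for _try in range(200):
                    start = int(rng.integers(0, length - len(motif) + 1))
                    end = start + len(motif)
                    if all(end <= s or start >= e for s, e in placements):
                        realized = _realize(motif, rng)
                        if rng.random() < 0.5:
                            realized = reverse_complement(realized)
                        seq[start:end] = realized
                        placements.append((start, end))
                        break
                else:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        text = "".join(seq)
        # iteratively resample windows of accidental hits
        for _repair in range(50):
            extra = []
            for pat, hits in scan_motifs(text, library).items():
                target = wanted.get(pat, 0)
                if len(hits) == target:
                    continue
                planted_starts = {
                    s for s, e in placements
                }  # planted windows of this or other motifs
                for pos, strand in hits:
                    window = (pos, pos + len(pat))
                    if not any(
                        pos >= s and window[1] <= e for s, e in placements
                    ):
                        extra.append(window)
            if not extra:
                break
            chars = list(text)
            bad = False
            for s, e in extra:
                if any(e > ps and s < pe for ps, pe in placements):
                    bad = True  # accidental hit overlaps a planted window
                    break
                chars[s:e] = _random_dna(rng, e - s)
            if bad:
                break
            text = "".join(chars)
        counts = count_motifs(text, library)
        if all(counts[p] == wanted.get(p, 0) for p in library):
            return text
    raise RuntimeError("could not realize planted motif counts; region too dense")


@dataclass
class PromoterSim:
    regions: dict[str, str]
    peak_genome: dict[str, str]
    peaks: list[tuple[str, int, int, str]]
    truth: GroundTruth


def gen_promoters_and_peaks(config: SimConfig) -> PromoterSim:
    """Upstream regions with exact planted motif counts, plus a peak set.

    Peaks carry a chosen subset of the motif library (each subset pattern
    planted wholly inside >= 1 peak; no other library pattern occurs inside
    any peak), so phase filtering must recover exactly that subset.  Gene
    regions contain exactly their planted occurrences and nothing else from
    the library.
    """
    config.validate()
    rng = _rng(config.seed, 6)
    library = list(config.motif_library)
    truth = GroundTruth()

    subset = sorted(
        str(p)
        for p in rng.choice(library, min(config.peak_subset_size, len(library)), replace=False)
    ) if library else []
    truth.peak_motif_subset = list(subset)

    planted = {g: dict(c) for g, c in config.planted_motif_counts.items()}
    if not planted and library:
        # default scenario: half the promoter genes are targets carrying
        # subset patterns, a few decoys carry only non-subset patterns
        non_subset = [p for p in library if p not in subset]
        for i in range(config.n_promoter_genes):
            gid = f"P{i + 1:03d}"
            if i < config.n_promoter_genes // 2 and subset:
                pat = subset[i % len(subset)]
                planted[gid] = {pat: int(rng.integers(1, 4))}
            elif i < config.n_promoter_genes // 2 + 4 and non_subset:
                pat = non_subset[i % len(non_subset)]
                planted[gid] = {pat: 1}
            else:
                planted[gid] = {}

    regions: dict[str, str] = {}
    for gid in sorted(planted):
        wanted = {p: planted[gid].get(p, 0) for p in library}
        regions[gid] = _plant_region(rng, config.promoter_length, wanted, library)
        truth.true_motif_counts[gid] = {p: n for p, n in wanted.items() if n > 0}
    truth.true_targets = sorted(
        g for g, c in truth.true_motif_counts.items()
        if any(p in subset and n > 0 for p, n in c.items())
    )

    # peak genome: one chromosome; subset patterns planted inside peaks
    spacing, width = 400, config.peak_width
    peaks: list[tuple[str, int, int, str]] = []
    chrom_parts: list[str] = []
    pos = 0
    for i in range(config.n_peaks):
        gap = _plant_region(rng, spacing, {p: 0 for p in library}, library)
        chrom_parts.append(gap)
        pos += spacing
        wanted = {p: 0 for p in library}
        if subset:
            wanted[subset[i % len(subset)]] = 1
        peak_seq = _plant_region(rng, width, wanted, library)
        chrom_parts.append(peak_seq)
        peaks.append(("PeakChr", pos, pos + width, f"peak{i + 1}"))
        pos += width
    chrom_parts.append(_plant_region(rng, spacing, {p: 0 for p in library}, library))
    genome = {"PeakChr": "".join(chrom_parts)}

    if library:
        got = filter_phase_motifs(library, peaks, genome, "check")
        assert sorted(got.retained) == list(subset), "peak planting failed"
    return PromoterSim(regions, genome, peaks, truth)


# ---------------------------------------------------------------------------
# Interactome and GO annotations


@dataclass
class InteractomeSim:
    graph: "object"  # networkx.Graph
    annotations: dict[str, set[str]]
    enriched_term: str
    truth: GroundTruth


def gen_interactome(config: SimConfig, target_nodes=None) -> InteractomeSim:
    """Scale-free interactome with optional planted hubs and one enriched term.

    Node degrees are drawn from the discrete power law (Zipf) at
    ``powerlaw_exponent`` and realized exactly with a Havel-Hakimi
    construction followed by a random relabeling, so the degree distribution
    carries the target exponent.  Hub planting (``n_hubs`` > 0) then adds
    edges to push designated nodes above every other degree.  One GO term is
    attached to ``enriched_term_fraction`` of the target set on top of a
    uniform background annotation rate.
    """
    import networkx as nx

    config.validate()
    if config.powerlaw_exponent <= 1:
        raise ValueError("powerlaw_exponent must be > 1")
    if config.interactome_size < 10:
        raise ValueError("interactome_size must be >= 10")
    rng = _rng(config.seed, 7)
    n = config.interactome_size
    for _ in range(100):
        deg = rng.zipf(config.powerlaw_exponent, n)
        while (deg > n - 1).any():
            deg[deg > n - 1] = rng.zipf(config.powerlaw_exponent, int((deg > n - 1).sum()))
        if deg.sum() % 2:
            deg[int(rng.integers(n))] += 1
        if nx.is_graphical(deg):
            break
    else:
        raise RuntimeError("could not draw a graphical degree sequence")
    g = nx.havel_hakimi_graph([int(d) for d in deg])
    names = [f"At{i + 1:04d}" for i in range(n)]
    perm = rng.permutation(n)
    g = nx.relabel_nodes(g, {i: names[perm[i]] for i in range(n)})

    truth = GroundTruth()
    if config.n_hubs:
        hubs = sorted(str(h) for h in rng.choice(names, config.n_hubs, replace=False))
        top = max(d for _, d in g.degree())
        for rank, hub in enumerate(hubs):
            want = top + 2 + (config.n_hubs - rank)
            candidates = [v for v in names if v != hub and not g.has_edge(hub, v)]
            extra = want - g.degree(hub)
            if extra > 0:
                picks = rng.choice(len(candidates), extra, replace=False)
                g.add_edges_from((hub, candidates[int(i)]) for i in picks)
        truth.hub_nodes = hubs

    if target_nodes is None:
        target_nodes = sorted(
            str(x) for x in rng.choice(names, min(config.n_true_targets, n), replace=False)
        )
    truth.true_targets = sorted(target_nodes)

    enriched = "GO:0009909"  # regulation of flower development, by convention
    background_terms = [f"GO:{7000000 + i:07d}" for i in range(config.n_go_terms)]
    annotations: dict[str, set[str]] = {}
    for name in names:
        terms = {
            t for t in background_terms if rng.random() < config.go_background_rate
        }
        if rng.random() < config.go_background_rate:
            terms.add(enriched)
        if name in set(target_nodes) and rng.random() < config.enriched_term_fraction:
            terms.add(enriched)
        if terms:
            annotations[name] = terms
    if config.enriched_term_fraction > 0:
        truth.enriched_terms = [enriched]
    return InteractomeSim(g, annotations, enriched, truth)


# ---------------------------------------------------------------------------
# Dataset emission and validation


def write_dataset(config: SimConfig, outdir) -> dict[str, Path]:
    """Generate every input and write it with a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    prot = gen_proteome(config)
    paths["proteome"] = outdir / "proteome.fasta"
    mio.write_fasta(prot.proteins, paths["proteome"])

    layout = gen_genome_layout(config)
    paths["genome"] = outdir / "genome.fasta"
    mio.write_fasta(layout.chromosomes, paths["genome"])
    paths["gff3"] = outdir / "genes.gff3"
    mio.write_gff3(layout.genes, paths["gff3"])
    paths["family_proteins"] = outdir / "family_proteins.fasta"
    mio.write_fasta(layout.family_proteins, paths["family_proteins"])

    expr = gen_expression(config)
    paths["expression"] = outdir / "expression.tsv"
    mio.write_expression(expr.matrix, expr.phases, paths["expression"])

    prom = gen_promoters_and_peaks(config)
    paths["promoters"] = outdir / "promoters.fasta"
    mio.write_fasta(prom.regions, paths["promoters"])
    paths["peak_genome"] = outdir / "peak_genome.fasta"
    mio.write_fasta(prom.peak_genome, paths["peak_genome"])
    paths["peaks"] = outdir / "peaks.bed"
    mio.write_bed(prom.peaks, paths["peaks"])
    paths["motifs"] = outdir / "motif_library.tsv"
    Path(paths["motifs"]).write_text(
        "\n".join(f"M{i + 1:02d}\t{p}" for i, p in enumerate(config.motif_library)) + "\n"
    )

    inter = gen_interactome(config)
    paths["interactome"] = outdir / "interactome.tsv"
    mio.write_edge_list(sorted(tuple(sorted(e)) for e in inter.graph.edges()), paths["interactome"])
    paths["go"] = outdir / "go_annotations.tsv"
    mio.write_annotations(inter.annotations, paths["go"])

    truth = GroundTruth()
    for part in (prot.truth, layout.truth, expr.truth, prom.truth, inter.truth):
        truth.family_membership.update(part.family_membership)
        truth.duplication_class.update(part.duplication_class)
        truth.duplication_events += part.duplication_events
        truth.archetype.update(part.archetype)
        truth.expression_pairs += part.expression_pairs
        truth.true_motif_counts.update(part.true_motif_counts)
        truth.peak_motif_subset = truth.peak_motif_subset or part.peak_motif_subset
        truth.true_targets = sorted(set(truth.true_targets) | set(part.true_targets))
        truth.hub_nodes = truth.hub_nodes or part.hub_nodes
        truth.enriched_terms = truth.enriched_terms or part.enriched_terms
    paths["truth"] = outdir / "ground_truth.json"
    Path(paths["truth"]).write_text(truth.to_json())
    return paths


def validate_dataset(outdir) -> list[str]:
    """Cross-file ID consistency: every truth record names an emitted entity.

    Returns a list of problems (empty means the dataset is consistent).
    """
    outdir = Path(outdir)
    truth = GroundTruth.from_json((outdir / "ground_truth.json").read_text())
    problems: list[str] = []
    proteome = set(mio.read_fasta(outdir / "proteome.fasta"))
    gff_ids = {g.gene_id for g in mio.read_gff3(outdir / "genes.gff3")}
    promoters = set(mio.read_fasta(outdir / "promoters.fasta"))
    expr, _ = mio.read_expression(outdir / "expression.tsv")
    nodes = set()
    for a, b in mio.read_edge_list(outdir / "interactome.tsv"):
        nodes |= {a, b}
    for gene in truth.duplication_class:
        if gene not in gff_ids:
            problems.append(f"duplication truth gene {gene} absent from GFF3")
    for gene, member in truth.family_membership.items():
        if gene not in proteome and gene not in gff_ids:
            problems.append(f"family truth gene {gene} absent from proteome/GFF3")
    for gene in truth.archetype:
        if gene not in expr.index:
            problems.append(f"expression truth gene {gene} absent from matrix")
    for gene in truth.true_motif_counts:
        if gene not in promoters:
            problems.append(f"motif truth gene {gene} absent from promoters")
    for node in truth.hub_nodes:
        if node not in nodes:
            problems.append(f"hub node {node} absent from interactome")
    return problems
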