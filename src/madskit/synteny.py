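"""Genome organization: homolog pairs, collinear blocks, duplication modes.

Homologous gene pairs come from all-vs-all Smith-Waterman with
Karlin-Altschul e-values; collinear blocks are found by dynamic-programming
chaining of anchors over gene-order ranks (both orientations), in the spirit
of MCScanX; each family gene is then assigned exactly one duplication mode
under the precedence segmental > tandem > proximal > dispersed > singleton,
so the modes partition the family.  Cluster detection groups family genes
lying close together along a chromosome (few intervening genes, small bp
gap), the usual tandem-array convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .io import GeneModel

# gapped BLOSUM62 Karlin-Altschul parameters
_LAMBDA, _K = 0.267, 0.041
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class HomologPair:
    """Unordered homologous pair with alignment score and e-value."""

    gene_a: str
    gene_b: str
    score: float
    evalue: float

    @property
    def genes(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]   # ordered (gene on chrom_a, gene on chrom_b)
    chain_score: float
    orientation: int                 # +1 or -1


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    mode: str  # segmental | tandem | proximal | dispersed | singleton


@dataclass
class GeneCluster:
    chromosome: str
    members: list[str]               # ordered by rank
    subfamily_composition: dict[str, int] = field(default_factory=dict)
    pure_subfamily: str | None = None


def _evalue(score: float, m: int, n: int) -> float:
    return _K * m * n * math.exp(-_LAMBDA * score)


def build_homolog_pairs(
    proteins: dict[str, str],
    evalue_threshold: float = 1e-10,
    top_k: int = 5,
) -> list[HomologPair]:
    """All-vs-all local alignment; per query keep <= top_k best subjects.

    E-values use the Karlin-Altschul formula E = K m n e^(-lambda S) with
    gapped BLOSUM62 constants.  The per-query top-k lists are closed
    symmetrically and deduplicated into unordered pairs.
    """
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    ids = sorted(proteins)
    scores: dict[frozenset, float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            scores[frozenset((a, b))] = float(aligner.score(proteins[a], proteins[b]))
    kept: dict[frozenset, HomologPair] = {}
    for q in ids:
        cands = []
        for s in ids:
            if s == q:
                continue
            sc = scores[frozenset((q, s))]
            ev = _evalue(sc, len(proteins[q]), len(proteins[s]))
            if ev <= evalue_threshold:
                cands.append((sc, s, ev))
        cands.sort(key=lambda t: (-t[0], t[1]))
        for sc, s, ev in cands[:top_k]:
            key = frozenset((q, s))
            if key not in kept:
                a, b = sorted(key)
                kept[key] = HomologPair(a, b, sc, ev)
    return sorted(kept.values(), key=lambda p: (p.gene_a, p.gene_b))


# ---------------------------------------------------------------------------
# Collinearity chaining


def chain_score(anchors: list[tuple[int, int]], gap_penalty: float) -> float:
    """Score of an ordered anchor chain: +1 per anchor minus gap penalties."""
    s = float(len(anchors))
    for (a0, b0), (a1, b1) in zip(anchors, anchors[1:]):
        s -= gap_penalty * ((abs(a1 - a0) - 1) + (abs(b1 - b0) - 1))
    return s


def best_chain(
    coords: list[tuple[int, int]],
    max_gap: int = 25,
    gap_penalty: float = 0.01,
    orientation: int = 1,
):
    """Maximal-scoring monotone chain over (rank_a, rank_b) anchors by DP.

    Chains are strictly increasing in rank_a and strictly increasing
    (orientation +1) or decreasing (-1) in rank_b, with per-step rank gaps
    <= max_gap on both axes.  Deterministic tie-break: leftmost (smallest
    coordinates) chain.  Returns (score, chain as index list into coords).
    """
    order = sorted(range(len(coords)), key=lambda i: (coords[i][0], coords[i][1]))
    dp = [1.0] * len(order)
    back = [-1] * len(order)
    for ii, i in enumerate(order):
        ai, bi = coords[i]
        for jj in range(ii):
            j = order[jj]
            aj, bj = coords[j]
            if aj >= ai:
                continue
            if orientation > 0 and not (bj < bi):
                continue
            if orientation < 0 and not (bj > bi):
                continue
            if ai - aj > max_gap or abs(bi - bj) > max_gap:
                continue
            cand = dp[jj] + 1.0 - gap_penalty * ((ai - aj - 1) + (abs(bi - bj) - 1))
            if cand > dp[ii] + 1e-12:
                dp[ii] = cand
                back[ii] = jj
    if not order:
        return 0.0, []
    best_ii = max(range(len(order)), key=lambda ii: (dp[ii], -order[ii]))
    chain = []
    ii = best_ii
    while ii != -1:
        chain.append(order[ii])
        ii = back[ii]
    return dp[best_ii], chain[::-1]


def chain_collinear(
    pairs: list[HomologPair],
    gene_models: list[GeneModel],
    max_gap: int = 25,
    min_block: int = 5,
    gap_penalty: float = 0.01,
    min_self_separation: int = 30,
) -> list[CollinearBlock]:
    """Collinear blocks by iterative best-chain extraction per chromosome pair.

    Anchors on the same chromosome closer than ``min_self_separation`` ranks
    are local duplications (tandem/proximal arrays), not synteny, and are
    excluded from chaining.  Blocks need >= ``min_block`` anchors.
    """
    models = {g.gene_id: g for g in gene_models}
    by_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for p in pairs:
        ga, gb = models.get(p.gene_a), models.get(p.gene_b)
        if ga is None or gb is None:
            continue
        if ga.chromosome == gb.chromosome:
            if abs(ga.rank - gb.rank) <= min_self_separation:
                continue
            lo, hi = sorted((ga, gb), key=lambda g: g.rank)
            key = (ga.chromosome, gb.chromosome)
            by_pair.setdefault(key, []).append((lo.rank, hi.rank, lo.gene_id, hi.gene_id))
        else:
            ga, gb = sorted((ga, gb), key=lambda g: g.chromosome)
            key = (ga.chromosome, gb.chromosome)
            by_pair.setdefault(key, []).append((ga.rank, gb.rank, ga.gene_id, gb.gene_id))

    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in sorted(by_pair.items()):
        remaining = list(anchors)
        while len(remaining) >= min_block:
            coords = [(a[0], a[1]) for a in remaining]
            cands = []
            for orient in (1, -1):
                score, chain = best_chain(coords, max_gap, gap_penalty, orient)
                cands.append((score, orient, chain))
            score, orient, chain = max(cands, key=lambda t: (t[0], t[1]))
            if len(chain) < min_block:
                break
            chosen = [remaining[i] for i in chain]
            blocks.append(
                CollinearBlock(
                    ca,
                    cb,
                    [(a[2], a[3]) for a in chosen],
                    score,
                    orient,
                )
            )
            used = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in used]
    return blocks


# ---------------------------------------------------------------------------
# Duplication classification


def classify_duplications(
    family_genes,
    pairs: list[HomologPair],
    blocks: list[CollinearBlock],
    gene_models: list[GeneModel],
    proximal_window: int = 20,
) -> list[DuplicationCall]:
    """One duplication mode per family gene, by precedence.

    segmental (block anchor) > tandem (homolog at adjacent rank, same
    chromosome) > proximal (homolog within ``proximal_window`` ranks) >
    dispersed (any other homolog) > singleton (no homolog).
    """
    models = {g.gene_id: g for g in gene_models}
    anchored = {g for b in blocks for pair in b.anchors for g in pair}
    neighbors: dict[str, set[str]] = {}
    for p in pairs:
        neighbors.setdefault(p.gene_a, set()).add(p.gene_b)
        neighbors.setdefault(p.gene_b, set()).add(p.gene_a)
    calls = []
    for gene in family_genes:
        g = models.get(gene)
        homs = neighbors.get(gene, set())
        if gene in anchored:
            mode = "segmental"
        elif not homs:
            mode = "singleton"
        else:
            gaps = [
                abs(models[h].rank - g.rank)
                for h in homs
                if g is not None and h in models and models[h].chromosome == g.chromosome
            ]
            if any(d == 1 for d in gaps):
                mode = "tandem"
            elif any(d <= proximal_window for d in gaps):
                mode = "proximal"
            else:
                mode = "dispersed"
        calls.append(DuplicationCall(gene, mode))
    return calls


# ---------------------------------------------------------------------------
# Gene clusters


def detect_clusters(
    family_models: list[GeneModel],
    max_rank_gap: int = 5,
    max_bp_gap: int = 250_000,
    subfamilies: dict[str, str] | None = None,
) -> list[GeneCluster]:
    """Single-linkage clusters of family genes along each chromosome.

    Consecutive family genes join when the number of intervening genes
    (rank gap - 1) is <= ``max_rank_gap`` AND the bp gap is <= ``max_bp_gap``;
    clusters of size >= 2 are reported with their subfamily composition and
    flagged when solely composed of one subfamily.
    """
    subfamilies = subfamilies or {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in family_models:
        by_chrom.setdefault(g.chromosome, []).append(g)
    clusters = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: g.rank)
        current = [genes[0]]
        runs = []
        for prev, cur in zip(genes, genes[1:]):
            rank_gap = cur.rank - prev.rank - 1
            bp_gap = cur.start - prev.end
            if rank_gap <= max_rank_gap and bp_gap <= max_bp_gap:
                current.append(cur)
            else:
                runs.append(current)
                current = [cur]
        runs.append(current)
        for run in runs:
            if len(run) < 2:
                continue
            comp: dict[str, int] = {}
            for g in run:
                sf = subfamilies.get(g.gene_id, "unassigned")
                comp[sf] = comp.get(sf, 0) + 1
            pure = next(iter(comp)) if len(comp) == 1 else None
            clusters.append(
                GeneCluster(chrom, [g.gene_id for g in run], comp, pure)
            )
    return clusters


def chromosome_summary(
    family_models: list[GeneModel],
    calls: list[DuplicationCall] | None = None,
    clusters: list[GeneCluster] | None = None,
) -> pd.DataFrame:
    """Per-chromosome counts of family genes, duplication modes and clusters.

    Includes each mode's percentage of the family in a trailing TOTAL row.
    """
    modes = ["segmental", "tandem", "proximal", "dispersed", "singleton"]
    call_map = {c.gene_id: c.mode for c in (calls or [])}
    chroms = sorted({g.chromosome for g in family_models})
    rows = []
    for chrom in chroms:
        genes = [g for g in family_models if g.chromosome == chrom]
        row = {"chromosome": chrom, "n_genes": len(genes)}
        for m in modes:
            row[m] = sum(1 for g in genes if call_map.get(g.gene_id) == m)
        row["n_clusters"] = sum(
            1 for c in (clusters or []) if c.chromosome == chrom
        )
        row["clustered_genes"] = sum(
            len(c.members) for c in (clusters or []) if c.chromosome == chrom
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        total = {"chromosome": "TOTAL", "n_genes": int(df["n_genes"].sum())}
        for m in modes:
            total[m] = int(df[m].sum())
        total["n_clusters"] = int(df["n_clusters"].sum())
        total["clustered_genes"] = int(df["clustered_genes"].sum())
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
        n_family = len(family_models)
        for m in modes:
            df[f"{m}_pct"] = 100.0 * df[m] / n_family if n_family else 0.0
    return df
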