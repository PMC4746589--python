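"""Promoter cis-element counting and TF target prediction with network analysis.

The target-prediction procedure mirrors the ChIP-anchored motif-intersection
strategy used for SVP/DAM-type MADS-domain transcription factors: a library of
IUPAC binding-site patterns is first filtered to those actually occurring
inside ChIP peaks of a given phase (vegetative or reproductive), the surviving
patterns are scanned against 2-kb upstream regions to call candidate target
genes, the targets' orthologs are mapped onto a protein-protein interaction
network, and the resulting subnetwork is summarized by its degree
distribution (discrete power-law MLE), hub set and GO-term enrichment
(hypergeometric upper tail with Benjamini-Hochberg correction).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io import GeneModel

# IUPAC nucleotide codes -> matched bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, IUPAC-code aware."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide symbol {exc.args[0]!r}") from None


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for c in pattern.upper():
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {c!r} in pattern {pattern!r}")
        bases = IUPAC[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences are all found
    return re.compile(f"(?=({''.join(parts)}))")


def scan_motifs(
    sequence: str,
    patterns: list[str],
    both_strands: bool = True,
) -> dict[str, list[tuple[int, str]]]:
    """Find every occurrence of each degenerate pattern in ``sequence``.

    Returns pattern -> list of (0-based offset on the forward sequence,
    strand).  Reverse-strand hits are located by scanning the pattern's
    reverse complement on the forward sequence; overlapping occurrences are
    all reported.
    """
    seq = sequence.upper()
    hits: dict[str, list[tuple[int, str]]] = {}
    for pat in patterns:
        found = [(m.start(), "+") for m in _iupac_regex(pat).finditer(seq)]
        if both_strands:
            rc = reverse_complement(pat)
            found += [(m.start(), "-") for m in _iupac_regex(rc).finditer(seq)]
        hits[pat] = sorted(found)
    return hits


def count_motifs(sequence: str, patterns: list[str], both_strands: bool = True) -> dict[str, int]:
    return {p: len(h) for p, h in scan_motifs(sequence, patterns, both_strands).items()}


# Default low-temperature-responsive element patterns: the CCGAC core shared
# by LTRE/CRT elements and the CBF/DRE variant with a degenerate 5' base.
LTRE_PATTERNS = ["CCGAC", "RYCGAC"]
CBF_DRE_PATTERNS = ["RCCGAC"]


# ---------------------------------------------------------------------------
# Upstream extraction


@dataclass(frozen=True)
class UpstreamRegion:
    """Promoter window 5'->3' relative to the gene (revcomp for - strand)."""

    gene_id: str
    sequence: str
    requested: int
    truncated: bool = False

    def __len__(self):
        return len(self.sequence)


def extract_upstream(
    genes: list[GeneModel], genome: dict[str, str], window: int
) -> list[UpstreamRegion]:
    """Extract ``window`` bp upstream of each gene's transcription start.

    For + strand genes this is the ``[start - window, start)`` slice of the
    chromosome in 0-based half-open coordinates; for - strand genes the
    ``(end, end + window]`` slice reverse-complemented.  Windows are truncated
    at chromosome edges and flagged.
    """
    out = []
    for g in genes:
        if g.chromosome not in genome:
            raise ValueError(f"unknown chromosome {g.chromosome!r} for gene {g.gene_id}")
        chrom = genome[g.chromosome]
        if g.strand == "+":
            lo = max(0, (g.start - 1) - window)
            seq = chrom[lo : g.start - 1]
        else:
            hi = min(len(chrom), g.end + window)
            seq = reverse_complement(chrom[g.end : hi])
        out.append(UpstreamRegion(g.gene_id, seq, window, len(seq) < window))
    return out


# ---------------------------------------------------------------------------
# Phase filtering and target prediction


@dataclass
class PhaseMotifSet:
    """Patterns from the library retained for one developmental phase."""

    phase: str
    retained: list[str]
    peak_hit_counts: dict[str, int] = field(default_factory=dict)


def filter_phase_motifs(
    library: list[str],
    peaks: list[tuple],
    genome: dict[str, str],
    phase: str,
    both_strands: bool = True,
) -> PhaseMotifSet:
    """Keep the library patterns with >= 1 hit wholly inside >= 1 peak.

    ``peaks`` are (chrom, start, end[, name]) in 0-based half-open
    coordinates.  A match must lie entirely within a peak interval: matches
    spanning a peak boundary are not counted.
    """
    counts = {p: 0 for p in library}
    for iv in peaks:
        chrom, start, end = iv[0], iv[1], iv[2]
        if chrom not in genome:
            raise ValueError(f"peak on unknown chromosome {chrom!r}")
        seq = genome[chrom][start:end]
        for pat, n in count_motifs(seq, library, both_strands).items():
            counts[pat] += n
    retained = [p for p in library if counts[p] > 0]
    return PhaseMotifSet(phase, retained, counts)


def predict_targets(
    phase_motifs: PhaseMotifSet | list[str],
    regions: list[UpstreamRegion],
    both_strands: bool = True,
):
    """Call target genes from phase-filtered motifs and upstream regions.

    A gene is a target iff >= 1 retained pattern hits its upstream region.
    Returns (target gene set, set of distinct patterns present in >= 1
    region, per-gene per-pattern counts).
    """
    patterns = (
        phase_motifs.retained if isinstance(phase_motifs, PhaseMotifSet) else list(phase_motifs)
    )
    targets: set[str] = set()
    present: set[str] = set()
    per_gene: dict[str, dict[str, int]] = {}
    for region in regions:
        counts = count_motifs(region.sequence, patterns, both_strands)
        per_gene[region.gene_id] = counts
        if any(n > 0 for n in counts.values()):
            targets.add(region.gene_id)
        present |= {p for p, n in counts.items() if n > 0}
    return targets, present, per_gene


# ---------------------------------------------------------------------------
# Network construction and topology


@dataclass
class TargetNetwork:
    """Predicted-target orthologs mapped onto an interactome."""

    graph: nx.Graph
    seeds: set[str]
    largest_component: set[str]

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())


def map_and_build_network(
    targets: set[str],
    ortholog_map: dict[str, str],
    interactome,
) -> TargetNetwork:
    """Map target genes to orthologs and induce their interaction network.

    Seed nodes are target orthologs present in the interactome; the network
    keeps every interactome edge with >= 1 endpoint in the seed set.
    Duplicate edges are merged, self-loops dropped, and seeds without any
    interaction partner eliminated.
    """
    if isinstance(interactome, nx.Graph):
        base = nx.Graph(interactome)
    else:
        base = nx.Graph()
        base.add_edges_from(interactome)
    if base.number_of_nodes() == 0:
        raise ValueError("empty interactome")
    base.remove_edges_from(nx.selfloop_edges(base))
    seeds = {ortholog_map.get(t, t) for t in targets} & set(base.nodes)
    g = nx.Graph()
    for u, v in base.edges():
        if u in seeds or v in seeds:
            g.add_edge(u, v)
    seeds &= set(g.nodes)  # isolated seeds eliminated
    if g.number_of_nodes():
        largest = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    else:
        largest = set()
    return TargetNetwork(g, seeds, set(largest))


@dataclass
class PowerLawFit:
    alpha: float          # discrete power-law exponent (MLE)
    xmin: int
    ks: float             # KS distance, empirical vs fitted CDF
    loglog_slope: float   # secondary descriptor: log-log LS slope of P(k)
    loglog_r2: float
    n: int


def powerlaw_mle(degrees, xmin: int = 1, bounds=(1.01, 8.0)) -> float:
    """Discrete power-law exponent by maximum likelihood.

    Maximizes L(a) = -a * sum(log k) - n * log(zeta(a, xmin)) over the degrees
    k >= xmin.
    """
    ks = np.asarray([k for k in degrees if k >= xmin], dtype=float)
    if ks.size == 0:
        raise ValueError("no degrees >= xmin")
    if np.all(ks == ks[0]):
        raise ValueError("degenerate degree support: all degrees equal")
    slogk = np.log(ks).sum()

    def nll(a):
        return a * slogk + ks.size * math.log(special.zeta(a, xmin))

    res = optimize.minimize_scalar(
        nll, bounds=bounds, method="bounded", options={"xatol": 1e-10}
    )
    return float(res.x)


def degree_and_powerlaw(network, xmin: int = 1) -> PowerLawFit:
    """Degree-distribution summary: MLE exponent, KS distance, log-log slope.

    ``network`` may be a TargetNetwork, a networkx graph, or a degree list.
    """
    if isinstance(network, TargetNetwork):
        degs = list(network.degrees.values())
    elif isinstance(network, nx.Graph):
        degs = [d for _, d in network.degree()]
    else:
        degs = list(network)
    if len(degs) < 10:
        raise ValueError("need >= 10 nodes to fit a degree distribution")
    degs = np.asarray([d for d in degs if d >= xmin])
    alpha = powerlaw_mle(degs, xmin)

    # KS distance between empirical and fitted discrete CDFs
    kmax = int(degs.max())
    support = np.arange(xmin, kmax + 1)
    pmf = support.astype(float) ** (-alpha) / special.zeta(alpha, xmin)
    fitted_cdf = np.cumsum(pmf)
    emp_cdf = np.searchsorted(np.sort(degs), support, side="right") / degs.size
    ks_dist = float(np.max(np.abs(emp_cdf - fitted_cdf)))

    # secondary descriptor: least-squares slope of log P(k) vs log k
    uniq, counts = np.unique(degs, return_counts=True)
    x = np.log(uniq.astype(float))
    y = np.log(counts / degs.size)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return PowerLawFit(alpha, xmin, ks_dist, float(slope), r2, int(degs.size))


def find_hubs(network: TargetNetwork, k: int = 5, top_fraction: float | None = None):
    """Top-degree nodes of the largest connected component.

    Ranks the component's nodes by degree (ties broken by node id) and
    returns (hub list, hubs as a percentage of the component size).  With
    ``top_fraction`` set, k = ceil(fraction * component size).
    """
    comp = network.largest_component
    if not comp:
        raise ValueError("empty network")
    if top_fraction is not None:
        k = max(1, math.ceil(top_fraction * len(comp)))
    if k > len(comp):
        raise ValueError(f"k={k} exceeds largest-component size {len(comp)}")
    ranked = sorted(comp, key=lambda n: (-network.graph.degree(n), n))
    hubs = ranked[:k]
    return hubs, 100.0 * k / len(comp)


# ---------------------------------------------------------------------------
# GO enrichment


@dataclass
class EnrichmentResult:
    term: str
    overlap: int       # k: genes in the set annotated with the term
    set_size: int      # n
    term_size: int     # K: universe genes annotated with the term
    universe: int      # N
    p: float           # hypergeometric upper tail P(X >= k)
    fdr: float = 1.0
    significant: bool = False


def go_enrichment(
    gene_set,
    annotations: dict[str, set[str]],
    universe,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test per term with BH correction.

    p(term) = sum_{i >= k} C(K,i) C(N-K, n-i) / C(N,n); terms with
    BH-adjusted p < ``alpha`` are flagged significant.  Annotations are taken
    as a flat table (no ontology-graph propagation).
    """
    gene_set = set(gene_set)
    universe = set(universe)
    outside = gene_set - universe
    if outside:
        raise ValueError(
            "gene set not contained in universe: " + ", ".join(sorted(outside))
        )
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        if gene not in universe:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    n, N = len(gene_set), len(universe)
    results = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        k = len(term_genes[term] & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, n, K, N, min(p, 1.0)))
    if results:
        _, fdrs, _, _ = multipletests(
            [r.p for r in results], alpha=alpha, method="fdr_bh"
        )
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
            r.significant = r.fdr < alpha
    return results
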