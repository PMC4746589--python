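"""Gene-family mining by profile scanning with two-stage confirmation.

The family profile is a log-odds position-specific score matrix (bits) built
from a gap-free seed alignment of the conserved domain.  Candidate proteins
are scored by their best profile-length window; significance is empirical,
from shuffled-decoy copies of the protein itself, mirroring the common
two-stage practice of a broad profile search followed by an independent
confirmation scan at the same e-value cutoff (1e-4).  Best hits against a
reference proteome (Smith-Waterman, BLOSUM62) classify members as "regular"
when both percent similarity and query coverage exceed 50%.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io import GeneModel

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}


def _encode(seq: str) -> np.ndarray:
    # unknown residues map to a sentinel column scoring 0 bits
    return np.fromiter(
        (_INDEX.get(c, len(ALPHABET)) for c in seq), dtype=np.int64, count=len(seq)
    )


@dataclass
class ProfileModel:
    """Log-odds PSSM: ``matrix[j, a]`` is the bit score of residue a at j."""

    matrix: np.ndarray        # (length, 21); last column = unknown residue, 0 bits
    background: np.ndarray    # (20,)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def score_sequence(self, seq: str) -> float:
        """Score a sequence of exactly profile length."""
        if len(seq) != self.length:
            raise ValueError("sequence length != profile length")
        enc = _encode(seq)
        return float(self.matrix[np.arange(self.length), enc].sum())


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    start: int           # 0-based half-open window on the protein
    end: int
    bit_score: float
    evalue: float


def build_profile(
    seed_alignment: dict[str, str] | list[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> ProfileModel:
    """Log-odds profile from a gap-free seed alignment.

    score(j, a) = log2( ((count_j(a) + pc * bg_a) / (n + pc)) / bg_a ), so a
    column matching the background exactly scores 0 bits for every residue.
    """
    seqs = list(seed_alignment.values()) if isinstance(seed_alignment, dict) else list(seed_alignment)
    if len(seqs) < 2:
        raise ValueError("need >= 2 seed sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("ragged seed alignment: sequences differ in length")
    if background is None:
        background = np.full(20, 1 / 20)
    counts = np.zeros((L, 20))
    for s in seqs:
        enc = _encode(s)
        if (enc >= 20).any():
            bad = s[int(np.argmax(enc >= 20))]
            raise ValueError(f"unknown residue symbol {bad!r} in seed alignment")
        counts[np.arange(L), enc] += 1
    freq = (counts + pseudocount * background) / (len(seqs) + pseudocount)
    matrix = np.zeros((L, 21))
    matrix[:, :20] = np.log2(freq / background)
    return ProfileModel(matrix, background)


def best_window(protein: str, profile: ProfileModel):
    """Best-scoring profile-length window: (score, start), or None if too short."""
    enc = _encode(protein)
    L, Lp = len(enc), profile.length
    if L < Lp:
        return None
    nwin = L - Lp + 1
    scores = np.zeros(nwin)
    for j in range(Lp):
        scores += profile.matrix[j, enc[j : j + nwin]]
    k = int(np.argmax(scores))
    return float(scores[k]), k


def scan_profile(
    protein_id: str,
    protein: str,
    profile: ProfileModel,
    n_decoys: int = 200,
    seed: int = 0,
    evalue_threshold: float = 1e-4,
) -> list[DomainHit]:
    """Best-window hit with an empirical e-value from shuffled decoys.

    evalue = (1 + #decoy windows scoring >= observed) / (1 + #decoy windows),
    where decoys are residue-shuffled copies of the protein itself.  Hits
    with evalue <= ``evalue_threshold`` are returned (proteins shorter than
    the profile yield no hit).
    """
    bw = best_window(protein, profile)
    if bw is None:
        return []
    obs, start = bw
    enc = _encode(protein)
    tag = zlib.crc32(protein_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
    decoys = rng.permuted(np.tile(enc, (n_decoys, 1)), axis=1)
    Lp = profile.length
    nwin = len(enc) - Lp + 1
    dscores = np.zeros((n_decoys, nwin))
    for j in range(Lp):
        dscores += profile.matrix[j, decoys[:, j : j + nwin]]
    evalue = (1 + int((dscores >= obs).sum())) / (1 + dscores.size)
    if evalue <= evalue_threshold:
        return [DomainHit(protein_id, start, start + Lp, obs, evalue)]
    return []


def scan_proteome(
    proteins: dict[str, str],
    profile: ProfileModel,
    n_decoys: int = 200,
    seed: int = 0,
    evalue_threshold: float = 1e-4,
) -> list[DomainHit]:
    hits: list[DomainHit] = []
    for pid, seq in proteins.items():
        hits += scan_profile(pid, seq, profile, n_decoys, seed, evalue_threshold)
    return hits


def confirm_members(
    proteins: dict[str, str],
    profile: ProfileModel,
    seed_alignment: dict[str, str] | list[str] | None = None,
    n_decoys: int = 200,
    evalue_threshold: float = 1e-4,
    seed: int = 0,
    min_self_fraction: float = 0.4,
) -> set[str]:
    """Two-stage membership: pass the scan twice with independent decoys.

    A protein is confirmed iff both stages yield evalue <= threshold and, as
    a bit-score floor (the decoy count only resolves e = 1e-4 coarsely), its
    best-window score reaches ``min_self_fraction`` x the minimum self-score
    of the seed alignment's own sequences.
    """
    cutoff = -np.inf
    if seed_alignment is not None:
        seqs = (
            list(seed_alignment.values())
            if isinstance(seed_alignment, dict)
            else list(seed_alignment)
        )
        cutoff = min(profile.score_sequence(s) for s in seqs) * min_self_fraction
    stage1 = {
        h.protein_id: h
        for h in scan_proteome(proteins, profile, n_decoys, seed, evalue_threshold)
    }
    survivors = {
        pid: proteins[pid]
        for pid, h in stage1.items()
        if h.bit_score >= cutoff
    }
    stage2 = scan_proteome(
        survivors, profile, n_decoys, seed + 104729, evalue_threshold
    )
    return {h.protein_id for h in stage2 if h.bit_score >= cutoff}


# ---------------------------------------------------------------------------
# Local alignment and ortholog calling

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = _BLOSUM62
    a.open_gap_score = -(gap_open + gap_extend)
    a.extend_gap_score = -gap_extend
    return a


def align_local(
    query: str,
    subject: str,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
):
    """Optimal Smith-Waterman local alignment under BLOSUM62 + affine gaps.

    Returns (score, percent_similarity, query_coverage): similarity counts
    substitution-matrix-positive aligned pairs over alignment columns (the
    BLASTP "positives" convention); coverage is the aligned query span over
    the query length.  A pair with no positive-scoring alignment gets score 0
    and an empty alignment.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    for seq in (query, subject):
        for c in seq:
            if c not in ALPHABET:
                raise ValueError(f"unknown residue symbol {c!r}")
    aligner = _aligner(gap_open, gap_extend)
    score = float(aligner.score(query, subject))
    if score <= 0:
        return 0.0, 0.0, 0.0
    aln = next(iter(aligner.align(query, subject)))
    blocks_q, blocks_s = aln.aligned
    matched = 0
    positives = 0
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        matched += qe - qs
        for a, b in zip(query[qs:qe], subject[ss:se]):
            if _BLOSUM62[a, b] > 0:
                positives += 1
    q_span = int(blocks_q[-1][1] - blocks_q[0][0])
    s_span = int(blocks_s[-1][1] - blocks_s[0][0])
    columns = matched + (q_span - matched) + (s_span - matched)
    similarity = 100.0 * positives / columns if columns else 0.0
    coverage = 100.0 * q_span / len(query)
    return score, similarity, coverage


@dataclass(frozen=True)
class OrthologCall:
    query_id: str
    subject_id: str
    alignment_score: float
    percent_similarity: float
    query_coverage: float
    regular: bool


def call_orthologs(
    queries: dict[str, str],
    reference: dict[str, str],
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> list[OrthologCall]:
    """Best reference hit per query; "regular" iff similarity AND coverage > 50.

    Ties on score are broken by subject identifier (lexicographic), so the
    call is deterministic.
    """
    if not reference:
        raise ValueError("empty reference proteome")
    aligner = _aligner(gap_open, gap_extend)
    calls = []
    for qid, qseq in queries.items():
        best = None
        for sid in sorted(reference):
            s = float(aligner.score(qseq, reference[sid]))
            if best is None or s > best[0]:
                best = (s, sid)
        score, similarity, coverage = align_local(
            qseq, reference[best[1]], gap_open, gap_extend
        )
        calls.append(
            OrthologCall(
                qid,
                best[1],
                score,
                similarity,
                coverage,
                regular=similarity > 50.0 and coverage > 50.0,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Positional naming


@dataclass
class FamilyMember:
    gene_id: str
    assigned_name: str
    type_class: str = "unassigned"
    subfamily: str = "unassigned"


def assign_names(
    members,
    gene_models: list[GeneModel],
    prefix: str = "MdMADS",
    chromosome_order: list[str] | None = None,
) -> list[FamilyMember]:
    """Name members positionally: top-to-bottom along ordered chromosomes.

    Members are sorted by (chromosome order, ascending start) and named
    <prefix>001..<prefix>N; members without a gene model are named after the
    placed ones, in input order.  Naming is invariant to input permutation
    of the placed members.
    """
    members = list(members)
    models = {}
    for g in gene_models:
        if g.gene_id in models:
            raise ValueError(f"duplicate gene id {g.gene_id}")
        models[g.gene_id] = g
    if len(set(members)) != len(members):
        raise ValueError("duplicate member ids")
    placed = [m for m in members if m in models]
    unplaced = [m for m in members if m not in models]
    if chromosome_order is None:
        chromosome_order = sorted({models[m].chromosome for m in placed})
    order = {c: i for i, c in enumerate(chromosome_order)}
    placed.sort(key=lambda m: (order[models[m].chromosome], models[m].start, m))
    width = max(3, len(str(len(members))))
    return [
        FamilyMember(m, f"{prefix}{i + 1:0{width}d}")
        for i, m in enumerate(placed + unplaced)
    ]
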