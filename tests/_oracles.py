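"""Independent brute-force oracles shared across test modules."""

from itertools import combinations

from madskit import regulatory, synteny


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


def exhaustive_best_chain(coords, max_gap=25, gap_penalty=0.01, orientation=1):
    """Oracle: enumerate every subset of anchors, keep valid monotone chains."""
    best = 0.0
    for r in range(1, len(coords) + 1):
        for subset in combinations(range(len(coords)), r):
            chain = sorted(subset, key=lambda i: (coords[i][0], coords[i][1]))
            ok = True
            for a, b in zip(chain, chain[1:]):
                (a0, b0), (a1, b1) = coords[a], coords[b]
                if not (a0 < a1):
                    ok = False
                    break
                if orientation > 0 and not (b0 < b1):
                    ok = False
                    break
                if orientation < 0 and not (b0 > b1):
                    ok = False
                    break
                if a1 - a0 > max_gap or abs(b1 - b0) > max_gap:
                    ok = False
                    break
            if ok:
                best = max(
                    best,
                    synteny.chain_score([coords[i] for i in chain], gap_penalty),
                )
    return best
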