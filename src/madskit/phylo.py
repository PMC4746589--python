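"""Distance-based phylogenetics: NJ trees, bootstrap support, clade anchoring.

Distances come from gap-free or pairwise-gap-deleted protein alignments
(p-distance or Poisson-corrected); trees are built with the Saitou-Nei
neighbor-joining agglomeration with deterministic tie-breaking and
MEGA-style clamping of negative branch-length estimates; bootstrap support
is the percentage of column-resampled replicate trees containing each
internal bipartition of the original tree.  Subfamily and functional calls
(DAM / FLC-like) are made by reference anchoring: a query takes the label of
the smallest edge-bounded subtree around it whose reference taxa are
label-pure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAP_CHARS = {"-", ".", "?"}


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("nonzero diagonal")
        if not np.isfinite(m).all():
            raise ValueError("non-finite distances")
        self.matrix = m


def _encode_alignment(alignment: dict[str, str]):
    taxa = list(alignment)
    L = len(alignment[taxa[0]])
    if any(len(alignment[t]) != L for t in taxa):
        raise ValueError("ragged alignment")
    arr = np.array([list(alignment[t]) for t in taxa])
    gaps = np.isin(arr, list(GAP_CHARS))
    return taxa, arr, gaps


def distance_from_alignment(
    alignment: dict[str, str], model: str = "poisson"
) -> DistanceMatrix:
    """Pairwise distances with per-pair deletion of gap columns.

    p = mismatches / compared sites; the Poisson correction is
    d = -ln(1 - p), which diverges (and raises, naming the pair) at p = 1.
    """
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    taxa, arr, gaps = _encode_alignment(alignment)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            compared = int(ok.sum())
            if compared == 0:
                raise ValueError(f"no comparable sites for pair ({taxa[i]}, {taxa[j]})")
            p = float((arr[i, ok] != arr[j, ok]).sum()) / compared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair ({taxa[i]}, {taxa[j]}): p = 1 gives infinite Poisson distance"
                    )
                p = -np.log1p(-p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class PhyloNode:
    """Node of an (unrooted) tree, stored rooted at the final NJ join."""

    name: str | None = None
    children: list["PhyloNode"] = field(default_factory=list)
    length: float = 0.0          # branch length to parent
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node, top=False):
            if node.is_leaf():
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = ""
                if with_support and node.support is not None and not top:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            return body if top else f"{body}:{node.length:.10g}"

        return fmt(self, top=True) + ";"


def nj_tree(dm: DistanceMatrix) -> PhyloNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q = (m-2) d_ij - r_i - r_j is joined
    (ties broken by the smallest (i, j) index pair); branch lengths follow
    the standard NJ formulas, with negative estimates clamped to zero and
    the deficit transferred to the sister branch.  Returns the tree rooted
    at the final three-way join (an unrooted binary tree).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes = [PhyloNode(name=t) for t in dm.taxa]
    D = dm.matrix.copy()
    active = list(range(n))

    def clamp(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ii, jj = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if ii > jj:
            ii, jj = jj, ii
        i, j = active[ii], active[jj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = PhyloNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # grow the distance matrix with the new node
        new_row = np.zeros(D.shape[0])
        for kk in active:
            if kk in (i, j):
                continue
            new_row[kk] = 0.5 * (D[i, kk] + D[j, kk] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row
        D[:-1, -1] = new_row
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = PhyloNode(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    return root


def path_length_matrix(tree: PhyloNode):
    """Leaf-to-leaf path lengths summed along branches; (names, matrix)."""
    adj: dict[int, list[tuple[int, float]]] = {}
    leaves: dict[str, int] = {}

    def walk(node):
        nid = id(node)
        adj.setdefault(nid, [])
        if node.is_leaf():
            leaves[node.name] = nid
        for c in node.children:
            cid = id(c)
            adj.setdefault(cid, [])
            adj[nid].append((cid, c.length))
            adj[cid].append((nid, c.length))
            walk(c)

    walk(tree)
    names = sorted(leaves)
    n = len(names)
    mat = np.zeros((n, n))
    for a, src in enumerate(names):
        dist = {leaves[src]: 0.0}
        stack = [leaves[src]]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for b, dst in enumerate(names):
            mat[a, b] = dist[leaves[dst]]
    return names, mat


def bipartitions(tree: PhyloNode) -> dict[frozenset, PhyloNode]:
    """Internal-edge bipartitions, each as the leaf set not containing the
    lexicographically first taxon.  Trivial splits are excluded."""
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    out: dict[frozenset, PhyloNode] = {}

    def walk(node, is_root):
        below = frozenset(node.leaf_names())
        if not is_root and not node.is_leaf():
            side = below if anchor not in below else all_leaves - below
            if 1 < len(side) < len(all_leaves) - 1:
                out[side] = node
        for c in node.children:
            walk(c, False)

    walk(tree, True)
    return out


def same_topology(a: PhyloNode, b: PhyloNode) -> bool:
    """Unrooted topology equality via bipartition sets."""
    if set(a.leaf_names()) != set(b.leaf_names()):
        return False
    return set(bipartitions(a)) == set(bipartitions(b))


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class SupportedTree:
    tree: PhyloNode
    supports: dict[frozenset, float]   # bipartition -> % of replicates
    n_replicates: int

    def to_newick(self) -> str:
        return self.tree.to_newick(with_support=True)


def bootstrap_support(
    alignment: dict[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "poisson",
) -> SupportedTree:
    """NJ tree plus per-edge bootstrap support from column resampling.

    Each replicate resamples alignment columns with replacement, rebuilds
    the distance matrix and the NJ tree; support for an internal edge of the
    original tree is the percentage of replicate trees containing the same
    bipartition.  Taxa are canonically sorted first, so the result does not
    depend on input order.
    """
    alignment = {t: alignment[t] for t in sorted(alignment)}
    taxa, arr, gaps = _encode_alignment(alignment)
    L = arr.shape[1]
    if L < 1:
        raise ValueError("empty alignment")
    original = nj_tree(distance_from_alignment(alignment, model))
    targets = bipartitions(original)
    counts = {bp: 0 for bp in targets}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    for _ in range(n_reps):
        cols = rng.integers(0, L, L)
        rep = {t: "".join(arr[i, cols]) for i, t in enumerate(taxa)}
        rep_tree = nj_tree(distance_from_alignment(rep, model))
        rep_bps = set(bipartitions(rep_tree))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    for bp, node in targets.items():
        node.support = supports[bp]
    return SupportedTree(original, supports, n_reps)


# ---------------------------------------------------------------------------
# Clade assignment


@dataclass(frozen=True)
class CladeAssignment:
    taxon: str
    label: str                  # subfamily/clade label or "unassigned"
    functional: str = "none"    # "DAM", "FLC-like" or "none"


def assign_clades(
    tree: PhyloNode | SupportedTree,
    reference_labels: dict[str, str],
    functional_anchors: dict[str, str] | None = None,
    functional_subfamilies=("MIKCc",),
) -> list[CladeAssignment]:
    """Label queries by the smallest label-pure reference-containing subtree.

    Every edge of the tree bounds two subtrees; a query takes the label of
    the smallest edge-bounded subtree containing it and >= 1 reference taxon,
    provided that subtree's references carry a single label (otherwise the
    query stays unassigned).  A functional DAM / FLC-like call is made when
    that label-pure subtree also contains a functional anchor (SVP/DAM or
    FLC) and the label is an MIKC^C-type subfamily.
    """
    if isinstance(tree, SupportedTree):
        tree = tree.tree
    functional_anchors = functional_anchors or {}
    all_leaves = frozenset(tree.leaf_names())
    refs = set(reference_labels) & all_leaves
    if not refs:
        raise ValueError("tree contains no reference taxa")

    sides: set[frozenset] = set()

    def walk(node, is_root):
        below = frozenset(node.leaf_names())
        if not is_root:
            sides.add(below)
            sides.add(all_leaves - below)
        for c in node.children:
            walk(c, False)

    walk(tree, True)

    assignments = []
    for taxon in sorted(all_leaves):
        cands = [s for s in sides if taxon in s and (refs & s)]
        label, functional = "unassigned", "none"
        if cands:
            smallest = min(len(s) for s in cands)
            # all minimal subtrees must agree on a single reference label
            minimal = [s for s in cands if len(s) == smallest]
            labels = {reference_labels[r] for s in minimal for r in refs & s}
            if len(labels) == 1:
                label = labels.pop()
                if label in functional_subfamilies:
                    roles = {
                        functional_anchors[a].upper()
                        for s in minimal
                        for a in functional_anchors
                        if a in s
                    }
                    if roles and roles <= {"SVP", "DAM", "SVP/DAM"}:
                        functional = "DAM"
                    elif roles == {"FLC"}:
                        functional = "FLC-like"
        assignments.append(CladeAssignment(taxon, label, functional))
    return assignments
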