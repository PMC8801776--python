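"""Distance phylogenetics for subfamily classification.

Pairwise global protein alignment (BLOSUM62, affine gaps), Kimura-corrected
protein distances, deterministic neighbor-joining, Felsenstein bootstrap
support, nearest-reference subfamily assignment for the 16 MADS subfamilies,
and the FLC vs MIKC* diagnostic-residue test.

The multiple alignment used for bootstrapping is a center-star progressive
merge of pairwise alignments: adequate at the desk scale this package runs
at, and fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"

#: distance assigned when the Kimura correction saturates (matrix use only)
MAX_DISTANCE = 10.0

M_SUBFAMILIES = frozenset({"Malpha", "Mbeta", "Mgamma"})
MIKC_SUBFAMILIES = frozenset(
    {
        "AP1", "AP3", "PI", "AG_STK", "SEP", "AGL6", "AGL12", "AGL17",
        "Bsister", "MIKCstar", "OsMADS32", "SOC1", "SVP", "FLC",
    }
)


def superclade_of(subfamily: str) -> str:
    """Map a subfamily name to its superclade (M-type vs MIKC-type)."""
    if subfamily in M_SUBFAMILIES:
        return "M"
    if subfamily in MIKC_SUBFAMILIES:
        return "MIKC"
    raise ValueError(f"unknown subfamily: {subfamily!r}")


@dataclass
class AlignmentPair:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")


def _make_protein_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_global(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentPair:
    """Optimal global protein alignment (end gaps penalized), BLOSUM62.

    Deterministic: of the co-optimal alignments Biopython enumerates, the
    first (its canonical traceback order) is taken.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_protein_aligner(gap_open, gap_extend)
    aln = aligner.align(a.upper(), b.upper())[0]
    return AlignmentPair(str(aln[0]), str(aln[1]), float(aln.score))


def protein_distance(pair: AlignmentPair) -> Tuple[float, bool]:
    """Kimura-corrected protein distance d = −ln(1 − p − 0.2·p²).

    ``p`` is the mismatch fraction over columns ungapped in both rows.
    Returns ``(distance, saturated)``; saturated pairs get ``inf``.
    """
    matches = mismatches = 0
    for ca, cb in zip(pair.aligned_a, pair.aligned_b):
        if ca == GAP or cb == GAP:
            continue
        if ca == cb:
            matches += 1
        else:
            mismatches += 1
    total = matches + mismatches
    if total == 0:
        raise ValueError("no ungapped columns: distance undefined")
    p = mismatches / total
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        return math.inf, True
    return -math.log(arg), False


# ---------------------------------------------------------------------------
# trees


@dataclass
class Node:
    """Rooted-view tree node; NJ trees are unrooted (trifurcating root)."""

    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: List["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["Node"]:
        if self.is_leaf:
            return [self]
        out: List[Node] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> List[str]:
        return [leaf.name for leaf in self.leaves()]

    def postorder(self) -> Iterable["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        label = f"{self.support:g}" if (with_support and self.support is not None) else ""
        return f"({inner}){label};"


Bipartition = FrozenSet[str]


def bipartitions(root: Node) -> Dict[Bipartition, Node]:
    """Canonical non-trivial bipartitions of an (un)rooted tree.

    Each internal edge is keyed by the side NOT containing the tree's
    lexicographically smallest leaf, so rootings agree.
    """
    all_leaves = frozenset(root.leaf_names())
    anchor = min(all_leaves)
    result: Dict[Bipartition, Node] = {}

    def walk(node: Node) -> FrozenSet[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not root and 1 < len(below) < len(all_leaves) - 1:
            key = below if anchor not in below else all_leaves - below
            result[key] = node
        return below

    walk(root)
    return result


class DataError(ValueError):
    pass


def build_nj_tree(labels: Sequence[str], matrix: np.ndarray) -> Node:
    """Neighbor-joining on a symmetric distance matrix.

    Deterministic tie-break: among minimal-Q pairs the pair whose cluster
    names (each cluster named by its lexicographically smallest leaf) sort
    first is joined.  Negative branch lengths are clamped to zero.  On an
    additive matrix the generating topology and branch lengths are returned.
    Result is an unrooted tree represented with a trifurcating root.
    """
    D = np.asarray(matrix, dtype=float)
    n = len(labels)
    if n < 3:
        raise DataError("need at least 3 taxa")
    if D.shape != (n, n):
        raise DataError("matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-8):
        raise DataError("distance matrix is not symmetric")

    nodes: List[Node] = [Node(name=str(lab)) for lab in labels]
    names: List[str] = [str(lab) for lab in labels]  # tie-break keys
    D = D.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-9))
        best = min(
            (tuple(sorted((names[i], names[j]))), i, j)
            for i, j in candidates
            if i < j
        )
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        a, b = nodes[i], nodes[j]
        a.length = max(li, 0.0)
        b.length = max(lj, 0.0)
        parent = Node(children=[a, b])
        new_dists = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.empty((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = new_dists[keep]
        newD[:-1, -1] = new_dists[keep]
        newD[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
        D = newD

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    return Node(children=[a, b, c])


def _tree_graph(tree: Node):
    """Undirected edge graph of a tree.

    Returns (nodes, adjacency) where adjacency maps id(node) -> list of
    (neighbor, length, support); edge support is the support stored on the
    child end (it belongs to the bipartition, i.e. the edge).
    """
    nodes: List[Node] = list(tree.postorder())
    adj: Dict[int, List[Tuple[Node, float, Optional[float]]]] = {id(n): [] for n in nodes}

    def walk(node: Node) -> None:
        for child in node.children:
            adj[id(node)].append((child, child.length, child.support))
            adj[id(child)].append((node, child.length, child.support))
            walk(child)

    walk(tree)
    return nodes, adj


def midpoint_root(tree: Node) -> Node:
    """Re-root an unrooted tree at the midpoint of its longest leaf path.

    Edge supports (stored on the child end of each edge) travel with their
    edges through the re-rooting.
    """
    nodes, adj = _tree_graph(tree)
    leaves = [n for n in nodes if n.is_leaf]
    if len(leaves) < 2:
        return tree

    def farthest(start: Node):
        """BFS: distances and predecessor edges from ``start``."""
        dist = {id(start): 0.0}
        prev: Dict[int, Tuple[Node, Node, float, Optional[float]]] = {}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb, length, support in adj[id(cur)]:
                if id(nb) not in dist:
                    dist[id(nb)] = dist[id(cur)] + length
                    prev[id(nb)] = (cur, nb, length, support)
                    stack.append(nb)
        return dist, prev

    # double sweep finds the two ends of the longest leaf path
    d0, _ = farthest(leaves[0])
    end_a = max(leaves, key=lambda l: (d0[id(l)], l.name))
    da, prev = farthest(end_a)
    end_b = max(leaves, key=lambda l: (da[id(l)], l.name))
    total = da[id(end_b)]

    # path end_a -> end_b as a list of edges (parent_side, child_side, len, sup)
    path = []
    cur = end_b
    while id(cur) != id(end_a):
        frm, to, length, support = prev[id(cur)]
        path.append((frm, to, length, support))
        cur = frm
    path.reverse()
    if total <= 0 or not path:
        return tree

    half = total / 2.0
    acc = 0.0
    for frm, to, length, support in path:
        if acc + length >= half - 1e-12:
            frac = (half - acc) / length if length > 0 else 0.5
            return _root_on_edge(adj, frm, to, length, support, frac)
        acc += length
    frm, to, length, support = path[-1]
    return _root_on_edge(adj, frm, to, length, support, 1.0)


def _root_on_edge(adj, u: Node, v: Node, length: float, support: Optional[float],
                  frac: float) -> Node:
    """Build a rooted tree with the root placed on edge (u, v).

    ``frac`` of the edge length is on the ``u`` side.  Node objects are
    rebuilt so the input tree is left untouched.
    """
    frac = min(max(frac, 0.0), 1.0)

    def orient(node: Node, came_from: Optional[Node], length_in: float,
               support_in: Optional[float]) -> Node:
        fresh = Node(name=node.name, length=length_in, support=support_in)
        for nb, elen, esup in sorted(
            adj[id(node)], key=lambda t: min(t[0].leaf_names())
        ):
            if came_from is not None and nb is came_from:
                continue
            fresh.children.append(orient(nb, node, elen, esup))
        return fresh

    left = orient(u, v, length * frac, support)
    right = orient(v, u, length * (1.0 - frac), support)
    return Node(children=[left, right])


# ---------------------------------------------------------------------------
# multiple alignment + distance matrices


def progressive_msa(sequences: Mapping[str, str], gap_open: float = 10.0,
                    gap_extend: float = 0.5) -> Dict[str, str]:
    """Center-star progressive multiple alignment.

    The center is the sequence with the greatest total pairwise alignment
    score; every other sequence is aligned to it and gaps are merged into
    the growing profile.
    """
    names = sorted(sequences)
    if len(names) == 1:
        return {names[0]: sequences[names[0]]}
    aligner = _make_protein_aligner(gap_open, gap_extend)
    scores = {name: 0.0 for name in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            s = float(aligner.score(sequences[a].upper(), sequences[b].upper()))
            scores[a] += s
            scores[b] += s
    center = max(names, key=lambda n: (scores[n], n))

    master = sequences[center].upper()  # gapped center row
    rows: Dict[str, str] = {center: master}
    for name in names:
        if name == center:
            continue
        aln = aligner.align(master.replace(GAP, ""), sequences[name].upper())[0]
        c_row, s_row = str(aln[0]), str(aln[1])
        # re-insert existing master gaps into the fresh pairwise alignment
        merged_c: List[str] = []
        merged_new: List[str] = []
        insert_cols: List[int] = []  # columns (old-master frame) gaining a gap
        mi = 0  # position in old master (with gaps)
        pi = 0  # position in c_row
        while mi < len(master) or pi < len(c_row):
            if mi < len(master) and master[mi] == GAP:
                merged_c.append(GAP)
                merged_new.append(GAP)
                mi += 1
            elif pi < len(c_row) and c_row[pi] == GAP:
                insert_cols.append(mi)
                merged_c.append(GAP)
                merged_new.append(s_row[pi])
                pi += 1
            else:
                merged_c.append(c_row[pi])
                merged_new.append(s_row[pi])
                mi += 1
                pi += 1
        # propagate the new gap columns into previously merged rows
        if insert_cols:
            for rname, row in rows.items():
                chars = list(row)
                for off, col in enumerate(insert_cols):
                    chars.insert(col + off, GAP)
                rows[rname] = "".join(chars)
        master = "".join(merged_c)
        # master row with its residues restored
        rows[center] = master if center not in rows else rows[center]
        rows[name] = "".join(merged_new)
        master = rows[center]
    return rows


_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(_AA)}


def encode_msa(rows: Mapping[str, str]) -> Tuple[List[str], np.ndarray]:
    """Encode an MSA as an int8 matrix; gaps and unknowns are −1."""
    names = sorted(rows)
    length = len(rows[names[0]])
    mat = np.full((len(names), length), -1, dtype=np.int8)
    for r, name in enumerate(names):
        for c, ch in enumerate(rows[name].upper()):
            mat[r, c] = _AA_INDEX.get(ch, -1)
    return names, mat


def distance_matrix_from_msa(mat: np.ndarray) -> np.ndarray:
    """Pairwise Kimura protein distances over shared ungapped MSA columns.

    Saturated or column-free pairs are capped at :data:`MAX_DISTANCE`.
    """
    valid = mat >= 0
    n = mat.shape[0]
    D = np.zeros((n, n))
    both = valid[:, None, :] & valid[None, :, :]
    neq = mat[:, None, :] != mat[None, :, :]
    mismatch = (both & neq).sum(axis=2)
    total = both.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, mismatch / np.maximum(total, 1), 1.0)
    arg = 1.0 - p - 0.2 * p * p
    D = np.where(arg > 0, -np.log(np.maximum(arg, 1e-300)), MAX_DISTANCE)
    D = np.minimum(D, MAX_DISTANCE)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def bootstrap_support(
    rows: Mapping[str, str], replicates: int = 100, seed: int = 0
) -> Node:
    """NJ tree from an MSA with Felsenstein bootstrap supports.

    Columns are resampled with replacement ``replicates`` times; the support
    of each internal edge of the full-data tree is the percentage of
    replicate trees containing its bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    names, mat = encode_msa(rows)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 alignment columns")
    main = build_nj_tree(names, distance_matrix_from_msa(mat))
    main_bip = bipartitions(main)
    counts = {bip: 0 for bip in main_bip}
    rng = np.random.default_rng(seed)
    ncols = mat.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep = build_nj_tree(names, distance_matrix_from_msa(mat[:, cols]))
        rep_bips = bipartitions(rep).keys()
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    for bip, node in main_bip.items():
        node.support = 100.0 * counts[bip] / replicates
    return main


# ---------------------------------------------------------------------------
# subfamily assignment


@dataclass
class SubfamilyAssignment:
    gene_id: str
    superclade: str
    subfamily: str
    nearest_reference: str
    score: float
    support: Optional[float] = None
    ambiguous_with: List[str] = field(default_factory=list)


def assign_subfamily(
    gene_id: str,
    protein: str,
    references: Mapping[str, Tuple[str, str]],
    tree: Optional[Node] = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> SubfamilyAssignment:
    """Assign a gene the subfamily of its best-scoring reference.

    ``references`` maps reference id -> (subfamily, protein sequence).  A
    score tie between references of different subfamilies is reported via
    ``ambiguous_with``.  When a tree containing both the gene and the chosen
    reference is supplied, the support of their smallest joining clade is
    attached.
    """
    if not references:
        raise ValueError("need at least one reference")
    aligner = _make_protein_aligner(gap_open, gap_extend)
    scored: List[Tuple[float, str, str]] = []
    for ref_id in sorted(references):
        subfam, seq = references[ref_id]
        s = float(aligner.score(protein.upper(), seq.upper()))
        scored.append((s, ref_id, subfam))
    best_score = max(s for s, _, _ in scored)
    top = [(rid, sf) for s, rid, sf in scored if s == best_score]
    ref_id, subfamily = top[0]
    others = sorted({sf for _, sf in top[1:] if sf != subfamily})
    support = None
    if tree is not None:
        support = _joining_clade_support(tree, gene_id, ref_id)
    return SubfamilyAssignment(
        gene_id=gene_id,
        superclade=superclade_of(subfamily),
        subfamily=subfamily,
        nearest_reference=ref_id,
        score=best_score,
        support=support,
        ambiguous_with=others,
    )


def _joining_clade_support(tree: Node, a: str, b: str) -> Optional[float]:
    best: Optional[Tuple[int, Optional[float]]] = None
    for node in tree.postorder():
        leaves = set(node.leaf_names())
        if a in leaves and b in leaves:
            if best is None or len(leaves) < best[0]:
                best = (len(leaves), node.support)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# FLC vs MIKC* diagnostic residues (MADS-domain alignment positions 30/34/50)

FLC_TRIPLES = {("E", "Q", "A"), ("E", "Q", "G"), ("E", "Q", "S")}
MIKCSTAR_TRIPLE = ("K", "E", "P")


def diagnose_flc(residues: Sequence[str]) -> Tuple[str, Optional[str]]:
    """Classify a (pos30, pos34, pos50) residue triple.

    (E, Q, A|G|S) → ``FLC_like``; (K, E, P) → ``MIKCstar_like``; a gap at any
    position → ``indeterminate`` with a reason; anything else →
    ``indeterminate``.
    """
    if len(residues) != 3:
        raise ValueError("expected residues at positions 30, 34 and 50")
    triple = tuple(r.upper() for r in residues)
    if any(r in (GAP, "", None) for r in triple):
        return "indeterminate", "gap at a diagnostic position"
    if triple in FLC_TRIPLES:
        return "FLC_like", None
    if triple == MIKCSTAR_TRIPLE:
        return "MIKCstar_like", None
    return "indeterminate", None
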