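"""Alignment, Kimura distances, NJ, bootstrap and subfamily assignment."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polymads import phylo


def brute_force_global(a, b, gap_open, gap_extend, matrix):
    """Exhaustive affine-gap global alignment over tiny strings."""
    best = [-math.inf]

    def rec(i, j, rows_a, rows_b, score, prev_gap):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, rows_a + a[i], rows_b + b[j],
                score + matrix[a[i], b[j]], None)
        if i < len(a):
            pen = gap_extend if prev_gap == "a" else gap_open
            rec(i + 1, j, rows_a + a[i], rows_b + "-", score - pen, "a")
        if j < len(b):
            pen = gap_extend if prev_gap == "b" else gap_open
            rec(i, j + 1, rows_a + "-", rows_b + b[j], score - pen, "b")

    rec(0, 0, "", "", 0.0, None)
    return best[0]


def test_alignment_score_matches_exhaustive_search():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    for a, b in [("ACD", "AD"), ("WKL", "WL"), ("MKF", "MKKF")]:
        pair = phylo.align_global(a, b)
        assert pair.score == pytest.approx(
            brute_force_global(a, b, 10.0, 0.5, blosum)
        )


def test_alignment_identical_is_gapless_diagonal():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    seq = "MKVLWAALLG"
    pair = phylo.align_global(seq, seq)
    assert pair.aligned_a == seq and pair.aligned_b == seq
    assert pair.score == pytest.approx(sum(blosum[c, c] for c in seq))


def test_alignment_score_symmetric():
    assert phylo.align_global("MKVLW", "MKW").score == pytest.approx(
        phylo.align_global("MKW", "MKVLW").score
    )


def test_kimura_distance_closed_form():
    pair = phylo.AlignmentPair("A" * 90 + "C" * 10, "A" * 90 + "D" * 10, 0.0)
    d, saturated = phylo.protein_distance(pair)
    assert not saturated
    assert d == pytest.approx(-math.log(1 - 0.1 - 0.2 * 0.01))


def test_kimura_distance_monotone_in_mismatches():
    dists = []
    for k in (0, 5, 10, 20):
        pair = phylo.AlignmentPair("A" * 50, "A" * (50 - k) + "C" * k, 0.0)
        dists.append(phylo.protein_distance(pair)[0])
    assert dists == sorted(dists)
    assert dists[0] == 0.0


def test_kimura_distance_needs_ungapped_columns():
    with pytest.raises(ValueError):
        phylo.protein_distance(phylo.AlignmentPair("A-", "-A", 0.0))


# ---------------------------------------------------------------------------
# neighbor-joining


def test_nj_recovers_additive_four_taxon_tree():
    # ((A:1,B:2):1,(C:3,D:4))
    labels = ["A", "B", "C", "D"]
    D = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )
    tree = phylo.build_nj_tree(labels, D)
    bips = set(phylo.bipartitions(tree))
    assert bips == {frozenset({"C", "D"})}  # AB|CD split
    lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})


def test_nj_three_taxa_star():
    D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
    tree = phylo.build_nj_tree(["A", "B", "C"], D)
    assert sorted(tree.leaf_names()) == ["A", "B", "C"]
    assert len(tree.children) == 3


def test_nj_rejects_asymmetric_matrix():
    D = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(phylo.DataError):
        phylo.build_nj_tree(["A", "B", "C"], D)


def _tree_to_matrix(rng, n):
    """Random additive matrix built from explicit leaf paths."""
    labels = [chr(65 + i) for i in range(n)]
    # random binary topology by sequential insertion; edges carry lengths
    edges = {}  # node -> (parent, length)
    next_id = [0]

    def new_node():
        next_id[0] += 1
        return f"n{next_id[0]}"

    # start with two leaves joined
    root = new_node()
    edges[labels[0]] = (root, rng.uniform(0.5, 3.0))
    edges[labels[1]] = (root, rng.uniform(0.5, 3.0))
    edge_list = [labels[0], labels[1]]
    for leaf in labels[2:]:
        target = edge_list[rng.integers(len(edge_list))]
        parent, length = edges[target]
        mid = new_node()
        split = rng.uniform(0.25, 0.75) * length
        edges[target] = (mid, length - split)
        edges[mid] = (parent, split)
        edges[leaf] = (mid, rng.uniform(0.5, 3.0))
        edge_list.extend([leaf, mid])

    def path_to_root(x):
        out = {}
        total = 0.0
        while x in edges:
            parent, length = edges[x]
            total += length
            out[parent] = total
            x = parent
        return out

    D = np.zeros((n, n))
    for i, x in enumerate(labels):
        px = path_to_root(x)
        for j, y in enumerate(labels):
            if i < j:
                py = path_to_root(y)
                best = min(px[k] + py[k] for k in px if k in py)
                D[i, j] = D[j, i] = best

    # true bipartitions from leaf sets below each internal edge
    children = {}
    for child, (parent, _) in edges.items():
        children.setdefault(parent, []).append(child)

    def leaves_below(x):
        if x not in children:
            return {x}
        out = set()
        for c in children[x]:
            out |= leaves_below(c)
        return out

    full = frozenset(labels)
    truth = set()
    for node in children:
        below = frozenset(leaves_below(node))
        if 1 < len(below) < n - 1:
            truth.add(below if "A" not in below else full - below)
    return labels, D, truth


def enumerate_topologies(labels):
    """All unrooted binary topologies as bipartition sets + path matrices."""
    n = len(labels)
    topologies = []

    def build(placed, structure):
        # structure: list of edges (u, v); nodes are labels or ints
        if placed == n:
            topologies.append(list(structure))
            return
        leaf = labels[placed]
        for k in range(len(structure)):
            u, v = structure[k]
            mid = ("internal", placed, k)
            new = structure[:k] + structure[k + 1 :]
            new += [(u, mid), (mid, v), (mid, leaf)]
            build(placed + 1, new)

    build(3, [(labels[0], ("internal", 2, -1)),
              (labels[1], ("internal", 2, -1)),
              (labels[2], ("internal", 2, -1))])
    return topologies


def topology_bipartitions(edge_structure, labels):
    adj = {}
    for u, v in edge_structure:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    full = frozenset(labels)
    bips = set()
    for u, v in edge_structure:
        # leaves on v's side when edge (u, v) is cut
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if isinstance(x, str):
                side.add(x)
            for nb in adj[x]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(side)
        if 1 < len(side) < len(labels) - 1:
            bips.add(side if "A" not in side else full - side)
    return bips


def ols_total_length(edge_structure, labels, D):
    """OLS branch lengths for a fixed topology; returns total tree length."""
    adj = {}
    for u, v in edge_structure:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    edge_index = {frozenset((u, v)): k for k, (u, v) in enumerate(edge_structure)}
    pairs = list(combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edge_structure)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        # path from labels[i] to labels[j]
        start, goal = labels[i], labels[j]
        stack = [(start, [])]
        seen = {start}
        while stack:
            x, path = stack.pop()
            if x == goal:
                for e in path:
                    A[row, edge_index[e]] = 1.0
                break
            for nb in adj[x]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, path + [frozenset((x, nb))]))
        y[row] = D[i, j]
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(lengths.sum())


@pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2), (6, 7)])
def test_nj_matches_minimum_evolution_on_additive_input(n, seed):
    rng = np.random.default_rng(seed)
    labels, D, truth = _tree_to_matrix(rng, n)
    tree = phylo.build_nj_tree(labels, D)
    nj_bips = set(phylo.bipartitions(tree))
    assert nj_bips == truth
    # brute-force minimum evolution agrees
    best = None
    for topo in enumerate_topologies(labels):
        score = ols_total_length(topo, labels, D)
        bips = topology_bipartitions(topo, labels)
        if best is None or score < best[0] - 1e-9:
            best = (score, bips)
    assert best[1] == truth


def test_nj_invariant_to_taxon_order():
    rng = np.random.default_rng(3)
    labels, D, truth = _tree_to_matrix(rng, 6)
    tree1 = phylo.build_nj_tree(labels, D)
    order = [5, 2, 0, 4, 1, 3]
    labels2 = [labels[i] for i in order]
    D2 = D[np.ix_(order, order)]
    tree2 = phylo.build_nj_tree(labels2, D2)
    assert set(phylo.bipartitions(tree1)) == set(phylo.bipartitions(tree2))


# ---------------------------------------------------------------------------
# bootstrap


def _msa_for_split(n_informative, n_noise, seed):
    rng = np.random.default_rng(seed)
    rows = {"A": [], "B": [], "C": [], "D": []}
    for _ in range(n_informative):
        rows["A"].append("K"); rows["B"].append("K")
        rows["C"].append("E"); rows["D"].append("E")
    for _ in range(n_noise):
        for k in rows:
            # two-state noise keeps pairwise distances off the saturation cap
            rows[k].append("KE"[rng.integers(2)])
    return {k: "".join(v) for k, v in rows.items()}


def test_bootstrap_full_support_for_conflict_free_columns():
    msa = _msa_for_split(100, 0, 0)
    tree = phylo.bootstrap_support(msa, replicates=100, seed=1)
    bips = phylo.bipartitions(tree)
    assert set(bips) == {frozenset({"C", "D"})}
    assert bips[frozenset({"C", "D"})].support == 100.0


def test_bootstrap_deterministic_under_seed():
    msa = _msa_for_split(20, 30, 5)
    t1 = phylo.bootstrap_support(msa, replicates=50, seed=42)
    t2 = phylo.bootstrap_support(msa, replicates=50, seed=42)
    assert t1.to_newick() == t2.to_newick()


def test_noise_columns_spread_over_the_three_resolutions():
    # resampled NJ trees from pure-noise 4-taxon alignments should fall on
    # each of the 3 possible resolutions with near-equal frequency
    counts = {frozenset(p): 0 for p in
              [("C", "D"), ("B", "D"), ("B", "C")]}
    rng = np.random.default_rng(0)
    total = 0
    for seed in range(40):
        msa = _msa_for_split(0, 60, seed + 100)
        names, mat = phylo.encode_msa(msa)
        for _ in range(25):
            cols = rng.integers(0, mat.shape[1], size=mat.shape[1])
            rep = phylo.build_nj_tree(
                names, phylo.distance_matrix_from_msa(mat[:, cols])
            )
            for bip in phylo.bipartitions(rep):
                if bip in counts:
                    counts[bip] += 1
                    total += 1
    freqs = [c / total for c in counts.values()]
    assert all(0.2 < f < 0.5 for f in freqs), freqs


def test_bootstrap_rejects_bad_replicates():
    with pytest.raises(ValueError):
        phylo.bootstrap_support(_msa_for_split(5, 0, 0), replicates=0, seed=0)


# ---------------------------------------------------------------------------
# subfamily assignment + diagnostic residues


def test_reference_assigned_its_own_label():
    refs = {
        "REF_SEP": ("SEP", "MKVLWAALLGGG"),
        "REF_SVP": ("SVP", "MMMMWPPPPPPP"),
    }
    a = phylo.assign_subfamily("REF_SEP", refs["REF_SEP"][1], refs)
    assert a.subfamily == "SEP" and a.superclade == "MIKC"


def test_perturbed_reference_still_nearest():
    rng = np.random.default_rng(0)
    base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 120))
    other = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 120))
    refs = {"REF_SEP": ("SEP", base), "REF_Malpha": ("Malpha", other)}
    mutated = list(base)
    for pos in rng.choice(len(base), 5, replace=False):
        mutated[pos] = "A"
    a = phylo.assign_subfamily("g1", "".join(mutated), refs)
    assert a.subfamily == "SEP"
    assert not a.ambiguous_with


def test_assignment_invariant_to_reference_order():
    rng = np.random.default_rng(1)
    seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80)) for _ in range(4)]
    refs1 = {f"R{i}": (sf, s) for i, (sf, s) in
             enumerate(zip(["SEP", "SVP", "AP1", "Malpha"], seqs))}
    refs2 = dict(reversed(list(refs1.items())))
    q = seqs[2]
    assert (phylo.assign_subfamily("g", q, refs1).subfamily
            == phylo.assign_subfamily("g", q, refs2).subfamily)


@pytest.mark.parametrize(
    "triple,expected",
    [
        (("E", "Q", "G"), "FLC_like"),
        (("E", "Q", "A"), "FLC_like"),
        (("E", "Q", "S"), "FLC_like"),
        (("K", "E", "P"), "MIKCstar_like"),
        (("E", "E", "P"), "indeterminate"),
    ],
)
def test_flc_diagnostic_triples(triple, expected):
    verdict, reason = phylo.diagnose_flc(triple)
    assert verdict == expected


def test_flc_gap_is_indeterminate_with_reason():
    verdict, reason = phylo.diagnose_flc(("E", "-", "G"))
    assert verdict == "indeterminate"
    assert "gap" in reason
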