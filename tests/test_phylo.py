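import math
import random

import numpy as np
import pytest

from mitochar.phylo import (
    DistanceMatrix,
    PhyloTree,
    bootstrap_support,
    nj_tree,
    root_with_outgroup,
    tn93_distance,
    tn93_matrix,
    unroot,
)
from mitochar.variation import AlignmentMatrix

# ---------------------------------------------------------------------------
# independent helpers (oracles; no package tree code)


def _random_additive_tree(names, rng):
    """Random binary unrooted tree as nested tuples: a node is either a leaf
    name or a tuple of (child, edge length) pairs; the root has no edge."""
    items = [(name, rng.uniform(0.5, 3.0)) for name in names]
    rng.shuffle(items)
    while len(items) > 3:
        a = items.pop()
        b = items.pop()
        items.insert(0, ((a, b), rng.uniform(0.5, 3.0)))
    return tuple(items)


def _leaves(sub):
    node = sub[0] if isinstance(sub, tuple) and len(sub) == 2 else sub
    if isinstance(node, str):
        return [node]
    out = []
    for child in node:
        out.extend(_leaves(child))
    return out


def _path_matrix(root):
    """Leaf-to-leaf path lengths by brute-force recursion over the tuples."""
    dists = {}

    def descend(node):
        # node: str leaf or tuple of (subtree, length) children
        if isinstance(node, str):
            return [(node, 0.0)]
        gathered = []
        for child, length in node:
            sub = [(nm, d + length) for nm, d in descend(child)]
            for nm_a, d_a in gathered:
                for nm_b, d_b in sub:
                    key = (nm_a, nm_b) if nm_a < nm_b else (nm_b, nm_a)
                    dists[key] = d_a + d_b
            gathered.extend(sub)
        return gathered

    descend(root)
    return dists


def _true_splits(root, all_names):
    anchor = min(all_names)
    full = frozenset(all_names)
    splits = set()

    def descend(node):
        if isinstance(node, str):
            return {node}
        below_all = set()
        for child, _ in node:
            below = descend(child)
            side = frozenset(below)
            if anchor in side:
                side = full - side
            if 2 <= len(side) <= len(all_names) - 2:
                splits.add(side)
            below_all |= below
        return below_all

    descend(root)
    return splits


def _matrix_from_paths(names, paths):
    n = len(names)
    mat = np.zeros((n, n))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                key = (a, b) if a < b else (b, a)
                mat[i, j] = mat[j, i] = paths[key]
    return DistanceMatrix(names=names, matrix=mat)


def _node_path_lengths(tree):
    """Independent traversal of a package PhyloTree (no leaf_path_lengths)."""
    dists = {}

    def descend(node):
        if not node.children:
            return [(node.name, 0.0)]
        gathered = []
        for child in node.children:
            sub = [(nm, d + (child.length or 0.0)) for nm, d in descend(child)]
            for nm_a, d_a in gathered:
                for nm_b, d_b in sub:
                    key = (nm_a, nm_b) if nm_a < nm_b else (nm_b, nm_a)
                    dists[key] = d_a + d_b
            gathered.extend(sub)
        return gathered

    descend(tree.root)
    return dists


def _k2p(p, q):
    return -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))


def _balanced_pair(k, a, b):
    """Sequence pair with equal pooled base frequencies, P1 = P2 = a-pair
    transitions each way and 4b evenly spread transversions."""
    pairs = (
        [("A", "A"), ("C", "C"), ("G", "G"), ("T", "T")] * k
        + [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")] * a
        + [("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")] * b
    )
    return "".join(x for x, _ in pairs), "".join(y for _, y in pairs)


# ---------------------------------------------------------------------------
# TN93


class TestTn93Distance:
    def test_identical_sequences(self):
        assert tn93_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_symmetry(self):
        a, b = _balanced_pair(50, 3, 2)
        assert tn93_distance(a, b) == pytest.approx(tn93_distance(b, a))

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            tn93_distance("ACGT", "ACG")

    @pytest.mark.parametrize("k,a,b", [(100, 5, 3), (200, 10, 1), (50, 2, 2)])
    def test_k2p_closed_form_limit(self, k, a, b):
        # equal base frequencies + equal transition split collapse TN93 to
        # the Kimura two-parameter closed form
        seq_a, seq_b = _balanced_pair(k, a, b)
        n = len(seq_a)
        p = (4 * a) / n
        q = (4 * b) / n
        assert tn93_distance(seq_a, seq_b) == pytest.approx(_k2p(p, q), rel=1e-9)

    def test_ambiguous_columns_excluded_pairwise(self):
        a, b = _balanced_pair(50, 3, 2)
        d0 = tn93_distance(a, b)
        assert tn93_distance(a + "N-", b + "AC") == pytest.approx(d0)

    def test_saturation_inapplicable(self):
        assert tn93_distance("A" * 100, "G" * 100) is None

    def test_monotone_in_mutation_count(self):
        rng = random.Random(7)
        base = "".join(rng.choice("ACGT") for _ in range(4000))
        prev = 0.0
        seq = list(base)
        positions = rng.sample(range(4000), 600)
        dists = []
        for i, pos in enumerate(positions, 1):
            cur = seq[pos]
            seq[pos] = rng.choice([c for c in "ACGT" if c != cur])
            if i % 100 == 0:
                dists.append(tn93_distance(base, "".join(seq)))
        assert all(d is not None for d in dists)
        assert dists == sorted(dists)


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(names=["a", "b"], matrix=np.array([[0, 1], [2, 0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(names=["a", "b"], matrix=np.array([[1.0, 1], [1, 0]]))

    def test_tsv_roundtrip_with_inapplicable(self, tmp_path):
        mat = np.array([[0.0, 0.5, np.nan], [0.5, 0.0, 0.1], [np.nan, 0.1, 0.0]])
        dm = DistanceMatrix(names=["a", "b", "c"], matrix=mat)
        path = tmp_path / "d.tsv"
        dm.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.names == dm.names
        assert back.inapplicable_pairs() == [("a", "c")]
        assert back.get("a", "b") == pytest.approx(0.5)

    def test_tn93_matrix_marks_inapplicable(self):
        aln = AlignmentMatrix(
            names=["a", "b", "c"],
            seqs=["A" * 40, "G" * 40, "".join("AG"[i % 2] for i in range(40))],
        )
        dm = tn93_matrix(aln)
        assert ("a", "b") in dm.inapplicable_pairs()


# ---------------------------------------------------------------------------
# neighbor joining


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d_ab, d_ac, d_bc = 3.0, 4.0, 5.0
        dm = _matrix_from_paths(["A", "B", "C"], {("A", "B"): d_ab, ("A", "C"): d_ac, ("B", "C"): d_bc})
        tree = nj_tree(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): AB|CD with internal edge 1
        paths = {
            ("A", "B"): 3.0,
            ("A", "C"): 5.0,
            ("A", "D"): 6.0,
            ("B", "C"): 6.0,
            ("B", "D"): 7.0,
            ("C", "D"): 7.0,
        }
        tree = nj_tree(_matrix_from_paths(["A", "B", "C", "D"], paths))
        assert tree.split_set() == {frozenset({"C", "D"})}
        got = _node_path_lengths(tree)
        for key, expected in paths.items():
            assert got[key] == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("n_taxa,seed", [(5, 0), (6, 1), (7, 2), (8, 3), (8, 4)])
    def test_random_additive_recovery(self, n_taxa, seed):
        rng = random.Random(seed)
        names = [f"t{i}" for i in range(n_taxa)]
        root = _random_additive_tree(names, rng)
        paths = _path_matrix(root)
        tree = nj_tree(_matrix_from_paths(names, paths))
        assert tree.split_set() == _true_splits(root, names)
        got = _node_path_lengths(tree)
        for key, expected in paths.items():
            assert got[key] == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_ultrametric_matches_single_linkage_topology(self, seed):
        # oracle: scipy single-linkage on an ultrametric matrix recovers the
        # generating coalescent topology; NJ must produce the same splits
        from scipy.cluster.hierarchy import linkage, to_tree
        from scipy.spatial.distance import squareform

        rng = random.Random(100 + seed)
        n = rng.randint(4, 6)
        names = [f"u{i}" for i in range(n)]
        clusters = [{nm} for nm in names]
        height = 0.0
        dist = {}
        while len(clusters) > 1:
            height += rng.uniform(0.5, 1.5)
            i, j = sorted(rng.sample(range(len(clusters)), 2))
            for a in clusters[i]:
                for b in clusters[j]:
                    key = (a, b) if a < b else (b, a)
                    dist[key] = 2 * height
            clusters[i] |= clusters[j]
            clusters.pop(j)
        dm = _matrix_from_paths(names, dist)

        link = linkage(squareform(dm.matrix), method="single")
        anchor, full = min(names), frozenset(names)

        sl_splits = set()

        def collect(node):
            if node.is_leaf():
                return {names[node.id]}
            below = collect(node.left) | collect(node.right)
            side = frozenset(below)
            if anchor in side:
                side = full - side
            if 2 <= len(side) <= n - 2:
                sl_splits.add(side)
            return below

        collect(to_tree(link))
        assert nj_tree(dm).split_set() == sl_splits

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(names=["a", "b"], matrix=np.array([[0.0, 1], [1, 0]])))

    def test_inapplicable_entry_names_pair(self):
        mat = np.array([[0.0, 0.5, np.nan], [0.5, 0.0, 0.1], [np.nan, 0.1, 0.0]])
        with pytest.raises(ValueError, match="a--c"):
            nj_tree(DistanceMatrix(names=["a", "b", "c"], matrix=mat))


# ---------------------------------------------------------------------------
# tree / Newick / rooting


def _demo_tree():
    paths = {
        ("A", "B"): 3.0,
        ("A", "C"): 5.0,
        ("A", "D"): 6.0,
        ("B", "C"): 6.0,
        ("B", "D"): 7.0,
        ("C", "D"): 7.0,
    }
    return nj_tree(_matrix_from_paths(["A", "B", "C", "D"], paths))


class TestNewick:
    def test_roundtrip_preserves_everything(self):
        tree = _demo_tree()
        for split, node in tree.splits().items():
            node.support = 87.0
        text = tree.newick()
        back = PhyloTree.from_newick(text)
        assert sorted(back.leaf_names()) == ["A", "B", "C", "D"]
        assert back.split_set() == tree.split_set()
        for split, node in back.splits().items():
            assert node.support == 87.0
        a, b = _node_path_lengths(tree), _node_path_lengths(back)
        for key in a:
            assert b[key] == pytest.approx(a[key], abs=1e-5)

    def test_min_support_display_rule(self):
        tree = _demo_tree()
        for _, node in tree.splits().items():
            node.support = 55.0
        assert "55" in tree.newick()
        assert "55" not in tree.newick(min_support=70)

    def test_clamp_negative_display_option(self):
        dm = _matrix_from_paths(
            ["a", "b", "c"], {("a", "b"): 1.0, ("a", "c"): 0.1, ("b", "c"): 0.2}
        )
        tree = nj_tree(dm)  # produces a negative pendant edge
        assert "-" in tree.newick()
        assert "-" not in tree.newick(clamp_negative=True)

    def test_dendropy_cross_check(self):
        dendropy = pytest.importorskip("dendropy")
        tree = _demo_tree()
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == ["A", "B", "C", "D"]
        total = sum(e.length for e in parsed.edges() if e.length is not None)
        mine = sum(
            n.length for n in tree.root.walk() if n.length is not None
        )
        assert total == pytest.approx(mine, abs=1e-5)

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            PhyloTree.from_newick("(A,B")


class TestRooting:
    def test_outgroup_child_of_root(self):
        rooted = root_with_outgroup(_demo_tree(), "D")
        assert rooted.rooted
        names = {c.name for c in rooted.root.children}
        assert "D" in names
        assert len(rooted.root.children) == 2

    def test_unknown_taxon_rejected(self):
        with pytest.raises(KeyError):
            root_with_outgroup(_demo_tree(), "Z")

    def test_root_unroot_preserves_splits(self):
        tree = _demo_tree()
        before = tree.split_set()
        rooted = root_with_outgroup(tree, "C")
        assert unroot(rooted).split_set() == before
        assert rooted.split_set() == before  # splits are rooting-invariant

    def test_rooting_preserves_path_lengths(self):
        tree = _demo_tree()
        before = _node_path_lengths(tree)
        after = _node_path_lengths(root_with_outgroup(tree, "B"))
        for key in before:
            assert after[key] == pytest.approx(before[key], abs=1e-10)

    def test_supports_follow_bipartitions(self):
        tree = _demo_tree()
        for _, node in tree.splits().items():
            node.support = 91.0
        rooted = root_with_outgroup(tree, "D")
        rooted_supports = {
            split: node.support for split, node in rooted.splits().items()
        }
        assert rooted_supports == {split: 91.0 for split in tree.split_set()}


# ---------------------------------------------------------------------------
# bootstrap


def _clade_alignment(reps=60):
    """Six taxa, two internally identical clades, de-saturated signal."""
    # column patterns: (clade1 base, clade2 base)
    patterns = [("A", "A"), ("C", "C"), ("A", "G"), ("T", "T"), ("C", "T"), ("G", "G")]
    cols = []
    for x, y in patterns * reps:
        cols.append([x, x, x, y, y, y])
    seqs = ["".join(col[i] for col in cols) for i in range(6)]
    names = ["a1", "a2", "a3", "b1", "b2", "b3"]
    return AlignmentMatrix(names=names, seqs=seqs)


class TestBootstrap:
    def test_perfect_signal_all_supports_100(self):
        result = bootstrap_support(_clade_alignment(), replicates=25, seed=5)
        supports = [n.support for n in result.tree.splits().values()]
        assert supports and all(s == 100.0 for s in supports)
        assert result.dropped == 0

    def test_supports_in_range_and_reproducible(self):
        aln = _clade_alignment()
        r1 = bootstrap_support(aln, replicates=30, seed=11)
        r2 = bootstrap_support(aln, replicates=30, seed=11)
        assert r1.tree.newick() == r2.tree.newick()
        for node in r1.tree.splits().values():
            assert 0.0 <= node.support <= 100.0

    def test_different_seed_can_differ(self):
        # not guaranteed in general, but determinism per seed is
        aln = _clade_alignment()
        r1 = bootstrap_support(aln, replicates=10, seed=1)
        r2 = bootstrap_support(aln, replicates=10, seed=1)
        assert r1.tree.newick() == r2.tree.newick()

    def test_taxon_reordering_invariance(self):
        # needs tie-free distances, so simulate a generic alignment
        from mitochar.synth import simulate_alignment
        from mitochar.phylo import PhyloTree

        tree = PhyloTree.from_newick(
            "((a1:0.05,a2:0.07):0.1,(b1:0.06,b2:0.04):0.1,(c1:0.05,c2:0.08):0.1);"
        )
        aln = simulate_alignment(tree, length=800, seed=9)
        order = [3, 0, 4, 1, 5, 2]
        shuffled = AlignmentMatrix(
            names=[aln.names[i] for i in order], seqs=[aln.seqs[i] for i in order]
        )
        s1 = {
            split: node.support
            for split, node in bootstrap_support(aln, 20, seed=3).tree.splits().items()
        }
        s2 = {
            split: node.support
            for split, node in bootstrap_support(shuffled, 20, seed=3).tree.splits().items()
        }
        assert s1 == s2

    def test_invalid_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(_clade_alignment(), replicates=0)
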