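import io
import itertools

import numpy as np
import pytest

from aavgenotyper import (
    DistanceMatrix,
    SimConfig,
    cluster_by_threshold,
    extract_region,
    neighbor_joining,
    pairwise_matrix,
    simulate_population,
    to_newick,
)
from aavgenotyper.njtree import MissingDistanceError, root_on

QUARTET_SPLITS = {
    ("AB", "CD"): [(0, 1), (2, 3)],
    ("AC", "BD"): [(0, 2), (1, 3)],
    ("AD", "BC"): [(0, 3), (1, 2)],
}


def quartet_ls_fit(d: np.ndarray, split) -> float:
    """Least-squares residual of a quartet topology (brute-force oracle).

    Five edges: four pendant, one internal; the internal edge separates the
    two cherries of the split. Solves the 6-equation path-length system.
    """
    (a, b), (c, e) = split
    rows, rhs = [], []
    for i, j in itertools.combinations(range(4), 2):
        coef = [0.0] * 5
        coef[i] += 1
        coef[j] += 1
        same_cherry = {i, j} in ({a, b}, {c, e})
        if not same_cherry:
            coef[4] = 1.0
        rows.append(coef)
        rhs.append(d[i, j])
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    resid = np.array(rows) @ sol - np.array(rhs)
    return float(np.sum(resid**2))


def additive_quartet(rng) -> tuple[np.ndarray, tuple]:
    """Random additive 4-taxon matrix with a known AB|CD-style split."""
    pend = rng.uniform(0.05, 0.35, size=4)
    internal = rng.uniform(0.02, 0.2)
    order = rng.permutation(4)
    split = [tuple(sorted(order[:2])), tuple(sorted(order[2:]))]
    d = np.zeros((4, 4))
    for i, j in itertools.combinations(range(4), 2):
        same = {i, j} in ({*split[0]}, {*split[1]})
        d[i, j] = d[j, i] = pend[i] + pend[j] + (0 if same else internal)
    return d, tuple(split)


def nj_split(tree) -> tuple:
    """The cherry split of a 4-leaf NJ tree (root has a 2-leaf child)."""
    names = sorted(tree.leaf_names())
    for child in tree.root.children:
        leaves = sorted(child.leaf_names())
        if len(leaves) == 2:
            rest = sorted(set(names) - set(leaves))
            return (tuple(leaves), tuple(rest))
    raise AssertionError("no cherry under root")


class TestNeighborJoining:
    def test_known_additive_quartet_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) scaled by 0.1
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                     float) / 10
        dm = DistanceMatrix(list("ABCD"), d)
        tree = neighbor_joining(dm)
        assert nj_split(tree) == (("A", "B"), ("C", "D"))
        paths = tree.path_lengths()
        expect = dm.to_dataframe().loc[list(paths.index), list(paths.index)].to_numpy()
        assert np.allclose(paths.values, expect, atol=1e-12)

    def test_matches_brute_force_quartet_oracle(self, rng):
        labels = list("ABCD")
        for _ in range(25):
            d, _ = additive_quartet(rng)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            # oracle: the unique topology with zero least-squares residual
            resids = {
                split: quartet_ls_fit(d, QUARTET_SPLITS[split])
                for split in QUARTET_SPLITS
            }
            best = min(resids, key=resids.get)
            assert resids[best] < 1e-12
            oracle_split = (
                tuple(labels[i] for i in QUARTET_SPLITS[best][0]),
                tuple(labels[i] for i in QUARTET_SPLITS[best][1]),
            )
            got = nj_split(tree)
            assert {frozenset(got[0]), frozenset(got[1])} == {
                frozenset(oracle_split[0]), frozenset(oracle_split[1])
            }

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree = neighbor_joining(DistanceMatrix(list("ABC"), d))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.2)
        assert lengths["C"] == pytest.approx(0.3)

    def test_all_zero_matrix_gives_zero_lengths(self):
        dm = DistanceMatrix(list("abcde"), np.zeros((5, 5)))
        tree = neighbor_joining(dm)
        assert np.allclose(tree.path_lengths().values, 0.0)

    def test_two_taxa(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        nwk = to_newick(neighbor_joining(dm))
        assert nwk == "(A:0.200000,B:0.200000);"

    def test_missing_entries_rejected(self):
        vals = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(MissingDistanceError):
            neighbor_joining(DistanceMatrix(["A", "B"], vals))

    def test_negative_lengths_clamped_and_flagged(self):
        # triangle-inequality violation: the three-point formula for A gives
        # (0.1 + 0.1 - 0.5) / 2 < 0
        d = np.array([[0, 0.1, 0.1], [0.1, 0, 0.5], [0.1, 0.5, 0]])
        tree = neighbor_joining(DistanceMatrix(list("ABC"), d))
        assert tree.n_negative_clamped > 0

        def no_negative(node):
            assert node.length is None or node.length >= 0
            for c in node.children:
                no_negative(c)

        no_negative(tree.root)

    def test_additive_consistency_random_sizes(self, rng):
        """Atteson consistency: path lengths reproduce additive inputs."""
        for n in (5, 8, 12):
            d = random_additive_matrix(rng, n)
            dm = DistanceMatrix([f"t{i}" for i in range(n)], d)
            paths = neighbor_joining(dm).path_lengths()
            expect = dm.to_dataframe().loc[list(paths.index), list(paths.index)].to_numpy()
            assert np.allclose(paths.values, expect, atol=1e-10)

    def test_agrees_with_skbio_on_random_additive_matrix(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        d = random_additive_matrix(rng, 7)
        labels = [f"t{i}" for i in range(7)]
        ours = neighbor_joining(DistanceMatrix(labels, d))
        theirs = sk_nj(SkDM(d, labels))
        for i in range(7):
            for j in range(i + 1, 7):
                assert theirs.find(labels[i]).distance(
                    theirs.find(labels[j])
                ) == pytest.approx(d[i, j], abs=1e-9)
        paths = ours.path_lengths()
        expect = np.array([[d[int(a[1:]), int(b[1:])] for b in list(paths.index)]
                           for a in list(paths.index)])
        assert np.allclose(paths.values, expect, atol=1e-9)


def random_additive_matrix(rng, n: int) -> np.ndarray:
    """Pairwise path lengths of a random binary tree (hence additive)."""
    # grow a tree by attaching each new leaf to a random existing edge
    # represent as leaf-to-leaf distances updated incrementally
    d = np.zeros((n, n))
    d[0, 1] = d[1, 0] = rng.uniform(0.1, 0.5)
    for k in range(2, n):
        # subdivide at leaf j's old position: j moves out by `stem`,
        # the new leaf k hangs off the subdivision point by `p`
        j = int(rng.integers(k))
        p = rng.uniform(0.02, 0.3)
        stem = rng.uniform(0.01, 0.1)
        for m in range(k):
            if m != j:
                d[k, m] = d[m, k] = d[j, m] + p
                d[j, m] = d[m, j] = d[j, m] + stem
        d[k, j] = d[j, k] = stem + p
    # uniform rescaling preserves additivity; keep values p-distance-sized
    peak = d.max()
    if peak > 0.95:
        d *= 0.95 / peak
    return d


class TestNewick:
    def test_round_trips_through_skbio(self, rng):
        from skbio import TreeNode as SkNode

        d = random_additive_matrix(rng, 6)
        labels = [f"leaf{i}" for i in range(6)]
        tree = neighbor_joining(DistanceMatrix(labels, d))
        parsed = SkNode.read(io.StringIO(to_newick(tree)))
        assert sorted(t.name for t in parsed.tips()) == sorted(labels)
        for i in range(6):
            for j in range(i + 1, 6):
                assert parsed.find(labels[i]).distance(
                    parsed.find(labels[j])
                ) == pytest.approx(d[i, j], abs=1e-5)

    def test_reserved_characters_quoted(self):
        dm = DistanceMatrix(["a b(c)", "plain"],
                            np.array([[0, 0.2], [0.2, 0]]))
        nwk = to_newick(neighbor_joining(dm))
        assert "'a b(c)'" in nwk

    def test_root_on_outgroup_keeps_leaves(self):
        nwk = "((A:1,B:1):1,C:2,D:3);"
        rooted = root_on(nwk, "D")
        from skbio import TreeNode as SkNode

        t = SkNode.read(io.StringIO(rooted))
        assert sorted(x.name for x in t.tips()) == ["A", "B", "C", "D"]


def test_genotypes_form_clans_on_rep_tree(default_population):
    """Each simulated genotype is a clan (monophyletic in some rooting)."""
    cfg, msa, truth = default_population
    rep = extract_region(msa, cfg.rep_region)
    dm = pairwise_matrix(rep)
    tree = neighbor_joining(dm)
    clustering = cluster_by_threshold(dm, 0.10)
    # bipartition check: for every internal edge, each side's genotype set;
    # a genotype is a clan iff some edge splits exactly its members off.
    all_leaves = set(tree.leaf_names())

    def clades(node, acc):
        if node.is_leaf:
            return {node.name}
        below = set()
        for c in node.children:
            below |= clades(c, acc)
        acc.append(below)
        return below

    acc: list[set] = []
    clades(tree.root, acc)
    sides = {frozenset(s) for s in acc} | {frozenset(all_leaves - s) for s in acc}
    for g in set(truth.genotype.values()):
        members = frozenset(i for i, gg in truth.genotype.items() if gg == g)
        assert members in sides
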