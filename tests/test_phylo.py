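"""Global alignment, p-distances, neighbor-joining, bootstrap, clades."""

import itertools

import numpy as np
import pytest

from mybkit.align import center_star_alignment, global_align, p_distance_aligned
from mybkit.errors import (
    ConfigurationError,
    LookupError_,
    MybkitError,
    SequenceValidationError,
    SizeError,
)
from mybkit.phylo import (
    CladeAssignment,
    DistanceMatrix,
    DomainAlignmentSet,
    assign_clades,
    bootstrap_consensus,
    distances_from_alignment,
    nj_build,
    pairwise_distances,
)

from conftest import mutate, random_additive_tree, random_protein


class TestGlobalAlign:
    def test_identical_sequences(self):
        score, (a, b) = global_align("WWWWW", "WWWWW")
        assert score == 5 and a == b == "WWWWW"

    def test_two_by_one_dp_table(self):
        # AC vs C: align C/C (+1), gap the A (-1) -> 0
        score, (a, b) = global_align("AC", "C", 1, -1, -1)
        assert score == 0 and (a, b) == ("AC", "-C")

    def test_empty_rejected_unless_relaxed(self):
        with pytest.raises(SequenceValidationError):
            global_align("", "AAA")
        score, (a, b) = global_align("AAA", "", 1, -1, -1, allow_empty=True)
        assert score == -3 and b == "---"

    def test_invalid_residue_rejected(self):
        with pytest.raises(SequenceValidationError):
            global_align("AB1", "AAA")


class TestPDistance:
    def test_identical_is_zero(self):
        assert p_distance_aligned("WWAA", "WWAA") == (0.0, 4)

    def test_all_different_is_one(self):
        assert p_distance_aligned("AAAA", "WWWW")[0] == 1.0

    def test_half_different(self):
        a = "AAAAAWWWWW"
        b = "AAAAACCCCC"
        assert p_distance_aligned(a, b) == (0.5, 10)

    def test_gap_columns_excluded(self):
        assert p_distance_aligned("AW-A", "AC-A") == (pytest.approx(1 / 3), 3)

    def test_saturated_pair_reports_one(self):
        assert p_distance_aligned("--AA", "AA--") == (1.0, 0)

    def test_matrix_requires_three_sequences(self):
        s = DomainAlignmentSet({"a": "AA", "b": "AA"}, {"a": "query", "b": "query"})
        with pytest.raises(SizeError):
            pairwise_distances(s)


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        m = np.array([[0, 1.0, 2], [1, 0, 3], [2.0, 3.1, 0]])
        with pytest.raises(MybkitError):
            DistanceMatrix(["a", "b", "c"], m)

    def test_negative_rejected(self):
        m = np.array([[0, -0.1], [-0.1, 0]])
        with pytest.raises(MybkitError):
            DistanceMatrix(["a", "b"], m)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        t = nj_build(dm)
        lengths = {n.name: n.length for n in t.root.children}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2, abs=1e-12)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2, abs=1e-12)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2, abs=1e-12)

    def test_four_taxon_additive_recovers_topology_and_lengths(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive matrix; oracle below
        # scores all three unrooted quartet topologies by four-point sums
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        # four-point condition oracle: the true split pairs the two
        # smallest of the three pairwise sums
        sums = {
            frozenset([frozenset("AB"), frozenset("CD")]): D[0, 1] + D[2, 3],
            frozenset([frozenset("AC"), frozenset("BD")]): D[0, 2] + D[1, 3],
            frozenset([frozenset("AD"), frozenset("BC")]): D[0, 3] + D[1, 2],
        }
        oracle_split = min(sums, key=sums.get)
        assert oracle_split == frozenset([frozenset("AB"), frozenset("CD")])

        t = nj_build(DistanceMatrix(ids, D))
        assert t.splits() == {frozenset({"C", "D"})}
        # path lengths between all leaf pairs reproduce the metric
        dist = _leaf_path_lengths(t)
        for i, j in itertools.combinations(range(4), 2):
            assert dist[(ids[i], ids[j])] == pytest.approx(D[i, j], abs=1e-9)

    def test_random_additive_matrices_recover_generating_topology(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            ids, D, true_splits = random_additive_tree(rng, n)
            t = nj_build(DistanceMatrix(ids, D))
            assert t.splits() == true_splits  # RF distance 0

    def test_agrees_with_skbio_on_noisy_matrices(self):
        # independent NJ implementation as cross-check, on perturbed
        # (non-additive) matrices where join order actually matters
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(31)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            ids, D, _ = random_additive_tree(rng, n)
            noise = rng.uniform(0, 0.05, size=(n, n))
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            D = D + noise
            mine = nj_build(DistanceMatrix(ids, D)).splits()
            sk = sknj(SkDM(D, ids))
            all_l, ref = frozenset(ids), min(ids)
            theirs = set()
            for node in sk.traverse():
                if node.is_tip() or node.parent is None:
                    continue
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = all_l - side
                if 2 <= len(side) <= n - 2:
                    theirs.add(side)
            assert mine == theirs

    def test_equidistant_taxa_join_lexicographically_first_pair(self):
        ids = ["d", "c", "b", "a"]
        D = np.ones((4, 4)) - np.eye(4)
        t = nj_build(DistanceMatrix(ids, D))
        # the single internal join must contain the lexicographically
        # smallest pair {a, b} (tie rule), i.e. split {a,b} | {c,d}
        assert t.splits() == {frozenset({"c", "d"})}

    def test_negative_branch_estimates_are_clamped(self):
        D = np.array(
            [[0, 0.1, 0.4, 0.5], [0.1, 0, 0.45, 0.55], [0.4, 0.45, 0, 0.05], [0.5, 0.55, 0.05, 0]]
        )
        t = nj_build(DistanceMatrix(list("abcd"), D))
        for node in t.root.postorder():
            if node.length is not None:
                assert node.length >= 0


def _leaf_path_lengths(tree):
    """Patristic distances between all leaf pairs of a small tree."""
    import collections

    adj = collections.defaultdict(list)
    for node in tree.root.postorder():
        for c in node.children:
            adj[id(node)].append((id(c), c.length or 0.0))
            adj[id(c)].append((id(node), c.length or 0.0))
    leaves = {id(n): n.name for n in tree.root.postorder() if n.is_leaf()}
    out = {}
    for lid, name in leaves.items():
        dist = {lid: 0.0}
        dq = collections.deque([lid])
        while dq:
            u = dq.popleft()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    dq.append(v)
        for lid2, name2 in leaves.items():
            if name < name2:
                out[(name, name2)] = dist[lid2]
    return out


class TestBootstrap:
    def _two_clade_alignment(self, seed=0, n_per=4, length=80, within=0.04):
        rng = np.random.default_rng(seed)
        base1 = random_protein(rng, length)
        base2 = random_protein(rng, length)
        seqs = {f"A{i}": mutate(rng, base1, within) for i in range(n_per)}
        seqs |= {f"B{i}": mutate(rng, base2, within) for i in range(n_per)}
        return seqs

    def test_same_seed_reproduces_supports(self):
        aln = center_star_alignment(self._two_clade_alignment())
        t1 = bootstrap_consensus(aln, B=50, seed=9)
        t2 = bootstrap_consensus(aln, B=50, seed=9)
        assert t1.newick() == t2.newick()

    def test_congruent_signal_gives_full_support(self):
        # every column separates the same two clades perfectly
        aln = {"A0": "AAAA", "A1": "AAAA", "B0": "CCCC", "B1": "CCCC", "B2": "CCCC"}
        t = bootstrap_consensus(aln, B=30, seed=1)
        supports = [
            n.support
            for n in t.root.postorder()
            if not n.is_leaf() and n is not t.root and n.support is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_strong_two_clade_structure_highly_supported(self):
        aln = center_star_alignment(self._two_clade_alignment(seed=3))
        t = bootstrap_consensus(aln, B=100, seed=42)
        split = frozenset({"B0", "B1", "B2", "B3"})
        support = {
            (n.leaf_names() if "A0" not in n.leaf_names() else None): n.support
            for n in t.root.postorder()
            if not n.is_leaf() and n is not t.root
        }.get(split)
        assert support is not None and support >= 95

    def test_zero_replicates_rejected(self):
        with pytest.raises(ConfigurationError):
            bootstrap_consensus({"a": "AA", "b": "AA", "c": "AA"}, B=0, seed=0)

    def test_supports_bounded_and_majority(self):
        aln = center_star_alignment(self._two_clade_alignment(seed=6, within=0.15))
        B = 60
        t = bootstrap_consensus(aln, B=B, seed=2)
        for n in t.root.postorder():
            if n.support is not None:
                assert 50 < n.support <= 100


class TestCladeAssignment:
    def test_query_sister_to_labeled_reference(self):
        # quartet: query q sits right next to reference r25
        D = np.array(
            [
                [0.0, 0.05, 0.5, 0.5],
                [0.05, 0.0, 0.5, 0.5],
                [0.5, 0.5, 0.0, 0.1],
                [0.5, 0.5, 0.1, 0.0],
            ]
        )
        t = nj_build(DistanceMatrix(["q", "r25", "x1", "x2"], D))
        (a,) = assign_clades(t, {"r25": "clade25", "x1": "clade9"}, ["q"])
        assert a.clade == "clade25"

    def test_reference_free_subtree_is_lineage_specific(self):
        # six labelled clades plus one reference-free clade N, as in the
        # survey design: N is cohesive but attaches to no single
        # labelled clade with support, so its members form one
        # lineage-specific component
        rng = np.random.default_rng(4)
        base = random_protein(rng, 80)
        names = ["A", "B", "C", "D", "E", "F", "N"]
        clades = {c: mutate(rng, base, 0.3) for c in names}
        seqs = {}
        for c, anc in clades.items():
            for i in range(5 if c == "N" else 3):
                seqs[f"{c}{i}"] = mutate(rng, anc, 0.04)
        labels = {
            f"{c}{i}": f"clade_{c}" for c in names if c != "N" for i in range(3)
        }
        queries = [f"N{i}" for i in range(5)]
        t = bootstrap_consensus(center_star_alignment(seqs), B=60, seed=8)
        asg = assign_clades(t, labels, queries)
        assert {a.clade for a in asg} == {"lineage-specific:1"}

    def test_query_tied_between_equal_label_sets_is_unresolved(self):
        # star topology: the smallest clade holding q plus a reference
        # is the whole tree, where the two labels tie -> unresolved
        from mybkit.phylo import Node, Tree

        root = Node()
        for name in ("q", "r1", "r2"):
            leaf = Node(name=name, length=0.1)
            root.add(leaf)
        t = Tree(root)
        (a,) = assign_clades(t, {"r1": "cladeA", "r2": "cladeB"}, ["q"])
        assert a.clade == "unresolved"

    def test_unknown_query_raises(self):
        D = np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        t = nj_build(DistanceMatrix(["a", "b", "c"], D))
        with pytest.raises(LookupError_):
            assign_clades(t, {"a": "c1"}, ["zz"])

    def test_recovery_on_clean_separation(self, bundle):
        from mybkit.align import center_star_alignment

        aln = center_star_alignment(bundle.domains)
        t = bootstrap_consensus(aln, B=100, seed=3)
        queries = [s for s, r in bundle.roles.items() if r == "query"]
        asg = assign_clades(t, bundle.clade_labels, queries)
        man = bundle.manifest["genes"]
        ok = sum(
            (a.clade == man[a.query_id]["clade"])
            or (
                man[a.query_id]["clade"] == "lineage-specific"
                and a.clade.startswith("lineage-specific")
            )
            for a in asg
        )
        assert ok / len(asg) >= 0.95


class TestSerialization:
    def test_newick_roundtrips_through_dendropy(self):
        import dendropy

        D = np.array([[0, 0.2, 0.5, 0.6], [0.2, 0, 0.55, 0.6], [0.5, 0.55, 0, 0.3], [0.6, 0.6, 0.3, 0]])
        t = nj_build(DistanceMatrix(list("abcd"), D))
        parsed = dendropy.Tree.get(data=t.newick(), schema="newick")
        assert {x.taxon.label for x in parsed.leaf_node_iter()} == set("abcd")
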