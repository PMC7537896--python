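"""Distance-based phylogeny and reference-clade assignment.

MYB family classification works by placing query domain sequences in a
tree together with labelled reference domains (e.g. the Arabidopsis
family plus landmark MYBs) and reading the clade label off the smallest
well-supported surrounding clade.  The machinery here is deliberately
classical: p-distances over pairwise or master alignments,
Saitou-Nei neighbor-joining with deterministic tie-breaking, bootstrap
column resampling with a majority-rule consensus, and a clade-assignment
rule that also flags lineage-specific (reference-free) subtrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import GAP, center_star_alignment, global_align, p_distance_aligned
from .errors import ConfigurationError, LookupError_, SizeError, MybkitError

DEFAULT_BOOTSTRAP = 1000
DEFAULT_SUPPORT_THRESHOLD = 50.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class DomainAlignmentSet:
    """Domain sequences with query/reference roles and reference labels."""

    sequences: dict[str, str]
    roles: dict[str, str]
    clade_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, role in self.roles.items():
            if role not in ("query", "reference"):
                raise ConfigurationError(f"unknown role {role!r} for {sid}")
        refs = [s for s, r in self.roles.items() if r == "reference"]
        missing = [s for s in refs if s not in self.clade_labels]
        if missing:
            raise ConfigurationError(f"references without clade label: {missing}")

    @property
    def queries(self) -> list[str]:
        return sorted(s for s, r in self.roles.items() if r == "query")

    @property
    def references(self) -> list[str]:
        return sorted(s for s, r in self.roles.items() if r == "reference")


class DistanceMatrix:
    """Symmetric pairwise distance matrix keyed by an ordered id list."""

    def __init__(self, ids: list[str], d: np.ndarray):
        d = np.asarray(d, dtype=float)
        if d.shape != (len(ids), len(ids)):
            raise MybkitError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise MybkitError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise MybkitError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise MybkitError("distances must be non-negative")
        self.ids = list(ids)
        self.d = d

    def __len__(self) -> int:
        return len(self.ids)


class Node:
    """One node of an (arbitrarily rooted) phylogeny."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.postorder() if n.is_leaf())


class Tree:
    """Unrooted phylogeny stored with an arbitrary root.

    Internal-edge bootstrap supports live on ``Node.support`` (percent).
    """

    def __init__(self, root: Node, n_clamped: int = 0):
        self.root = root
        self.n_clamped = n_clamped  # negative NJ branch estimates set to 0

    @property
    def leaves(self) -> list[str]:
        return sorted(self.root.leaf_names())

    def find_leaf(self, name: str) -> Node:
        for n in self.root.postorder():
            if n.is_leaf() and n.name == name:
                return n
        raise LookupError_(f"leaf {name!r} not in tree")

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, each oriented away from the
        lexicographically smallest leaf."""
        all_leaves = self.root.leaf_names()
        ref = min(all_leaves)
        out = set()
        for node in self.root.postorder():
            if node is self.root or node.is_leaf():
                continue
            side = node.leaf_names()
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf():
                label = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                sup = "" if node.support is None else f"{node.support:g}"
                label = f"({inner}){sup}"
            if node.length is None:
                return label
            return f"{label}:{node.length:.6f}"

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# distances


def pairwise_distances(
    aln_set: DomainAlignmentSet,
    poisson_correct: bool = False,
) -> DistanceMatrix:
    """p-distance matrix over pairwise global alignments.

    Columns containing a gap are excluded from each comparison; a
    saturated pair with no comparable columns gets distance 1.  With
    ``poisson_correct`` distances become -ln(1 - p) (p capped below 1).
    """
    ids = sorted(aln_set.sequences)
    if len(ids) < 3:
        raise SizeError("need at least 3 sequences")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, (aa, ab) = global_align(
                aln_set.sequences[ids[i]], aln_set.sequences[ids[j]]
            )
            p, _ = p_distance_aligned(aa, ab)
            if poisson_correct:
                p = -np.log(max(1.0 - p, 1e-9))
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids, d)


def distances_from_alignment(aligned: dict[str, str]) -> DistanceMatrix:
    """p-distances straight from the columns of a master alignment."""
    ids = sorted(aligned)
    mat = np.array([list(aligned[i]) for i in ids])
    return _distances_from_char_matrix(ids, mat)


def _distances_from_char_matrix(ids: list[str], mat: np.ndarray) -> DistanceMatrix:
    n = len(ids)
    gap = mat == GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            nc = int(ok.sum())
            if nc == 0:
                p = 1.0
            else:
                p = float((mat[i, ok] != mat[j, ok]).mean())
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# neighbor-joining


def nj_build(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor-joining.

    At each step the pair minimising the Q-criterion is joined; ties are
    broken by the lexicographically smallest (representative) id pair.
    Negative branch-length estimates are clamped to zero and counted on
    ``Tree.n_clamped``.
    """
    n = len(dm)
    if n < 3:
        raise SizeError("neighbor-joining needs at least 3 taxa")
    d = dm.d.copy()
    nodes = [Node(name=i) for i in dm.ids]
    reps = list(dm.ids)  # smallest contained leaf id per cluster
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))))
        parent = Node()
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent.add(ni)
        parent.add(nj_)
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [new_rep]

    # final three clusters joined at a trifurcating root (three-point formulas)
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp((dab + dac - dbc) / 2)
    b.length = clamp((dab + dbc - dac) / 2)
    c.length = clamp((dac + dbc - dab) / 2)
    root = Node()
    for x in (a, b, c):
        root.add(x)
    return Tree(root, n_clamped=clamped)


# ---------------------------------------------------------------------------
# bootstrap + consensus


def _majority_consensus(
    leaves: list[str],
    split_counts: dict[frozenset, int],
    split_lengths: dict[frozenset, list[float]],
    leaf_lengths: dict[str, list[float]],
    B: int,
) -> Tree:
    """Build the >50% majority-rule consensus tree from split counts."""
    majority = [
        (cnt, s) for s, cnt in split_counts.items() if cnt > B / 2
    ]
    majority.sort(key=lambda t: (-t[0], sorted(t[1])))
    root = Node()
    leaf_nodes = {}
    for name in leaves:
        ln = Node(name=name)
        lens = leaf_lengths.get(name)
        ln.length = float(np.mean(lens)) if lens else 0.0
        root.add(ln)
        leaf_nodes[name] = ln

    ref = min(leaves)
    for cnt, split in majority:
        # locate the lowest node whose clade contains the split
        node = root
        descended = True
        while descended:
            descended = False
            for ch in node.children:
                if not ch.is_leaf() and split <= ch.leaf_names():
                    node = ch
                    descended = True
                    break
        group = [ch for ch in node.children if ch.leaf_names() <= split]
        if frozenset().union(*(ch.leaf_names() for ch in group)) != split:
            continue  # incompatible with an earlier (more frequent) split
        new = Node(support=100.0 * cnt / B)
        lens = split_lengths.get(split)
        new.length = float(np.mean(lens)) if lens else 0.0
        for ch in group:
            node.children.remove(ch)
            new.add(ch)
        node.add(new)
    return Tree(root)


def bootstrap_consensus(
    aligned: dict[str, str],
    B: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> Tree:
    """Column-resampling bootstrap with majority-rule (>50%) consensus.

    ``aligned`` maps id -> aligned sequence (equal lengths).  Columns
    are resampled with replacement B times, an NJ tree is rebuilt from
    p-distances each time, and the consensus carries percent supports on
    its internal edges.  Branch lengths are averaged over the replicates
    containing each edge.  Reproducible for a fixed seed.
    """
    if B < 1:
        raise ConfigurationError("bootstrap replicate count B must be >= 1")
    ids = sorted(aligned)
    if len(ids) < 3:
        raise SizeError("need at least 3 sequences")
    widths = {len(s) for s in aligned.values()}
    if len(widths) != 1:
        raise ConfigurationError("sequences are not aligned (unequal lengths)")
    L = widths.pop()
    mat = np.array([list(aligned[i]) for i in ids])
    rng = np.random.default_rng(seed)

    split_counts: dict[frozenset, int] = {}
    split_lengths: dict[frozenset, list[float]] = {}
    leaf_lengths: dict[str, list[float]] = {i: [] for i in ids}
    all_leaves = frozenset(ids)
    ref = min(ids)
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        dm = _distances_from_char_matrix(ids, mat[:, cols])
        t = nj_build(dm)
        for node in t.root.postorder():
            if node.is_leaf():
                leaf_lengths[node.name].append(node.length or 0.0)
                continue
            if node is t.root:
                continue
            side = node.leaf_names()
            if ref in side:
                side = all_leaves - side
            if not (2 <= len(side) <= len(ids) - 2):
                continue
            split_counts[side] = split_counts.get(side, 0) + 1
            split_lengths.setdefault(side, []).append(node.length or 0.0)
    return _majority_consensus(ids, split_counts, split_lengths, leaf_lengths, B)


def build_master_alignment(
    sequences: dict[str, str], prealigned: bool = False
) -> dict[str, str]:
    """Master alignment for bootstrapping: user-supplied pre-aligned
    sequences, or a center-star progressive alignment."""
    if prealigned:
        widths = {len(s) for s in sequences.values()}
        if len(widths) != 1:
            raise ConfigurationError("pre-aligned input has unequal lengths")
        return {k: v.upper() for k, v in sequences.items()}
    return center_star_alignment(sequences)


# ---------------------------------------------------------------------------
# clade assignment


@dataclass(frozen=True)
class CladeAssignment:
    """Clade call for one query: a reference label, ``lineage-specific:k``
    or ``unresolved``, with the percent support of the defining edge."""

    query_id: str
    clade: str
    support: float


def assign_clades(
    tree: Tree,
    labels: dict[str, str],
    queries: list[str],
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    min_component: int = 2,
) -> list[CladeAssignment]:
    """Assign each query to a labelled reference clade.

    For each query the smallest surrounding clade that is well supported
    (support >= threshold; unannotated edges and the root pass) and
    contains at least one reference determines the label by reference
    majority; an exact tie is ``unresolved``.  A maximal well-supported
    clade of >= ``min_component`` query-only leaves is a novel,
    reference-free clade and is reported as ``lineage-specific:k``
    (k numbered by smallest member id) — unless it is nested inside
    some label's own reference clade (the minimal clade spanning that
    label's references), in which case it is ordinary within-clade
    expansion and inherits the label.  Attaching as a sister next to a
    labelled clade does not count as membership: that is exactly how
    genuinely lineage-specific clades sit in a reference phylogeny.
    """
    leaf_set = set(tree.leaves)
    for lid in labels:
        if lid not in leaf_set:
            raise LookupError_(f"label id {lid!r} is not a leaf")
    for q in queries:
        if q not in leaf_set:
            raise LookupError_(f"query {q!r} is not a leaf")
    qset = set(queries)
    refs = set(labels)
    all_leaves = frozenset(tree.leaves)

    # Clades of the unrooted topology: both sides of every edge.  Each
    # non-root node contributes its leaf set and the complement, carrying
    # the edge's bootstrap support (unannotated edges pass the threshold).
    sides: list[tuple[frozenset, float]] = []
    for node in tree.root.postorder():
        if node is tree.root:
            continue
        down = node.leaf_names()
        sup = node.support if node.support is not None else 100.0
        if sup < support_threshold:
            continue
        sides.append((down, sup))
        sides.append((all_leaves - down, sup))
    sides.append((all_leaves, 100.0))  # whole tree as last resort

    def smallest_with_ref(
        containing: frozenset,
    ) -> list[tuple[frozenset, float]]:
        """All minimal-size clades containing ``containing`` plus >= 1
        reference; several clades of the tied minimal size may exist."""
        cands = [
            (len(s), s, sup) for s, sup in sides if containing <= s and s & refs
        ]
        if not cands:
            return []
        best = min(c[0] for c in cands)
        minimal = {}
        for size, s, sup in cands:
            if size == best:
                minimal[s] = max(sup, minimal.get(s, 0.0))
        return sorted(minimal.items(), key=lambda kv: tuple(sorted(kv[0])))

    def majority_label(side: frozenset) -> str:
        counts: dict[str, int] = {}
        for r in side & refs:
            counts[labels[r]] = counts.get(labels[r], 0) + 1
        top = max(counts.values())
        winners = sorted(c for c, v in counts.items() if v == top)
        return winners[0] if len(winners) == 1 else "unresolved"

    by_label: dict[str, frozenset] = {}
    for r, lab in labels.items():
        by_label[lab] = by_label.get(lab, frozenset()) | {r}

    def nested_in_reference_clade(comp: frozenset) -> bool:
        """Whether a query-only clade sits inside some label's own
        reference clade (as opposed to attaching next to it)."""
        ctx_labels = {labels[r] for s, _ in smallest_with_ref(comp) for r in s & refs}
        for lab in ctx_labels:
            ref_set = by_label[lab]
            if len(ref_set) >= 2:
                # minimal clade spanning the label's references; the
                # component is nested iff some minimal spanning clade
                # holds it too
                spans = [s for s, _ in sides if ref_set <= s]
                best = min(len(s) for s in spans)
                if any(comp <= s for s in spans if len(s) == best):
                    return True
            else:
                # single reference: nested iff the smallest clade
                # holding component + reference has no foreign label
                union = [
                    s for s, _ in sides if comp <= s and ref_set <= s
                ]
                best = min(len(s) for s in union)
                tight = [s for s in union if len(s) == best]
                if all(
                    {labels[r] for r in s & refs} == {lab} for s in tight
                ):
                    return True
        return False

    # Reference-free (query-only) maximal clades of >= min_component
    # leaves mark candidate novel clades; they are lineage-specific
    # unless nested inside a labelled reference clade, in which case
    # their members inherit that label through the normal rule below.
    qonly = [s for s, _ in sides if s and s <= qset and len(s) >= min_component]
    maximal = [s for s in qonly if not any(s < t for t in qonly)]
    comp_of: dict[str, int] = {}
    k = 0
    for comp in sorted(set(maximal), key=lambda s: min(s)):
        if nested_in_reference_clade(comp):
            continue
        k += 1
        for q in comp:
            comp_of[q] = k

    out = []
    for q in sorted(queries):
        if q in comp_of:
            out.append(CladeAssignment(q, f"lineage-specific:{comp_of[q]}", 100.0))
            continue
        found = smallest_with_ref(frozenset([q]))
        if not found:
            out.append(CladeAssignment(q, "unresolved", 0.0))
            continue
        calls = {majority_label(s) for s, _ in found}
        sup = max(sup for _, sup in found)
        label = calls.pop() if len(calls) == 1 else "unresolved"
        out.append(CladeAssignment(q, label, sup))
    return out
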