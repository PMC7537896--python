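import collections

import numpy as np
import pytest

from mybkit.data import load_table1_catalog, load_table2_expression
from mybkit.profiles import AMINO_ACIDS, RepeatProfile
from mybkit.synthetic import FamilySpec, generate


@pytest.fixture(scope="session")
def profile():
    return RepeatProfile()


@pytest.fixture(scope="session")
def table1():
    return load_table1_catalog()


@pytest.fixture(scope="session")
def table2():
    return load_table2_expression()


@pytest.fixture(scope="session")
def bundle():
    """Default-sized noise-free synthetic bundle shared across tests."""
    return generate(FamilySpec(seed=11))


@pytest.fixture(scope="session")
def bundle200():
    """200-protein noise-free bundle for planted-interval recovery."""
    spec = FamilySpec(
        n_genes={"none": 10, "1R": 10, "R2R3": 150, "3R": 20, "4R": 10},
        seed=42,
    )
    return generate(spec)


def random_protein(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([a for a in AMINO_ACIDS if a != out[i]])
    return "".join(out)


def random_additive_tree(rng, n):
    """Random binary tree metric: returns (leaf ids, distance matrix,
    set of generating nontrivial splits oriented away from min leaf)."""
    adj = {}

    def add_edge(a, b, w):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    ids = []
    for i in range(3):
        lid = f"L{i:02d}"
        add_edge(0, lid, rng.uniform(0.05, 1.0))
        ids.append(lid)
    nxt = 1
    for i in range(3, n):
        edges = [(a, b, w) for a in adj for (b, w) in adj[a] if str(a) < str(b)]
        a, b, w = edges[rng.integers(0, len(edges))]
        adj[a] = [(x, y) for x, y in adj[a] if x != b]
        adj[b] = [(x, y) for x, y in adj[b] if x != a]
        mid = f"I{nxt}"
        nxt += 1
        frac = rng.uniform(0.1, 0.9)
        add_edge(a, mid, frac * w)
        add_edge(mid, b, (1 - frac) * w)
        lid = f"L{i:02d}"
        add_edge(mid, lid, rng.uniform(0.05, 1.0))
        ids.append(lid)

    D = np.zeros((n, n))
    for i, s in enumerate(ids):
        dist = {s: 0.0}
        dq = collections.deque([s])
        while dq:
            u = dq.popleft()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    dq.append(v)
        for j, t in enumerate(ids):
            D[i, j] = dist[t]
    D = (D + D.T) / 2

    # generating splits: remove each internal edge, collect one side
    all_leaves = frozenset(ids)
    ref = min(ids)
    splits = set()
    internal = [x for x in adj if not str(x).startswith("L")]
    for a in internal:
        for b, _ in adj[a]:
            if str(b).startswith("L") or str(a) > str(b):
                continue
            # leaves on b's side of edge (a, b)
            seen = {a, b}
            dq = collections.deque([b])
            side = set()
            while dq:
                u = dq.popleft()
                if str(u).startswith("L"):
                    side.add(u)
                for v, _w in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        dq.append(v)
            side = frozenset(side)
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= n - 2:
                splits.add(side)
    return ids, D, splits
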