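"""Shared fixtures and independent oracle helpers.

The helpers here deliberately avoid the package's own code paths: the
random additive-tree generator builds trees as plain adjacency dicts and
computes path lengths and bipartitions by graph traversal, and the naive
K2P evaluator is a character-by-character loop.  They serve as
independent references for the optimized implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
BASES = PURINES | PYRIMIDINES


# ---------------------------------------------------------------- K2P oracle

def naive_k2p(seq_a: str, seq_b: str) -> tuple[float, float, float, int]:
    """Direct closed-form K2P evaluation via a per-character loop.

    Returns (d, P, Q, n_sites); raises ValueError on saturation.
    """
    n = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in BASES or y not in BASES:
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        raise ValueError("saturated")
    d = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
    return d, P, Q, n


def random_sequence_pair(
    rng: np.random.Generator, length: int = 400
) -> tuple[str, str]:
    """A random pair with random substitutions and some missing data."""
    bases = np.array(list("ACGT"))
    a = bases[rng.integers(0, 4, size=length)]
    b = a.copy()
    n_sub = int(rng.integers(0, length // 6))
    pos = rng.choice(length, size=n_sub, replace=False) if n_sub else []
    for p in pos:
        b[p] = rng.choice([c for c in "ACGT" if c != b[p]])
    # sprinkle gaps/N on both
    for seq in (a, b):
        n_miss = int(rng.integers(0, length // 20))
        if n_miss:
            mp = rng.choice(length, size=n_miss, replace=False)
            seq[mp] = rng.choice(["-", "N"], size=n_miss)
    return "".join(a), "".join(b)


# --------------------------------------------- random additive trees (oracle)

class AdjacencyTree:
    """Unrooted weighted tree held as an adjacency dict (oracle container)."""

    def __init__(self):
        self.adj: dict[int, dict[int, float]] = {}
        self.tip_labels: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if label is not None:
            self.tip_labels[nid] = label
        return nid

    def connect(self, a: int, b: int, length: float) -> None:
        self.adj[a][b] = length
        self.adj[b][a] = length

    def disconnect(self, a: int, b: int) -> float:
        length = self.adj[a].pop(b)
        self.adj[b].pop(a)
        return length

    @property
    def tips(self) -> list[str]:
        return [self.tip_labels[n] for n in sorted(self.tip_labels)]

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """All tip-to-tip path sums by DFS from each tip."""
        tip_ids = sorted(self.tip_labels)
        labels = [self.tip_labels[t] for t in tip_ids]
        n = len(tip_ids)
        mat = np.zeros((n, n))
        for i, start in enumerate(tip_ids):
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in self.adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, t in enumerate(tip_ids):
                mat[i, j] = dist[t]
        return labels, mat

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial splits, each as the frozenset of the smaller-or-
        lexicographically-first side's tip labels, normalized by taking
        both sides and keeping the one containing the first tip."""
        all_tips = frozenset(self.tip_labels.values())
        first = min(all_tips)
        splits: set[frozenset[str]] = set()
        edges = [
            (a, b) for a in self.adj for b in self.adj[a] if a < b
        ]
        for a, b in edges:
            length = self.disconnect(a, b)
            side = set()
            stack = [a]
            seen = {a}
            while stack:
                u = stack.pop()
                if u in self.tip_labels:
                    side.add(self.tip_labels[u])
                for v in self.adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            self.connect(a, b, length)
            if 1 < len(side) < len(all_tips) - 1:
                norm = (
                    frozenset(side) if first in side else all_tips - frozenset(side)
                )
                splits.add(norm)
        return splits


def random_additive_tree(
    n_tips: int, rng: np.random.Generator, min_len: float = 0.05, max_len: float = 1.0
) -> AdjacencyTree:
    """Random unrooted binary tree with positive random branch lengths.

    Built independently of any package code: start from a 3-tip star and
    repeatedly subdivide a random edge to attach each new tip.
    """
    assert n_tips >= 3
    t = AdjacencyTree()
    center = t.new_node()
    for k in range(3):
        tip = t.new_node(label=f"T{k}")
        t.connect(center, tip, rng.uniform(min_len, max_len))
    for k in range(3, n_tips):
        edges = [(a, b) for a in t.adj for b in t.adj[a] if a < b]
        a, b = edges[rng.integers(0, len(edges))]
        w = t.disconnect(a, b)
        mid = t.new_node()
        cut = rng.uniform(0.2, 0.8) * w
        t.connect(a, mid, cut)
        t.connect(mid, b, w - cut)
        tip = t.new_node(label=f"T{k}")
        t.connect(mid, tip, rng.uniform(min_len, max_len))
    return t


def dendropy_bipartitions(tree) -> set[frozenset[str]]:
    """Nontrivial splits of a dendropy tree, normalized as above."""
    sets: dict[int, frozenset] = {}
    out: list[frozenset] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(sets[id(c)] for c in node.child_nodes()))
        sets[id(node)] = s
        out.append(s)
    all_tips = frozenset().union(*out)
    first = min(all_tips)
    splits = set()
    for s in out:
        if 1 < len(s) < len(all_tips) - 1:
            splits.add(s if first in s else all_tips - s)
    return splits


# ------------------------------------------------------------------ fixtures

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140702)


@pytest.fixture(scope="session")
def basic_sim():
    """One planted-structure dataset shared across read-only tests."""
    from barcodegap import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        n_species=6,
        specimens_per_species=6,
        planted_splits=((1, 6.0, 0.5),),
        planted_lumps=(3,),
        seed=42,
    )
    return simulate_dataset(cfg)
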