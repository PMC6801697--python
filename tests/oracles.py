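"""Independent reference implementations used only by the test suite.

Each oracle re-derives the quantity from first principles in the most
naive way available (exact rational arithmetic, exhaustive enumeration),
sharing no code path with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# NG86 brute force


def oracle_syn_sites(codon: str) -> Fraction:
    """Synonymous sites of one codon: per position, the fraction of the 3
    possible changes that preserve the amino acid (stops never count)."""
    s = Fraction(0)
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mut) == _aa(codon) and _aa(mut) != "*":
                s += Fraction(1, 3)
    return s


def oracle_pathways(c1: str, c2: str) -> tuple[Fraction, Fraction]:
    """Average synonymous/nonsynonymous step counts over all minimal
    pathways between two codons, stop-free pathways only (all pathways
    when every one passes through a stop)."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return Fraction(0), Fraction(0)
    paths = []
    for order in itertools.permutations(pos):
        cur = c1
        sd = nd = 0
        stop_free = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if _aa(nxt) == "*":
                stop_free = False
            if _aa(nxt) == _aa(cur) and _aa(nxt) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((stop_free, sd, nd))
    usable = [(s, n) for ok, s, n in paths if ok] or [(s, n) for _, s, n in paths]
    k = len(usable)
    return (
        sum(Fraction(s) for s, _ in usable) / k,
        sum(Fraction(n) for _, n in usable) / k,
    )


def oracle_ng86(codons_a: list[str], codons_b: list[str]) -> tuple[float, float]:
    """(ka, ks) by exhaustive enumeration; NaN where the correction
    saturates."""
    S = sum(oracle_syn_sites(a) + oracle_syn_sites(b) for a, b in zip(codons_a, codons_b)) / 2
    N = 3 * len(codons_a) - S
    Sd = Nd = Fraction(0)
    for a, b in zip(codons_a, codons_b):
        sd, nd = oracle_pathways(a, b)
        Sd += sd
        Nd += nd
    ps = Sd / S if S else Fraction(0)
    pn = Nd / N if N else Fraction(0)

    def jc(p: Fraction) -> float:
        if p >= Fraction(3, 4):
            return math.nan
        return -0.75 * math.log(1 - 4 * float(p) / 3)

    return jc(pn), jc(ps)


# ---------------------------------------------------------------------------
# Exhaustive chain enumeration


def _oracle_step_ok(x, y, sign: int, max_gap: int) -> bool:
    if y.index_a <= x.index_a or y.index_a - x.index_a - 1 > max_gap:
        return False
    db = (y.index_b - x.index_b) * sign
    return db >= 1 and db - 1 <= max_gap


def oracle_longest_chain(anchors, sign: int, max_gap: int):
    """Canonical longest chain by full enumeration of every valid chain:
    maximal length, ties broken by the lexicographically smallest tuple
    of positions in the (index_a, index_b)-sorted anchor list."""
    srt = sorted(anchors, key=lambda a: (a.index_a, a.index_b))
    n = len(srt)
    best: tuple[int, tuple[int, ...]] | None = None

    def extend(chain: tuple[int, ...]) -> None:
        nonlocal best
        key = (-len(chain), chain)
        if best is None or key < best:
            best = key
        last = chain[-1]
        for j in range(last + 1, n):
            if _oracle_step_ok(srt[last], srt[j], sign, max_gap):
                extend(chain + (j,))

    for i in range(n):
        extend((i,))
    if best is None:
        return []
    return [srt[i] for i in best[1]]


def oracle_chain_blocks(anchors, min_anchors: int, max_gap: int):
    """Greedy longest-first decomposition using the exhaustive chain
    finder; forward wins length ties, mirroring the chaining contract."""
    remaining = list(anchors)
    blocks = []
    while True:
        fwd = oracle_longest_chain(remaining, +1, max_gap)
        rev = oracle_longest_chain(remaining, -1, max_gap)
        chain, orient = (fwd, "forward") if len(fwd) >= len(rev) else (rev, "reverse")
        if len(chain) < min_anchors:
            break
        blocks.append((orient, tuple((a.index_a, a.index_b) for a in chain)))
        ids = {id(a) for a in chain}
        remaining = [a for a in remaining if id(a) not in ids]
    blocks.sort(key=lambda b: b[1][0][0])
    return blocks


# ---------------------------------------------------------------------------
# Random additive trees (for NJ recovery)


class AdditiveTree:
    """Unrooted tree built by random edge subdivision; provides exact
    path-length distances and the set of nontrivial leaf bipartitions."""

    def __init__(self, n_leaves: int, rng: np.random.Generator):
        if n_leaves < 3:
            raise ValueError("need >= 3 leaves")
        self.adj: dict[str, dict[str, float]] = {}
        self.leaves = [f"T{i}" for i in range(n_leaves)]
        hub = "I0"
        self._n_internal = 1
        for leaf in self.leaves[:3]:
            self._add_edge(hub, leaf, self._blen(rng))
        for leaf in self.leaves[3:]:
            edges = [
                (u, v) for u in self.adj for v in self.adj[u] if u < v
            ]
            u, v = edges[rng.integers(0, len(edges))]
            w = f"I{self._n_internal}"
            self._n_internal += 1
            L = self.adj[u][v]
            frac = float(rng.uniform(0.2, 0.8))
            del self.adj[u][v], self.adj[v][u]
            self._add_edge(u, w, frac * L)
            self._add_edge(w, v, (1 - frac) * L)
            self._add_edge(w, leaf, self._blen(rng))

    @staticmethod
    def _blen(rng) -> float:
        return float(rng.uniform(0.05, 1.0))

    def _add_edge(self, u: str, v: str, length: float) -> None:
        self.adj.setdefault(u, {})[v] = length
        self.adj.setdefault(v, {})[u] = length

    def distance_matrix(self) -> np.ndarray:
        n = len(self.leaves)
        D = np.zeros((n, n))
        for i, leaf in enumerate(self.leaves):
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                u = stack.pop()
                for v, L in self.adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + L
                        stack.append(v)
            for j, other in enumerate(self.leaves):
                D[i, j] = dist[other]
        return D

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        out = set()
        all_leaves = frozenset(self.leaves)
        for u in self.adj:
            for v in self.adj[u]:
                if u < v:
                    side = self._leaves_beyond(u, v)
                    if 2 <= len(side) <= len(all_leaves) - 2:
                        out.add(frozenset({side, all_leaves - side}))
        return out

    def _leaves_beyond(self, u: str, v: str) -> frozenset[str]:
        seen = {u, v}
        stack = [v]
        found = set()
        while stack:
            x = stack.pop()
            if x in self.leaves:
                found.add(x)
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(found)


def tree_bipartitions(tree) -> set[frozenset[frozenset[str]]]:
    """Nontrivial leaf bipartitions of a Biopython tree (root ignored)."""
    all_leaves = frozenset(t.name for t in tree.get_terminals())
    out = set()
    for clade in tree.get_nonterminals():
        for child in clade.clades:
            side = frozenset(t.name for t in child.get_terminals())
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(frozenset({side, all_leaves - side}))
    return out
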