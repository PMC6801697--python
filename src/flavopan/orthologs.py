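"""Ortholog group inference from filtered all-vs-all similarity hits.

The filter keeps a hit only when (a) the alignment covers at least 80% of
the longer of the two proteins and (b) percent identity clears a
length-dependent floor: a flat 30% for alignments of 150 aa or more, and
for shorter alignments the empirical curve

    threshold(L) = 100 * (0.06 + 4.8 * L**(-0.32 * (1 + exp(-L / 1000))))

which decreases with L and meets the 30% floor near L = 150.  Surviving
hits define a weighted undirected graph (weight = -log10 e-value) that is
partitioned by Markov clustering (MCL): alternate expansion (matrix
squaring) and inflation (entrywise power followed by column
renormalization) of the column-stochastic adjacency matrix until the
matrix is idempotent, then read clusters off the attractor structure.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from flavopan.io import SimilarityHit

logger = logging.getLogger(__name__)

EVALUE_FLOOR = 1e-300  # caps -log10(evalue) at 300


def short_threshold(aligned_length: float) -> float:
    """Identity threshold (%) for alignments shorter than 150 aa."""
    L = float(aligned_length)
    return 100.0 * (0.06 + 4.8 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0))))


@dataclasses.dataclass(frozen=True)
class FilterRule:
    """Hit-filtering thresholds (defaults are the published rules)."""

    coverage_fraction: float = 0.8
    identity_floor_long: float = 30.0
    long_length: int = 150

    def identity_threshold(self, aligned_length: int) -> float:
        if aligned_length >= self.long_length:
            return self.identity_floor_long
        return short_threshold(aligned_length)

    def keeps(self, hit: SimilarityHit) -> bool:
        if hit.query_id == hit.subject_id:
            return False
        longer = max(hit.query_length, hit.subject_length)
        if hit.aligned_length < self.coverage_fraction * longer:
            return False
        return hit.percent_identity >= self.identity_threshold(hit.aligned_length)


def filter_hits(
    hits: Iterable[SimilarityHit], rule: FilterRule | None = None
) -> list[SimilarityHit]:
    """Apply the coverage and length-dependent identity rules per hit.

    Self-hits are removed.  Idempotent and order-independent.
    """
    rule = rule or FilterRule()
    hits = list(hits)
    kept = [h for h in hits if rule.keeps(h)]
    logger.info("filter_hits: %d in, %d kept", len(hits), len(kept))
    return kept


@dataclasses.dataclass
class OrthologGroupSet:
    """Result of clustering: multi-gene groups, singletons, gene->genome."""

    groups: dict[str, frozenset[str]]
    singletons: frozenset[str]
    genome_of: dict[str, str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gid, members in self.groups.items():
            if len(members) < 2:
                raise ValueError(f"group {gid!r} has fewer than 2 members")
            if seen & members:
                raise ValueError("groups are not pairwise disjoint")
            seen |= members
        if seen & self.singletons:
            raise ValueError("singleton also appears in a group")

    @property
    def all_genes(self) -> frozenset[str]:
        out = set(self.singletons)
        for members in self.groups.values():
            out |= members
        return frozenset(out)

    def genomes_of_group(self, group_id: str) -> set[str]:
        return {self.genome_of[g] for g in self.groups[group_id]}


def mcl_cluster(
    hits: Sequence[SimilarityHit],
    genome_of: Mapping[str, str],
    inflation: float = 1.5,
    max_iter: int = 200,
    tol: float = 1e-8,
    prune: float = 1e-9,
) -> OrthologGroupSet:
    """Markov clustering of the filtered similarity graph.

    Edge weight between two genes is the average of the two directed
    -log10(e-value) scores (e-values floored at 1e-300); a missing
    reciprocal hit contributes 0 to the average.  Every gene of
    ``genome_of`` absent from any multi-gene cluster is reported as a
    singleton.  Ties in attractor assignment go to the group whose
    smallest member sorts first.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    genes = sorted(genome_of)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    # directed weights, then symmetrize by averaging with the transpose
    w: dict[tuple[int, int], float] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        i, j = index[h.query_id], index[h.subject_id]
        wt = -math.log10(max(h.evalue, EVALUE_FLOOR))
        w[(i, j)] = max(w.get((i, j), 0.0), wt)
    sym: dict[tuple[int, int], float] = {}
    for (i, j), wt in w.items():
        a, b = min(i, j), max(i, j)
        sym[(a, b)] = sym.get((a, b), 0.0) + wt / 2.0

    if not sym:
        return OrthologGroupSet({}, frozenset(genes), dict(genome_of))

    rows, cols, vals = [], [], []
    for (i, j), wt in sym.items():
        rows += [i, j]
        cols += [j, i]
        vals += [wt, wt]
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    # self-loops at each node's max incident weight stabilize convergence
    loop = np.asarray(M.max(axis=0).todense()).ravel()
    loop[loop == 0] = 1.0
    M = (M + sp.diags(loop)).tocsc()

    M = _normalize_columns(M)
    for it in range(max_iter):
        prev = M
        M = M @ M  # expansion
        M = M.power(inflation)  # inflation
        M = _normalize_columns(M)
        M.data[M.data < prune] = 0.0
        M.eliminate_zeros()
        residual = abs(M - prev).max()
        if residual < tol:
            logger.info("MCL converged after %d iterations", it + 1)
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iter} iterations "
            f"(residual {residual:.3g})"
        )

    clusters = _interpret(M, n)

    groups: dict[str, frozenset[str]] = {}
    singles: set[str] = set(genes)
    multi = sorted(
        (sorted(genes[i] for i in c) for c in clusters if len(c) > 1),
        key=lambda ms: ms[0],
    )
    for k, members in enumerate(multi, start=1):
        groups[f"OG{k:06d}"] = frozenset(members)
        singles -= set(members)
    logger.info(
        "mcl_cluster: %d genes -> %d groups, %d singletons",
        n,
        len(groups),
        len(singles),
    )
    return OrthologGroupSet(groups, frozenset(singles), dict(genome_of))


def _normalize_columns(M: sp.spmatrix) -> sp.csc_matrix:
    M = sp.csc_matrix(M)
    sums = np.asarray(M.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return M @ sp.diags(1.0 / sums)


def _interpret(M: sp.csc_matrix, n: int, eps: float = 1e-6) -> list[set[int]]:
    """Clusters from the idempotent MCL matrix.

    Attractors are nodes with mass on their own diagonal; attractors
    connected through the limit matrix form one attractor system; every
    node joins the system holding the largest share of its column (ties:
    the system with the smallest node index).
    """
    D = M.toarray()
    attractors = [i for i in range(n) if D[i, i] > eps]
    if not attractors:  # degenerate; fall back to graph components
        nc, labels = connected_components(M + M.T, directed=False)
        return [set(np.where(labels == c)[0]) for c in range(nc)]
    sub = (D[np.ix_(attractors, attractors)] > eps).astype(int)
    nc, labels = connected_components(sp.csr_matrix(sub), directed=False)
    systems: list[set[int]] = [set() for _ in range(nc)]
    for a, lab in zip(attractors, labels):
        systems[lab].add(a)
    anchor = [min(s) for s in systems]
    clusters = [set(s) for s in systems]
    attractor_set = set(attractors)
    for j in range(n):
        if j in attractor_set:
            continue
        mass = np.zeros(nc)
        for lab, s in enumerate(systems):
            mass[lab] = sum(D[i, j] for i in s)
        if mass.max() <= eps:
            clusters.append({j})  # unattached node: its own singleton
            continue
        best = np.flatnonzero(mass >= mass.max() - 1e-12)
        lab = min(best, key=lambda b: anchor[b])
        clusters[lab].add(j)
    return [c for c in clusters if c]


def core_groups(
    groups: OrthologGroupSet, genomes: Sequence[str], min_genomes: int
) -> list[str]:
    """Group ids with members from at least ``min_genomes`` distinct genomes."""
    if min_genomes > len(genomes):
        raise ValueError("min_genomes exceeds the number of genomes")
    genome_set = set(genomes)
    out = []
    for gid in sorted(groups.groups):
        present = groups.genomes_of_group(gid) & genome_set
        if len(present) >= min_genomes:
            out.append(gid)
    return out


def pairwise_orthologs(
    groups: OrthologGroupSet, genome_a: str, genome_b: str
) -> list[tuple[str, str]]:
    """1:1 ortholog pairs between two genomes.

    A group yields a pair only when it holds exactly one member from each
    genome; groups with in-genome paralogs are skipped.
    """
    genomes = set(groups.genome_of.values())
    for g in (genome_a, genome_b):
        if g not in genomes:
            raise ValueError(f"unknown genome {g!r}")
    pairs: list[tuple[str, str]] = []
    for gid in sorted(groups.groups):
        members = groups.groups[gid]
        a = [m for m in members if groups.genome_of[m] == genome_a]
        b = [m for m in members if groups.genome_of[m] == genome_b]
        if len(a) == 1 and len(b) == 1:
            pairs.append((a[0], b[0]))
    return pairs
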