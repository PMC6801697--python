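"""Pan-genome structure: accumulation curves, Heaps' law, ordination, NJ.

The pan-genome of a genome set is the union of its gene families.  Its
openness is judged by Heaps' law applied to the gene-accumulation curve:
with genomes added in random order, the median number of *new* families
contributed by the N-th genome is modelled as n(N) = kappa * N**(-alpha);
alpha < 1 means the pan-genome keeps growing without bound (open).

Also here: PCA of presence/absence (and count) matrices via SVD, binary
distance matrices, and the classical Saitou-Nei neighbor-joining tree.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Phylo.BaseTree import Clade, Tree
from scipy.spatial.distance import pdist, squareform

from flavopan.orthologs import OrthologGroupSet

logger = logging.getLogger(__name__)


class PresenceMatrix:
    """Genomes x families matrix: 0/1 presence or non-negative counts.

    Thin wrapper over a pandas DataFrame that enforces there is no
    all-zero family column (such a family belongs to no genome and would
    distort accumulation and distance computations).
    """

    def __init__(self, df: pd.DataFrame):
        if (df.values < 0).any():
            raise ValueError("matrix cells must be non-negative")
        if df.shape[1] and (df.values.sum(axis=0) == 0).any():
            bad = df.columns[df.values.sum(axis=0) == 0][0]
            raise ValueError(f"all-zero family column {bad!r}")
        self.df = df

    @property
    def genomes(self) -> list[str]:
        return list(self.df.index.astype(str))

    @property
    def families(self) -> list[str]:
        return list(self.df.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.df.values

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.df.values, (0, 1)).all())

    @classmethod
    def from_groups(
        cls, groups: OrthologGroupSet, include_singletons: bool = True
    ) -> "PresenceMatrix":
        """Binary matrix from a clustering; singletons become their own
        single-genome families when requested."""
        genomes = sorted(set(groups.genome_of.values()))
        fam_members: dict[str, set[str]] = {
            gid: set(groups.genomes_of_group(gid)) for gid in groups.groups
        }
        if include_singletons:
            for g in sorted(groups.singletons):
                fam_members[f"SG_{g}"] = {groups.genome_of[g]}
        fams = sorted(fam_members)
        data = np.zeros((len(genomes), len(fams)), dtype=int)
        gi = {g: i for i, g in enumerate(genomes)}
        for j, f in enumerate(fams):
            for g in fam_members[f]:
                data[gi[g], j] = 1
        return cls(pd.DataFrame(data, index=genomes, columns=fams))


@dataclasses.dataclass
class AccumulationCurve:
    """Pan-genome size at each N for every genome permutation."""

    sizes: np.ndarray  # (permutations, n_genomes)
    medians: np.ndarray  # per-N median pan size

    @property
    def n_genomes(self) -> int:
        return self.sizes.shape[1]

    def new_gene_medians(self) -> tuple[np.ndarray, np.ndarray]:
        """Median count of new families contributed at each N >= 2."""
        new = np.diff(self.sizes, axis=1)
        return np.arange(2, self.n_genomes + 1), np.median(new, axis=0)


def accumulation_curve(
    matrix: PresenceMatrix, permutations: int = 100, seed: int | None = None
) -> AccumulationCurve:
    """Gene-accumulation curve over random genome orderings."""
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    present = matrix.values > 0
    n = present.shape[0]
    rng = np.random.default_rng(seed)
    sizes = np.empty((permutations, n), dtype=int)
    for p in range(permutations):
        order = rng.permutation(n)
        cum = np.logical_or.accumulate(present[order], axis=0)
        sizes[p] = cum.sum(axis=1)
    return AccumulationCurve(sizes=sizes, medians=np.median(sizes, axis=0))


@dataclasses.dataclass
class HeapsFit:
    kappa: float
    alpha: float
    r_squared: float

    @property
    def openness(self) -> bool:
        """Open pan-genome: new-family discovery decays slower than 1/N."""
        return self.alpha < 1

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


def fit_heaps(curve: AccumulationCurve, mode: str = "new") -> HeapsFit:
    """Power-law regression of the accumulation curve.

    mode="new" (default): fit median new-family counts n(N) = kappa*N**-alpha
    for N >= 2 by least squares in log-log space.  mode="pan": fit the
    median pan size P(N) = kappa*N**gamma instead and report alpha = -gamma
    (so ``openness`` keeps its alpha < 1 reading only for mode="new").
    """
    if curve.n_genomes < 4:
        raise ValueError("need at least 4 genomes to fit Heaps' law")
    if mode == "new":
        N, y = curve.new_gene_medians()
        keep = y > 0
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("fit_heaps: dropped %d zero-median points", dropped)
        N, y = N[keep], y[keep]
        if len(N) < 3:
            raise ValueError("fewer than 3 non-zero new-gene medians")
    elif mode == "pan":
        N = np.arange(1, curve.n_genomes + 1)
        y = curve.medians.astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    x = np.log(N.astype(float))
    ly = np.log(y)
    slope, intercept = np.polyfit(x, ly, 1)
    pred = slope * x + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return HeapsFit(kappa=float(np.exp(intercept)), alpha=float(-slope),
                    r_squared=r2)


# ---------------------------------------------------------------------------
# Ordination


@dataclasses.dataclass
class PcaResult:
    coordinates: pd.DataFrame  # genomes x PCk
    explained_percent: np.ndarray

    def __post_init__(self) -> None:
        ep = np.asarray(self.explained_percent, dtype=float)
        if np.any(np.diff(ep) > 1e-9):
            raise ValueError("explained percentages must be non-increasing")
        if ep.sum() > 100 + 1e-6:
            raise ValueError("explained percentages sum above 100")


def pca(
    matrix: PresenceMatrix | pd.DataFrame,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> PcaResult:
    """Principal components of a genomes x families matrix via SVD.

    Binary presence/absence matrices are conventionally centered but not
    scaled (scaling near-constant 0/1 columns amplifies noise); count
    matrices such as per-family enzyme counts are centered and scaled.
    """
    df = matrix.df if isinstance(matrix, PresenceMatrix) else matrix
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 genomes and 2 families")
    X = df.values.astype(float)
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    if not np.any(np.abs(X) > 1e-12):
        raise ValueError("zero-variance matrix after centering")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components or len(s), len(s))
    expl = 100.0 * s**2 / (s**2).sum()
    coords = pd.DataFrame(
        U[:, :k] * s[:k],
        index=df.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(coordinates=coords, explained_percent=expl[:k])


def binary_distance(
    matrix: PresenceMatrix, metric: str = "jaccard"
) -> pd.DataFrame:
    """Pairwise genome distances on a binary matrix (jaccard or hamming)."""
    if metric not in ("jaccard", "hamming"):
        raise ValueError(f"unknown metric {metric!r}")
    if not matrix.is_binary:
        raise ValueError("binary_distance requires a 0/1 matrix")
    X = matrix.values.astype(bool)
    D = squareform(pdist(X, metric=metric))
    return pd.DataFrame(D, index=matrix.genomes, columns=matrix.genomes)


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclasses.dataclass
class NJResult:
    """Unrooted NJ tree plus bookkeeping on numerical repairs."""

    tree: Tree
    clamped_branches: int  # negative branch lengths clamped to 0
    ties: int  # Q-criterion ties broken by index order


def neighbor_joining(distances: pd.DataFrame) -> NJResult:
    """Classical Saitou-Nei neighbor joining.

    Iteratively joins the taxon pair minimizing the Q criterion
    Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k), computing branch
    lengths for the joined pair and reducing the matrix, until three nodes
    remain; those are attached to a final internal node, giving an
    unrooted (trifurcating-root) tree.  Negative branch lengths are
    clamped to zero with the deficit moved to the sister branch.  Ties in
    Q are broken by the smallest (row, column) index pair.
    """
    D = distances.values.astype(float)
    labels = [str(x) for x in distances.index]
    if D.shape[0] != D.shape[1] or list(distances.columns.astype(str)) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if D.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(D).any() or (D < 0).any():
        raise ValueError("distances must be finite and non-negative")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix diagonal must be zero")

    nodes: list[Clade] = [Clade(name=lab) for lab in labels]
    clamped = 0
    ties = 0

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = D.sum(axis=1)
        Q = (r - 2) * D - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        cand = [(i, j) for i, j in cand if i < j]
        if len(cand) > 1:
            ties += 1
        i, j = min(cand)
        d_ij = D[i, j]
        li = 0.5 * d_ij + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = d_ij - li
        li, lj, c = _clamp_pair(li, lj)
        clamped += c
        parent = Clade()
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent.clades = [nodes[i], nodes[j]]
        new_d = 0.5 * (D[i] + D[j] - d_ij)
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_d[keep][None, :]])
        D = np.hstack([D, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final three nodes around one internal vertex
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    lens = [l0, l1, l2]
    for k in range(3):
        if lens[k] < 0:
            clamped += 1
            deficit = lens[k]
            lens[k] = 0.0
            # spread the deficit over the other two terminal branches
            for m in range(3):
                if m != k:
                    lens[m] = max(0.0, lens[m] + deficit / 2)
    root = Clade()
    for node, ln in zip(nodes, lens):
        node.branch_length = ln
        root.clades.append(node)
    tree = Tree(root=root, rooted=False)
    if clamped:
        logger.warning("neighbor_joining: clamped %d negative branches", clamped)
    return NJResult(tree=tree, clamped_branches=clamped, ties=ties)


def _clamp_pair(li: float, lj: float) -> tuple[float, float, int]:
    clamped = 0
    if li < 0:
        lj = max(0.0, lj + li)
        li, clamped = 0.0, 1
    if lj < 0:
        li = max(0.0, li + lj)
        lj, clamped = 0.0, clamped + 1
    return li, lj, clamped
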