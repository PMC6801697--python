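"""Synthetic genome-set generators with known ground truth.

Every downstream stage of the pipeline has a parameter-recovery test
built on one of these generators:

* ``simulate_family_matrix`` -- gene-family presence/absence whose
  permutation-averaged gene-accumulation curve follows Heaps' law with a
  chosen exponent alpha.
* ``simulate_codon_pair`` -- codon sequence pairs diverged under a
  continuous-time codon process with a chosen synonymous branch length
  (Ks) and nonsynonymous/synonymous rate ratio (omega), matching the
  assumptions of the NG86 estimator (equal codon usage, uniform rates,
  no stop codons) so estimation error measures the estimator, not model
  mismatch.
* ``simulate_rearranged_orders`` -- two gene orders related by planted
  inversions, with the expected synteny-block structure recorded.
* ``simulate_genome_set`` -- a full input bundle (FASTAs, gene order,
  similarity hits derived from true family membership) for end-to-end
  clustering tests.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import gammaln

from flavopan.io import GeneLocation, GenomeRecord, SimilarityHit
from flavopan.kaks import CODON_TO_AA, SENSE_CODONS, _neighbors
from flavopan.pangenome import PresenceMatrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SimTruth:
    """Ground truth planted by a generator."""

    true_alpha: float | None = None
    family_membership: dict[str, set[str]] | None = None
    pair_ks_targets: list[tuple[str, float, int]] | None = None
    omega_target: float | None = None
    planted_blocks: list[tuple[int, int, str]] | None = None

    def to_dict(self) -> dict:
        return {
            "true_alpha": self.true_alpha,
            "family_membership": (
                {g: sorted(f) for g, f in self.family_membership.items()}
                if self.family_membership
                else None
            ),
            "pair_ks_targets": self.pair_ks_targets,
            "omega_target": self.omega_target,
            "planted_blocks": self.planted_blocks,
        }


# ---------------------------------------------------------------------------
# Heaps-law family matrix


def _log_choose(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _first_appearance_matrix(n: int) -> np.ndarray:
    """H[N-1, m-1] = P(a family carried by m of n genomes first appears
    at position N of a uniformly random genome ordering)."""
    H = np.zeros((n, n))
    m = np.arange(1, n + 1)
    for N in range(1, n + 1):
        ok = m - 1 <= n - N
        H[N - 1, ok] = np.exp(
            _log_choose(n - N, m[ok] - 1) - _log_choose(n, m[ok])
        )
    return H


def family_multiplicity_spectrum(
    n_genomes: int, kappa: float, alpha: float
) -> np.ndarray:
    """Integer family counts per multiplicity m = 1..n whose expected
    first-appearance curve is kappa * N**(-alpha).

    Solved by non-negative least squares; rounded counts are adjusted in
    the low-multiplicity buckets so the total family count equals
    sum_k round(kappa * k**(-alpha)) exactly.
    """
    H = _first_appearance_matrix(n_genomes)
    target = kappa * np.arange(1, n_genomes + 1, dtype=float) ** (-alpha)
    G, residual = nnls(H, target)
    if residual > 0.05 * np.linalg.norm(target):
        logger.warning(
            "multiplicity spectrum residual %.3g is large; the accumulation "
            "curve will deviate from the requested power law",
            residual,
        )
    counts = np.round(G).astype(int)
    total_target = int(
        sum(round(kappa * k**-alpha) for k in range(1, n_genomes + 1))
    )
    diff = total_target - int(counts.sum())
    for m in range(n_genomes):  # absorb rounding drift, smallest m first
        if diff == 0:
            break
        take = max(diff, -counts[m]) if diff < 0 else diff
        counts[m] += take
        diff -= take
    return counts


def simulate_family_matrix(
    n_genomes: int,
    core_size: int,
    kappa: float,
    alpha: float,
    seed: int | None = None,
) -> tuple[PresenceMatrix, SimTruth]:
    """Presence/absence matrix with a planted Heaps exponent.

    All genomes share ``core_size`` core families.  Accessory families
    are created with the multiplicity spectrum that makes the expected
    number of new families at position N of a random genome ordering
    equal kappa * N**(-alpha); each family's carrier genomes are then a
    uniformly random subset of the required size.  Under the generator's
    own genome numbering this reads: genome k introduces on average
    round(kappa * k**(-alpha)) unseen families, and later genomes
    re-carry (resample) part of the earlier accessory repertoire.
    """
    if n_genomes < 3:
        raise ValueError("need at least 3 genomes")
    if kappa <= 0 or alpha <= 0:
        raise ValueError("kappa and alpha must be positive")
    # alpha far above the open/closed boundary is the intended closed-limit
    # regime (all accessory discovery in the first genome); below it, zero
    # new families at k=2 means kappa is too small to build an accessory
    # genome at all.
    if alpha <= 5.0 and round(kappa * 2**-alpha) == 0:
        raise ValueError("parameters yield 0 new families at k=2")
    rng = np.random.default_rng(seed)
    counts = family_multiplicity_spectrum(n_genomes, kappa, alpha)

    genomes = [f"G{k:03d}" for k in range(1, n_genomes + 1)]
    fam_carriers: dict[str, np.ndarray] = {}
    fid = 0
    for m, c in enumerate(counts, start=1):
        for _ in range(int(c)):
            fid += 1
            fam_carriers[f"F_acc{fid:05d}"] = rng.choice(
                n_genomes, size=m, replace=False
            )
    fams = [f"F_core{i:05d}" for i in range(1, core_size + 1)] + sorted(fam_carriers)
    data = np.zeros((n_genomes, len(fams)), dtype=int)
    data[:, :core_size] = 1
    for j, f in enumerate(sorted(fam_carriers), start=core_size):
        data[fam_carriers[f], j] = 1
    matrix = PresenceMatrix(pd.DataFrame(data, index=genomes, columns=fams))
    membership = {
        g: {f for f, v in zip(fams, row) if v} for g, row in zip(genomes, data)
    }
    return matrix, SimTruth(true_alpha=alpha, family_membership=membership)


# ---------------------------------------------------------------------------
# Codon pairs with planted Ks


_SYN_NBRS = {c: [n for n, s in _neighbors(c) if s] for c in SENSE_CODONS}
_NONSYN_NBRS = {
    c: [n for n, s in _neighbors(c) if not s and CODON_TO_AA[n] != "*"]
    for c in SENSE_CODONS
}


@dataclasses.dataclass
class CodonPair:
    cds_a: str
    cds_b: str
    target_ks: float
    omega: float
    saturation_warning: bool


def simulate_codon_pair(
    n_codons: int,
    target_ks: float,
    omega: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CodonPair:
    """Diverge a random stop-free codon sequence under a Gillespie codon
    process.

    Each single-nucleotide change that keeps the amino acid has rate 1,
    each amino-acid-changing one has rate omega, and changes to stop
    codons are forbidden.  Because every sense codon accrues synonymous
    substitutions at 3x the rate per NG86 synonymous site, evolving for
    time target_ks / 3 plants an expected Ks of exactly ``target_ks``.

    ``saturation_warning`` flags pairs whose expected synonymous
    difference proportion approaches the Jukes-Cantor ceiling of 3/4,
    where the correction becomes unreliable.
    """
    if n_codons < 50:
        raise ValueError("need at least 50 codons")
    if target_ks < 0 or omega < 0:
        raise ValueError("target_ks and omega must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    t_total = target_ks / 3.0
    ancestor = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    derived = []
    for codon in ancestor:
        t = 0.0
        cur = codon
        while True:
            syn = _SYN_NBRS[cur]
            non = _NONSYN_NBRS[cur]
            rate = len(syn) + omega * len(non)
            if rate == 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= t_total:
                break
            if rng.random() < len(syn) / rate:
                cur = syn[rng.integers(0, len(syn))]
            else:
                cur = non[rng.integers(0, len(non))]
        derived.append(cur)
    expected_ps = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    return CodonPair(
        cds_a="".join(ancestor),
        cds_b="".join(derived),
        target_ks=target_ks,
        omega=omega,
        saturation_warning=expected_ps >= 0.74,
    )


def simulate_codon_pairs(
    n_pairs: int,
    n_codons: int,
    target_ks: float | Sequence[float],
    omega: float,
    seed: int | None = None,
) -> tuple[list[CodonPair], SimTruth]:
    """A batch of independent codon pairs; ``target_ks`` may be a single
    value or a per-pair sequence (e.g. draws from a planted mixture)."""
    rng = np.random.default_rng(seed)
    if np.isscalar(target_ks):
        targets = [float(target_ks)] * n_pairs
    else:
        targets = [float(v) for v in target_ks]
        if len(targets) != n_pairs:
            raise ValueError("len(target_ks) must equal n_pairs")
    pairs = [
        simulate_codon_pair(n_codons, ks, omega, rng=rng) for ks in targets
    ]
    truth = SimTruth(
        pair_ks_targets=[(f"pair{i + 1:04d}", ks, 1) for i, ks in enumerate(targets)],
        omega_target=omega,
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# Rearranged gene orders


def simulate_rearranged_orders(
    n_genes: int,
    inversions: Sequence[tuple[int, int]],
    seed: int | None = None,
    gene_length: tuple[int, int] = (900, 1500),
    intergenic: int = 100,
) -> tuple[list[GeneLocation], list[GeneLocation], SimTruth]:
    """Two gene orders related by planted inversions.

    ``inversions`` are 1-based inclusive index spans of genome A;
    genome B carries each span in reverse order with strands flipped.
    The expected synteny-block structure (alternating forward segments
    and reversed spans) is recorded in the returned truth.
    """
    spans = sorted(inversions)
    for s, e in spans:
        if not (1 <= s <= e <= n_genes):
            raise ValueError(f"inversion span ({s}, {e}) out of range")
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping inversion spans ({s1},{e1}) and ({s2},{e2})")

    rng = np.random.default_rng(seed)
    lengths = rng.integers(gene_length[0], gene_length[1] + 1, n_genes)
    strands = rng.choice(["+", "-"], n_genes)
    ids = [f"g{i + 1:04d}" for i in range(n_genes)]

    order_a = _lay_out(ids, lengths, strands, intergenic)

    perm = list(range(n_genes))
    flip = np.zeros(n_genes, dtype=bool)
    for s, e in spans:
        perm[s - 1 : e] = perm[s - 1 : e][::-1]
        flip[s - 1 : e] = True
    ids_b = [ids[i] for i in perm]
    lengths_b = lengths[perm]
    strands_b = [
        ("-" if strands[i] == "+" else "+") if flip[i] else strands[i] for i in perm
    ]
    order_b = _lay_out(ids_b, lengths_b, strands_b, intergenic)

    blocks: list[tuple[int, int, str]] = []
    prev = 1
    for s, e in spans:
        if s > prev:
            blocks.append((prev, s - 1, "forward"))
        blocks.append((s, e, "reverse"))
        prev = e + 1
    if prev <= n_genes:
        blocks.append((prev, n_genes, "forward"))
    return order_a, order_b, SimTruth(planted_blocks=blocks)


def _lay_out(
    ids: Sequence[str],
    lengths: Sequence[int],
    strands: Sequence[str],
    intergenic: int,
) -> list[GeneLocation]:
    out = []
    pos = 1
    for gid, ln, st in zip(ids, lengths, strands):
        out.append(GeneLocation(gid, pos, pos + int(ln) - 1, st))
        pos += int(ln) + intergenic
    return out


# ---------------------------------------------------------------------------
# Full input bundle


@dataclasses.dataclass
class GenomeSetBundle:
    genomes: list[GenomeRecord]
    hits: list[SimilarityHit]
    matrix: PresenceMatrix
    truth: SimTruth


def simulate_genome_set(
    n_genomes: int,
    core_size: int,
    kappa: float,
    alpha: float,
    seed: int | None = None,
    n_codons: int = 100,
    identity_noise: float = 0.0,
) -> GenomeSetBundle:
    """Full pipeline input bundle from a planted family structure.

    Every family gets one ancestral stop-free CDS; each carrier genome
    holds one copy.  Similarity hits are emitted (both directions) for
    every within-family gene pair, with percent identity 100 minus a
    uniform draw scaled by ``identity_noise``; with zero noise, Markov
    clustering must recover the planted families exactly.
    """
    matrix, truth = simulate_family_matrix(n_genomes, core_size, kappa, alpha, seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)

    fam_seqs: dict[str, str] = {}
    for fam in matrix.families:
        codons = [
            SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)
        ]
        fam_seqs[fam] = "".join(codons)

    genomes: list[GenomeRecord] = []
    members: dict[str, list[str]] = {f: [] for f in matrix.families}
    for g in matrix.genomes:
        fams = sorted(truth.family_membership[g])
        proteins: dict[str, str] = {}
        cds: dict[str, str] = {}
        locs: list[GeneLocation] = []
        pos = 1
        for fam in fams:
            gid = f"{g}_{fam}"
            seq = fam_seqs[fam]
            cds[gid] = seq
            proteins[gid] = "".join(
                CODON_TO_AA[seq[i : i + 3]] for i in range(0, len(seq), 3)
            )
            locs.append(GeneLocation(gid, pos, pos + len(seq) - 1, "+"))
            pos += len(seq) + 100
            members[fam].append(gid)
        genomes.append(GenomeRecord(g, proteins, cds, locs))

    hits: list[SimilarityHit] = []
    aa_len = n_codons
    for fam in matrix.families:
        genes = members[fam]
        for qi in genes:
            for si in genes:
                if qi == si:
                    continue
                ident = 100.0 - identity_noise * float(rng.random())
                hits.append(
                    SimilarityHit(
                        query_id=qi,
                        subject_id=si,
                        percent_identity=ident,
                        aligned_length=aa_len,
                        evalue=1e-180,
                        bitscore=500.0,
                        query_length=aa_len,
                        subject_length=aa_len,
                    )
                )
    logger.info(
        "simulate_genome_set: %d genomes, %d families, %d hits",
        n_genomes,
        len(matrix.families),
        len(hits),
    )
    return GenomeSetBundle(genomes=genomes, hits=hits, matrix=matrix, truth=truth)
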