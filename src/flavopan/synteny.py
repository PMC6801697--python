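"""Collinear synteny-block detection from 1:1 ortholog anchors.

An anchor is a 1:1 ortholog pair placed at its ordinal gene rank on each
genome.  Blocks are maximal chains of anchors collinear in gene-rank
space: strictly increasing in both genomes (forward) or increasing in A
and strictly decreasing in B (reverse / inverted), with at most
``max_gap`` intervening genes between consecutive anchors on either
genome.  Chains are found by longest-chain dynamic programming per
orientation and extracted greedily, longest first, so each anchor
belongs to at most one block.  Coverage is the fraction of genome base
pairs inside the union of block spans.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import pandas as pd

from flavopan.io import GeneLocation

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SyntenyAnchor:
    a_id: str
    b_id: str
    index_a: int  # 0-based gene rank on genome A
    index_b: int
    span_a: tuple[int, int]  # bp (start, end), 1-based inclusive
    span_b: tuple[int, int]
    orientation: str  # "same" | "opposite" (product of strands)


@dataclasses.dataclass
class SyntenyBlock:
    anchors: list[SyntenyAnchor]
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        ia = [a.index_a for a in self.anchors]
        ib = [a.index_b for a in self.anchors]
        if any(y <= x for x, y in zip(ia, ia[1:])):
            raise ValueError("block anchors not increasing on genome A")
        if self.orientation == "forward":
            if any(y <= x for x, y in zip(ib, ib[1:])):
                raise ValueError("forward block not increasing on genome B")
        elif self.orientation == "reverse":
            if any(y >= x for x, y in zip(ib, ib[1:])):
                raise ValueError("reverse block not decreasing on genome B")
        else:
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def anchor_count(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        return (
            min(a.span_a[0] for a in self.anchors),
            max(a.span_a[1] for a in self.anchors),
        )

    @property
    def span_b(self) -> tuple[int, int]:
        return (
            min(a.span_b[0] for a in self.anchors),
            max(a.span_b[1] for a in self.anchors),
        )

    @property
    def index_range_a(self) -> tuple[int, int]:
        return self.anchors[0].index_a, self.anchors[-1].index_a


@dataclasses.dataclass
class SyntenyReport:
    blocks: list[SyntenyBlock]
    coverage_a: float  # % of genome A bp inside block spans
    coverage_b: float
    dotplot: pd.DataFrame  # anchor bp midpoints and orientation


def build_anchors(
    pairs: Sequence[tuple[str, str]],
    order_a: Sequence[GeneLocation],
    order_b: Sequence[GeneLocation],
) -> list[SyntenyAnchor]:
    """Anchors for 1:1 ortholog pairs present in both gene-order tables.

    Pairs whose genes lack coordinates are dropped with a warning; each
    gene may appear in at most one anchor.
    """
    loc_a = {g.gene_id: (i, g) for i, g in enumerate(order_a)}
    loc_b = {g.gene_id: (i, g) for i, g in enumerate(order_b)}
    anchors = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    dropped = 0
    for a_id, b_id in pairs:
        if a_id not in loc_a or b_id not in loc_b:
            dropped += 1
            continue
        if a_id in used_a or b_id in used_b:
            raise ValueError(f"gene in more than one anchor: {a_id}/{b_id}")
        ia, ga = loc_a[a_id]
        ib, gb = loc_b[b_id]
        anchors.append(
            SyntenyAnchor(
                a_id=a_id,
                b_id=b_id,
                index_a=ia,
                index_b=ib,
                span_a=(ga.start, ga.end),
                span_b=(gb.start, gb.end),
                orientation="same" if ga.strand == gb.strand else "opposite",
            )
        )
        used_a.add(a_id)
        used_b.add(b_id)
    if dropped:
        logger.warning("build_anchors: dropped %d pairs lacking coordinates", dropped)
    return anchors


def _step_ok(x: SyntenyAnchor, y: SyntenyAnchor, sign: int, max_gap: int) -> bool:
    """May anchor y directly follow x in a chain of the given orientation?

    The gap between consecutive anchors is the count of intervening genes
    on each genome and must not exceed max_gap.
    """
    if y.index_a <= x.index_a:
        return False
    if y.index_a - x.index_a - 1 > max_gap:
        return False
    db = (y.index_b - x.index_b) * sign
    return db >= 1 and db - 1 <= max_gap


def _longest_chain(
    anchors: list[SyntenyAnchor], sign: int, max_gap: int
) -> list[SyntenyAnchor]:
    """Canonical longest valid chain: maximum length, and among those the
    lexicographically smallest sequence of anchor indices (anchors sorted
    by (index_a, index_b))."""
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].index_a,
                                                       anchors[i].index_b))
    srt = [anchors[i] for i in order]
    n = len(srt)
    R = [1] * n  # longest chain starting at i
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if _step_ok(srt[i], srt[j], sign, max_gap) and R[j] + 1 > R[i]:
                R[i] = R[j] + 1
    if n == 0:
        return []
    best = max(R)
    start = min(i for i in range(n) if R[i] == best)
    chain = [start]
    need = best - 1
    cur = start
    while need:
        nxt = min(
            j
            for j in range(cur + 1, n)
            if R[j] == need and _step_ok(srt[cur], srt[j], sign, max_gap)
        )
        chain.append(nxt)
        cur = nxt
        need -= 1
    return [srt[i] for i in chain]


def chain_blocks(
    anchors: Sequence[SyntenyAnchor],
    min_anchors: int = 5,
    max_gap: int = 25,
) -> list[SyntenyBlock]:
    """Greedy longest-first extraction of collinear chains.

    Repeatedly finds the longest forward and reverse chains over the
    remaining anchors, keeps the longer (forward wins ties), and removes
    its anchors, until no chain reaches ``min_anchors``.  Invariant to
    the input order of anchors.  Blocks are returned sorted by their
    start rank on genome A.
    """
    if min_anchors < 2:
        raise ValueError("min_anchors must be >= 2")
    remaining = list(anchors)
    blocks: list[SyntenyBlock] = []
    while True:
        fwd = _longest_chain(remaining, +1, max_gap)
        rev = _longest_chain(remaining, -1, max_gap)
        chain, orient = (
            (fwd, "forward") if len(fwd) >= len(rev) else (rev, "reverse")
        )
        if len(chain) < min_anchors:
            break
        blocks.append(SyntenyBlock(anchors=chain, orientation=orient))
        chosen = set(id(a) for a in chain)
        remaining = [a for a in remaining if id(a) not in chosen]
    blocks.sort(key=lambda b: b.index_range_a[0])
    logger.info(
        "chain_blocks: %d anchors -> %d blocks (%d anchors chained)",
        len(anchors),
        len(blocks),
        sum(b.anchor_count for b in blocks),
    )
    return blocks


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by a union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def coverage(
    blocks: Sequence[SyntenyBlock],
    genome_length_a: int,
    genome_length_b: int,
) -> SyntenyReport:
    """Percent of each genome inside the union of block spans, plus a
    dotplot table of anchor midpoints."""
    if genome_length_a <= 0 or genome_length_b <= 0:
        raise ValueError("genome lengths must be positive")
    for b in blocks:
        if b.span_a[1] > genome_length_a or b.span_b[1] > genome_length_b:
            raise ValueError("block span exceeds genome length")
    cov_a = 100.0 * _union_length([b.span_a for b in blocks]) / genome_length_a
    cov_b = 100.0 * _union_length([b.span_b for b in blocks]) / genome_length_b
    rows = [
        {
            "block": i + 1,
            "a_id": a.a_id,
            "b_id": a.b_id,
            "x_bp": (a.span_a[0] + a.span_a[1]) / 2.0,
            "y_bp": (a.span_b[0] + a.span_b[1]) / 2.0,
            "orientation": blk.orientation,
        }
        for i, blk in enumerate(blocks)
        for a in blk.anchors
    ]
    dotplot = pd.DataFrame(
        rows, columns=["block", "a_id", "b_id", "x_bp", "y_bp", "orientation"]
    )
    return SyntenyReport(
        blocks=list(blocks), coverage_a=cov_a, coverage_b=cov_b, dotplot=dotplot
    )
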