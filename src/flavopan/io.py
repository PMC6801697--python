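"""Readers and writers for the pipeline's external formats.

Formats
-------
* Protein and CDS FASTA, one file per genome, headers carrying gene ids.
* A tab-separated gene-order table with columns
  ``genome_id  gene_id  start  end  strand`` -- coordinates are 1-based
  inclusive base pairs, strand is ``+`` or ``-``.
* All-vs-all similarity hits in the standard 12-column tabular dialect
  (BLAST ``outfmt 6`` compatible): query, subject, %identity, alignment
  length, mismatches, gap opens, qstart, qend, sstart, send, e-value,
  bitscore.  Real BLASTP/DIAMOND output is accepted; the pipeline never
  runs an aligner itself -- hits are an input.
* Newick trees with branch lengths.
* TSV matrices with a header row and a label column.

All parsers reject malformed input with an error naming the offending
record rather than silently repairing it.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class GeneLocation:
    """Placement of one gene on its genome (1-based inclusive bp)."""

    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


@dataclasses.dataclass
class GenomeRecord:
    """One genome: proteins, coding sequences, and gene order.

    Invariants enforced on construction: gene ids unique; every CDS a
    multiple of 3; where a gene has both protein and CDS, the CDS is
    3*len(protein) or 3*(len(protein)+1) (trailing stop codon).
    """

    genome_id: str
    proteins: dict[str, str]
    cds: dict[str, str]
    gene_order: list[GeneLocation]

    def __post_init__(self) -> None:
        order_ids = [g.gene_id for g in self.gene_order]
        seen: set[str] = set()
        for gid in order_ids:
            if gid in seen:
                raise ValueError(
                    f"genome {self.genome_id!r}: duplicate gene_id {gid!r}"
                )
            seen.add(gid)
        for gid, s in self.cds.items():
            if len(s) % 3 != 0:
                raise ValueError(
                    f"genome {self.genome_id!r}, gene {gid!r}: "
                    f"CDS length {len(s)} not a multiple of 3"
                )
            if gid in self.proteins:
                n_aa = len(self.proteins[gid])
                if len(s) not in (3 * n_aa, 3 * (n_aa + 1)):
                    raise ValueError(
                        f"genome {self.genome_id!r}, gene {gid!r}: CDS length "
                        f"{len(s)} inconsistent with protein length {n_aa}"
                    )

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.gene_order]

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)


@dataclasses.dataclass(frozen=True)
class SimilarityHit:
    """One pairwise protein alignment record.

    ``aligned_length`` is the alignment length L in amino acids on which
    the short-alignment identity threshold operates; ``query_length`` and
    ``subject_length`` are full protein lengths used by the coverage rule.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    aligned_length: int
    evalue: float
    bitscore: float
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")
        if self.query_length < 1 or self.subject_length < 1:
            raise ValueError("sequence lengths must be >= 1")


# ---------------------------------------------------------------------------
# Genome sets


def read_genome_set(
    order_path: str | Path,
    protein_fastas: Mapping[str, str | Path],
    cds_fastas: Mapping[str, str | Path] | None = None,
) -> list[GenomeRecord]:
    """Read per-genome FASTA files plus the shared gene-order table.

    Parameters
    ----------
    order_path
        TSV with columns genome_id, gene_id, start, end, strand.
    protein_fastas, cds_fastas
        Maps from genome id to FASTA path; FASTA headers must match the
        gene ids of the order table.
    """
    order = pd.read_csv(
        order_path,
        sep="\t",
        dtype={"genome_id": str, "gene_id": str, "strand": str},
    )
    required = ["genome_id", "gene_id", "start", "end", "strand"]
    missing = [c for c in required if c not in order.columns]
    if missing:
        raise ValueError(f"gene-order table missing columns: {missing}")

    cds_fastas = cds_fastas or {}
    records: list[GenomeRecord] = []
    for genome_id, sub in order.groupby("genome_id", sort=True):
        if genome_id not in protein_fastas:
            raise ValueError(f"no protein FASTA supplied for genome {genome_id!r}")
        proteins = _read_fasta(protein_fastas[genome_id])
        cds = _read_fasta(cds_fastas[genome_id]) if genome_id in cds_fastas else {}
        locs = [
            GeneLocation(row.gene_id, int(row.start), int(row.end), row.strand)
            for row in sub.itertuples()
        ]
        order_ids = {g.gene_id for g in locs}
        for gid in proteins:
            if gid not in order_ids:
                raise ValueError(
                    f"genome {genome_id!r}: FASTA gene {gid!r} absent "
                    "from the gene-order table"
                )
        rec = GenomeRecord(str(genome_id), proteins, cds, locs)
        records.append(rec)
    logger.info("read %d genomes from %s", len(records), order_path)
    return records


def _read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate gene_id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_genome_set(
    genomes: Sequence[GenomeRecord], outdir: str | Path
) -> dict[str, Path]:
    """Write one .faa / .fna per genome plus gene_order.tsv; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    paths: dict[str, Path] = {}
    for g in genomes:
        faa = outdir / f"{g.genome_id}.faa"
        _write_fasta(faa, g.proteins)
        paths[f"{g.genome_id}.faa"] = faa
        if g.cds:
            fna = outdir / f"{g.genome_id}.fna"
            _write_fasta(fna, g.cds)
            paths[f"{g.genome_id}.fna"] = fna
        for loc in g.gene_order:
            rows.append((g.genome_id, loc.gene_id, loc.start, loc.end, loc.strand))
    order = pd.DataFrame(
        rows, columns=["genome_id", "gene_id", "start", "end", "strand"]
    )
    order_path = outdir / "gene_order.tsv"
    order.to_csv(order_path, sep="\t", index=False)
    paths["gene_order.tsv"] = order_path
    return paths


def _write_fasta(path: Path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=gid, description="") for gid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Similarity hits


def read_hits(
    path: str | Path, genomes: Sequence[GenomeRecord]
) -> list[SimilarityHit]:
    """Parse a 12-column tabular hit file, joining in protein lengths.

    Rows with a wrong field count raise with the 1-based line number; a
    hit naming a gene absent from ``genomes`` raises.
    """
    lengths: dict[str, int] = {}
    for g in genomes:
        for gid, seq in g.proteins.items():
            lengths[gid] = len(seq)

    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            for gid in (q, s):
                if gid not in lengths:
                    raise ValueError(
                        f"{path}: line {lineno}: unknown gene {gid!r}"
                    )
            try:
                hit = SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    percent_identity=float(fields[2]),
                    aligned_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    query_length=lengths[q],
                    subject_length=lengths[s],
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            hits.append(hit)
    logger.info("read %d hits from %s", len(hits), path)
    return hits


def write_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect (mismatches/gaps/coords zeroed
    when unknown, as produced by the simulator)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.aligned_length,
                        0,
                        0,
                        1,
                        h.aligned_length,
                        1,
                        h.aligned_length,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Matrices


def read_matrix(path: str | Path) -> pd.DataFrame:
    """TSV matrix with genome labels in the first column, family labels
    in the header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: Tree | Clade) -> str:
    """Serialize a tree to Newick with branch lengths.

    Every leaf must carry a name; internal nodes are unnamed.  Branch
    lengths are printed with ``repr(float)`` so a round trip through a
    Newick parser preserves them exactly.
    """
    root = tree.root if isinstance(tree, Tree) else tree

    def fmt(clade: Clade) -> str:
        if not clade.clades:
            if not clade.name:
                raise ValueError("unlabeled leaf in tree")
            label = clade.name
        else:
            label = "(" + ",".join(fmt(c) for c in clade.clades) + ")"
        if clade.branch_length is not None:
            label += f":{float(clade.branch_length)}"
        return label

    inner = ",".join(fmt(c) for c in root.clades) if root.clades else fmt(root)
    return f"({inner});" if root.clades else f"{inner};"


def read_newick(text: str) -> Tree:
    """Parse a Newick string into a Biopython tree."""
    from io import StringIO

    return Phylo.read(StringIO(text), "newick")
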