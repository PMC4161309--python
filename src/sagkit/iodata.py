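"""On-disk formats and in-memory containers for genome bundles.

A *genome bundle* is the unit the pipeline operates on: a FASTA assembly,
a per-contig mean-coverage table, and a gene table (TSV with columns
``genome  contig  gene_id  start  end  strand  product``, 1-based inclusive
coordinates on disk).  Internally coordinates are 0-based half-open;
minus-strand CDS are stored reverse-complemented so codon analyses always
operate in reading frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_VALID = re.compile(r"^[ACGTN]*$")

GENE_COLUMNS = ["genome", "contig", "gene_id", "start", "end", "strand", "product"]


@dataclass
class Contig:
    id: str
    seq: str
    coverage: float = 0.0

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeAssembly:
    genome_id: str
    contigs: dict = field(default_factory=dict)  # contig id -> Contig

    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs.values())

    def __iter__(self):
        return iter(self.contigs.values())


@dataclass
class GeneRecord:
    """A CDS with 0-based half-open coordinates on its contig.

    ``cds`` is always the coding strand 5'->3' (reverse-complemented for
    minus-strand genes); ``partial`` marks CDS whose length is not a
    multiple of 3 — these are excluded from codon-level analyses.
    """

    genome: str
    contig: str
    gene_id: str
    start: int
    end: int
    strand: str
    cds: str
    protein: str = ""
    product: str = ""
    partial: bool = False

    def __post_init__(self) -> None:
        self.partial = self.partial or (len(self.cds) % 3 != 0)
        if not self.partial and not self.protein:
            self.protein = str(Seq(self.cds).translate()).rstrip("*")

    @property
    def length(self) -> int:
        return self.end - self.start


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path) -> dict:
    """FASTA -> ordered dict of id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records) -> None:
    """Write ``records`` (mapping or iterable of (id, seq)) as FASTA, 70 cols."""
    items = records.items() if hasattr(records, "items") else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_coverage_table(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    if not {"contig", "coverage"} <= set(df.columns):
        raise ValueError("coverage table needs columns 'contig' and 'coverage'")
    cov = dict(zip(df["contig"], df["coverage"].astype(float)))
    for cid, value in cov.items():
        if value < 0:
            raise ValueError(f"negative coverage for contig {cid}")
    return cov


def write_coverage_table(path, assembly: GenomeAssembly) -> None:
    rows = [(c.id, c.coverage) for c in assembly]
    pd.DataFrame(rows, columns=["contig", "coverage"]).to_csv(path, sep="\t", index=False)


def write_gene_table(path, genes) -> None:
    """Genes to TSV; coordinates emitted 1-based inclusive."""
    rows = [
        (g.genome, g.contig, g.gene_id, g.start + 1, g.end, g.strand, g.product)
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genome_bundle(assembly_path, coverage_path, genes_path, genome_id=None):
    """Load a FASTA assembly + coverage TSV + gene TSV into a genome bundle.

    Returns ``(GenomeAssembly, list[GeneRecord])``.  Sequences are upper-cased
    and validated (ACGTN only); gene coordinates are converted from the
    on-disk 1-based inclusive convention to 0-based half-open, and any CDS
    whose length is not a multiple of 3 is flagged partial.

    Raises ``ValueError`` for a gene naming a missing contig, coordinates
    outside the contig, or a non-ACGTN character (with its position).
    """
    seqs = read_fasta(assembly_path)
    if not seqs:
        raise ValueError(f"no sequences in {assembly_path}")
    coverage = read_coverage_table(coverage_path)
    for cid, seq in seqs.items():
        if not _VALID.match(seq):
            pos = next(i for i, ch in enumerate(seq) if ch not in "ACGTN")
            raise ValueError(
                f"contig {cid}: non-ACGTN character {seq[pos]!r} at position {pos + 1}"
            )

    genes_df = pd.read_csv(genes_path, sep="\t", dtype={"contig": str, "gene_id": str})
    missing_cols = set(GENE_COLUMNS) - set(genes_df.columns)
    if missing_cols:
        raise ValueError(f"gene table missing columns: {sorted(missing_cols)}")

    gid = genome_id or (genes_df["genome"].iloc[0] if len(genes_df) else "genome")
    assembly = GenomeAssembly(
        genome_id=gid,
        contigs={
            cid: Contig(cid, seq, float(coverage.get(cid, 0.0)))
            for cid, seq in seqs.items()
        },
    )

    genes = []
    for row in genes_df.itertuples(index=False):
        if row.contig not in seqs:
            raise ValueError(f"gene {row.gene_id} references missing contig {row.contig}")
        start, end = int(row.start) - 1, int(row.end)  # -> 0-based half-open
        contig_seq = seqs[row.contig]
        if start < 0 or end > len(contig_seq) or start >= end:
            raise ValueError(
                f"gene {row.gene_id}: coordinates {row.start}-{row.end} fall outside "
                f"contig {row.contig} (length {len(contig_seq)})"
            )
        cds = contig_seq[start:end]
        if row.strand == "-":
            cds = revcomp(cds)
        genes.append(
            GeneRecord(
                genome=row.genome,
                contig=row.contig,
                gene_id=row.gene_id,
                start=start,
                end=end,
                strand=row.strand,
                cds=cds,
                product="" if pd.isna(row.product) else str(row.product),
            )
        )
    return assembly, genes


def read_fastq(path):
    """FASTQ -> list of (read id, sequence)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path, reads) -> None:
    """Write (id, seq) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_alignment_fasta(path, alignment) -> None:
    write_fasta(path, alignment)


def read_alignment_fasta(path):
    """Aligned FASTA -> list of (id, seq); all rows must share one length."""
    aln = list(read_fasta(path).items())
    lengths = {len(s) for _, s in aln}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    return aln
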