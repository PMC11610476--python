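"""Input/output for the standard formats the pipeline touches.

Protein sequences come in as FASTA, gene models as GFF3, and gene
nomenclature is established by chromosomal order (the family convention of
naming members ``<prefix>-1 .. <prefix>-N`` along the chromosomes).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "ProteinRecord",
    "GeneModel",
    "FastaFormatError",
    "Gff3FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "assign_names",
    "chromosome_sort_key",
]


class FastaFormatError(ValueError):
    """Malformed FASTA input (bad header, empty sequence, duplicate id)."""


class Gff3FormatError(ValueError):
    """Malformed GFF3 input (missing parents, exon outside gene, ...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified protein sequence.

    Sequence is uppercase single-letter amino-acid code restricted to the
    20 standard residues; ``X`` is tolerated (a warning is emitted at
    construction) so that real proteomes with ambiguous positions load.
    """

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("protein record with empty id")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise FastaFormatError(f"empty sequence for record {self.id!r}")
        bad = set(seq) - STANDARD_RESIDUES - {"X"}
        if bad:
            raise FastaFormatError(
                f"record {self.id!r} contains non-standard residues "
                f"{''.join(sorted(bad))!r}"
            )
        if "X" in seq:
            warnings.warn(
                f"record {self.id!r} contains {seq.count('X')} 'X' residue(s); "
                "they are excluded from physicochemical sums",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene with its genomic location and exon structure.

    Coordinates are 1-based inclusive (GFF3 convention). When a gene has
    several mRNAs the exon intervals of the longest one (by summed exon
    length) are kept.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise Gff3FormatError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        self.exon_intervals = sorted(self.exon_intervals)
        prev_end = 0
        for s, e in self.exon_intervals:
            if s > e:
                raise Gff3FormatError(
                    f"gene {self.gene_id!r}: exon interval ({s}, {e}) inverted"
                )
            if s <= prev_end:
                raise Gff3FormatError(
                    f"gene {self.gene_id!r}: overlapping exon intervals"
                )
            if s < self.start or e > self.end:
                raise Gff3FormatError(
                    f"gene {self.gene_id!r}: exon ({s}, {e}) outside gene span "
                    f"({self.start}, {self.end})"
                )
            prev_end = e

    @property
    def exon_count(self) -> int:
        return len(self.exon_intervals)

    @property
    def intron_count(self) -> int:
        return max(0, len(self.exon_intervals) - 1)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Whitespace is stripped, sequences are case-normalised and duplicate
    ids are rejected.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: entry with empty header")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = re.sub(r"\s+", "", str(rec.seq))
        if not seq:
            raise FastaFormatError(f"{path}: empty sequence for {rec.id!r}")
        records.append(ProteinRecord(id=rec.id, sequence=seq, source=str(path)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA; ``read_fasta(write_fasta(x)) == x``."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def _transcript_exons(db, mrna) -> list[tuple[int, int]]:
    return sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon features).

    For multi-transcript genes the exons of the longest mRNA (summed exon
    length; ties broken by exon count then transcript id) are kept.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            scored = []
            for m in mrnas:
                exons = _transcript_exons(db, m)
                if not exons:
                    raise Gff3FormatError(
                        f"{path}: mRNA {m.id!r} of gene {gene.id!r} has no exons"
                    )
                total = sum(e - s + 1 for s, e in exons)
                scored.append((total, len(exons), m.id, exons, m))
            scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
            exons = scored[0][3]
            best_mrna = scored[0][4]
            protein_id = (
                best_mrna.attributes.get("protein_id", [None])[0]
                or best_mrna.attributes.get("Name", [None])[0]
                or best_mrna.id
            )
        else:
            # exons attached directly to the gene
            exons = sorted((f.start, f.end) for f in db.children(gene, featuretype="exon"))
            if not exons:
                exons = [(gene.start, gene.end)]
            protein_id = gene.attributes.get("protein_id", [None])[0]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exon_intervals=exons,
                protein_id=protein_id,
            )
        )
    return genes


_CHROM_RE = re.compile(r"^(\D*?)0*(\d+)$")


def chromosome_sort_key(name: str) -> tuple:
    """Natural-sort key for chromosome names.

    Names ending in an integer (``Zj01``, ``chr2``, ``7``) sort as
    chromosomes by (alphabetic prefix, number); anything else (unplaced
    scaffolds) sorts after all chromosomes, alphabetically.
    """
    m = _CHROM_RE.match(name.strip())
    if m:
        return (0, m.group(1).lower(), int(m.group(2)))
    return (1, name.lower(), 0)


def assign_names(genes: Sequence[GeneModel], prefix: str) -> dict[str, str]:
    """Name genes ``prefix-1 .. prefix-N`` by chromosomal order.

    Genes are sorted by (chromosome in natural order, start); ties on
    (chromosome, start) are broken by end then gene_id with a warning.
    Returns a bijective mapping ``gene_id -> ordinal name``.
    """
    seen: dict[tuple[str, int], str] = {}
    for g in genes:
        key = (g.chromosome, g.start)
        if key in seen:
            warnings.warn(
                f"genes {seen[key]!r} and {g.gene_id!r} share position "
                f"{key}; tie broken by end then gene_id",
                stacklevel=2,
            )
        seen[key] = g.gene_id
    ordered = sorted(
        genes,
        key=lambda g: (chromosome_sort_key(g.chromosome), g.start, g.end, g.gene_id),
    )
    return {g.gene_id: f"{prefix}-{i}" for i, g in enumerate(ordered, start=1)}
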