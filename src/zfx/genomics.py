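"""Genomic stages: chromosomal distribution, tandem duplication, gene structure.

Tandem duplicates are adjacent paralogous family genes on the same
chromosome; here "adjacent" means at most ``max_intervening`` family
genes in between, and "paralogous" means the encoded proteins align
globally at >= ``min_identity`` percent identity (BLOSUM62, gap open 10,
extend 0.5; identity = matches / alignment length).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .io_core import GeneModel, ProteinRecord, chromosome_sort_key

__all__ = [
    "DuplicationPair",
    "chromosome_distribution",
    "global_identity",
    "detect_tandem_duplicates",
    "exon_intron_structure",
]


@dataclass(frozen=True)
class DuplicationPair:
    gene_a: str
    gene_b: str
    chromosome: str
    intervening_genes: int
    identity: float  # percent

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be a percentage in [0, 100]")


def chromosome_distribution(genes: list[GeneModel]) -> dict[str, int]:
    """Gene count per chromosome, in natural chromosome order."""
    counts = Counter(g.chromosome for g in genes)
    return {c: counts[c] for c in sorted(counts, key=chromosome_sort_key)}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def global_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of a global alignment (matches / alignment length)."""
    aligner = _make_aligner()
    alignment = next(iter(aligner.align(seq_a.upper(), seq_b.upper())))
    counts = alignment.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / aln_len


def detect_tandem_duplicates(
    genes: list[GeneModel],
    proteins: list[ProteinRecord],
    max_intervening: int = 1,
    min_identity: float = 70.0,
) -> list[DuplicationPair]:
    """Find tandem-duplicated family gene pairs.

    Genes are ordered along each chromosome; every same-chromosome pair
    separated by at most ``max_intervening`` family genes is aligned and
    reported when protein identity reaches ``min_identity`` percent.
    Genes without an available protein are skipped with a warning.
    """
    seq_by_id = {p.id: p.sequence for p in proteins}

    def _protein_for(g: GeneModel) -> str | None:
        for key in (g.protein_id, g.gene_id):
            if key is not None and key in seq_by_id:
                return seq_by_id[key]
        return None

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (chromosome_sort_key(g.chromosome), g.start)):
        by_chrom.setdefault(g.chromosome, []).append(g)

    pairs: list[DuplicationPair] = []
    for chrom, members in by_chrom.items():
        usable = []
        for g in members:
            seq = _protein_for(g)
            if seq is None:
                warnings.warn(
                    f"no protein sequence for gene {g.gene_id!r}; skipped in "
                    "tandem-duplication scan",
                    stacklevel=2,
                )
                continue
            usable.append((g, seq))
        for i, (ga, seq_a) in enumerate(usable):
            for j in range(i + 1, len(usable)):
                gb, seq_b = usable[j]
                intervening = j - i - 1
                if intervening > max_intervening:
                    break
                identity = global_identity(seq_a, seq_b)
                if identity >= min_identity:
                    pairs.append(
                        DuplicationPair(
                            gene_a=ga.gene_id,
                            gene_b=gb.gene_id,
                            chromosome=chrom,
                            intervening_genes=intervening,
                            identity=round(identity, 2),
                        )
                    )
    return pairs


def exon_intron_structure(
    genes: list[GeneModel],
    subsets: dict[str, str] | None = None,
) -> tuple[dict[str, tuple[int, int]], dict[str, float]]:
    """Per-gene (exon count, intron count) and per-subset mean intron count.

    ``subsets`` maps gene_id -> subset label; subset means are rounded
    to 1 decimal.  Intron count is exon count - 1.
    """
    per_gene = {g.gene_id: (g.exon_count, g.intron_count) for g in genes}
    subset_means: dict[str, float] = {}
    if subsets:
        groups: dict[str, list[int]] = {}
        for g in genes:
            label = subsets.get(g.gene_id)
            if label is not None:
                groups.setdefault(label, []).append(g.intron_count)
        subset_means = {
            label: round(sum(v) / len(v), 1) for label, v in sorted(groups.items())
        }
    return per_gene, subset_means
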