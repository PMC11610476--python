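"""Synthetic study inputs with the structural properties the pipeline assumes.

Generates (i) proteomes in which every protein realises a prescribed
finger architecture — spacing signatures, linker lengths, diagnostic
motifs, neutral background residues — so that the scanner and the
classifier can be validated by round trip against the planted truth;
(ii) FPKM matrices with planted expression-profile groups; and (iii)
replicate enzyme panels with prescribed treatment means and noise.

The background residue alphabet excludes cysteine and histidine so no
unplanned finger can arise; every generated protein is re-scanned and
re-classified at generation time and an error is raised if the planted
label is not recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import GeneModel, ProteinRecord
from . import classify as _classify
from .fingerscan import parse_signature

__all__ = [
    "BACKGROUND_ALPHABET",
    "ArchitectureSpec",
    "ARCHITECTURE_TEMPLATES",
    "STUDY_PROTEOME_COMPOSITION",
    "WATER_STRESS_REFERENCE_PANEL",
    "make_protein",
    "make_proteome",
    "make_fpkm",
    "make_enzyme_panel",
    "genes_to_gff3",
]

# the 18 standard residues that can never seed a finger
BACKGROUND_ALPHABET = "ADEFGIKLMNPQRSTVWY"

# buffer after a planted PCYCC block so its cysteines cannot combine with a
# downstream finger into a spurious match (inner spacer cap is 20)
_PCYCC_BUFFER = 25


@dataclass(frozen=True)
class ArchitectureSpec:
    """A planted finger architecture and its expected classification."""

    label: str
    finger_signatures: tuple[str, ...]
    linkers: tuple[int, ...]
    has_qalggh: bool = False
    has_satall: bool = False
    has_pcycc: bool = False
    background_length: tuple[int, int] = (30, 30)

    def __post_init__(self) -> None:
        object.__setattr__(self, "finger_signatures", tuple(self.finger_signatures))
        object.__setattr__(self, "linkers", tuple(self.linkers))
        if len(self.linkers) != max(0, len(self.finger_signatures) - 1):
            raise ValueError("need exactly one linker between consecutive fingers")
        if any(l < 0 for l in self.linkers):
            raise ValueError("linkers must be non-negative")
        for sig in self.finger_signatures:
            parse_signature(sig)  # raises on malformed signatures


_A1_ROW = {
    "A1a": ("CX2CX12HX3H", "CX4CX17HX4H", "CX2CX12HX3C", "CX1CX12HX3C"),
    "A1b": ("CX2CX12HX3H", "CX4CX17HX4H", "CX2CX12HX3C", "CX1CX12HX3C"),
    "A1c": ("CX2CX12HX3H", "CX4CX20HX4H", "CX2CX13HX3C", "CX1CX12HX6H"),
    "A1d": ("CX2CX12HX3H", "CX4CX20HX4H", "CX2CX12HX3C", "CX1CX12HX7H"),
}

ARCHITECTURE_TEMPLATES: dict[str, ArchitectureSpec] = {
    "A1a": ArchitectureSpec("A1a", _A1_ROW["A1a"], (5, 5, 5), has_satall=True),
    "A1b": ArchitectureSpec("A1b", _A1_ROW["A1b"], (5, 5, 5)),
    "A1c": ArchitectureSpec("A1c", _A1_ROW["A1c"], (5, 5, 5)),
    "A1d": ArchitectureSpec("A1d", _A1_ROW["A1d"], (5, 5, 5), has_pcycc=True),
    "A2": ArchitectureSpec("A2", ("CX2CX12HX3H",) * 3, (20, 5)),
    "A4": ArchitectureSpec("A4", ("CX2CX12HX3H",) * 3, (5, 5)),
    "B": ArchitectureSpec(
        "B", ("CX2CX12HX3H",) * 9, (20, 5, 5, 30, 5, 5, 5, 5)
    ),
    "C1-1": ArchitectureSpec("C1-1", ("CX2CX12HX3H",), (), has_qalggh=True),
    "C1-2": ArchitectureSpec("C1-2", ("CX2CX12HX3H",) * 2, (15,), has_qalggh=True),
    "C1-3": ArchitectureSpec("C1-3", ("CX2CX12HX3H",) * 3, (15, 15)),
    "C1-4": ArchitectureSpec("C1-4", ("CX2CX12HX3H",) * 4, (15, 15, 15)),
    "C1-5": ArchitectureSpec("C1-5", ("CX2CX12HX3H",) * 5, (15,) * 4),
    "C1C2mixed": ArchitectureSpec(
        "C1C2mixed", ("CX2CX12HX3H", "CX2CX12HX4H"), (15,)
    ),
    "C2": ArchitectureSpec("C2", ("CX2CX12HX4H",), ()),
    "C3": ArchitectureSpec("C3", ("CX2CX12HX5H",), ()),
}

# the composition of the study proteome: 77 proteins, 29 in set A
# (A1a/A1b/A1c/A1d = 13/1/3/7, A2 = 2, A4 = 3), 2 TFIIIA-like set B,
# 46 in set C (C1 = 36 incl. 2 C1C2mixed, C2 = 9, C3 = 1)
STUDY_PROTEOME_COMPOSITION: tuple[tuple[str, int], ...] = (
    ("A1a", 13),
    ("A1b", 1),
    ("A1c", 3),
    ("A1d", 7),
    ("A2", 2),
    ("A4", 3),
    ("B", 2),
    ("C1-1", 19),
    ("C1-2", 11),
    ("C1-3", 1),
    ("C1-4", 2),
    ("C1-5", 1),
    ("C1C2mixed", 2),
    ("C2", 9),
    ("C3", 1),
)

# reference water-stress enzyme panel: per analyte, treatment -> (mean, sd);
# units: SOD/POD/CAT U/g, MDA nmol/g, H2O2 umol/g, proline g/kg
WATER_STRESS_REFERENCE_PANEL: dict[str, dict[str, tuple[float, float]]] = {
    "SOD": {"CK": (630.85, 19.01), "LS": (794.60, 68.88),
            "MS": (914.52, 42.69), "SS": (1021.59, 32.08)},
    "POD": {"CK": (86931.97, 685.16), "LS": (55909.43, 678.79),
            "MS": (75926.12, 804.25), "SS": (68229.46, 498.09)},
    "CAT": {"CK": (1385.92, 10.92), "LS": (1255.08, 27.67),
            "MS": (1423.33, 52.94), "SS": (997.16, 74.93)},
    "MDA": {"CK": (59.94, 1.06), "LS": (71.87, 1.05),
            "MS": (70.05, 1.73), "SS": (68.91, 0.43)},
    "H2O2": {"CK": (5.73, 0.24), "LS": (7.55, 0.31),
             "MS": (8.41, 0.22), "SS": (9.62, 0.51)},
    "proline": {"CK": (0.175, 0.0029), "LS": (0.045, 0.0017),
                "MS": (0.035, 0.001), "SS": (0.044, 0.0012)},
}


def _background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BACKGROUND_ALPHABET), size=n)) if n > 0 else ""


def _realize_finger(
    rng: np.random.Generator, signature: str, insert_qalggh: bool
) -> str:
    (a, b, c), (t1, t2) = parse_signature(signature)
    helix = _background(rng, b)
    if insert_qalggh:
        if b < len(_classify.MOTIF_QALGGH):
            raise ValueError(f"helix of {signature} too short for QALGGH")
        helix = _classify.MOTIF_QALGGH + helix[len(_classify.MOTIF_QALGGH):]
    return "C" + _background(rng, a) + "C" + helix + t1 + _background(rng, c) + t2


def make_protein(
    spec: ArchitectureSpec, seed: int, protein_id: str = "syn-1"
) -> ProteinRecord:
    """Realise one protein from an architecture spec, deterministically.

    Coordinating residues follow the signatures exactly; all other
    positions are background (no C, no H).  QALGGH goes at the start of
    the first sufficiently long helix, the SATALLQKAAQMGS block at the
    C-terminus, PCYCC in the N-terminal flank with a buffer wide enough
    that its cysteines cannot reach any downstream finger.  The result
    is re-classified and an error is raised if the planted label is not
    recovered.
    """
    rng = np.random.default_rng(seed)
    n_flank, c_flank = spec.background_length
    parts: list[str] = []
    if spec.has_pcycc:
        parts.append(_background(rng, max(0, n_flank - _PCYCC_BUFFER)))
        parts.append(_classify.MOTIF_PCYCC)
        parts.append(_background(rng, _PCYCC_BUFFER))
    else:
        parts.append(_background(rng, n_flank))
    qalggh_pending = spec.has_qalggh
    for i, sig in enumerate(spec.finger_signatures):
        (a, b, c), _ = parse_signature(sig)
        insert = qalggh_pending and b >= len(_classify.MOTIF_QALGGH)
        parts.append(_realize_finger(rng, sig, insert))
        qalggh_pending = qalggh_pending and not insert
        if i < len(spec.linkers):
            parts.append(_background(rng, spec.linkers[i]))
    if qalggh_pending:
        raise ValueError("no helix long enough to host the requested QALGGH")
    parts.append(_background(rng, c_flank))
    if spec.has_satall:
        parts.append(_classify.MOTIF_SATALL_BLOCK)
    record = ProteinRecord(id=protein_id, sequence="".join(parts), source="synthetic")

    observed = _classify.classify_protein(record)
    got = observed.subset if observed.subset != "none" else observed.subgroup
    if got != spec.label or observed.signatures != list(spec.finger_signatures):
        raise ValueError(
            f"architecture {spec.label!r} not recovered at generation "
            f"(got {got!r} with {observed.n_fingers} fingers)"
        )
    return record


def make_proteome(
    composition: tuple[tuple[str, int], ...] | list[tuple[ArchitectureSpec, int]] = STUDY_PROTEOME_COMPOSITION,
    seed: int = 0,
    id_prefix: str = "syn",
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Generate a proteome from (architecture, copies) pairs.

    Architectures may be given as template labels or explicit specs.
    Returns the records plus the truth table protein_id -> planted label.
    Flank lengths are jittered per protein so copies are not identical.
    """
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth: dict[str, str] = {}
    idx = 0
    for entry, copies in composition:
        spec = ARCHITECTURE_TEMPLATES[entry] if isinstance(entry, str) else entry
        for _ in range(copies):
            idx += 1
            flanks = (int(rng.integers(25, 60)), int(rng.integers(25, 60)))
            pspec = replace(spec, background_length=flanks)
            pid = f"{id_prefix}-{idx:04d}"
            records.append(make_protein(pspec, seed=int(rng.integers(2**31)), protein_id=pid))
            truth[pid] = spec.label
    return records, truth


def _archetypes(k: int, n_conditions: int) -> np.ndarray:
    """k unit-peak profile archetypes with peaks spread over conditions."""
    centers = np.linspace(0, n_conditions - 1, k)
    j = np.arange(n_conditions)
    return np.exp(-((j[None, :] - centers[:, None]) ** 2) / (2 * 0.6**2))


def make_fpkm(
    n_genes: int = 77,
    conditions: tuple[str, ...] = ("CK", "LS", "MS", "SS"),
    k: int = 7,
    noise_sd: float = 0.0,
    n_below_threshold: int = 0,
    threshold: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """FPKM matrix with planted profile groups.

    Expressed genes follow one of ``k`` peak-shaped archetypes scaled to
    a realistic FPKM range with Gaussian noise (linear scale, truncated
    at zero); ``n_below_threshold`` genes are scaled so their maximum
    stays below the expression ``threshold``.  Returns the matrix and
    the truth grouping (planted group per expressed gene; silenced genes
    are labelled ``below``).
    """
    if n_below_threshold > n_genes:
        raise ValueError("cannot silence more genes than exist")
    rng = np.random.default_rng(seed)
    arch = _archetypes(k, len(conditions))
    genes = [f"gene-{i + 1:04d}" for i in range(n_genes)]
    n_expressed = n_genes - n_below_threshold
    rows = []
    truth: dict[str, str] = {}
    for i, gene in enumerate(genes):
        if i < n_expressed:
            group = i % k
            scale = rng.uniform(20.0, 100.0)
            profile = arch[group] * scale
            truth[gene] = f"g{group + 1}"
        else:
            profile = arch[i % k] * (threshold * 0.5)  # max below threshold
            truth[gene] = "below"
        noisy = profile + rng.normal(0.0, noise_sd, size=len(conditions))
        rows.append(np.maximum(noisy, 0.0))
    matrix = pd.DataFrame(rows, index=genes, columns=list(conditions))
    return matrix, truth


def make_enzyme_panel(
    reference: dict[str, dict[str, tuple[float, float]]] = WATER_STRESS_REFERENCE_PANEL,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate panel drawn Normal(mean, sd) per (treatment, analyte),
    in long format (treatment, replicate, analyte, value)."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rows = []
    for analyte in sorted(reference):
        for treatment in sorted(reference[analyte]):
            mean, sd = reference[analyte][treatment]
            if sd < 0:
                raise ValueError(f"negative sd for ({treatment}, {analyte})")
            values = rng.normal(mean, sd, size=n_replicates)
            for rep, v in enumerate(values, start=1):
                rows.append(
                    {"treatment": treatment, "replicate": rep,
                     "analyte": analyte, "value": float(v)}
                )
    return pd.DataFrame(rows)


def genes_to_gff3(genes: list[GeneModel], path) -> None:
    """Write minimal GFF3 (gene/mRNA/exon) for toy gene models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chromosome}\tzfx\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            extra = f";protein_id={g.protein_id}" if g.protein_id else ""
            fh.write(
                f"{g.chromosome}\tzfx\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}{extra}\n"
            )
            for n, (s, e) in enumerate(g.exon_intervals, start=1):
                fh.write(
                    f"{g.chromosome}\tzfx\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{n};Parent={mrna_id}\n"
                )
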