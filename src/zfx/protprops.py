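"""Physicochemical profiling of protein sequences.

Computes the ExPASy-style attributes commonly reported for a gene
family: length, average molecular weight, theoretical isoelectric point
(Bjellqvist pKa set, charge bisection), Guruprasad instability index,
Kyte-Doolittle GRAVY, and amino-acid / atomic composition.

``X`` residues are tolerated: they count toward length and composition
but are excluded from the numerical sums, with a per-protein warning.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .io_core import ProteinRecord

__all__ = [
    "PhysicoProfile",
    "molecular_weight",
    "isoelectric_point",
    "instability_index",
    "gravy",
    "atomic_composition",
    "profile_protein",
    "profile_table",
    "profiles_to_frame",
]

# element counts (C, H, N, O, S) of the free amino acids; a peptide bond
# removes one water per junction
_FREE_AA_FORMULA: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 7, 1, 2, 0),
    "R": (6, 14, 4, 2, 0),
    "N": (4, 8, 2, 3, 0),
    "D": (4, 7, 1, 4, 0),
    "C": (3, 7, 1, 2, 1),
    "E": (5, 9, 1, 4, 0),
    "Q": (5, 10, 2, 3, 0),
    "G": (2, 5, 1, 2, 0),
    "H": (6, 9, 3, 2, 0),
    "I": (6, 13, 1, 2, 0),
    "L": (6, 13, 1, 2, 0),
    "K": (6, 14, 2, 2, 0),
    "M": (5, 11, 1, 2, 1),
    "F": (9, 11, 1, 2, 0),
    "P": (5, 9, 1, 2, 0),
    "S": (3, 7, 1, 3, 0),
    "T": (4, 9, 1, 3, 0),
    "W": (11, 12, 2, 2, 0),
    "Y": (9, 11, 1, 3, 0),
    "V": (5, 11, 1, 2, 0),
}


@dataclass
class PhysicoProfile:
    protein_id: str
    length: int
    mw: float
    pi: float
    instability: float
    gravy: float
    aa_composition: dict[str, int]
    atomic_composition: dict[str, int]


def _clean(sequence: str, what: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError(f"empty sequence passed to {what}")
    if "X" in seq:
        warnings.warn(
            f"{seq.count('X')} 'X' residue(s) excluded from {what}", stacklevel=3
        )
        seq = seq.replace("X", "")
        if not seq:
            raise ValueError(f"sequence is all-X; cannot compute {what}")
    return seq


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in daltons (residue masses + one water)."""
    return ProteinAnalysis(_clean(sequence, "molecular weight")).molecular_weight()


def isoelectric_point(sequence: str) -> float:
    """Theoretical pI: pH of zero net charge under the Bjellqvist
    (ExPASy) pKa set with N/C termini included, found by bisection."""
    return ProteinAnalysis(_clean(sequence, "pI")).isoelectric_point()


def instability_index(sequence: str) -> float:
    """Guruprasad instability index: (10/L) x sum of dipeptide weights."""
    seq = _clean(sequence, "instability index")
    if len(seq) < 2:
        raise ValueError("instability index needs at least two residues")
    return ProteinAnalysis(seq).instability_index()


def gravy(sequence: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle score)."""
    return ProteinAnalysis(_clean(sequence, "GRAVY")).gravy()


def atomic_composition(sequence: str) -> dict[str, int]:
    """Element counts C/H/N/O/S of the whole chain (peptide bonds formed)."""
    seq = _clean(sequence, "atomic composition")
    totals = [0, 0, 0, 0, 0]
    for aa in seq:
        f = _FREE_AA_FORMULA[aa]
        for i in range(5):
            totals[i] += f[i]
    # remove one water per peptide bond
    totals[1] -= 2 * (len(seq) - 1)
    totals[3] -= len(seq) - 1
    return dict(zip("CHNOS", totals))


def profile_protein(protein: ProteinRecord) -> PhysicoProfile:
    seq = protein.sequence
    return PhysicoProfile(
        protein_id=protein.id,
        length=len(seq),
        mw=molecular_weight(seq),
        pi=isoelectric_point(seq),
        instability=instability_index(seq),
        gravy=gravy(seq),
        aa_composition=dict(Counter(seq)),
        atomic_composition=atomic_composition(seq),
    )


def profile_table(proteins: list[ProteinRecord]) -> list[PhysicoProfile]:
    """One profile per protein; per-protein failures are collected as
    warnings and the table is still emitted for the valid proteins."""
    profiles: list[PhysicoProfile] = []
    for p in proteins:
        try:
            profiles.append(profile_protein(p))
        except ValueError as exc:  # pragma: no cover - defensive
            warnings.warn(f"{p.id}: {exc}", stacklevel=2)
    return profiles


def profiles_to_frame(profiles: list[PhysicoProfile]) -> pd.DataFrame:
    """Flatten profiles into a table (one row per protein)."""
    rows = []
    for pr in profiles:
        rows.append(
            {
                "protein": pr.protein_id,
                "length": pr.length,
                "mw": round(pr.mw, 2),
                "pi": round(pr.pi, 2),
                "instability": round(pr.instability, 2),
                "gravy": round(pr.gravy, 3),
                **{f"n_{el}": v for el, v in pr.atomic_composition.items()},
            }
        )
    return pd.DataFrame(rows)
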