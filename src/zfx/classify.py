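"""Structural classification of C2H2 zinc-finger proteins.

Proteins are partitioned into three sets by the layout of their fingers:
set A (three-to-five fingers with at least one tandem array), set B
(TFIIIA-like proteins with many fingers in several tandem arrays) and
set C (a single isolated finger or multiple dispersed fingers).  Set C
splits by the spacer between the two terminal coordinating residues
(the "H-gap": 3 -> C1, 4 -> C2, 5 -> C3; a 3/4 mixture is the C1C2mixed
subset kept inside C1), and pure C1 further by finger count (C1-1 ..
C1-5).  Set A splits into A1 (a conserved four-finger template, with
subsets A1a-A1d decided by diagnostic motifs and spacings) and the
heuristic A2/A4 subgroups.

Two conserved non-finger blocks are diagnostic: the C-terminal
SATALLQKAAQMGS block (subset A1a) and the PCYCC motif (subset A1d).  The
plant-specific QALGGH hexapeptide inside a finger helix marks Q-type
fingers and is recorded as metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections import Counter

from .io_core import ProteinRecord
from .fingerscan import (
    DEFAULT_GRAMMAR,
    TANDEM_THRESHOLD,
    FingerArray,
    FingerGrammar,
    ZincFinger,
    finger_signature,
    group_arrays,
    scan_fingers,
)

__all__ = [
    "ClassifyConfig",
    "ClassificationRecord",
    "ProteomeSummary",
    "MOTIF_QALGGH",
    "MOTIF_SATALL_BLOCK",
    "MOTIF_PCYCC",
    "detect_motif",
    "assign_set",
    "assign_subgroup_C",
    "assign_subgroup_A",
    "classify_protein",
    "classify_proteome",
]

MOTIF_QALGGH = "QALGGH"
MOTIF_SATALL_BLOCK = "SATALLQKAAQMGS"
MOTIF_SATALL = "SATALL"
MOTIF_PCYCC = "PCYCC"

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifyConfig:
    """Tunable thresholds of the taxonomy.

    ``set_b_min_fingers``/``set_b_min_arrays`` define the TFIIIA-like
    trigger (>= 6 fingers in >= 2 tandem arrays); the A2/A4 split is a
    documented heuristic: >= ``a2_min_fingers`` fingers spread over more
    than one run -> A2, otherwise A4.
    """

    tandem_threshold: int = TANDEM_THRESHOLD
    set_b_min_fingers: int = 6
    set_b_min_arrays: int = 2
    a2_min_fingers: int = 3
    a4_max_fingers: int = 3


DEFAULT_CONFIG = ClassifyConfig()

# the four-finger template shared by the A1 subsets
A1_FINGER1_SIGNATURE = "CX2CX12HX3H"
A1_FINGER2_PAIR1_GAP = 4
A1C_FINGER2_INNER_GAP = 20
A1C_FINGER3_SIGNATURE = "CX2CX13HX3C"


@dataclass
class ClassificationRecord:
    protein_id: str
    n_fingers: int
    set_label: str  # "A" | "B" | "C" | "unclassified"
    subgroup: str  # "A1" | "A2" | "A4" | "B" | "C1" | "C2" | "C3" | "none"
    subset: str  # "A1a".."A1d" | "C1-1".."C1-5" | "C1C2mixed" | "none"
    h_gaps: list[int]
    q_type: bool
    has_satall: bool
    has_pcycc: bool
    arrays: list[FingerArray]
    isolated: list[int]
    signatures: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def has_tandem_array(self) -> bool:
        return len(self.arrays) > 0


@dataclass
class ProteomeSummary:
    n_proteins: int
    set_counts: dict[str, int]
    subgroup_counts: dict[str, int]
    subset_counts: dict[str, int]
    n_tandem_proteins: int
    n_unclassified: int

    def as_dict(self) -> dict:
        return {
            "n_proteins": self.n_proteins,
            "set_counts": dict(self.set_counts),
            "subgroup_counts": dict(self.subgroup_counts),
            "subset_counts": dict(self.subset_counts),
            "n_tandem_proteins": self.n_tandem_proteins,
            "n_unclassified": self.n_unclassified,
        }


def detect_motif(
    protein: ProteinRecord | str,
    motif: str,
    region: str = "anywhere",
    fingers: list[ZincFinger] | None = None,
) -> tuple[bool, list[int]]:
    """Search for a diagnostic motif; returns (present, 1-based positions).

    ``region`` is one of ``helix`` (inside detected finger helices only),
    ``c_terminal`` (after the last finger, or the whole sequence when no
    fingers are given) or ``anywhere``.  SATALL is accepted as the exact
    start of the longer conserved SATALLQKAAQMGS block.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else str(protein).upper()
    pattern = MOTIF_SATALL if motif.upper().startswith(MOTIF_SATALL) else motif.upper()
    if region == "helix":
        if fingers is None:
            raise ValueError("region='helix' requires finger evidence")
        positions = []
        for f in fingers:
            off = f.helix.find(pattern)
            if off >= 0:
                positions.append(f.c2 + 1 + off)
        return (len(positions) > 0, positions)
    if region == "c_terminal" and fingers:
        offset = fingers[-1].t2  # 0-based index right after the last finger
        sub = seq[offset:]
    else:
        offset = 0
        sub = seq
    positions = []
    start = 0
    while True:
        hit = sub.find(pattern, start)
        if hit < 0:
            break
        positions.append(offset + hit + 1)
        start = hit + 1
    return (len(positions) > 0, positions)


def assign_set(
    fingers: list[ZincFinger],
    arrays: list[FingerArray],
    isolated: list[int],
    config: ClassifyConfig = DEFAULT_CONFIG,
) -> str:
    """Set label from finger count and tandem-array layout."""
    n = len(fingers)
    if n == 0:
        return UNCLASSIFIED
    if n >= config.set_b_min_fingers and len(arrays) >= config.set_b_min_arrays:
        return "B"
    if any(len(a) >= 2 for a in arrays):
        return "A"
    return "C"


def assign_subgroup_C(fingers: list[ZincFinger]) -> tuple[str, str, list[str]]:
    """Subgroup/subset inside set C from the per-finger H-gaps.

    All gaps 3 -> C1 (subset C1-k, k = finger count); all 4 -> C2; all
    5 -> C3; a 3/4 mixture -> subset C1C2mixed kept inside C1.  Gaps
    outside 3-5 are atypical: the protein is classified by the majority
    gap with a warning.
    """
    notes: list[str] = []
    gaps = [f.h_gap for f in fingers]
    typical = [g for g in gaps if 3 <= g <= 5]
    atypical = [g for g in gaps if g < 3 or g > 5]
    if atypical:
        notes.append(f"atypical H-gap(s) {sorted(atypical)} ignored; majority vote used")
    pool = typical if typical else [min(5, max(3, g)) for g in gaps]
    distinct = set(pool)
    if distinct == {3}:
        n = len(fingers)
        subset = f"C1-{n}" if n <= 5 else "none"
        return "C1", subset, notes
    if distinct == {4}:
        return "C2", "none", notes
    if distinct == {5}:
        return "C3", "none", notes
    if distinct == {3, 4}:
        return "C1", "C1C2mixed", notes
    # other mixtures: majority vote, ties resolved toward the smaller gap
    counts = Counter(pool)
    gap = min(sorted(counts), key=lambda g: (-counts[g], g))
    notes.append(f"mixed H-gaps {sorted(distinct)}; majority gap {gap} used")
    sub = {3: "C1", 4: "C2", 5: "C3"}[gap]
    subset = f"C1-{len(fingers)}" if sub == "C1" and len(fingers) <= 5 else "none"
    return sub, subset, notes


def _is_a1_template(fingers: list[ZincFinger]) -> bool:
    if len(fingers) != 4:
        return False
    return (
        finger_signature(fingers[0]) == A1_FINGER1_SIGNATURE
        and fingers[1].gaps[0] == A1_FINGER2_PAIR1_GAP
    )


def assign_subgroup_A(
    fingers: list[ZincFinger],
    arrays: list[FingerArray],
    isolated: list[int],
    has_satall: bool,
    has_pcycc: bool,
    config: ClassifyConfig = DEFAULT_CONFIG,
) -> tuple[str, str, list[str]]:
    """Subgroup/subset inside set A.

    A1 requires the conserved four-finger template (finger 1 =
    CX2CX12HX3H, finger 2 with a 4-residue cysteine spacer); its subsets
    are decided by the SATALL block (A1a), the PCYCC motif (A1d), the
    A1c spacings (20-residue helix on finger 2 and finger 3 =
    CX2CX13HX3C), defaulting to A1b.  Non-A1 proteins fall to the
    heuristic A2 (fingers spread over more than one run) or A4 (one
    compact array).
    """
    notes: list[str] = []
    if _is_a1_template(fingers):
        if has_satall:
            return "A1", "A1a", notes
        if has_pcycc:
            return "A1", "A1d", notes
        if (
            fingers[1].gaps[1] == A1C_FINGER2_INNER_GAP
            and finger_signature(fingers[2]) == A1C_FINGER3_SIGNATURE
        ):
            return "A1", "A1c", notes
        return "A1", "A1b", notes
    n_runs = len(arrays) + len(isolated)
    if len(fingers) >= config.a2_min_fingers and n_runs > 1:
        return "A2", "none", notes
    if len(fingers) <= config.a4_max_fingers:
        return "A4", "none", notes
    notes.append("ambiguous A2-vs-A4 layout; defaulted to A4")
    return "A4", "none", notes


def classify_protein(
    protein: ProteinRecord,
    grammar: FingerGrammar = DEFAULT_GRAMMAR,
    config: ClassifyConfig = DEFAULT_CONFIG,
) -> ClassificationRecord:
    """Scan one protein and assign its set/subgroup/subset with evidence."""
    fingers = scan_fingers(protein, grammar)
    arrays, isolated = group_arrays(fingers, config.tandem_threshold)
    q_type, _ = detect_motif(protein, MOTIF_QALGGH, region="helix", fingers=fingers)
    has_satall, _ = detect_motif(protein, MOTIF_SATALL_BLOCK, region="anywhere")
    has_pcycc, _ = detect_motif(protein, MOTIF_PCYCC, region="anywhere")
    set_label = assign_set(fingers, arrays, isolated, config)
    notes: list[str] = []
    if set_label == "A":
        subgroup, subset, notes = assign_subgroup_A(
            fingers, arrays, isolated, has_satall, has_pcycc, config
        )
    elif set_label == "C":
        subgroup, subset, notes = assign_subgroup_C(fingers)
    elif set_label == "B":
        subgroup, subset = "B", "none"
    else:
        subgroup, subset = "none", "none"
        notes = ["no finger detected; protein left unclassified"]
    for note in notes:
        warnings.warn(f"{protein.id}: {note}", stacklevel=2)
    return ClassificationRecord(
        protein_id=protein.id,
        n_fingers=len(fingers),
        set_label=set_label,
        subgroup=subgroup,
        subset=subset,
        h_gaps=[f.h_gap for f in fingers],
        q_type=q_type,
        has_satall=has_satall,
        has_pcycc=has_pcycc,
        arrays=arrays,
        isolated=isolated,
        signatures=[finger_signature(f) for f in fingers],
        warnings=notes,
    )


def classify_proteome(
    proteins: list[ProteinRecord],
    grammar: FingerGrammar = DEFAULT_GRAMMAR,
    config: ClassifyConfig = DEFAULT_CONFIG,
) -> tuple[ProteomeSummary, list[ClassificationRecord]]:
    """Classify every protein and tally set/subgroup/subset counts."""
    records = [classify_protein(p, grammar, config) for p in proteins]
    set_counts = Counter(r.set_label for r in records if r.set_label != UNCLASSIFIED)
    subgroup_counts = Counter(r.subgroup for r in records if r.subgroup != "none")
    subset_counts = Counter(r.subset for r in records if r.subset != "none")
    summary = ProteomeSummary(
        n_proteins=len(records),
        set_counts=dict(set_counts),
        subgroup_counts=dict(subgroup_counts),
        subset_counts=dict(subset_counts),
        n_tandem_proteins=sum(1 for r in records if r.has_tandem_array),
        n_unclassified=sum(1 for r in records if r.set_label == UNCLASSIFIED),
    )
    return summary, records
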