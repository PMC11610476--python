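"""C2H2 zinc-finger detection with a spacing grammar.

A C2H2-type finger is the unit Cys-X(a)-Cys-X(b)-Z-X(c)-Z where the two
cysteines and the two terminal residues (histidine in the canonical case,
cysteine in degenerate variants) coordinate a zinc ion.  The grammar is a
set of allowed spacer ranges; the default covers the canonical consensus
Cys-X2-4-Cys-X12-His-X3-5-His widened to the degenerate fingers seen in
plant family surveys (inner spacer up to 20, terminal spacer up to 7,
terminal cysteines).

Fingers separated by a short linker (<= 10 residues by convention) form a
tandem array; longer spacers make them dispersed/isolated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io_core import ProteinRecord

__all__ = [
    "FingerGrammar",
    "ZincFinger",
    "FingerArray",
    "DEFAULT_GRAMMAR",
    "TANDEM_THRESHOLD",
    "scan_fingers",
    "finger_signature",
    "parse_signature",
    "group_arrays",
]

TANDEM_THRESHOLD = 10  # residues between fingers; <= 10 means tandem


@dataclass(frozen=True)
class FingerGrammar:
    """Allowed spacings and terminal residues for one finger.

    ``pair1_gap_range`` — residues between the two cysteines;
    ``inner_gap_range`` — residues between the second cysteine and the
    first terminal coordinating residue (the finger helix);
    ``pair2_gap_range`` — residues between the two terminal residues;
    ``terminal_alphabet`` — residues allowed at the two terminal
    positions.  With ``require_histidine`` at least one terminal must be
    H (a finger ending C...C on both terminals is not accepted).
    """

    pair1_gap_range: tuple[int, int] = (1, 4)
    inner_gap_range: tuple[int, int] = (12, 20)
    pair2_gap_range: tuple[int, int] = (3, 7)
    terminal_alphabet: frozenset[str] = frozenset({"H", "C"})
    require_histidine: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.pair1_gap_range, self.inner_gap_range, self.pair2_gap_range):
            if lo < 1 or hi < lo:
                raise ValueError("gap ranges must be non-empty positive intervals")
        if not self.terminal_alphabet:
            raise ValueError("terminal alphabet must be non-empty")
        object.__setattr__(self, "terminal_alphabet", frozenset(self.terminal_alphabet))

    def template(self) -> str:
        """Serialize to a signature template, e.g. ``CX1-4CX12-20ZX3-7Z``."""
        z = "".join(sorted(self.terminal_alphabet))
        z = z if len(z) == 1 else "Z"
        a, b, c = self.pair1_gap_range, self.inner_gap_range, self.pair2_gap_range
        fmt = lambda r: f"{r[0]}" if r[0] == r[1] else f"{r[0]}-{r[1]}"
        return f"CX{fmt(a)}CX{fmt(b)}{z}X{fmt(c)}{z}"

    @classmethod
    def from_template(cls, template: str, **kwargs) -> "FingerGrammar":
        m = re.fullmatch(
            r"CX(\d+)(?:-(\d+))?CX(\d+)(?:-(\d+))?([A-Z])X(\d+)(?:-(\d+))?([A-Z])",
            template,
        )
        if m is None:
            raise ValueError(f"unparsable grammar template {template!r}")
        a1, a2, b1, b2, z1, c1, c2, z2 = m.groups()
        rng = lambda lo, hi: (int(lo), int(hi if hi is not None else lo))
        alphabet = {"H", "C"} if "Z" in (z1, z2) else {z1, z2}
        return cls(
            pair1_gap_range=rng(a1, a2),
            inner_gap_range=rng(b1, b2),
            pair2_gap_range=rng(c1, c2),
            terminal_alphabet=frozenset(alphabet),
            **kwargs,
        )


DEFAULT_GRAMMAR = FingerGrammar()


@dataclass(frozen=True)
class ZincFinger:
    """One detected finger; all positions are 1-based inclusive."""

    c1: int
    c2: int
    t1: int
    t2: int
    terminal_types: tuple[str, str]
    helix: str

    def __post_init__(self) -> None:
        if not (self.c1 < self.c2 < self.t1 < self.t2):
            raise ValueError("coordinating residues out of order")

    @property
    def start(self) -> int:
        return self.c1

    @property
    def end(self) -> int:
        return self.t2

    @property
    def gaps(self) -> tuple[int, int, int]:
        return (self.c2 - self.c1 - 1, self.t1 - self.c2 - 1, self.t2 - self.t1 - 1)

    @property
    def h_gap(self) -> int:
        """Residues between the two terminal coordinating residues."""
        return self.t2 - self.t1 - 1

    @property
    def canonical(self) -> bool:
        return self.terminal_types == ("H", "H")


@dataclass
class FingerArray:
    """A maximal run of tandem-linked fingers (indices into the scan order)."""

    member_fingers: list[int]
    linkers: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.member_fingers)


def finger_signature(f: ZincFinger) -> str:
    """Compact spacing notation, e.g. ``CX2CX12HX3H``."""
    a, b, c = f.gaps
    t1, t2 = f.terminal_types
    return f"CX{a}CX{b}{t1}X{c}{t2}"


def parse_signature(signature: str) -> tuple[tuple[int, int, int], tuple[str, str]]:
    """Parse ``CX{a}CX{b}{T1}X{c}{T2}`` into (gaps, terminal letters)."""
    m = re.fullmatch(r"CX(\d+)CX(\d+)([A-Z])X(\d+)([A-Z])", signature)
    if m is None:
        raise ValueError(f"unparsable finger signature {signature!r}")
    a, b, t1, c, t2 = m.groups()
    return (int(a), int(b), int(c)), (t1, t2)


def _matches_at(seq: str, i: int, grammar: FingerGrammar) -> list[ZincFinger]:
    """All grammar-compatible fingers whose first cysteine is seq[i] (0-based)."""
    out: list[ZincFinger] = []
    if seq[i] != "C":
        return out
    n = len(seq)
    for a in range(grammar.pair1_gap_range[0], grammar.pair1_gap_range[1] + 1):
        c2 = i + a + 1
        if c2 >= n or seq[c2] != "C":
            continue
        for b in range(grammar.inner_gap_range[0], grammar.inner_gap_range[1] + 1):
            t1 = c2 + b + 1
            if t1 >= n or seq[t1] not in grammar.terminal_alphabet:
                continue
            for c in range(grammar.pair2_gap_range[0], grammar.pair2_gap_range[1] + 1):
                t2 = t1 + c + 1
                if t2 >= n or seq[t2] not in grammar.terminal_alphabet:
                    continue
                if grammar.require_histidine and "H" not in (seq[t1], seq[t2]):
                    continue
                out.append(
                    ZincFinger(
                        c1=i + 1,
                        c2=c2 + 1,
                        t1=t1 + 1,
                        t2=t2 + 1,
                        terminal_types=(seq[t1], seq[t2]),
                        helix=seq[c2 + 1 : t1],
                    )
                )
    return out


def _selection_key(f: ZincFinger) -> tuple:
    # canonical (H,H) preferred, then shortest span, then smallest gaps
    return (not f.canonical, f.end - f.start, f.gaps)


def scan_fingers(
    protein: ProteinRecord | str, grammar: FingerGrammar = DEFAULT_GRAMMAR
) -> list[ZincFinger]:
    """Detect fingers left to right, non-overlapping.

    At the leftmost position admitting any parse, the canonical
    (H,H)-terminated parse is preferred, then the shortest; scanning
    resumes after the emitted finger.  Deterministic; returns an empty
    list when nothing matches.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else str(protein).upper()
    fingers: list[ZincFinger] = []
    i = 0
    n = len(seq)
    while i < n:
        candidates = _matches_at(seq, i, grammar)
        if candidates:
            best = min(candidates, key=_selection_key)
            fingers.append(best)
            i = best.t2  # 1-based end == 0-based index after the finger
        else:
            i += 1
    return fingers


def group_arrays(
    fingers: list[ZincFinger], tandem_threshold: int = TANDEM_THRESHOLD
) -> tuple[list[FingerArray], list[int]]:
    """Group ordered fingers into tandem arrays by linker length.

    The linker is the residue count strictly between the last
    coordinating residue of one finger and the first cysteine of the
    next; consecutive fingers with linker <= ``tandem_threshold`` merge
    transitively.  Returns ``(arrays, isolated)`` where arrays have >= 2
    members and ``isolated`` lists indices of single fingers.
    """
    for left, right in zip(fingers, fingers[1:]):
        if right.c1 <= left.t2:
            raise ValueError(
                f"overlapping fingers at positions {left.c1}-{left.t2} and "
                f"{right.c1}-{right.t2}"
            )
    runs: list[FingerArray] = []
    current = FingerArray(member_fingers=[0]) if fingers else None
    for idx in range(1, len(fingers)):
        linker = fingers[idx].c1 - fingers[idx - 1].t2 - 1
        if linker <= tandem_threshold:
            current.member_fingers.append(idx)
            current.linkers.append(linker)
        else:
            runs.append(current)
            current = FingerArray(member_fingers=[idx])
    if current is not None:
        runs.append(current)
    arrays = [r for r in runs if len(r) >= 2]
    isolated = [r.member_fingers[0] for r in runs if len(r) == 1]
    return arrays, isolated
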