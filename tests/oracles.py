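"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's scanning/charge code paths: the
finger oracle enumerates residue-index quadruples directly, and the pI
oracle evaluates the Henderson-Hasselbalch net charge from the published
Bjellqvist pKa constants with a plain bisection.
"""

from __future__ import annotations

import math


def enumerate_fingers(
    seq: str,
    pair1=(1, 4),
    inner=(12, 20),
    pair2=(3, 7),
    terminals=frozenset({"H", "C"}),
    require_h=True,
):
    """All grammar-compatible (c1, c2, t1, t2) 0-based index quadruples."""
    n = len(seq)
    cys = [i for i in range(n) if seq[i] == "C"]
    term = [i for i in range(n) if seq[i] in terminals]
    out = []
    for p in cys:
        for q in cys:
            if not pair1[0] <= q - p - 1 <= pair1[1]:
                continue
            for r in term:
                if not inner[0] <= r - q - 1 <= inner[1]:
                    continue
                for s in term:
                    if not pair2[0] <= s - r - 1 <= pair2[1]:
                        continue
                    if require_h and "H" not in (seq[r], seq[s]):
                        continue
                    out.append((p, q, r, s))
    return out


def greedy_select(seq: str, quadruples):
    """Leftmost-first, canonical-preferred, then shortest selection."""
    chosen = []
    pos = 0
    remaining = sorted(quadruples)
    while True:
        live = [q for q in remaining if q[0] >= pos]
        if not live:
            break
        first = min(q[0] for q in live)
        at_first = [q for q in live if q[0] == first]

        def key(q):
            p, a, r, s = q
            canonical = seq[r] == "H" and seq[s] == "H"
            gaps = (a - p - 1, r - a - 1, s - r - 1)
            return (not canonical, s - p, gaps)

        best = min(at_first, key=key)
        chosen.append(best)
        pos = best[3] + 1
    return chosen


def brute_force_scan(seq: str, **grammar_kwargs):
    """Expected (c1, c2, t1, t2) quadruples, 1-based, for comparison."""
    quads = enumerate_fingers(seq, **grammar_kwargs)
    return [tuple(i + 1 for i in q) for q in greedy_select(seq, quads)]


# published Bjellqvist/ExPASy pKa constants, including the residue-specific
# terminal refinements from the 1993/1994 focusing-position papers
_POSITIVE_PKA = {"K": 10.0, "R": 12.0, "H": 5.98}
_NEGATIVE_PKA = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_NTERM_PKA = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44,
              "E": 7.7}
_CTERM_PKA = {"D": 4.55, "E": 4.75}


def net_charge(seq: str, ph: float) -> float:
    nterm_pka = _NTERM_PKA.get(seq[0], 7.5)
    cterm_pka = _CTERM_PKA.get(seq[-1], 3.55)
    pos = 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    for aa, pka in _POSITIVE_PKA.items():
        pos += seq.count(aa) / (1.0 + 10 ** (ph - pka))
    neg = 1.0 / (1.0 + 10 ** (cterm_pka - ph))
    for aa, pka in _NEGATIVE_PKA.items():
        neg += seq.count(aa) / (1.0 + 10 ** (pka - ph))
    return pos - neg


def bisect_pi(seq: str, tol: float = 1e-4) -> float:
    lo, hi = 0.0, 14.0
    assert net_charge(seq, lo) > 0 and net_charge(seq, hi) < 0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def pearson_r(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return sxy / (sx * sy)
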