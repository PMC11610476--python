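"""Water-stress panel statistics.

Enzyme/metabolite panels (SOD, POD, CAT activities; MDA, H2O2, proline
contents) measured in replicate under watering treatments (control CK
and light/moderate/severe stress LS/MS/SS) are summarised as mean +/-
sample sd, compared to control as signed percent change, grouped by a
compact letter display (one-way ANOVA followed by Tukey HSD), and
correlated with gene expression (Pearson r with two-sided t-test).
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PANEL_COLUMNS",
    "CorrelationResult",
    "read_panel",
    "summarize_panel",
    "percent_change",
    "significance_letters",
    "correlate_expression",
    "benjamini_hochberg",
]

PANEL_COLUMNS = ("treatment", "replicate", "analyte", "value")


@dataclass(frozen=True)
class CorrelationResult:
    a: str
    b: str
    r: float
    p: float | None
    n: int
    significant: bool

    def __post_init__(self) -> None:
        if not np.isnan(self.r) and not -1.0 <= round(self.r, 9) <= 1.0:
            raise ValueError("Pearson r outside [-1, 1]")
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def read_panel(path) -> pd.DataFrame:
    """Read a long-format panel CSV (treatment, replicate, analyte, value)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: panel file lacks columns {sorted(missing)}")
    return df


def summarize_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample sd (n-1 denominator) per (treatment, analyte).

    Single-replicate cells get mean only, with sd reported as NaN and a
    warning.
    """
    grouped = panel.groupby(["analyte", "treatment"])["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    singles = out[out["n"] < 2]
    for _, row in singles.iterrows():
        warnings.warn(
            f"single replicate for ({row['treatment']}, {row['analyte']}); "
            "sd unavailable",
            stacklevel=2,
        )
    return out


def percent_change(treated_mean: float, control_mean: float) -> float:
    """Signed percent change of a treatment mean vs the control mean,
    100 x (treated - control) / control, rounded to 2 decimals."""
    if control_mean == 0:
        raise ZeroDivisionError("control mean is zero; percent change undefined")
    return round(100.0 * (treated_mean - control_mean) / control_mean, 2)


def _compact_letters(
    treatments: list[str],
    means: dict[str, float],
    nonsig_pairs: set[frozenset[str]],
) -> dict[str, str]:
    """Compact letter display from the graph of non-significant pairs.

    Each maximal clique of mutually non-different treatments gets one
    letter; letters are issued in descending order of the clique's best
    mean so the largest-mean group always carries 'a'.
    """
    graph = nx.Graph()
    graph.add_nodes_from(treatments)
    graph.add_edges_from(tuple(p) for p in nonsig_pairs if len(p) == 2)
    cliques = list(nx.find_cliques(graph))
    cliques.sort(key=lambda c: (-max(means[t] for t in c), sorted(c)))
    letters: dict[str, list[str]] = {t: [] for t in treatments}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for t in clique:
            letters[t].append(letter)
    return {t: "".join(sorted(v)) for t, v in letters.items()}


def significance_letters(
    panel: pd.DataFrame, analyte: str, alpha: float = 0.05
) -> dict[str, str]:
    """Letter groups for one analyte: treatments sharing no letter
    differ significantly (one-way ANOVA, then pairwise Tukey HSD at
    ``alpha``); the highest mean is lettered 'a'."""
    sub = panel[panel["analyte"] == analyte]
    if sub.empty:
        raise ValueError(f"analyte {analyte!r} absent from panel")
    groups = {t: g["value"].to_numpy(float) for t, g in sub.groupby("treatment")}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("significance letters need >= 2 replicates per treatment")
    treatments = sorted(groups, key=lambda t: -groups[t].mean())
    means = {t: float(groups[t].mean()) for t in treatments}
    samples = [groups[t] for t in treatments]
    if all(v.std(ddof=1) == 0 for v in samples):
        warnings.warn(
            f"{analyte}: zero within-group variance; letters assigned by "
            "distinct means",
            stacklevel=2,
        )
        distinct = sorted({means[t] for t in treatments}, reverse=True)
        letter_of = dict(zip(distinct, string.ascii_lowercase))
        return {t: letter_of[means[t]] for t in treatments}
    _, anova_p = stats.f_oneway(*samples)
    if anova_p >= alpha:
        return {t: "a" for t in treatments}
    tukey = stats.tukey_hsd(*samples)
    nonsig: set[frozenset[str]] = set()
    for i, j in itertools.combinations(range(len(treatments)), 2):
        if tukey.pvalue[i, j] >= alpha:
            nonsig.add(frozenset({treatments[i], treatments[j]}))
    return _compact_letters(treatments, means, nonsig)


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted.tolist()


def correlate_expression(
    expr: pd.DataFrame,
    physio: pd.DataFrame,
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[CorrelationResult]:
    """Pearson correlation of each gene with each analyte, and between
    analytes, over matched sample columns.

    ``expr`` is genes x samples (original FPKM scale), ``physio`` is
    analytes x samples on the same column labels (treatment means or
    per-replicate values).  Pairs with n < 3 are emitted with p absent
    and a warning.  With ``adjust`` the significance flag uses
    Benjamini-Hochberg adjusted p-values.
    """
    common = [c for c in expr.columns if c in physio.columns]
    if not common:
        raise ValueError("no matching sample labels between expression and physiology")
    e = expr[common]
    ph = physio[common]
    pairs: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    for gene in e.index:
        for analyte in ph.index:
            pairs.append((str(gene), str(analyte), e.loc[gene].to_numpy(float),
                          ph.loc[analyte].to_numpy(float)))
    for a1, a2 in itertools.combinations(list(ph.index), 2):
        pairs.append((str(a1), str(a2), ph.loc[a1].to_numpy(float),
                      ph.loc[a2].to_numpy(float)))

    results: list[tuple[str, str, float, float | None, int]] = []
    for a, b, x, y in pairs:
        n = len(common)
        if n < 3:
            warnings.warn(f"({a}, {b}): n={n} < 3, p-value unavailable", stacklevel=2)
            r = float(np.corrcoef(x, y)[0, 1]) if n == 2 else float("nan")
            results.append((a, b, r, None, n))
            continue
        r, p = stats.pearsonr(x, y)
        results.append((a, b, float(r), float(p), n))

    ps = [p for *_, p, _ in results if p is not None]
    if adjust and ps:
        adj = iter(benjamini_hochberg(ps))
        flags = [next(adj) < alpha if p is not None else False for *_, p, _ in results]
    else:
        flags = [p is not None and p < alpha for *_, p, _ in results]
    return [
        CorrelationResult(a=a, b=b, r=r, p=p, n=n, significant=flag)
        for (a, b, r, p, n), flag in zip(results, flags)
    ]
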