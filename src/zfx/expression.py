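"""Expression-matrix processing and qPCR fold changes.

FPKM matrices (genes x conditions, e.g. the fruit development stages
Y/EN/WM/HR/FR or the water-stress treatments CK/LS/MS/SS) are filtered
for expressed genes (max FPKM strictly above a threshold), transformed
as log2(FPKM + 1), and clustered into k expression-profile groups by
hierarchical clustering (correlation distance, average linkage) on
per-gene z-scores.  qPCR relative expression uses the 2^-ddCt rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ProfileGrouping",
    "QpcrMeasurement",
    "read_matrix",
    "filter_expressed",
    "log2_transform",
    "zscore_rows",
    "cluster_profiles",
    "ddct_fold_change",
]


@dataclass
class ProfileGrouping:
    """Gene -> profile-group assignment plus the linkage used to get it."""

    labels: dict[str, str]
    k: int
    method: str
    metric: str
    linkage: np.ndarray = field(repr=False, default=None)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, lab in self.labels.items():
            out.setdefault(lab, []).append(gene)
        return out


@dataclass(frozen=True)
class QpcrMeasurement:
    sample: str
    target_ct: float
    reference_ct: float
    calibrator: bool = False

    def __post_init__(self) -> None:
        if self.target_ct <= 0 or self.reference_ct <= 0:
            raise ValueError("Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def read_matrix(path) -> pd.DataFrame:
    """Read a genes-x-samples delimited matrix (first column = gene id)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    if df.columns.duplicated().any() or df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene or condition labels")
    return df


def filter_expressed(matrix: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Keep genes whose maximum FPKM over conditions is strictly above
    ``threshold`` (a gene expressed in any condition is kept)."""
    return matrix.loc[matrix.max(axis=1) > threshold]


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(FPKM + 1); order-preserving, zeros map to zero."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return np.log2(matrix + 1.0)


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-scores; constant rows are left at zero and reported."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = sd.ravel() == 0
    sd[constant] = 1.0
    z = (values - mean) / sd
    flagged = list(matrix.index[constant])
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged


def cluster_profiles(
    matrix: pd.DataFrame,
    k: int = 7,
    label_prefix: str = "g",
    method: str = "average",
    metric: str = "correlation",
) -> ProfileGrouping:
    """Cut a hierarchical clustering of per-gene profiles into k groups.

    Rows are z-scored; constant (zero-variance) rows are set aside with
    a warning and assigned afterwards to the nearest group centroid.
    Groups are labelled ``<prefix>1 .. <prefix>k`` ordered by the peak
    position of their mean profile (earliest-peaking group first, ties
    broken by descending group size then first-gene order).  The
    procedure is fully deterministic.
    """
    if len(matrix) < k:
        raise ValueError(f"need at least k={k} genes, got {len(matrix)}")
    z, constant_genes = zscore_rows(matrix)
    if constant_genes:
        warnings.warn(
            f"{len(constant_genes)} constant expression row(s) assigned by "
            "nearest centroid: " + ", ".join(map(str, constant_genes[:5])),
            stacklevel=2,
        )
    variable = z.drop(index=constant_genes)
    if len(variable) < k:
        raise ValueError("fewer variable genes than requested groups")
    dist = pdist(variable.to_numpy(), metric=metric)
    linkage = hierarchy.linkage(dist, method=method)
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    clusters: dict[int, list[str]] = {}
    for gene, cid in zip(variable.index, flat):
        clusters.setdefault(int(cid), []).append(gene)

    # order clusters by mean-profile peak position
    order = []
    for cid, genes in clusters.items():
        prof = variable.loc[genes].mean(axis=0).to_numpy()
        order.append((int(np.argmax(prof)), -len(genes), min(
            matrix.index.get_loc(g) for g in genes), cid))
    order.sort()
    label_of = {cid: f"{label_prefix}{rank}" for rank, (_, _, _, cid) in enumerate(order, 1)}

    labels = {gene: label_of[int(cid)] for gene, cid in zip(variable.index, flat)}

    if constant_genes:
        centroids = {
            cid: variable.loc[genes].mean(axis=0).to_numpy()
            for cid, genes in clusters.items()
        }
        for gene in constant_genes:
            row = z.loc[gene].to_numpy()
            best = min(
                sorted(centroids),
                key=lambda cid: float(np.linalg.norm(row - centroids[cid])),
            )
            labels[gene] = label_of[best]

    labels = {gene: labels[gene] for gene in matrix.index}
    return ProfileGrouping(labels=labels, k=k, method=method, metric=metric, linkage=linkage)


def ddct_fold_change(treated: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Relative expression 2^-ddCt.

    dCt = target Ct - reference Ct within each sample; ddCt = treated
    dCt - control dCt; the fold change is 2 to the minus ddCt.
    """
    ddct = treated.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))
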