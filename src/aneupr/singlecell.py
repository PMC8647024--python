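"""Single-cell analysis of RIDD target-gene expression.

Cells (with given tumor / macrophage / other labels) are transformed to
log2(TPM/10 + 1), hierarchically clustered with Ward's variance-minimizing
criterion on Euclidean distances over the RIDD target genes, and the
per-cell mean RIDD expression is compared between tumor cells and
macrophages with a two-sided Wilcoxon rank-sum test. ITGB2 and TAPBP are
excluded from the comparison because their expression behaves counter to
degradation by IRE1alpha (RIDD) activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from aneupr.genesets import SC_RIDD_EXCLUDE

CELL_TYPES = ("tumor", "macrophage", "other")


@dataclass
class SingleCellMatrix:
    """Cells x genes matrix on the log2(TPM/10 + 1) scale with cell-type labels."""

    values: pd.DataFrame  # cells x genes
    cell_types: pd.Series  # cell id -> label

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate cell ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("transformed expression must be >= 0")
        labels = self.cell_types.reindex(self.values.index)
        bad = sorted(set(labels.dropna().unique()) - set(CELL_TYPES))
        if bad:
            raise ValueError(f"unknown cell type labels {bad}")
        object.__setattr__(self, "cell_types", labels)

    def cells_of(self, label: str) -> list[str]:
        return self.cell_types.index[self.cell_types == label].tolist()


def sc_transform(tpm: pd.DataFrame, cell_types: pd.Series) -> SingleCellMatrix:
    """Transform a cells x genes TPM matrix to log2(TPM/10 + 1)."""
    mat = tpm.astype(float)
    if (mat.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    return SingleCellMatrix(values=np.log2(mat / 10.0 + 1.0), cell_types=cell_types)


@dataclass
class WardClustering:
    """Ward linkage over cells: the scipy linkage matrix and the leaf order."""

    linkage: np.ndarray
    leaves: list[str]


def ward_cluster(matrix: SingleCellMatrix) -> WardClustering:
    """Agglomerative Ward clustering of cells on Euclidean distances.

    Deterministic for a given cell order: scipy's linkage breaks distance
    ties by the lexicographically smallest cluster index pair.
    """
    x = matrix.values.to_numpy()
    if x.shape[0] < 2:
        raise ValueError("clustering requires >= 2 cells")
    if not np.isfinite(x).all():
        raise ValueError("missing values in single-cell matrix")
    z = hierarchy.linkage(x, method="ward")
    order = hierarchy.leaves_list(z)
    return WardClustering(
        linkage=z, leaves=[matrix.values.index[i] for i in order]
    )


def first_bipartition(clustering: WardClustering, n_cells: int) -> np.ndarray:
    """0/1 labels from cutting the Ward tree into its two top clusters."""
    return hierarchy.fcluster(clustering.linkage, t=2, criterion="maxclust") - 1


@dataclass
class RiddComparison:
    """Tumor-vs-macrophage comparison of mean RIDD target expression."""

    per_cell_mean: pd.Series
    statistic: float
    p: float
    mean_tumor: float
    mean_macrophage: float


def compare_ridd(
    matrix: SingleCellMatrix,
    exclude: tuple[str, ...] = SC_RIDD_EXCLUDE,
) -> RiddComparison:
    """Compare per-cell mean RIDD expression between tumor cells and macrophages."""
    genes = [g for g in matrix.values.columns if g not in set(exclude)]
    if not genes:
        raise ValueError("all genes excluded; empty feature set")
    tumor = matrix.cells_of("tumor")
    macro = matrix.cells_of("macrophage")
    if not tumor or not macro:
        raise ValueError("both tumor and macrophage populations must be present")
    means = matrix.values[genes].mean(axis=1)
    stat, p = stats.ranksums(means[tumor], means[macro])
    return RiddComparison(
        per_cell_mean=means,
        statistic=float(stat),
        p=float(p),
        mean_tumor=float(means[tumor].mean()),
        mean_macrophage=float(means[macro].mean()),
    )
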