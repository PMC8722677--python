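"""Single-cell QC filtering, normalization and two-group marker detection.

QC rules: cells expressing fewer than 200 genes or carrying fewer than
3,000 UMIs are removed first, then genes detected in fewer than 3 of the
surviving cells.  Marker detection tests only genes detected in at least
``min_pct`` of cells in one of the two groups, scores them with a
two-sided Wilcoxon rank-sum test (exact for small tie-free groups, normal
approximation with tie correction otherwise), and controls FDR with
Benjamini-Hochberg across the tested genes.  Bulk counts are normalized as
log2(TPM + 1).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "QCReport",
    "EmptyMatrixError",
    "qc_filter",
    "lognormalize",
    "find_markers",
    "tpm_log2",
]

log = logging.getLogger(__name__)


class EmptyMatrixError(ValueError):
    """QC removed every cell."""


@dataclass
class CountMatrix:
    """Gene x cell UMI counts with per-cell group labels.

    ``counts`` may be dense or scipy.sparse, shape (n_genes, n_cells),
    integral and non-negative.
    """

    genes: np.ndarray
    cells: np.ndarray
    counts: np.ndarray | sp.spmatrix
    group_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.cells = np.asarray(self.cells)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell ids")
        shape = self.counts.shape
        if shape != (len(self.genes), len(self.cells)):
            raise ValueError("counts shape does not match gene/cell ids")
        dense = self.dense()
        if (dense < 0).any() or not np.allclose(dense, np.round(dense)):
            raise ValueError("counts must be non-negative integers")
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if len(self.group_labels) != len(self.cells):
                raise ValueError("one group label per cell required")

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)


@dataclass
class QCReport:
    """Identities and tallies of QC-removed cells and genes."""

    removed_cells: list[str] = field(default_factory=list)
    removed_genes: list[str] = field(default_factory=list)
    n_cells_in: int = 0
    n_genes_in: int = 0

    @property
    def n_cells_removed(self) -> int:
        return len(self.removed_cells)

    @property
    def n_genes_removed(self) -> int:
        return len(self.removed_genes)


def qc_filter(
    m: CountMatrix,
    min_genes: int = 200,
    min_cells: int = 3,
    min_umi: int = 3000,
) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells, then rarely detected genes.

    Cells with fewer than ``min_genes`` detected genes OR fewer than
    ``min_umi`` total UMIs go first; genes detected in fewer than
    ``min_cells`` of the surviving cells go second.  Boundary semantics are
    strict "fewer than": a cell with exactly 200 genes and a gene in
    exactly 3 cells are retained.
    """
    counts = m.dense()
    genes_per_cell = (counts > 0).sum(axis=0)
    umi_per_cell = counts.sum(axis=0)
    keep_cells = (genes_per_cell >= min_genes) & (umi_per_cell >= min_umi)
    if not keep_cells.any():
        raise EmptyMatrixError("QC removed every cell")
    sub = counts[:, keep_cells]
    cells_per_gene = (sub > 0).sum(axis=1)
    keep_genes = cells_per_gene >= min_cells
    out = CountMatrix(
        genes=m.genes[keep_genes],
        cells=m.cells[keep_cells],
        counts=sub[keep_genes, :],
        group_labels=None if m.group_labels is None
        else m.group_labels[keep_cells],
    )
    report = QCReport(
        removed_cells=list(m.cells[~keep_cells]),
        removed_genes=list(m.genes[~keep_genes]),
        n_cells_in=len(m.cells),
        n_genes_in=len(m.genes),
    )
    return out, report


def lognormalize(m: CountMatrix, scale: float = 10000.0) -> np.ndarray:
    """Library-size normalization: ln(1 + scale * count / cell_total)."""
    counts = m.dense().astype(float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-total cell (run qc_filter first)")
    return np.log1p(scale * counts / totals)


_PERM_LIMIT = 20000  # max label assignments for full enumeration


def _perm_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating every group labeling.

    Works with ties (midranks); two-sided p doubles the smaller tail
    probability including the observed statistic, capped at 1.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = a.size
    obs = ranks[:n1].sum()
    sums = np.array([ranks[list(idx)].sum()
                     for idx in itertools.combinations(range(pooled.size),
                                                       n1)])
    tol = 1e-9
    p_le = np.mean(sums <= obs + tol)
    p_ge = np.mean(sums >= obs - tol)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p.

    Small groups (all labelings enumerable) get the exact permutation
    distribution, tie-free groups of <= 25 the exact rank-sum distribution;
    everything else the normal approximation with tie correction.
    """
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # all-ties convention
    if math.comb(a.size + b.size, a.size) <= _PERM_LIMIT:
        return _perm_ranksum_p(a, b)
    exact_ok = (a.size <= 25 and b.size <= 25
                and np.unique(np.concatenate([a, b])).size == a.size + b.size)
    method = "exact" if exact_ok else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def find_markers(
    norm: np.ndarray,
    group_labels: np.ndarray,
    min_pct: float = 0.3,
    logfc_threshold: float = 0.0,
    eps: float = 1e-9,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Two-group Wilcoxon marker table on log-normalized expression.

    Genes are tested only when detected in at least ``min_pct`` of cells in
    one group.  ``avg_log2FC`` is log2 of the ratio of de-logged group
    means (expm1 of the normalized values) with additive ``eps``; positive
    values mark group-1 genes, negative group-2.  ``p_adj`` is
    Benjamini-Hochberg across the tested genes; rows are sorted by p.

    ``norm`` must be indexable as (n_genes, n_cells); pass a
    pandas DataFrame to keep gene names, else rows are numbered.
    """
    if isinstance(norm, pd.DataFrame):
        gene_names = norm.index.to_numpy()
        values = norm.to_numpy(dtype=float)
    else:
        values = np.asarray(norm, dtype=float)
        gene_names = np.arange(values.shape[0])
    labels = np.asarray(group_labels)
    uniq = pd.unique(labels) if groups is None else np.asarray(groups)
    if len(uniq) != 2 or not set(uniq) == set(pd.unique(labels)):
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    in1 = labels == uniq[0]
    in2 = labels == uniq[1]
    if in1.sum() < 3 or in2.sum() < 3:
        raise ValueError("each group needs >= 3 cells")

    x1, x2 = values[:, in1], values[:, in2]
    pct1 = (x1 > 0).mean(axis=1)
    pct2 = (x2 > 0).mean(axis=1)
    mean1 = np.expm1(x1).mean(axis=1)
    mean2 = np.expm1(x2).mean(axis=1)
    lfc = np.log2((mean1 + eps) / (mean2 + eps))
    testable = np.nonzero(
        ((pct1 >= min_pct) | (pct2 >= min_pct))
        & (np.abs(lfc) >= logfc_threshold)
    )[0]

    pvals = np.array([_wilcoxon_p(x1[i], x2[i]) for i in testable])
    if pvals.size:
        p_adj = multipletests(pvals, method="fdr_bh")[1]
    else:
        p_adj = pvals
    table = pd.DataFrame({
        "gene": gene_names[testable],
        "avg_log2FC": lfc[testable],
        "pct_1": pct1[testable],
        "pct_2": pct2[testable],
        "p": pvals,
        "p_adj": p_adj,
    }).sort_values("p", kind="stable").reset_index(drop=True)
    return table


def tpm_log2(
    counts: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    """log2(TPM + 1) for one bulk sample.

    TPM = 1e6 * (count/length) / sum(count/length); the pre-log TPM vector
    sums to 1e6.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    return np.log2(1e6 * rate / total + 1.0)
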