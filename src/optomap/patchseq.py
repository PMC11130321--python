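"""Patch-seq quality control, marker panels, gene gating and DEG calls.

The two-stage cell QC removes (1) cells whose library size is below the
depth floor (500 counts), then (2) cells whose summed log2(x+1) expression
of the three GABAergic markers (Slc32a1, Gad1, Gad2) exceeds the
contamination ceiling (7). Gene gating keeps genes "expressed" (count ≥ 5)
in at least 10 passing cells. Differential expression is thresholded at
q < 0.05 and fold-change > 2 (|log2FC| > 1); the bundled test engine is a
two-sided rank-sum with Benjamini–Hochberg adjustment, and externally
computed (log2FC, q) tables can be fed straight into :func:`call_degs`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "QCReport",
    "DEGTable",
    "INHIBITORY_MARKERS",
    "log_transform",
    "qc_cells",
    "gene_gate",
    "marker_panel_summary",
    "de_test",
    "call_degs",
]

INHIBITORY_MARKERS = ("Slc32a1", "Gad1", "Gad2")
DEPTH_FLOOR = 500
MARKER_CEILING = 7.0
DEG_Q_MAX = 0.05
DEG_FC_MIN = 2.0


@dataclass
class CountMatrix:
    """Genes × cells raw-count matrix with optional class labels."""

    counts: pd.DataFrame                 # genes × cells, nonnegative ints
    labels: pd.Series | None = None      # per-cell class label

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("gene names and cell ids must be unique")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.counts.columns)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    def subset_cells(self, cells) -> "CountMatrix":
        labels = self.labels.loc[cells] if self.labels is not None else None
        return CountMatrix(self.counts.loc[:, cells], labels)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.labels)


@dataclass
class QCReport:
    """Per-cell QC verdicts: pass | fail_low_depth | fail_inhibitory."""

    table: pd.DataFrame     # total_counts, inhibitory_marker_log2_sum, verdict
    depth_floor: int
    marker_ceiling: float
    inhibitory_markers: tuple[str, ...]

    @property
    def passing_cells(self) -> pd.Index:
        return self.table.index[self.table["verdict"] == "pass"]

    @property
    def n_pass(self) -> int:
        return int((self.table["verdict"] == "pass").sum())


@dataclass
class DEGTable:
    """Per-gene DE calls: up_a | up_b | not_de, with thresholds used."""

    table: pd.DataFrame      # log2fc, q_value, call
    q_max: float
    fc_min: float
    class_a: str | None = None
    class_b: str | None = None
    orientation_note: str = field(
        default="log2FC is class A over class B", repr=False)


def log_transform(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1)."""
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative entries")
    return np.log2(counts + 1.0)


def qc_cells(
    matrix: CountMatrix,
    inhibitory_markers: tuple[str, ...] = INHIBITORY_MARKERS,
    depth_floor: int = DEPTH_FLOOR,
    marker_ceiling: float = MARKER_CEILING,
) -> QCReport:
    """Two-stage cell QC: library-size floor, then inhibitory-marker ceiling.

    A cell below the depth floor is ``fail_low_depth`` regardless of its
    marker expression (the low-depth rule takes precedence).
    """
    missing = [g for g in inhibitory_markers if g not in matrix.genes]
    if missing:
        raise ValueError(f"marker genes missing from matrix: {missing}")
    totals = matrix.counts.sum(axis=0)
    inh = np.log2(matrix.counts.loc[list(inhibitory_markers)] + 1.0).sum(axis=0)
    verdict = pd.Series("pass", index=matrix.cells, dtype=object)
    verdict[inh > marker_ceiling] = "fail_inhibitory"
    verdict[totals < depth_floor] = "fail_low_depth"   # precedence
    table = pd.DataFrame({
        "total_counts": totals,
        "inhibitory_marker_log2_sum": inh,
        "verdict": verdict,
    })
    return QCReport(table=table, depth_floor=depth_floor,
                    marker_ceiling=marker_ceiling,
                    inhibitory_markers=tuple(inhibitory_markers))


def gene_gate(matrix: CountMatrix, min_cells: int = 10,
              min_count: int = 5) -> pd.Index:
    """Retain genes with count ≥ ``min_count`` in ≥ ``min_cells`` cells.

    Run on the QC-passing cells.
    """
    expressed_in = (matrix.counts >= min_count).sum(axis=1)
    return matrix.genes[expressed_in >= min_cells]


def marker_panel_summary(matrix: CountMatrix,
                         panels: dict[str, tuple[str, ...]]) -> pd.DataFrame:
    """Per-panel, per-cell mean log2(x+1) expression (panels × cells)."""
    log = log_transform(matrix)
    rows = {}
    for name, genes in panels.items():
        if len(genes) == 0:
            raise ValueError(f"panel {name!r} is empty")
        missing = [g for g in genes if g not in log.index]
        if missing:
            raise ValueError(f"panel {name!r} genes missing: {missing}")
        rows[name] = log.loc[list(genes)].mean(axis=0)
    return pd.DataFrame(rows).T


def de_test(matrix: CountMatrix, labels: pd.Series | None = None,
            class_a: str | None = None,
            class_b: str | None = None) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test on log2(x+1) counts, BH-adjusted.

    Returns a DataFrame (log2fc, p_value, q_value) oriented class A over
    class B: log2FC is the difference of class means of log2(x+1), which
    back-transforms to the fold change of (mean-detransformed + 1)
    pseudocounted expression. This engine is a pluggable default —
    externally computed tables with the same columns feed
    :func:`call_degs` directly.
    """
    if labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValueError("no class labels available")
    labels = labels.reindex(matrix.cells)
    classes = sorted(labels.dropna().unique().tolist())
    if class_a is None or class_b is None:
        if len(classes) != 2:
            raise ValueError("specify class_a and class_b")
        class_a, class_b = classes
    a_cells = labels.index[labels == class_a]
    b_cells = labels.index[labels == class_b]
    if min(len(a_cells), len(b_cells)) < 3:
        raise ValueError("each class needs at least 3 cells")

    log = log_transform(matrix)
    a = log.loc[:, a_cells].to_numpy()
    b = log.loc[:, b_cells].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    pvals = np.ones(log.shape[0])
    for i in range(log.shape[0]):
        ai, bi = a[i], b[i]
        if np.ptp(np.concatenate([ai, bi])) == 0:
            continue  # identical constant gene: p = 1
        pvals[i] = mannwhitneyu(ai, bi, alternative="two-sided").pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"log2fc": log2fc, "p_value": pvals,
                         "q_value": qvals}, index=matrix.genes)


def call_degs(stats: pd.DataFrame, q_max: float = DEG_Q_MAX,
              fc_min: float = DEG_FC_MIN,
              class_a: str | None = None,
              class_b: str | None = None) -> DEGTable:
    """Threshold per-gene (log2FC, q) statistics into DEG calls.

    ``up_a``: q < q_max and log2FC > log2(fc_min); ``up_b``: q < q_max and
    log2FC < −log2(fc_min); otherwise ``not_de``.
    """
    if not {"log2fc", "q_value"}.issubset(stats.columns):
        raise ValueError("stats needs columns log2fc and q_value")
    q = stats["q_value"].to_numpy()
    if np.any((q < 0) | (q > 1) | ~np.isfinite(q)):
        raise ValueError("q values must lie in [0, 1]")
    lfc_min = np.log2(fc_min)
    lfc = stats["log2fc"].to_numpy()
    call = np.where((q < q_max) & (lfc > lfc_min), "up_a",
                    np.where((q < q_max) & (lfc < -lfc_min), "up_b",
                             "not_de"))
    table = stats.copy()
    table["call"] = call
    return DEGTable(table=table, q_max=q_max, fc_min=fc_min,
                    class_a=class_a, class_b=class_b)
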