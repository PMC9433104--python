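"""Single-cell qPCR analysis: Ct transform, QC, differential expression.

A Fluidigm-style run reports one Ct (cycle-threshold) value per gene per
cell.  Expression on a log2 scale is obtained as Et = LOD - Ct, floored at
zero, with the limit of detection (LOD) conventionally at 40 cycles; a
gene that never amplifies is assigned Ct >= LOD and hence zero expression.
Cells carry a migration label (migratory / nonmigratory) assigned from the
time-lapse tracks before retrieval, plus no-cell / no-RT control columns
used for QC only.

Differential expression between the migration groups uses a per-gene
Mann-Whitney U test with Benjamini-Hochberg adjustment across the tested
panel; correlation structure with the continuous migration metric uses
Pearson correlation with a p < 0.05 visibility mask (the "correlogram").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "ExpressionMatrix",
    "ct_to_expression",
    "qc_filter",
    "differential_expression",
    "migration_correlogram",
]


@dataclass
class ExpressionMatrix:
    """genes x cells log2-expression with per-cell metadata.

    ``values`` is a DataFrame indexed by gene, columns are cell ids.
    ``labels`` maps cell id -> {"migratory", "nonmigratory", "control"}.
    ``migration_metric`` (optional) is a continuous per-cell migration
    measurement for correlation analyses.
    """

    values: pd.DataFrame
    labels: pd.Series
    lod_ct: float = 40.0
    migration_metric: pd.Series | None = None

    def cells(self, label: str | None = None) -> pd.Index:
        if label is None:
            return self.values.columns
        return self.labels.index[self.labels == label]

    @property
    def non_control_cells(self) -> pd.Index:
        return self.labels.index[self.labels != "control"]


def ct_to_expression(ct: pd.DataFrame, lod_ct: float = 40.0) -> pd.DataFrame:
    """Transform Ct cycles to log2 expression: max(0, LOD - Ct).

    Missing / undetermined Ct values map to zero expression.
    """
    if lod_ct <= 0:
        raise ValueError("LOD_Ct must be positive")
    expr = (lod_ct - ct).clip(lower=0.0)
    return expr.fillna(0.0)


def qc_filter(
    matrix: ExpressionMatrix,
    min_genes: int = 5,
    control_tolerance: float = 0.0,
) -> tuple[ExpressionMatrix, dict]:
    """Remove low-quality cells and flag contaminated genes.

    A gene is flagged (not removed) if any control column (no-cell or
    no-RT) shows expression above ``control_tolerance``; a non-control
    cell is removed if it expresses fewer than ``min_genes`` genes.
    Returns the filtered matrix and a report of removals/flags.
    """
    values = matrix.values
    controls = matrix.cells("control")
    flagged_genes: list = []
    if len(controls):
        contaminated = (values[controls] > control_tolerance).any(axis=1)
        flagged_genes = list(values.index[contaminated])

    cells = matrix.non_control_cells
    genes_per_cell = (values[cells] > 0).sum(axis=0)
    bad_cells = list(genes_per_cell.index[genes_per_cell < min_genes])
    keep = [c for c in cells if c not in set(bad_cells)]
    if not keep:
        raise ValueError("QC removed every cell; check inputs")

    filtered = ExpressionMatrix(
        values=values[keep].copy(),
        labels=matrix.labels.loc[keep].copy(),
        lod_ct=matrix.lod_ct,
        migration_metric=(
            matrix.migration_metric.loc[keep].copy()
            if matrix.migration_metric is not None
            else None
        ),
    )
    report = {
        "removed_cells": bad_cells,
        "flagged_genes": flagged_genes,
        "n_cells_kept": len(keep),
    }
    return filtered, report


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str = "migratory",
    group_b: str = "nonmigratory",
    fdr: float = 0.1,
    min_cells: int = 30,
) -> pd.DataFrame:
    """Per-gene Mann-Whitney DE between two cell groups with BH FDR.

    Returns a DataFrame indexed by gene with columns ``statistic``, ``p``,
    ``q``, ``direction`` (+1 if group_a median expression higher),
    ``significant`` (q < fdr) and ``flag``.  Constant genes receive p = 1
    by convention and are flagged.
    """
    cells_a = matrix.cells(group_a)
    cells_b = matrix.cells(group_b)
    if len(cells_a) < min_cells or len(cells_b) < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells per group "
            f"(got {len(cells_a)} / {len(cells_b)})"
        )
    rows = []
    for gene, row in matrix.values.iterrows():
        a = row[cells_a].to_numpy(dtype=float)
        b = row[cells_b].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append((gene, float("nan"), 1.0, 0, "constant"))
            continue
        res = _stats.mann_whitney_u(a, b)
        direction = int(np.sign(np.median(a) - np.median(b)))
        rows.append((gene, res.statistic, res.p_two_sided, direction, ""))
    out = pd.DataFrame(
        rows, columns=["gene", "statistic", "p", "direction", "flag"]
    ).set_index("gene")
    out["q"] = _stats.bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out[["statistic", "p", "q", "direction", "significant", "flag"]]


def migration_correlogram(
    matrix: ExpressionMatrix,
    genes=None,
    alpha: float = 0.05,
    migration_name: str = "migration",
) -> pd.DataFrame:
    """Pairwise Pearson correlations of genes and the migration metric.

    Returns a symmetric DataFrame over ``genes + [migration]`` with unit
    diagonal; entries whose two-sided p >= ``alpha`` (or involving a
    zero-variance variable) are masked to NaN.
    """
    if matrix.migration_metric is None:
        raise ValueError("matrix has no per-cell migration metric")
    cells = matrix.non_control_cells
    if genes is None:
        genes = list(matrix.values.index)
    data = {g: matrix.values.loc[g, cells].to_numpy(dtype=float) for g in genes}
    data[migration_name] = matrix.migration_metric.loc[cells].to_numpy(dtype=float)
    names = list(data)
    k = len(names)
    corr = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    for i, a in enumerate(names):
        corr.iloc[i, i] = 1.0
        for j in range(i + 1, k):
            b = names[j]
            res = _stats.correlation(data[a], data[b], method="pearson")
            if "degenerate" in res.flags or res.p_two_sided >= alpha:
                continue
            corr.loc[a, b] = res.statistic
            corr.loc[b, a] = res.statistic
    return corr
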