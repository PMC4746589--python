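"""Expression profiling across a phenological stage design.

FPKM matrices (genes x samples) are log2-transformed with a pseudocount,
thresholded into expressed / not-expressed calls, and screened for
reciprocal (anti-correlated) repressor/activator pairs over the
dormancy-to-bloom window.  qPCR quantification uses the comparative
delta-delta Ct method (fold = 2^-ddCt) and can be checked for concordance
with FPKM-derived fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ExpressionCall:
    gene: str
    expressed: bool
    max_fpkm: float


@dataclass(frozen=True)
class FoldChange:
    dct_test: float
    dct_calibrator: float

    @property
    def ddct(self) -> float:
        return self.dct_test - self.dct_calibrator

    @property
    def fold(self) -> float:
        return float(2.0 ** (-self.ddct))


def log_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """value -> log2(value + pseudocount); rejects negative FPKM."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative FPKM values")
    return pd.DataFrame(
        np.log2(values + pseudocount), index=matrix.index, columns=matrix.columns
    )


def inverse_log_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    return pd.DataFrame(
        2.0 ** matrix.to_numpy(dtype=float) - pseudocount,
        index=matrix.index,
        columns=matrix.columns,
    )


def call_expressed(matrix: pd.DataFrame, threshold: float = 1.0) -> list[ExpressionCall]:
    """A gene is expressed iff FPKM >= threshold in >= 1 sample (>= rule:
    a gene exactly at the threshold counts as expressed)."""
    maxima = matrix.max(axis=1)
    return [
        ExpressionCall(g, bool(maxima[g] >= threshold), float(maxima[g]))
        for g in matrix.index
    ]


def expressed_summary(calls: list[ExpressionCall]) -> dict:
    n = len(calls)
    k = sum(1 for c in calls if c.expressed)
    return {"n_genes": n, "expressed": k, "fraction": k / n if n else 0.0}


def reciprocal_score(
    matrix: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    samples: list[str] | None = None,
    method: str = "pearson",
    cutoff: float = -0.5,
    pseudocount: float = 1.0,
):
    """Correlation of two genes' log profiles over a stage window.

    Computed on log2(FPKM + pseudocount) restricted to ``samples`` (default:
    all columns; the conventional window is the dormancy-to-bloom stages).
    Returns (correlation, reciprocal flag) with reciprocal meaning
    correlation <= ``cutoff``.  Symmetric in the two genes.
    """
    cols = list(samples) if samples is not None else list(matrix.columns)
    if len(cols) < 3:
        raise ValueError("need >= 3 stages in the window")
    a = np.log2(matrix.loc[gene_a, cols].to_numpy(dtype=float) + pseudocount)
    b = np.log2(matrix.loc[gene_b, cols].to_numpy(dtype=float) + pseudocount)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        flat = gene_a if np.ptp(a) == 0 else gene_b
        raise ValueError(f"constant profile for {flat}: correlation undefined")
    if method == "pearson":
        r = float(stats.pearsonr(a, b).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(a, b).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return r, r <= cutoff


def ddct_fold(
    ct_target_test: float,
    ct_reference_test: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> FoldChange:
    """Comparative delta-delta Ct: fold = 2^-(dCt_test - dCt_calibrator).

    dCt is the target Ct minus the internal-control (e.g. GAPDH) Ct in the
    same sample.
    """
    for ct in (ct_target_test, ct_reference_test, ct_target_calibrator, ct_reference_calibrator):
        if not np.isfinite(ct):
            raise ValueError("non-finite Ct value")
    return FoldChange(
        dct_test=ct_target_test - ct_reference_test,
        dct_calibrator=ct_target_calibrator - ct_reference_calibrator,
    )


def concordance(fpkm_folds, qpcr_folds) -> float:
    """Pearson correlation of matched log2 fold changes (>= 3 points)."""
    a = np.log2(np.asarray(list(fpkm_folds), dtype=float))
    b = np.log2(np.asarray(list(qpcr_folds), dtype=float))
    if a.size != b.size:
        raise ValueError("fold-change vectors differ in length")
    if a.size < 3:
        raise ValueError("need >= 3 matched fold changes")
    return float(stats.pearsonr(a, b).statistic)


def heatmap_matrix(
    matrix: pd.DataFrame,
    sample_order: list[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """The log2 matrix exactly as exported for heat-map rendering,
    columns ordered by the stage design."""
    out = log_transform(matrix, pseudocount)
    return out[sample_order] if sample_order is not None else out
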