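"""Expression-side computations: z-scored log expression, group log2
fold changes, methylation-expression correlation with percentile
trimming, and qPCR relative expression (2^-ddCt).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

LOG_PSEUDOCOUNT = 1.0


def zscore_log_expression(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-gene z-scores of log2(RPKM + 1) across samples.

    Rows are genes, columns samples. Standardization uses the sample
    (n-1) standard deviation. Constant genes cannot be standardized:
    their row is all zeros and flagged in the returned boolean Series.

    Returns ``(z_matrix, constant_flags)``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = np.log2(matrix.to_numpy(dtype=float) + LOG_PSEUDOCOUNT)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0.0
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[constant, :] = 0.0
    return (
        pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        pd.Series(constant, index=matrix.index, name="constant"),
    )


def group_log2_fc(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.Series:
    """Per-gene log2 fold change of group B over group A.

    Computed on group means of linear RPKM with a pseudocount of 1:
    log2((mean_B + 1) / (mean_A + 1)). Antisymmetric under swapping the
    groups; a gene at zero in both groups maps to 0.
    """
    a = [s for s in group_a if s in matrix.columns]
    b = [s for s in group_b if s in matrix.columns]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    mean_a = matrix[a].mean(axis=1)
    mean_b = matrix[b].mean(axis=1)
    return np.log2((mean_b + LOG_PSEUDOCOUNT) / (mean_a + LOG_PSEUDOCOUNT)).rename(
        "log2_fc"
    )


def trimmed_indices(values: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Boolean mask keeping values inside the [trim, 1-trim] percentile
    band (inclusive); ``trim_fraction=0`` keeps everything."""
    if trim_fraction == 0:
        return np.ones(len(values), dtype=bool)
    lo = np.quantile(values, trim_fraction)
    hi = np.quantile(values, 1.0 - trim_fraction)
    return (values >= lo) & (values <= hi)


def meth_expr_correlation(
    meth: Sequence[float],
    expr: Sequence[float],
    trim_fraction: float = 0.05,
) -> Tuple[float, int]:
    """Pearson correlation after symmetric percentile trimming.

    Samples falling in the top or bottom ``trim_fraction`` of either
    variable are dropped, then Pearson r is computed on the remainder.
    Returns ``(r, n_used)``.
    """
    x = np.asarray(meth, dtype=float)
    y = np.asarray(expr, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    keep = trimmed_indices(x, trim_fraction) & trimmed_indices(y, trim_fraction)
    xs, ys = x[keep], y[keep]
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} pairs left after trimming; need >= 3")
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("zero variance after trimming")
    r, _ = stats.pearsonr(xs, ys)
    return float(r), int(len(xs))


def correlation_table(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    trim_fraction: float = 0.05,
    log_expression: bool = True,
) -> pd.DataFrame:
    """Per-gene methylation-expression correlation over shared samples.

    ``meth`` is patients x genes, ``expr`` genes x samples; only
    samples present in both are used. Expression enters as
    log2(RPKM + 1) by default.
    """
    shared = [s for s in expr.columns if s in meth.index]
    rows = []
    for gene in expr.index:
        if gene not in meth.columns:
            continue
        m = meth.loc[shared, gene].to_numpy(dtype=float)
        e = expr.loc[gene, shared].to_numpy(dtype=float)
        if log_expression:
            e = np.log2(e + LOG_PSEUDOCOUNT)
        try:
            r, n_used = meth_expr_correlation(m, e, trim_fraction)
        except ValueError:
            r, n_used = float("nan"), 0
        rows.append({"gene_id": gene, "r": r, "n_used": n_used})
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass(frozen=True)
class CtMeasurement:
    """Ct values of target and reference genes under treated and
    control conditions, for one gene/condition pair."""

    gene: str
    condition: str
    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for f in ("ct_target_treated", "ct_ref_treated",
                  "ct_target_control", "ct_ref_control"):
            v = getattr(self, f)
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValueError(f"{self.gene}/{self.condition}: missing or "
                                 f"non-positive Ct value {f}={v}")


def ddct_relative_expression(ct: CtMeasurement) -> float:
    """Relative expression 2^-ddCt.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control).
    """
    ddct = (ct.ct_target_treated - ct.ct_ref_treated) - (
        ct.ct_target_control - ct.ct_ref_control
    )
    return float(2.0 ** (-ddct))


_CT_COLUMNS = ["gene", "condition", "ct_target_treated", "ct_ref_treated",
               "ct_target_control", "ct_ref_control"]


def read_ct_table(path) -> list[CtMeasurement]:
    """Read a qPCR Ct TSV (header: gene condition ct_target_treated
    ct_ref_treated ct_target_control ct_ref_control)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        CtMeasurement(
            gene=str(row["gene"]), condition=str(row["condition"]),
            ct_target_treated=float(row["ct_target_treated"]),
            ct_ref_treated=float(row["ct_ref_treated"]),
            ct_target_control=float(row["ct_target_control"]),
            ct_ref_control=float(row["ct_ref_control"]),
        )
        for _, row in df.iterrows()
    ]


def relative_expression_table(measurements: Sequence[CtMeasurement]) -> pd.DataFrame:
    rows = [
        {"gene": m.gene, "condition": m.condition,
         "relative_expression": ddct_relative_expression(m)}
        for m in measurements
    ]
    return pd.DataFrame(rows)
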