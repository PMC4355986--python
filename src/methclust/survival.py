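"""Gene-cluster survival stratification.

The workflow mirrors a cluster-level prognostic analysis: per-gene
promoter methylation is dichotomized at the third quartile into
high/low methylation (HM/LM) codes; genes of a cluster are screened by
univariate Cox hazard direction and log-rank significance (HR > 1,
log-rank P < 0.3 keeps a gene in the hypermethylation-risk set); each
patient's HM count over the selected genes is reduced to a binary
group by an ROC-selected integer cutoff (Youden's J, aggregated over
bootstrap resamples); and the groups are compared by Kaplan-Meier /
log-rank and a multivariable Cox proportional-hazards model.

Survival fits are delegated to lifelines (Efron tie handling).
"""
from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


class UnevaluableCluster(ValueError):
    """Raised when a cluster yields no usable gene set or group split."""


def dichotomize_q3(matrix: pd.DataFrame) -> pd.DataFrame:
    """Binary HM/LM codes per gene: 1 iff strictly above the gene's Q3.

    The third quartile is the linear-interpolation quantile at position
    0.75*(n-1). Strict inequality guarantees at most 25% of patients
    are HM when values are distinct. Columns are genes, rows patients.
    """
    if len(matrix) < 4:
        raise ValueError("need >= 4 patients to dichotomize at the third quartile")
    if matrix.isna().any().any():
        raise ValueError("methylation matrix contains missing values; impute upstream")
    q3 = matrix.quantile(0.75, axis=0, interpolation="linear")
    return (matrix > q3).astype(int)


@dataclass
class GeneSurvivalStat:
    gene_id: str
    hazard_ratio: float
    logrank_p: float
    n_hm: int
    n_lm: int
    evaluable: bool = True


def per_gene_survival(
    hm_codes: Sequence[int],
    times: Sequence[float],
    events: Sequence[int],
    gene_id: str = "",
) -> GeneSurvivalStat:
    """Univariate Cox HR (HM vs LM) and two-group log-rank p for one gene."""
    hm = np.asarray(hm_codes, dtype=int)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n_hm, n_lm = int(hm.sum()), int((1 - hm).sum())
    if n_hm == 0 or n_lm == 0:
        return GeneSurvivalStat(gene_id, float("nan"), float("nan"),
                                n_hm, n_lm, evaluable=False)
    df = pd.DataFrame({"hm": hm, "t": t, "e": e})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="t", event_col="e",
                    fit_options={"precision": 1e-12})
        hr = float(np.exp(cph.params_["hm"]))
    except ConvergenceError:
        # monotone likelihood (complete separation): report the direction
        hm_events = e[hm == 1]
        lm_events = e[hm == 0]
        hr = float("inf") if hm_events.sum() >= lm_events.sum() else 0.0
    lr = logrank_test(t[hm == 1], t[hm == 0], e[hm == 1], e[hm == 0])
    return GeneSurvivalStat(gene_id, hr, float(lr.p_value), n_hm, n_lm)


def select_cluster_genes(
    stats: Sequence[GeneSurvivalStat], p_threshold: float = 0.3
) -> tuple[list[str], list[str]]:
    """Partition cluster genes by hazard direction and keep the risk set.

    Returns ``(risk_set, protective_set)``: the risk set holds genes
    with HR > 1 and log-rank p below the threshold (borderline genes
    are deliberately retained so they can contribute jointly); the
    complementary HR < 1 subset is reported but unused downstream.
    Raises :class:`UnevaluableCluster` when the risk set is empty.
    """
    risk, protective = [], []
    for s in stats:
        if not s.evaluable or not np.isfinite(s.logrank_p):
            continue
        if s.hazard_ratio > 1 and s.logrank_p < p_threshold:
            risk.append(s.gene_id)
        elif s.hazard_ratio < 1:
            protective.append(s.gene_id)
    if not risk:
        raise UnevaluableCluster("no gene with HR > 1 and log-rank p below threshold")
    return risk, protective


def _youden_best_cutoff(counts: np.ndarray, dead: np.ndarray,
                        candidates: np.ndarray) -> int:
    """Cutoff maximizing J = sens + spec - 1 for classifying dead as
    count >= cutoff; ties resolved toward the smaller cutoff."""
    n_dead = dead.sum()
    n_alive = len(dead) - n_dead
    best_c, best_j = None, -np.inf
    for c in candidates:
        pred = counts >= c
        sens = (pred & dead).sum() / n_dead if n_dead else 0.0
        spec = (~pred & ~dead).sum() / n_alive if n_alive else 0.0
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and
                                  best_c is not None and c < best_c):
            best_c, best_j = int(c), j
    return int(best_c)


def roc_cutoff(
    hm_counts: Sequence[int],
    vital_dead: Sequence[int],
    n_boot: int = 200,
    seed: int = 0,
) -> int:
    """ROC-optimal integer HM-count cutoff, bootstrap-aggregated.

    Candidate cutoffs are the observed HM counts (floored at 1). Each
    bootstrap resample (patients drawn with replacement) picks the
    cutoff maximizing Youden's J for classifying dead patients; the
    final cutoff is the median over resamples (lower median on even
    splits). The median is used rather than the mode because several
    near-equivalent adjacent cutoffs split the vote under a mode,
    letting a strictly worse but distinctive candidate win.
    ``n_boot <= 1`` disables resampling and maximizes J on the full
    sample directly.
    """
    counts = np.asarray(hm_counts, dtype=int)
    dead = np.asarray(vital_dead, dtype=int).astype(bool)
    if dead.all() or not dead.any():
        raise ValueError("need both dead and alive patients for an ROC cutoff")
    candidates = np.unique(np.maximum(counts, 1))
    if n_boot <= 1:
        return _youden_best_cutoff(counts, dead, candidates)
    rng = np.random.default_rng(seed)
    picks = []
    n = len(counts)
    for _ in range(int(n_boot)):
        idx = rng.integers(0, n, size=n)
        d = dead[idx]
        if d.all() or not d.any():
            continue  # degenerate resample carries no ROC information
        picks.append(_youden_best_cutoff(counts[idx], d, candidates))
    if not picks:
        raise ValueError("all bootstrap resamples degenerate")
    picks.sort()
    return int(picks[(len(picks) - 1) // 2])  # lower median


@dataclass
class ClusterStratification:
    """Result of stratifying one cluster's patients by HM count."""

    cluster_id: str
    selected_genes: list[str]
    protective_genes: list[str]
    hm_counts: pd.Series  # per patient
    cutoff: int
    group_high: pd.Series  # bool per patient: hm_count >= cutoff
    logrank_stat: float
    logrank_p: float
    km_curves: Dict[str, pd.DataFrame] = field(default_factory=dict)


def stratify_km_logrank(
    hm_counts: pd.Series,
    cutoff: int,
    times: pd.Series,
    events: pd.Series,
    cluster_id: str = "",
    selected_genes: Optional[list] = None,
    protective_genes: Optional[list] = None,
) -> ClusterStratification:
    """Kaplan-Meier curves and two-group log-rank for high vs low HM count."""
    high = hm_counts >= cutoff
    if high.all() or not high.any():
        raise UnevaluableCluster(
            f"cutoff {cutoff} leaves an empty group; choose a different cutoff"
        )
    lr = logrank_test(times[high], times[~high], events[high], events[~high])
    curves = {}
    for label, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(times[mask], events[mask], label=label)
        curves[label] = km.survival_function_.reset_index().rename(
            columns={"timeline": "time", label: "survival"}
        )
    return ClusterStratification(
        cluster_id=cluster_id,
        selected_genes=list(selected_genes or []),
        protective_genes=list(protective_genes or []),
        hm_counts=hm_counts,
        cutoff=int(cutoff),
        group_high=high,
        logrank_stat=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        km_curves=curves,
    )


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with 95% CIs and Wald p-values."""

    table: pd.DataFrame  # index: covariate; columns: hr, ci_low, ci_high, p
    n: int
    n_events: int
    converged: bool = True
    flags: list[str] = field(default_factory=list)


def cox_fit(
    group: Sequence[int],
    times: Sequence[float],
    events: Sequence[int],
    age: Optional[Sequence[float]] = None,
    grade: Optional[Sequence[int]] = None,
    er_status: Optional[Sequence[str]] = None,
) -> CoxResult:
    """Multivariable Cox PH fit (Efron ties) for the methylation group
    plus optional age, grade and ER covariates.

    Age and grade enter as numeric covariates; ER as binary
    (positive=1) with unknown-status patients excluded. Non-convergence
    and separation are flagged rather than raised.
    """
    data = {"group": np.asarray(group, dtype=float),
            "t": np.asarray(times, dtype=float),
            "e": np.asarray(events, dtype=int)}
    if age is not None:
        data["age"] = np.asarray(age, dtype=float)
    if grade is not None:
        data["grade"] = np.asarray(grade, dtype=float)
    df = pd.DataFrame(data)
    if er_status is not None:
        er = pd.Series(list(er_status))
        df["er_positive"] = (er == "positive").astype(float)
        keep = er.isin(["positive", "negative"]).to_numpy()
        df = df.loc[keep].reset_index(drop=True)
    flags: list[str] = []
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="t", event_col="e",
                    fit_options={"precision": 1e-12})
        converged = True
    except ConvergenceError as exc:
        flags.append(f"non-convergence: {exc}")
        return CoxResult(table=pd.DataFrame(), n=len(df),
                         n_events=int(df["e"].sum()), converged=False, flags=flags)
    summary = cph.summary
    table = pd.DataFrame(
        {
            "hr": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
        }
    )
    if (np.abs(summary["coef"]) > 10).any():
        flags.append("possible monotone likelihood (separation): extreme coefficient")
    return CoxResult(table=table, n=len(df), n_events=int(df["e"].sum()),
                     converged=converged, flags=flags)


def analyze_cluster(
    meth: pd.DataFrame,
    cluster_genes: Sequence[str],
    times: pd.Series,
    events: pd.Series,
    cluster_id: str = "",
    n_boot: int = 200,
    seed: int = 0,
    cutoff_override: Optional[int] = None,
    selection_p: float = 0.3,
    select_genes: bool = True,
) -> ClusterStratification:
    """Full cluster pipeline: Q3 codes -> gene selection -> cutoff -> KM.

    ``cutoff_override`` skips ROC selection (e.g. a fixed cutoff of 1
    groups together every patient hypermethylated in at least one
    selected gene). ``select_genes=False`` keeps the whole cluster
    instead of the HR > 1 / log-rank screen: the screen conditions on
    the same survival data it feeds, so a cluster with no true effect
    is pushed toward significance; recovery evaluations against known
    ground truth should disable it.
    """
    genes = [g for g in cluster_genes if g in meth.columns]
    if not genes:
        raise UnevaluableCluster(f"cluster {cluster_id}: no genes in matrix")
    binary = dichotomize_q3(meth[genes])
    stats = [
        per_gene_survival(binary[g].to_numpy(), times.to_numpy(),
                          events.to_numpy(), gene_id=g)
        for g in genes
    ]
    if select_genes:
        risk, protective = select_cluster_genes(stats, p_threshold=selection_p)
    else:
        risk, protective = list(genes), []
    hm_counts = binary[risk].sum(axis=1)
    if cutoff_override is not None:
        cutoff = int(cutoff_override)
    else:
        cutoff = roc_cutoff(hm_counts.to_numpy(), events.to_numpy(),
                            n_boot=n_boot, seed=seed)
    return stratify_km_logrank(
        hm_counts, cutoff, times, events,
        cluster_id=cluster_id, selected_genes=risk, protective_genes=protective,
    )
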