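"""Group comparison and clinical correlation of network properties.

Two-sample Student's t-tests (pooled variance — the one-factor general
linear model) compare smokers against controls per metric, both on AUC
summaries and along the sparsity grid; Bonferroni controls the family
of planned comparisons (10 global metrics; per nodal metric, the number
of nodes).  Pearson or Spearman correlation relates metrics to clinical
covariates within the smoker group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "two_sample_t",
    "bonferroni",
    "compare_global",
    "compare_nodal",
    "clinical_correlation",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One metric's (or one node-metric pair's) group contrast."""

    metric: str
    t: float
    p: float
    p_bonferroni: float
    m: int
    significant: bool
    node: int | None = None


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int
    x_name: str = ""
    y_name: str = ""


def two_sample_t(
    a: np.ndarray, b: np.ndarray, pooled: bool = True
) -> tuple[float, float]:
    """Two-sample t-test of group a minus group b.

    Pooled-variance Student's t (df = n_a + n_b - 2) by default; Welch
    with ``pooled=False``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if pooled and a.var(ddof=1) + b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p)


def bonferroni(
    p_values: np.ndarray, m: int | None = None, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction: corrected = min(1, m * p); flag at alpha."""
    p_values = np.asarray(p_values, dtype=float)
    family = p_values.size if m is None else int(m)
    if family < p_values.size:
        raise ValueError("correction family smaller than the number of tests")
    corrected = np.minimum(1.0, family * p_values)
    return corrected, corrected < alpha


def _split_groups(groups: list[str] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    # smoker-minus-control orientation when those labels are present
    if set(levels) == {"smoker", "control"}:
        first, second = "smoker", "control"
    else:
        first, second = levels[0], levels[1]
    return groups == first, groups == second


def compare_global(
    auc_table: pd.DataFrame,
    groups: list[str] | np.ndarray,
    m: int = 10,
    alpha: float = 0.05,
    pooled: bool = True,
) -> list[ComparisonResult]:
    """Per-metric group contrast of global-metric AUC values.

    ``auc_table`` has one row per subject and one column per global
    metric; the Bonferroni family defaults to the 10 planned global
    comparisons.
    """
    if auc_table.shape[1] == 0:
        raise ValueError("AUC table has no metric columns")
    in_a, in_b = _split_groups(groups)
    results = []
    raw_p = []
    stats_ = []
    for col in auc_table.columns:
        vals = auc_table[col].to_numpy(dtype=float)
        t, p = two_sample_t(vals[in_a], vals[in_b], pooled=pooled)
        raw_p.append(p)
        stats_.append(t)
    corrected, flags = bonferroni(np.array(raw_p), m=max(m, len(raw_p)), alpha=alpha)
    for col, t, p, pc, sig in zip(auc_table.columns, stats_, raw_p, corrected, flags):
        results.append(
            ComparisonResult(
                metric=str(col), t=t, p=p, p_bonferroni=float(pc),
                m=max(m, len(raw_p)), significant=bool(sig),
            )
        )
    return results


def compare_nodal(
    auc_tables: dict[str, np.ndarray],
    groups: list[str] | np.ndarray,
    alpha: float = 0.05,
    pooled: bool = True,
) -> list[ComparisonResult]:
    """Per-node group contrasts, one Bonferroni family per nodal metric.

    ``auc_tables`` maps metric name to a (subjects x nodes) array of
    nodal AUC values; within each metric the correction family is the
    node count.
    """
    in_a, in_b = _split_groups(groups)
    results = []
    for metric, table in auc_tables.items():
        table = np.asarray(table, dtype=float)
        n_nodes = table.shape[1]
        raw = np.empty(n_nodes)
        ts = np.empty(n_nodes)
        for node in range(n_nodes):
            ts[node], raw[node] = two_sample_t(
                table[in_a, node], table[in_b, node], pooled=pooled
            )
        corrected, flags = bonferroni(raw, m=n_nodes, alpha=alpha)
        for node in range(n_nodes):
            results.append(
                ComparisonResult(
                    metric=metric, t=float(ts[node]), p=float(raw[node]),
                    p_bonferroni=float(corrected[node]), m=n_nodes,
                    significant=bool(flags[node]), node=node + 1,
                )
            )
    return results


def clinical_correlation(
    values: np.ndarray,
    covariate: np.ndarray,
    method: str = "pearson",
    x_name: str = "metric",
    y_name: str = "covariate",
) -> CorrelationResult:
    """Correlate a per-subject metric with a clinical covariate.

    Pairs with a missing value on either side are dropped; Spearman is
    the rank (tie-corrected) version of the Pearson machinery.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    ok = np.isfinite(values) & np.isfinite(covariate)
    x, y = values[ok], covariate[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has no defined correlation")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        method=method, r=float(r), p=float(p), n=int(x.size),
        x_name=x_name, y_name=y_name,
    )
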