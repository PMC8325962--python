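"""Nested (superplot-style) aggregation and multiple-comparison adjustment.

The figure-level convention implemented here: per-cell values are averaged
within each independent experiment, each experiment contributes one
unweighted point, and the reported statistic is the mean of the experiment
means with a t-based 95% confidence interval across experiments.  Pairwise
p-values are adjusted with the step-down Šidák (Holm–Šidák) procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


@dataclass
class NestedSummary:
    metric_name: str
    experiment_means: List[float]
    grand_mean: float
    ci_half_width_95: float  # NaN when n_experiments == 1
    n_experiments: int


def t_ci_half_width(values: np.ndarray, confidence: float = 0.95) -> float:
    """t-based CI half-width of the mean of ``values``; NaN for n < 2."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        return float("nan")
    q = sps.t.ppf(0.5 + confidence / 2, n - 1)
    return float(q * np.std(values, ddof=1) / np.sqrt(n))


def nan_mean_ci(values: np.ndarray, axis: int = 0,
                confidence: float = 0.95):
    """Per-position mean, t-based CI half-width and count over non-missing
    samples.  Positions with a single sample get an undefined (NaN) CI."""
    values = np.asarray(values, dtype=float)
    present = ~np.isnan(values)
    n = present.sum(axis=axis)
    n_safe = np.maximum(n, 1)
    total = np.where(present, values, 0.0).sum(axis=axis)
    mean = np.where(n > 0, total / n_safe, np.nan)
    dev2 = np.where(present, (values - np.expand_dims(mean, axis)) ** 2, 0.0)
    ok = n > 1
    var = np.where(ok, dev2.sum(axis=axis) / np.maximum(n - 1, 1), np.nan)
    q = np.full(n.shape, np.nan)
    q[ok] = sps.t.ppf(0.5 + confidence / 2, n[ok] - 1)
    half = q * np.sqrt(var) / np.sqrt(n_safe)
    return mean, half, n


GroupedValues = Union[Dict[str, Sequence[float]], pd.DataFrame]


def nested_summary(
    values: GroupedValues,
    metric_name: str = "metric",
    value_column: str = "value",
    experiment_column: str = "experiment_id",
    pooled: bool = False,
) -> NestedSummary:
    """Mean of per-experiment means with a 95% CI across experiments.

    ``values`` is ``{experiment_id: [per-cell values]}`` or a long DataFrame.
    With ``pooled=True`` all values are pooled into one group instead (the
    per-structure-n convention some analyses use), and the CI is computed
    across the pooled values.
    """
    if isinstance(values, pd.DataFrame):
        groups = {
            k: np.asarray(v[value_column], dtype=float)
            for k, v in values.groupby(experiment_column, sort=False)
        }
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    if not groups:
        raise ValidationError("no experiments supplied")
    for k, v in groups.items():
        if v.size == 0:
            raise ValidationError(f"experiment {k!r} has no values")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"experiment {k!r} has non-finite values")
    if pooled:
        pooled_vals = np.concatenate(list(groups.values()))
        return NestedSummary(
            metric_name=metric_name,
            experiment_means=[float(np.mean(v)) for v in groups.values()],
            grand_mean=float(np.mean(pooled_vals)),
            ci_half_width_95=t_ci_half_width(pooled_vals),
            n_experiments=len(groups),
        )
    means = np.array([np.mean(v) for v in groups.values()], dtype=float)
    return NestedSummary(
        metric_name=metric_name,
        experiment_means=[float(m) for m in means],
        grand_mean=float(np.mean(means)),
        ci_half_width_95=t_ci_half_width(means),
        n_experiments=means.size,
    )


def holm_sidak(
    p_values: Sequence[float], alpha: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Step-down Šidák adjustment.

    Sort the m raw p-values ascending; the i-th (1-based) adjusted value is
    ``max_{j<=i} (1 - (1 - p_(j))^(m - j + 1))`` clamped at 1; rejection when
    the adjusted value is below ``alpha``.  Returns (adjusted p-values,
    reject flags) in the original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-D sequence")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    exponents = m - np.arange(m)  # m, m-1, ..., 1
    adj_sorted = 1.0 - (1.0 - p[order]) ** exponents
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < alpha


def ttest_two_groups(a: Sequence[float], b: Sequence[float]) -> float:
    """Convenience two-sided Student's t-test p-value for two groups."""
    return float(sps.ttest_ind(np.asarray(a, float), np.asarray(b, float)).pvalue)


def anova_oneway(*groups: Sequence[float]) -> float:
    """Convenience one-way ANOVA p-value across groups."""
    return float(sps.f_oneway(*[np.asarray(g, float) for g in groups]).pvalue)
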