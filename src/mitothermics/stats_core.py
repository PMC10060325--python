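"""Group-comparison machinery shared by all analysis stages.

Two-group comparisons are gated on normality: Shapiro-Wilk is run on each
group at alpha = 0.05 and only when both groups pass is an unpaired
two-tailed Student t-test used; otherwise the comparison falls back to the
Mann-Whitney U test.  More than two groups go to one-way ANOVA with Tukey
HSD pairwise contrasts.  Benjamini-Hochberg step-up correction and a simple
Pearson R^2 report round out the toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["GroupComparison", "compare_groups", "bh_fdr", "correlate"]

NORMALITY_ALPHA = 0.05
MIN_N_FOR_GATE = 3


@dataclass
class GroupComparison:
    """Outcome of a gated group comparison.

    ``mean_diff`` (second group minus first) is reported for any two-group
    test; ``ci_low``/``ci_high`` — the two-sided 95% t-interval on the
    difference of means — only for the parametric branch.
    """

    test_name: str                       # "t-test" | "Mann-Whitney" | "ANOVA+Tukey"
    statistic: float
    p: float
    mean_diff: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    normality_p: dict[str, float] = field(default_factory=dict)
    gate_note: str | None = None
    pairwise: pd.DataFrame | None = None  # Tukey table for >2 groups


def _shapiro_gate(groups: Mapping[str, np.ndarray]) -> tuple[bool, dict, str | None]:
    """True when every group passes Shapiro-Wilk at NORMALITY_ALPHA."""
    pvals: dict[str, float] = {}
    for name, vals in groups.items():
        if len(vals) < MIN_N_FOR_GATE:
            return False, pvals, f"group '{name}' below n={MIN_N_FOR_GATE}; nonparametric forced"
        if np.ptp(vals) == 0:
            return False, pvals, f"group '{name}' has zero variance; nonparametric forced"
        pvals[name] = float(stats.shapiro(vals).pvalue)
    ok = all(p >= NORMALITY_ALPHA for p in pvals.values())
    return ok, pvals, None


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    welch: bool = False,
) -> GroupComparison:
    """Normality-gated comparison of two or more groups.

    Two groups: Shapiro-Wilk on each; both pass => unpaired two-tailed
    Student t-test (``welch=True`` switches to Welch), else Mann-Whitney U
    (exact for n <= 8 per group, normal approximation with tie correction
    above).  More than two groups: one-way ANOVA with Tukey HSD.
    """
    arrays = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in arrays.values()):
        raise ValueError("every group needs at least two values")

    if len(arrays) > 2:
        f, p = stats.f_oneway(*arrays.values())
        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
        tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        return GroupComparison("ANOVA+Tukey", float(f), float(p), pairwise=pairwise)

    (name_a, a), (name_b, b) = arrays.items()
    normal, shapiro_p, note = _shapiro_gate(arrays)

    if normal:
        res = stats.ttest_ind(b, a, equal_var=not welch)
        diff = float(np.mean(b) - np.mean(a))
        ci = res.confidence_interval(0.95)
        return GroupComparison(
            "t-test",
            float(res.statistic),
            float(res.pvalue),
            mean_diff=diff,
            ci_low=float(ci.low),
            ci_high=float(ci.high),
            normality_p=shapiro_p,
        )

    diff = float(np.mean(b) - np.mean(a))
    if np.ptp(np.concatenate([a, b])) == 0:
        # fully tied pooled sample: U is at its null mean, no evidence either way
        return GroupComparison(
            "Mann-Whitney", len(a) * len(b) / 2.0, 1.0,
            mean_diff=diff, normality_p=shapiro_p, gate_note=note,
        )
    method = "exact" if max(len(a), len(b)) <= 8 and not _has_ties(a, b) else "asymptotic"
    res = stats.mannwhitneyu(b, a, alternative="two-sided", method=method)
    return GroupComparison(
        "Mann-Whitney",
        float(res.statistic),
        float(res.pvalue),
        mean_diff=diff,
        normality_p=shapiro_p,
        gate_note=note,
    )


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson R^2 and two-sided p for zero slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)
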