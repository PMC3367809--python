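"""Statistical toolkit for sweep analysis.

Mean persistence changes are judged against a baseline parameter set
with the Tukey-Kramer multiple-comparison method (studentized-range
critical intervals, valid for unequal group sizes) at alpha = 0.05.
Sub-group analysis splits parameter sets at a mean-persistence threshold
(20 time steps) and characterizes the high-persistence sub-group:
per-parameter means +/- s.e.m. in both groups with Welch two-sample
p-values, value-frequency tables, and Pearson product-moment
correlations (with p-values for r = 0) between parameter pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def tukey_kramer(groups, baseline=None, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons of group means.

    Parameters
    ----------
    groups : mapping of label -> 1-d sample array
    baseline : label, optional
        Compare every group against this one only; default compares all
        pairs.
    alpha : float
        Family-wise significance level (default 0.05).

    Returns
    -------
    DataFrame with one row per comparison: the mean difference, the
    Tukey-Kramer critical half-width
    ``q_crit * sqrt(MSW/2 * (1/n_i + 1/n_j))``, the studentized-range
    p-value, and the significance flag.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    data = {k: np.asarray(groups[k], dtype=float) for k in labels}
    sizes = {k: v.size for k, v in data.items()}
    if any(n < 2 for n in sizes.values()):
        raise ValueError("every group needs at least two observations")
    k = len(labels)
    n_total = sum(sizes.values())
    df_w = n_total - k
    msw = sum((v.size - 1) * v.var(ddof=1) for v in data.values()) / df_w
    if msw <= 0:
        raise ValueError("zero within-group variance is degenerate for "
                         "the studentized range")
    q_crit = sps.studentized_range.isf(alpha, k, df_w)
    if baseline is not None and baseline not in data:
        raise KeyError(f"baseline {baseline!r} not among the groups")
    pairs = ([(baseline, other) for other in labels if other != baseline]
             if baseline is not None
             else [(a, b) for i, a in enumerate(labels)
                   for b in labels[i + 1:]])
    rows = []
    for a, b in pairs:
        diff = data[b].mean() - data[a].mean()
        se = np.sqrt(msw / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        q = abs(diff) / se
        rows.append({
            "group": b, "reference": a, "diff": diff,
            "halfwidth": q_crit * se,
            "p_value": float(sps.studentized_range.sf(q, k, df_w)),
            "significant": bool(abs(diff) > q_crit * se)})
    return pd.DataFrame(rows)


@dataclass
class SubgroupReport:
    """High- vs low-persistence sub-group comparison."""

    threshold: float
    n_total: int
    n_high: int
    n_low: int
    empty_high: bool
    #: per-parameter: mean_high, sem_high, mean_low, sem_low, welch_p
    parameter_table: pd.DataFrame
    #: parameter -> relative value frequencies in the high group
    frequencies: dict = field(default_factory=dict)
    #: Pearson r between parameter pairs in the high group
    corr: pd.DataFrame | None = None
    #: p-values for the null hypothesis r = 0
    corr_p: pd.DataFrame | None = None

    def __str__(self):
        head = (f"{self.n_high}/{self.n_total} parameter sets at mean "
                f"persistence >= {self.threshold}")
        return head + ("\n" + self.parameter_table.to_string()
                       if not self.empty_high else " (empty high group)")


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def subgroup_analysis(params_df: pd.DataFrame, means,
                      threshold: float = 20.0) -> SubgroupReport:
    """Split parameter sets at ``mean persistence >= threshold`` and
    characterize both groups (see module docstring).

    ``params_df`` holds one numeric-coded row per parameter set (see
    :func:`chainabm.sweep.params_frame`); ``means`` the aligned mean
    persistences.
    """
    means = np.asarray(means, dtype=float)
    if len(params_df) != means.size:
        raise ValueError("params_df and means are not aligned")
    hi = means >= threshold
    high = params_df.loc[hi]
    low = params_df.loc[~hi]
    rows = []
    for col in params_df.columns:
        h = high[col].to_numpy(dtype=float)
        lo = low[col].to_numpy(dtype=float)
        if h.size >= 2 and lo.size >= 2 and (h.var() > 0 or lo.var() > 0):
            p = float(sps.ttest_ind(h, lo, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append({"parameter": col,
                     "mean_high": h.mean() if h.size else float("nan"),
                     "sem_high": _sem(h),
                     "mean_low": lo.mean() if lo.size else float("nan"),
                     "sem_low": _sem(lo),
                     "welch_p": p})
    table = pd.DataFrame(rows).set_index("parameter")
    freqs = {col: high[col].value_counts(normalize=True).sort_index()
             for col in params_df.columns} if hi.any() else {}
    corr = corr_p = None
    if hi.sum() >= 3:
        cols = [c for c in params_df.columns
                if high[c].to_numpy(dtype=float).var() > 0]
        corr = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
        corr_p = pd.DataFrame(np.zeros((len(cols), len(cols))),
                              index=cols, columns=cols)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                r, p = sps.pearsonr(high[a], high[b])
                corr.loc[a, b] = corr.loc[b, a] = float(r)
                corr_p.loc[a, b] = corr_p.loc[b, a] = float(p)
    return SubgroupReport(threshold=float(threshold), n_total=int(means.size),
                          n_high=int(hi.sum()), n_low=int((~hi).sum()),
                          empty_high=not bool(hi.any()),
                          parameter_table=table, frequencies=freqs,
                          corr=corr, corr_p=corr_p)
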