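"""Cohort demographics summary with normality-routed group tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _summarize(vals: np.ndarray, normal: bool) -> str:
    if len(vals) == 0:
        return "n/a"
    if normal:
        return f"{vals.mean():.1f} (+/-{vals.std(ddof=1):.1f})"
    return f"{np.median(vals):.1f} ({vals.min():.1f}-{vals.max():.1f})"


def demographics_report(
    samples: pd.DataFrame,
    group_a: str = "SPMS",
    group_b: str = "RRMS",
    variables: tuple[str, ...] = ("age", "edss", "disease_duration"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group summary of demographic variables with a group-A-vs-B test.

    Variables that pass Shapiro-Wilk normality (p >= alpha in both groups)
    are summarized as mean (+/-SD) and tested with Welch's t-test; otherwise
    median (range) and Mann-Whitney U. Sex uses a chi-squared test.
    """
    groups = list(dict.fromkeys(samples["group"]))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    a_mask = samples["group"] == group_a
    b_mask = samples["group"] == group_b
    for var in variables:
        per_group = {}
        vals_a = samples.loc[a_mask, var].dropna().to_numpy(dtype=float)
        vals_b = samples.loc[b_mask, var].dropna().to_numpy(dtype=float)
        normal = True
        for v in (vals_a, vals_b):
            if len(v) >= 3 and np.unique(v).size > 1:
                if stats.shapiro(v).pvalue < alpha:
                    normal = False
        for g in groups:
            v = samples.loc[samples["group"] == g, var].dropna().to_numpy(dtype=float)
            per_group[g] = _summarize(v, normal)
        if len(vals_a) >= 2 and len(vals_b) >= 2:
            if np.array_equal(np.sort(vals_a), np.sort(vals_b)):
                p, test = 1.0, "identical"
            elif normal:
                p = float(stats.ttest_ind(vals_a, vals_b, equal_var=False).pvalue)
                test = "welch"
            else:
                p = float(stats.mannwhitneyu(vals_a, vals_b,
                                             alternative="two-sided").pvalue)
                test = "mann-whitney"
        else:
            p, test = float("nan"), "n/a"
        rows.append({"variable": var, **per_group, "test": test, "p_value": p})

    # sex: chi-squared on the A-vs-B contingency table
    if "sex" in samples.columns:
        ct = pd.crosstab(samples.loc[a_mask | b_mask, "group"],
                         samples.loc[a_mask | b_mask, "sex"])
        per_group = {}
        for g in groups:
            counts = samples.loc[samples["group"] == g, "sex"].value_counts()
            per_group[g] = f"{counts.get('F', 0)}/{counts.get('M', 0)}"
        if ct.shape == (2, 2) and (ct.to_numpy() > 0).all():
            p = float(stats.chi2_contingency(ct.to_numpy())[1])
        else:
            try:
                p = float(stats.chi2_contingency(ct.to_numpy())[1])
            except ValueError:
                p = float("nan")
        rows.append({"variable": "sex (F/M)", **per_group,
                     "test": "chi-squared", "p_value": p})
    return pd.DataFrame(rows).set_index("variable")
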