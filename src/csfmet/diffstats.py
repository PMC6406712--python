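"""Differential statistics on cross-validated VIP selections.

Selection keeps variables whose CV-averaged VIP is >= 1.0; those are then
described univariately with log2 fold changes, Welch's t-test and
Benjamini-Hochberg FDR across the selected set.
"""

from __future__ import annotations

import math
import re

import numpy as np
import pandas as pd
from scipy import stats


def select_altered(vip_mean: pd.Series, threshold: float = 1.0) -> pd.Series:
    """Variables with mean VIP >= threshold, sorted by VIP descending."""
    sel = vip_mean[vip_mean >= threshold]
    return sel.sort_values(ascending=False)


def log2_fc(matrix: pd.DataFrame, group_a_ids, group_b_ids) -> pd.Series:
    """Per-feature mean(A) - mean(B) on log2 values (positive = up in A)."""
    a = list(group_a_ids)
    b = list(group_b_ids)
    if not a or not b:
        raise ValueError("both contrast groups must be non-empty")
    return matrix[a].mean(axis=1) - matrix[b].mean(axis=1)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    sea, seb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(sea + seb)
    df = (sea + seb) ** 2 / (
        sea ** 2 / (len(a) - 1) + seb ** 2 / (len(b) - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


_ADDUCT_RE = re.compile(r"\[\s*M\s*[+−–-]\s*H\s*\]", flags=re.IGNORECASE)


def canonical_name(name: str) -> str:
    """Collapse adduct variants / footnote marks / case of a metabolite name."""
    s = _ADDUCT_RE.sub("", name)
    s = s.replace("*", "")
    s = re.sub(r"\s*-\s*", "-", s)  # "N6- (x)-y" and "N6-(x)-y" are the same
    s = re.sub(r"\s+", " ", s).strip()
    return s.casefold()


def overlap_altered(names_a, names_b) -> list[str]:
    """Sorted intersection of two altered-metabolite name sets, canonicalized."""
    canon_a = {canonical_name(n) for n in names_a}
    canon_b = {canonical_name(n) for n in names_b}
    return sorted(canon_a & canon_b)


def altered_table(
    matrix: pd.DataFrame,
    group_a_ids,
    group_b_ids,
    vip_mean: pd.Series,
    vip_ci: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    vip_threshold: float = 1.0,
) -> pd.DataFrame:
    """Assemble the altered-metabolite report for one contrast.

    FDR correction is applied over the VIP-selected set only (m = number of
    selected metabolites). Returns one row per selected feature with VIP
    mean/CI, log2 FC, Welch p, FDR and direction.
    """
    selected = select_altered(vip_mean, vip_threshold)
    fc = log2_fc(matrix, group_a_ids, group_b_ids)
    rows = []
    for fid in selected.index:
        vals_a = matrix.loc[fid, list(group_a_ids)].to_numpy(dtype=float)
        vals_b = matrix.loc[fid, list(group_b_ids)].to_numpy(dtype=float)
        _, _, p = welch_t(vals_a, vals_b)
        row = {
            "feature_id": fid,
            "vip_mean": float(selected.loc[fid]),
            "log2_fc": float(fc.loc[fid]),
            "p_value": p,
            "direction": "up" if fc.loc[fid] >= 0 else "down",
        }
        if vip_ci is not None:
            row["vip_ci_lower"] = float(vip_ci.loc[fid, "lower"])
            row["vip_ci_upper"] = float(vip_ci.loc[fid, "upper"])
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.set_index("feature_id")
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    if annotations is not None:
        out = annotations.reindex(out.index).join(out)
    return out
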