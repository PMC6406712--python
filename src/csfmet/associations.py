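"""Spearman associations with clinical measures and row clustering.

Correlations are computed over MS patients only (controls carry no EDSS or
disease duration); per-cell significance is marked at p < 0.05 without
multiplicity adjustment, and metabolite rows are ordered by complete-linkage
hierarchical clustering of their correlation profiles.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

CLINICAL_MEASURES = ("spinal_cord", "third_ventricle", "edss",
                     "disease_duration", "total_t1", "total_t2")

EXACT_P_MAX_N = 9


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks (ties averaged). The
    p-value uses the exact permutation distribution for n <= 9 and the
    t-distribution approximation otherwise. A constant input yields
    (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 paired complete observations")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if rx.std() == 0 or ry.std() == 0:
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_P_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p: fraction of y-rank permutations with
    |rho| >= |rho_obs| (tolerance guards float ties)."""
    n = len(rx)
    perms = np.array(list(permutations(range(n))), dtype=np.intp)
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry.mean()
    denom = math.sqrt((rxc ** 2).sum()) * math.sqrt((ryc[0] ** 2).sum())
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def associate_all(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    measures=CLINICAL_MEASURES,
    groups: tuple[str, ...] = ("RRMS", "SPMS"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Metabolite x measure Spearman correlations over MS patients only.

    ``matrix`` is features x samples (log2); ``samples`` is indexed by
    sample id with a ``group`` column plus the clinical measure columns.
    Returns a long-form frame (feature, measure, rho, p, significant, n).
    """
    ms_ids = [s for s in matrix.columns
              if s in samples.index and samples.loc[s, "group"] in groups]
    rows = []
    for fid in matrix.index:
        mvals = matrix.loc[fid, ms_ids].to_numpy(dtype=float)
        for measure in measures:
            cvals = samples.loc[ms_ids, measure].to_numpy(dtype=float)
            ok = np.isfinite(mvals) & np.isfinite(cvals)
            if ok.sum() < 4:
                rho, p = math.nan, math.nan
            else:
                rho, p = spearman(mvals[ok], cvals[ok])
            rows.append({
                "feature_id": fid, "measure": measure, "rho": rho, "p_value": p,
                "significant": bool(p < alpha) if not math.isnan(p) else False,
                "n": int(ok.sum()),
            })
    return pd.DataFrame(rows)


def association_matrix(assoc_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-form association table to a feature x measure rho grid."""
    return assoc_long.pivot(index="feature_id", columns="measure", values="rho")


def cluster_rows(rho_matrix: pd.DataFrame, method: str = "complete"):
    """Order metabolite rows by hierarchical clustering of rho profiles.

    Euclidean distance between rho vectors, complete linkage by default.
    Returns (ordered row labels, scipy linkage matrix). Rows containing
    undefined correlations are rejected by name.
    """
    if len(rho_matrix) < 2:
        raise ValueError("need >= 2 rows to cluster")
    bad = list(rho_matrix.index[rho_matrix.isna().any(axis=1)])
    if bad:
        raise ValueError(f"rows with undefined correlations: {bad}")
    z = linkage(rho_matrix.to_numpy(dtype=float), method=method, metric="euclidean")
    order = leaves_list(z)
    return [rho_matrix.index[i] for i in order], z


def plot_heatmap(
    assoc_long: pd.DataFrame, path, method: str = "complete"
) -> list[str]:
    """Clustered rho heatmap with significance asterisks; returns row order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rho = association_matrix(assoc_long)
    rho = rho.dropna(axis=0, how="any")
    order, _ = cluster_rows(rho, method=method)
    rho = rho.loc[order]
    sig = assoc_long.pivot(index="feature_id", columns="measure",
                           values="significant").loc[order, rho.columns]
    fig, ax = plt.subplots(figsize=(1.2 * len(rho.columns) + 2,
                                    0.3 * len(rho) + 1.5))
    im = ax.imshow(rho.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(rho.columns)))
    ax.set_xticklabels(rho.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(rho)))
    ax.set_yticklabels(rho.index, fontsize=7)
    for i in range(len(rho)):
        for j in range(len(rho.columns)):
            if bool(sig.iloc[i, j]):
                ax.text(j, i, "*", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return list(rho.index)
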