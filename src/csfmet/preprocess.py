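"""Filtering cascade and normalization for quantified injection tables.

Order of operations (enforced by :func:`run_cascade`): blank-contaminant
filter -> dilution-series correlation filter -> log2 transform -> TIC
outlier removal -> coverage filter -> (library matching happens in the
identification module) -> LOESS drift normalization -> QC CV -> replicate
merging -> albumin-ratio filter -> mean imputation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from csfmet.associations import spearman
from csfmet.tables import FeatureMatrix, FilterReport, InjectionTable


def filter_blank_contaminants(
    table: InjectionTable, blank_ratio_threshold: float = 0.5
) -> tuple[InjectionTable, FilterReport]:
    """Drop features whose mean blank intensity reaches
    ``blank_ratio_threshold`` x their mean QC intensity (missing -> 0)."""
    blanks = table.values_for("blank")
    if blanks.shape[1] == 0:
        raise ValueError(
            "no blank injections present; pass skip_blank_filter=True to run "
            "the cascade without contaminant removal")
    qcs = table.values_for("qc")
    blank_mean = blanks.fillna(0.0).mean(axis=1)
    qc_mean = qcs.fillna(0.0).mean(axis=1)
    removed = blank_mean >= blank_ratio_threshold * qc_mean
    reasons = {fid: f"blank/QC ratio >= {blank_ratio_threshold}"
               for fid in table.intensities.index[removed]}
    out = table.drop_features(list(reasons), "blank_contaminants", reasons)
    return out, out.log[-1]


def filter_dilution_series(
    table: InjectionTable, min_abs_r: float = 0.7
) -> tuple[InjectionTable, FilterReport]:
    """Keep features whose intensity correlates with injection volume.

    Pearson r is computed across the dilution injections with missing
    intensities treated as 0 (absence at low volume is informative). A
    zero-variance (flat) feature has undefined r and is removed.
    """
    dil = table.injections[table.injections["type"] == "dilution"]
    vols = dil["volume"].to_numpy(dtype=float)
    if len(dil) < 3 or len(np.unique(vols)) < 3:
        raise ValueError("need >= 3 dilution injections with distinct volumes")
    vals = table.intensities[dil.index].fillna(0.0).to_numpy(dtype=float)
    vc = vols - vols.mean()
    xc = vals - vals.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1)) * np.sqrt((vc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ vc) / denom
    keep = np.abs(r) >= min_abs_r
    keep &= ~np.isnan(r)
    reasons = {}
    for fid, ok, ri in zip(table.intensities.index, keep, r):
        if not ok:
            why = "flat across dilution series" if np.isnan(ri) else f"|r|={abs(ri):.3f} < {min_abs_r}"
            reasons[fid] = why
    out = table.drop_features(list(reasons), "dilution_series", reasons)
    return out, out.log[-1]


def log2_transform(table: InjectionTable) -> InjectionTable:
    """log2 of positive intensities; zeros and missing stay missing."""
    if table.is_log2:
        raise ValueError("table is already log2 transformed")
    vals = table.intensities.to_numpy(dtype=float)
    if (vals[np.isfinite(vals)] < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    res = table.copy()
    res.intensities = pd.DataFrame(out, index=table.intensities.index,
                                   columns=table.intensities.columns)
    res.is_log2 = True
    res.log.append(FilterReport("log2_transform", table.n_features, table.n_features,
                                table._n_study(), table._n_study()))
    return res


def detect_tic_outliers(
    table: InjectionTable, min_frac: float = 0.6
) -> tuple[InjectionTable, FilterReport]:
    """Remove study injections whose total ion count falls below
    ``min_frac`` of the mean study TIC. TIC uses raw (non-log) intensities;
    QC/blank/dilution injections are never removed."""
    study = table.injections.index[table.injections["type"] == "study"]
    if len(study) < 2:
        raise ValueError("need >= 2 study injections")
    vals = table.intensities[study].to_numpy(dtype=float)
    if table.is_log2:
        vals = 2.0 ** vals
    tic = np.nansum(np.where(np.isnan(vals), 0.0, vals), axis=0)
    mean_tic = tic.mean()
    bad = tic < min_frac * mean_tic
    reasons = {inj: f"TIC {t:.4g} < {min_frac} x mean {mean_tic:.4g}"
               for inj, t, b in zip(study, tic, bad) if b}
    out = table.drop_injections(list(reasons), "tic_outliers", reasons)
    return out, out.log[-1]


def coverage_filter(
    table: InjectionTable, min_coverage: float = 0.75
) -> tuple[InjectionTable, FilterReport]:
    """Keep features observed in at least ``min_coverage`` of study samples."""
    study = table.injections.index[table.injections["type"] == "study"]
    frac = table.intensities[study].notna().mean(axis=1)
    reasons = {fid: f"coverage {f:.3f} < {min_coverage}"
               for fid, f in frac.items() if f < min_coverage}
    out = table.drop_features(list(reasons), "coverage", reasons)
    return out, out.log[-1]


# ---------------------------------------------------------------------------
# LOESS drift normalization
# ---------------------------------------------------------------------------

def _loess_fit_eval(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float) -> np.ndarray:
    """Locally weighted linear regression with tricube weights.

    Fitted on (x, y); evaluated at ``x_eval`` using, for each evaluation
    point, the ``ceil(span * n)`` nearest fit points (minimum 2). Points
    outside the fitted range extrapolate the local line.
    """
    n = len(x)
    k = max(2, int(np.ceil(span * n)))
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="mergesort")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-9)  # keep the farthest point from degenerating
        xw, yw = x[idx], y[idx]
        sw = w.sum()
        xm = (w * xw).sum() / sw
        ym = (w * yw).sum() / sw
        sxx = (w * (xw - xm) ** 2).sum()
        slope = 0.0 if sxx == 0 else (w * (xw - xm) * (yw - ym)).sum() / sxx
        out[i] = ym + slope * (x0 - xm)
    return out


def loess_normalize(table: InjectionTable, span: float = 0.3) -> InjectionTable:
    """Remove injection-order drift using LOESS curves anchored on QCs.

    Per feature, a tricube locally linear fit of QC log2 intensity on
    injection order is evaluated at every injection; the fitted value is
    subtracted and the feature's QC mean added back, so the QC-predicted
    level becomes flat and centered. Features with fewer than 2 observed QC
    values pass through unchanged.
    """
    if not table.is_log2:
        raise ValueError("loess_normalize expects a log2 table")
    qc_ids = table.injections.index[table.injections["type"] == "qc"]
    if len(qc_ids) < 5:
        raise ValueError(
            "need >= 5 QC injections for LOESS normalization; consider a "
            "median-centering fallback (--no-loess)")
    qc_order = table.injections.loc[qc_ids, "order"].to_numpy(dtype=float)
    all_order = table.injections["order"].to_numpy(dtype=float)
    vals = table.intensities.to_numpy(dtype=float).copy()
    qc_pos = [table.intensities.columns.get_loc(c) for c in qc_ids]
    for fi in range(vals.shape[0]):
        yq = vals[fi, qc_pos]
        ok = np.isfinite(yq)
        if ok.sum() < 2:
            continue
        fitted = _loess_fit_eval(qc_order[ok], yq[ok], all_order, span)
        vals[fi, :] = vals[fi, :] - fitted + yq[ok].mean()
    res = table.copy()
    res.intensities = pd.DataFrame(vals, index=table.intensities.index,
                                   columns=table.intensities.columns)
    res.log.append(FilterReport("loess_normalize", table.n_features, table.n_features,
                                table._n_study(), table._n_study()))
    return res


def qc_cv(table: InjectionTable) -> pd.Series:
    """Per-feature coefficient of variation (%) over QC injections,
    computed on inverse-log2 (i.e. raw-scale) values."""
    if not table.is_log2:
        raise ValueError("qc_cv expects a log2 table")
    qcs = table.values_for("qc")
    if qcs.shape[1] < 2:
        raise ValueError("need >= 2 QC injections")
    raw = 2.0 ** qcs
    return 100.0 * raw.std(axis=1, ddof=1) / raw.mean(axis=1)


def merge_replicates(
    table: InjectionTable, replicate_map: dict[str, list[str]] | None = None
) -> tuple[FeatureMatrix, float | None]:
    """Average technical replicates into one column per subject.

    ``replicate_map`` maps sample_id -> injection ids; by default it is
    derived from the injection metadata. Returns the per-sample matrix and
    the minimum pairwise Pearson correlation between replicate log2 profiles
    (None when no subject has >= 2 replicates).
    """
    if not table.is_log2:
        raise ValueError("merge_replicates expects a log2 table")
    if replicate_map is None:
        study = table.injections[table.injections["type"] == "study"]
        replicate_map = {
            sid: list(grp.index) for sid, grp in study.groupby("sample_id", sort=True)
        }
    min_r: float | None = None
    cols = {}
    for sid, inj_ids in replicate_map.items():
        sub = table.intensities[inj_ids]
        if len(inj_ids) > 1:
            arr = sub.to_numpy(dtype=float)
            for i in range(arr.shape[1]):
                for j in range(i + 1, arr.shape[1]):
                    ok = np.isfinite(arr[:, i]) & np.isfinite(arr[:, j])
                    if ok.sum() >= 2 and arr[ok, i].std() > 0 and arr[ok, j].std() > 0:
                        r = float(np.corrcoef(arr[ok, i], arr[ok, j])[0, 1])
                        min_r = r if min_r is None else min(min_r, r)
        cols[sid] = sub.mean(axis=1)
    values = pd.DataFrame(cols, index=table.intensities.index)
    fm = FeatureMatrix(values, table.feature_meta, log=list(table.log))
    fm.log.append(FilterReport("merge_replicates", table.n_features, table.n_features,
                               table._n_study(), len(cols)))
    return fm, min_r


def albumin_filter(
    matrix: FeatureMatrix,
    albumin_ratios: pd.Series,
    abs_rho_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> tuple[FeatureMatrix, FilterReport]:
    """Remove likely blood-derived features: those with a significant
    (p < ``p_threshold``) Spearman correlation of magnitude above
    ``abs_rho_threshold`` with the albumin ratio."""
    missing = [s for s in matrix.sample_ids
               if s not in albumin_ratios.index or pd.isna(albumin_ratios.loc[s])]
    if missing:
        raise ValueError(f"albumin ratio missing for samples: {missing}")
    alb = albumin_ratios.loc[matrix.sample_ids].to_numpy(dtype=float)
    reasons = {}
    for fid in matrix.feature_ids:
        y = matrix.values.loc[fid].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 4:
            continue
        rho, p = spearman(y[ok], alb[ok])
        if not np.isnan(rho) and p < p_threshold and abs(rho) > abs_rho_threshold:
            reasons[fid] = f"albumin rho={rho:.3f}, p={p:.3g}"
    out = matrix.drop_features(list(reasons), "albumin_filter", reasons)
    return out, out.log[-1]


def impute_mean(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace missing entries by the feature's mean over observed samples."""
    vals = matrix.values.to_numpy(dtype=float)
    all_missing = (~np.isfinite(vals)).all(axis=1)
    if all_missing.any():
        bad = list(np.asarray(matrix.feature_ids)[all_missing])
        raise ValueError(f"features with no observed values: {bad}")
    row_means = np.nanmean(vals, axis=1)
    filled = np.where(np.isfinite(vals), vals, row_means[:, None])
    out = matrix.copy()
    out.values = pd.DataFrame(filled, index=matrix.values.index,
                              columns=matrix.values.columns)
    out.log.append(FilterReport("impute_mean", len(matrix.feature_ids),
                                len(matrix.feature_ids), len(matrix.sample_ids),
                                len(matrix.sample_ids)))
    return out
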