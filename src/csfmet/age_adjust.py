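"""Linear age detrending estimated on the reference groups.

The age effect per feature is fit by ordinary least squares on RRMS patients
and controls only (including the progressive group would risk absorbing the
disease signal into the age term). Features with a significant slope
(p < alpha) are corrected in *all* subjects by subtracting
``slope * (age - mean reference age)``, which preserves the reference-set
mean and makes the correction idempotent on the reference fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_GROUPS = ("RRMS", "control")


@dataclass
class AgeModel:
    feature_id: str
    intercept: float
    age_slope: float
    slope_p: float
    corrected: bool
    reference_mean_age: float
    reference_group_ids: list[str]


def fit_age_models(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    ref_groups=REFERENCE_GROUPS,
    alpha: float = 0.05,
) -> list[AgeModel]:
    """OLS of each feature's log2 level on age over the reference subjects.

    ``matrix`` is features x samples; ``samples`` is indexed by sample id
    with ``group`` and ``age`` columns. Marks a feature for correction when
    the two-sided slope p-value is below ``alpha``.
    """
    ref_ids = [s for s in matrix.columns
               if s in samples.index and samples.loc[s, "group"] in ref_groups]
    if len(ref_ids) < 3:
        raise ValueError("need >= 3 reference subjects")
    ages = samples.loc[ref_ids, "age"].to_numpy(dtype=float)
    if np.unique(ages).size < 2:
        raise ValueError("reference ages are constant; cannot fit age models")
    mean_age = float(ages.mean())
    models = []
    for fid in matrix.index:
        y = matrix.loc[fid, ref_ids].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 3 or np.unique(ages[ok]).size < 2:
            models.append(AgeModel(fid, float("nan"), 0.0, 1.0, False, mean_age, ref_ids))
            continue
        res = stats.linregress(ages[ok], y[ok])
        p = float(res.pvalue) if np.isfinite(res.pvalue) else 0.0
        models.append(AgeModel(
            feature_id=fid, intercept=float(res.intercept),
            age_slope=float(res.slope), slope_p=p,
            corrected=bool(p < alpha), reference_mean_age=mean_age,
            reference_group_ids=ref_ids,
        ))
    return models


def apply_age_correction(
    matrix: pd.DataFrame, models: list[AgeModel], samples: pd.DataFrame
) -> pd.DataFrame:
    """Subtract ``slope * (age - reference mean age)`` from every subject for
    each corrected feature; uncorrected features pass through untouched."""
    by_id = {m.feature_id: m for m in models}
    missing = [f for f in matrix.index if f not in by_id]
    if missing:
        raise ValueError(f"no age model for features: {missing[:5]}")
    ages = samples.reindex(matrix.columns)["age"]
    if ages.isna().any():
        bad = list(ages.index[ages.isna()])
        raise ValueError(f"unknown age for samples: {bad}")
    ages = ages.to_numpy(dtype=float)
    out = matrix.copy()
    for fid in matrix.index:
        m = by_id[fid]
        if m.corrected:
            out.loc[fid] = matrix.loc[fid].to_numpy(dtype=float) - \
                m.age_slope * (ages - m.reference_mean_age)
    return out


def models_to_frame(models: list[AgeModel]) -> pd.DataFrame:
    return pd.DataFrame([
        {"feature_id": m.feature_id, "age_slope": m.age_slope,
         "slope_p": m.slope_p, "corrected": m.corrected}
        for m in models
    ]).set_index("feature_id")
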