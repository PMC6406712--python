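"""Readers for the plain-text study input formats (comma- or tab-sniffed)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from csfmet.tables import InjectionTable

META_COLUMNS = ("mz", "rt")


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: expected a sample_id column")
    return df.set_index("sample_id")


def read_injection_table(
    features_path: str | Path, injections_path: str | Path
) -> InjectionTable:
    """Load a wide feature table (feature_id, mz, rt, one column per
    injection) plus its injection metadata."""
    feats = _read_table(features_path)
    if "feature_id" not in feats.columns:
        raise ValueError(f"{features_path}: expected a feature_id column")
    feats = feats.set_index("feature_id")
    meta_cols = [c for c in META_COLUMNS if c in feats.columns]
    feature_meta = feats[meta_cols]
    intensities = feats.drop(columns=meta_cols)

    inj = _read_table(injections_path)
    if "injection_id" not in inj.columns:
        raise ValueError(f"{injections_path}: expected an injection_id column")
    inj = inj.set_index("injection_id")
    missing = [c for c in intensities.columns if c not in inj.index]
    if missing:
        raise ValueError(f"injections metadata missing for columns: {missing[:5]}")
    return InjectionTable(intensities.astype(float), inj.loc[list(intensities.columns)],
                         feature_meta)
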