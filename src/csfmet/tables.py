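"""Core tabular containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INJECTION_TYPES = ("study", "qc", "blank", "dilution")


@dataclass
class FilterReport:
    """Bookkeeping for one filtering step."""

    step: str
    features_before: int
    features_after: int
    samples_before: int
    samples_after: int
    removed: dict[str, str] = field(default_factory=dict)  # id -> reason

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "features_before": self.features_before,
            "features_after": self.features_after,
            "samples_before": self.samples_before,
            "samples_after": self.samples_after,
            "removed": dict(self.removed),
        }


class InjectionTable:
    """A feature x injection intensity matrix plus injection metadata.

    Parameters
    ----------
    intensities : DataFrame
        Rows indexed by feature id, one column per injection id. Values are
        raw (non-negative) intensities, or log2 intensities once
        ``is_log2`` is set. Missing values are NaN.
    injections : DataFrame
        Indexed by injection id with columns ``type`` (one of
        ``study``/``qc``/``blank``/``dilution``), ``order`` (1-based unique
        contiguous ints), ``sample_id`` (study injections only) and
        ``volume`` (dilution injections only, in microliters).
    feature_meta : DataFrame, optional
        Indexed by feature id; typically carries ``mz`` and ``rt`` columns.
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        injections: pd.DataFrame,
        feature_meta: pd.DataFrame | None = None,
        is_log2: bool = False,
        log: list[FilterReport] | None = None,
    ):
        if list(intensities.columns) != list(injections.index):
            injections = injections.loc[intensities.columns]
        self.intensities = intensities
        self.injections = injections
        if feature_meta is None:
            feature_meta = pd.DataFrame(index=intensities.index)
        self.feature_meta = feature_meta.loc[intensities.index]
        self.is_log2 = is_log2
        self.log = list(log) if log else []
        self._validate()

    def _validate(self) -> None:
        inj = self.injections
        bad = set(inj["type"]) - set(INJECTION_TYPES)
        if bad:
            raise ValueError(f"unknown injection types: {sorted(bad)}")
        orders = np.sort(inj["order"].to_numpy())
        if len(orders) and not np.array_equal(orders, np.arange(1, len(orders) + 1)):
            raise ValueError("injection_order must be unique and contiguous from 1")
        nonstudy = inj.loc[inj["type"] != "study"]
        if "sample_id" in inj.columns and nonstudy["sample_id"].notna().any():
            raise ValueError("qc/blank/dilution injections must not carry a sample_id")

    # -- convenience selectors -------------------------------------------------
    def ids_of_type(self, kind: str) -> list[str]:
        return list(self.injections.index[self.injections["type"] == kind])

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def n_features(self) -> int:
        return len(self.intensities.index)

    @property
    def n_injections(self) -> int:
        return len(self.injections)

    def values_for(self, kind: str) -> pd.DataFrame:
        """Sub-matrix restricted to injections of one type, in run order."""
        ids = self.injections.loc[self.injections["type"] == kind].sort_values("order")
        return self.intensities[ids.index]

    def drop_features(self, ids, step: str, reasons: dict[str, str]) -> "InjectionTable":
        keep = [f for f in self.intensities.index if f not in set(ids)]
        out = InjectionTable(
            self.intensities.loc[keep],
            self.injections,
            self.feature_meta.loc[keep],
            is_log2=self.is_log2,
            log=self.log,
        )
        out.log = self.log + [
            FilterReport(step, self.n_features, len(keep),
                         self._n_study(), self._n_study(), dict(reasons))
        ]
        return out

    def drop_injections(self, ids, step: str, reasons: dict[str, str]) -> "InjectionTable":
        keep = [i for i in self.injections.index if i not in set(ids)]
        inj = self.injections.loc[keep].copy()
        # re-pack order to stay contiguous
        inj["order"] = inj["order"].rank(method="first").astype(int)
        before = self._n_study()
        out = InjectionTable(
            self.intensities[keep], inj, self.feature_meta,
            is_log2=self.is_log2, log=self.log,
        )
        out.log = self.log + [
            FilterReport(step, self.n_features, self.n_features,
                         before, out._n_study(), dict(reasons))
        ]
        return out

    def _n_study(self) -> int:
        return int((self.injections["type"] == "study").sum())

    def copy(self) -> "InjectionTable":
        return InjectionTable(
            self.intensities.copy(), self.injections.copy(),
            self.feature_meta.copy(), is_log2=self.is_log2, log=list(self.log),
        )


class FeatureMatrix:
    """Per-sample metabolite matrix (features x samples, log2 units)."""

    def __init__(
        self,
        values: pd.DataFrame,
        feature_meta: pd.DataFrame | None = None,
        log: list[FilterReport] | None = None,
    ):
        self.values = values
        if feature_meta is None:
            feature_meta = pd.DataFrame(index=values.index)
        self.feature_meta = feature_meta.loc[values.index]
        self.log = list(log) if log else []

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def drop_features(self, ids, step: str, reasons: dict[str, str]) -> "FeatureMatrix":
        keep = [f for f in self.values.index if f not in set(ids)]
        out = FeatureMatrix(self.values.loc[keep], self.feature_meta.loc[keep], self.log)
        out.log = self.log + [
            FilterReport(step, len(self.values.index), len(keep),
                         len(self.values.columns), len(self.values.columns),
                         dict(reasons))
        ]
        return out

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.feature_meta.copy(), list(self.log))
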