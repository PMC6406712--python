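import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from csfmet import preprocess
from csfmet.pipeline import PipelineConfig, run_preprocess
from csfmet.synthetic import SimConfig, cohort_to_frame, generate_cohort, generate_injection_table
from csfmet.tables import FeatureMatrix


class TestBlankFilter:
    def _table(self):
        return make_table(
            {"equal": [100, 100, 50], "absent": [100, np.nan, 50], "low": [100, 10, 50]},
            {"QC1": "qc", "BL1": "blank", "S1": "study"},
            sample_ids={"S1": "P1"},
        )

    def test_blank_equal_qc_removed(self):
        out, report = preprocess.filter_blank_contaminants(self._table())
        assert "equal" in report.removed
        assert "equal" not in out.feature_ids

    def test_absent_from_blanks_kept(self):
        out, _ = preprocess.filter_blank_contaminants(self._table())
        assert "absent" in out.feature_ids
        assert "low" in out.feature_ids

    def test_no_blanks_errors(self):
        t = make_table({"f": [1, 2]}, {"QC1": "qc", "S1": "study"},
                       sample_ids={"S1": "P1"})
        with pytest.raises(ValueError, match="skip"):
            preprocess.filter_blank_contaminants(t)

    def test_recovers_ground_truth(self):
        cfg = SimConfig(seed=3, frac_contaminant=0.1, noise_sd=0.0,
                        drift_amplitude=0.0, missing_rate=0.0, n_features=60)
        table, truth = generate_injection_table(generate_cohort(cfg), cfg)
        out, report = preprocess.filter_blank_contaminants(table)
        removed = set(report.removed)
        expected = {fid for fid, c in zip(truth.feature_ids, truth.is_contaminant) if c}
        assert removed == expected


class TestDilutionFilter:
    VOLUMES = (0.5, 1, 2, 4, 8, 16, 32)

    def _table(self, values):
        n = len(self.VOLUMES)
        types = {f"D{i}": "dilution" for i in range(n)}
        types["S1"] = "study"
        vols = {f"D{i}": v for i, v in enumerate(self.VOLUMES)}
        return make_table({k: list(v) + [1.0] for k, v in values.items()},
                          types, volumes=vols, sample_ids={"S1": "P1"})

    def test_proportional_kept(self):
        t = self._table({"f": np.array(self.VOLUMES) * 3.0})
        out, _ = preprocess.filter_dilution_series(t)
        assert "f" in out.feature_ids

    def test_flat_removed(self):
        t = self._table({"f": np.full(7, 5.0)})
        out, report = preprocess.filter_dilution_series(t)
        assert "f" not in out.feature_ids
        assert "flat" in report.removed["f"]

    def test_pearson_matches_brute_force(self):
        # (1,2,4,8,16,32,64) with the first two swapped
        vals = np.array([2.0, 1.0, 4.0, 8.0, 16.0, 32.0, 64.0])
        vols = np.array(self.VOLUMES, dtype=float)
        # brute-force Pearson formula
        n = 7
        sx, sy = vals.sum(), vols.sum()
        sxy = (vals * vols).sum()
        sxx, syy = (vals ** 2).sum(), (vols ** 2).sum()
        r_oracle = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx ** 2) * (n * syy - sy ** 2))
        t = self._table({"f": vals})
        out, report = preprocess.filter_dilution_series(t, min_abs_r=abs(r_oracle) - 1e-12)
        assert "f" in out.feature_ids
        out2, report2 = preprocess.filter_dilution_series(t, min_abs_r=abs(r_oracle) + 1e-9)
        assert "f" not in out2.feature_ids
        reported = float(report2.removed["f"].split("=")[1].split(" ")[0])
        assert reported == pytest.approx(abs(r_oracle), abs=1e-3)

    def test_too_few_points_errors(self):
        t = make_table({"f": [1, 2, 3]},
                       {"D0": "dilution", "D1": "dilution", "S1": "study"},
                       volumes={"D0": 1.0, "D1": 2.0}, sample_ids={"S1": "P1"})
        with pytest.raises(ValueError, match="3 dilution"):
            preprocess.filter_dilution_series(t)


class TestLog2:
    def test_values(self):
        t = make_table({"a": [8.0, 1.0, np.nan], "b": [0.0, 2.0, 4.0]},
                       {"S1": "study", "S2": "study", "S3": "study"},
                       sample_ids={"S1": "P1", "S2": "P2", "S3": "P3"})
        out = preprocess.log2_transform(t)
        assert out.intensities.loc["a", "S1"] == 3.0
        assert out.intensities.loc["a", "S2"] == 0.0
        assert np.isnan(out.intensities.loc["a", "S3"])
        assert np.isnan(out.intensities.loc["b", "S1"])  # zero stays missing
        assert out.is_log2

    def test_negative_rejected(self):
        t = make_table({"a": [-1.0]}, {"S1": "study"}, sample_ids={"S1": "P1"})
        with pytest.raises(ValueError, match="negative"):
            preprocess.log2_transform(t)


class TestTICOutliers:
    def test_crafted_five_samples(self):
        tics = [100.0, 100.0, 100.0, 100.0, 40.0]
        t = make_table({"f": tics}, {f"S{i}": "study" for i in range(5)},
                       sample_ids={f"S{i}": f"P{i}" for i in range(5)})
        out, report = preprocess.detect_tic_outliers(t)
        assert list(report.removed) == ["S4"]
        assert out.n_injections == 4

    def test_below_sixty_percent_of_mean(self):
        # mean of (100*9, 55) is 95.5; 55/95.5 = 0.576 < 0.6
        vals = [100.0] * 9 + [55.0]
        t = make_table({"f": vals}, {f"S{i}": "study" for i in range(10)},
                       sample_ids={f"S{i}": f"P{i}" for i in range(10)})
        out, report = preprocess.detect_tic_outliers(t)
        assert "S9" in report.removed

    def test_identical_none_removed(self):
        t = make_table({"f": [5.0, 5.0, 5.0]}, {f"S{i}": "study" for i in range(3)},
                       sample_ids={f"S{i}": f"P{i}" for i in range(3)})
        _, report = preprocess.detect_tic_outliers(t)
        assert not report.removed

    def test_qc_never_removed(self):
        t = make_table({"f": [100.0, 100.0, 1.0]},
                       {"S1": "study", "S2": "study", "QC1": "qc"},
                       sample_ids={"S1": "P1", "S2": "P2"})
        out, report = preprocess.detect_tic_outliers(t)
        assert "QC1" in out.injections.index


class TestCoverage:
    def _table(self, present: int, total: int = 56):
        vals = [1.0] * present + [np.nan] * (total - present)
        return make_table({"f": vals}, {f"S{i}": "study" for i in range(total)},
                          sample_ids={f"S{i}": f"P{i}" for i in range(total)})

    def test_boundary_inclusive(self):
        out, _ = preprocess.coverage_filter(self._table(42))  # 42/56 = 0.75
        assert "f" in out.feature_ids

    def test_below_boundary_removed(self):
        out, _ = preprocess.coverage_filter(self._table(41))
        assert "f" not in out.feature_ids

    def test_all_present_kept(self):
        out, _ = preprocess.coverage_filter(self._table(56))
        assert "f" in out.feature_ids


def _drifted_table(drift_fn, n_study=24, qc_every=4, noise=0.0, seed=0):
    """log2 table with QCs interleaved and a known injection-order drift."""
    rng = np.random.default_rng(seed)
    kinds, sample_ids = {}, {}
    idx = 0
    for i in range(n_study):
        if i % qc_every == 0:
            idx += 1
            kinds[f"QC{idx}"] = "qc"
        kinds[f"S{i}"] = "study"
        sample_ids[f"S{i}"] = f"P{i}"
    idx += 1
    kinds[f"QC{idx}"] = "qc"
    n = len(kinds)
    orders = np.arange(1, n + 1)
    base = 10.0
    vals = base + drift_fn(orders) + rng.normal(0, noise, size=n)
    return make_table({"f": vals}, kinds, sample_ids=sample_ids, is_log2=True)


class TestLoess:
    def test_zero_drift_identity(self):
        t = _drifted_table(lambda o: np.zeros_like(o, dtype=float))
        out = preprocess.loess_normalize(t)
        assert np.allclose(out.intensities.to_numpy(), t.intensities.to_numpy(),
                           atol=1e-9)

    def test_linear_drift_exactly_removed(self):
        n = 30
        t = _drifted_table(lambda o: (o - 1) / n * 1.0)  # +1 log2 unit over run
        out = preprocess.loess_normalize(t)
        qc = out.values_for("qc").to_numpy().ravel()
        assert qc.std() < 1e-6
        # study injections flattened too (same line)
        sv = out.values_for("study").to_numpy().ravel()
        assert sv.std() < 1e-6

    def test_qc_cv_reduced_on_drifted_synthetic(self):
        improved = total = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, noise_sd=0.05, drift_amplitude=0.8,
                            missing_rate=0.0, n_features=25, frac_contaminant=0.0)
            table, _ = generate_injection_table(generate_cohort(cfg), cfg)
            t = preprocess.log2_transform(table)
            pre_cv = preprocess.qc_cv(t)
            post_cv = preprocess.qc_cv(preprocess.loess_normalize(t))
            improved += int((post_cv < pre_cv).sum())
            total += len(pre_cv)
        assert improved / total >= 0.95

    def test_too_few_qcs_errors(self):
        t = make_table({"f": [1.0, 2.0]}, {"QC1": "qc", "S1": "study"},
                       sample_ids={"S1": "P1"}, is_log2=True)
        with pytest.raises(ValueError, match="5 QC"):
            preprocess.loess_normalize(t)


class TestQcCv:
    def test_constant_zero(self):
        t = make_table({"f": [3.0, 3.0]}, {"QC1": "qc", "QC2": "qc"}, is_log2=True)
        assert preprocess.qc_cv(t).loc["f"] == 0.0

    def test_hand_example(self):
        # raw QC values 1 and 3: CV = 100 * sd(1,3)/mean(1,3) = 70.71%
        t = make_table({"f": [np.log2(1.0), np.log2(3.0)]},
                       {"QC1": "qc", "QC2": "qc"}, is_log2=True)
        assert preprocess.qc_cv(t).loc["f"] == pytest.approx(70.71, abs=0.01)

    def test_scale_free(self):
        t1 = make_table({"f": [np.log2(2.0), np.log2(5.0)]},
                        {"QC1": "qc", "QC2": "qc"}, is_log2=True)
        t2 = make_table({"f": [np.log2(20.0), np.log2(50.0)]},
                        {"QC1": "qc", "QC2": "qc"}, is_log2=True)
        assert preprocess.qc_cv(t1).loc["f"] == pytest.approx(
            preprocess.qc_cv(t2).loc["f"], abs=1e-10)


class TestMergeReplicates:
    def _table(self, a, b):
        return make_table(
            {f"f{i}": [a[i], b[i]] for i in range(len(a))},
            {"S1a": "study", "S1b": "study"},
            sample_ids={"S1a": "P1", "S1b": "P1"}, is_log2=True)

    def test_identical_replicates(self):
        fm, min_r = preprocess.merge_replicates(self._table([1, 2, 3], [1, 2, 3]))
        assert min_r == pytest.approx(1.0)
        assert list(fm.values["P1"]) == [1, 2, 3]

    def test_anticorrelated(self):
        _, min_r = preprocess.merge_replicates(self._table([1, 2, 3], [3, 2, 1]))
        assert min_r == pytest.approx(-1.0)

    def test_averaging(self):
        fm, _ = preprocess.merge_replicates(self._table([2, 2, 2], [4, 6, 8]))
        assert list(fm.values["P1"]) == [3, 4, 5]

    def test_singletons_no_correlation(self):
        t = make_table({"f": [1.0, 2.0]}, {"S1": "study", "S2": "study"},
                       sample_ids={"S1": "P1", "S2": "P2"}, is_log2=True)
        fm, min_r = preprocess.merge_replicates(t)
        assert min_r is None
        assert list(fm.values.columns) == ["P1", "P2"]

    def test_generator_replicates_high_correlation(self):
        cfg = SimConfig(seed=6, n_replicates=2, noise_sd=0.02, missing_rate=0.0,
                        n_features=40, n_per_group=(3, 6, 4))
        table, _ = generate_injection_table(generate_cohort(cfg), cfg)
        t = preprocess.log2_transform(table)
        fm, min_r = preprocess.merge_replicates(t)
        assert min_r is not None and min_r > 0.95
        assert len(fm.values.columns) == 13


class TestAlbuminFilter:
    def test_monotone_transform_removed(self):
        rng = np.random.default_rng(0)
        alb = pd.Series(rng.uniform(2, 10, size=56),
                        index=[f"P{i}" for i in range(56)])
        fm = FeatureMatrix(pd.DataFrame({p: [np.sqrt(alb[p]), rng.normal()]
                                         for p in alb.index}, index=["linked", "free"]))
        out, report = preprocess.albumin_filter(fm, alb)
        assert "linked" in report.removed
        assert "free" in out.feature_ids

    def test_small_n_kept(self):
        # |rho| = 0.8 at n = 4 is not significant
        alb = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        fm = FeatureMatrix(pd.DataFrame({"a": [2.0], "b": [1.0], "c": [4.0], "d": [3.0]},
                                        index=["f"]))
        out, _ = preprocess.albumin_filter(fm, alb)
        assert "f" in out.feature_ids

    def test_missing_albumin_errors(self):
        fm = FeatureMatrix(pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["f"]))
        with pytest.raises(ValueError, match="b"):
            preprocess.albumin_filter(fm, pd.Series({"a": 5.0}))

    def test_null_false_positive_rate(self):
        hits = 0
        n_trials = 20
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            alb = pd.Series(rng.uniform(2, 10, 56), index=[f"P{i}" for i in range(56)])
            fm = FeatureMatrix(pd.DataFrame(
                rng.normal(size=(10, 56)), index=[f"f{i}" for i in range(10)],
                columns=alb.index))
            _, report = preprocess.albumin_filter(fm, alb)
            hits += len(report.removed)
        assert hits / (n_trials * 10) < 0.05


class TestImputeMean:
    def test_fills_with_mean(self):
        fm = FeatureMatrix(pd.DataFrame({"a": [1.0], "b": [np.nan], "c": [3.0]},
                                        index=["f"]))
        out = preprocess.impute_mean(fm)
        assert list(out.values.loc["f"]) == [1.0, 2.0, 3.0]

    def test_no_missing_unchanged(self):
        fm = FeatureMatrix(pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["f"]))
        out = preprocess.impute_mean(fm)
        pd.testing.assert_frame_equal(out.values, fm.values)

    def test_all_missing_errors(self):
        fm = FeatureMatrix(pd.DataFrame({"a": [np.nan], "b": [np.nan]}, index=["f"]))
        with pytest.raises(ValueError, match="no observed"):
            preprocess.impute_mean(fm)


class TestCascade:
    def test_provenance_order(self, quiet_study):
        cohort, samples, table, truth = quiet_study
        res = run_preprocess(table, samples, PipelineConfig(seed=11))
        steps = [r.step for r in res["log"]]
        assert steps == ["blank_contaminants", "dilution_series", "log2_transform",
                         "tic_outliers", "coverage", "loess_normalize",
                         "merge_replicates", "albumin_filter", "impute_mean"]
        for r in res["log"]:
            assert r.features_before - r.features_after == \
                len([k for k in r.removed]) or r.features_before == r.features_after

    def test_identity_on_clean_data(self, clean_config):
        cohort = generate_cohort(clean_config)
        samples = cohort_to_frame(cohort)
        table, _ = generate_injection_table(cohort, clean_config)
        res = run_preprocess(table, samples, PipelineConfig(seed=5))
        final = res["matrix"].values
        study = table.injections[table.injections["type"] == "study"]
        for sid in final.columns:
            inj_id = study.index[study["sample_id"] == sid][0]
            orig = np.log2(table.intensities[inj_id].loc[final.index].to_numpy())
            assert np.allclose(final[sid].to_numpy(), orig, atol=1e-9)
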