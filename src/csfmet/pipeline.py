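"""End-to-end orchestration: simulate -> preprocess -> identify -> age-adjust
-> discriminate -> enrich -> associate, with a manifest for exact replay."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from csfmet import __version__, age_adjust, associations, diffstats, identification
from csfmet import pathways as pw
from csfmet import plsda, preprocess
from csfmet.synthetic import SimConfig, cohort_to_frame, generate_study, write_study
from csfmet.tables import FeatureMatrix, InjectionTable

DEFAULT_CONTRASTS = ("SPMS:RRMS", "SPMS:control", "RRMS:control")


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their documented defaults."""

    blank_ratio: float = 0.5
    dilution_min_r: float = 0.7
    tic_min_frac: float = 0.6
    coverage: float = 0.75
    ppm: float = 15.0
    rt_s: float = 20.0
    span: float = 0.3
    albumin_rho: float = 0.5
    albumin_p: float = 0.05
    age_alpha: float = 0.05
    k: int = 5
    repeats: int = 10
    vip_threshold: float = 1.0
    n_perm: int = 100
    alpha: float = 0.05
    n_components: int | None = None
    seed: int = 0
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS

    _RANGES = {
        "blank_ratio": (0.0, 10.0), "dilution_min_r": (0.0, 1.0),
        "tic_min_frac": (0.0, 1.0), "coverage": (0.0, 1.0),
        "ppm": (0.0, 1e4), "rt_s": (0.0, 1e5), "span": (0.0, 1.0),
        "albumin_rho": (0.0, 1.0), "albumin_p": (0.0, 1.0),
        "age_alpha": (0.0, 1.0), "vip_threshold": (0.0, 100.0),
        "alpha": (0.0, 1.0),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        for name in ("k", "repeats", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contrasts" in raw:
            raw["contrasts"] = tuple(raw["contrasts"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = list(self.contrasts)
        return d


def run_preprocess(
    table: InjectionTable,
    samples: pd.DataFrame,
    config: PipelineConfig,
    library: list[identification.LibraryEntry] | None = None,
) -> dict:
    """Run the full filtering cascade in its mandated order.

    Returns a dict with the final imputed FeatureMatrix, the identification
    results, QC CVs, the minimum replicate correlation and the step log.
    """
    t, _ = preprocess.filter_blank_contaminants(table, config.blank_ratio)
    t, _ = preprocess.filter_dilution_series(t, config.dilution_min_r)
    t = preprocess.log2_transform(t)
    t, _ = preprocess.detect_tic_outliers(t, config.tic_min_frac)
    t, _ = preprocess.coverage_filter(t, config.coverage)

    id_results = None
    if library is not None:
        id_results = identification.match_library(
            t.feature_meta, library, ppm_tol=config.ppm, rt_tol_s=config.rt_s)
        unmatched = {r.feature_id: "no library match" for r in id_results
                     if not r.matched}
        t = t.drop_features(list(unmatched), "library_match", unmatched)
        id_results = [r for r in id_results if r.matched]

    t = preprocess.loess_normalize(t, span=config.span)
    cvs = preprocess.qc_cv(t)
    matrix, min_rep_r = preprocess.merge_replicates(t)
    matrix, _ = preprocess.albumin_filter(
        matrix, samples["albumin_ratio"], config.albumin_rho, config.albumin_p)
    matrix = preprocess.impute_mean(matrix)
    return {
        "matrix": matrix,
        "id_results": id_results,
        "qc_cv": cvs.reindex(matrix.feature_ids),
        "min_replicate_r": min_rep_r,
        "log": matrix.log,
    }


def run_contrast(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: str,
    config: PipelineConfig,
    annotations: pd.DataFrame | None = None,
    exclude_ids: set[str] | None = None,
) -> dict:
    """Fit + cross-validate one pairwise PLS-DA contrast ("A:B")."""
    group_a, group_b = contrast.split(":")
    ids = [s for s in matrix.columns
           if samples.loc[s, "group"] in (group_a, group_b)
           and not (exclude_ids and s in exclude_ids)]
    y = samples.loc[ids, "group"].to_numpy()
    X = matrix[ids].T  # samples x features
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = plsda.fit_plsda(X, y, n_components=config.n_components,
                                positive=group_a, seed=config.seed)
        model.q2 = plsda.q2(X, y, n_components=model.n_components,
                            seed=config.seed, positive=group_a)
        if model.q2 >= 0:
            model.r2_perm_p, model.q2_perm_p = plsda.permutation_test(
                X, y, n_perm=config.n_perm, n_components=model.n_components,
                seed=config.seed, positive=group_a)
    out = {"contrast": contrast, "model": model, "predictive": model.q2 >= 0}
    if not out["predictive"]:
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = plsda.repeated_cv(X, y, k=config.k, repeats=config.repeats,
                               seed=config.seed, n_components=model.n_components,
                               positive=group_a)
    a_ids = [s for s in ids if samples.loc[s, "group"] == group_a]
    b_ids = [s for s in ids if samples.loc[s, "group"] == group_b]
    table = diffstats.altered_table(
        matrix, a_ids, b_ids, cv.vip_mean, cv.vip_ci,
        annotations=annotations, vip_threshold=config.vip_threshold)
    out.update({"cv": cv, "altered": table})
    return out


def run_all(
    outdir: str | Path,
    sim_config: SimConfig | None = None,
    config: PipelineConfig | None = None,
    n_pathways: int = 10,
    universe_size: int = 80,
) -> dict:
    """Full synthetic-study run; writes all outputs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    config.validate()
    sim_config = sim_config or SimConfig(seed=config.seed)

    cohort, table, truth, library, pathway_library = generate_study(
        sim_config, n_pathways=n_pathways, universe_size=universe_size)
    write_study(outdir / "inputs", cohort, table, truth, library,
                pathway_library, sim_config)
    samples = cohort_to_frame(cohort)

    pre = run_preprocess(table, samples, config, library=library)
    matrix_fm: FeatureMatrix = pre["matrix"]
    annotations = identification.results_to_frame(pre["id_results"]) \
        if pre["id_results"] is not None else None

    models = age_adjust.fit_age_models(matrix_fm.values, samples,
                                       alpha=config.age_alpha)
    adjusted = age_adjust.apply_age_correction(matrix_fm.values, models, samples)
    adjusted.to_csv(outdir / "cleaned_matrix.csv", float_format="%.8g")
    age_adjust.models_to_frame(models).to_csv(outdir / "age_models.csv")
    pre["qc_cv"].rename("qc_cv_percent").to_csv(outdir / "qc_cv.csv")
    (outdir / "filter_report.json").write_text(json.dumps(
        [r.to_dict() for r in pre["log"]], indent=1))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "sim_config": sim_config.to_dict(),
        "n_samples": len(samples),
        "n_features_final": len(adjusted.index),
        "min_replicate_r": pre["min_replicate_r"],
        "stages": [r.to_dict() for r in pre["log"]],
        "contrasts": {},
    }

    results = {}
    kegg_map = {}
    if annotations is not None:
        kegg_map = annotations["kegg_id"].dropna().to_dict()
    altered_union: list[str] = []
    for contrast in config.contrasts:
        res = run_contrast(adjusted, samples, contrast, config,
                           annotations=annotations)
        results[contrast] = res
        m = res["model"]
        entry = {"n_components": m.n_components, "r2y": m.r2y, "q2": m.q2,
                 "predictive": res["predictive"]}
        if res["predictive"]:
            entry.update({
                "r2_perm_p": m.r2_perm_p, "q2_perm_p": m.q2_perm_p,
                "auroc_mean": res["cv"].auroc_mean,
                "auroc_sd": res["cv"].auroc_sd,
                "n_altered": int(len(res["altered"])),
            })
            tag = contrast.replace(":", "_vs_")
            res["altered"].to_csv(outdir / f"altered_{tag}.csv")
            roc = pd.DataFrame({"one_minus_specificity": res["cv"].roc_grid,
                                "sensitivity_mean": res["cv"].roc_mean,
                                "sensitivity_sem": res["cv"].roc_sem})
            roc.to_csv(outdir / f"roc_{tag}.csv", index=False)
            # pathway enrichment on KEGG-identified altered metabolites
            query = {kegg_map[f] for f in res["altered"].index if f in kegg_map}
            if query:
                enr = pw.enrich_all(query, pathway_library)
                pw.enrichment_to_frame(enr).to_csv(outdir / f"enrichment_{tag}.csv")
                entry["n_pathways_significant"] = sum(
                    r.p_hyper < config.alpha for r in enr)
            altered_union.extend(res["altered"].index)
        else:
            entry["note"] = "no significant difference (Q2 < 0)"
        manifest["contrasts"][contrast] = entry

    altered_union = list(dict.fromkeys(altered_union))
    if altered_union:
        assoc = associations.associate_all(adjusted.loc[altered_union], samples)
        assoc.to_csv(outdir / "associations.csv", index=False)
        manifest["n_associated_metabolites"] = len(altered_union)

    blob = json.dumps(manifest, sort_keys=True, default=float)
    manifest["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=float))
    return {"manifest": manifest, "results": results, "matrix": adjusted,
            "samples": samples, "truth": truth}
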