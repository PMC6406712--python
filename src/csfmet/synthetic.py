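"""Synthetic study generator.

Emits a complete synthetic cohort — sample metadata, injection sequence with
pooled-QC/blank pairs and a terminal dilution series, a feature intensity
matrix with injection-order drift, group effects, age and albumin structure,
contaminants and missingness — together with a matching spectral library,
a pathway library and the ground truth needed to validate every downstream
filtering and modelling stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from csfmet.identification import LibraryEntry, write_msp
from csfmet.pathways import PathwayDef, write_gmt, write_edges
from csfmet.tables import InjectionTable

GROUPS = ("control", "RRMS", "SPMS")
STANDARD_VOLUME_UL = 10.0


@dataclass
class SimConfig:
    """Parameters controlling the synthetic study design.

    Defaults reproduce the reference design: 10 controls, 30 RRMS and
    16 SPMS subjects with per-group age distributions (39 +/- 13.1,
    39 +/- 10.6, 58 +/- 9.3 years), a QC + blank pair every 8th study
    injection and a 2-fold dilution series from 0.5 to 32 uL.
    """

    n_per_group: tuple[int, int, int] = (10, 30, 16)  # control, RRMS, SPMS
    age_params: tuple[tuple[float, float], ...] = ((39.0, 13.1), (39.0, 10.6), (58.0, 9.3))
    n_features: int = 120
    frac_identified: float = 0.9
    frac_age_dependent: float = 0.15
    frac_contaminant: float = 0.1
    group_effect_log2fc: tuple[float, ...] = tuple(
        round(float(x), 2) for x in np.linspace(0.1, 1.2, 30)
    )
    drift_amplitude: float = 0.5
    drift_shape: str = "decay"  # "decay" (monotone + sinusoid) or "linear"
    qc_interval: int = 8
    dilution_volumes: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    noise_sd: float = 0.1
    missing_rate: float = 0.02
    albumin_link_frac: float = 0.05
    n_replicates: int = 1
    n_transitioned: int = 4
    frac_kegg: float = 0.8
    n_decoys: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_identified", "frac_age_dependent", "frac_contaminant",
                     "missing_rate", "albumin_link_frac", "frac_kegg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_features", "qc_interval", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("n_per_group counts must be >= 1")
        if len(self.n_per_group) != 3 or len(self.age_params) != 3:
            raise ValueError("n_per_group and age_params must have 3 entries "
                             "(control, RRMS, SPMS)")
        vols = np.asarray(self.dilution_volumes, dtype=float)
        if len(vols) and not np.all(np.diff(vols) > 0):
            raise ValueError("dilution_volumes must be strictly increasing")
        if self.drift_shape not in ("decay", "linear"):
            raise ValueError(f"drift_shape must be 'decay' or 'linear', got {self.drift_shape!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_params"] = [[float(v) for v in p] for p in self.age_params]
        d["group_effect_log2fc"] = [float(v) for v in self.group_effect_log2fc]
        d["dilution_volumes"] = [float(v) for v in self.dilution_volumes]
        return d


@dataclass
class SampleMeta:
    sample_id: str
    group: str
    age: float
    sex: str
    on_treatment: bool
    edss: float | None
    disease_duration: float | None  # months
    albumin_ratio: float
    third_ventricle: float
    spinal_cord: float
    total_t1: int
    total_t2: int
    transitioned: bool


@dataclass
class GroundTruth:
    """Per-feature generative flags for validating the filter cascade."""

    feature_ids: list[str]
    is_contaminant: np.ndarray
    is_age_dependent: np.ndarray
    age_slope: np.ndarray  # log2 units / year, 0 where not age-dependent
    albumin_linked: np.ndarray
    true_group_log2fc: dict[str, np.ndarray]  # contrast -> per-feature fc
    library_identity: list[str | None]

    def to_dict(self) -> dict:
        return {
            "feature_ids": self.feature_ids,
            "is_contaminant": self.is_contaminant.astype(bool).tolist(),
            "is_age_dependent": self.is_age_dependent.astype(bool).tolist(),
            "age_slope": self.age_slope.tolist(),
            "albumin_linked": self.albumin_linked.astype(bool).tolist(),
            "true_group_log2fc": {k: v.tolist() for k, v in self.true_group_log2fc.items()},
            "library_identity": self.library_identity,
        }


def _truncated_normal(rng, mean, sd, low, size):
    out = rng.normal(mean, sd, size=size)
    while True:
        bad = out < low
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def generate_cohort(config: SimConfig) -> list[SampleMeta]:
    """Draw the subject-level metadata for one synthetic study."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples: list[SampleMeta] = []
    # latent progression severity drives EDSS/duration/MRI jointly
    edss_center = {"control": None, "RRMS": 2.5, "SPMS": 5.5}
    dur_logmean = {"control": None, "RRMS": np.log(92.0), "SPMS": np.log(283.0)}
    idx = 0
    for g, n, (mu, sd) in zip(GROUPS, config.n_per_group, config.age_params):
        ages = _truncated_normal(rng, mu, sd, 18.0, n)
        for j in range(n):
            idx += 1
            sid = f"S{idx:03d}"
            sex = "F" if rng.random() < 0.65 else "M"
            severity = float(rng.normal(0.0, 1.0))
            if g == "control":
                edss = duration = None
                on_treatment = False
                sev = -1.0 + 0.3 * severity
            else:
                edss = float(np.clip(np.round((edss_center[g] + 1.2 * severity) * 2) / 2, 0, 10))
                duration = float(np.exp(dur_logmean[g] + 0.45 * severity))
                on_treatment = bool(rng.random() < (0.5 if g == "RRMS" else 0.08))
                sev = (1.2 if g == "SPMS" else 0.0) + 0.5 * severity
            albumin = float(np.exp(rng.normal(np.log(5.0), 0.3)))
            samples.append(SampleMeta(
                sample_id=sid, group=g, age=float(ages[j]), sex=sex,
                on_treatment=on_treatment, edss=edss, disease_duration=duration,
                albumin_ratio=albumin,
                third_ventricle=float(np.exp(0.8 + 0.35 * sev + rng.normal(0, 0.15))),
                spinal_cord=float(np.exp(4.4 - 0.10 * sev + rng.normal(0, 0.05))),
                total_t1=int(rng.poisson(np.exp(1.2 + 0.5 * sev))),
                total_t2=int(rng.poisson(np.exp(1.8 + 0.5 * sev))),
                transitioned=False,
            ))
    rrms = [s for s in samples if s.group == "RRMS"]
    n_trans = min(config.n_transitioned, len(rrms))
    for s in rng.choice(len(rrms), size=n_trans, replace=False):
        rrms[int(s)].transitioned = True
    return samples


def _drift(config: SimConfig, order: np.ndarray, n_total: int) -> np.ndarray:
    """Smooth log2-scale intensity drift as a function of injection order."""
    x = (order - 1) / max(n_total - 1, 1)
    if config.drift_shape == "linear":
        return config.drift_amplitude * x
    return config.drift_amplitude * (-x + 0.25 * np.sin(2 * np.pi * x))


def _assign_flags(config: SimConfig, rng) -> dict:
    p = config.n_features
    perm = rng.permutation(p)
    n_cont = int(round(config.frac_contaminant * p))
    contaminant = np.zeros(p, dtype=bool)
    contaminant[perm[:n_cont]] = True
    clean = np.flatnonzero(~contaminant)

    identified = np.zeros(p, dtype=bool)
    n_id = int(round(config.frac_identified * len(clean)))
    identified[rng.choice(clean, size=n_id, replace=False)] = True

    age_dep = np.zeros(p, dtype=bool)
    n_age = int(round(config.frac_age_dependent * len(clean)))
    age_dep[rng.choice(clean, size=n_age, replace=False)] = True
    slopes = np.zeros(p)
    slopes[age_dep] = rng.choice([-1, 1], size=n_age) * rng.uniform(0.01, 0.04, size=n_age)

    alb = np.zeros(p, dtype=bool)
    n_alb = int(round(config.albumin_link_frac * len(clean)))
    alb[rng.choice(clean, size=n_alb, replace=False)] = True

    fc = np.zeros(p)
    effects = np.asarray(config.group_effect_log2fc, dtype=float)
    # effects go to identified, non-contaminant, non-albumin features so the
    # cascade cannot silently discard the injected signal
    eligible = np.flatnonzero(identified & ~alb)
    n_eff = min(len(effects), len(eligible))
    chosen = rng.choice(eligible, size=n_eff, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_eff)
    fc[chosen] = signs * effects[:n_eff]
    return {
        "contaminant": contaminant, "identified": identified,
        "age_dep": age_dep, "age_slope": slopes, "albumin": alb, "spms_fc": fc,
    }


def generate_injection_table(
    cohort: list[SampleMeta], config: SimConfig
) -> tuple[InjectionTable, GroundTruth]:
    """Build the full injection sequence and its intensity matrix.

    Study injections are run in a seeded random order with a QC + blank pair
    inserted every ``qc_interval`` study injections (plus one leading pair);
    the dilution series is appended last. Intensities are constructed on the
    log2 scale (baseline + group effect + age term + albumin term + drift +
    noise) and exponentiated; contaminants appear in blanks at or above study
    level and flat across the dilution series.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    p = config.n_features

    feature_ids = [f"F{i + 1:04d}" for i in range(p)]
    mz = rng.uniform(70.0, 800.0, size=p)
    rt = rng.uniform(30.0, 900.0, size=p)
    base = rng.normal(14.0, 1.5, size=p)
    flags = _assign_flags(config, rng)

    truth = GroundTruth(
        feature_ids=feature_ids,
        is_contaminant=flags["contaminant"],
        is_age_dependent=flags["age_dep"],
        age_slope=flags["age_slope"],
        albumin_linked=flags["albumin"],
        true_group_log2fc={
            "SPMS:RRMS": flags["spms_fc"].copy(),
            "SPMS:control": flags["spms_fc"].copy(),
            "RRMS:control": np.zeros(p),
        },
        library_identity=[f"MET_{i + 1:04d}" if flags["identified"][i] else None
                         for i in range(p)],
    )

    # ---- per-subject log2 signal (before drift/noise) -----------------------
    ages = np.array([s.age for s in cohort])
    albs = np.array([s.albumin_ratio for s in cohort])
    mean_age = ages.mean()
    alb_z = (np.log(albs) - np.log(albs).mean()) / max(np.log(albs).std(), 1e-12)
    subject_log2 = np.empty((p, len(cohort)))
    for j, s in enumerate(cohort):
        v = base.copy()
        if s.group == "SPMS":
            v = v + flags["spms_fc"]
        v = v + flags["age_slope"] * (s.age - mean_age)
        v = v + np.where(flags["albumin"], 1.0 * alb_z[j], 0.0)
        subject_log2[:, j] = v
    # pooled QC: average of study samples on the raw scale
    qc_log2 = np.log2(np.mean(2.0 ** subject_log2, axis=1))

    # ---- injection sequence --------------------------------------------------
    study_units: list[tuple[str, int]] = []  # (sample_id, replicate_no)
    for j, s in enumerate(cohort):
        for r in range(config.n_replicates):
            study_units.append((s.sample_id, r + 1))
    order_perm = rng.permutation(len(study_units))
    rows = []  # (injection_id, type, sample_id, volume, signal_column)
    qc_count = blank_count = 0

    def add_qc_blank():
        nonlocal qc_count, blank_count
        qc_count += 1
        rows.append((f"QC{qc_count:02d}", "qc", None, None, ("qc", None)))
        blank_count += 1
        rows.append((f"BL{blank_count:02d}", "blank", None, None, ("blank", None)))

    add_qc_blank()
    for i, k in enumerate(order_perm):
        sid, rep = study_units[int(k)]
        rows.append((f"{sid}_r{rep}" if config.n_replicates > 1 else sid,
                     "study", sid, None, ("study", sid)))
        if (i + 1) % config.qc_interval == 0 and i + 1 < len(order_perm):
            add_qc_blank()
    add_qc_blank()
    for v in config.dilution_volumes:
        rows.append((f"DIL_{v:g}", "dilution", None, float(v), ("dilution", v)))

    n_inj = len(rows)
    orders = np.arange(1, n_inj + 1)
    drift = _drift(config, orders, n_inj)
    sample_index = {s.sample_id: j for j, s in enumerate(cohort)}

    blank_log2 = np.where(flags["contaminant"], base + 0.5, np.nan)

    cols = {}
    inj_meta = []
    for i, (inj_id, kind, sid, vol, sig) in enumerate(rows):
        if sig[0] == "study":
            v = subject_log2[:, sample_index[sig[1]]].copy()
        elif sig[0] == "qc":
            v = qc_log2.copy()
        elif sig[0] == "blank":
            v = blank_log2.copy()
        else:  # dilution: raw intensity scales with volume; contaminants flat
            scale = np.where(flags["contaminant"], 1.0, sig[1] / STANDARD_VOLUME_UL)
            v = qc_log2 + np.log2(scale)
        v = v + drift[i]
        if config.noise_sd > 0:
            v = v + rng.normal(0.0, config.noise_sd, size=p)
        raw = np.where(np.isnan(v), np.nan, 2.0 ** v)
        cols[inj_id] = raw
        inj_meta.append({"injection_id": inj_id, "type": kind, "order": int(orders[i]),
                         "sample_id": sid, "volume": vol})

    intensities = pd.DataFrame(cols, index=feature_ids)
    if config.missing_rate > 0:
        study_cols = [r["injection_id"] for r in inj_meta if r["type"] == "study"]
        mask = rng.random((p, len(study_cols))) < config.missing_rate
        sub = intensities[study_cols].to_numpy()
        sub[mask] = np.nan
        intensities[study_cols] = sub

    injections = pd.DataFrame(inj_meta).set_index("injection_id")
    feature_meta = pd.DataFrame({"mz": mz, "rt": rt}, index=feature_ids)
    table = InjectionTable(intensities, injections, feature_meta)
    return table, truth


def generate_library(
    feature_meta: pd.DataFrame, truth: GroundTruth, config: SimConfig
) -> list[LibraryEntry]:
    """Spectral library matching the identified synthetic features.

    Each identified feature gets an entry within 5 ppm / 5 s of its m/z and
    retention time, an optional KEGG-style id and a reproducible MS/MS peak
    list; ``config.n_decoys`` decoy entries sit 50+ ppm away and must never
    match at the default 15 ppm tolerance.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    entries: list[LibraryEntry] = []
    kegg_counter = 0
    for i, fid in enumerate(truth.feature_ids):
        name = truth.library_identity[i]
        if name is None:
            continue
        fmz = float(feature_meta.loc[fid, "mz"])
        frt = float(feature_meta.loc[fid, "rt"])
        kegg_counter += 1
        kegg = f"C{kegg_counter:05d}" if rng.random() < config.frac_kegg else None
        n_peaks = int(rng.integers(5, 11))
        pk_mz = np.sort(rng.uniform(50.0, fmz, size=n_peaks))
        pk_int = rng.uniform(1.0, 100.0, size=n_peaks)
        entries.append(LibraryEntry(
            name=name, kegg_id=kegg,
            mz=fmz * (1.0 + rng.uniform(-5, 5) * 1e-6),
            rt=frt + rng.uniform(-5, 5),
            adduct="[M + H]",
            ms2_peaks=[(round(float(m), 4), round(float(h), 2))
                       for m, h in zip(pk_mz, pk_int)],
        ))
    for d in range(config.n_decoys):
        fid = truth.feature_ids[int(rng.integers(0, len(truth.feature_ids)))]
        fmz = float(feature_meta.loc[fid, "mz"])
        entries.append(LibraryEntry(
            name=f"DECOY_{d + 1:03d}", kegg_id=None,
            mz=fmz * (1.0 + rng.uniform(50, 100) * 1e-6),
            rt=float(feature_meta.loc[fid, "rt"]) + rng.uniform(-5, 5),
            adduct="[M + H]",
            ms2_peaks=[(round(float(m), 4), 50.0)
                       for m in np.sort(rng.uniform(50.0, fmz, size=5))],
        ))
    return entries


def generate_pathway_library(
    n_pathways: int, size_range: tuple[int, int], universe_size: int, seed: int
) -> list[PathwayDef]:
    """Random pathway definitions: compound sets with connected graphs."""
    lo, hi = size_range
    if hi > universe_size:
        raise ValueError(f"size_range max {hi} exceeds universe_size {universe_size}")
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid size_range {size_range}")
    rng = np.random.default_rng(seed)
    universe = [f"C{i + 1:05d}" for i in range(universe_size)]
    paths = []
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        compounds = sorted(rng.choice(universe, size=size, replace=False))
        perm = list(rng.permutation(compounds))
        # random spanning tree, then a few chords
        edges = set()
        for i in range(1, len(perm)):
            j = int(rng.integers(0, i))
            edges.add(tuple(sorted((perm[i], perm[j]))))
        n_extra = int(rng.integers(0, max(1, size // 3)))
        for _ in range(n_extra):
            a, b = rng.choice(compounds, size=2, replace=False)
            edges.add(tuple(sorted((a, b))))
        paths.append(PathwayDef(
            pathway_id=f"path{k + 1:03d}", name=f"Synthetic pathway {k + 1}",
            compounds=set(compounds), edges=sorted(edges),
        ))
    return paths


# ---------------------------------------------------------------------------
# Disk writers (all plain text)
# ---------------------------------------------------------------------------

def cohort_to_frame(cohort: list[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in cohort]).set_index("sample_id")


def write_study(
    outdir: str | Path,
    cohort: list[SampleMeta],
    table: InjectionTable,
    truth: GroundTruth,
    library: list[LibraryEntry],
    pathway_library: list[PathwayDef],
    config: SimConfig,
) -> dict[str, Path]:
    """Write every artifact of one synthetic study to ``outdir``."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["samples"] = outdir / "samples.csv"
    cohort_to_frame(cohort).to_csv(paths["samples"], float_format="%.6g")

    feats = table.feature_meta.join(table.intensities)
    feats.index.name = "feature_id"
    paths["features"] = outdir / "features.csv"
    feats.to_csv(paths["features"], float_format="%.8g")

    paths["injections"] = outdir / "injections.csv"
    table.injections.to_csv(paths["injections"], float_format="%.6g")

    paths["library"] = outdir / "library.msp"
    write_msp(library, paths["library"])

    paths["pathways"] = outdir / "pathways.gmt"
    write_gmt(pathway_library, paths["pathways"])
    paths["pathway_edges"] = outdir / "pathway_edges.tsv"
    write_edges(pathway_library, paths["pathway_edges"])

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))

    paths["config"] = outdir / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return paths


def generate_study(config: SimConfig, n_pathways: int = 10, universe_size: int = 80):
    """Convenience wrapper producing all pieces of one synthetic study."""
    cohort = generate_cohort(config)
    table, truth = generate_injection_table(cohort, config)
    library = generate_library(table.feature_meta, truth, config)
    pathway_library = generate_pathway_library(
        n_pathways, (4, max(4, universe_size // 5)), universe_size, config.seed + 3
    )
    return cohort, table, truth, library, pathway_library
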