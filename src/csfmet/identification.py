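"""Library matching by m/z and retention time, plus MS/MS validation levels.

A feature matches a library entry when its mass error is within ``ppm_tol``
and its retention-time error within ``rt_tol_s``. Matched identities are then
graded: level 1 (m/z + RT only), level 2 (MS/MS fragmentation also matches)
or rejected (MS/MS available but inconsistent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

LEVEL1 = "level1"
LEVEL2 = "level2"
REJECTED = "rejected"
UNMATCHED = "unmatched"


@dataclass
class LibraryEntry:
    name: str
    mz: float
    rt: float
    kegg_id: str | None = None
    adduct: str = ""
    ms2_peaks: list[tuple[float, float]] | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"library entry {self.name!r}: mz must be > 0")
        if self.rt < 0:
            raise ValueError(f"library entry {self.name!r}: rt must be >= 0")
        if self.ms2_peaks:
            if any(i <= 0 for _, i in self.ms2_peaks):
                raise ValueError(f"library entry {self.name!r}: ms2 intensities must be > 0")


@dataclass
class IdentificationResult:
    feature_id: str
    entry: LibraryEntry | None = None
    ppm_error: float = math.nan
    rt_error: float = math.nan
    msms_peak_coverage: float = math.nan
    msms_shared_peaks: int = 0
    msms_dot_product: float = math.nan
    validation_level: str = LEVEL1

    @property
    def matched(self) -> bool:
        return self.entry is not None


def match_library(
    feature_meta: pd.DataFrame,
    library: list[LibraryEntry],
    ppm_tol: float = 15.0,
    rt_tol_s: float = 20.0,
) -> list[IdentificationResult]:
    """Match each feature (rows of ``feature_meta`` with ``mz``/``rt``) to the
    best library entry within tolerance.

    Ties are broken by smallest |ppm error|, then smallest |RT error|.
    Features without any in-tolerance entry come back with ``entry=None``.
    """
    if not library:
        raise ValueError("library is empty")
    results = []
    for fid, row in feature_meta.iterrows():
        fmz, frt = float(row["mz"]), float(row["rt"])
        best = None
        for entry in library:
            ppm = abs(fmz - entry.mz) / entry.mz * 1e6
            drt = abs(frt - entry.rt)
            if ppm <= ppm_tol and drt <= rt_tol_s:
                key = (ppm, drt)
                if best is None or key < best[0]:
                    best = (key, entry, (fmz - entry.mz) / entry.mz * 1e6, frt - entry.rt)
        if best is None:
            results.append(IdentificationResult(feature_id=str(fid), entry=None,
                                                validation_level=UNMATCHED))
        else:
            results.append(IdentificationResult(
                feature_id=str(fid), entry=best[1],
                ppm_error=best[2], rt_error=best[3],
            ))
    return results


def msms_match(
    observed: list[tuple[float, float]],
    reference: list[tuple[float, float]],
    frag_tol: float = 0.01,
) -> tuple[float, int, float, bool]:
    """Compare an observed MS/MS spectrum with a reference spectrum.

    Peaks are paired greedily by closest m/z within ``frag_tol`` (each peak
    used at most once). Returns ``(coverage, shared, dot, is_match)`` where
    coverage = shared / len(reference), dot is the cosine between the paired
    intensity vectors (unpaired peaks contribute zero to the numerator and
    their squared intensity to the norms), and the spectra match when
    (coverage >= 0.5 or shared >= 5) and dot > 0.5.
    """
    if not observed or not reference:
        raise ValueError("spectra must be non-empty")
    cands = []
    for i, (mo, _) in enumerate(observed):
        for j, (mr, _) in enumerate(reference):
            d = abs(mo - mr)
            if d <= frag_tol:
                cands.append((d, i, j))
    cands.sort()
    used_o: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cands:
        if i not in used_o and j not in used_r:
            pairs.append((i, j))
            used_o.add(i)
            used_r.add(j)
    shared = len(pairs)
    coverage = shared / len(reference)
    num = sum(observed[i][1] * reference[j][1] for i, j in pairs)
    norm_o = math.sqrt(sum(h * h for _, h in observed))
    norm_r = math.sqrt(sum(h * h for _, h in reference))
    dot = num / (norm_o * norm_r) if norm_o > 0 and norm_r > 0 else 0.0
    is_match = (coverage >= 0.5 or shared >= 5) and dot > 0.5
    return coverage, shared, dot, is_match


def assign_validation_level(
    result: IdentificationResult,
    observed_ms2: list[tuple[float, float]] | None,
    frag_tol: float = 0.01,
) -> str:
    """Grade a library match: level1 without MS/MS, level2 with a matching
    MS/MS, rejected when acquired MS/MS contradicts the reference."""
    if not result.matched:
        raise ValueError(f"feature {result.feature_id} has no library match")
    ref = result.entry.ms2_peaks
    if observed_ms2 is None or not ref:
        result.validation_level = LEVEL1
        return LEVEL1
    cov, shared, dot, ok = msms_match(observed_ms2, ref, frag_tol)
    result.msms_peak_coverage = cov
    result.msms_shared_peaks = shared
    result.msms_dot_product = dot
    result.validation_level = LEVEL2 if ok else REJECTED
    return result.validation_level


def results_to_frame(results: list[IdentificationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "feature_id": r.feature_id,
            "name": r.entry.name if r.entry else None,
            "kegg_id": r.entry.kegg_id if r.entry else None,
            "adduct": r.entry.adduct if r.entry else None,
            "ppm_error": r.ppm_error,
            "rt_error": r.rt_error,
            "msms_peak_coverage": r.msms_peak_coverage,
            "msms_shared_peaks": r.msms_shared_peaks,
            "msms_dot_product": r.msms_dot_product,
            "validation_level": r.validation_level,
            "matched": r.matched,
        })
    return pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# MSP I/O (NIST dialect: Name / PrecursorMZ / RT / Num Peaks + peak lines)
# ---------------------------------------------------------------------------

def write_msp(entries: list[LibraryEntry], path: str | Path) -> None:
    lines = []
    for e in entries:
        lines.append(f"Name: {e.name}")
        if e.kegg_id:
            lines.append(f"KEGG: {e.kegg_id}")
        if e.adduct:
            lines.append(f"Precursor_type: {e.adduct}")
        lines.append(f"PrecursorMZ: {e.mz:.6f}")
        lines.append(f"RT: {e.rt:.2f}")
        peaks = e.ms2_peaks or []
        lines.append(f"Num Peaks: {len(peaks)}")
        for m, h in peaks:
            lines.append(f"{m} {h}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_msp(path: str | Path) -> list[LibraryEntry]:
    entries: list[LibraryEntry] = []
    cur: dict = {}
    peaks: list[tuple[float, float]] = []
    expecting = 0

    def flush():
        if cur.get("name") is not None:
            entries.append(LibraryEntry(
                name=cur["name"], mz=cur["mz"], rt=cur.get("rt", 0.0),
                kegg_id=cur.get("kegg"), adduct=cur.get("adduct", ""),
                ms2_peaks=list(peaks) or None,
            ))

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if expecting > 0 and line[0].isdigit():
            m, h = line.split()[:2]
            peaks.append((float(m), float(h)))
            expecting -= 1
            continue
        key, _, val = line.partition(":")
        key = key.strip().lower()
        val = val.strip()
        if key == "name":
            flush()
            cur = {"name": val}
            peaks = []
            expecting = 0
        elif key == "precursormz":
            cur["mz"] = float(val)
        elif key == "rt":
            cur["rt"] = float(val)
        elif key == "kegg":
            cur["kegg"] = val
        elif key == "precursor_type":
            cur["adduct"] = val
        elif key == "num peaks":
            expecting = int(val)
    flush()
    return entries
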