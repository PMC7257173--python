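"""Transition-level to peptide-level quantification.

Raw peptide abundance in PRM is the sum of the chromatographic peak areas of
the monitored product ions (transitions). This module also provides the two
cosine-type spectral similarity scores used for identity QC (dotp against a
spectral library; rdotp between endogenous light and spiked heavy patterns),
light/heavy ratios for isotope-dilution accuracy checks, and APOE genotype
calls from the allele-specific peptide channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_TRANSITION_COLUMNS = [
    "sample_id", "batch", "injection_index", "protein", "peptide", "charge",
    "label", "fragment_ion", "area",
]


@dataclass(frozen=True)
class SpectralLibraryEntry:
    """Reference fragment-ion pattern for one peptide (max intensity = 1)."""

    peptide: str
    fragment_ions: tuple[str, ...]
    rel_intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fragment_ions) < 3:
            raise ValueError("spectral library entries need at least 3 fragments")
        if len(self.fragment_ions) != len(self.rel_intensity):
            raise ValueError("fragment_ions and rel_intensity length mismatch")
        if any(v < 0 for v in self.rel_intensity):
            raise ValueError("relative intensities must be non-negative")
        peak = max(self.rel_intensity)
        if not np.isclose(peak, 1.0):
            object.__setattr__(self, "rel_intensity",
                               tuple(v / peak for v in self.rel_intensity))

    def as_series(self) -> pd.Series:
        return pd.Series(self.rel_intensity, index=list(self.fragment_ions))


def library_from_frame(library: pd.DataFrame) -> dict[str, SpectralLibraryEntry]:
    """Build per-peptide library entries from a long (peptide, fragment_ion,
    rel_intensity) table."""
    entries = {}
    for pep, sub in library.groupby("peptide", sort=False):
        entries[pep] = SpectralLibraryEntry(
            peptide=pep,
            fragment_ions=tuple(sub["fragment_ion"]),
            rel_intensity=tuple(sub["rel_intensity"]),
        )
    return entries


# ---------------------------------------------------------------------------
# peptide area summation
# ---------------------------------------------------------------------------

def sum_transitions(records: pd.DataFrame, peptide: str | None = None,
                    sample: str | None = None, label: str = "light"):
    """Sum product-ion peak areas into raw peptide areas.

    With ``peptide`` and ``sample`` given, returns a dict for that single
    (peptide, sample) pair, or ``None`` when no matching transition exists
    (missing, never zero). Without them, returns a peptides x samples
    DataFrame of raw areas with NaN for unobserved pairs.
    """
    sub = records[records["label"] == label]
    if peptide is not None and sample is not None:
        sub = sub[(sub["peptide"] == peptide) & (sub["sample_id"] == sample)]
        if sub.empty:
            return None
        return {"peptide": peptide, "sample_id": sample,
                "raw_area": float(sub["area"].sum()),
                "n_transitions": int(len(sub))}
    wide = sub.pivot_table(index="peptide", columns="sample_id", values="area",
                           aggfunc="sum")
    # preserve first-appearance ordering rather than alphabetical
    pep_order = sub["peptide"].drop_duplicates()
    samp_order = sub["sample_id"].drop_duplicates()
    return wide.reindex(index=pep_order, columns=samp_order)


# ---------------------------------------------------------------------------
# spectral similarity
# ---------------------------------------------------------------------------

def _aligned(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    ions = a.index.union(b.index, sort=False)
    return (a.reindex(ions, fill_value=0.0).to_numpy(float),
            b.reindex(ions, fill_value=0.0).to_numpy(float))


def _cosine(x: np.ndarray, y: np.ndarray, sqrt_transform: bool) -> float | None:
    if np.all(x == 0):
        return None
    if np.all(y == 0):
        return 0.0
    if sqrt_transform:
        x, y = np.sqrt(x), np.sqrt(y)
    return float(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)))


def dotp(observed: pd.Series, library: SpectralLibraryEntry,
         sqrt_transform: bool = True) -> float | None:
    """Library dot product: cosine similarity between the observed transition
    areas and the library pattern, aligned on the union of fragment ions
    (absent ions contribute 0).

    By default intensities are square-root transformed before the cosine
    (the convention of the mainstream targeted-proteomics software); pass
    ``sqrt_transform=False`` for a plain-intensity cosine. Returns ``None``
    when the observed vector is all zero.
    """
    obs, lib = _aligned(observed, library.as_series())
    if np.any(obs < 0) or np.any(lib < 0):
        raise ValueError("intensities must be non-negative")
    return _cosine(obs, lib, sqrt_transform)


def rdotp(light: pd.Series, heavy: pd.Series,
          sqrt_transform: bool = True) -> float | None:
    """Ratio dot product: cosine similarity between the endogenous (light)
    and heavy-standard transition patterns, aligned on the union of ions."""
    x, y = _aligned(light, heavy)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("intensities must be non-negative")
    return _cosine(x, y, sqrt_transform)


def dotp_table(records: pd.DataFrame, library: pd.DataFrame,
               sqrt_transform: bool = True) -> pd.DataFrame:
    """dotp for every (peptide, sample) with light transitions present."""
    entries = library_from_frame(library)
    rows = []
    sub = records[records["label"] == "light"]
    for (pep, samp), grp in sub.groupby(["peptide", "sample_id"], sort=False):
        entry = entries.get(pep)
        if entry is None:
            continue
        obs = grp.set_index("fragment_ion")["area"]
        rows.append((pep, samp, dotp(obs, entry, sqrt_transform)))
    return pd.DataFrame(rows, columns=["peptide", "sample_id", "dotp"])


# ---------------------------------------------------------------------------
# light / heavy ratios
# ---------------------------------------------------------------------------

def light_heavy_ratio(light_area: float, heavy_area: float) -> float:
    """Endogenous / heavy-standard peak-area ratio; NaN when the heavy area
    is missing or non-positive."""
    if heavy_area is None or not np.isfinite(heavy_area) or heavy_area <= 0:
        return float("nan")
    if light_area is None or not np.isfinite(light_area):
        return float("nan")
    return float(light_area) / float(heavy_area)


def light_heavy_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per (peptide, sample) light/heavy ratio for peptides with a spiked
    heavy counterpart."""
    light = sum_transitions(records, label="light")
    heavy = sum_transitions(records, label="heavy")
    shared = heavy.index.intersection(light.index)
    ratio = light.loc[shared] / heavy.loc[shared].where(heavy.loc[shared] > 0)
    out = ratio.stack().rename("ratio").reset_index()
    return out


# ---------------------------------------------------------------------------
# APOE genotyping
# ---------------------------------------------------------------------------

def apoe_genotype(e2_area: float, e4_area: float,
                  detection_threshold: float) -> str:
    """Call an APOE genotype from the allele-specific peptide areas.

    An allele counts as present when its specific peptide area is at or
    above ``detection_threshold``; E3 (which has no variant-specific
    peptide) fills the remaining allele slots:

    - neither detected -> E3/E3
    - one variant detected -> heterozygote with E3 (single-allele assumption)
    - both detected -> E2/E4
    """
    e2 = np.isfinite(e2_area) and e2_area >= detection_threshold
    e4 = np.isfinite(e4_area) and e4_area >= detection_threshold
    if e2 and e4:
        return "E2/E4"
    if e2:
        return "E2/E3"
    if e4:
        return "E3/E4"
    return "E3/E3"


def apoe_detection_threshold(blank_areas, factor: float = 5.0) -> float:
    """Default detection cutoff: ``factor`` times the median blank-level area."""
    arr = np.asarray(blank_areas, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no blank-level areas provided")
    return factor * float(np.median(arr))


def apoe_genotype_table(apoe: pd.DataFrame,
                        detection_threshold: float | None = None) -> pd.DataFrame:
    """Genotype every sample in an APOE channel table.

    When no threshold is given it is derived as 5x the median of the lower
    half of each allele channel (a blank-level proxy), pooled over alleles.
    """
    if detection_threshold is None:
        pooled = np.concatenate([
            np.sort(apoe["apoee2_area"].to_numpy())[: max(1, len(apoe) // 2)],
            np.sort(apoe["apoee4_area"].to_numpy())[: max(1, len(apoe) // 2)],
        ])
        detection_threshold = apoe_detection_threshold(pooled)
    calls = [apoe_genotype(r.apoee2_area, r.apoee4_area, detection_threshold)
             for r in apoe.itertuples()]
    out = apoe[["sample_id"]].copy()
    out["genotype"] = calls
    return out
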