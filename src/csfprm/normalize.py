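"""Normalization cascade for label-free PRM peak areas.

Stage order (enforced by the pipeline, tracked in ``DataFrame.attrs``):

1. drift correction — per-injection factors from spiked reference standards,
2. peptide -> protein roll-up (sum of observed peptides),
3. GIS-pool normalization — divide by the per-batch mean of the pooled
   global internal standard injections (per-batch GIS mean becomes 1),
4. log2 transform,
5. covariate regression — residuals of an OLS fit on age and sex, centered
   to mean zero per protein.

Precision QC (CV% on GIS replicate injections, pre and post normalization)
lives here too.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CV_PRECISION_THRESHOLD = 30.0  # % — at or below counts as high precision


class NormalizationError(ValueError):
    """Raised when a normalization stage cannot be computed."""


def _stage(frame: pd.DataFrame, stage: str) -> pd.DataFrame:
    frame.attrs["stage"] = stage
    return frame


# ---------------------------------------------------------------------------
# drift correction from reference standards
# ---------------------------------------------------------------------------

def drift_factors(reference_areas: pd.DataFrame) -> pd.Series:
    """Per-injection drift factor from spiked reference-standard areas.

    ``reference_areas`` is reference peptides x injections. Each reference
    peptide is scaled by its own across-injection median; the factor for an
    injection is the geometric mean of those scaled values over reference
    peptides. Dividing by the factor removes shared multiplicative signal
    drift while the geometric mean keeps one aberrant standard from
    dominating.
    """
    dead = reference_areas.isna().all(axis=0)
    if dead.any():
        missing = ", ".join(map(str, reference_areas.columns[dead]))
        raise NormalizationError(
            f"injection(s) with no reference peptide measured: {missing}")
    if (reference_areas <= 0).any().any():
        raise NormalizationError("reference areas must be positive")
    med = reference_areas.median(axis=1)
    scaled = np.log(reference_areas.div(med, axis=0))
    return np.exp(scaled.mean(axis=0, skipna=True)).rename("drift_factor")


def apply_drift_correction(peptide_matrix: pd.DataFrame,
                           factors: pd.Series) -> pd.DataFrame:
    """Divide every injection's peptide areas by its drift factor."""
    missing = peptide_matrix.columns.difference(factors.index)
    if len(missing):
        raise NormalizationError(
            f"no drift factor for injection(s): {', '.join(map(str, missing))}")
    out = peptide_matrix.div(factors.reindex(peptide_matrix.columns), axis=1)
    return _stage(out, "drift_corrected")


# ---------------------------------------------------------------------------
# protein roll-up
# ---------------------------------------------------------------------------

def rollup_protein(peptide_matrix: pd.DataFrame,
                   peptide_protein: pd.Series) -> pd.DataFrame:
    """Sum drift-corrected peptide areas into protein areas.

    ``peptide_protein`` maps peptide -> protein (must be single-valued:
    targets are proteotypic). Missing peptides are excluded from the sum,
    not zero-filled; a protein with no observed peptide in an injection is
    missing there.
    """
    if peptide_protein.index.has_duplicates:
        dup = peptide_protein.index[peptide_protein.index.duplicated()][0]
        raise NormalizationError(
            f"peptide mapped to more than one protein: {dup}")
    mapping = peptide_protein.reindex(peptide_matrix.index)
    if mapping.isna().any():
        lost = ", ".join(map(str, mapping.index[mapping.isna()][:5]))
        raise NormalizationError(f"peptides without protein mapping: {lost}")
    grouped = peptide_matrix.groupby(mapping, sort=False).sum(min_count=1)
    grouped.index.name = "protein"
    return _stage(grouped, "protein_raw")


# ---------------------------------------------------------------------------
# GIS-pool normalization
# ---------------------------------------------------------------------------

def gis_normalize(protein_matrix: pd.DataFrame, metadata: pd.DataFrame,
                  per_batch: bool = True) -> pd.DataFrame:
    """Normalize each protein by the mean of the GIS pool injections.

    With ``per_batch`` (default) the divisor is the arithmetic mean of the
    GIS injections in the same batch, so the per-batch GIS mean of every
    protein becomes exactly 1 and batch-scale differences cancel; with
    ``per_batch=False`` a single global GIS mean is used.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns \
        else metadata
    gis_ids = meta.index[meta["group"] == "GIS"]
    gis_cols = protein_matrix.columns.intersection(gis_ids)
    if len(gis_cols) == 0:
        raise NormalizationError("no GIS injections present in the matrix")
    if not per_batch:
        denom = protein_matrix[gis_cols].mean(axis=1)
        bad = ~(denom > 0) | denom.isna()
        if bad.any():
            raise NormalizationError(
                f"non-positive/missing GIS mean for protein(s): "
                f"{', '.join(map(str, denom.index[bad][:5]))}")
        return _stage(protein_matrix.div(denom, axis=0), "gis_ratio")

    batches = meta.loc[protein_matrix.columns, "batch"]
    out = pd.DataFrame(index=protein_matrix.index,
                       columns=protein_matrix.columns, dtype=float)
    for b, cols in protein_matrix.columns.groupby(batches).items():
        b_gis = [c for c in cols if c in set(gis_cols)]
        if not b_gis:
            raise NormalizationError(f"batch {b} has no GIS injection")
        denom = protein_matrix[b_gis].mean(axis=1)
        bad = ~(denom > 0) | denom.isna()
        if bad.any():
            raise NormalizationError(
                f"non-positive/missing GIS mean in batch {b} for protein(s): "
                f"{', '.join(map(str, denom.index[bad][:5]))}")
        out[list(cols)] = protein_matrix[list(cols)].div(denom, axis=0)
    return _stage(out, "gis_ratio")


# ---------------------------------------------------------------------------
# precision QC
# ---------------------------------------------------------------------------

def compute_cv(values) -> float:
    """Coefficient of variation, percent: 100 * sample SD / mean.

    Computed on linear-scale replicate measurements; NaN when fewer than two
    replicates are present or the mean is not positive.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean <= 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


def gis_cv_table(matrix: pd.DataFrame, metadata: pd.DataFrame,
                 cv_threshold: float = CV_PRECISION_THRESHOLD) -> pd.DataFrame:
    """Per-row CV% across GIS replicate injections, with a precision flag
    (high precision iff CV <= threshold)."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns \
        else metadata
    gis_cols = matrix.columns.intersection(meta.index[meta["group"] == "GIS"])
    if len(gis_cols) < 2:
        raise NormalizationError("need at least two GIS injections for CVs")
    cvs = matrix[gis_cols].apply(compute_cv, axis=1)
    return pd.DataFrame({
        "cv_pct": cvs,
        "high_precision": cvs <= cv_threshold,
    })


def qc_report(raw_peptides: pd.DataFrame, corrected_peptides: pd.DataFrame,
              proteins_normalized: pd.DataFrame, metadata: pd.DataFrame,
              cv_threshold: float = CV_PRECISION_THRESHOLD) -> dict:
    """Summarize precision on the GIS replicates before and after
    normalization, at peptide and protein level."""
    pep_pre = gis_cv_table(raw_peptides, metadata, cv_threshold)
    pep_post = gis_cv_table(corrected_peptides, metadata, cv_threshold)
    prot_post = gis_cv_table(proteins_normalized, metadata, cv_threshold)
    return {
        "peptide_cv_pre": pep_pre,
        "peptide_cv_post": pep_post,
        "protein_cv": prot_post,
        "mean_peptide_cv_pre_pct": float(pep_pre["cv_pct"].mean()),
        "mean_peptide_cv_post_pct": float(pep_post["cv_pct"].mean()),
        "mean_protein_cv_pct": float(prot_post["cv_pct"].mean()),
        "frac_proteins_high_precision": float(prot_post["high_precision"].mean()),
    }


# ---------------------------------------------------------------------------
# covariate regression
# ---------------------------------------------------------------------------

def regress_covariates(log2_matrix: pd.DataFrame, metadata: pd.DataFrame,
                       covariates: tuple[str, ...] = ("age", "sex")) -> pd.DataFrame:
    """Residualize each protein's log2 ratios on age and sex, centered to
    mean zero.

    GIS injections must already be excluded. A covariate with no variation
    (e.g. a single-sex cohort) is dropped with a warning rather than making
    the design rank-deficient. Residuals of an OLS fit with intercept have
    mean exactly zero and zero sample covariance with every retained
    covariate.
    """
    import warnings

    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns \
        else metadata
    cols = log2_matrix.columns
    if (meta.loc[cols, "group"] == "GIS").any():
        raise NormalizationError("exclude GIS injections before regression")
    design_cols = []
    for cov in covariates:
        vals = pd.to_numeric(meta.loc[cols, cov])
        if vals.isna().any():
            raise NormalizationError(f"missing {cov} among included samples")
        if vals.nunique() < 2:
            warnings.warn(f"covariate {cov!r} has no variation; dropped",
                          UserWarning, stacklevel=2)
            continue
        design_cols.append(vals.to_numpy(float))
    x = np.column_stack([np.ones(len(cols))] + design_cols)
    y = log2_matrix.to_numpy(float).T          # injections x proteins
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    resid -= resid.mean(axis=0, keepdims=True)  # exact zero mean per protein
    out = pd.DataFrame(resid.T, index=log2_matrix.index, columns=cols)
    return _stage(out, "regressed_log2")


# ---------------------------------------------------------------------------
# convenience: full cascade
# ---------------------------------------------------------------------------

def normalize_cascade(peptide_matrix: pd.DataFrame,
                      reference_areas: pd.DataFrame,
                      peptide_protein: pd.Series,
                      metadata: pd.DataFrame,
                      per_batch_gis: bool = True) -> dict:
    """Run drift correction -> roll-up -> GIS normalization -> log2 ->
    covariate regression; returns every intermediate stage."""
    factors = drift_factors(reference_areas)
    corrected = apply_drift_correction(peptide_matrix, factors)
    proteins = rollup_protein(corrected, peptide_protein)
    ratios = gis_normalize(proteins, metadata, per_batch=per_batch_gis)
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns \
        else metadata
    bio_cols = [c for c in ratios.columns if meta.loc[c, "group"] != "GIS"]
    log2_bio = _stage(np.log2(ratios[bio_cols]), "log2_ratio")
    regressed = regress_covariates(log2_bio, metadata)
    return {
        "drift_factors": factors,
        "peptides_corrected": corrected,
        "proteins_raw": proteins,
        "proteins_ratio": ratios,
        "proteins_log2": log2_bio,
        "proteins_regressed": regressed,
    }
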