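"""Differential abundance, robust trait correlation, and cohort concordance.

Differential abundance follows the targeted-panel convention: one-way ANOVA
across the three diagnostic groups per protein, Tukey HSD for the pairwise
contrasts, and Benjamini-Hochberg FDR across the protein family on the ANOVA
p-values. A protein is called an AD-specific marker when its FDR-adjusted
ANOVA q is significant, both Tukey contrasts involving AD are significant,
and the AD group mean is consistently the extreme one.

Trait association uses the biweight midcorrelation (bicor), a median/MAD-
based robust correlation, with Student-type p-values on n-2 degrees of
freedom.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GROUPS = ("Control", "AD", "NonAD")
CONTRASTS = (("AD", "Control"), ("AD", "NonAD"), ("NonAD", "Control"))


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def diff_test(matrix: pd.DataFrame, groups: pd.Series, alpha: float = 0.05,
              fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein one-way ANOVA with Tukey HSD post hoc and BH FDR.

    ``matrix`` is proteins x biological samples (regressed log2 values);
    ``groups`` maps sample -> diagnostic group. Returns one row per protein
    with group means +- SE, ANOVA F and p, Tukey-adjusted p for the three
    pairwise contrasts, the BH-adjusted q across proteins, and an
    ``ad_marker`` flag (q < fdr_alpha, both AD contrasts' Tukey p < alpha,
    AD mean strictly highest or lowest).
    """
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group assignment")
    present = [g for g in GROUPS if (groups == g).any()]
    if len(present) < 2:
        raise ValueError("need at least two diagnostic groups")
    idx = {g: matrix.columns[(groups == g).to_numpy()] for g in present}
    if any(len(idx[g]) < 2 for g in present):
        raise ValueError("every group needs at least two samples")

    rows = []
    for protein, values in matrix.iterrows():
        samples = [values[idx[g]].to_numpy(float) for g in present]
        if all(np.ptp(s) == 0 for s in samples):
            raise ValueError(
                f"zero within-group variance for every group ({protein})")
        f_stat, p_anova = sps.f_oneway(*samples)
        tukey = sps.tukey_hsd(*samples)
        row = {"protein": protein, "anova_F": float(f_stat),
               "anova_p": float(p_anova)}
        for g, s in zip(present, samples):
            row[f"mean_{g}"] = float(s.mean())
            row[f"se_{g}"] = float(s.std(ddof=1) / np.sqrt(len(s)))
        for a, b in CONTRASTS:
            if a in present and b in present:
                row[f"tukey_p_{a}_vs_{b}"] = float(
                    tukey.pvalue[present.index(a), present.index(b)])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("protein")
    out["anova_q"] = multipletests(out["anova_p"], method="fdr_bh")[1]

    if all(g in present for g in GROUPS):
        means = out[[f"mean_{g}" for g in GROUPS]].to_numpy()
        ad, ctl, non = means[:, 1], means[:, 0], means[:, 2]
        extreme = ((ad > ctl) & (ad > non)) | ((ad < ctl) & (ad < non))
        out["ad_marker"] = ((out["anova_q"] < fdr_alpha)
                            & (out["tukey_p_AD_vs_Control"] < alpha)
                            & (out["tukey_p_AD_vs_NonAD"] < alpha)
                            & extreme)
    return out


def group_log2fc(matrix: pd.DataFrame, groups: pd.Series,
                 case: str = "AD", control: str = "Control") -> pd.Series:
    """Per-protein mean difference case - control (log2 fold change when the
    matrix holds log2 values)."""
    groups = groups.reindex(matrix.columns)
    return (matrix.loc[:, (groups == case).to_numpy()].mean(axis=1)
            - matrix.loc[:, (groups == control).to_numpy()].mean(axis=1))


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------

def _biweight(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Tukey biweight deviations w*(x-med); returns (weighted deviations,
    fell_back_to_identity_weights)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x - np.mean(x), True
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    return w * (x - med), False


def bicor(x, y) -> float:
    """Biweight midcorrelation between two vectors.

    Each vector is centered at its median and downweighted by Tukey
    biweights computed from deviations scaled by 9*MAD; observations beyond
    9 MADs get zero weight, which makes the statistic resistant to gross
    outliers. When a vector has zero MAD (more than half its values tied)
    that side falls back to Pearson-style mean-centering, with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("bicor needs at least 4 observations")
    dx, fb_x = _biweight(x)
    dy, fb_y = _biweight(y)
    if fb_x or fb_y:
        warnings.warn("zero MAD; falling back to Pearson-style centering",
                      UserWarning, stacklevel=2)
    denom = np.sqrt((dx ** 2).sum() * (dy ** 2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def cor_pvalue(r: float, n: int) -> float:
    """Two-sided Student p-value for a correlation on n-2 df."""
    if not np.isfinite(r) or n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def trait_correlations(matrix: pd.DataFrame, metadata: pd.DataFrame,
                       traits: tuple[str, ...] = ("ttau", "ptau", "abeta42",
                                                  "tau_abeta_ratio"),
                       method: str = "bicor", platform: str | None = "Luminex",
                       log_transform: bool = False) -> pd.DataFrame:
    """Correlate each protein (or peptide) row with immunoassay traits.

    Restricted by default to samples assayed on one immunoassay platform so
    absolute trait values are comparable. ``tau_abeta_ratio`` is derived as
    ttau / abeta42. ``method`` is ``"bicor"`` (robust, default) or
    ``"pearson"``; ``log_transform`` applies log2 to both sides first.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns \
        else metadata
    cols = matrix.columns.intersection(meta.index[meta["group"] != "GIS"])
    if platform is not None:
        cols = cols.intersection(meta.index[meta["platform"] == platform])
    rows = []
    for trait in traits:
        if trait == "tau_abeta_ratio":
            tvals = meta.loc[cols, "ttau"] / meta.loc[cols, "abeta42"]
        else:
            tvals = pd.to_numeric(meta.loc[cols, trait])
        ok = tvals.notna()
        for feature, values in matrix[cols].iterrows():
            v = values[ok.to_numpy()].astype(float)
            t = tvals[ok].to_numpy(float)
            keep = np.isfinite(v.to_numpy())
            v, t = v.to_numpy()[keep], t[keep]
            if log_transform:
                v, t = np.log2(v), np.log2(t)
            if len(v) < 4:
                r = float("nan")
            elif method == "bicor":
                r = bicor(v, t)
            elif method == "pearson":
                r = float(sps.pearsonr(v, t).statistic)
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append((feature, trait, r, cor_pvalue(r, len(v)), len(v)))
    return pd.DataFrame(rows, columns=["feature", "trait", "cor", "p", "n"])


# ---------------------------------------------------------------------------
# cross-cohort concordance
# ---------------------------------------------------------------------------

def cohort_concordance(log2fc_replication: pd.Series,
                       log2fc_discovery: pd.Series) -> dict:
    """Agreement of per-protein log2 fold changes between a replication and
    a discovery cohort: Pearson correlation, its p-value, and the OLS line
    replication ~ discovery, on shared proteins."""
    shared = log2fc_replication.index.intersection(log2fc_discovery.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared proteins")
    x = log2fc_discovery.loc[shared].to_numpy(float)
    y = log2fc_replication.loc[shared].to_numpy(float)
    fit = sps.linregress(x, y)
    r, p = sps.pearsonr(x, y)
    return {"cor": float(r), "p": float(p), "slope": float(fit.slope),
            "intercept": float(fit.intercept), "n": int(len(shared))}
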