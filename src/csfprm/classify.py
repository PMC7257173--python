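"""Per-protein cross-validated logistic classification and ROC analysis.

Each candidate biomarker is evaluated alone: a logistic regression on the
single protein value (plus intercept) is trained with stratified five-fold
cross-validation, the out-of-fold predicted probabilities are pooled, and
one ROC curve / AUC is computed from the pooled predictions. Three binary
tasks mirror the clinical questions: AD vs control, AD vs non-AD cognitive
impairment, and CSF amyloid/tau biomarker positivity (Abeta42/tTau ratio
below a fixed cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

ABETA_TAU_THRESHOLD = 4.6  # Abeta42 / tTau below this = biomarker positive

IRLS_MAX_ITER = 100
IRLS_DEVIANCE_TOL = 1e-8


# ---------------------------------------------------------------------------
# task labels
# ---------------------------------------------------------------------------

def abeta_tau_label(abeta42: float, ttau: float,
                    threshold: float = ABETA_TAU_THRESHOLD) -> int | None:
    """AD biomarker positivity from the CSF Abeta42/total-Tau ratio.

    Positive (1, AD-like: low amyloid relative to tau) iff
    ``abeta42 / ttau < threshold``; a ratio exactly at the threshold is
    negative (positivity is a strict inequality). Missing immunoassay
    values return ``None`` (sample excluded); non-positive tTau is an error.
    """
    if abeta42 is None or ttau is None or not np.isfinite(abeta42) \
            or not np.isfinite(ttau):
        return None
    if ttau <= 0:
        raise ValueError("total-Tau must be positive")
    return int(abeta42 / ttau < threshold)


@dataclass
class BinaryTask:
    """A named binary classification task over a subset of samples."""

    name: str
    labels: pd.Series  # sample_id -> {0, 1}

    def __post_init__(self) -> None:
        vals = set(self.labels.dropna().unique().tolist())
        if not vals <= {0, 1}:
            raise ValueError("labels must be 0/1")
        if len(vals) < 2:
            raise ValueError(f"task {self.name!r} needs both classes")

    @property
    def samples(self) -> pd.Index:
        return self.labels.index


def diagnosis_task(metadata: pd.DataFrame, case: str = "AD",
                   control: str = "Control") -> BinaryTask:
    """Label ``case`` samples 1 and ``control`` samples 0; others excluded."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns \
        else metadata
    keep = meta["group"].isin([case, control])
    labels = (meta.loc[keep, "group"] == case).astype(int)
    return BinaryTask(name=f"{case}_vs_{control}", labels=labels)


def ratio_task(metadata: pd.DataFrame, threshold: float = ABETA_TAU_THRESHOLD,
               platform: str | None = "Luminex") -> BinaryTask:
    """Biomarker-positivity task from immunoassay Abeta42/tTau ratios,
    restricted to one assay platform (absolute values are platform-bound)."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns \
        else metadata
    sub = meta[meta["group"] != "GIS"]
    if platform is not None:
        sub = sub[sub["platform"] == platform]
    labels = {}
    for sid, row in sub.iterrows():
        lab = abeta_tau_label(row.get("abeta42"), row.get("ttau"), threshold)
        if lab is not None:
            labels[sid] = lab
    return BinaryTask(name="AbetaTauRatio", labels=pd.Series(labels, dtype=int))


# ---------------------------------------------------------------------------
# logistic regression by IRLS
# ---------------------------------------------------------------------------

def fit_logistic_irls(x: np.ndarray, y: np.ndarray,
                      max_iter: int = IRLS_MAX_ITER,
                      tol: float = IRLS_DEVIANCE_TOL) -> dict:
    """Unregularized single-feature logistic regression via iteratively
    reweighted least squares.

    Returns intercept, slope, deviance, iteration count and a ``separated``
    flag. Under complete separation the deviance keeps shrinking and the
    coefficients diverge; iterations are capped, the flag is set, and the
    (monotone) linear scores remain usable for ranking-based metrics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xmat = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    deviance = np.inf
    separated = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = np.clip(xmat @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        wx = xmat * w[:, None]
        try:
            beta = np.linalg.solve(xmat.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            separated = True
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = y * np.log(np.clip(mu, 1e-300, 1)) \
                + (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))
        new_dev = -2.0 * ll.sum()
        if abs(deviance - new_dev) < tol:
            deviance = new_dev
            break
        deviance = new_dev
    else:
        separated = True
    if np.abs(beta[1]) > 1e3 or deviance < tol:
        separated = True
    return {"intercept": float(beta[0]), "slope": float(beta[1]),
            "deviance": float(deviance), "n_iter": n_iter,
            "separated": bool(separated)}


def predict_logistic(model: dict, x: np.ndarray) -> np.ndarray:
    eta = np.clip(model["intercept"] + model["slope"] * np.asarray(x, float),
                  -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC points at every distinct score threshold (ties grouped), from
    (0, 0) to (1, 1)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores,
                                         drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


def auc_trapezoid(scores, labels) -> float:
    """Area under the ROC curve by the trapezoid rule (equals the tie-aware
    Mann-Whitney statistic U / (n1 * n0))."""
    curve = roc_curve(scores, labels)
    return float(np.trapezoid(curve["tpr"], curve["fpr"]))


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Cross-validated single-protein classification result."""

    protein: str
    task: str
    auc: float
    predictions: pd.Series          # out-of-fold probability per sample
    curve: pd.DataFrame             # fpr / tpr / threshold
    n_positive: int
    n_negative: int
    folds: int
    seed: int
    separated_folds: int = 0
    fold_models: list[dict] = field(default_factory=list)


def train_cv_classifier(values: pd.Series, task: BinaryTask, k: int = 5,
                        seed: int = 0, protein: str = "") -> RocResult:
    """Stratified k-fold cross-validated logistic regression on one protein.

    Out-of-fold predicted probabilities are pooled into a single ROC/AUC
    (one curve per protein rather than averaging per-fold curves).
    Deterministic given ``seed`` (fold shuffling is the only randomness).
    """
    common = task.samples.intersection(values.dropna().index)
    y = task.labels.loc[common].to_numpy(int)
    x = values.loc[common].to_numpy(float)
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required after filtering")
    if len(y) < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    prob = np.empty(len(y))
    models = []
    n_sep = 0
    for train_idx, test_idx in skf.split(x.reshape(-1, 1), y):
        model = fit_logistic_irls(x[train_idx], y[train_idx])
        n_sep += int(model["separated"])
        models.append(model)
        prob[test_idx] = predict_logistic(model, x[test_idx])
    curve = roc_curve(prob, y)
    auc = float(np.trapezoid(curve["tpr"], curve["fpr"]))
    return RocResult(protein=protein, task=task.name, auc=auc,
                     predictions=pd.Series(prob, index=common),
                     curve=curve, n_positive=n1, n_negative=n0, folds=k,
                     seed=seed, separated_folds=n_sep, fold_models=models)


def roc_panel(matrix: pd.DataFrame, tasks: list[BinaryTask], k: int = 5,
              seed: int = 0) -> pd.DataFrame:
    """Cross-validated AUC for every protein x task combination."""
    rows = []
    for task in tasks:
        for protein, values in matrix.iterrows():
            res = train_cv_classifier(values, task, k=k, seed=seed,
                                      protein=str(protein))
            rows.append((protein, task.name, res.auc, res.n_positive,
                         res.n_negative, res.separated_folds))
    return pd.DataFrame(rows, columns=["protein", "task", "auc", "n_positive",
                                       "n_negative", "separated_folds"])
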