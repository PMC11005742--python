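"""Simulated-vs-real mismatch diagnostics and performance evaluation.

Covariate shift between the simulated (source) and real (target) domains is
quantified three ways: per-statistic two-sample tests (Kolmogorov-Smirnov
and Mann-Whitney U, with Benjamini-Hochberg adjustment across the 40
statistics), joint PCA of the pooled feature space, and a cross-validated
RBF-kernel SVM trained to tell the domains apart, with label-shuffle
controls whose AUC should sit at 0.5.

Evaluation follows the sweep-detection conventions: linked and neutral
classes are negatives, selected classes positives; the model's sweep score
is P(hard) + P(soft); confusion matrices are oriented with true labels on
columns and predicted labels on rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .dann import CLASS_ORDER

HARD, LINKED_HARD, SOFT, LINKED_SOFT, NEUTRAL = range(5)
SWEEP_CLASSES = (HARD, SOFT)


@dataclass
class MismatchReport:
    per_stat_tests: pd.DataFrame
    pca_source: np.ndarray
    pca_target: np.ndarray
    explained_variance: np.ndarray
    domain_auc: float
    control_aucs: list[float] = field(default_factory=list)


def collapse_features(X: np.ndarray) -> np.ndarray:
    """Collapse (N, n_stats, m) grids to one value per statistic per case.

    The mean is taken over occupied positional intervals only, so the
    zero-fill of empty intervals does not dilute the statistic level.
    """
    if X.ndim == 2:
        return X
    occupied = np.any(X != 0, axis=1, keepdims=True)  # (N, 1, m)
    denom = np.maximum(occupied.sum(axis=2), 1)
    return (X * occupied).sum(axis=2) / denom


def per_stat_mismatch(
    source_feats: np.ndarray, target_feats: np.ndarray, names: list[str] | None = None
) -> pd.DataFrame:
    """Two-sample K-S and Mann-Whitney U tests per statistic.

    Returns one row per statistic with D, U, raw p-values and BH-adjusted q
    values; statistics constant on both sides are flagged and skipped.
    """
    src = collapse_features(np.asarray(source_feats))
    tgt = collapse_features(np.asarray(target_feats))
    if src.shape[0] < 20 or tgt.shape[0] < 20:
        raise ValueError("need at least 20 cases per domain per statistic")
    n_stats = src.shape[1]
    names = names if names is not None else [f"stat_{i}" for i in range(n_stats)]
    rows = []
    for i in range(n_stats):
        a, b = src[:, i], tgt[:, i]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            rows.append((names[i], np.nan, np.nan, np.nan, np.nan, True))
            continue
        ks = stats.ks_2samp(a, b)
        mwu = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append((names[i], ks.statistic, ks.pvalue, mwu.statistic, mwu.pvalue, False))
    df = pd.DataFrame(
        rows, columns=["stat", "ks_D", "ks_p", "mwu_U", "mwu_p", "skipped"]
    )
    for col in ("ks_p", "mwu_p"):
        q = np.full(len(df), np.nan)
        ok = df[col].notna().to_numpy()
        if ok.any():
            q[ok] = multipletests(df.loc[ok, col], method="fdr_bh")[1]
        df[col.replace("_p", "_q")] = q
    return df


def joint_pca(
    source_feats: np.ndarray, target_feats: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray, PCA]:
    """PCA fitted on the pooled, centered feature matrix.

    Features enter this function already on a common scale (min-max
    standardized grids, or extractor embeddings), so only centering is
    applied; between-domain mean shifts then surface directly in the
    leading components.
    """
    src = collapse_features(np.asarray(source_feats))
    tgt = collapse_features(np.asarray(target_feats))
    pooled = np.vstack([src, tgt])
    if pooled.shape[0] < n_components:
        raise ValueError("fewer samples than components")
    pca = PCA(n_components=n_components).fit(pooled)
    proj = pca.transform(pooled)
    return proj[: len(src)], proj[len(src) :], pca.explained_variance_ratio_, pca


def domain_classifier_auc(
    source_feats: np.ndarray,
    target_feats: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    shuffle_control: bool = False,
    n_controls: int = 2,
) -> tuple[float, list[float]]:
    """Cross-validated SVM AUC for source-vs-target discrimination.

    With ``shuffle_control`` the same procedure is repeated on permuted
    domain labels; those AUCs should be ~0.5 when the pipeline is unbiased.
    """
    src = collapse_features(np.asarray(source_feats))
    tgt = collapse_features(np.asarray(target_feats))
    if len(src) < 50 or len(tgt) < 50:
        raise ValueError("need at least 50 cases per domain")
    X = StandardScaler().fit_transform(np.vstack([src, tgt]))
    y = np.concatenate([np.zeros(len(src)), np.ones(len(tgt))])
    rng = np.random.default_rng(seed)

    def cv_auc(labels: np.ndarray) -> float:
        # per-fold AUCs are averaged rather than pooling decision scores:
        # decision-function scales differ between folds and pooling them
        # inflates the variance of the null (shuffled-label) AUC
        aucs = []
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for tr, te in skf.split(X, labels):
            clf = SVC(kernel="rbf").fit(X[tr], labels[tr])
            aucs.append(roc_auc_score(labels[te], clf.decision_function(X[te])))
        return float(np.mean(aucs))

    auc = cv_auc(y)
    controls = []
    if shuffle_control:
        for _ in range(n_controls):
            controls.append(cv_auc(rng.permutation(y)))
    return auc, controls


def mismatch_report(
    source_feats, target_feats, names=None, seed: int = 0, shuffle_control: bool = True
) -> MismatchReport:
    table = per_stat_mismatch(source_feats, target_feats, names)
    ps, pt, evr, _ = joint_pca(source_feats, target_feats)
    auc, controls = domain_classifier_auc(
        source_feats, target_feats, seed=seed, shuffle_control=shuffle_control
    )
    return MismatchReport(table, ps, pt, evr, auc, controls)


# ---------------------------------------------------------------------------
# performance evaluation


def sweep_score_from_probs(probs: np.ndarray) -> np.ndarray:
    """Scalar sweep evidence: P(hard) + P(soft)."""
    return probs[:, HARD] + probs[:, SOFT]


def classical_extreme_score(
    values: np.ndarray, positions: np.ndarray, length: float, region=(0.45, 0.55)
) -> float:
    """Extreme-|statistic| score over the central 0.45L-0.55L segment.

    Comparison hook for classical single-statistic scans: the most extreme
    absolute statistic value among windows whose position falls in the
    central region is the per-case prediction score.
    """
    sel = (positions >= region[0] * length) & (positions <= region[1] * length)
    if not sel.any():
        return 0.0
    return float(np.max(np.abs(values[sel])))


def sweep_roc(scores: np.ndarray, labels: np.ndarray, positive=SWEEP_CLASSES):
    """ROC and AUC with selected classes positive, linked+neutral negative."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = np.isin(labels, positive).astype(int)
    if y.min() == y.max():
        raise ValueError("need both positive and negative cases")
    fpr, tpr, thr = roc_curve(y, scores)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thr, "auc": float(roc_auc_score(y, scores))}


def per_type_rocs(probs: np.ndarray, labels: np.ndarray) -> dict[str, dict]:
    """One-vs-rest ROC per sweep type (linked + neutral negatives)."""
    out = {}
    for cls, name in ((HARD, "hard"), (SOFT, "soft")):
        mask = np.isin(labels, (cls, LINKED_HARD, LINKED_SOFT, NEUTRAL))
        out[name] = sweep_roc(probs[mask, cls], labels[mask], positive=(cls,))
    out["any_sweep"] = sweep_roc(sweep_score_from_probs(probs), labels)
    return out


def confusion_5class(pred: np.ndarray, truth: np.ndarray):
    """5x5 confusion counts (rows = predicted, columns = true) and rates.

    Rates are column-normalised: the fraction of each true class assigned
    to each predicted class.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    k = len(CLASS_ORDER)
    if ((pred < 0) | (pred >= k) | (truth < 0) | (truth >= k)).any():
        raise ValueError("labels must be in 0..4")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (pred, truth), 1)
    col = counts.sum(axis=0)
    rates = np.divide(counts, col, where=col > 0, out=np.zeros((k, k)))
    per_class_acc = {CLASS_ORDER[i]: float(rates[i, i]) for i in range(k)}
    return {"counts": counts, "rates": rates, "per_class_accuracy": per_class_acc}


def domain_score_histogram(scores: np.ndarray, bins: int = 20):
    """Histogram of discriminator outputs plus the mass below 0.5.

    After successful alignment, target-domain scores concentrate to the
    left of 0.5 (the discriminator can no longer tell the target apart).
    """
    scores = np.asarray(scores, dtype=float)
    hist, edges = np.histogram(scores, bins=bins, range=(0.0, 1.0))
    return {"hist": hist, "edges": edges, "mass_below_half": float(np.mean(scores < 0.5))}
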