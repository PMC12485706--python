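"""Epoch-level calcium features and leave-one-subject-out decoding.

Calcium traces are low-pass filtered at 1 Hz and brought to 50 Hz,
then summarized per 10 s epoch by five statistics: standard deviation,
median absolute deviation, interquartile range, root mean square of
successive differences, and relative 0.2-0.5 Hz power (normalized by
total power between 0.05 and 3 Hz).  A standardized elastic-net
logistic regression is evaluated with leave-one-mouse-out
cross-validation; chance level comes from re-running the whole scheme
with labels permuted within each mouse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .signals import mad

__all__ = ["FEATURE_NAMES", "DecodingResult", "preprocess_calcium",
           "epoch_features", "label_epochs", "lomo_decode"]

FEATURE_NAMES = ("std", "mad", "iqr", "rms_dx", "pow_0.2_0.5")

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class DecodingResult:
    per_fold_auc: list[float]
    mean_auc: float
    mean_tpr: np.ndarray            # vertical average on FPR_GRID
    fpr_grid: np.ndarray
    shuffled_auc: list[float]
    shuffled_mean_auc: float
    feature_weights: np.ndarray     # mean signed coefficients across folds
    per_fold_weights: list = field(default_factory=list)
    subjects: list = field(default_factory=list)
    skipped_folds: list = field(default_factory=list)


def preprocess_calcium(dff, fs: float, target_fs: float = 50.0,
                       cutoff: float = 1.0) -> np.ndarray:
    """Zero-phase 1 Hz low-pass, then bring the trace to 50 Hz."""
    if fs < target_fs:
        raise ValueError(f"sample rate {fs} below target {target_fs}")
    x = np.asarray(dff, dtype=float)
    sos = sps.butter(4, cutoff / (fs / 2), btype="low", output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    if fs == target_fs:
        return filtered
    n_out = int(round(x.size * target_fs / fs))
    t_in = np.arange(x.size) / fs
    t_out = np.arange(n_out) / target_fs
    return np.interp(t_out, t_in, filtered)


def epoch_features(trace50, fs: float = 50.0,
                   epoch: float = 10.0) -> pd.DataFrame:
    """The five summary statistics per consecutive epoch.

    The spectral ratio comes from a per-epoch periodogram; a constant
    epoch gets ratio 0 and the ``degenerate`` flag set.
    """
    x = np.asarray(trace50, dtype=float)
    per = int(round(epoch * fs))
    if x.size < per:
        raise ValueError("trace shorter than one epoch")
    n_epochs = x.size // per
    rows = []
    for k in range(n_epochs):
        seg = x[k * per:(k + 1) * per]
        q75, q25 = np.percentile(seg, [75, 25])
        rms_dx = float(np.sqrt(np.mean(np.diff(seg) ** 2))) if per > 1 else 0.0
        degenerate = np.ptp(seg) == 0.0
        if degenerate:
            ratio = 0.0
        else:
            freqs, pxx = sps.periodogram(seg, fs=fs)
            num = pxx[(freqs >= 0.2) & (freqs <= 0.5)].sum()
            den = pxx[(freqs >= 0.05) & (freqs <= 3.0)].sum()
            ratio = float(num / den) if den > 0 else 0.0
        rows.append({
            "std": float(seg.std()),
            "mad": mad(seg),
            "iqr": float(q75 - q25),
            "rms_dx": rms_dx,
            "pow_0.2_0.5": ratio,
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def label_epochs(n_epochs: int, intervals, epoch_len: float = 10.0
                 ) -> np.ndarray:
    """Positive label iff any interval overlaps the half-open epoch."""
    labels = np.zeros(n_epochs, dtype=bool)
    for start, end in intervals:
        k0 = max(int(start // epoch_len), 0)
        k1 = min(int(np.ceil(end / epoch_len)), n_epochs)
        if end > start:
            labels[k0:k1] = True
        elif 0 <= k0 < n_epochs:      # zero-length: point event
            labels[k0] = True
    return labels


def _fold_roc(model, X_test, y_test):
    scores = model.predict_proba(X_test)[:, 1]
    auc = roc_auc_score(y_test, scores)
    fpr, tpr, _ = roc_curve(y_test, scores)
    tpr_grid = np.interp(FPR_GRID, fpr, tpr)
    return auc, tpr_grid


def _make_model(seed: int):
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(solver="saga", l1_ratio=0.5, C=1.0,
                           max_iter=5000, random_state=seed),
    )


def lomo_decode(features, labels, subjects, seed: int = 0,
                n_shuffles: int = 1) -> DecodingResult:
    """Leave-one-mouse-out decoding with a within-subject shuffle baseline.

    Standardization is fit on the training folds only.  Folds whose
    held-out subject shows a single class are skipped with a warning;
    if every fold is skipped an error is raised.  The shuffled baseline
    repeats the identical procedure after permuting labels within each
    subject (class counts preserved per subject).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    groups = np.asarray(subjects)
    if np.unique(groups).size < 2:
        raise ValueError("need at least 2 subjects for leave-one-out")
    if np.unique(y).size < 2:
        raise ValueError("need both classes present overall")

    def run(y_run):
        aucs, tprs, weights, used, skipped = [], [], [], [], []
        logo = LeaveOneGroupOut()
        for train, test in logo.split(X, y_run, groups):
            subj = groups[test][0]
            if (np.unique(y_run[test]).size < 2
                    or np.unique(y_run[train]).size < 2):
                skipped.append(subj)
                continue
            model = _make_model(seed)
            model.fit(X[train], y_run[train])
            auc, tpr_grid = _fold_roc(model, X[test], y_run[test])
            aucs.append(float(auc))
            tprs.append(tpr_grid)
            weights.append(model[-1].coef_.ravel().copy())
            used.append(subj)
        return aucs, tprs, weights, used, skipped

    aucs, tprs, weights, used, skipped = run(y)
    if skipped:
        warnings.warn(f"skipped single-class folds: {skipped}", stacklevel=2)
    if not aucs:
        raise ValueError("all folds skipped (single-class held-out sets)")

    rng = np.random.default_rng(seed)
    shuffled_aucs: list[float] = []
    for _ in range(n_shuffles):
        y_shuf = y.copy()
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            y_shuf[idx] = y_shuf[rng.permutation(idx)]
        s_aucs, _, _, _, _ = run(y_shuf)
        shuffled_aucs.extend(s_aucs)

    return DecodingResult(
        per_fold_auc=aucs,
        mean_auc=float(np.mean(aucs)),
        mean_tpr=np.mean(tprs, axis=0),
        fpr_grid=FPR_GRID,
        shuffled_auc=shuffled_aucs,
        shuffled_mean_auc=float(np.mean(shuffled_aucs)) if shuffled_aucs
        else float("nan"),
        feature_weights=np.mean(weights, axis=0),
        per_fold_weights=weights,
        subjects=used,
        skipped_folds=skipped,
    )
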