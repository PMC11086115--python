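"""Classification metrics, validation gates, robustness and modality studies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, recall_score

from .cascade import CascadeForestClassifier
from .features import ECG_FEATURES, EEG_FEATURES
from .io import split_dataset

#: Perturbation intensities for the adversarial robustness sweep.
DEFAULT_NOISE_LEVELS = (0.01, 0.05, 0.1, 0.3, 0.5, 0.7, 1.0)


@dataclass
class EvalReport:
    """Binary-classification report with optional per-subject breakdown."""

    accuracy: float
    per_class: dict            # class -> {precision, recall, f1, support}
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: dict            # {tp, tn, fp, fn} with 'Y' as the positive class
    per_subject_accuracy: dict | None = None
    subject_accuracy_std: float | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion,
            "per_class": self.per_class,
        }
        if self.per_subject_accuracy is not None:
            d["per_subject_accuracy"] = self.per_subject_accuracy
            d["subject_accuracy_std"] = self.subject_accuracy_std
        return d


def evaluate(y_true, y_pred, subject_ids=None) -> EvalReport:
    """Accuracy, per-class precision/recall/F1 and confusion counts.

    ``accuracy = (TP+TN)/(TP+TN+FP+FN)`` with fatigued (``"Y"``) as the
    positive class.  With ``subject_ids``, per-subject accuracies and their
    standard deviation are included.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    acc = float(np.mean(y_true == y_pred))
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0)
    per_class = {c: {"precision": float(p), "recall": float(r), "f1": float(f),
                     "support": int(s)}
                 for c, p, r, f, s in zip(classes, prec, rec, f1, supp)}
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    if len(classes) == 2:
        (tn, fp), (fn, tp) = cm  # classes sorted -> N first, Y second
        confusion = {"tp": int(tp), "tn": int(tn), "fp": int(fp), "fn": int(fn)}
    else:
        confusion = {"matrix": cm.tolist(), "labels": classes}
    per_subj, subj_std = None, None
    if subject_ids is not None:
        subject_ids = np.asarray(subject_ids)
        per_subj = {str(s): float(np.mean(y_true[subject_ids == s] == y_pred[subject_ids == s]))
                    for s in np.unique(subject_ids)}
        subj_std = float(np.std(list(per_subj.values()), ddof=0))
    return EvalReport(
        accuracy=acc, per_class=per_class,
        macro_precision=float(np.mean(prec)), macro_recall=float(np.mean(rec)),
        macro_f1=float(np.mean(f1)), confusion=confusion,
        per_subject_accuracy=per_subj, subject_accuracy_std=subj_std,
    )


def validation_gate(report: EvalReport, threshold: float = 0.90) -> tuple[bool, list[str]]:
    """Pass iff accuracy and all macro metrics reach the threshold."""
    checks = {
        "accuracy": report.accuracy,
        "macro_recall": report.macro_recall,
        "macro_precision": report.macro_precision,
        "macro_f1": report.macro_f1,
    }
    failing = [name for name, v in checks.items() if v < threshold]
    return (not failing), failing


def adversarial_test(model, X_test, y_test, noise_levels=DEFAULT_NOISE_LEVELS,
                     train_std=None, seed: int = 0) -> dict[float, float]:
    """Macro recall under Gaussian feature perturbations of growing intensity.

    Each level ``nu`` adds zero-mean noise with per-feature standard
    deviation ``nu * train_std`` (i.e. ``nu`` on the standardised feature
    scale).  ``nu = 0`` leaves the input bitwise unchanged.
    """
    noise_levels = list(noise_levels)
    if not noise_levels:
        raise ValueError("noise_levels must be non-empty")
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    std = np.asarray(train_std, dtype=float) if train_std is not None else X_test.std(axis=0)
    rng = np.random.default_rng(seed)
    out: dict[float, float] = {}
    for nu in noise_levels:
        Xp = X_test if nu == 0 else X_test + rng.standard_normal(X_test.shape) * (nu * std)
        pred = model.predict(Xp)
        out[float(nu)] = float(recall_score(y_test, pred, average="macro", zero_division=0))
    return out


def run_protocol(X, y, subjects=None, seed: int = 0, **cascade_kw) -> EvalReport:
    """The standard protocol: stratified 60/20/20 split, fit on train, score on test."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    tr, va, te = split_dataset(X, y, seed=seed)
    clf = CascadeForestClassifier(random_state=seed, **cascade_kw).fit(X[tr], y[tr])
    pred = clf.predict(X[te])
    subj = np.asarray(subjects)[te] if subjects is not None else None
    return evaluate(y[te], pred, subject_ids=subj)


def compare_modalities(features: pd.DataFrame, selection=None, seed: int = 0,
                       **cascade_kw) -> pd.DataFrame:
    """EEG-only vs ECG-only vs fused-feature accuracy under the same protocol.

    ``features`` is a feature table (as from
    :func:`fatigueforest.fusion.dataset_feature_table`) holding all 25
    feature columns plus ``label`` and ``subject_id``.  ``selection`` names
    the fused feature subset (default: all 25).
    """
    from .fusion import resolve_selection

    fused = resolve_selection(selection)
    sets = {
        "eeg": list(EEG_FEATURES),
        "ecg": list(ECG_FEATURES),
        "fused": fused,
    }
    y = features["label"].to_numpy()
    subjects = features["subject_id"].to_numpy() if "subject_id" in features else None
    rows = []
    for name, cols in sets.items():
        rep = run_protocol(features[cols].to_numpy(), y, subjects, seed=seed, **cascade_kw)
        rows.append({"feature_set": name, "n_features": len(cols),
                     "accuracy": rep.accuracy, "macro_f1": rep.macro_f1,
                     "subject_accuracy_std": rep.subject_accuracy_std})
    return pd.DataFrame(rows)
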