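"""Random-forest evaluation protocols.

Two complementary views of harmonisation quality:

* **centre identification** — how much centre signal the features still
  carry: stratified 5-fold cross-validation predicting the centre of
  origin from one ROI's first- or second-order features (lower balanced
  accuracy = better harmonisation);
* **generalisation** — train a healthy-vs-HCM classifier on a single
  centre (first + second order features from all ROIs pooled, no feature
  selection) and test on every held-out centre, over 5 seeds x 5 folds
  (higher balanced accuracy = better generalisation).

Both use random forests (500 trees, sqrt(p) features per split, unlimited
depth) and balanced accuracy (mean per-class recall), which is robust to
the cohort's class imbalance.  All runs are deterministic under the given
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .io import FeatureTable

N_TREES = 500


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recalls.  Classes present only in the predictions
    are ignored; empty input is an error."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(balanced_accuracy_score(y_true, y_pred))


@dataclass
class EvalReport:
    """Cross-validated classification results for one protocol run."""

    task: str  # "centre_id" | "generalisation"
    fold_accuracies: pd.DataFrame  # per (seed, fold): validation/test scores
    importances: pd.Series  # mean Gini importance per feature
    n_folds: int
    seeds: list
    meta: dict = field(default_factory=dict)

    @property
    def mean_validation(self) -> float:
        return float(self.fold_accuracies["validation"].mean())

    @property
    def mean_test(self) -> float | None:
        if "test" not in self.fold_accuracies:
            return None
        return float(self.fold_accuracies["test"].mean())


def centre_id_protocol(table: FeatureTable, *, pathology: str | None = "healthy",
                       order: str | None = None, roi: str | None = None,
                       phase: str | None = None, n_folds: int = 5,
                       seed: int = 0, n_trees: int = N_TREES) -> EvalReport:
    """Stratified k-fold CV predicting centre of origin.

    Features are restricted to one (order, roi) block when given; rows to
    one pathology group (healthy by default, mirroring the variability
    analysis).
    """
    sub = table.select(pathology=pathology, order=order, roi=roi, phase=phase)
    centres = sub.row_meta["centre"]
    counts = centres.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 centres")
    if counts.min() < n_folds:
        raise ValueError(
            f"centre {counts.idxmin()!r} has {counts.min()} subjects, fewer "
            f"than {n_folds} folds; reduce n_folds")
    x = sub.data.to_numpy(dtype=float)
    y = centres.to_numpy()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    imps = np.zeros(x.shape[1])
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed,
            n_jobs=1)
        clf.fit(x[tr], y[tr])
        acc = balanced_accuracy(y[te], clf.predict(x[te]))
        rows.append({"seed": seed, "fold": fold, "validation": acc})
        imps += clf.feature_importances_
    return EvalReport(
        task="centre_id",
        fold_accuracies=pd.DataFrame(rows),
        importances=pd.Series(imps / n_folds, index=sub.data.columns),
        n_folds=n_folds, seeds=[seed],
        meta={"order": order, "roi": roi, "pathology": pathology,
              "n_classes": int(len(counts))},
    )


def generalisation_protocol(table: FeatureTable, train_centre: str, *,
                            seeds=(0, 1, 2, 3, 4), n_folds: int = 5,
                            phase: str | None = None,
                            n_trees: int = N_TREES) -> EvalReport:
    """Train healthy-vs-HCM on one centre, test on all the others.

    For each seed, k-fold CV within the training centre gives validation
    accuracy, and each fold's model is evaluated on the pooled held-out
    subjects (test accuracy).  Features are first + second order from all
    ROIs; no prior feature selection.
    """
    sub = table.select(phase=phase)
    in_centre = (sub.row_meta["centre"] == train_centre).values
    if not in_centre.any():
        raise ValueError(f"unknown training centre {train_centre!r}")
    x = sub.data.to_numpy(dtype=float)
    y = sub.row_meta["pathology"].to_numpy()
    x_tr_all, y_tr_all = x[in_centre], y[in_centre]
    x_te_all, y_te_all = x[~in_centre], y[~in_centre]
    if len(np.unique(y_tr_all)) < 2:
        raise ValueError(f"training centre {train_centre!r} has a single class")
    if x_te_all.shape[0] == 0:
        raise ValueError("no held-out centres")

    rows = []
    imps = np.zeros(x.shape[1])
    n_models = 0
    for seed in seeds:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold, (tr, va) in enumerate(skf.split(x_tr_all, y_tr_all)):
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features="sqrt", random_state=seed,
                n_jobs=1)
            clf.fit(x_tr_all[tr], y_tr_all[tr])
            val = balanced_accuracy(y_tr_all[va], clf.predict(x_tr_all[va]))
            test = balanced_accuracy(y_te_all, clf.predict(x_te_all))
            rows.append({"seed": seed, "fold": fold,
                         "validation": val, "test": test})
            imps += clf.feature_importances_
            n_models += 1
    return EvalReport(
        task="generalisation",
        fold_accuracies=pd.DataFrame(rows),
        importances=pd.Series(imps / n_models, index=sub.data.columns),
        n_folds=n_folds, seeds=list(seeds),
        meta={"train_centre": train_centre},
    )


def feature_importances(report: EvalReport, table: FeatureTable,
                        k: int = 20) -> pd.DataFrame:
    """Top-k features by mean Gini importance, annotated with ROI/family."""
    import warnings

    imp = report.importances.sort_values(ascending=False)
    if k > len(imp):
        warnings.warn(f"k={k} exceeds {len(imp)} features; truncating",
                      stacklevel=2)
        k = len(imp)
    top = imp.head(k)
    meta = table.col_meta.loc[top.index, ["roi", "family", "name"]]
    out = meta.copy()
    out["importance"] = top.values
    return out.reset_index()
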