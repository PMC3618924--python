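"""Cross-validated ROC evaluation stratified by breast density.

The experimental design: prototypes (ROI patches) are partitioned at random
into 30 near-equal test folds; for each fold the remaining prototypes are
split 80/20 into training and validation.  Per fold, the ICA basis is fitted
on training patches only, a classifier is trained and model-selected on the
validation set, and its scores on the held-out test fold are swept over
thresholds to produce an ROC curve and trapezoidal AUC.  The 30 fold AUCs
are summarized as mean with a 95% Student-t confidence interval, overall and
per density grade.  Fold selection ignores class labels (balance emerges
statistically), and per-stratum experiments draw fresh fold plans.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import classify as _classify
from . import ica as _ica
from .roi import ROIPatch

__all__ = [
    "CVPlan",
    "ROCCurve",
    "ExperimentResult",
    "make_cv_plan",
    "roc_curve",
    "mean_auc_ci",
    "percent_change",
    "imbalance_percent",
    "prototype_table",
    "run_experiment",
]


@dataclass
class CVPlan:
    """Fold assignments: per fold, disjoint test / train / validation id arrays."""

    folds: list[dict[str, np.ndarray]]
    seed: int
    val_frac: float = 0.2

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_cv_plan(
    ids: Sequence, n_folds: int = 30, val_frac: float = 0.2, seed: int = 0
) -> CVPlan:
    """Random unstratified k-fold plan with an internal train/validation split.

    Each id lands in exactly one test fold; within each fold the non-test
    ids are split ``1 - val_frac`` / ``val_frac`` (80/20 by default, to
    within one prototype) at random.  Deterministic under ``seed``.
    """
    ids = np.asarray(ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} prototypes, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold_indices = np.array_split(perm, n_folds)
    folds = []
    for test_idx in fold_indices:
        rest = np.setdiff1d(perm, test_idx, assume_unique=True)
        rest = rest[rng.permutation(len(rest))]
        n_train = int(round((1.0 - val_frac) * len(rest)))
        folds.append(
            {
                "test": ids[np.sort(test_idx)],
                "train": ids[np.sort(rest[:n_train])],
                "val": ids[np.sort(rest[n_train:])],
            }
        )
    return CVPlan(folds=folds, seed=seed, val_frac=val_frac)


@dataclass
class ROCCurve:
    """Threshold sweep of a score vector against binary labels."""

    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve from a threshold sweep, with trapezoidal AUC.

    Thresholds sit at the unique score values (tied scores collapse to one
    sweep point, equivalent to half-credit for ties in the rank form); the
    curve runs from (0, 0) to (1, 1) with non-decreasing coordinates.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, np.asarray(scores, dtype=float),
                                  drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def mean_auc_ci(aucs: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a Student-t confidence interval: mean +/- t_{1-a/2, n-1} s/sqrt(n)."""
    a = np.asarray(aucs, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 AUC values for a confidence interval")
    mean = float(a.mean())
    half = float(
        stats.t.ppf(0.5 + level / 2.0, a.size - 1) * a.std(ddof=1) / np.sqrt(a.size)
    )
    return mean, mean - half, mean + half


def percent_change(auc_from: float, auc_to: float) -> float:
    """Signed relative change 100 (to - from) / from, to two decimals."""
    if auc_from <= 0:
        raise ValueError("baseline AUC must be positive")
    return round(100.0 * (auc_to - auc_from) / auc_from, 2)


def imbalance_percent(n_mass_m: float, n_mass_b: float, n_normal: float) -> int:
    """Normal-vs-mass prototype imbalance, percent of the normal count,
    rounded to the nearest integer."""
    if n_normal <= 0:
        raise ValueError("normal prototype count must be positive")
    return int(round(100.0 * (n_normal - (n_mass_m + n_mass_b)) / n_normal))


@dataclass
class ExperimentResult:
    """Per-fold AUCs with mean and 95% CI for one stratum and classifier."""

    stratum: str  # "overall" | "1".."4"
    classifier: str
    fold_aucs: list[float]
    mean_auc: float
    ci95: tuple[float, float]
    n_folds_skipped: int = 0
    selections: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "classifier": self.classifier,
            "mean_auc": self.mean_auc,
            "ci95": list(self.ci95),
            "fold_aucs": self.fold_aucs,
            "n_folds_skipped": self.n_folds_skipped,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def prototype_table(plan: CVPlan, patches: Sequence[ROIPatch]) -> pd.DataFrame:
    """Mean prototype counts per (density, subset, class) across folds.

    Mirrors the bookkeeping table of the cross-validation design: rows are
    density grades plus an overall row, columns are (subset, class) mean
    counts plus a total column equal to the dataset size per row.
    """
    by_id = {i: p for i, p in enumerate(patches)}
    classes = {"malignant": "M", "benign": "B", "normal": "N"}
    records = []
    for fold in plan.folds:
        for subset in ("train", "val", "test"):
            for pid in fold[subset]:
                p = by_id[int(pid)]
                records.append((p.density, subset, classes[p.label]))
    df = pd.DataFrame(records, columns=["density", "subset", "cls"])
    counts = (
        df.groupby(["density", "subset", "cls"]).size().unstack(["subset", "cls"], fill_value=0)
        / plan.n_folds
    )
    counts = counts.reindex(
        columns=pd.MultiIndex.from_product([("train", "val", "test"), ("M", "B", "N")]),
        fill_value=0.0,
    )
    counts.columns = [f"{subset}_{cls}" for subset, cls in counts.columns]
    overall = counts.sum(axis=0).to_frame().T
    overall.index = ["overall"]
    table = pd.concat([counts, overall])
    table["total"] = table.sum(axis=1)
    return table


def _labels01(patches: Sequence[ROIPatch]) -> np.ndarray:
    return np.array([1 if p.is_mass else 0 for p in patches])


def run_experiment(
    patches: Sequence[ROIPatch],
    stratum: str = "overall",
    n_components: int = 10,
    classifier: str = "both",
    seed: int = 0,
    n_folds: int = 30,
    val_frac: float = 0.2,
    hidden_grid: Sequence[int] = _classify.DEFAULT_HIDDEN_GRID,
    mlp_restarts: int = 4,
    mlp_max_epochs: int = 2000,
    mlp_patience: int = 30,
    gamma_grid: Sequence[float] = _classify.DEFAULT_GAMMA_GRID,
    C_grid: Sequence[float] = _classify.DEFAULT_C_GRID,
    shared_basis: bool = False,
    permute_labels: bool = False,
) -> dict[str, ExperimentResult]:
    """Cross-validated ROC study for one stratum.

    Per fold: fit the ICA basis on that fold's training patches (unless
    ``shared_basis``, which fits one basis on all patches — the cheaper but
    leakage-prone variant), project all subsets, train/select the
    classifier(s) on train+validation, and score the test fold.  Folds whose
    test set is single-class are skipped with a warning and counted.
    ``permute_labels`` shuffles class labels once before the run (null
    behaviour check).  Returns one :class:`ExperimentResult` per requested
    classifier kind.
    """
    if stratum != "overall":
        patches = [p for p in patches if p.density == int(stratum)]
    if not patches:
        raise ValueError(f"stratum {stratum!r} contains no patches")
    kinds = ("mlp", "svm") if classifier == "both" else (classifier,)
    rng = np.random.default_rng(seed)
    y_all = _labels01(patches)
    if permute_labels:
        y_all = y_all[rng.permutation(len(y_all))]
    X_pix = np.stack([p.pixels.ravel() for p in patches])

    plan = make_cv_plan(np.arange(len(patches)), n_folds=n_folds,
                        val_frac=val_frac, seed=int(rng.integers(2**31)))
    basis_all = None
    if shared_basis:
        basis_all = _ica.fit_basis(
            X_pix, n_components, seed=int(rng.integers(2**31)), on_fail="best"
        )

    fold_aucs: dict[str, list[float]] = {k: [] for k in kinds}
    selections: dict[str, list[dict]] = {k: [] for k in kinds}
    skipped = 0
    for fold_i, fold in enumerate(plan.folds):
        tr, va, te = (fold[s].astype(int) for s in ("train", "val", "test"))
        if len(np.unique(y_all[te])) < 2:
            warnings.warn(f"fold {fold_i}: single-class test set, skipped")
            skipped += 1
            continue
        basis = basis_all or _ica.fit_basis(
            X_pix[tr], n_components, seed=int(rng.integers(2**31)), on_fail="best"
        )
        F_tr = _ica.project(X_pix[tr], basis)
        F_va = _ica.project(X_pix[va], basis)
        F_te = _ica.project(X_pix[te], basis)
        for kind in kinds:
            if kind == "mlp":
                clf = _classify.grid_select_mlp(
                    F_tr, y_all[tr], F_va, y_all[va],
                    hidden_grid=hidden_grid, restarts=mlp_restarts,
                    seed=int(rng.integers(2**31)),
                    max_epochs=mlp_max_epochs, patience=mlp_patience,
                )
            else:
                clf = _classify.train_svm_grid(
                    F_tr, y_all[tr], F_va, y_all[va],
                    gamma_grid=gamma_grid, C_grid=C_grid,
                )
            roc = roc_curve(clf.score(F_te), y_all[te])
            fold_aucs[kind].append(roc.auc)
            selections[kind].append({"fold": fold_i, **clf.selection})

    results = {}
    for kind in kinds:
        mean, lo, hi = mean_auc_ci(fold_aucs[kind])
        results[kind] = ExperimentResult(
            stratum=stratum,
            classifier=kind,
            fold_aucs=[float(a) for a in fold_aucs[kind]],
            mean_auc=mean,
            ci95=(lo, hi),
            n_folds_skipped=skipped,
            selections=selections[kind],
        )
    return results
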