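"""Evaluation protocol: repeated 80/20 trials, k-fold CV, per-class and
macro precision/recall/F1, one-vs-rest AUC, relative improvements, the
ablation ladder, and paired t-tests.

All aggregate metrics use macro (unweighted) averaging over the three
outcome classes, so minority-phenotype performance counts as much as the
majority class.  AUC uses the rank (Mann-Whitney) formulation with mid-rank
ties, evaluated per class one-vs-rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .schema import CohortTable, trial_split

__all__ = [
    "MetricsReport",
    "macro_prf",
    "ovr_auc",
    "relative_improvement",
    "run_trials",
    "cross_validate",
    "ablation_study",
    "paired_t_test",
    "PairedTResult",
]

N_CLASSES = 3


def macro_prf(y_true, y_pred) -> dict:
    """Per-class one-vs-rest precision/recall/F1 plus macro averages."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between truth and predictions")
    present = np.unique(y_true)
    absent = sorted(set(range(N_CLASSES)) - set(present.tolist()))
    if absent:
        warnings.warn(f"class(es) {absent} absent from truth; metrics set to 0")
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(range(N_CLASSES)), zero_division=0
    )
    return {
        "precision": p,
        "recall": r,
        "f1": f1,
        "macro_precision": float(p.mean()),
        "macro_recall": float(r.mean()),
        "macro_f1": float(f1.mean()),
    }


def ovr_auc(y_true, scores) -> dict:
    """One-vs-rest AUC per class (Mann-Whitney with mid-rank ties) + macro.

    A class absent from the truth has undefined AUC; it is reported as NaN
    and excluded from the macro average with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores and labels disagree on n")
    per_class = np.full(N_CLASSES, np.nan)
    for c in range(N_CLASSES):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} has no positives or no negatives; AUC undefined")
            continue
        per_class[c] = roc_auc_score(pos.astype(int), scores[:, c])
    defined = ~np.isnan(per_class)
    macro = float(per_class[defined].mean()) if defined.any() else np.nan
    return {"auc": per_class, "macro_auc": macro}


def relative_improvement(new: float, base: float) -> float:
    """Percent improvement 100*(new-base)/base, rounded to one decimal."""
    if base <= 0:
        raise ValueError(f"baseline must be positive, got {base}")
    return round(100.0 * (new - base) / base, 1)


@dataclass
class MetricsReport:
    """Per-trial metric rows plus mean and standard-error aggregates."""

    trials: pd.DataFrame  # one row per trial

    @property
    def mean(self) -> pd.Series:
        return self.trials.drop(columns=["seed"]).mean()

    @property
    def se(self) -> pd.Series:
        t = self.trials.drop(columns=["seed"])
        if len(t) < 2:
            return pd.Series(0.0, index=t.columns)
        return t.std(ddof=1) / np.sqrt(len(t))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "se": self.se})


def _score_trial(method, cohort: CohortTable, split) -> dict:
    """Fit ``method`` on the train rows and score the held-out rows."""
    scores = method(cohort, split)
    scores = np.asarray(scores, float)
    y_test = cohort.y[split.test]
    hard = np.argmax(scores, axis=1)
    prf = macro_prf(y_test, hard)
    auc = ovr_auc(y_test, scores)
    return {
        "macro_precision": prf["macro_precision"],
        "macro_recall": prf["macro_recall"],
        "macro_f1": prf["macro_f1"],
        "macro_auc": auc["macro_auc"],
        "auc_non_mafld": auc["auc"][0],
        "auc_nondiabetic": auc["auc"][1],
        "auc_diabetic": auc["auc"][2],
        "f1_non_mafld": prf["f1"][0],
        "f1_nondiabetic": prf["f1"][1],
        "f1_diabetic": prf["f1"][2],
    }


def run_trials(
    method,
    cohort: CohortTable,
    n_trials: int = 10,
    seeds=None,
    f: float = 0.8,
) -> MetricsReport:
    """Repeat: stratified 80/20 split, fit, score; aggregate mean and SE.

    ``method(cohort, split) -> (n_test, 3) score matrix`` is any callable
    following the pipeline-runner contract.
    """
    if seeds is None:
        seeds = list(range(n_trials))
    rows = []
    for seed in seeds:
        split = trial_split(cohort.n, seed=seed, f=f, y=cohort.y)
        try:
            row = _score_trial(method, cohort, split)
        except Exception as exc:  # noqa: BLE001 - annotate trial then re-raise
            raise RuntimeError(f"trial with seed {seed} failed: {exc}") from exc
        rows.append({"seed": seed} | row)
    return MetricsReport(trials=pd.DataFrame(rows))


def cross_validate(
    method_factory,
    cohort: CohortTable,
    train_idx: np.ndarray,
    grid: list[dict],
    k: int = 5,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Pick the grid point with the best mean validation macro AUC.

    ``method_factory(**params)`` must return a pipeline-runner callable.
    Folds are stratified so every fold keeps all three classes.  Ties break
    toward the earlier grid entry.  Returns (best params, per-point table).
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    train_idx = np.asarray(train_idx)
    y = cohort.y[train_idx]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_pairs = [
        (train_idx[tr], train_idx[va]) for tr, va in skf.split(train_idx, y)
    ]
    records = []
    means = []
    for params in grid:
        method = method_factory(**params)
        fold_aucs = []
        for fold_train, fold_val in fold_pairs:
            from .schema import TrialSplit

            split = TrialSplit(seed=seed, train=fold_train, test=fold_val)
            row = _score_trial(method, cohort, split)
            fold_aucs.append(row["macro_auc"])
        means.append(float(np.mean(fold_aucs)))
        records.append({**params, "mean_macro_auc": means[-1]})
    best = int(np.argmax(means))  # first maximum wins ties
    return grid[best], pd.DataFrame(records)


def ablation_study(
    cohort: CohortTable,
    methods: dict,
    seeds,
    f: float = 0.8,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Run each ablation mode over the same splits for paired comparison.

    ``methods`` maps mode name -> pipeline-runner callable.  Returns a
    summary table (mode, mean AUC, SE) and the per-trial macro-AUC vectors
    keyed by mode (aligned across modes by seed).
    """
    splits = [
        trial_split(cohort.n, seed=s, f=f, y=cohort.y) for s in seeds
    ]
    per_mode: dict[str, np.ndarray] = {}
    rows = []
    for name, method in methods.items():
        aucs = []
        for split in splits:
            aucs.append(_score_trial(method, cohort, split)["macro_auc"])
        aucs = np.asarray(aucs)
        per_mode[name] = aucs
        se = aucs.std(ddof=1) / np.sqrt(len(aucs)) if len(aucs) > 1 else 0.0
        rows.append({"mode": name, "mean_auc": aucs.mean(), "se": se})
    return pd.DataFrame(rows), per_mode


@dataclass(frozen=True)
class PairedTResult:
    t: float | None
    p: float | None
    df: int
    degenerate: bool = False

    def __repr__(self):
        if self.degenerate:
            return f"PairedTResult(degenerate: zero-variance differences, df={self.df})"
        return f"PairedTResult(t={self.t:.4f}, p={self.p:.4g}, df={self.df})"


def paired_t_test(a, b) -> PairedTResult:
    """Classical paired two-tailed t-test on matched metric vectors.

    Zero-variance differences (e.g. identical vectors) are reported as an
    explicitly degenerate result rather than a number.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 paired observations")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedTResult(t=None, p=None, df=len(a) - 1, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTResult(t=float(t), p=float(p), df=len(a) - 1)
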