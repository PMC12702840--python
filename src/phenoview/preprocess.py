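"""Dense-path data preparation: z-scoring, one-hot encoding, class weights,
and k-nearest-neighbor imputation.

Numeric features are standardized with the population (divide-by-n) standard
deviation computed on training rows only; categorical features are expanded
to one-hot blocks in declared level order.  Missing cells propagate as NaN
through :func:`transform`; the hierarchical classifier path and benchmarks
that need complete inputs call :func:`knn_impute` afterwards, while the
graph/contrastive components consume the raw masked survey data directly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.impute import KNNImputer

from .schema import CohortTable, FeatureSchema

__all__ = [
    "PreprocessState",
    "fit_preprocessor",
    "transform",
    "knn_impute",
    "compute_class_weights",
]


@dataclass
class PreprocessState:
    """Training statistics needed to transform any conforming table."""

    schema: FeatureSchema
    means: dict[str, float]
    sds: dict[str, float]
    #: (start, stop) column slice of each feature in the dense output
    blocks: dict[str, tuple[int, int]]
    n_columns: int

    @property
    def onehot_blocks(self) -> list[tuple[int, int]]:
        return [
            self.blocks[f.name]
            for f in self.schema.features
            if f.kind == "categorical"
        ]

    def column_names(self) -> list[str]:
        names = []
        for f in self.schema.features:
            if f.kind == "numeric":
                names.append(f.name)
            else:
                names.extend(f"{f.name}={lvl}" for lvl in f.levels)
        return names

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "schema": self.schema.to_dict(),
                    "means": self.means,
                    "sds": self.sds,
                    "blocks": {k: list(v) for k, v in self.blocks.items()},
                    "n_columns": self.n_columns,
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "PreprocessState":
        d = json.loads(Path(path).read_text())
        return cls(
            FeatureSchema.from_dict(d["schema"]),
            d["means"],
            d["sds"],
            {k: tuple(v) for k, v in d["blocks"].items()},
            d["n_columns"],
        )


def fit_preprocessor(train: CohortTable) -> PreprocessState:
    """Compute per-feature statistics on (observed) training cells only."""
    if train.n == 0:
        raise ValueError("cannot fit a preprocessor on an empty table")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    blocks: dict[str, tuple[int, int]] = {}
    col = 0
    for f in train.schema.features:
        if f.kind == "numeric":
            obs = ~train.mask[f.name].to_numpy()
            vals = train.data[f.name].to_numpy(float)[obs]
            if vals.size == 0:
                raise ValueError(f"numeric feature {f.name!r} has no observed value")
            mu = float(vals.mean())
            sd = float(vals.std(ddof=0))  # population convention
            if sd == 0.0:
                warnings.warn(
                    f"numeric feature {f.name!r} has zero variance on the "
                    "training rows; its sd is replaced by 1 so transformed "
                    "values are all zero"
                )
                sd = 1.0
            means[f.name], sds[f.name] = mu, sd
            blocks[f.name] = (col, col + 1)
            col += 1
        else:
            blocks[f.name] = (col, col + len(f.levels))
            col += len(f.levels)
    return PreprocessState(train.schema, means, sds, blocks, col)


def transform(state: PreprocessState, table: CohortTable) -> np.ndarray:
    """Dense (n, d) float matrix; missing cells appear as NaN in their block."""
    if tuple(table.schema.feature_names) != tuple(state.schema.feature_names):
        raise ValueError("table does not conform to the fitted schema")
    out = np.zeros((table.n, state.n_columns))
    for f in state.schema.features:
        lo, hi = state.blocks[f.name]
        miss = table.mask[f.name].to_numpy()
        if f.kind == "numeric":
            vals = table.data[f.name].to_numpy(float)
            out[:, lo] = (vals - state.means[f.name]) / state.sds[f.name]
            out[miss, lo] = np.nan
        else:
            level_idx = {lvl: k for k, lvl in enumerate(f.levels)}
            col = table.data[f.name]
            for i, (cell, m) in enumerate(zip(col, miss)):
                if m:
                    out[i, lo:hi] = np.nan
                elif cell in level_idx:
                    out[i, lo + level_idx[cell]] = 1.0
                else:
                    warnings.warn(
                        f"row {i}: unseen level {cell!r} for {f.name!r}; "
                        "emitting an all-zero block"
                    )
    return out


def knn_impute(
    matrix: np.ndarray,
    k: int = 5,
    onehot_blocks: list[tuple[int, int]] | None = None,
    train_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Fill NaN cells from the k nearest rows by Euclidean distance over
    mutually observed features.

    Numeric cells receive the neighbor mean; one-hot blocks (if their column
    slices are given) are renormalized to the modal indicator so every
    imputed block is a valid one-hot vector.  When ``train_matrix`` is given
    the neighbor pool is the training rows, so test-time imputation reuses
    training data only.
    """
    matrix = np.asarray(matrix, dtype=float)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if np.isnan(matrix).all(axis=1).any():
        bad = int(np.flatnonzero(np.isnan(matrix).all(axis=1))[0])
        raise ValueError(f"row {bad} has all features missing; cannot impute")
    if not np.isnan(matrix).any():
        return matrix.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    if train_matrix is None:
        filled = imputer.fit_transform(matrix)
    else:
        imputer.fit(np.asarray(train_matrix, dtype=float))
        filled = imputer.transform(matrix)
    if onehot_blocks:
        was_nan = np.isnan(matrix)
        for lo, hi in onehot_blocks:
            rows = np.flatnonzero(was_nan[:, lo:hi].any(axis=1))
            for i in rows:
                block = filled[i, lo:hi]
                winner = int(np.argmax(block))  # ties -> lowest level index
                filled[i, lo:hi] = 0.0
                filled[i, lo + winner] = 1.0
    return filled


def compute_class_weights(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Balanced inverse-frequency weights, w_c = N / (K * n_c)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("no labels given")
    K = int(n_classes) if n_classes is not None else int(labels.max()) + 1
    counts = np.bincount(labels, minlength=K)
    if np.any(counts == 0):
        raise ValueError(
            f"class(es) {np.flatnonzero(counts == 0).tolist()} absent; "
            "weights undefined"
        )
    return labels.size / (K * counts.astype(float))
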