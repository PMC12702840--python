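"""Hierarchical two-stage risk estimator.

Stage 1 estimates the probability ``p`` that a person develops any MAFLD;
stage 2 estimates a distribution over the H = 2 phenotypes (nondiabetic,
diabetic) conditional on having MAFLD.  The two stages share a feed-forward
trunk and are composed into a single three-class distribution

    (1 - p,  p * q_1,  ...,  p * q_H)

which always sums to one.  Training minimizes a three-term objective: the
class-weighted negative log-likelihood of the composed distribution, plus a
``gamma``-weighted binary cross-entropy for stage 1, plus a
``lambda``-weighted phenotype cross-entropy evaluated on the true-MAFLD rows
(teacher forcing: conditioning on the true rather than the predicted stage-1
outcome keeps the term differentiable and stable early in training).  Each
term uses balanced inverse-frequency class weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import MLP, Adam, Linear, Tensor, softmax
from .preprocess import compute_class_weights

__all__ = [
    "LossConfig",
    "TwoStagePrediction",
    "TwoStageModel",
    "compose_probabilities",
    "two_stage_loss",
    "fit",
    "predict",
    "threshold_report",
]

N_PHENOTYPES = 2  # H: nondiabetic, diabetic
_EPS = 1e-12


@dataclass(frozen=True)
class LossConfig:
    """Trade-off weights and optimizer settings for the joint objective."""

    gamma: float = 1.0  # stage-1 term weight
    lam: float = 1.0  # stage-2 term weight
    # a single moderate hidden layer generalizes best under heavy class
    # imbalance; deeper trunks memorize the minority classes
    hidden: int = 64
    n_hidden_layers: int = 1
    epochs: int = 150
    batch_size: int = 256
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.gamma < 0 or self.lam < 0:
            raise ValueError("gamma and lambda must be nonnegative")


@dataclass
class TwoStagePrediction:
    """Per-row stage-wise and composed probability distributions."""

    stage1: np.ndarray  # (n, 2): (1-p, p)
    stage2: np.ndarray  # (n, H)
    composed: np.ndarray  # (n, 1+H)
    labels: np.ndarray  # (n,) hard labels, argmax w/ lowest-index tie-break

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "p_mafld": self.stage1[:, 1],
                "p_nondiabetic_given_mafld": self.stage2[:, 0],
                "p_diabetic_given_mafld": self.stage2[:, 1],
                "p_non_mafld": self.composed[:, 0],
                "p_nondiabetic_mafld": self.composed[:, 1],
                "p_diabetic_mafld": self.composed[:, 2],
                "hard_label": self.labels,
            }
        )
        return df


def compose_probabilities(p, stage2, atol: float = 1e-6) -> np.ndarray:
    """Compose stage-1 prob(s) and stage-2 distribution(s) into 1+H classes.

    Accepts a scalar ``p`` with an (H,) vector, or an (n,) vector with an
    (n, H) matrix.  The stage-2 input must sum to one within ``atol``.
    """
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(stage2, dtype=float))
    if np.any((p_arr < -atol) | (p_arr > 1 + atol)):
        raise ValueError("stage-1 probability outside [0, 1]")
    sums = q.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > atol):
        raise ValueError("stage-2 distribution does not sum to 1")
    out = np.concatenate([(1.0 - p_arr)[:, None], p_arr[:, None] * q], axis=1)
    if np.isscalar(p) or np.asarray(p).ndim == 0:
        return out[0]
    return out


@dataclass
class _WeightSet:
    overall: np.ndarray  # (3,)
    binary: np.ndarray  # (2,)
    phenotype: np.ndarray  # (H,)


def _weight_set(labels: np.ndarray) -> _WeightSet:
    labels = np.asarray(labels, dtype=int)
    overall = compute_class_weights(labels, n_classes=3)
    binary = compute_class_weights((labels > 0).astype(int), n_classes=2)
    mafld = labels[labels > 0] - 1
    phenotype = compute_class_weights(mafld, n_classes=N_PHENOTYPES)
    return _WeightSet(overall, binary, phenotype)


def two_stage_loss(
    composed: np.ndarray,
    stage1: np.ndarray,
    stage2: np.ndarray,
    labels: np.ndarray,
    config: LossConfig | None = None,
    weights: _WeightSet | None = None,
) -> float:
    """Reference (non-differentiable) evaluation of the joint objective.

    Sum over rows of the class-weighted NLL of the composed distribution,
    plus ``gamma`` x the weighted binary stage-1 cross-entropy, plus
    ``lambda`` x the weighted phenotype cross-entropy over true-MAFLD rows.
    Zero probabilities are clamped at 1e-12 with a warning.
    """
    cfg = config or LossConfig()
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() > 2:
        raise ValueError("labels must lie in {0, 1, 2}")
    w = weights or _weight_set(labels)

    composed = np.atleast_2d(np.asarray(composed, float))
    stage1 = np.atleast_2d(np.asarray(stage1, float))
    stage2 = np.atleast_2d(np.asarray(stage2, float))
    n = len(labels)

    def _logp(p):
        if np.any(p < _EPS):
            warnings.warn("probability clamped at 1e-12 inside the loss")
        return np.log(np.maximum(p, _EPS))

    term1 = -np.sum(w.overall[labels] * _logp(composed[np.arange(n), labels]))
    binary = (labels > 0).astype(int)
    term2 = cfg.gamma * -np.sum(
        w.binary[binary] * _logp(stage1[np.arange(n), binary])
    )
    mafld_rows = np.flatnonzero(labels > 0)
    pheno = labels[mafld_rows] - 1
    term3 = cfg.lam * -np.sum(
        w.phenotype[pheno] * _logp(stage2[mafld_rows, pheno])
    )
    return float(term1 + term2 + term3)


class TwoStageModel:
    """Shared trunk with a binary stage-1 head and an H-way stage-2 head."""

    def __init__(self, d_in: int, config: LossConfig, rng: np.random.Generator):
        self.config = config
        sizes = [d_in] + [config.hidden] * config.n_hidden_layers
        self.trunk = MLP(sizes, rng)  # note: last trunk layer linear
        self.head_a = Linear(config.hidden, 2, rng)
        self.head_b = Linear(config.hidden, N_PHENOTYPES, rng)
        self.d_in = d_in

    @property
    def parameters(self):
        return self.trunk.parameters + self.head_a.parameters + self.head_b.parameters

    def forward(self, x: Tensor):
        h = self.trunk(x).relu()
        ya = softmax(self.head_a(h), axis=1)  # (n, 2): (1-p, p)
        yb = softmax(self.head_b(h), axis=1)  # (n, H)
        return ya, yb

    def predict_arrays(self, x: np.ndarray):
        x = np.asarray(x, float)
        if x.ndim != 2 or x.shape[1] != self.d_in:
            raise ValueError(
                f"input has {x.shape[1] if x.ndim == 2 else '?'} columns, "
                f"model expects {self.d_in}"
            )
        ya, yb = self.forward(Tensor(x))
        return ya.data, yb.data


def fit(
    x: np.ndarray, labels: np.ndarray, config: LossConfig | None = None
) -> TwoStageModel:
    """Train the two-stage network; deterministic under ``config.seed``."""
    cfg = config or LossConfig()
    x = np.asarray(x, float)
    labels = np.asarray(labels, dtype=int)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if not np.any(labels > 0):
        raise ValueError("no MAFLD rows in training data; stage-2 term undefined")
    if np.isnan(x).any():
        raise ValueError("classifier input contains NaN; impute first")
    w = _weight_set(labels)
    rng = np.random.default_rng(cfg.seed)
    model = TwoStageModel(x.shape[1], cfg, rng)
    opt = Adam(model.parameters, lr=cfg.lr)

    n = len(labels)
    onehot3 = np.zeros((n, 3))
    onehot3[np.arange(n), labels] = 1.0
    binary = (labels > 0).astype(int)
    onehot2 = np.zeros((n, 2))
    onehot2[np.arange(n), binary] = 1.0
    mafld_mask = labels > 0
    onehot_ph = np.zeros((n, N_PHENOTYPES))
    onehot_ph[mafld_mask, labels[mafld_mask] - 1] = 1.0

    w3_row = w.overall[labels]
    w2_row = w.binary[binary]
    wph_row = np.where(mafld_mask, w.phenotype[np.clip(labels - 1, 0, None)], 0.0)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb = Tensor(x[idx])
            ya, yb = model.forward(xb)
            p = (ya * Tensor(np.tile([0.0, 1.0], (len(idx), 1)))).sum(
                axis=1, keepdims=True
            )
            comp = _t_compose(p, yb)
            nll = -(
                (comp.clip_min(_EPS).log() * Tensor(onehot3[idx]))
                .sum(axis=1) * Tensor(w3_row[idx])
            ).sum()
            bce = -(
                (ya.clip_min(_EPS).log() * Tensor(onehot2[idx]))
                .sum(axis=1) * Tensor(w2_row[idx])
            ).sum()
            pce = -(
                (yb.clip_min(_EPS).log() * Tensor(onehot_ph[idx]))
                .sum(axis=1) * Tensor(wph_row[idx])
            ).sum()
            loss = (nll + cfg.gamma * bce + cfg.lam * pce) * (1.0 / len(idx))
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def _t_compose(p: Tensor, yb: Tensor) -> Tensor:
    from .nn import concat

    return concat([1.0 - p, yb * p], axis=1)


def hard_labels(composed: np.ndarray) -> np.ndarray:
    """Argmax of the composed distribution; ties break to the lower index."""
    return np.argmax(np.atleast_2d(composed), axis=1)


def predict(model: TwoStageModel, x: np.ndarray) -> TwoStagePrediction:
    """Per-row distributions and hard labels (ties break to lower index)."""
    ya, yb = model.predict_arrays(x)
    p = ya[:, 1]
    composed = compose_probabilities(p, yb)
    return TwoStagePrediction(
        stage1=ya, stage2=yb, composed=composed, labels=hard_labels(composed)
    )


def threshold_report(
    probs: np.ndarray, binary_labels: np.ndarray, thresholds
) -> pd.DataFrame:
    """Stage-1 precision/recall per decision threshold.

    Rows with ``p >= t`` are flagged.  Precision with zero flags is reported
    as missing (NaN), not zero.
    """
    probs = np.asarray(probs, float)
    binary_labels = np.asarray(binary_labels, dtype=int)
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n_pos = int(binary_labels.sum())
    rows = []
    for t in thresholds:
        flagged = probs >= t
        n_flag = int(flagged.sum())
        tp = int(np.sum(flagged & (binary_labels == 1)))
        precision = tp / n_flag if n_flag else np.nan
        recall = tp / n_pos if n_pos else np.nan
        rows.append(
            {
                "threshold": float(t),
                "flagged": n_flag,
                "precision": precision,
                "recall": recall,
            }
        )
    return pd.DataFrame(rows)
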