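"""End-to-end method runners and the ablation ladder.

Every runner follows one contract: ``runner(cohort, split) -> (n_test, 3)``
matrix of class scores for the held-out rows.  Four modes are provided:

``mlp``
    Baseline: dense preprocessed input (z-scored numerics, one-hot
    categoricals, kNN-imputed with k=5) into a class-weighted softmax MLP.
``graph``
    Baseline input plus the triplet-trained lifestyle/genetics graph
    embeddings, same classifier.
``graph_cl``
    Baseline input plus the contrastive view embeddings (z_a, z_c), same
    classifier.
``full``
    The complete method: the same preprocessed dense matrix as the
    baseline, concatenated with the contrastive view embeddings, into the
    two-stage hierarchical estimator (every mode shares the dense input;
    the method's components additionally consume the raw, non-imputed
    survey responses).

Graphs are built over all persons' raw (non-imputed) survey responses
without any use of labels, so the construction is transductive but does not
leak outcome information; the teacher, learners and classifiers are fitted
on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import contrastive, graph, preprocess, twostage
from .nn import MLP, Adam, Tensor, softmax
from .schema import CohortTable, TrialSplit

__all__ = [
    "PipelineConfig",
    "MlpConfig",
    "full_method",
    "mlp_baseline",
    "graph_mode",
    "graph_cl_mode",
    "ablation_methods",
    "make_runner",
    "fit_full_pipeline",
    "FittedPipeline",
]


@dataclass(frozen=True)
class MlpConfig:
    hidden: int = 64
    n_hidden_layers: int = 2
    epochs: int = 150
    batch_size: int = 256
    lr: float = 1e-3
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    triplet: graph.TripletConfig = field(default_factory=graph.TripletConfig)
    contrastive: contrastive.ContrastiveConfig = field(
        default_factory=contrastive.ContrastiveConfig
    )
    loss: twostage.LossConfig = field(default_factory=twostage.LossConfig)
    mlp: MlpConfig = field(default_factory=MlpConfig)
    knn_k: int = 5
    include_teacher_embedding: bool = False
    seed: int = 0

    def reseed(self, seed: int) -> "PipelineConfig":
        """Derive a config whose every component seed follows ``seed``."""
        ss = np.random.SeedSequence(seed)
        s = [int(x) for x in ss.generate_state(4) % (2**31)]
        return replace(
            self,
            triplet=replace(self.triplet, seed=s[0]),
            contrastive=replace(self.contrastive, seed=s[1]),
            loss=replace(self.loss, seed=s[2]),
            mlp=replace(self.mlp, seed=s[3]),
            seed=seed,
        )

    def fast(self) -> "PipelineConfig":
        """Reduced-budget variant for small fixtures and quick experiments."""
        return replace(
            self,
            triplet=replace(self.triplet, epochs=20, dim=16),
            contrastive=replace(
                self.contrastive, teacher_epochs=30, learner_epochs=30, dim=16
            ),
            loss=replace(self.loss, epochs=60),
            mlp=replace(self.mlp, epochs=60),
        )


# ---------------------------------------------------------------------------
# shared building blocks
# ---------------------------------------------------------------------------


def _dense_imputed(cohort: CohortTable, split: TrialSplit, k: int):
    """Preprocess on train rows, transform all rows, kNN-impute both."""
    train_tab = cohort.subset(split.train)
    state = preprocess.fit_preprocessor(train_tab)
    x_all = preprocess.transform(state, cohort)
    x_train = x_all[split.train]
    blocks = state.onehot_blocks
    x_train_f = preprocess.knn_impute(x_train, k=k, onehot_blocks=blocks)
    x_all_f = preprocess.knn_impute(
        x_all, k=k, onehot_blocks=blocks, train_matrix=x_train
    )
    x_all_f[split.train] = x_train_f
    return state, x_all_f


def _graph_embeddings(cohort: CohortTable, cfg: PipelineConfig):
    """Triplet-trained person embeddings for both survey views."""
    emb = {}
    for i, group in enumerate(("S_lif", "S_gen")):
        g = graph.build_graph(cohort, group)
        tcfg = replace(cfg.triplet, seed=cfg.triplet.seed + i)
        emb[group] = graph.train_graph_encoder(g, tcfg)
    return emb["S_lif"], emb["S_gen"]


def _contrastive_embeddings(
    cohort: CohortTable, split: TrialSplit, cfg: PipelineConfig,
    a_lif: np.ndarray, a_gen: np.ndarray,
):
    """Teacher + learners trained on the train rows, applied to all rows."""
    train_tab = cohort.subset(split.train)
    state = preprocess.fit_preprocessor(train_tab)
    x_all = preprocess.transform(state, cohort)
    cols = []
    for f in cohort.schema.features:
        if cohort.schema.group_of(f.name) == "C":
            lo, hi = state.blocks[f.name]
            cols.extend(range(lo, hi))
    clin_all = x_all[:, cols]
    if np.isnan(clin_all).any():
        clin_all = preprocess.knn_impute(
            clin_all, k=cfg.knn_k, train_matrix=clin_all[split.train]
        )
    teacher = contrastive.pretrain_teacher(clin_all[split.train], cfg.contrastive)
    stack, _ = contrastive.train_learners(
        a_lif[split.train],
        a_gen[split.train],
        clin_all[split.train],
        cfg.contrastive,
        teacher=teacher,
    )
    views = stack.embed(a_lif, clin_all, a_gen)
    return views


class _WeightedSoftmaxMLP:
    """Three-class MLP trained with class-weighted cross-entropy."""

    def __init__(self, d_in: int, cfg: MlpConfig):
        rng = np.random.default_rng(cfg.seed)
        sizes = [d_in] + [cfg.hidden] * cfg.n_hidden_layers + [3]
        self.net = MLP(sizes, rng)
        self.cfg = cfg
        self.rng = rng

    def fit(self, x: np.ndarray, y: np.ndarray):
        cfg = self.cfg
        w = preprocess.compute_class_weights(y, n_classes=3)
        n = len(y)
        onehot = np.zeros((n, 3))
        onehot[np.arange(n), y] = 1.0
        w_row = w[y]
        opt = Adam(self.net.parameters, lr=cfg.lr)
        for _ in range(cfg.epochs):
            order = self.rng.permutation(n)
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                probs = softmax(self.net(Tensor(x[idx])), axis=1)
                loss = -(
                    (probs.clip_min(1e-12).log() * Tensor(onehot[idx])).sum(axis=1)
                    * Tensor(w_row[idx])
                ).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError("non-finite MLP loss")
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.net(Tensor(np.asarray(x, float))), axis=1).data


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------


def mlp_baseline(cohort, split, config: PipelineConfig | None = None):
    cfg = config or PipelineConfig()
    _, x = _dense_imputed(cohort, split, cfg.knn_k)
    clf = _WeightedSoftmaxMLP(x.shape[1], cfg.mlp).fit(
        x[split.train], cohort.y[split.train]
    )
    return clf.predict_proba(x[split.test])


def graph_mode(cohort, split, config: PipelineConfig | None = None):
    cfg = config or PipelineConfig()
    _, x = _dense_imputed(cohort, split, cfg.knn_k)
    a_lif, a_gen = _graph_embeddings(cohort, cfg)
    x = np.concatenate([x, a_lif, a_gen], axis=1)
    clf = _WeightedSoftmaxMLP(x.shape[1], cfg.mlp).fit(
        x[split.train], cohort.y[split.train]
    )
    return clf.predict_proba(x[split.test])


def graph_cl_mode(cohort, split, config: PipelineConfig | None = None):
    cfg = config or PipelineConfig()
    _, x = _dense_imputed(cohort, split, cfg.knn_k)
    a_lif, a_gen = _graph_embeddings(cohort, cfg)
    views = _contrastive_embeddings(cohort, split, cfg, a_lif, a_gen)
    x = np.concatenate([x, views.z_lifestyle, views.z_genetics], axis=1)
    clf = _WeightedSoftmaxMLP(x.shape[1], cfg.mlp).fit(
        x[split.train], cohort.y[split.train]
    )
    return clf.predict_proba(x[split.test])


@dataclass
class FittedPipeline:
    """Everything the full method fits for one split."""

    model: twostage.TwoStageModel
    features: np.ndarray  # (n_all, d) classifier input for every row
    views: contrastive.ViewEmbeddings
    split: TrialSplit

    def predict(self, idx=None) -> twostage.TwoStagePrediction:
        x = self.features if idx is None else self.features[np.asarray(idx)]
        return twostage.predict(self.model, x)


def fit_full_pipeline(
    cohort: CohortTable, split: TrialSplit, config: PipelineConfig | None = None
) -> FittedPipeline:
    """Fit the complete two-stage multiview method on one trial split."""
    cfg = config or PipelineConfig()
    a_lif, a_gen = _graph_embeddings(cohort, cfg)
    views = _contrastive_embeddings(cohort, split, cfg, a_lif, a_gen)
    _, x_dense = _dense_imputed(cohort, split, cfg.knn_k)
    parts = [x_dense, views.z_lifestyle, views.z_genetics]
    if cfg.include_teacher_embedding:
        parts.append(views.z_clinical)
    x = np.concatenate(parts, axis=1)
    model = twostage.fit(x[split.train], cohort.y[split.train], cfg.loss)
    return FittedPipeline(model=model, features=x, views=views, split=split)


def full_method(cohort, split, config: PipelineConfig | None = None):
    fitted = fit_full_pipeline(cohort, split, config)
    return fitted.predict(split.test).composed


def make_runner(mode: str, config: PipelineConfig | None = None):
    """Bind a mode name to a ``runner(cohort, split)`` callable."""
    runners = {
        "mlp": mlp_baseline,
        "graph": graph_mode,
        "graph_cl": graph_cl_mode,
        "full": full_method,
    }
    if mode not in runners:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(runners)}")
    fn = runners[mode]

    def runner(cohort, split):
        return fn(cohort, split, config)

    return runner


def ablation_methods(config: PipelineConfig | None = None) -> dict:
    """The four ablation modes in ladder order, sharing one config."""
    return {m: make_runner(m, config) for m in ("mlp", "graph", "graph_cl", "full")}
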