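"""Person-feature bipartite graphs and triplet-trained node embeddings.

Each survey view (lifestyle, genetic family history) becomes an undirected
bipartite graph: one node per person, one node per *feature value* (feature
``i``, coded category ``j`` of ``J_i``), and an edge wherever a person's
response on that feature is observed with that value.  Missing cells simply
contribute no edge, so incomplete survey data needs no imputation here.
Numeric survey features, if present, are quantile-binned into a small number
of categories first so that every feature contributes coded-value nodes.

Node embeddings are learned with a two-layer mean-aggregation neighborhood
encoder (GraphSAGE-style: each layer maps the concatenation of a node's own
representation and its neighbors' mean through a dense layer) trained with a
margin-based triplet objective: an anchor person is pulled toward a positive
(a uniformly drawn neighbor, or the anchor itself when it is isolated) and
pushed from a negative (a uniformly drawn non-neighbor).

Initial node features (fixed, injective): each feature-value node gets the
one-hot of its own identity; each person node gets zeros there plus two
summary coordinates — its normalized degree and the mean of its normalized
observed response codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .nn import Adam, Linear, Tensor, concat, spmm
from .schema import CohortTable

__all__ = [
    "BipartiteGraph",
    "TripletConfig",
    "build_graph",
    "sample_triplet",
    "triplet_loss",
    "train_graph_encoder",
]

#: number of quantile bins used to discretize numeric survey features
NUMERIC_BINS = 4


@dataclass
class BipartiteGraph:
    """Persons vs feature-value nodes with a symmetric weighted adjacency.

    Node indexing: persons occupy indices ``0 .. n_persons-1``; feature-value
    node ``k`` occupies index ``n_persons + k``.
    """

    group: str
    n_persons: int
    feature_values: list[tuple[str, str]]  # (feature name, coded level)
    adjacency: sp.csr_matrix  # (n_nodes, n_nodes), symmetric
    #: per-person mean of normalized observed response codes (in [0, 1])
    person_value_summary: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.n_persons + len(self.feature_values)

    def neighbors(self, node: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[node] : self.adjacency.indptr[node + 1]
        ]

    def degree(self, node: int) -> int:
        return self.adjacency.indptr[node + 1] - self.adjacency.indptr[node]

    def is_bipartite(self) -> bool:
        coo = self.adjacency.tocoo()
        p = self.n_persons
        return bool(np.all((coo.row < p) != (coo.col < p)))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_persons), bipartite=0)
        g.add_nodes_from(
            (self.n_persons + k for k in range(len(self.feature_values))),
            bipartite=1,
        )
        coo = sp.triu(self.adjacency).tocoo()
        g.add_weighted_edges_from(zip(coo.row, coo.col, coo.data))
        return g

    def to_edge_list(self, path) -> None:
        """Export edges as TSV (person_id, feature, level, weight)."""
        coo = self.adjacency.tocoo()
        rows = []
        for r, c, w in zip(coo.row, coo.col, coo.data):
            if r < self.n_persons <= c:
                feat, level = self.feature_values[c - self.n_persons]
                rows.append((int(r), feat, level, float(w)))
        pd.DataFrame(
            rows, columns=["person_id", "feature", "level", "weight"]
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class TripletConfig:
    """Defaults chosen so linear probes of the embeddings retain the
    survey's aggregate class signal (a narrower encoder measurably loses
    part of it)."""

    margin: float = 0.5
    dim: int = 96
    n_layers: int = 2
    epochs: int = 100
    negatives_per_anchor: int = 2
    lr: float = 1e-2
    seed: int = 0

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError(f"margin must be positive, got {self.margin}")
        if self.dim < 2:
            raise ValueError(f"embedding dim must be >= 2, got {self.dim}")


def _bin_numeric(values: np.ndarray, observed: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-bin observed values into codes 0..n_bins-1 (-1 = missing)."""
    codes = np.full(len(values), -1, dtype=int)
    obs_vals = values[observed]
    if obs_vals.size == 0:
        return codes
    qs = np.quantile(obs_vals, np.linspace(0, 1, n_bins + 1)[1:-1])
    codes[observed] = np.searchsorted(qs, obs_vals, side="right")
    return codes


def build_graph(table: CohortTable, group: str) -> BipartiteGraph:
    """Construct the person-feature bipartite graph for one survey group."""
    feats = table.schema.group_features(group)
    if not feats:
        raise ValueError(f"group {group!r} has no features")
    n = table.n

    feature_values: list[tuple[str, str]] = []
    fv_index: dict[tuple[str, str], int] = {}
    person_codes: dict[str, np.ndarray] = {}
    levels_per_feature: dict[str, int] = {}
    for f in feats:
        observed = ~table.mask[f.name].to_numpy()
        if f.kind == "categorical":
            levels = list(f.levels)
            lvl_idx = {lvl: k for k, lvl in enumerate(levels)}
            codes = np.full(n, -1, dtype=int)
            col = table.data[f.name]
            for i in np.flatnonzero(observed):
                codes[i] = lvl_idx[col.iloc[i]]
        else:
            codes = _bin_numeric(
                table.data[f.name].to_numpy(float), observed, NUMERIC_BINS
            )
            levels = [f"bin{k}" for k in range(NUMERIC_BINS)]
        levels_per_feature[f.name] = len(levels)
        for lvl in levels:
            fv_index[(f.name, lvl)] = n + len(feature_values)
            feature_values.append((f.name, lvl))
        person_codes[f.name] = codes

    rows, cols = [], []
    norm_sum = np.zeros(n)
    norm_cnt = np.zeros(n)
    first_fv: dict[str, int] = {}
    for fname, lvl in reversed(feature_values):
        first_fv[fname] = fv_index[(fname, lvl)]
    for f in feats:
        codes = person_codes[f.name]
        J = levels_per_feature[f.name]
        idx = np.flatnonzero(codes >= 0)
        # feature-value node index = this feature's first level node + code
        rows.extend(idx.tolist())
        cols.extend((first_fv[f.name] + codes[idx]).tolist())
        norm_sum[idx] += codes[idx] / max(J - 1, 1)
        norm_cnt[idx] += 1

    n_nodes = n + len(feature_values)
    # categorical/coded values carry unit edge weight
    data = np.ones(len(rows))
    upper = sp.coo_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes))
    adjacency = (upper + upper.T).tocsr()
    with np.errstate(invalid="ignore"):
        summary = np.where(norm_cnt > 0, norm_sum / np.maximum(norm_cnt, 1), 0.0)
    return BipartiteGraph(
        group=group,
        n_persons=n,
        feature_values=feature_values,
        adjacency=adjacency,
        person_value_summary=summary,
    )


def sample_triplet(
    graph: BipartiteGraph, anchor: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Draw (anchor, positive, negative) node indices for one anchor person.

    The positive is a uniformly chosen neighbor — or the anchor itself if it
    has none; the negative is a uniformly chosen node that is neither the
    anchor nor one of its neighbors.
    """
    if not 0 <= anchor < graph.n_persons:
        raise ValueError(f"anchor {anchor} is not a person node")
    nbrs = graph.neighbors(anchor)
    pos = anchor if len(nbrs) == 0 else int(rng.choice(nbrs))
    forbidden = set(nbrs.tolist()) | {anchor}
    if len(forbidden) >= graph.n_nodes:
        raise ValueError("no valid negative: anchor neighbors every other node")
    while True:
        neg = int(rng.integers(graph.n_nodes))
        if neg not in forbidden:
            return anchor, pos, neg


def triplet_loss(f_a: np.ndarray, f_p: np.ndarray, f_n: np.ndarray, alpha: float) -> float:
    """Margin loss max(0, d(a,p) - d(a,n) + alpha) with Euclidean d."""
    f_a, f_p, f_n = (np.asarray(v, dtype=float) for v in (f_a, f_p, f_n))
    if not (f_a.shape == f_p.shape == f_n.shape):
        raise ValueError(
            f"dimension mismatch: {f_a.shape} vs {f_p.shape} vs {f_n.shape}"
        )
    if alpha <= 0:
        raise ValueError(f"margin must be positive, got {alpha}")
    d_ap = float(np.linalg.norm(f_a - f_p))
    d_an = float(np.linalg.norm(f_a - f_n))
    return max(0.0, d_ap - d_an + alpha)


def _initial_features(graph: BipartiteGraph) -> np.ndarray:
    """Fixed injective node features (see module docstring)."""
    n_fv = len(graph.feature_values)
    X = np.zeros((graph.n_nodes, n_fv + 2))
    X[graph.n_persons :, :n_fv] = np.eye(n_fv)
    degrees = np.diff(graph.adjacency.indptr)[: graph.n_persons]
    max_deg = max(int(degrees.max()), 1) if len(degrees) else 1
    X[: graph.n_persons, n_fv] = degrees / max_deg
    X[: graph.n_persons, n_fv + 1] = graph.person_value_summary
    return X


class _SageEncoder:
    """Two-layer mean-aggregation encoder computing all node embeddings."""

    def __init__(self, graph: BipartiteGraph, dim: int, n_layers: int, rng):
        self.X = _initial_features(graph)
        degrees = np.maximum(np.diff(graph.adjacency.indptr), 1)
        inv_deg = sp.diags(1.0 / degrees)
        self.A_mean = (inv_deg @ graph.adjacency).tocsr()
        self.layers = []
        d_in = self.X.shape[1]
        for _ in range(n_layers):
            self.layers.append(Linear(2 * d_in, dim, rng))
            d_in = dim

    def __call__(self) -> Tensor:
        h = Tensor(self.X)
        for i, layer in enumerate(self.layers):
            agg = spmm(self.A_mean, h)
            h = layer(concat([h, agg], axis=1))
            if i < len(self.layers) - 1:
                h = h.relu()
        return h

    @property
    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters]


def train_graph_encoder(
    graph: BipartiteGraph,
    config: TripletConfig | None = None,
    return_history: bool = False,
):
    """Learn person embeddings (n_persons, dim) by minimizing mean triplet loss.

    Deterministic under ``config.seed``.  Raises on non-finite loss.  With
    ``return_history`` the per-epoch mean triplet losses are returned too.
    """
    cfg = config or TripletConfig()
    rng = np.random.default_rng(cfg.seed)
    encoder = _SageEncoder(graph, cfg.dim, cfg.n_layers, rng)
    opt = Adam(encoder.parameters, lr=cfg.lr)

    anchors = np.arange(graph.n_persons)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        a_idx, p_idx, n_idx = [], [], []
        for a in anchors:
            for _ in range(cfg.negatives_per_anchor):
                _, p, neg = sample_triplet(graph, int(a), rng)
                a_idx.append(a)
                p_idx.append(p)
                n_idx.append(neg)
        h = encoder()
        fa = h.take_rows(a_idx)
        fp = h.take_rows(p_idx)
        fn = h.take_rows(n_idx)
        # epsilon keeps sqrt differentiable when positive == anchor (d = 0)
        d_ap = ((fa - fp).pow(2.0).sum(axis=1) + 1e-12).sqrt()
        d_an = ((fa - fn).pow(2.0).sum(axis=1) + 1e-12).sqrt()
        loss = (d_ap - d_an + cfg.margin).clip_min(0.0).mean()
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite triplet loss at epoch {epoch}: {loss.data}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss.data))

    embeddings = encoder().data[: graph.n_persons].copy()
    if return_history:
        return embeddings, history
    return embeddings
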