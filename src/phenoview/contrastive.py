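"""Teacher-guided multiview contrastive pretraining with adaptive temperature.

The clinical view is encoded by a *teacher*: the encoder half of an
autoencoder pretrained to reconstruct the standardized clinical matrix.  The
lifestyle and genetics *learners* (3-layer MLPs sharing an architecture)
take the triplet-trained graph embeddings as input and are trained to align
each person's view embedding with that person's clinical embedding using a
one-directional InfoNCE objective: the positive pair is the same person
across views, negatives are the other persons in the batch.

The softmax temperature is not fixed: a lightweight adaptive temperature
network (ATN) maps the batch-mean clinical embedding through a ReLU and a
linear read-out to one temperature per batch.  The raw linear form can emit
non-positive temperatures, so it is safeguarded as
``tau = softplus(w . relu(v_batch)) + tau_min`` with ``tau_min = 0.05``,
which preserves the dynamic adjustment while keeping InfoNCE well defined.
The teacher is frozen during learner training; the ATN trains jointly with
the learners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import MLP, Adam, Tensor, softmax

__all__ = [
    "ContrastiveConfig",
    "EncoderStack",
    "ViewEmbeddings",
    "TAU_MIN",
    "pretrain_teacher",
    "batch_temperature",
    "infonce_loss",
    "multiview_loss",
    "train_learners",
]

TAU_MIN = 0.05


@dataclass(frozen=True)
class ContrastiveConfig:
    dim: int = 64  # embedding dimension d_z
    hidden: int = 64
    batch_size: int = 256
    teacher_epochs: int = 100
    learner_epochs: int = 100
    lr: float = 1e-3
    tau_min: float = TAU_MIN
    freeze_teacher: bool = True
    teacher_activation: str = "relu"
    seed: int = 0


@dataclass
class ViewEmbeddings:
    """Row-aligned per-person embeddings of the three views."""

    z_lifestyle: np.ndarray  # z_a
    z_clinical: np.ndarray  # z_b
    z_genetics: np.ndarray  # z_c

    def __post_init__(self):
        shapes = {
            self.z_lifestyle.shape,
            self.z_clinical.shape,
            self.z_genetics.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"view embeddings not aligned: {shapes}")
        for name in ("z_lifestyle", "z_clinical", "z_genetics"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} contains non-finite values")


class _Autoencoder:
    def __init__(self, d_in, hidden, d_z, rng, activation):
        self.encoder = MLP([d_in, hidden, hidden, d_z], rng, activation)
        self.decoder = MLP([d_z, hidden, hidden, d_in], rng, activation)

    @property
    def parameters(self):
        return self.encoder.parameters + self.decoder.parameters


class TeacherEncoder:
    """Frozen encoder half of the clinical autoencoder.

    Keeps a handle on the decoder and the per-epoch training losses so that
    reconstruction quality can be inspected after pretraining.
    """

    def __init__(self, model: _Autoencoder, loss_history: list[float]):
        self._model = model
        self.loss_history = list(loss_history)

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self._model.encoder(Tensor(np.asarray(x, float))).data

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._model.decoder(
            self._model.encoder(Tensor(np.asarray(x, float)))
        ).data


@dataclass
class EncoderStack:
    """The three view encoders plus the ATN read-out weights."""

    enc_lifestyle: MLP  # Enc_a
    teacher: TeacherEncoder  # Enc_b
    enc_genetics: MLP  # Enc_c
    atn_weights: np.ndarray  # (d_z,)
    tau_min: float = TAU_MIN

    def embed(self, a_lif: np.ndarray, clinical: np.ndarray, a_gen: np.ndarray) -> ViewEmbeddings:
        return ViewEmbeddings(
            z_lifestyle=self.enc_lifestyle(Tensor(np.asarray(a_lif, float))).data,
            z_clinical=self.teacher.encode(clinical),
            z_genetics=self.enc_genetics(Tensor(np.asarray(a_gen, float))).data,
        )


def pretrain_teacher(
    clinical: np.ndarray, config: ContrastiveConfig | None = None
) -> TeacherEncoder:
    """Train an autoencoder on the (complete, standardized) clinical matrix
    by mean squared reconstruction error; return its encoder half."""
    cfg = config or ContrastiveConfig()
    clinical = np.asarray(clinical, dtype=float)
    if clinical.ndim != 2 or clinical.shape[0] == 0:
        raise ValueError("clinical matrix must be 2-D and non-empty")
    if np.isnan(clinical).any():
        raise ValueError("teacher pretraining needs a complete clinical matrix")
    rng = np.random.default_rng(cfg.seed)
    model = _Autoencoder(
        clinical.shape[1], cfg.hidden, cfg.dim, rng, cfg.teacher_activation
    )
    opt = Adam(model.parameters, lr=cfg.lr)
    n = clinical.shape[0]
    history: list[float] = []
    for epoch in range(cfg.teacher_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, cfg.batch_size):
            batch = clinical[order[lo : lo + cfg.batch_size]]
            x = Tensor(batch)
            recon = model.decoder(model.encoder(x))
            loss = (recon - x).pow(2.0).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite reconstruction loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
    return TeacherEncoder(model, history)


def batch_temperature(
    z_b_batch: np.ndarray, weights: np.ndarray, tau_min: float = TAU_MIN
) -> float:
    """ATN forward pass: tau = softplus(w . relu(mean(z_b))) + tau_min."""
    z_b_batch = np.atleast_2d(np.asarray(z_b_batch, float))
    weights = np.asarray(weights, float).reshape(-1)
    v = z_b_batch.mean(axis=0)
    raw = float(weights @ np.maximum(v, 0.0))
    return float(np.logaddexp(0.0, raw) + tau_min)


def _cosine_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-norm embedding row; cosine similarity undefined")
    return (a @ b.T) / np.outer(na, nb)


def infonce_loss(z_x: np.ndarray, z_b: np.ndarray, tau: float) -> float:
    """One-directional InfoNCE with cosine similarity.

    Mean over persons i of -log softmax_i of sim(z_x(i), z_b(k))/tau over
    in-batch candidates k, with k = i the positive.
    """
    z_x = np.atleast_2d(np.asarray(z_x, float))
    z_b = np.atleast_2d(np.asarray(z_b, float))
    if z_x.shape != z_b.shape:
        raise ValueError(f"batch mismatch: {z_x.shape} vs {z_b.shape}")
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    s = _cosine_rows(z_x, z_b) / tau
    s -= s.max(axis=1, keepdims=True)
    log_denom = np.log(np.exp(s).sum(axis=1))
    return float(np.mean(log_denom - np.diag(s)))


def multiview_loss(
    z_a: np.ndarray, z_b: np.ndarray, z_c: np.ndarray, tau: float
) -> float:
    """Sum of the two learner-vs-teacher InfoNCE terms."""
    return infonce_loss(z_a, z_b, tau) + infonce_loss(z_c, z_b, tau)


# ---------------------------------------------------------------------------
# learner training (differentiable path)
# ---------------------------------------------------------------------------


def _t_rownorm(z: Tensor) -> Tensor:
    norms = (z.pow(2.0).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    return z / norms


def _t_infonce(z_x: Tensor, z_b_unit: np.ndarray, tau: Tensor) -> Tensor:
    """Tensor InfoNCE against a constant (frozen-teacher) unit-row matrix."""
    zx = _t_rownorm(z_x)
    sims = zx @ Tensor(z_b_unit.T)
    logits = sims / tau
    probs = softmax(logits, axis=1)
    n = z_b_unit.shape[0]
    eye = Tensor(np.eye(n))
    pos = (probs * eye).sum(axis=1).clip_min(1e-12)
    return -(pos.log().mean())


def train_learners(
    a_lif: np.ndarray,
    a_gen: np.ndarray,
    clinical: np.ndarray,
    config: ContrastiveConfig | None = None,
    teacher: TeacherEncoder | None = None,
) -> tuple[EncoderStack, ViewEmbeddings]:
    """Align lifestyle/genetics encoders to the frozen clinical teacher.

    Inputs are row-aligned per person: the two graph-embedding matrices and
    the standardized clinical matrix.  The ATN weights receive gradients
    from the same loss.  Returns the trained encoder stack and the final
    per-person view embeddings.  Deterministic under ``config.seed``.
    """
    cfg = config or ContrastiveConfig()
    a_lif = np.asarray(a_lif, float)
    a_gen = np.asarray(a_gen, float)
    clinical = np.asarray(clinical, float)
    if not (a_lif.shape[0] == a_gen.shape[0] == clinical.shape[0]):
        raise ValueError("view inputs are not row-aligned")
    rng = np.random.default_rng(cfg.seed)

    if teacher is None:
        teacher = pretrain_teacher(clinical, cfg)
    z_b = teacher.encode(clinical)  # frozen

    enc_a = MLP([a_lif.shape[1], cfg.hidden, cfg.hidden, cfg.dim], rng)
    enc_c = MLP([a_gen.shape[1], cfg.hidden, cfg.hidden, cfg.dim], rng)
    w_atn = Tensor(np.zeros(cfg.dim), requires_grad=True)
    opt = Adam(enc_a.parameters + enc_c.parameters + [w_atn], lr=cfg.lr)

    n = clinical.shape[0]
    zb_norms = np.linalg.norm(z_b, axis=1, keepdims=True)
    if np.any(zb_norms == 0):
        raise ValueError("teacher produced a zero-norm embedding row")
    z_b_unit = z_b / zb_norms

    for epoch in range(cfg.learner_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            if len(idx) < 2:
                continue
            # ATN: batch-mean clinical embedding -> temperature
            v = Tensor(z_b[idx].mean(axis=0))
            raw_t = (v.relu() * w_atn).sum()
            tau = raw_t.softplus() + cfg.tau_min

            za = enc_a(Tensor(a_lif[idx]))
            zc = enc_c(Tensor(a_gen[idx]))
            zbu = z_b_unit[idx]
            loss = _t_infonce(za, zbu, tau) + _t_infonce(zc, zbu, tau)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite contrastive loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()

    stack = EncoderStack(
        enc_lifestyle=enc_a,
        teacher=teacher,
        enc_genetics=enc_c,
        atn_weights=w_atn.data.copy(),
        tau_min=cfg.tau_min,
    )
    views = stack.embed(a_lif, clinical, a_gen)
    return stack, views
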