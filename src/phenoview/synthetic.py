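"""Synthetic cohort generator with planted multi-view structure.

The generator emulates the statistical features the prediction method relies
on, without attempting to match any real cohort's marginals:

* a heavily imbalanced three-class outcome (default priors 0.850 / 0.115 /
  0.035 for non-MAFLD, nondiabetic MAFLD, diabetic MAFLD);
* intraphenotype heterogeneity, modeled as latent subclusters within each
  outcome class: each (class, subcluster) pair owns a mean in a
  low-dimensional latent factor space, and every person draws a latent
  vector around their pair's mean;
* clinical variables as noisy linear read-outs of the latent factors, plus
  two "definitive" diabetic markers elevated in the diabetic class only;
* categorical survey responses (lifestyle, family history) drawn from
  softmax models over the same latent factors, scaled by a coupling
  strength ``rho`` — at ``rho = 0`` the surveys are pure noise, at larger
  ``rho`` they carry class signal that is weak per item but strong in
  aggregate, which is exactly the regime where graph aggregation and
  teacher-guided contrastive alignment can help;
* missing-completely-at-random survey responses at a configurable rate,
  restricted to the survey groups (demographics, clinical values and labels
  are never masked by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import SURVEY_GROUPS, CohortTable, FeatureSchema

__all__ = ["SyntheticConfig", "GroundTruth", "generate_cohort", "inject_missingness"]

#: outcome priors observed in the study cohort (3747/507/154 of 4408)
DEFAULT_PRIORS = (0.850, 0.115, 0.035)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults; see module docstring for what each knob plants."""

    n: int = 4408
    priors: tuple[float, float, float] = DEFAULT_PRIORS
    k_sub: int = 2  # latent subclusters per outcome class
    rho: float = 0.8  # cross-view coupling strength in [0, 1]
    missing_rate: float = 0.3  # MCAR rate on survey cells, in [0, 1)
    n_demo: int = 2
    n_clinical: int = 36
    n_lifestyle: int = 32
    n_genetic: int = 42
    latent_dim: int = 6
    #: clinical variables read only the first `clinical_latent_dims` factors
    #: (the "metabolic state"); surveys read all factors, so behavioral and
    #: hereditary predisposition dims are visible only through the surveys
    clinical_latent_dims: int = 4
    class_sep: float = 0.85  # spread of (class, subcluster) latent means
    within_sd: float = 1.0  # person-level latent noise sd
    clinical_noise_sd: float = 3.0
    survey_logit_scale: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise ValueError(f"priors must sum to 1, got {self.priors}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing rate must be in [0, 1), got {self.missing_rate}")
        if self.n < 1 or self.k_sub < 1:
            raise ValueError("n and k_sub must be positive")


@dataclass
class GroundTruth:
    """Latent state behind a generated cohort, for diagnostics and tests."""

    y: np.ndarray  # (n,) true class
    subcluster: np.ndarray  # (n,) subcluster id within class
    latent: np.ndarray  # (n, q) person latent factors
    class_means: np.ndarray  # (3, k_sub, q) latent means
    clinical_loadings: np.ndarray  # (n_clinical, q)
    survey_loadings: dict[str, np.ndarray]  # feature name -> (J, q)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def generate_cohort(
    config: SyntheticConfig, schema: FeatureSchema | None = None
) -> tuple[CohortTable, GroundTruth]:
    """Draw a cohort and its ground truth; byte-identical under a fixed seed."""
    cfg = config
    if schema is None:
        schema = FeatureSchema.default(
            cfg.n_demo, cfg.n_clinical, cfg.n_lifestyle, cfg.n_genetic
        )
    rng = np.random.default_rng(cfg.seed)
    n, q = cfg.n, cfg.latent_dim

    y = rng.choice(3, size=n, p=np.asarray(cfg.priors) / sum(cfg.priors))
    absent = [c for c in range(3) if not np.any(y == c)]
    if absent:
        warnings.warn(
            f"class(es) {absent} absent from the drawn cohort (n={n}, "
            f"priors={cfg.priors})"
        )
    sub = rng.integers(cfg.k_sub, size=n)

    # latent means per (class, subcluster); each person scatters around theirs
    class_means = rng.normal(0.0, cfg.class_sep, size=(3, cfg.k_sub, q))
    latent = class_means[y, sub] + rng.normal(0.0, cfg.within_sd, size=(n, q))

    data: dict[str, pd.Series] = {}

    # demographics: age with a mild any-MAFLD shift, sex from study marginals
    demo_feats = schema.group_features("D")
    for f in demo_feats:
        if f.name == "age":
            age = 58.18 + 12.94 * rng.normal(size=n) + 2.0 * (y > 0)
            data[f.name] = pd.Series(age)
        elif f.name == "sex":
            sex = np.where(rng.random(n) < 0.681, "female", "male")
            data[f.name] = pd.Series(sex, dtype=object)
        else:
            data[f.name] = pd.Series(rng.normal(size=n))

    # clinical variables: linear read-outs of the latent factors, plus two
    # definitive diabetic markers elevated only in the diabetic class
    clin_feats = schema.group_features("C")
    q_clin = min(cfg.clinical_latent_dims, q)
    loadings = np.zeros((len(clin_feats), q))
    loadings[:, :q_clin] = rng.normal(
        0.0, 1.0, size=(len(clin_feats), q_clin)
    ) / np.sqrt(q_clin)
    if len(clin_feats) >= 2:
        loadings[0] = 0.0
        loadings[1] = 0.0
    noise = cfg.clinical_noise_sd * rng.normal(size=(n, len(clin_feats)))
    if len(clin_feats) >= 2:
        # definitive markers keep unit noise so their diabetic shift stays legible
        noise[:, :2] *= 1.0 / cfg.clinical_noise_sd
    clinical = latent @ loadings.T + noise
    if len(clin_feats) >= 2:
        clinical[:, 0] += 3.0 * (y == 2)
        clinical[:, 1] += 2.5 * (y == 2)
    for j, f in enumerate(clin_feats):
        data[f.name] = pd.Series(clinical[:, j])

    # survey responses: softmax over latent factors, attenuated by rho
    survey_loadings: dict[str, np.ndarray] = {}
    for group in SURVEY_GROUPS:
        for f in schema.group_features(group):
            J = len(f.levels)
            W = rng.normal(0.0, 1.0, size=(J, q)) / np.sqrt(q)
            survey_loadings[f.name] = W
            logits = cfg.rho * cfg.survey_logit_scale * (latent @ W.T)
            probs = _softmax(logits)
            u = rng.random(n)
            draws = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            data[f.name] = pd.Series(
                [f.levels[k] for k in draws], dtype=object
            )

    frame = pd.DataFrame(data, columns=list(schema.feature_names))
    mask = pd.DataFrame(
        False, index=frame.index, columns=frame.columns
    )
    table = CohortTable(schema, frame, mask, y)
    if cfg.missing_rate > 0.0:
        table = inject_missingness(
            table, cfg.missing_rate, seed=int(rng.integers(2**31))
        )
    truth = GroundTruth(
        y=y,
        subcluster=sub,
        latent=latent,
        class_means=class_means,
        clinical_loadings=loadings,
        survey_loadings=survey_loadings,
    )
    return table, truth


def inject_missingness(table: CohortTable, m: float, seed: int = 0) -> CohortTable:
    """Mask survey cells completely at random at rate ``m``.

    Only lifestyle and family-history cells are eligible; demographics,
    clinical values and the outcome are never touched.  Returns a new table.
    """
    if not 0.0 <= m < 1.0:
        raise ValueError(f"missing rate must be in [0, 1), got {m}")
    data = table.data.copy()
    mask = table.mask.copy()
    if m == 0.0:
        return CohortTable(table.schema, data, mask, table.y.copy())
    rng = np.random.default_rng(seed)
    survey_cols = [
        f.name for g in SURVEY_GROUPS for f in table.schema.group_features(g)
    ]
    hit = rng.random((table.n, len(survey_cols))) < m
    for j, col in enumerate(survey_cols):
        rows = hit[:, j]
        mask.loc[rows, col] = True
        data.loc[rows, col] = np.nan
    return CohortTable(table.schema, data, mask, table.y.copy())
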