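"""Data model for mixed-type patient cohorts and reproducible trial splits.

A cohort is a table of one row per person with four feature groups —
demographics (``D``), clinical variables (``C``), lifestyle survey items
(``S_lif``) and genetic family history items (``S_gen``) — and a three-level
outcome: no MAFLD, nondiabetic MAFLD, or diabetic MAFLD.  Features are
declared in a :class:`FeatureSchema`; missing values (allowed on the survey
groups by default) are tracked in an explicit boolean mask that is the single
source of truth for missingness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

GROUPS = ("D", "C", "S_lif", "S_gen")
SURVEY_GROUPS = ("S_lif", "S_gen")

#: Outcome classes, in order of class index 0/1/2.
LABELS = ("non_MAFLD", "nondiabetic_MAFLD", "diabetic_MAFLD")
LABEL_COLUMN = "mafld_status"

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


class SchemaError(ValueError):
    """A cohort file or value violates its declared schema."""


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str  # "numeric" | "categorical"
    levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("numeric", "categorical"):
            raise SchemaError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if self.levels is None or len(self.levels) < 2:
                raise SchemaError(
                    f"categorical feature {self.name!r} needs >= 2 declared levels"
                )
        elif self.levels is not None:
            raise SchemaError(f"numeric feature {self.name!r} must not declare levels")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature lists for the four groups D, C, S_lif, S_gen."""

    groups: dict[str, tuple[Feature, ...]]

    def __post_init__(self):
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise SchemaError(f"unknown group(s): {sorted(unknown)}")
        names = [f.name for feats in self.groups.values() for f in feats]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"feature name(s) in more than one place: {sorted(dupes)}")
        if LABEL_COLUMN in names:
            raise SchemaError(f"{LABEL_COLUMN!r} is reserved for the outcome")

    @property
    def features(self) -> tuple[Feature, ...]:
        return tuple(f for g in GROUPS for f in self.groups.get(g, ()))

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def group_of(self, name: str) -> str:
        for g, feats in self.groups.items():
            if any(f.name == name for f in feats):
                return g
        raise SchemaError(f"unknown feature {name!r}")

    def group_features(self, group: str) -> tuple[Feature, ...]:
        return tuple(self.groups.get(group, ()))

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise SchemaError(f"unknown feature {name!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            g: [
                {"name": f.name, "kind": f.kind}
                | ({"levels": list(f.levels)} if f.levels else {})
                for f in feats
            ]
            for g, feats in self.groups.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            {
                g: tuple(
                    Feature(
                        entry["name"],
                        entry["kind"],
                        tuple(str(x) for x in entry["levels"])
                        if entry.get("levels")
                        else None,
                    )
                    for entry in feats
                )
                for g, feats in d.items()
            }
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(
        cls,
        n_demo: int = 2,
        n_clinical: int = 36,
        n_lifestyle: int = 32,
        n_genetic: int = 42,
    ) -> "FeatureSchema":
        """Schema mirroring the study's feature-group sizes (2/36/32/42).

        Demographics are age (numeric) and sex (binary); clinical variables
        are numeric laboratory/anthropometric measurements; lifestyle items
        are 4-point ordinal survey responses; family-history items are
        yes/no.
        """
        demo: list[Feature] = []
        if n_demo >= 1:
            demo.append(Feature("age", "numeric"))
        if n_demo >= 2:
            demo.append(Feature("sex", "categorical", ("female", "male")))
        for i in range(2, n_demo):
            demo.append(Feature(f"demo_{i + 1:02d}", "numeric"))
        return cls(
            {
                "D": tuple(demo),
                "C": tuple(
                    Feature(f"clin_{i + 1:02d}", "numeric") for i in range(n_clinical)
                ),
                "S_lif": tuple(
                    Feature(f"lif_{i + 1:02d}", "categorical", ("0", "1", "2", "3"))
                    for i in range(n_lifestyle)
                ),
                "S_gen": tuple(
                    Feature(f"gen_{i + 1:02d}", "categorical", ("0", "1"))
                    for i in range(n_genetic)
                ),
            }
        )


@dataclass
class CohortTable:
    """n persons x declared features, with outcome labels and a missingness mask.

    ``data`` holds floats for numeric features and level strings (or NaN) for
    categorical ones; ``mask`` is True where a cell is missing; ``y`` holds
    class indices 0 (non-MAFLD), 1 (nondiabetic MAFLD), 2 (diabetic MAFLD).
    """

    schema: FeatureSchema
    data: pd.DataFrame
    mask: pd.DataFrame
    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if list(self.data.columns) != list(self.schema.feature_names):
            raise SchemaError("data columns do not match schema feature order")
        if self.data.shape != self.mask.shape:
            raise SchemaError("mask shape differs from data shape")
        if len(self.y) != len(self.data):
            raise SchemaError("every row needs a label")
        if len(self.y) and not np.all((self.y >= 0) & (self.y < len(LABELS))):
            raise SchemaError("labels must be class indices 0..2")

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, idx) -> "CohortTable":
        idx = np.asarray(idx)
        return CohortTable(
            self.schema,
            self.data.iloc[idx].reset_index(drop=True),
            self.mask.iloc[idx].reset_index(drop=True),
            self.y[idx],
        )

    def group_columns(self, group: str) -> list[str]:
        return [f.name for f in self.schema.group_features(group)]

    def equals(self, other: "CohortTable") -> bool:
        if self.n != other.n or not np.array_equal(self.y, other.y):
            return False
        if not self.mask.equals(other.mask):
            return False
        for f in self.schema.features:
            a, b = self.data[f.name], other.data[f.name]
            obs = ~self.mask[f.name].to_numpy()
            if f.kind == "numeric":
                if not np.allclose(
                    a.to_numpy(float)[obs], b.to_numpy(float)[obs], equal_nan=False
                ):
                    return False
            elif not (a[obs] == b[obs]).all():
                return False
        return True


def _validate_cell(feature: Feature, raw: str, row: int):
    if feature.kind == "numeric":
        try:
            return float(raw)
        except ValueError:
            raise SchemaError(
                f"row {row}: non-numeric value {raw!r} for numeric "
                f"feature {feature.name!r}"
            ) from None
    if raw not in feature.levels:
        raise SchemaError(
            f"row {row}: undeclared level {raw!r} for categorical "
            f"feature {feature.name!r} (declared: {list(feature.levels)})"
        )
    return raw


def load_cohort(path, schema: FeatureSchema, sep: str | None = None) -> CohortTable:
    """Read a delimited cohort file and validate it against ``schema``.

    The file must carry a header with every schema feature name plus the
    ``mafld_status`` label column.  Empty cells and the literal ``NA`` are
    read as missing; missing is only legal where the cell can be masked
    (any feature cell — downstream components decide what missingness they
    tolerate), never on the label.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    expected = set(schema.feature_names) | {LABEL_COLUMN}
    unknown = set(raw.columns) - expected
    if unknown:
        raise SchemaError(f"unknown column(s): {sorted(unknown)}")
    missing_cols = expected - set(raw.columns)
    if missing_cols:
        raise SchemaError(f"missing column(s): {sorted(missing_cols)}")

    n = len(raw)
    label_to_idx = {lab: i for i, lab in enumerate(LABELS)}
    y = np.empty(n, dtype=int)
    for i, val in enumerate(raw[LABEL_COLUMN]):
        if val in _MISSING_TOKENS:
            raise SchemaError(f"row {i}: missing label")
        if val not in label_to_idx:
            raise SchemaError(
                f"row {i}: unknown label {val!r} (expected one of {list(LABELS)})"
            )
        y[i] = label_to_idx[val]

    data = {}
    mask = {}
    for f in schema.features:
        col = raw[f.name]
        miss = col.isin(_MISSING_TOKENS).to_numpy()
        vals: list = []
        for i, (cell, m) in enumerate(zip(col, miss)):
            if m:
                vals.append(np.nan)
            else:
                vals.append(_validate_cell(f, cell, i))
        data[f.name] = pd.Series(
            vals, dtype=float if f.kind == "numeric" else object
        )
        mask[f.name] = pd.Series(miss)

    table = CohortTable(
        schema,
        pd.DataFrame(data, columns=list(schema.feature_names)),
        pd.DataFrame(mask, columns=list(schema.feature_names)),
        y,
    )
    frac = float(table.mask.to_numpy().mean()) if n else 0.0
    import logging

    logging.getLogger(__name__).info(
        "loaded cohort: %d rows, %d features, %.1f%% cells missing",
        n,
        len(schema.feature_names),
        100.0 * frac,
    )
    return table


def write_cohort(table: CohortTable, path, sep: str | None = None) -> None:
    """Write a cohort table; masked cells become empty fields."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    cols = {}
    for f in table.schema.features:
        col = table.data[f.name]
        if f.kind == "numeric":
            col = col.map(lambda v: "" if pd.isna(v) else repr(float(v)))
        else:
            col = col.map(lambda v: "" if (not isinstance(v, str)) else v)
        col[table.mask[f.name].to_numpy()] = ""
        cols[f.name] = col
    cols[LABEL_COLUMN] = pd.Series([LABELS[c] for c in table.y])
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# trial splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialSplit:
    """A reproducible train/test partition of row indices."""

    seed: int
    train: np.ndarray
    test: np.ndarray

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": int(self.seed),
                    "train": [int(i) for i in self.train],
                    "test": [int(i) for i in self.test],
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "TrialSplit":
        d = json.loads(Path(path).read_text())
        return cls(d["seed"], np.array(d["train"]), np.array(d["test"]))


def trial_split(
    n: int,
    seed: int,
    f: float = 0.8,
    y: np.ndarray | None = None,
    stratify: bool = True,
) -> TrialSplit:
    """Split ``n`` rows into round(f*n) train rows and the rest for test.

    When labels are supplied the split is stratified by class (proportional
    allocation with largest-remainder rounding), so that a 3.5%-prevalence
    class does not occasionally vanish from a 20% test set.  Deterministic
    under a fixed ``(n, seed, f)``.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"train fraction must be in (0, 1), got {f}")
    if n < 2:
        raise ValueError(f"need at least 2 rows to split, got {n}")
    n_train = int(round(f * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"split f={f} of n={n} leaves an empty train or test set")

    rng = np.random.default_rng(seed)
    if y is None or not stratify:
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
    else:
        y = np.asarray(y)
        classes = np.unique(y)
        ideal = {c: f * np.sum(y == c) for c in classes}
        base = {c: int(np.floor(v)) for c, v in ideal.items()}
        leftover = n_train - sum(base.values())
        if leftover:
            by_frac = sorted(
                classes, key=lambda c: (-(ideal[c] - base[c]), c)
            )
            for c in by_frac[:leftover]:
                base[c] += 1
        train_parts, test_parts = [], []
        for c in classes:
            rows = np.flatnonzero(y == c)
            rows = rng.permutation(rows)
            k = min(base[c], len(rows))
            train_parts.append(rows[:k])
            test_parts.append(rows[k:])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts))
        if len(test) == 0:  # pragma: no cover - guarded by n_train bound
            raise ValueError("stratified split left no test rows")
        small = [int(c) for c in classes if np.sum(y == c) < 2]
        if small:
            warnings.warn(
                f"class(es) {small} have < 2 rows; stratification is degenerate"
            )
    return TrialSplit(seed=seed, train=np.asarray(train), test=np.asarray(test))
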