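"""Schema-driven cohort loading, validation and preprocessing.

The pipeline mirrors common clinical-ML practice: schema-based type
conversion at load time, then a separately *fitted* preprocessing step
(label encoding of categoricals, z-scoring of numerics) whose statistics
come from training rows only, so that held-out splits never leak into the
transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import FeatureSchema, SchemaError

log = logging.getLogger(__name__)


class CohortError(ValueError):
    """Raised for malformed cohort files or invalid preprocessing requests."""


@dataclass(frozen=True)
class CohortTable:
    """An n-patients x p-features matrix with a binary outcome.

    ``values`` holds encoded feature values in schema order: numeric and
    binary columns as floats, categorical columns as float-valued integer
    codes once a preprocessor has been applied (raw labels are kept in a
    side dictionary before that).
    """

    values: np.ndarray  # (n, p) float
    outcome: np.ndarray  # (n,) int {0,1}
    schema: FeatureSchema
    raw_categories: dict[str, np.ndarray] | None = None  # pre-encoding labels

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        y = np.asarray(self.outcome)
        if v.ndim != 2:
            raise CohortError("values must be 2-D")
        if v.shape[0] != y.shape[0]:
            raise CohortError("values and outcome row counts differ")
        if v.shape[1] != self.schema.n_features:
            raise CohortError(
                f"values has {v.shape[1]} columns, schema declares "
                f"{self.schema.n_features}"
            )
        if not np.isin(y, [0, 1]).all():
            raise CohortError("outcome must contain only 0 and 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "outcome", y.astype(int))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def prevalence(self) -> float:
        return float(self.outcome.mean())

    def require_both_classes(self) -> None:
        if self.outcome.min() == self.outcome.max():
            raise CohortError("outcome contains a single class")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.schema.index(name)]

    def subset_rows(self, idx: np.ndarray) -> "CohortTable":
        raw = None
        if self.raw_categories is not None:
            raw = {k: v[idx] for k, v in self.raw_categories.items()}
        return replace(
            self, values=self.values[idx], outcome=self.outcome[idx], raw_categories=raw
        )


@dataclass(frozen=True)
class PreprocessorState:
    """Frozen preprocessing statistics fitted on a training split.

    Numeric columns are z-scored with a sample (n-1 denominator) standard
    deviation; categorical columns are label-encoded with consecutive
    integers following schema category order.
    """

    means: dict[str, float]
    sds: dict[str, float]
    label_maps: dict[str, dict[str, int]]
    schema: FeatureSchema


def load_cohort(path: str | Path, schema: FeatureSchema) -> CohortTable:
    """Read a cohort CSV, coercing every column to its declared kind.

    Values are validated but *not* standardized; that is the job of
    :func:`fit_preprocessor` / :func:`apply_preprocessor` so that scaling
    statistics can be restricted to training rows.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [n for n in schema.names + [schema.outcome_name] if n not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing column(s): {missing}")

    n = len(df)
    values = np.empty((n, schema.n_features), dtype=float)
    raw_categories: dict[str, np.ndarray] = {}
    for j, spec in enumerate(schema.specs):
        col = df[spec.name]
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise CohortError(
                f"missing value at row {row}, column {spec.name!r} "
                "(imputation is not enabled)"
            )
        if spec.kind in ("numeric", "binary"):
            try:
                x = col.astype(float).to_numpy()
            except ValueError:
                bad = col[pd.to_numeric(col, errors="coerce").isna()]
                row = int(bad.index[0])
                raise CohortError(
                    f"cannot parse {col[row]!r} as a number at row {row}, "
                    f"column {spec.name!r}"
                ) from None
            if spec.kind == "binary" and not np.isin(x, [0.0, 1.0]).all():
                bad_rows = np.flatnonzero(~np.isin(x, [0.0, 1.0]))
                raise CohortError(
                    f"binary column {spec.name!r} holds non-0/1 value at row "
                    f"{int(bad_rows[0])}"
                )
            values[:, j] = x
        else:
            labels = col.to_numpy(dtype=object)
            admissible = set(spec.categories)
            unknown = sorted({str(v) for v in labels} - admissible)
            if unknown:
                raise SchemaError(
                    f"column {spec.name!r}: unknown label(s) {unknown}; "
                    f"admissible: {list(spec.categories)}"
                )
            raw_categories[spec.name] = labels.astype(str)
            # provisional code so the matrix is complete; re-encoded by the
            # preprocessor with the fitted (identical) map
            lut = {c: k for k, c in enumerate(spec.categories)}
            values[:, j] = [lut[str(v)] for v in labels]

    try:
        y = df[schema.outcome_name].astype(float).to_numpy()
    except ValueError:
        raise CohortError(f"outcome column {schema.outcome_name!r} is not numeric")
    if not np.isin(y, [0.0, 1.0]).all():
        raise CohortError("outcome column must contain only 0 and 1")

    kinds = schema.kinds()
    log.info(
        "loaded cohort %s: n=%d, p=%d, prevalence=%.3f "
        "(numeric=%d, binary=%d, categorical=%d)",
        path.name, n, schema.n_features, float(y.mean()),
        kinds.count("numeric"), kinds.count("binary"), kinds.count("categorical"),
    )
    return CohortTable(
        values=values, outcome=y.astype(int), schema=schema,
        raw_categories=raw_categories or None,
    )


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV so that load -> write -> load round-trips."""
    cols: dict[str, object] = {}
    for j, spec in enumerate(table.schema.specs):
        if spec.kind == "categorical":
            if table.raw_categories is not None and spec.name in table.raw_categories:
                cols[spec.name] = table.raw_categories[spec.name]
            else:
                codes = table.values[:, j].astype(int)
                cols[spec.name] = [spec.categories[c] for c in codes]
        else:
            cols[spec.name] = table.values[:, j]
    cols[table.schema.outcome_name] = table.outcome
    pd.DataFrame(cols).to_csv(path, index=False)


def fit_preprocessor(train: CohortTable) -> PreprocessorState:
    """Fit standardization/encoding statistics on training rows only.

    Numeric standard deviations use the sample (n-1) denominator, matching
    the pooled-covariance convention of the Hotelling machinery downstream.
    Constant numeric columns are rejected: they carry no information and
    would produce a zero divisor.
    """
    if train.n < 2:
        raise CohortError("need at least 2 rows to fit a preprocessor")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    label_maps: dict[str, dict[str, int]] = {}
    for j, spec in enumerate(train.schema.specs):
        if spec.kind == "numeric":
            x = train.values[:, j]
            sd = float(np.std(x, ddof=1))
            if sd == 0.0:
                raise CohortError(f"numeric column {spec.name!r} is constant")
            means[spec.name] = float(np.mean(x))
            sds[spec.name] = sd
        elif spec.kind == "categorical":
            label_maps[spec.name] = {c: k for k, c in enumerate(spec.categories)}
    return PreprocessorState(
        means=means, sds=sds, label_maps=label_maps, schema=train.schema
    )


def apply_preprocessor(state: PreprocessorState, table: CohortTable) -> CohortTable:
    """Z-score numeric columns and integer-encode categoricals using a
    previously fitted state.  Binary columns pass through as 0/1."""
    if state.schema.names != table.schema.names:
        raise SchemaError("preprocessor state fitted on a different schema")
    values = table.values.copy()
    for j, spec in enumerate(table.schema.specs):
        if spec.kind == "numeric":
            values[:, j] = (values[:, j] - state.means[spec.name]) / state.sds[spec.name]
        elif spec.kind == "categorical":
            if table.raw_categories is not None and spec.name in table.raw_categories:
                lut = state.label_maps[spec.name]
                values[:, j] = [lut[v] for v in table.raw_categories[spec.name]]
            # else: already integer codes under the schema-order map
    return CohortTable(
        values=values, outcome=table.outcome, schema=table.schema, raw_categories=None
    )
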