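import numpy as np
import pytest

from t2select import (
    CohortTable,
    FeatureSchema,
    FeatureSpec,
    GeneratorConfig,
    SelectorHyperparams,
    generate,
)


@pytest.fixture
def small_schema() -> FeatureSchema:
    return FeatureSchema(
        specs=(
            FeatureSpec("age", "numeric", group="clinical", in_domain_knowledge=True),
            FeatureSpec("qrs", "numeric", group="ecg", in_domain_knowledge=True),
            FeatureSpec("diabetes", "binary", group="clinical"),
            FeatureSpec(
                "valve_type", "categorical", group="procedural",
                categories=("balloon", "self_expanding"),
            ),
        ),
        outcome_name="event",
    )


@pytest.fixture
def small_cohort(small_schema) -> CohortTable:
    rng = np.random.default_rng(7)
    n = 40
    values = np.column_stack(
        [
            rng.normal(80, 6, n),
            rng.normal(100, 20, n),
            rng.integers(0, 2, n).astype(float),
            rng.integers(0, 2, n).astype(float),
        ]
    )
    outcome = np.r_[np.ones(12, dtype=int), np.zeros(n - 12, dtype=int)]
    raw = {
        "valve_type": np.where(values[:, 3] == 0, "balloon", "self_expanding")
    }
    return CohortTable(
        values=values, outcome=outcome, schema=small_schema, raw_categories=raw
    )


@pytest.fixture
def tiny_hp() -> SelectorHyperparams:
    """Small, fast configuration for unit tests of the selector."""
    return SelectorHyperparams(
        d_token=8, n_heads=2, epochs=3, seed=0, dtype="float64"
    )


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """A 30-patient mixed-type synthetic cohort."""
    cfg = GeneratorConfig(
        n=30, event_rate=0.4, n_numeric=4, n_binary=2, n_categorical=1,
        block_size=2, informative=((0, 1.2),), seed=11,
    )
    table, _ = generate(cfg)
    return table
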