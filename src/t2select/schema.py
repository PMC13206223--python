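"""Feature schemas for clinical tabular cohorts.

A schema declares, for every candidate feature, its statistical kind
(numeric / binary / categorical), the clinical group it belongs to
(clinical, echo, ecg, ct, procedural) and whether it is part of the
clinically established ("domain knowledge") set.  The order of features in
the schema is the canonical feature index used by every downstream module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

KINDS = ("numeric", "binary", "categorical")
GROUPS = ("clinical", "echo", "ecg", "ct", "procedural")


class SchemaError(ValueError):
    """Raised when a schema document or a table violates its schema."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of a single candidate feature.

    Parameters
    ----------
    name
        Unique column name.
    kind
        One of ``numeric``, ``binary``, ``categorical``.
    group
        Clinical group the variable belongs to.
    categories
        Ordered admissible labels; required exactly when ``kind`` is
        ``categorical``.  Their order fixes the integer encoding 0..K-1.
    in_domain_knowledge
        True if the feature is part of the clinically established set.
    """

    name: str
    kind: str
    group: str = "clinical"
    categories: tuple[str, ...] = ()
    in_domain_knowledge: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if self.group not in GROUPS:
            raise SchemaError(f"feature {self.name!r}: unknown group {self.group!r}")
        if self.kind == "categorical":
            if not self.categories:
                raise SchemaError(
                    f"categorical feature {self.name!r} declares no categories"
                )
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"feature {self.name!r}: duplicate categories")
        elif self.categories:
            raise SchemaError(
                f"feature {self.name!r} of kind {self.kind!r} must not declare categories"
            )


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` plus the outcome column name."""

    specs: tuple[FeatureSpec, ...]
    outcome_name: str

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate feature names: {dup}")
        if self.outcome_name in names:
            raise SchemaError(
                f"outcome {self.outcome_name!r} collides with a feature name"
            )

    # -- convenience views -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def n_features(self) -> int:
        return len(self.specs)

    def spec(self, name: str) -> FeatureSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def domain_knowledge(self) -> list[str]:
        """Names of the clinically established feature subset."""
        return [s.name for s in self.specs if s.in_domain_knowledge]

    def kinds(self) -> list[str]:
        return [s.kind for s in self.specs]

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "features": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "group": s.group,
                    **({"categories": list(s.categories)} if s.categories else {}),
                    "in_domain_knowledge": s.in_domain_knowledge,
                }
                for s in self.specs
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FeatureSchema":
        try:
            feats = doc["features"]
            outcome = doc["outcome_name"]
        except KeyError as e:  # pragma: no cover - defensive
            raise SchemaError(f"schema document missing key {e}") from None
        specs = tuple(
            FeatureSpec(
                name=f["name"],
                kind=f["kind"],
                group=f.get("group", "clinical"),
                categories=tuple(f.get("categories", ()) or ()),
                in_domain_knowledge=bool(f.get("in_domain_knowledge", False)),
            )
            for f in feats
        )
        return cls(specs=specs, outcome_name=outcome)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(doc, indent=2))
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureSchema":
        path = Path(path)
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(doc)


def make_schema(
    specs: Sequence[FeatureSpec], outcome_name: str = "outcome"
) -> FeatureSchema:
    return FeatureSchema(specs=tuple(specs), outcome_name=outcome_name)
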