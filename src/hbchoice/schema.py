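"""Attribute/level schema and effect coding for paired-choice conjoint designs.

A choice-based conjoint (discrete choice) exercise describes hypothetical
products by a small set of categorical attributes, each taking one of a few
levels.  This module holds the schema types, the default six-attribute
treatment schema (long-term efficacy, 5-year bone-thinning risk, 5-year
kidney-damage risk, patients treated worldwide, years on the US market, and
monthly out-of-pocket cost), and the sum-to-zero ("effect") coding that maps
a product to the numeric covariate vector used by the choice likelihood.

Under effect coding an attribute with ``L`` levels contributes ``L - 1``
coefficients; the part-worth of the omitted last level is minus the sum of
the others, so level part-worths always sum to zero within an attribute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "AttributeSpec",
    "AttributeSchema",
    "Product",
    "build_default_schema",
    "load_schema",
    "save_schema",
    "encode_product",
    "level_partworths",
]


@dataclass(frozen=True)
class AttributeSpec:
    """One product attribute: a name, a description, and 3-4 ordered levels."""

    name: str
    description: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if not (3 <= len(self.levels) <= 4):
            raise ValueError(
                f"attribute {self.name!r} must have 3 or 4 levels, "
                f"got {len(self.levels)}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"attribute {self.name!r} has duplicate level labels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of attributes defining the product space."""

    attributes: tuple[AttributeSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")

    def __iter__(self):
        return iter(self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    @property
    def n_coefficients(self) -> int:
        """Dimension p of the effect-coded covariate space: sum of (L - 1)."""
        return sum(a.n_levels - 1 for a in self.attributes)

    @property
    def coef_names(self) -> list[str]:
        """One name per coded coefficient: ``attr[level]`` for all but the last level."""
        out = []
        for a in self.attributes:
            out.extend(f"{a.name}[{lvl}]" for lvl in a.levels[:-1])
        return out

    @property
    def n_products(self) -> int:
        return int(np.prod([a.n_levels for a in self.attributes]))

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "attributes": [
                {"name": a.name, "description": a.description, "levels": list(a.levels)}
                for a in self.attributes
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttributeSchema":
        return cls(
            tuple(
                AttributeSpec(a["name"], a.get("description", ""), tuple(a["levels"]))
                for a in d["attributes"]
            )
        )


@dataclass(frozen=True)
class Product:
    """A product configuration: one 0-based level index per attribute, in schema order."""

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(int(i) for i in self.levels))

    def validate(self, schema: AttributeSchema) -> None:
        if len(self.levels) != len(schema):
            raise ValueError(
                f"product has {len(self.levels)} attributes, schema has {len(schema)}"
            )
        for attr, idx in zip(schema, self.levels):
            if not 0 <= idx < attr.n_levels:
                raise ValueError(
                    f"invalid level index {idx} for attribute {attr.name!r} "
                    f"({attr.n_levels} levels)"
                )

    def labels(self, schema: AttributeSchema) -> dict[str, str]:
        self.validate(schema)
        return {a.name: a.levels[i] for a, i in zip(schema, self.levels)}

    @classmethod
    def from_labels(cls, schema: AttributeSchema, labels: dict[str, str]) -> "Product":
        idx = []
        for a in schema:
            lbl = labels[a.name]
            if lbl not in a.levels:
                raise ValueError(f"unknown level {lbl!r} for attribute {a.name!r}")
            idx.append(a.levels.index(lbl))
        return cls(tuple(idx))


def build_default_schema() -> AttributeSchema:
    """Load the packaged six-attribute oral-antiviral schema.

    Efficacy, bone risk, kidney risk, patients worldwide and years on market
    have three levels each; monthly cost has four ($0/$50/$100/$150), giving
    an effect-coded dimension of p = 5*2 + 3 = 13.
    """
    text = resources.files("hbchoice.data").joinpath("default_schema.yaml").read_text()
    return AttributeSchema.from_dict(yaml.safe_load(text))


def load_schema(path: str | Path) -> AttributeSchema:
    """Read a schema from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return AttributeSchema.from_dict(json.loads(text))
    return AttributeSchema.from_dict(yaml.safe_load(text))


def save_schema(schema: AttributeSchema, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(schema.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(schema.to_dict(), sort_keys=False))


def _effect_code(level: int, n_levels: int) -> np.ndarray:
    """Sum-to-zero code of one level: unit vector for levels 0..L-2, all -1 for the last."""
    v = np.zeros(n_levels - 1)
    if level == n_levels - 1:
        v[:] = -1.0
    else:
        v[level] = 1.0
    return v


def encode_product(schema: AttributeSchema, product: Product) -> np.ndarray:
    """Effect-code a product into the length-p covariate vector of the choice model."""
    product.validate(schema)
    return np.concatenate(
        [_effect_code(i, a.n_levels) for a, i in zip(schema, product.levels)]
    )


def encode_products(schema: AttributeSchema, products: Iterable[Product]) -> np.ndarray:
    """Stack coded vectors for several products into a (K, p) matrix."""
    return np.array([encode_product(schema, pr) for pr in products])


def level_partworths(schema: AttributeSchema, beta: Sequence[float]) -> list[np.ndarray]:
    """Reconstruct full level part-worths from an effect-coded vector.

    Returns one array of length ``n_levels`` per attribute; the last level's
    part-worth is minus the sum of the coded ones, so each array sums to zero.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (schema.n_coefficients,):
        raise ValueError(
            f"beta has shape {beta.shape}, expected ({schema.n_coefficients},)"
        )
    out = []
    pos = 0
    for a in schema:
        coded = beta[pos : pos + a.n_levels - 1]
        out.append(np.concatenate([coded, [-coded.sum()]]))
        pos += a.n_levels - 1
    return out
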