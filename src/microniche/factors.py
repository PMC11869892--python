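"""Habitat-factor definitions and categorical binning.

Habitat-selection indices operate on ordered categories, not raw
measurements: each continuous factor (altitude, temperature, ...) is cut
into a small number of ordered levels, and each categorical factor
(landscape habitat, vegetation type, ...) carries its levels directly.
This module holds the declarative description of those factors and the
binning rule, including the packaged default scheme of 13 factors with
three levels each used throughout the microhabitat survey pipeline.

Boundary convention: continuous bins are lower-closed, ``[a, b)``, with the
final bin open-ended, so a value equal to a cut point falls in the upper
bin (altitude 200 m with edges (200, 400) is level 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import yaml

__all__ = [
    "FactorDefinition",
    "FactorScheme",
    "bin_value",
    "default_scheme",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """A value or structure violates a domain contract."""


class FormatError(ValueError):
    """An input file does not match the expected tabular/serialized format."""


@dataclass(frozen=True)
class FactorDefinition:
    """One habitat factor and its ordered categories.

    Parameters
    ----------
    name:
        Factor identifier, e.g. ``"altitude"``.
    kind:
        ``"continuous_binned"`` for measured quantities cut at ``bin_edges``,
        ``"categorical"`` for factors recorded directly as labels.
    bin_edges:
        Strictly increasing cut points (same units as the raw values);
        empty for categorical factors. ``len(bin_edges) == n_categories - 1``.
    categories:
        Ordered category labels; the 1-based position is the category index.
    """

    name: str
    kind: str
    bin_edges: tuple[float, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("continuous_binned", "categorical"):
            raise ValidationError(f"unknown factor kind {self.kind!r}")
        if len(self.categories) < 2:
            raise ValidationError(
                f"factor {self.name!r} needs >= 2 categories, got {len(self.categories)}"
            )
        if self.kind == "continuous_binned":
            if len(self.bin_edges) != len(self.categories) - 1:
                raise ValidationError(
                    f"factor {self.name!r}: {len(self.categories)} categories require "
                    f"{len(self.categories) - 1} bin edges, got {len(self.bin_edges)}"
                )
            if any(b <= a for a, b in zip(self.bin_edges, self.bin_edges[1:])):
                raise ValidationError(
                    f"factor {self.name!r}: bin edges must be strictly increasing"
                )
        elif self.bin_edges:
            raise ValidationError(
                f"categorical factor {self.name!r} must not define bin edges"
            )

    @property
    def n_categories(self) -> int:
        return len(self.categories)


def bin_value(factor: FactorDefinition, raw: float | str) -> int:
    """Map a raw value to its 1-based category index.

    Continuous factors use lower-closed intervals ``[e_i, e_{i+1})`` with an
    open-ended final bin; categorical factors look the label up. Raises
    :class:`ValidationError` for non-finite numerics or unknown labels.
    """
    if factor.kind == "categorical":
        try:
            return factor.categories.index(str(raw)) + 1
        except ValueError:
            raise ValidationError(
                f"unknown label {raw!r} for categorical factor {factor.name!r}; "
                f"known: {list(factor.categories)}"
            ) from None
    try:
        x = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"non-numeric value {raw!r} for continuous factor {factor.name!r}"
        ) from None
    if not math.isfinite(x):
        raise ValidationError(f"non-finite value for factor {factor.name!r}")
    idx = 1
    for edge in factor.bin_edges:
        if x >= edge:
            idx += 1
        else:
            break
    return idx


@dataclass(frozen=True)
class FactorScheme:
    """Ordered collection of :class:`FactorDefinition` with unique names."""

    factors: tuple[FactorDefinition, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValidationError("factor names must be unique")

    def __iter__(self) -> Iterator[FactorDefinition]:
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    def __getitem__(self, name: str) -> FactorDefinition:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.factors)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def to_dict(self) -> list[dict]:
        return [
            {
                "name": f.name,
                "kind": f.kind,
                "bin_edges": list(f.bin_edges),
                "categories": list(f.categories),
            }
            for f in self.factors
        ]

    @classmethod
    def from_dict(cls, entries: Sequence[Mapping]) -> "FactorScheme":
        factors = []
        for e in entries:
            try:
                factors.append(
                    FactorDefinition(
                        name=str(e["name"]),
                        kind=str(e["kind"]),
                        bin_edges=tuple(float(x) for x in e.get("bin_edges", ())),
                        categories=tuple(str(c) for c in e["categories"]),
                    )
                )
            except KeyError as exc:
                raise FormatError(f"factor entry missing key {exc}") from None
        return cls(tuple(factors))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"factors": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "FactorScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, Mapping) or "factors" not in doc:
            raise FormatError(f"{path}: expected a mapping with a 'factors' list")
        return cls.from_dict(doc["factors"])


def _cont(name: str, e1: float, e2: float, labels: tuple[str, str, str]) -> FactorDefinition:
    return FactorDefinition(name, "continuous_binned", (e1, e2), labels)


#: The 13 habitat factors of the pitviper microhabitat survey, three ordered
#: levels each. Continuous cut points follow the survey's published legend;
#: categorical factors carry their field levels directly.
_DEFAULT_FACTORS: tuple[FactorDefinition, ...] = (
    _cont("altitude", 200.0, 400.0, ("<200m", "200-400m", ">400m")),
    FactorDefinition(
        "landscape_habitat", "categorical", (), ("stream", "forest", "agricultural")
    ),
    FactorDefinition("vegetation_type", "categorical", (), ("grass", "shrub", "tree")),
    _cont("temperature", 20.0, 30.0, ("<20C", "20-30C", ">30C")),
    _cont("humidity", 40.0, 70.0, ("<40%", "40-70%", ">70%")),
    _cont("vegetation_coverage", 20.0, 70.0, ("<20%", "20-70%", ">70%")),
    _cont("vegetation_height", 2.0, 5.0, ("0-2m", "2-5m", ">5m")),
    _cont("slope", 15.0, 40.0, ("0-15deg", "15-40deg", ">40deg")),
    FactorDefinition(
        "slope_position", "categorical", (), ("down_slope", "mid_slope", "up_slope")
    ),
    _cont("dist_roads", 10.0, 30.0, ("0-10m", "10-30m", ">30m")),
    _cont("dist_water", 5.0, 20.0, ("<5m", "5-20m", ">20m")),
    _cont("dist_residential", 100.0, 500.0, ("<100m", "100-500m", ">500m")),
    FactorDefinition(
        "aspect", "categorical", (), ("sunny", "half_shaded", "shaded")
    ),
)

#: Factor excluded from niche breadth/overlap aggregation downstream: all
#: groups show at-most-weak selection on aspect, so it carries no signal.
EXCLUDED_DOWNSTREAM: tuple[str, ...] = ("aspect",)


def default_scheme() -> FactorScheme:
    """The packaged default 13-factor, 3-level scheme."""
    return FactorScheme(_DEFAULT_FACTORS)
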