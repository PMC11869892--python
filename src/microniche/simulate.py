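"""Synthetic survey generator with known group-level selection structure.

Emulates a use-versus-availability quadrat survey: four season x sex
groups of presence points (default sizes BM=43, BF=19, NBM=15, NBF=15,
the sizes of the motivating pitviper survey) plus 50 pseudo-absence
points per season. Each presence draws its category on each factor from
the element-wise product of the landscape availability vector and the
group's preference weights (renormalized), so preference strength is a
known, recoverable ground truth. Pseudo-absence points draw from
availability alone and are placed by rejection sampling at least an
exclusion radius (default 50 m) from every same-season presence and
outside rectangular unsuitable zones (the highway / open-water / cliff
analogue).

Raw continuous values are synthesized uniformly *within* the drawn
category's interval, so downstream binning recovers the drawn category
exactly; categorical factors store the drawn label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .factors import FactorDefinition, FactorScheme, ValidationError, default_scheme
from .records import Dataset, GROUPS, QuadratRecord

__all__ = [
    "GroupPreferenceProfile",
    "LandscapeConfig",
    "Rect",
    "generate_presences",
    "generate_pseudo_absences",
    "generate_survey",
    "default_profiles",
    "default_landscape",
    "uniform_profiles",
    "SamplingError",
    "ConfigurationError",
]

_DEFAULT_SIZES = {"BM": 43, "BF": 19, "NBM": 15, "NBF": 15}
_MAX_ATTEMPTS_PER_POINT = 10_000
#: Synthetic span of each continuous factor's open-ended bins, per factor;
#: only used to realize a raw value inside a drawn category.
_OPEN_BIN_SPAN = 1.0


class SamplingError(RuntimeError):
    """Rejection sampling could not satisfy the placement constraints."""


class ConfigurationError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in planar metres: (xmin, ymin, xmax, ymax)."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise ConfigurationError("rectangle must have positive extent")

    def contains(self, x: float, y: float) -> bool:
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)


@dataclass(frozen=True)
class GroupPreferenceProfile:
    """Ground-truth category preferences of one group.

    ``weights`` maps factor name -> positive category weights (normalized
    on construction). A uniform vector encodes no preference; mass
    concentrated on one category encodes selection for it.
    """

    group: str
    weights: Mapping[str, np.ndarray]
    n_individuals: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be positive")
        norm = {}
        for name, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if np.any(w < 0) or w.sum() <= 0:
                raise ConfigurationError(
                    f"profile {self.group}: weights for {name!r} must be "
                    "nonnegative with positive sum"
                )
            norm[name] = w / w.sum()
        object.__setattr__(self, "weights", norm)

    @property
    def season(self) -> str:
        return "breeding" if self.group in ("BM", "BF") else "non_breeding"

    @property
    def sex(self) -> str:
        return self.group[-1]


@dataclass(frozen=True)
class LandscapeConfig:
    """Background habitat availability over a rectangular survey extent.

    ``availability`` maps factor name -> background category probabilities,
    optionally per season (``{"breeding": vec, "non_breeding": vec}``) to
    emulate a seasonal availability shift; a bare vector applies to both.
    """

    extent: Rect = Rect(0.0, 0.0, 2000.0, 2000.0)
    availability: Mapping[str, object] = field(default_factory=dict)
    unsuitable_zones: tuple[Rect, ...] = ()
    scheme: FactorScheme = field(default_factory=default_scheme)

    def __post_init__(self) -> None:
        for z in self.unsuitable_zones:
            if not (
                self.extent.xmin <= z.xmin
                and z.xmax <= self.extent.xmax
                and self.extent.ymin <= z.ymin
                and z.ymax <= self.extent.ymax
            ):
                raise ConfigurationError("unsuitable zone lies outside the extent")

    def availability_vector(self, factor: str, season: str) -> np.ndarray:
        n = self.scheme[factor].n_categories
        spec = self.availability.get(factor)
        if spec is None:
            vec = np.full(n, 1.0 / n)
        elif isinstance(spec, Mapping):
            vec = np.asarray(spec[season], dtype=float)
        else:
            vec = np.asarray(spec, dtype=float)
        if vec.size != n or np.any(vec < 0) or vec.sum() <= 0:
            raise ConfigurationError(
                f"availability for {factor!r} must be {n} nonnegative values"
            )
        return vec / vec.sum()


def _raw_value_for_category(
    fdef: FactorDefinition, cat: int, rng: np.random.Generator
) -> float | str:
    """A raw value that bins back into the drawn 1-based category."""
    if fdef.kind == "categorical":
        return fdef.categories[cat - 1]
    edges = fdef.bin_edges
    span = max(_OPEN_BIN_SPAN, 0.5 * (edges[-1] - edges[0]))
    lo = edges[cat - 2] if cat >= 2 else edges[0] - span
    hi = edges[cat - 1] if cat <= len(edges) else edges[-1] + span
    return float(rng.uniform(lo, hi))


def _sample_location(
    landscape: LandscapeConfig,
    rng: np.random.Generator,
    exclusion: tuple[np.ndarray, float] | None = None,
) -> tuple[float, float]:
    ext = landscape.extent
    for _ in range(_MAX_ATTEMPTS_PER_POINT):
        x = float(rng.uniform(ext.xmin, ext.xmax))
        y = float(rng.uniform(ext.ymin, ext.ymax))
        if any(z.contains(x, y) for z in landscape.unsuitable_zones):
            continue
        if exclusion is not None:
            pts, radius = exclusion
            if pts.size and np.min(np.hypot(pts[:, 0] - x, pts[:, 1] - y)) < radius:
                continue
        return x, y
    raise SamplingError(
        f"could not place a point after {_MAX_ATTEMPTS_PER_POINT} attempts"
    )


def generate_presences(
    landscape: LandscapeConfig,
    profiles: Sequence[GroupPreferenceProfile],
    seed: int = 0,
) -> tuple[Dataset, dict[str, GroupPreferenceProfile]]:
    """Presence records for each profiled group, with ground truth attached.

    Each individual's category on each factor is drawn from
    availability * preference (element-wise, renormalized); coordinates are
    uniform over the extent minus unsuitable zones. Deterministic under a
    fixed seed. Returns the dataset and the profile map (the ground truth).
    """
    rng = np.random.default_rng(seed)
    scheme = landscape.scheme
    records: list[QuadratRecord] = []
    truth: dict[str, GroupPreferenceProfile] = {}
    for prof in profiles:
        truth[prof.group] = prof
        season = prof.season
        probs: dict[str, np.ndarray] = {}
        for fdef in scheme:
            avail = landscape.availability_vector(fdef.name, season)
            pref = prof.weights.get(fdef.name, np.full(fdef.n_categories, 1.0))
            v = avail * np.asarray(pref, dtype=float)
            if v.sum() <= 0:
                raise ConfigurationError(
                    f"group {prof.group}, factor {fdef.name!r}: availability and "
                    "preference have disjoint support"
                )
            probs[fdef.name] = v / v.sum()
        for j in range(prof.n_individuals):
            x, y = _sample_location(landscape, rng)
            values: dict[str, float | str] = {}
            for fdef in scheme:
                cat = int(rng.choice(fdef.n_categories, p=probs[fdef.name])) + 1
                values[fdef.name] = _raw_value_for_category(fdef, cat, rng)
            records.append(
                QuadratRecord(
                    point_id=f"{prof.group}_{j + 1:03d}",
                    point_class="presence",
                    season=season,
                    sex=prof.sex,
                    x=x,
                    y=y,
                    values=values,
                )
            )
    return Dataset(records, scheme), truth


def generate_pseudo_absences(
    landscape: LandscapeConfig,
    presences: Dataset,
    n: int = 50,
    exclusion_radius_m: float = 50.0,
    seed: int = 0,
    seasons: Sequence[str] = ("breeding", "non_breeding"),
) -> Dataset:
    """Background (pseudo-absence) records, ``n`` per season.

    Every point is placed by rejection sampling at least
    ``exclusion_radius_m`` from each same-season presence and outside all
    unsuitable zones; factor categories are drawn from availability alone.
    The distance and zone constraints are re-verified exhaustively on the
    emitted points. Raises :class:`SamplingError` when the constraints
    cannot be met within the attempt budget.
    """
    rng = np.random.default_rng(seed)
    scheme = landscape.scheme
    records: list[QuadratRecord] = []
    for season in seasons:
        pres = presences.presences(season=season)
        pts = np.array([[r.x, r.y] for r in pres]) if len(pres) else np.empty((0, 2))
        placed = 0
        for j in range(n):
            try:
                x, y = _sample_location(landscape, rng, exclusion=(pts, exclusion_radius_m))
            except SamplingError:
                raise SamplingError(
                    f"season {season}: placed {placed} of {n} pseudo-absence "
                    f"points before exhausting the attempt budget"
                ) from None
            placed += 1
            values: dict[str, float | str] = {}
            for fdef in scheme:
                avail = landscape.availability_vector(fdef.name, season)
                cat = int(rng.choice(fdef.n_categories, p=avail)) + 1
                values[fdef.name] = _raw_value_for_category(fdef, cat, rng)
            records.append(
                QuadratRecord(
                    point_id=f"PA_{season}_{j + 1:03d}",
                    point_class="pseudo_absence",
                    season=season,
                    sex="NA",
                    x=x,
                    y=y,
                    values=values,
                )
            )
    ds = Dataset(records, scheme)
    _verify_constraints(ds, presences, landscape, exclusion_radius_m)
    return ds


def _verify_constraints(
    pa: Dataset, presences: Dataset, landscape: LandscapeConfig, radius: float
) -> None:
    """Exhaustive post-hoc check of every emitted pseudo-absence point."""
    for r in pa:
        if any(z.contains(r.x, r.y) for z in landscape.unsuitable_zones):
            raise SamplingError(f"point {r.point_id} inside an unsuitable zone")
        for p in presences.presences(season=r.season):
            if np.hypot(p.x - r.x, p.y - r.y) < radius:
                raise SamplingError(
                    f"point {r.point_id} within {radius} m of presence {p.point_id}"
                )


def uniform_profiles(
    sizes: Mapping[str, int] | None = None, scheme: FactorScheme | None = None
) -> list[GroupPreferenceProfile]:
    """No-preference profiles (uniform weights) for all four groups."""
    sizes = dict(sizes) if sizes is not None else dict(_DEFAULT_SIZES)
    scheme = scheme if scheme is not None else default_scheme()
    return [
        GroupPreferenceProfile(
            group=g,
            weights={f.name: np.full(f.n_categories, 1.0) for f in scheme},
            n_individuals=sizes[g],
        )
        for g in sizes
    ]


def default_profiles(
    sizes: Mapping[str, int] | None = None, scheme: FactorScheme | None = None
) -> list[GroupPreferenceProfile]:
    """Default group preferences emulating the motivating survey's structure.

    All groups share moderate preferences (mid-altitude, warm, humid,
    vegetated, near-water quadrats); non-breeding females are shifted
    toward low altitude, down-slope positions and far-from-road quadrats.
    The exact numbers are arbitrary synthetic choices — the survey reports
    index values, not availability or preference distributions.
    """
    sizes = dict(sizes) if sizes is not None else dict(_DEFAULT_SIZES)
    scheme = scheme if scheme is not None else default_scheme()
    base: dict[str, tuple[float, float, float]] = {
        "altitude": (0.25, 0.55, 0.20),
        "landscape_habitat": (0.40, 0.45, 0.15),
        "vegetation_type": (0.30, 0.45, 0.25),
        "temperature": (0.15, 0.60, 0.25),
        "humidity": (0.10, 0.40, 0.50),
        "vegetation_coverage": (0.15, 0.45, 0.40),
        "vegetation_height": (0.35, 0.45, 0.20),
        "slope": (0.40, 0.45, 0.15),
        "slope_position": (0.40, 0.40, 0.20),
        "dist_roads": (0.20, 0.35, 0.45),
        "dist_water": (0.45, 0.35, 0.20),
        "dist_residential": (0.20, 0.50, 0.30),
        "aspect": (0.34, 0.33, 0.33),
    }
    nbf_shift: dict[str, tuple[float, float, float]] = {
        "altitude": (0.60, 0.30, 0.10),
        "slope_position": (0.60, 0.30, 0.10),
        "dist_roads": (0.10, 0.25, 0.65),
    }
    profiles = []
    for g in sizes:
        weights = {f.name: np.asarray(base[f.name]) for f in scheme}
        if g == "NBF":
            weights.update({k: np.asarray(v) for k, v in nbf_shift.items()})
        profiles.append(
            GroupPreferenceProfile(group=g, weights=weights, n_individuals=sizes[g])
        )
    return profiles


def default_landscape(scheme: FactorScheme | None = None) -> LandscapeConfig:
    """A 2 x 2 km extent with mildly non-uniform availability and one
    unsuitable zone per corner (synthetic stand-ins for highway/water/cliff
    areas)."""
    scheme = scheme if scheme is not None else default_scheme()
    availability = {
        "altitude": (0.30, 0.45, 0.25),
        "temperature": (0.25, 0.50, 0.25),
        "humidity": (0.25, 0.40, 0.35),
        "dist_roads": (0.30, 0.35, 0.35),
        "dist_water": (0.30, 0.35, 0.35),
        "dist_residential": (0.25, 0.45, 0.30),
        "landscape_habitat": (0.30, 0.40, 0.30),
        "vegetation_type": (0.35, 0.35, 0.30),
        "vegetation_coverage": (0.30, 0.40, 0.30),
        "vegetation_height": (0.35, 0.40, 0.25),
        "slope": (0.40, 0.40, 0.20),
        "slope_position": (0.35, 0.40, 0.25),
        "aspect": (0.34, 0.33, 0.33),
    }
    zones = (
        Rect(0.0, 0.0, 150.0, 150.0),
        Rect(1850.0, 1850.0, 2000.0, 2000.0),
    )
    return LandscapeConfig(
        extent=Rect(0.0, 0.0, 2000.0, 2000.0),
        availability=availability,
        unsuitable_zones=zones,
        scheme=scheme,
    )


def generate_survey(
    seed: int = 0,
    sizes: Mapping[str, int] | None = None,
    landscape: LandscapeConfig | None = None,
    profiles: Sequence[GroupPreferenceProfile] | None = None,
    n_pseudo_absences: int = 50,
    exclusion_radius_m: float = 50.0,
) -> tuple[Dataset, dict[str, GroupPreferenceProfile]]:
    """One full synthetic survey: presences of all four groups plus
    per-season pseudo-absences, merged into a single dataset."""
    landscape = landscape if landscape is not None else default_landscape()
    if profiles is None:
        profiles = default_profiles(sizes, landscape.scheme)
    presences, truth = generate_presences(landscape, profiles, seed=seed)
    pa = generate_pseudo_absences(
        landscape,
        presences,
        n=n_pseudo_absences,
        exclusion_radius_m=exclusion_radius_m,
        seed=seed + 1,
    )
    merged = Dataset(list(presences) + list(pa), landscape.scheme)
    return merged, truth
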