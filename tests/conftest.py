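"""Shared fixtures: tiny factor schemes and hand-buildable survey datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microniche import Dataset, FactorDefinition, FactorScheme, QuadratRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_scheme() -> FactorScheme:
    """Two continuous 3-level factors with easy integer cut points."""
    return FactorScheme(
        (
            FactorDefinition("f1", "continuous_binned", (10.0, 20.0), ("lo", "mid", "hi")),
            FactorDefinition("f2", "continuous_binned", (10.0, 20.0), ("lo", "mid", "hi")),
        )
    )


def _raw_for_cat(fdef: FactorDefinition, cat: int):
    """A raw value that bins into the requested 1-based category."""
    if fdef.kind == "categorical":
        return fdef.categories[cat - 1]
    edges = fdef.bin_edges
    if cat == 1:
        return edges[0] - 1.0
    if cat == len(edges) + 1:
        return edges[-1] + 1.0
    return 0.5 * (edges[cat - 2] + edges[cat - 1])


def build_dataset(
    scheme: FactorScheme,
    presence_counts: dict[str, dict[str, tuple[int, int, int]]],
    pa_counts: dict[str, dict[str, tuple[int, int, int]]] | None = None,
) -> Dataset:
    """Build a dataset with exact per-category counts.

    ``presence_counts``: group -> factor -> counts per category (all factors
    of a group must share the same total). ``pa_counts``: season -> factor ->
    counts for the pseudo-absence pool.
    """
    records: list[QuadratRecord] = []
    for group, per_factor in presence_counts.items():
        season = "breeding" if group.startswith("B") else "non_breeding"
        sex = group[-1]
        totals = {sum(c) for c in per_factor.values()}
        assert len(totals) == 1, "factor totals must agree within a group"
        total = totals.pop()
        cat_seq = {
            f: [c + 1 for c, k in enumerate(counts) for _ in range(k)]
            for f, counts in per_factor.items()
        }
        for j in range(total):
            values = {f: _raw_for_cat(scheme[f], cat_seq[f][j]) for f in per_factor}
            for f in scheme.names:
                values.setdefault(f, _raw_for_cat(scheme[f], 1))
            records.append(
                QuadratRecord(
                    point_id=f"{group}_{j}",
                    point_class="presence",
                    season=season,
                    sex=sex,
                    x=float(j),
                    y=float(len(records)),
                    values=values,
                )
            )
    for season, per_factor in (pa_counts or {}).items():
        totals = {sum(c) for c in per_factor.values()}
        assert len(totals) == 1
        total = totals.pop()
        cat_seq = {
            f: [c + 1 for c, k in enumerate(counts) for _ in range(k)]
            for f, counts in per_factor.items()
        }
        for j in range(total):
            values = {f: _raw_for_cat(scheme[f], cat_seq[f][j]) for f in per_factor}
            for f in scheme.names:
                values.setdefault(f, _raw_for_cat(scheme[f], 1))
            records.append(
                QuadratRecord(
                    point_id=f"PA_{season}_{j}",
                    point_class="pseudo_absence",
                    season=season,
                    sex="NA",
                    x=1000.0 + j,
                    y=1000.0 + len(records),
                    values=values,
                )
            )
    return Dataset(records, scheme)


@pytest.fixture
def build(tiny_scheme):
    def _build(presence_counts, pa_counts=None):
        return build_dataset(tiny_scheme, presence_counts, pa_counts)

    return _build
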