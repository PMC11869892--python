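"""Quadrat survey records: data model, CSV round-trip, preprocessing.

A record is one 4 x 4 m sampling quadrat: either a *presence* point (an
animal was located there; carries season and sex) or a *pseudo-absence*
point (a random background location sampling available habitat; sex is
not applicable). Presence records derive a group label from season x sex:
BM / BF (breeding males / females), NBM / NBF (non-breeding).

Values are kept raw; binning into factor categories happens on demand via
the attached :class:`~microniche.factors.FactorScheme`. Missing values are
``None`` in memory and empty cells on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from .factors import (
    FactorScheme,
    FormatError,
    ValidationError,
    bin_value,
    default_scheme,
)

__all__ = [
    "QuadratRecord",
    "Dataset",
    "PreprocessOptions",
    "load_records",
    "write_records",
    "preprocess",
    "GROUPS",
    "SEASONS",
]

GROUPS = ("BM", "BF", "NBM", "NBF")
SEASONS = ("breeding", "non_breeding")
_META_COLUMNS = ("point_id", "point_class", "season", "sex", "x_m", "y_m")


@dataclass(frozen=True)
class QuadratRecord:
    """One sampling point with its raw habitat-factor values."""

    point_id: str
    point_class: str  # "presence" | "pseudo_absence"
    season: str  # "breeding" | "non_breeding"
    sex: str  # "M" | "F" | "NA"
    x: float
    y: float
    values: Mapping[str, Optional[float | str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.point_class not in ("presence", "pseudo_absence"):
            raise ValidationError(
                f"point {self.point_id!r}: bad point_class {self.point_class!r}"
            )
        if self.season not in SEASONS:
            raise ValidationError(
                f"point {self.point_id!r}: bad season {self.season!r}"
            )
        if self.point_class == "presence" and self.sex not in ("M", "F"):
            raise ValidationError(
                f"presence point {self.point_id!r}: sex must be M or F, got {self.sex!r}"
            )
        if self.point_class == "pseudo_absence" and self.sex != "NA":
            raise ValidationError(
                f"pseudo-absence point {self.point_id!r}: sex must be NA, got {self.sex!r}"
            )

    @property
    def group(self) -> Optional[str]:
        """Season x sex group label for presence points, None for background."""
        if self.point_class != "presence":
            return None
        prefix = "" if self.season == "breeding" else "N"
        return f"{prefix}B{self.sex}"


class Dataset:
    """A collection of :class:`QuadratRecord` under one factor scheme."""

    def __init__(self, records: Iterable[QuadratRecord], scheme: FactorScheme | None = None):
        self.records: list[QuadratRecord] = list(records)
        self.scheme = scheme if scheme is not None else default_scheme()
        ids = [r.point_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate point_id(s): {dupes}")
        for r in self.records:
            for name in self.scheme.names:
                if name not in r.values:
                    raise ValidationError(
                        f"point {r.point_id!r}: no value (or missing marker) "
                        f"for factor {name!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[QuadratRecord]:
        return iter(self.records)

    def presences(self, group: str | None = None, season: str | None = None) -> "Dataset":
        recs = [r for r in self.records if r.point_class == "presence"]
        if group is not None:
            recs = [r for r in recs if r.group == group]
        if season is not None:
            recs = [r for r in recs if r.season == season]
        return Dataset(recs, self.scheme)

    def pseudo_absences(self, season: str | None = None) -> "Dataset":
        recs = [r for r in self.records if r.point_class == "pseudo_absence"]
        if season is not None:
            recs = [r for r in recs if r.season == season]
        return Dataset(recs, self.scheme)

    @property
    def groups_present(self) -> tuple[str, ...]:
        present = {r.group for r in self.records if r.group is not None}
        return tuple(g for g in GROUPS if g in present)

    def to_frame(self) -> pd.DataFrame:
        """Long metadata + one raw-value column per factor (NaN = missing)."""
        rows = []
        for r in self.records:
            row = {
                "point_id": r.point_id,
                "point_class": r.point_class,
                "season": r.season,
                "sex": r.sex,
                "x_m": r.x,
                "y_m": r.y,
            }
            for name in self.scheme.names:
                v = r.values.get(name)
                row[name] = np.nan if v is None else v
            rows.append(row)
        cols = list(_META_COLUMNS) + list(self.scheme.names)
        return pd.DataFrame(rows, columns=cols)

    def category_counts(self, factor: str, records: Iterable[QuadratRecord] | None = None) -> np.ndarray:
        """Counts per category (1..n) of a factor, skipping missing values."""
        fdef = self.scheme[factor]
        counts = np.zeros(fdef.n_categories, dtype=int)
        for r in self.records if records is None else records:
            v = r.values.get(factor)
            if v is None:
                continue
            counts[bin_value(fdef, v) - 1] += 1
        return counts


def load_records(path, scheme: FactorScheme | None = None) -> Dataset:
    """Read a records CSV into a :class:`Dataset`.

    Rows whose point_class/season/sex fields cannot be interpreted are
    rejected with a per-row diagnostic (collected on the returned dataset as
    ``rejected_rows``); missing factor cells are retained as missing markers.

    Raises :class:`FormatError` when a required column is absent and
    :class:`ValidationError` on duplicate point ids.
    """
    scheme = scheme if scheme is not None else default_scheme()
    df = pd.read_csv(path, dtype={"point_id": str})
    missing_cols = [c for c in _META_COLUMNS if c not in df.columns]
    missing_cols += [n for n in scheme.names if n not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required column(s) {missing_cols}")

    records: list[QuadratRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        values: dict[str, Optional[float | str]] = {}
        for name in scheme.names:
            cell = row[name]
            if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                values[name] = None
            elif scheme[name].kind == "categorical":
                values[name] = str(cell)
            else:
                values[name] = float(cell)
        try:
            records.append(
                QuadratRecord(
                    point_id=str(row["point_id"]),
                    point_class=str(row["point_class"]),
                    season=str(row["season"]),
                    sex="NA" if pd.isna(row["sex"]) else str(row["sex"]),
                    x=float(row["x_m"]),
                    y=float(row["y_m"]),
                    values=values,
                )
            )
        except (ValidationError, ValueError) as exc:
            rejected.append((int(i) + 2, str(exc)))  # +2: header + 1-based
    ds = Dataset(records, scheme)
    ds.rejected_rows = rejected  # type: ignore[attr-defined]
    return ds


def write_records(ds: Dataset, path) -> None:
    """Write a dataset to CSV; inverse of :func:`load_records`."""
    ds.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PreprocessOptions:
    """Options for :func:`preprocess`.

    ``iqr_k`` sets the extreme-outlier fence at median +/- k*IQR per factor
    and point class; ``log_transform`` applies ln(x+1) to continuous factors
    (off by default: the selection/niche pipeline bins values into ordered
    categories, which is invariant to monotone transforms only if the bin
    edges are transformed too).
    """

    iqr_k: float = 3.0
    log_transform: bool = False


def preprocess(ds: Dataset, cfg: PreprocessOptions | None = None) -> Dataset:
    """Flag extreme outliers as missing and optionally log-transform.

    Continuous values outside ``median +/- k*IQR`` (computed per factor and
    per point class) become missing. The returned dataset carries a
    ``processing_log`` listing every modification. Record count never
    changes.
    """
    cfg = cfg or PreprocessOptions()
    log: list[str] = []
    continuous = [f.name for f in ds.scheme if f.kind == "continuous_binned"]

    fences: dict[tuple[str, str], tuple[float, float]] = {}
    for name in continuous:
        for pclass in ("presence", "pseudo_absence"):
            vals = np.array(
                [
                    float(r.values[name])
                    for r in ds.records
                    if r.point_class == pclass and r.values.get(name) is not None
                ]
            )
            if vals.size == 0:
                continue
            med = float(np.median(vals))
            q1, q3 = np.percentile(vals, [25, 75])
            iqr = float(q3 - q1)
            fences[(name, pclass)] = (med - cfg.iqr_k * iqr, med + cfg.iqr_k * iqr)

    out: list[QuadratRecord] = []
    for r in ds.records:
        new_values = dict(r.values)
        for name in continuous:
            v = new_values.get(name)
            if v is None:
                continue
            x = float(v)
            fence = fences.get((name, r.point_class))
            if fence is not None and not (fence[0] <= x <= fence[1]):
                new_values[name] = None
                log.append(
                    f"{r.point_id}: {name}={x:g} outside "
                    f"[{fence[0]:g}, {fence[1]:g}] -> missing"
                )
                continue
            if cfg.log_transform:
                if x < 0:
                    raise ValidationError(
                        f"point {r.point_id!r}: negative {name}={x:g} under log transform"
                    )
                new_values[name] = math.log1p(x)
                log.append(f"{r.point_id}: {name} ln(x+1) {x:g} -> {math.log1p(x):g}")
        out.append(replace(r, values=new_values))
    result = Dataset(out, ds.scheme)
    result.processing_log = log  # type: ignore[attr-defined]
    return result
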