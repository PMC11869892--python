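"""Vanderploeg-Scavia electivity indices and preference classification.

Habitat preference is inferred by comparing use against availability per
factor category. With ``r_i`` the number of used (presence) quadrats in
category ``i``, ``p_i`` the number of available quadrats in that category
and ``n`` the number of categories:

    W_i = (r_i / p_i) / sum_i (r_i / p_i)          (normalized selectivity)
    E_i = (W_i - 1/n) / (W_i + 1/n)                (relative electivity)

E_i lives in [-1, (1 - 1/n)/(1 + 1/n)], is 0 at the no-preference point
W_i = 1/n, and is classified on the five-level rubric: E_i = 1 strong
preference, 0.1 < E_i < 1 selection, -0.1 < E_i < 0.1 random,
-1 < E_i < -0.1 avoidance, E_i = -1 no selection. The rubric's open
boundaries at +/-0.1 are resolved to the adjacent non-random class so the
classification is total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .factors import EXCLUDED_DOWNSTREAM, FactorScheme, ValidationError
from .records import Dataset, GROUPS

__all__ = [
    "SelectionResult",
    "vanderploeg_wi",
    "scavia_ei",
    "classify_ei",
    "selection_table",
    "AvailabilityViolation",
    "DegenerateInputError",
]

logger = logging.getLogger(__name__)

_CLASSES = ("strong_preference", "selection", "random", "avoidance", "no_selection")
_ENDPOINT_TOL = 1e-9


class AvailabilityViolation(ValidationError):
    """Use recorded in a category with zero availability."""


class DegenerateInputError(ValidationError):
    """Inputs admit no meaningful index (e.g. no use at all)."""


def vanderploeg_wi(r, p) -> np.ndarray:
    """Normalized selectivity coefficients W_i from use and availability counts.

    Categories with zero availability and zero use are excluded from the
    normalizing sum and returned as NaN (no data); zero availability with
    positive use is an :class:`AvailabilityViolation`, since the ratio is
    infinite. The finite entries sum to 1.
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if r.shape != p.shape or r.ndim != 1 or r.size < 2:
        raise ValidationError("r and p must be 1-d vectors of equal length >= 2")
    if np.any(r < 0) or np.any(p < 0):
        raise ValidationError("counts must be nonnegative")
    bad = (p == 0) & (r > 0)
    if np.any(bad):
        cats = np.flatnonzero(bad) + 1
        raise AvailabilityViolation(
            f"use recorded with zero availability in category(ies) {cats.tolist()}"
        )
    if not np.any(r > 0):
        raise DegenerateInputError("all use counts are zero")
    ratio = np.full(r.shape, np.nan)
    ok = p > 0
    ratio[ok] = r[ok] / p[ok]
    total = np.nansum(ratio)
    wi = ratio / total
    return wi


def scavia_ei(wi, n: int | None = None) -> np.ndarray:
    """Relative electivity E_i = (W_i - 1/n) / (W_i + 1/n).

    ``n`` defaults to the length of ``wi``; NaN entries (no-data
    categories) propagate.
    """
    wi = np.asarray(wi, dtype=float)
    if n is None:
        n = wi.size
    if n < 2:
        raise ValidationError("need n >= 2 categories")
    with np.errstate(invalid="ignore"):
        if np.any((wi < -1e-12) | (wi > 1 + 1e-12)):
            raise ValidationError("W_i must lie in [0, 1]")
    inv_n = 1.0 / n
    return (wi - inv_n) / (wi + inv_n)


def classify_ei(ei: float) -> str:
    """Five-level preference class for one electivity value.

    Endpoints +/-1 are matched with tolerance 1e-9; the boundary values
    +/-0.1 map to the adjacent non-random class (0.1 -> selection,
    -0.1 -> avoidance).
    """
    if np.isnan(ei):
        return "no_data"
    if ei < -1 - _ENDPOINT_TOL or ei > 1 + _ENDPOINT_TOL:
        raise ValidationError(f"E_i = {ei} outside [-1, 1]")
    if ei >= 1 - _ENDPOINT_TOL:
        return "strong_preference"
    if ei <= -1 + _ENDPOINT_TOL:
        return "no_selection"
    if ei >= 0.1:
        return "selection"
    if ei <= -0.1:
        return "avoidance"
    return "random"


@dataclass(frozen=True)
class SelectionResult:
    """Electivity of one group on one factor.

    ``excluded_downstream`` marks factors computed here but dropped from
    niche breadth/overlap aggregation (aspect, by default).
    """

    group: str
    factor: str
    r: np.ndarray
    p: np.ndarray
    n: int
    wi: np.ndarray
    ei: np.ndarray
    classes: tuple[str, ...]
    excluded_downstream: bool = False


def selection_table(
    ds: Dataset,
    scheme: FactorScheme | None = None,
    *,
    pool_seasons: bool = False,
    availability_includes_presences: bool = False,
) -> list[SelectionResult]:
    """Per group x factor electivity over a survey dataset.

    Use counts ``r`` come from the group's presence quadrats; availability
    counts ``p`` from the season-matched pseudo-absence quadrats (the
    background points were generated per survey period). ``pool_seasons``
    pools both seasons' background points instead;
    ``availability_includes_presences`` adds the season's presence quadrats
    to the availability pool.

    Empty groups are skipped with a warning. The aspect factor is computed
    but flagged ``excluded_downstream``.
    """
    scheme = scheme if scheme is not None else ds.scheme
    results: list[SelectionResult] = []
    for group in GROUPS:
        used = ds.presences(group=group)
        if len(used) == 0:
            warnings.warn(f"group {group} has no presence records; skipped", stacklevel=2)
            logger.warning("group %s empty; skipped", group)
            continue
        season = None if pool_seasons else used.records[0].season
        avail = ds.pseudo_absences(season=season)
        avail_extra = ds.presences(season=season) if availability_includes_presences else None
        for fdef in scheme:
            r = used.category_counts(fdef.name)
            p = avail.category_counts(fdef.name)
            if avail_extra is not None:
                p = p + avail_extra.category_counts(fdef.name)
            wi = vanderploeg_wi(r, p)
            ei = scavia_ei(wi, fdef.n_categories)
            classes = tuple(classify_ei(e) for e in ei)
            results.append(
                SelectionResult(
                    group=group,
                    factor=fdef.name,
                    r=r,
                    p=p,
                    n=fdef.n_categories,
                    wi=wi,
                    ei=ei,
                    classes=classes,
                    excluded_downstream=fdef.name in EXCLUDED_DOWNSTREAM,
                )
            )
    return results


def selection_frame(results: list[SelectionResult]):
    """Long-format table: group, factor, category, r, p, Wi, Ei, class."""
    import pandas as pd

    rows = []
    for res in results:
        for i in range(res.n):
            rows.append(
                {
                    "group": res.group,
                    "factor": res.factor,
                    "category": i + 1,
                    "r": int(res.r[i]),
                    "p": int(res.p[i]),
                    "Wi": res.wi[i],
                    "Ei": res.ei[i],
                    "class": res.classes[i],
                    "excluded_downstream": res.excluded_downstream,
                }
            )
    return pd.DataFrame(rows)
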