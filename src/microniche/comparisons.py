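"""Univariate seasonal and sexual difference tests on presence quadrats.

Continuous factors are gated per grouping: if every group passes a
normality check and the groups pass a variance-homogeneity check
(Brown-Forsythe Levene, median-centred) at the gate alpha, a one-way
ANOVA is used; otherwise a Mann-Whitney U test with the normal
approximation (midranks, tie-corrected variance, no continuity
correction). Categorical factors use a Pearson chi-square test on the
grouping x category contingency table. Group mean +/- sample SD summaries
accompany every result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .factors import FactorScheme, ValidationError
from .records import Dataset

__all__ = ["TestResult", "mann_whitney", "chi_square", "compare_groups"]

_GROUPINGS = {
    "sex": ("M", "F"),
    "season": ("breeding", "non_breeding"),
}


@dataclass(frozen=True)
class TestResult:
    """One variable's between-level test under one grouping."""

    variable: str
    grouping: str  # "sex" | "season"
    test: str  # "mann_whitney" | "anova" | "chi_square"
    statistic: float  # Z, F, or chi2
    df: object  # int, tuple, or None (Z has no df)
    p_value: float
    group_summaries: Mapping[str, tuple[float, float, int]]  # (mean, sd, n)


def mann_whitney(x, y, continuity: bool = False) -> tuple[float, float]:
    """Mann-Whitney U via the normal approximation; returns (Z, p).

    U is computed from midranks; the variance carries the tie correction

        var(U) = n1 n2 / 12 * [(N + 1) - sum(t^3 - t) / (N (N - 1))].

    ``continuity`` applies the 0.5 continuity correction toward the mean
    (off by default). Identical pooled samples give Z = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples need >= 1 observation")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    mean_u = n1 * n2 / 2.0
    N = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var_u <= 0:  # all values identical across both samples
        return 0.0, 1.0
    diff = u - mean_u
    if continuity and diff != 0:
        diff -= 0.5 * np.sign(diff)
    z = diff / np.sqrt(var_u)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns (chi2, df, p). A zero row or column margin is a validation
    error; expected counts below 5 emit a small-expected-count warning.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValidationError("table must be a 2-d nonnegative count matrix")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("need at least two non-empty rows and columns")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected < 5):
        warnings.warn(
            f"{int(np.sum(expected < 5))} cell(s) with expected count < 5; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def _summaries(
    groups: Mapping[str, np.ndarray]
) -> dict[str, tuple[float, float, int]]:
    out = {}
    for g, v in groups.items():
        n = int(v.size)
        sd = float(np.std(v, ddof=1)) if n > 1 else float("nan")
        out[g] = (float(np.mean(v)) if n else float("nan"), sd, n)
    return out


def compare_groups(
    ds: Dataset,
    grouping: str,
    scheme: FactorScheme | None = None,
    gate_alpha: float = 0.05,
    continuity: bool = False,
    normality_test: str = "shapiro",
    exclude_factors: Sequence[str] = (),
) -> list[TestResult]:
    """Table of per-factor two-level tests for one grouping (sex or season).

    Only presence records enter. Continuous factors are dispatched to ANOVA
    or Mann-Whitney by the normality/homogeneity gate; categorical factors
    go to chi-square on the level x category table. Missing values are
    dropped per factor (listwise within the variable).
    """
    if grouping not in _GROUPINGS:
        raise ValidationError(f"grouping must be one of {sorted(_GROUPINGS)}")
    scheme = scheme if scheme is not None else ds.scheme
    levels = _GROUPINGS[grouping]
    pres = ds.presences()
    by_level = {
        lv: [r for r in pres if (r.sex if grouping == "sex" else r.season) == lv]
        for lv in levels
    }
    if any(len(v) == 0 for v in by_level.values()):
        raise ValidationError(f"both {grouping} levels must be non-empty")

    norm_tests = {
        "shapiro": lambda v: stats.shapiro(v).pvalue,
        "normaltest": lambda v: stats.normaltest(v).pvalue,
    }
    if normality_test not in norm_tests:
        raise ValidationError(f"unknown normality test {normality_test!r}")
    norm_p = norm_tests[normality_test]

    results: list[TestResult] = []
    for fdef in scheme:
        if fdef.name in exclude_factors:
            continue
        if fdef.kind == "continuous_binned":
            samples = {
                lv: np.array(
                    [
                        float(r.values[fdef.name])
                        for r in by_level[lv]
                        if r.values.get(fdef.name) is not None
                    ]
                )
                for lv in levels
            }
            if any(v.size < 3 for v in samples.values()):
                warnings.warn(
                    f"{fdef.name}: a {grouping} level has < 3 values; skipped",
                    stacklevel=2,
                )
                continue
            vals = [samples[lv] for lv in levels]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normal = all(norm_p(v) > gate_alpha for v in vals)
                homogeneous = (
                    stats.levene(*vals, center="median").pvalue > gate_alpha
                )
            if normal and homogeneous:
                f_stat, p = stats.f_oneway(*vals)
                df = (len(vals) - 1, sum(v.size for v in vals) - len(vals))
                results.append(
                    TestResult(
                        variable=fdef.name,
                        grouping=grouping,
                        test="anova",
                        statistic=float(f_stat),
                        df=df,
                        p_value=float(p),
                        group_summaries=_summaries(samples),
                    )
                )
            else:
                z, p = mann_whitney(vals[0], vals[1], continuity=continuity)
                results.append(
                    TestResult(
                        variable=fdef.name,
                        grouping=grouping,
                        test="mann_whitney",
                        statistic=z,
                        df=None,
                        p_value=p,
                        group_summaries=_summaries(samples),
                    )
                )
        else:
            table = np.vstack(
                [ds.category_counts(fdef.name, records=by_level[lv]) for lv in levels]
            )
            try:
                chi2, df, p = chi_square(table)
            except ValidationError as exc:
                warnings.warn(f"{fdef.name}: {exc}; skipped", stacklevel=2)
                continue
            counts = {
                lv: (float("nan"), float("nan"), int(table[i].sum()))
                for i, lv in enumerate(levels)
            }
            results.append(
                TestResult(
                    variable=fdef.name,
                    grouping=grouping,
                    test="chi_square",
                    statistic=chi2,
                    df=df,
                    p_value=p,
                    group_summaries=counts,
                )
            )
    return results


def comparison_frame(results: list[TestResult]):
    """Tabular (long) form of :func:`compare_groups` output."""
    import pandas as pd

    rows = []
    for r in results:
        row = {
            "variable": r.variable,
            "grouping": r.grouping,
            "test": r.test,
            "statistic": r.statistic,
            "df": "" if r.df is None else str(r.df),
            "p_value": r.p_value,
        }
        for g, (mean, sd, n) in r.group_summaries.items():
            row[f"{g}_mean"] = mean
            row[f"{g}_sd"] = sd
            row[f"{g}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows)
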