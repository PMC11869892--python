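"""Levins niche breadth, directional niche overlap, and a resampling null.

Resource states are the ordered categories of each habitat factor. With
``P_j`` the proportion of a group's quadrats in category ``j`` of a factor
(j = 1..R):

    B    = 1 / sum_j P_j^2                    (Levins breadth, in [1, R])
    O_ik = sum_j P_ij P_kj / sum_j P_ij^2     (directional overlap of group
                                               k onto group i's niche)

O_ik is asymmetric and may exceed 1 (group i's own concentration
normalizes it). Per-factor values are aggregated by arithmetic mean over
the retained factors (aspect excluded); pairwise overlaps are symmetrized
(default: mean of the two directions) and reported in percent.

Significance of between-group differentiation is assessed by shuffling
group labels across all presence records (sizes preserved), recomputing
the pairwise overlap matrix, and comparing the six observed pair values
with the resampled ones by a paired t-test (df = 5). With many resamples a
permutation p (fraction of null mean overlaps <= the observed mean) is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .factors import EXCLUDED_DOWNSTREAM, FactorScheme, ValidationError
from .records import Dataset, GROUPS, QuadratRecord
from .selection import DegenerateInputError

__all__ = [
    "UsageProfile",
    "NicheWidthResult",
    "OverlapReport",
    "usage_profile",
    "levins_width",
    "group_niche_width",
    "levins_overlap",
    "overlap_matrix",
    "resample_null",
    "overlap_significance",
]

_PROB_TOL = 1e-12
SYMMETRIZE_CONVENTIONS = ("mean", "row_reference", "min", "geometric")
AGGREGATION_CONVENTIONS = ("mean_factors",)


@dataclass(frozen=True)
class UsageProfile:
    """Category-use proportions of one group on one factor."""

    group: str
    factor: str
    P: np.ndarray
    R: int

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.P)) - 1.0) > 1e-9 or np.any(self.P < 0):
            raise ValidationError(
                f"usage profile {self.group}/{self.factor}: P must be a probability vector"
            )


@dataclass(frozen=True)
class NicheWidthResult:
    group: str
    per_factor_B: dict[str, float]
    aggregate_B: float
    aggregation: str = "mean_factors"


@dataclass(frozen=True)
class OverlapReport:
    """Pairwise niche-overlap matrices and the resampling-null summary.

    ``O_dir[i, k]`` is the factor-averaged directional overlap of group
    ``groups[k]`` onto ``groups[i]`` (unitless); ``O_sym`` is the
    symmetrized matrix in percent. Null fields are populated by
    :func:`overlap_significance`.
    """

    groups: tuple[str, ...]
    O_dir: np.ndarray
    O_sym: np.ndarray  # percent
    resampled: list[np.ndarray] = field(default_factory=list)  # percent
    t_stat: float | None = None
    df: int | None = None
    p_value: float | None = None
    mean_obs: float | None = None
    sd_obs: float | None = None
    mean_null: float | None = None
    sd_null: float | None = None
    permutation_p: float | None = None

    @property
    def abs_t(self) -> float | None:
        return None if self.t_stat is None else abs(self.t_stat)

    def pair_values(self, matrix: np.ndarray | None = None) -> np.ndarray:
        """The unordered-pair values (upper triangle, row-major)."""
        m = self.O_sym if matrix is None else matrix
        iu = np.triu_indices(len(self.groups), k=1)
        return np.asarray(m)[iu]


def usage_profile(ds: Dataset, group: str, factor: str) -> UsageProfile:
    """Proportion of a group's quadrats per category of a factor."""
    used = ds.presences(group=group)
    counts = used.category_counts(factor)
    total = counts.sum()
    if total == 0:
        raise DegenerateInputError(
            f"group {group!r} has no non-missing values for factor {factor!r}"
        )
    return UsageProfile(group=group, factor=factor, P=counts / total, R=counts.size)


def levins_width(P) -> float:
    """Levins niche breadth B = 1 / sum P_j^2, in [1, R]."""
    P = np.asarray(P, dtype=float)
    if np.any(P < -_PROB_TOL) or abs(float(P.sum()) - 1.0) > 1e-9:
        raise ValidationError("P must be a normalized probability vector")
    return float(1.0 / np.sum(P**2))


def _retained_factors(scheme: FactorScheme, exclude: Sequence[str]) -> list[str]:
    return [f.name for f in scheme if f.name not in exclude]


def group_niche_width(
    ds: Dataset,
    group: str,
    scheme: FactorScheme | None = None,
    aggregation: str = "mean_factors",
    exclude_factors: Sequence[str] = EXCLUDED_DOWNSTREAM,
) -> NicheWidthResult:
    """Per-factor Levins breadth for one group, averaged over retained factors.

    The aggregate is the arithmetic mean of the per-factor B values over
    the retained (non-excluded) factors; each per-factor B lies in
    [1, R_factor], so with three-level factors the aggregate lies in [1, 3].
    """
    if aggregation not in AGGREGATION_CONVENTIONS:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    scheme = scheme if scheme is not None else ds.scheme
    per_factor: dict[str, float] = {}
    for name in _retained_factors(scheme, exclude_factors):
        per_factor[name] = levins_width(usage_profile(ds, group, name).P)
    return NicheWidthResult(
        group=group,
        per_factor_B=per_factor,
        aggregate_B=float(np.mean(list(per_factor.values()))),
        aggregation=aggregation,
    )


def levins_overlap(Pi, Pk) -> float:
    """Directional Levins overlap O_ik = sum(P_ij P_kj) / sum(P_ij^2)."""
    Pi = np.asarray(Pi, dtype=float)
    Pk = np.asarray(Pk, dtype=float)
    if Pi.shape != Pk.shape:
        raise ValidationError("profiles must have equal length")
    for P in (Pi, Pk):
        if abs(float(P.sum()) - 1.0) > 1e-9 or np.any(P < -_PROB_TOL):
            raise ValidationError("profiles must be normalized probability vectors")
    return float(np.sum(Pi * Pk) / np.sum(Pi**2))


def _profiles_from_counts(
    counts: dict[str, dict[str, np.ndarray]],
) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    for g, per_factor in counts.items():
        out[g] = {}
        for f, c in per_factor.items():
            total = c.sum()
            if total == 0:
                raise DegenerateInputError(
                    f"group {g!r} has no non-missing values for factor {f!r}"
                )
            out[g][f] = c / total
    return out


def _group_counts(
    groups: Sequence[str],
    members: dict[str, list[QuadratRecord]],
    ds: Dataset,
    factors: Sequence[str],
) -> dict[str, dict[str, np.ndarray]]:
    return {
        g: {f: ds.category_counts(f, records=members[g]) for f in factors}
        for g in groups
    }


def _overlap_matrices(
    groups: Sequence[str],
    profiles: dict[str, dict[str, np.ndarray]],
    factors: Sequence[str],
    symmetrize: str,
) -> tuple[np.ndarray, np.ndarray]:
    k = len(groups)
    O_dir = np.eye(k)
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            vals = [
                levins_overlap(profiles[groups[a]][f], profiles[groups[b]][f])
                for f in factors
            ]
            O_dir[a, b] = np.mean(vals)
    O_sym = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            oik, oki = O_dir[a, b], O_dir[b, a]
            if symmetrize == "mean":
                v = 0.5 * (oik + oki)
            elif symmetrize == "row_reference":
                v = oik
            elif symmetrize == "min":
                v = min(oik, oki)
            elif symmetrize == "geometric":
                v = float(np.sqrt(oik * oki))
            else:
                raise ValidationError(f"unknown symmetrization {symmetrize!r}")
            O_sym[a, b] = O_sym[b, a] = v
    return O_dir, O_sym


def overlap_matrix(
    ds: Dataset,
    scheme: FactorScheme | None = None,
    symmetrize: str = "mean",
    exclude_factors: Sequence[str] = EXCLUDED_DOWNSTREAM,
    groups: Sequence[str] | None = None,
) -> OverlapReport:
    """Pairwise niche overlap among groups, factor-averaged, in percent.

    Per unordered pair the directional overlaps are averaged over the
    retained factors in each direction, then symmetrized (``mean`` of the
    two directions by default; ``row_reference``, ``min`` and ``geometric``
    are available) and scaled x100. No clipping at 100%: the raw index can
    exceed 1.
    """
    scheme = scheme if scheme is not None else ds.scheme
    groups = tuple(groups) if groups is not None else ds.groups_present
    if len(groups) < 2:
        raise DegenerateInputError("need at least two non-empty groups")
    factors = _retained_factors(scheme, exclude_factors)
    members = {g: list(ds.presences(group=g)) for g in groups}
    for g in groups:
        if not members[g]:
            raise DegenerateInputError(f"group {g!r} is empty")
    profiles = _profiles_from_counts(_group_counts(groups, members, ds, factors))
    O_dir, O_sym = _overlap_matrices(groups, profiles, factors, symmetrize)
    O_sym_pct = O_sym * 100.0
    np.fill_diagonal(O_sym_pct, 100.0)
    return OverlapReport(groups=groups, O_dir=O_dir, O_sym=O_sym_pct)


def resample_null(
    ds: Dataset,
    n_resamples: int = 1,
    seed: int = 0,
    scheme: FactorScheme | None = None,
    symmetrize: str = "mean",
    exclude_factors: Sequence[str] = EXCLUDED_DOWNSTREAM,
    groups: Sequence[str] | None = None,
) -> list[np.ndarray]:
    """Pairwise overlap matrices (percent) under group-label shuffling.

    Each resample permutes the group labels across all presence records
    while preserving the observed group sizes, then recomputes the full
    symmetrized overlap matrix. Deterministic under a fixed seed.
    """
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    scheme = scheme if scheme is not None else ds.scheme
    groups = tuple(groups) if groups is not None else ds.groups_present
    factors = _retained_factors(scheme, exclude_factors)
    pool: list[QuadratRecord] = []
    sizes: list[int] = []
    for g in groups:
        recs = list(ds.presences(group=g))
        pool.extend(recs)
        sizes.append(len(recs))
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    for _ in range(n_resamples):
        perm = rng.permutation(len(pool))
        members: dict[str, list[QuadratRecord]] = {}
        start = 0
        for g, size in zip(groups, sizes):
            members[g] = [pool[j] for j in perm[start : start + size]]
            start += size
        profiles = _profiles_from_counts(_group_counts(groups, members, ds, factors))
        _, O_sym = _overlap_matrices(groups, profiles, factors, symmetrize)
        O_sym_pct = O_sym * 100.0
        np.fill_diagonal(O_sym_pct, 100.0)
        out.append(O_sym_pct)
    return out


def overlap_significance(
    observed: OverlapReport | np.ndarray,
    null_matrices: Sequence[np.ndarray],
    groups: Sequence[str] | None = None,
    null_reduction: str = "first",
) -> OverlapReport:
    """Paired t-test between observed and resampled pairwise overlaps.

    The unordered-pair values (m = k(k-1)/2 of them; 6 for four groups) are
    extracted from the observed matrix and from the null matrix (the first
    resample by default, or their element-wise mean with
    ``null_reduction="mean"``). Reports mean and sample SD (n-1 denominator)
    of each set, the paired t = mean(d) / (sd(d)/sqrt(m)) with df = m - 1,
    and the two-sided p. With more than one resample a permutation p — the
    fraction of null mean overlaps <= the observed mean — is attached.
    """
    if len(null_matrices) < 1:
        raise ValidationError("need at least one null matrix")
    if isinstance(observed, OverlapReport):
        report = observed
    else:
        observed = np.asarray(observed, dtype=float)
        k = observed.shape[0]
        glabels = tuple(groups) if groups is not None else tuple(GROUPS[:k])
        report = OverlapReport(groups=glabels, O_dir=np.eye(k), O_sym=observed)
    obs_pairs = report.pair_values()
    m = obs_pairs.size

    if null_reduction == "first":
        null_matrix = np.asarray(null_matrices[0], dtype=float)
    elif null_reduction == "mean":
        null_matrix = np.mean([np.asarray(M, dtype=float) for M in null_matrices], axis=0)
    else:
        raise ValidationError(f"unknown null_reduction {null_reduction!r}")
    null_pairs = report.pair_values(null_matrix)

    d = obs_pairs - null_pairs
    sd_d = float(np.std(d, ddof=1))
    mean_d = float(np.mean(d))
    if sd_d == 0.0:
        if mean_d != 0.0:
            raise DegenerateInputError(
                "constant nonzero paired difference: t is undefined"
            )
        t, p = 0.0, 1.0
    else:
        t = mean_d / (sd_d / np.sqrt(m))
        p = float(2.0 * stats.t.sf(abs(t), df=m - 1))

    permutation_p = None
    if len(null_matrices) > 1:
        iu = np.triu_indices(len(report.groups), k=1)
        null_means = np.array(
            [float(np.asarray(M, dtype=float)[iu].mean()) for M in null_matrices]
        )
        obs_mean = float(obs_pairs.mean())
        permutation_p = float(
            (1 + np.sum(null_means <= obs_mean)) / (1 + len(null_means))
        )

    return OverlapReport(
        groups=report.groups,
        O_dir=report.O_dir,
        O_sym=report.O_sym,
        resampled=[np.asarray(M, dtype=float) for M in null_matrices],
        t_stat=float(t),
        df=m - 1,
        p_value=p,
        mean_obs=float(np.mean(obs_pairs)),
        sd_obs=float(np.std(obs_pairs, ddof=1)),
        mean_null=float(np.mean(null_pairs)),
        sd_null=float(np.std(null_pairs, ddof=1)),
        permutation_p=permutation_p,
    )
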