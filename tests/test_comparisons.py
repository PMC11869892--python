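"""Mann-Whitney, chi-square, and the ANOVA/rank-test gating."""

import itertools

import numpy as np
import pytest
from scipy import stats

from microniche import ValidationError, chi_square, compare_groups, mann_whitney
from microniche.records import Dataset, QuadratRecord


class TestMannWhitney:
    def test_identical_samples_give_zero(self):
        z, p = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert (z, p) == (0.0, 1.0)

    def test_fully_separated_small_samples(self):
        z, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert z == pytest.approx(-4.5 / np.sqrt(9 * 7 / 12), rel=1e-9)  # -1.964

    def test_antisymmetry(self):
        z1, _ = mann_whitney([1, 5, 3], [2, 8, 9, 4])
        z2, _ = mann_whitney([2, 8, 9, 4], [1, 5, 3])
        assert z1 == pytest.approx(-z2, rel=1e-12)

    def test_constant_pooled_sample(self):
        assert mann_whitney([7, 7], [7, 7, 7]) == (0.0, 1.0)

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=25), rng.normal(0.4, size=30)
        z, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (3, 4), (4, 4), (3, 5), (2, 6), (1, 7)])
    def test_agreement_with_exhaustive_permutation(self, n1, n2):
        """Normal-approximation p vs the exact permutation p over all label
        assignments of tie-free ranks; bounds measured with the oracle first
        (0.35 overall, 0.19 when both groups have >= 3 observations)."""
        N = n1 + n2
        vals = list(range(1, N + 1))

        def u_stat(xs, ys):
            r = stats.rankdata(xs + ys)
            return float(np.sum(r[: len(xs)])) - len(xs) * (len(xs) + 1) / 2

        bound = 0.19 if min(n1, n2) >= 3 else 0.35
        for idx in itertools.combinations(range(N), n1):
            x = [vals[i] for i in idx]
            y = [vals[i] for i in range(N) if i not in idx]
            _, p_norm = mann_whitney(x, y)
            dev = abs(u_stat(x, y) - n1 * n2 / 2)
            hits = sum(
                abs(u_stat([vals[i] for i in comb], [vals[i] for i in range(N) if i not in comb]) - n1 * n2 / 2)
                >= dev - 1e-9
                for comb in itertools.combinations(range(N), n1)
            )
            p_exact = hits / len(list(itertools.combinations(range(N), n1)))
            assert abs(p_norm - p_exact) <= bound


class TestChiSquare:
    def test_homogeneous_table(self):
        chi2, df, p = chi_square([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_worked_two_by_two(self):
        chi2, df, p = chi_square([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(20 / 3, rel=1e-9)
        assert df == 1

    def test_transpose_invariance(self):
        t = [[12, 5, 9], [3, 14, 6]]
        assert chi_square(t)[0] == pytest.approx(
            chi_square(np.transpose(t))[0], rel=1e-12
        )

    def test_small_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="expected count"):
            chi_square([[1, 9], [2, 8]])

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square([[0, 0], [0, 0]])


def _continuous_ds(scheme, x, y, grouping="sex"):
    """Presence-only dataset putting samples x, y on factor f1's raw scale."""
    records = []
    for j, v in enumerate(x):
        records.append(
            QuadratRecord(
                f"a{j}", "presence", "breeding", "M", 0.0, 0.0,
                {"f1": float(v), "f2": 1.0},
            )
        )
    season = "breeding" if grouping == "sex" else "non_breeding"
    sex = "F" if grouping == "sex" else "M"
    for j, v in enumerate(y):
        records.append(
            QuadratRecord(
                f"b{j}", "presence", season, sex, 0.0, 0.0,
                {"f1": float(v), "f2": 1.0},
            )
        )
    return Dataset(records, scheme)


class TestCompareGroups:
    def test_normal_data_dispatches_to_anova(self, tiny_scheme):
        # exact normal quantiles: passes any omnibus normality check
        q = stats.norm.ppf(np.linspace(0.005, 0.995, 200))
        ds = _continuous_ds(tiny_scheme, 15 + 2 * q, 15.5 + 2 * q)
        res = {r.variable: r for r in compare_groups(ds, "sex")}
        assert res["f1"].test == "anova"

    def test_skewed_data_dispatches_to_mann_whitney(self, tiny_scheme):
        rng = np.random.default_rng(1)
        ds = _continuous_ds(
            tiny_scheme, rng.lognormal(1, 1.2, 200), rng.lognormal(1, 1.2, 200)
        )
        res = {r.variable: r for r in compare_groups(ds, "sex")}
        assert res["f1"].test == "mann_whitney"

    def test_group_summaries_report_mean_sd_n(self, tiny_scheme):
        x = [10.0, 12.0, 14.0]
        y = [20.0, 22.0, 24.0, 26.0]
        ds = _continuous_ds(tiny_scheme, x, y)
        res = {r.variable: r for r in compare_groups(ds, "sex")}["f1"]
        mean, sd, n = res.group_summaries["M"]
        assert (mean, n) == (12.0, 3)
        assert sd == pytest.approx(np.std(x, ddof=1))
        assert sum(s[2] for s in res.group_summaries.values()) == 7

    def test_categorical_factor_uses_chi_square(self):
        from microniche import FactorDefinition, FactorScheme
        from conftest import build_dataset

        scheme = FactorScheme(
            (FactorDefinition("hab", "categorical", (), ("a", "b", "c")),)
        )
        ds = build_dataset(
            scheme,
            {"BM": {"hab": (10, 5, 5)}, "BF": {"hab": (5, 10, 5)}},
        )
        res = compare_groups(ds, "sex")
        assert res[0].test == "chi_square"
        chi2_ref, df_ref, p_ref = chi_square([[10, 5, 5], [5, 10, 5]])
        assert res[0].statistic == pytest.approx(chi2_ref)
        assert res[0].df == df_ref

    def test_empty_level_rejected(self, tiny_scheme):
        recs = [
            QuadratRecord(
                f"a{j}", "presence", "breeding", "M", 0.0, 0.0,
                {"f1": 1.0, "f2": 1.0},
            )
            for j in range(4)
        ]
        with pytest.raises(ValidationError):
            compare_groups(Dataset(recs, tiny_scheme), "sex")

    def test_type_i_error_of_dispatched_test(self, tiny_scheme):
        """Under identical generating distributions the dispatched test
        (ANOVA or Mann-Whitney, chosen per dataset by the gate) rejects at
        alpha = 0.05 within +/-0.02 over 2000 simulated datasets."""
        rng = np.random.default_rng(12345)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(15.0, 3.0, 25)
            y = rng.normal(15.0, 3.0, 25)
            ds = _continuous_ds(tiny_scheme, x, y)
            res = {r.variable: r for r in compare_groups(ds, "sex")}["f1"]
            rejections += res.p_value < 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.02
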