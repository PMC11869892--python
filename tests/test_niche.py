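"""Levins breadth and overlap, the resampling null, and the paired-t summary."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from microniche import (
    DegenerateInputError,
    ValidationError,
    group_niche_width,
    levins_overlap,
    levins_width,
    overlap_matrix,
    overlap_significance,
    resample_null,
    usage_profile,
)

# The published pairwise overlap matrices (percent) of the motivating
# pitviper survey: observed values and the single group-label resample,
# groups ordered BF, BM, NBF, NBM.
OBSERVED_PAIRS = (97.51, 84.75, 98.63, 53.86, 82.74, 60.96)
NULL_PAIRS = (82.08, 65.17, 83.72, 78.20, 96.48, 108.00)


def pairs_to_matrix(pairs, k=4):
    m = np.full((k, k), 100.0)
    iu = np.triu_indices(k, 1)
    m[iu] = pairs
    m.T[iu] = pairs
    return m


probvec = st.lists(
    st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=8
).map(lambda w: np.array(w) / np.sum(w))


class TestLevinsWidth:
    @pytest.mark.parametrize(
        "P,expected",
        [
            ((1 / 3, 1 / 3, 1 / 3), 3.0),
            ((1.0, 0.0, 0.0), 1.0),
            ((0.5, 0.3, 0.2), 1 / 0.38),
        ],
    )
    def test_examples(self, P, expected):
        assert levins_width(P) == pytest.approx(expected, rel=1e-9)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            levins_width((0.5, 0.6))

    @given(P=probvec)
    def test_bounds_and_permutation_invariance(self, P):
        """1 <= B <= R, with equality at point mass / uniform; B ignores order."""
        b = levins_width(P)
        assert 1 - 1e-9 <= b <= len(P) + 1e-9
        assert levins_width(P[::-1]) == pytest.approx(b, rel=1e-12)


class TestLevinsOverlap:
    def test_identical_profiles_give_one(self):
        assert levins_overlap((0.5, 0.3, 0.2), (0.5, 0.3, 0.2)) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert levins_overlap((1, 0, 0), (0, 0.5, 0.5)) == 0.0

    def test_directional_asymmetry(self):
        assert levins_overlap((1, 0, 0), (0.5, 0.5, 0)) == pytest.approx(0.5)
        assert levins_overlap((0.5, 0.5, 0), (1, 0, 0)) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            levins_overlap((0.5, 0.5), (1 / 3, 1 / 3, 1 / 3))

    @given(Pi=probvec, Pk=probvec)
    def test_nonnegative_and_jointly_permutation_invariant(self, Pi, Pk):
        n = min(Pi.size, Pk.size)
        Pi = Pi[:n] / Pi[:n].sum()
        Pk = Pk[:n] / Pk[:n].sum()
        o = levins_overlap(Pi, Pk)
        assert o >= 0
        assert levins_overlap(Pi[::-1], Pk[::-1]) == pytest.approx(o, rel=1e-12)

    @given(Pi=probvec, Pk=probvec)
    def test_symmetry_when_concentrations_match(self, Pi, Pk):
        """O_ik = O_ki whenever sum Pi^2 = sum Pk^2."""
        n = min(Pi.size, Pk.size)
        Pi = Pi[:n] / Pi[:n].sum()
        Pk = Pk[:n] / Pk[:n].sum()
        if abs(np.sum(Pi**2) - np.sum(Pk**2)) < 1e-12:
            assert levins_overlap(Pi, Pk) == pytest.approx(
                levins_overlap(Pk, Pi), rel=1e-9
            )


class TestUsageProfileAndWidth:
    def test_point_mass(self, build):
        ds = build({"BM": {"f1": (0, 10, 0)}})
        np.testing.assert_allclose(usage_profile(ds, "BM", "f1").P, (0, 1, 0))

    def test_proportions(self, build):
        ds = build({"BM": {"f1": (5, 3, 2)}})
        np.testing.assert_allclose(usage_profile(ds, "BM", "f1").P, (0.5, 0.3, 0.2))

    def test_empty_group_is_degenerate(self, build):
        ds = build({"BM": {"f1": (1, 0, 0)}})
        with pytest.raises(DegenerateInputError):
            usage_profile(ds, "NBF", "f1")

    def test_uniform_group_aggregate_is_three(self, build):
        ds = build({"BM": {"f1": (4, 4, 4), "f2": (4, 4, 4)}})
        res = group_niche_width(ds, "BM", exclude_factors=())
        assert res.aggregate_B == pytest.approx(3.0)

    def test_concentrated_group_aggregate_is_one(self, build):
        ds = build({"BM": {"f1": (12, 0, 0), "f2": (0, 12, 0)}})
        res = group_niche_width(ds, "BM", exclude_factors=())
        assert res.aggregate_B == pytest.approx(1.0)


class TestOverlapMatrix:
    def test_identical_groups_full_overlap(self, build):
        ds = build(
            {
                "BM": {"f1": (2, 2, 2), "f2": (3, 2, 1)},
                "BF": {"f1": (2, 2, 2), "f2": (3, 2, 1)},
            }
        )
        rep = overlap_matrix(ds, exclude_factors=())
        assert rep.O_sym[0, 1] == pytest.approx(100.0)
        np.testing.assert_allclose(np.diag(rep.O_dir), 1.0)

    def test_disjoint_groups_zero_overlap(self, build):
        ds = build(
            {
                "BM": {"f1": (6, 0, 0), "f2": (6, 0, 0)},
                "BF": {"f1": (0, 6, 0), "f2": (0, 0, 6)},
            }
        )
        rep = overlap_matrix(ds, exclude_factors=())
        assert rep.O_sym[0, 1] == 0.0

    def test_symmetrization_conventions(self, build):
        ds = build(
            {
                "BM": {"f1": (6, 0, 0), "f2": (6, 0, 0)},
                "BF": {"f1": (3, 3, 0), "f2": (3, 3, 0)},
            }
        )
        mean_rep = overlap_matrix(ds, symmetrize="mean", exclude_factors=())
        min_rep = overlap_matrix(ds, symmetrize="min", exclude_factors=())
        # O(BM->ref) = 0.5, O(BF->ref) = 1.0 per factor
        assert mean_rep.O_sym[0, 1] == pytest.approx(75.0)
        assert min_rep.O_sym[0, 1] == pytest.approx(50.0)


class TestResampleNull:
    def test_same_seed_reproduces(self, build):
        ds = build(
            {
                "BM": {"f1": (3, 2, 1), "f2": (2, 2, 2)},
                "BF": {"f1": (1, 2, 3), "f2": (4, 1, 1)},
            }
        )
        a = resample_null(ds, n_resamples=3, seed=5)
        b = resample_null(ds, n_resamples=3, seed=5)
        for m1, m2 in zip(a, b):
            np.testing.assert_array_equal(m1, m2)

    def test_identity_permutation_recovers_observed(self, build):
        """If every group keeps exactly its own records, the resampled matrix
        equals the observed one (checked by exhausting seeds on a tiny case
        where the two groups are internally homogeneous)."""
        ds = build(
            {
                "BM": {"f1": (2, 0, 0), "f2": (2, 0, 0)},
                "BF": {"f1": (2, 0, 0), "f2": (2, 0, 0)},
            }
        )
        obs = overlap_matrix(ds, exclude_factors=())
        null = resample_null(ds, n_resamples=1, seed=0, exclude_factors=())
        np.testing.assert_allclose(null[0], obs.O_sym)

    def test_group_sizes_preserved(self, build):
        ds = build(
            {
                "BM": {"f1": (5, 1, 0), "f2": (6, 0, 0)},
                "NBF": {"f1": (0, 1, 1), "f2": (2, 0, 0)},
            }
        )
        # sizes preserved => every resampled profile uses 6 and 2 records:
        # overlap values must come from proportion vectors with denominators 6, 2
        nulls = resample_null(ds, n_resamples=5, seed=1, exclude_factors=())
        assert len(nulls) == 5
        for m in nulls:
            assert m.shape == (2, 2)

    def test_zero_resamples_rejected(self, build):
        ds = build({"BM": {"f1": (1, 1, 0), "f2": (2, 0, 0)}})
        with pytest.raises(ValidationError):
            resample_null(ds, n_resamples=0, seed=0)


class TestOverlapSignificance:
    def test_published_matrices_reproduce_summary(self):
        """The six observed and six resampled pair overlaps reproduce the
        reported mean +/- SD pairs and |t| = 0.533 at df = 5, p = 0.617."""
        rep = overlap_significance(
            pairs_to_matrix(OBSERVED_PAIRS), [pairs_to_matrix(NULL_PAIRS)]
        )
        assert rep.mean_obs == pytest.approx(79.74, abs=0.005)
        assert rep.sd_obs == pytest.approx(18.60, abs=0.005)
        assert rep.mean_null == pytest.approx(85.61, abs=0.005)
        assert rep.sd_null == pytest.approx(14.89, abs=0.005)
        assert rep.abs_t == pytest.approx(0.533, abs=0.0005)
        assert rep.df == 5
        assert rep.p_value == pytest.approx(0.617, abs=0.0005)

    def test_agrees_with_scipy_paired_t(self):
        rep = overlap_significance(
            pairs_to_matrix(OBSERVED_PAIRS), [pairs_to_matrix(NULL_PAIRS)]
        )
        t_ref, p_ref = stats.ttest_rel(OBSERVED_PAIRS, NULL_PAIRS)
        assert rep.t_stat == pytest.approx(float(t_ref), rel=1e-12)
        assert rep.p_value == pytest.approx(float(p_ref), rel=1e-12)

    def test_null_equal_to_observed(self):
        m = pairs_to_matrix(OBSERVED_PAIRS)
        rep = overlap_significance(m, [m.copy()])
        assert rep.t_stat == 0.0
        assert rep.p_value == 1.0

    def test_three_pair_toy(self):
        """Differences (1, 2, 3) give t = 2 / (1/sqrt(3)) = 3.4641, df = 2."""
        obs = pairs_to_matrix((11.0, 12.0, 13.0), k=3)
        null = pairs_to_matrix((10.0, 10.0, 10.0), k=3)
        rep = overlap_significance(obs, [null], groups=("A", "B", "C"))
        assert rep.t_stat == pytest.approx(2 / (1 / np.sqrt(3)), rel=1e-9)
        assert rep.df == 2

    def test_constant_nonzero_difference_is_degenerate(self):
        obs = pairs_to_matrix((11.0, 12.0, 13.0), k=3)
        null = pairs_to_matrix((10.0, 11.0, 12.0), k=3)
        with pytest.raises(DegenerateInputError):
            overlap_significance(obs, [null], groups=("A", "B", "C"))
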