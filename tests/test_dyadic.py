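"""Permutation tests on distance matrices, with exhaustive oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from scentmhc.dyadic import (TestResult, bonferroni_alpha, mantel,
                             partial_mantel, partial_pearson,
                             partial_spearman_rect)
from scentmhc.dyads import DyadMatrix


def sym(n, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, size=(n, n))
    m = np.abs(x - x.T)
    np.fill_diagonal(m, 0.0)
    return m


def residual_corr_oracle(x, y, covs):
    """Independent partial correlation: residualize via lstsq, correlate."""
    z = np.column_stack([np.ones(len(x))] + [np.asarray(c, float) for c in covs])
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestBonferroni:
    def test_published_family_thresholds(self):
        assert round(bonferroni_alpha(0.05, 6), 3) == 0.008
        assert round(bonferroni_alpha(0.05, 9), 4) == 0.0056

    def test_single_test_identity(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.0, 3)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestPartialPearson:
    def test_matches_textbook_single_covariate_formula(self):
        rng = np.random.default_rng(1)
        x, y, z = rng.normal(size=(3, 30))
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert partial_pearson(x, y, z) == pytest.approx(expected, abs=1e-10)

    def test_self_association_with_orthogonal_covariate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        z = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])  # orthogonal to trend
        assert partial_pearson(x, x, z) == pytest.approx(1.0)

    def test_response_equal_to_covariate_is_degenerate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        z = rng.normal(size=10)
        with pytest.raises(ValueError, match="constant"):
            partial_pearson(x, z, z)

    def test_multiple_covariates_match_residual_oracle(self):
        rng = np.random.default_rng(3)
        x, y, z1, z2 = rng.normal(size=(4, 25))
        got = partial_pearson(x, y, [z1, z2])
        assert got == pytest.approx(residual_corr_oracle(x, y, [z1, z2]), abs=1e-10)

    def test_no_covariate_reduces_to_pearson(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 12))
        assert partial_pearson(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_length_and_size_checks(self):
        with pytest.raises(ValueError, match="length"):
            partial_pearson([1, 2, 3, 4], [1, 2, 3], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="at least 4"):
            partial_pearson([1, 2, 3], [1, 2, 3], [0, 1, 0])


def exhaustive_partial_mantel(a, b, covs, tail="two-sided"):
    """Exact permutation distribution over all n! relabelings of A."""
    n = a.shape[0]
    iu = np.tril_indices(n, k=-1)
    bu = b[iu]
    cu = [c[iu] for c in covs]
    obs = residual_corr_oracle(a[iu], bu, cu)
    stats = []
    for perm in itertools.permutations(range(n)):
        ap = a[np.ix_(perm, perm)]
        stats.append(residual_corr_oracle(ap[iu], bu, cu))
    stats = np.array(stats)
    if tail == "two-sided":
        p = np.mean(np.abs(stats) >= abs(obs) - 1e-12)
    else:
        p = np.mean(stats >= obs - 1e-12)
    return obs, p


class TestPartialMantel:
    def test_self_association_minimal_p(self):
        m = sym(8, seed=5)
        a = DyadMatrix.square(m, [f"i{k}" for k in range(8)])
        c = DyadMatrix.square(sym(8, seed=6), a.row_ids)
        res = partial_mantel(a, a, c, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_monte_carlo_p_matches_exhaustive_five_labels(self):
        rng = np.random.default_rng(7)
        am, bm, cm = sym(5, 10), sym(5, 11), sym(5, 12)
        ids = list("abcde")
        a = DyadMatrix.square(am, ids)
        b = DyadMatrix.square(bm, ids)
        c = DyadMatrix.square(cm, ids)
        obs_ex, p_ex = exhaustive_partial_mantel(am, bm, [cm])
        res = partial_mantel(a, b, c, n_perm=10_000, seed=3)
        assert res.statistic == pytest.approx(obs_ex, abs=1e-10)
        se = np.sqrt(p_ex * (1 - p_ex) / 10_000)
        assert abs(res.p_value - p_ex) <= 3 * se + 1 / 10_001

    def test_observed_statistic_symmetric_in_a_and_b(self):
        ids = [f"i{k}" for k in range(7)]
        a = DyadMatrix.square(sym(7, 13), ids)
        b = DyadMatrix.square(sym(7, 14), ids)
        c = DyadMatrix.square(sym(7, 15), ids)
        r1 = partial_mantel(a, b, c, n_perm=99, seed=1).statistic
        r2 = partial_mantel(b, a, c, n_perm=99, seed=1).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_statistic_invariant_under_common_relabeling(self):
        ids = [f"i{k}" for k in range(6)]
        am, bm = sym(6, 16), sym(6, 17)
        a = DyadMatrix.square(am, ids)
        b = DyadMatrix.square(bm, ids)
        perm = [3, 1, 5, 0, 4, 2]
        ids_p = [ids[k] for k in perm]
        ap = DyadMatrix.square(am[np.ix_(perm, perm)], ids_p)
        bp = DyadMatrix.square(bm[np.ix_(perm, perm)], ids_p)
        r1 = mantel(a, b, n_perm=49, seed=2).statistic
        r2 = mantel(ap, bp, n_perm=49, seed=2).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_covariate_reduces_to_simple_mantel(self):
        ids = [f"i{k}" for k in range(8)]
        a = DyadMatrix.square(sym(8, 18), ids)
        b = DyadMatrix.square(sym(8, 19), ids)
        # an all-equal off-diagonal covariate carries no information
        cm = np.ones((8, 8)) - np.eye(8)
        c = DyadMatrix.square(cm, ids)
        r_partial = partial_mantel(a, b, c, n_perm=99, seed=3).statistic
        r_simple = mantel(a, b, n_perm=99, seed=3).statistic
        assert r_partial == pytest.approx(r_simple, abs=1e-10)

    def test_constant_chemical_matrix_is_an_error(self):
        ids = list("abcd")
        cm = np.ones((4, 4)) - np.eye(4)
        a = DyadMatrix.square(cm, ids)
        b = DyadMatrix.square(sym(4, 20), ids)
        with pytest.raises(ValueError, match="constant"):
            partial_mantel(a, b, None, n_perm=9, seed=0)

    def test_p_value_floor_and_seed_determinism(self):
        ids = [f"i{k}" for k in range(6)]
        a = DyadMatrix.square(sym(6, 21), ids)
        b = DyadMatrix.square(sym(6, 22), ids)
        r1 = mantel(a, b, n_perm=99, seed=9)
        r2 = mantel(a, b, n_perm=99, seed=9)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 100


def exhaustive_rect_spearman(am, bm, cm, tail="two-sided"):
    """Exact dyad-entry permutation null for a tiny rectangular problem."""
    au, bu, cu = am.ravel(), bm.ravel(), cm.ravel()
    ra, rb, rc = rankdata(au), rankdata(bu), rankdata(cu)
    obs = residual_corr_oracle(ra, rb, [rc])
    stats = []
    for perm in itertools.permutations(range(au.size)):
        stats.append(residual_corr_oracle(ra[list(perm)], rb, [rc]))
    stats = np.array(stats)
    if tail == "two-sided":
        p = np.mean(np.abs(stats) >= abs(obs) - 1e-12)
    else:
        p = np.mean(stats >= obs - 1e-12)
    return obs, p


class TestPartialSpearmanRect:
    def _mats(self, am, bm, cm):
        rows = [f"m{k}" for k in range(am.shape[0])]
        cols = [f"f{k}" for k in range(am.shape[1])]
        return (DyadMatrix.rect(am, rows, cols), DyadMatrix.rect(bm, rows, cols),
                DyadMatrix.rect(cm, rows, cols))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(23)
        am = rng.uniform(0.1, 2.0, size=(4, 5))
        bm = np.exp(am)  # strictly increasing transform
        cm = rng.uniform(0, 1, size=(4, 5))
        a, b, c = self._mats(am, bm, cm)
        res = partial_spearman_rect(a, b, c, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_tied_entries_use_average_ranks(self):
        am = np.array([[1.0, 1.0, 2.0], [3.0, 2.0, 4.0]])
        bm = np.array([[1.0, 2.0, 2.0], [3.0, 4.0, 4.0]])
        cm = np.zeros((2, 3)) + np.array([[0.3, 0.1, 0.7], [0.2, 0.9, 0.5]])
        a, b, c = self._mats(am, bm, cm)
        res = partial_spearman_rect(a, b, c, n_perm=99, seed=1)
        expected = residual_corr_oracle(rankdata(am.ravel()), rankdata(bm.ravel()),
                                        [rankdata(cm.ravel())])
        assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_constant_chemical_matrix_reported(self):
        am = np.full((2, 3), 1.5)
        bm = np.arange(6.0).reshape(2, 3)
        cm = np.ones((2, 3)) * 0.2
        a, b, c = self._mats(am, bm, cm)
        with pytest.raises(ValueError, match="constant"):
            partial_spearman_rect(a, b, c, n_perm=9, seed=0)

    def test_monte_carlo_matches_exhaustive_2x2(self):
        rng = np.random.default_rng(24)
        am = rng.uniform(size=(2, 2))
        bm = rng.uniform(size=(2, 2))
        cm = rng.uniform(size=(2, 2))
        obs_ex, p_ex = exhaustive_rect_spearman(am, bm, cm)
        a, b, c = self._mats(am, bm, cm)
        res = partial_spearman_rect(a, b, c, n_perm=5_000, seed=5)
        assert res.statistic == pytest.approx(obs_ex, abs=1e-10)
        se = np.sqrt(p_ex * (1 - p_ex) / 5_000)
        assert abs(res.p_value - p_ex) <= 3 * se + 1 / 5_001

    def test_restricted_null_runs_and_differs_in_scheme(self):
        rng = np.random.default_rng(25)
        am = rng.uniform(size=(5, 6))
        bm = rng.uniform(size=(5, 6))
        cm = rng.uniform(size=(5, 6))
        a, b, c = self._mats(am, bm, cm)
        full = partial_spearman_rect(a, b, c, n_perm=199, seed=6)
        restr = partial_spearman_rect(a, b, c, n_perm=199, seed=6, restricted=True)
        assert full.statistic == pytest.approx(restr.statistic)
        assert 0 < restr.p_value <= 1


class TestResultContract:
    def test_minimum_p_and_statistic_bound_enforced(self):
        with pytest.raises(AssertionError):
            TestResult("Mantel r", 0.5, 0.0, 99, "two-sided", 0, 10)
        with pytest.raises(AssertionError):
            TestResult("Mantel r", 1.5, 0.5, 99, "two-sided", 0, 10)

    def test_significance_flag_uses_adjusted_alpha(self):
        r = TestResult("Mantel r", 0.5, 0.004, 999, "two-sided", 0, 10,
                       adjusted_alpha=0.0056)
        assert r.significant is True
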