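"""Power-law scaling fits and Mann-Whitney comparisons."""

import itertools

import numpy as np
import pytest
from scipy import stats

import foramtracer as ft
from foramtracer.allometry import PowerLawScaling
from foramtracer.errors import InvalidInputError, SingularFitError


class TestPowerLawFit:
    def test_exact_isometry(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        fit = ft.fit_power_law(x, 2.0 * x)
        assert fit.a == pytest.approx(2.0, rel=1e-10)
        assert fit.b == pytest.approx(1.0, rel=1e-10)
        assert fit.se_b == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_three_quarters_exponent(self):
        x = np.geomspace(0.5, 20.0, 7)
        fit = ft.fit_power_law(x, 3.0 * x ** 0.75)
        assert fit.a == pytest.approx(3.0, rel=1e-10)
        assert fit.b == pytest.approx(0.75, rel=1e-10)

    def test_noisy_recovery_within_two_se(self):
        rng = np.random.default_rng(7)
        x = np.repeat([0.8, 2.5, 6.0], 6)
        y = 0.05 * x ** 0.57 * np.exp(rng.normal(0.0, 0.2, x.size))
        fit = ft.fit_power_law(x, y)
        assert abs(fit.b - 0.57) < 2 * fit.se_b
        assert fit.ci_b[0] < fit.b < fit.ci_b[1]

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        x = np.geomspace(0.3, 9.0, 12)
        y = 1.7 * x ** 0.6 * np.exp(rng.normal(0, 0.1, 12))
        k = 3.5
        base = ft.fit_power_law(x, y)
        scaled = ft.fit_power_law(k * x, y)
        assert scaled.b == pytest.approx(base.b, abs=1e-10)
        assert scaled.a == pytest.approx(base.a * k ** (-base.b), rel=1e-9)

    def test_estimator_predict_and_score(self):
        x = np.geomspace(1, 10, 8)
        est = PowerLawScaling().fit(x, 2.0 * x ** 0.9)
        assert est.predict([4.0])[0] == pytest.approx(2.0 * 4.0 ** 0.9, rel=1e-9)
        assert est.score(x, 2.0 * x ** 0.9) == pytest.approx(1.0)
        assert est.get_params() == {"ci_level": 0.95}

    @pytest.mark.parametrize("x, y, err", [
        ([1, 2], [1, 2], InvalidInputError),            # too few points
        ([1, -2, 3], [1, 2, 3], InvalidInputError),     # non-positive predictor
        ([1, 2, 3], [1, 0, 3], InvalidInputError),      # non-positive response
        ([2, 2, 2, 2], [1, 2, 3, 4], SingularFitError),  # constant predictor
    ])
    def test_fit_errors(self, x, y, err):
        with pytest.raises(err):
            ft.fit_power_law(x, y)


class TestClassifyScaling:
    @pytest.mark.parametrize("b, ci, expected", [
        (1.0, (0.9, 1.1), "isometric"),
        (0.57, (0.5, 0.64), "hypoallometric"),
        (1.3, (1.1, 1.5), "hyperallometric"),
        (0.99, (0.8, 1.0), "isometric"),  # boundary: 1 inside the closed interval
    ])
    def test_regimes(self, b, ci, expected):
        fit = ft.ScalingFit(response="Y", predictor="X", a=1.0, b=b, se_b=0.05,
                            ci_b=ci, n=10, r_squared=0.9, equation="")
        assert ft.classify_scaling(fit) == expected

    def test_invariant_under_unit_rescaling(self):
        rng = np.random.default_rng(2)
        x = np.geomspace(0.5, 8, 15)
        y = 0.3 * x ** 0.75 * np.exp(rng.normal(0, 0.15, 15))
        a = ft.classify_scaling(ft.fit_power_law(x, y))
        b = ft.classify_scaling(ft.fit_power_law(1000 * x, 1e-3 * y))
        assert a == b


def _enumeration_oracle(x1, x2):
    """Exact two-sided p by brute force over all group relabellings,
    computing U from pairwise comparisons (no ranks)."""
    pooled = list(x1) + list(x2)
    n1, n2 = len(x1), len(x2)

    def u_of(group):
        rest = list(pooled)
        for v in group:
            rest.remove(v)
        return sum(1.0 if a > b else 0.5 if a == b else 0.0
                   for a in group for b in rest)

    u_obs = u_of(list(x1))
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    assignments = list(itertools.combinations(range(n1 + n2), n1))
    hits = sum(1 for idx in assignments
               if abs(u_of([pooled[i] for i in idx]) - mu) >= dev - 1e-12)
    return u_obs, hits / len(assignments)


class TestMannWhitney:
    def test_identical_tied_groups_give_p_one(self):
        res = ft.mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "exact"

    def test_fully_separated_small_groups(self):
        res = ft.mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.U_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 rank assignments

    def test_symmetry_under_group_swap(self):
        g1, g2 = [3.2, 5.0, 4.4, 4.4], [4.1, 6.3, 5.9]
        a = ft.mann_whitney(g1, g2)
        b = ft.mann_whitney(g2, g1)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.U_statistic + b.U_statistic == a.n1 * a.n2

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            ft.mann_whitney([], [1.0])

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(9)
        for n1, n2 in [(3, 3), (4, 5), (6, 6)]:
            x1 = rng.normal(0, 1, n1)
            x2 = rng.normal(0.5, 1, n2)
            ours = ft.mann_whitney(x1, x2)
            ref = stats.mannwhitneyu(x1, x2, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(4)
        for n1, n2 in [(2, 3), (3, 3), (4, 4), (5, 3)]:
            x1 = rng.integers(0, 4, n1).astype(float)  # heavy ties
            x2 = rng.integers(0, 4, n2).astype(float)
            ours = ft.mann_whitney(x1, x2)
            u_ref, p_ref = _enumeration_oracle(x1, x2)
            assert ours.U_statistic == pytest.approx(u_ref)
            assert ours.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_normal_branch_close_to_exact_at_threshold(self):
        rng = np.random.default_rng(12)
        x1 = rng.normal(0, 1, 15)
        x2 = rng.normal(0.8, 1, 15)
        exact = ft.mann_whitney(x1, x2)  # 225 <= 400 -> exact
        approx = ft.mann_whitney(x1, x2, exact_limit=1)
        assert approx.method == "normal"
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)


def test_standard_fit_set_keys(incorporation_table):
    per_ind = ft.per_individual_table(incorporation_table)
    fits = ft.standard_fits(per_ind)
    assert set(fits) == {
        "toc_per_ind~dw_per_ind", "tn_per_ind~dw_per_ind",
        "pc_per_ind~dw_per_ind", "pn_per_ind~dw_per_ind",
        "pc_per_ind~toc_per_ind", "pn_per_ind~tn_per_ind"}
    for fit in fits.values():
        assert fit.n == per_ind.shape[0]
        assert fit.ci_b[0] < fit.b < fit.ci_b[1]
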