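"""Kolmogorov-Smirnov machinery, Q-Q data and group reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from genehurst.exceptions import (
    DegenerateSampleError,
    DomainError,
    InputError,
)
from genehurst.normality import (
    GroupComparison,
    group_normality,
    ks_pvalue,
    ks_statistic,
    ks_test_family,
    qq_normal,
)


def brute_force_sup_gap(sample, cdf, n_grid=20_001):
    """Independent oracle: sup |ECDF - F| over a dense grid augmented with
    the jump points and their left limits."""
    x = np.sort(np.asarray(sample, dtype=float))
    lo, hi = x[0] - 1.0, x[-1] + 1.0
    grid = np.concatenate([np.linspace(lo, hi, n_grid), x, x - 1e-12])
    ecdf = np.searchsorted(x, grid, side="right") / x.size
    return float(np.max(np.abs(ecdf - cdf(grid))))


class TestKSStatistic:
    def test_single_point_uniform(self):
        assert ks_statistic([0.5], sps.uniform(0, 1).cdf) == pytest.approx(0.5)

    def test_two_quantiles(self):
        f = sps.norm(0, 1)
        sample = [f.ppf(0.25), f.ppf(0.75)]
        assert ks_statistic(sample, f.cdf) == pytest.approx(0.25)

    def test_degenerate_cdf_attains_one(self):
        assert ks_statistic([1.0, 2.0, 3.0], lambda x: np.zeros_like(x)) == 1.0

    def test_empty_sample(self):
        with pytest.raises(InputError):
            ks_statistic([], sps.norm.cdf)

    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=20),
           st.sampled_from([0.5, 1.0, 2.0]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_grid(self, sample, scale):
        """D equals the dense-grid sup-gap oracle (ties included)."""
        cdf = sps.norm(0, scale).cdf
        d = ks_statistic(sample, cdf)
        assert d == pytest.approx(brute_force_sup_gap(sample, cdf), abs=1e-6)

    def test_ties_collapse_to_single_jump(self):
        # four tied points: ECDF jumps by 4/4 at 0.5
        d = ks_statistic([0.5] * 4, sps.uniform(0, 1).cdf)
        assert d == pytest.approx(0.5)


class TestKSPvalue:
    def test_perfect_fit(self):
        assert ks_pvalue(0.0, 10) == 1.0

    def test_maximal_discrepancy(self):
        assert ks_pvalue(1.0, 100) < 1e-8

    def test_classical_critical_point(self):
        """lambda = 1.36 is the classical 5% point of the Kolmogorov law."""
        n = 100
        d = 1.36 / (np.sqrt(n) + 0.12 + 0.11 / np.sqrt(n))
        # independent oracle: direct summation of the alternating series
        direct = 2.0 * sum(
            (-1) ** (k - 1) * np.exp(-2.0 * k * k * 1.36**2) for k in range(1, 200)
        )
        p = ks_pvalue(d, n)
        assert p == pytest.approx(direct, abs=1e-9)
        assert p == pytest.approx(0.05, abs=0.002)

    def test_agrees_with_scipy_kolmogorov_law(self):
        for lam in (0.8, 1.0, 1.36, 1.8):
            n = 400
            d = lam / (np.sqrt(n) + 0.12 + 0.11 / np.sqrt(n))
            assert ks_pvalue(d, n) == pytest.approx(sps.kstwobign.sf(lam), abs=1e-8)

    def test_monotone_in_d_and_n(self):
        ds = np.linspace(0.01, 0.9, 40)
        ps = [ks_pvalue(d, 50) for d in ds]
        assert np.all(np.diff(ps) < 0)
        assert ks_pvalue(0.2, 200) < ks_pvalue(0.2, 20)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            ks_pvalue(1.5, 10)


class TestKSTestFamily:
    def test_normal_null_accepted(self, rng):
        sample = rng.normal(0.6, 0.05, 500)
        res = ks_test_family(sample, "normal")
        assert res.accepted and res.p >= 0.05
        assert res.estimated_params["mean"] == pytest.approx(0.6, abs=0.01)

    def test_exponential_sample_rejects_normal(self, rng):
        sample = rng.exponential(1.0, 500)
        assert not ks_test_family(sample, "normal").accepted

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            ks_test_family([0.5] * 20, "normal")

    def test_negative_values_rejected_for_positive_families(self):
        sample = np.linspace(-1, 1, 20)
        for family in ("exponential", "poisson"):
            with pytest.raises(DomainError):
                ks_test_family(sample, family)

    def test_poisson_integerization_flagged(self, rng):
        sample = rng.normal(0.6, 0.05, 100)
        res = ks_test_family(sample, "poisson")
        assert res.integerized
        assert res.estimated_params["rate"] == pytest.approx(60, abs=3)

    def test_small_sample_rejected(self):
        with pytest.raises(InputError):
            ks_test_family([0.1, 0.2, 0.3], "normal")

    def test_lilliefors_mc_less_conservative(self, rng):
        """The Monte-Carlo corrected p is below the plug-in asymptotic p."""
        sample = rng.normal(0.0, 1.0, 200)
        plug_in = ks_test_family(sample, "normal").p
        corrected = ks_test_family(sample, "normal", lilliefors_mc=200, seed=1).p
        assert corrected < plug_in


class TestQQNormal:
    def test_blom_positions_small_sample(self):
        qq = qq_normal([-1.0, 0.0, 1.0])
        expected = (np.array([1, 2, 3]) - 0.375) / 3.25
        np.testing.assert_allclose(qq.plotting_positions, expected)
        assert qq.theoretical_quantiles[1] == pytest.approx(0.0)  # sample mean

    def test_affine_equivariance(self, rng):
        sample = rng.normal(0, 1, 50)
        base = qq_normal(sample)
        shifted = qq_normal(3.0 + 2.0 * sample)
        np.testing.assert_allclose(
            shifted.theoretical_quantiles, 3.0 + 2.0 * base.theoretical_quantiles,
            rtol=1e-10,
        )

    def test_linearity_under_normality(self, rng):
        sample = rng.normal(0, 1, 1000)
        qq = qq_normal(sample)
        r = np.corrcoef(qq.ordered_sample, qq.theoretical_quantiles)[0, 1]
        assert r**2 >= 0.99

    def test_output_invariants(self, rng):
        sample = rng.uniform(0, 1, 37)
        qq = qq_normal(sample)
        assert len(qq.ordered_sample) == len(qq.plotting_positions) == 37
        assert np.all(np.diff(qq.ordered_sample) >= 0)
        assert np.all(np.diff(qq.plotting_positions) > 0)
        assert np.all((qq.plotting_positions > 0) & (qq.plotting_positions < 1))

    def test_degenerate_sample(self):
        with pytest.raises(DegenerateSampleError):
            qq_normal([1.0, 1.0, 1.0])


class TestGroupNormality:
    def test_mirrors_group_contrast(self):
        """Essential ~ normal vs full-set ~ contaminated by a bimodal
        nonessential majority: essential p should beat full p in most
        replicates (scaled-down version of the full acceptance sweep)."""
        wins = 0
        reps = 20
        for r in range(reps):
            g = np.random.default_rng(5000 + r)
            ess = g.normal(0.62, 0.04, 300)
            comp = g.integers(0, 2, 2700)
            non = np.where(
                comp == 0, g.normal(0.55, 0.03, 2700), g.normal(0.72, 0.05, 2700)
            )
            reports, cmp_ = group_normality(
                {
                    "full_gene_set": np.concatenate([ess, non]),
                    "essential": ess,
                    "nonessential": non,
                },
                families=("normal",),
            )
            assert isinstance(cmp_, GroupComparison)
            wins += cmp_.essential_more_normal_than_full
        assert wins >= int(0.9 * reps)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            group_normality({"full_gene_set": [0.5] * 20, "essential": []})

    def test_missing_full_set_for_comparison(self):
        with pytest.raises(InputError):
            group_normality({"essential": np.linspace(0.4, 0.8, 30)})

    def test_one_report_per_group_and_family(self, rng):
        h = rng.normal(0.6, 0.05, 60)
        reports, _ = group_normality(
            {"full_gene_set": h, "essential": h[:20]},
            families=("normal", "uniform"),
        )
        assert len(reports) == 2
        for rep in reports:
            assert [r.family for r in rep.results] == ["normal", "uniform"]
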