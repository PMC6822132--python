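import numpy as np
import pytest

from fishbeta.richness import (
    bootstrap_ci,
    chao_estimate,
    completeness,
    incidence_estimate,
    rarefaction_curve,
)


class TestChaoEstimate:
    def test_no_singletons_returns_observed(self):
        for variant in ("classic", "bias_corrected"):
            assert chao_estimate(10, 0, 3, variant) == 10.0
            assert chao_estimate(10, 0, 0, variant) == 10.0

    def test_classic_hand_value(self):
        assert chao_estimate(4, 2, 1, "classic") == pytest.approx(6.0)

    def test_bias_corrected_branch_when_no_doubletons(self):
        # classic falls back to the bias-corrected form at q2 = 0
        assert chao_estimate(5, 3, 0, "classic") == pytest.approx(8.0)
        assert chao_estimate(5, 3, 0, "bias_corrected") == pytest.approx(8.0)

    def test_classic_dominates_bias_corrected(self):
        for q1 in range(0, 12):
            for q2 in range(1, 8):
                s = q1 + q2 + 5
                assert chao_estimate(s, q1, q2, "classic") >= chao_estimate(
                    s, q1, q2, "bias_corrected"
                ) - 1e-12

    def test_estimate_never_below_observed(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            q1, q2 = rng.integers(0, 10, 2)
            s = int(q1 + q2 + rng.integers(0, 20))
            if s == 0:
                continue
            assert chao_estimate(s, int(q1), int(q2)) >= s

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            chao_estimate(-1, 0, 0)
        with pytest.raises(ValueError):
            chao_estimate(3, 3, 1)


class TestChaoAgainstSkbio:
    def test_matches_reference_implementation(self):
        pytest.importorskip("skbio")
        from skbio.diversity.alpha import chao1

        rng = np.random.default_rng(9)
        for _ in range(50):
            counts = rng.poisson(1.2, size=40)
            if counts.sum() == 0:
                continue
            s = int((counts > 0).sum())
            q1, q2 = int((counts == 1).sum()), int((counts == 2).sum())
            assert chao_estimate(s, q1, q2, "classic") == pytest.approx(
                chao1(counts, bias_corrected=False)
            )
            assert chao_estimate(s, q1, q2, "bias_corrected") == pytest.approx(
                chao1(counts, bias_corrected=True)
            )


class TestCompleteness:
    def test_definitional_values(self):
        assert completeness(10, 10.0) == 1.0
        assert completeness(95, 100.0) == pytest.approx(0.95)

    def test_saturated_survey_is_complete(self):
        # every species in >= 3 units: no uniques, estimate = observed
        table = np.ones((4, 12), dtype=int)
        est = incidence_estimate(table, n_bootstrap=0)
        assert est.q1 == 0
        assert est.completeness == 1.0

    def test_invalid_estimate_rejected(self):
        with pytest.raises(ValueError):
            completeness(10, 0.0)
        with pytest.raises(ValueError):
            completeness(10, 5.0)


class TestBootstrapCI:
    def test_constant_statistic_zero_width(self):
        data = np.ones((10, 3))
        lo, hi = bootstrap_ci(data, lambda a: 7.0, n_bootstrap=50, seed=0)
        assert lo == hi == 7.0

    def test_same_seed_identical_interval(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(30, 1))
        ci1 = bootstrap_ci(data, lambda a: float(a.mean()), 200, seed=5)
        ci2 = bootstrap_ci(data, lambda a: float(a.mean()), 200, seed=5)
        assert ci1 == ci2

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.ones((1, 2)), lambda a: 0.0)

    def test_coverage_of_normal_mean(self):
        # 95% percentile interval for the mean of n=100 iid N(0,1) draws
        # should cover 0 in about 95% of outer replications
        rng = np.random.default_rng(2)
        hits = 0
        n_outer = 200
        for i in range(n_outer):
            data = rng.normal(size=(100, 1))
            lo, hi = bootstrap_ci(
                data, lambda a: float(a.mean()), n_bootstrap=1000, seed=int(i)
            )
            hits += lo <= 0.0 <= hi
        rate = hits / n_outer
        band = 1.96 * np.sqrt(0.95 * 0.05 / n_outer)
        assert abs(rate - 0.95) < band + 0.01


class TestRarefaction:
    def fixture_table(self, seed=0, units=5, species=30, p=0.4):
        rng = np.random.default_rng(seed)
        table = (rng.random((units, species)) < p).astype(int)
        table[0, 0] = 1  # at least one observation
        return table

    def test_full_effort_returns_observed_richness(self):
        table = self.fixture_table()
        s_obs = int((table.sum(axis=0) > 0).sum())
        curve = rarefaction_curve(table, grid=[table.shape[0]])
        assert curve["richness"].iloc[0] == pytest.approx(s_obs)

    def test_single_unit_effort_is_mean_unit_richness(self):
        table = self.fixture_table(seed=3)
        curve = rarefaction_curve(table, grid=[1])
        assert curve["richness"].iloc[0] == pytest.approx(table.sum(axis=1).mean())

    def test_monotone_and_concave_on_interpolation_range(self):
        table = self.fixture_table(seed=4, units=8)
        grid = list(range(1, 9))
        r = rarefaction_curve(table, grid=grid)["richness"].to_numpy()
        assert np.all(np.diff(r) >= -1e-9)
        assert np.all(np.diff(r, 2) <= 1e-9)

    def test_extrapolation_monotone_and_capped(self):
        table = self.fixture_table(seed=5)
        t = table.shape[0]
        curve = rarefaction_curve(table, grid=[t, t + 1, 2 * t])
        r = curve["richness"].to_numpy()
        assert np.all(np.diff(r) >= -1e-9)
        with pytest.warns(UserWarning, match="2T"):
            capped = rarefaction_curve(table, grid=[3 * t])
        assert capped["effort"].iloc[0] == 2 * t

    def test_invalid_effort_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve(self.fixture_table(), grid=[0])

    def test_matches_subsampling_oracle(self):
        # Monte-Carlo oracle: average richness over random t-subsets of units
        table = self.fixture_table(seed=6, units=5, species=25)
        rng = np.random.default_rng(7)
        t = 3
        n_draws = 10_000
        riches = np.empty(n_draws)
        for k in range(n_draws):
            idx = rng.choice(table.shape[0], size=t, replace=False)
            riches[k] = (table[idx].sum(axis=0) > 0).sum()
        expected = rarefaction_curve(table, grid=[t])["richness"].iloc[0]
        se = riches.std(ddof=1) / np.sqrt(n_draws)
        assert abs(riches.mean() - expected) < 3 * se


class TestIncidenceEstimate:
    def test_counts_and_ci_ordering(self):
        rng = np.random.default_rng(8)
        table = (rng.random((6, 40)) < 0.3).astype(int)
        table[0, 0] = 1
        est = incidence_estimate(table, n_bootstrap=100, seed=1)
        freq = table.sum(axis=0)
        assert est.s_obs == int((freq > 0).sum())
        assert est.q1 == int((freq == 1).sum())
        assert est.q2 == int((freq == 2).sum())
        assert est.estimate >= est.s_obs
        assert 0 < est.completeness <= 1
        assert est.ci_low <= est.ci_high
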