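"""Generators: Brownian motion, exact fBm (law checks against analytic
covariances), coefficient contamination, and cohort structure."""

import numpy as np
import pytest

from pupilwave import (
    CohortSpec,
    contaminate_coefficients,
    dwt_forward,
    fbm_covariance,
    simulate_brownian,
    simulate_cohort,
    simulate_fbm,
)
from pupilwave.synthetic import DomainError


class TestBrownian:
    def test_length_and_determinism(self):
        x = simulate_brownian(1024, seed=5)
        assert x.shape == (1024,)
        np.testing.assert_array_equal(x, simulate_brownian(1024, seed=5))

    def test_increments_are_standard_normal(self):
        x = simulate_brownian(100_000, seed=1)
        inc = np.diff(x)
        n = inc.size
        assert abs(inc.mean()) < 3 / np.sqrt(n)
        assert abs(inc.var() - 1) < 3 * np.sqrt(2 / n)

    def test_too_short_rejected(self):
        with pytest.raises(DomainError):
            simulate_brownian(1)


class TestFbm:
    def test_parameter_validation(self):
        with pytest.raises(DomainError):
            simulate_fbm(100, 1.0)
        with pytest.raises(DomainError):
            simulate_fbm(100, 0.0)
        with pytest.raises(DomainError):
            simulate_fbm(1, 0.5)

    def test_determinism(self):
        np.testing.assert_array_equal(simulate_fbm(256, 0.7, 3), simulate_fbm(256, 0.7, 3))

    def test_half_hurst_increments_uncorrelated(self):
        rng = np.random.default_rng(2)
        r = np.mean(
            [
                np.corrcoef(np.diff(simulate_fbm(4096, 0.5, rng))[:-1],
                            np.diff(simulate_fbm(4096, 0.5, rng))[1:])[0, 1]
                for _ in range(20)
            ]
        )
        assert abs(r) < 0.05

    def test_lag_one_increment_autocorrelation_closed_form(self):
        """fGn lag-1 autocorrelation is 2^(2H-1) - 1; check H = 0.7 via
        the unscaled autocovariance (ratio of lag-1 to lag-0 moments
        pooled over replicates, avoiding small-sample corrcoef bias)."""
        hurst = 0.7
        rng = np.random.default_rng(3)
        num = den = 0.0
        for _ in range(40):
            inc = np.diff(simulate_fbm(4096, hurst, rng))
            num += (inc[:-1] * inc[1:]).sum()
            den += (inc**2).sum()
        expected = 2 ** (2 * hurst - 1) - 1
        assert num / den == pytest.approx(expected, abs=0.03)

    def test_variance_growth_exponent(self):
        """Var(X_t) grows like t^(2H): log-log regression of the
        ensemble variance recovers the exponent within 0.1 for H=0.8."""
        hurst = 0.8
        rng = np.random.default_rng(4)
        paths = np.array([simulate_fbm(2**14, hurst, rng) for _ in range(150)])
        t = np.arange(1, 2**14 + 1)
        keep = slice(50, None)
        slope = np.polyfit(np.log(t[keep]), np.log(paths.var(axis=0)[keep]), 1)[0]
        assert slope == pytest.approx(2 * hurst, abs=0.1)

    @pytest.mark.parametrize("hurst", [0.3, 0.7])
    def test_small_n_covariance_matches_analytic(self, hurst):
        """Empirical covariance over many replicates matches the fBm
        covariance (s^2H + t^2H - |s-t|^2H)/2 elementwise; with ~100
        distinct entries tested at 3 standard errors a stray excursion
        is expected, so demand 98% within 3 SE and everything within
        5 SE."""
        n, reps = 12, 20_000
        rng = np.random.default_rng(5)
        paths = np.array([simulate_fbm(n, hurst, rng) for _ in range(reps)])
        emp = (paths[:, :, None] * paths[:, None, :]).mean(axis=0)
        cov = fbm_covariance(n, hurst)
        # SE of a Gaussian cross-moment estimate
        se = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov**2) / reps)
        z = np.abs(emp - cov) / se
        iu = np.triu_indices(n)
        assert (z[iu] < 3).mean() > 0.98
        assert z[iu].max() < 5

    def test_cholesky_and_circulant_agree_in_law(self):
        rng = np.random.default_rng(6)
        var_c = np.var([simulate_fbm(32, 0.8, rng)[-1] for _ in range(4000)])
        var_l = np.var([simulate_fbm(32, 0.8, rng, method="cholesky")[-1] for _ in range(4000)])
        expected = 32 ** (2 * 0.8)
        assert var_c == pytest.approx(expected, rel=0.1)
        assert var_l == pytest.approx(expected, rel=0.1)


class TestContamination:
    @pytest.fixture
    def decomp(self, rng):
        return dwt_forward(rng.standard_normal(1024), "db6", coarsest_level=1)

    def test_zero_noise_is_identity(self, decomp):
        out = contaminate_coefficients(decomp, 100, 0.0, seed=1)
        for j in decomp.levels:
            np.testing.assert_array_equal(out.details[j], decomp.details[j])

    def test_zero_count_is_identity(self, decomp):
        out = contaminate_coefficients(decomp, 0, 1.0, seed=1)
        for j in decomp.levels:
            np.testing.assert_array_equal(out.details[j], decomp.details[j])

    def test_exactly_requested_positions_differ(self, decomp):
        """100 per level on a 512-coefficient level changes exactly 100
        entries; shorter levels are fully contaminated (min rule);
        smooth and unselected coefficients stay bit-identical."""
        out = contaminate_coefficients(decomp, 100, 1.0, seed=2)
        np.testing.assert_array_equal(out.smooth, decomp.smooth)
        for j in decomp.levels:
            n_diff = int((out.details[j] != decomp.details[j]).sum())
            assert n_diff == min(100, 2**j)

    def test_determinism(self, decomp):
        a = contaminate_coefficients(decomp, 10, 0.5, seed=3)
        b = contaminate_coefficients(decomp, 10, 0.5, seed=3)
        for j in decomp.levels:
            np.testing.assert_array_equal(a.details[j], b.details[j])

    def test_negative_inputs_rejected(self, decomp):
        with pytest.raises(DomainError):
            contaminate_coefficients(decomp, -1, 1.0)
        with pytest.raises(DomainError):
            contaminate_coefficients(decomp, 5, -0.1)


class TestCohort:
    def test_cardinality_and_labels(self):
        spec = CohortSpec(
            n_cases=2, n_controls=2, sessions_per_subject=8,
            session_length=2048, missing_fraction=0.1, seed=1,
        )
        recs = simulate_cohort(spec)
        assert len(recs) == 4
        assert all(len(r.sessions) == 8 for r in recs)
        assert sorted(r.group for r in recs) == ["case", "case", "control", "control"]

    def test_missing_fraction_in_band(self):
        spec = CohortSpec(
            n_cases=1, n_controls=1, sessions_per_subject=2,
            session_length=8192, missing_fraction=0.3,
            blink_burst_length=100, seed=2,
        )
        for rec in simulate_cohort(spec):
            for sig in rec.sessions:
                assert 0.25 <= sig.missing_fraction <= 0.35

    def test_bursts_are_contiguous(self):
        spec = CohortSpec(
            n_cases=1, n_controls=0, sessions_per_subject=1,
            session_length=8192, missing_fraction=0.1,
            blink_burst_length=500, seed=3,
        )
        mask = simulate_cohort(spec)[0].sessions[0].missing_mask
        starts = int(np.diff(mask.astype(int)).clip(min=0).sum() + mask[0])
        # masked runs have the burst length scale, not isolated samples
        assert mask.sum() / starts >= 100

    def test_reproducible_from_seed(self):
        spec = CohortSpec(n_cases=1, n_controls=1, sessions_per_subject=1,
                          session_length=1024, seed=9)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        for ra, rb in zip(a, b):
            for sa, sb in zip(ra.sessions, rb.sessions):
                np.testing.assert_array_equal(sa.values, sb.values)
                np.testing.assert_array_equal(sa.missing_mask, sb.missing_mask)

    def test_invalid_specs_rejected(self):
        with pytest.raises(DomainError):
            CohortSpec(H_case=1.2)
        with pytest.raises(DomainError):
            CohortSpec(missing_fraction=0.9)
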