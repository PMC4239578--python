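"""Conservative estimator: interval arithmetic and the worst-case information bound.

The independent oracle for CSI is a brute-force minimization of the weighted
biallelic information over a dense grid spanning the (error-widened) interval
box, with the Agresti-Coull intervals themselves cross-checked against
statsmodels.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from poolinfo.conservative import (
    BinomialInterval,
    EstimatorConfig,
    agresti_coull,
    conservative_allele_log_odds,
    conservative_site_information,
    widen_by_error,
)
from poolinfo.info import expected_site_information


def interval(lower, upper):
    return BinomialInterval(x=0, n=1, z=1.96, n_tilde=1.0, p_tilde=0.5, lower=lower, upper=upper)


def grid_csi_biallelic(x_p, n_p, x_q, n_q, epsilon=0.0, confidence=0.95, points=1000):
    """Brute-force CSI oracle: minimize the weighted two-allele information over
    a dense (p, q) grid spanning the error-widened Agresti-Coull box."""
    lp, up = proportion_confint(x_p, n_p, alpha=1 - confidence, method="agresti_coull")
    lq, uq = proportion_confint(x_q, n_q, alpha=1 - confidence, method="agresti_coull")
    lp, up = max(0.0, lp - epsilon), min(1.0, up + epsilon)
    lq, uq = max(0.0, lq - epsilon), min(1.0, uq + epsilon)
    p_grid = np.linspace(lp, up, points)
    q_grid = np.linspace(lq, uq, points)
    p_grid = np.union1d(p_grid, np.clip(q_grid, lp, up))
    q_grid = np.union1d(q_grid, np.clip(p_grid, lq, uq))
    w1 = 0.5 * (x_p / n_p + x_q / n_q)
    P, Q = np.meshgrid(p_grid, q_grid, indexing="ij")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = w1 * np.abs(np.log2(P / Q)) + (1 - w1) * np.abs(
            np.log2((1 - P) / (1 - Q))
        )
    values = np.where(np.isnan(values), np.inf, values)
    return float(values.min())


counts_pair = st.integers(min_value=1, max_value=200).flatmap(
    lambda n: st.tuples(st.integers(min_value=0, max_value=n), st.just(n))
)


class TestAgrestiCoull:
    def test_zero_successes(self):
        ci = agresti_coull(0, 20, 0.95)
        assert ci.lower == 0.0  # clamped
        assert ci.upper == pytest.approx(0.1899, abs=5e-4)

    def test_balanced(self):
        ci = agresti_coull(10, 20, 0.95)
        assert ci.p_tilde == pytest.approx(0.5)
        assert ci.n_tilde == pytest.approx(20 + 1.959964**2, abs=1e-4)
        assert (ci.lower, ci.upper) == (
            pytest.approx(0.2993, abs=5e-4),
            pytest.approx(0.7007, abs=5e-4),
        )

    @given(counts_pair)
    def test_mirror_symmetry(self, xn):
        x, n = xn
        ci = agresti_coull(x, n)
        mirrored = agresti_coull(n - x, n)
        assert mirrored.lower == pytest.approx(1 - ci.upper, abs=1e-12)
        assert mirrored.upper == pytest.approx(1 - ci.lower, abs=1e-12)

    @given(counts_pair)
    def test_contains_point_estimate(self, xn):
        x, n = xn
        ci = agresti_coull(x, n, 0.95)
        assert ci.lower <= x / n <= ci.upper

    @pytest.mark.parametrize("x, n", [(0, 20), (3, 20), (10, 20), (19, 20), (7, 60)])
    def test_matches_statsmodels(self, x, n):
        ci = agresti_coull(x, n, 0.95)
        lo, hi = proportion_confint(x, n, alpha=0.05, method="agresti_coull")
        assert ci.lower == pytest.approx(max(0.0, lo), abs=1e-9)
        assert ci.upper == pytest.approx(min(1.0, hi), abs=1e-9)

    @pytest.mark.parametrize("x, n", [(0, 0), (5, 4), (-1, 4)])
    def test_invalid_counts_rejected(self, x, n):
        with pytest.raises(ValueError):
            agresti_coull(x, n)


class TestWidenByError:
    def test_symmetric_widening(self):
        out = widen_by_error(interval(0.30, 0.70), 0.01)
        assert (out.lower, out.upper) == (pytest.approx(0.29), pytest.approx(0.71))

    def test_clamped_at_zero(self):
        out = widen_by_error(interval(0.0, 0.19), 0.01)
        assert (out.lower, out.upper) == (0.0, pytest.approx(0.20))

    def test_zero_is_identity(self):
        ci = interval(0.2, 0.4)
        out = widen_by_error(ci, 0.0)
        assert (out.lower, out.upper) == (ci.lower, ci.upper)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=0.4),
    )
    def test_never_narrows(self, a, b, eps):
        lo, hi = min(a, b), max(a, b)
        out = widen_by_error(interval(lo, hi), eps)
        assert out.lower <= lo and out.upper >= hi


class TestConservativeAlleleLogOdds:
    def test_overlap_gives_zero(self):
        assert conservative_allele_log_odds(interval(0.29, 0.71), interval(0.30, 0.70)) == 0.0

    def test_nearest_endpoints(self):
        value = conservative_allele_log_odds(interval(0.02, 0.18), interval(0.55, 0.85))
        assert value == pytest.approx(abs(math.log2(0.18 / 0.55)), abs=1e-9)

    def test_zero_far_endpoint_is_harmless(self):
        """A zero at the far end of the lower interval never enters a denominator."""
        value = conservative_allele_log_odds(interval(0.0, 0.10), interval(0.60, 0.90))
        assert value == pytest.approx(abs(math.log2(0.10 / 0.60)), abs=1e-9)

    def test_degenerate_zero_interval_contributes_nothing(self):
        assert conservative_allele_log_odds(interval(0.0, 0.0), interval(0.6, 0.9)) == 0.0

    def test_symmetric_in_arguments(self):
        a, b = interval(0.02, 0.18), interval(0.55, 0.85)
        assert conservative_allele_log_odds(a, b) == conservative_allele_log_odds(b, a)


class TestConservativeSiteInformation:
    def test_identical_counts_give_zero(self):
        counts = {"A": 10, "C": 10}
        for eps in (0.0, 0.01, 0.05):
            config = EstimatorConfig(epsilon=eps)
            assert conservative_site_information(counts, counts, config) == 0.0

    def test_example_bounded_by_point_estimate_esi(self):
        config = EstimatorConfig(epsilon=0.01, confidence=0.95)
        csi = conservative_site_information({"A": 2, "C": 38}, {"A": 30, "C": 10}, config)
        esi = expected_site_information(2 / 40, 30 / 40)
        assert 0.0 < csi < esi

    def test_example_matches_grid_oracle(self):
        config = EstimatorConfig(epsilon=0.01, confidence=0.95)
        csi = conservative_site_information({"A": 2, "C": 38}, {"A": 30, "C": 10}, config)
        assert csi == pytest.approx(grid_csi_biallelic(2, 40, 30, 40, epsilon=0.01), abs=1e-3)

    @pytest.mark.parametrize(
        "x_p, n_p, x_q, n_q, eps",
        [
            (0, 20, 10, 20, 0.0),
            (2, 40, 30, 40, 0.0),
            (2, 40, 30, 40, 0.02),
            (1, 10, 9, 10, 0.0),
            (5, 60, 55, 60, 0.01),
            (3, 20, 12, 20, 0.0),
            (10, 20, 10, 20, 0.01),
            (0, 5, 5, 5, 0.0),
            (30, 60, 31, 60, 0.0),
        ],
    )
    def test_grid_oracle_agreement_small_depths(self, x_p, n_p, x_q, n_q, eps):
        """Per-allele nearest-endpoint CSI equals joint box minimization (depth <= 60)."""
        config = EstimatorConfig(epsilon=eps)
        counts_p = {"A": x_p, "C": n_p - x_p}
        counts_q = {"A": x_q, "C": n_q - x_q}
        csi = conservative_site_information(counts_p, counts_q, config)
        assert csi == pytest.approx(grid_csi_biallelic(x_p, n_p, x_q, n_q, eps), abs=1e-3)

    def test_conservative_below_esi_on_random_counts(self, rng):
        config = EstimatorConfig(epsilon=0.01)
        for _ in range(200):
            n_p, n_q = rng.integers(5, 100, size=2)
            x_p, x_q = rng.integers(0, n_p + 1), rng.integers(0, n_q + 1)
            counts_p = {"A": int(x_p), "C": int(n_p - x_p)}
            counts_q = {"A": int(x_q), "C": int(n_q - x_q)}
            csi = conservative_site_information(counts_p, counts_q, config)
            assert csi >= 0.0 and math.isfinite(csi)
            esi = expected_site_information(x_p / n_p, x_q / n_q)
            if math.isfinite(esi):
                assert csi <= esi + 1e-12

    def test_monotone_in_depth(self):
        config = EstimatorConfig(epsilon=0.0)
        previous = -1.0
        for k in (1, 2, 4, 8, 16, 64):
            csi = conservative_site_information(
                {"A": 3 * k, "C": 17 * k}, {"A": 12 * k, "C": 8 * k}, config
            )
            assert csi >= previous - 1e-12
            previous = csi
        assert previous > 0.0

    def test_monotone_in_epsilon(self):
        previous = math.inf
        for eps in (0.0, 0.002, 0.01, 0.02, 0.05, 0.1):
            csi = conservative_site_information(
                {"A": 2, "C": 38}, {"A": 30, "C": 10}, EstimatorConfig(epsilon=eps)
            )
            assert csi <= previous + 1e-12
            previous = csi

    def test_converges_to_esi_at_large_depth(self):
        n = 10**6
        x_p, x_q = int(0.17 * n), n // 2
        csi = conservative_site_information(
            {"A": x_p, "C": n - x_p}, {"A": x_q, "C": n - x_q}, EstimatorConfig(epsilon=0.0)
        )
        assert csi == pytest.approx(expected_site_information(x_p / n, x_q / n), abs=0.01)

    def test_finite_where_esi_is_infinite(self):
        """One-sided zero counts blow up ESI but never CSI."""
        csi = conservative_site_information({"A": 5}, {"C": 7}, EstimatorConfig(epsilon=0.0))
        assert math.isfinite(csi) and csi > 0.0
        assert expected_site_information(*_paired({"A": 5}, {"C": 7})) == math.inf

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            conservative_site_information({"A": 0}, {"A": 5}, EstimatorConfig())


def _paired(cp, cq):
    from poolinfo.compare import paired_frequencies

    return paired_frequencies(cp, cq)


class TestEstimatorConfig:
    @pytest.mark.parametrize("eps, conf", [(-0.01, 0.95), (0.5, 0.95), (0.01, 0.4), (0.01, 1.0)])
    def test_invalid_rejected(self, eps, conf):
        with pytest.raises(ValueError):
            EstimatorConfig(epsilon=eps, confidence=conf)

    def test_default_z_quantile(self):
        assert EstimatorConfig().z == pytest.approx(1.959964, abs=1e-6)
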