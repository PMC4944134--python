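import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from levyswitch import (
    Domain1D,
    NoiseSpec,
    RCFSetting,
    brownian_mfet_closed_form,
    extract_K,
    intensities_from_rcf,
    solve_mfet,
    stochastic_basin,
    sweep_fep,
    sweep_mfet,
    ustar_for_width,
)

from conftest import X_MINUS, X_U


class TestRCF:
    @pytest.mark.parametrize(
        "lam, expected",
        [(1.0, (0.5, 0.5)), (0.0, (1.0, 0.0)), (3.0, (0.25, 0.75))],
    )
    def test_intensity_split(self, lam, expected):
        assert intensities_from_rcf(lam) == pytest.approx(expected)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            intensities_from_rcf(-0.1)

    @settings(max_examples=30, deadline=None)
    @given(lam=st.floats(1e-3, 1e3))
    def test_round_trip(self, lam):
        sigma, eps = intensities_from_rcf(lam)
        assert sigma + eps == pytest.approx(1.0, abs=1e-12)
        assert eps / sigma == pytest.approx(lam, rel=1e-12)

    def test_setting_builds_constrained_noise(self):
        noise = RCFSetting(3.0).noise(1.5)
        assert noise.constrained and noise.lambda_rcf == pytest.approx(3.0)


class TestSweeps:
    def test_mfet_sweep_runs_for_figure_start_points(self, params, low_region):
        df = sweep_mfet(
            [0.3, X_MINUS, 0.9, 1.2], 1.5, [RCFSetting(1.0)], low_region, params, J=100
        )
        assert len(df) == 4
        assert (df["value"] > 0).all()
        assert list(df.columns) == [
            "x0", "alpha", "sigma", "epsilon", "lambda", "scenario", "quantity", "value",
        ]

    def test_single_setting_sweep_equals_direct_solve(self, params, low_region):
        noise = NoiseSpec(0.0, 0.5, 1.5)
        df = sweep_mfet([0.9], 1.5, [noise], low_region, params, J=100)
        direct = solve_mfet(low_region, params, noise, J=100)(0.9)
        assert df["value"].iloc[0] == pytest.approx(direct, rel=1e-12)

    def test_mfet_monotone_in_levy_intensity(self, params, low_region):
        df = sweep_mfet(
            [0.3, X_MINUS, 0.9, 1.2],
            1.5,
            [NoiseSpec(0.0, 0.25, 1.5), NoiseSpec(0.0, 1.0, 1.5)],
            low_region,
            params,
            J=100,
        )
        for _, grp in df.groupby("x0"):
            weak = grp[grp["epsilon"] == 0.25]["value"].iloc[0]
            strong = grp[grp["epsilon"] == 1.0]["value"].iloc[0]
            assert strong < weak

    def test_scenario2_pure_gaussian_null(self, params, low_region):
        df = sweep_fep(
            [0.3, 0.9], 1.5, [RCFSetting(0.0)], low_region,
            Domain1D.interval(3, 5), 2, params, J=100,
        )
        assert np.allclose(df["value"], 0.0, atol=1e-10)

    def test_scenario2_larger_jumps_escape_more(self, params, low_region):
        target = Domain1D.interval(3, 5)
        vals = {}
        for alpha in (0.5, 1.5):
            df = sweep_fep(
                [0.745], alpha, [NoiseSpec(0.5, 0.5, alpha)], low_region,
                target, 2, params, J=200,
            )
            vals[alpha] = df["value"].iloc[0]
        assert vals[0.5] > vals[1.5]

    def test_scenario1_full_complement_certain(self, params, low_region):
        full = Domain1D([(-np.inf, 0.0), (X_U, np.inf)])
        df = sweep_fep(
            [0.3, 0.9], 1.5, [RCFSetting(1.0)], low_region, full, 1, params, J=100
        )
        assert np.allclose(df["value"], 1.0, atol=1e-6)

    def test_scenario2_requires_detached_target(self, params, low_region):
        with pytest.raises(ValueError, match="non-adjacent"):
            sweep_fep(
                [0.3], 1.5, [RCFSetting(1.0)], low_region,
                Domain1D.interval(X_U, 3.0), 2, params, J=100,
            )


@pytest.fixture(scope="module")
def u_brownian(params, low_region):
    return solve_mfet(low_region, params, NoiseSpec(1.0, 0.0), J=400)


@pytest.fixture(scope="module")
def brownian_sba(params):
    noise = NoiseSpec(1.0, 0.0)
    u = solve_mfet(Domain1D.interval(0.0, X_U), params, noise, J=200)
    us = ustar_for_width(u, 0.55)
    return stochastic_basin(params, noise, Domain1D.interval(0.0, 6.0), us, 0.6, J=200)


class TestExtractK:
    def test_threshold_at_maximum_degenerates(self, u_brownian):
        xs, vs = u_brownian.interval_arrays(0)
        lo, hi = extract_K(u_brownian, float(vs.max()))
        assert hi - lo < 1e-9
        assert lo == pytest.approx(xs[np.argmax(vs)], abs=1e-9)

    def test_vanishing_threshold_recovers_domain(self, u_brownian, low_region):
        lo, hi = extract_K(u_brownian, 1e-12)
        a, b = low_region.intervals[0]
        assert lo == pytest.approx(a, abs=1e-4) and hi == pytest.approx(b, abs=1e-4)

    def test_empty_K_rejected(self, u_brownian):
        xs, vs = u_brownian.interval_arrays(0)
        with pytest.raises(ValueError, match="empty K"):
            extract_K(u_brownian, 2 * vs.max())

    def test_endpoints_match_closed_form_superlevel(self, params, u_brownian):
        # the oracle's own superlevel set, endpoints by root finding
        u_exact = lambda x: brownian_mfet_closed_form(params, 1.0, (0.0, X_U), x)
        xs, vs = u_brownian.interval_arrays(0)
        level = 0.5 * vs.max()
        x_peak = xs[np.argmax(vs)]
        lo_ref = brentq(lambda x: u_exact(x) - level, 1e-9, x_peak)
        hi_ref = brentq(lambda x: u_exact(x) - level, x_peak, X_U - 1e-9)
        lo, hi = extract_K(u_brownian, level)
        assert lo == pytest.approx(lo_ref, abs=1e-3)
        assert hi == pytest.approx(hi_ref, abs=1e-3)

    def test_matched_width_threshold(self, u_brownian):
        us = ustar_for_width(u_brownian, 0.5)
        lo, hi = extract_K(u_brownian, us)
        assert hi - lo == pytest.approx(0.5, abs=1e-6)


class TestStochasticBasin:
    WINDOW = Domain1D.interval(0.0, 6.0)

    def test_K_and_M_partition_size(self, brownian_sba):
        r = brownian_sba
        assert r.sba_size == pytest.approx(r.K_length + r.M_length)
        for a, b in r.M:  # M avoids K
            assert b <= r.K[0] + 1e-12 or a >= r.K[1] - 1e-12

    def test_brownian_M_has_at_most_two_components(self, brownian_sba):
        assert 1 <= len(brownian_sba.M) <= 2

    def test_high_probability_threshold_empties_M(self, params):
        noise = NoiseSpec(1.0, 0.0)
        u = solve_mfet(Domain1D.interval(0.0, X_U), params, noise, J=200)
        us = ustar_for_width(u, 0.55)
        r = stochastic_basin(params, noise, self.WINDOW, us, 1.0 - 1e-9, J=200)
        assert r.M == []
        assert r.sba_size == pytest.approx(r.K_length)

    def test_size_shrinks_with_pstar(self, params):
        noise = NoiseSpec(1.0, 0.0)
        u = solve_mfet(Domain1D.interval(0.0, X_U), params, noise, J=200)
        us = ustar_for_width(u, 0.55)
        sizes = [
            stochastic_basin(params, noise, self.WINDOW, us, ps, J=200).sba_size
            for ps in (0.3, 0.6, 0.9)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_size_shrinks_with_ustar(self, params):
        noise = NoiseSpec(1.0, 0.0)
        u = solve_mfet(Domain1D.interval(0.0, X_U), params, noise, J=200)
        u_max = u.values.max()
        sizes = [
            stochastic_basin(params, noise, self.WINDOW, f * u_max, 0.6, J=200).sba_size
            for f in (0.3, 0.5, 0.7)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_larger_alpha_grows_return_set(self, params):
        # matched |K| across stability indices, same escape threshold
        m_len = {}
        for alpha in (0.5, 1.5):
            noise = NoiseSpec(0.0, 0.5, alpha)
            u = solve_mfet(Domain1D.interval(0.0, X_U), params, noise, J=200)
            us = ustar_for_width(u, 0.55)
            r = stochastic_basin(params, noise, self.WINDOW, us, 0.5, J=200)
            assert r.K_length == pytest.approx(0.55, abs=1e-4)
            m_len[alpha] = r.M_length
        assert m_len[1.5] > m_len[0.5]

    def test_bad_thresholds_rejected(self, params):
        with pytest.raises(ValueError):
            stochastic_basin(params, NoiseSpec(1.0, 0.0), self.WINDOW, 0.1, 1.5)
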