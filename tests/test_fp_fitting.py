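"""Fractional polynomial fitting and goodness-of-fit diagnostics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fetalvelocity as fv
from fetalvelocity.fp_fitting import empirical_centiles, fit_fp, fit_velocity_standard
from fetalvelocity.fpmodel import FP_POWERS, fp_basis

ALL = ["HC", "BPD", "OFD", "AC", "FL"]


class TestFPBasis:
    def test_log_power(self):
        assert fp_basis(np.e, (0,))[0, 0] == pytest.approx(1.0)

    def test_repeated_power_rule(self):
        row = fp_basis(2.0, (2, 2))[0]
        assert row[0] == pytest.approx(4.0)
        assert row[1] == pytest.approx(4.0 * np.log(2.0))

    def test_unit_predictor(self):
        assert np.allclose(fp_basis(1.0, (-2, 3))[0], [1.0, 1.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fp_basis([1.0, 0.0], (1,))


class TestFitFP:
    def test_noiseless_log_recovery(self):
        x = np.linspace(1, 30, 50)
        y = 2 + 3 * np.log(x)
        res = fit_fp(x, y, degree=1)
        assert res.model.powers == (0.0,)
        assert res.model.coefficients == pytest.approx((2.0, 3.0), abs=1e-8)
        assert res.rss < 1e-16
        assert res.candidate_count == 8

    def test_noiseless_published_mean_recovery(self, standards):
        """The chart-construction search recovers the published HC curve."""
        ga = np.linspace(16, 38, 120)
        y = np.asarray(standards["HC"].mean_model(ga))
        res = fit_fp(ga, y, degree=2, scale=10.0)
        assert res.model.powers == (2.0, 2.0)
        assert res.model.coefficients == pytest.approx(
            standards["HC"].mean_model.coefficients, abs=1e-6
        )
        assert res.candidate_count == 36

    def test_constant_response_tie_breaks_lexicographically(self):
        x = np.linspace(1, 5, 20)
        res = fit_fp(x, np.full_like(x, 7.0), degree=1)
        assert res.model.powers == (-2.0,)  # first enumerated power
        assert res.rss == pytest.approx(0.0, abs=1e-18)
        assert res.model.coefficients[1] == pytest.approx(0.0, abs=1e-9)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_fp([1.0, 2.0], [1.0, 2.0], degree=1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10)
    def test_equals_brute_force_oracle(self, seed):
        """FP2 search equals an independent statsmodels enumeration."""
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        x = rng.uniform(0.5, 4.0, n)
        y = 1 + x + rng.standard_normal(n)
        res = fit_fp(x, y, degree=2)
        best = None
        for combo in itertools.combinations_with_replacement(FP_POWERS, 2):
            X = sm.add_constant(fp_basis(x, combo))
            fit = sm.OLS(y, X).fit()
            rss = float(fit.ssr)
            if best is None or rss < best[0] - 1e-9:
                best = (rss, combo, fit.params)
        assert res.model.powers == tuple(best[1])
        assert res.rss == pytest.approx(best[0], rel=1e-6)
        assert np.allclose(res.model.coefficients, best[2], rtol=1e-5, atol=1e-6)


class TestSelfConsistency:
    @pytest.mark.parametrize("b", ALL)
    def test_mean_equation_refits_exactly(self, b, standards):
        model = standards[b].mean_model
        ga = np.linspace(16, 38, 200)
        res = fit_fp(ga, np.asarray(model(ga)), degree=2, scale=10.0)
        assert res.model.powers == model.powers
        assert res.model.coefficients == pytest.approx(model.coefficients, abs=1e-6)

    @pytest.mark.parametrize("b", ALL)
    def test_sd_equation_refits_exactly(self, b, standards):
        model = standards[b].sd_model
        ga = np.linspace(16, 38, 200)
        res = fit_fp(ga, np.asarray(model(ga)), degree=1, scale=model.scale)
        assert res.model.powers == model.powers
        assert res.model.coefficients == pytest.approx(model.coefficients, abs=1e-6)


class TestEmpiricalCentiles:
    def test_uniform_grid_median(self):
        cents = empirical_centiles(np.arange(101.0))
        assert cents[50.0] == 50.0

    def test_constant_bin(self):
        cents = empirical_centiles(np.full(25, 3.3))
        assert set(cents.values()) == {3.3}

    def test_normal_tail_quantile(self):
        rng = np.random.default_rng(99)
        cents = empirical_centiles(rng.standard_normal(10_000))
        assert cents[97.0] == pytest.approx(1.881, abs=0.05)

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            empirical_centiles([], min_n=1)


class TestFitVelocityStandard:
    def make_observations(self, b, n, seed, standards):
        """Increments drawn directly from the published mean/SD at mid GA."""
        import pandas as pd

        rng = np.random.default_rng(seed)
        mid = rng.uniform(16, 38, n)
        std = standards[b]
        v = np.asarray(std.mean_model(mid)) + np.asarray(std.sd_model(mid)) * rng.standard_normal(n)
        return pd.DataFrame({"biometry": b, "mid_ga": mid, "increment": v})

    def test_recovers_published_median_curve(self, standards):
        obs = self.make_observations("HC", 20_000, 4, standards)
        std, report, mean_fit = fit_velocity_standard(obs)
        weeks = np.arange(16.0, 39.0)
        err = np.abs(std.mean(weeks) - np.asarray(standards["HC"].mean(weeks)))
        assert float(err.max()) < 0.1
        assert std.biometry is fv.BiometryCode.HC

    def test_noiseless_ac_recovery_of_published_powers(self, standards):
        import pandas as pd

        ga = np.linspace(16, 38, 300)
        obs = pd.DataFrame(
            {"biometry": "AC", "mid_ga": ga, "increment": np.asarray(standards["AC"].mean_model(ga))}
        )
        std, _, mean_fit = fit_velocity_standard(obs)
        assert mean_fit.model.powers == (-2.0, 3.0)

    def test_zscore_calibration_and_coverage(self, standards):
        obs = self.make_observations("FL", 20_000, 11, standards)
        std, report, _ = fit_velocity_standard(obs)
        assert abs(report.z_mean) < 0.02
        assert report.z_sd == pytest.approx(1.0, abs=0.02)
        # ~3% of correctly specified data falls below the 3rd centile
        below = report.coverage["below_c3"]
        assert below.mean() == pytest.approx(0.03, abs=0.01)

    def test_too_few_observations(self, standards):
        obs = self.make_observations("HC", 3, 0, standards)
        with pytest.raises(ValueError):
            fit_velocity_standard(obs)

    def test_gof_export(self, tmp_path, standards):
        obs = self.make_observations("BPD", 2_000, 5, standards)
        _, report, _ = fit_velocity_standard(obs)
        paths = report.export(str(tmp_path / "bpd"))
        assert len(paths) == 3
        for p in paths:
            assert (tmp_path / p.split("/")[-1]).exists()
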