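"""Standard evaluation: means, SDs, centiles, Z-scores, peaks, charts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fetalvelocity as fv
from fetalvelocity.fpmodel import chart_round, round_half_up

ALL = ["HC", "BPD", "OFD", "AC", "FL"]


class TestMeanAndSD:
    @pytest.mark.parametrize(
        "biometry, ga, expected, dp",
        [("HC", 16, 12.24, 2), ("AC", 38, 9.2, 1), ("FL", 28, 2.2, 1)],
    )
    def test_mean_matches_printed_median(self, biometry, ga, expected, dp):
        assert chart_round(fv.mean_velocity(biometry, ga), dp) == expected

    @pytest.mark.parametrize(
        "biometry, ga, expected",
        [("HC", 16, 0.8593549), ("BPD", 20, 0.4329844)],
    )
    def test_sd_hand_evaluation(self, biometry, ga, expected):
        assert fv.sd_velocity(biometry, ga) == pytest.approx(expected, abs=1e-6)

    def test_sd_consistent_with_printed_centile_spread(self, published_table):
        # C97 - C50 = 1.88 * SD, checked against the printed AC chart row
        row = published_table.query("biometry == 'AC' and ga == 16").iloc[0]
        spread = 1.88 * fv.sd_velocity("AC", 16)
        assert row["c97"] - row["c50"] == pytest.approx(spread, abs=0.1)

    def test_hard_domain_bound_is_an_error(self):
        with pytest.raises(ValueError):
            fv.mean_velocity("HC", 45)
        with pytest.raises(ValueError):
            fv.mean_velocity("HC", 0.0)

    def test_outside_chart_range_warns_by_default_and_raises_in_strict_mode(self):
        with pytest.warns(fv.GARangeWarning):
            fv.mean_velocity("HC", 15.0)
        with pytest.raises(ValueError):
            fv.mean_velocity("HC", 15.0, out_of_range="error")
        fv.mean_velocity("HC", 15.0, out_of_range="ignore")  # silent

    def test_unknown_biometry_rejected(self):
        with pytest.raises(ValueError, match="unknown biometry"):
            fv.mean_velocity("XYZ", 20)

    def test_sd_positive_across_range(self):
        ga = np.linspace(16, 38, 100)
        for b in ALL:
            assert np.all(np.asarray(fv.sd_velocity(b, ga)) > 0)


class TestCentilesAndZ:
    @pytest.mark.parametrize(
        "biometry, ga, p, expected, dp",
        [("HC", 16, 3, 10.62, 2), ("BPD", 20, 97, 4.1, 1)],
    )
    def test_centile_matches_printed_cell(self, biometry, ga, p, expected, dp):
        assert chart_round(fv.centile_velocity(biometry, ga, p), dp) == expected

    def test_median_centile_is_the_mean(self):
        for b in ALL:
            assert fv.centile_velocity(b, 25, 50) == fv.mean_velocity(b, 25)

    def test_centile_out_of_domain(self):
        with pytest.raises(ValueError):
            fv.centile_velocity("HC", 20, 0)
        with pytest.raises(ValueError):
            fv.centile_velocity("HC", 20, 100)

    def test_zscore_identity_and_construction(self):
        assert fv.zscore_velocity("HC", 16, fv.mean_velocity("HC", 16)) == 0.0
        v97 = fv.centile_velocity("HC", 16, 97)
        assert fv.zscore_velocity("HC", 16, v97) == pytest.approx(1.88, abs=1e-12)

    def test_printed_fl_median_scores_near_zero(self):
        # 2.2 mm/wk is the printed FL median at 28 weeks
        assert abs(fv.zscore_velocity("FL", 28, 2.2)) < 0.06

    @given(
        b=st.sampled_from(ALL),
        ga=st.floats(16, 38),
        p=st.floats(0.5, 99.5),
    )
    def test_zscore_centile_round_trip(self, b, ga, p):
        v = fv.centile_velocity(b, ga, p, out_of_range="ignore")
        z = fv.zscore_velocity(b, ga, v, out_of_range="ignore")
        assert z == pytest.approx(fv.centile_multiplier(p), abs=1e-12)

    @given(b=st.sampled_from(ALL), ga=st.floats(16, 38))
    def test_centiles_strictly_increasing_in_p(self, b, ga):
        ps = [1, 3, 5, 10, 25, 50, 75, 90, 95, 97, 99]
        vals = [fv.centile_velocity(b, ga, p, out_of_range="ignore") for p in ps]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_centile_symmetry_about_median(self):
        for b in ALL:
            c3 = fv.centile_velocity(b, 30, 3)
            c50 = fv.centile_velocity(b, 30, 50)
            c97 = fv.centile_velocity(b, 30, 97)
            assert c50 - c3 == pytest.approx(c97 - c50, abs=1e-12)


class TestChartTables:
    def test_full_chart_reproduction(self, published_table):
        """Every printed cell of the five charts at printed rounding."""
        for b in ALL:
            sub = published_table[published_table.biometry == b]
            table = fv.centile_table(b)
            for _, row in sub.iterrows():
                for p in (3, 5, 10, 50, 90, 95, 97):
                    got = table.loc[float(row.ga), f"c{p}"]
                    assert got == row[f"c{p}"], (b, row.ga, p)

    def test_negative_low_centiles_near_term_not_clamped(self):
        vals = fv.centile_table("OFD", [36, 37, 38], centiles=[3])["c3"].tolist()
        assert vals == [-0.1, -0.5, -0.8]

    def test_single_cell(self):
        assert fv.centile_table("AC", [16], centiles=[50]).iloc[0, 0] == 11.8

    def test_export_round_trip(self, tmp_path):
        import pandas as pd

        path = tmp_path / "hc.csv"
        table = fv.export_chart_csv("HC", path)
        back = pd.read_csv(path)
        assert list(back.columns) == ["ga", "c3", "c5", "c10", "c50", "c90", "c95", "c97"]
        assert len(back) == 23
        assert back.loc[0, "c50"] == 12.24
        assert np.allclose(back.set_index("ga").to_numpy(), table.to_numpy())


class TestPeakVelocity:
    def grid_argmax(self, b):
        ga = np.arange(16.0, 38.0 + 1e-9, 0.001)
        v = np.asarray(fv.mean_velocity(b, ga, out_of_range="ignore"))
        i = int(np.argmax(v))
        return float(ga[i]), float(v[i])

    @pytest.mark.parametrize("b", ALL)
    def test_agrees_with_dense_grid_oracle(self, b):
        ga, v = fv.peak_velocity(b)
        ga_o, v_o = self.grid_argmax(b)
        assert ga == pytest.approx(ga_o, abs=0.01)
        assert v == pytest.approx(v_o, abs=1e-6)

    def test_known_peak_locations(self):
        assert fv.peak_velocity("BPD")[0] == pytest.approx(19.4, abs=0.05)
        for b in ("HC", "OFD", "AC", "FL"):
            assert fv.peak_velocity(b)[0] == 16.0


class TestPercentOfTermSize:
    def test_head_circumference_range(self):
        # term HC 334 mm; weekly gain spans 3.7% down to 0.8% of term size
        assert round_half_up(fv.percent_of_term_size("HC", 16, 334.0), 1) == 3.7
        assert round_half_up(fv.percent_of_term_size("HC", 38, 334.0), 1) == 0.8

    def test_nonpositive_term_size_rejected(self):
        with pytest.raises(ValueError):
            fv.percent_of_term_size("HC", 20, 0.0)


class TestStandardSerialization:
    def test_json_round_trip(self, tmp_path, standards):
        path = tmp_path / "std.json"
        standards.to_json(path)
        back = fv.load_standard_set(path)
        for b in ALL:
            ga = np.linspace(16, 38, 23)
            assert np.allclose(back[b].mean(ga), standards[b].mean(ga))
            assert np.allclose(back[b].sd(ga), standards[b].sd(ga))
            assert back[b].decimals == standards[b].decimals

    def test_sd_must_be_positive_over_range(self, standards):
        bad = fv.FPModel(powers=(1.0,), coefficients=(-10.0, 0.01), scale=1.0)
        with pytest.raises(ValueError, match="positive"):
            fv.VelocityStandard("HC", standards["HC"].mean_model, bad)
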