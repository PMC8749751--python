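import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agegrowth.ages import AgeScheme
from agegrowth.backcalc import (
    RadiusLengthRegression,
    back_calculate,
    compare_regressions,
    expand_dataset,
    fit_radius_length,
)
from agegrowth.growth import fit_model, predict_length
from agegrowth.simulate import SyntheticConfig, generate_population
from agegrowth.types import SpecimenRecord

from conftest import make_specimen


def _line_population(a, b, slope_noise_sd, n, seed, sex="female", tl_range=(40, 85)):
    rng = np.random.default_rng(seed)
    tl = rng.uniform(*tl_range, n)
    vr = a + b * tl + rng.normal(0, slope_noise_sd, n)
    return [
        make_specimen(
            specimen_id=f"{sex[0]}{i}",
            sex=sex,
            total_length=float(t),
            vertebral_radius=float(max(v, 0.1)),
            band_radii=(float(max(v, 0.1)) * 0.2,),
        )
        for i, (t, v) in enumerate(zip(tl, vr))
    ]


class TestRadiusLengthRegression:
    def test_exact_line(self):
        specimens = _line_population(-0.65, 0.08, 0.0, 30, 0)
        reg = fit_radius_length(specimens, group_by_sex=False)["all"]
        assert reg.a == pytest.approx(-0.65, abs=1e-9)
        assert reg.b == pytest.approx(0.08, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_slope_within_3se(self):
        specimens = _line_population(-0.65, 0.08, 0.2, 200, 1)
        reg = fit_radius_length(specimens, group_by_sex=False)["all"]
        # se of the slope from residual scatter
        tl = np.array([s.total_length for s in specimens])
        se = 0.2 / np.sqrt(np.sum((tl - tl.mean()) ** 2))
        assert abs(reg.b - 0.08) < 3 * se

    def test_constant_length_rejected(self):
        specimens = [
            make_specimen(specimen_id=f"S{i}", total_length=60.0) for i in range(5)
        ]
        with pytest.raises(ValueError, match="constant"):
            fit_radius_length(specimens, group_by_sex=False)

    def test_too_few_specimens(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_radius_length([make_specimen()], group_by_sex=False)

    def test_by_sex_keys(self):
        specimens = _line_population(-0.65, 0.08, 0.05, 30, 2, sex="female")
        specimens += _line_population(-0.2, 0.07, 0.05, 30, 3, sex="male")
        regs = fit_radius_length(specimens, group_by_sex=True)
        assert set(regs) == {"female", "male"}


class TestCompareRegressions:
    def test_identical_groups_nonsignificant(self):
        f = _line_population(-0.65, 0.08, 0.1, 100, 4, sex="female")
        m = _line_population(-0.65, 0.08, 0.1, 100, 5, sex="male")
        res = compare_regressions(f + m)
        assert res.slope_p > 0.05
        assert res.elevation_p is not None and res.elevation_p > 0.05

    def test_different_slopes_detected(self):
        f = _line_population(-0.65, 0.08, 0.05, 200, 6, sex="female")
        m = _line_population(-0.65, 0.12, 0.05, 200, 7, sex="male")
        res = compare_regressions(f + m)
        assert res.slope_p < 0.05
        assert res.elevation_p is None
        assert "not applicable" in res.note

    def test_offset_intercepts_detected(self):
        f = _line_population(-0.65, 0.08, 0.05, 200, 8, sex="female")
        m = _line_population(-0.35, 0.08, 0.05, 200, 9, sex="male")
        res = compare_regressions(f + m)
        assert res.slope_p > 0.05
        assert res.elevation_p < 0.05

    def test_single_sex_rejected(self):
        with pytest.raises(ValueError):
            compare_regressions(_line_population(-0.65, 0.08, 0.05, 30, 10))


class TestBackCalculate:
    def test_exact_at_capture(self):
        assert back_calculate(80.0, 5.75, 5.75, -0.65, 0.08) == pytest.approx(80.0)

    def test_hand_arithmetic(self):
        # -(a/b) = 8.125
        assert back_calculate(80.0, 5.75, 2.875, -0.65, 0.08) == pytest.approx(44.0625)

    def test_small_radius_limit(self):
        val = back_calculate(80.0, 5.75, 1e-12, -0.65, 0.08)
        assert val == pytest.approx(8.125, abs=1e-6)

    def test_band_outside_centrum_rejected(self):
        with pytest.raises(ValueError):
            back_calculate(80.0, 5.0, 5.5, -0.65, 0.08)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            back_calculate(80.0, 5.0, 2.0, -0.65, 0.0)

    @given(
        st.floats(40.0, 90.0),
        st.floats(3.0, 8.0),
        st.floats(0.05, 1.0),
        st.floats(-2.0, 2.0),
        st.floats(0.02, 0.3),
    )
    @settings(max_examples=100)
    def test_capture_anchor_any_parameterization(self, l_c, vr_c, frac, a, b):
        assert back_calculate(l_c, vr_c, vr_c, a, b) == pytest.approx(l_c, rel=1e-9)
        lo = back_calculate(l_c, vr_c, vr_c * frac, a, b)
        hi = back_calculate(l_c, vr_c, vr_c * min(frac * 1.5, 1.0), a, b)
        if l_c + a / b > 0:  # monotone increasing in vr_i
            assert hi >= lo - 1e-9


class TestExpandDataset:
    def test_record_counting(self):
        reg = RadiusLengthRegression("all", -0.65, 0.08, 1.0, 10, 0.0)
        s = make_specimen(band_radii=(0.8, 2.0, 3.1, 4.0))  # 3 post-birth bands
        data = expand_dataset([s], AgeScheme.adjusted_dc(), reg)
        assert len(data) == 5  # 4 back-calculated + 1 observed
        assert (data["source"] == "back_calculated").sum() == 4

    def test_total_count_formula(self, default_population):
        specimens, _ = default_population
        reg = fit_radius_length(specimens, group_by_sex=False)["all"]
        data = expand_dataset(specimens, AgeScheme.adjusted_dc(), reg)
        expected = sum(len(s.band_radii) + 1 for s in specimens)
        assert len(data) == expected

    def test_age_zero_record_per_specimen(self, default_population):
        specimens, _ = default_population
        reg = fit_radius_length(specimens, group_by_sex=False)["all"]
        data = expand_dataset(specimens, AgeScheme.adjusted_dc(), reg)
        assert (data["age"] == 0.0).sum() == len(specimens)

    def test_noise_free_back_calculation_recovers_truth(self, noisefree_population):
        specimens, truth = noisefree_population
        reg = fit_radius_length(specimens, group_by_sex=False)["all"]
        scheme = AgeScheme.adjusted_dc()
        data = expand_dataset(specimens, scheme, reg, include_observed=False)
        merged = data.merge(
            truth.bands,
            left_on=["specimen_id", "band_index"],
            right_on=["specimen_id", "band_index"],
        )
        np.testing.assert_allclose(merged["length"], merged["band_length"], atol=1e-6)

    def test_lengths_nondecreasing_within_specimen(self, default_population):
        specimens, _ = default_population
        reg = fit_radius_length(specimens, group_by_sex=False)["all"]
        data = expand_dataset(specimens, AgeScheme.adjusted_dc(), reg)
        back = data[data["source"] == "back_calculated"]
        for _, sub in back.groupby("specimen_id"):
            lengths = sub.sort_values("band_index")["length"].to_numpy()
            assert (np.diff(lengths) >= -1e-12).all()

    def test_end_to_end_noise_free_fit_recovers_generator(self, noisefree_population):
        specimens, _ = noisefree_population
        reg = fit_radius_length(specimens, group_by_sex=False)["all"]
        data = expand_dataset(specimens, AgeScheme.adjusted_dc(), reg)
        fit = fit_model("VBG3", data["age"].to_numpy(), data["length"].to_numpy())
        assert fit.params.l_inf == pytest.approx(81.87, abs=1e-4)
        assert fit.params.k == pytest.approx(0.168, abs=1e-4)
        assert fit.params.t0 == pytest.approx(-1.384, abs=1e-4)

    def test_missing_radii_skipped_with_warning(self):
        reg = RadiusLengthRegression("all", -0.65, 0.08, 1.0, 10, 0.0)
        bare = make_specimen(specimen_id="BARE", band_radii=())
        full = make_specimen(specimen_id="FULL")
        with pytest.warns(UserWarning, match="skipped 1"):
            data = expand_dataset([bare, full], AgeScheme.adjusted_dc(), reg)
        assert set(data["specimen_id"]) == {"FULL"}
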