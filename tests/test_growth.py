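"""Growth-rate fitting, doubling times, production and predator budgets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypograze import (RegrowthSeries, SimConfig, doubling_time,
                       fit_growth_rate, gen_regrowth, predator_budget,
                       predator_doubling_time, production_removed, q10_scale)


def _series(rate, n0=1e6, days=7, reps=1):
    t = np.arange(days, dtype=float)
    return RegrowthSeries(day=t, abundance=np.tile(n0 * np.exp(rate * t), (reps, 1)))


class TestFitGrowthRate:
    def test_exact_on_pure_exponential(self):
        fit = fit_growth_rate(_series(0.136))
        assert fit.rate == pytest.approx(0.136, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.doubling_time_h == pytest.approx(24 * math.log(2) / 0.136)

    def test_independent_of_n0(self):
        f1 = fit_growth_rate(_series(0.2, n0=1e5))
        f2 = fit_growth_rate(_series(0.2, n0=1e7))
        assert f1.rate == pytest.approx(f2.rate, abs=1e-12)

    def test_constant_series_rate_zero(self):
        fit = fit_growth_rate(_series(0.0))
        assert fit.rate == 0.0
        assert math.isinf(fit.doubling_time_h)

    def test_window_skips_lag_phase(self):
        """With 2 flat days then growth, the best window avoids the lag."""
        cfg = SimConfig(seed=1, growth_rate_per_day=0.25, obs_cv=0.0,
                        regrowth_lag_days=2)
        fit = fit_growth_rate(gen_regrowth(cfg))
        assert fit.window[0] >= 2.0
        assert fit.rate == pytest.approx(0.25, abs=1e-9)

    def test_ties_broken_to_earliest_window(self):
        fit = fit_growth_rate(_series(0.1, days=7))
        assert fit.window == (0.0, 3.0)  # all windows exact; earliest wins

    def test_replicates_fit_then_averaged(self):
        cfg = SimConfig(seed=2, growth_rate_per_day=0.136)
        fit = fit_growth_rate(gen_regrowth(cfg, n_days=6, n_reps=3))
        assert len(fit.replicate_rates) == 3
        assert fit.rate == pytest.approx(np.mean(fit.replicate_rates))
        assert fit.rate_sd == pytest.approx(np.std(fit.replicate_rates, ddof=1))

    def test_recovery_under_observation_noise(self):
        """Median |error| < 5% of truth over 200 seeded triplicate assays."""
        errs = []
        for seed in range(200):
            cfg = SimConfig(seed=seed, growth_rate_per_day=0.136, obs_cv=0.03)
            fit = fit_growth_rate(gen_regrowth(cfg, n_days=6, n_reps=3))
            errs.append(abs(fit.rate - 0.136))
        assert np.median(errs) < 0.05 * 0.136

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_growth_rate(_series(0.1, days=3))

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(ValueError):
            RegrowthSeries(day=[0, 1, 2, 3], abundance=[1e6, 0.0, 1e6, 1e6])


class TestDoublingTime:
    @pytest.mark.parametrize("rate,hours", [
        (0.136, 122.3),  # 11 August assay
        (0.116, 143.4),  # 25 August assay
        (math.log(2), 24.0),
    ])
    def test_known_rates(self, rate, hours):
        assert doubling_time(rate) == pytest.approx(hours, abs=0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            doubling_time(0.0)

    @given(rate=st.floats(1e-3, 10))
    @settings(max_examples=50, deadline=None)
    def test_identity_r_times_td(self, rate):
        assert doubling_time(rate) * rate == pytest.approx(24 * math.log(2))


class TestProductionRemoved:
    def test_back_solved_linear_case(self):
        assert production_removed(8.50, 0.136) == pytest.approx(62.5, abs=0.01)

    def test_balanced_grazing(self):
        assert production_removed(13.6, 0.136) == pytest.approx(100.0)

    def test_zero_grazing(self):
        assert production_removed(0.0, 0.116) == 0.0

    def test_compounded_convention_is_smaller_denominator_aware(self):
        lin = production_removed(10.0, 0.2, convention="linear")
        comp = production_removed(10.0, 0.2, convention="compounded")
        assert comp < lin  # e^r - 1 > r

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            production_removed(10.0, 0.0)


class TestPredatorDoubling:
    def test_gge_endpoints_reconstruction(self):
        """Biovolume budget of the scuticociliate: 98.9–131.8 h over GGE
        40%–30% with the mean-dimension cell volume."""
        vol = math.pi / 6 * 17.1 * 8.5**2
        assert predator_doubling_time(202, 0.081, vol, 0.30) == pytest.approx(131.8, abs=1.0)
        assert predator_doubling_time(202, 0.081, vol, 0.40) == pytest.approx(98.9, abs=1.0)

    def test_unit_case(self):
        # gge=1 and daily ingested volume equal to predator volume → 24 h
        assert predator_doubling_time(1.0, 1.0, 24.0, 1.0) == pytest.approx(24.0)

    def test_budget_range_ordering(self):
        pb = predator_budget(202, 0.081, 661.0)
        lo, hi = pb.doubling_time_range_h
        assert lo < hi  # higher GGE doubles faster
        assert pb.ingested_volume_daily == pytest.approx(202 * 24 * 0.081)

    def test_exponential_convention_scales_by_ln2(self):
        lin = predator_doubling_time(202, 0.081, 661, 0.3)
        exp = predator_doubling_time(202, 0.081, 661, 0.3, convention="exponential")
        assert exp == pytest.approx(lin * math.log(2))

    @given(
        uptake=st.floats(1, 1000), mcv=st.floats(0.01, 1),
        vol=st.floats(10, 1e4), gge=st.floats(0.05, 1.0),
        c=st.floats(1.1, 4.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_proportionality(self, uptake, mcv, vol, gge, c):
        base = predator_doubling_time(uptake, mcv, vol, gge)
        assert predator_doubling_time(uptake * c, mcv, vol, gge) == pytest.approx(base / c)
        assert predator_doubling_time(uptake, mcv, vol * c, gge) == pytest.approx(base * c)
        if gge * c <= 1.0:
            assert predator_doubling_time(uptake, mcv, vol, gge * c) == pytest.approx(base / c)

    def test_invalid_gge_rejected(self):
        with pytest.raises(ValueError):
            predator_doubling_time(202, 0.081, 661, 1.5)


class TestQ10:
    def test_identity_same_temperature(self):
        assert q10_scale(0.136, 5.8, 5.8) == 0.136

    def test_ten_degree_drop(self):
        assert q10_scale(1.0, 15.8, 5.8, 2.5) == pytest.approx(0.4)

    def test_hypolimnion_to_epilimnion(self):
        # 5.8 → 20 °C at Q10 2.5: ~3.7-fold faster
        assert q10_scale(1.0, 5.8, 20.0, 2.5) == pytest.approx(3.67, abs=0.01)

    @given(t1=st.floats(0, 30), t2=st.floats(0, 30), t3=st.floats(0, 30))
    @settings(max_examples=50, deadline=None)
    def test_composition(self, t1, t2, t3):
        direct = q10_scale(1.0, t1, t3)
        via = q10_scale(q10_scale(1.0, t1, t2), t2, t3)
        assert via == pytest.approx(direct, rel=1e-9)
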