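"""Synthetic generators: moments, determinism and degenerate cases.

The gamma-Poisson count generator is cross-checked against an independent
two-stage Monte-Carlo oracle (rates drawn with scipy, counts with a separate
Poisson stream) rather than against its own output.
"""

import numpy as np
import pytest
from scipy import stats

from hypograze import (SimConfig, default_ciliate_config, gen_cell_dims,
                       gen_flb_counts, gen_regrowth, gen_timeseries)


def _mixture_oracle(mean, sd, f, minutes, n, seed):
    """Two-stage gamma-Poisson reference draw, independent of the package."""
    rng = np.random.RandomState(seed)
    shape = (mean / sd) ** 2
    rates = stats.gamma.rvs(shape, scale=sd**2 / mean, size=n, random_state=rng)
    return stats.poisson.rvs(rates * f * minutes / 60.0, random_state=rng)


class TestFlbCounts:
    def test_mean_matches_closed_form(self):
        """E[count] = U·f·t/60 ≈ 6.06 under the study's ciliate settings."""
        cfg = default_ciliate_config(seed=1, n_cells_inspected=100_000)
        counts = gen_flb_counts(cfg, "ciliate").counts
        expected = 202 * 0.18 * 10 / 60
        assert counts.mean() == pytest.approx(expected, rel=0.01)

    def test_variance_matches_mixture_oracle(self):
        """Mean and overdispersed variance match an independent two-stage
        Monte-Carlo draw of the same gamma-Poisson mixture."""
        cfg = default_ciliate_config(seed=2, n_cells_inspected=200_000)
        counts = gen_flb_counts(cfg, "ciliate").counts
        oracle = _mixture_oracle(202, 103, 0.18, 10, 200_000, seed=1234)
        m = 202 * 0.18 * 10 / 60
        var_analytic = m + (m * 103 / 202) ** 2  # Poisson + gamma heterogeneity
        assert counts.mean() == pytest.approx(oracle.mean(), rel=0.01)
        assert counts.mean() == pytest.approx(m, rel=0.01)
        assert counts.var() == pytest.approx(var_analytic, rel=0.03)
        assert oracle.var() == pytest.approx(var_analytic, rel=0.03)

    def test_zero_mean_limit_gives_all_zero_counts(self):
        cfg = default_ciliate_config(seed=3, true_uptake_mean=1e-12,
                                     true_uptake_sd=0.0)
        counts = gen_flb_counts(cfg, "ciliate").counts
        assert np.all(counts == 0)

    def test_sd_zero_is_pure_poisson(self):
        """Without heterogeneity, counts are Poisson: variance ≈ mean."""
        cfg = SimConfig(seed=4, true_uptake_mean=5.0, true_uptake_sd=0.0,
                        tracer_fraction=0.999, incubation_min=60,
                        n_cells_inspected=20_000)
        counts = gen_flb_counts(cfg, "ciliate").counts
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_counts_are_nonnegative_integers(self, ciliate_cfg):
        counts = gen_flb_counts(ciliate_cfg, "hnf").counts
        assert counts.min() >= 0
        assert np.issubdtype(counts.dtype, np.integer)

    def test_bad_group_rejected(self, ciliate_cfg):
        with pytest.raises(ValueError):
            gen_flb_counts(ciliate_cfg, "copepod")

    @pytest.mark.parametrize("bad", [
        dict(tracer_fraction=0.0), dict(tracer_fraction=1.2),
        dict(incubation_min=-5), dict(true_uptake_mean=float("nan")),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(seed=0, **bad)

    def test_lognormal_heterogeneity_matches_moments(self):
        cfg = default_ciliate_config(seed=5, heterogeneity="lognormal",
                                     n_cells_inspected=100_000)
        counts = gen_flb_counts(cfg, "ciliate").counts
        assert counts.mean() == pytest.approx(202 * 0.18 / 6, rel=0.01)


class TestCellDims:
    def test_sample_means_within_3se(self):
        dims = gen_cell_dims(SimConfig(seed=7, n_cells_inspected=100))
        L = np.array([d.length for d in dims])
        W = np.array([d.width for d in dims])
        assert abs(L.mean() - 17.1) < 3 * 1.4 / 10
        assert abs(W.mean() - 8.5) < 3 * 1.3 / 10

    def test_degenerate_sds_give_exact_means(self):
        dims = gen_cell_dims(SimConfig(seed=8, length_sd_um=0, width_sd_um=0,
                                       n_cells_inspected=10))
        assert all(d.length == 17.1 and d.width == 8.5 for d in dims)

    def test_perfect_correlation_equal_cv(self):
        cv = 1.4 / 17.1
        dims = gen_cell_dims(SimConfig(seed=9, dim_correlation=1.0,
                                       width_sd_um=8.5 * cv,
                                       n_cells_inspected=500))
        L = np.array([d.length for d in dims])
        W = np.array([d.width for d in dims])
        assert np.corrcoef(L, W)[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_length_geq_width_always(self):
        # wide config provokes draws with W > L, which must be swapped
        dims = gen_cell_dims(SimConfig(seed=10, length_mean_um=9.0,
                                       length_sd_um=2.0, width_mean_um=8.5,
                                       width_sd_um=2.0, n_cells_inspected=2000))
        assert all(d.length >= d.width > 0 for d in dims)


class TestRegrowth:
    def test_noiseless_closed_form(self):
        cfg = SimConfig(seed=11, growth_rate_per_day=0.136, obs_cv=0.0)
        s = gen_regrowth(cfg, n_days=6, n_reps=1)
        assert s.abundance[0, 3] == pytest.approx(1e6 * np.exp(0.408), rel=1e-12)

    def test_zero_rate_constant_series(self):
        cfg = SimConfig(seed=12, growth_rate_per_day=0.0, obs_cv=0.0)
        s = gen_regrowth(cfg)
        assert np.allclose(s.abundance, 1e6)

    def test_lag_flattens_leading_days(self):
        cfg = SimConfig(seed=13, growth_rate_per_day=0.2, obs_cv=0.0,
                        regrowth_lag_days=2)
        s = gen_regrowth(cfg)
        assert np.allclose(s.abundance[0, :3], 1e6)
        assert s.abundance[0, 3] > s.abundance[0, 2]

    def test_replicates_share_rate(self):
        cfg = SimConfig(seed=14, obs_cv=0.0)
        s = gen_regrowth(cfg, n_reps=3)
        assert np.allclose(s.abundance[0], s.abundance[2])

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            gen_regrowth(SimConfig(seed=15), n_days=3)


class TestTimeseries:
    def test_campaign_has_18_samplings(self):
        obs = gen_timeseries(SimConfig(seed=16))
        assert len(obs) == 18

    def test_zero_cv_hits_configured_means(self):
        obs = gen_timeseries(SimConfig(seed=17, obs_cv=0.0))
        assert obs[0].prok_per_ml == pytest.approx(1.35e6)
        assert obs[0].hnf_per_ml == pytest.approx(700)
        assert obs[-1].ciliates_per_ml == pytest.approx(10)

    def test_oxygen_declines_temperature_stable(self):
        obs = gen_timeseries(SimConfig(seed=18))
        o2 = [o.oxygen_mg_l for o in obs]
        assert o2[0] == pytest.approx(5.8) and o2[-1] == pytest.approx(3.8)
        assert all(a >= b for a, b in zip(o2, o2[1:]))
        assert {o.temperature_c for o in obs} == {5.8}

    def test_all_quantities_positive(self):
        for o in gen_timeseries(SimConfig(seed=19, obs_cv=0.5)):
            assert min(o.prok_per_ml, o.hnf_per_ml, o.ciliates_per_ml) > 0


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = gen_flb_counts(default_ciliate_config(seed=42), "ciliate")
        b = gen_flb_counts(default_ciliate_config(seed=42), "ciliate")
        assert np.array_equal(a.counts, b.counts)
        da = gen_cell_dims(SimConfig(seed=42))
        db = gen_cell_dims(SimConfig(seed=42))
        assert da == db
        ra = gen_regrowth(SimConfig(seed=42))
        rb = gen_regrowth(SimConfig(seed=42))
        assert np.array_equal(ra.abundance, rb.abundance)

    def test_streams_independent_of_call_order(self):
        cfg = SimConfig(seed=7)
        first = gen_regrowth(cfg).abundance
        gen_flb_counts(cfg, "ciliate")  # interleaved call must not perturb
        again = gen_regrowth(SimConfig(seed=7)).abundance
        assert np.array_equal(first, again)

    def test_different_seeds_differ(self):
        a = gen_flb_counts(default_ciliate_config(seed=1), "ciliate").counts
        b = gen_flb_counts(default_ciliate_config(seed=2), "ciliate").counts
        assert not np.array_equal(a, b)
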