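"""Synthetic hypolimnion measurements with the statistical structure the
analysis assumes.

Four generators emulate the study's data streams: tracer-FLB counts per
inspected grazer cell (a gamma-Poisson mixture — per-cell uptake rates are
gamma-heterogeneous and counts conditionally Poisson), cell length/width
pairs (truncated bivariate normal), 1-μm-filtered regrowth series
(exponential growth with multiplicative lognormal observation noise), and a
sampling-campaign time series of abundances with physical context.

All randomness derives from ``SimConfig.seed`` through fixed per-operation
sub-streams, so identical configs give bit-identical output regardless of
the order in which generators are called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biometry import CellDimension
from .config import SimConfig
from .grazing import TracerExperiment
from .growth import RegrowthSeries

__all__ = [
    "SampleObservation",
    "gen_flb_counts",
    "gen_cell_dims",
    "gen_regrowth",
    "gen_timeseries",
]

# fixed sub-stream keys: one independent generator per operation
_STREAMS = {"flb": 11, "dims": 23, "regrowth": 37, "timeseries": 53}

_GRAZER_GROUPS = ("ciliate", "hnf")


@dataclass
class SampleObservation:
    """One sampling date's abundances and physical context at one depth."""

    date: str
    prok_per_ml: float
    hnf_per_ml: float
    ciliates_per_ml: float
    temperature_c: float
    oxygen_mg_l: float


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(cfg.seed),
                               spawn_key=(_STREAMS[stream],))
    )


def _draw_rates(rng: np.random.Generator, mean: float, sd: float,
                n: int, family: str) -> np.ndarray:
    """Per-cell true uptake rates with the configured heterogeneity."""
    if mean == 0:
        return np.zeros(n)
    if sd == 0:
        return np.full(n, mean)
    if family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return rng.gamma(shape, scale, size=n)
    # lognormal with matching mean and SD
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def gen_flb_counts(cfg: SimConfig, group: str = "ciliate",
                   date: str | None = None) -> TracerExperiment:
    """Simulate per-cell FLB counts from one tracer incubation.

    Each inspected cell ingests at a true rate U_i drawn from the
    heterogeneity distribution (gamma by default, mean ``true_uptake_mean``,
    SD ``true_uptake_sd``); its count is Poisson(U_i · f · t/60), with f the
    tracer fraction and t the incubation in minutes. The expected mean count
    is therefore U·f·t/60 and the counts are overdispersed relative to
    Poisson whenever SD > 0. Cells with zero counts are retained.
    """
    if group not in _GRAZER_GROUPS:
        raise ValueError(f"group must be one of {_GRAZER_GROUPS}, got {group!r}")
    cfg.validate()
    rng = _rng(cfg, "flb")
    rates = _draw_rates(rng, cfg.true_uptake_mean, cfg.true_uptake_sd,
                        cfg.n_cells_inspected, cfg.heterogeneity)
    lam = rates * cfg.tracer_fraction * cfg.incubation_min / 60.0
    counts = rng.poisson(lam)
    return TracerExperiment(
        group=group,
        tracer_fraction=cfg.tracer_fraction,
        incubation_min=cfg.incubation_min,
        counts=counts,
        date=date,
    )


def gen_cell_dims(cfg: SimConfig) -> list[CellDimension]:
    """Simulate length/width pairs of the sized cells.

    Pairs are bivariate normal with the configured means, SDs and
    correlation, truncated at zero by redrawing (no point mass at 0);
    length >= width is enforced by swapping the rare violating pair.
    """
    cfg.validate()
    rng = _rng(cfg, "dims")
    n = cfg.n_cells_inspected
    mean = np.array([cfg.length_mean_um, cfg.width_mean_um])
    sds = np.array([cfg.length_sd_um, cfg.width_sd_um])
    if np.all(sds == 0):
        pairs = np.tile(mean, (n, 1))
    else:
        cov = np.diag(sds**2).astype(float)
        cov[0, 1] = cov[1, 0] = cfg.dim_correlation * sds[0] * sds[1]
        pairs = np.empty((0, 2))
        while pairs.shape[0] < n:
            draw = rng.multivariate_normal(mean, cov, size=n,
                                           method="svd")
            draw = draw[np.all(draw > 0, axis=1)]
            pairs = np.vstack([pairs, draw])
        pairs = pairs[:n]
    out = []
    for length, width in pairs:
        if length < width:
            length, width = width, length
        out.append(CellDimension(float(length), float(width)))
    return out


def gen_regrowth(cfg: SimConfig, n_days: int = 6,
                 n_reps: int = 3) -> RegrowthSeries:
    """Simulate replicate regrowth series from a 1-μm-filtered incubation.

    abundance(t, rep) = N0 · exp(r·max(t − k, 0)) · ε with ε lognormal,
    mean 1 and CV ``obs_cv``; k = ``regrowth_lag_days`` flattens the first
    days to mimic a post-filtration lag (default 0). All replicates share
    the true rate r.
    """
    if n_days < 4:
        raise ValueError("need at least 4 daily points (n_days >= 4)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg.validate()
    rng = _rng(cfg, "regrowth")
    day = np.arange(n_days + 1, dtype=float)  # day 0 .. n_days
    t_eff = np.maximum(day - cfg.regrowth_lag_days, 0.0)
    expected = cfg.regrowth_n0 * np.exp(cfg.growth_rate_per_day * t_eff)
    if cfg.obs_cv == 0:
        noise = np.ones((n_reps, day.size))
    else:
        sigma2 = np.log1p(cfg.obs_cv**2)
        noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2),
                              size=(n_reps, day.size))
    return RegrowthSeries(day=day, abundance=expected[None, :] * noise)


def gen_timeseries(cfg: SimConfig) -> list[SampleObservation]:
    """Simulate the sampling campaign's abundance/context time series.

    Dates are evenly spaced; prokaryote, HNF and ciliate abundances are
    lognormal (mean at the configured level, CV ``obs_cv``); temperature is
    the stable hypolimnetic value and oxygen declines linearly over the
    campaign.
    """
    if cfg.n_dates < 1:
        raise ValueError("n_dates must be >= 1")
    cfg.validate()
    rng = _rng(cfg, "timeseries")
    dates = pd.date_range("2023-08-07", periods=cfg.n_dates, freq="2D")
    if cfg.n_dates > 1:
        oxygen = np.linspace(cfg.oxygen_start_mg_l, cfg.oxygen_end_mg_l,
                             cfg.n_dates)
    else:
        oxygen = np.array([cfg.oxygen_start_mg_l])
    means = np.array([cfg.prok_mean, cfg.hnf_mean, cfg.ciliate_mean])
    if cfg.obs_cv == 0:
        abund = np.tile(means, (cfg.n_dates, 1))
    else:
        sigma2 = np.log1p(cfg.obs_cv**2)
        abund = means[None, :] * rng.lognormal(
            -sigma2 / 2.0, np.sqrt(sigma2), size=(cfg.n_dates, 3)
        )
    return [
        SampleObservation(
            date=d.date().isoformat(),
            prok_per_ml=float(a[0]),
            hnf_per_ml=float(a[1]),
            ciliates_per_ml=float(a[2]),
            temperature_c=cfg.temperature_c,
            oxygen_mg_l=float(o),
        )
        for d, a, o in zip(dates, abund, oxygen)
    ]
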