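"""Simulation configuration for the synthetic-data generator."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class SimConfig:
    """Parameters of the synthetic hypolimnion study.

    Defaults mirror the field conditions the generator emulates: a cold
    (5.8 °C) oxic hypolimnion sampled 18 times, FLB tracer added at ~18%
    of total prokaryotes, short incubations, and a dominant bacterivorous
    scuticociliate with mean cell-specific uptake 202 ± 103 prey h⁻¹ and
    cell dimensions 17.1 ± 1.4 × 8.5 ± 1.3 μm.

    Parameters
    ----------
    seed
        Root seed; every generator operation derives its own sub-stream
        deterministically from it, so identical configs give bit-identical
        output regardless of call order.
    true_uptake_mean, true_uptake_sd
        Mean and SD (prey·cell⁻¹·h⁻¹) of the per-cell uptake-rate
        distribution (gamma by default, lognormal via ``heterogeneity``).
    tracer_fraction
        FLB as a fraction of *total* prokaryotes (tracer + ambient), in (0,1).
    incubation_min
        Tracer incubation length in minutes.
    obs_cv
        Multiplicative (lognormal) observation noise CV applied to
        abundances and regrowth counts.
    regrowth_lag_days
        Number of leading days of a regrowth series held flat before
        exponential growth starts (growth-lag after filtration); default 0.
    """

    seed: int = 0
    n_dates: int = 18
    prok_mean: float = 1.35e6       # cells ml-1
    hnf_mean: float = 700.0         # cells ml-1
    ciliate_mean: float = 10.0      # cells ml-1
    true_uptake_mean: float = 202.0  # prey cell-1 h-1
    true_uptake_sd: float = 103.0
    tracer_fraction: float = 0.18
    incubation_min: float = 10.0
    n_cells_inspected: int = 960
    length_mean_um: float = 17.1
    length_sd_um: float = 1.4
    width_mean_um: float = 8.5
    width_sd_um: float = 1.3
    dim_correlation: float = 0.0
    growth_rate_per_day: float = 0.136
    regrowth_n0: float = 1.0e6      # cells ml-1 after 1-um filtration
    regrowth_lag_days: int = 0
    obs_cv: float = 0.03
    temperature_c: float = 5.8
    oxygen_start_mg_l: float = 5.8
    oxygen_end_mg_l: float = 3.8
    heterogeneity: str = "gamma"    # or "lognormal"
    include_zero_cells: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "n_dates": self.n_dates,
            "prok_mean": self.prok_mean,
            "hnf_mean": self.hnf_mean,
            "ciliate_mean": self.ciliate_mean,
            "incubation_min": self.incubation_min,
            "n_cells_inspected": self.n_cells_inspected,
            "length_mean_um": self.length_mean_um,
            "width_mean_um": self.width_mean_um,
            "regrowth_n0": self.regrowth_n0,
        }
        for name, value in positive.items():
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and positive, got {value}")
        nonneg = {
            "true_uptake_mean": self.true_uptake_mean,
            "true_uptake_sd": self.true_uptake_sd,
            "length_sd_um": self.length_sd_um,
            "width_sd_um": self.width_sd_um,
            "obs_cv": self.obs_cv,
            "regrowth_lag_days": self.regrowth_lag_days,
        }
        for name, value in nonneg.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {value}")
        if not (0.0 < self.tracer_fraction < 1.0):
            raise ValueError(
                f"tracer_fraction must lie in (0,1), got {self.tracer_fraction}"
            )
        if abs(self.dim_correlation) > 1.0:
            raise ValueError("|dim_correlation| must be <= 1")
        if self.heterogeneity not in ("gamma", "lognormal"):
            raise ValueError("heterogeneity must be 'gamma' or 'lognormal'")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls(**json.loads(Path(path).read_text()))


def default_ciliate_config(seed: int = 0, **overrides) -> SimConfig:
    """Tracer settings for the dominant scuticociliate (10-min incubation)."""
    kw = dict(seed=seed, true_uptake_mean=202.0, true_uptake_sd=103.0,
              incubation_min=10.0, n_cells_inspected=960)
    kw.update(overrides)
    return SimConfig(**kw)


def default_hnf_config(seed: int = 0, **overrides) -> SimConfig:
    """Tracer settings for heterotrophic nanoflagellates (60-min incubation).

    Community HNF uptake rates in the emulated system span roughly
    3.5–11.8 prey h⁻¹; the default mean 7.0 ± 2.5 sits mid-range.
    """
    kw = dict(seed=seed, true_uptake_mean=7.0, true_uptake_sd=2.5,
              incubation_min=60.0, n_cells_inspected=400)
    kw.update(overrides)
    return SimConfig(**kw)
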