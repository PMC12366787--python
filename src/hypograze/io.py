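"""Table readers/writers and the end-to-end pipeline.

All inputs are delimiter-separated text (comma or tab, auto-detected) with
headers; outputs are always comma-delimited. Each reader role has a fixed
schema; validation errors carry row-addressed messages. Dates are accepted
in ISO-8601 or natural "11 August, 2023" style and normalized to ISO on
output.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biometry import CellDimension, mcv_from_dims, prolate_spheroid_volume
from .community import TaxonRecord, bacterivory_shares, composition_summary
from .config import SimConfig, default_ciliate_config, default_hnf_config
from .grazing import (TracerExperiment, cell_specific_uptake,
                      community_grazing, uptake_histogram)
from .growth import (RegrowthSeries, fit_growth_rate, predator_budget,
                     production_removed)
from . import synthetic

log = logging.getLogger("hypograze")

SCHEMAS: dict[str, list[str]] = {
    "abundance": ["date", "group", "cells_per_ml"],
    "counts": ["date", "group", "taxon", "flb_count"],
    "incubation": ["date", "group", "tracer_fraction", "incubation_min"],
    "regrowth": ["day", "replicate", "cells_per_ml"],
    "dims": ["length_um", "width_um"],
    "taxa": ["name", "class_name", "feeding_mode", "uptake_mean",
             "uptake_sd", "proportion_pct"],
    "timeseries": ["date", "prok_per_ml", "hnf_per_ml", "ciliates_per_ml",
                   "temperature_c", "oxygen_mg_l"],
}

_NUMERIC = {
    "abundance": ["cells_per_ml"],
    "counts": ["flb_count"],
    "incubation": ["tracer_fraction", "incubation_min"],
    "regrowth": ["day", "replicate", "cells_per_ml"],
    "dims": ["length_um", "width_um"],
    "taxa": ["proportion_pct"],
    "timeseries": ["prok_per_ml", "hnf_per_ml", "ciliates_per_ml",
                   "temperature_c", "oxygen_mg_l"],
}

_UNIQUE_KEYS = {"abundance": ["date", "group"], "incubation": ["date", "group"]}


class SchemaError(ValueError):
    """Input file does not match its role's schema."""


def _read_delimited(path: str | Path) -> pd.DataFrame:
    text = Path(path).read_text()
    if not text.strip():
        raise SchemaError(f"{path}: file is empty")
    sep = "\t" if text.splitlines()[0].count("\t") > text.splitlines()[0].count(",") else ","
    log.info("reading %s (delimiter %r)", path, sep)
    return pd.read_csv(_io.StringIO(text), sep=sep)


def read_table(path: str | Path, role: str) -> pd.DataFrame:
    """Read and validate a delimited table for the given schema role.

    Returns a DataFrame with normalized columns. Raises :class:`SchemaError`
    on missing columns, non-numeric cells, negative quantities, or
    duplicated key rows, naming the offending rows.
    """
    if role not in SCHEMAS:
        raise ValueError(f"unknown schema role {role!r}; known: {sorted(SCHEMAS)}")
    if not Path(path).exists():
        raise FileNotFoundError(path)
    df = _read_delimited(path)
    missing = [c for c in SCHEMAS[role] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} for role {role!r}")
    df = df[SCHEMAS[role]].copy()
    for col in _NUMERIC[role]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()].tolist()
        if bad:
            raise SchemaError(
                f"{path}: non-numeric values in column {col!r}, rows "
                f"{[i + 2 for i in bad]} (1-based incl. header)"
            )
        if col not in ("temperature_c",) and (vals < 0).any():
            neg = df.index[vals < 0].tolist()
            raise SchemaError(
                f"{path}: negative values in column {col!r}, rows "
                f"{[i + 2 for i in neg]}"
            )
        df[col] = vals
    if role == "taxa":
        for col in ("uptake_mean", "uptake_sd"):
            df[col] = pd.to_numeric(df[col], errors="coerce")  # blank => NaN
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"], format="mixed",
                                    dayfirst=False).dt.date.astype(str)
    key = _UNIQUE_KEYS.get(role)
    if key:
        dup = df[df.duplicated(key, keep=False)]
        if not dup.empty:
            pairs = sorted(set(map(tuple, dup[key].values.tolist())))
            raise SchemaError(f"{path}: duplicated {key} rows: {pairs}")
    log.info("role %s: %d rows, %d columns", role, len(df), df.shape[1])
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as comma-delimited text (no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# typed conversions between tables and domain objects

def experiments_from_tables(counts: pd.DataFrame,
                            incubation: pd.DataFrame) -> list[TracerExperiment]:
    """Join per-cell count rows with incubation metadata by (date, group)."""
    meta = incubation.set_index(["date", "group"])
    out = []
    for (date, group), sub in counts.groupby(["date", "group"], sort=True):
        try:
            row = meta.loc[(date, group)]
        except KeyError:
            raise SchemaError(
                f"no incubation metadata for date={date!r} group={group!r}"
            ) from None
        out.append(TracerExperiment(
            group=str(group),
            tracer_fraction=float(row["tracer_fraction"]),
            incubation_min=float(row["incubation_min"]),
            counts=sub["flb_count"].to_numpy(dtype=int),
            date=str(date),
        ))
    return out


def regrowth_from_table(df: pd.DataFrame) -> RegrowthSeries:
    wide = df.pivot_table(index="replicate", columns="day",
                          values="cells_per_ml", sort=True)
    if wide.isna().any().any():
        raise SchemaError("regrowth table has missing day×replicate cells")
    return RegrowthSeries(day=wide.columns.to_numpy(dtype=float),
                          abundance=wide.to_numpy(dtype=float))


def taxa_from_table(df: pd.DataFrame) -> list[TaxonRecord]:
    out = []
    for _, r in df.iterrows():
        out.append(TaxonRecord(
            name=str(r["name"]),
            class_name=str(r["class_name"]),
            feeding_mode=str(r["feeding_mode"]),
            proportion_pct=float(r["proportion_pct"]),
            uptake_mean=None if pd.isna(r["uptake_mean"]) else float(r["uptake_mean"]),
            uptake_sd=None if pd.isna(r["uptake_sd"]) else float(r["uptake_sd"]),
        ))
    return out


def dims_from_table(df: pd.DataFrame) -> list[CellDimension]:
    return [CellDimension(float(r.length_um), float(r.width_um))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run.

    ``inputs`` maps schema roles (counts, incubation, abundance or
    timeseries, regrowth, dims, taxa) to file paths; roles left out are
    synthesized from ``sim`` so a default run needs no files at all.
    """

    output_dir: str | Path
    inputs: dict[str, str] = field(default_factory=dict)
    sim: SimConfig = field(default_factory=SimConfig)
    class_width: float = 100.0
    include_zeros: bool = True
    tracer_convention: str = "total"
    production_convention: str = "linear"
    doubling_convention: str = "linear"
    prey_mcv: float = 0.081          # um^3, measured prokaryote MCV
    predator_volume: float | None = None  # um^3; None => from dims
    gge_low: float = 0.30
    gge_high: float = 0.40
    q10: float = 2.5

    def __post_init__(self) -> None:
        for role, path in self.inputs.items():
            if role not in SCHEMAS:
                raise ValueError(f"unknown input role {role!r}")
            if not Path(path).exists():
                raise FileNotFoundError(f"input {role!r}: {path}")
        if self.production_convention not in ("linear", "compounded"):
            raise ValueError("production_convention must be linear|compounded")
        if self.tracer_convention not in ("total", "ambient"):
            raise ValueError("tracer_convention must be total|ambient")


def simulate_inputs(cfg: SimConfig, out_dir: str | Path) -> dict[str, str]:
    """Write a full set of synthetic input tables plus a config sidecar.

    Emits the same schemas the readers consume: timeseries, counts,
    incubation, abundance, regrowth, dims — with ciliate tracer settings
    from the passed config and HNF settings from ``default_hnf_config``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    obs = synthetic.gen_timeseries(cfg)
    ts = pd.DataFrame([vars(o) for o in obs])
    paths["timeseries"] = str(out_dir / "timeseries.csv")
    write_table(ts, paths["timeseries"])

    abund = pd.concat([
        pd.DataFrame({"date": ts["date"], "group": "ciliate",
                      "cells_per_ml": ts["ciliates_per_ml"]}),
        pd.DataFrame({"date": ts["date"], "group": "hnf",
                      "cells_per_ml": ts["hnf_per_ml"]}),
    ], ignore_index=True)
    paths["abundance"] = str(out_dir / "abundance.csv")
    write_table(abund, paths["abundance"])

    date0 = ts["date"].iloc[0]
    cil = synthetic.gen_flb_counts(cfg, "ciliate", date=date0)
    hnf_cfg = default_hnf_config(seed=int(cfg.seed) + 1,
                                 tracer_fraction=cfg.tracer_fraction,
                                 obs_cv=cfg.obs_cv)
    hnf = synthetic.gen_flb_counts(hnf_cfg, "hnf", date=date0)
    counts = pd.concat([
        pd.DataFrame({"date": e.date, "group": e.group, "taxon": tax,
                      "flb_count": e.counts})
        for e, tax in ((cil, "scuticociliate"), (hnf, "hnf"))
    ], ignore_index=True)
    paths["counts"] = str(out_dir / "flb_counts.csv")
    write_table(counts, paths["counts"])

    inc = pd.DataFrame([
        {"date": e.date, "group": e.group, "tracer_fraction": e.tracer_fraction,
         "incubation_min": e.incubation_min}
        for e in (cil, hnf)
    ])
    paths["incubation"] = str(out_dir / "incubation.csv")
    write_table(inc, paths["incubation"])

    series = synthetic.gen_regrowth(cfg)
    reg = pd.DataFrame([
        {"day": d, "replicate": rep + 1, "cells_per_ml": series.abundance[rep, i]}
        for rep in range(series.n_reps) for i, d in enumerate(series.day)
    ])
    paths["regrowth"] = str(out_dir / "regrowth.csv")
    write_table(reg, paths["regrowth"])

    dims = synthetic.gen_cell_dims(
        SimConfig(seed=cfg.seed, n_cells_inspected=100,
                  length_mean_um=cfg.length_mean_um,
                  length_sd_um=cfg.length_sd_um,
                  width_mean_um=cfg.width_mean_um,
                  width_sd_um=cfg.width_sd_um,
                  dim_correlation=cfg.dim_correlation)
    )
    dimdf = pd.DataFrame({"length_um": [d.length for d in dims],
                          "width_um": [d.width for d in dims]})
    paths["dims"] = str(out_dir / "cell_dimensions.csv")
    write_table(dimdf, paths["dims"])

    cfg.to_json(out_dir / "sim_config.json")
    return paths


def run_pipeline(cfg: RunConfig) -> dict:
    """Run tracer grazing → growth/budget → community and write the report.

    Returns a bundle dict with the fitted/derived objects; writes
    budget.csv, uptake_histogram.csv, shares.csv (when taxa supplied) and a
    summary.txt restating every convention used. Output bytes depend only
    on the inputs and the config (fixed-seed runs are reproducible).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = dict(cfg.inputs)
    if not {"counts", "incubation", "abundance"} <= set(inputs):
        log.info("synthesizing missing core inputs under %s", out / "synthetic")
        synth = simulate_inputs(cfg.sim, out / "synthetic")
        for role, p in synth.items():
            inputs.setdefault(role, p)

    bundle: dict = {"conventions": {
        "tracer_fraction": cfg.tracer_convention,
        "production": cfg.production_convention,
        "predator_doubling": cfg.doubling_convention,
        "zeros_included": cfg.include_zeros,
        "histogram_class_width": cfg.class_width,
    }}

    # --- tracer grazing stage ---
    counts = read_table(inputs["counts"], "counts")
    incubation = read_table(inputs["incubation"], "incubation")
    abundance = read_table(inputs["abundance"], "abundance")
    experiments = experiments_from_tables(counts, incubation)
    estimates = {}
    for exp in experiments:
        est = cell_specific_uptake(exp, include_zeros=cfg.include_zeros)
        estimates[exp.group] = est
    mean_abund = abundance.groupby("group")["cells_per_ml"].mean().to_dict()
    prok = None
    if "timeseries" in inputs:
        ts = read_table(inputs["timeseries"], "timeseries")
        prok = float(ts["prok_per_ml"].mean())
    if prok is None:
        raise SchemaError("prokaryote abundance required (timeseries input)")
    budget = community_grazing(
        {g: estimates[g] for g in estimates},
        {g: mean_abund[g] for g in estimates},
        prok_abundance=prok,
    )
    bundle["uptake_estimates"] = estimates
    bundle["grazing_budget"] = budget
    hist = uptake_histogram(estimates["ciliate"], cfg.class_width) \
        if "ciliate" in estimates else None
    if hist is not None:
        write_table(hist, out / "uptake_histogram.csv")
        bundle["uptake_histogram"] = hist

    # --- growth stage ---
    fit = None
    if "regrowth" in inputs:
        series = regrowth_from_table(read_table(inputs["regrowth"], "regrowth"))
        fit = fit_growth_rate(series)
        bundle["growth_fit"] = fit
        bundle["production_removed_pct"] = production_removed(
            budget.pct_standing_stock_daily, fit.rate,
            convention=cfg.production_convention)
    else:
        log.warning("no regrowth input: growth stage skipped, "
                    "production_removed omitted")

    # --- predator budget ---
    predator_volume = cfg.predator_volume
    dims_stats = None
    if predator_volume is None and "dims" in inputs:
        dims = dims_from_table(read_table(inputs["dims"], "dims"))
        dims_stats = mcv_from_dims(dims)
        predator_volume = dims_stats.mean
        bundle["predator_biovolume"] = dims_stats
    if predator_volume is not None and "ciliate" in estimates:
        pb = predator_budget(estimates["ciliate"].mean, cfg.prey_mcv,
                             predator_volume, cfg.gge_low, cfg.gge_high,
                             convention=cfg.doubling_convention)
        bundle["predator_budget"] = pb

    # --- community stage ---
    if "taxa" in inputs:
        taxa = taxa_from_table(read_table(inputs["taxa"], "taxa"))
        shares = bacterivory_shares(taxa)
        write_table(shares, out / "shares.csv")
        write_table(composition_summary(taxa), out / "composition.csv")
        bundle["bacterivory_shares"] = shares

    _write_budget_table(bundle, out / "budget.csv")
    (out / "summary.txt").write_text(_render_summary(bundle))
    return bundle


def _write_budget_table(bundle: dict, path: Path) -> None:
    b = bundle["grazing_budget"]
    rows = [{"quantity": f"grazing_{g}", "value": v,
             "units": "prey ml-1 day-1"} for g, v in b.per_group_grazing.items()]
    rows += [
        {"quantity": "total_grazing", "value": b.total_grazing,
         "units": "prey ml-1 day-1"},
        {"quantity": "pct_standing_stock_daily",
         "value": b.pct_standing_stock_daily, "units": "% day-1"},
        {"quantity": "removal_time", "value": b.removal_time_h, "units": "h"},
    ]
    rows += [{"quantity": f"share_{g}", "value": s, "units": "% of grazing"}
             for g, s in b.group_share.items()]
    fit = bundle.get("growth_fit")
    if fit is not None:
        rows += [
            {"quantity": "prok_growth_rate", "value": fit.rate, "units": "day-1"},
            {"quantity": "prok_doubling_time", "value": fit.doubling_time_h,
             "units": "h"},
            {"quantity": "production_removed",
             "value": bundle["production_removed_pct"], "units": "% day-1"},
            {"quantity": "unexplained_production_fraction",
             "value": 100.0 - bundle["production_removed_pct"],
             "units": "% day-1"},
        ]
    pb = bundle.get("predator_budget")
    if pb is not None:
        lo_h, hi_h = pb.doubling_time_range_h
        rows += [
            {"quantity": "predator_ingested_volume_daily",
             "value": pb.ingested_volume_daily, "units": "um3 day-1"},
            {"quantity": "predator_doubling_time_high_gge", "value": lo_h,
             "units": "h"},
            {"quantity": "predator_doubling_time_low_gge", "value": hi_h,
             "units": "h"},
        ]
    write_table(pd.DataFrame(rows), path)


def _render_summary(bundle: dict) -> str:
    b = bundle["grazing_budget"]
    conv = bundle["conventions"]
    lines = [
        "Hypolimnetic bacterivory budget",
        "===============================",
        "",
        "Conventions: tracer fraction of {} prokaryotes; {} production; "
        "{} predator doubling; zeros {}; histogram class width {:g}.".format(
            conv["tracer_fraction"], conv["production"],
            conv["predator_doubling"],
            "included" if conv["zeros_included"] else "excluded",
            conv["histogram_class_width"]),
        "",
    ]
    for g, est in bundle["uptake_estimates"].items():
        lines.append(
            f"{g}: mean uptake {est.mean:.1f} ± {est.sd:.1f} prey h-1 "
            f"(median {est.median:.1f}, n={est.n})")
    lines += [
        "",
        f"Total grazing: {b.total_grazing:.3g} prey ml-1 day-1",
        f"Standing stock removed: {b.pct_standing_stock_daily:.2f} % day-1 "
        f"(removal time {b.removal_time_h:.1f} h)",
        "Group shares: " + ", ".join(
            f"{g} {s:.1f}%" for g, s in b.group_share.items()),
    ]
    fit = bundle.get("growth_fit")
    if fit is not None:
        lines += [
            "",
            f"Prokaryotic growth rate: {fit.rate:.3f} ± {fit.rate_sd:.3f} day-1 "
            f"(doubling {fit.doubling_time_h:.1f} h, window days "
            f"{fit.window[0]:g}-{fit.window[1]:g}, R2 {fit.r_squared:.3f})",
            f"Production removed by grazing: "
            f"{bundle['production_removed_pct']:.1f} % day-1 "
            f"(unexplained: {100 - bundle['production_removed_pct']:.1f} %)",
        ]
    else:
        lines += ["", "Growth stage skipped (no regrowth input); "
                      "production removal not computed."]
    pb = bundle.get("predator_budget")
    if pb is not None:
        lines += [
            "",
            f"Predator budget: ingests {pb.ingested_volume_daily:.1f} um3 day-1; "
            f"doubling {pb.doubling_time_range_h[0]:.1f}-"
            f"{pb.doubling_time_range_h[1]:.1f} h over GGE "
            f"{pb.gge_range[0]:.0%}-{pb.gge_range[1]:.0%}",
        ]
    shares = bundle.get("bacterivory_shares")
    if shares is not None:
        top = shares.sort_values("share_pct", ascending=False).iloc[0]
        lines += ["", f"Dominant bacterivore: {top['name']} "
                      f"({top['share_pct']:.1f}% of ciliate bacterivory)"]
    return "\n".join(lines) + "\n"
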