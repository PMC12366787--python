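# hypograze

Quantitative tools for protistan bacterivory in cold, dark, oxic lake
hypolimnia — for microbial ecologists estimating who eats the
bacterioplankton, how fast, and whether grazing balances prokaryotic
production.

## The science

In a stratified reservoir's hypolimnion (~5.8 °C), bacterivorous ciliates
and heterotrophic nanoflagellates (HNF) are the main prokaryote grazers.
The package implements the standard quantitative chain around the
fluorescently-labeled-bacteria (FLB) tracer technique:

- **Tracer inversion.** FLB added at a fraction *f* of total prokaryotes are
  counted in grazer food vacuoles after a short incubation of *t* minutes.
  Under linear, unselective uptake, a cell ingesting *U* prey h⁻¹ holds on
  average *U·f·t/60* FLB, so per-cell rates are recovered as
  *Û = count / f / (t/60)*. Per-cell heterogeneity makes counts a
  gamma-Poisson mixture, which the synthetic generator reproduces.
- **Community grazing.** Mean uptake × in situ grazer abundance × 24 gives
  prey removed ml⁻¹ day⁻¹ per group; relative to the prokaryote standing
  stock this yields the % of stock removed daily and the stock removal time
  (2400 / pct hours).
- **Prokaryotic growth.** Regrowth of 1-μm-filtered (predator-free) water is
  counted daily; the rate *r* (day⁻¹) is the slope of the ln-linear
  regression over the best 3-day window per replicate, and the doubling time
  is *24·ln 2 / r* hours. Comparing grazing with production *r·N* gives the
  % of daily production removed by protists.
- **Predator biovolume budget.** A grazer of volume *V* (prolate spheroid,
  *V = π/6·L·W²*) ingesting *24·U·v_prey* μm³ of prey biovolume per day with
  gross growth efficiency *g* doubles its cell volume in
  *V / (g·24·U·v_prey)* days.
- **Community shares.** Taxon *i*'s share of total ciliate bacterivory is
  *100·U_i·p_i / Σ_j U_j·p_j* over taxa with measured uptake.
- **Q10 scaling.** Rates move between temperatures as
  *rate × Q10^(ΔT/10)*, Q10 ≈ 2.5 for cold-water microbial activity.

A synthetic-data generator (`hypograze.synthetic`) emulates every
measurement stream — tracer counts, cell sizings, regrowth series, the
sampling campaign — so the whole analysis runs and is tested without any
field data.

## Worked example

```python
import hypograze as hg

# invert a tracer assay: mean 6.06 FLB/cell at f=0.18 over 10 min
exp = hg.gen_flb_counts(hg.default_ciliate_config(seed=1), "ciliate")
est = hg.cell_specific_uptake(exp)
print(f"{est.mean:.0f} ± {est.sd:.0f} prey/h, n={est.n}")
# -> 201 ± 133 prey/h, n=960

budget = hg.community_grazing({"ciliate": 202.0, "hnf": 7.0},
                              {"ciliate": 10.0, "hnf": 700.0},
                              prok_abundance=1.35e6)
print(f"{budget.pct_standing_stock_daily:.1f}%/day, "
      f"removal in {budget.removal_time_h:.0f} h")
# -> 12.3%/day, removal in 195 h

print(f"{hg.doubling_time(0.136):.0f} h prokaryotic doubling")   # -> 122 h
print(f"{hg.production_removed(8.5, 0.136):.1f}% of production") # -> 62.5%

vol = hg.prolate_spheroid_volume(hg.CellDimension(17.1, 8.5))    # 647 μm³
print(f"{hg.predator_doubling_time(202, 0.081, vol, 0.30):.0f} h")
# -> 132 h (ciliate doubling at 30% gross growth efficiency)
```

The numbers read: the simulated tracer assay recovers the true mean uptake
(202 prey h⁻¹) within sampling error; the community budget removes 12.3% of
the prokaryote standing stock per day, i.e. one full stock in ~195 h; the
fitted growth rate implies a 122-h prokaryotic doubling, of which grazing
removes 62.5% of daily production; and the biovolume/GGE budget supports a
scuticociliate doubling time of ~132 h at the conservative efficiency.

## Analysis pipeline

Numbered drivers under `analysis/` rebuild the whole study on synthetic
data and write tables under `results/`:

```
python analysis/01_simulate.py          # synthetic campaign inputs
python analysis/02_grazing.py           # uptake estimates, histogram, budget
python analysis/03_growth.py            # regrowth rate fit
python analysis/04_budget.py            # grazing vs production, GGE budget
python analysis/05_community_shares.py  # taxon bacterivory shares
```

`hypograze.run_pipeline(RunConfig(...))` runs the same chain as one call,
on user files or self-generated synthetic inputs, and writes a summary that
restates every convention used (tracer-fraction definition, zero-count
inclusion, production and doubling-time conventions).

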