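# Methods

## Tracer-FLB uptake model

Each inspected grazer cell is assumed to feed unselectively on suspended
prokaryotes at a constant rate over the incubation, which is kept short
(10 min for ciliates, 60 min for HNF) precisely so that uptake stays linear
and egestion can be neglected; no saturation or egestion correction is
applied. With tracer fraction *f* (FLB / total prokaryotes, tracer
included — the default convention; a fraction-of-ambient variant is
selectable) and incubation *t* minutes, the expected count in a cell
feeding at *U* prey h⁻¹ is *λ = U·f·t/60*, and the estimator is the exact
linear inversion *Û = count/(f·t/60)*.

Cells with zero counted FLB are genuine observations — a 10-minute window
catches some feeding cells between ingestions (at the default settings the
zero probability of a Poisson cell at the mean rate is small but the
gamma's left tail contributes) — and are included in all summaries by
default; exclusion is a flag because published histograms do not always
state the choice.

Per-cell rate heterogeneity is modeled as a gamma distribution with the
observed mean 202 and SD 103 prey h⁻¹ (shape ≈ 3.85), matching a unimodal
right-skewed rate histogram; a lognormal alternative with the same first
two moments is available via `SimConfig.heterogeneity`. Counts are then
conditionally Poisson, so simulated counts have mean *λ̄* and variance
*λ̄ + (λ̄·CV_U)²* — the overdispersion the tests verify against an
independent two-stage Monte-Carlo draw.

Whether the "two modal classes hold >70% of cells" feature of the real
histogram holds under a fitted gamma depends on the true dispersion plus
the count-discretization noise of the estimator (rate granularity
60/(f·t) prey h⁻¹); under the defaults the simulated share is ~60–70%, so
the test asserts the two classes are modal and jointly exceed 50% rather
than hard-coding 70%.

## Community grazing and stock removal

Per-group grazing = mean uptake × in situ abundance × 24 (prey ml⁻¹ d⁻¹);
mean (not median) uptake is used because total grazing is the sum of
per-cell rates. The % of standing stock removed daily divides by the same
sample's prokaryote abundance (no time-averaging within a date); study-
period values are unweighted means across dates. Removal time is
2400/pct hours, so removal_time × pct = 2400 exactly — a conservation
identity the property tests pin down along with shares summing to 100.

## Growth-rate fitting

Regrowth series (1-μm-filtered water, daily counts, ≥ 4 points) are fitted
per replicate by ordinary least squares on ln abundance over every
contiguous window spanning 3 days; the window with maximal R² is taken
(ties to the earliest), which lets the fit skip a post-filtration lag or a
late plateau. Replicate slopes are averaged and their SD reported —
fit-then-average rather than pooling, matching triplicate-experiment
reporting. A flat window is treated as a perfect fit with slope 0, so a
constant series returns rate 0 rather than an error. Doubling time is
24·ln 2/r hours; rates ≤ 0 raise.

Production removed by grazing uses the linear convention P = r·N per day
by default — the compounded alternative (e^r − 1)·N is a flag and yields a
slightly larger denominator, hence smaller percentages; reports state the
convention because published percentages rarely say which was used.

## Biovolume and the predator budget

Cells are prolate spheroids, V = π/6·L·W². MCV is computed per cell and
then averaged: by E[W²] = E[W]² + Var W the per-cell mean for the
scuticociliate dimensions (17.1 ± 1.4 × 8.5 ± 1.3 μm) is ≈ 662 μm³,
above the 647 μm³ of the mean-dimension cell, and the averaging order is
fixed because the two differ by ~2%. Sample SD uses n−1; n = 1 reports
SD 0 with a warning.

The predator doubling time is the linear biovolume ratio
V_predator/(g·24·U·v_prey) days — the time for assimilated prey volume to
equal one cell volume — not the ln 2-scaled exponential analogue, which is
exposed as a convention flag. The reconstruction of the 98–132 h range for
the dominant scuticociliate reproduces both endpoints only with the
mean-dimension cell volume (647 μm³); with the per-cell mean (661 μm³)
both endpoints shift up ~2%. Either volume is an accepted input; the
mean-dimension reconstruction is documented as this package's choice, not
asserted as anyone else's method. Prey MCV is a measured input
(default 0.081 μm³); likewise the FLB stock's MCV must be supplied as
measured, never derived from `mixture_mcv` of the strain volumes, since
labeling/freezing can shrink cells below the arithmetic mixture.

## Community shares

Shares use study-period mean uptake × mean proportion, the only form
available when per-date tables are not supplied; with the bundled taxon
table this attributes 92.0% of ciliate bacterivory to the dominant
scuticociliate. Time-resolved weighting (supported when per-date tables
are provided) generally pushes the dominant taxon higher because the minor
bacterivores peak on few dates. Proportions summing above 100% (beyond
1e-9) are a validation error; any shortfall is reported as unidentified.

## Synthetic generator: what it emulates, what it does not

The generator reproduces the measurement *statistics* of the study system:
gamma-Poisson tracer counts; truncated bivariate-normal cell dimensions
(redraw, not clip, to avoid a point mass at zero; length ≥ width by swap);
exponential regrowth with mean-1 lognormal observation noise of CV 3%; an
18-date campaign with lognormal abundances around 1.35 × 10⁶ prokaryotes,
700 HNF and 10 ciliates ml⁻¹, constant 5.8 °C and oxygen declining
5.8 → 3.8 mg l⁻¹. HNF tracer settings default to mean 7.0 ± 2.5 prey h⁻¹
over 60 min — the midpoint of the 3.5–11.8 range typical for such
communities, chosen once.

It does **not** simulate predator–prey dynamics, vertical structure,
per-date covariance between grazers and prey, selectivity by prey size, or
sequencing data. Passing recovery tests therefore shows the estimators are
correct and unbiased under the assumed statistical model, not that the
model captures every feature of field data (e.g. real uptake histograms
may be more peaked than a moment-matched gamma).

Determinism: one root integer seed feeds fixed per-operation sub-streams
(`SeedSequence(seed, spawn_key=...)`), so outputs are bit-identical for a
given config regardless of call order, and pipeline reports are
byte-reproducible.

## Problem sizes and numerical choices

Recovery experiments use the study's own sizes: 960 inspected ciliate
cells per assay, 100 sized cells, 6-day triplicate regrowth; grand means
are taken over 100 seeds (50 for sizing), which bounds the Monte-Carlo
error of the grand mean well below the tolerances asserted. Window ties in
growth fitting break to the earliest window; histogram classes are
half-open (0,w] with inclusive integer labels; proportions/shares use a
1e-9 sum tolerance; hours are kept at full precision internally and
rounded only in printed reports.

## Known limitations

- Grazing on particle-attached prokaryotes is outside the tracer's scope.
- The production-removed percentages depend on the linear-vs-compounded
  convention (~7% relative at r ≈ 0.13 day⁻¹).
- Carbon-mass budgets are not computed; everything stays in biovolume.
- Mortality not explained by grazing is reported only as the residual
  "unexplained production fraction" (viral lysis, predatory bacteria are
  not partitioned).
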