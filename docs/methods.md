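# Methods

## Scope and data model

`iaqrisk` assesses non-carcinogenic and carcinogenic inhalation risks from
indoor formaldehyde and benzene using building-survey concentration data.
The canonical input is a CSV of building-level records (`building_id`,
`building_type`, `compound`, `concentration_ug_m3`), one row per
(building, compound) after within-building room averaging. Because many
surveys publish only per-stratum summaries, the pipeline can run entirely
from (n, mean, SD, median) tuples; the packaged default scenario carries
four strata — dwelling/office × formaldehyde/benzene with means ± SDs of
131±90 (n=383), 85±56 (n=406), 17±16 (n=379) and 30±34 (n=375) µg/m³ —
which are the study conditions every default reproduces.

## Lognormal concentration model

Indoor pollutant concentrations are modelled as lognormal within each
stratum, the conventional distribution for environmental concentration
data. Fitting is by the method of moments from the arithmetic mean and SD:

    σ² = ln(1 + (s/m)²),  μ = ln(m) − σ²/2

chosen over maximum likelihood as the default because it needs only the
two printed moments and reproduces them exactly (a property the tests
assert at machine precision). MLE (`fit_lognormal_mle`) is available when
raw records exist. When a published median accompanies the moments, the
implied median exp(μ) is checked against it; a discrepancy beyond 15%
raises a model-adequacy *warning*, not an error — for the packaged strata
the implied medians (108, 71, 12.4, 19.9 µg/m³) sit within that band of
the published 100, 74, 11 and 16.

Guideline exceedance is the analytic upper tail P(X > t); the empirical
counterpart (strict `>`, ties compliant) is used when raw records are
supplied. Non-positive concentrations are hard errors — they are
physically impossible and break the log transform; no detection-limit
imputation is attempted because the source summaries report none.

## Guideline and toxicity registry

Reference values ship as a versioned CSV (`data/registry.csv`) rather than
hard-coded constants so compounds and sources can be added. Concentrations
are held in µg/m³ everywhere; the GB/T 18883-2002 limits (0.10 and
0.11 mg/m³) are converted at load. IURs are stored as lifetime (70-year)
excess cancer risk per (µg/m³); per-million scaling is applied exactly
once, in the risk module. EPA IRIS publishes two benzene IURs; the upper
value 7.8×10⁻⁶ is the default variant — giving a maximum risk estimate —
with 2.2×10⁻⁶ retained as `alternate`. IRIS has no chronic RfC for
formaldehyde; the registry raises a named lookup error rather than
substituting a value.

## Time-use model

The exposure equation needs per-person daily fractions of time at home and
in the office. Nationally representative time-use distributions are not
distributed with this package, so the defaults are calibrated from the
study conditions themselves: the ratio of published personal home exposure
to home concentration gives f̄_home = 86/131 ≈ 0.657, and the office pair
gives f̄_office = 15/85 ≈ 0.176 (the benzene strata give 0.647/0.167,
consistent). Both marginals are normals truncated to [0, 1] with SDs 0.05
and 0.04 — small, so exposure spread is concentration-dominated — and a
joint cap f_home + f_office ≤ 0.95 enforced by rejection sampling keeps a
physically plausible remainder of outdoor/other time. All four parameters
are configurable; an infeasible model (mean fractions exceeding the cap)
is rejected before sampling. The model is sex-pooled; a two-group
configuration can be expressed by running two scenarios.

Note a deliberate gap this calibration flags rather than hides: with
near-point-mass fractions the simulated home-exposure SD is ≈ 0.66 × 90 ≈
59 µg/m³, somewhat above the published 52, implying an unprinted time-use
spread or correlation in the original simulation. The published medians
and means are nonetheless reproduced within the stated tolerances.

## Exposure Monte Carlo

Each simulated person draws a home concentration, an office concentration
(independent by default; a log-scale Gaussian correlation `rho` is exposed
because no home-office pairing is reported) and a time-use pair. The
contributions are e_home = C_home·f_home and e_office = C_office·f_office;
their sum is the indoor fraction of total personal exposure. The fractions
are never renormalized to 1 — T in the denominator is total time in all
microenvironments. Concentrations are drawn from the fitted stratum
distribution (parametric Monte Carlo); bootstrap-from-records is available
by MLE-fitting raw data first. The package default is 5,000 trials,
matching the original study setting; the acceptance script and the
reproduction tests use 50,000 so that Monte Carlo error on the median
(≈0.5% at that size) is small against the 15% comparison tolerance.
Summaries use type-7 (linear-interpolation) quantiles; this matters when
medians are compared at 10–15% tolerance.

## Risk computation

risk_i = E_i × IUR × 10⁶ per million (raw probabilities via
`per_million=False`). Home and office components scale identically, so
disaggregation shares — share_x = mean(risk_x)/mean(risk_total) — sum to 1
exactly. The decay scenario multiplies every statistic by the retained
concentration fraction (0.35 for formaldehyde ~3 years after remodeling,
0.25 for benzene within a year) rather than re-simulating: risk is linear
in concentration, so the two routes agree to machine precision (asserted
as a commutation test). No lifetime-adequacy adjustment (exposure duration
vs the 70-year IUR basis) is applied; the scenario population lives and
works in such buildings over a lifetime. The reported "95%" statistic is
the 95th percentile of the simulated risk distribution, the usual Monte
Carlo output convention, not a confidence bound.

The source material itself reports the IRIS medians inconsistently
(1,150/106 in one place, 1,160/107 in another); the reproduction tolerance
comfortably covers both, and this package makes no attempt to adjudicate.

## Pipeline and determinism

`run_study` drives generate → fit → screen → simulate → assess from one
YAML config. All randomness flows from a single root seed split per stage
with `numpy.random.SeedSequence`, so identical config ⇒ byte-identical CSV
and JSON outputs (tested). A manifest (config hash, seed, package version,
stage outputs) is written atomically at run end; any stage failure removes
that run's partial outputs and raises an error naming the stage.

## Synthetic data: what it does and does not emulate

The generator draws i.i.d. lognormal concentrations per stratum and
truncated-normal time-use pairs. It reproduces the published group
moments, the lognormal shape, and the seed-determinism contract — which is
what the downstream statistics consume. It does **not** emulate seasonal
or ventilation-driven dynamics (air-exchange-rate data were unavailable to
the original survey), within-building room correlation, spatial structure,
sex-specific time use, or the missingness that left the published stratum
Ns below the building counts. Passing tests therefore demonstrate that the
pipeline's statistics are correct *given the lognormal/time-use model*,
not that the model captures every feature of real survey data.

## Numerical choices and limitations

- Strict `>` for exceedance; ties count as compliant.
- Percentages reported to one decimal; risk statistics as integers with
  thousands separators in rendered reports.
- Degenerate inputs (empty record sets, single draws, zero/negative
  concentrations, non-positive thresholds or retained fractions) raise
  `ValueError` with the offending quantity named.
- No dose–response modelling beyond the linear IUR, no benchmark-dose
  derivation, no mixture/synergy across compounds, no cohort life-table
  adjustment, no outdoor/transport microenvironment.
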