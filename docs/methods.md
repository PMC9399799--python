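# Methods

This note documents the models, the estimation procedure, the synthetic
data generator, and the numerical and design choices behind `pbtgerm`.

## Population-based threshold models

All three models share one idea: the germination time of an individual seed
is deterministic given its personal threshold, and the spread of a seed
lot's time course is entirely the spread of thresholds across the
population. Writing Φ for the standard normal CDF and g for the cumulative
germinated fraction:

| model | accumulation rule | per-seed threshold | searched parameter(s) |
|---|---|---|---|
| TT sub-optimal | θT = (T − Tb)·t | θT ~ N(θT(50), σθT) | Tb |
| TT supra-optimal | Tc = T + θT2/t | Tc ~ N(Tc(50), σTc) | θT2 |
| HT (one T) | θH = (Ψ − Ψb)·t | Ψb ~ N(Ψb(50), σΨb) | θH |
| HTT sub-optimal | θHT = (Ψ − Ψb)(T − Tb)·t | Ψb ~ N(Ψb(50), σΨb) | (Tb, θHT) jointly |
| HTT supra-optimal | as HTT with Ψb(50) + K_T(T − To) | Ψb ~ N | (θHT, K_T), given Tb, To |

Assumptions worth keeping in mind: thresholds are normal (the probit forms
require it — no Weibull/log-normal variants are offered); thresholds are
constant in time (no priming or hydrotime "repair"); conditions are
constant (laboratory assays, not fluctuating field environments);
non-germinating seeds are simply the part of the distribution whose
threshold the imposed condition never exceeds — dormancy and viability loss
are not modelled separately.

At a single temperature the HTT model reduces exactly to HT with
θH = θHT/(T − Tb); this nesting identity is verified numerically to 1e-12
in the test suite.

## Data flow

1. **Counts.** Long-format CSV, one row per (condition, replicate,
   observation): cumulative germinated count out of `n_seeds` at `time_h`
   hours. Times are hours everywhere; day-based files convert on read.
   Replicates of a condition are pooled by summation (they must share the
   observation grid; there is no interpolation at pooling).
2. **Fractions.** Cumulative fractions are computed against seeds *sown*,
   not seeds that eventually germinated: the threshold models describe the
   whole population including its non-germinating tail.
3. **Percentile times.** For each condition, the times t(g) at which the
   pooled fraction reaches g = 10 %, 20 %, … 90 % (truncated at the final
   observed fraction). Observed fractions of exactly 0 or 1 are
   uninformative on the probit scale and are excluded.
4. **Fits.** All (condition, percentile) points enter one unweighted probit
   regression per candidate of the searched parameter; the engine returns
   the candidate with maximal probit-scale R².

### Percentile extraction: local, not global

Observed fractions are placed on the (log10 t, probit f) plane. The default
extraction interpolates t(g) piecewise-linearly between the two observed
points bracketing each g. A single global least-squares line on that plane
(available as `method="regress"`) is attractive but subtly wrong as a
default: under any of the threshold models the probit trend against log
time is *curved* (e.g. probit g = A − B/t for hydrotime), so a global line
systematically displaces the tail percentiles, and those displaced times
bias the downstream fits — measured at the study design, by roughly +19 %
in θHT and −0.6 °C in Tb. Local interpolation needs no linearity beyond the
bracketing interval and recovers generating parameters to ~1 % (see
"Validation" below). Percentiles outside the observed probit range have no
bracket and are dropped rather than extrapolated.

The t50 germination index, by contrast, *is* computed from the global
probit–log-time line — it is the conventional definition of that index and
uses the centre of the data where the line is adequate. t50 and GR50 = 1/t50
are reported as undefined when fewer than half the seeds germinated.

Mean germination time is the germination-weighted mean of recorded counting
times, Σnᵢtᵢ/Σnᵢ over interval-new germinations nᵢ; counts are attributed
to the observation at which they were recorded (no mid-interval
correction), matching how bench counts are actually taken.

## The repeated-probit search engine

The searched parameters enter the predictor nonlinearly, so the engine is a
derivative-free grid search with geometric refinement:

1. evaluate a coarse grid over the declared bounds (cartesian over
   parameters; candidates are vectorised through one batched OLS);
2. re-grid a ±1-step window around the incumbent with 2·5+1 points per
   refined parameter, shrinking the spacing 5× per stage;
3. stop when every spacing is below its tolerance (default 1e-3 in the
   parameter's unit for linear-scale parameters; 1e-5 *relative* for
   log-scale time constants, which are searched in log10 space).

Two details matter for correctness:

- **Ridge walking.** (Tb, θHT) are strongly correlated — many pairs along a
  ridge fit almost equally well. If the window shrank every stage, the
  search could strand beside the ridge crest. Whenever the incumbent lands
  on a window *edge*, the window is therefore re-centred without shrinking,
  letting the search track the ridge until the maximum is interior. Without
  this, noise-free closed-loop recovery stalls at R² ≈ 0.99998 a few units
  from the optimum; with it, recovery is exact to the final grid step.
- **Determinism.** Candidates with non-positive slope or degenerate
  predictor variance are rejected; exact R² ties break toward the
  lexicographically smallest parameter vector, so fits are bit-reproducible
  and a rerun of any pipeline with the same seed produces byte-identical
  parameter JSONs.

The objective is R² on the probit scale — the quantity the original
repeated-probit literature reports for these fits — not a binomial
likelihood; consequently no standard errors are produced, and the search
trace (incumbent per stage) is retained on the result object for audit.
Search bounds default to [0 °C, min(T) − 0.5 °C] for Tb (a base temperature
cannot reach the coldest tested condition) and generous log-spaced ranges
[0.1–10⁴] °C·h / [1–10⁵] MPa·h for the time constants.

## Reference parameter values

The worked examples and default validations use the parameter set
established for *Parthenium hysterophorus*: sub-optimal θT(50) = 3.01 °C·h,
Tb = 7.2 °C, σθT = 0.30; supra-optimal θT2 = 3.21 °C·h, Tc(50) = 42.8 °C,
σTc = 0.37; hydrotime at 20 °C θH = 65.0 MPa·h, Ψb(50) = −0.70 MPa,
σΨb = 0.35; hydrothermal θHT = 516.6 MPa·°C·h, Tb = 7.2 °C,
Ψb(50) = −0.54 MPa, σΨb = 0.40 (fitted over 10 and 20 °C). The derived
optimum temperature from the GR(50)-line intersection of the thermal
constants is 24.4 °C; the empirical optimum (argmax germination among
tested temperatures) is reported separately by the CLI, since the two need
not coincide and the reference study quotes 20 °C.

A unit caveat: the thermal-time constants above are irreconcilable with a
twice-daily counting schedule — 3.01 °C·h over a 12.8 °C excess means a
median germination time of ~14 minutes, entirely inside the first counting
interval. The hydro- and hydrothermal constants, by contrast, are perfectly
consistent with hours (t50 ≈ 93 h and 75 h at 20 °C/0 MPa). The package
therefore treats time units as declared by the user and never rescales;
the thermal reference values are exercised through model-exact percentile
curves, where no observation schedule is involved.

## Synthetic data generator

`pbtgerm.simulate` draws one threshold per seed from the model's normal
population (untruncated — the sign conditions alone decide "never
germinates", which preserves the probit forms exactly), computes each
seed's deterministic germination time, and records cumulative counts on the
observation schedule, attributing each germination to the *next* count
(right-point attribution, as on the bench). Random streams are spawned per
condition and replicate from a single seed, so enlarging the design leaves
existing replicates' data untouched.

The default designs mirror the reference study: constant temperatures
5–40 °C in 5 °C steps at 0 MPa (thermal time); Ψ ∈ {0, −0.25, −0.5, −0.75,
−1.0} MPa at 10/20/30 °C (hydro-/hydrothermal time); 10 replicates × 25
seeds per treatment; counts every 12 h to a 240 h censoring horizon. The
default HTT generator additionally applies K_T = 0.02 MPa/°C above
To = 20 °C so the 30 °C conditions behave supra-optimally; the HT defaults
are the 20 °C hydrotime set.

The thermal-time generator defaults keep the reference cardinal
temperatures (Tb = 7.2 °C, Tc(50) = 42.8 °C) but use thermal constants
θT(50) = θT2 = 250 °C·h with σθT = 75 °C·h and σTc = 3.0 °C, chosen once so
that germination spreads over ~1–4 days and resolves on the twice-daily
schedule (see the unit caveat above). These magnitudes correspond to
~10 °C·d, typical for a 10-day assay.

What the simulator does *not* emulate: Petri-dish random effects
(replicates are exchangeable draws from one population), observation error
in counting, seed lot dormancy fractions, or fluctuating conditions.
Passing recovery tests therefore demonstrates correctness of the estimation
machinery under the models' own assumptions — not robustness of the models
to real-data violations of those assumptions (which is why R² values of
fits to real data are substantially lower than those of fits to simulated
data).

## Validation and problem sizes

The test suite checks, among others:

- **Engine vs brute force.** The hierarchical search matches an independent
  exhaustive dense-grid scan at the final tolerance on small instances (1-D
  θH and 2-D (Tb, θHT), ≤ 200 probit points), in seconds.
- **Noise-free closed loop.** Model-exact percentile curves → fit recovers
  every generating parameter of all three models to the final grid step
  with probit R² = 1 ± 1e-6.
- **Stochastic recovery.** At the full factorial design (3 T × 5 Ψ ×
  250 seeds, binomial counting noise), the mean estimate over 20 seeded
  simulation replicates recovers Ψb(50) within ±0.05 MPa, θHT within ±10 %,
  and Tb within ±1 °C (measured bias: ≈0.003 MPa, 1.3 %, 0.01 °C; the
  per-replicate SD of θHT is ≈7 %, which is why the criterion is on the
  mean).
- **Distributional correctness of the simulator.** Empirical pooled
  fractions converge to the model's g(t) (sup-distance < 0.02 at 10⁵
  seeds), and expected final counts match the forward model at the
  censoring horizon.

All simulations in the shipped tests and in `scripts/acceptance.py` use the
study-sized design (250 seeds per treatment; 10–20 generator replicates),
which keeps the whole suite under ten seconds while leaving Monte-Carlo
error well below the tolerances being asserted.

## Known limitations

- Supra-optimal HTT fitting (K_T, To) is implemented and tested against
  synthetic data but marked experimental: no reference estimate of K_T
  exists for this species, and To must be supplied (defaulting to the
  thermal-time estimate).
- The probit-scale R² objective has no likelihood interpretation; fits at
  different percentile grids or point counts are not directly comparable,
  and no parameter uncertainty is reported.
- Percentile extraction needs at least two informative counts per
  condition; conditions that complete germination within one counting
  interval (or never start) contribute nothing to a fit and are skipped
  with a log message rather than failing the pipeline.
- At strongly censored conditions (e.g. 10 °C at low Ψ, where most of the
  population outlasts 240 h) only the fast percentiles exist; fits lean on
  the fast tail of the distribution there, and location/spread estimates
  from such conditions alone are correspondingly fragile.
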