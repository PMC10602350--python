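# Methods

`cardiovar` studies how heart failure with reduced ejection fraction (HFrEF)
reshapes beat-to-beat cardiovascular variability in mice. Its empirical
finding of interest is a dissociation: under anesthesia, cycle-duration
variability (HRV) is preserved in HFrEF while stroke-volume variability (SVV)
is markedly reduced alongside the reduction of stroke volume itself. The
package provides (i) an analysis chain from raw pressure–volume (PV)
recordings to Poincaré variability indices and group statistics, (ii) a
mechanistic two-compartment circulation model that explains the SVV reduction
through the Frank–Starling gain, and (iii) a seeded synthetic-cohort
generator so every stage is testable without animal data.

## Poincaré indices

For a per-cycle series x_1…x_n (cycle duration in ms or stroke volume in μl),
the Poincaré plot is the set of n−1 consecutive pairs (x_i, x_{i+1}). With
d_i = (x_{i+1} − x_i)/√2 and s_i = (x_{i+1} + x_i)/√2,

    SD1 = population SD of {d_i}   (dispersion ⊥ the identity line y = x),
    SD2 = population SD of {s_i}   (dispersion along the identity line).

Population (ddof = 0) SDs over the n−1 pairs are used so that small worked
examples are exact. Because the 45° rotation is orthogonal,
SD1² + SD2² equals the sum of the population variances of the two pair
coordinates exactly — asserted to machine precision in the tests. For a
stationary AR(1) series with lag-1 autocorrelation a and innovation SD σ,
SD1² → σ²/(1+a) and SD2² → σ²/(1−a); this links the indices to the
circulation model below. SD1/SD2 are invariant to transposing the plot axes,
so the axis convention affects only plot exports.

## PV-loop segmentation and hemodynamics

Recordings are uniform time series of left-ventricular pressure (mmHg) and
volume (μl). Cycle boundaries are placed at end diastole: the local volume
maximum immediately preceding each pressure upstroke, where an upstroke is a
rising crossing of dP/dt through 10% of its record-wide maximum. Secondary
within-cycle crossings are debounced using the upper-quartile gap between
crossings as the period estimate (the median is not robust when every cycle
produces exactly one extra crossing). Records with flat traces or fewer than
two upstrokes raise an explicit "unsegmentable" error.

Per cycle, fourteen parameters are extracted: HR, ESP, EDP, Pmax, Pmin,
[dP/dt]max, [dP/dt]min, Vmax, Vmin, ESV, EDV, SV, CO, EF. Landmark
conventions (acquisition systems leave them unstated) are:

* end diastole = the segmentation boundary; EDV and EDP are read there;
* end systole = the instant of minimum dP/dt; ESV and ESP are read there;
* SV = EDV − ESV by construction, hence the identity also holds for means
  (as it does in the published group tables: 39.13 − 15.33 = 23.80 μl for
  controls, 25.45 − 13.36 = 12.09 μl for HFrEF);
* EF = 100·SV/EDV; per-animal CO = mean SV × mean HR (μl/min);
* dP/dt by central differences, unsmoothed (a Savitzky–Golay window is
  config-exposed, off by default).

Cycles with non-positive EDV or negative SV are dropped and counted, never
imputed. On the synthetic waveform template the dP/dt minimum falls
mid-relaxation, so extracted "ESP" sits between the template's ejection-end
pressure and Pmin (roughly their mean). This is a documented
convention/template interaction: it biases the absolute ESP level, leaves
group contrasts intact, and does not affect volumes or timings.

## Two-compartment Frank–Starling model

Blood volume V_T is split between a venous and an arterial compartment with
compliances C_V, C_A (μl/mmHg) and pressures P_x = V_x/C_x. Each cycle the
heart ejects SV = β·P_V (linearised Frank–Starling law, gain β ≤ C_V in
μl/mmHg) from the venous to the arterial side, and blood returns passively
through the peripheral resistance R, V_R = (P_A − P_V)/R per cycle. The
per-cycle interval Δt is absorbed into R's units (mmHg·cycle/μl) — this
reproduces the standard closed forms exactly. Eliminating volumes gives

    SV_{i+1} = A·SV_i + B,
    A = (1 − β/C_V)·[1 − (1/R)(1/C_A + 1/C_V)],
    B = V_T·β/(R·C_A·C_V),

with fixed point SV̄ = B/(1−A) when |A| < 1 (enforced; instability raises an
error rather than silently diverging). The mechanistic stepper conserves
V_V + V_A = V_T exactly, clips SV below at zero (events counted), and
raises an explicit error when parameters would drive a compartment volume
negative — which can happen when R·C_A < 1, i.e. when a single relaxation
step would over-drain the arterial compartment; such regimes are treated as
non-physical.

### Stochastic variability

With i.i.d. Gaussian innovations η_i of SD σ_eff, the recursion
SV_{i+1} = A·SV_i + B + η_i is a stationary AR(1) with

    mean = B/(1−A),  variance = σ_eff²/(1−A²),
    SD1 = σ_eff/√(1+A),  SD2 = σ_eff/√(1−A).

Two noise entries are provided. `recursion_additive` perturbs the recursion
directly in μl (σ_eff = σ). `preload` models a fluctuating venous filling
pressure (respiration-like, σ in mmHg) sensed through the Frank–Starling
gain, σ_eff = β·σ; it is the default because it makes stationary SV variance
proportional to β², so a loss of contractility (smaller β) *reduces* SVV even
though it *raises* A — reconciling the two directions in which β enters. Under
additive noise the two statements conflict (variance grows with A); the
package implements both and the β sweep makes the tension explicit rather
than resolving it.

A modelling subtlety, stated here deliberately: feeding per-cycle preload
noise through the *full mechanistic stepper* propagates each ξ_i into the
next cycle's state, yielding SV_{i+2} = A·SV_{i+1} + B + βξ_{i+1} − kβξ_i
with k = 1 − (1/R)(1/C_A + 1/C_V) — an ARMA(1,1), not a pure AR(1). The
stochastic analytics (`simulate`, `stationary_moments`, `beta_sweep`) are
therefore defined on the recursion itself, where the closed forms above are
exact; `simulate_mechanistic` retains the state-level path (used for the
conservation checks) and its docstring flags the moving-average correction.

Default parameters place a control-like murine operating point:
C_A = 2, C_V = 50 μl/mmHg, R = 2.853 mmHg·cycle/μl, β = 6 μl/mmHg,
V_T = 320 μl, giving P_V ≈ 4 mmHg, P_A ≈ 60 mmHg, SV̄ ≈ 24 μl and A ≈ 0.72.
Preload noise σ = 0.2 mmHg yields a stationary SV SD of ≈ 1.7 μl (≈ 7% of
SV̄). V_T here is the *effective* volume exchanged between the two lumped
compartments, not total murine blood volume; the model has no pulmonary
compartment, baroreflex, or heart-rate coupling.

## Synthetic cohorts

The generator emulates the two study groups at the level the analyses
consume. Group targets (means of HR, SV, EDV and the four pressures) are the
published control (n = 14) and HFrEF (n = 10) murine reference values kept in
`cardiovar.reference`. Within-animal beat-to-beat laws:

* cycle durations: i.i.d. Gaussian, SD `hrv_sd`, floored at 20% of the mean;
* stroke volumes: stationary AR(1) with SD `svv_sd` and lag-1
  autocorrelation 0.5, floored at 0.1 μl. AR(1) is the stationary law the
  circulation model itself implies; alternatively the mechanistic simulator
  can supply SV series.

No within-animal SDs are published (the reference SDs are between-animal), so
the defaults are free parameters of the generator, chosen once: hrv_sd = 3 ms
in both groups (HRV preserved; ~2.4% of the cycle, typical for anesthetized
mice) and svv_sd = 1.2 μl control vs 0.6 μl HFrEF (≈5% of SV; halved in
HFrEF, mirroring the observed SVV reduction). Between-animal dispersion uses
a single coefficient of variation (default 0.15) applied to the means *and*
to the within-animal SDs — animals genuinely differ in variability level,
and without that the per-animal index spread would be pure estimation noise.
SV and EDV share a per-animal size factor (loading 0.3) so ejection fraction
varies and SV–EF correlate positively (~0.6 on pooled cohorts); the four
pressure means share one scale factor so their ordering
Pmin ≤ EDP ≤ ESP ≤ Pmax is exact; the within-animal SV SD is capped at
EDV/12 and the SV mean kept 6 SDs below EDV so rendered cycles always have
positive end-systolic volume. The default recording length is 2000 beats per
animal (≈4 min at ~480 bpm, a standard variability-recording duration);
sampling is 1 kHz.

Waveforms are rendered from a fixed piecewise raised-cosine template per
cycle — EDP plateau and isovolumic contraction (12% of the cycle), ejection
(to 40%), relaxation fall and Pmin plateau (to 52%), filling (to 100%) —
built so that every landmark (EDV, ESV = EDV − SV, EDP, Pmax, Pmin) is
attained exactly, the concatenated trace is continuous, and every derivative
landmark sits at a smooth interior extremum (so extraction converges as the
sampling rate grows: doubling it from 2 kHz moves every extracted parameter
by < 0.3%). Seeds derive deterministically from the master seed via
`SeedSequence([master_seed, group_code, animal_index])`; identical
configurations reproduce byte-identical cohorts.

What the generator does *not* emulate: ECG, explicit respiratory waveforms
(respiration enters only as unresolved beat-to-beat noise), anesthetic
drift, catheter artefacts, conductance-volume calibration error, or
non-Gaussian/heavy-tailed beat distributions. Passing tests therefore show
the pipeline recovers truth under an idealised data-generating law, not that
it is robust to every artefact of real catheter recordings.

## Statistics

Group comparisons follow the routed procedure: Shapiro–Wilk per group at
α = 0.05; both normal → two-sample equal-variance t-test (Welch available by
flag); otherwise the two-sided Mann–Whitney U. Constant samples are routed to
the rank test with a logged warning. Significance is p < 0.05. The routing
gate (per group, both must pass) is the most common reading of
"t-test or Mann–Whitney depending on normality" and is a documented choice.
No multiple-testing correction is applied across the hemodynamic parameters
by default (Holm step-down is available by flag), matching common practice in
this literature. Calibration: on Gaussian nulls at the study's group sizes
(14 vs 10), the routed procedure's type-I error is 0.05 within ±0.01 over
10⁴ replicates. The SV–EF association uses Pearson correlation with a
two-sided p-value.

## Replication study and its structural ceiling

`pipeline.replicate_dissociation` repeats the cohort → variability →
statistics chain over seeded replicates (seeds base, base+1, …) and scores
each for the full HFrEF signature: SV significantly reduced, SV SD1 and SD2
significantly reduced, duration SD1 and SD2 *not* significant. One caveat is
intrinsic: the two duration tests are true nulls at α = 0.05 each, so the
expected fraction of replicates with *neither* firing can never exceed 95%,
with equality only in the limit where the two indices are estimated precisely
enough to be near-perfectly correlated across animals. At the default 2000
beats per animal the SD1/SD2 estimation noise (~1.6%) is small against the
15% between-animal spread, the duration tests are nearly redundant, and the
observed pattern fraction sits at the ~95% ceiling; with short recordings
(e.g. 300 beats) the two tests decorrelate and the fraction drops to ~90%.
Reported fractions for other seed windows fluctuate binomially around the
ceiling.

## Numerical and interface choices

* AR(1)/recursion trajectories are generated with a one-pole IIR filter
  (`scipy.signal.lfilter`) with exact stationary initial conditions.
* Simulations flag the first 100 cycles as burn-in; stationary statistics
  drop them.
* CSV round trips are exact: floats are written at full shortest-repr
  precision and parsed with the round-trip parser, so re-analysing a written
  cohort reproduces byte-identical reports; the manifest carries the
  sampling rate so it need not be re-inferred.
* All randomness flows from explicit integer seeds; no global RNG state.
* Degenerate inputs fail loudly: flat records, unstable maps, zero-variance
  correlations, < 3-beat series, empty β grids.

## Known limitations

* The waveform template is stylised; absolute levels of convention-dependent
  quantities (extracted ESP, dP/dt extrema) depend on its phase fractions.
* The circulation model is two-compartment and noise-driven at the cycle
  scale; it is not fitted to the recordings and makes no claim about
  absolute murine compliances or resistances.
* Between-animal dispersion uses one CV for all parameters, whereas real
  cohorts show parameter-specific CVs (≈9% for HR, ≈23% for volumes).
* The ~95% ceiling on the dissociation replication fraction is a property of
  running two true-null tests at α = 0.05, not of the implementation.
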