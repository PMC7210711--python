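# Methods

## The model

`thermotol` analyses static-temperature heat-tolerance assays of small
aquatic ectotherms (the synthetic generator emulates a *Daphnia magna*
assay). The organising model is the thermal death time curve (TDTC): over a
range of stressfully high temperatures, the time an individual can maintain
locomotory function declines log-linearly with temperature,

    log10 t = (CTmax − T) / z ,

with `t` the knock-down time in minutes, `T` the exposure temperature in °C,
`z` the temperature sensitivity coefficient (°C per decade of time; −1/slope
of the regression of log10 t on T — a *high* z means *low* sensitivity) and
`CTmax` the extrapolated temperature at which log10 t = 0, i.e. failure
within one minute. CTmax is unit-dependent; minutes are part of the model
definition here. The elevation (intercept) of a TDTC measures the overall
magnitude of heat tolerance; groups can differ in elevation, in z, or both.

The observable is `T_imm`, time to immobilisation: the time from an
individual's introduction into a heated well until its tracked swimming
velocity is last observed above a threshold. Recording starts only after the
last individual of a run is introduced, so each individual's introduction
offset (recorded by the experimenter) must be added back to its
recording-clock time; omitting it would bias every estimate low by the 3–6
minute staggering window.

## Detection (`knockdown`)

`estimate_timm` finds the last sample that begins a run of at least
`min_bout_samples` consecutive samples with velocity above
`velocity_threshold_mm_s`, and reports
`(intro_offset_s + sample_time_s) / 60` minutes. Defaults:
threshold 1.0 mm/s, `min_bout_samples` 1 (the literal "last sample above
threshold"), `max_gap_s` 2.0 s before a gap warning. The original tracking
workflow's exact threshold and any smoothing are not published; these
defaults are explicit, configurable stand-ins, and every result that depends
on them is validated against the synthetic generator's latent truth rather
than against published detection output. Flags: `never_moved` (no
qualifying sample; such subjects are excluded downstream), `right_censored`
(still moving when recording ends; excluded from model input by default,
since the protocol films until all subjects are motionless),
`gap_warning` (sampling dropouts; retained).

## TDTC fitting (`tdtc`)

Ordinary least squares of log10(T_imm minutes) on temperature, per group
and pooled. The pooled fit constrains a common slope with one intercept per
group, so the intercept contrast is the elevation difference at equal
temperature sensitivity. z = −1/slope and CTmax = −intercept/slope are
derived quantities; a non-negative slope marks the fit invalid (z, CTmax
NaN) rather than raising, and a CTmax outside the observed 35–40 °C range —
the usual case — is flagged as an extrapolation warning.

## Model selection (`model_selection`)

Three linear mixed models for log10 T_imm share crossed Gaussian random
intercepts for source beaker (10 levels) and measuring run (14 levels) and
differ only in fixed effects: temperature × size (with main effects),
temperature + size, temperature only. Body size enters as a continuous
covariate in mm (this makes the parameter counts k = 7/6/5: fixed
coefficients + two variance components + residual variance). All fits use
maximum likelihood, not REML, because the candidates differ in fixed
effects. Temperature is centered at its sample mean for optimizer
stability; coefficients are reported back on the natural scale.

Fitting is statsmodels MixedLM (variance-components formulation); its
solution is then polished by an exact profiled-likelihood optimizer over
the two variance ratios (residual variance and fixed effects profiled out
in closed form; the marginal covariance handled through the Woodbury
identity on the 24 random-effect columns). The polish costs microseconds
per evaluation, pins the reported log-likelihood to the exact ML optimum,
and takes over entirely in the rare case MixedLM does not converge. A
variance component within 1e-8 of zero (relative to the response variance)
sets a boundary flag.

Comparison: AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); Akaike weights
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2) computed after subtracting the minimum so
the normalisation cannot overflow. Ranking is by AICc, exact ties broken by
smaller k; a near-tie note is attached when the top two models differ by
less than 2. R² is reported as the squared Pearson correlation between
conditional predictions (fixed effects + BLUP random intercepts) and
observations; a marginal (fixed-effects-only) variant is selectable. No
published R² definition is reproduced deliberately — the definition behind
the published values is not stated, so R² here is a descriptive column, not
a correctness anchor.

## Synthetic assays (`synthetic`)

The generator emulates the full protocol: temperatures 35–40 °C in 1 °C
steps; 14 runs allocated (3,2,2,2,2,3) across temperatures (the published
design states only 14 runs with at most three per temperature; the split is
configurable); 20 subjects per run — one small and one large individual per
source beaker, 10 beakers; body lengths truncated-normal within the
published ranges (small 1.14 mm mean, 0.92–1.51; large 2.70 mm mean,
2.37–3.17; SDs 0.12/0.15 mm chosen to fill those ranges); staggered
introduction over a uniformly drawn 3–6 min window; 3 Hz velocity sampling.
Latent knock-down times follow the TDTC linear predictor with crossed
beaker/run random intercepts and residual noise (defaults σ_beaker = σ_run
= 0.05, σ_resid = 0.10 log10-minutes).

Default coefficients: β_T = −0.45 log10-min/°C (z ≈ 2.22 °C), β_S = −0.12
log10-min/mm, β_TS = 0, and β0 = 19.2368, anchoring the mean small subject
at log10 t = 1.1 (≈12.6 min) at 40 °C. These were set from two published
anchors — the briefest exposures are "~5 min" and the mildest exceed 15 h —
under the protocol constraint that knock-down should almost never precede
the start of recording: with a ~5 min *mean* at 40 °C, subjects introduced
5–6 min before recording would routinely be immobile before the camera
starts, which the published 277/280 estimability rules out. At these
defaults the lower tail at 40 °C reaches ~5 min and the 35 °C mean is
≈2240 min (>15 h). For the same reason the small (more tolerant) group is
introduced first, so the large group carries the short offsets.

Velocity traces alternate move bouts (0.5–2 s, lognormal speeds with median
5 mm/s) and pauses (0.1–0.7 s); pauses and everything after knock-down are
uniform jitter below 0.3 mm/s. The worst-case detection error is therefore
one pause plus one sample interval ≈ 1.03 s. A subject knocked down before
recording starts yields an all-jitter trace (`never_moved`), mirroring
real subjects whose T_imm could not be estimated.

Randomness: one integer seed; per-run and per-subject substreams are
spawned deterministically, so adding runs never perturbs earlier draws, and
identical configurations reproduce tables byte for byte.

What the generator does **not** emulate: 2-D trajectories and tracking
artefacts (occlusion, reflections), water-temperature dynamics, behavioural
slowing *before* knock-down, non-Gaussian random effects, and any
mortality/immobilisation distinction. Passing tests therefore validate the
statistical pipeline under its own assumptions, not the upstream tracking.

## Problem sizes and numerical choices

Full-fidelity traces of the default design are enormous by construction
(>15 h at 3 Hz for 35 °C runs, tens of millions of rows per experiment), so
trace-level stages — the detection-fidelity checks and the trace-level
pipeline — run on a time-compressed configuration (`compress_time`, factor
1/60: elevation shifted by log10(1/60), introduction window scaled alike).
Compression leaves temperature sensitivity, size effects, noise structure
and the detector's absolute error bound unchanged. Replicate recovery
studies (100–200 experiments) consume the latent knock-down times directly:
trace-level detection is validated separately and its ≤1 s error is
negligible on the log10-minutes scale.

Tolerances worth knowing: the two-variance polish optimizer caps
Nelder-Mead at 500 iterations (a boundary optimum walks log-ratios toward
−∞ on a likelihood flat to <1e-8); reported log-likelihoods agree with a
dense brute-force optimizer to 1e-5 in tests. AICc requires n > k + 1 and
raises otherwise. Degenerate inputs are errors, not NaNs: empty traces,
single-temperature TDTC input, random factors with one level.

## Known limitations

* ±2·SE intervals for the temperature coefficient are mildly
  anticonservative (~0.89–0.93 simulated coverage vs 0.954 nominal):
  temperature varies only between the 14 runs, and ML underestimates the
  run variance with that few levels. REML would reduce the bias but is
  incompatible with AICc comparison of fixed-effect structures, so it is
  out of scope by design.
* CTmax is always an extrapolation from the 35–40 °C window and inherits
  the slope's sampling error amplified by the extrapolation distance.
* The detection defaults (threshold, bout length) stand in for unpublished
  values; on real exports they should be set from the tracking software's
  noise floor.
* Right-censored subjects are dropped rather than modelled; with faithful
  protocol data none should occur.
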