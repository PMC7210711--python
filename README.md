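# thermotol

Thermal death time curve analysis of static-temperature heat-tolerance
assays, built around the kind of experiment run on the zooplankton
*Daphnia magna*: individuals of different body sizes are placed in heated
wells (35–40 °C), video-tracked at 3 Hz, and the time until each one stops
swimming is the measure of heat tolerance.

The package is for experimentalists and modellers who have (or want to
simulate) velocity tracking exports from such assays and need the full
analysis chain:

1. **Knock-down detection** — T_imm, the time from an individual's
   introduction into the well until its swimming velocity is last observed
   above a threshold (the video starts only after the last introduction, so
   each subject's introduction offset is added back).
2. **Thermal death time curves (TDTC)** — the semi-log law
   `log10 t = (CTmax − T) / z`, fitted by OLS of log10(T_imm, minutes) on
   temperature. `z = −1/slope` (°C; *high* z = *low* sensitivity) and
   `CTmax = −intercept/slope`, the extrapolated temperature of failure
   within one minute.
3. **Mixed-model selection** — three candidates for log10 T_imm
   (temperature × size, temperature + size, temperature only), all with
   crossed random intercepts for source beaker and measuring run, fitted by
   maximum likelihood and ranked by AICc with Akaike weights
   `w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`.
4. **Synthetic assays** — a generator that emulates the whole protocol
   (run/beaker structure, size groups, staggered introduction, 3 Hz bouts
   of swimming) with known ground truth, so detection fidelity and
   parameter recovery are testable without any real data.

See `docs/methods.md` for the model, the generator's defaults and the
numerical choices.

## Worked example

```python
import thermotol as tt
from thermotol.pipeline import estimates_from_truth

cfg = tt.SyntheticConfig(seed=3)               # 14 runs, 280 subjects, 35-40 C
runs, subjects, _, truths = tt.generate_experiment(cfg, with_traces=False)
est = estimates_from_truth(subjects, truths)   # error-free T_imm estimates

fits, pooled = tt.fit_tdtc_by_group(est, subjects, runs)
print(f"pooled z = {pooled.z_C:.2f} C  (generating value {cfg.z_true():.2f})")
for g, f in sorted(fits.items()):
    print(f"{g:>5}: z = {f.z_C:.2f} C, CTmax = {f.ctmax_C:.2f} C")
print(f"elevation shift (large - small) = "
      f"{pooled.elevation_difference('large', 'small'):.3f} log10 min")

frame = tt.build_model_frame(est, subjects, runs)
table = tt.compare_models([tt.fit_lmm(frame, s) for s in tt.CANDIDATE_SPECS])
print(table.table.round(2).to_string(index=False))
```

prints

```
pooled z = 2.22 C  (generating value 2.22)
large: z = 2.23 C, CTmax = 42.09 C
small: z = 2.22 C, CTmax = 42.48 C
elevation shift (large - small) = -0.177 log10 min

 model      fixed_effects  k    AICc  dAICc    w  acc_w   R2
     1 temperature + size  6 -399.54   0.00 0.74   0.74 0.98
     2 temperature × size  7 -397.45   2.09 0.26   1.00 0.98
     3        temperature  5 -257.27 142.27 0.00   1.00 0.97
```

Read it as: both size groups share the same temperature sensitivity
(z ≈ 2.2 °C — knock-down time shrinks tenfold per 2.2 °C), but the large
group's curve sits 0.18 decades lower, i.e. large individuals tolerate
every temperature for ~2/3 the duration of small ones. The AICc table
ranks the additive model first, with the interaction model a near-tie
(ΔAICc ≈ 2) — exactly the structure generated (a size effect on elevation,
none on slope). AICc values are negative here because the error-free
synthetic responses are tighter than real data; only differences matter.

On real tracking exports, start instead from the CSVs:

```sh
thermotol detect --runs runs.csv --subjects subjects.csv \
    --traces traces.csv --threshold 1.0 --out estimates.csv
thermotol fit --estimates estimates.csv --runs runs.csv \
    --subjects subjects.csv --out tdtc_fits.csv
thermotol compare --estimates estimates.csv --runs runs.csv \
    --subjects subjects.csv --out table1.csv
```

(`thermotol simulate` writes synthetic datasets in the same dialect;
`thermotol run` chains everything; `thermotol recover` runs replicate
parameter-recovery studies.)

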