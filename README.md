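# abrkit

Analysis battery for mouse auditory brainstem response (ABR) phenotyping
screens, together with a seeded synthetic cochlea simulator that provides
ground truth for every stage of the pipeline.

ABR screens characterise hearing in mutant mouse lines with a standard
stimulus battery: click and tone-pip level series (3–42 kHz, 0–95 dB SPL in
5 dB steps) for thresholds and wave-1 growth functions, forward-masked
frequency tuning curves, forward-masking recovery at increasing
masker–probe gaps, click-rate and onset-ramp series for neural adaptation
and synchrony, octave-band noise exposure with longitudinal follow-up, and
qRT-PCR confirmation of gene knockdown. `abrkit` implements the analysis
side of that battery as a tested, reusable library with a thin CLI.

## What it computes

* **Wave-1 metrics** — P1/N1 latencies and peak-to-peak amplitude of ABR
  wave 1, extracted from averaged traces; amplitude growth functions over
  level series.
* **Thresholds** — automated stand-in for visual threshold judgement: the
  lowest level whose response, and that of every higher level, passes a
  detection criterion (template correlation with the high-level response,
  or a 4σ amplitude rule). Censored thresholds ("> 95 dB SPL") are carried
  as such.
* **Frequency tuning curves** — forward-masked probe paradigm; masked
  threshold is the masker level producing a 50 % reduction of the
  normalised probe amplitude (isotonic regression + interpolated first
  crossing), per masker/probe ratio 0.5–1.6.
* **Forward-masking recovery** — normalised wave-1 amplitude vs
  masker–probe gap (4–64 ms), fitted with the exponential growth-to-maximum
  function

  ```
  y = y0 + a · (1 − e^(−b·x)),   τ = 1/b
  ```

  where `y0` is the predicted amplitude at zero gap, `a` the maximal rise
  and `τ` the recovery time constant in ms.
* **Group statistics** — pooled-wildtype 2.5–97.5 percentile reference
  ranges; Kruskal–Wallis one-way ANOVA on ranks with tie correction; Dunn's
  multiple comparison versus a control group
  (`Q = |R̄_i − R̄_c| / SE`, two-sided p scaled by the comparison family and
  capped at 1); Bonferroni-corrected significance levels (0.05/12 → 0.00417
  for the main battery, 0.05/4 → 0.0125 for noise-exposure groups).
* **qPCR fold changes** — relative expression by 2^−ΔΔCt with a
  housekeeping reference gene and wildtype calibration.
* **Noise exposure** — per-frequency threshold shifts against the
  pre-exposure baseline across 1 d / 3 d / 1 wk / 2 wk / 6 wk follow-up,
  split inside/above the 8–16 kHz exposure band, with censoring propagated
  as lower bounds; 6-week endpoint comparison vs sham and vs exposed
  wildtype.

The simulator (`abrkit.synthetic_cochlea`) generates complete session
archives for all of these paradigms from known per-mouse physiology
(thresholds, growth sigmoid, latency curve, recovery time constant, tuning
filter, adaptation coefficients), with configurable genotype effects and
noise-exposure dynamics — so every estimator can be validated by parameter
recovery.

## Worked example

```python
from abrkit import synthetic_cochlea as sc
from abrkit.group_statistics import threshold_endpoint_table, reference_range
from abrkit.temporal_analysis import recovery_curve, mean_recovery_curve, fit_recovery

archive, truth = sc.simulate_cohort(
    6, {"wildtype": sc.GenotypeEffect()}, "recovery", seed=42, return_truth=True
)

table = threshold_endpoint_table(archive)
click = table[table.condition == "click"]
rr = reference_range(click.value, stimulus_family="click")
print(f"click thresholds (n={rr.n}): mean {rr.mean:.1f} dB SPL, "
      f"95% reference range {rr.lo:.1f}-{rr.hi:.1f} dB SPL")

curves = [c for m in archive.mouse_ids() if (c := recovery_curve(archive, m, 50.0))]
fit = fit_recovery(mean_recovery_curve(curves))
print(f"forward-masking recovery (50 dB SL, n={len(curves)}): "
      f"y0={fit.y0:.3f}, a={fit.a:.3f}, tau={fit.tau_ms:.1f} ms, R^2={fit.r_squared:.3f}")
```

prints

```
click thresholds (n=6): mean 23.3 dB SPL, 95% reference range 20.0-29.4 dB SPL
forward-masking recovery (50 dB SL, n=6): y0=0.545, a=0.471, tau=20.2 ms, R^2=0.998
```

The six simulated mice have click thresholds near the 20 dB SPL wildtype
baseline (estimates carry the 5 dB grid resolution), and the group-mean
recovery fit returns the generating time constant of ≈20 ms with the fit
quality typical of mean forward-masking curves.

The same analyses are available from the shell: `abrkit simulate`,
`measure`, `thresholds`, `tuning`, `recovery`, `growth`, `stats`, `qpcr`,
`noise`, `report`; every subcommand reads/writes plain TSV.

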