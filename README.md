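# plusend

Simulation and quantification of actin filament **plus-end dynamics** in
single-filament TIRF experiments.

The growing (plus/barbed) end of an actin filament is a contested site:
formins such as mDia1 accelerate elongation (dramatically so with
profilin), capping protein (CP) arrests it, scaffolding dimers such as
IQGAP1 transiently pause it and can displace the other end-binders, and
formin–CP "decision complexes" stall growth until one partner leaves.
`plusend` packages the desk-side quantification used to characterise this
regulation from microscopy-derived tables:

- **kinetics** — per-filament elongation rates and pause detection. The
  elongation rate is the OLS slope of length vs time (µm/s) converted to
  subunits s⁻¹ µM⁻¹ via actin's linear density of 370 subunits/µm:
  `rate = slope × 370 / [actin]`. A pause is ≥ `min_frames` (default 3)
  consecutive frame increments with |Δlength| below a stall tolerance, so
  the shortest resolvable pause is `min_frames × frame_interval`
  (15 s at the standard 5 s interval).
- **distfit** — pause-duration frequency histograms fit with a Gaussian
  `A·exp(−0.5·((x − x̄)/SD)²)` vs an exponential decay
  `(Y0 − Dmax)·e^(−k·x) + Dmax`, compared by R².
- **photobleach** — oligomeric-state inference from step photobleaching:
  with labeling efficiency `p`, an n-mer shows `k ~ Binomial(n, p)` steps
  (conditioned on k ≥ 1, since unlabeled molecules are invisible);
  candidate states 1–4 are ranked by chi-square distance between the
  predicted and observed step histograms. Includes automated step counting
  by changepoint segmentation and labeling-efficiency spectroscopy
  arithmetic.
- **occupancy** — plus-end dwell-time survival curves (empirical or
  Kaplan–Meier for movie-end censoring) and two-channel single-molecule
  colocalization with greedy one-to-one matching plus a spatial-Poisson
  chance correction.
- **cellmetrics** — bundling skewness of pixel intensities, cell
  circularity `4πA/P²`, thresholded signal ratios, wound closure, and
  molecule budgets for a lamellipodium-scale compartment
  (`molecules = c·N_A·V`; one oligomer occupies one filament end).
- **simulate** — a seeded generator producing every input above with
  ground truth: filaments as a continuous-time jump process over end
  states (free / formin / formin+profilin / capped / decision complex /
  paused) with state-dependent growth rates and Gaussian pause durations,
  plus bleaching traces, dwell records, spot fields and bundle pixels.

## Worked example

```python
import numpy as np
from plusend import (SimConfig, simulate_filament_population,
                     estimate_elongation_rate, detect_pauses,
                     build_histogram, fit_gaussian)

cfg = SimConfig(seed=1)                       # 5 s frames, 600 s movie, 1 µM actin
tracks, truth = simulate_filament_population(cfg, 75)
rates = [estimate_elongation_rate(t, cfg.actin_conc).rate for t in tracks]
print(f"mean elongation rate: {np.mean(rates):.1f} subunits/s/uM")

pauses = [p for t in tracks for p in detect_pauses(t)]
fit = fit_gaussian(build_histogram([p.duration for p in pauses]))
print(f"{len(pauses)} pauses, Gaussian mean {fit.params['mean']:.1f} s, R2 {fit.r2:.2f}")
```

prints

```
mean elongation rate: 9.8 subunits/s/uM
34 pauses, Gaussian mean 19.1 s, R2 0.78
```

The mean rate sits below the configured 10.2 subunits s⁻¹ µM⁻¹ free-end
rate because pause frames are included in each whole-track slope; the
detected pause durations refit near the configured 20.6 s Gaussian mean
(with only 34 events the histogram is still noisy — R² approaches 0.99+
by n ≈ 1000, see `scripts/acceptance.py`).

A command-line layer mirrors the library:

```sh
plusend simulate --seed 1 --out bundle/
plusend kinetics --tracks bundle/tracks.tsv --conc 1.0 --out kinetics.json
plusend metrics budget --spec lamellipodium.yaml
```

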