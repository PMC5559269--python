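# endopatch

Quantification of cortical endocytic patch dynamics in two-channel
live-cell fluorescence movies of budding yeast — with a synthetic-movie
generator that provides ground truth for validating every step.

In yeast, clathrin-mediated endocytosis proceeds at cortical "patches":
coat proteins and nucleation-promoting factors (NPFs, e.g. the WASP
homologue Las17, the WIP homologue Vrp1, type I myosins) accumulate at a
site on the plasma membrane for tens of seconds, actin then assembles in a
burst (marked by Abp1 or Sac6), and the nascent vesicle moves inward off
the cortex. A central quantitative question is *when* actin assembly
fires relative to NPF accumulation: if assembly is switch-like, the actin
marker should appear when the NPF trace first crosses a fixed fraction
*f* of its own maximum, regardless of how long that takes.

`endopatch` implements the measurement chain this question needs:

- **`synth_movie`** — renders two-channel movies of a single cell
  (65 nm/pixel, 1–1.8 s frame intervals): diffraction-limited cortical
  patches with piecewise-linear intensity profiles, red-channel onset
  coupled to the green fraction-of-max crossing (or to a drawn delay),
  late inward internalization, an alternative "comet-tail" condition
  (static green patches + independently moving red objects with decaying
  tails), Poisson shot noise and Gaussian read noise. Every event carries
  full ground truth.
- **`cell_geometry`** — cell-outline segmentation and radial/angular
  coordinates; defines the cortical band.
- **`patch_tracking`** — difference-of-Gaussians spot detection with
  subpixel localization, optimal-assignment linking with gap closing,
  motility classification (static / internalizing / cytoplasmic-motile),
  and the crowded-patch exclusion rule (patches ever closer than 5 px to
  another patch are dropped from quantification).
- **`kymography`** — radial kymographs (one site, shows internalization)
  and circumferential kymographs (the unrolled cortex, shows all sites).
- **`event_quant`** — aperture-photometry intensity traces, threshold-run
  lifetimes, green/red pairing, actin-onset detection (T2), the
  **onset fraction** (green intensity at T2 over the green maximum — the
  70–80 % "threshold" statistic), T1 (first sustained crossing of the
  cohort-mean intensity-at-onset level L), the T2-on-T1 regression,
  aligned averaged profiles, arrival delays and colocalization fractions.
- **`stats_report`** / **`pipeline`** — two-sided Mann–Whitney U tests,
  cohort summaries, and a config-driven end-to-end driver.

## Worked example

Simulate three wild-type-like cells (Sla1-like lifetimes 24.1 ± 4.9 s,
actin onset at 75 % of the green maximum) and run the full pipeline:

```yaml
# wildtype.yaml
label: wild-type
simulation:
  n_movies: 3
  n_events: 8
  n_frames: 120
  lifetime_mean_s: 24.1
  lifetime_sd_s: 4.9
  threshold_fraction_f: 0.75
```

```sh
endopatch run --config wildtype.yaml --seed 7 --out out/
```

prints (abbreviated):

```json
{
  "n": 24,
  "lifetime_mean_s": 24.42,
  "lifetime_sd_s": 4.13,
  "onset_fraction_mean": 0.757,
  "onset_fraction_sd": 0.030,
  "n_internalizing": 23,
  "arrival_delay_mean_s": 9.96
}
```

All 24 simulated events were recovered; the blind pipeline measures a mean
patch lifetime of 24.4 s against the generating 24.1 s, finds the actin
marker appearing when the green trace is at 75.7 % of its maximum (the
hidden coupling fraction was 75 %), classifies 23/24 patches as
internalizing, and measures a 10 s NPF-before-actin delay (the coupling
implies f × rise time ≈ 0.75 × 0.6 × 24 s ≈ 11 s). `out/` additionally
contains per-track and per-event CSV tables, ground-truth tables, radial
and circumferential kymograph PNG/CSV files and a run log; rerunning with
the same seed reproduces every file byte-for-byte.

The same library surface is available in Python:

```python
from endopatch import SimParams, simulate_movie, analyze_movie

movie, truth = simulate_movie(SimParams(n_events=8, seed=1))
result = analyze_movie(movie)
result.lifetimes_s, result.pairs  # per-event measurements
```

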