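# reachfield

Analysis toolkit for single-neuron encoding of reach **direction** and
**amplitude** during movement planning, built around a synthetic generator of
Poisson-spiking neurons with known ground-truth tuning. It implements, as a
tested end-to-end pipeline:

- **Task geometry** — center-out reach-target layouts: a sparse task
  (4 directions × 2 amplitudes) and a dense task (16 directions × 3 amplitude
  rings, optionally staggered off a perfectly radial configuration), plus
  cm ↔ visual-degree conversion (`atan` and small-angle conventions).
- **Synthetic sessions** — per-trial firing rates in five 500 ms epochs
  (baseline, cue, early memory, late memory, movement) from a mixed
  population of untuned, direction-tuned, gain-modulated, and Gaussian
  position-tuned neurons, with Poisson spike-count noise.
- **Selectivity screening** — task-relatedness (paired t-test vs baseline at
  0.05/4 plus a 1 Hz floor), two-way fixed-effects ANOVA with interaction
  (direction × amplitude, type II sums of squares), direction-wise amplitude
  t-tests, Bonferroni selectivity flags (0.05/8 any-epoch, 0.05/4 planning),
  exact one-tailed binomial proportion tests, and a label-shuffle null.
- **Tuning geometry** — preferred directions, ΔPD (wrapped difference between
  the direction of strongest amplitude modulation and the preferred
  direction), Rayleigh test, circular mean ± SE, and amplitude-response
  curves along the preferred / anti-preferred rays.
- **Response fields** — piecewise-linear interpolation of per-target mean
  rates onto an 11×11 grid spanning 14 cm × 14 cm (nearest-fill plus validity
  mask outside the target hull), mid-range normalization to [0, 1], peak
  eccentricity and top-quartile field width in visual degrees, and a
  display-only Gaussian blur that quantification functions refuse.
- **Encoding models** — five parametric models (cosine tuning; cosine ×
  linear amplitude gain; Von Mises tuning; Von Mises × gain; 2D Gaussian
  position tuning), constrained multi-start least squares with analytic
  Jacobians, split-half cross-validated **model consistency** against the
  split-half internal-consistency noise ceiling (50 resamples by default),
  and pairwise Wilcoxon signed-rank model comparison.

Note: the Gaussian position model is implemented as
`exp(-½ (x−μ)ᵀ Σ⁻¹ (x−μ))`; a divergent sign variant that appears in some
descriptions cannot describe a response field peaking at μ.

## CLI

```sh
reachfield simulate  --task task2 --seed 1 --out run/ --n-neurons 20
reachfield selectivity --task task1 --seed 1 --out run/
reachfield fields    --task task2 --seed 1 --out run/
reachfield models    --task task2 --seed 1 --out run/ --n-repeats 50 --n-restarts 10
reachfield pipeline  --config config.json
reachfield recover   --ground-truth run/ground_truth.tsv --run-dir run/
```

Every command accepts `--config <json>` (see `reachfield.pipeline_cli.RunConfig`
for the schema) with CLI flags overriding config values. All tabular outputs
are tab-delimited text with headers; summaries are JSON; `manifest.json`
records the config, master seed, and config hash, and suffices to reproduce
any table bit-for-bit. Random draws derive from the master seed through
per-stage and per-neuron streams, so runs are deterministic and adding
neurons does not perturb existing ones.

To analyze recorded (non-synthetic) data, pass `--input-table` / set
`input_table` to a trial table with columns
`neuron_id, trial_id, target_index, direction_deg, amplitude_cm,
rate_baseline_hz, rate_c_hz, rate_em_hz, rate_lm_hz, rate_rtmt_hz`.

## Layout

```
src/reachfield/
  task_geometry.py    targets, configurations, angle/visual-degree utilities
  synthetic_data.py   ground-truth neurons, Poisson session simulator, tables
  selectivity.py      ANOVA battery, t-tests, Bonferroni flags, shuffle null
  tuning_geometry.py  preferred direction, delta-PD, circular statistics
  response_field.py   grid interpolation, normalization, field metrics
  encoding_models.py  model specs, fitting, split-half consistency, comparison
  pipeline_cli.py     orchestration, RunConfig, recovery scoring, CLI
```
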