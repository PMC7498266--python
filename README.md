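# mapkdyn

Single-cell quantification of MAPK/ERK signaling dynamics in epithelial
monolayers, for imaging labs working with kinase translocation reporters
(KTRs) and mosaic oncogene-induction cocultures. The package turns
per-cell tracking tables, confocal z-stacks, EdU counts and supernatant
proteomics tables into the quantities such experiments are judged by:

- **ERK activity traces and peak calling** — per-cell cytoplasm/nucleus
  KTR ratio C/N(t), cleaned by track-switch/segmentation/coverage rules,
  with a findPeaks-style caller (Gaussian-refined extrema; a maximum is a
  peak iff rise ≥ `min_amplitude`, rise rate ≥ `min_slope`, and a
  subsequent fall ≥ `fall_fraction`·rise), and a pulsatile / sustained /
  quiescent call from (duty cycle, peak count).
- **Directed migration** — displacement angles θ ∈ [0°, 180°] of
  neighboring cells over 20-min intervals relative to the inducible-group
  center (0° = toward), radial histograms, and the subsampled two-sample
  Kolmogorov–Smirnov procedure (median p over `n_iter` iterations of
  `n_sub` angles each).
- **Apical extrusion** — per-channel intensity-vs-z profiles from
  two-channel z-stacks, single-Gaussian fits, and
  ΔZ = µ̂(inducible) − µ̂(all) in µm, baseline-normalized and compared by
  Welch's t-test.
- **Population statistics** — EdU S-phase fractions and ±Dox fold changes
  normalized to a parental mean of exactly 1, the proportion–response
  relation, and the shed-protein filter (both p < 0.05 and, for the "box",
  both |ln FC| > ln 1.5).
- **Synthetic data with ground truth** — seeded generators for every
  input modality (pulse trains, logistic steps, von Mises-biased
  trajectories, Gaussian-blob z-stacks, binomial EdU counts, triplicate
  shed-protein abundances), used by the test suite for recovery checks.

See `docs/methods.md` for models, parameter defaults and their rationale,
numerical choices and known limitations.

## Worked example

Simulate one coculture movie (150 cells, 6 h at 5-min frames, 10%
pulsatile inducible cells, neighbors acquiring a toward-center migration
bias κ = 1 after 2 h) and quantify it:

```python
import numpy as np
from mapkdyn.params import PulseTrainParams, MigrationSimParams
from mapkdyn import simulate, traces, migration as mig

motion = MigrationSimParams(n_cells=150, n_frames=72, bias_kappa=1.0,
                            inducible_fraction=0.1, bias_start_min=120.0, seed=7)
table, gt = simulate.simulate_track_population(
    PulseTrainParams(mean_rate=2.0, seed=7), motion)

n_frames = int(table["frame"].max()) + 1
all_traces = [traces.compute_activity_trace(g, n_frames)
              for _, g in table.groupby("cell_id", sort=True)]
kept, excluded = traces.clean_traces(all_traces)
ind = [t for t in kept
       if table.loc[table.cell_id == t.cell_id, "population"].iat[0] == "inducible"]
counts = [traces.count_peaks(t).count for t in ind]

before = mig.collect_angle_sample(table, (0.0, 120.0), epoch_label="before")
after = mig.collect_angle_sample(table, (120.0, 355.0), epoch_label="after")
res = mig.subsampled_ks_test(before, after, n_iter=1000, n_sub=1000, seed=7)
```

Output:

```
retained 150/150 traces (0 excluded)
inducible cells: mean peak count 6.3 over 6 h (true mean 6.3)
angles: 150 before, 286 after; mean angle 86 deg -> 40 deg
subsampled KS: median p = 9.1e-20 (***)
```

The caller recovers the simulated pulse count exactly on average; the
neighbors' mean migration angle drops from ~90° (isotropic) before
induction to 40° (toward the inducible group) after, and the subsampled KS
procedure calls the shift highly significant.

The same analyses are scriptable from the shell (`mapkdyn simulate ...`,
`mapkdyn peaks`, `mapkdyn migrate`, `mapkdyn extrude`, `mapkdyn edu-fold`,
`mapkdyn shed-filter`), and `mapkdyn run --config pipeline.yaml` chains
simulate → analyze → report with a checksummed run manifest.

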