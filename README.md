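# kar3team

Stochastic simulation and single-molecule trajectory analysis for elastically
coupled kinesin motor teams, plus the supporting synthetic-data, tracking and
hydrodynamics machinery.

The package contains five analysis layers:

- **`team_model`** — fixed-step stochastic simulation of N motors coupled by
  identical springs to a massless cargo node (star topology, so the node sits
  at the mean of the engaged head positions). Motors carry persistent
  intrinsic velocities, obey a linear force–velocity relation clamped at the
  stall force, and detach with a capped exponential force-dependent rate.
  Includes per-team-size summary statistics and a grid fit of
  (stall force, rebinding rate, saturated unbinding rate) to observed
  per-size velocity/run-length tables.
- **`synthetic_data`** — ground-truthed generators: directed / diffusive /
  static 1-D trajectory populations from named motility presets, quantized
  photobleaching intensity traces, and TIRF-like 16-bit TIFF stacks rendered
  with pixel-integrated Gaussian PSFs, Poisson + read noise and optional
  shading fields.
- **`tracking`** — the detection/linking pipeline: 11×11 median-filter
  shading correction (divide), 3×3 Gaussian smoothing, MAD-thresholded
  local-maxima detection with a 532 nm suppression radius and 332 nm circular
  ROIs, and greedy best-circle-overlap frame-to-frame linking (a globally
  optimal assignment variant serves as a cross-check oracle).
- **`track_stats`** — per-track velocities, Gaussian and right-censored
  exponential MLE fits, count-weighted ensemble MSD with power-law
  (`a·t^n + c`) and linear-diffusion fits, diffusion fold-change tables,
  photobleaching step counting by binary segmentation with a BIC stop, and a
  constrained Gaussian-mixture (means `k·μ1`, SDs `√k·σ1`) for fluorophore
  stoichiometry.
- **`hydro`** — native molecular weight from a Stokes radius and a
  sedimentation coefficient (Siegel–Monty relation) plus linear calibration
  against standards.

`cli_io` ties the layers together: YAML configuration, track CSV I/O,
deterministic per-stage seeding, and a staged demo pipeline
(simulate → generate → render → re-track → analyse).

## Command line

```sh
kar3team simulate --size 3 --runs 200 --seed 1 --out runs.csv
kar3team fit --observed team_size_stats.csv --grid grid.yaml --runs 200
kar3team generate --preset wt_atp --n-tracks 100 --interval-s 3 --out tracks.csv
kar3team track movie.tif --pixel-nm 133 --interval-s 3 --out tracks.csv
kar3team stats tracks.csv --analysis msd
kar3team hydro --rs 9.1 --s 5.6
kar3team demo --seed 1 --out-dir demo_out
```

Motility presets (`wt_atp`, `vik1_atp`, `chimera_atp`, `adp`, `mutant_atp`,
`apo`, `amppnp`) ship with the package; see
`kar3team.synthetic_data.PRESETS`.

## Notes

- All randomness flows through `numpy.random.Generator`s seeded from the
  caller; every generator, simulation and rendering is bit-reproducible for
  a fixed seed.
- Coordinates are nm along the microtubule axis, minus-end positive; pixel
  indexing is 0-based (row, col).
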