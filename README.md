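# egfrsim

A 3D multiscale Brownian-Dynamics simulator of EGFR/ERK-driven tumour
initiation. Three scales are coupled by operator splitting:

1. **Extracellular signalling** — individual EGF ligands diffuse through a
   spherical tissue domain as Brownian particles, are introduced in an outer
   shell, degrade with a 30-minute mean lifetime, and bind receptor clusters
   on cell surfaces by a reaction-on-overlap rule.
2. **Intracellular cascade** — each cell carries an explicit particle-based
   EGFR → Ras → Raf → ERK → transcription-factor (TF) cascade: 610 proteins
   (200 Ras, 60 Raf, 300 ERK, 50 TF) diffuse inside the cell, activate on
   contact with an active upstream partner, and switch off after
   exponentially distributed residence times. K-Ras / B-Raf mutations slow
   the corresponding switch-off rate, turning a transient response into a
   constitutive one; EGFR overexpression raises the receptor-cluster count.
3. **Cell mechanics and fate** — cells are soft spheres with incompressible
   nuclei interacting through the repulsive force
   `f = K (h0 − h) / (h − (h0 − h1))`, integrated with inertia and friction.
   At the G1 checkpoint a cell commits to division if its active-TF count
   exceeds a threshold, otherwise it dies; committed cells grow linearly to
   twice their birth volume and divide.

The simulator reproduces the qualitative biology of tumour initiation: a
normal cell's TF signal is a transient pulse (peak ≈ 40 min, gone by
≈ 3 h); Ras/Raf mutants signal constitutively and their tumours never fail
the checkpoint; EGFR overexpression helps only while signalling is not
saturated (6 ≪ 12 ≈ 24 receptor clusters); widely spaced receptor clusters
out-signal adjacent ones.

Model details, parameter tables with units and provenance, calibration
procedure, and numerical choices are in [docs/methods.md](docs/methods.md).

## Worked example

Python API — compare the normal transient with the constitutive K-Ras
response in the single-cell scenario (one receptor cluster active for its
8-minute window):

```python
from egfrsim import Config, MutationProfile, run_single_cell

cfg = Config()
normal = run_single_cell(cfg, seed=7, replicates=25, t_end=120.0)
kras = run_single_cell(cfg, MutationProfile(kras=True), seed=7, replicates=5, t_end=120.0)

for name, df in (("normal", normal), ("kras", kras)):
    tf = df[df.species == "TF"].groupby("time")["active"].mean()
    print(f"{name:7s} peak mean active TF = {tf.max():5.1f} at t = {tf.idxmax():3.0f} min, "
          f"final (120 min) = {tf.iloc[-1]:.1f}")
```

Output (verbatim):

```
normal  peak mean active TF =  40.8 at t =  28 min, final (120 min) = 4.2
kras    peak mean active TF =  48.0 at t =  82 min, final (120 min) = 47.4
```

The normal ensemble peaks half an hour after stimulation and decays back to
zero (it reaches exactly 0 by ≈ 180 min); the K-Ras ensemble saturates and
stays high — the signature that later drives unchecked growth in the tumour
scenario.

Command line — the same scenario, plus the receptor-placement and
tumour-growth scenarios:

```
$ egfr-sim single-cell --seed 1 --replicates 10 --t-end 120 --out /tmp/demo
wrote /tmp/demo/single_cell_timeseries.csv (peak mean active TF = 42.5)

$ egfr-sim placement --seed 1 --replicates 25 --out out/placement
$ egfr-sim tumour --seed 1 --kras --t-end 2880 --out out/tumour
```

Every command writes tidy CSV time series plus a `manifest.json` recording
the full configuration and seed, so any run can be reproduced exactly.
`run_tumour` / `egfr-sim tumour` also write a final spatial snapshot (cells
and free ligands).

## Configuration

All lengths are in µm, all times in minutes. `--config cfg.yaml` accepts a
YAML file with any subset of sections/keys; unknown keys are an error.
Defaults (see `egfrsim.config` for per-key provenance):

| Section | Keys (defaults) |
| --- | --- |
| `domain` | `r_domain: 120`, `shell_thickness: 2` |
| `field` | `d_egf: 600`, `introduction_rate: 22`, `degradation_rate: 0.0333`, `r_egf: 0.05`, `rerelease_on_unbind: false` |
| `receptors` | `r_rec: 1.0`, `r_rec_outer: 0.4`, `k_off: 0.125`, `n_egfr: 6` |
| `intracellular` | `n_ras: 200`, `n_raf: 60`, `n_erk: 300`, `n_tf: 50`, `d_protein: 0.25`, `r_bd: 0.2`, `k_off_ras/raf/erk: 0.1`, `k_off_tf: 0.0667` |
| `cell` | `r_cell: 5`, `r_nucleus: 2.5` |
| `mechanics` | `m: 1`, `mu: 10`, `K: 50`, `overdamped: false` |
| `cycle` | `cycle_mean: 1440`, `cycle_jitter: 180`, `g1_duration: 660`, `n_tf_star: 40`, `replenish_daughters: true` |
| `run` | `dt: 0.005`, `record_every: 1` |

`egfrsim.scaled_tumour_config()` returns the desk-scale tumour
configuration (60 µm domain, scarce ligand supply, 12-hour cycle) used by
the growth experiments; per-cell parameters are unchanged.

## Repository layout

```
src/egfrsim/        the package
  config.py         defaults, units, provenance, YAML loading, validation
  core.py           seed streams, reflection, sampling primitives
  _kernels.py       numba kernels (particle stepping, overlap search, forces)
  extracellular.py  EGF field, receptor clusters, binding/release
  intracellular.py  per-cell particle cascade
  mechanics.py      cell objects, forces, motion, cycle/fate, division
  orchestrator.py   operator-split step and the three scenario runners
  io.py             CSV/JSON writers, deterministic fixtures
  cli.py            egfr-sim command group
tests/              unit tests + tests/test_acceptance.py
scripts/acceptance.py   recomputes the acceptance targets
docs/methods.md     full model and methods description
```
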