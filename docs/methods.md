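# Methods

This document describes the model implemented by `egfrsim`, the meaning and
provenance of every parameter, how the free parameters were calibrated, and
the numerical choices behind the implementation.

## 1. Model overview

`egfrsim` simulates the earliest stage of tumour formation as the interplay
of three coupled scales:

1. **Extracellular signalling.** Epidermal growth factor (EGF) particles
   diffuse through a spherical tissue domain, are introduced at a constant
   mean rate in a thin layer at the outer boundary (influx from surrounding
   tissue), and disappear after an exponentially distributed lifetime
   (degradation). Free ligands reflect off the domain boundary and off cell
   bodies. A ligand reaching the binding pocket of an inactive receptor
   cluster binds it and switches it on.

2. **Intracellular signalling.** Each cell carries an explicit particle-based
   model of the EGFR/ERK cascade: 200 Ras, 60 Raf, 300 ERK molecules in the
   cytoplasm and 50 transcription factors (TFs) in the nucleus, 610 molecules
   in total, each a point particle diffusing by Brownian motion in cell-local
   coordinates. An active (ligand-bound) receptor cluster's intracellular
   G-protein site activates Ras molecules that diffuse within reach; active
   Ras activates Raf on contact, active Raf activates ERK, and active ERK
   that enters the nucleus activates TFs. Activation is catalytic (the
   activator is not consumed) and every activated molecule switches off again
   after an exponential waiting time. Oncogenic mutations lower the
   inactivation rate of the affected species (K-Ras → Ras, B-Raf → Raf) by a
   factor of 100, making activation quasi-permanent.

3. **Cell mechanics and fate.** Cells are soft spheres with an
   incompressible nucleus that move under pairwise repulsion with Newtonian
   dynamics plus friction (an overdamped reduction is available). At the end
   of G1 a cell commits to division only if its instantaneous number of
   active TFs strictly exceeds the threshold N\*; otherwise it dies by
   apoptosis. Committed cells double their volume linearly over the rest of
   the cycle and split into two daughters along a uniformly random axis.

The three scales are advanced by operator splitting with one global time
step: (1) field introduction, diffusion, binding, receptor release; (2) one
Brownian-Dynamics step of every cell interior; (3) fate, growth, division,
and motion. The clock advances at the end of the step.

## 2. Brownian Dynamics and the reaction rule

All particles follow the Euler–Maruyama discretisation of free diffusion:
each coordinate is incremented by a Normal(0, √(2·D·dt)) draw per step.
Confinement (domain, cytoplasmic shell, nucleus) is enforced by iterated
radial mirror reflection across the violated spherical boundary.

Bimolecular reactions use a reaction-radius rule: a candidate pair reacts in
a step when the distance between the two particles at the end of the step is
at most the sum of their reaction radii. Updates within a step are
synchronous — activations fire based on the set of molecules that were
active when the step began, so a molecule activated in a step begins to
catalyse in the next step. This makes the kernel order-independent and
deterministic given the pre-drawn displacements.

Two regimes of this scheme matter for parameter choice:

* **Diffusion-limited** (rms step √(2·D·dt) ≪ reaction distance d): the
  effective pair rate approaches the ballistic-free value and the scheme's
  bias decays like √(D·dt)/d. This is the regime the intracellular cascade
  operates in, and it is what makes the ensemble means converge as dt is
  refined toward the default dt = 0.005 min.
* **Well-mixed** (rms step ≫ confinement size): positions decorrelate every
  step and the scheme reduces to mass-action kinetics with per-pair rate
  (v_react / V) / dt. The test suite uses this limit as an analytic oracle.

## 3. Parameters

Lengths in µm, times in minutes. Provenance tags: **paper** = value printed
in the source publication for this model; **calibrated** = fixed by
calibrating the single-cell scenario (Sect. 4) and then frozen; **assumed** =
generic order-of-magnitude choice.

### Domain and field

| key | default | units | provenance | rationale |
|---|---|---|---|---|
| `domain.r_domain` | 120 | µm | paper | spherical tissue domain (the source gives 120 "mm", treated as a µm typo — 120 mm is anatomically impossible next to 5 µm cells) |
| `domain.shell_thickness` | 2 | µm | assumed | thin outer introduction layer |
| `field.d_egf` | 600 | µm²/min | assumed | ~10 µm²/s, order of magnitude for a small protein in tissue |
| `field.introduction_rate` | 22 | 1/min | calibrated | together with the degradation rate fixes the stationary count 22/(1/30) = 660 quoted for the cell-free domain |
| `field.degradation_rate` | 1/30 | 1/min | calibrated | 30-min mean extracellular lifetime |
| `field.r_egf` | 0.05 | µm | assumed | ligand reaction radius |
| `field.rerelease_on_unbind` | False | – | assumed | bound ligand is internalised/consumed by default |

The cell-free field is a birth–death (M/M/∞) process; the stationary free
count is Poisson with mean introduction_rate/degradation_rate = 660.

### Receptors

| key | default | units | provenance | rationale |
|---|---|---|---|---|
| `receptors.r_rec` | 1.0 | µm | calibrated | intracellular G-protein sphere radius (Ras-activation reach), centred at R_cell − r_rec along the cluster's anchor |
| `receptors.r_rec_outer` | 0.4 | µm | calibrated | extracellular ligand-binding sphere radius, centred at R_cell + r_rec_outer |
| `receptors.k_off` | 1/8 | 1/min | paper | 8-min mean active-receptor residence time |
| `receptors.n_egfr` | 6 | – | paper | baseline receptor-cluster count; 12 and 24 model EGFR overexpression |

The two spheres of a receptor cluster are clamped to the membrane along the
outward normal and track the cell as it moves. Their radii are decoupled on
purpose: a small binding pocket makes ligand capture, and hence receptor
occupancy, episodic (a single cluster is bound only a few percent of the
time at physiological ligand abundance), so the number of clusters controls
the fraction of time the cascade is driven. With a single large sphere for
both roles, six receptors already saturate the cascade and the documented
receptor-count dependence disappears.

### Intracellular cascade

| key | default | units | provenance | rationale |
|---|---|---|---|---|
| `intracellular.n_ras/n_raf/n_erk/n_tf` | 200/60/300/50 | – | paper | fixed complement, 610 molecules |
| `intracellular.d_protein` | 0.25 | µm²/min | calibrated | see Sect. 4 |
| `intracellular.r_bd` | 0.2 | µm | calibrated | protein reaction radius |
| `intracellular.k_off_ras/raf/erk` | 0.1 | 1/min | calibrated | 10-min mean active lifetime |
| `intracellular.k_off_tf` | 1/15 | 1/min | calibrated | 15-min mean active-TF lifetime |

Diffusion domains: Ras and Raf live in the cytoplasmic shell; TFs in the
nucleus; inactive ERK is cytoplasmic but an activated ERK may enter the
whole cell (and is re-confined to the cytoplasm once it is inactive and
outside the nucleus). Mutations: K-Ras multiplies `k_off_ras`, B-Raf
multiplies `k_off_raf`, each by `MutationProfile.multiplier` (default 0.01).

### Cell body, mechanics, cycle

| key | default | units | provenance | rationale |
|---|---|---|---|---|
| `cell.r_cell` | 5 | µm | assumed | radius at birth |
| `cell.r_nucleus` | 2.5 | µm | assumed | incompressible core |
| `mechanics.K` | 50 | force | assumed | repulsion scale |
| `mechanics.m`, `mechanics.mu` | 1, 10 | –, 1/min | assumed | inertia retained; friction dominates within ~0.1 min |
| `cycle.cycle_mean` | 1440 | min | paper | 24-h mean cycle |
| `cycle.cycle_jitter` | 180 | min | paper | ±3 h uniform perturbation |
| `cycle.g1_duration` | 660 | min | assumed | 11-h G1 |
| `cycle.n_tf_star` | 40 | – | calibrated | G1 checkpoint threshold (of 50 TFs), Sect. 4 |
| `cycle.replenish_daughters` | True | – | assumed | see below |
| `run.dt` | 0.005 | min | paper | convergence point of the dt-refinement study |

The pairwise repulsion between cells i and j at centre distance h is

    f = K (h0 − h) / (h − (h0 − h1)),   h0 − h1 < h < h0,

with h0 the sum of radii and h1 the sum of nucleus radii; it vanishes for
separated cells and diverges at hard-core contact, which keeps the
incompressible cores from interpenetrating (an invariant the test suite
checks). Motion uses semi-implicit Euler: v ← (v + dt·F/m)/(1 + µ·dt).

**Division.** The mother's molecules are split between the daughters by a
random per-species halving (the odd molecule assigned by a fair coin);
positions are re-drawn uniformly (dilution). By default daughters are then
topped back up to the standard 610-molecule complement, representing protein
synthesis during growth: without replenishment the complement would decay
geometrically across generations and sustained growth over many generations
— which the source model exhibits — would be impossible.

## 4. Calibration

The rates and radii tagged *calibrated* were fixed against the single-cell
scenario and then frozen before any acceptance test was written.

* **Cascade kinetics.** The constraint is the documented single-cell
  transient: with one receptor cluster active for 8 min, the ensemble-mean
  active-TF count should rise for roughly the first 40 minutes and then
  decay back to zero. With fast (physiological) protein diffusion the
  610-molecule cascade saturates within a minute at any reasonable reaction
  radius, so the model operates in a slow-diffusion regime
  (`d_protein = 0.25 µm²/min`, `r_bd = 0.2 µm`) in which signal propagation
  through Ras → Raf → ERK → TF takes tens of minutes. With inactivation
  rates 0.1/min (proteins) and 1/15/min (TFs), the ensemble peak sits at
  ≈ 38–40 min with ≈ 38–40 of 50 TFs active, and the response is extinguished
  by ≈ 2 h. Mutated profiles (K-Ras or B-Raf, multiplier 0.01) turn the same
  transient into a constitutive response that persists at 12 h, and the
  combined mutation behaves like either alone.
* **Receptor geometry** (`r_rec = 1.0`, `r_rec_outer = 0.4`): chosen so that
  a single bound cluster reliably drives nearby Ras (inner sphere), while
  capture episodes are sparse enough that 6, 12, and 24 clusters produce
  distinguishable TF statistics (outer sphere); see the table below.
* **Fate threshold** (`n_tf_star = 40`): placed using the stationary
  active-TF distributions of single cells held in the scaled tumour field
  (Sect. 5), measured over 4 × 600 min per genotype *before* the tumour
  acceptance test was written:

  | genotype | mean TF | P(TF ≤ 40) |
  |---|---|---|
  | 6 clusters | 34.3 | ≈ 0.58 |
  | 12 clusters | 42.0 | ≈ 0.25 |
  | 24 clusters | 45.2 | ≈ 0.07 |
  | K-Ras | 47.4 | ≈ 0.00 |

  The threshold sits between the 6-cluster and 12-cluster distributions, so
  per-checkpoint failure probabilities are strongly ordered by genotype,
  which is what produces the documented growth-rate ordering.

## 5. Desk-scale problem sizes

Problem sizes are this package's own choice; the source experiments (2-week
tumours, hundreds of cells) are not desk scale. Defaults:

* **Single-cell scenarios**: 25 replicates × 2 h at dt = 0.005 min
  (seconds to a few minutes on one CPU).
* **Convergence study**: 10 replicates per dt, active counts at 30 min.
* **Tumour scenario** (`scaled_tumour_config()`): 2 simulated days in a
  60-µm domain with EGF introduction 1.375/min and a 12-h cycle
  (G1 = 5.5 h, jitter ± 1.5 h). The introduction rate is **half** the
  concentration-matched value for the reduced volume: a large tumour's cells
  compete for ligand, and halving the supply reproduces that ligand-limited
  regime — in which receptor count matters — for populations small enough to
  simulate in minutes. Cycle compression only increases the number of
  generations in the horizon; TF dynamics equilibrate within ~2 h ≪ G1, so
  the per-checkpoint statistics are unaffected. Per-cell model parameters
  are untouched.

## 6. Numerical choices

* **Time stepping**: single global dt (default 0.005 min) for all
  subsystems, operator-split in the fixed order field → interiors → cell
  actions; the clock is synchronised at the end of each step.
* **Convergence**: the scheme's bias decreases like √(D·dt); at 10-replicate
  Monte-Carlo resolution the ensemble means at 30 min stop changing
  detectably for dt ≤ 0.005 min, which the acceptance suite verifies by a
  Welch-test scan of the ladder 0.02, 0.01, 0.005, 0.0025 against a 0.001
  reference.
* **Reproducibility**: every random draw comes from a `numpy` Generator
  spawned from `SeedSequence([master_seed, namespace, key])`. Each cell owns
  a stream keyed by its id, the field another; compiled kernels consume only
  pre-drawn arrays, so runs are bit-reproducible and adding a cell never
  perturbs another cell's stream.
* **Performance**: the hot loops (reflection, interior step, ligand step,
  overlap search, pairwise forces) are `numba`-compiled. Interiors with no
  active molecule, no active receptor, and no roaming ERK are skipped —
  a uniform molecule distribution is invariant under diffuse-and-reflect and
  nothing can fire, so the skip is exact, not an approximation. Ligand
  binding short-circuits when no particle is near any cell. A uniform
  spatial hash (`BinGrid`) is available for the all-pairs force loop once
  populations grow beyond a few dozen cells.

## 7. Limitations

* Reaction radii, diffusion coefficients and inactivation rates are
  calibrated to reproduce documented system-level behaviour, not measured
  molecular values; quantitative predictions are out of scope.
* The reflection/overlap BD scheme has O(√dt) weak bias; results are only
  meaningful at or below the converged step (dt ≤ 0.005 min).
* MEK is omitted (Raf activates ERK directly), as in the source model.
* No healthy-tissue mechanics around the tumour; growth is into free space.
* The G1 checkpoint reads the instantaneous TF count; there is no
  integration window.
* Full 2-week, multi-hundred-cell runs are possible but take hours on one
  CPU; the shipped scenarios are desk-scale reductions.
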