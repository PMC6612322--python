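"""Center-based cell mechanics, cycle, fate, growth, and division.

Cells are soft spheres with an incompressible nucleus.  Motion follows
Newtonian dynamics with friction, m x'' + m mu x' = sum of pairwise
repulsive forces; the inertial term is retained by default (the model is
meant to cover micro-environments of different Reynolds numbers) with an
overdamped first-order reduction available as an option.  The repulsive
force between two cells at centre distance h is

    f = K (h0 - h) / (h - (h0 - h1))   for h0 - h1 < h < h0,   0 otherwise,

with h0 the sum of radii and h1 the sum of nucleus radii, diverging as the
incompressible cores come into contact.

Fate: at the end of G1 a cell commits to growth and division if its active
transcription-factor count strictly exceeds the threshold N_TF*; otherwise
it dies by apoptosis.  Committed cells double their volume linearly by the
end of the cycle and split into two daughters along a uniformly random
axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .config import Config, MutationProfile
from .core import NS_CELL, spawn_stream, uniform_point_on_sphere
from .extracellular import Receptors, make_receptors
from .intracellular import (
    CellInterior,
    count_active_tf,
    halve_on_division,
    init_cell_molecules,
    replenish,
)

__all__ = [
    "Cell",
    "repulsion_force",
    "integrate_motion",
    "advance_cycle_and_fate",
    "grow",
    "divide",
    "make_cell",
]

PHASE_G1 = "G1"
PHASE_COMMITTED = "committed"
PHASE_DYING = "dying"


@dataclass
class Cell:
    id: int
    pos: np.ndarray                 # (3,) µm
    vel: np.ndarray                 # (3,) µm/min
    radius: float                   # current radius, µm
    r_nucleus: float                # incompressible radius, µm
    birth_radius: float             # radius at creation (volume V_birth)
    cycle_length: float             # min
    cycle_clock: float = 0.0        # min since birth
    phase: str = PHASE_G1
    interior: CellInterior = None   # type: ignore[assignment]
    receptors: Receptors = None     # type: ignore[assignment]
    profile: MutationProfile = field(default_factory=MutationProfile)
    rng: np.random.Generator = None  # type: ignore[assignment]

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def active_tf(self) -> int:
        return count_active_tf(self.interior)


def make_cell(
    cell_id: int,
    pos: np.ndarray,
    config: Config,
    master_seed: int,
    profile: MutationProfile | None = None,
    cycle_length: float | None = None,
    n_receptors: int | None = None,
) -> Cell:
    """Create a fresh G1 cell with its own derived random stream."""
    profile = profile or MutationProfile()
    rng = spawn_stream(master_seed, NS_CELL, cell_id)
    if cycle_length is None:
        cy = config.cycle
        cycle_length = cy.cycle_mean + rng.uniform(-cy.cycle_jitter, cy.cycle_jitter)
    if n_receptors is None:
        n_receptors = profile.n_egfr or config.receptors.n_egfr
    interior = init_cell_molecules(
        config.cell.r_cell, config.cell.r_nucleus, config.intracellular, rng, profile
    )
    return Cell(
        id=cell_id,
        pos=np.asarray(pos, dtype=float).copy(),
        vel=np.zeros(3),
        radius=config.cell.r_cell,
        r_nucleus=config.cell.r_nucleus,
        birth_radius=config.cell.r_cell,
        cycle_length=float(cycle_length),
        interior=interior,
        receptors=make_receptors(n_receptors, rng),
        profile=profile,
        rng=rng,
    )


def repulsion_force(h_ij: float, h0: float, h1: float, K: float) -> float:
    """Magnitude of the pairwise repulsion at centre distance ``h_ij``.

    Diverges as ``h_ij`` approaches the hard-core distance ``h0 - h1`` and
    vanishes for separated cells (``h_ij >= h0``).
    """
    if not (0 < h1 < h0):
        raise ValueError(f"need 0 < h1 < h0, got h0={h0!r}, h1={h1!r}")
    if K <= 0:
        raise ValueError(f"K must be positive, got {K!r}")
    if h_ij >= h0:
        return 0.0
    if h_ij <= h0 - h1:
        raise ValueError(
            f"incompressibility violated: h_ij={h_ij!r} <= h0 - h1 = {h0 - h1!r}"
        )
    return K * (h0 - h_ij) / (h_ij - (h0 - h1))


def integrate_motion(cells: list[Cell], dt: float, config: Config, grid=None) -> float:
    """Advance positions and velocities by one semi-implicit Euler step.

    With inertia, v <- (v + dt F / m) / (1 + mu dt); overdamped option uses
    v = F / (m mu).  Forces are accumulated all-pairs for small
    populations, or over neighbour-bin candidates when a grid is supplied.
    Returns the minimum hard-core margin min(h_ij - (h0 - h1)) observed
    (+inf when no pair interacts).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    if not cells:
        return np.inf
    mech = config.mechanics
    pos = np.array([c.pos for c in cells], dtype=float)
    radii = np.array([c.radius for c in cells], dtype=float)
    nuc = np.array([c.r_nucleus for c in cells], dtype=float)
    forces = np.zeros_like(pos)
    if grid is not None:
        margin = _forces_with_grid(pos, radii, nuc, mech.K, forces, grid)
    else:
        margin = _kernels.pairwise_forces(pos, radii, nuc, mech.K, forces)
    for i, c in enumerate(cells):
        if mech.overdamped:
            c.vel = forces[i] / (mech.m * mech.mu)
        else:
            c.vel = (c.vel + dt * forces[i] / mech.m) / (1.0 + mech.mu * dt)
        c.pos = c.pos + dt * c.vel
    return float(margin) if margin < 1.0e29 else np.inf


def _forces_with_grid(pos, radii, nuc, K, forces, grid) -> float:
    """Accumulate forces over candidate pairs from a neighbour grid."""
    grid.build(pos)
    min_margin = np.inf
    for i, j in grid.candidate_pairs():
        d = pos[i] - pos[j]
        h = float(np.linalg.norm(d))
        h0 = radii[i] + radii[j]
        if h >= h0:
            continue
        core = h0 - (nuc[i] + nuc[j])
        margin = h - core
        min_margin = min(min_margin, margin)
        if margin < 1.0e-9:
            margin = 1.0e-9
            h = core + 1.0e-9
        f = K * (h0 - h) / margin
        if h > 0:
            u = d / h
            forces[i] += f * u
            forces[j] -= f * u
    return min_margin


def advance_cycle_and_fate(cell: Cell, dt: float, config: Config) -> str:
    """Advance the cycle clock; return 'none', 'committed', 'apoptosis' or 'divide'.

    At the G1/S checkpoint the instantaneous active-TF count must strictly
    exceed N_TF* for the cell to commit; otherwise it dies.  A committed
    cell divides when its cycle completes.
    """
    cy = config.cycle
    prev = cell.cycle_clock
    cell.cycle_clock = prev + dt
    if cell.phase == PHASE_G1 and prev < cy.g1_duration <= cell.cycle_clock:
        if cell.active_tf() > cy.n_tf_star:
            cell.phase = PHASE_COMMITTED
            return "committed"
        cell.phase = PHASE_DYING
        return "apoptosis"
    if cell.phase == PHASE_COMMITTED and cell.cycle_clock >= cell.cycle_length:
        return "divide"
    return "none"


def grow(cell: Cell, config: Config) -> float:
    """Linear volume growth of a committed cell; returns the new radius.

    Volume interpolates linearly from V_birth at commitment (end of G1) to
    2 V_birth at the end of the cycle.
    """
    if cell.phase != PHASE_COMMITTED:
        return cell.radius
    cy = config.cycle
    frac = (cell.cycle_clock - cy.g1_duration) / (cell.cycle_length - cy.g1_duration)
    frac = min(max(frac, 0.0), 1.0)
    v_birth = 4.0 / 3.0 * np.pi * cell.birth_radius**3
    v = v_birth * (1.0 + frac)
    cell.radius = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
    return cell.radius


def divide(
    cell: Cell, config: Config, master_seed: int, new_ids: tuple[int, int]
) -> tuple[Cell, Cell]:
    """Split a committed cell whose cycle is complete into two daughters.

    Daughters are placed symmetrically about the mother's centre along a
    uniformly random axis, tangent to each other, each with the mother's
    birth volume (half the doubled division volume).  Interiors are
    inherited by random halves (optionally topped back up to the standard
    complement); receptors are re-laid uniformly at the genotype's count;
    each daughter draws a fresh cycle length of 24 h +/- 3 h uniform.
    """
    rng = cell.rng
    int1, int2 = halve_on_division(cell.interior, rng)
    if config.cycle.replenish_daughters:
        int1 = replenish(int1, config.intracellular, rng)
        int2 = replenish(int2, config.intracellular, rng)
    axis = uniform_point_on_sphere(np.zeros(3), 1.0, rng)
    r_d = cell.birth_radius
    offset = r_d * axis  # centres 2 r_d apart: daughters tangent
    n_rec = cell.profile.n_egfr or config.receptors.n_egfr
    cy = config.cycle
    daughters = []
    for did, interior, sign in ((new_ids[0], int1, 1.0), (new_ids[1], int2, -1.0)):
        drng = spawn_stream(master_seed, NS_CELL, did)
        d = Cell(
            id=did,
            pos=cell.pos + sign * offset,
            vel=cell.vel.copy(),
            radius=r_d,
            r_nucleus=cell.r_nucleus,
            birth_radius=r_d,
            cycle_length=cy.cycle_mean + drng.uniform(-cy.cycle_jitter, cy.cycle_jitter),
            cycle_clock=0.0,
            phase=PHASE_G1,
            interior=interior,
            receptors=make_receptors(n_rec, drng),
            profile=cell.profile,
            rng=drng,
        )
        daughters.append(d)
    return daughters[0], daughters[1]
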