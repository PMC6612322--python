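"""Per-cell Brownian-Dynamics model of the EGFR/ERK cascade.

Each cell interior holds a fixed complement of point molecules (Ras, Raf,
ERK, transcription factors) diffusing in cell-local coordinates.  Active
G-protein sites (the inner spheres of ligand-bound receptor clusters)
switch nearby Ras on; active Ras activates Raf, Raf activates ERK, and ERK
entering the nucleus activates transcription factors.  Every activation is
reversed after an exponential waiting time; oncogenic K-Ras / B-Raf
mutations multiply the corresponding inactivation rate, prolonging the
active state.

Diffusion domains: Ras and Raf live in the cytoplasm (spherical shell
between nucleus and membrane); TFs live in the nucleus; ERK starts in the
cytoplasm but gains access to the whole cell while active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import SP_ERK, SP_RAF, SP_RAS, SP_TF
from .config import IntracellularConfig, MutationProfile
from .core import sample_exponential

__all__ = [
    "CellInterior",
    "init_cell_molecules",
    "apply_mutation",
    "step_interior",
    "count_active",
    "count_active_tf",
    "halve_on_division",
    "SPECIES_NAMES",
]

SPECIES_NAMES = ("Ras", "Raf", "ERK", "TF")


@dataclass
class CellInterior:
    """Struct-of-arrays container for one cell's molecules."""

    r_cell: float
    r_nucleus: float
    species: np.ndarray       # (n,) int8
    active: np.ndarray        # (n,) bool
    erk_free: np.ndarray      # (n,) bool — ERK currently allowed in the whole cell
    t_off: np.ndarray         # (n,) float64 — absolute switch-off time (when active)
    pos: np.ndarray           # (n, 3) cell-local coordinates
    rates: np.ndarray         # (4,) effective inactivation rates, 1/min
    d_protein: float
    r_bd: float
    profile: MutationProfile = field(default_factory=MutationProfile)
    # scratch buffers reused across steps
    _new_idx: np.ndarray | None = None
    _disp: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.species.shape[0]

    def counts(self) -> np.ndarray:
        """Per-species total counts (Ras, Raf, ERK, TF)."""
        return np.bincount(self.species, minlength=4)

    def active_counts(self) -> np.ndarray:
        """Per-species active counts (Ras, Raf, ERK, TF)."""
        return np.bincount(self.species[self.active], minlength=4)


def _uniform_in_shell(rng: np.random.Generator, n: int, r_in: float, r_out: float) -> np.ndarray:
    """Sample points uniformly in the shell r_in <= |p| <= r_out (radial inverse CDF)."""
    u = rng.random(n)
    r = (u * (r_out**3 - r_in**3) + r_in**3) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return r[:, None] * v


def apply_mutation(profile: MutationProfile, base_rates: np.ndarray) -> np.ndarray:
    """Effective per-species inactivation rates for a genotype.

    K-Ras multiplies the Ras rate, B-Raf the Raf rate; ERK and TF rates are
    never altered.
    """
    base_rates = np.asarray(base_rates, dtype=float)
    if np.any(base_rates <= 0):
        raise ValueError("inactivation rates must be positive")
    rates = base_rates.copy()
    if profile.kras:
        rates[SP_RAS] *= profile.multiplier
    if profile.braf:
        rates[SP_RAF] *= profile.multiplier
    return rates


def init_cell_molecules(
    r_cell: float,
    r_nucleus: float,
    params: IntracellularConfig,
    rng: np.random.Generator,
    profile: MutationProfile | None = None,
) -> CellInterior:
    """Create a cell interior with all molecules in the 'off' state.

    Ras, Raf and ERK are placed uniformly in the cytoplasm, TFs uniformly
    in the nucleus.
    """
    if not (0 < r_nucleus < r_cell):
        raise ValueError(f"need 0 < r_nucleus < r_cell, got {r_nucleus!r}, {r_cell!r}")
    profile = profile or MutationProfile()
    counts = (params.n_ras, params.n_raf, params.n_erk, params.n_tf)
    n = sum(counts)
    species = np.repeat(np.arange(4, dtype=np.int8), counts)
    pos = np.empty((n, 3))
    cyt = species != SP_TF
    pos[cyt] = _uniform_in_shell(rng, int(cyt.sum()), r_nucleus, r_cell)
    nuc = ~cyt
    pos[nuc] = _uniform_in_shell(rng, int(nuc.sum()), 0.0, r_nucleus)
    base = np.array([params.k_off_ras, params.k_off_raf, params.k_off_erk, params.k_off_tf])
    return CellInterior(
        r_cell=r_cell,
        r_nucleus=r_nucleus,
        species=species,
        active=np.zeros(n, dtype=bool),
        erk_free=np.zeros(n, dtype=bool),
        t_off=np.zeros(n),
        pos=pos,
        rates=apply_mutation(profile, base),
        d_protein=params.d_protein,
        r_bd=params.r_bd,
        profile=profile,
    )


def step_interior(
    interior: CellInterior,
    rec_inner: np.ndarray,
    rec_on: np.ndarray,
    r_rec: float,
    dt: float,
    clock: float,
    rng: np.random.Generator,
) -> None:
    """Advance the interior by one BD step ending at ``clock + dt``.

    Sub-steps in order: diffuse and reflect every molecule; fire
    activations on reaction-radius overlap (using states at step entry);
    assign exponential switch-off times to newly active molecules; switch
    off molecules whose waiting time has expired.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    # Fully quiescent interior with no active G-protein site: nothing can
    # fire and the uniform molecule distribution is diffusion-invariant, so
    # the step has no observable effect and is skipped.
    if not (interior.active.any() or np.any(rec_on) or interior.erk_free.any()):
        return
    n = interior.n
    if interior._new_idx is None or interior._new_idx.shape[0] != n:
        interior._new_idx = np.empty(n, dtype=np.int64)
        interior._disp = np.empty((n, 3))
    sigma = np.sqrt(2.0 * interior.d_protein * dt)
    disp = rng.standard_normal(out=interior._disp)
    disp *= sigma
    d_rec = r_rec + interior.r_bd
    d_pp = 2.0 * interior.r_bd
    if rec_inner.size == 0:
        rec_inner = np.zeros((0, 3))
        rec_on = np.zeros(0, dtype=bool)
    n_new = _kernels.step_interior(
        interior.pos,
        interior.species,
        interior.active,
        interior.erk_free,
        disp,
        interior.r_nucleus,
        interior.r_cell,
        np.ascontiguousarray(rec_inner, dtype=np.float64),
        np.ascontiguousarray(rec_on, dtype=np.bool_),
        d_rec * d_rec,
        d_pp * d_pp,
        interior._new_idx,
    )
    t_end = clock + dt
    if n_new:
        idx = interior._new_idx[:n_new]
        interior.active[idx] = True
        rates = interior.rates[interior.species[idx]]
        interior.t_off[idx] = t_end + rng.exponential(1.0 / rates)
        erk_new = idx[interior.species[idx] == SP_ERK]
        interior.erk_free[erk_new] = True
    expired = interior.active & (interior.t_off <= t_end)
    if n_new:
        expired[interior._new_idx[:n_new]] = False
    interior.active[expired] = False


def count_active(interior: CellInterior, species: int) -> int:
    return int(np.count_nonzero(interior.active & (interior.species == species)))


def count_active_tf(interior: CellInterior) -> int:
    """Number of transcription factors currently in the active state."""
    return count_active(interior, SP_TF)


def _redraw_positions(interior: CellInterior, rng: np.random.Generator) -> None:
    """Re-initialise molecule coordinates uniformly in their domains (dilution)."""
    sp = interior.species
    pos = interior.pos
    nuc = sp == SP_TF
    pos[nuc] = _uniform_in_shell(rng, int(nuc.sum()), 0.0, interior.r_nucleus)
    whole = (sp == SP_ERK) & interior.active
    pos[whole] = _uniform_in_shell(rng, int(whole.sum()), 0.0, interior.r_cell)
    cyt = ~nuc & ~whole
    pos[cyt] = _uniform_in_shell(rng, int(cyt.sum()), interior.r_nucleus, interior.r_cell)
    # inactive ERK redrawn in the cytoplasm is shell-confined again
    interior.erk_free[(sp == SP_ERK) & ~interior.active] = False
    interior.erk_free[whole] = True


def halve_on_division(
    mother: CellInterior, rng: np.random.Generator
) -> tuple[CellInterior, CellInterior]:
    """Split a mother's molecules into two inherited halves.

    Per-species counts split exactly in half (a fair coin assigns the odd
    molecule); which individual molecules go to which daughter is random,
    so on/off states and remaining switch-off times are inherited with
    them.  All coordinates are re-drawn uniformly (dilution at division).
    """
    take = np.zeros(mother.n, dtype=bool)
    for sp in range(4):
        idx = np.flatnonzero(mother.species == sp)
        k = idx.size // 2
        if idx.size % 2 and rng.random() < 0.5:
            k += 1
        chosen = rng.permutation(idx)[:k]
        take[chosen] = True

    daughters = []
    for mask in (take, ~take):
        d = CellInterior(
            r_cell=mother.r_cell,
            r_nucleus=mother.r_nucleus,
            species=mother.species[mask].copy(),
            active=mother.active[mask].copy(),
            erk_free=mother.erk_free[mask].copy(),
            t_off=mother.t_off[mask].copy(),
            pos=mother.pos[mask].copy(),
            rates=mother.rates.copy(),
            d_protein=mother.d_protein,
            r_bd=mother.r_bd,
            profile=mother.profile,
        )
        _redraw_positions(d, rng)
        daughters.append(d)
    return daughters[0], daughters[1]


def replenish(
    interior: CellInterior, params: IntracellularConfig, rng: np.random.Generator
) -> CellInterior:
    """Top an inherited half-complement back up to the standard counts.

    The added molecules are fresh 'off' proteins placed uniformly in their
    domains, representing synthesis during the growth phase of the cycle
    (degradation remains absent within a cell's lifetime).
    """
    target = np.array([params.n_ras, params.n_raf, params.n_erk, params.n_tf])
    have = interior.counts()
    missing = np.maximum(target - have, 0)
    n_add = int(missing.sum())
    if n_add == 0:
        return interior
    add_species = np.repeat(np.arange(4, dtype=np.int8), missing)
    add_pos = np.empty((n_add, 3))
    nuc = add_species == SP_TF
    add_pos[nuc] = _uniform_in_shell(rng, int(nuc.sum()), 0.0, interior.r_nucleus)
    add_pos[~nuc] = _uniform_in_shell(rng, int((~nuc).sum()), interior.r_nucleus, interior.r_cell)
    interior.species = np.concatenate([interior.species, add_species])
    interior.active = np.concatenate([interior.active, np.zeros(n_add, dtype=bool)])
    interior.erk_free = np.concatenate([interior.erk_free, np.zeros(n_add, dtype=bool)])
    interior.t_off = np.concatenate([interior.t_off, np.zeros(n_add)])
    interior.pos = np.concatenate([interior.pos, add_pos])
    interior._new_idx = None
    return interior
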