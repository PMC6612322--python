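"""EGF field dynamics and receptor-cluster binding.

Free EGF particles are introduced at a constant mean rate in a thin layer
at the outer boundary of the spherical domain, diffuse by Brownian motion,
reflect at the domain boundary and off cell bodies, and disappear after an
exponential lifetime.  Each receptor cluster is a pair of spheres clamped
to the membrane along the outward normal: the outer sphere binds ligand,
the inner sphere is the G-protein site that activates Ras.  A ligand
binding an 'off' receptor switches it 'on' for an exponential residence
time, after which the receptor returns to 'off'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .config import FieldConfig, ReceptorConfig
from .core import sample_exponential

__all__ = [
    "Receptors",
    "ExtracellularField",
    "make_receptors",
    "introduce_egf",
    "step_field",
    "attempt_binding",
    "release_expired_receptors",
]


@dataclass
class Receptors:
    """Receptor clusters of one cell (struct of arrays).

    ``anchors`` are unit vectors from the cell centre; sphere centres are
    recomputed from the current cell position each step, so clusters track
    cell motion.  ``holds_egf`` marks receptors whose bound ligand would be
    re-released on switch-off when that option is enabled.
    """

    anchors: np.ndarray          # (m, 3) unit vectors
    on: np.ndarray               # (m,) bool
    switch_off_time: np.ndarray  # (m,) float64, absolute clock time
    holds_egf: np.ndarray        # (m,) bool

    @property
    def m(self) -> int:
        return self.anchors.shape[0]

    def outer_centers(self, cell_pos: np.ndarray, r_cell: float, r_rec: float) -> np.ndarray:
        return cell_pos + (r_cell + r_rec) * self.anchors

    def inner_centers_local(self, r_cell: float, r_rec: float) -> np.ndarray:
        """Inner-sphere centres in cell-local coordinates."""
        return (r_cell - r_rec) * self.anchors


def make_receptors(n: int, rng: np.random.Generator, anchors: np.ndarray | None = None) -> Receptors:
    """Create ``n`` inactive receptor clusters, uniformly placed unless given."""
    if anchors is None:
        v = rng.normal(size=(n, 3))
        anchors = v / np.linalg.norm(v, axis=1, keepdims=True)
    else:
        anchors = np.asarray(anchors, dtype=float)
        anchors = anchors / np.linalg.norm(anchors, axis=1, keepdims=True)
    return Receptors(
        anchors=anchors,
        on=np.zeros(n, dtype=bool),
        switch_off_time=np.zeros(n),
        holds_egf=np.zeros(n, dtype=bool),
    )


@dataclass
class ExtracellularField:
    """Free EGF particles in the spherical domain."""

    r_domain: float
    shell_thickness: float
    params: FieldConfig
    pos: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    degradation_time: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_free(self) -> int:
        return self.pos.shape[0]

    def stationary_mean(self) -> float:
        """Analytic long-run mean free-EGF count in a cell-free domain.

        The field is a birth–death (M/M/∞) process: Poisson arrivals at the
        introduction rate, independent exponential lifetimes, so the
        stationary count is Poisson with mean rate/degradation.
        """
        return self.params.introduction_rate / self.params.degradation_rate


def introduce_egf(
    fld: ExtracellularField, dt: float, clock: float, rng: np.random.Generator
) -> int:
    """Add a Poisson number of new ligands in the outer introduction layer.

    Each new particle receives an absolute degradation time drawn from the
    exponential lifetime distribution.  Returns the number added.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    lam = fld.params.introduction_rate * dt
    k = int(rng.poisson(lam)) if lam > 0 else 0
    if k == 0:
        return 0
    r_in = fld.r_domain - fld.shell_thickness
    u = rng.random(k)
    r = (u * (fld.r_domain**3 - r_in**3) + r_in**3) ** (1.0 / 3.0)
    v = rng.normal(size=(k, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    new_pos = r[:, None] * v
    lifetimes = sample_exponential(fld.params.degradation_rate, rng, size=k)
    fld.pos = np.concatenate([fld.pos, new_pos])
    fld.degradation_time = np.concatenate([fld.degradation_time, clock + lifetimes])
    return k


def step_field(
    fld: ExtracellularField,
    cells,
    dt: float,
    clock: float,
    rng: np.random.Generator,
    cell_c: np.ndarray | None = None,
    cell_r: np.ndarray | None = None,
) -> None:
    """Diffuse free EGF, reflect at boundaries and off cells, degrade.

    ``cells`` is a sequence with ``pos`` and ``radius`` attributes (may be
    empty).  Particles whose degradation time has passed are removed at the
    end of the step.  ``cell_c``/``cell_r`` may be passed to reuse centre
    and radius arrays already built by the caller.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    n = fld.n_free
    if n:
        sigma = np.sqrt(2.0 * fld.params.d_egf * dt)
        disp = rng.normal(0.0, sigma, size=(n, 3))
        if cell_c is None:
            if cells:
                cell_c = np.array([c.pos for c in cells], dtype=float)
                cell_r = np.array([c.radius for c in cells], dtype=float)
            else:
                cell_c = np.zeros((0, 3))
                cell_r = np.zeros(0)
        _kernels.step_egf(fld.pos, disp, fld.r_domain, cell_c, cell_r)
    if n and fld.degradation_time.min() <= clock + dt:
        alive = fld.degradation_time > clock + dt
        fld.pos = fld.pos[alive]
        fld.degradation_time = fld.degradation_time[alive]


def attempt_binding(
    fld: ExtracellularField,
    cells,
    r_outer: float,
    k_off: float,
    clock: float,
    rng: np.random.Generator,
    cell_c: np.ndarray | None = None,
    cell_r: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Bind free EGF to overlapping 'off' receptors; nearest pairs first.

    All (ligand, inactive receptor) pairs whose reaction radii overlap are
    collected and matched greedily by increasing distance so that each
    ligand binds at most one receptor and vice versa, independently of
    storage order.  A bound ligand leaves free diffusion; the receptor
    switches 'on' and receives an exponential residence time.

    ``r_outer`` is the outer (ligand-binding) sphere radius.  Returns a
    list of (cell index, receptor index) binding events.
    """
    if fld.n_free == 0 or not cells:
        return []
    # cheap rejection: no ligand anywhere near a cell surface
    if cell_c is None:
        cell_c = np.array([c.pos for c in cells], dtype=float)
        cell_r = np.array([c.radius for c in cells], dtype=float)
    reach = 2.0 * r_outer + fld.params.r_egf
    if not _kernels.any_near(fld.pos, cell_c, cell_r, reach):
        return []
    rec_pos_list = []
    rec_owner = []
    rec_idx = []
    rec_off = []
    for ci, cell in enumerate(cells):
        rec = cell.receptors
        if rec.m == 0:
            continue
        centers = rec.outer_centers(np.asarray(cell.pos, dtype=float), cell.radius, r_outer)
        rec_pos_list.append(centers)
        rec_owner.extend([ci] * rec.m)
        rec_idx.extend(range(rec.m))
        rec_off.extend(list(~rec.on))
    if not rec_pos_list:
        return []
    rec_pos = np.concatenate(rec_pos_list)
    rec_off_arr = np.array(rec_off, dtype=bool)
    if not rec_off_arr.any():
        return []
    d_bind = r_outer + fld.params.r_egf
    cap = fld.n_free * rec_pos.shape[0]
    out_e = np.empty(cap, dtype=np.int64)
    out_r = np.empty(cap, dtype=np.int64)
    out_d2 = np.empty(cap)
    cnt = _kernels.overlap_pairs(
        fld.pos, rec_pos, rec_off_arr, d_bind * d_bind, out_e, out_r, out_d2
    )
    if cnt == 0:
        return []
    order = np.argsort(out_d2[:cnt], kind="stable")
    used_e: set[int] = set()
    used_r: set[int] = set()
    events: list[tuple[int, int]] = []
    bound_mask = np.zeros(fld.n_free, dtype=bool)
    for k in order:
        e, r = int(out_e[k]), int(out_r[k])
        if e in used_e or r in used_r:
            continue
        used_e.add(e)
        used_r.add(r)
        ci, ri = rec_owner[r], rec_idx[r]
        rec = cells[ci].receptors
        rec.on[ri] = True
        rec.switch_off_time[ri] = clock + sample_exponential(k_off, rng)
        rec.holds_egf[ri] = True
        bound_mask[e] = True
        events.append((ci, ri))
    fld.pos = fld.pos[~bound_mask]
    fld.degradation_time = fld.degradation_time[~bound_mask]
    return events


def release_expired_receptors(
    fld: ExtracellularField,
    cells,
    r_outer: float,
    clock: float,
    rng: np.random.Generator,
) -> int:
    """Switch off receptors whose residence time has elapsed.

    By default the bound ligand is consumed (internalisation-like); with
    ``rerelease_on_unbind`` the ligand re-enters free diffusion at the
    receptor position with a fresh exponential lifetime.  Returns the
    number of receptors released.
    """
    released = 0
    for cell in cells:
        rec = cell.receptors
        if rec.m == 0 or not rec.on.any():
            continue
        expired = rec.on & (rec.switch_off_time <= clock)
        k = int(expired.sum())
        if k == 0:
            continue
        released += k
        if fld.params.rerelease_on_unbind:
            idx = np.flatnonzero(expired & rec.holds_egf)
            if idx.size:
                centers = rec.outer_centers(np.asarray(cell.pos, dtype=float), cell.radius, r_outer)
                new_pos = centers[idx]
                lifetimes = sample_exponential(fld.params.degradation_rate, rng, size=idx.size)
                fld.pos = np.concatenate([fld.pos, new_pos])
                fld.degradation_time = np.concatenate([fld.degradation_time, clock + lifetimes])
        rec.on[expired] = False
        rec.holds_egf[expired] = False
    return released
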