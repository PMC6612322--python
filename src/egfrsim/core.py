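"""Shared geometry, random sampling, and waiting-time machinery.

Positions are plain ``(..., 3)`` float64 arrays in micrometres; time is in
minutes throughout the package.  All stochastic draws go through
:class:`numpy.random.Generator` streams derived from a single master seed so
that every run is bit-reproducible and adding a cell never perturbs the
draws of another subsystem.
"""

from __future__ import annotations

import numpy as np

from . import _kernels

__all__ = [
    "spawn_stream",
    "sample_exponential",
    "brownian_step",
    "reflect_in_shell",
    "uniform_point_on_sphere",
]

# Namespaces used to derive independent per-subsystem streams from the
# master seed.  Cell streams are keyed by cell id, so a cell's interior
# dynamics do not depend on how many other cells exist.
NS_FIELD = 1
NS_CELL = 2
NS_MECHANICS = 3
NS_SCENARIO = 4


def spawn_stream(master_seed: int, namespace: int, key: int = 0) -> np.random.Generator:
    """Derive an independent generator from ``(master_seed, namespace, key)``.

    Identical arguments always yield an identical stream, independently of
    any other stream that has been spawned.
    """
    seq = np.random.SeedSequence([int(master_seed), int(namespace), int(key)])
    return np.random.default_rng(seq)


def sample_exponential(rate: float, rng: np.random.Generator, size=None):
    """Draw exponential waiting times with the given rate (1/min).

    Parameters
    ----------
    rate : float
        Rate parameter in 1/min; the mean waiting time is ``1 / rate``.
    rng : numpy.random.Generator
    size : optional shape for vectorised draws.
    """
    if not rate > 0:
        raise ValueError(f"exponential rate must be positive, got {rate!r}")
    return rng.exponential(1.0 / rate, size=size)


def brownian_step(p: np.ndarray, D: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Advance point(s) ``p`` by one Brownian step.

    Each coordinate is incremented by an independent Normal(0, sqrt(2*D*dt))
    draw, so the mean squared displacement per step is ``6*D*dt``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    if D < 0:
        raise ValueError(f"diffusion coefficient must be non-negative, got {D!r}")
    p = np.asarray(p, dtype=float)
    if D == 0.0:
        return p.copy()
    sigma = np.sqrt(2.0 * D * dt)
    return p + rng.normal(0.0, sigma, size=p.shape)


def reflect_in_shell(
    p: np.ndarray,
    center: np.ndarray,
    r_inner: float,
    r_outer: float,
) -> np.ndarray:
    """Mirror-reflect point(s) into the spherical shell ``r_inner <= r <= r_outer``.

    Reflection is radial (mirror-like across the violated spherical
    boundary) and is applied iteratively until the point lies inside, so
    steps larger than the shell thickness are handled.  Interior points are
    returned unchanged.  ``r_inner = 0`` reduces to reflection in a ball.
    """
    if r_inner < 0 or r_inner >= r_outer:
        raise ValueError(
            f"need 0 <= r_inner < r_outer, got r_inner={r_inner!r}, r_outer={r_outer!r}"
        )
    p = np.array(p, dtype=float, copy=True)
    center = np.asarray(center, dtype=float)
    single = p.ndim == 1
    q = np.atleast_2d(p) - center
    _kernels.reflect_shell_inplace(q, float(r_inner), float(r_outer))
    q += center
    return q[0] if single else q


def uniform_point_on_sphere(
    center: np.ndarray,
    r: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Sample point(s) uniformly on the sphere of radius ``r`` about ``center``."""
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r!r}")
    n = 1 if size is None else int(size)
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # A zero-norm gaussian triple has probability zero; guard for safety.
    norms[norms == 0.0] = 1.0
    pts = np.asarray(center, dtype=float) + r * v / norms
    return pts[0] if size is None else pts
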