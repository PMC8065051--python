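"""Deterministic direction sets on the unit sphere.

Directional kurtosis metrics are spherical averages of a smooth rational
function of the gradient direction; they are evaluated by equal-weight
quadrature over a near-uniform point set rather than in closed form.  The
default set is a Fibonacci spiral lattice, which is deterministic, needs no
stored table, and is accurate to well below the tolerances used in the test
suite (cross-checked against dense Monte-Carlo averages).
"""

from __future__ import annotations

import numpy as np

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def sphere_directions(n: int = 250) -> np.ndarray:
    """Return ``n`` near-uniform unit vectors (Fibonacci spiral lattice).

    Parameters
    ----------
    n : int
        Number of directions, >= 1.

    Returns
    -------
    (n, 3) float array of unit vectors.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = _GOLDEN_ANGLE * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def hemisphere_directions(n: int = 30) -> np.ndarray:
    """``n`` near-uniform directions on the upper (z > 0) hemisphere.

    Suitable as a diffusion gradient table: antipodal directions are
    redundant for diffusion MRI, so sampling one hemisphere is standard.
    """
    full = sphere_directions(2 * n)
    # the lattice enumerates z from +1 down to -1, so the first n lie at z > 0
    return full[:n]


def orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``axis`` to a right-handed orthonormal frame."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be a nonzero vector")
    axis = axis / norm
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def great_circle_directions(axis: np.ndarray, n: int = 64) -> np.ndarray:
    """``n`` equally spaced unit vectors on the great circle perpendicular to ``axis``."""
    u, v = orthonormal_basis(axis)
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)
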