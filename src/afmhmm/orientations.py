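"""Unit quaternions, deterministic SO(3) orientation grids and rotational constraints.

Rotations are represented as unit quaternions in ``(w, x, y, z)`` order.
``q`` and ``-q`` denote the same rotation; every operation in this module is
invariant to a sign flip of its quaternion arguments.

The orientation grid is a deterministic layered Hopf-fibration grid: a
Fibonacci lattice on the base sphere S^2 combined with an evenly spaced ring
of fiber angles, which covers SO(3) quasi-uniformly and is bit-identical
across runs.  Explicit quaternion lists (e.g. published grids) can be loaded
from plain-text files with :func:`load_grid`.
"""

from __future__ import annotations

import operator
from dataclasses import replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "IDENTITY",
    "quat_multiply",
    "quat_conjugate",
    "quat_to_matrix",
    "quat_distance",
    "pairwise_distance",
    "generate_grid",
    "load_grid",
    "rotate",
    "rotation_constraint_mask",
]

#: The identity rotation (w, x, y, z).
IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

_UNIT_TOL = 1e-9


def _as_quat(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError(f"quaternion must have shape (4,), got {q.shape}")
    return q


def _validate_unit(q: np.ndarray) -> np.ndarray:
    q = _as_quat(q)
    n = float(np.dot(q, q))
    if abs(n - 1.0) > 10 * _UNIT_TOL:
        raise ValueError(f"quaternion is not unit norm (|q|^2 = {n!r})")
    return q


def quat_multiply(a, b) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` (both in (w, x, y, z) order)."""
    aw, ax, ay, az = _as_quat(a)
    bw, bx, by, bz = _as_quat(b)
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by + ay * bw + az * bx - ax * bz,
            aw * bz + az * bw + ax * by - ay * bx,
        ]
    )


def quat_conjugate(q) -> np.ndarray:
    w, x, y, z = _as_quat(q)
    return np.array([w, -x, -y, -z])


def quat_to_matrix(q) -> np.ndarray:
    """3x3 rotation matrix for a unit quaternion (w, x, y, z)."""
    w, x, y, z = _validate_unit(q)
    # scipy uses scalar-last (x, y, z, w) ordering
    return Rotation.from_quat([x, y, z, w]).as_matrix()


def quat_distance(q1, q2) -> float:
    """Sign-invariant quaternion distance ``d = 1 − (q1·q2)²`` in [0, 1].

    Zero iff the two quaternions denote the same rotation; 1 for rotations
    separated by 180 degrees.  Used to forbid large orientation jumps between
    adjacent movie frames.
    """
    q1 = _validate_unit(q1)
    q2 = _validate_unit(q2)
    d = 1.0 - float(np.dot(q1, q2)) ** 2
    return float(min(max(d, 0.0), 1.0))


def pairwise_distance(qs1: np.ndarray, qs2: np.ndarray | None = None) -> np.ndarray:
    """Matrix of quaternion distances between two stacks of unit quaternions."""
    qs1 = np.atleast_2d(np.asarray(qs1, dtype=float))
    qs2 = qs1 if qs2 is None else np.atleast_2d(np.asarray(qs2, dtype=float))
    dots = qs1 @ qs2.T
    return np.clip(1.0 - dots**2, 0.0, 1.0)


def generate_grid(n_target: int) -> np.ndarray:
    """Deterministic quasi-uniform grid of ~``n_target`` rotations over SO(3).

    Returns an ``(n, 4)`` array of unit quaternions with ``n`` close to
    ``n_target`` (exact when the layer factorization divides evenly, e.g.
    576 = 8 fiber angles x 72 sphere points).  ``n_target=1`` returns the
    identity rotation only.
    """
    n_target = operator.index(n_target)
    if n_target < 1:
        raise ValueError(f"n_target must be >= 1, got {n_target}")
    if n_target == 1:
        return IDENTITY.copy()[None, :]

    n_psi = max(1, round(n_target ** (1.0 / 3.0)))
    n_s2 = max(1, round(n_target / n_psi))

    k = np.arange(n_s2)
    z = 1.0 - 2.0 * (k + 0.5) / n_s2
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    phi = (2.0 * np.pi * k / golden) % (2.0 * np.pi)
    psi = 2.0 * np.pi * (np.arange(n_psi) + 0.5) / n_psi

    th = theta[:, None] / 2.0
    ph = phi[:, None]
    ps = psi[None, :] / 2.0
    q = np.stack(
        [
            np.cos(th) * np.cos(ps),
            np.cos(th) * np.sin(ps),
            np.sin(th) * np.cos(ph + ps),
            np.sin(th) * np.sin(ph + ps),
        ],
        axis=-1,
    ).reshape(-1, 4)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return q


def load_grid(path) -> np.ndarray:
    """Load an explicit quaternion list: one ``w x y z`` per line, '#' comments."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 components 'w x y z', got {len(parts)}"
                )
            rows.append([float(p) for p in parts])
    if not rows:
        raise ValueError(f"{path}: no quaternions found")
    grid = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(grid, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(norms - 1.0)))
        raise ValueError(f"{path}: quaternion on data line {bad + 1} is not unit norm")
    return grid / norms[:, None]


def rotate(structure, q):
    """Rigid rotation of a bead structure about its centroid.

    Radii and labels are unchanged; returns a new structure.
    """
    q = _validate_unit(q)
    coords = structure.coords
    if len(coords) == 0:
        return replace(structure, coords=coords.copy())
    rot = quat_to_matrix(q)
    center = coords.mean(axis=0)
    return replace(structure, coords=(coords - center) @ rot.T + center)


def rotation_constraint_mask(grid: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Boolean matrix over orientation pairs: True where transitions are allowed.

    ``mask[i, j]`` is True iff ``quat_distance(grid[i], grid[j]) <= threshold``.
    The mask is symmetric with an all-True diagonal.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    mask = pairwise_distance(grid) <= threshold
    np.fill_diagonal(mask, True)
    return mask
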