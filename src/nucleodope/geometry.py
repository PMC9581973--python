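"""Ring-plane fitting and the stacking-geometry primitives.

A ring plane is the least-squares plane through the ring atoms: the centroid
is the unweighted mean and the normal is the eigenvector of the smallest
eigenvalue of the centred coordinate covariance. The normal sign is fixed by
convention (positive z-component, ties broken by x then y) so downstream
quantities are deterministic.

For two planes a, b the stacking geometry is measured along the sign-aligned
bisector n of the two unit normals:

    vertical separation = |(c_b - c_a) . n|
    lateral offset      = |(c_b - c_a) - ((c_b - c_a) . n) n|

which is symmetric in the two rings and reduces to the obvious values for
parallel rings. The interplanar angle is the acute angle between the normals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

_COLLINEAR_TOL = 1e-10


@dataclass(frozen=True)
class RingPlane:
    """Least-squares plane of one ring: centroid (nm), unit normal, rms planarity (nm)."""

    centroid: np.ndarray
    normal: np.ndarray
    planarity_rms: float


def _fix_normal_sign(normals: np.ndarray) -> np.ndarray:
    """Canonical sign: positive z-component, ties broken by x then y."""
    arr = np.asarray(normals, dtype=float)
    n = np.atleast_2d(arr).copy()
    tol = 1e-12
    sign = np.zeros(len(n))
    for axis in (2, 0, 1):
        undecided = sign == 0
        comp = n[:, axis]
        sign[undecided & (comp > tol)] = 1.0
        sign[undecided & (comp < -tol)] = -1.0
    sign[sign == 0] = 1.0
    n *= sign[:, None]
    return n if arr.ndim == 2 else n[0]


def fit_ring_plane(coords: np.ndarray) -> RingPlane:
    """Fit the least-squares plane to >=3 non-collinear atom positions."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3 or coords.shape[1] != 3:
        raise GeometryError("ring plane fit needs an (n>=3, 3) coordinate array")
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = centred.T @ centred / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending eigenvalues; evals[1] ~ 0 means collinear
    if evals[1] <= _COLLINEAR_TOL * max(evals[2], 1.0):
        raise GeometryError("ring atoms are collinear; no plane defined")
    normal = _fix_normal_sign(evecs[:, 0])
    return RingPlane(
        centroid=centroid,
        normal=normal,
        planarity_rms=float(np.sqrt(max(evals[0], 0.0))),
    )


def fit_ring_planes_batch(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized plane fit for a stack of equally-sized rings.

    coords: (R, m, 3). Returns (centroids (R,3), normals (R,3), rms (R,)).
    """
    coords = np.asarray(coords, dtype=float)
    centroids = coords.mean(axis=1)
    centred = coords - centroids[:, None, :]
    cov = np.einsum("rmi,rmj->rij", centred, centred) / coords.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals[:, 1] <= _COLLINEAR_TOL * np.maximum(evals[:, 2], 1.0)):
        raise GeometryError("a ring in the batch is collinear; no plane defined")
    normals = _fix_normal_sign(evecs[:, :, 0])
    rms = np.sqrt(np.clip(evals[:, 0], 0.0, None))
    return centroids, normals, rms


def _bisector(na: np.ndarray, nb: np.ndarray) -> np.ndarray:
    """Sign-aligned bisector of two unit normals."""
    nb = np.where((np.sum(na * nb, axis=-1, keepdims=True)) < 0, -nb, nb)
    n = na + nb
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise GeometryError("anti-parallel normals: bisector undefined")
    return n / norm


def vertical_separation(a: RingPlane, b: RingPlane) -> float:
    """Centroid displacement along the sign-aligned normal bisector (nm)."""
    n = _bisector(a.normal, b.normal)
    return float(abs(np.dot(b.centroid - a.centroid, n)))


def lateral_offset(a: RingPlane, b: RingPlane) -> float:
    """In-plane component of the centroid displacement (nm)."""
    n = _bisector(a.normal, b.normal)
    d = b.centroid - a.centroid
    return float(np.linalg.norm(d - np.dot(d, n) * n))


def interplanar_angle(a: RingPlane, b: RingPlane) -> float:
    """Acute angle between the two ring planes, degrees in [0, 90]."""
    c = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def pairwise_stack_geometry(
    centroids_a: np.ndarray,
    normals_a: np.ndarray,
    centroids_b: np.ndarray,
    normals_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (A x B) vertical separation, lateral offset, angle, centroid distance."""
    na = normals_a[:, None, :]
    nb = np.broadcast_to(normals_b[None, :, :], (len(normals_a), len(normals_b), 3))
    n = _bisector(na, nb)
    d = centroids_b[None, :, :] - centroids_a[:, None, :]
    proj = np.sum(d * n, axis=-1)
    vsep = np.abs(proj)
    lat = np.linalg.norm(d - proj[..., None] * n, axis=-1)
    cosang = np.abs(np.sum(na * nb, axis=-1))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    cdist = np.linalg.norm(d, axis=-1)
    return vsep, lat, ang, cdist
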