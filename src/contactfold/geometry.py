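"""Coarse-grained chain geometry helpers.

The model is a Cα trace plus a virtual Cβ per residue. All distances in Å.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

#: ideal Cα(i)-Cα(i+1) bond length
BOND_LENGTH = 3.8
#: accepted bonded-distance window
BOND_MIN = 3.6
BOND_MAX = 4.0
#: hard excluded-volume floor for non-bonded Cα pairs
CLASH_MIN = 3.4
#: Cα-Cβ bond length
CB_LENGTH = 1.53


class GeometryError(ValueError):
    """A conformation violates chain-geometry invariants."""


def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.sqrt((v * v).sum(axis=axis, keepdims=True))
    return v / np.where(n < 1e-12, 1.0, n)


def _cross3(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Cross product without np.cross's axis-juggling overhead; supports
    single vectors and (n, 3) stacks."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    out = np.empty(np.broadcast(u, v).shape)
    out[..., 0] = u[..., 1] * v[..., 2] - u[..., 2] * v[..., 1]
    out[..., 1] = u[..., 2] * v[..., 0] - u[..., 0] * v[..., 2]
    out[..., 2] = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    return out


def virtual_cb(ca: np.ndarray) -> np.ndarray:
    """Place a virtual Cβ for every residue of a Cα trace.

    Interior residues use a fixed tetrahedral-like construction from the two
    flanking Cα positions: the Cβ points away from the bond bisector, tilted
    out of the local chain plane. Terminal residues (no flanking pair) fall
    back to Cβ = Cα, which is the conservative choice for distance terms.
    """
    ca = np.asarray(ca, dtype=float)
    n = len(ca)
    cb = ca.copy()
    if n < 3:
        return cb
    u = _unit(ca[:-2] - ca[1:-1])   # toward previous residue
    v = _unit(ca[2:] - ca[1:-1])    # toward next residue
    direction = _cross3(u, v) - (u + v)
    norms = np.sqrt((direction * direction).sum(axis=1))
    # collinear backbone: any stable perpendicular will do
    bad = norms < 1e-8
    if np.any(bad):
        ref = np.array([1.0, 0.0, 0.0])
        for idx in np.nonzero(bad)[0]:
            perp = _cross3(u[idx], ref)
            if np.linalg.norm(perp) < 1e-8:
                perp = _cross3(u[idx], np.array([0.0, 1.0, 0.0]))
            direction[idx] = perp
            norms[idx] = np.linalg.norm(perp)
    cb[1:-1] = ca[1:-1] + CB_LENGTH * direction / norms[:, None]
    return cb


def bond_lengths(ca: np.ndarray) -> np.ndarray:
    ca = np.asarray(ca, dtype=float)
    d = ca[1:] - ca[:-1]
    return np.sqrt((d * d).sum(axis=1))


def validate_chain(ca: np.ndarray, *, bond_min: float = BOND_MIN,
                   bond_max: float = BOND_MAX,
                   clash_min: float = CLASH_MIN) -> None:
    """Raise :class:`GeometryError` unless the Cα trace satisfies invariants.

    Bonded neighbours must sit within [bond_min, bond_max]; every non-bonded
    pair must be at least ``clash_min`` apart.
    """
    ca = np.asarray(ca, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise GeometryError(f"expected (n, 3) coordinates, got {ca.shape}")
    if len(ca) < 2:
        return
    b = bond_lengths(ca)
    if b.min() < bond_min or b.max() > bond_max:
        k = int(np.argmin(b)) if b.min() < bond_min else int(np.argmax(b))
        raise GeometryError(
            f"bond {k}-{k + 1} length {b[k]:.3f} outside "
            f"[{bond_min}, {bond_max}]")
    if len(ca) > 2:
        d = pdist(ca)[nonbonded_condensed_mask(len(ca))]
        if d.min() < clash_min:
            raise GeometryError(
                f"non-bonded clash below {clash_min} Å "
                f"(min {d.min():.3f})")


@lru_cache(maxsize=128)
def nonbonded_condensed_mask(n: int) -> np.ndarray:
    """Boolean mask over scipy's condensed pairwise-distance ordering
    selecting pairs with |i - j| > 1."""
    i, j = np.triu_indices(n, k=1)
    return (j - i) > 1


def chain_is_valid(ca: np.ndarray, **kw) -> bool:
    try:
        validate_chain(ca, **kw)
    except GeometryError:
        return False
    return True


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-RMSD rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rmsd, transformed_mobile, rotation, translation)`` where the
    transform maps mobile frame coordinates as ``x @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("shape mismatch in superposition")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - mc @ R.T
    moved = mobile @ R.T + t
    # recompute the residual from coordinates: scipy's rssd loses precision
    # near zero through cancellation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rmsd, moved, R, t


def triad_frame(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Orthonormal frame anchored at ``a`` built from three chain points."""
    x = _unit(np.asarray(b, float) - a)
    zraw = _cross3(b - a, np.asarray(c, float) - b)
    if (zraw * zraw).sum() < 1e-16:
        zraw = _cross3(x, np.array([1.0, 0.0, 0.0]))
        if (zraw * zraw).sum() < 1e-16:
            zraw = _cross3(x, np.array([0.0, 1.0, 0.0]))
    z = _unit(zraw)
    y = _cross3(z, x)
    return np.stack([x, y, z], axis=1), np.asarray(a, float)


def frame_transform(src_frame, dst_frame):
    """Rigid transform mapping one triad frame onto another.

    Returns ``(R, t)`` with the convention ``x' = (x - src_origin) @ R.T
    + dst_origin`` folded into ``x' = x @ R.T + t``.
    """
    (Ms, os_), (Md, od) = src_frame, dst_frame
    R = Md @ Ms.T
    t = od - os_ @ R.T
    return R, t


def rotate_about_axis(points: np.ndarray, origin: np.ndarray,
                      axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(np.asarray(axis, float))
    rot = Rotation.from_rotvec(axis * angle)
    return (points - origin) @ rot.as_matrix().T + origin
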