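"""Vectorized internal-coordinate geometry: bond lengths, bend angles and
torsion angles for arrays of index tuples, plus their analytic gradients.

All angle gradients guard against the collinear limit (sin θ → 0) by
clamping, which is adequate for the near-native geometries a structure-based
model visits.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "distances",
    "bend_angles",
    "torsion_angles",
    "wrap_angle",
    "distance_forces",
    "bend_forces",
    "torsion_forces",
]

_EPS = 1e-12


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis-handling overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _norm(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", a, a))


def distances(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Pairwise distances for an (M, 2) index array."""
    if len(pairs) == 0:
        return np.zeros(0)
    d = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    return _norm(d)


def bend_angles(coords: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Bend angle θ(i, j, k) at vertex j, in [0, π], for (M, 3) indices."""
    if len(triples) == 0:
        return np.zeros(0)
    u = coords[triples[:, 0]] - coords[triples[:, 1]]
    v = coords[triples[:, 2]] - coords[triples[:, 1]]
    cosang = np.einsum("ij,ij->i", u, v) / (_norm(u) * _norm(v))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def torsion_angles(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Torsion angle φ(i, j, k, l) in (−π, π] for (M, 4) indices.

    Sign follows the IUPAC convention (right-handed rotation about j→k).
    """
    if len(quads) == 0:
        return np.zeros(0)
    b1 = coords[quads[:, 1]] - coords[quads[:, 0]]
    b2 = coords[quads[:, 2]] - coords[quads[:, 1]]
    b3 = coords[quads[:, 3]] - coords[quads[:, 2]]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    b2n = _norm(b2)
    y = np.einsum("ij,ij->i", _cross(n1, n2), b2) / np.maximum(b2n, _EPS)
    x = np.einsum("ij,ij->i", n1, n2)
    return np.arctan2(y, x)


def wrap_angle(delta: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (−π, π]."""
    return (np.asarray(delta) + np.pi) % (2.0 * np.pi) - np.pi


def _accumulate(forces: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    # bincount is much faster than np.add.at for repeated indices
    n = forces.shape[0]
    for k in range(3):
        forces[:, k] += np.bincount(idx, weights=contrib[:, k], minlength=n)


def distance_forces(
    coords: np.ndarray, pairs: np.ndarray, dv_dr: np.ndarray, forces: np.ndarray
) -> None:
    """Accumulate −dV/dr along each pair direction into ``forces``.

    ``dv_dr`` is dV/dr per pair (positive = repulsive when r grows energy).
    """
    if len(pairs) == 0:
        return
    d = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    r = np.maximum(_norm(d), _EPS)
    f = (dv_dr / r)[:, None] * d  # force on atom i along +d
    _accumulate(forces, pairs[:, 0], f)
    _accumulate(forces, pairs[:, 1], -f)


def bend_forces(
    coords: np.ndarray, triples: np.ndarray, dv_dtheta: np.ndarray, forces: np.ndarray
) -> None:
    """Accumulate forces for energies V(θ) given dV/dθ per triple."""
    if len(triples) == 0:
        return
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu = np.maximum(_norm(u), _EPS)
    nv = np.maximum(_norm(v), _EPS)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    sinang = np.maximum(np.sqrt(1.0 - cosang**2), 1e-8)
    # dθ/dr_i = (cosθ·û − v̂) / (|u| sinθ);  symmetric for k
    dth_di = (cosang[:, None] * uh - vh) / (nu * sinang)[:, None]
    dth_dk = (cosang[:, None] * vh - uh) / (nv * sinang)[:, None]
    fi = -dv_dtheta[:, None] * dth_di
    fk = -dv_dtheta[:, None] * dth_dk
    _accumulate(forces, i, fi)
    _accumulate(forces, k, fk)
    _accumulate(forces, j, -(fi + fk))


def torsion_forces(
    coords: np.ndarray, quads: np.ndarray, dv_dphi: np.ndarray, forces: np.ndarray
) -> None:
    """Accumulate forces for energies V(φ) given dV/dφ per quadruple.

    Uses the standard analytic gradient of the torsion angle
    (∂φ/∂r_i = −|b2| n1/|n1|², ∂φ/∂r_l = |b2| n2/|n2|²) with the chain-rule
    distribution onto the inner atoms.
    """
    if len(quads) == 0:
        return
    i, j, k, l = quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), _EPS)
    n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), _EPS)
    b2n = np.maximum(_norm(b2), _EPS)
    dphi_di = -(b2n / n1sq)[:, None] * n1
    dphi_dl = (b2n / n2sq)[:, None] * n2
    s12 = np.einsum("ij,ij->i", b1, b2) / b2n**2
    s32 = np.einsum("ij,ij->i", b3, b2) / b2n**2
    dphi_dj = -(1.0 + s12)[:, None] * dphi_di + s32[:, None] * dphi_dl
    dphi_dk = -(1.0 + s32)[:, None] * dphi_dl + s12[:, None] * dphi_di
    g = dv_dphi[:, None]
    _accumulate(forces, i, -g * dphi_di)
    _accumulate(forces, j, -g * dphi_dj)
    _accumulate(forces, k, -g * dphi_dk)
    _accumulate(forces, l, -g * dphi_dl)
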