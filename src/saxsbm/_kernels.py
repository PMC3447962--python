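"""Compiled (numba) force kernel and BAOAB integration loop.

These kernels evaluate exactly the same potential as the reference numpy
implementation in :mod:`saxsbm.sampler` (which remains the documented API
and the target of the finite-difference tests); they exist so Langevin
runs long enough to decorrelate domain arrangements stay cheap.  The
Gaussian thermostat noise is pre-drawn with numpy's seeded generator and
passed in, so trajectories are reproducible and independent of numba's
internal RNG.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["force_kernel", "baoab_chunk", "topology_arrays"]


@njit(cache=False)
def force_kernel(
    coords,
    bonds,
    bond_r0,
    eps_r,
    angles,
    angle_theta0,
    eps_theta,
    torsions,  # impropers + all dihedrals, (M, 4)
    torsion_ref,
    torsion_harmonic,  # bool: harmonic (eps_xi) vs cosine (weight)
    torsion_coeff,  # eps_xi for harmonic rows, weight for cosine rows
    contacts,
    contact_r0,
    contact_eps,
    nb_pairs,
    eps_nc,
    sigma_nc,
    forces,
):
    """Accumulate -grad V into ``forces`` (zeroed here); returns V."""
    n = coords.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    energy = 0.0

    for m in range(bonds.shape[0]):
        i, j = bonds[m, 0], bonds[m, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[m]
        energy += eps_r * dr * dr
        g = 2.0 * eps_r * dr / r  # dV/dr / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    for m in range(angles.shape[0]):
        i, j, k = angles[m, 0], angles[m, 1], angles[m, 2]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[k, 0] - coords[j, 0]
        vy = coords[k, 1] - coords[j, 1]
        vz = coords[k, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cosang = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cosang > 1.0:
            cosang = 1.0
        elif cosang < -1.0:
            cosang = -1.0
        theta = np.arccos(cosang)
        sinang = np.sqrt(1.0 - cosang * cosang)
        if sinang < 1e-8:
            sinang = 1e-8
        dth = theta - angle_theta0[m]
        energy += eps_theta * dth * dth
        dv = 2.0 * eps_theta * dth
        # dtheta/dr_i = (cos*uh - vh)/(nu*sin)
        uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
        vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
        ci = 1.0 / (nu * sinang)
        ck = 1.0 / (nv * sinang)
        fix = -dv * (cosang * uhx - vhx) * ci
        fiy = -dv * (cosang * uhy - vhy) * ci
        fiz = -dv * (cosang * uhz - vhz) * ci
        fkx = -dv * (cosang * vhx - uhx) * ck
        fky = -dv * (cosang * vhy - uhy) * ck
        fkz = -dv * (cosang * vhz - uhz) * ck
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz

    for m in range(torsions.shape[0]):
        i, j, k, l = torsions[m, 0], torsions[m, 1], torsions[m, 2], torsions[m, 3]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if b2n < 1e-12:
            b2n = 1e-12
        cx = n1y * n2z - n1z * n2y
        cy = n1z * n2x - n1x * n2z
        cz = n1x * n2y - n1y * n2x
        y = (cx * b2x + cy * b2y + cz * b2z) / b2n
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(y, x)
        dphi = phi - torsion_ref[m]
        # wrap into (-pi, pi]
        while dphi > np.pi:
            dphi -= 2.0 * np.pi
        while dphi <= -np.pi:
            dphi += 2.0 * np.pi
        if torsion_harmonic[m]:
            energy += torsion_coeff[m] * dphi * dphi
            dv = 2.0 * torsion_coeff[m] * dphi
        else:
            energy += torsion_coeff[m] * (
                (1.0 - np.cos(dphi)) + 0.5 * (1.0 - np.cos(3.0 * dphi))
            )
            dv = torsion_coeff[m] * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        if dv == 0.0:
            continue
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12:
            n1sq = 1e-12
        if n2sq < 1e-12:
            n2sq = 1e-12
        aix = -(b2n / n1sq) * n1x
        aiy = -(b2n / n1sq) * n1y
        aiz = -(b2n / n1sq) * n1z
        dlx = (b2n / n2sq) * n2x
        dly = (b2n / n2sq) * n2y
        dlz = (b2n / n2sq) * n2z
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        djx = -(1.0 + s12) * aix + s32 * dlx
        djy = -(1.0 + s12) * aiy + s32 * dly
        djz = -(1.0 + s12) * aiz + s32 * dlz
        dkx = -(1.0 + s32) * dlx + s12 * aix
        dky = -(1.0 + s32) * dly + s12 * aiy
        dkz = -(1.0 + s32) * dlz + s12 * aiz
        forces[i, 0] -= dv * aix
        forces[i, 1] -= dv * aiy
        forces[i, 2] -= dv * aiz
        forces[j, 0] -= dv * djx
        forces[j, 1] -= dv * djy
        forces[j, 2] -= dv * djz
        forces[k, 0] -= dv * dkx
        forces[k, 1] -= dv * dky
        forces[k, 2] -= dv * dkz
        forces[l, 0] -= dv * dlx
        forces[l, 1] -= dv * dly
        forces[l, 2] -= dv * dlz

    for m in range(contacts.shape[0]):
        i, j = contacts[m, 0], contacts[m, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        x6 = (contact_r0[m] * contact_r0[m] / r2) ** 3
        energy += contact_eps[m] * (x6 * x6 - 2.0 * x6)
        g = 12.0 * contact_eps[m] * (x6 - x6 * x6) / r2  # (dV/dr)/r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    s2 = sigma_nc * sigma_nc
    for m in range(nb_pairs.shape[0]):
        i, j = nb_pairs[m, 0], nb_pairs[m, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        x12 = (s2 / r2) ** 6
        energy += eps_nc * x12
        g = -12.0 * eps_nc * x12 / r2
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    return energy


@njit(cache=False)
def baoab_chunk(
    coords,
    vel,
    forces,
    n_steps,
    dt,
    c1,
    noise,  # (n_steps, n_atoms, 3) pre-drawn standard normals × noise_scale
    use_noise,
    bonds,
    bond_r0,
    eps_r,
    angles,
    angle_theta0,
    eps_theta,
    torsions,
    torsion_ref,
    torsion_harmonic,
    torsion_coeff,
    contacts,
    contact_r0,
    contact_eps,
    nb_pairs,
    eps_nc,
    sigma_nc,
):
    """Advance ``n_steps`` BAOAB steps in place; returns final potential."""
    n = coords.shape[0]
    energy = 0.0
    for step in range(n_steps):
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
            coords[i, 0] += 0.5 * dt * vel[i, 0]
            coords[i, 1] += 0.5 * dt * vel[i, 1]
            coords[i, 2] += 0.5 * dt * vel[i, 2]
        if use_noise:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + noise[step, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + noise[step, i, 1]
                vel[i, 2] = c1 * vel[i, 2] + noise[step, i, 2]
        elif c1 != 1.0:
            for i in range(n):
                vel[i, 0] *= c1
                vel[i, 1] *= c1
                vel[i, 2] *= c1
        for i in range(n):
            coords[i, 0] += 0.5 * dt * vel[i, 0]
            coords[i, 1] += 0.5 * dt * vel[i, 1]
            coords[i, 2] += 0.5 * dt * vel[i, 2]
        energy = force_kernel(
            coords,
            bonds,
            bond_r0,
            eps_r,
            angles,
            angle_theta0,
            eps_theta,
            torsions,
            torsion_ref,
            torsion_harmonic,
            torsion_coeff,
            contacts,
            contact_r0,
            contact_eps,
            nb_pairs,
            eps_nc,
            sigma_nc,
            forces,
        )
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
    return energy


def topology_arrays(t) -> dict:
    """Contiguous, typed views of a Topology for the kernels.

    Impropers and dihedrals are merged into one torsion list: impropers
    and rigid dihedrals are harmonic (ε_ξ), flexible dihedrals carry their
    stabilizing weight in the cosine form.
    """
    n_imp = len(t.impropers)
    n_dih = len(t.dihedrals)
    torsions = np.vstack([t.impropers.reshape(-1, 4), t.dihedrals.reshape(-1, 4)]).astype(np.int64)
    torsion_ref = np.concatenate([t.improper_xi0, t.dihedral_phi0])
    harmonic = np.concatenate(
        [np.ones(n_imp, dtype=np.bool_), t.dihedral_rigid.astype(np.bool_)]
    )
    coeff = np.concatenate(
        [
            np.full(n_imp, t.params.eps_xi),
            np.where(t.dihedral_rigid, t.params.eps_xi, t.dihedral_weight),
        ]
    )
    nb = t.nonbonded_pairs() if not hasattr(t, "_nb_pairs_cache") else t._nb_pairs_cache
    return {
        "bonds": np.ascontiguousarray(t.bonds, dtype=np.int64),
        "bond_r0": np.ascontiguousarray(t.bond_r0, dtype=np.float64),
        "eps_r": float(t.params.eps_r),
        "angles": np.ascontiguousarray(t.angles, dtype=np.int64),
        "angle_theta0": np.ascontiguousarray(t.angle_theta0, dtype=np.float64),
        "eps_theta": float(t.params.eps_theta),
        "torsions": np.ascontiguousarray(torsions),
        "torsion_ref": np.ascontiguousarray(torsion_ref, dtype=np.float64),
        "torsion_harmonic": harmonic,
        "torsion_coeff": np.ascontiguousarray(coeff, dtype=np.float64),
        "contacts": np.ascontiguousarray(t.contacts.reshape(-1, 2), dtype=np.int64),
        "contact_r0": np.ascontiguousarray(t.contact_r0, dtype=np.float64),
        "contact_eps": np.ascontiguousarray(t.contact_eps, dtype=np.float64),
        "nb_pairs": np.ascontiguousarray(nb, dtype=np.int64),
        "eps_nc": float(t.params.eps_nc),
        "sigma_nc": float(t.params.sigma_nc),
    }
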