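"""Reduced-unit potential evaluation and Langevin conformational sampling.

Energies are in reduced units; all atoms carry unit mass during dynamics
(the conventional choice for structure-based models — reported radii of
gyration use real masses via :mod:`saxsbm.structure`).  The integrator is
velocity Verlet with the BAOAB Langevin splitting, which reduces exactly to
symplectic NVE integration when the friction is zero.

Functional form of the potential:

* bonds           ε_r (r − r0)²
* angles          ε_θ (θ − θ0)²
* impropers       ε_ξ wrap(ξ − ξ0)²
* rigid torsions  ε_ξ wrap(φ − φ0)²  (peptide ω, rings)
* flexible torsions, weight w:  w·[(1 − cos Δφ) + ½(1 − cos 3Δφ)]
* native contacts ε_C [(r0/r)¹² − 2 (r0/r)⁶]
* excluded volume ε_nc (σ_nc/r)¹² over all non-excluded pairs
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import geometry
from .forcefield import Topology
from .structure import ConformationSet, Structure, radius_of_gyration

__all__ = [
    "SamplerParams",
    "EnergyBreakdown",
    "potential_energy",
    "forces",
    "run_sampling",
]


@dataclasses.dataclass
class SamplerParams:
    """Langevin sampling protocol in reduced units.

    Defaults follow the conventional SBM protocol: dt = 0.0005, snapshots
    every 0.5 time units (40,000 snapshots over the full 20,000-unit
    production run), temperature and friction 1.0.  Scaled-down runs
    shorten ``total_time``, never the snapshot interval.
    """

    timestep: float = 0.0005
    total_time: float = 20_000.0
    snapshot_interval: float = 0.5
    temperature: float = 1.0
    friction: float = 1.0
    seed: int = 0
    energy_bound: float = 1e8  # abort if |V| exceeds this

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.snapshot_interval < self.timestep:
            raise ValueError("snapshot_interval must be >= timestep")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")


@dataclasses.dataclass
class EnergyBreakdown:
    bond: float
    angle: float
    improper: float
    dihedral: float
    contact: float
    excluded_volume: float
    total: float = 0.0

    def __post_init__(self) -> None:
        self.total = (
            self.bond
            + self.angle
            + self.improper
            + self.dihedral
            + self.contact
            + self.excluded_volume
        )


def _nonbonded_pairs(t: Topology) -> np.ndarray:
    cached = getattr(t, "_nb_pairs_cache", None)
    if cached is None:
        cached = t.nonbonded_pairs()
        object.__setattr__(t, "_nb_pairs_cache", cached)
    return cached


def _check_coords(t: Topology, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] != t.n_atoms:
        raise ValueError(f"expected {t.n_atoms} atoms, got {coords.shape[0]}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinate encountered")
    return coords


def potential_energy(t: Topology, coords: np.ndarray) -> EnergyBreakdown:
    """Evaluate the SBM potential, term by term."""
    coords = _check_coords(t, coords)
    p = t.params

    r = geometry.distances(coords, t.bonds)
    e_bond = float(np.sum(p.eps_r * (r - t.bond_r0) ** 2))

    th = geometry.bend_angles(coords, t.angles)
    e_angle = float(np.sum(p.eps_theta * (th - t.angle_theta0) ** 2))

    xi = geometry.torsion_angles(coords, t.impropers)
    e_improper = float(
        np.sum(p.eps_xi * geometry.wrap_angle(xi - t.improper_xi0) ** 2)
    )

    phi = geometry.torsion_angles(coords, t.dihedrals)
    dphi = geometry.wrap_angle(phi - t.dihedral_phi0)
    rigid = t.dihedral_rigid
    e_dih = float(np.sum(p.eps_xi * dphi[rigid] ** 2))
    w = t.dihedral_weight[~rigid]
    d = dphi[~rigid]
    e_dih += float(np.sum(w * ((1.0 - np.cos(d)) + 0.5 * (1.0 - np.cos(3.0 * d)))))

    rc = geometry.distances(coords, t.contacts)
    if len(rc):
        x6 = (t.contact_r0 / rc) ** 6
        e_contact = float(np.sum(t.contact_eps * (x6**2 - 2.0 * x6)))
    else:
        e_contact = 0.0

    nb = _nonbonded_pairs(t)
    if len(nb):
        rnb = geometry.distances(coords, nb)
        e_ev = float(np.sum(p.eps_nc * (p.sigma_nc / rnb) ** 12))
    else:
        e_ev = 0.0

    return EnergyBreakdown(e_bond, e_angle, e_improper, e_dih, e_contact, e_ev)


def forces(t: Topology, coords: np.ndarray) -> np.ndarray:
    """Analytic forces F = −∇V, shape (n_atoms, 3)."""
    coords = _check_coords(t, coords)
    p = t.params
    f = np.zeros_like(coords)

    if len(t.bonds):
        r = geometry.distances(coords, t.bonds)
        geometry.distance_forces(coords, t.bonds, 2.0 * p.eps_r * (r - t.bond_r0), f)

    if len(t.angles):
        th = geometry.bend_angles(coords, t.angles)
        geometry.bend_forces(coords, t.angles, 2.0 * p.eps_theta * (th - t.angle_theta0), f)

    if len(t.impropers):
        xi = geometry.torsion_angles(coords, t.impropers)
        dxi = geometry.wrap_angle(xi - t.improper_xi0)
        geometry.torsion_forces(coords, t.impropers, 2.0 * p.eps_xi * dxi, f)

    if len(t.dihedrals):
        phi = geometry.torsion_angles(coords, t.dihedrals)
        dphi = geometry.wrap_angle(phi - t.dihedral_phi0)
        dv = np.where(
            t.dihedral_rigid,
            2.0 * p.eps_xi * dphi,
            t.dihedral_weight * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi)),
        )
        geometry.torsion_forces(coords, t.dihedrals, dv, f)

    if len(t.contacts):
        r = geometry.distances(coords, t.contacts)
        x6 = (t.contact_r0 / r) ** 6
        dv_dr = 12.0 * t.contact_eps * (x6 - x6**2) / r
        geometry.distance_forces(coords, t.contacts, dv_dr, f)

    nb = _nonbonded_pairs(t)
    if len(nb):
        r = geometry.distances(coords, nb)
        dv_dr = -12.0 * p.eps_nc * p.sigma_nc**12 / r**13
        geometry.distance_forces(coords, nb, dv_dr, f)

    return f


class EnergyDivergenceError(RuntimeError):
    """Simulation left the physically meaningful energy range."""


_KERNEL_KEYS = (
    "bonds",
    "bond_r0",
    "eps_r",
    "angles",
    "angle_theta0",
    "eps_theta",
    "torsions",
    "torsion_ref",
    "torsion_harmonic",
    "torsion_coeff",
    "contacts",
    "contact_r0",
    "contact_eps",
    "nb_pairs",
    "eps_nc",
    "sigma_nc",
)


def _kernel_args(arrs: dict) -> tuple:
    return tuple(arrs[k] for k in _KERNEL_KEYS)


def run_sampling(
    t: Topology,
    start: Structure,
    p: SamplerParams,
) -> ConformationSet:
    """Generate candidate conformations by Langevin dynamics.

    Returns ``total_time / snapshot_interval`` snapshots (the native
    protocol yields 40,000).  With ``friction == 0`` the thermostat is
    disabled (NVE).  Fully deterministic for a given seed.  The returned
    set carries per-snapshot ``potential`` and ``kinetic`` energy arrays.
    """
    from ._kernels import baoab_chunk, force_kernel, topology_arrays

    coords = _check_coords(t, start.coords).copy()
    dt = p.timestep
    n_steps = int(round(p.total_time / dt))
    snap_stride = max(1, int(round(p.snapshot_interval / dt)))
    rng = np.random.default_rng(p.seed)

    if p.temperature > 0:
        vel = rng.normal(0.0, np.sqrt(p.temperature), size=coords.shape)
    else:
        vel = np.zeros_like(coords)
    c1 = float(np.exp(-p.friction * dt)) if p.friction > 0 else 1.0
    noise_scale = float(np.sqrt(p.temperature * (1.0 - c1 * c1)))

    arrs = topology_arrays(t)
    f = np.zeros_like(coords)
    force_kernel(coords, *_kernel_args(arrs), f)
    frames = []
    pe_series: list[float] = []
    ke_series: list[float] = []
    steps_done = 0
    while steps_done < n_steps:
        chunk = min(snap_stride, n_steps - steps_done)
        if noise_scale > 0:
            noise = noise_scale * rng.standard_normal((chunk, t.n_atoms, 3))
            use_noise = True
        else:
            noise = np.zeros((1, t.n_atoms, 3))
            use_noise = False
        e = baoab_chunk(
            coords, vel, f, chunk, dt, c1, noise, use_noise, *_kernel_args(arrs)
        )
        steps_done += chunk
        if steps_done % snap_stride == 0:
            frames.append(coords.copy())
            pe_series.append(float(e))
            ke_series.append(float(0.5 * np.sum(vel * vel)))
        if not np.isfinite(e) or abs(e) > p.energy_bound:
            raise EnergyDivergenceError(
                f"potential energy {e:.3g} at step {steps_done} exceeds bound "
                f"{p.energy_bound:.3g}; reduce the timestep or temperature"
            )
    frames_arr = np.array(frames) if frames else np.zeros((0, t.n_atoms, 3))
    rg = np.array(
        [radius_of_gyration(start.with_coords(fr)) for fr in frames_arr]
    )
    cs = ConformationSet(
        template=start,
        frames=frames_arr,
        frame_index=np.arange(1, len(frames_arr) + 1) * snap_stride,
        rg=rg,
    )
    # per-snapshot energies (reduced units), useful for protocol diagnostics
    cs.potential = np.array(pe_series)
    cs.kinetic = np.array(ke_series)
    return cs
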