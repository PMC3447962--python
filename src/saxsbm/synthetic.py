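"""Synthetic inputs: toy multi-domain structures, conformer families and
mock experimental SAXS curves with known ground truth.

The toy structures are miniature analogs of a multi-domain kinase
architecture (compact globular domains joined by extended flexible
linkers): random self-avoiding clusters with ~1.5 Å bonds and ≥2.2 Å
non-bonded separations.  They are not real folds — they exercise every
geometric code path (connectivity, shadow contacts, hinge motion,
scattering) without downloads, which is exactly what the pipeline's tests
need and no more.

Mock experimental curves are weighted mixtures of conformer profiles with
Gaussian noise whose standard deviation grows linearly with q,
σ(q) = relative_noise · I(q) · (1 + q_growth · q / q_max), emulating the
error inflation of real detector data toward high q.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .curve import ScatteringCurve
from .saxs import debye_profile, default_qgrid
from .structure import LINKER_LABEL, ConformationSet, Structure, radius_of_gyration

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "toy_multidomain",
    "conformer_family",
    "domain_rotation_jitter",
    "mock_experiment",
]

_BOND = 1.5  # Å, chain step
_MIN_DIST = 2.2  # Å, non-bonded steric floor
_ELEMENT_CYCLE = ("C", "N", "C", "O", "C")


@dataclasses.dataclass
class NoiseModel:
    """Multiplicative, q-inflated Gaussian noise for mock experiments."""

    relative_noise: float = 0.01
    q_growth: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_noise <= 0:
            raise ValueError("relative_noise must be > 0")
        if self.q_growth < 0:
            raise ValueError("q_growth must be >= 0")

    def sigma(self, q: np.ndarray, intensity: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return (
            self.relative_noise
            * np.abs(intensity)
            * (1.0 + self.q_growth * q / q.max())
        )


@dataclasses.dataclass
class GroundTruth:
    """Generating conformers and weights behind a mock curve."""

    member_ids: tuple[int, ...]
    weights: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("ground-truth weights must be non-negative and sum to 1")
        self.weights = w


class StericError(RuntimeError):
    """Chain growth could not satisfy the steric constraints."""


def _grow_cluster(
    rng: np.random.Generator,
    start: np.ndarray,
    n_atoms: int,
    existing: list[np.ndarray],
    compact_bias: float,
) -> list[np.ndarray]:
    """Grow a self-avoiding chain of ``n_atoms`` from ``start``; bias pulls
    each step toward the running centroid so the cluster stays globular."""
    placed = [np.asarray(start, dtype=float)]
    for _ in range(n_atoms - 1):
        centroid = np.mean(placed, axis=0)
        last = placed[-1]
        for attempt in range(400):
            direction = rng.standard_normal(3)
            pull = centroid - last
            norm = np.linalg.norm(pull)
            if norm > 1e-9 and compact_bias > 0:
                # ease the bias off when attempts fail so growth can escape
                b = compact_bias * max(0.2, 1.0 - attempt / 200.0)
                direction = direction + b * pull / norm * np.linalg.norm(direction)
            direction /= np.linalg.norm(direction)
            cand = last + _BOND * direction
            others = placed[:-1] + existing
            if others:
                dmin = np.min(np.linalg.norm(np.array(others) - cand, axis=1))
                if dmin < _MIN_DIST:
                    continue
            placed.append(cand)
            break
        else:
            raise StericError("self-avoiding growth stalled")
    return placed


def toy_multidomain(
    n_domains: int = 3,
    atoms_per_domain: int = 60,
    linker_length: int = 16,
    seed: int = 0,
    compact_bias: float = 0.9,
) -> Structure:
    """Random multi-domain toy structure: compact self-avoiding globular
    clusters joined by extended linkers.

    Atom count is ``n_domains·atoms_per_domain + (n_domains−1)·linker_length``;
    each atom is its own residue (a bead-chain convention, so the
    sequence-separation contact rule acts per atom); domain labels are
    ``"D1"``, ``"D2"``, ... with linker atoms labelled ``"linker"``.
    Deterministic for a given seed.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    if atoms_per_domain < 1 or (n_domains > 1 and linker_length < 1):
        raise ValueError("domains and linkers must contain at least one atom")
    master = np.random.default_rng(seed)
    for restart in range(30):
        rng = np.random.default_rng(master.integers(2**31))
        try:
            coords: list[np.ndarray] = []
            labels: list[str] = []
            pos = np.zeros(3)
            for d in range(n_domains):
                cluster = _grow_cluster(rng, pos, atoms_per_domain, coords, compact_bias)
                coords.extend(cluster)
                labels.extend([f"D{d + 1}"] * atoms_per_domain)
                if d == n_domains - 1:
                    break
                # extended linker: nearly straight, pointing away from the
                # domain it leaves
                centroid = np.mean(cluster, axis=0)
                away = coords[-1] - centroid
                away /= max(np.linalg.norm(away), 1e-9)
                direction = away + 0.5 * rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                for _ in range(linker_length):
                    for _attempt in range(200):
                        jitter = direction + 0.15 * rng.standard_normal(3)
                        jitter /= np.linalg.norm(jitter)
                        cand = coords[-1] + _BOND * jitter
                        dmin = np.min(
                            np.linalg.norm(np.array(coords[:-1]) - cand, axis=1)
                        )
                        if dmin >= _MIN_DIST:
                            coords.append(cand)
                            labels.append(LINKER_LABEL)
                            break
                    else:
                        raise StericError("linker growth stalled")
                pos = coords[-1] + _BOND * direction
            n = len(coords)
            elements = [_ELEMENT_CYCLE[i % len(_ELEMENT_CYCLE)] for i in range(n)]
            return Structure(
                elements=np.array(elements),
                residue_index=np.arange(1, n + 1),
                chain_ids=np.full(n, "A"),
                coords=np.array(coords),
                domain_labels=np.array(labels),
            )
        except StericError:
            continue
    raise StericError(
        "could not build a sterically valid toy structure; "
        "parameters may be geometrically impossible"
    )


def _linker_pivots(s: Structure) -> list[int]:
    """First atom index of each contiguous linker run."""
    is_linker = s.domain_labels == LINKER_LABEL
    starts = np.flatnonzero(is_linker & ~np.roll(is_linker, 1))
    if is_linker[0]:
        starts = np.unique(np.concatenate([[0], starts]))
    return [int(i) for i in starts]


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def conformer_family(
    base: Structure,
    n: int,
    mode: str = "hinge",
    seed: int = 0,
    max_angle: float = 2.5,
    sampler_params=None,
    require_bracket: bool = True,
) -> ConformationSet:
    """Family of conformations spanning compact to extended arrangements.

    ``hinge`` mode rotates everything downstream of each linker rigidly
    about a seeded random axis through the linker's first atom, drawing
    per-frame hinge angles from ±``max_angle`` rad; the returned frames are
    ordered (and selected) so Rg increases strictly across the series and
    (when ``require_bracket`` — disable it for small-angle jitter around an
    extreme conformer) brackets the base structure's Rg.  ``sampled`` mode delegates to the
    Langevin sampler (:func:`saxsbm.sampler.run_sampling`).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode == "sampled":
        from .forcefield import build_topology
        from .sampler import SamplerParams, run_sampling

        params = sampler_params or SamplerParams(
            total_time=n * 0.5, snapshot_interval=0.5, seed=seed
        )
        topo = build_topology(base)
        return run_sampling(topo, base, params)
    if mode != "hinge":
        raise ValueError(f"unknown mode {mode!r}")

    pivots = _linker_pivots(base)
    if not pivots:
        raise ValueError("hinge mode requires a structure with >= 2 domains")
    rng = np.random.default_rng(seed)
    axes = [rng.standard_normal(3) for _ in pivots]

    def hinge_frame(angles: np.ndarray) -> np.ndarray:
        coords = base.coords.copy()
        for pivot, axis, angle in zip(pivots, axes, angles):
            rot = _rotation_matrix(axis, float(angle))
            origin = coords[pivot]
            coords[pivot:] = (coords[pivot:] - origin) @ rot.T + origin
        return coords

    base_rg = radius_of_gyration(base)
    m = max(4 * n, n + 16)
    angle_sets = rng.uniform(-max_angle, max_angle, size=(m, len(pivots)))
    angle_sets[0] = 0.05 * angle_sets[0]  # keep some frames near the base
    frames = np.array([hinge_frame(a) for a in angle_sets])
    rgs = np.array(
        [radius_of_gyration(base.with_coords(f)) for f in frames]
    )
    order = np.argsort(rgs)
    pick = np.unique(np.round(np.linspace(0, m - 1, n)).astype(int))
    idx = order[pick]
    # top up if rounding collapsed any picks
    extra = [i for i in order if i not in set(idx)]
    while len(idx) < n and extra:
        idx = np.sort(np.append(idx, extra.pop(0)))
        idx = idx[np.argsort(rgs[idx])]
    sel_order = idx[np.argsort(rgs[idx])]
    sel_rg = rgs[sel_order]
    if np.any(np.diff(sel_rg) <= 0):
        keep = np.concatenate([[True], np.diff(sel_rg) > 0])
        sel_order, sel_rg = sel_order[keep], sel_rg[keep]
    if require_bracket and n >= 3 and not (sel_rg[0] < base_rg < sel_rg[-1]):
        # one retry with a wider hinge range before giving up
        if max_angle < 2.8:
            return conformer_family(base, n, mode, seed, max_angle=2.0 * max_angle)
    return ConformationSet(
        template=base,
        frames=frames[sel_order],
        frame_index=np.arange(len(sel_order)),
        rg=sel_rg,
    )


def domain_rotation_jitter(
    base: Structure,
    n: int,
    max_angle: float = 1.0,
    seed: int = 0,
) -> ConformationSet:
    """Within-state thermal jitter: each domain rotated rigidly about its
    own centroid by random angles up to ±``max_angle`` rad per frame.

    Because domain centroids (and hence the inter-domain distance
    distribution) are preserved, the scattering curve barely changes while
    coordinates move on the Å scale — the frames are RMSD-distinct
    structures with nearly identical SAXS profiles, which is how one
    conformational population looks to a scattering experiment.  Linker
    atoms are left in place.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    labels = [lab for lab in np.unique(base.domain_labels) if lab != LINKER_LABEL]
    frames = np.empty((n, base.n_atoms, 3))
    for f in range(n):
        c = base.coords.copy()
        for lab in labels:
            m = base.domain_labels == lab
            axis = rng.standard_normal(3)
            angle = rng.uniform(-max_angle, max_angle)
            centroid = c[m].mean(axis=0)
            c[m] = (c[m] - centroid) @ _rotation_matrix(axis, angle).T + centroid
        frames[f] = c
    return ConformationSet(base, frames)


def mock_experiment(
    members: ConformationSet,
    weights,
    qgrid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    mode: str = "vacuum",
    member_curves: np.ndarray | None = None,
) -> tuple[ScatteringCurve, GroundTruth]:
    """Mock experimental curve: noisy weighted mixture of member profiles.

    I_exp(q) = Σ w_i I_i(q) + ε(q) with ε ~ N(0, σ(q)) and σ(q) from the
    noise model; the σ column is emitted with the curve and the generating
    members, weights and noise seed are recorded as ground truth.
    """
    noise = noise or NoiseModel()
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(members):
        raise ValueError("one weight per member conformation required")
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise ValueError("weights must be non-negative and sum to 1")
    q = np.asarray(default_qgrid() if qgrid is None else qgrid, dtype=float)
    if member_curves is None:
        member_curves = np.stack(
            [debye_profile(members[i], q, mode=mode).intensity for i in range(len(members))]
        )
    ideal = weights @ member_curves
    sigma = noise.sigma(q, ideal)
    rng = np.random.default_rng(noise.seed)
    intensity = ideal + rng.normal(0.0, sigma)
    truth = GroundTruth(
        member_ids=tuple(int(i) for i in members.frame_index),
        weights=weights,
        seed=noise.seed,
    )
    return ScatteringCurve(q, intensity, sigma), truth
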