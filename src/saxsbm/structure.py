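"""Atomic structures, conformation sets and geometric primitives.

The central container is :class:`Structure`, a heavy-atom model of a
(possibly multi-domain) protein.  Every atom carries a domain label taken
from a user-supplied domain map; residues outside any named domain are
labelled ``"linker"``.  Hydrogens are dropped on input.

Geometric primitives follow the conventions used throughout small-angle
scattering work: the radius of gyration is mass-weighted with standard
atomic masses, and RMSD is the minimum over rigid-body superpositions
(Kabsch).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as bts
import biotite.structure.io.pdb as bts_pdb

__all__ = [
    "Structure",
    "ConformationSet",
    "ATOMIC_MASSES",
    "read_pdb",
    "write_pdb",
    "read_conformations",
    "write_conformations",
    "domain_map_from_labels",
    "radius_of_gyration",
    "rmsd_superposed",
]

#: Standard atomic masses (u) for the heavy atoms that occur in proteins.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
}

LINKER_LABEL = "linker"


class PDBFormatError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


class DomainMapError(ValueError):
    """Raised when the domain map does not cover the structure."""


@dataclasses.dataclass
class Structure:
    """Heavy-atom structure with per-atom domain labels.

    Parameters
    ----------
    elements
        Chemical element symbols, upper case (``"C"``, ``"N"``, ...).
    residue_index
        1-based serial residue index per atom, non-decreasing within a chain.
    chain_ids
        Chain identifier per atom.
    coords
        Cartesian coordinates, Å, shape ``(n_atoms, 3)``.
    domain_labels
        Domain label per atom (e.g. ``"SH3"``, ``"SH2"``, ``"kinase"``,
        ``"linker"``).
    atom_names, res_names
        Optional PDB-style names, used when writing PDB output.
    """

    elements: np.ndarray
    residue_index: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    domain_labels: np.ndarray
    atom_names: np.ndarray | None = None
    res_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.elements = np.asarray(self.elements, dtype="U2")
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.domain_labels = np.asarray(self.domain_labels, dtype="U32")
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.atom_names is None:
            self.atom_names = np.array(
                [f"{el}{i + 1}"[:4] for i, el in enumerate(self.elements)], dtype="U6"
            )
        if self.res_names is None:
            self.res_names = np.full(n, "GLY", dtype="U5")
        for chain in np.unique(self.chain_ids):
            res = self.residue_index[self.chain_ids == chain]
            if np.any(np.diff(res) < 0):
                raise ValueError(f"residue_index decreases within chain {chain!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[e] for e in self.elements])
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"no standard mass for element {exc}") from None

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        return dataclasses.replace(self, coords=np.array(coords, dtype=float))

    def to_atom_array(self) -> bts.AtomArray:
        arr = bts.AtomArray(self.n_atoms)
        arr.coord = self.coords.astype(np.float32)
        arr.chain_id = self.chain_ids
        arr.res_id = self.residue_index
        arr.res_name = self.res_names
        arr.atom_name = self.atom_names
        arr.element = self.elements
        arr.hetero = np.zeros(self.n_atoms, dtype=bool)
        return arr


@dataclasses.dataclass
class ConformationSet:
    """Ordered conformations sharing one topology (atom count and order).

    ``frames`` has shape ``(n_frames, n_atoms, 3)``;  ``frame_index`` and
    ``rg`` are per-frame metadata.
    """

    template: Structure
    frames: np.ndarray
    frame_index: np.ndarray | None = None
    rg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.template.n_atoms, 3):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.template.n_atoms} atoms"
            )
        if self.frame_index is None:
            self.frame_index = np.arange(len(self.frames))
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.rg is None:
            self.rg = np.array(
                [radius_of_gyration(self.template.with_coords(f)) for f in self.frames]
            )
        self.rg = np.asarray(self.rg, dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Structure:
        return self.template.with_coords(self.frames[i])

    def subset(self, idx: np.ndarray) -> "ConformationSet":
        idx = np.asarray(idx)
        return ConformationSet(
            self.template, self.frames[idx], self.frame_index[idx], self.rg[idx]
        )


def _normalize_domain_map(
    domain_map: Mapping[str, object],
) -> list[tuple[str, int, int]]:
    """Flatten ``label -> (start, stop) | [(start, stop), ...]`` to triples."""
    out: list[tuple[str, int, int]] = []
    for label, ranges in domain_map.items():
        if not isinstance(ranges, Sequence) or len(ranges) == 0:
            raise DomainMapError(f"invalid range spec for domain {label!r}")
        if np.isscalar(ranges[0]):
            ranges = [ranges]
        for rng in ranges:
            start, stop = int(rng[0]), int(rng[1])
            if stop < start:
                raise DomainMapError(f"empty range {rng} for domain {label!r}")
            out.append((label, start, stop))
    return out


def assign_domains(
    residue_index: np.ndarray,
    domain_map: Mapping[str, object],
    default_label: str | None = LINKER_LABEL,
) -> np.ndarray:
    """Map residue indices to domain labels; uncovered residues get
    ``default_label`` (``None`` makes uncovered residues an error)."""
    triples = _normalize_domain_map(domain_map)
    labels = np.full(len(residue_index), "", dtype="U32")
    for label, start, stop in triples:
        labels[(residue_index >= start) & (residue_index <= stop)] = label
    uncovered = labels == ""
    if uncovered.any():
        if default_label is None:
            missing = sorted(set(residue_index[uncovered].tolist()))
            raise DomainMapError(
                f"residues not covered by domain map and no default label: {missing[:10]}"
            )
        labels[uncovered] = default_label
    return labels


def _structure_from_atom_array(
    arr: bts.AtomArray,
    domain_map: Mapping[str, object] | None,
    default_label: str | None,
) -> Structure:
    if np.any(arr.ins_code != ""):
        raise PDBFormatError("insertion codes are not supported; renumber the input")
    mask = ~arr.hetero  # drop waters, ligands, ions
    mask &= np.char.upper(arr.element) != "H"
    arr = arr[mask]
    if arr.array_length() == 0:
        raise PDBFormatError("no protein ATOM records found")
    elements = np.char.upper(arr.element)
    if domain_map is None:
        labels = np.full(arr.array_length(), LINKER_LABEL)
    else:
        labels = assign_domains(arr.res_id, domain_map, default_label)
    return Structure(
        elements=elements,
        residue_index=arr.res_id,
        chain_ids=arr.chain_id,
        coords=np.asarray(arr.coord, dtype=float),
        domain_labels=labels,
        atom_names=arr.atom_name.astype("U6"),
        res_names=arr.res_name.astype("U5"),
    )


def read_pdb(
    path: str | Path,
    domain_map: Mapping[str, object] | None = None,
    default_label: str | None = LINKER_LABEL,
) -> Structure:
    """Read a heavy-atom :class:`Structure` from a PDB file.

    Only ``ATOM`` records are kept (waters and ligands are stripped);
    hydrogens are dropped; for alternate locations the first (or blank)
    altloc is retained.  ``domain_map`` maps domain labels to inclusive
    residue-index ranges, e.g. ``{"SH3": (9, 70), "SH2": (82, 169)}``;
    residues outside every range are labelled ``default_label``.
    """
    try:
        pdb_file = bts_pdb.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1, altloc="first")
    except PDBFormatError:
        raise
    except Exception as exc:
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    return _structure_from_atom_array(arr, domain_map, default_label)


def write_pdb(path: str | Path, s: Structure) -> None:
    """Write a single-model PDB file."""
    pdb_file = bts_pdb.PDBFile()
    pdb_file.set_structure(s.to_atom_array())
    pdb_file.write(str(path))


def write_conformations(path: str | Path, cs: ConformationSet) -> None:
    """Write a :class:`ConformationSet` as a multi-model PDB file."""
    n = len(cs)
    stack = bts.AtomArrayStack(n, cs.template.n_atoms)
    template_arr = cs.template.to_atom_array()
    for name in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(name, template_arr.get_annotation(name))
    stack.coord = cs.frames.astype(np.float32)
    pdb_file = bts_pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_conformations(
    path: str | Path,
    domain_map: Mapping[str, object] | None = None,
    default_label: str | None = LINKER_LABEL,
) -> ConformationSet:
    """Read a multi-model PDB file into a :class:`ConformationSet`."""
    try:
        pdb_file = bts_pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(altloc="first")
    except Exception as exc:
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if isinstance(stack, bts.AtomArray):
        stack = bts.stack([stack])
    first = stack[0]
    template = _structure_from_atom_array(first, domain_map, default_label)
    mask = ~first.hetero
    mask &= np.char.upper(first.element) != "H"
    frames = np.asarray(stack.coord, dtype=float)[:, mask, :]
    return ConformationSet(template, frames)


def domain_map_from_labels(s: Structure) -> dict[str, list[list[int]]]:
    """Recover a residue-range domain map from per-atom labels.

    Contiguous runs of one label become inclusive residue ranges; linker
    runs are omitted (they are the default label on re-read).
    """
    out: dict[str, list[list[int]]] = {}
    start = 0
    for i in range(1, s.n_atoms + 1):
        if i == s.n_atoms or s.domain_labels[i] != s.domain_labels[start]:
            label = str(s.domain_labels[start])
            if label != LINKER_LABEL:
                out.setdefault(label, []).append(
                    [int(s.residue_index[start]), int(s.residue_index[i - 1])]
                )
            start = i
    return out


def radius_of_gyration(s: Structure) -> float:
    """Mass-weighted radius of gyration, Å.

    Rg = sqrt( Σ m_i |r_i − r_cm|² / Σ m_i ), with standard atomic masses
    and the mass-weighted centroid r_cm.
    """
    if s.n_atoms == 0:
        raise ValueError("empty structure")
    m = s.masses
    com = np.average(s.coords, axis=0, weights=m)
    d2 = np.sum((s.coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=m)))


def rmsd_superposed(a: Structure, b: Structure) -> float:
    """Minimum RMSD (Å) over all rigid-body superpositions of ``b`` onto ``a``.

    Uses the optimal (Kabsch) rotation after centering; atoms are compared
    in order, so both structures must share atom count and ordering.
    """
    if a.n_atoms != b.n_atoms:
        raise ValueError(f"atom count mismatch: {a.n_atoms} vs {b.n_atoms}")
    if a.n_atoms == 0:
        raise ValueError("empty structure")
    pa = a.coords - a.coords.mean(axis=0)
    pb = b.coords - b.coords.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(a.n_atoms))
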