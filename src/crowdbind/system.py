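"""Molecular data model: atoms with roles, trajectories, and periodic geometry.

Every downstream analysis (surface partitioning, transport, pathway
coordinates) classifies atoms by their *role* in the crowded-solution
problem: exactly one TARGET protein (the kinase), any number of CROWDER
proteins (e.g. serum albumins), and one or more LIGAND molecules (the
inhibitor).  Coarse synthetic systems represent a whole protein as a single
"heavy atom" with a per-atom radius offset, so all distance rules subtract
that offset and work unchanged for atomistic and sphere-model input.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray


class Role(enum.Enum):
    """Molecule role in the crowded-solution system."""

    TARGET = "TARGET"
    CROWDER = "CROWDER"
    LIGAND = "LIGAND"


class SystemError_(ValueError):
    """Raised when a MolecularSystem violates its structural invariants."""


@dataclass
class MolecularSystem:
    """Atom records plus molecule bookkeeping.

    Parameters
    ----------
    element : array of str
        Element symbol per atom ("X" for coarse pseudo-atoms).
    heavy_atom : bool array
        False exactly for hydrogen atoms.
    res_name, res_id, chain_id : per-atom residue/chain identity.
    molecule_id : int array
        Each atom belongs to exactly one molecule.
    role : array of Role
        Role of the molecule owning each atom.
    radius_offset : float array, optional
        Per-atom radius (Å) subtracted from centre–centre distances before
        applying any cutoff rule; zero for atomistic input, the sphere
        radius for coarse synthetic proteins.
    atom_name : array of str, optional
        PDB-style atom names (e.g. "CA"); empty strings if unknown.
    """

    element: NDArray
    heavy_atom: NDArray
    res_name: NDArray
    res_id: NDArray
    chain_id: NDArray
    molecule_id: NDArray
    role: NDArray  # dtype=object, entries are Role
    radius_offset: NDArray = field(default=None)  # type: ignore[assignment]
    atom_name: NDArray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.element)
        if self.radius_offset is None:
            self.radius_offset = np.zeros(n)
        if self.atom_name is None:
            self.atom_name = np.array([""] * n, dtype=object)
        for name in ("heavy_atom", "res_name", "res_id", "chain_id",
                     "molecule_id", "role", "radius_offset", "atom_name"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise SystemError_(f"field {name!r} has length {len(arr)}, "
                                   f"expected {n} atoms")
        self._validate()

    def _validate(self) -> None:
        roles_per_mol = {}
        for mol, role in zip(self.molecule_id, self.role):
            prev = roles_per_mol.setdefault(int(mol), role)
            if prev is not role:
                raise SystemError_(f"molecule {mol} has conflicting roles "
                                   f"{prev} and {role}")
        n_target = sum(1 for r in roles_per_mol.values() if r is Role.TARGET)
        if n_target != 1:
            raise SystemError_(f"expected exactly one TARGET molecule, "
                               f"found {n_target}")
        # ligand-free systems are permitted (structure-only input, e.g.
        # SASA on a crystal structure); ligand-dependent analyses check
        # for ligands at their own entry points
        is_h = np.asarray([e.upper() == "H" for e in self.element])
        heavy = np.asarray(self.heavy_atom, dtype=bool)
        if np.any(heavy & is_h) or np.any(~heavy & ~is_h):
            raise SystemError_("heavy_atom must be False exactly for H atoms")

    # -- convenience selections -------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.element)

    def role_mask(self, role: Role) -> NDArray:
        return np.array([r is role for r in self.role], dtype=bool)

    def heavy_mask(self, role: Role | None = None) -> NDArray:
        mask = np.asarray(self.heavy_atom, dtype=bool)
        if role is not None:
            mask = mask & self.role_mask(role)
        return mask

    def molecules(self, role: Role | None = None) -> list[int]:
        """Sorted molecule ids, optionally restricted to one role."""
        seen: dict[int, Role] = {}
        for mol, r in zip(self.molecule_id, self.role):
            seen.setdefault(int(mol), r)
        return sorted(m for m, r in seen.items()
                      if role is None or r is role)

    def counts_per_role(self) -> dict[Role, int]:
        out = {r: 0 for r in Role}
        for m in {int(m): r for m, r in
                  zip(self.molecule_id, self.role)}.items():
            out[m[1]] += 1
        return out


@dataclass(frozen=True)
class BoxGeometry:
    """Orthorhombic box with either periodic or open (non-periodic) metric."""

    lengths: tuple[float, float, float]
    periodic: bool = True

    def __post_init__(self) -> None:
        if any(L <= 0 for L in self.lengths):
            raise ValueError(f"box lengths must be positive, got {self.lengths}")

    @property
    def volume(self) -> float:
        a, b, c = self.lengths
        return a * b * c


def min_image_displacement(a, b, box: BoxGeometry) -> NDArray:
    """Minimal-image displacement vector(s) b - a (Å).

    Broadcasts over leading axes; the last axis must be 3.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box.periodic:
        L = np.asarray(box.lengths)
        d = d - L * np.round(d / L)
    return d


def min_image_distance(a, b, box: BoxGeometry):
    """Minimal-image distance(s) between points a and b (Å)."""
    d = min_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


class TrajectoryError(ValueError):
    """Raised for malformed or inconsistent trajectory data."""


@dataclass
class Trajectory:
    """Time-ordered coordinate frames with a periodic box.

    coords : (n_frames, n_atoms, 3) float array, Å
    box_lengths : (n_frames, 3) float array, Å
    dt_ps : frame spacing in ps
    """

    coords: NDArray
    box_lengths: NDArray
    dt_ps: float
    periodic: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(
                f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.box_lengths.shape != (self.coords.shape[0], 3):
            raise TrajectoryError(
                f"box_lengths must be (n_frames, 3), got {self.box_lengths.shape}")
        if np.any(self.box_lengths <= 0):
            raise TrajectoryError("box lengths must be strictly positive")
        if self.dt_ps <= 0:
            raise TrajectoryError("frame spacing must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def box(self, frame: int) -> BoxGeometry:
        return BoxGeometry(tuple(self.box_lengths[frame]), periodic=self.periodic)

    def times_ps(self) -> NDArray:
        return np.arange(self.n_frames) * self.dt_ps
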