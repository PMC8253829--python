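"""Structure and trajectory I/O.

Structures come from standard PDB files (parsed with :mod:`biotite`); a
role-assignment rule maps chains or residue names onto the
TARGET/CROWDER/LIGAND roles, and any chain left without a rule is an error
rather than a silent default.

Trajectories use a small self-describing text dialect (one header, then one
block per frame) so that synthetic runs, fixtures, and analyses all share a
single on-disk form::

    # crowdbind-traj 1
    natoms 3
    dt_ps 0.5
    frame 0 time_ps 0.0 box 200.0 200.0 200.0
    1.000000 2.000000 3.000000
    ...

Systems round-trip through a JSON sidecar carrying roles, elements and the
per-atom radius offsets the coarse sphere models need.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .system import (BoxGeometry, MolecularSystem, Role, SystemError_,
                     Trajectory, TrajectoryError)

TRAJ_MAGIC = "# crowdbind-traj 1"


class RoleRuleError(ValueError):
    """A chain or residue has no role-assignment rule."""


class PDBParseError(ValueError):
    pass


def load_structure(path, chain_roles: dict[str, str] | None = None,
                   residue_roles: dict[str, str] | None = None,
                   model: int = 1):
    """Read a PDB file and assign molecule roles.

    Parameters
    ----------
    path : PDB file path
    chain_roles : mapping chain id -> role name ("TARGET"/"CROWDER"/"LIGAND")
    residue_roles : mapping residue name -> role name; takes precedence over
        the chain rule for matching residues (e.g. ``{"PP1": "LIGAND"}``).

    Returns
    -------
    (MolecularSystem, coords) where coords is an (n_atoms, 3) Å array.

    Chains covered by neither rule raise :class:`RoleRuleError`.  Each
    non-ligand chain becomes one molecule; each ligand residue becomes its
    own molecule.
    """
    chain_roles = chain_roles or {}
    residue_roles = residue_roles or {}
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=model)
    except Exception as exc:  # re-raise with file context
        raise PDBParseError(f"failed to parse PDB file {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise PDBParseError(f"no atoms in {path}")

    elements = np.array([e.capitalize() if e else "X"
                         for e in atoms.element], dtype=object)
    n = atoms.array_length()
    role_names = np.empty(n, dtype=object)
    for i in range(n):
        res = atoms.res_name[i]
        ch = atoms.chain_id[i]
        if res in residue_roles:
            role_names[i] = residue_roles[res]
        elif ch in chain_roles:
            role_names[i] = chain_roles[ch]
        else:
            raise RoleRuleError(
                f"chain {ch!r} / residue {res!r} matched no role rule; "
                f"every chain must be assigned TARGET, CROWDER or LIGAND")
    roles = np.array([Role[r] for r in role_names], dtype=object)

    # Molecule ids: one per (chain, role) for proteins, one per ligand residue.
    mol_ids = np.zeros(n, dtype=int)
    key_to_id: dict[tuple, int] = {}
    for i in range(n):
        if roles[i] is Role.LIGAND:
            key = ("L", atoms.chain_id[i], int(atoms.res_id[i]))
        else:
            key = ("P", atoms.chain_id[i])
        mol_ids[i] = key_to_id.setdefault(key, len(key_to_id))

    system = MolecularSystem(
        element=elements,
        heavy_atom=np.array([e.upper() != "H" for e in elements]),
        res_name=np.array(atoms.res_name, dtype=object),
        res_id=np.array(atoms.res_id, dtype=int),
        chain_id=np.array(atoms.chain_id, dtype=object),
        molecule_id=mol_ids,
        role=roles,
        atom_name=np.array(atoms.atom_name, dtype=object),
    )
    return system, np.asarray(atoms.coord, dtype=float)


# ---------------------------------------------------------------------------
# Trajectory text dialect
# ---------------------------------------------------------------------------

def write_trajectory(path, traj: Trajectory) -> None:
    times = traj.times_ps()
    with open(path, "w") as fh:
        fh.write(f"{TRAJ_MAGIC}\n")
        fh.write(f"natoms {traj.n_atoms}\n")
        fh.write(f"dt_ps {traj.dt_ps:g}\n")
        for f in range(traj.n_frames):
            bx = traj.box_lengths[f]
            fh.write(f"frame {f} time_ps {times[f]:.6f} "
                     f"box {bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f}\n")
            np.savetxt(fh, traj.coords[f], fmt="%.6f")


def load_trajectory(path, system: MolecularSystem | None = None) -> Trajectory:
    """Read the text dialect; validates atom count against *system* if given."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0].strip() != TRAJ_MAGIC:
        raise TrajectoryError(f"{path}: missing trajectory magic line")
    try:
        natoms = int(lines[1].split()[1])
        dt_ps = float(lines[2].split()[1])
    except (IndexError, ValueError) as exc:
        raise TrajectoryError(f"{path}: malformed header: {exc}") from exc
    if system is not None and natoms != system.n_atoms:
        raise TrajectoryError(
            f"{path}: trajectory has {natoms} atoms but system has "
            f"{system.n_atoms}")

    frames, boxes, times = [], [], []
    i = 3
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        tok = lines[i].split()
        if tok[0] != "frame":
            raise TrajectoryError(f"{path}:{i + 1}: expected 'frame' record, "
                                  f"got {lines[i]!r}")
        times.append(float(tok[3]))
        boxes.append([float(x) for x in tok[5:8]])
        block = lines[i + 1:i + 1 + natoms]
        if len(block) < natoms:
            raise TrajectoryError(f"{path}: truncated frame at line {i + 1}")
        try:
            xyz = np.array([[float(x) for x in ln.split()] for ln in block])
        except ValueError as exc:
            raise TrajectoryError(
                f"{path}: bad coordinate near line {i + 2}: {exc}") from exc
        if xyz.shape != (natoms, 3):
            raise TrajectoryError(
                f"{path}: frame at line {i + 1} has shape {xyz.shape}, "
                f"expected ({natoms}, 3)")
        # a 4th coordinate line where the next frame should start
        nxt = i + 1 + natoms
        if nxt < len(lines) and lines[nxt].strip() and \
                not lines[nxt].startswith("frame"):
            raise TrajectoryError(
                f"{path}:{nxt + 1}: extra coordinate line — atom count "
                f"mismatch with declared natoms {natoms}")
        frames.append(xyz)
        i = nxt
    if not frames:
        raise TrajectoryError(f"{path}: no frames")
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        raise TrajectoryError(f"{path}: frame times are not strictly increasing")
    return Trajectory(np.array(frames), np.array(boxes), dt_ps)


# ---------------------------------------------------------------------------
# System JSON sidecar
# ---------------------------------------------------------------------------

def write_system(path, system: MolecularSystem) -> None:
    payload = {
        "element": list(system.element),
        "heavy_atom": [bool(h) for h in system.heavy_atom],
        "res_name": list(system.res_name),
        "res_id": [int(r) for r in system.res_id],
        "chain_id": list(system.chain_id),
        "molecule_id": [int(m) for m in system.molecule_id],
        "role": [r.value for r in system.role],
        "radius_offset": [float(r) for r in system.radius_offset],
        "atom_name": list(system.atom_name),
    }
    Path(path).write_text(json.dumps(payload))


def read_system(path) -> MolecularSystem:
    d = json.loads(Path(path).read_text())
    return MolecularSystem(
        element=np.array(d["element"], dtype=object),
        heavy_atom=np.array(d["heavy_atom"], dtype=bool),
        res_name=np.array(d["res_name"], dtype=object),
        res_id=np.array(d["res_id"], dtype=int),
        chain_id=np.array(d["chain_id"], dtype=object),
        molecule_id=np.array(d["molecule_id"], dtype=int),
        role=np.array([Role[r] for r in d["role"]], dtype=object),
        radius_offset=np.array(d["radius_offset"], dtype=float),
        atom_name=np.array(d["atom_name"], dtype=object),
    )
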