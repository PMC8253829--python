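"""Superposition and ligand occupancy maps around the target.

The spatial-distribution analysis asks, after least-squares superposition
of the target onto a reference structure, in what fraction of frames a
ligand heavy atom visits each voxel of a grid around the target.  Maps are
exported as OpenDX scalar fields readable by the usual molecular viewers,
with voxel counts above chosen isosurface thresholds (e.g. 0.5% and 1.5%
occupancy) summarized alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import Trajectory


class FitError(ValueError):
    pass


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation R and translation t mapping mobile → reference
    in the least-squares sense (proper rotation, SVD)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise FitError("need two matching selections of ≥3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12:  # rank < 2: collinear/degenerate selection
        raise FitError("degenerate selection: fewer than 3 non-collinear points")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = rc - rot @ mc
    return rot, t


def superpose(traj: Trajectory, reference: np.ndarray, fit_selection):
    """Superpose every frame onto *reference* using the selection.

    The Kabsch rotation/translation fitted on ``fit_selection`` is applied
    to all atoms of the frame.  Returns ``(fitted Trajectory, per-frame
    RMSD over the selection in Å)``.  The fitted trajectory is returned
    with its periodic flag cleared — a superposed cluster no longer lives
    on the original lattice.
    """
    sel = np.asarray(fit_selection)
    if sel.dtype == bool:
        sel = np.nonzero(sel)[0]
    if sel.size == 0:
        raise FitError("empty fit selection")
    ref_sel = np.asarray(reference, dtype=float)[sel]
    out = np.empty_like(traj.coords)
    rmsd = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        rot, t = kabsch(traj.coords[f, sel], ref_sel)
        out[f] = traj.coords[f] @ rot.T + t
        diff = out[f, sel] - ref_sel
        rmsd[f] = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    fitted = Trajectory(out, traj.box_lengths.copy(), traj.dt_ps,
                        periodic=False)
    return fitted, rmsd


@dataclass
class OccupancyGrid:
    """Voxelized ligand occupancy in % of frames."""

    origin: np.ndarray          # (3,) Å
    spacing: float              # Å
    occupancy: np.ndarray       # (nx, ny, nz) %, in [0, 100]
    n_frames: int

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[k] + self.spacing * (np.arange(
            self.occupancy.shape[k]) + 0.5) for k in range(3))

    def count_above(self, threshold: float) -> int:
        return int(np.count_nonzero(self.occupancy >= threshold))


def accumulate_occupancy(traj_fitted: Trajectory, ligand_selection,
                         spacing: float = 1.0, padding: float = 10.0,
                         reference: np.ndarray | None = None,
                         mode: str = "presence") -> OccupancyGrid:
    """Bin selected atoms of a superposed trajectory onto a uniform grid.

    ``mode='presence'`` (default) scores a voxel once per frame in which at
    least one selected atom falls inside it — the "% occupancy" convention
    of isosurface maps; ``mode='count'`` accumulates atom counts instead.
    Grid extents are the axis-aligned bounding box of *reference* (default:
    the selected atoms over the whole trajectory) plus *padding*; voxels
    are half-open intervals [lo, hi) per axis.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if mode not in ("presence", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    sel = np.asarray(ligand_selection)
    if sel.dtype == bool:
        sel = np.nonzero(sel)[0]
    pts = traj_fitted.coords[:, sel, :]
    bounds_src = np.asarray(reference, dtype=float) if reference is not None \
        else pts.reshape(-1, 3)
    lo = bounds_src.min(axis=0) - padding
    hi = bounds_src.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    acc = np.zeros(shape)
    for f in range(traj_fitted.n_frames):
        idx = np.floor((pts[f] - lo) / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        if idx.size == 0:
            continue
        if mode == "presence":
            idx = np.unique(idx, axis=0)
            acc[idx[:, 0], idx[:, 1], idx[:, 2]] += 1.0
        else:
            np.add.at(acc, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    occ = 100.0 * acc / traj_fitted.n_frames
    return OccupancyGrid(origin=lo, spacing=spacing, occupancy=occ,
                         n_frames=traj_fitted.n_frames)


def write_dx(path, origin, spacing, values: np.ndarray,
             name: str = "occupancy") -> None:
    """Write a 3D scalar field as an OpenDX general array file."""
    values = np.asarray(values, dtype=float)
    nx, ny, nz = values.shape
    with open(path, "w") as fh:
        fh.write(f"# {name}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {origin[0]:.6f} {origin[1]:.6f} {origin[2]:.6f}\n")
        fh.write(f"delta {spacing:.6f} 0 0\n")
        fh.write(f"delta 0 {spacing:.6f} 0\n")
        fh.write(f"delta 0 0 {spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items "
                 f"{values.size} data follows\n")
        flat = values.ravel(order="C")  # x fastest-varying last, DX order
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def export_map(grid: OccupancyGrid, path, thresholds=(0.5, 1.5)):
    """Write the grid as OpenDX and report voxel counts at/above each
    isosurface threshold (non-increasing in threshold by construction)."""
    for t in thresholds:
        if not 0.0 <= t <= 100.0:
            raise ValueError(f"threshold {t} outside [0, 100]%")
    write_dx(path, grid.origin, grid.spacing, grid.occupancy)
    return {float(t): grid.count_above(t) for t in thresholds}
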