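"""Numerical solvent-accessible surface area (Shrake–Rupley).

Each heavy atom is inflated by the probe radius (default 1.4 Å, a water
molecule) and covered with a deterministic quasi-uniform point set (golden
spiral); the accessible fraction of points — those outside every other
inflated sphere of the same molecule — times the sphere area gives the
per-atom SASA.  Molecules are treated in isolation (each molecule's area is
computed against its own atoms only), matching the convention of quoting
one SASA per crystal structure.
"""

from __future__ import annotations

import numpy as np

from .system import MolecularSystem

#: van der Waals radii (Å) for common elements
DEFAULT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "Se": 1.90, "Zn": 1.39, "Mg": 1.73, "Na": 2.27, "K": 2.75,
}


class RadiusError(KeyError):
    pass


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points on a golden spiral."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_radii(system: MolecularSystem, radii: dict | None = None,
               heavy_only: bool = True) -> np.ndarray:
    """Resolve the per-atom radius: the explicit radius offset when set
    (coarse sphere models), the element table otherwise."""
    table = DEFAULT_RADII if radii is None else radii
    out = np.empty(system.n_atoms)
    for i in range(system.n_atoms):
        if system.radius_offset[i] > 0:
            out[i] = system.radius_offset[i]
        else:
            el = str(system.element[i]).capitalize()
            if el not in table:
                raise RadiusError(
                    f"no van der Waals radius for element {el!r} "
                    f"(atom {i}); extend the radii table")
            out[i] = table[el]
    return out


def sasa_of_spheres(centers: np.ndarray, radii: np.ndarray,
                    probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-sphere accessible area (Å²) for one isolated group of spheres."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    ext = np.asarray(radii, dtype=float) + probe
    pts = sphere_points(n_points)
    n = len(centers)
    areas = np.empty(n)
    for i in range(n):
        surf = centers[i] + ext[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((surf - centers[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return areas


def compute_sasa(system: MolecularSystem, coords: np.ndarray,
                 probe: float = 1.4, radii: dict | None = None,
                 n_points: int = 960) -> dict[int, float]:
    """SASA (Å²) per molecule, heavy atoms only, each molecule isolated."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system.n_atoms, 3):
        raise ValueError(f"coords shape {coords.shape} does not match "
                         f"{system.n_atoms} atoms")
    r = atom_radii(system, radii)
    heavy = np.asarray(system.heavy_atom, dtype=bool)
    out: dict[int, float] = {}
    for mol in system.molecules():
        sel = (system.molecule_id == mol) & heavy
        if not sel.any():
            out[mol] = 0.0
            continue
        out[mol] = float(sasa_of_spheres(coords[sel], r[sel], probe,
                                         n_points).sum())
    return out
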