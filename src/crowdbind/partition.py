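"""Surface/bulk partitioning of ligands.

A ligand counts as *bulk* only when every one of its heavy atoms is more
than a cutoff (default 5 Å) from every protein heavy atom, measured with
the minimal-image metric and reduced by any per-atom radius offset (so the
coarse sphere proteins of the synthetic generator obey the same rule as
atomistic structures).  Otherwise the ligand belongs to the surface region
of whichever protein class — target or crowder — owns the nearest heavy
atom, with exact ties awarded to the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .system import MolecularSystem, Role, Trajectory, min_image_displacement
from .synthetic import BULK, TARGET_SURF, CROWDER_SURF, COMPARTMENT_NAMES


@dataclass
class RegionSeries:
    """Per-frame, per-ligand compartment labels."""

    labels: np.ndarray          # (n_frames, n_ligands) int8
    cutoff: float
    ligand_molecules: list[int] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_ligands(self) -> int:
        return self.labels.shape[1]


@dataclass
class PartitionSummary:
    fractions_pct: dict[str, float]
    se_pct: dict[str, float]
    n_replicates: int
    sasa_target: float | None = None
    sasa_crowder: float | None = None

    def per_area(self) -> dict[str, float]:
        """Per-unit-SASA probabilities (%/Å²) for the two surface classes."""
        out = {}
        if self.sasa_target:
            out["TARGET_SURF"] = per_area_probability(
                self.fractions_pct["TARGET_SURF"], self.sasa_target)
        if self.sasa_crowder:
            out["CROWDER_SURF"] = per_area_probability(
                self.fractions_pct["CROWDER_SURF"], self.sasa_crowder)
        return out


def classify_regions(traj: Trajectory, system: MolecularSystem,
                     cutoff: float = 5.0) -> RegionSeries:
    """Label every (frame, ligand) as BULK / TARGET_SURF / CROWDER_SURF."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prot_mask = system.heavy_mask(Role.TARGET) | system.heavy_mask(Role.CROWDER)
    if not prot_mask.any():
        raise ValueError("system contains no protein heavy atoms")
    prot_idx = np.nonzero(prot_mask)[0]
    prot_is_target = np.array(
        [system.role[i] is Role.TARGET for i in prot_idx])
    prot_off = system.radius_offset[prot_idx]

    lig_mols = system.molecules(Role.LIGAND)
    if not lig_mols:
        raise ValueError("system contains no ligand molecules")
    heavy = np.asarray(system.heavy_atom, dtype=bool)
    lig_atoms = [np.nonzero((system.molecule_id == m) & heavy)[0]
                 for m in lig_mols]

    labels = np.empty((traj.n_frames, len(lig_mols)), dtype=np.int8)
    for f in range(traj.n_frames):
        box = traj.box(f)
        prot_xyz = traj.coords[f, prot_idx]
        for j, atoms in enumerate(lig_atoms):
            lig_xyz = traj.coords[f, atoms]
            disp = min_image_displacement(prot_xyz[None, :, :],
                                          lig_xyz[:, None, :], box)
            d = np.linalg.norm(disp, axis=-1) - prot_off[None, :] \
                - system.radius_offset[atoms][:, None]
            dmin = d.min()
            if dmin > cutoff:
                labels[f, j] = BULK
            else:
                d_target = d[:, prot_is_target].min() \
                    if prot_is_target.any() else np.inf
                d_crowder = d[:, ~prot_is_target].min() \
                    if (~prot_is_target).any() else np.inf
                labels[f, j] = TARGET_SURF if d_target <= d_crowder \
                    else CROWDER_SURF
    return RegionSeries(labels=labels, cutoff=cutoff,
                        ligand_molecules=lig_mols)


def partition_fractions(regions: RegionSeries,
                        replicate_boundaries=None) -> PartitionSummary:
    """Compartment fractions in % of ligand·frames, with the standard error
    of the mean across replicate trajectory segments.

    ``replicate_boundaries`` lists the frame index starting each replicate
    (the first replicate implicitly starts at 0); omit for a single
    replicate, in which case the SE is reported as 0.
    """
    labels = regions.labels
    if labels.size == 0:
        raise ValueError("empty region series")
    bounds = [0] + sorted(replicate_boundaries or [])
    bounds.append(labels.shape[0])
    per_rep = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        chunk = labels[lo:hi]
        if chunk.size == 0:
            warnings.warn(f"empty replicate [{lo}, {hi}) skipped")
            continue
        per_rep.append([100.0 * np.count_nonzero(chunk == c) / chunk.size
                        for c in (BULK, TARGET_SURF, CROWDER_SURF)])
    rep = np.asarray(per_rep)
    weights = np.array([hi - lo for lo, hi in zip(bounds[:-1], bounds[1:])
                        if hi > lo], dtype=float)
    # overall fraction from the pooled counts, SE across replicates
    pooled = np.average(rep, axis=0, weights=weights)
    if len(rep) > 1:
        se = rep.std(axis=0, ddof=1) / np.sqrt(len(rep))
    else:
        se = np.zeros(3)
    names = [COMPARTMENT_NAMES[c] for c in (BULK, TARGET_SURF, CROWDER_SURF)]
    return PartitionSummary(
        fractions_pct=dict(zip(names, pooled)),
        se_pct=dict(zip(names, se)),
        n_replicates=len(rep))


def per_area_probability(fraction_pct: float, sasa: float) -> float:
    """Probability of finding the ligand per unit protein surface area
    (%/Å²): the compartment fraction divided by that protein's SASA."""
    if sasa <= 0:
        raise ValueError(f"SASA must be positive, got {sasa}")
    return fraction_pct / sasa


def write_partition_table(path, rows: list[dict]) -> None:
    """CSV with columns system, compartment, fraction_pct, se_pct, sasa_A2,
    prob_per_A2 (blank where not applicable)."""
    import csv
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=[
            "system", "compartment", "fraction_pct", "se_pct",
            "sasa_A2", "prob_per_A2"])
        writer.writeheader()
        writer.writerows(rows)
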