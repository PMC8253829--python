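"""Ligand transport analysis: region-conditioned MSD, diffusion
coefficients, and contact residence times.

Mean-square displacements are computed from periodic-boundary-unwrapped
ligand centroids with a sliding time origin; a (ligand, origin, lag)
window contributes to a region's curve only if the ligand carries that
region label at *every* frame of the window, so each curve measures
diffusion while the ligand genuinely stays in bulk water or on a protein
surface.  Diffusion coefficients follow the Einstein relation
``MSD = 6 D t`` fitted over a chosen lag range.  Residence times are the
durations of continuous ligand–protein contact episodes under a minimum
heavy-atom distance cutoff, with an optional buffer that bridges brief
excursions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partition import RegionSeries
from .system import MolecularSystem, Role, Trajectory, min_image_displacement


@dataclass
class MSDCurve:
    lags_ps: np.ndarray
    msd: np.ndarray             # Å²
    counts: np.ndarray          # samples per lag
    region: str                 # conditioning region or "all"


@dataclass
class ResidenceSummary:
    durations_ps: np.ndarray    # uncensored event durations
    censored_ps: np.ndarray     # durations of boundary-truncated events
    cutoff: float
    buffer_frames: int

    @property
    def mean_ps(self) -> float:
        return float(self.durations_ps.mean()) if self.durations_ps.size \
            else float("nan")

    @property
    def n_events(self) -> int:
        return int(self.durations_ps.size)

    def survival(self, t) -> np.ndarray:
        """Empirical survival S(t) = fraction of (uncensored) events with
        duration ≥ t; equals the complementary CDF of the duration list."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.durations_ps.size == 0:
            return np.full(t.shape, np.nan)
        return (self.durations_ps[None, :] >= t[:, None]).mean(axis=1)


def unwrap_ligand_centroids(traj: Trajectory,
                            system: MolecularSystem) -> np.ndarray:
    """(n_frames, n_ligands, 3) unwrapped heavy-atom centroids, built by
    accumulating minimal-image frame-to-frame displacements."""
    heavy = np.asarray(system.heavy_atom, dtype=bool)
    lig_mols = system.molecules(Role.LIGAND)
    groups = [np.nonzero((system.molecule_id == m) & heavy)[0]
              for m in lig_mols]
    cent = np.stack([traj.coords[:, g, :].mean(axis=1) for g in groups],
                    axis=1)
    out = np.empty_like(cent)
    out[0] = cent[0]
    for f in range(1, traj.n_frames):
        step = min_image_displacement(cent[f - 1], cent[f], traj.box(f))
        out[f] = out[f - 1] + step
    return out


def msd_by_region(traj: Trajectory, system: MolecularSystem,
                  regions: RegionSeries | None = None,
                  max_lag: int | None = None) -> dict[str, MSDCurve]:
    """MSD curves conditioned on compartment labels (plus an "all" curve).

    Windows spanning a label change are dropped from every region curve;
    the unconditioned curve keeps them.
    """
    from .synthetic import COMPARTMENT_NAMES

    if max_lag is None:
        max_lag = traj.n_frames // 2
    if max_lag >= traj.n_frames:
        raise ValueError(f"max_lag {max_lag} must be below the frame count "
                         f"{traj.n_frames}")
    pos = unwrap_ligand_centroids(traj, system)
    n_frames, n_lig = pos.shape[:2]
    if regions is not None and regions.labels.shape != (n_frames, n_lig):
        raise ValueError("region series not aligned with trajectory")

    lags = np.arange(max_lag + 1)
    curves: dict[str, MSDCurve] = {}

    def curve_for(mask_by_frame, name: str) -> MSDCurve:
        msd = np.zeros(max_lag + 1)
        cnt = np.zeros(max_lag + 1, dtype=int)
        cnt[0] = int(mask_by_frame.sum())
        for n in range(1, max_lag + 1):
            d = pos[n:] - pos[:-n]
            # window valid iff every frame t0..t0+n carries the label
            valid = np.ones((n_frames - n, n_lig), dtype=bool)
            for k in range(n + 1):
                valid &= mask_by_frame[k:n_frames - n + k]
            sq = np.sum(d * d, axis=-1)
            cnt[n] = int(valid.sum())
            msd[n] = sq[valid].mean() if cnt[n] else np.nan
        return MSDCurve(lags * traj.dt_ps, msd, cnt, name)

    all_mask = np.ones((n_frames, n_lig), dtype=bool)
    curves["all"] = curve_for(all_mask, "all")
    if regions is not None:
        for code, name in COMPARTMENT_NAMES.items():
            curves[name] = curve_for(regions.labels == code, name)
    return curves


def fit_diffusion(msd: MSDCurve, fit_range: tuple[float, float]) -> float:
    """Einstein-relation diffusion coefficient (Å²/ps): slope/6 of an
    unweighted straight-line fit of MSD vs lag over ``fit_range`` (ps)."""
    lo, hi = fit_range
    sel = (msd.lags_ps >= lo) & (msd.lags_ps <= hi) & np.isfinite(msd.msd)
    if np.count_nonzero(sel) < 2:
        raise ValueError("fit range must contain at least two finite lags")
    slope = np.polyfit(msd.lags_ps[sel], msd.msd[sel], 1)[0]
    return float(slope) / 6.0


def _contact_series(traj: Trajectory, system: MolecularSystem,
                    partner_role: Role, cutoff: float) -> np.ndarray:
    heavy = np.asarray(system.heavy_atom, dtype=bool)
    part_idx = np.nonzero(system.role_mask(partner_role) & heavy)[0]
    if part_idx.size == 0:
        raise ValueError(f"no heavy atoms with role {partner_role}")
    lig_mols = system.molecules(Role.LIGAND)
    groups = [np.nonzero((system.molecule_id == m) & heavy)[0]
              for m in lig_mols]
    off_p = system.radius_offset[part_idx]
    contact = np.zeros((traj.n_frames, len(groups)), dtype=bool)
    for f in range(traj.n_frames):
        box = traj.box(f)
        px = traj.coords[f, part_idx]
        for j, g in enumerate(groups):
            disp = min_image_displacement(px[None, :, :],
                                          traj.coords[f, g][:, None, :], box)
            d = np.linalg.norm(disp, axis=-1) - off_p[None, :] \
                - system.radius_offset[g][:, None]
            contact[f, j] = d.min() <= cutoff
    return contact


def events_from_series(contact: np.ndarray, dt_ps: float,
                       buffer_frames: int = 0):
    """Split one boolean contact series into events.

    An event runs from its first to its last in-contact frame; it ends only
    after more than ``buffer_frames`` consecutive out-of-contact frames.
    Returns (durations_ps, censored_ps): events touching either trajectory
    end are censored.
    """
    contact = np.asarray(contact, dtype=bool)
    n = len(contact)
    durations, censored = [], []
    i = 0
    while i < n:
        if not contact[i]:
            i += 1
            continue
        start = i
        last_in = i
        j = i + 1
        gap = 0
        while j < n:
            if contact[j]:
                last_in = j
                gap = 0
            else:
                gap += 1
                if gap > buffer_frames:
                    break
            j += 1
        dur = (last_in - start + 1) * dt_ps
        # an event is censored when the trajectory ends before the contact
        # resolved (still in contact, or inside an unexpired buffer gap)
        if j >= n:
            censored.append(dur)
        else:
            durations.append(dur)
        i = last_in + 1
    return np.asarray(durations), np.asarray(censored)


def residence_times(traj: Trajectory, system: MolecularSystem,
                    partner_role: Role, contact_cutoff: float = 5.0,
                    buffer_frames: int = 0) -> ResidenceSummary:
    """Residence-time statistics of ligand contacts with one protein class.

    Events truncated by either trajectory end are reported separately and
    excluded from the mean.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    contact = _contact_series(traj, system, partner_role, contact_cutoff)
    durs, cens = [], []
    for j in range(contact.shape[1]):
        d, c = events_from_series(contact[:, j], traj.dt_ps, buffer_frames)
        durs.append(d)
        cens.append(c)
    return ResidenceSummary(
        durations_ps=np.concatenate(durs) if durs else np.array([]),
        censored_ps=np.concatenate(cens) if cens else np.array([]),
        cutoff=contact_cutoff, buffer_frames=buffer_frames)
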