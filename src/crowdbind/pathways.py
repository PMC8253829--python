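"""Binding-pathway coordinates, event detection, and free-energy landscapes.

The ligand's position relative to the binding site is reduced to a
distance ξ (site centroid to ligand heavy-atom centroid, Å) and two
azimuth angles: the polar angle θ ∈ [0°, 180°] from a body-frame z-axis
and the azimuth φ ∈ (−180°, 180°] in the x–y plane.  A binding event is a
transition from the unbound state (ξ above a threshold, 15 Å by default)
into a bound state (ξ at or below a bound threshold, sustained for a dwell
window); the encounter coordinates — where the ligand last left the
unbound region — discriminate approach pathways by their θ band.

Free-energy landscapes are raw-histogram estimates F = −ln(P/P_max) in kT
over (ξ, θ), min-shifted to zero with empty bins masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import MolecularSystem, Role, Trajectory, min_image_displacement


class FrameError(ValueError):
    pass


@dataclass
class PathwayCoords:
    """Per-frame, per-ligand (ξ, θ, φ)."""

    xi: np.ndarray          # (n_frames, n_ligands) Å
    theta: np.ndarray       # deg, [0, 180]
    phi: np.ndarray         # deg, (−180, 180]
    dt_ps: float = 1.0


@dataclass
class BindingEvent:
    ligand: int
    encounter_frame: int
    bound_frame: int
    encounter_xi: float
    encounter_theta: float
    encounter_phi: float
    pathway_class: str


@dataclass
class FELGrid:
    xi_edges: np.ndarray
    theta_edges: np.ndarray
    free_energy: np.ndarray     # kT, min-shifted to 0; NaN on empty bins
    empty_mask: np.ndarray


def _body_frame(origin, z_anchor, x_anchor):
    z = np.asarray(z_anchor, dtype=float) - origin
    nz = np.linalg.norm(z)
    if nz < 1e-10:
        raise FrameError("z anchor coincides with the origin")
    z = z / nz
    xr = np.asarray(x_anchor, dtype=float) - origin
    x = xr - (xr @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-10:
        raise FrameError("collinear frame anchors: x anchor lies on the z axis")
    x = x / nx
    y = np.cross(z, x)
    return x, y, z


def coords_in_frame(points: np.ndarray, origin, z_anchor, x_anchor,
                    box=None):
    """(ξ, θ, φ) of points in the body frame defined by three anchors.

    θ is measured from z; φ from x toward y.  A point on the origin or on
    the z-axis has an undefined φ, reported as 0.
    """
    x, y, z = _body_frame(origin, z_anchor, x_anchor)
    pts = np.asarray(points, dtype=float)
    if box is not None:
        rel = min_image_displacement(origin, pts, box)
    else:
        rel = pts - np.asarray(origin, dtype=float)
    xi = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ct = np.where(xi > 0, (rel @ z) / np.where(xi > 0, xi, 1.0), 1.0)
    theta = np.degrees(np.arccos(np.clip(ct, -1.0, 1.0)))
    px, py = rel @ x, rel @ y
    phi = np.degrees(np.arctan2(py, px))
    on_axis = np.hypot(px, py) < 1e-10
    phi = np.where(on_axis, 0.0, phi)
    phi = np.where(phi <= -180.0, 180.0, phi)
    return xi, theta, phi


def _centroid(coords_frame, idx):
    return coords_frame[idx].mean(axis=0)


def reaction_coords(traj: Trajectory, system: MolecularSystem,
                    site_selection=None, frame_axes=None,
                    virtual_anchors=None,
                    virtual_origin=None) -> PathwayCoords:
    """Pathway coordinates of every ligand over a trajectory.

    Parameters
    ----------
    site_selection : atom indices (or boolean mask) of the binding-site
        atoms; their heavy-atom centroid is the body-frame origin.
    frame_axes : pair of atom-index groups ``(z_group, x_group)``; the
        z-axis points from the origin toward the z-group centroid and the
        x-axis is the orthogonalized direction to the x-group centroid.
        Required unless ``virtual_anchors`` is given.
    virtual_anchors : optional ``(z_point, x_point)`` static coordinates —
        used by coarse synthetic systems whose frame is defined by the
        pocket axis rather than by atom groups.
    virtual_origin : optional static origin point; coarse systems place it
        at the pocket marker on the target surface (their site centroid),
        which no atom marks.
    """
    if virtual_origin is None:
        sel = np.asarray(site_selection)
        if sel.dtype == bool:
            sel = np.nonzero(sel)[0]
        if sel.size == 0:
            raise FrameError("empty site selection")
    else:
        sel = None
    heavy = np.asarray(system.heavy_atom, dtype=bool)
    lig_groups = [np.nonzero((system.molecule_id == m) & heavy)[0]
                  for m in system.molecules(Role.LIGAND)]

    n_f, n_l = traj.n_frames, len(lig_groups)
    xi = np.empty((n_f, n_l))
    theta = np.empty((n_f, n_l))
    phi = np.empty((n_f, n_l))
    for f in range(n_f):
        fr = traj.coords[f]
        origin = np.asarray(virtual_origin, dtype=float) \
            if virtual_origin is not None else _centroid(fr, sel)
        if virtual_anchors is not None:
            z_pt, x_pt = virtual_anchors
        elif frame_axes is not None:
            z_pt = _centroid(fr, np.asarray(frame_axes[0]))
            x_pt = _centroid(fr, np.asarray(frame_axes[1]))
        else:
            raise FrameError("provide frame_axes or virtual_anchors")
        lig = np.array([_centroid(fr, g) for g in lig_groups])
        box = traj.box(f) if traj.periodic else None
        xi[f], theta[f], phi[f] = coords_in_frame(lig, origin, z_pt, x_pt,
                                                  box=box)
    return PathwayCoords(xi=xi, theta=theta, phi=phi, dt_ps=traj.dt_ps)


DEFAULT_THETA_BANDS = {"A": (30.0, 90.0), "B": (90.0, 150.0)}


def detect_binding_events(coords: PathwayCoords, unbound_xi: float = 15.0,
                          bound_xi: float = 5.0, dwell: int = 10,
                          theta_bands: dict | None = None,
                          surface_contact: np.ndarray | None = None,
                          contact_gap: int = 0) -> list[BindingEvent]:
    """Detect unbound → bound transitions and classify them by encounter θ.

    A bound episode is a run of ≥ ``dwell`` frames with ξ ≤ ``bound_xi``.
    When ``surface_contact`` — a per-frame, per-ligand boolean (e.g. the
    target-surface labels of a RegionSeries) — is supplied, bound frames
    must additionally be in surface contact (which excludes ligands merely
    hovering over the site), and the encounter frame is the last frame
    with ξ > ``unbound_xi`` before the first target-surface contact of the
    visit that leads to binding; without it, the bound state is judged on
    ξ alone and the encounter falls back to the last unbound frame before
    the episode.  ``contact_gap`` lets the visit span brief surface
    excursions of at most that many frames.
    Episodes never preceded by an unbound frame (e.g. a ligand that starts
    bound) produce no event.
    """
    if bound_xi >= unbound_xi:
        raise ValueError("bound_xi must be below unbound_xi")
    bands = DEFAULT_THETA_BANDS if theta_bands is None else theta_bands
    events: list[BindingEvent] = []
    n_f, n_l = coords.xi.shape
    for lig in range(n_l):
        xi = coords.xi[:, lig]
        bound = xi <= bound_xi
        if surface_contact is not None:
            bound = bound & surface_contact[:, lig]
        f = 0
        last_event_end = -1
        while f < n_f:
            if not bound[f]:
                f += 1
                continue
            start = f
            while f < n_f and bound[f]:
                f += 1
            if f - start < dwell:
                continue
            anchor = start
            if surface_contact is not None:
                # rewind to the start of the surface visit, bridging
                # non-contact gaps of at most contact_gap frames
                contact = surface_contact[:, lig]
                gap = 0
                k = start - 1
                while k > last_event_end:
                    if contact[k]:
                        anchor = k
                        gap = 0
                    else:
                        gap += 1
                        if gap > contact_gap:
                            break
                    k -= 1
            prior = np.nonzero(xi[:anchor] > unbound_xi)[0] \
                if anchor > 0 else np.array([], dtype=int)
            prior = prior[prior > last_event_end]
            if prior.size == 0:
                last_event_end = f - 1
                continue
            enc = int(prior[-1])
            band = "other"
            th = coords.theta[enc, lig]
            for name, (lo, hi) in bands.items():
                if lo <= th <= hi:
                    band = name
                    break
            events.append(BindingEvent(
                ligand=lig, encounter_frame=enc, bound_frame=start,
                encounter_xi=float(xi[enc]),
                encounter_theta=float(th),
                encounter_phi=float(coords.phi[enc, lig]),
                pathway_class=band))
            last_event_end = f - 1
    return events


def fel_from_histogram(xi, theta, xi_edges, theta_edges,
                       weights=None) -> FELGrid:
    """2D free-energy landscape F = −ln(P/P_max) in kT over (ξ, θ)."""
    xi = np.asarray(xi, dtype=float).ravel()
    theta = np.asarray(theta, dtype=float).ravel()
    w = None if weights is None else np.asarray(weights, dtype=float).ravel()
    h, xe, te = np.histogram2d(xi, theta, bins=[xi_edges, theta_edges],
                               weights=w)
    if h.sum() <= 0:
        raise ValueError("no samples fall inside the landscape range")
    p = h / h.sum()
    empty = p <= 0
    with np.errstate(divide="ignore"):
        f = -np.log(p / p.max())
    f[empty] = np.nan
    return FELGrid(xi_edges=np.asarray(xe), theta_edges=np.asarray(te),
                   free_energy=f, empty_mask=empty)


def kt_to_kcal_per_mol(f_kt, temperature_k: float = 300.0):
    """Convert a dimensionless free energy (kT units) to kcal/mol."""
    kB = 0.0019872041  # kcal/(mol·K)
    return np.asarray(f_kt) * kB * temperature_k


def project_events(coords: PathwayCoords, events: list[BindingEvent]):
    """Per-event ordered (ξ, θ) polylines from encounter to binding."""
    out = []
    for ev in events:
        sl = slice(ev.encounter_frame, ev.bound_frame + 1)
        out.append(np.column_stack([coords.xi[sl, ev.ligand],
                                    coords.theta[sl, ev.ligand]]))
    return out
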