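"""Conformational-state analysis.

Covers the two-state treatment of a hinge sidechain distance (compact
"IN" vs extended "OUT", distance modes near 5 and 8.5 Å), population-shift
tables across a crowder series, pseudo-torsion angles of four anchor
groups (the DFG-motif style descriptor), per-atom RMSF after superposition,
and Cα contact counts between crowder and target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .system import MolecularSystem, Role, Trajectory, min_image_displacement
from .synthetic import STATE_IN, STATE_OUT


@dataclass
class StateSeries:
    distances: np.ndarray       # Å
    states: np.ndarray          # int8, 0 = IN, 1 = OUT
    rule: str                   # e.g. "threshold=6.5" or "mixture"


@dataclass
class StatePopulations:
    in_pct: float
    out_pct: float
    mean_in: float | None = None
    mean_out: float | None = None
    sd_in: float | None = None
    sd_out: float | None = None
    crowder_count: int | None = None


def classify_two_state(distances, method: str = "threshold",
                       threshold: float = 6.5, seed: int = 0):
    """Label a distance series as IN/OUT.

    ``threshold``: IN iff d < threshold (default 6.5 Å, between the two
    modes).  ``mixture``: two-component Gaussian mixture fitted by EM;
    the component with the smaller mean is IN and frames take the
    maximum-posterior label.  A degenerate mixture (an empty component)
    falls back to the threshold rule with a warning.

    Returns ``(StateSeries, StatePopulations)``.
    """
    d = np.asarray(distances, dtype=float).ravel()
    if method == "mixture":
        if d.size < 100:
            raise ValueError("mixture method needs at least 100 frames")
        gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
        labels_raw = gm.fit_predict(d[:, None])
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        order = np.argsort(means)
        in_comp = order[0]
        states = np.where(labels_raw == in_comp, STATE_IN,
                          STATE_OUT).astype(np.int8)
        if (states == STATE_IN).all() or (states == STATE_OUT).all():
            warnings.warn("degenerate mixture (one empty component); "
                          "falling back to the threshold rule")
            return classify_two_state(d, "threshold", threshold)
        pops = StatePopulations(
            in_pct=100.0 * np.mean(states == STATE_IN),
            out_pct=100.0 * np.mean(states == STATE_OUT),
            mean_in=float(means[order[0]]), mean_out=float(means[order[1]]),
            sd_in=float(sds[order[0]]), sd_out=float(sds[order[1]]))
        return StateSeries(d, states, "mixture"), pops
    if method == "threshold":
        states = np.where(d < threshold, STATE_IN, STATE_OUT).astype(np.int8)
        pops = StatePopulations(
            in_pct=100.0 * np.mean(states == STATE_IN),
            out_pct=100.0 * np.mean(states == STATE_OUT))
        for code, attr_m, attr_s in ((STATE_IN, "mean_in", "sd_in"),
                                     (STATE_OUT, "mean_out", "sd_out")):
            sel = states == code
            if sel.any():
                setattr(pops, attr_m, float(d[sel].mean()))
                setattr(pops, attr_s, float(d[sel].std()))
        return StateSeries(d, states, f"threshold={threshold}"), pops
    raise ValueError(f"unknown method {method!r}")


def population_shift_table(series_by_system: dict, crowder_counts: dict,
                           **classify_kwargs):
    """Populations per system, ordered by crowder count, plus the trend.

    Parameters
    ----------
    series_by_system : mapping system label -> distance series (or
        StateSeries, reused as-is).
    crowder_counts : mapping system label -> crowder count.

    Returns ``(table, trend)`` where table is a list of
    ``(label, crowder_count, StatePopulations)`` ordered by crowder count
    and ``trend`` reports whether the OUT fraction is non-decreasing and
    where the OUT state first becomes the majority.
    """
    if len(series_by_system) < 2:
        raise ValueError("need at least two systems for a shift table")
    rows = []
    for label, series in series_by_system.items():
        if isinstance(series, StateSeries):
            states = series.states
            pops = StatePopulations(
                in_pct=100.0 * np.mean(states == STATE_IN),
                out_pct=100.0 * np.mean(states == STATE_OUT))
        else:
            _, pops = classify_two_state(series, **classify_kwargs)
        pops.crowder_count = int(crowder_counts[label])
        rows.append((label, pops.crowder_count, pops))
    rows.sort(key=lambda r: r[1])
    out = [r[2].out_pct for r in rows]
    majority_at = next((r[1] for r in rows if r[2].out_pct > 50.0), None)
    trend = {
        "out_pct_non_decreasing": bool(np.all(np.diff(out) >= 0)),
        "flat": bool(np.allclose(np.diff(out), 0.0)),
        "majority_switch_at_crowders": majority_at,
    }
    return rows, trend


def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle (deg, (−180, 180]) of four points; the
    IUPAC convention (cis = 0, trans = 180)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 \
            or nb2 < 1e-10:
        return float("nan")
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b2 / nb2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def pseudo_torsion(traj: Trajectory, four_atom_sets) -> np.ndarray:
    """Per-frame signed dihedral (deg) over the centroids of four atom
    groups; degenerate (collinear) frames yield NaN."""
    groups = [np.asarray(g).ravel() for g in four_atom_sets]
    if len(groups) != 4:
        raise ValueError("need exactly four atom groups")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        cents = [traj.coords[f, g].mean(axis=0) for g in groups]
        out[f] = dihedral(*cents)
    return out


def rmsf(traj_fitted: Trajectory, selection=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) about the time-average
    position; the trajectory must already be superposed."""
    if traj_fitted.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    sel = slice(None) if selection is None else np.asarray(selection)
    xyz = traj_fitted.coords[:, sel, :]
    mean = xyz.mean(axis=0)
    return np.sqrt(np.mean(np.sum((xyz - mean) ** 2, axis=-1), axis=0))


def ca_contact_count(traj: Trajectory, system: MolecularSystem,
                     cutoff: float = 8.0,
                     states: StateSeries | None = None,
                     atom_name: str = "CA") -> dict:
    """Mean crowder–target Cα contacts per frame, optionally split by
    conformational state.

    A contact is a Cα pair (one target, one crowder atom named
    ``atom_name``; coarse systems may designate any marker name) within
    ``cutoff`` Å under the minimal-image metric.
    """
    names = np.asarray(system.atom_name, dtype=object)
    t_idx = np.nonzero(system.role_mask(Role.TARGET) & (names == atom_name))[0]
    c_idx = np.nonzero(system.role_mask(Role.CROWDER) & (names == atom_name))[0]
    if t_idx.size == 0:
        raise ValueError(f"no target atoms named {atom_name!r}")
    per_frame = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        if c_idx.size == 0:
            continue
        box = traj.box(f)
        disp = min_image_displacement(traj.coords[f, t_idx][None, :, :],
                                      traj.coords[f, c_idx][:, None, :], box)
        d = np.linalg.norm(disp, axis=-1)
        per_frame[f] = np.count_nonzero(d <= cutoff)
    result = {"mean_contacts": float(per_frame.mean()),
              "per_frame": per_frame}
    if states is not None:
        if len(states.states) != traj.n_frames:
            raise ValueError("state series not aligned with trajectory")
        for code, key in ((STATE_IN, "mean_contacts_in"),
                          (STATE_OUT, "mean_contacts_out")):
            sel = states.states == code
            result[key] = float(per_frame[sel].mean()) if sel.any() \
                else float("nan")
    return result
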