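"""End-to-end orchestration: generate → classify → analyze → report.

A pipeline config (YAML/JSON) names a series of synthetic systems (a
crowder-count ladder by default), toggles analysis stages, and fixes one
seed; a run writes every stage's tabular output plus a machine-readable
``summary.json`` and a ``manifest.json`` recording versions, seeds and
parameters.  Identical config + seed reproduce all numbers exactly; every
stage always recomputes from its inputs (no implicit caching).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .density import accumulate_occupancy, export_map
from .hill import fit_hill, ic50_shift
from .partition import (classify_regions, partition_fractions,
                        per_area_probability, write_partition_table)
from .pathways import detect_binding_events, reaction_coords
from .sasa import sasa_of_spheres
from .states import classify_two_state, population_shift_table
from .synthetic import (SynthConfig, TARGET_SURF, generate_dose_response,
                        sidechain_series_from_gate, simulate_crowded_box,
                        write_ground_truth)
from .system import Role
from .transport import fit_diffusion, msd_by_region, residence_times
from .io import write_trajectory

log = logging.getLogger("crowdbind")

ALL_STAGES = ("simulate", "partition", "sdf", "transport", "pathways",
              "states", "dose")

#: θ bands for encounter classification in the coarse synthetic frame:
#: the body-frame origin sits on the target surface, so approaches through
#: the gate-closed window map to encounter θ below ~105° and approaches
#: through the gate-open window above it
SYNTH_THETA_BANDS = {"A": (0.0, 105.0), "B": (105.0, 180.0)}


class PipelineError(RuntimeError):
    pass


def load_pipeline_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise PipelineError(f"{path}: expected a mapping")
    return validate_pipeline_config(cfg)


def validate_pipeline_config(cfg: dict) -> dict:
    cfg = dict(cfg)
    cfg.setdefault("stages", list(ALL_STAGES))
    unknown = set(cfg["stages"]) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}")
    # default series: the dilute/2/4/8-crowder ladder at a desk-scale
    # geometry that equilibrates within the default step budget
    cfg.setdefault("systems", [
        {"label": f"crowd{n}", "n_crowders": n, "box_length": 120.0,
         "target_radius": 15.0, "crowder_radius": 18.0, "n_ligands": 24,
         "n_steps": 20000, "record_stride": 10,
         "k_open": 0.02, "k_close": 0.06}
        for n in (0, 2, 4, 8)])
    needs_seed = "dose" in cfg["stages"] or any(
        "trajectory" not in sys_def for sys_def in cfg["systems"])
    if needs_seed and "seed" not in cfg:
        raise PipelineError("seed is mandatory when a synthetic stage "
                            "is enabled")
    for sys_def in cfg.get("systems", []):
        if "trajectory" in sys_def and not Path(sys_def["trajectory"]).exists():
            raise PipelineError(
                f"referenced trajectory {sys_def['trajectory']} does not exist")
    return cfg


def synth_pocket_frame(scfg: SynthConfig):
    """Body-frame anchors of the synthetic canonical site: origin at the
    pocket marker on the target surface, z along the pocket axis, x along
    a fixed equatorial direction."""
    center = np.full(3, scfg.box_length / 2.0)
    axis = np.asarray(scfg.pocket_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    origin = center + scfg.target_radius * axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    equat = ref - (ref @ axis) * axis
    equat /= np.linalg.norm(equat)
    return origin, origin + 10.0 * axis, origin + 10.0 * equat


def pocket_bound_xi(scfg: SynthConfig) -> float:
    """Bound-state ξ threshold for the sphere model: the marker distance
    of an inner-shell point at the pocket cone edge, 2R·sin(γ/2).  Surface
    points with ξ at or below this value lie (essentially) inside the
    pocket, so ξ ≤ threshold together with target-surface contact is a
    sound bound-state criterion."""
    return float(2.0 * scfg.target_radius
                 * np.sin(np.radians(scfg.pocket_half_angle_deg) / 2.0))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(cfg: dict, output_dir=None) -> dict:
    """Execute the enabled stages for every system in the series.

    Returns the summary dict (also written to ``summary.json``).  Any
    stage failure aborts with the stage name; outputs written so far
    remain on disk.
    """
    cfg = validate_pipeline_config(cfg)
    out = Path(output_dir or cfg.get("output_dir", "crowdbind_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    seed = int(cfg.get("seed", 0))
    summary: dict = {"systems": {}}
    stage = "setup"
    try:
        sidechain_by_system = {}
        crowder_counts = {}
        for i_sys, sys_def in enumerate(cfg["systems"]):
            label = sys_def.get("label", f"system{i_sys}")
            sys_dir = out / label
            sys_dir.mkdir(exist_ok=True)
            block: dict = {}

            stage = "simulate"
            overrides = {k: v for k, v in sys_def.items()
                         if k not in ("label", "trajectory")}
            overrides.setdefault("seed", seed + 1000 * i_sys)
            for key in ("pocket_axis", "window_closed_deg",
                        "window_open_deg"):
                if key in overrides:
                    overrides[key] = tuple(overrides[key])
            scfg = SynthConfig(**overrides)
            log.info("simulating %s (%d crowders, seed %d)",
                     label, scfg.n_crowders, scfg.seed)
            traj, system, truth = simulate_crowded_box(scfg)
            if "simulate" in stages:
                write_trajectory(sys_dir / "trajectory.txt", traj)
                write_ground_truth(sys_dir / "ground_truth.csv", truth)
            crowder_counts[label] = scfg.n_crowders
            block["n_crowders"] = scfg.n_crowders
            block["gate_n_contact"] = truth.n_contact

            if "partition" in stages:
                stage = "partition"
                pcfg = cfg.get("partition", {})
                regions = classify_regions(
                    traj, system, cutoff=pcfg.get("cutoff", 5.0))
                # drop the relaxation from the uniform start before
                # accumulating equilibrium statistics
                n0 = int(regions.n_frames
                         * pcfg.get("discard_fraction", 0.25))
                from .partition import RegionSeries
                eq = RegionSeries(regions.labels[n0:], regions.cutoff,
                                  regions.ligand_molecules)
                reps = pcfg.get("replicates", 4)
                bounds = [eq.n_frames * k // reps for k in range(1, reps)]
                summ = partition_fractions(eq, bounds)
                # sphere-model SASA: closed form via the numerical sampler
                probe = pcfg.get("probe", 1.4)
                s_t = float(sasa_of_spheres(
                    np.zeros((1, 3)), np.array([scfg.target_radius]),
                    probe)[0])
                s_c = float(sasa_of_spheres(
                    np.zeros((1, 3)), np.array([scfg.crowder_radius]),
                    probe)[0])
                summ.sasa_target = s_t
                summ.sasa_crowder = s_c
                rows = []
                for comp, frac in summ.fractions_pct.items():
                    sasa = {"TARGET_SURF": s_t,
                            "CROWDER_SURF": s_c}.get(comp)
                    rows.append({
                        "system": label, "compartment": comp,
                        "fraction_pct": f"{frac:.6f}",
                        "se_pct": f"{summ.se_pct[comp]:.6f}",
                        "sasa_A2": f"{sasa:.2f}" if sasa else "",
                        "prob_per_A2": f"{per_area_probability(frac, sasa):.8f}"
                        if sasa else ""})
                write_partition_table(sys_dir / "partition.csv", rows)
                block["partition"] = {
                    "fractions_pct": summ.fractions_pct,
                    "se_pct": summ.se_pct,
                    "per_area_pct_per_A2": summ.per_area(),
                    "sasa_target_A2": s_t, "sasa_crowder_A2": s_c}

            if "sdf" in stages:
                stage = "sdf"
                gcfg = cfg.get("sdf", {})
                lig_sel = system.role_mask(Role.LIGAND)
                # static target: frames are already in the target frame
                grid = accumulate_occupancy(
                    traj, lig_sel,
                    spacing=gcfg.get("spacing", 2.0),
                    padding=gcfg.get("padding",
                                     scfg.target_radius
                                     + scfg.shell_width + 5.0),
                    reference=traj.coords[0][system.role_mask(Role.TARGET)])
                thresholds = gcfg.get("thresholds", [0.5, 1.5])
                counts = export_map(grid, sys_dir / "sdf.dx", thresholds)
                block["sdf_voxels_at_threshold"] = {
                    str(t): c for t, c in counts.items()}

            if "transport" in stages:
                stage = "transport"
                tcfg = cfg.get("transport", {})
                max_lag = min(tcfg.get("max_lag", 40), traj.n_frames - 1)
                curves = msd_by_region(traj, system, regions
                                       if "partition" in stages else None,
                                       max_lag=max_lag)
                fit_lo, fit_hi = tcfg.get(
                    "fit_range", [traj.dt_ps, max_lag * traj.dt_ps / 2])
                block["diffusion_A2_per_ps"] = {}
                for name, curve in curves.items():
                    np.savetxt(sys_dir / f"msd_{name}.csv",
                               np.column_stack([curve.lags_ps, curve.msd,
                                                curve.counts]),
                               delimiter=",", header="lag_ps,msd_A2,n",
                               comments="")
                    try:
                        block["diffusion_A2_per_ps"][name] = fit_diffusion(
                            curve, (fit_lo, fit_hi))
                    except ValueError:
                        block["diffusion_A2_per_ps"][name] = None
                res = residence_times(
                    traj, system, Role.TARGET,
                    contact_cutoff=tcfg.get("contact_cutoff", 5.0),
                    buffer_frames=tcfg.get("buffer_frames", 0))
                block["residence_mean_ps_target"] = res.mean_ps
                block["residence_events_target"] = res.n_events

            if "pathways" in stages:
                stage = "pathways"
                wcfg = cfg.get("pathways", {})
                origin, z_pt, x_pt = synth_pocket_frame(scfg)
                coords = reaction_coords(traj, system,
                                         virtual_origin=origin,
                                         virtual_anchors=(z_pt, x_pt))
                surface = (regions.labels == TARGET_SURF) \
                    if "partition" in stages else None
                events = detect_binding_events(
                    coords,
                    unbound_xi=wcfg.get("unbound_xi", 15.0),
                    bound_xi=wcfg.get("bound_xi", pocket_bound_xi(scfg)),
                    dwell=wcfg.get("dwell", 5),
                    theta_bands=wcfg.get("theta_bands", SYNTH_THETA_BANDS),
                    surface_contact=surface)
                by_band: dict[str, int] = {}
                for ev in events:
                    by_band[ev.pathway_class] = \
                        by_band.get(ev.pathway_class, 0) + 1
                block["binding_events"] = len(events)
                block["binding_events_by_theta_band"] = by_band
                with open(sys_dir / "binding_events.csv", "w") as fh:
                    fh.write("ligand,encounter_frame,bound_frame,"
                             "encounter_xi,encounter_theta,encounter_phi,"
                             "pathway_class\n")
                    for ev in events:
                        fh.write(f"{ev.ligand},{ev.encounter_frame},"
                                 f"{ev.bound_frame},{ev.encounter_xi:.3f},"
                                 f"{ev.encounter_theta:.3f},"
                                 f"{ev.encounter_phi:.3f},"
                                 f"{ev.pathway_class}\n")

            if "states" in stages:
                stage = "states"
                scfg_states = cfg.get("states", {})
                dist = sidechain_series_from_gate(
                    truth.gate_open,
                    mode_in=scfg_states.get("mode_in", 5.0),
                    mode_out=scfg_states.get("mode_out", 8.5),
                    sd=scfg_states.get("sd", 0.5),
                    seed=scfg.seed + 7)
                method = scfg_states.get("method", "threshold")
                series, pops = classify_two_state(dist, method=method)
                sidechain_by_system[label] = series
                block["state_populations_pct"] = {
                    "IN": pops.in_pct, "OUT": pops.out_pct}
            summary["systems"][label] = block

        if "states" in stages and len(sidechain_by_system) >= 2:
            stage = "states"
            rows, trend = population_shift_table(sidechain_by_system,
                                                 crowder_counts)
            summary["state_shift"] = {
                "table": [{"system": lab, "n_crowders": n,
                           "in_pct": p.in_pct, "out_pct": p.out_pct}
                          for lab, n, p in rows],
                "trend": trend}

        if "dose" in stages:
            stage = "dose"
            dcfg = cfg.get("dose", {})
            conditions = dcfg.get("conditions", [
                {"label": "dilute", "ic50": 45.1, "alpha": 1.0},
                {"label": "crowded", "ic50": 470.0, "alpha": 1.0},
            ])
            conc = np.asarray(dcfg.get(
                "concentrations_nM",
                np.logspace(0, 5, 12).tolist()))
            fits = {}
            summary["hill_fits"] = {}
            for k, cond in enumerate(conditions):
                data = generate_dose_response(
                    ic50=cond["ic50"], alpha=cond.get("alpha", 1.0),
                    concentrations=conc,
                    noise_sd=dcfg.get("noise_sd", 0.0),
                    replicates=dcfg.get("replicates", 3),
                    seed=seed + 500 + k, condition=cond["label"])
                fit = fit_hill(data)
                fits[cond["label"]] = fit
                summary["hill_fits"][cond["label"]] = {
                    "ic50_nM": fit.ic50, "alpha": fit.alpha,
                    "ic50_se_nM": fit.ic50_se, "converged": fit.converged}
            labels = [c["label"] for c in conditions]
            if len(labels) >= 2:
                summary["ic50_shift"] = ic50_shift(fits[labels[0]],
                                                   fits[labels[1]])
            (out / "hill_fits.json").write_text(
                json.dumps(summary["hill_fits"], indent=1, sort_keys=True,
                           default=_jsonable))
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=_jsonable))
    manifest = {"version": __version__, "seed": seed, "config": cfg}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=_jsonable))
    return summary
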