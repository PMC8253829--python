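"""Synthetic crowded-solution generator.

Desk-scale stand-in for atomistic MD of an inhibitor in a crowded protein
solution: point ligands undergo overdamped Brownian motion in a periodic box
containing one static target sphere (the kinase) and a series of static
crowder spheres (the albumins), with

* a square-well attraction of depth ``eps`` (kT) in a shell of width ``w``
  around every protein surface — the weak, non-specific surface stickiness
  that traps ligands on crowders;
* a deeper pocket (``eps + eps_pocket``) on a cone of the target surface —
  the canonical binding site;
* a two-state telegraph gate (the TYR-in/TYR-out analogue) whose opening
  rate grows with the number of crowders in contact with the target, and
  which selects the polar-angle window through which a ligand arriving at
  the target surface becomes eligible to enter the pocket.

The dynamics are Euler–Maruyama displacements filtered through a Metropolis
acceptance on the square-well energy, so the stationary distribution over
the shell/bulk compartments is exactly Boltzmann — the analytic oracle the
test-suite checks against.  Identical seeds reproduce runs bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .system import (BoxGeometry, MolecularSystem, Role, Trajectory,
                     min_image_displacement)

BULK, TARGET_SURF, CROWDER_SURF = 0, 1, 2
COMPARTMENT_NAMES = {BULK: "BULK", TARGET_SURF: "TARGET_SURF",
                     CROWDER_SURF: "CROWDER_SURF"}


class ConfigError(ValueError):
    pass


class PackingError(RuntimeError):
    """Crowder placement failed within the retry budget."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic crowded box.

    Defaults mimic the simulated crowding series: a 200 Å box, a 25 Å
    target, 30 Å crowders (0/2/4/8 of them), a 5 Å surface shell matching
    the surface-region cutoff, and a ligand load of two dozen inhibitors.
    ``dt_ps`` and ``diffusion`` keep the RMS step below half the shell
    width, which is enforced.
    """

    seed: int
    box_length: float = 200.0
    n_crowders: int = 0
    target_radius: float = 25.0
    crowder_radius: float = 30.0
    n_ligands: int = 24
    shell_width: float = 5.0
    eps: float = 2.0                    # surface well depth, kT
    eps_pocket: float = 2.0             # extra pocket depth, kT
    pocket_half_angle_deg: float = 25.0
    pocket_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    diffusion: float = 0.2              # bulk D, Å²/ps
    dt_ps: float = 0.5
    n_steps: int = 2000
    k_open: float = 0.002               # 1/ps
    k_close: float = 0.006              # 1/ps
    contact_multiplier: float = 0.5     # m in k_open*(1 + m*n_contact)
    contact_cutoff: float = 60.0        # surface-surface Å, for n_contact
    window_closed_deg: tuple[float, float] = (40.0, 80.0)   # entry band, gate closed
    window_open_deg: tuple[float, float] = (100.0, 140.0)   # entry band, gate open
    gate_mode: str = "dynamic"          # dynamic | open | closed | off
    arm_margin: float = 2.0             # Å above the shell where arming works
    disarm_distance: float | None = None  # Å above surface; default w + 10
    record_stride: int = 1
    max_placement_tries: int = 20000

    def __post_init__(self) -> None:
        if self.eps < 0 or self.eps_pocket < 0:
            raise ConfigError("well depths must be non-negative")
        if self.gate_mode not in ("dynamic", "open", "closed", "off"):
            raise ConfigError(f"unknown gate_mode {self.gate_mode!r}")
        if self.n_ligands < 1:
            raise ConfigError("need at least one ligand")
        if self.dt_ps <= 0 or self.diffusion <= 0:
            raise ConfigError("dt_ps and diffusion must be positive")
        rms_step = np.sqrt(6.0 * self.diffusion * self.dt_ps)
        if rms_step >= self.shell_width / 2.0:
            raise ConfigError(
                f"RMS step {rms_step:.3f} Å must stay below half the shell "
                f"width ({self.shell_width / 2:.3f} Å); reduce dt_ps or D")


@dataclass
class GroundTruth:
    """Generator-side truth used as a test oracle by the analyses."""

    compartments: np.ndarray          # (n_frames, n_ligands) int8
    gate_open: np.ndarray             # (n_frames,) bool
    events: list[dict] = field(default_factory=list)
    n_contact: int = 0
    config: dict = field(default_factory=dict)

    def compartment_fractions(self) -> dict[str, float]:
        total = self.compartments.size
        return {name: 100.0 * np.count_nonzero(self.compartments == code) / total
                for code, name in COMPARTMENT_NAMES.items()}


def _place_crowders(cfg: SynthConfig, rng: np.random.Generator,
                    center: np.ndarray, box: BoxGeometry) -> np.ndarray:
    """Random non-overlapping crowder centres (min-image metric)."""
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < cfg.n_crowders:
        if tries >= cfg.max_placement_tries:
            raise PackingError(
                f"could not place {cfg.n_crowders} crowders of radius "
                f"{cfg.crowder_radius} Å in a {cfg.box_length} Å box after "
                f"{tries} tries")
        tries += 1
        pos = rng.uniform(0.0, cfg.box_length, size=3)
        d_target = np.linalg.norm(min_image_displacement(center, pos, box))
        if d_target < cfg.target_radius + cfg.crowder_radius:
            continue
        ok = all(np.linalg.norm(min_image_displacement(c, pos, box))
                 >= 2.0 * cfg.crowder_radius for c in centers)
        if ok:
            centers.append(pos)
    return np.array(centers).reshape(cfg.n_crowders, 3)


def _build_system(cfg: SynthConfig) -> MolecularSystem:
    n = 1 + cfg.n_crowders + cfg.n_ligands
    element = np.array(["X"] * n, dtype=object)
    res_name = np.array(["TGT"] + ["CRW"] * cfg.n_crowders
                        + ["LIG"] * cfg.n_ligands, dtype=object)
    chain_id = np.array(["T"] + ["C"] * cfg.n_crowders
                        + ["L"] * cfg.n_ligands, dtype=object)
    roles = np.array([Role.TARGET] + [Role.CROWDER] * cfg.n_crowders
                     + [Role.LIGAND] * cfg.n_ligands, dtype=object)
    radius = np.array([cfg.target_radius]
                      + [cfg.crowder_radius] * cfg.n_crowders
                      + [0.0] * cfg.n_ligands)
    return MolecularSystem(
        element=element,
        heavy_atom=np.ones(n, dtype=bool),
        res_name=res_name,
        res_id=np.arange(1, n + 1),
        chain_id=chain_id,
        molecule_id=np.arange(n),
        role=roles,
        radius_offset=radius,
        atom_name=np.array(["X"] * n, dtype=object),
    )


def simulate_crowded_box(cfg: SynthConfig):
    """Run the Brownian-dynamics generator.

    Returns
    -------
    (Trajectory, MolecularSystem, GroundTruth)
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.box_length
    box = BoxGeometry((L, L, L), periodic=True)
    center = np.full(3, L / 2.0)
    crowders = _place_crowders(cfg, rng, center, box)
    prot_centers = np.vstack([center[None, :], crowders]) \
        if cfg.n_crowders else center[None, :]
    prot_radii = np.array([cfg.target_radius]
                          + [cfg.crowder_radius] * cfg.n_crowders)
    axis = np.asarray(cfg.pocket_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cos_pocket = np.cos(np.radians(cfg.pocket_half_angle_deg))
    w = cfg.shell_width

    # crowders in contact with the target modulate the gate opening rate
    if cfg.n_crowders:
        d_tc = np.linalg.norm(min_image_displacement(center, crowders, box),
                              axis=-1)
        n_contact = int(np.count_nonzero(
            d_tc - cfg.target_radius - cfg.crowder_radius
            <= cfg.contact_cutoff))
    else:
        n_contact = 0
    k_open_eff = cfg.k_open * (1.0 + cfg.contact_multiplier * n_contact)
    p_open = 1.0 - np.exp(-k_open_eff * cfg.dt_ps)
    p_close = 1.0 - np.exp(-cfg.k_close * cfg.dt_ps)

    def geometry(pos: np.ndarray):
        """Per-ligand (d_eff, in_shell, owner, in_pocket, psi_deg)."""
        disp = min_image_displacement(prot_centers[None, :, :],
                                      pos[:, None, :], box)
        dist = np.linalg.norm(disp, axis=-1)           # (n_lig, n_prot)
        d_eff = dist - prot_radii[None, :]
        in_shell_any = (d_eff >= 0) & (d_eff <= w)
        owner = np.argmin(d_eff, axis=1)
        # tie at equal effective distance resolves to the target (index 0)
        tmin = d_eff[:, 0]
        omin = d_eff[np.arange(len(pos)), owner]
        owner = np.where(np.isclose(tmin, omin), 0, owner)
        in_shell = in_shell_any.any(axis=1)
        to_target = disp[:, 0, :]                      # ligand - center
        r_t = dist[:, 0]
        with np.errstate(invalid="ignore"):
            cos_psi = (to_target @ axis) / np.where(r_t > 0, r_t, 1.0)
        psi = np.degrees(np.arccos(np.clip(cos_psi, -1.0, 1.0)))
        in_target_shell = in_shell_any[:, 0]
        in_pocket = in_target_shell & (cos_psi >= cos_pocket)
        in_core = np.any(d_eff < 0, axis=1)
        return d_eff, in_shell, owner, in_pocket, psi, in_target_shell, in_core

    def energy(in_shell, in_pocket):
        u = np.where(in_shell, -cfg.eps, 0.0)
        return u - np.where(in_pocket, cfg.eps_pocket, 0.0)

    # initial ligand positions in free space (outside every core)
    pos = np.empty((cfg.n_ligands, 3))
    placed = 0
    tries = 0
    while placed < cfg.n_ligands:
        if tries > cfg.max_placement_tries:
            raise PackingError("could not place ligands outside protein cores")
        tries += 1
        cand = rng.uniform(0.0, L, size=3)
        d = np.linalg.norm(min_image_displacement(prot_centers, cand, box),
                           axis=-1) - prot_radii
        if np.all(d >= 0):
            pos[placed] = cand
            placed += 1

    sigma = np.sqrt(2.0 * cfg.diffusion * cfg.dt_ps)
    gate_open = cfg.gate_mode == "open"
    if cfg.gate_mode == "dynamic":
        gate_open = rng.random() < k_open_eff / (k_open_eff + cfg.k_close)

    d_eff, in_shell, owner, in_pocket, psi, in_tshell, _ = geometry(pos)
    d_target = d_eff[:, 0]
    disarm = cfg.disarm_distance if cfg.disarm_distance is not None \
        else w + 10.0
    # a ligand is "armed" for pocket entry after visiting the active
    # entry-window polar band close to the target surface; it disarms when
    # it drifts well away from the surface
    armed = np.zeros(cfg.n_ligands, dtype=bool)
    armed_psi = np.full(cfg.n_ligands, np.nan)
    armed_step = np.full(cfg.n_ligands, -1, dtype=int)
    shell_entry_step = np.full(cfg.n_ligands, -1, dtype=int)
    # one binding event per approach: a new event requires the ligand to
    # have wandered beyond the disarm distance since its last pocket visit
    fresh_approach = np.ones(cfg.n_ligands, dtype=bool)
    events: list[dict] = []

    n_rec = cfg.n_steps // cfg.record_stride + 1
    n_atoms = 1 + cfg.n_crowders + cfg.n_ligands
    coords = np.empty((n_rec, n_atoms, 3))
    compartments = np.empty((n_rec, cfg.n_ligands), dtype=np.int8)
    gates = np.empty(n_rec, dtype=bool)

    def record(idx, pos, in_shell, owner, in_pocket):
        coords[idx, :len(prot_centers)] = prot_centers
        coords[idx, len(prot_centers):] = pos
        comp = np.where(in_shell,
                        np.where(owner == 0, TARGET_SURF, CROWDER_SURF),
                        BULK)
        compartments[idx] = comp
        gates[idx] = gate_open

    record(0, pos, in_shell, owner, in_pocket)
    rec_idx = 1

    for step in range(1, cfg.n_steps + 1):
        if cfg.gate_mode == "dynamic":
            if gate_open:
                if rng.random() < p_close:
                    gate_open = False
            elif rng.random() < p_open:
                gate_open = True
        if cfg.gate_mode in ("dynamic", "closed", "open"):
            lo, hi = (cfg.window_open_deg if gate_open
                      else cfg.window_closed_deg)

        prop = pos + rng.normal(0.0, sigma, size=pos.shape)
        prop %= L
        (n_deff, n_shell, n_owner, n_pocket, n_psi,
         n_tshell, n_core) = geometry(prop)

        accept = ~n_core
        du = energy(n_shell, n_pocket) - energy(in_shell, in_pocket)
        u_rand = rng.random(cfg.n_ligands)
        accept &= (du <= 0) | (u_rand < np.exp(-np.clip(du, None, 700.0)))
        if cfg.gate_mode != "off":
            entering_pocket = n_pocket & ~in_pocket
            accept &= ~entering_pocket | armed

        # commit accepted moves
        pos[accept] = prop[accept]
        new_tshell = np.where(accept, n_tshell, in_tshell)
        entered_shell = new_tshell & ~in_tshell
        shell_entry_step[entered_shell] = step
        new_d = np.where(accept, n_deff[:, 0], d_target)
        new_psi = np.where(accept, n_psi, psi)
        if cfg.gate_mode != "off":
            trigger = (new_d <= w + cfg.arm_margin) \
                & (new_psi >= lo) & (new_psi <= hi)
            armed_psi[trigger] = new_psi[trigger]
            armed_step[trigger] = step
            armed |= trigger
            armed[new_d > disarm] = False

        new_pocket = np.where(accept, n_pocket, in_pocket)
        fresh_approach |= new_d > disarm
        for i in np.nonzero(new_pocket & ~in_pocket & fresh_approach)[0]:
            events.append({
                "ligand": int(i),
                "bound_step": int(step),
                "bound_frame": int(step // cfg.record_stride),
                "shell_entry_step": int(shell_entry_step[i]),
                "entry_psi_deg": float(armed_psi[i]),
                "entry_step": int(armed_step[i]),
                "gate_open": bool(gate_open),
            })
            fresh_approach[i] = False

        in_shell = np.where(accept, n_shell, in_shell)
        owner = np.where(accept, n_owner, owner)
        in_pocket = new_pocket
        in_tshell = new_tshell
        psi = new_psi
        d_target = new_d

        if step % cfg.record_stride == 0:
            record(rec_idx, pos, in_shell, owner, in_pocket)
            rec_idx += 1

    system = _build_system(cfg)
    traj = Trajectory(coords,
                      np.full((n_rec, 3), L),
                      cfg.dt_ps * cfg.record_stride)
    truth = GroundTruth(compartments=compartments, gate_open=gates,
                        events=events, n_contact=n_contact,
                        config=asdict(cfg))
    return traj, system, truth


# ---------------------------------------------------------------------------
# Sidechain-distance generators (TYR-in / TYR-out analogue)
# ---------------------------------------------------------------------------

STATE_IN, STATE_OUT = 0, 1


def generate_sidechain_series(mode_in: float, mode_out: float, sd: float,
                              dwell_in: float, dwell_out: float,
                              length: int, seed: int,
                              dt_ps: float = 1.0):
    """Two-state Markov jump process with Gaussian emission per state.

    Emulates the bimodal hinge-tyrosine distance dynamics: the compact
    state fluctuates about ``mode_in`` and the extended state about
    ``mode_out``; dwell times are exponential with the given means (ps).
    A zero dwell time removes that state entirely.

    Returns ``(distances, states)`` with states 0 = IN, 1 = OUT.
    """
    if mode_in >= mode_out:
        raise ConfigError("mode_in must be smaller than mode_out")
    if sd < 0 or dwell_in < 0 or dwell_out < 0:
        raise ConfigError("sd and dwell times must be non-negative")
    if dwell_in == 0 and dwell_out == 0:
        raise ConfigError("at least one dwell time must be positive")
    rng = np.random.default_rng(seed)
    states = np.empty(length, dtype=np.int8)
    if dwell_out == 0:
        states[:] = STATE_IN
    elif dwell_in == 0:
        states[:] = STATE_OUT
    else:
        p_out = 1.0 - np.exp(-dt_ps / dwell_in)   # leave IN
        p_in = 1.0 - np.exp(-dt_ps / dwell_out)   # leave OUT
        s = STATE_IN if rng.random() < dwell_in / (dwell_in + dwell_out) \
            else STATE_OUT
        for t in range(length):
            states[t] = s
            if s == STATE_IN:
                if rng.random() < p_out:
                    s = STATE_OUT
            elif rng.random() < p_in:
                s = STATE_IN
    means = np.where(states == STATE_IN, mode_in, mode_out)
    distances = means + (rng.normal(0.0, sd, size=length) if sd > 0 else 0.0)
    return distances, states


def sidechain_series_from_gate(gate_open: np.ndarray, mode_in: float = 5.0,
                               mode_out: float = 8.5, sd: float = 0.5,
                               seed: int = 0):
    """Emit a sidechain-distance series conditioned on a gate-state series
    (gate open ⇔ extended/OUT)."""
    rng = np.random.default_rng(seed)
    gate_open = np.asarray(gate_open, dtype=bool)
    means = np.where(gate_open, mode_out, mode_in)
    return means + rng.normal(0.0, sd, size=gate_open.shape)


# ---------------------------------------------------------------------------
# Dose–response generator
# ---------------------------------------------------------------------------

def generate_dose_response(ic50: float, alpha: float, concentrations,
                           noise_sd: float = 0.0, replicates: int = 1,
                           seed: int = 0, condition: str = "synthetic"):
    """Hill-curve activities with per-replicate Gaussian noise.

    Mean activity follows the constrained Hill curve (100% at zero
    inhibitor, 50% at c = ic50, → 0 at saturation); activity at zero
    concentration is exactly 100% by definition (the no-inhibitor anchor)
    and carries no noise.
    """
    from .hill import DoseResponseData, hill_activity

    conc = np.asarray(concentrations, dtype=float)
    if ic50 <= 0:
        raise ConfigError("ic50 must be positive")
    if np.any(conc < 0):
        raise ConfigError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    mean_true = hill_activity(conc, ic50, alpha)
    reps = np.tile(mean_true, (replicates, 1))
    if noise_sd > 0:
        reps = reps + rng.normal(0.0, noise_sd, size=reps.shape)
    reps[:, conc == 0] = 100.0
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if replicates > 1 else np.zeros_like(mean)
    return DoseResponseData(condition=condition, conc=conc, activity=mean,
                            sd=sd, n_replicates=replicates,
                            replicates=reps)


# ---------------------------------------------------------------------------
# Config file + ground-truth table I/O
# ---------------------------------------------------------------------------

def synth_config_from_file(path) -> SynthConfig:
    """Load a SynthConfig from a flat YAML/JSON mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of config keys")
    if "seed" not in data:
        raise ConfigError(f"{path}: seed is mandatory")
    for key in ("pocket_axis", "window_closed_deg", "window_open_deg"):
        if key in data:
            data[key] = tuple(data[key])
    try:
        return SynthConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_ground_truth(path, truth: GroundTruth) -> None:
    """CSV: frame, ligand_id, compartment, gate_state."""
    n_frames, n_lig = truth.compartments.shape
    with open(path, "w") as fh:
        fh.write("frame,ligand_id,compartment,gate_state\n")
        for f in range(n_frames):
            g = "open" if truth.gate_open[f] else "closed"
            for i in range(n_lig):
                name = COMPARTMENT_NAMES[int(truth.compartments[f, i])]
                fh.write(f"{f},{i},{name},{g}\n")
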