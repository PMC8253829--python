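"""Shared fixtures: tiny PDB files and reusable synthetic simulations."""

import numpy as np
import pytest

from crowdbind import SynthConfig, simulate_crowded_box


TOY_PDB_ONE_CHAIN = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.147  -4.916  1.00  0.00           C
END
"""

TOY_PDB_TWO_CHAIN = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      5  H   ALA A   1      -0.500   0.800   0.000  1.00  0.00           H
HETATM    6  C1  LIG B   1       8.000   0.000   0.000  1.00  0.00           C
HETATM    7  N1  LIG B   1       9.200   0.500   0.000  1.00  0.00           N
END
"""


@pytest.fixture()
def toy_pdb_one_chain(tmp_path):
    p = tmp_path / "toy1.pdb"
    p.write_text(TOY_PDB_ONE_CHAIN)
    return p


@pytest.fixture()
def toy_pdb_two_chain(tmp_path):
    p = tmp_path / "toy2.pdb"
    p.write_text(TOY_PDB_TWO_CHAIN)
    return p


@pytest.fixture(scope="session")
def free_box():
    """Non-interacting ligands (ε = 0) in a small box — the volume-ratio
    and diffusion-recovery substrate."""
    cfg = SynthConfig(seed=101, box_length=50.0, n_crowders=0,
                      target_radius=10.0, n_ligands=16, n_steps=30000,
                      eps=0.0, eps_pocket=0.0, gate_mode="off",
                      record_stride=5)
    traj, system, truth = simulate_crowded_box(cfg)
    return cfg, traj, system, truth


@pytest.fixture(scope="session")
def sticky_box():
    """Attractive surface (ε = 2 kT), no crowders — the Boltzmann-oracle
    substrate."""
    cfg = SynthConfig(seed=202, box_length=50.0, n_crowders=0,
                      target_radius=10.0, n_ligands=16, n_steps=30000,
                      eps=2.0, eps_pocket=0.0, gate_mode="off",
                      record_stride=5)
    traj, system, truth = simulate_crowded_box(cfg)
    return cfg, traj, system, truth


def shell_bulk_ratio_per_ligand(truth, discard_fraction=1 / 3):
    """Per-ligand (surface frames)/(bulk frames) after burn-in."""
    comp = truth.compartments
    comp = comp[int(comp.shape[0] * discard_fraction):]
    f_surf = (comp == 1).mean(axis=0)
    f_bulk = (comp == 0).mean(axis=0)
    return f_surf / np.maximum(f_bulk, 1e-12)


def boltzmann_shell_bulk_ratio(cfg):
    """Analytic (V_shell e^ε)/V_bulk for a single target sphere."""
    r_in = cfg.target_radius
    r_out = cfg.target_radius + cfg.shell_width
    v_shell = 4.0 / 3.0 * np.pi * (r_out ** 3 - r_in ** 3)
    v_bulk = cfg.box_length ** 3 - 4.0 / 3.0 * np.pi * r_out ** 3
    return v_shell * np.exp(cfg.eps) / v_bulk
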