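# crowdbind

Analysis of small-molecule inhibitor behaviour in **crowded protein
solutions**: where the ligand partitions (bulk water vs. protein
surfaces), how it diffuses, through which angular window it reaches the
binding pocket, how the target's local conformational equilibrium shifts
with crowding, and how much inhibitory potency (IC50) is lost when
crowder proteins compete for the ligand.

The package is aimed at computational biophysicists studying
protein–ligand binding under macromolecular crowding — the regime where
25–45% of the volume is occupied by bystander macromolecules (e.g. serum
albumin used as a crowder around a kinase target). It provides the full
trajectory-analysis stack for such studies plus a Brownian-dynamics
generator that produces synthetic crowded-box trajectories with known
ground truth, so every analysis stage is testable against an exact oracle.

## What it computes

Given trajectory frames with a topology assigning each molecule a role
(one `TARGET`, any number of `CROWDER`s, one or more `LIGAND`s):

- **Partitioning** — each ligand in each frame is `BULK` iff every heavy
  atom is more than 5 Å (configurable) from every protein heavy atom;
  otherwise it belongs to the surface region of the protein class owning
  the nearest heavy atom. Compartment fractions are reported in % of
  ligand·frames with standard errors over replicates, and per unit
  solvent-accessible surface area (Shrake–Rupley numerical SASA):
  `P_area = fraction / SASA` in %/Å².
- **Occupancy maps** — voxelized % -of-frames ligand occupancy around the
  (superposed) target, exported as OpenDX with isosurface-threshold voxel
  counts (e.g. at 0.5% and 1.5%).
- **Transport** — region-conditioned mean-square displacements from
  periodic-unwrapped centroids, Einstein-relation diffusion coefficients
  `D = slope/6`, and residence-time statistics of ligand–protein contact
  episodes (with survival curves and censoring of truncated events).
- **Binding pathways** — reaction coordinates (ξ, θ, φ): site–ligand
  distance plus polar/azimuth angles in a body frame anchored on the
  binding site; detection of unbound → bound events (unbound: ξ > 15 Å)
  classified by the θ band of their encounter; free-energy landscapes
  `F(ξ, θ) = −ln(P/P_max)` in kT from raw histograms.
- **Conformational states** — two-state classification of a sidechain
  distance series (compact "IN" ≈ 5 Å vs extended "OUT" ≈ 8.5 Å modes) by
  threshold or two-component Gaussian-mixture EM; population-shift tables
  across a crowder series; pseudo-torsions; RMSF; Cα contact counts.
- **Dose–response** — constrained Hill fits of inhibition assays,

  ```
  activity(c) = 100 / (1 + (c / IC50)^α),     activity(0) ≡ 100%
  ```

  with IC50 and Hill coefficient α free, standard errors from the
  linearized covariance, and IC50 fold-shift between conditions.

The synthetic generator (`crowdbind.synthetic`) evolves point ligands by
Metropolis-filtered Brownian dynamics among static protein spheres with a
square-well surface attraction, a deeper gated pocket on the target, and
a crowder-modulated two-state gate — reproducing, with known ground
truth, the qualitative signatures of crowding: falling bulk fractions,
surface-trapped ligands, slowed transport, gate-dependent entry windows,
and conformational population shifts.

## Worked example

```python
from crowdbind.pipeline import run_pipeline

summary = run_pipeline({"seed": 11}, output_dir="out")
for label, block in summary["systems"].items():
    print(label,
          round(block["partition"]["fractions_pct"]["BULK"], 2),
          round(block["state_populations_pct"]["OUT"], 1))
print(round(summary["ic50_shift"]["ratio"], 2))
```

This simulates the default crowder ladder (0/2/4/8 crowders in a 120 Å
box), classifies regions, analyses transport, pathways and states, fits
dose–response curves, and prints:

```
crowd0 97.48 23.7
crowd2 71.51 43.6
crowd4 56.36 48.6
crowd8 43.9 61.5
10.42
```

i.e. the ligand bulk fraction falls from 97.5% to 43.9% as crowders are
added, the extended ("OUT") conformation of the gate grows from 23.7% to
61.5% of frames, and the fitted IC50 rises 10.42-fold between the two
assay conditions. Full per-stage tables (partition CSV, MSD curves,
binding events, OpenDX maps, Hill-fit JSON) are written under `out/`.

The same stages are available from the shell:

```bash
crowdbind simulate synth.yaml -o run/     # generate a crowded box
crowdbind partition run/trajectory.txt run/system.json
crowdbind dose assay.csv                  # Hill fits per condition
crowdbind run-all pipeline.yaml -o out/   # everything
```

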