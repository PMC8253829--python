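# Methods

## The synthetic crowded box

The generator replaces atomistic MD with the smallest model that still
exhibits the crowding phenomenology the analyses are built to measure.

**Dynamics.** Ligands are points evolved by Euler–Maruyama overdamped
Langevin steps (`Δx ~ N(0, √(2DΔt))` per coordinate) in a periodic cubic
box, filtered through a Metropolis acceptance on the interaction energy.
Because the proposal is symmetric, the stationary distribution is exactly
Boltzmann in the square-well energy — this is what makes the
shell-occupancy oracle *exact* rather than approximate: at equilibrium

    (surface frames)/(bulk frames) = V_shell · e^ε / V_bulk.

The RMS step `√(6DΔt)` is required to stay below half the shell width
(enforced at construction), so wells are not stepped over.

**Geometry.** Proteins are static spheres: one target (default R = 25 Å)
and `n` crowders (default R = 30 Å) placed uniformly without overlap in a
200 Å box (bounded retries; loud `PackingError` on failure). Sphere radii
enter every distance rule as per-atom radius offsets, so the same 5 Å
surface cutoff applies to spheres and to atomistic input. Protein
mobility is deliberately out of scope — static obstacles keep all
equilibrium oracles closed-form; a rigid drift could be layered on if
surface co-diffusion were ever needed quantitatively.

**Energies.** A square well of depth ε (kT, default 2) covers the shell
[R, R + w] of every protein (w = 5 Å, matching the surface-region
definition); the pocket — the shell restricted to a cone of half-angle γ
(default 25°) about the pocket axis — is deeper by ε_p (default 2).

**The gate.** A two-state telegraph process (rates `k_open`, `k_close`)
stands in for the target's local conformational equilibrium (compact
"IN" ⇔ gate closed, extended "OUT" ⇔ gate open). Its opening rate is
multiplied by `(1 + m·n_contact)` with `n_contact` the number of crowders
within a contact cutoff of the target surface. With the defaults
(m = 0.5, k_close/k_open = 3) the open-state fraction is
(1 + 0.5n)/(4 + 0.5n): 25% with no crowders, 50% at four, 62.5% at eight
— the majority switch falls inside the crowder ladder. The contact
cutoff defaults to 60 Å surface-to-surface; anything much tighter would
count zero contacts under random placement in the default box, making
the gate insensitive to the ladder.

**Gated entry windows.** A ligand may cross into the pocket only if
*armed*: it arms by visiting the active entry window — a polar-angle band
measured from the target centre about the pocket axis — while within
2 Å of the surface shell, and disarms when it drifts more than
shell + 10 Å from the surface. The closed-gate window defaults to
[40°, 80°] (adjacent to the pocket, the "direct" pathway) and the
open-gate window to [100°, 140°] (the distal pathway). The arm/disarm
memory, rather than a strict stay-on-surface rule, is what makes distal-
window binding events observable at desk scale: a ligand may hop along
and just above the surface between arming and pocket entry.

**Ground truth.** Each run records per-frame compartments (computed from
the same geometry the classifier sees, but by an independent in-generator
code path), the gate state series, and a binding-event log with one entry
per *approach* (a new event requires the ligand to have left the
disarm neighbourhood since its last pocket visit), carrying the arming
angle and the pocket-entry step.

**Auxiliary generators.** The sidechain-distance generator emits a
two-state Markov jump process with Gaussian emissions about the two
conformational modes (defaults 5.0 and 8.5 Å, SD 0.5 Å). Note the
dwell-time oracle for the discrete chain is geometric with mean
`1/(1 − e^(−Δt/τ))`, not exactly τ. The dose–response generator evaluates
the constrained Hill curve at given concentrations and adds per-replicate
Gaussian noise; zero concentration is the exact 100% anchor and carries
no noise.

**What the generator does and does not emulate.** It reproduces, with
known truth: volume exclusion, weak nonspecific surface trapping,
competitive capture by crowders, slowed effective transport, a
crowding-driven conformational population shift, and gate-selected entry
windows. It does *not* attempt the absolute partition percentages,
per-area probabilities, event counts or time scales of any atomistic
system: proteins are static and featureless, ligands are points, there is
no solvent, no hydrodynamics, no rotational degrees of freedom, and the
surface well is uniform rather than site-resolved. Passing tests
therefore validate the *analysis machinery* and the qualitative crowding
trends, not quantitative predictions for real systems.

## Analysis conventions

- **Surface rule.** A ligand is BULK iff every heavy atom is > cutoff
  (5 Å default) from every protein heavy atom, minimal-image metric,
  minus per-atom radius offsets. Ownership of a surface ligand goes to
  the class of the nearest protein heavy atom; an exact tie goes to the
  target (deterministic, measure-zero in practice). Only heavy atoms
  participate on both sides.
- **SASA** is Shrake–Rupley-style: golden-spiral points (960 per atom by
  default) on each probe-inflated atom, occluded by the same molecule's
  atoms only — one area per molecule, as when quoting the SASA of a
  crystal structure. Sphere-model atoms use their radius offset directly.
  Per-area probability is the exact quotient fraction/SASA.
- **Occupancy maps** use presence counting (a voxel scores once per frame
  with ≥ 1 selected atom inside; atom-count mode available), half-open
  voxels [lo, hi), and grid extents from the reference structure's
  bounding box plus padding.
- **MSD** uses unwrapped centroids (accumulated minimal-image
  frame-to-frame displacements). A (ligand, origin, lag) window counts
  toward a region only if the label holds at every frame of the window.
  D is slope/6 of an unweighted straight-line fit over a chosen lag
  range; fits use the early-lag regime where windows are plentiful.
- **Residence events** run from first to last in-contact frame; a
  configurable buffer bridges excursions. Events unresolved at the
  trajectory end are censored and excluded from the mean (reported
  separately); an event beginning at frame 0 is kept — its onset is
  observed even if the preceding history is not.
- **Pathway coordinates.** ξ is the distance from the site centroid to
  the ligand heavy-atom centroid (centroid convention chosen over
  min-distance; both are defensible, this one is smooth). The body frame
  puts z toward the first anchor group and x along the orthogonalized
  second anchor. For the sphere model the site centroid is a virtual
  marker on the target surface at the pocket axis; a surface approach at
  centre-polar angle ψ then maps to body-frame θ ≈ 90° + ψ/2, which is
  why the synthetic θ bands (split at 105°) differ from the 60°/120°
  style bands natural to an atomistic frame.
- **Binding events** require ξ > 15 Å (unbound) → ξ ≤ bound threshold
  sustained for a dwell window. When region labels are available the
  bound state additionally requires target-surface contact — for the
  sphere model, with the bound threshold set to 2R·sin(γ/2), this
  conjunction is equivalent to pocket membership, whereas ξ alone cannot
  distinguish a pocket-bound ligand from one hovering just outside the
  gated cone. The encounter frame is the last unbound frame before the
  surface visit that leads to binding (gap-tolerant rewind); without
  region labels it falls back to the last unbound frame before the bound
  episode.
- **FELs** are raw-histogram estimates `−ln(P/P_max)` in kT, min-shifted
  to exactly 0, empty bins masked as NaN (never reported as 0).
  Reweighted enhanced-sampling estimation is out of scope; a kT →
  kcal/mol helper covers unit conversion.
- **Two-state classification** defaults to a 6.5 Å threshold (between
  the 5 and 8.5 Å modes); the mixture method fits a two-component
  Gaussian mixture by EM (scikit-learn), labels by maximum posterior,
  and falls back to the threshold with a warning if a component empties.
  Which atoms define the distance is an input (residue selectors), never
  hard-coded: construct-vs-crystal residue numbering differs between
  published descriptions of this system, so any fixed numbering would be
  wrong for someone.
- **Hill model.** The fitted form is the *decreasing* constrained Hill
  curve `100/(1 + (c/IC50)^α)`. (The equation as printed in at least one
  primary description of this assay has the concentration ratio inverted,
  which would make activity rise with inhibitor; the decreasing form is
  the one consistent with the reported data, e.g. ~33% activity at
  c ≈ 2×IC50.) Zero-concentration points are the constraint, not data,
  and are excluded from residuals. The fit runs in log-IC50
  parameterization, initialized at the concentration nearest 50%
  activity with α = 1, bounded to IC50 ∈ [min c/100, max c·100] and
  α ∈ (0, 10]; SEs come from the linearized covariance with the
  delta-method for IC50. Unweighted residuals by default;
  inverse-variance weighting by replicate SD is optional because assay
  protocols rarely state their weighting.

## Pipeline problem sizes

The default pipeline ladder runs 0/2/4/8 crowders in a 120 Å box
(target R = 15 Å, crowders R = 18 Å, 24 ligands, 20,000 steps of 0.5 ps,
recorded every 10 steps, gate rates 0.02/0.06 ps⁻¹). This geometry was
chosen so that the ladder *equilibrates* within the run: ligands reach
the nearest surface in a few hundred ps, and the first 25% of frames are
discarded before computing partition statistics. The larger default
`SynthConfig` geometry (200 Å box) is better proportioned but needs
several-fold longer runs to converge its partition fractions. The
pipeline recomputes every enabled stage on every run — there is no
implicit caching — and identical config + seed reproduce all outputs
byte-for-byte.

## Known limitations and open points

- Static proteins make surface diffusion artificially slow (a
  surface-bound ligand co-moves with nothing); the qualitative ordering
  surface-D ≤ bulk-D holds, the magnitudes are not meaningful.
- The gate's contact count is frozen at placement time (static
  crowders), so gate kinetics do not fluctuate with crowder motion.
- A published description of this assay system states a crowder
  concentration of "12.7 μM = 5 mg/ml"; for a ~66 kDa protein 5 mg/ml is
  ~75 μM, so the two numbers are mutually inconsistent. The generator
  works in crowder counts, not molar concentrations, and makes no attempt
  to resolve this.
- Mixture SEs for the mode-recovery checks use σ/√n per component —
  adequate for well-separated modes (7 SDs apart), optimistic otherwise.
- The acceptance script exercises the dose–response and two-state
  machinery; the trajectory-trend properties (partition ordering, gate
  shift, θ-band shift) live in the test suite where their stochastic
  tolerances are defined.
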