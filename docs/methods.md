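# Methods notes

This note records the models implemented in `bindmodes`, the numerical
choices behind them, what the synthetic fixtures do and do not emulate, and
the known limitations. Units are Å and kcal mol⁻¹ throughout; GRO files
(nm) are converted at the I/O boundary.

## Single-trajectory MM-PBSA

The binding energy of a dimer frame is

E_bind = E_coul + E_vdW + Solv_polar + Solv_apolar,

each term a complex − monomerA − monomerB difference with all three
geometries taken from the same complex frame (single-trajectory
approximation). Consequences built into the code:

* **Vacuum terms.** Intramolecular Coulomb/LJ contributions are identical
  in the complex and in the isolated monomers and cancel exactly, so
  `binding_energy_frame` evaluates the direct intermolecular sums. The
  Δ-route (`delta_route_vacuum`) exists as a numerical consistency check
  and accumulates the combined term series with correctly-rounded summation
  (`math.fsum`), so the cancellation holds to ~10⁻¹¹ relative instead of
  being limited by the rounding of three large subtotals. No distance
  cutoff and no periodicity: these are rescoring conventions, distinct from
  the cutoffs an MD engine uses during sampling.
* **Dielectric screening.** E_coul is screened by the interior dielectric
  (default ε = 4, the value commonly adopted for protein–protein MM-PBSA;
  3 and 5 are accepted for sensitivity scans) and scales exactly as 1/ε.
* **Apolar solvation.** The SASA-only model ΔG = γ·SASA + β with defaults
  γ = 0.00542 kcal mol⁻¹ Å⁻², β = 0.92 kcal mol⁻¹ (a widely used
  parameterization; both are configuration keys). In the binding
  difference the constant β cancels, so `solv_apolar = γ·ΔSASA` and a
  non-interacting dimer scores exactly zero.
* **Entropy** is not estimated. The method targets relative stabilities of
  conformers of the same system, where the configurational-entropy
  contribution largely cancels.
* **Trajectory statistics.** Frame energies are averaged over an optional
  time window and stride; the standard error is computed over 3 contiguous
  pseudo-replicates (block means; a trailing remainder that does not fill a
  block is dropped, keeping blocks contiguous and equal).

## Finite-difference Poisson–Boltzmann solver

Linearized PB on a cubic grid with DelPhi-style parameter semantics.

* **Grid.** `scale` grid points per Å (default 2); `gsize` =
  round(scale · 2 · max|r − acent|), incremented to odd, with `acent` the
  unweighted geometric center of the coordinates. Two guards modify the
  raw formula: a floor of 33 points for tiny solutes, and a minimum box
  that keeps every atom center ≥ (max PB radius + 2 Å) from the faces —
  the raw formula alone would let the solute span the box exactly, which
  both degrades the boundary condition and violates the enclosure
  invariant. Because the grid is solute-centered, rigid translation of the
  solute leaves the discretization, and hence the energy, exactly
  invariant.
* **Dielectric boundary.** Edge-centered: an edge midpoint inside any
  atom's van der Waals sphere gets ε_in, otherwise ε_out. This is a van
  der Waals surface — deliberately simpler than DelPhi's molecular
  (reentrant) surface, which shifts absolute Solv_polar values; see
  Limitations.
* **Charges** are spread trilinearly (cloud-in-cell) to the 8 enclosing
  nodes; total grid charge matches total atomic charge to 10⁻¹⁰ e.
* **Boundary condition.** Dirichlet faces carry the superposition of
  (Debye–Hückel-screened) Coulomb potentials of the actual atomic charges.
* **Relaxation.** Red–black successive over-relaxation of
  φ₀ = (Σ_f ε_f φ_f + 4πC q₀/h) / (Σ_f ε_f + ε_out κ² h² [solvent]),
  stopping when the largest per-sweep change drops below `convergence`
  (default 0.01 kT/e) or after `nlit` sweeps (default 500;
  non-convergence flags the result rather than aborting). The SOR factor
  defaults to 1.6 for fidelity to the reference protocol; `relaxation="auto"`
  selects the near-optimal 2/(1 + sin(π/g)), which validation-grade runs
  use together with a raised `nlit`, since tight convergence is what the
  analytic comparisons measure.
* **Reaction field.** Solv_polar = ½Σqᵢφ_rf(rᵢ) with φ_rf the solvated
  solve minus a uniform-ε_in reference solve on the identical grid and
  identical spread charges, so the grid self-energy cancels exactly; the
  potential is interpolated back to the atom positions trilinearly.
  Against the analytic Born ion (radii 1.5–4 Å, ε 1→80) the solver is
  within ~5% at scale 2 and ~1.5% at scale 4; a two-charge Kirkwood cavity
  agrees with the analytic multipole series within 10%.
* **`nonit`** (nonlinear iterations) is accepted in the configuration for
  interface fidelity but is a no-op: only the linearized equation is
  solved, and at the default zero ionic strength the nonlinear term
  vanishes identically. Salt, when requested, enters through the linear
  κ² term and the screened boundary.

## SASA and interfaces

* Shrake–Rupley with a golden-section (Fibonacci) spiral point set
  (default 960 points, probe 1.4 Å). The point set is deterministic, so
  SASA is bit-for-bit reproducible, occlusion is exactly monotone, and
  buried areas are exactly non-negative. The single-sphere error is < 1%
  at 960 points and halves at 3840.
* Buried area per monomer = SASA(alone) − SASA(in complex); the dimer
  interfacial area is the mean of the two monomers' buried areas (nm²).
* Per-residue percentages use a two-pass normalization: pass 1 finds the
  maximum isolated-monomer per-residue SASA for each residue *type*
  (3-letter name, pooled over both monomers and all dimers of the
  ensemble); pass 2 divides each residue's buried area by its type
  maximum. Membership is strictly > 10% (a tie at exactly 10% is out).
  Retention of the initial interface is the percentage of initial member
  residues (both monomers pooled) still present at time t; an empty
  initial interface yields NaN rather than a number.
* Both instantaneous (per-frame) and time-averaged percent profiles are
  available; ensemble statistics default to time-averaged membership.

## Clustering and ΔP

* Core-Cα RMSD: one Kabsch fit on the concatenated core atoms of both
  monomers (the β-sandwich core residues 23–27, 36–39, 51–55, 62–66,
  78–82 for the real protein; toy fixtures define their own core). The
  SVD reflection branch is corrected, so rotations are always proper.
* Homodimer permutation: RMSD is the minimum over the A→A/B→B and
  A→B/B→A mappings.
* gromos clustering: repeatedly emit the structure with most neighbors at
  distance strictly < cutoff (ties → lowest index) together with those
  neighbors, remove, repeat. Binding-mode cutoff 4 Å; the per-trajectory
  representative-selection cutoff is not prescribed anywhere and defaults
  to 2 Å (configurable). The representative of a trajectory is the
  *central member* of its largest cluster, never a coordinate average
  (averages break stereochemistry).
* ΔP: dimers sorted by E_bind; best/worst sets hold ⌊fraction·n⌋ members
  (minimum 1; fraction default 0.10, valid in (0, 0.5]). P, P_best and
  P_worst are per-position interface probabilities with residue positions
  pooled over the two monomers; ΔP = P_best(worst) − P. Selection
  operates on individual dimers (not on clustered modes) by default.

## Oligomer propagation

* The generating transform superposes monomer A's core Cα onto monomer
  B's (floppy termini excluded). Propagation keeps the dimer's own two
  units and applies the transform repeatedly to the last unit, so a
  2-unit "oligomer" reproduces the input exactly; no steric relaxation is
  performed — the construction is purely geometric.
* Screw decomposition: θ from the rotation trace, axis from the
  antisymmetric part (with the dedicated θ = 180° branch), axial advance
  d = t·axis, axis point from the least-squares solution of
  (I − R)p = t_⊥. Recomposition reproduces the transform to 10⁻⁶ Å.
* Classification thresholds operationalize what was originally a visual
  call, and are therefore configuration-exposed: *limited* when any
  non-adjacent unit pair clashes (< 2 Å minimum heavy-atom distance) or
  any later unit lands on an earlier one within 3 Å direct RMSD (the
  chain closes), or when θ > 15° with axial advance < 0.5 Å (a ring wider
  than the built n-mer); otherwise *linear* for θ ≤ 15°, else *helical*.
  Classification is invariant under rigid motion of the input dimer.

## Synthetic fixtures

All generators are pure functions of their seed (NumPy PCG64), so every
test input is reproducible bit-for-bit.

* **Toy helical monomers** exercise the full stack on self-avoiding,
  protein-like geometry with standard residue/atom names and a mini force
  field (neutral residues, radii 1.5–2.5 Å, LJ pairs with analytic
  minima at rᵢ + rⱼ and depth 0.15 kcal mol⁻¹).
* **The planted ensemble** is the controlled experiment for the
  clustering + ΔP pipeline: 12 near-rod dimers in 3 antiparallel binding
  modes whose contact windows are {1..12} (8 dimers), {1..8} (3 dimers,
  containing the planted worst) and {5..12} (1 dimer, the planted best),
  with a planted per-dimer energy table. The rod geometry (3.8 Å residue
  spacing, 0.3 Å helical twist to avoid collinearity, 5.0 Å lateral
  separation) was chosen so in-window residues bury ≥ ~15% of their
  type-max SASA while out-of-window residues stay ≤ ~5% — decisively on
  either side of the 10% threshold under 0.05 Å frame jitter, for any
  seed. The analytically expected outcomes (3 clusters; ΔP_best > 0
  exactly on {9..12}; ΔP_worst > 0 exactly on {1..4}) are returned by the
  generator itself, making end-to-end recovery a closed-loop test.
* What the fixtures do **not** emulate: real conformational sampling,
  side-chain packing, solvent structure, force-field realism, or the
  scale of a production study (hundreds of dimers × 1000 frames). Passing
  tests demonstrate correctness of the estimators and the pipeline logic,
  not the biological conclusions one would draw from real trajectories;
  production-scale absolute energies additionally depend on the force
  field and the dielectric-surface convention.

## Problem sizes

The test suite and the acceptance script run desk-scale problems chosen as
the smallest systems that still exercise every code path meaningfully:
33³–49³ PB grids, 36–72-atom toy systems, 12-dimer ensembles, 3–8-frame
trajectories. The same code paths scale to production inputs (the PB solve
is the dominant cost, ~O(g³) per sweep).

## Known limitations

* Van der Waals dielectric surface (no reentrant/molecular surface, no
  Gaussian smoothing): absolute Solv_polar values differ from
  molecular-surface DelPhi results; relative comparisons across
  conformers of the same system are the intended use.
* Linearized PB only; `nonit` is decorative (logged as such).
* No per-residue energy decomposition, no three-trajectory MM-PBSA, no
  entropy terms.
* Binary trajectory formats (XTC) are out of scope; trajectories are
  consumed as concatenated GRO frames.
* Growth classification evaluates one binding mode at a time; oligomers
  mixing different modes are not modeled.
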