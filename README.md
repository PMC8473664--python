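# bindmodes

Binding-mode analysis for protein homodimer ensembles: single-trajectory
MM-PBSA binding energies, SASA-based interface characterization, RMSD
clustering of dimer conformations into binding modes, hot-spot enrichment
statistics, and geometric oligomer propagation.

The package targets the situation that arises in aggregation studies of
amyloidogenic proteins (the motivating system is the aggregation-prone I2
intermediate of the D76N mutant of β2-microglobulin): a docking or sampling
protocol produces hundreds of candidate dimer conformations, and one needs
to (i) score their stability quantitatively, (ii) reduce them to unique
binding modes (BMs), (iii) identify which residues make interfaces stable,
and (iv) predict whether each binding mode can propagate into extended
oligomers.

## The methods

**Single-trajectory MM-PBSA.** For each complex frame the binding energy is
decomposed into four terms, all in kcal mol⁻¹:

    E_bind = E_coul + E_vdW + Solv_polar + Solv_apolar

where each term is value(complex) − value(monomer A) − value(monomer B) with
monomer geometries taken from the complex frame itself. The vacuum terms are
explicit pair sums — E_coul = Σᵢⱼ k_e qᵢqⱼ/(ε rᵢⱼ) with k_e = 332.0636
kcal Å mol⁻¹ e⁻² and interior dielectric ε = 4, E_vdW = Σᵢⱼ C12/r¹² − C6/r⁶ —
with no cutoff; in the single-trajectory scheme the intramolecular
contributions cancel exactly, leaving the intermolecular sums. Solv_polar
comes from a finite-difference linearized Poisson–Boltzmann solver
(DelPhi-style grid: scale 2 points/Å, convergence 0.01 kT/e, 500 linear
iterations, ε_in 4 / ε_out 80, grid size and center derived from the atomic
coordinates), as the reaction-field energy ½Σqφ_rf of a solvated solve
minus a uniform-dielectric reference solve on the identical grid.
Solv_apolar uses the SASA-only linear model γ·SASA + β. Trajectory averages
carry standard errors over 3 contiguous pseudo-replicates.

**Interfaces.** SASA is computed with a deterministic Shrake–Rupley scheme
(960 golden-spiral points, 1.4 Å probe). The buried area of each monomer is
SASA(alone) − SASA(in complex); the dimer's interfacial area is the mean of
the two, in nm². Per-residue buried areas are converted to percentages of
the maximum SASA observed for that residue type across the ensemble;
residues above 10% are interface members.

**Binding modes.** Dimer conformations are clustered with the greedy gromos
algorithm on pairwise core-Cα RMSD (Kabsch superposition on the structured
core of both monomers, with A/B ↔ B/A monomer permutation so homodimer
relabeling cannot inflate distances) at a 4 Å cutoff, then ranked by mean
member binding energy.

**ΔP hot-spots.** Sorting dimers by binding energy, the best and worst 10%
form two sets; ΔP(residue) = P_best(worst)(residue) − P(residue) contrasts
each set's per-position interface probability with the ensemble-wide one.
Positions with ΔP_best > 0 are enriched in stable interfaces — candidate
aggregation hot-spots.

**Oligomer propagation.** For a homodimer A·B, the rigid transform that
superposes A's core onto B's is applied repeatedly to build an ABBBB…
n-mer. The screw decomposition of that transform (rotation angle θ, axial
advance d) plus explicit clash/closure checks classify growth as *limited*
(chain closes on itself), *linear* (θ ≤ 15°) or *helical* (finite θ with
axial advance).

## Worked example

Everything runs on synthetic fixtures, so no external data is needed.
Build a toy dimer trajectory and score it:

```python
import numpy as np
from bindmodes.fixtures import ToySpec, make_toy_monomer, make_dimer, make_trajectory
from bindmodes.oligomer import RigidTransform
from bindmodes.structure_io import write_gro_trajectory

mono = make_toy_monomer(ToySpec(seed=0))                    # 12-residue pseudo-protein
side_by_side = RigidTransform.from_screw(180.0, [0, 0, 1], 0.0, axis_point=[5.6, 0, 0])
dimer = make_dimer(mono, side_by_side, jitter=0.05, seed=1) # C2 head-to-head contact
write_gro_trajectory(make_trajectory(dimer, n_frames=3, noise=0.05, seed=2), "traj.gro")
```

```sh
bindmodes fixtures --kind toy -o ff        # writes the mini force-field tables
bindmodes mmpbsa --trajectory traj.gro \
    --charges ff/charges.tsv --radii ff/radii.tsv --lj ff/lj.tsv -o run
cat run/summary.tsv
```

```
# trajectory means with pseudo-replicate SEs, kcal/mol
n_frames  e_coul    e_vdw     solv_polar  solv_apolar  e_bind    ...  e_bind_apolar  e_bind_polar
3         0.035289  -0.49322  0.010014    -1.24403     -1.69195  ...  -1.73725       0.045303
```

The toy dimer binds at −1.69 kcal mol⁻¹. The decomposition shows the
pattern typical of hydrophobically driven association: the apolar
contribution (van der Waals + apolar solvation, −1.74) provides all the
stability while the polar contribution (Coulomb + polar solvation, +0.05)
slightly opposes binding — desolvating charged groups costs more than their
cross-interface interactions return.

The full pipeline — clustering into binding modes, ΔP hot-spot profile, and
growth classification of each mode — runs over a directory of dimer
structures plus a per-dimer energy table:

```sh
bindmodes fixtures --kind planted --seed 0 -o ens   # 12 dimers in 3 planted modes
bindmodes pipeline --dimer-dir ens --energies ens/energies.tsv \
    --radii ens/radii.tsv --core 2-11 -o out
```

`out/clusters.tsv` recovers the 3 planted binding modes (8 + 3 + 1
members), `out/binding_modes.tsv` ranks them by mean binding energy, and in
`out/delta_p.tsv` the positions with ΔP_best > 0 are exactly the residues
planted into the single most stable dimer's interface (positions 9–12).

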