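"""Deterministic synthetic structures, trajectories and a mini force field.

Everything here is a pure function of its seed and spec (NumPy PCG64
generators), so fixtures are bit-identical across runs and platforms.  Two
families of toy systems are provided:

* *helical* pseudo-proteins (:func:`make_toy_monomer`) — compact,
  self-avoiding, with Cα/N/CB/O atoms and standard 3-letter residue names,
  used to exercise energetics, SASA and clustering on realistic-looking
  geometry;
* *rod* monomers (:func:`make_rod_monomer`) — one Cα per residue on a
  straight axis, used by the planted-ensemble generator where exact control
  of which residues touch the interface matters.

The planted ensemble (:func:`make_planted_ensemble`) builds 12 dimers in 3
antiparallel binding modes with known contact windows and a planted
binding-energy table, and returns the analytically expected cluster count
and ΔP-enriched positions for end-to-end recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .oligomer import RigidTransform
from .structure_io import (Atom, CoreSelection, ForceField, Structure,
                           Trajectory, merge)

__all__ = [
    "ToySpec", "make_toy_monomer", "make_rod_monomer", "make_dimer",
    "random_transform", "make_trajectory", "mini_forcefield",
    "PlantedEnsemble", "make_planted_ensemble",
]

_RESNAMES = ["ALA", "LEU", "SER", "TRP", "GLY", "VAL",
             "PHE", "ASN", "THR", "ILE", "TYR", "GLU"]
_ATOM_NAMES = ["N", "CA", "CB", "O"]


@dataclass(frozen=True)
class ToySpec:
    """Specification of a toy monomer; same spec → bit-identical output."""

    n_residues: int = 12
    atoms_per_residue: int = 3
    core_ranges: tuple[tuple[int, int], ...] = ((3, 5), (8, 10))
    noise: float = 0.05      # Å, Gaussian perturbation of the ideal fold
    seed: int = 0

    @property
    def core(self) -> CoreSelection:
        return CoreSelection(self.core_ranges)


def make_toy_monomer(spec: ToySpec = ToySpec()) -> Structure:
    """A compact self-avoiding α-helical pseudo-protein (chain A).

    Cα atoms trace an ideal helix (radius 2.3 Å, 100°/residue, 1.5 Å rise,
    ≈3.8 Å Cα–Cα); N, CB and O are placed at fixed offsets inside/outside
    the helical barrel.  Minimum interatomic distance stays above 1 Å.
    """
    if not 1 <= spec.atoms_per_residue <= 4:
        raise ValueError("atoms_per_residue must be in 1..4")
    rng = np.random.default_rng(spec.seed)
    r_helix, omega, rise = 2.3, np.radians(100.0), 1.5
    atoms = []
    serial = 0
    for i in range(spec.n_residues):
        ang = omega * i
        z = rise * i
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        tangential = np.array([-np.sin(ang), np.cos(ang), 0.0])
        positions = {
            "CA": r_helix * radial + np.array([0, 0, z]),
            "N": (r_helix - 1.2) * radial + np.array([0, 0, z - 0.6]),
            "CB": (r_helix + 1.5) * radial + 0.3 * tangential + np.array([0, 0, z + 0.3]),
            "O": (r_helix + 0.8) * radial + 0.9 * tangential + np.array([0, 0, z + 0.9]),
        }
        resname = _RESNAMES[i % len(_RESNAMES)]
        for name in _ATOM_NAMES[: spec.atoms_per_residue]:
            serial += 1
            xyz = positions[name] + rng.normal(0.0, spec.noise, 3)
            atoms.append(Atom(serial, name, resname, i + 1, "A", xyz))
    return Structure.from_atoms(atoms)


def make_rod_monomer(n_residues: int = 12, spacing: float = 3.8,
                     twist_radius: float = 0.3,
                     distinct_resnames: bool = True) -> Structure:
    """A near-straight rod: one Cα per residue advancing ``spacing`` Å along
    z, with a gentle helical twist of radius ``twist_radius`` so the point
    set is never collinear (a straight line has no defined rotation about
    its own axis, which would break superposition-based transforms).

    With ``distinct_resnames`` each residue gets its own 3-letter name, so
    the per-type SASA normalization reduces to per-residue normalization —
    the property the planted-ensemble design relies on.
    """
    omega = np.radians(100.0)
    atoms = []
    for i in range(n_residues):
        resname = _RESNAMES[i % len(_RESNAMES)] if distinct_resnames else "GLY"
        xyz = np.array([twist_radius * np.cos(omega * i),
                        twist_radius * np.sin(omega * i),
                        spacing * i])
        atoms.append(Atom(i + 1, "CA", resname, i + 1, "A", xyz))
    return Structure.from_atoms(atoms)


def make_dimer(monomer: Structure, transform: RigidTransform,
               jitter: float = 0.0, seed: int = 0) -> Structure:
    """Homodimer: chain A is the monomer, chain B its rigid transform plus
    optional Gaussian jitter."""
    rng = np.random.default_rng(seed)
    a = monomer.with_chain("A")
    b = transform.apply_structure(monomer).with_chain("B")
    if jitter > 0:
        b = b.with_coords(b.coords + rng.normal(0.0, jitter, b.coords.shape))
    b = Structure(b.serials + a.serials.max(), b.names, b.resnames,
                  b.resseqs, b.chains, b.coords)
    return merge(a, b)


def random_transform(rng: np.random.Generator, separation: float = 14.0) -> RigidTransform:
    """A uniformly random proper rotation plus a random-direction translation
    of the given length — enough to keep toy monomers from overlapping."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    if np.linalg.det(R) < 0:  # cannot happen for a unit quaternion; guard anyway
        R = -R
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return RigidTransform(R, separation * direction)


def make_trajectory(dimer: Structure, n_frames: int, noise: float = 0.1,
                    drift: float = 0.0, seed: int = 0,
                    time_per_frame: float = 100.0) -> Trajectory:
    """Frames = dimer + per-frame Gaussian noise, with an optional slow
    detachment drift that translates monomer B away from A by up to
    ``drift`` Å at the final frame (for interface-retention tests)."""
    if n_frames < 1:
        raise ValueError("n_frames must be ≥ 1")
    rng = np.random.default_rng(seed)
    b_mask = dimer.chains == "B"
    direction = dimer.subset(b_mask).centroid() - dimer.subset(~b_mask).centroid()
    direction = direction / np.linalg.norm(direction)
    frames = []
    for k in range(n_frames):
        xyz = dimer.coords.copy()
        if noise > 0:
            xyz += rng.normal(0.0, noise, xyz.shape)
        if drift != 0.0 and n_frames > 1:
            xyz[b_mask] += direction * (drift * k / (n_frames - 1))
        frames.append(dimer.with_coords(xyz))
    return Trajectory(frames, time_per_frame=time_per_frame)


def mini_forcefield(n_types: int = 4) -> ForceField:
    """A small symmetric nonbonded parameter set for the toy atom names.

    Charges sum to zero over an N/CA/CB residue (and over N/CA/CB/O, since O
    is apolar here); radii span 1.5–2.5 Å; every LJ pair has its minimum at
    r_min = r_i + r_j with depth 0.15 kcal mol⁻¹, so the analytic minimum
    −C6²/(4·C12) is known by construction.
    """
    if not 2 <= n_types <= 4:
        raise ValueError("n_types must be in 2..4")
    names = _ATOM_NAMES[:n_types]
    charge_by_name = {"N": 0.20, "CA": -0.35, "CB": 0.15, "O": 0.0}
    radius_by_name = {"N": 1.6, "CA": 2.0, "CB": 2.2, "O": 1.5}
    depth = 0.15
    charges = {("*", n): charge_by_name[n] for n in names}
    radii = {("*", n): radius_by_name[n] for n in names}
    lj = {}
    for i, ti in enumerate(names):
        for tj in names[i:]:
            rmin = radius_by_name[ti] + radius_by_name[tj]
            c6 = 2.0 * depth * rmin ** 6
            c12 = depth * rmin ** 12
            lj[(ti, tj)] = (c6, c12)
            lj[(tj, ti)] = (c6, c12)
    return ForceField(charges=charges, radii=radii, lj_pairs=lj)


# ---------------------------------------------------------------------------
# Planted ensemble
# ---------------------------------------------------------------------------

def _antiparallel_transform(contact_sum: int, dx: float, spacing: float) -> RigidTransform:
    """Rotate 180° about x and offset so A residue i touches B residue
    ``contact_sum − i`` at lateral distance ``dx``."""
    R = np.diag([1.0, -1.0, -1.0])
    zc = spacing * (contact_sum - 2)
    return RigidTransform(R, np.array([dx, 0.0, zc]))


@dataclass
class PlantedEnsemble:
    """A synthetic dimer ensemble with known structure and energetics."""

    dimers: dict[str, Structure]
    energies: dict[str, dict[str, float]]
    core: CoreSelection
    mode_of: dict[str, int]
    n_modes: int
    planted_best_positions: frozenset
    planted_worst_positions: frozenset
    radii: dict = field(repr=False, default_factory=dict)


def make_planted_ensemble(seed: int = 0, n_residues: int = 12,
                          jitter: float = 0.05) -> PlantedEnsemble:
    """12 rod dimers in 3 planted antiparallel binding modes.

    Contact windows (residue positions, pooled over both monomers):
    mode 1 (8 dimers) {1..12}; mode 2 (3 dimers, contains the planted worst
    dimer) {1..8}; mode 3 (1 dimer, the planted best) {5..12}.  The planted
    binding-energy table makes the mode-3 dimer the single best and one
    mode-2 dimer the single worst, so at the 10% cutoff ΔP_best is strictly
    positive exactly on {9..12} and ΔP_worst exactly on {1..4} — positions
    present in the best (worst) interface but absent from some other mode.
    """
    # lateral separation chosen so in-window residues bury ≥ ~15% of their
    # type-max SAS while out-of-window residues stay ≤ ~5% — decisively on
    # either side of the 10% membership threshold under frame jitter
    spacing, dx = 3.8, 5.0
    rod = make_rod_monomer(n_residues, spacing)
    core = CoreSelection(((2, n_residues - 1),))
    modes = {1: _antiparallel_transform(13, dx, spacing),
             2: _antiparallel_transform(9, dx, spacing),
             3: _antiparallel_transform(17, dx, spacing)}
    assignment = [1] * 8 + [2] * 3 + [3]
    e_bind = [-60.0, -57.0, -54.0, -51.0, -48.0, -45.0, -42.0, -40.0,  # mode 1
              -30.0, -25.0, -20.0,                                     # mode 2 (worst: -20)
              -90.0]                                                   # mode 3 (best)
    rng = np.random.default_rng(seed)
    dimers: dict[str, Structure] = {}
    energies: dict[str, dict[str, float]] = {}
    mode_of: dict[str, int] = {}
    for k, (mode, eb) in enumerate(zip(assignment, e_bind)):
        did = f"dimer{k:03d}"
        dimers[did] = make_dimer(rod, modes[mode], jitter=jitter,
                                 seed=int(rng.integers(2**31)))
        # planted MM-PBSA-style split: apolar dominates, polar opposes
        energies[did] = {"e_bind": eb,
                         "apolar_contribution": 1.4 * eb,
                         "polar_contribution": -0.4 * eb}
        mode_of[did] = mode
    radii = {"CA": 2.0}
    return PlantedEnsemble(
        dimers=dimers, energies=energies, core=core, mode_of=mode_of,
        n_modes=3,
        planted_best_positions=frozenset(range(9, n_residues + 1)),
        planted_worst_positions=frozenset(range(1, 5)),
        radii=radii,
    )
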