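"""Single-trajectory MM-PBSA binding energies.

Four components per frame, all in kcal mol⁻¹:

* ``e_coul`` — intermolecular Coulomb sum, screened by the interior
  dielectric (default 4), no cutoff, no periodicity;
* ``e_vdw`` — intermolecular 12–6 Lennard-Jones sum, no cutoff;
* ``solv_polar`` — ΔG_PB(complex) − ΔG_PB(A) − ΔG_PB(B), three
  finite-difference PB solves;
* ``solv_apolar`` — γ·SASA + β differences from three SASA evaluations.

Because monomer geometries are taken from the complex frame itself (the
single-trajectory approach), intramolecular vacuum terms cancel exactly in
the complex − A − B difference, which therefore equals the direct
intermolecular sum; both routes are exposed so the cancellation can be
verified numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import interface as _interface
from .pb_solver import KE, PBConfig, polar_solvation
from .structure_io import ForceField, Structure, Trajectory, partition_dimer

__all__ = [
    "SasaConfig", "EnergyComponents", "EnergySummary", "ClashError",
    "coulomb_energy", "lj_energy", "apolar_solvation",
    "intra_coulomb_energy", "intra_lj_energy",
    "delta_route_vacuum", "binding_energy_frame",
    "trajectory_binding_energy", "pseudo_replicate_se",
]


class ClashError(ValueError):
    """Two atoms at zero separation."""


@dataclass
class SasaConfig:
    """Apolar-solvation settings: probe and point count for Shrake–Rupley,
    and the SASA-only linear model ΔG = γ·SASA + β (a widely used
    parameterization; both coefficients are configurable)."""

    probe: float = 1.4            # Å
    n_points: int = 960
    gamma: float = 0.00542        # kcal mol⁻¹ Å⁻²
    beta: float = 0.92            # kcal mol⁻¹


@dataclass
class EnergyComponents:
    """The 4-term MM-PBSA decomposition; ``e_bind`` is their exact sum."""

    e_coul: float
    e_vdw: float
    solv_polar: float
    solv_apolar: float
    e_bind: float = field(init=False)

    def __post_init__(self) -> None:
        vals = (self.e_coul, self.e_vdw, self.solv_polar, self.solv_apolar)
        if not all(np.isfinite(vals)):
            raise ValueError("non-finite energy component")
        self.e_bind = float(sum(vals))

    @property
    def apolar_contribution(self) -> float:
        return self.e_vdw + self.solv_apolar

    @property
    def polar_contribution(self) -> float:
        return self.e_coul + self.solv_polar

    def as_dict(self) -> dict[str, float]:
        return {"e_coul": self.e_coul, "e_vdw": self.e_vdw,
                "solv_polar": self.solv_polar, "solv_apolar": self.solv_apolar,
                "e_bind": self.e_bind}


@dataclass
class EnergySummary:
    """Trajectory averages with pseudo-replicate standard errors."""

    mean: EnergyComponents
    se: dict[str, float]
    n_frames: int

    @property
    def apolar_contribution(self) -> float:
        return self.mean.apolar_contribution

    @property
    def polar_contribution(self) -> float:
        return self.mean.polar_contribution


def _pair_distances(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    r = cdist(coords_a, coords_b)
    if np.any(r < 1e-9):
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise ClashError(f"zero interatomic distance between atoms {i} (A) and {j} (B)")
    return r


def coulomb_energy(
    atoms_a: Structure,
    atoms_b: Structure,
    forcefield: ForceField,
    eps_interior: float = 4.0,
) -> float:
    """Intermolecular Coulomb energy Σ k_e qᵢ qⱼ / (ε rᵢⱼ), kcal mol⁻¹."""
    if eps_interior <= 0:
        raise ValueError("eps_interior must be positive")
    qa = forcefield.assign_charges(atoms_a)
    qb = forcefield.assign_charges(atoms_b)
    r = _pair_distances(atoms_a.coords, atoms_b.coords)
    # correctly-rounded accumulation (math.fsum): the Δ-route consistency
    # check subtracts large intramolecular sums, and exact summation makes
    # identical pair terms cancel exactly between the two routes
    return KE / eps_interior * math.fsum((np.outer(qa, qb) / r).ravel())


def lj_energy(atoms_a: Structure, atoms_b: Structure, forcefield: ForceField) -> float:
    """Intermolecular Lennard-Jones energy Σ C12/r¹² − C6/r⁶, kcal mol⁻¹."""
    ta = forcefield.assign_types(atoms_a)
    tb = forcefield.assign_types(atoms_b)
    r = _pair_distances(atoms_a.coords, atoms_b.coords)
    c6 = np.empty(r.shape)
    c12 = np.empty(r.shape)
    cache: dict[tuple[str, str], tuple[float, float]] = {}
    for i, ti in enumerate(ta):
        for j, tj in enumerate(tb):
            key = (str(ti), str(tj))
            if key not in cache:
                cache[key] = forcefield.lj_of(*key)
            c6[i, j], c12[i, j] = cache[key]
    inv6 = r ** -6.0
    return math.fsum((c12 * inv6 * inv6 - c6 * inv6).ravel())


def _intra_pairs(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(structure.n_atoms, k=1)
    d = np.linalg.norm(structure.coords[iu] - structure.coords[ju], axis=1)
    if np.any(d < 1e-9):
        k = int(np.argmin(d))
        raise ClashError(f"zero interatomic distance between atoms {iu[k]} and {ju[k]}")
    return np.stack([iu, ju]), d


def _intra_coulomb_terms(structure: Structure, forcefield: ForceField,
                         eps_interior: float) -> np.ndarray:
    q = forcefield.assign_charges(structure)
    (iu, ju), d = _intra_pairs(structure)
    return KE / eps_interior * (q[iu] * q[ju] / d)


def _intra_lj_terms(structure: Structure, forcefield: ForceField) -> np.ndarray:
    t = forcefield.assign_types(structure)
    (iu, ju), d = _intra_pairs(structure)
    cache: dict[tuple[str, str], tuple[float, float]] = {}
    c6 = np.empty(len(d))
    c12 = np.empty(len(d))
    for k, (i, j) in enumerate(zip(iu, ju)):
        key = (str(t[i]), str(t[j]))
        if key not in cache:
            cache[key] = forcefield.lj_of(*key)
        c6[k], c12[k] = cache[key]
    inv6 = d ** -6.0
    return c12 * inv6 * inv6 - c6 * inv6


def intra_coulomb_energy(structure: Structure, forcefield: ForceField, eps_interior: float = 4.0) -> float:
    """All-pairs Coulomb energy within one structure (Δ-route building block)."""
    return math.fsum(_intra_coulomb_terms(structure, forcefield, eps_interior))


def intra_lj_energy(structure: Structure, forcefield: ForceField) -> float:
    """All-pairs Lennard-Jones energy within one structure."""
    return math.fsum(_intra_lj_terms(structure, forcefield))


def delta_route_vacuum(
    complex_structure: Structure,
    forcefield: ForceField,
    partition: str | int = "chain",
    eps_interior: float = 4.0,
) -> tuple[float, float]:
    """Vacuum terms via value(complex) − value(A) − value(B).

    In the single-trajectory geometry this equals the direct intermolecular
    sums to arithmetic precision (intramolecular terms cancel).  The whole
    difference is accumulated as one correctly-rounded sum so the identical
    intramolecular terms cancel exactly rather than through three rounded
    subtotals.
    """
    a, b = partition_dimer(complex_structure, partition)
    coul = math.fsum(np.concatenate([
        _intra_coulomb_terms(complex_structure, forcefield, eps_interior),
        -_intra_coulomb_terms(a, forcefield, eps_interior),
        -_intra_coulomb_terms(b, forcefield, eps_interior)]))
    vdw = math.fsum(np.concatenate([
        _intra_lj_terms(complex_structure, forcefield),
        -_intra_lj_terms(a, forcefield),
        -_intra_lj_terms(b, forcefield)]))
    return coul, vdw


def apolar_solvation(total_sasa: float, gamma: float = 0.00542, beta: float = 0.92) -> float:
    """SASA-only apolar solvation: γ·SASA + β (SASA in Å², result kcal mol⁻¹)."""
    if total_sasa < 0:
        raise ValueError("SASA must be non-negative")
    return gamma * total_sasa + beta


def binding_energy_frame(
    complex_structure: Structure,
    forcefield: ForceField,
    pb_config: PBConfig | None = None,
    sasa_config: SasaConfig | None = None,
    partition: str | int = "chain",
) -> EnergyComponents:
    """4-component MM-PBSA binding energy for one complex frame.

    Vacuum terms are the direct intermolecular sums (exactly the
    complex − A − B difference by single-trajectory cancellation); polar
    solvation requires three PB solves and apolar solvation three SASA
    evaluations, each as complex − A − B.
    """
    pb_config = pb_config or PBConfig()
    sasa_config = sasa_config or SasaConfig()
    a, b = partition_dimer(complex_structure, partition)
    e_coul = coulomb_energy(a, b, forcefield, pb_config.eps_in)
    e_vdw = lj_energy(a, b, forcefield)
    solv_polar = (polar_solvation(complex_structure, forcefield, pb_config)
                  - polar_solvation(a, forcefield, pb_config)
                  - polar_solvation(b, forcefield, pb_config))
    def _total(s: Structure) -> float:
        return _interface.sasa(s, forcefield, sasa_config.probe, sasa_config.n_points).total
    # three SASA evaluations; the constant β offsets of the absolute
    # solvation model cancel in the binding difference, so a non-interacting
    # dimer scores exactly zero
    solv_apolar = sasa_config.gamma * (_total(complex_structure) - _total(a) - _total(b))
    return EnergyComponents(e_coul=e_coul, e_vdw=e_vdw,
                            solv_polar=solv_polar, solv_apolar=solv_apolar)


def pseudo_replicate_se(values: Sequence[float], n_blocks: int = 3) -> float:
    """Standard error of the mean over contiguous pseudo-replicates.

    The series is split into ``n_blocks`` contiguous equal segments (any
    trailing remainder is dropped); SE = stdev(block means) / √n_blocks.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be ≥ 2")
    values = np.asarray(values, dtype=float)
    if len(values) < n_blocks:
        raise ValueError(f"need at least {n_blocks} values, got {len(values)}")
    m = len(values) // n_blocks
    block_means = values[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(np.std(block_means, ddof=1) / np.sqrt(n_blocks))


def trajectory_binding_energy(
    trajectory: Trajectory,
    forcefield: ForceField,
    pb_config: PBConfig | None = None,
    sasa_config: SasaConfig | None = None,
    partition: str | int = "chain",
    stride_ps: float | None = None,
    window: tuple[float, float] | None = None,
    n_blocks: int = 3,
) -> tuple[EnergySummary, pd.DataFrame]:
    """Per-frame MM-PBSA over a trajectory with pseudo-replicate errors.

    ``window=(start_ps, end_ps)`` restricts the analysis (e.g. to the
    equilibrated tail); ``stride_ps`` subsamples frames.  Returns the summary
    and the retained frame-level table.
    """
    times = trajectory.times
    mask = np.ones(len(trajectory), dtype=bool)
    if window is not None:
        mask &= (times >= window[0]) & (times <= window[1])
    idx = np.where(mask)[0]
    if stride_ps is not None:
        if trajectory.time_per_frame <= 0:
            raise ValueError("time_per_frame must be positive for striding")
        step = max(1, int(round(stride_ps / trajectory.time_per_frame)))
        idx = idx[::step]
    if len(idx) < max(3, n_blocks):
        raise ValueError(f"need at least {max(3, n_blocks)} frames after striding, got {len(idx)}")
    rows = []
    for i in idx:
        comp = binding_energy_frame(trajectory.frames[i], forcefield, pb_config, sasa_config, partition)
        rows.append({"frame_time_ps": float(times[i]), **comp.as_dict()})
    table = pd.DataFrame(rows)
    mean = EnergyComponents(
        e_coul=float(table["e_coul"].mean()),
        e_vdw=float(table["e_vdw"].mean()),
        solv_polar=float(table["solv_polar"].mean()),
        solv_apolar=float(table["solv_apolar"].mean()),
    )
    se = {col: pseudo_replicate_se(table[col].to_numpy(), n_blocks)
          for col in ("e_coul", "e_vdw", "solv_polar", "solv_apolar", "e_bind")}
    return EnergySummary(mean=mean, se=se, n_frames=len(idx)), table
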