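"""Oligomer propagation from a dimer interface and growth classification.

A homodimer's interface defines a rigid transform T: the proper rotation and
translation superposing monomer A's core Cα atoms onto monomer B's.  Applying
T repeatedly to the last monomer propagates the binding mode into an n-mer
with the ABBBBB… arrangement — a purely geometric construction with no
relaxation.  The screw decomposition of T (rotation angle θ about a unit
axis, axial advance d) predicts the aggregate shape:

* θ ≈ 0 — linear chains (translation-dominated growth);
* θ finite, d ≈ 0 — chains that close on themselves (limited growth);
* both finite — helical chains.

Classification combines these thresholds with explicit geometry checks on
the propagated n-mer: steric clashes or a later unit superposing onto an
earlier one mark limited growth regardless of θ/d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ensemble import kabsch
from .structure_io import CoreSelection, Structure, partition_dimer

#: Rotation angles at or below this (degrees) count as linear growth.
DEFAULT_THETA_LINEAR = 15.0
#: Minimum axial advance (Å) for a finite-angle transform to be helical.
DEFAULT_D_MIN = 0.5
#: A later unit within this RMSD (Å) of an earlier one closes the chain.
DEFAULT_CLOSURE_RMSD = 3.0
#: Non-adjacent units with atoms closer than this (Å) clash.
DEFAULT_CLASH_CUTOFF = 2.0

__all__ = [
    "RigidTransform", "OligomerModel", "interface_transform", "propagate",
    "detect_clashes", "classify_growth", "write_oligomer_pdb",
]


@dataclass
class RigidTransform:
    """A proper rigid motion x ↦ R x + t with its screw decomposition."""

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det +1)")

    # -- application --------------------------------------------------
    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def apply_structure(self, structure: Structure) -> Structure:
        return structure.transformed(self.rotation, self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    # -- screw decomposition -----------------------------------------
    @property
    def theta_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    @property
    def axis(self) -> np.ndarray:
        """Unit rotation axis (oriented along the translation when θ ≈ 0)."""
        R = self.rotation
        theta = math.radians(self.theta_deg)
        if theta < 1e-8:
            norm = np.linalg.norm(self.translation)
            return self.translation / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        if abs(theta - math.pi) > 1e-6:
            v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
            return v / (2.0 * math.sin(theta))
        # θ = 180°: axis from the dominant column of (R + I)/2
        M = (R + np.eye(3)) / 2.0
        k = int(np.argmax(np.diag(M)))
        v = M[:, k]
        return v / np.linalg.norm(v)

    @property
    def d_axial(self) -> float:
        """Translation component along the screw axis, Å."""
        return float(np.dot(self.translation, self.axis))

    @property
    def axis_point(self) -> np.ndarray:
        """A point on the screw axis (the one closest to the origin)."""
        theta = math.radians(self.theta_deg)
        if theta < 1e-8:
            return np.zeros(3)
        a = self.axis
        t_perp = self.translation - self.d_axial * a
        # solve (I - R) p = t_perp in the plane normal to the axis
        A = np.eye(3) - self.rotation
        p, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
        return p - np.dot(p, a) * a

    @classmethod
    def from_screw(cls, theta_deg: float, axis: np.ndarray, d: float,
                   axis_point: np.ndarray | None = None) -> "RigidTransform":
        """Recompose a transform from screw parameters (for round-trip
        validation and synthetic dimers)."""
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        th = math.radians(theta_deg)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + math.sin(th) * K + (1.0 - math.cos(th)) * (K @ K)
        p = np.zeros(3) if axis_point is None else np.asarray(axis_point, float)
        t = d * axis + p - R @ p
        return cls(R, t)


@dataclass
class OligomerModel:
    """A propagated n-mer: ordered monomer units, the generating transform
    and (after classification) the growth class."""

    units: list[Structure]
    transform: RigidTransform
    classification: Literal["limited", "linear", "helical", ""] = ""
    clash_report: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_units(self) -> int:
        return len(self.units)


def interface_transform(dimer: Structure, core: CoreSelection) -> RigidTransform:
    """The rigid transform superposing MonA's core Cα onto MonB's.

    This is the interface-propagation generator: applying it to monomer B
    places the next unit the way B sits relative to A.
    """
    a, b = partition_dimer(dimer, "chain")
    ca = core.ca_coords(a)
    cb = core.ca_coords(b)
    R, t, rmsd = kabsch(cb, ca)  # maps A onto B
    return RigidTransform(R, t, fit_rmsd=rmsd)


def propagate(dimer: Structure, n_units: int = 6,
              core: CoreSelection | None = None,
              transform: RigidTransform | None = None) -> OligomerModel:
    """Propagate a dimer into an n-mer (ABBBBB… arrangement).

    Units 1 and 2 are the dimer's own monomers, so ``n_units=2`` reproduces
    the input exactly; every further unit is the transform applied to the
    previous one.  No steric relaxation is performed.
    """
    if n_units < 2:
        raise ValueError("n_units must be ≥ 2")
    if transform is None:
        if core is None:
            raise ValueError("provide either a core selection or an explicit transform")
        transform = interface_transform(dimer, core)
    a, b = partition_dimer(dimer, "chain")
    units = [a, b]
    for _ in range(n_units - 2):
        units.append(transform.apply_structure(units[-1]))
    labels = [chr(ord("A") + i) for i in range(n_units)]
    units = [u.with_chain(lab) for u, lab in zip(units, labels)]
    return OligomerModel(units=units, transform=transform)


def detect_clashes(oligomer: OligomerModel,
                   clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
                   exclude_adjacent: bool = True) -> pd.DataFrame:
    """Minimum interatomic distance for every (non-adjacent) unit pair;
    pairs below the cutoff are flagged.  Hydrogens are ignored."""
    if oligomer.n_units < 3:
        raise ValueError("clash detection needs at least 3 units")
    heavy = []
    for u in oligomer.units:
        mask = np.array([not str(e).upper().startswith("H") for e in
                         (_guess_elements(u))], dtype=bool)
        heavy.append(u.coords[mask])
    rows = []
    for i in range(oligomer.n_units):
        tree = cKDTree(heavy[i])
        for j in range(i + 1, oligomer.n_units):
            if exclude_adjacent and j == i + 1:
                continue
            d, _ = tree.query(heavy[j], k=1)
            dmin = float(np.min(d))
            rows.append({"unit_i": i + 1, "unit_j": j + 1,
                         "min_distance_A": dmin, "clash": dmin < clash_cutoff})
    return pd.DataFrame(rows)


def _guess_elements(u: Structure) -> list[str]:
    out = []
    for name in u.names:
        el = ""
        for ch in str(name).strip():
            if ch.isalpha():
                el = ch.upper()
                break
        out.append(el)
    return out


def _direct_rmsd(u1: Structure, u2: Structure) -> float:
    return float(np.sqrt(np.mean(np.sum((u1.coords - u2.coords) ** 2, axis=1))))


def classify_growth(oligomer: OligomerModel,
                    theta_linear: float = DEFAULT_THETA_LINEAR,
                    d_min: float = DEFAULT_D_MIN,
                    closure_rmsd: float = DEFAULT_CLOSURE_RMSD,
                    clash_cutoff: float = DEFAULT_CLASH_CUTOFF) -> str:
    """Classify an oligomer as ``limited``, ``linear`` or ``helical``.

    Limited: any non-adjacent clash, or a later unit superposing onto an
    earlier one (direct RMSD < ``closure_rmsd`` — the chain closes), or a
    finite rotation with negligible axial advance (a ring larger than the
    built n-mer).  Otherwise linear when θ ≤ ``theta_linear``, else helical.
    The class is also stored on the model.
    """
    if oligomer.n_units < 6:
        raise ValueError("classification requires an oligomer of ≥ 6 units")
    report = detect_clashes(oligomer, clash_cutoff=clash_cutoff)
    oligomer.clash_report = report
    closed = any(
        _direct_rmsd(oligomer.units[i], oligomer.units[j]) < closure_rmsd
        for i in range(oligomer.n_units)
        for j in range(i + 2, oligomer.n_units)
    )
    t = oligomer.transform
    if closed or bool(report["clash"].any()):
        cls = "limited"
    elif t.theta_deg <= theta_linear:
        cls = "linear"
    elif abs(t.d_axial) >= d_min:
        cls = "helical"
    else:
        cls = "limited"
    oligomer.classification = cls
    return cls


def write_oligomer_pdb(oligomer: OligomerModel, path) -> None:
    """Write the n-mer as a multi-chain PDB (chains A, B, C, … per unit)."""
    from .structure_io import merge, write_pdb

    combined = None
    serial = 0
    for u in oligomer.units:
        u = Structure(np.arange(serial + 1, serial + u.n_atoms + 1),
                      u.names, u.resnames, u.resseqs, u.chains, u.coords)
        serial += u.n_atoms
        combined = u if combined is None else merge(combined, u)
    write_pdb(combined, path)
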