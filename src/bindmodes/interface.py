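"""Solvent-accessible surface areas and dimer interface characterization.

SASA uses the Shrake–Rupley sphere-point method with a deterministic
golden-section (Fibonacci) spiral point set, so results are bit-for-bit
reproducible for a given ``n_points``.  Interfacial (buried) area follows
the monomer-wise convention: for each monomer, SASA in isolation minus SASA
in the complex; the dimer's interfacial area is the mean of the two, in nm².

Per-residue interface percentages are normalized by the maximum isolated
per-residue SASA observed for that residue *type* (3-letter name) across a
whole ensemble; residues above 10% are interface members.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import ForceField, Structure, StructureError, partition_dimer

A2_TO_NM2 = 0.01

#: Residues with buried-area percent strictly above this are interface members.
MEMBERSHIP_THRESHOLD_PCT = 10.0
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

__all__ = [
    "SasaResult", "InterfaceProfile", "sasa", "interfacial_area",
    "residue_type_max", "interface_profile", "residue_interface_percent",
    "mean_profile", "initial_interface_retention",
    "MEMBERSHIP_THRESHOLD_PCT", "DEFAULT_PROBE", "DEFAULT_N_POINTS",
]


@lru_cache(maxsize=8)
def _unit_sphere(n_points: int) -> np.ndarray:
    """Golden-section spiral: n nearly uniform points on the unit sphere."""
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    theta = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    """Accessible areas in Å²: per atom, summed per residue, and total."""

    atom_area: np.ndarray
    residue_area: dict[tuple[str, int], float]
    residue_names: dict[tuple[str, int], str]
    total: float


def _resolve_radii(structure: Structure, radii) -> np.ndarray:
    if isinstance(radii, ForceField):
        return radii.assign_radii(structure)
    if isinstance(radii, Mapping):
        return np.array([radii[(str(rn), str(n))] if (str(rn), str(n)) in radii else radii[str(n)]
                         for rn, n in zip(structure.resnames, structure.names)], dtype=float)
    return np.asarray(radii, dtype=float)


def sasa(
    structure: Structure,
    radii: ForceField | np.ndarray | Mapping,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Shrake–Rupley SASA with a deterministic spiral point set."""
    r = _resolve_radii(structure, radii)
    if np.any(r <= 0):
        raise ValueError("all radii must be positive")
    expanded = r + probe
    centers = structure.coords
    n = structure.n_atoms
    pts0 = _unit_sphere(n_points)
    tree = cKDTree(centers)
    atom_area = np.zeros(n)
    for i in range(n):
        neighbors = [j for j in tree.query_ball_point(centers[i], expanded[i] + float(expanded.max()))
                     if j != i and np.linalg.norm(centers[j] - centers[i]) < expanded[i] + expanded[j]]
        pts = centers[i] + expanded[i] * pts0
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - centers[j], pts - centers[j])
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        atom_area[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    residue_area: dict[tuple[str, int], float] = {}
    residue_names: dict[tuple[str, int], str] = {}
    for area, c, rs, rn in zip(atom_area, structure.chains, structure.resseqs, structure.resnames):
        key = (str(c), int(rs))
        residue_area[key] = residue_area.get(key, 0.0) + float(area)
        residue_names[key] = str(rn)
    return SasaResult(atom_area=atom_area, residue_area=residue_area,
                      residue_names=residue_names, total=float(atom_area.sum()))


def interfacial_area(
    complex_structure: Structure,
    radii: ForceField | np.ndarray | Mapping,
    partition: str | int = "chain",
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> tuple[float, float, float]:
    """Buried area of each monomer and their mean, in nm².

    buried_X = SASA(X alone) − SASA of X's atoms within the complex.  With a
    deterministic point set occlusion is monotone, so a meaningfully negative
    buried area indicates a broken partition and raises.
    """
    a, b = partition_dimer(complex_structure, partition)
    r_all = _resolve_radii(complex_structure, radii)
    res_complex = sasa(complex_structure, r_all, probe, n_points)
    na = a.n_atoms
    sasa_a_in = float(res_complex.atom_area[:na].sum())
    sasa_b_in = float(res_complex.atom_area[na:].sum())
    buried_a = sasa(a, r_all[:na], probe, n_points).total - sasa_a_in
    buried_b = sasa(b, r_all[na:], probe, n_points).total - sasa_b_in
    for name, val in (("A", buried_a), ("B", buried_b)):
        if val < -1e-6:
            raise StructureError(f"negative buried area for monomer {name}: {val:.3g} Å² (bad partition?)")
    buried_a, buried_b = max(buried_a, 0.0), max(buried_b, 0.0)
    return buried_a * A2_TO_NM2, buried_b * A2_TO_NM2, 0.5 * (buried_a + buried_b) * A2_TO_NM2


@dataclass
class InterfaceProfile:
    """Per-residue interface description of one dimer conformation."""

    table: pd.DataFrame          # chain, resseq, resname, buried_A2, percent, member
    membership: frozenset        # {(chain, resseq)} with percent > threshold
    interfacial_area_nm2: float

    def pooled_positions(self) -> frozenset:
        """Residue positions in the interface of either monomer."""
        return frozenset(rs for _, rs in self.membership)


def residue_type_max(
    monomers: Iterable[Structure],
    radii: ForceField | Mapping,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[str, float]:
    """Pass 1 of the percent normalization: the maximum isolated-monomer
    per-residue SASA observed for each residue type (3-letter name)."""
    out: dict[str, float] = {}
    for mono in monomers:
        res = sasa(mono, radii, probe, n_points)
        for key, area in res.residue_area.items():
            rn = res.residue_names[key]
            out[rn] = max(out.get(rn, 0.0), float(area))
    return out


def interface_profile(
    complex_structure: Structure,
    radii: ForceField | Mapping,
    type_max: Mapping[str, float],
    partition: str | int = "chain",
    threshold: float = MEMBERSHIP_THRESHOLD_PCT,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> InterfaceProfile:
    """Per-residue buried areas, percents of type-max, and membership for
    one dimer conformation."""
    a, b = partition_dimer(complex_structure, partition)
    r_all = _resolve_radii(complex_structure, radii)
    res_complex = sasa(complex_structure, r_all, probe, n_points)
    na = a.n_atoms
    rows = []
    membership = set()
    buried_total = {"A": 0.0, "B": 0.0}
    for mono, sl in ((a, slice(0, na)), (b, slice(na, None))):
        res_alone = sasa(mono, r_all[sl], probe, n_points)
        # per-residue in-complex sums for this monomer's atoms
        in_complex: dict[tuple[str, int], float] = {}
        for area, c, rs in zip(res_complex.atom_area[sl], mono.chains, mono.resseqs):
            key = (str(c), int(rs))
            in_complex[key] = in_complex.get(key, 0.0) + float(area)
        for key, alone in res_alone.residue_area.items():
            rn = res_alone.residue_names[key]
            buried = max(alone - in_complex.get(key, 0.0), 0.0)
            buried_total[key[0]] += buried
            if rn not in type_max:
                raise KeyError(f"residue type {rn!r} absent from the type-max table")
            pct = 100.0 * buried / type_max[rn] if type_max[rn] > 0 else 0.0
            member = pct > threshold
            if member:
                membership.add(key)
            rows.append({"chain": key[0], "resseq": key[1], "resname": rn,
                         "buried_A2": buried, "percent": pct, "member": int(member)})
    table = pd.DataFrame(rows).sort_values(["chain", "resseq"]).reset_index(drop=True)
    area_nm2 = 0.5 * (buried_total["A"] + buried_total["B"]) * A2_TO_NM2
    return InterfaceProfile(table=table, membership=frozenset(membership),
                            interfacial_area_nm2=area_nm2)


def residue_interface_percent(
    ensemble: Sequence[Structure],
    radii: ForceField | Mapping,
    partition: str | int = "chain",
    threshold: float = MEMBERSHIP_THRESHOLD_PCT,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> list[InterfaceProfile]:
    """Two-pass per-frame interface profiles for an ensemble of complexes:
    pass 1 collects the type-max table over all isolated monomers, pass 2
    normalizes each residue's buried area by its type-max."""
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    monomers = []
    for cx in ensemble:
        a, b = partition_dimer(cx, partition)
        monomers.extend([a, b])
    tmax = residue_type_max(monomers, radii, probe, n_points)
    return [interface_profile(cx, radii, tmax, partition, threshold, probe, n_points)
            for cx in ensemble]


def mean_profile(profiles: Sequence[InterfaceProfile],
                 threshold: float = MEMBERSHIP_THRESHOLD_PCT) -> InterfaceProfile:
    """Time-averaged profile: per-residue percents averaged over frames;
    membership re-derived from the averaged percent."""
    if not profiles:
        raise ValueError("no profiles to average")
    concat = pd.concat([p.table for p in profiles])
    table = (concat.groupby(["chain", "resseq", "resname"], as_index=False)
             [["buried_A2", "percent"]].mean())
    table["member"] = (table["percent"] > threshold).astype(int)
    membership = frozenset((r.chain, int(r.resseq)) for r in table.itertuples() if r.member)
    area = float(np.mean([p.interfacial_area_nm2 for p in profiles]))
    return InterfaceProfile(table=table, membership=membership, interfacial_area_nm2=area)


def initial_interface_retention(profile_t: InterfaceProfile, profile_0: InterfaceProfile) -> float:
    """Percent of the initial interface membership retained at time t,
    pooling the residues of both monomers.  NaN when the initial interface
    is empty."""
    m0, mt = profile_0.membership, profile_t.membership
    if not m0:
        return float("nan")
    return 100.0 * len(mt & m0) / len(m0)
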