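"""Binding-mode clustering and the best/worst ΔP hot-spot statistic.

The clustering protocol has three steps: (1) per-trajectory gromos
clustering on core-Cα RMSD to pick one representative conformation per
dimer; (2) an all-pairs RMSD matrix between representatives, fitted on the
concatenated core Cα atoms of both monomers; (3) A/B ↔ B/A monomer
permutations, keeping the lower RMSD, before gromos clustering of the matrix
at a 4 Å cutoff.  Each resulting cluster is a binding mode (BM).

The ΔP statistic contrasts the per-position interface probability of the
best (lowest binding energy) and worst deciles of the ensemble with the
ensemble-wide probability: ΔP = P_B(W) − P; positive values mark enriched
(putative hot-spot) positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import CoreSelection, Structure, Trajectory

#: Binding-mode clustering cutoff on permuted core-Cα RMSD (Å).
DEFAULT_CLUSTER_CUTOFF = 4.0
#: Per-trajectory (step 1) gromos cutoff on core-Cα RMSD (Å).
DEFAULT_FRAME_CUTOFF = 2.0
#: Fraction of the ensemble in the best/worst sets for ΔP.
DEFAULT_HOTSPOT_FRACTION = 0.10

__all__ = [
    "kabsch", "core_rmsd", "permuted_rmsd", "rmsd_matrix",
    "Cluster", "gromos_cluster", "representative_frame",
    "rank_binding_modes", "DeltaPProfile", "hotspot_delta_p",
    "DEFAULT_CLUSTER_CUTOFF", "DEFAULT_FRAME_CUTOFF", "DEFAULT_HOTSPOT_FRACTION",
]


def kabsch(coords_ref: np.ndarray, coords_mobile: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid superposition of ``coords_mobile`` onto
    ``coords_ref``.

    Returns ``(rotation, translation, rmsd)`` with
    ``aligned = mobile @ rotation.T + translation``; the reflection branch of
    the SVD is corrected so the rotation is always proper (det +1).
    """
    P = np.asarray(coords_ref, dtype=float)
    Q = np.asarray(coords_mobile, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate (rank-deficient) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    aligned = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - P) ** 2, axis=1))))
    return R, t, rmsd


def _dimer_core(dimer: Structure, core: CoreSelection, swap: bool = False) -> np.ndarray:
    chains = ("B", "A") if swap else ("A", "B")
    return np.vstack([core.ca_coords(dimer, c) for c in chains])


def core_rmsd(dimer1: Structure, dimer2: Structure, core: CoreSelection) -> float:
    """RMSD over the concatenated core Cα atoms of both monomers after a
    single rigid fit (A→A, B→B mapping)."""
    return kabsch(_dimer_core(dimer1, core), _dimer_core(dimer2, core))[2]


def permuted_rmsd(dimer1: Structure, dimer2: Structure, core: CoreSelection) -> float:
    """Minimum core RMSD over the two homodimer monomer mappings
    (A→A/B→B and A→B/B→A)."""
    ref = _dimer_core(dimer1, core)
    direct = kabsch(ref, _dimer_core(dimer2, core))[2]
    swapped = kabsch(ref, _dimer_core(dimer2, core, swap=True))[2]
    return min(direct, swapped)


def rmsd_matrix(dimers: Sequence[Structure], core: CoreSelection,
                permute: bool = True) -> np.ndarray:
    """Symmetric pairwise (permuted) core RMSD matrix."""
    n = len(dimers)
    mat = np.zeros((n, n))
    fn = permuted_rmsd if permute else core_rmsd
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = fn(dimers[i], dimers[j], core)
    return mat


@dataclass
class Cluster:
    center: int
    members: list[int]   # includes the center


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> list[Cluster]:
    """Greedy gromos clustering of a dissimilarity matrix.

    Repeatedly take the structure with the most neighbours at distance
    < cutoff (ties: lowest index), emit it with its neighbours as one
    cluster, remove them, and continue.  Clusters are returned in emission
    order and partition the index set.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("RMSD matrix must be square")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("RMSD matrix must be symmetric")
    remaining = list(range(n))
    clusters: list[Cluster] = []
    while remaining:
        idx = np.array(remaining)
        sub = matrix[np.ix_(idx, idx)]
        counts = np.sum(sub < cutoff, axis=1) - 1  # exclude self
        center_pos = int(np.argmax(counts))        # argmax → lowest index on ties
        members = idx[sub[center_pos] < cutoff].tolist()
        center = int(idx[center_pos])
        if center not in members:
            members.append(center)
        clusters.append(Cluster(center=center, members=sorted(members)))
        remaining = [i for i in remaining if i not in set(members)]
    return clusters


def representative_frame(trajectory: Trajectory, core: CoreSelection,
                         cutoff: float = DEFAULT_FRAME_CUTOFF) -> int:
    """Step-1 representative: gromos-cluster the frames on permuted core
    RMSD and return the centre of the largest cluster (ties → the cluster
    whose centre is the earliest frame)."""
    if len(trajectory) == 1:
        return 0
    mat = rmsd_matrix(trajectory.frames, core, permute=True)
    clusters = gromos_cluster(mat, cutoff)
    best = max(clusters, key=lambda c: (len(c.members), -c.center))
    return best.center


def rank_binding_modes(
    clusters: Sequence[Cluster],
    dimer_ids: Sequence[str],
    energies: Mapping[str, Mapping[str, float]],
    interface_stats: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Rank binding modes by mean member binding energy (most negative
    first).

    ``energies[dimer_id]`` must provide at least ``e_bind``; apolar/polar
    contributions and interface statistics (``interfacial_area_nm2``,
    ``initial_interface_pct``) are averaged when available.  Columns mirror
    the usual BM summary: rank, members, representative, Ebind, Ebind(Apo),
    Ebind(Pol), interfacial area, initial-interface retention.
    """
    rows = []
    for k, cl in enumerate(clusters):
        ids = [dimer_ids[i] for i in cl.members]
        missing = [d for d in ids if d not in energies]
        if missing:
            raise KeyError(f"no energy record for dimer(s) {missing}")
        eb = [float(energies[d]["e_bind"]) for d in ids]
        row = {
            "binding_mode": k + 1,
            "representative": dimer_ids[cl.center],
            "n_members": len(ids),
            "members": ",".join(map(str, ids)),
            "e_bind": float(np.mean(eb)),
            "e_bind_se": float(np.std(eb, ddof=1) / math.sqrt(len(eb))) if len(eb) > 1 else 0.0,
        }
        for key, col in (("apolar_contribution", "e_bind_apolar"),
                         ("polar_contribution", "e_bind_polar")):
            vals = [float(energies[d][key]) for d in ids if key in energies[d]]
            row[col] = float(np.mean(vals)) if vals else float("nan")
        if interface_stats is not None:
            for key in ("interfacial_area_nm2", "initial_interface_pct"):
                vals = [float(interface_stats[d][key]) for d in ids
                        if d in interface_stats and key in interface_stats[d]]
                row[key] = float(np.mean(vals)) if vals else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("e_bind", kind="stable").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


@dataclass
class DeltaPProfile:
    """Per-position interface probabilities and their best/worst-set
    differences."""

    table: pd.DataFrame   # position, P, P_best, P_worst, dP_best, dP_worst
    best_ids: list[str]
    worst_ids: list[str]

    def enriched_best(self) -> frozenset:
        t = self.table
        return frozenset(int(p) for p in t.loc[t["dP_best"] > 0, "position"])

    def enriched_worst(self) -> frozenset:
        t = self.table
        return frozenset(int(p) for p in t.loc[t["dP_worst"] > 0, "position"])


def hotspot_delta_p(
    memberships: Mapping[str, frozenset | set],
    e_bind: Mapping[str, float],
    fraction: float = DEFAULT_HOTSPOT_FRACTION,
) -> DeltaPProfile:
    """Best/worst interface-probability enrichment.

    ``memberships[dimer_id]`` is the set of residue positions (pooled over
    the two monomers) in that dimer's interface; dimers are sorted by
    ``e_bind`` and the lowest/highest ⌊fraction·n⌋ (minimum 1) form the best
    and worst sets.  ΔP_best = P_best − P and ΔP_worst = P_worst − P per
    position.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    ids = sorted(memberships)
    n = len(ids)
    if n < 2:
        raise ValueError("ΔP needs at least 2 dimers")
    missing = [d for d in ids if d not in e_bind]
    if missing:
        raise KeyError(f"no binding energy for dimer(s) {missing}")
    order = sorted(ids, key=lambda d: (float(e_bind[d]), d))
    k = max(1, int(math.floor(fraction * n)))
    best, worst = order[:k], order[-k:]
    positions = sorted({p for m in memberships.values() for p in m})
    rows = []
    for pos in positions:
        p_all = sum(pos in memberships[d] for d in ids) / n
        p_best = sum(pos in memberships[d] for d in best) / k
        p_worst = sum(pos in memberships[d] for d in worst) / k
        rows.append({"position": pos, "P": p_all, "P_best": p_best, "P_worst": p_worst,
                     "dP_best": p_best - p_all, "dP_worst": p_worst - p_all})
    return DeltaPProfile(table=pd.DataFrame(rows), best_ids=best, worst_ids=worst)
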