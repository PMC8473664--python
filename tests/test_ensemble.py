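"""Kabsch superposition, permuted core RMSD, gromos clustering, BM ranking
and the ΔP hot-spot statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindmodes.ensemble import (
    Cluster, core_rmsd, gromos_cluster, hotspot_delta_p, kabsch,
    permuted_rmsd, rank_binding_modes, representative_frame, rmsd_matrix,
)
from bindmodes.fixtures import (ToySpec, make_dimer, make_toy_monomer,
                                make_trajectory, random_transform)
from bindmodes.structure_io import CoreSelection, Trajectory
from conftest import random_rotation


def gromos_oracle(mat, cutoff):
    """Independent brute-force greedy rule: most neighbours (strict <),
    ties to the lowest index."""
    n = len(mat)
    remaining = list(range(n))
    out = []
    while remaining:
        best = None
        for i in remaining:
            nb = {j for j in remaining if mat[i][j] < cutoff} | {i}
            if best is None or len(nb) > len(best[1]):
                best = (i, nb)
        out.append((best[0], sorted(best[1])))
        remaining = [i for i in remaining if i not in best[1]]
    return out


def random_symmetric(rng, n, hi=10.0):
    m = rng.uniform(0, hi, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(8, 3))
        R, t, rmsd = kabsch(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_rotation(self, rng):
        pts = rng.normal(size=(10, 3))
        th = np.radians(30.0)
        Rz = np.array([[np.cos(th), -np.sin(th), 0],
                       [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        moved = pts @ Rz.T + np.array([1.0, -2.0, 3.0])
        R, t, rmsd = kabsch(moved, pts)
        np.testing.assert_allclose(R, Rz, atol=1e-8)
        assert rmsd < 1e-8

    def test_mirror_gives_proper_rotation(self, rng):
        pts = rng.normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        R, t, rmsd = kabsch(pts, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)
        assert rmsd > 0.1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError):
            kabsch(line, line)

    def test_scipy_cross_check(self, rng):
        from scipy.spatial.transform import Rotation
        pts = rng.normal(size=(12, 3))
        moved = pts @ random_rotation(rng).T + rng.normal(size=3)
        R, _, rmsd = kabsch(pts, moved)
        R_sp, rssd = Rotation.align_vectors(pts - pts.mean(0), moved - moved.mean(0))
        np.testing.assert_allclose(R, R_sp.as_matrix(), atol=1e-8)


@pytest.fixture(scope="module")
def dimer():
    mono = make_toy_monomer(ToySpec(seed=2))
    return make_dimer(mono, random_transform(np.random.default_rng(5), 13.0))


class TestCoreRmsd:
    def test_rigid_copy_zero(self, dimer, rng):
        core = ToySpec().core
        moved = dimer.transformed(random_rotation(rng), rng.normal(size=3) * 15)
        assert core_rmsd(dimer, moved, core) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric(self, dimer, rng):
        other = make_dimer(make_toy_monomer(ToySpec(seed=2)),
                           random_transform(rng, 13.0), jitter=0.3, seed=8)
        core = ToySpec().core
        assert core_rmsd(dimer, other, core) == pytest.approx(
            core_rmsd(other, dimer, core), rel=1e-9)

    def test_single_displacement_closed_form(self):
        # 6-point toy core with one point displaced radially by d: without a
        # fit the rmsd would be d/sqrt(6); the optimal fit absorbs the d/6
        # centroid shift (no torque for a radial displacement), leaving
        # residuals (5d/6, -d/6 x5) -> rmsd = sqrt(30 d²/36 / 6) = d*sqrt(5)/6
        ang = np.radians(np.arange(0, 360, 60))
        hexagon = np.column_stack([5 * np.cos(ang), 5 * np.sin(ang), np.zeros(6)])
        d = 1e-3
        displaced = hexagon.copy()
        displaced[0, 0] += d
        _, _, rmsd = kabsch(hexagon, displaced)
        assert rmsd == pytest.approx(d * np.sqrt(5) / 6, rel=1e-4)
        assert rmsd <= d / np.sqrt(6)  # the null-fit bound


class TestPermutedRmsd:
    def test_self_swap_zero(self):
        mono = make_toy_monomer(ToySpec(seed=4))
        dimer = make_dimer(mono, random_transform(np.random.default_rng(1), 13.0))
        from bindmodes.structure_io import merge
        a, b = dimer.chain("A"), dimer.chain("B")
        swapped = merge(b.with_chain("A"), a.with_chain("B"))
        core = ToySpec().core
        assert permuted_rmsd(dimer, swapped, core) == pytest.approx(0.0, abs=1e-9)

    def test_minimum_over_both_mappings(self, rng):
        core = ToySpec().core
        mono = make_toy_monomer(ToySpec(seed=4))
        d1 = make_dimer(mono, random_transform(rng, 13.0), jitter=0.4, seed=1)
        d2 = make_dimer(mono, random_transform(rng, 13.0), jitter=0.4, seed=2)
        from bindmodes.structure_io import merge
        a, b = d2.chain("A"), d2.chain("B")
        swapped = merge(b.with_chain("A"), a.with_chain("B"))
        direct = core_rmsd(d1, d2, core)
        other = core_rmsd(d1, swapped, core)
        assert permuted_rmsd(d1, d2, core) == pytest.approx(min(direct, other), rel=1e-9)
        assert permuted_rmsd(d1, d2, core) <= direct + 1e-12


class TestGromos:
    def test_all_within_cutoff_single_cluster(self):
        m = random_symmetric(np.random.default_rng(0), 8, hi=2.0)
        clusters = gromos_cluster(m, 4.0)
        assert len(clusters) == 1
        assert clusters[0].members == list(range(8))

    def test_all_far_singletons(self):
        m = random_symmetric(np.random.default_rng(1), 6, hi=10.0) + 5.0
        np.fill_diagonal(m, 0.0)
        clusters = gromos_cluster(m, 4.0)
        assert len(clusters) == 6
        assert all(len(c.members) == 1 for c in clusters)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 11))
            m = random_symmetric(rng, n)
            cutoff = float(rng.uniform(1, 9))
            ours = [(c.center, c.members) for c in gromos_cluster(m, cutoff)]
            assert ours == gromos_oracle(m.tolist(), cutoff)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        m = random_symmetric(rng, n)
        clusters = gromos_cluster(m, float(rng.uniform(0.5, 9)))
        all_members = [i for c in clusters for i in c.members]
        assert sorted(all_members) == list(range(n))
        assert len(set(all_members)) == n
        assert all(c.center in c.members for c in clusters)

    def test_lower_cutoff_never_fewer_clusters(self, rng):
        m = random_symmetric(rng, 10)
        counts = [len(gromos_cluster(m, c)) for c in (8.0, 6.0, 4.0, 2.0, 1.0)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestRepresentativeFrame:
    def test_single_and_identical_frames(self):
        mono = make_toy_monomer(ToySpec(seed=6))
        dimer = make_dimer(mono, random_transform(np.random.default_rng(2), 13.0))
        core = ToySpec().core
        one = Trajectory([dimer])
        assert representative_frame(one, core) == 0
        flat = make_trajectory(dimer, n_frames=4, noise=0.0, seed=0)
        assert representative_frame(flat, core) == 0

    def test_packed_majority_wins(self, rng):
        mono = make_toy_monomer(ToySpec(seed=6))
        dimer = make_dimer(mono, random_transform(rng, 13.0))
        core = ToySpec().core
        packed = make_trajectory(dimer, n_frames=4, noise=0.05, seed=3).frames
        outlier = dimer.transformed(None, None).with_coords(dimer.coords.copy())
        xyz = outlier.coords.copy()
        xyz[outlier.chains == "B"] += 30.0
        frames = packed + [outlier.with_coords(xyz)]
        idx = representative_frame(Trajectory(frames), core, cutoff=2.0)
        assert idx in (0, 1, 2, 3)
        # agrees with the oracle clustering on the same matrix
        mat = rmsd_matrix(frames, core)
        centers = gromos_oracle(mat.tolist(), 2.0)
        largest = max(centers, key=lambda c: (len(c[1]), -c[0]))
        assert idx == largest[0]

    def test_rigid_motion_invariance(self, rng):
        mono = make_toy_monomer(ToySpec(seed=7))
        dimer = make_dimer(mono, random_transform(rng, 13.0))
        core = ToySpec().core
        traj = make_trajectory(dimer, n_frames=5, noise=0.3, seed=5)
        R, t = random_rotation(rng), rng.normal(size=3) * 10
        moved = Trajectory([f.transformed(R, t) for f in traj.frames])
        assert representative_frame(traj, core) == representative_frame(moved, core)


class TestRanking:
    def test_order_and_shuffle_invariance(self):
        clusters = [Cluster(center=0, members=[0, 1]), Cluster(center=2, members=[2])]
        ids = ["d0", "d1", "d2"]
        energies = {"d0": {"e_bind": -55.0}, "d1": {"e_bind": -65.0},
                    "d2": {"e_bind": -80.0}}
        table = rank_binding_modes(clusters, ids, energies)
        assert list(table["e_bind"]) == [-80.0, -60.0]
        assert list(table["rank"]) == [1, 2]
        shuffled = rank_binding_modes(list(reversed(clusters)), ids, energies)
        assert list(shuffled["e_bind"]) == [-80.0, -60.0]

    def test_missing_energy_rejected(self):
        with pytest.raises(KeyError, match="d1"):
            rank_binding_modes([Cluster(center=0, members=[0, 1])], ["d0", "d1"],
                               {"d0": {"e_bind": -1.0}})


class TestDeltaP:
    def test_counting_by_hand(self):
        # 10 dimers; position 5 in the single best interface and in half of
        # all interfaces -> dP_best = 1 - 0.5 = 0.5
        memberships = {f"d{i}": frozenset({5} if i < 5 else {9}) for i in range(10)}
        e = {f"d{i}": float(i) for i in range(10)}  # d0 best, d9 worst
        prof = hotspot_delta_p(memberships, e, fraction=0.10)
        row = prof.table.set_index("position").loc[5]
        assert row["P"] == 0.5 and row["P_best"] == 1.0
        assert row["dP_best"] == 0.5
        assert prof.best_ids == ["d0"] and prof.worst_ids == ["d9"]

    def test_identical_ensemble_zero(self):
        memberships = {f"d{i}": frozenset({1, 2, 3}) for i in range(10)}
        e = {f"d{i}": float(i) for i in range(10)}
        prof = hotspot_delta_p(memberships, e)
        assert (prof.table["dP_best"] == 0).all()
        assert (prof.table["dP_worst"] == 0).all()

    def test_bounds_and_decomposition(self, rng):
        n = 20
        memberships = {f"d{i}": frozenset(int(p) for p in
                                          rng.choice(30, size=rng.integers(1, 10), replace=False))
                       for i in range(n)}
        e = {f"d{i}": float(rng.normal()) for i in range(n)}
        prof = hotspot_delta_p(memberships, e, fraction=0.10)
        t = prof.table
        assert t[["P", "P_best", "P_worst"]].min().min() >= 0.0
        assert t[["P", "P_best", "P_worst"]].max().max() <= 1.0
        assert (t["dP_best"].abs() <= 1.0).all()
        # weighted decomposition: P = f_b P_best + f_w P_worst + f_m P_mid
        k = 2
        mid = [d for d in memberships if d not in prof.best_ids + prof.worst_ids]
        for _, row in t.iterrows():
            p_mid = sum(row["position"] in memberships[d] for d in mid) / len(mid)
            recomposed = (k / n) * row["P_best"] + (k / n) * row["P_worst"] \
                + (len(mid) / n) * p_mid
            assert recomposed == pytest.approx(row["P"], abs=1e-12)

    def test_fraction_validation(self):
        memberships = {f"d{i}": frozenset({1}) for i in range(10)}
        e = {f"d{i}": float(i) for i in range(10)}
        for bad in (0.0, 0.6, -0.1, 1.0):
            with pytest.raises(ValueError):
                hotspot_delta_p(memberships, e, fraction=bad)

    def test_floor_with_minimum_one(self):
        memberships = {f"d{i}": frozenset({1}) for i in range(12)}
        e = {f"d{i}": float(i) for i in range(12)}
        prof = hotspot_delta_p(memberships, e, fraction=0.10)
        assert len(prof.best_ids) == len(prof.worst_ids) == 1
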