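"""NSD, superposition, clustering and density-to-bead conversion."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from saskit import shapes, synthio
from saskit.sasio import BeadModel, DensityGrid, ValidationError
from saskit.shapes import EmptyModelError


def unit_cube(offset=(0.0, 0.0, 0.0), edge=1.0):
    pts = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                   dtype=float) * edge
    return BeadModel(coords=pts + np.asarray(offset, float))


def brute_force_nsd(a: BeadModel, b: BeadModel) -> float:
    """Literal double-loop evaluation of the NSD definition."""
    def med_nn(c):
        n = len(c)
        d = np.full(n, np.inf)
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[i] = min(d[i], np.linalg.norm(c[i] - c[j]))
        return np.median(d)

    ca, cb = a.coords, b.coords
    da, db = med_nn(ca), med_nn(cb)
    t1 = np.mean([min(np.sum((p - q) ** 2) for q in cb) for p in ca]) / db**2
    t2 = np.mean([min(np.sum((q - p) ** 2) for p in ca) for q in cb]) / da**2
    return float(np.sqrt(0.5 * (t1 + t2)))


class TestNSD:
    def test_identity(self):
        m = synthio.random_bead_model(50, seed=0)
        assert shapes.nsd(m, m) == 0.0

    def test_symmetry(self):
        a = synthio.random_bead_model(40, seed=1)
        b = synthio.random_bead_model(40, seed=2)
        assert shapes.nsd(a, b) == pytest.approx(shapes.nsd(b, a), rel=1e-12)

    def test_offset_cubes_match_brute_force(self):
        a = unit_cube()
        b = unit_cube(offset=(10.0, 0.0, 0.0))
        assert shapes.nsd(a, b) == pytest.approx(brute_force_nsd(a, b), rel=1e-12)

    def test_invariance_under_common_rigid_motion(self):
        a = synthio.random_bead_model(40, seed=3)
        b = synthio.random_bead_model(40, seed=4)
        base = shapes.nsd(a, b)
        rng = np.random.default_rng(5)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20, 20, 3)
        moved = shapes.nsd(a.transformed(R, t), b.transformed(R, t))
        assert moved == pytest.approx(base, rel=1e-10)

    def test_single_point_rejected(self):
        one = BeadModel(coords=[[0.0, 0.0, 0.0]])
        with pytest.raises(ValidationError):
            shapes.nsd(one, one)


class TestSuperpose:
    def test_planted_rigid_motion_recovered(self):
        a = synthio.random_bead_model(40, envelope_radius=15, seed=6)
        rng = np.random.default_rng(7)
        R = Rotation.random(rng=rng).as_matrix()
        t = np.array([8.0, -5.0, 3.0])
        b = a.transformed(R, t)
        res = shapes.superpose(a, b)
        assert res.nsd_min < 1e-3
        restored = res.apply(b)
        np.testing.assert_allclose(restored.coords, a.coords, atol=0.2)

    def test_self_superposition_is_identity_like(self):
        a = synthio.random_bead_model(30, seed=8)
        res = shapes.superpose(a, a)
        assert res.nsd_min < 1e-6

    def test_mirror_image_needs_enantiomer_search(self):
        rng = np.random.default_rng(9)
        # a chiral point set: random, no internal symmetry
        a = synthio.random_bead_model(40, envelope_radius=15, seed=10)
        b = BeadModel(coords=a.coords * np.array([1.0, 1.0, -1.0]))
        with_m = shapes.superpose(a, b, enantiomers=True)
        without = shapes.superpose(a, b, enantiomers=False)
        assert with_m.nsd_min < 1e-3
        assert with_m.mirrored
        assert without.nsd_min > 10 * max(with_m.nsd_min, 1e-6)

    def test_pn_mode_recovers_rotation_modulo_symmetry(self):
        # C3-symmetric model: three blobs at 120° around z
        rng = np.random.default_rng(11)
        blob = rng.uniform(-3, 3, (10, 3)) + np.array([12.0, 0.0, 0.0])
        parts = []
        for ang in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
            c, s = np.cos(ang), np.sin(ang)
            Rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            parts.append(blob @ Rz.T)
        a = BeadModel(coords=np.vstack(parts))
        phi = np.deg2rad(40.0)
        c, s = np.cos(phi), np.sin(phi)
        b = a.transformed(np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]]),
                          np.zeros(3))
        res = shapes.superpose(a, b, symmetry="P3")
        assert res.nsd_min < 1e-3
        ang = np.arctan2(res.rotation[1, 0], res.rotation[0, 0])
        residual = (np.degrees(ang) + 40.0) % 120.0
        assert min(residual, 120.0 - residual) < 1.0


class TestClustering:
    def test_two_planted_groups(self):
        a = synthio.random_bead_model(30, seed=12)
        b = synthio.random_bead_model(30, seed=13, envelope_radius=50)
        models = [a, a, a, b, b, b]
        res = shapes.cluster_models(models, align_first=False)
        assert res.k_chosen == 2
        labels = res.labels
        assert len({labels[0], labels[1], labels[2]}) == 1
        assert len({labels[3], labels[4], labels[5]}) == 1
        assert labels[0] != labels[3]

    def test_seven_models_three_groups(self):
        """Seven reconstructions drawn from three distinct shapes split into
        three clusters (3 + 2 + 2)."""
        shapes_src = [synthio.random_bead_model(30, seed=k, envelope_radius=r)
                      for k, r in ((20, 15), (21, 30), (22, 60))]
        rng = np.random.default_rng(23)

        def jitter(m):
            return BeadModel(coords=m.coords + rng.normal(0, 0.15, m.coords.shape))

        models = ([jitter(shapes_src[0]) for _ in range(3)]
                  + [jitter(shapes_src[1]) for _ in range(2)]
                  + [jitter(shapes_src[2]) for _ in range(2)])
        res = shapes.cluster_models(models, align_first=False)
        assert res.k_chosen == 3
        sizes = sorted(np.bincount(res.labels))
        assert sizes == [2, 2, 3]
        for rep, c in zip(res.representatives, np.unique(res.labels)):
            assert res.labels[rep] == c

    def test_planted_k_recovery_rate_under_noise(self):
        srcs = [synthio.random_bead_model(25, seed=k, envelope_radius=r)
                for k, r in ((30, 12), (31, 30), (32, 70))]
        hits = 0
        for trial in range(20):
            rng = np.random.default_rng(100 + trial)
            models = [BeadModel(coords=s.coords + rng.normal(0, 0.2, s.coords.shape))
                      for s in srcs for _ in range(3)]
            res = shapes.cluster_models(models, align_first=False)
            hits += res.k_chosen == 3
        assert hits >= 16          # ≥ 80% of runs

    def test_permutation_invariance(self):
        srcs = [synthio.random_bead_model(20, seed=k, envelope_radius=r)
                for k, r in ((40, 12), (41, 40))]
        rng = np.random.default_rng(42)
        models = [BeadModel(coords=s.coords + rng.normal(0, 0.1, s.coords.shape))
                  for s in srcs for _ in range(3)]
        res1 = shapes.cluster_models(models, align_first=False)
        perm = [5, 2, 0, 4, 1, 3]
        res2 = shapes.cluster_models([models[i] for i in perm], align_first=False)
        # same partition up to relabelling
        for i in range(6):
            for j in range(6):
                same1 = res1.labels[perm[i]] == res1.labels[perm[j]]
                same2 = res2.labels[i] == res2.labels[j]
                assert same1 == same2

    def test_identical_models_single_cluster(self):
        m = synthio.random_bead_model(20, seed=50)
        res = shapes.cluster_models([m, m, m], align_first=False)
        assert res.k_chosen == 1


class TestDensityToBeads:
    def test_single_voxel(self):
        vals = np.zeros((3, 3, 3))
        vals[1, 1, 1] = 1.0
        g = DensityGrid(values=vals, voxel_size=2.0, origin=np.zeros(3))
        m = shapes.density_to_beads(g, 0.5)
        assert len(m) == 1
        np.testing.assert_allclose(m.coords[0], [2.0, 2.0, 2.0])

    def test_solid_block_surface_core_split(self):
        vals = np.zeros((9, 9, 9))
        vals[2:7, 2:7, 2:7] = 1.0
        g = DensityGrid(values=vals, voxel_size=2.0)
        m = shapes.density_to_beads(g, 0.5, surface_cutoff=1.0)
        assert len(m) == 125
        assert int(np.sum(m.refinable)) == 98          # 5³ − 3³
        assert int(np.sum(~m.refinable)) == 27

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        g = DensityGrid(values=rng.random((8, 8, 8)), voxel_size=1.5)
        counts = [len(shapes.density_to_beads(g, t))
                  for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_above_max_rejected(self):
        g = DensityGrid(values=np.full((4, 4, 4), 0.5), voxel_size=1.0)
        with pytest.raises(EmptyModelError):
            shapes.density_to_beads(g, 2.0)
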