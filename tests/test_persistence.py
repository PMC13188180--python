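import numpy as np
import pytest
from scipy import ndimage

import topovox as tv
from topovox.persistence import PersistenceDiagram, PersistencePair
from topovox.preprocess import DegenerateROIError


def _betti_from_pairs(diagram, t):
    return diagram.betti_at(t)


class TestComplexConstruction:
    def test_single_voxel_cell_census(self):
        cx = tv.build_filtration(np.array([[[7.0]]]))
        assert cx.n_cells == 27
        counts = np.bincount(cx.dims[cx.order], minlength=4)
        assert list(counts) == [8, 12, 6, 1]
        assert (cx.cell_values() == 7.0).all()

    def test_min_rule_on_shared_faces(self):
        # two voxels valued 3 and 5: the 9 shared-plane cells take the min
        cx = tv.build_filtration(np.array([3.0, 5.0]).reshape(2, 1, 1))
        vals = cx.cell_values()
        assert cx.n_cells == 45
        assert (vals == 3.0).sum() == 27   # left cube incl. shared plane
        assert (vals == 5.0).sum() == 18   # cells unique to the right cube

    def test_2d_lattice_count(self):
        cx = tv.build_filtration(np.ones((2, 2)))
        assert cx.n_cells == 25
        counts = np.bincount(cx.dims[cx.order], minlength=3)
        assert list(counts) == [9, 12, 4]

    def test_facets_present_with_smaller_value(self):
        rng = np.random.default_rng(0)
        cx = tv.build_filtration(rng.integers(0, 5, size=(3, 3, 3)).astype(float))
        vals = cx.values.ravel()
        for cell in list(cx.cells())[::7]:
            flat = np.ravel_multi_index(cell.anchor, cx.cell_shape)
            for facet in cx.boundary_of(flat):
                assert vals[facet] <= cell.value

    def test_mask_excludes_voxels(self):
        data = np.ones((2, 2, 2))
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        cx = tv.build_filtration(tv.VoxelGrid(data=data, mask=mask))
        assert cx.n_cells == 27  # only the one in-mask cube survives
        with pytest.raises(DegenerateROIError):
            tv.build_filtration(tv.VoxelGrid(data=data, mask=np.zeros((2, 2, 2), bool)))


class TestWorkedFiltration:
    def test_component_and_loop_events(self, worked_grid):
        D = tv.compute_persistence(tv.build_filtration(worked_grid))
        h0 = [p for p in D.pairs if p.dim == 0]
        h1 = [p for p in D.pairs if p.dim == 1]
        assert len(h0) == 4
        assert all(p.birth == 1 for p in h0)
        deaths = sorted(p.death for p in h0)
        assert deaths == [3, 5, 5, 5]
        assert sum(p.essential for p in h0) == 1
        assert len(h1) == 1
        assert (h1[0].birth, h1[0].death) == (1, 4)
        assert not h1[0].essential


class TestKnownTopology:
    def test_uniform_block_is_contractible(self):
        D = tv.roi_diagram(np.ones((5, 5, 5)))
        assert len(D.pairs) == 1
        p = D.pairs[0]
        assert (p.dim, p.essential) == (0, True)

    def test_hollow_sphere_has_one_cavity(self):
        # value-1 shell inside value-255 surroundings: H2 class born at 1
        vol = np.full((11, 11, 11), 255.0)
        c = np.array([5, 5, 5])
        d = np.sqrt(((np.indices(vol.shape) - c[:, None, None, None]) ** 2).sum(0))
        vol[(d > 2.5) & (d <= 4)] = 1.0
        D = tv.roi_diagram(vol)
        h2 = [p for p in D.pairs if p.dim == 2]
        assert len(h2) == 1
        assert h2[0].birth == 1.0
        assert h2[0].death == 255.0

    def test_solid_cube_betti(self):
        cx = tv.build_filtration(np.full((3, 3, 3), 9.0))
        assert tv.betti_at_threshold(cx, 9) == (1, 0, 0)
        assert tv.betti_at_threshold(cx, 8) == (0, 0, 0)

    def test_torus_and_shell_betti(self):
        ring, _ = tv.make_phantom(tv.PhantomSpec(shape=(14, 14, 14), n_blobs=0,
                                                 n_rings=1, seed=5))
        cx = tv.build_filtration(ring)
        assert tv.betti_at_threshold(cx, 100) == (1, 1, 0)
        hollow, _ = tv.make_phantom(tv.PhantomSpec(shape=(16, 16, 16), n_blobs=0,
                                                   n_hollow_tori=1, seed=7))
        assert tv.betti_at_threshold(tv.build_filtration(hollow), 100) == (1, 2, 1)


class TestOracleEquivalence:
    def test_pairs_match_rank_oracle_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            g = rng.integers(0, 4, size=(4, 4, 4)).astype(float)
            cx = tv.build_filtration(g)
            D = tv.compute_persistence(cx)
            for t in np.unique(g):
                assert D.betti_at(t) == tv.betti_at_threshold(cx, t)

    def test_pairs_match_rank_oracle_on_binary_2d(self):
        rng = np.random.default_rng(43)
        for _ in range(40):
            g = rng.integers(0, 2, size=(3, 3)).astype(float)
            if g.min() > 0.5:
                g[0, 0] = 0
            cx = tv.build_filtration(g)
            D = tv.compute_persistence(cx)
            for t in [0.0, 1.0]:
                assert D.betti_at(t) == tv.betti_at_threshold(cx, t)

    def test_h0_births_equal_connected_components_of_min_level(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            g = rng.integers(0, 3, size=(5, 5, 5)).astype(float)
            g.flat[rng.integers(0, g.size)] = 0  # ensure min level present
            D = tv.roi_diagram(g)
            n_born_at_min = sum(1 for p in D.pairs if p.dim == 0 and p.birth == g.min())
            # T-construction merges diagonally: 26-connectivity labeling
            _, n_comp = ndimage.label(g == g.min(), structure=np.ones((3, 3, 3)))
            assert n_born_at_min == n_comp


class TestEulerCurve:
    def test_single_voxel(self):
        cx = tv.build_filtration(np.array([[[4.0]]]))
        assert tv.euler_curve(cx, [4.0])[0] == 1.0
        assert tv.euler_curve(cx, [3.0])[0] == 0.0

    def test_2d_pixel_ring(self):
        g = np.full((5, 5), 9.0)
        g[1:4, 1:4] = 1.0
        g[2, 2] = 9.0  # ring of 8 pixels around a hole
        cx = tv.build_filtration(g)
        assert tv.euler_curve(cx, [1.0])[0] == 0.0  # beta0=1, beta1=1

    def test_identity_on_random_2d_grids(self):
        rng = np.random.default_rng(45)
        for _ in range(10):
            g = rng.integers(0, 5, size=(6, 6)).astype(float)
            cx = tv.build_filtration(g)
            for t in np.unique(g):
                b0, b1, _ = tv.betti_at_threshold(cx, t)
                assert tv.euler_curve(cx, [t])[0] == b0 - b1


class TestDiagramProperties:
    def test_birth_not_after_death(self):
        rng = np.random.default_rng(46)
        g = rng.integers(0, 6, size=(5, 5, 5)).astype(float)
        D = tv.roi_diagram(g)
        assert all(p.birth <= p.death for p in D.pairs)
        assert all(p.dim in (0, 1, 2) for p in D.pairs)
        assert any(p.dim == 0 for p in D.pairs)

    def test_invariant_under_monotone_relabeling(self):
        rng = np.random.default_rng(47)
        g = rng.integers(0, 6, size=(4, 4, 4)).astype(float)
        f = lambda v: v ** 2 + 3 * v   # strictly increasing on [0, inf)
        D1 = tv.roi_diagram(g)
        D2 = tv.roi_diagram(f(g))
        k1 = sorted((p.dim, f(p.birth), f(p.death), p.essential) for p in D1.pairs
                    if not p.essential)
        k2 = sorted((p.dim, p.birth, p.death, p.essential) for p in D2.pairs
                    if not p.essential)
        assert k1 == k2

    def test_json_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(48)
        D = tv.roi_diagram(rng.integers(0, 6, size=(4, 4, 4)).astype(float))
        p = tmp_path / "diagram.json"
        D.to_json(p)
        back = PersistenceDiagram.from_json(p)
        assert [(q.dim, q.birth, q.death, q.essential) for q in back.pairs] == \
               [(q.dim, q.birth, q.death, q.essential) for q in D.pairs]
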