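import numpy as np
import pytest

import topovox as tv
from topovox import features as ft
from topovox.persistence import PersistenceDiagram, PersistencePair


def diag(pairs_by_dim):
    pairs = [PersistencePair(d, b, dd) for d, pts in pairs_by_dim.items()
             for (b, dd) in pts]
    return PersistenceDiagram(pairs=pairs)


EMPTY = diag({})


class TestStats:
    def test_single_h1_point(self):
        s = dict(zip(ft._STAT_NAMES, ft.diagram_stats(diag({1: [(1, 4)]}), 1)))
        assert s["n_points"] == 1
        assert s["life_sum"] == 3 and s["life_mean"] == 3 and s["life_std"] == 0
        assert s["birth_max"] == 1 and s["death_max"] == 4

    def test_two_points_population_std(self):
        s = dict(zip(ft._STAT_NAMES, ft.diagram_stats(diag({0: [(0, 10), (0, 20)]}), 0)))
        assert s["life_mean"] == 15 and s["life_std"] == 5 and s["death_max"] == 20

    def test_empty_is_all_zero(self):
        assert (ft.diagram_stats(EMPTY, 0) == 0).all()


class TestEntropy:
    @pytest.mark.parametrize("pts,expected", [
        ([(0, 5)], 0.0),
        ([(0, 2), (3, 5)], np.log(2)),
        ([(0, 1), (0, 3)], -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))),
    ])
    def test_closed_forms(self, pts, expected):
        assert ft.persistence_entropy(diag({0: pts}), 0) == pytest.approx(expected)

    def test_empty_and_zero_lifetime(self):
        assert ft.persistence_entropy(EMPTY, 0) == 0.0


class TestBettiCurve:
    def test_single_interval(self):
        curve = ft.betti_curve(diag({0: [(10, 20)]}), 0)
        t = ft._bin_centers(0, 255, 30)
        np.testing.assert_array_equal(curve, ((10 <= t) & (t < 20)).astype(float))

    def test_empty_and_full_range(self):
        assert (ft.betti_curve(EMPTY, 1) == 0).all()
        assert (ft.betti_curve(diag({1: [(0, 255)]}), 1) == 1).all()


class TestLandscape:
    def test_single_tent(self):
        lam = ft.persistence_landscape(diag({0: [(10, 20)]}), 0).reshape(3, 50)
        t = ft._bin_centers(0, 255, 50)
        expected = np.maximum(0, np.minimum(t - 10, 20 - t))
        np.testing.assert_allclose(lam[0], expected)
        assert (lam[1:] == 0).all()

    def test_two_overlapping_tents_second_layer(self):
        lam = ft.persistence_landscape(diag({0: [(0, 20), (10, 30)]}), 0).reshape(3, 50)
        t = ft._bin_centers(0, 255, 50)
        t1 = np.maximum(0, np.minimum(t - 0, 20 - t))
        t2 = np.maximum(0, np.minimum(t - 10, 30 - t))
        np.testing.assert_allclose(lam[0], np.maximum(t1, t2))
        np.testing.assert_allclose(lam[1], np.minimum(t1, t2))

    def test_layers_are_pointwise_ordered(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0, 200, 20)
        pts = list(zip(b, b + rng.uniform(0, 55, 20)))
        lam = ft.persistence_landscape(diag({0: pts}), 0).reshape(3, 50)
        assert (lam[0] >= lam[1]).all() and (lam[1] >= lam[2]).all()
        assert (lam >= 0).all()


class TestAmplitudes:
    def test_closed_forms(self):
        a = ft.amplitudes(diag({0: [(0, 10)]}), 0)
        assert a[0] == pytest.approx(5.0)           # bottleneck = max l / 2
        assert a[1] == pytest.approx(10 / np.sqrt(2))
        assert (ft.amplitudes(EMPTY, 0) == 0).all()


class TestRasterSummaries:
    def test_empty_diagrams(self):
        assert (ft.persistence_image(EMPTY, 0) == 0).all()
        assert (ft.heat_kernel(EMPTY, 0) == 0).all()
        assert ft.persistence_image(EMPTY, 0).size == 20

    def test_image_linearity_in_multiplicity(self):
        one = ft.persistence_image(diag({0: [(100, 200)]}), 0)
        two = ft.persistence_image(diag({0: [(100, 200), (100, 200)]}), 0)
        np.testing.assert_allclose(two, 2 * one, atol=1e-12)

    def test_image_max_block_location(self):
        # point (birth=100, persistence=100) falls in 4x4 block (1, 1)
        vals = ft.persistence_image(diag({0: [(100, 200)]}), 0)
        blocks = vals[4:].reshape(4, 4)
        assert np.unravel_index(blocks.argmax(), (4, 4)) == (1, 1)

    def test_heat_kernel_vanishes_on_diagonal_and_antisymmetry(self):
        assert ft.heat_kernel(diag({0: [(50, 50)]}), 0) == pytest.approx(0)
        vals = ft.heat_kernel(diag({0: [(40, 90), (10, 200)]}), 0)
        grid_sum = vals[3]  # total signed mass ~ 0 by mirror antisymmetry
        assert abs(grid_sum) < 1e-6


class TestAssembly:
    def test_length_and_unique_names(self):
        vec = tv.assemble_features(diag({0: [(0, 50)], 1: [(10, 30)], 2: []}))
        assert vec.values.size == 717
        assert len(set(vec.names)) == 717
        assert np.isfinite(vec.values).all()

    def test_empty_everything_is_zero(self):
        vec = tv.assemble_features(EMPTY)
        assert (vec.values == 0).all()

    def test_point_order_invariance(self):
        pts = [(0, 30), (10, 90), (5, 200)]
        v1 = tv.assemble_features(diag({1: pts}))
        v2 = tv.assemble_features(diag({1: pts[::-1]}))
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_continuity_under_death_perturbation(self):
        eps = 1e-3
        pts = [(20.1, 60.2), (30.3, 90.4)]
        v1 = tv.assemble_features(diag({1: pts}))
        v2 = tv.assemble_features(diag({1: [(20.1, 60.2 + eps), (30.3, 90.4)]}))
        sel = [i for i, n in enumerate(v1.names)
               if n.startswith(("landscape_d1", "betti_d1", "life_", "death_"))]
        assert np.abs(v1.values[sel] - v2.values[sel]).max() < 10 * eps


class TestNaming:
    @pytest.mark.parametrize("name,family", [
        ("landscape_d1_l2_b30", "land_d1_l2"),
        ("landscape_d2_l0_b34", "land_d2_l0"),
        ("betti_d0_b12", "betti_d0"),
        ("pi_blk2_3_d0", "pi_d0"),
        ("hk_blk0_1_d1", "hk_d1"),
        ("life_std_d2", "life_std_d2"),
        ("entropy_d1", "entropy_d1"),
        ("amp_bottleneck_d2", "amp_bottleneck_d2"),
        ("hk_mean_d1", "hk_mean_d1"),
    ])
    def test_family_collapse(self, name, family):
        assert ft.feature_family(name) == family

    def test_expected_names_present(self):
        names = set(tv.feature_names())
        assert {"landscape_d1_l2_b30", "landscape_d2_l0_b34", "life_std_d2",
                "entropy_d0", "betti_d0_b12", "amp_wasserstein_d1",
                "pi_blk2_3_d0", "hk_mean_d1"} <= names


class TestGroupMeanLandscape:
    def test_equals_mean_of_per_sample_curves(self):
        rng = np.random.default_rng(1)
        diags = {}
        for i in range(6):
            b = rng.uniform(0, 100, 5)
            diags[f"s{i}"] = diag({1: list(zip(b, b + rng.uniform(5, 50, 5)))})
        table = ft.feature_table(diags)
        labels = [0, 0, 0, 1, 1, 1]
        out = ft.group_mean_landscape(table, labels, dim=1)
        manual = np.mean([ft.persistence_landscape(diags[f"s{i}"], 1).reshape(3, 50)
                          for i in range(3)], axis=0)
        np.testing.assert_allclose(out[0], manual, atol=1e-12)
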