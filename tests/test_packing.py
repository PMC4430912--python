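"""Tree-constrained CRF: energy terms, exact binary solver, alpha-expansion."""

import numpy as np
import pytest

import aphseg
from aphseg.packing import (ConstraintError, _binary_pylon_cut, leaf_unaries,
                            leaf_pair_weights)
from conftest import enumerate_valid_labelings, make_random_tree


def _toy_tree():
    """2x2 image, four singleton leaves + root, distinct intensities."""
    tree = aphseg.SegmentationTree(
        parent=np.array([4, 4, 4, 4, -1]),
        children=[[], [], [], [], [0, 1, 2, 3]],
        birth_level=np.zeros(5, dtype=np.int64),
        death_level=np.zeros(5, dtype=np.int64),
        sizes=np.array([1, 1, 1, 1, 4]),
        leaf_sets=[np.array([i]) for i in range(4)] + [np.arange(4)],
        root=4, n_levels=1,
        leaf_labels=np.array([[0, 1], [2, 3]], dtype=np.int32))
    img = np.array([[10, 60], [140, 230]], dtype=np.uint8)
    return tree, img


def _model(bins=4, k=2):
    h = np.full((k, bins), 1.0 / bins)
    return aphseg.HistogramModel(bins=bins, h=h, epsilon=1e-6)


class TestUnaryCost:
    def test_single_pixel_flat_histogram_costs_log_bins(self):
        tree, img = _toy_tree()
        model = _model(bins=4)
        assert aphseg.unary_cost(tree, 0, 1, img, model) == \
            pytest.approx(np.log(4))

    def test_additive_over_children(self, nodule_phantom):
        _, img, _, seed_raster = nodule_phantom
        ladder = aphseg.build_nested_ladder(img, [1, 16, 256])
        tree = aphseg.build_tree(ladder)
        model = aphseg.build_histograms(img, aphseg.seeds_from_raster(seed_raster))
        node = tree.root
        assert tree.children[node]
        parent_cost = aphseg.unary_cost(tree, node, 2, img, model)
        child_sum = sum(aphseg.unary_cost(tree, c, 2, img, model)
                        for c in tree.children[node])
        assert parent_cost == pytest.approx(child_sum)

    def test_hand_summed_five_pixel_node(self):
        tree, img = _toy_tree()
        h = np.array([[0.5, 0.25, 0.125, 0.125],
                      [0.1, 0.2, 0.3, 0.4]])
        model = aphseg.HistogramModel(bins=4, h=h, epsilon=1e-6)
        # root covers intensities 10, 60, 140, 230 -> bins 0, 0, 2, 3
        expected = -(2 * np.log(0.5) + np.log(0.125) + np.log(0.125))
        assert aphseg.unary_cost(tree, tree.root, 1, img, model) == \
            pytest.approx(expected)
        expected2 = -(2 * np.log(0.1) + np.log(0.3) + np.log(0.4))
        assert aphseg.unary_cost(tree, tree.root, 2, img, model) == \
            pytest.approx(expected2)

    def test_unselected_costs_nothing(self):
        tree, img = _toy_tree()
        assert aphseg.unary_cost(tree, 0, 0, img, _model()) == 0.0


class TestPairwiseCost:
    def test_uniform_labelmap_costs_nothing(self):
        tree, img = _toy_tree()
        params = aphseg.EnergyParams(n_labels=2, gamma=50.0, beta=0.1)
        assert aphseg.pairwise_cost(img, np.ones_like(img, dtype=int), params) == 0.0

    def test_gamma_zero(self):
        _, img = _toy_tree()
        params = aphseg.EnergyParams(n_labels=2, gamma=0.0, beta=0.1)
        labels = np.array([[1, 2], [2, 1]])
        assert aphseg.pairwise_cost(img, labels, params) == 0.0

    def test_vertical_split_arithmetic_oracle(self):
        img = np.array([[10, 30], [20, 70]], dtype=np.uint8)
        labels = np.array([[1, 2], [1, 2]])
        gamma, beta = 7.0, 1e-3
        params = aphseg.EnergyParams(n_labels=2, gamma=gamma, beta=beta)
        expected = gamma * (np.exp(-beta * 20.0**2) + np.exp(-beta * 50.0**2))
        assert aphseg.pairwise_cost(img, labels, params) == pytest.approx(expected)


class TestTotalEnergy:
    def test_single_node_tree(self):
        img = np.array([[50]], dtype=np.uint8)
        tree = aphseg.SegmentationTree(
            parent=np.array([-1]), children=[[]],
            birth_level=np.zeros(1, np.int64), death_level=np.zeros(1, np.int64),
            sizes=np.array([1]), leaf_sets=[np.array([0])], root=0, n_levels=0,
            leaf_labels=np.zeros((1, 1), dtype=np.int32))
        model = _model(bins=4)
        params = aphseg.EnergyParams(n_labels=2, gamma=1.0, beta=0.1)
        e = aphseg.total_energy(tree, aphseg.Labeling(y=np.array([1])),
                                img, model, params)
        assert e == pytest.approx(np.log(4))

    def test_matches_oracle_sums(self):
        tree, img = _toy_tree()
        h = np.array([[0.5, 0.25, 0.125, 0.125], [0.1, 0.2, 0.3, 0.4]])
        model = aphseg.HistogramModel(bins=4, h=h, epsilon=1e-6)
        gamma, beta = 3.0, 1e-4
        params = aphseg.EnergyParams(n_labels=2, gamma=gamma, beta=beta)
        y = np.array([1, 2, 2, 1, 0])   # leaves labelled individually
        labelmap = np.array([[1, 2], [2, 1]])
        # intensities 10, 60, 140, 230 fall in bins 0, 0, 2, 3
        u = -(np.log(0.5) + np.log(0.1) + np.log(0.3) + np.log(0.125))
        diffs = [(10, 60), (10, 140), (60, 230), (140, 230)]
        v = gamma * sum(np.exp(-beta * (a - b) ** 2) for a, b in diffs)
        e = aphseg.total_energy(tree, aphseg.Labeling(y=y), img, model, params)
        assert e == pytest.approx(u + v)
        assert np.array_equal(
            aphseg.labeling_to_pixelmap(tree, aphseg.Labeling(y=y)), labelmap)

    def test_overlapping_selection_rejected(self):
        tree, img = _toy_tree()
        y = np.array([1, 1, 1, 1, 2])   # root and leaves both selected
        with pytest.raises(ConstraintError):
            aphseg.total_energy(tree, aphseg.Labeling(y=y), img, _model(),
                                aphseg.EnergyParams(n_labels=2))

    def test_incomplete_labeling_rejected(self):
        tree, _ = _toy_tree()
        with pytest.raises(ConstraintError):
            aphseg.validate_labeling(tree, np.array([1, 1, 1, 0, 0]), 2)


class TestBinaryPylon:
    def test_single_node_tree_picks_argmin(self):
        img = np.array([[200]], dtype=np.uint8)
        tree = aphseg.SegmentationTree(
            parent=np.array([-1]), children=[[]],
            birth_level=np.zeros(1, np.int64), death_level=np.zeros(1, np.int64),
            sizes=np.array([1]), leaf_sets=[np.array([0])], root=0, n_levels=0,
            leaf_labels=np.zeros((1, 1), dtype=np.int32))
        h = np.array([[0.9, 0.1 / 3, 0.1 / 3, 0.1 / 3],
                      [0.1 / 3, 0.1 / 3, 0.1 / 3, 0.9]])
        model = aphseg.HistogramModel(bins=4, h=h, epsilon=1e-6)
        lab = aphseg.solve_binary_pylon(tree, img,
                                        model, aphseg.EnergyParams(n_labels=2))
        assert lab.y[0] == 2   # intensity 200 falls in the last bin

    def test_matches_exhaustive_minimum_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            tree = make_random_tree(rng, max_nodes=9)
            n, n_leaves = tree.n_nodes, tree.n_leaves
            c1, c2 = rng.random(n) * 3, rng.random(n) * 3
            pairs = sorted({(min(a, b), max(a, b))
                            for a, b in rng.integers(0, n_leaves, (n_leaves, 2))
                            if a != b})
            pa = np.array([p[0] for p in pairs], dtype=np.int64)
            pb = np.array([p[1] for p in pairs], dtype=np.int64)
            w = rng.random(pa.size) * 2
            theta = np.zeros((pa.size, 2, 2))
            theta[:, 0, 1] = w
            theta[:, 1, 0] = w
            side, y = _binary_pylon_cut(tree, c1, c2, pa, pb, theta)
            aphseg.validate_labeling(tree, y, 2)
            cost = sum((c1 if y[i] == 1 else c2)[i] for i in np.nonzero(y)[0])
            cost += sum(theta[e][side[pa[e]] - 1, side[pb[e]] - 1]
                        for e in range(pa.size))
            best = np.inf
            for sel in enumerate_valid_labelings(tree):
                s = np.zeros(n_leaves, dtype=int)
                c = 0.0
                for node, lab in sel:
                    c += (c1 if lab == 1 else c2)[node]
                    s[tree.leaf_sets[node]] = lab
                c += sum(theta[e][s[pa[e]] - 1, s[pb[e]] - 1]
                         for e in range(pa.size))
                best = min(best, c)
            assert cost == pytest.approx(best, abs=1e-5)

    def test_gamma_zero_reduces_to_per_path_argmin(self):
        # with no pairwise term the optimum labels every leaf independently
        # at the cheapest (node, label) on its path; additive unaries make
        # that the per-leaf argmin label
        tree, img = _toy_tree()
        h = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7]])
        model = aphseg.HistogramModel(bins=4, h=h, epsilon=1e-6)
        params = aphseg.EnergyParams(n_labels=2, gamma=0.0, beta=0.1)
        lab = aphseg.solve_binary_pylon(tree, img, model, params)
        pixmap = aphseg.labeling_to_pixelmap(tree, lab)
        table = leaf_unaries(tree, img, model)
        expected_leaf = 1 + np.argmin(table, axis=1)
        assert np.array_equal(pixmap.ravel()[[0, 1, 2, 3]],
                              expected_leaf[tree.leaf_labels.ravel()[[0, 1, 2, 3]]])

    def test_empty_tree_rejected(self):
        tree, img = _toy_tree()
        empty = aphseg.SegmentationTree(
            parent=np.empty(0, np.int64), children=[],
            birth_level=np.empty(0, np.int64), death_level=np.empty(0, np.int64),
            sizes=np.empty(0, np.int64), leaf_sets=[], root=-1, n_levels=0)
        with pytest.raises(ValueError):
            aphseg.solve_binary_pylon(empty, img, _model(),
                                      aphseg.EnergyParams(n_labels=2))


class TestSolveMultilabel:
    def test_k2_agrees_with_exact_binary_solver(self, two_level_img):
        ladder = aphseg.build_nested_ladder(two_level_img, [1, 4, 16])
        tree = aphseg.build_tree(ladder)
        raster = np.zeros_like(two_level_img, dtype=int)
        raster[2, 2], raster[2, 13] = 1, 2
        model = aphseg.build_histograms(two_level_img,
                                        aphseg.seeds_from_raster(raster))
        params = aphseg.EnergyParams(n_labels=2)
        exact = aphseg.solve_binary_pylon(tree, two_level_img, model, params)
        sweep = aphseg.solve_multilabel(tree, two_level_img, model, params)
        e_exact = aphseg.total_energy(tree, exact, two_level_img, model, params)
        e_sweep = aphseg.total_energy(tree, sweep, two_level_img, model, params)
        assert e_sweep == pytest.approx(e_exact)

    def test_energy_strictly_decreasing(self, nodule_phantom):
        _, img, _, seed_raster = nodule_phantom
        ladder = aphseg.build_nested_ladder(img, aphseg.default_q_ladder(64))
        tree = aphseg.build_tree(ladder)
        model = aphseg.build_histograms(img, aphseg.seeds_from_raster(seed_raster))
        params = aphseg.EnergyParams(n_labels=4)
        _, trace = aphseg.solve_multilabel(tree, img, model, params,
                                           return_trace=True)
        assert len(trace) >= 2
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_clean_phantom_with_informative_seeds_recovered(
            self, clean_nodule_phantom):
        _, img, gt, seed_raster = clean_nodule_phantom
        ladder = aphseg.build_nested_ladder(img, aphseg.default_q_ladder(256))
        tree = aphseg.build_tree(ladder)
        model = aphseg.build_histograms(img, aphseg.seeds_from_raster(seed_raster))
        params = aphseg.EnergyParams(n_labels=4)
        lab = aphseg.solve_multilabel(tree, img, model, params)
        aphseg.validate_labeling(tree, lab.y, 4)
        pixmap = aphseg.labeling_to_pixelmap(tree, lab)
        assert (pixmap == gt).mean() >= 0.99


class TestLabelingToPixelmap:
    def test_root_only(self):
        tree, _ = _toy_tree()
        out = aphseg.labeling_to_pixelmap(
            tree, aphseg.Labeling(y=np.array([0, 0, 0, 0, 1])))
        assert np.array_equal(out, np.ones((2, 2), dtype=int))

    def test_per_leaf(self):
        tree, _ = _toy_tree()
        out = aphseg.labeling_to_pixelmap(
            tree, aphseg.Labeling(y=np.array([1, 2, 1, 2, 0])))
        assert np.array_equal(out, np.array([[1, 2], [1, 2]]))

    def test_incomplete_rejected(self):
        tree, _ = _toy_tree()
        with pytest.raises(ConstraintError):
            aphseg.labeling_to_pixelmap(
                tree, aphseg.Labeling(y=np.array([1, 2, 1, 0, 0])))

    def test_mixed_depths_match_ancestor_walk(self, nodule_phantom):
        _, img, _, _ = nodule_phantom
        ladder = aphseg.build_nested_ladder(img[:48, :48], [1, 16, 256])
        tree = aphseg.build_tree(ladder)
        rng = np.random.default_rng(2)
        # random valid labelling: greedy antichain from the root
        y = np.zeros(tree.n_nodes, dtype=np.int64)
        stack = [tree.root]
        while stack:
            node = stack.pop()
            if not tree.children[node] or rng.random() < 0.5:
                y[node] = int(rng.integers(1, 3))
            else:
                stack.extend(tree.children[node])
        pixmap = aphseg.labeling_to_pixelmap(tree, aphseg.Labeling(y=y))
        # oracle: per-pixel ancestor walk
        leaf_lab = tree.leaf_labels
        for r in range(0, 48, 7):
            for c in range(0, 48, 7):
                node = int(leaf_lab[r, c])
                while y[node] == 0:
                    node = int(tree.parent[node])
                assert pixmap[r, c] == y[node]
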