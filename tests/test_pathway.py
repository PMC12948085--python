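"""Pathway-level encodings, attribution and spot extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scresponse import pathway as pw
from scresponse.containers import ExpressionMatrix, GeneSetCollection
from scresponse.errors import ValidationError


def _random_fixture(seed):
    rng = np.random.default_rng(seed)
    n_cells = rng.integers(2, 6)
    n_genes = rng.integers(3, 10)
    genes = [f"g{i}" for i in range(n_genes)]
    X = ExpressionMatrix(
        pd.DataFrame(
            np.round(rng.gamma(1.0, 1.0, size=(n_cells, n_genes)) * rng.integers(0, 2, (n_cells, n_genes)), 4),
            index=[f"c{i}" for i in range(n_cells)],
            columns=genes,
        )
    )
    n_paths = rng.integers(1, 5)
    sets = {}
    for p in range(n_paths):
        size = rng.integers(1, n_genes + 1)
        sets[f"P{p}"] = list(rng.choice(genes, size=size, replace=False))
    return X, GeneSetCollection(sets)


class TestPairExpansion:
    def test_enumerated_example(self, tiny_matrix, tiny_sets):
        pairs = pw.expand_gene_pathway_pairs(tiny_matrix, tiny_sets)
        assert list(pairs.columns) == ["g1.P1", "g2.P1", "g2.P2", "g3.P2"]
        # pair column equals the underlying gene column for every cell
        np.testing.assert_array_equal(pairs["g2.P1"], tiny_matrix.data["g2"])
        np.testing.assert_array_equal(pairs["g2.P2"], tiny_matrix.data["g2"])

    def test_gene_outside_all_pathways_contributes_nothing(self, tiny_matrix):
        sets = GeneSetCollection({"P1": ["g1", "zzz"]})
        pairs = pw.expand_gene_pathway_pairs(tiny_matrix, sets)
        assert list(pairs.columns) == ["g1.P1"]

    def test_empty_overlap_rejected(self, tiny_matrix):
        with pytest.raises(ValidationError):
            pw.expand_gene_pathway_pairs(tiny_matrix, GeneSetCollection({"P1": ["nope"]}))


class TestImages:
    def test_membership_zeros_and_values(self, tiny_matrix, tiny_sets):
        stack, legend = pw.build_gene_pathway_images(tiny_matrix, tiny_sets)
        assert stack.shape == (2, 3, 2)
        g1 = legend.genes.index("g1")
        p1 = legend.pathways.index("P1")
        p2 = legend.pathways.index("P2")
        np.testing.assert_array_equal(stack[:, g1, p1], tiny_matrix.data["g1"])
        np.testing.assert_array_equal(stack[:, g1, p2], 0.0)  # g1 not in P2

    def test_requested_shape_matches_universe(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(383)]
        X = ExpressionMatrix(
            pd.DataFrame(rng.gamma(1, 1, size=(2, 383)), index=["c0", "c1"], columns=genes)
        )
        sets = GeneSetCollection(
            {f"P{p:03d}": genes[p * 2 : p * 2 + 13] for p in range(186)}
        )
        stack, legend = pw.build_gene_pathway_images(X, sets)
        assert stack.shape[1:] == (len(legend.genes), 186)

    @given(st.integers(0, 199))
    def test_pair_and_image_encodings_conserve_nonzero_triples(self, seed):
        X, sets = _random_fixture(seed)
        try:
            pairs = pw.expand_gene_pathway_pairs(X, sets)
        except ValidationError:
            return  # no overlap in this random fixture
        stack, legend = pw.build_gene_pathway_images(X, sets)
        for ci, cell in enumerate(X.row_ids):
            from_pairs = {
                (col.split(".")[0], col.split(".")[1]): v
                for col, v in pairs.loc[cell].items()
                if v != 0
            }
            from_image = {
                (legend.genes[gi], legend.pathways[pi]): float(stack[ci, gi, pi])
                for gi, pi in zip(*np.nonzero(stack[ci]))
            }
            assert set(from_pairs) == set(from_image)
            for key, v in from_pairs.items():
                # images are stored float32; values agree to that precision
                assert from_image[key] == pytest.approx(v, rel=1e-6)
        # feature-count conservation: pair columns = nonstructural-zero capacity
        assert pairs.shape[1] == int(legend.membership.sum())


class TestSpotExtraction:
    def _legend(self, h, w):
        return pw.ImageLegend(
            genes=[f"g{i}" for i in range(h)],
            pathways=[f"P{j}" for j in range(w)],
            membership=np.ones((h, w), dtype=bool),
        )

    def test_constructed_block_recovered_exactly(self):
        grid = np.zeros((8, 6))
        grid[2:6, 1:3] = 5.0  # one contiguous 4x2 positive block
        grid[7, 5] = -3.0
        spots = pw.extract_spots(grid, self._legend(8, 6), q=0.5)
        pos = [s for s in spots if s.sign == "responder"][0]
        assert pos.genes == ["g2", "g3", "g4", "g5"]
        assert pos.pathways == ["P1", "P2"]
        assert pos.mass == pytest.approx(40.0)
        neg = [s for s in spots if s.sign == "non-responder"][0]
        assert neg.genes == ["g7"] and neg.pathways == ["P5"]

    def test_all_zero_grid_has_no_spots(self):
        assert pw.extract_spots(np.zeros((4, 4)), self._legend(4, 4)) == []

    def test_boundary_quantile_keeps_argmax_only(self):
        grid = np.arange(12.0).reshape(3, 4)
        spots = pw.extract_spots(grid, self._legend(3, 4), q=1.0)
        assert len(spots) == 1
        assert spots[0].coordinates == [(2, 3)]

    def test_antisymmetry_of_signs(self):
        rng = np.random.default_rng(1)
        grid = rng.normal(size=(6, 6))
        a = pw.extract_spots(grid, self._legend(6, 6), q=0.7)
        b = pw.extract_spots(-grid, self._legend(6, 6), q=0.7)
        by_sign_a = {s.sign: s for s in a}
        by_sign_b = {s.sign: s for s in b}
        assert by_sign_a["responder"].coordinates == by_sign_b["non-responder"].coordinates


class TestBaselinesShareSplits:
    def test_fingerprints_identical_across_models(self, rng):
        n = 80
        pairs = pd.DataFrame(
            rng.gamma(1, 1, size=(n, 24)),
            index=[f"c{i}" for i in range(n)],
            columns=[f"g{i}.P0" for i in range(24)],
        )
        labels = np.array(["responder", "non-responder"] * (n // 2))
        reports = pw.baseline_suite_on_pairs(
            pairs, labels, models=("logistic_regression", "xgboost"), seed=0, cv_folds=3, n_iter=1
        )
        fps = {r.params["split_fingerprint"] for r in reports.values()}
        assert len(fps) == 1


class TestGradCamUpsampling:
    def test_maps_are_nonnegative_and_image_shaped(self, rng):
        from scresponse import nn

        net = nn.build_pathway_cnn2d(12, 10, seed=0, filters=(4, 3), dense_units=4)
        X = rng.gamma(1, 1, size=(3, 12, 10))
        cams = pw.gradcam_heatmap(net, X, class_index=1)
        assert cams.shape == (3, 12, 10)
        assert (cams >= 0).all()

    def test_single_cell_per_class_maps_equal_those_cells_maps(self, rng):
        from scresponse import nn

        net = nn.build_pathway_cnn2d(12, 10, seed=0, filters=(4, 3), dense_units=4)
        X = rng.gamma(1, 1, size=(2, 12, 10))
        labels = np.array(["responder", "non-responder"])
        legend = pw.ImageLegend(
            genes=[f"g{i}" for i in range(12)],
            pathways=[f"P{j}" for j in range(10)],
            membership=np.ones((12, 10), dtype=bool),
        )
        att = pw.class_mean_maps(net, X, labels, legend)
        np.testing.assert_allclose(att.responder, pw.gradcam_heatmap(net, X[:1], 1)[0])
        np.testing.assert_allclose(att.nonresponder, pw.gradcam_heatmap(net, X[1:], 0)[0])
        np.testing.assert_allclose(att.difference, att.responder - att.nonresponder)

    def test_missing_class_rejected(self, rng):
        from scresponse import nn

        net = nn.build_pathway_cnn2d(12, 10, seed=0, filters=(4, 3), dense_units=4)
        X = rng.gamma(1, 1, size=(3, 12, 10))
        legend = pw.ImageLegend(
            genes=[f"g{i}" for i in range(12)],
            pathways=[f"P{j}" for j in range(10)],
            membership=np.ones((12, 10), dtype=bool),
        )
        with pytest.raises(ValidationError):
            pw.class_mean_maps(net, X, np.array(["responder"] * 3), legend)
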