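"""Feature-to-image template: normalization, layout, assignment, rendering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from locforge.descriptors import FeatureVector
from locforge.pfimg import (
    PFImgTemplate,
    assign_to_grid,
    build_template,
    feature_distance_matrix,
    fit_normalizer,
    reduce_to_plane,
    render_image,
    render_images,
    square_grid_dims,
)


def _assignment_cost(points, placement, grid):
    h, w = grid
    lo, hi = points.min(axis=0), points.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (points - lo) / span * np.array([h, w])
    return sum(
        ((scaled[i] - np.array([r + 0.5, c + 0.5])) ** 2).sum()
        for i, (r, c) in placement.items()
    )


class TestNormalizer:
    def test_affine_mapping(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        norm = fit_normalizer(frame)
        np.testing.assert_allclose(norm.apply(np.array([[1.0], [2.0], [3.0]])).ravel(), [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        norm = fit_normalizer(pd.DataFrame({"x": [5.0, 5.0, 5.0]}))
        np.testing.assert_array_equal(norm.apply(np.array([5.0])), [0.0])

    def test_unseen_value_extrapolates_then_clamps_at_render(self):
        frame = pd.DataFrame({"x": [1.0, 3.0]})
        norm = fit_normalizer(frame)
        assert norm.apply(np.array([4.0]))[0] == pytest.approx(1.5)
        template = PFImgTemplate(1, 1, {"x": (0, 0)}, norm)
        image = render_image(FeatureVector(["x"], np.array([4.0])), template)
        assert image.pixels[0, 0] == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_normalizer(pd.DataFrame())


class TestDistance:
    def test_identical_columns_distance_zero(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert feature_distance_matrix(X)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_columns_distance_one(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert feature_distance_matrix(X)[0, 1] == pytest.approx(1.0)

    def test_hand_computed_cosine(self):
        X = np.array([[1.0, 1.0], [0.0, 1.0]])
        assert feature_distance_matrix(X)[0, 1] == pytest.approx(1 - 1 / np.sqrt(2))

    def test_zero_column_is_maximally_dissimilar(self):
        X = np.array([[0.0, 1.0, 0.5], [0.0, 2.0, 0.25]])
        D = feature_distance_matrix(X)
        assert D[0, 1] == 1.0 and D[0, 2] == 1.0 and D[0, 0] == 0.0

    def test_protein_row_permutation_invariance(self, rng):
        X = rng.random((10, 6))
        perm = rng.permutation(10)
        np.testing.assert_allclose(
            feature_distance_matrix(X), feature_distance_matrix(X[perm]), atol=1e-12
        )

    def test_needs_two_descriptors(self):
        with pytest.raises(ValueError):
            feature_distance_matrix(np.ones((3, 1)))


class TestReduction:
    def test_classical_mds_recovers_planar_distances(self):
        D = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, np.sqrt(2)], [1.0, np.sqrt(2), 0.0]])
        coords = reduce_to_plane(D, method="mds")
        recovered = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(recovered, D, atol=1e-6)

    def test_two_descriptors_minimal_case(self):
        coords = reduce_to_plane(np.array([[0.0, 0.5], [0.5, 0.0]]), method="mds")
        assert coords.shape == (2, 2)
        assert not np.allclose(coords[0], coords[1])

    @pytest.mark.parametrize("method", ["mds", "pca", "umap"])
    def test_same_seed_same_layout(self, method, rng):
        X = rng.random((12, 30))
        D = feature_distance_matrix(X)
        a = reduce_to_plane(D, method=method, seed=3)
        b = reduce_to_plane(D, method=method, seed=3)
        np.testing.assert_array_equal(a, b)


class TestAssignment:
    def test_four_corner_points_get_identity_assignment(self):
        # 2x2 grid: the four bounding-box corners map one-to-one onto the
        # four cells in reading order, at the exhaustive-minimum cost
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        placement = assign_to_grid(pts, 2, 2)
        assert placement == {0: (0, 0), 1: (0, 1), 2: (1, 0), 3: (1, 1)}
        cells = [(r, c) for r in range(2) for c in range(2)]
        brute = min(
            _assignment_cost(pts, dict(enumerate(perm)), (2, 2))
            for perm in itertools.permutations(cells, 4)
        )
        assert _assignment_cost(pts, placement, (2, 2)) == pytest.approx(brute)

    def test_matches_exhaustive_permutation_minimum(self, rng):
        for _ in range(10):
            pts = rng.random((6, 2))
            placement = assign_to_grid(pts, 2, 3)
            cost = _assignment_cost(pts, placement, (2, 3))
            cells = [(r, c) for r in range(2) for c in range(3)]
            brute = min(
                _assignment_cost(pts, dict(enumerate(perm)), (2, 3))
                for perm in itertools.permutations(cells, 6)
            )
            assert cost == pytest.approx(brute, rel=1e-12)

    def test_single_point_single_cell(self):
        assert assign_to_grid(np.array([[0.3, 0.7]]), 1, 1) == {0: (0, 0)}

    def test_overfull_grid_rejected(self):
        with pytest.raises(ValueError):
            assign_to_grid(np.zeros((5, 2)), 2, 2)

    def test_square_grid_dims(self):
        assert square_grid_dims(1484) == (39, 39)
        assert square_grid_dims(420) == (21, 21)
        assert square_grid_dims(16) == (4, 4)


class TestTemplateAndRender:
    @pytest.fixture()
    def small_template(self, rng):
        frame = pd.DataFrame(
            rng.random((15, 9)), columns=[f"d{i}" for i in range(9)]
        )
        return frame, build_template(frame, method="mds", seed=0)

    def test_placement_is_bijective(self, small_template):
        _, template = small_template
        cells = list(template.placement.values())
        assert len(set(cells)) == len(cells) == 9

    def test_duplicate_cell_rejected(self, small_template):
        _, template = small_template
        with pytest.raises(ValueError, match="injective"):
            PFImgTemplate(
                template.grid_height,
                template.grid_width,
                {"a": (0, 0), "b": (0, 0)},
                template.normalizer,
            )

    def test_zero_vector_renders_zero_image(self, small_template):
        frame, template = small_template
        lows = template.normalizer.min
        fv = FeatureVector(template.normalizer.names, lows)
        image = render_image(fv, template)
        assert np.all(image.pixels == 0.0)

    def test_pixel_sum_conservation(self, small_template, rng):
        frame, template = small_template
        values = rng.random(9)
        fv = FeatureVector(template.normalizer.names, values)
        image = render_image(fv, template)
        normalized = np.clip(template.normalizer.apply(values), 0, 1)
        assert image.pixels.sum() == pytest.approx(normalized.sum(), abs=1e-9)

    def test_missing_descriptor_named_in_error(self, small_template):
        _, template = small_template
        fv = FeatureVector(["other"], np.array([1.0]))
        with pytest.raises(ValueError, match="d0"):
            render_image(fv, template)

    def test_render_is_idempotent_given_template(self, small_template, rng):
        frame, template = small_template
        fv = FeatureVector(template.normalizer.names, rng.random(9))
        a = render_image(fv, template)
        b = render_image(fv, template)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_serialization_round_trip(self, small_template, tmp_path):
        _, template = small_template
        path = tmp_path / "template.json"
        template.to_json(path)
        loaded = PFImgTemplate.from_json(path)
        assert loaded.placement == template.placement
        np.testing.assert_array_equal(loaded.normalizer.min, template.normalizer.min)
        np.testing.assert_array_equal(loaded.normalizer.max, template.normalizer.max)

    def test_training_matrix_normalizes_into_unit_interval(self, small_template):
        frame, template = small_template
        normalized = template.normalizer.apply_frame(frame).to_numpy()
        assert normalized.min() >= 0.0 and normalized.max() <= 1.0

    def test_render_images_matches_single_renders(self, small_template, rng):
        frame, template = small_template
        images = render_images(frame, template)
        fv = FeatureVector(list(frame.columns), frame.iloc[0].to_numpy())
        single = render_image(fv, template)
        np.testing.assert_allclose(images[str(frame.index[0])].pixels, single.pixels)
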