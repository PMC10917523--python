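import numpy as np
import pandas as pd
import pytest

from magicquant.image_io import sum_project
from magicquant.synth import (
    ChaseSpec,
    PlacementError,
    SceneSpec,
    generate_chase,
    generate_scene,
    write_scene,
)

NOISELESS = dict(poisson_scale=0.0, read_noise_sd=0.0)


class TestSceneSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_cells=0),
            dict(mito_fraction=1.2),
            dict(aggregate_fraction_true=-0.1),
            dict(reporter_mito_enrichment=-1.0),
            dict(marker="golgi"),
            dict(image_shape=(0, 64, 64)),
            dict(n_cells=2, n_touching_pairs=2),
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SceneSpec(**kwargs)

    def test_placement_budget_exceeded(self):
        # far more cell area than the frame can hold
        spec = SceneSpec(
            image_shape=(2, 96, 96), n_cells=40, n_touching_pairs=0, max_placement_tries=50
        )
        with pytest.raises(PlacementError):
            generate_scene(spec)


class TestSceneDeterminism:
    def test_same_spec_same_seed_bit_identical(self):
        spec = SceneSpec(n_cells=5, n_touching_pairs=1, seed=7)
        s1, s2 = generate_scene(spec), generate_scene(spec)
        np.testing.assert_array_equal(s1.gfp_stack.voxels, s2.gfp_stack.voxels)
        np.testing.assert_array_equal(s1.marker_stack.voxels, s2.marker_stack.voxels)
        np.testing.assert_array_equal(s1.cell_truth.labels, s2.cell_truth.labels)
        pd.testing.assert_frame_equal(s1.true_values, s2.true_values)

    def test_different_seed_differs(self):
        a = generate_scene(SceneSpec(n_cells=5, seed=1))
        b = generate_scene(SceneSpec(n_cells=5, seed=2))
        assert not np.array_equal(a.cell_truth.labels, b.cell_truth.labels)


class TestSceneGroundTruth:
    def test_masks_contained_in_owning_cell(self, mito_scene):
        labels = mito_scene.cell_truth.labels
        for mask in (mito_scene.mito_truth, mito_scene.puncta_truth):
            on = mask > 0
            # every structure pixel lies inside exactly the cell that owns it
            assert np.array_equal(labels[on], mask[on])

    def test_one_truth_row_per_cell(self, mito_scene):
        assert len(mito_scene.true_values) == mito_scene.spec.n_cells
        assert set(mito_scene.true_values["cell_id"]) == set(mito_scene.cell_truth.cell_ids)

    def test_enrichment_one_uniform_inside_cells(self):
        spec = SceneSpec(
            n_cells=6, reporter_mito_enrichment=1.0, cell_brightness_cv=0.0, **NOISELESS
        )
        scene = generate_scene(spec)
        proj = sum_project(scene.gfp_stack).pixels
        labels = scene.cell_truth.labels
        for cid in scene.cell_truth.cell_ids:
            vals = proj[labels == cid]
            assert np.ptp(vals) < 1e-9  # mito pixels indistinguishable

    def test_noiseless_enrichment_ratio_exact(self):
        spec = SceneSpec(
            n_cells=8,
            reporter_mito_enrichment=3.0,
            cell_brightness_cv=0.0,
            background_level=0.0,
            **NOISELESS,
        )
        scene = generate_scene(spec)
        proj = sum_project(scene.gfp_stack).pixels
        mito = scene.mito_truth > 0
        cyto = (scene.cell_truth.labels > 0) & ~mito
        ratio = proj[mito].mean() / proj[cyto].mean()
        assert ratio == pytest.approx(3.0, abs=0.01)

    def test_noiseless_render_matches_designed_means(self):
        spec = SceneSpec(n_cells=5, reporter_mito_enrichment=2.0, **NOISELESS)
        scene = generate_scene(spec)
        proj = sum_project(scene.gfp_stack).pixels
        for _, row in scene.true_values.iterrows():
            cid = row["cell_id"]
            mito = scene.mito_truth == cid
            assert proj[mito].mean() == pytest.approx(row["mito_mean_true"], rel=1e-9)

    def test_touching_pair_adjacent_not_overlapping(self, mito_scene):
        labels = mito_scene.cell_truth.labels
        m1, m2 = labels == 1, labels == 2
        assert not (m1 & m2).any()
        from scipy import ndimage as ndi

        grown = ndi.binary_dilation(m1, iterations=2)
        assert (grown & m2).any()  # within 2 px: they share a boundary

    def test_aggregate_count_matches_fraction(self):
        spec = SceneSpec(n_cells=10, aggregate_fraction_true=0.3, seed=2)
        scene = generate_scene(spec)
        assert scene.true_values["has_aggregate_true"].sum() == 3


class TestWriteScene:
    def test_scene_files_written(self, tmp_path):
        scene = generate_scene(SceneSpec(n_cells=4, n_touching_pairs=0, seed=1))
        write_scene(scene, tmp_path)
        for name in ("gfp.tif", "marker.tif", "truth.csv", "scene_spec.json"):
            assert (tmp_path / name).exists()


class TestChase:
    def test_no_decay_no_noise_constant(self):
        spec = ChaseSpec(n_cells=3, decay_rate_per_min=0.0, cell_cv=0.0, seed=0)
        table = generate_chase(spec)
        chase = table[~table["is_background"]]
        assert np.allclose(chase["intensity"], spec.initial_mean + spec.background_mean)

    def test_half_life_closed_form(self):
        spec = ChaseSpec(
            n_cells=1,
            decay_rate_per_min=np.log(2) / 20.0,
            background_mean=0.0,
            cell_cv=0.0,
            seed=0,
        )
        table = generate_chase(spec)
        chase = table[~table["is_background"]].set_index("time_min")["intensity"]
        assert chase[20.0] == pytest.approx(chase[0.0] / 2.0, rel=1e-12)

    def test_sample_mean_tracks_closed_form(self):
        spec = ChaseSpec(n_cells=5000, decay_rate_per_min=0.05, cell_cv=0.2, seed=1)
        table = generate_chase(spec)
        chase = table[~table["is_background"]]
        means = chase.groupby("time_min")["intensity"].mean()
        for t, m in means.items():
            expected = spec.background_mean + spec.initial_mean * np.exp(-0.05 * t)
            assert m == pytest.approx(expected, rel=0.02)

    def test_background_rows_present(self):
        table = generate_chase(ChaseSpec(n_cells=4, seed=0))
        assert table["is_background"].sum() == 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(timepoints_min=(0.0, 10.0, 10.0)),
            dict(decay_rate_per_min=-0.1),
            dict(n_cells=0),
        ],
    )
    def test_invalid_chase_spec(self, kwargs):
        with pytest.raises(ValueError):
            ChaseSpec(**kwargs)
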