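import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germseg import (
    TRAINING_CONFIG,
    AugmentationSpec,
    OrthoView,
    augment_pair,
    build_training_set,
    extract_ortho_view,
    split_train_test,
)


class TestExtractOrthoView:
    def test_xy_view_is_the_raw_slice(self, small_scene):
        grid, labels, _ = small_scene
        view = extract_ortho_view(grid, labels, "xy", 10)
        np.testing.assert_array_equal(view.image, grid.data[10])
        np.testing.assert_array_equal(view.mask, labels.labels[10])

    @pytest.mark.parametrize("orientation", ["xz", "yz"])
    def test_side_views_resampled_to_isotropy(self, small_scene, orientation):
        grid, labels, _ = small_scene
        view = extract_ortho_view(grid, labels, orientation, 48)
        expected_h = grid.shape[0] * grid.anisotropy
        assert abs(view.image.shape[0] - expected_h) <= 1.5
        assert view.image.shape == view.mask.shape

    def test_side_view_labels_subset_of_volume_ids(self, small_scene):
        grid, labels, _ = small_scene
        view = extract_ortho_view(grid, labels, "xz", 40)
        assert set(np.unique(view.mask)) <= set(np.unique(labels.labels))

    def test_index_out_of_range(self, small_scene):
        grid, labels, _ = small_scene
        with pytest.raises(IndexError):
            extract_ortho_view(grid, labels, "xy", grid.shape[0])

    def test_bad_orientation(self, small_scene):
        grid, labels, _ = small_scene
        with pytest.raises(ValueError):
            extract_ortho_view(grid, labels, "zz", 0)


class TestSplitTrainTest:
    def test_120_items_give_108_train_12_test(self):
        train, test = split_train_test(list(range(120)), 0.1, seed=0)
        assert (len(train), len(test)) == (108, 12)

    def test_even_split_of_ten(self):
        train, test = split_train_test(list(range(10)), 0.5, seed=1)
        assert (len(train), len(test)) == (5, 5)

    def test_same_seed_reproduces_partition(self):
        items = [f"img{i}" for i in range(37)]
        assert split_train_test(items, 0.2, seed=9) == split_train_test(items, 0.2, seed=9)

    def test_is_a_partition(self):
        items = list(range(53))
        train, test = split_train_test(items, 0.25, seed=3)
        assert sorted(train + test) == items
        assert not set(train) & set(test)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_train_test([1], 0.5, seed=0)


def _checker_view(n=64, n_instances=3):
    rng = np.random.default_rng(0)
    img = rng.random((n, n)).astype(np.float32)
    mask = np.zeros((n, n), dtype=np.int32)
    for k in range(1, n_instances + 1):
        y, x = rng.integers(5, n - 15, size=2)
        mask[y : y + 9, x : x + 9] = k
    return OrthoView(image=img, mask=mask, orientation="xy", source_id="t")


class TestAugmentPair:
    def test_degenerate_spec_is_identity(self):
        view = _checker_view()
        spec = AugmentationSpec(
            p_flip_h=0.0,
            p_flip_v=0.0,
            rotation_range_deg=(0.0, 0.0),
            noise_sigma_range=(0.0, 0.0),
            intensity_rescale_range=(1.0, 1.0),
            blur_range=(0.0, 0.0),
        )
        out, params = augment_pair(view, spec, np.random.default_rng(0))
        np.testing.assert_allclose(out.image, view.image)
        np.testing.assert_array_equal(out.mask, view.mask)

    def test_flip_preserves_instance_voxel_counts(self):
        view = _checker_view()
        spec = AugmentationSpec(
            p_flip_h=1.0,
            p_flip_v=0.0,
            rotation_range_deg=(0.0, 0.0),
            noise_sigma_range=(0.0, 0.0),
            intensity_rescale_range=(1.0, 1.0),
            blur_range=(0.0, 0.0),
        )
        out, _ = augment_pair(view, spec, np.random.default_rng(1))
        ids0, c0 = np.unique(view.mask, return_counts=True)
        ids1, c1 = np.unique(out.mask, return_counts=True)
        np.testing.assert_array_equal(ids0, ids1)
        np.testing.assert_array_equal(c0, c1)

    def test_right_angle_rotation_is_a_lattice_bijection(self):
        view = _checker_view(n=65)
        spec = AugmentationSpec(
            p_flip_h=0.0,
            p_flip_v=0.0,
            rotation_range_deg=(90.0, 90.0),
            noise_sigma_range=(0.0, 0.0),
            intensity_rescale_range=(1.0, 1.0),
            blur_range=(0.0, 0.0),
        )
        out, _ = augment_pair(view, spec, np.random.default_rng(2))
        ids0, c0 = np.unique(view.mask, return_counts=True)
        ids1, c1 = np.unique(out.mask, return_counts=True)
        np.testing.assert_array_equal(ids0, ids1)
        np.testing.assert_array_equal(c0, c1)

    def test_geometry_shared_mask_ids_never_grow(self):
        view = _checker_view()
        spec = AugmentationSpec()
        rng = np.random.default_rng(3)
        for _ in range(10):
            out, _ = augment_pair(view, spec, rng)
            assert out.image.shape == view.image.shape
            assert set(np.unique(out.mask)) <= set(np.unique(view.mask))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_sampled_parameters_stay_in_spec_ranges(self, seed):
        view = _checker_view(n=32, n_instances=1)
        spec = AugmentationSpec()
        _, params = augment_pair(view, spec, np.random.default_rng(seed))
        assert 0.0 <= params["rotation_deg"] <= 90.0
        assert spec.noise_sigma_range[0] <= params["noise_sigma_rel"] <= spec.noise_sigma_range[1]
        assert (
            spec.intensity_rescale_range[0]
            <= params["intensity_factor"]
            <= spec.intensity_rescale_range[1]
        )
        assert 0.0 <= params["blur_sigma"] <= 3.5

    def test_out_of_bounds_spec_rejected(self):
        with pytest.raises(ValueError):
            AugmentationSpec(rotation_range_deg=(0.0, 120.0))
        with pytest.raises(ValueError):
            AugmentationSpec(blur_range=(0.0, 5.0))
        with pytest.raises(ValueError):
            AugmentationSpec(p_flip_h=1.5)


class TestBuildTrainingSet:
    def _views(self, counts=(4, 2, 2)):
        views = []
        for orientation, n in zip(("xy", "xz", "yz"), counts):
            views += [
                OrthoView(
                    image=np.random.default_rng(i).random((32, 32)).astype(np.float32),
                    mask=(np.random.default_rng(i).random((32, 32)) > 0.8).astype(np.int32),
                    orientation=orientation,
                    source_id=f"{orientation}{i}",
                )
                for i in range(n)
            ]
        return views

    def test_emits_original_plus_n_variants(self, tmp_path):
        views = self._views()
        spec = AugmentationSpec(n_augment_per_image=2, seed=0)
        manifest = build_training_set(views, spec, tmp_path / "out")
        assert len(manifest) == len(views) * 3
        assert len(list((tmp_path / "out").glob("*_img.tif"))) == len(views) * 3
        assert len(list((tmp_path / "out").glob("*_masks.tif"))) == len(views) * 3

    def test_orientation_counts_recoverable_from_manifest(self, tmp_path):
        views = self._views(counts=(4, 3, 2))
        spec = AugmentationSpec(n_augment_per_image=1, seed=0)
        manifest = build_training_set(views, spec, tmp_path / "out")
        originals = manifest[~manifest["augmented"]]
        assert originals["orientation"].value_counts().to_dict() == {
            "xy": 4, "xz": 3, "yz": 2,
        }

    def test_rerun_with_same_seed_is_byte_identical(self, tmp_path):
        views = self._views()
        spec = AugmentationSpec(n_augment_per_image=2, seed=7)
        build_training_set(views, spec, tmp_path / "a")
        build_training_set(views, spec, tmp_path / "b")
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_manifest_records_training_provenance(self, tmp_path):
        views = self._views(counts=(2, 0, 0))
        manifest = build_training_set(
            views, AugmentationSpec(n_augment_per_image=0), tmp_path / "out"
        )
        header = (tmp_path / "out" / "manifest.csv").read_text()
        assert "n_epochs=500" in header
        assert "learning_rate=0.05" in header
        assert manifest.attrs["min_train_masks"] == 2
        assert TRAINING_CONFIG["weight_decay"] == 1e-05

    def test_empty_input_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_training_set([], AugmentationSpec(), tmp_path / "out")
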