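"""Synthetic scenes, augmentation expansion, splitting and disk round trips."""

import dataclasses
import logging

import numpy as np
import pytest
from shapely.affinity import rotate, scale
from shapely.geometry import Point, box
from shapely.ops import unary_union

from aphidseg import SceneParams, augment_expand, split_dataset, synth_scene
from aphidseg.data import (
    SegSample,
    load_mask_png,
    load_pairs,
    sample_ellipses,
    save_mask_png,
    synth_dataset,
    write_dataset,
)


def test_same_seed_bitwise_identical():
    p = SceneParams(size=48, seed=11)
    a, b = synth_scene(p), synth_scene(p)
    np.testing.assert_array_equal(a.image, b.image)
    np.testing.assert_array_equal(a.mask, b.mask)
    c = synth_scene(dataclasses.replace(p, seed=12))
    assert not np.array_equal(a.image, c.image)


def test_no_clusters_means_empty_mask():
    s = synth_scene(SceneParams(size=32, n_clusters=0, seed=0))
    assert s.mask.sum() == 0


def test_oversized_aphids_rejected():
    with pytest.raises(ValueError):
        SceneParams(size=16, aphid_axes=(8.0, 10.0))


def test_mask_area_matches_geometric_union_oracle():
    """The rasterised mask must agree with an exact (shapely) ellipse-union
    area computed from the same ellipse population."""
    ratios = []
    for seed in range(12):
        p = SceneParams(size=96, seed=seed, n_clusters=3)
        s = synth_scene(p)
        rng = np.random.default_rng(p.seed)
        # reproduce the generator's random draws: scene nuisances first
        rng.uniform(0, 2 * np.pi); rng.uniform(0, np.pi)
        rng.uniform(0, 2 * np.pi)
        if rng.uniform() < p.shadow_probability:
            rng.uniform(0, p.size); rng.uniform(0.15 * p.size, 0.4 * p.size)
        shapes = []
        for ex, ey, a, b, theta in sample_ellipses(p, rng):
            e = scale(Point(ex, ey).buffer(1.0, quad_segs=64), a, b)
            shapes.append(rotate(e, np.degrees(theta), origin=(ex, ey)))
        union = unary_union(shapes)
        exact = union.intersection(box(0, 0, p.size, p.size)).area
        ratios.append(s.mask.sum() / exact)
    mean_ratio = float(np.mean(ratios))
    assert 0.8 < mean_ratio < 1.2


def test_scene_statistics_exercise_difficulty_axes():
    """Vein stripes, illumination gradient and speckle must leave visible
    structure; foreground must be lower-intensity than its surroundings."""
    p = SceneParams(size=96, seed=3)
    s = synth_scene(p)
    fg = s.image[s.mask == 1].mean()
    bg = s.image[s.mask == 0].mean()
    assert fg < bg  # low-contrast dark clusters
    flat = synth_scene(dataclasses.replace(
        p, vein_amplitude=0, speckle_sd=0, illumination_strength=0,
        shadow_probability=0))
    assert s.image[s.mask == 0].std() > flat.image[flat.mask == 0].std()


class TestAugmentExpand:
    def test_doubles_with_exact_transform_counts(self):
        samples = synth_dataset(8, SceneParams(size=16, seed=0))
        out = augment_expand(samples, seed=1)
        assert len(out) == 16
        kinds = [s.provenance for s in out[8:]]
        for kind in ("hflip", "vflip", "brightness", "noise"):
            assert kinds.count(f"augmented({kind})") == 2

    def test_612_originals_become_1224(self):
        base = synth_scene(SceneParams(size=16, seed=0))
        samples = [dataclasses.replace(base, id=f"s{i}") for i in range(612)]
        assert len(augment_expand(samples, seed=0)) == 1224

    def test_flip_is_involution(self):
        samples = synth_dataset(4, SceneParams(size=16, seed=2))
        out = augment_expand(samples, seed=0)
        flipped = [s for s in out if s.provenance == "augmented(hflip)"][0]
        orig = next(s for s in samples if flipped.id.startswith(s.id))
        np.testing.assert_array_equal(flipped.image[:, ::-1], orig.image)
        np.testing.assert_array_equal(flipped.mask[:, ::-1], orig.mask)

    def test_photometric_transforms_keep_mask(self):
        samples = synth_dataset(4, SceneParams(size=16, seed=3))
        out = augment_expand(samples, seed=0)
        for s in out:
            if s.provenance in ("augmented(brightness)", "augmented(noise)"):
                orig = next(o for o in samples if s.id.startswith(o.id))
                np.testing.assert_array_equal(s.mask, orig.mask)
                assert s.image.shape == orig.image.shape

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            augment_expand([], seed=0)


class TestSplit:
    def test_seven_three_sizes(self):
        samples = synth_dataset(10, SceneParams(size=16))
        train, test = split_dataset(samples, 0.7, seed=0)
        assert len(train) == 7 and len(test) == 3

    def test_partition_properties(self):
        samples = synth_dataset(9, SceneParams(size=16))
        train, test = split_dataset(samples, 0.7, seed=4)
        ids = {s.id for s in samples}
        assert {s.id for s in train} | {s.id for s in test} == ids
        assert {s.id for s in train} & {s.id for s in test} == set()

    def test_seeded_determinism_and_errors(self):
        samples = synth_dataset(10, SceneParams(size=16))
        t1, _ = split_dataset(samples, 0.7, seed=9)
        t2, _ = split_dataset(samples, 0.7, seed=9)
        assert [s.id for s in t1] == [s.id for s in t2]
        with pytest.raises(ValueError):
            split_dataset(samples, 1.5)
        with pytest.raises(ValueError):
            split_dataset(samples[:1], 0.7)


class TestDiskIO:
    def test_mask_png_round_trip(self, tmp_path, rng):
        mask = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
        save_mask_png(mask, tmp_path / "m.png")
        np.testing.assert_array_equal(load_mask_png(tmp_path / "m.png"), mask)

    def test_write_then_load_pairs(self, tmp_path):
        samples = synth_dataset(3, SceneParams(size=16, seed=0))
        manifest = write_dataset(samples, tmp_path)
        assert manifest.exists()
        loaded, orphans = load_pairs(tmp_path / "images", tmp_path / "masks")
        assert len(loaded) == 3 and not orphans
        by_id = {s.id: s for s in loaded}
        for s in samples:
            np.testing.assert_array_equal(by_id[s.id].mask, s.mask)

    def test_orphan_images_reported(self, tmp_path, caplog):
        samples = synth_dataset(3, SceneParams(size=16, seed=1))
        write_dataset(samples, tmp_path)
        from PIL import Image

        Image.fromarray(samples[0].image).save(tmp_path / "images" / "orphan.png")
        with caplog.at_level(logging.WARNING):
            loaded, orphans = load_pairs(tmp_path / "images", tmp_path / "masks")
        assert len(loaded) == 3 and orphans == ["orphan"]
        with pytest.raises(ValueError):
            load_pairs(tmp_path / "images", tmp_path / "masks", strict=True)

    def test_empty_directory_warns(self, tmp_path, caplog):
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        with caplog.at_level(logging.WARNING):
            loaded, _ = load_pairs(tmp_path / "images", tmp_path / "masks")
        assert loaded == [] and "no images" in caplog.text

    def test_resizing_on_load(self, tmp_path):
        samples = synth_dataset(1, SceneParams(size=32, seed=5))
        write_dataset(samples, tmp_path)
        loaded, _ = load_pairs(tmp_path / "images", tmp_path / "masks",
                               resolution=16)
        assert loaded[0].image.shape == (16, 16, 3)
        assert set(np.unique(loaded[0].mask)).issubset({0, 1})

    def test_sample_validation(self):
        with pytest.raises(ValueError):
            SegSample(image=np.zeros((4, 4, 3), np.uint8),
                      mask=np.zeros((5, 5), np.uint8), id="x")
        with pytest.raises(ValueError):
            SegSample(image=np.zeros((4, 4, 3), np.uint8),
                      mask=np.full((4, 4), 7, np.uint8), id="x")
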