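"""Synthetic blastocyst phantoms: geometry, textures, determinism, IO."""

import numpy as np
import pytest
from scipy import ndimage

from btformer.phantom import (DIFFICULTY, PhantomDataset, PhantomSpec, make_dataset,
                              load_mask_png, render_mask, render_phantom,
                              rotate_sample, save_mask_png)


def centered_spec(size=64, **kw):
    c = (size - 1) / 2.0
    defaults = dict(size=size, center=(c, c), radius=0.38 * size,
                    zp_thickness=0.08 * size, te_thickness=0.07 * size,
                    icm_angle=0.6, icm_radius=0.45 * (0.38 - 0.15) * size,
                    icm_ecc=0.25, seed=3)
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestRenderPhantom:
    def test_noiseless_limit_is_threshold_recoverable(self):
        spec = centered_spec(noise_sigma=0.0, blur_sigma=0.0, illum_strength=0.0,
                             intensities=(0.1, 0.3, 0.5, 0.7, 0.9))
        img, mask = render_phantom(spec)
        lut = {0.1: 0, 0.3: 1, 0.5: 2, 0.7: 3, 0.9: 4}
        recovered = np.vectorize(lambda v: lut[round(float(v), 3)])(img)
        np.testing.assert_array_equal(recovered, mask)

    def test_rotated_spec_matches_rotated_mask_oracle(self):
        alpha = 0.8
        base = render_mask(centered_spec())
        rotated = render_mask(centered_spec(rotation=alpha))
        oracle = ndimage.rotate(base, -np.degrees(alpha), reshape=False, order=0)
        # compare away from class boundaries, where NN rotation is exact
        uniform = np.ones_like(base, dtype=bool)
        for d in (1, -1):
            for ax in (0, 1):
                uniform &= np.roll(oracle, d, axis=ax) == oracle
        agree = (rotated == oracle)[uniform].mean()
        assert agree > 0.995

    def test_class_areas_match_analytic_formulas(self):
        spec = centered_spec(size=256)
        mask = render_mask(spec)
        counted = np.bincount(mask.ravel(), minlength=5)
        expected = spec.analytic_areas()
        rel = np.abs(counted - expected) / expected
        assert rel.max() < 0.02, rel

    def test_invalid_nesting_raises(self):
        with pytest.raises(ValueError):
            render_mask(centered_spec(zp_thickness=20.0, te_thickness=20.0))
        with pytest.raises(ValueError):
            render_mask(centered_spec(icm_ecc=1.2))

    def test_topological_nesting(self):
        """Each tissue is one connected component and adjacency respects the
        concentric order (bg|ZP, ZP|TE, TE|blastocoele/ICM, ICM|lumen)."""
        allowed = {0: {0, 1}, 1: {0, 1, 2}, 2: {1, 2, 3, 4},
                   3: {2, 3, 4}, 4: {2, 3, 4}}
        rng = np.random.default_rng(0)
        from btformer.phantom import random_spec
        for _ in range(5):
            mask = render_mask(random_spec(rng, size=64))
            for cls in range(1, 5):
                n = ndimage.label(mask == cls)[1]
                assert n == 1, f"class {cls} split into {n} components"
            for ax, d in ((0, 1), (1, 1)):
                a = mask
                b = np.roll(mask, d, axis=ax)
                edge = np.ones_like(mask, dtype=bool)
                if ax == 0:
                    edge[0, :] = False
                else:
                    edge[:, 0] = False
                pairs = set(zip(a[edge].ravel().tolist(), b[edge].ravel().tolist()))
                for u, v in pairs:
                    assert v in allowed[u], f"illegal adjacency {u}-{v}"


class TestMakeDataset:
    def test_deterministic_under_seed(self, tmp_path):
        d1 = make_dataset(4, seed=11, size=32)
        d2 = make_dataset(4, seed=11, size=32)
        for (i1, m1), (i2, m2) in zip(d1.pairs(), d2.pairs()):
            np.testing.assert_array_equal(i1, i2)
            np.testing.assert_array_equal(m1, m2)
        d1.save(tmp_path / "a")
        d2.save(tmp_path / "b")
        for sub in ("images/phantom_0000.png", "masks/phantom_0003.png", "manifest.json"):
            assert (tmp_path / "a" / sub).read_bytes() == (tmp_path / "b" / sub).read_bytes()

    def test_regeneration_from_manifest_is_identical(self):
        ds = make_dataset(3, seed=2, size=32)
        re = PhantomDataset.from_manifest(ds.manifest())
        for (i1, m1), (i2, m2) in zip(ds.pairs(), re.pairs()):
            np.testing.assert_allclose(i1, i2, atol=1e-7)
            np.testing.assert_array_equal(m1, m2)

    def test_all_masks_contain_all_five_classes(self):
        ds = make_dataset(20, seed=5, size=64)
        for _, mask in ds.pairs():
            assert set(np.unique(mask)) == {0, 1, 2, 3, 4}

    def test_hard_difficulty_has_boundary_contrast_below_noise(self):
        """TE/blastocoele boundary step (on the noise-free render) must sit
        below the additive noise scale at the hard setting."""
        ds = make_dataset(6, seed=4, size=64, difficulty="hard")
        import dataclasses
        steps, sigmas = [], []
        for spec, (_, mask) in zip(ds.specs, ds.pairs()):
            clean_spec = dataclasses.replace(spec, noise_sigma=0.0)
            img, _ = render_phantom(clean_spec)
            te = mask == 2
            bl = mask == 4
            border = te & (ndimage.binary_dilation(bl))
            inner = bl & (ndimage.binary_dilation(te))
            if border.any() and inner.any():
                steps.append(abs(img[border].mean() - img[inner].mean()))
                sigmas.append(spec.noise_sigma)
        assert np.mean(steps) < np.mean(sigmas)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            make_dataset(0)
        rng = np.random.default_rng(0)
        from btformer.phantom import random_spec
        with pytest.raises(ValueError):
            random_spec(rng, difficulty="impossible")


class TestRotationFixture:
    def test_rotated_pair_is_a_valid_sample(self):
        spec = centered_spec()
        img, mask = render_phantom(spec)
        rimg, rmask = rotate_sample(img, mask, 1.1)
        assert set(np.unique(rmask)) <= {0, 1, 2, 3, 4}
        assert rimg.shape == img.shape
        # interior class census is approximately preserved (embryo fits inside)
        for cls in range(1, 5):
            a, b = (mask == cls).sum(), (rmask == cls).sum()
            assert abs(a - b) / max(a, 1) < 0.2


class TestFolderLoader:
    def test_loads_plain_image_mask_layout(self, tmp_path):
        from btformer.phantom import load_image_mask_folder
        ds = make_dataset(3, seed=1, size=32)
        ds.save(tmp_path)
        pairs = load_image_mask_folder(tmp_path)
        assert len(pairs) == 3
        np.testing.assert_array_equal(pairs[0][1], ds.masks[0])
        # images round-trip through 8-bit quantization
        assert np.abs(pairs[0][0] - ds.images[0]).max() < 1 / 255 + 1e-6

    def test_missing_mask_raises(self, tmp_path):
        from btformer.phantom import load_image_mask_folder
        ds = make_dataset(1, seed=1, size=32)
        ds.save(tmp_path)
        (tmp_path / "masks" / "phantom_0000.png").unlink()
        with pytest.raises(FileNotFoundError):
            load_image_mask_folder(tmp_path)


class TestMaskIO:
    def test_indexed_png_roundtrip(self, tmp_path):
        mask = np.random.default_rng(0).integers(0, 5, (16, 16)).astype(np.uint8)
        p = tmp_path / "m.png"
        save_mask_png(mask, p)
        np.testing.assert_array_equal(load_mask_png(p), mask)
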