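"""Cytoprofile tests: closed-form shape/intensity/radial/GLCM oracles,
schema contract (exactly 228 ordered measurements), invariance properties,
and the texture separation the dotted-vs-smooth actin phenotypes require."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from cytoprofile.features import (HARALICK_NAMES, N_FEATURES, build_schema,
                                  assemble_cytoprofile,
                                  edge_actin_intensity_per_area,
                                  haralick_features, intensity_features,
                                  profile_objects, radial_distribution,
                                  shape_features)
from cytoprofile.segment import SegmentedObject, TwoChannelImage
from cytoprofile.synthesize import render_scene, sample_cell_geometry

from conftest import make_disc_archetype, quiet_scene


def disc_mask(r, size=None):
    size = size or (2 * r + 5)
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= r ** 2


class TestSchema:
    def test_exactly_228_unique_names(self, schema):
        assert len(schema) == N_FEATURES == 228
        assert len(set(schema.names)) == 228

    def test_family_composition(self, schema):
        fam = schema.table.groupby("family").size().to_dict()
        assert fam == {"shape": 28, "intensity": 48, "radial": 48,
                       "texture": 104}

    def test_hash_stable_across_builds(self, schema):
        assert schema.hash == build_schema().hash


class TestShapeFeatures:
    def test_square_closed_forms(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        f = shape_features(mask)
        assert f["area"] == 100
        assert f["extent"] == 1.0
        assert f["solidity"] == 1.0
        assert f["equivalent_diameter"] == pytest.approx(11.2838, abs=1e-3)

    def test_disc_near_circular(self):
        f = shape_features(disc_mask(30))
        assert f["eccentricity"] <= 0.1
        assert abs(f["form_factor"] - 1.0) <= 0.1

    @pytest.mark.parametrize("seed", range(5))
    def test_compactness_form_factor_identity(self, seed):
        """compactness x form factor == 1 for arbitrary connected masks."""
        arch = make_disc_archetype(14, boundary_irregularity=0.3,
                                  elongation_mean=1.5)
        geom = sample_cell_geometry(arch, np.random.default_rng(seed))
        f = shape_features(geom.cell_mask)
        assert f["compactness"] * f["form_factor"] == pytest.approx(1.0,
                                                                    abs=1e-9)

    def test_translation_invariance(self):
        arch = make_disc_archetype(12, boundary_irregularity=0.2)
        geom = sample_cell_geometry(arch, np.random.default_rng(3))
        base = np.zeros((90, 90), dtype=bool)
        h, w = geom.cell_mask.shape
        base[5:5 + h, 5:5 + w] = geom.cell_mask
        shifted = np.roll(np.roll(base, 17, axis=0), 9, axis=1)
        fa, fb = shape_features(base), shape_features(shifted)
        for key in fa:
            assert fa[key] == pytest.approx(fb[key], abs=1e-9), key

    def test_area_scales_quadratically(self):
        small, big = disc_mask(15), disc_mask(30)
        ratio = shape_features(big)["area"] / shape_features(small)["area"]
        assert ratio == pytest.approx(4.0, rel=0.03)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_features(np.zeros((5, 5), dtype=bool))


class TestIntensityFeatures:
    def test_constant_field(self):
        mask = disc_mask(8)
        f = intensity_features(mask, np.full(mask.shape, 3.0))
        assert f["integrated"] == pytest.approx(3.0 * mask.sum())
        assert f["std"] == 0.0
        assert f["mad"] == 0.0
        assert f["mass_displacement"] == 0.0

    def test_three_pixel_hand_computation(self):
        mask = np.zeros((1, 3), dtype=bool)
        mask[0, :] = True
        img = np.array([[1.0, 2.0, 3.0]])
        f = intensity_features(mask, img)
        assert f["integrated"] == 6.0
        assert f["mean"] == 2.0
        assert f["median"] == 2.0
        assert f["std"] == pytest.approx(0.8165, abs=1e-4)

    def test_centered_gaussian_has_no_mass_displacement(self):
        mask = disc_mask(15)
        c = mask.shape[0] // 2
        yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
        img = np.exp(-((yy - c) ** 2 + (xx - c) ** 2) / 50.0)
        assert intensity_features(mask, img)["mass_displacement"] <= 0.5


class TestRadialDistribution:
    def test_uniform_field(self):
        mask = disc_mask(20)
        f = radial_distribution(mask, np.ones(mask.shape))
        for b in range(1, 5):
            assert f[f"mean_frac_bin{b}"] == pytest.approx(1.0, abs=1e-6)
        total = sum(f[f"frac_at_d_bin{b}"] for b in range(1, 5))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_in_innermost_bin(self):
        mask = disc_mask(20)
        edt = ndi.distance_transform_edt(mask)
        inner = edt / edt.max() > 0.75
        f = radial_distribution(mask, inner.astype(float))
        assert f["frac_at_d_bin4"] == pytest.approx(1.0, abs=1e-9)
        for b in (1, 2, 3):
            assert f[f"frac_at_d_bin{b}"] == 0.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fractions_always_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        mask = disc_mask(int(rng.integers(5, 18)))
        img = rng.uniform(0.1, 5.0, mask.shape)
        f = radial_distribution(mask, img)
        total = sum(f[f"frac_at_d_bin{b}"] for b in range(1, 5))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestHaralick:
    def test_constant_image_conventions(self):
        mask = disc_mask(10)
        f = haralick_features(mask, np.full(mask.shape, 5.0), scale=3)
        assert f["asm"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["correlation"] == 0.0

    def test_alternating_stripes_contrast(self):
        """1-px vertical stripes of extreme levels: horizontal offset-1
        pairs always co-occur as (0,7)/(7,0), so contrast = 49 exactly."""
        img = np.zeros((16, 16))
        img[:, 1::2] = 7.0
        mask = np.ones_like(img, dtype=bool)
        f = haralick_features(mask, img, scale=1, directions=True)
        assert f["contrast_d0"] == pytest.approx(49.0)
        assert f["asm_d0"] == pytest.approx(0.5)

    def test_masked_pairs_only(self):
        """Pixels outside the mask never enter the co-occurrence counts."""
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0  # bright half lies outside the mask
        mask = np.zeros_like(img, dtype=bool)
        mask[:, :5] = True
        f = haralick_features(mask, img, scale=1)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["asm"] == pytest.approx(1.0)

    def test_m1_dotted_texture_has_higher_entropy_than_m2(self, archetypes):
        """Fine-grained ("dotted") M1 actin decorrelates at offset 3 px and
        spreads the co-occurrence matrix; smooth M2 actin concentrates it.
        Population means over ~500 rendered cells per class."""
        ent = {}
        for cls in ("M1", "M2"):
            vals = []
            for seed in range(42):
                cfg = quiet_scene(rng_seed=seed, cells_per_image=12,
                                  image_height=288, image_width=288,
                                  gaussian_noise_sd=5.0, poisson_noise=True,
                                  staining_cv=0.12, texture_jitter=0.2)
                image, truth = render_scene(cfg, archetypes,
                                            np.random.default_rng(seed),
                                            classes=[cls] * 12)
                for rec in truth.records:
                    mask = truth.cell_labels == rec.object_id
                    vals.append(haralick_features(mask, image.actin,
                                                  scale=3)["entropy"])
            ent[cls] = np.mean(vals)
        assert ent["M1"] > ent["M2"]


class TestAssemble:
    def _make_object(self, mask, image_id="img"):
        sl = ndi.find_objects(mask.astype(np.int8))[0]
        nucleus = ndi.binary_erosion(mask, iterations=3)
        return SegmentedObject(cell_id=1, nucleus_id=1, image_id=image_id,
                               bbox=sl, cell_mask=mask[sl],
                               nucleus_mask=nucleus[sl])

    def test_profile_has_228_finite_values(self, schema):
        mask = disc_mask(14, size=40)
        rng = np.random.default_rng(0)
        image = TwoChannelImage(dapi=rng.uniform(90, 250, (40, 40)),
                                actin=rng.uniform(90, 250, (40, 40)))
        vec = assemble_cytoprofile(self._make_object(mask), image, schema)
        assert vec.shape == (228,)
        assert np.isfinite(vec).all()

    def test_duplicate_object_identical_profile(self, schema):
        mask = disc_mask(12, size=36)
        rng = np.random.default_rng(1)
        image = TwoChannelImage(dapi=rng.uniform(90, 250, (36, 36)),
                                actin=rng.uniform(90, 250, (36, 36)))
        obj = self._make_object(mask)
        a = assemble_cytoprofile(obj, image, schema)
        b = assemble_cytoprofile(obj, image, schema)
        assert np.array_equal(a, b)

    def test_edge_actin_ratio_constant_field(self, schema):
        """For constant actin value v, edge intensity / area reduces to
        v x (boundary pixels / area)."""
        mask = disc_mask(12, size=36)
        v = 7.0
        image = TwoChannelImage(dapi=np.full((36, 36), 5.0),
                                actin=np.full((36, 36), v))
        obj = self._make_object(mask)
        vec = assemble_cytoprofile(obj, image, schema)
        inner = ndi.binary_erosion(
            mask, structure=ndi.generate_binary_structure(2, 1))
        n_edge = (mask & ~inner).sum()
        expected = v * n_edge / mask.sum()
        assert edge_actin_intensity_per_area(vec, schema) == \
            pytest.approx(expected, rel=1e-9)

    def test_tiny_object_stays_finite(self, schema):
        """A 3x3 cell with a 2x2 nucleus has no valid co-occurrence pair at
        either texture offset; the degenerate-texture conventions keep the
        profile finite."""
        mask = np.zeros((24, 24), dtype=bool)
        mask[10:13, 10:13] = True
        sl = ndi.find_objects(mask.astype(np.int8))[0]
        nucleus = np.zeros_like(mask)
        nucleus[10:12, 10:12] = True
        obj = SegmentedObject(cell_id=1, nucleus_id=1, image_id="t",
                              bbox=sl, cell_mask=mask[sl],
                              nucleus_mask=nucleus[sl])
        rng = np.random.default_rng(2)
        image = TwoChannelImage(dapi=rng.uniform(0, 9, (24, 24)),
                                actin=rng.uniform(0, 9, (24, 24)))
        vec = assemble_cytoprofile(obj, image, schema)
        assert np.isfinite(vec).all()

    def test_single_pixel_nucleus_rejected(self, schema):
        """An extractor failure (here: a 1-px nucleus, too small for any
        texture pair) rejects the profile with the object's provenance."""
        from cytoprofile.features import ProfileError
        mask = np.zeros((24, 24), dtype=bool)
        mask[10:13, 10:13] = True
        sl = ndi.find_objects(mask.astype(np.int8))[0]
        nucleus = np.zeros_like(mask)
        nucleus[11, 11] = True
        obj = SegmentedObject(cell_id=1, nucleus_id=1, image_id="t",
                              bbox=sl, cell_mask=mask[sl],
                              nucleus_mask=nucleus[sl])
        image = TwoChannelImage(dapi=np.ones((24, 24)),
                                actin=np.ones((24, 24)))
        with pytest.raises(ProfileError, match="t/1"):
            assemble_cytoprofile(obj, image, schema)

    def test_profile_objects_table_layout(self, schema, archetypes):
        from cytoprofile.segment import segment_image
        cfg = quiet_scene(cells_per_image=4)
        image, _ = render_scene(cfg, archetypes, np.random.default_rng(3))
        objs = segment_image(image, image_id="scene")
        table = profile_objects(objs, image, schema, class_label="M1",
                                image_id="scene")
        assert list(table.columns[:3]) == ["image_id", "object_id", "class"]
        assert list(table.columns[3:]) == schema.names
        assert len(table) == len(objs)
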