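"""Trait extraction: shape descriptors, counting, colour, view fusion."""

import math

import numpy as np
import pytest

from cpdus import traits
from cpdus.config import DEFAULT_CONFIG
from cpdus.imaging import extract_contours
from cpdus.schema import (
    DISTRIBUTION_CODES,
    MARGIN_CODES,
    SHAPE_CODES,
    TRAIT_IDS,
)
from cpdus.synthetic_flora import VarietySpec, _sector_mask, _whorl_mask, render_sample


def _contour_of(mask):
    return extract_contours(mask)[0]


def _disk(r=100, size=256):
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= r**2


class TestGeometryTraits:
    def test_disk_identities(self):
        g = traits.geometry_traits(_contour_of(_disk(100)))
        assert 0.95 <= g["circularity"] <= 1.05
        assert 0.98 <= g["solidity"] <= 1.0
        assert g["equal_circle_area"] == pytest.approx(g["area"], rel=0.02)
        assert g["max_diameter"] == pytest.approx(200, rel=0.02)

    def test_square_identities(self):
        mask = np.zeros((160, 160), dtype=bool)
        mask[20:120, 30:130] = True
        g = traits.geometry_traits(_contour_of(mask))
        assert g["circularity"] == pytest.approx(math.pi / 4, rel=0.03)
        assert g["compactness"] == pytest.approx(16, rel=0.03)
        assert g["min_rect_length"] == pytest.approx(100, abs=2)
        assert g["min_rect_width"] == pytest.approx(100, abs=2)

    def test_star_solidity_matches_vertex_polygon_oracle(self):
        """Rasterised 5-pointed star solidity equals the exact shoelace/hull
        ratio computed on the generating vertices."""
        R, r, size = 100.0, 40.0, 256
        ang = np.arange(10) * math.pi / 5 - math.pi / 2
        rad = np.where(np.arange(10) % 2 == 0, R, r)
        vx = size / 2 + rad * np.cos(ang)
        vy = size / 2 + rad * np.sin(ang)
        # exact polygon area by shoelace on vertices
        area = 0.5 * abs(np.sum(vx * np.roll(vy, -1) - np.roll(vx, -1) * vy))
        from scipy.spatial import ConvexHull

        hull = ConvexHull(np.column_stack([vx, vy]))
        oracle_solidity = area / hull.volume
        # rasterise the star
        from matplotlib.path import Path as MplPath

        yy, xx = np.mgrid[0:size, 0:size]
        pts = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
        mask = MplPath(np.column_stack([vx, vy])).contains_points(pts).reshape(size, size)
        g = traits.geometry_traits(_contour_of(mask))
        assert g["solidity"] == pytest.approx(oracle_solidity, rel=0.02)

    def test_degenerate_contour_rejected(self):
        from cpdus.imaging import ContourPath

        with pytest.raises(ValueError):
            ContourPath(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestCountPerianths:
    def test_disk_is_flat_profile(self):
        count, confident = traits.count_perianths(_disk(80))
        assert count == 1
        assert not confident

    @pytest.mark.parametrize("n", [6, 12])
    def test_rendered_lobe_counts(self, n):
        mask = _whorl_mask(256, n, length=100, width=30, apex_p=2.0, phase=0.3)
        count, confident = traits.count_perianths(mask)
        assert count == n
        assert confident


class TestColorTraits:
    def _img(self, mask, fill):
        img = np.zeros((*mask.shape, 3), dtype=np.uint8)
        img[mask] = fill
        return img

    def test_uniform_region_is_monochrome(self):
        mask = _disk(60, 160)
        res = traits.color_traits(self._img(mask, (240, 200, 40)), mask)
        assert res["secondary_pct"] == 0.0
        assert res["polychromatic"] == 0
        assert np.allclose(res["main_rgb"], (240, 200, 40), atol=1)

    def test_symmetric_bimodal_region(self):
        mask = np.ones((40, 40), dtype=bool)
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        img[:20] = (255, 255, 0)
        img[20:] = (128, 0, 128)
        res = traits.color_traits(img, mask)
        assert res["secondary_pct"] == pytest.approx(50, abs=1)
        assert res["polychromatic"] == 1

    def test_basal_placement_recovered_from_render(self):
        spec = VarietySpec(
            variety_id=1, group="intermedius", outer_count_mean=6, inner_count_mean=5,
            petal_length_px=150, petal_width_px=55, petal_aspect_jitter=0.0,
            base_rgb=(240, 200, 40), secondary_rgb=(180, 80, 140),
            inner_secondary_fraction=0.30, outer_secondary_fraction=0.0,
            secondary_distribution="basal", apex_type="obtuse",
            extension_angle_deg=90, pixel_noise_sd=3.0,
        )
        sample = render_sample(spec, np.random.default_rng(3), size=256)
        res = traits.color_traits(sample.images["inner"], sample.masks["inner"])
        assert res["secondary_pct"] == pytest.approx(30, abs=3)
        assert res["distribution_type"] == DISTRIBUTION_CODES["basal"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            traits.color_traits(np.zeros((4, 4, 3), np.uint8), np.zeros((4, 4), bool))


class TestCategorical:
    def test_high_aspect_petal_is_narrow_elliptic(self):
        mask = _whorl_mask(256, 6, length=120, width=30, apex_p=2.0, phase=0.1)
        petal = traits._petal_shape(mask, DEFAULT_CONFIG)
        aspect = petal["length"] / petal["width"]
        assert aspect > 3
        assert traits._shape_code(aspect, DEFAULT_CONFIG) == SHAPE_CODES["narrow_elliptic"]

    def test_circle_margin_is_entire(self):
        assert traits.margin_state(_disk(80), petal_count=1) == MARGIN_CODES["entire"]

    @pytest.mark.parametrize("angle", [60.0, 90.0, 140.0])
    def test_side_view_extension_angle(self, angle):
        mask = _sector_mask(256, angle, radius=120)
        assert traits.extension_angle(mask) == pytest.approx(angle, abs=10)


class TestExtractAll:
    def test_continuous_traits_match_ground_truth(self, rendered):
        """Area within 3%, secondary percentages within 3 points, main colour
        means within 5 levels of the renderer's records."""
        for sample in rendered:
            vec = traits.extract_all(sample.images)
            t = sample.truth
            assert vec["F4"] == pytest.approx(t["F4"], rel=0.03)
            assert vec["F25"] == pytest.approx(t["F25"], abs=3)
            assert vec["F40"] == pytest.approx(t["F40"], abs=3)
            for k in ("F19", "F20", "F21", "F34", "F35", "F36"):
                assert vec[k] == pytest.approx(t[k], abs=5)

    def test_concolor_sample_is_monochrome_inner(self, specs6, rendered):
        for spec, sample in zip(specs6, rendered):
            if spec.group == "concolor":
                vec = traits.extract_all(sample.images)
                assert vec["F41"] == 0.0
                assert vec["F40"] == 0.0

    def test_extraction_is_pure(self, rendered):
        v1 = traits.extract_all(rendered[0].images)
        v2 = traits.extract_all(rendered[0].images)
        assert (v1 == v2).all()

    def test_schema_conservation(self, rendered):
        vec = traits.extract_all(rendered[0].images)
        assert list(vec.index) == list(TRAIT_IDS)
        assert vec.notna().all()
        assert vec["F4"] > 0
        assert 0 < vec["F7"] <= 1.1
        assert 0 < vec["F6"] <= 1.0
        assert 0 <= vec["F25"] <= 100 and 0 <= vec["F40"] <= 100
        assert vec["F26"] in (0.0, 1.0) and vec["F41"] in (0.0, 1.0)
        assert vec["F11"] >= 1 and vec["F27"] >= 1

    def test_front_view_required(self):
        with pytest.raises(ValueError):
            traits.extract_all({"side": np.zeros((32, 32, 3), np.uint8)})

    def test_rotation_leaves_geometry_stable(self, rendered):
        sample = rendered[0]
        vec = traits.extract_all(sample.images)
        rotated = {v: np.rot90(img).copy() for v, img in sample.images.items()}
        vec_r = traits.extract_all(rotated)
        for k in ("F2", "F3", "F4", "F6", "F7"):
            assert vec_r[k] == pytest.approx(vec[k], rel=0.03)

    def test_upscaling_scales_area_and_perimeter(self, specs6, rendered):
        # use the broadest-petalled variety: its outline is fully resolved at
        # the base resolution, so no extra fine structure appears at 2x
        idx = int(np.argmax([s.petal_width_px for s in specs6]))
        sample = rendered[idx]
        vec = traits.extract_all(sample.images)
        from PIL import Image

        doubled = {
            v: np.asarray(
                Image.fromarray(img).resize((img.shape[1] * 2, img.shape[0] * 2), Image.BILINEAR)
            )
            for v, img in sample.images.items()
        }
        vec2 = traits.extract_all(doubled)
        assert vec2["F4"] == pytest.approx(4 * vec["F4"], rel=0.03)
        assert vec2["F3"] == pytest.approx(2 * vec["F3"], rel=0.05)
        assert vec2["F7"] == pytest.approx(vec["F7"], rel=0.05)
        assert vec2["F6"] == pytest.approx(vec["F6"], rel=0.03)


def test_extract_table_end_to_end(tmp_path):
    from cpdus.synthetic_flora import generate_dataset
    from cpdus.traits import extract_table

    generate_dataset(2, 2, seed=21, out_dir=tmp_path, size=192)
    table = extract_table(tmp_path / "manifest.csv")
    assert len(table) == 4
    assert table[list(TRAIT_IDS)].notna().all().all()
    assert set(table["variety_id"]) == {1, 2}
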