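"""Phantom specs, rasterization and scatterer extraction."""

import numpy as np
import pytest

from ringtomo.phantoms import (
    BackgroundSpec,
    LesionSpec,
    PhantomSpec,
    make_breast_phantom_3d,
    make_section_phantom,
    rasterize,
    slice_phantom,
    to_scatterers,
)


class TestSectionModels:
    def test_table1_section_matches_published_parameters(self):
        spec = make_section_phantom("table1_section")
        bg = spec.background
        assert (bg.diameter, bg.sound_speed, bg.density) == (180.0, 1515.0,
                                                             1040.0)
        got = [(l.diameter, l.sound_speed, l.density) for l in spec.lesions]
        assert got == [(10.0, 1479.0, 950.0), (10.0, 1518.0, 1060.0),
                       (5.0, 1518.0, 1060.0), (15.0, 1479.0, 950.0),
                       (10.0, 1518.0, 1060.0)]

    def test_multi_size_diameters(self):
        spec = make_section_phantom("multi_size")
        assert sorted(l.diameter for l in spec.lesions) == [0.3, 0.5, 1.0]

    @pytest.mark.parametrize("mode,expected_cc", [("edge", 3.0),
                                                  ("center", 2.0)])
    def test_two_lesion_separation_modes(self, mode, expected_cc):
        spec = make_section_phantom("two_lesion", d=2.0, center_mode=mode)
        c1, c2 = (np.asarray(l.center) for l in spec.lesions)
        assert np.hypot(*(c2 - c1)) == pytest.approx(expected_cc)
        assert spec.meta["center_mode"] == mode

    def test_degenerate_separation_rejected(self):
        with pytest.raises(ValueError):
            make_section_phantom("two_lesion", d=0.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            make_section_phantom("nope")

    def test_lesions_inside_background(self):
        for model in ("table1_section", "multi_size"):
            spec = make_section_phantom(model)
            for l in spec.lesions:
                r = np.hypot(*(np.asarray(l.center)
                               - np.asarray(spec.background.center)))
                assert r + l.radius <= spec.background.diameter / 2.0


class TestBreastModels:
    def test_model1_sphere_sizes_and_gap(self):
        spec = make_breast_phantom_3d("model1")
        diam = sorted(l.diameter for l in spec.lesions)
        assert diam == [5.0, 10.0, 15.0]
        les = {l.diameter: l for l in spec.lesions}
        cc = np.linalg.norm(np.asarray(les[10.0].center)
                            - np.asarray(les[5.0].center))
        assert cc - 5.0 - 2.5 == pytest.approx(2.0)  # surface gap

    def test_model1_speed_contrast(self):
        spec = make_breast_phantom_3d("model1")
        assert spec.lesions[0].sound_speed - spec.background.sound_speed \
            == pytest.approx(50.0)

    def test_model2_sphere_sizes(self):
        spec = make_breast_phantom_3d("model2")
        assert sorted(l.diameter for l in spec.lesions) == [0.3, 0.3, 1.0,
                                                            5.0]

    def test_acoustic_properties(self):
        spec = make_breast_phantom_3d("model2")
        assert spec.ambient_speed == 1500.0
        assert spec.background.sound_speed == 1510.0
        assert spec.lesions[0].sound_speed == 1560.0
        assert (spec.ambient_density, spec.background.density,
                spec.lesions[0].density) == (1000.0, 1040.0, 1060.0)

    def test_breast_solid_upper_diameter(self):
        spec = make_breast_phantom_3d("model1")
        assert spec.background.diameter == 160.0

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            make_breast_phantom_3d("model3")


class TestSlicing:
    def test_great_circle_slice(self):
        spec = make_breast_phantom_3d("model2")
        les5 = spec.lesions[0]
        sec = slice_phantom(spec, les5.center[2])
        circle = [l for l in sec.lesions if l.center[:2] == les5.center[:2]]
        assert circle[0].diameter == pytest.approx(5.0)

    def test_chord_diameter_off_center(self):
        # 5 mm sphere cut 2 mm off center: 2*sqrt(2.5^2 - 2^2) = 3 mm
        spec = make_breast_phantom_3d("model2")
        les5 = spec.lesions[0]
        sec = slice_phantom(spec, les5.center[2] + 2.0)
        circle = [l for l in sec.lesions if l.center[:2] == les5.center[:2]]
        assert circle[0].diameter == pytest.approx(3.0)

    def test_plane_missing_solid_raises(self):
        spec = make_breast_phantom_3d("model1")
        with pytest.raises(ValueError):
            slice_phantom(spec, 500.0)


class TestRasterize:
    def test_ambient_only_constant(self):
        bg = BackgroundSpec("disk", (0.0, 0.0), 10.0, 1500.0, 1000.0)
        spec = PhantomSpec(bg, ())
        amap = rasterize(spec, 0.5, ((-6, 6), (-6, 6)))
        assert np.all(amap.sound_speed[0] == amap.sound_speed.ravel()[0])

    def test_target2_center_speed(self):
        spec = make_section_phantom("table1_section")
        target2 = spec.lesions[1]
        amap = rasterize(spec, 0.3, ((-95, 95), (-95, 95)))
        ix = int(round((target2.center[0] - amap.origin[0]) / 0.3))
        iy = int(round((target2.center[1] - amap.origin[1]) / 0.3))
        assert amap.sound_speed[iy, ix] == 1518.0

    def test_disk_area_count_oracle(self):
        # voxel-center counting approximates pi*D^2/4h^2 within 2% for
        # D/h >= 50
        D, h = 30.0, 0.3
        bg = BackgroundSpec("disk", (0.0, 0.0), D, 1515.0, 1040.0)
        spec = PhantomSpec(bg, ())
        amap = rasterize(spec, h, ((-20, 20), (-20, 20)), clip=True)
        count = int(np.sum(amap.sound_speed == 1515.0))
        expected = np.pi * D**2 / (4.0 * h**2)
        assert abs(count - expected) / expected < 0.02

    def test_resolution_consistency(self):
        # halving the spacing changes the counted lesion area by less than
        # the perimeter*h discretization bound
        spec = make_section_phantom("table1_section")
        les = spec.lesions[3]  # 15 mm target
        areas = {}
        for h in (0.6, 0.3):
            amap = rasterize(spec, h, ((-95, 95), (-95, 95)))
            areas[h] = np.sum(amap.sound_speed == 1479.0) * h * h
        # two 1479-targets: diameters 15 and 10 -> total perimeter
        perimeter = np.pi * (15.0 + 10.0)
        assert abs(areas[0.3] - areas[0.6]) < perimeter * 0.6

    def test_extent_must_cover_background(self):
        spec = make_section_phantom("table1_section")
        with pytest.raises(ValueError):
            rasterize(spec, 0.5, ((-50, 50), (-50, 50)))

    def test_nonpositive_spacing_rejected(self):
        spec = make_section_phantom("multi_size")
        with pytest.raises(ValueError):
            rasterize(spec, 0.0, ((-31, 31), (-31, 31)))


class TestScatterers:
    def test_constant_map_empty(self):
        bg = BackgroundSpec("disk", (0.0, 0.0), 100.0, 1500.0, 1000.0)
        amap = rasterize(PhantomSpec(bg, ()), 1.0, ((-20, 20), (-20, 20)),
                         clip=True)
        assert len(to_scatterers(amap)) == 0

    def test_single_voxel_inclusion(self):
        bg = BackgroundSpec("disk", (0.0, 0.0), 100.0, 1500.0, 1000.0)
        les = LesionSpec((0.0, 0.0), 0.9, 1600.0, 1100.0)
        amap = rasterize(PhantomSpec(bg, (les,)), 1.0,
                         ((-10, 10), (-10, 10)), clip=True)
        cloud = to_scatterers(amap)
        assert len(cloud) == 1
        assert np.allclose(cloud.positions[0], (0.0, 0.0))
        assert cloud.reflectivities[0] > 0

    def test_disk_inclusion_scatterers_on_circle(self):
        bg = BackgroundSpec("disk", (0.0, 0.0), 100.0, 1500.0, 1000.0)
        les = LesionSpec((2.0, -3.0), 12.0, 1560.0, 1060.0)
        amap = rasterize(PhantomSpec(bg, (les,)), 0.3,
                         ((-15, 15), (-15, 15)), clip=True)
        cloud = to_scatterers(amap)
        assert len(cloud) > 0
        r = np.hypot(cloud.positions[:, 0] - 2.0, cloud.positions[:, 1] + 3.0)
        assert np.all(np.abs(r - 6.0) <= 0.3 * np.sqrt(2.0) + 1e-9)

    def test_reflectivity_sign_matches_contrast(self):
        bg = BackgroundSpec("disk", (0.0, 0.0), 100.0, 1500.0, 1000.0)
        soft = LesionSpec((-5.0, 0.0), 4.0, 1479.0, 950.0)  # Z below bg
        hard = LesionSpec((5.0, 0.0), 4.0, 1560.0, 1100.0)  # Z above bg
        amap = rasterize(PhantomSpec(bg, (soft, hard)), 0.5,
                         ((-10, 10), (-5, 5)), clip=True)
        cloud = to_scatterers(amap)
        near_soft = cloud.positions[:, 0] < 0
        # lesion-side voxels of the soft target have negative contrast
        soft_core = near_soft & (np.hypot(cloud.positions[:, 0] + 5.0,
                                          cloud.positions[:, 1]) < 2.0)
        hard_core = ~near_soft & (np.hypot(cloud.positions[:, 0] - 5.0,
                                           cloud.positions[:, 1]) < 2.0)
        assert np.all(cloud.reflectivities[soft_core] < 0)
        assert np.all(cloud.reflectivities[hard_core] > 0)


class TestSerialization:
    @pytest.mark.parametrize("builder,model", [
        (make_section_phantom, "table1_section"),
        (make_section_phantom, "multi_size"),
        (make_section_phantom, "two_lesion"),
        (make_breast_phantom_3d, "model1"),
        (make_breast_phantom_3d, "model2"),
    ])
    def test_yaml_round_trip(self, builder, model):
        spec = builder(model)
        again = PhantomSpec.from_yaml(spec.to_yaml())
        assert again == spec

    def test_json_round_trip(self):
        spec = make_section_phantom("two_lesion", d=3.0)
        assert PhantomSpec.from_json(spec.to_json()) == spec


class TestValidation:
    def test_lesion_invariants(self):
        with pytest.raises(ValueError):
            LesionSpec((0, 0), -1.0, 1500.0, 1000.0)
        with pytest.raises(ValueError):
            LesionSpec((0, 0), 1.0, -1500.0, 1000.0)
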