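"""Geometry of the ten arch traits: frozen examples, sign conventions,
rigid-motion invariance and oracle equivalence."""

import logging

import numpy as np
import pytest

from archtwin.geometry import (
    Arch,
    DegenerateGeometryError,
    LandmarkSet,
    MissingLandmarkError,
    Side,
    Stage,
    arch_length,
    extract_all_traits,
    intercanine_width,
    intermolar_width,
    molar_relationship,
    occlusal_plane,
    overbite,
    overjet,
)

from conftest import canonical_arches, random_rigid


def lms(arch, stage, pts):
    return LandmarkSet("s", stage, arch, pts)


class TestIntraArchDistances:
    def test_intercanine_width_cohort_mean_configuration(self):
        m = lms(Arch.MAXILLARY, Stage.PRIMARY,
                {"canine_cusp_R": (-14.25, 0, 0), "canine_cusp_L": (14.25, 0, 0)})
        assert intercanine_width(m) == pytest.approx(28.5, abs=1e-12)

    def test_intermolar_width_cohort_mean_configuration(self):
        m = lms(Arch.MAXILLARY, Stage.PRIMARY,
                {"molar_mb_cusp_R": (-20.45, 0, 0), "molar_mb_cusp_L": (20.45, 0, 0)})
        assert intermolar_width(m) == pytest.approx(40.9, abs=1e-12)

    def test_coincident_points_give_zero(self):
        m = lms(Arch.MAXILLARY, Stage.PRIMARY,
                {"canine_cusp_R": (1, 2, 3), "canine_cusp_L": (1, 2, 3),
                 "molar_mb_cusp_R": (0, 0, 0), "molar_mb_cusp_L": (0, 0, 0)})
        assert intercanine_width(m) == 0.0
        assert intermolar_width(m) == 0.0

    def test_pythagorean_345_configuration(self):
        m = lms(Arch.MAXILLARY, Stage.PRIMARY,
                {"canine_cusp_R": (0, 0, 0), "canine_cusp_L": (3, 4, 12)})
        assert intercanine_width(m) == pytest.approx(13.0, abs=1e-12)

    def test_width_symmetric_under_label_swap(self, rng):
        p, q = rng.normal(size=3), rng.normal(size=3)
        a = lms(Arch.MAXILLARY, Stage.MIXED, {"canine_cusp_R": p, "canine_cusp_L": q})
        b = lms(Arch.MAXILLARY, Stage.MIXED, {"canine_cusp_R": q, "canine_cusp_L": p})
        assert intercanine_width(a) == intercanine_width(b)

    def test_random_pair_matches_norm_oracle(self, rng):
        for _ in range(100):
            p, q = rng.normal(size=3) * 20, rng.normal(size=3) * 20
            m = lms(Arch.MANDIBULAR, Stage.PERMANENT,
                    {"molar_mb_cusp_R": p, "molar_mb_cusp_L": q})
            brute = sum((pi - qi) ** 2 for pi, qi in zip(p, q)) ** 0.5
            assert intermolar_width(m) == pytest.approx(brute, abs=1e-12)

    def test_missing_landmark_error_names_the_landmark(self):
        m = lms(Arch.MAXILLARY, Stage.PRIMARY, {"canine_cusp_R": (0, 0, 0)})
        with pytest.raises(MissingLandmarkError, match="canine_cusp_L"):
            intercanine_width(m)


class TestArchLength:
    def test_cohort_mean_configuration(self):
        m = lms(Arch.MAXILLARY, Stage.PRIMARY,
                {"incisor_mesial_R": (-2, 25.9, 0), "incisor_mesial_L": (2, 25.9, 0),
                 "molar_distal_contact_R": (-20, 0, 0),
                 "molar_distal_contact_L": (20, 0, 0)})
        assert arch_length(m) == pytest.approx(25.9, abs=1e-12)

    def test_midpoint_on_line_gives_zero(self):
        m = lms(Arch.MAXILLARY, Stage.PRIMARY,
                {"incisor_mesial_R": (-3, 0, 0), "incisor_mesial_L": (3, 0, 0),
                 "molar_distal_contact_R": (-20, 0, 0),
                 "molar_distal_contact_L": (20, 0, 0)})
        assert arch_length(m) == pytest.approx(0.0, abs=1e-12)

    def test_matches_cross_product_oracle_on_random_configurations(self, rng):
        # independent point-to-line formula |(p-a) x (b-a)| / |b-a|
        for _ in range(1000):
            pts = rng.normal(size=(4, 3)) * 15
            m = lms(Arch.MANDIBULAR, Stage.MIXED,
                    {"incisor_mesial_R": pts[0], "incisor_mesial_L": pts[1],
                     "molar_distal_contact_R": pts[2],
                     "molar_distal_contact_L": pts[3]})
            p = 0.5 * (pts[0] + pts[1])
            a, b = pts[2], pts[3]
            oracle = np.linalg.norm(np.cross(p - a, b - a)) / np.linalg.norm(b - a)
            assert arch_length(m) == pytest.approx(oracle, abs=1e-10)

    def test_coincident_distal_contacts_raise(self):
        m = lms(Arch.MAXILLARY, Stage.PRIMARY,
                {"incisor_mesial_R": (-2, 20, 0), "incisor_mesial_L": (2, 20, 0),
                 "molar_distal_contact_R": (5, 0, 0),
                 "molar_distal_contact_L": (5, 0, 0)})
        with pytest.raises(DegenerateGeometryError):
            arch_length(m)


class TestOcclusalPlane:
    def planar_maxilla(self):
        return lms(Arch.MAXILLARY, Stage.MIXED,
                   {"incisor_mesial_R": (-2, 30, 0), "incisor_mesial_L": (2, 30, 0),
                    "molar_mb_cusp_R": (-25, 0, 0), "molar_mb_cusp_L": (25, 0, 0)})

    def test_planar_configuration(self):
        plane = occlusal_plane(self.planar_maxilla())
        assert abs(plane.normal @ np.array([0, 0, 1.0])) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(plane.ap_axis, [0, 1, 0], atol=1e-12)

    def test_translation_invariance(self):
        m = self.planar_maxilla()
        shifted = m.transformed(np.eye(3), np.array([3.0, -7.0, 11.0]))
        p1, p2 = occlusal_plane(m), occlusal_plane(shifted)
        np.testing.assert_allclose(np.abs(p1.normal), np.abs(p2.normal), atol=1e-12)
        np.testing.assert_allclose(p1.ap_axis, p2.ap_axis, atol=1e-12)

    def test_normal_orthogonal_to_in_plane_edges(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 20
            m = lms(Arch.MAXILLARY, Stage.PERMANENT,
                    {"incisor_mesial_R": pts[0], "incisor_mesial_L": pts[1],
                     "molar_mb_cusp_R": pts[2], "molar_mb_cusp_L": pts[3]})
            plane = occlusal_plane(m)
            mid = 0.5 * (pts[0] + pts[1])
            assert abs(plane.normal @ (pts[2] - mid)) < 1e-10
            assert abs(plane.normal @ (pts[3] - mid)) < 1e-10

    def test_normal_points_toward_mandible(self, arches):
        maxilla, mandible = arches
        plane = occlusal_plane(maxilla, mandible)
        assert (mandible.centroid() - plane.origin) @ plane.normal > 0

    def test_collinear_points_raise(self):
        m = lms(Arch.MAXILLARY, Stage.PRIMARY,
                {"incisor_mesial_R": (-1, 0, 0), "incisor_mesial_L": (1, 0, 0),
                 "molar_mb_cusp_R": (-5, 0, 0), "molar_mb_cusp_L": (5, 0, 0)})
        with pytest.raises(DegenerateGeometryError):
            occlusal_plane(m)


class TestInterArch:
    def simple_pair(self, mand_mid):
        maxilla = lms(Arch.MAXILLARY, Stage.PRIMARY,
                      {"incisor_mesial_R": (-2, 30, 0), "incisor_mesial_L": (2, 30, 0),
                       "molar_mb_cusp_R": (-25, 0, 0), "molar_mb_cusp_L": (25, 0, 0)})
        mandible = lms(Arch.MANDIBULAR, Stage.PRIMARY,
                       {"incisor_mesial_R": np.array(mand_mid) + [-2, 0, 0],
                        "incisor_mesial_L": np.array(mand_mid) + [2, 0, 0],
                        "canine_cusp_R": (-10, 15, 3), "canine_cusp_L": (10, 15, 3)})
        return maxilla, mandible, occlusal_plane(maxilla, mandible)

    def test_overjet_overbite_cohort_mean_configuration(self):
        # maxillary incisal ref (0,30,0), mandibular (0,27.6,1.1)
        mx, md, plane = self.simple_pair((0, 27.6, 1.1))
        assert overjet(mx, md, plane) == pytest.approx(2.4, abs=1e-12)
        assert overbite(mx, md, plane) == pytest.approx(1.1, abs=1e-12)

    def test_identical_projected_points_give_zero_overjet(self):
        mx, md, plane = self.simple_pair((0, 30.0, 2.0))
        assert overjet(mx, md, plane) == pytest.approx(0.0, abs=1e-12)

    def test_anterior_mandible_gives_negative_overjet(self):
        mx, md, plane = self.simple_pair((0, 31.0, 1.0))
        assert overjet(mx, md, plane) == pytest.approx(-1.0, abs=1e-12)

    def test_open_bite_gives_negative_overbite(self):
        mx, md, plane = self.simple_pair((0, 27.0, -2.0))
        assert overbite(mx, md, plane) < 0

    def test_in_plane_mandibular_ref_gives_zero_overbite(self):
        mx, md, plane = self.simple_pair((0, 27.0, 0.0))
        assert overbite(mx, md, plane) == pytest.approx(0.0, abs=1e-12)


class TestMolarRelationship:
    def pair_with_groove(self, groove_R):
        maxilla = lms(Arch.MAXILLARY, Stage.MIXED,
                      {"incisor_mesial_R": (-2, 30, 0), "incisor_mesial_L": (2, 30, 0),
                       "molar_mb_cusp_R": (-25, 5, 0), "molar_mb_cusp_L": (25, 5, 0)})
        mandible = lms(Arch.MANDIBULAR, Stage.MIXED,
                       {"molar_buccal_groove_R": groove_R,
                        "molar_buccal_groove_L": (22, 5, 3),
                        "canine_cusp_R": (-10, 20, 3), "canine_cusp_L": (10, 20, 3)})
        return maxilla, mandible, occlusal_plane(maxilla, mandible)

    def test_neutral_occlusion_gives_zero(self):
        mx, md, plane = self.pair_with_groove((-25, 5, 3))  # directly below the cusp
        assert molar_relationship(mx, md, plane, Side.RIGHT) == pytest.approx(0, abs=1e-12)

    def test_distal_mandibular_landmark_positive(self):
        mx, md, plane = self.pair_with_groove((-25, 3, 3))  # 2 mm distal (posterior)
        assert molar_relationship(mx, md, plane, "right") == pytest.approx(2.0, abs=1e-12)

    def test_mesial_mandibular_landmark_negative(self):
        mx, md, plane = self.pair_with_groove((-25, 7, 3))  # 2 mm mesial (anterior)
        assert molar_relationship(mx, md, plane, Side.RIGHT) == pytest.approx(-2.0, abs=1e-12)

    def test_primary_stage_uses_distal_contacts(self, arches):
        maxilla, mandible, = arches
        plane = occlusal_plane(maxilla, mandible)
        # canonical arches: distal contacts vertically aligned -> neutral
        assert molar_relationship(maxilla, mandible, plane, Side.LEFT) == pytest.approx(
            0.0, abs=1e-12)


class TestRigidMotionInvariance:
    def test_all_traits_invariant_under_joint_rigid_motion(self, arches, rng):
        maxilla, mandible = arches
        base = extract_all_traits(maxilla, mandible).as_dict()
        for _ in range(25):
            R, t = random_rigid(rng)
            moved = extract_all_traits(maxilla.transformed(R, t),
                                       mandible.transformed(R, t)).as_dict()
            for name, v in base.items():
                assert moved[name] == pytest.approx(v, abs=1e-9), name


class TestExtractAllTraits:
    def test_full_extraction_on_canonical_arches(self, arches):
        maxilla, mandible = arches
        t = extract_all_traits(maxilla, mandible)
        assert t.max_intercanine_width == pytest.approx(28.5)
        assert t.max_intermolar_width == pytest.approx(40.9)
        assert t.max_arch_length == pytest.approx(25.9)
        assert t.overjet == pytest.approx(2.4)
        assert t.overbite == pytest.approx(1.1)

    def test_missing_landmarks_yield_none_and_warning(self, arches, caplog):
        maxilla, mandible = arches
        pts = dict(maxilla.points)
        del pts["canine_cusp_R"]
        maxilla2 = LandmarkSet("s1", maxilla.stage, maxilla.arch, pts)
        with caplog.at_level(logging.WARNING, logger="archtwin.geometry"):
            t = extract_all_traits(maxilla2, mandible)
        assert t.max_intercanine_width is None
        assert t.max_intermolar_width == pytest.approx(40.9)
        assert any("max_intercanine_width" in r.message for r in caplog.records)

    def test_unknown_landmark_name_rejected(self):
        with pytest.raises(ValueError, match="unknown landmark"):
            LandmarkSet("s", Stage.PRIMARY, Arch.MAXILLARY, {"mystery_point": (0, 0, 0)})
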