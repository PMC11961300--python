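import numpy as np
import pytest

from archtwin.geometry import Arch, ArchTraits, LandmarkSet, Stage


def canonical_arches(stage=Stage.PRIMARY):
    """Hand-placed arches in the canonical frame: maxillary occlusal plane
    z = 0, anterior +y, mandible toward +z.

    Built to match the primary-dentition cohort means: maxillary
    intercanine width 28.5, intermolar width 40.9, arch length 25.9,
    overjet 2.4, overbite 1.1.
    """
    maxilla = LandmarkSet(
        "s1", stage, Arch.MAXILLARY,
        {
            "incisor_mesial_R": (-1.5, 25.9, 0.0),
            "incisor_mesial_L": (1.5, 25.9, 0.0),
            "canine_cusp_R": (-14.25, 19.0, 0.0),
            "canine_cusp_L": (14.25, 19.0, 0.0),
            "molar_mb_cusp_R": (-20.45, 3.0, 0.0),
            "molar_mb_cusp_L": (20.45, 3.0, 0.0),
            "molar_distal_contact_R": (-19.0, 0.0, 0.0),
            "molar_distal_contact_L": (19.0, 0.0, 0.0),
        },
    )
    mandible = LandmarkSet(
        "s1", stage, Arch.MANDIBULAR,
        {
            "incisor_mesial_R": (-1.5, 23.5, 1.1),
            "incisor_mesial_L": (1.5, 23.5, 1.1),
            "canine_cusp_R": (-11.4, 18.0, 3.0),
            "canine_cusp_L": (11.4, 18.0, 3.0),
            "molar_mb_cusp_R": (-17.7, 3.0, 3.0),
            "molar_mb_cusp_L": (17.7, 3.0, 3.0),
            "molar_distal_contact_R": (-16.8, 0.0, 3.0),
            "molar_distal_contact_L": (16.8, 0.0, 3.0),
            "molar_buccal_groove_R": (-17.7, 3.0, 3.0),
            "molar_buccal_groove_L": (17.7, 3.0, 3.0),
        },
    )
    return maxilla, mandible


@pytest.fixture
def arches():
    return canonical_arches()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rigid(rng):
    """Random rotation matrix + translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return R, t


def primary_cohort_traits(subject_id="s1"):
    """ArchTraits at the primary-dentition cohort means."""
    return ArchTraits(
        subject_id, Stage.PRIMARY,
        max_intercanine_width=28.5, max_intermolar_width=40.9,
        max_arch_length=25.9, mand_intercanine_width=22.8,
        mand_intermolar_width=35.4, mand_arch_length=23.6,
        overjet=2.4, overbite=1.1,
        molar_relationship_R=-0.03, molar_relationship_L=-0.02,
    )
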