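"""Dental-arch trait computation from 3D landmark coordinates.

Ten arch traits are computed from landmarks digitised on maxillary and
mandibular dental models: intercanine width, intermolar width and arch
length per arch (intra-arch, computed as genuine 3D distances), and
overjet, overbite and the right/left molar relationships (inter-arch,
measured relative to the maxillary occlusal plane).

Coordinates are millimetres in a right-handed frame; every trait is
invariant under rigid motions applied jointly to both arches.

Landmark vocabulary (per arch):

========================  ====================================================
name                      anatomical point
========================  ====================================================
``incisor_mesial_R/L``    mesial incisal-edge point of the central incisor
``canine_cusp_R/L``       canine cusp tip (primary or permanent canine,
                          depending on dentition stage)
``molar_mb_cusp_R/L``     mesiobuccal cusp tip of the second primary molar
                          (primary stage) or first permanent molar
                          (mixed/permanent stages)
``molar_distal_contact_R/L``  distal contact point of the same molar
``molar_buccal_groove_R/L``   buccal groove of the mandibular first permanent
                          molar (mandibular arch, mixed/permanent only)
========================  ====================================================
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Iterable, Mapping, Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "Arch",
    "Side",
    "LandmarkSet",
    "OcclusalPlane",
    "ArchTraits",
    "MissingLandmarkError",
    "DegenerateGeometryError",
    "LANDMARK_VOCABULARY",
    "intercanine_width",
    "intermolar_width",
    "arch_length",
    "occlusal_plane",
    "overjet",
    "overbite",
    "molar_relationship",
    "extract_all_traits",
]


class Stage(str, Enum):
    """Dentition stage."""

    PRIMARY = "primary"
    MIXED = "mixed"
    PERMANENT = "permanent"


class Arch(str, Enum):
    MAXILLARY = "maxillary"
    MANDIBULAR = "mandibular"


class Side(str, Enum):
    RIGHT = "right"
    LEFT = "left"


#: Controlled vocabulary of landmark names.
LANDMARK_VOCABULARY = frozenset(
    {
        "incisor_mesial_R",
        "incisor_mesial_L",
        "canine_cusp_R",
        "canine_cusp_L",
        "molar_mb_cusp_R",
        "molar_mb_cusp_L",
        "molar_distal_contact_R",
        "molar_distal_contact_L",
        "molar_buccal_groove_R",
        "molar_buccal_groove_L",
    }
)


class MissingLandmarkError(KeyError):
    """A landmark required by the requested trait is absent."""

    def __init__(self, name: str, subject_id: str = "", arch: str = ""):
        self.landmark = name
        msg = f"missing landmark {name!r}"
        if subject_id or arch:
            msg += f" (subject={subject_id!r}, arch={arch!r})"
        super().__init__(msg)


class DegenerateGeometryError(ValueError):
    """Landmark configuration admits no well-defined trait value."""


@dataclass
class LandmarkSet:
    """Named 3D points for one subject x arch x stage.

    ``points`` maps landmark names from :data:`LANDMARK_VOCABULARY` to
    length-3 coordinate arrays in mm.
    """

    subject_id: str
    stage: Stage
    arch: Arch
    points: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        self.arch = Arch(self.arch)
        clean = {}
        for name, xyz in self.points.items():
            if name not in LANDMARK_VOCABULARY:
                raise ValueError(f"unknown landmark name {name!r}")
            p = np.asarray(xyz, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} must be a finite 3-vector, got {xyz!r}")
            clean[name] = p
        self.points = clean

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(name, self.subject_id, self.arch.value) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, names: Iterable[str]) -> list[np.ndarray]:
        return [self[n] for n in names]

    def centroid(self) -> np.ndarray:
        if not self.points:
            raise DegenerateGeometryError("empty landmark set has no centroid")
        return np.mean(list(self.points.values()), axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Return a rigidly moved copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return LandmarkSet(
            self.subject_id,
            self.stage,
            self.arch,
            {k: R @ v + t for k, v in self.points.items()},
        )


@dataclass(frozen=True)
class OcclusalPlane:
    """Maxillary occlusal reference plane.

    ``normal`` is the unit plane normal oriented toward the mandibular
    arch; ``ap_axis`` is the in-plane unit vector pointing anteriorly
    (posterior molar midpoint toward the incisal midpoint).
    """

    origin: np.ndarray
    normal: np.ndarray
    ap_axis: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "normal", np.asarray(self.normal, float))
        object.__setattr__(self, "ap_axis", np.asarray(self.ap_axis, float))
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")
        if abs(np.linalg.norm(self.ap_axis) - 1.0) > 1e-9:
            raise ValueError("ap_axis must be unit length")
        if abs(float(self.normal @ self.ap_axis)) > 1e-9:
            raise ValueError("ap_axis must lie in the plane")

    def project(self, p: np.ndarray) -> np.ndarray:
        """Orthogonal projection of ``p`` into the plane."""
        p = np.asarray(p, float)
        return p - ((p - self.origin) @ self.normal) * self.normal


TRAIT_NAMES = (
    "max_intercanine_width",
    "max_intermolar_width",
    "max_arch_length",
    "mand_intercanine_width",
    "mand_intermolar_width",
    "mand_arch_length",
    "overjet",
    "overbite",
    "molar_relationship_R",
    "molar_relationship_L",
)


@dataclass
class ArchTraits:
    """The ten measured arch traits for one subject x stage (mm).

    Molar relationships are signed: positive = distocclusion, negative =
    mesiocclusion. Missing values are ``None``.
    """

    subject_id: str
    stage: Stage
    max_intercanine_width: Optional[float] = None
    max_intermolar_width: Optional[float] = None
    max_arch_length: Optional[float] = None
    mand_intercanine_width: Optional[float] = None
    mand_intermolar_width: Optional[float] = None
    mand_arch_length: Optional[float] = None
    overjet: Optional[float] = None
    overbite: Optional[float] = None
    molar_relationship_R: Optional[float] = None
    molar_relationship_L: Optional[float] = None

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        for name in TRAIT_NAMES[:6]:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in TRAIT_NAMES}


# ---------------------------------------------------------------------------
# intra-arch traits


def _pair_distance(lms: LandmarkSet, right: str, left: str) -> float:
    a, b = lms.require([right, left])
    return float(np.linalg.norm(a - b))


def intercanine_width(lms: LandmarkSet) -> float:
    """3D distance between the right and left canine cusp tips (mm)."""
    return _pair_distance(lms, "canine_cusp_R", "canine_cusp_L")


def intermolar_width(lms: LandmarkSet) -> float:
    """3D distance between the right and left molar mesiobuccal cusp tips (mm).

    The landmark refers to the second primary molar in the primary
    dentition and the first permanent molar otherwise.
    """
    return _pair_distance(lms, "molar_mb_cusp_R", "molar_mb_cusp_L")


def incisal_midpoint(lms: LandmarkSet) -> np.ndarray:
    """Midpoint of the mesial incisal points of the two central incisors."""
    a, b = lms.require(["incisor_mesial_R", "incisor_mesial_L"])
    return 0.5 * (a + b)


def arch_length(lms: LandmarkSet) -> float:
    """Perpendicular distance (mm) from the incisal midpoint to the line
    joining the right and left molar distal contact points."""
    mid = incisal_midpoint(lms)
    a, b = lms.require(["molar_distal_contact_R", "molar_distal_contact_L"])
    ab = b - a
    denom = np.linalg.norm(ab)
    if denom < 1e-9:
        raise DegenerateGeometryError(
            "distal contact points coincide; the reference line is undefined"
        )
    return float(np.linalg.norm(np.cross(mid - a, ab)) / denom)


# ---------------------------------------------------------------------------
# occlusal plane and inter-arch traits


def occlusal_plane(
    maxilla: LandmarkSet, mandible: Optional[LandmarkSet] = None
) -> OcclusalPlane:
    """Maxillary occlusal plane through the incisal midpoint and the two
    molar mesiobuccal cusp tips.

    The normal is oriented toward the mandibular arch when ``mandible`` is
    supplied (its landmark centroid gets a positive coordinate along the
    normal), which makes overbite positive for a normal vertical overlap.
    """
    if maxilla.arch is not Arch.MAXILLARY:
        raise ValueError("occlusal plane is defined on the maxillary arch")
    mid = incisal_midpoint(maxilla)
    mr, ml = maxilla.require(["molar_mb_cusp_R", "molar_mb_cusp_L"])
    n = np.cross(mr - mid, ml - mid)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise DegenerateGeometryError("occlusal-plane defining points are collinear")
    n = n / nn
    if mandible is not None and ((mandible.centroid() - mid) @ n) < 0:
        n = -n
    molar_mid = 0.5 * (mr + ml)
    ap = mid - molar_mid
    ap = ap - (ap @ n) * n  # in-plane anterior direction
    na = np.linalg.norm(ap)
    if na < 1e-9:
        raise DegenerateGeometryError("anteroposterior axis is undefined")
    return OcclusalPlane(origin=mid, normal=n, ap_axis=ap / na)


def overjet(
    max_lms: LandmarkSet, mand_lms: LandmarkSet, plane: OcclusalPlane
) -> float:
    """Horizontal incisor overlap (mm): signed AP offset of the maxillary
    incisal midpoint ahead of the mandibular one, measured in the occlusal
    plane. Positive when the maxillary incisors are anterior."""
    pmax = plane.project(incisal_midpoint(max_lms))
    pmand = plane.project(incisal_midpoint(mand_lms))
    return float((pmax - pmand) @ plane.ap_axis)


def overbite(
    max_lms: LandmarkSet, mand_lms: LandmarkSet, plane: OcclusalPlane
) -> float:
    """Vertical incisor overlap (mm): signed offset of the mandibular
    incisal midpoint from the maxillary one along the plane normal
    (oriented toward the mandible). Positive for vertical overlap,
    negative for an open bite."""
    d = incisal_midpoint(mand_lms) - incisal_midpoint(max_lms)
    return float(d @ plane.normal)


def _molar_reference(lms: LandmarkSet, side: Side) -> np.ndarray:
    suffix = "R" if side is Side.RIGHT else "L"
    if lms.arch is Arch.MAXILLARY:
        name = (
            f"molar_distal_contact_{suffix}"
            if lms.stage is Stage.PRIMARY
            else f"molar_mb_cusp_{suffix}"
        )
    else:
        name = (
            f"molar_distal_contact_{suffix}"
            if lms.stage is Stage.PRIMARY
            else f"molar_buccal_groove_{suffix}"
        )
    return lms[name]


def molar_relationship(
    max_lms: LandmarkSet,
    mand_lms: LandmarkSet,
    plane: OcclusalPlane,
    side: Side | str,
) -> float:
    """Signed anteroposterior molar relation (mm) on one side.

    Primary dentition compares the distal contact points of the second
    primary molars; mixed/permanent compares the maxillary first-molar
    mesiobuccal cusp with the mandibular first-molar buccal groove. The
    in-plane AP component of (maxillary reference - mandibular reference)
    is positive when the mandibular landmark lies distal to the maxillary
    one (distocclusion) and negative for mesiocclusion.
    """
    side = Side(side)
    pmax = plane.project(_molar_reference(max_lms, side))
    pmand = plane.project(_molar_reference(mand_lms, side))
    return float((pmax - pmand) @ plane.ap_axis)


# ---------------------------------------------------------------------------
# batch extraction


def extract_all_traits(max_lms: LandmarkSet, mand_lms: LandmarkSet) -> ArchTraits:
    """Compute every trait available from the landmark sets.

    Traits whose landmarks are missing are left ``None`` with a logged
    warning; the subject is never aborted wholesale.
    """
    if max_lms.stage != mand_lms.stage:
        raise ValueError("maxillary and mandibular landmark sets are from different stages")
    traits = ArchTraits(subject_id=max_lms.subject_id, stage=max_lms.stage)

    def attempt(name, fn, *args):
        try:
            setattr(traits, name, fn(*args))
        except (MissingLandmarkError, DegenerateGeometryError) as exc:
            logger.warning("subject %s: %s not computed: %s", max_lms.subject_id, name, exc)

    attempt("max_intercanine_width", intercanine_width, max_lms)
    attempt("max_intermolar_width", intermolar_width, max_lms)
    attempt("max_arch_length", arch_length, max_lms)
    attempt("mand_intercanine_width", intercanine_width, mand_lms)
    attempt("mand_intermolar_width", intermolar_width, mand_lms)
    attempt("mand_arch_length", arch_length, mand_lms)

    try:
        plane = occlusal_plane(max_lms, mand_lms)
    except (MissingLandmarkError, DegenerateGeometryError) as exc:
        logger.warning(
            "subject %s: occlusal plane unavailable, inter-arch traits skipped: %s",
            max_lms.subject_id,
            exc,
        )
        return traits

    attempt("overjet", overjet, max_lms, mand_lms, plane)
    attempt("overbite", overbite, max_lms, mand_lms, plane)
    attempt("molar_relationship_R", molar_relationship, max_lms, mand_lms, plane, Side.RIGHT)
    attempt("molar_relationship_L", molar_relationship, max_lms, mand_lms, plane, Side.LEFT)
    return traits
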