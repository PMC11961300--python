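"""Synthetic twin-pair generator with the classical twin-design covariance
structure, plus landmark and repeated-measurement fixtures.

Trait values for a pair are built by summing independent standard-normal
latent factors, one per variance source, with the cross-twin correlations
the twin model posits: additive genetic effects (A) correlate 1.0 in MZ
pairs and 0.5 in same-sex DZ pairs, dominance effects (D) 1.0 and 0.25,
the shared environment (C) 1.0 in both, and the non-shared environment (E)
0 in both.  Opposite-sex DZ pairs use the sex-limitation correlations
``rA`` / ``rC`` / ``rD`` and sex-specific path coefficients, so the implied
cross-twin covariance is ``rA*am*af + rC*cm*cf + rD*dm*df``.

Path coefficients are the square roots of the standardized variance shares
scaled by the per-sex trait SD, so empirical group covariances converge to
the model-implied values as the number of pairs grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .geometry import Arch, ArchTraits, LandmarkSet, Stage

__all__ = [
    "VarianceShares",
    "GeneratorConfig",
    "TwinPair",
    "GROUPS",
    "simulate_pairs",
    "pairs_to_frame",
    "simulate_repeated_measures",
    "simulate_landmarks",
]

#: Zygosity-by-sex group labels; opposite-sex pairs are stored female-first.
GROUPS = ("MZF", "MZM", "DZF", "DZM", "DZOS")

#: Cross-twin latent correlations (A, C, D, E) for same-sex groups.
_SAME_SEX_R = {
    "MZ": (1.0, 1.0, 1.0, 0.0),
    "DZ": (0.5, 1.0, 0.25, 0.0),
}


@dataclass(frozen=True)
class VarianceShares:
    """Standardized variance components (dimensionless, sum to one).

    C and D are never jointly nonzero: the two are confounded in twins
    reared together, so ACE and ADE structures are alternatives, not a
    joint model.
    """

    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.a2, self.c2, self.d2, self.e2)
        if any(v < 0 for v in vals):
            raise ValueError(f"variance shares must be non-negative: {vals}")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise ValueError(f"variance shares must sum to 1, got {sum(vals)!r}")
        if self.c2 > 0 and self.d2 > 0:
            raise ValueError("C and D are confounded and cannot both be nonzero")

    def paths(self, sd: float) -> tuple[float, float, float, float]:
        """Path coefficients (a, c, d, e) on the raw mm scale."""
        return tuple(math.sqrt(v) * sd for v in (self.a2, self.c2, self.d2, self.e2))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one simulated trait x stage.

    Default group counts follow a primary-dentition cohort of 188 twin
    pairs (90 MZ, 98 DZ) with DZ pairs split roughly evenly between
    same-sex and opposite-sex groups.
    """

    trait: str = "trait"
    stage: Stage = Stage.PRIMARY
    n_pairs: Mapping[str, int] = field(
        default_factory=lambda: {"MZF": 45, "MZM": 45, "DZF": 33, "DZM": 33, "DZOS": 32}
    )
    mean_f: float = 0.0
    mean_m: float = 0.0
    sd_f: float = 1.0
    sd_m: float = 1.0
    shares_f: VarianceShares = field(default_factory=VarianceShares)
    shares_m: Optional[VarianceShares] = None  # None = same as female
    rA: float = 0.5  # opposite-sex additive genetic correlation
    rC: float = 1.0  # opposite-sex shared environmental correlation
    rD: float = 0.25  # opposite-sex dominance correlation
    error_sd: float = 0.2  # replicate measurement error (mm)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", Stage(self.stage))
        for g, n in self.n_pairs.items():
            if g not in GROUPS:
                raise ValueError(f"unknown twin group {g!r}")
            if n < 0:
                raise ValueError(f"negative pair count for {g}: {n}")
        if not 0.0 <= self.rA <= 0.5:
            raise ValueError("rA must lie in [0, 0.5]")
        if not 0.0 <= self.rC <= 1.0:
            raise ValueError("rC must lie in [0, 1]")
        if not 0.0 <= self.rD <= 0.25:
            raise ValueError("rD must lie in [0, 0.25]")
        if self.sd_f <= 0 or self.sd_m <= 0:
            raise ValueError("trait SDs must be positive")

    @property
    def shares_by_sex(self) -> dict[str, VarianceShares]:
        return {"F": self.shares_f, "M": self.shares_m or self.shares_f}

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class TwinPair:
    """One twin pair's values for a single trait x stage."""

    family_id: str
    zygosity: str  # MZ | DZ
    sex1: str  # M | F
    sex2: str
    stage: Stage
    trait: str
    value1: float
    value2: float

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise ValueError(f"zygosity must be MZ or DZ, got {self.zygosity!r}")
        if self.zygosity == "MZ" and self.sex1 != self.sex2:
            raise ValueError("MZ pairs must be same-sex")


def _group_sexes(group: str) -> tuple[str, str]:
    if group == "DZOS":
        return "F", "M"  # female twin listed first
    return (group[-1], group[-1])


def _simulate_group(
    cfg: GeneratorConfig, group: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, 2) array of pair values for one zygosity-by-sex group."""
    sex1, sex2 = _group_sexes(group)
    if group == "DZOS":
        r = (cfg.rA, cfg.rC, cfg.rD, 0.0)
    else:
        r = _SAME_SEX_R[group[:2]]
    paths1 = cfg.shares_by_sex[sex1].paths(cfg.sd_f if sex1 == "F" else cfg.sd_m)
    paths2 = cfg.shares_by_sex[sex2].paths(cfg.sd_f if sex2 == "F" else cfg.sd_m)
    means = (
        cfg.mean_f if sex1 == "F" else cfg.mean_m,
        cfg.mean_f if sex2 == "F" else cfg.mean_m,
    )
    out = np.empty((n, 2))
    out[:, 0] = means[0]
    out[:, 1] = means[1]
    for k in range(4):  # A, C, D, E latent factors
        rk = r[k]
        shared = rng.standard_normal(n)
        unique = rng.standard_normal((n, 2))
        factor = math.sqrt(rk) * shared[:, None] + math.sqrt(1.0 - rk) * unique
        out[:, 0] += paths1[k] * factor[:, 0]
        out[:, 1] += paths2[k] * factor[:, 1]
    return out


def simulate_pairs(cfg: GeneratorConfig) -> list[TwinPair]:
    """Draw twin pairs for every configured group.

    Each group follows a bivariate normal with per-sex means/variances and
    the model-implied cross-twin covariance. Fixed seed => identical
    output.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs: list[TwinPair] = []
    fam = 0
    for group in GROUPS:
        n = int(cfg.n_pairs.get(group, 0))
        if n == 0:
            continue
        sex1, sex2 = _group_sexes(group)
        values = _simulate_group(cfg, group, n, rng)
        for i in range(n):
            fam += 1
            pairs.append(
                TwinPair(
                    family_id=f"fam{fam:05d}",
                    zygosity=group[:2],
                    sex1=sex1,
                    sex2=sex2,
                    stage=cfg.stage,
                    trait=cfg.trait,
                    value1=float(values[i, 0]),
                    value2=float(values[i, 1]),
                )
            )
    return pairs


def pairs_to_frame(pairs: Sequence[TwinPair]) -> pd.DataFrame:
    """Long-format twin trait table: one row per twin individual."""
    rows = []
    for p in pairs:
        rows.append((p.family_id, 1, p.zygosity, p.sex1, p.stage.value, p.trait, p.value1))
        rows.append((p.family_id, 2, p.zygosity, p.sex2, p.stage.value, p.trait, p.value2))
    return pd.DataFrame(
        rows, columns=["family_id", "twin", "zygosity", "sex", "stage", "trait", "value"]
    )


def simulate_repeated_measures(
    traits: Sequence[float], error_sd: float, seed: int = 0
) -> pd.DataFrame:
    """Duplicate-measurement fixture for the reliability statistics.

    Adds independent zero-mean Gaussian error of SD ``error_sd`` to each
    true value twice (two measurement occasions). As n grows, Dahlberg's
    statistic on the output converges to ``error_sd`` and the agreement
    ICC to ``var(traits) / (var(traits) + error_sd**2)``.
    """
    if error_sd < 0:
        raise ValueError("error_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(traits, dtype=float)
    noise = rng.normal(0.0, error_sd, size=(t.size, 2)) if error_sd > 0 else np.zeros((t.size, 2))
    return pd.DataFrame(
        {
            "subject": [f"s{i:05d}" for i in range(t.size)],
            "value1": t + noise[:, 0],
            "value2": t + noise[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# landmark fixtures


def _point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    return float(np.linalg.norm(np.cross(p - a, ab)) / np.linalg.norm(ab))


def simulate_landmarks(
    target: ArchTraits, seed: int = 0
) -> tuple[LandmarkSet, LandmarkSet]:
    """Place landmarks on a parametric arch so the extracted traits
    reproduce ``target``.

    The arches are built in a canonical frame (maxillary occlusal plane
    z = 0, anterior +y, mandible toward +z) and then moved by a seeded
    random rigid motion, so the round-trip also exercises the rigid-motion
    invariance of the trait operations. All ten target traits must be set.

    Raises ``ValueError`` when the trait combination is geometrically
    infeasible (mandibular arch length shorter than the anteroposterior
    offset its landmarks must span).
    """
    t = target
    needed = t.as_dict()
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise ValueError(f"target traits missing values: {missing}")
    stage = t.stage

    al_max = t.max_arch_length
    oj, ob = t.overjet, t.overbite
    y_molar = 3.0  # AP station of the maxillary molar MB cusps
    h = 3.0  # nominal occlusal clearance of mandibular cusps

    maxilla = {
        "incisor_mesial_R": (-1.8, al_max, 0.0),
        "incisor_mesial_L": (1.8, al_max, 0.0),
        "canine_cusp_R": (-t.max_intercanine_width / 2, 0.72 * al_max, 0.0),
        "canine_cusp_L": (t.max_intercanine_width / 2, 0.72 * al_max, 0.0),
        "molar_mb_cusp_R": (-t.max_intermolar_width / 2, y_molar, 0.0),
        "molar_mb_cusp_L": (t.max_intermolar_width / 2, y_molar, 0.0),
        # distal contacts define the maxillary arch-length reference line
        "molar_distal_contact_R": (-0.95 * t.max_intermolar_width / 2, 0.0, 0.0),
        "molar_distal_contact_L": (0.95 * t.max_intermolar_width / 2, 0.0, 0.0),
    }

    y_mid_mand = al_max - oj  # overjet fixes the mandibular incisal midpoint
    mandible = {
        "incisor_mesial_R": (-1.5, y_mid_mand, ob),
        "incisor_mesial_L": (1.5, y_mid_mand, ob),
        "canine_cusp_R": (-t.mand_intercanine_width / 2, 0.70 * al_max, h),
        "canine_cusp_L": (t.mand_intercanine_width / 2, 0.70 * al_max, h),
        "molar_mb_cusp_R": (-t.mand_intermolar_width / 2, y_molar, h),
        "molar_mb_cusp_L": (t.mand_intermolar_width / 2, y_molar, h),
    }

    wd = 0.95 * t.mand_intermolar_width / 2
    if stage is Stage.PRIMARY:
        # distal contacts carry the molar relationship AND the arch length:
        # the AP position is pinned by the relationship, so solve for the
        # contact height that yields the target arch length.
        y_r = -t.molar_relationship_R  # maxillary distal contacts sit at y=0
        y_l = -t.molar_relationship_L
        p = np.array([0.0, y_mid_mand, ob])

        def gap(z: float) -> float:
            a = np.array([-wd, y_r, z])
            b = np.array([wd, y_l, z])
            return _point_line_distance(p, a, b) - t.mand_arch_length

        if gap(ob) > 0:
            raise ValueError(
                "infeasible target: mandibular arch length shorter than the "
                "anteroposterior span implied by overjet and molar relationship"
            )
        z_d = brentq(gap, ob, ob + 400.0, xtol=1e-12, rtol=8.9e-16)
        mandible["molar_distal_contact_R"] = (-wd, y_r, z_d)
        mandible["molar_distal_contact_L"] = (wd, y_l, z_d)
    else:
        # buccal grooves carry the molar relationship relative to the
        # maxillary MB cusps; distal contacts only set the arch length.
        mandible["molar_buccal_groove_R"] = (-wd, y_molar - t.molar_relationship_R, h)
        mandible["molar_buccal_groove_L"] = (wd, y_molar - t.molar_relationship_L, h)
        mandible["molar_distal_contact_R"] = (-wd, y_mid_mand - t.mand_arch_length, ob)
        mandible["molar_distal_contact_L"] = (wd, y_mid_mand - t.mand_arch_length, ob)

    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-50.0, 50.0, size=3)

    def build(arch: Arch, pts: dict) -> LandmarkSet:
        moved = {k: R @ np.asarray(v, float) + shift for k, v in pts.items()}
        return LandmarkSet(t.subject_id, stage, arch, moved)

    return build(Arch.MAXILLARY, maxilla), build(Arch.MANDIBULAR, mandible)
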