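"""CSV interfaces.

Three table schemas, all UTF-8 CSV:

* landmark table — ``subject_id, stage, arch, landmark, x, y, z``; one row
  per digitised landmark, coordinates in mm, names from the controlled
  vocabulary in :mod:`archtwin.geometry`.
* twin trait table — ``family_id, twin, zygosity, sex, stage, trait,
  value``; one row per twin individual. The generator seed is recorded in
  a leading ``#`` comment when known.
* trait table — one row per subject x stage with the ten trait columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .geometry import (
    LANDMARK_VOCABULARY,
    Arch,
    ArchTraits,
    LandmarkSet,
    Stage,
    TRAIT_NAMES,
)
from .reliability import ReplicatePairs

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "traits_to_frame",
    "write_traits",
    "write_twin_table",
    "read_twin_table",
    "read_replicates",
]

LANDMARK_COLUMNS = ["subject_id", "stage", "arch", "landmark", "x", "y", "z"]
TWIN_COLUMNS = ["family_id", "twin", "zygosity", "sex", "stage", "trait", "value"]


def read_landmarks(path) -> dict[tuple[str, str, str], LandmarkSet]:
    """Read a landmark CSV into LandmarkSets keyed (subject, stage, arch)."""
    df = pd.read_csv(path, comment="#")
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark table missing columns: {sorted(missing)}")
    out: dict[tuple[str, str, str], LandmarkSet] = {}
    for (subj, stage, arch), rows in df.groupby(["subject_id", "stage", "arch"]):
        dup = rows["landmark"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate landmark rows for subject {subj!r}: "
                f"{sorted(rows.loc[dup, 'landmark'])}")
        pts = {r.landmark: (r.x, r.y, r.z) for r in rows.itertuples()}
        out[(str(subj), str(stage), str(arch))] = LandmarkSet(
            str(subj), Stage(stage), Arch(arch), pts)
    return out


def write_landmarks(landmark_sets: Iterable[LandmarkSet], path) -> None:
    rows = []
    for lms in landmark_sets:
        for name, p in sorted(lms.points.items()):
            rows.append((lms.subject_id, lms.stage.value, lms.arch.value,
                         name, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def traits_to_frame(traits: Iterable[ArchTraits]) -> pd.DataFrame:
    rows = []
    for t in traits:
        row = {"subject_id": t.subject_id, "stage": t.stage.value}
        row.update(t.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "stage", *TRAIT_NAMES])


def write_traits(traits: Iterable[ArchTraits], path) -> None:
    traits_to_frame(traits).to_csv(path, index=False)


def write_twin_table(df: pd.DataFrame, path, seed: Optional[int] = None) -> None:
    """Write the long twin trait table, recording the generator seed in a
    header comment when given."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_twin_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(TWIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"twin table missing columns: {sorted(missing)}")
    return df


def read_replicates(path) -> dict[str, ReplicatePairs]:
    """Read a replicate CSV (subject, trait, measurement_occasion, value)
    into per-trait paired replicates."""
    df = pd.read_csv(path, comment="#")
    need = {"subject", "trait", "measurement_occasion", "value"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")
    out = {}
    for trait, rows in df.groupby("trait"):
        wide = rows.pivot(index="subject", columns="measurement_occasion",
                          values="value").dropna()
        occ = sorted(wide.columns)
        if len(occ) != 2:
            raise ValueError(
                f"trait {trait!r}: expected exactly 2 measurement occasions, got {occ}")
        out[str(trait)] = ReplicatePairs(
            str(trait), wide[occ[0]].to_numpy(), wide[occ[1]].to_numpy())
    return out
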