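"""Pipeline orchestration: landmarks -> traits -> descriptives ->
reliability -> twin models, driven by a YAML config.

Every stage writes CSV tables plus a JSON metadata sidecar carrying the
seed and package version, so outputs are a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import descriptives, io, reliability, twin_models
from .geometry import TRAIT_NAMES, extract_all_traits
from .simulate import (
    GeneratorConfig,
    VarianceShares,
    pairs_to_frame,
    simulate_pairs,
    simulate_repeated_measures,
)

logger = logging.getLogger("archtwin.pipeline")

ALL_STAGES = ("simulate", "traits", "describe", "reliability", "twin-fit")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "results"
    stages: tuple = ALL_STAGES
    landmark_csv: Optional[str] = None
    twin_csv: Optional[str] = None
    replicate_csv: Optional[str] = None
    seed: int = 0
    bootstrap_reps: int = 1000
    starts: int = 5
    alpha: float = 0.05
    bonferroni_m: int = 20
    error_sd: float = 0.2
    # generator section: list of dicts accepted by GeneratorConfig
    simulate: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def generator_configs(self) -> list[GeneratorConfig]:
        out = []
        for i, entry in enumerate(self.simulate):
            entry = dict(entry)
            shares = VarianceShares(
                a2=entry.pop("a2", 0.0), c2=entry.pop("c2", 0.0),
                d2=entry.pop("d2", 0.0), e2=entry.pop("e2", 1.0))
            entry.setdefault("seed", self.seed + i)
            entry.setdefault("error_sd", self.error_sd)
            out.append(GeneratorConfig(shares_f=shares, **entry))
        return out


def validate_inputs(config: RunConfig) -> list[str]:
    """Schema checks on the referenced input files; returns issue strings
    (empty when everything passes)."""
    issues: list[str] = []
    for label, path in (("landmark_csv", config.landmark_csv),
                        ("twin_csv", config.twin_csv),
                        ("replicate_csv", config.replicate_csv)):
        if path is None:
            continue
        if not Path(path).exists():
            issues.append(f"{label}: file not found: {path}")
            continue
        try:
            if label == "landmark_csv":
                io.read_landmarks(path)
            elif label == "twin_csv":
                df = io.read_twin_table(path)
                issues.extend(_check_twin_table(df))
            else:
                io.read_replicates(path)
        except (ValueError, KeyError) as exc:
            issues.append(f"{label}: {exc}")
    if "simulate" not in config.stages and config.twin_csv is None and (
            "describe" in config.stages or "twin-fit" in config.stages):
        issues.append("describe/twin-fit stages need twin_csv or the simulate stage")
    if "traits" in config.stages and config.landmark_csv is None:
        issues.append("traits stage needs landmark_csv")
    return issues


def _check_twin_table(df: pd.DataFrame) -> list[str]:
    issues = []
    bad_zyg = set(df["zygosity"].unique()) - {"MZ", "DZ"}
    if bad_zyg:
        issues.append(f"twin_csv: unknown zygosity labels {sorted(bad_zyg)}")
    bad_sex = set(df["sex"].unique()) - {"M", "F"}
    if bad_sex:
        issues.append(f"twin_csv: unknown sex labels {sorted(bad_sex)}")
    mz = df[df.zygosity == "MZ"]
    for (fam, trait, stage), rows in mz.groupby(["family_id", "trait", "stage"]):
        if rows["sex"].nunique() > 1:
            issues.append(f"twin_csv: MZ family {fam!r} has discordant sexes")
            break
    dup = df.duplicated(subset=["family_id", "twin", "trait", "stage"])
    if dup.any():
        first = df.index[dup][0]
        issues.append(f"twin_csv: duplicate individual/trait rows (first at line {first + 2})")
    return issues


def _sidecar(path: Path, config: RunConfig, **extra) -> None:
    meta = {"archtwin_version": __version__, "seed": config.seed, **extra}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True))


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the requested stages in dependency order.

    Returns a mapping from artifact label to path. Raises on any stage
    error (the CLI converts this to a nonzero exit status).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("archtwin")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {"log": out / "run.log"}
    logger.info("archtwin %s run, seed=%d, stages=%s", __version__,
                config.seed, ",".join(config.stages))

    issues = validate_inputs(config)
    if issues:
        for issue in issues:
            logger.error("input validation: %s", issue)
        raise ValueError("input validation failed: " + "; ".join(issues))

    try:
        twin_df: Optional[pd.DataFrame] = None
        if config.twin_csv:
            twin_df = io.read_twin_table(config.twin_csv)

        if "simulate" in config.stages:
            frames = [pairs_to_frame(simulate_pairs(g))
                      for g in config.generator_configs()]
            if not frames:
                raise ValueError("simulate stage requested but no generator entries")
            twin_df = pd.concat(frames, ignore_index=True)
            path = out / "twin_data.csv"
            io.write_twin_table(twin_df, path, seed=config.seed)
            _sidecar(path, config, stage="simulate")
            artifacts["twin_data"] = path
            logger.info("simulated %d twin individuals", len(twin_df))

        if "traits" in config.stages:
            lms = io.read_landmarks(config.landmark_csv)
            subjects = sorted({(s, st) for (s, st, _a) in lms})
            traits = []
            for subj, stage in subjects:
                mx = lms.get((subj, stage, "maxillary"))
                md = lms.get((subj, stage, "mandibular"))
                if mx is None or md is None:
                    logger.warning("subject %s/%s: missing an arch, skipped", subj, stage)
                    continue
                traits.append(extract_all_traits(mx, md))
            path = out / "arch_traits.csv"
            io.write_traits(traits, path)
            _sidecar(path, config, stage="traits", n_subjects=len(traits))
            artifacts["arch_traits"] = path
            logger.info("extracted traits for %d subject-stages", len(traits))

        if "describe" in config.stages:
            if twin_df is None:
                raise ValueError("describe stage needs twin data")
            artifacts.update(_describe_stage(twin_df, config, out))

        if "reliability" in config.stages:
            artifacts.update(_reliability_stage(twin_df, config, out))

        if "twin-fit" in config.stages:
            if twin_df is None:
                raise ValueError("twin-fit stage needs twin data")
            artifacts.update(_twin_fit_stage(twin_df, config, out))
    finally:
        root.removeHandler(handler)
        handler.close()
    return artifacts


def _describe_stage(twin_df, config: RunConfig, out: Path) -> dict[str, Path]:
    summaries = descriptives.summary_frame(descriptives.summarize(twin_df))
    threshold = descriptives.bonferroni_threshold(config.alpha, config.bonferroni_m)
    rows = []
    for (trait, stage), sub in twin_df.groupby(["trait", "stage"]):
        for contrast in ("MZ_vs_DZ", "M_vs_F"):
            try:
                res = descriptives.group_compare(sub, contrast, clustered=True)
            except ValueError as exc:
                logger.warning("%s/%s %s: %s", trait, stage, contrast, exc)
                continue
            rows.append({
                "trait": trait, "stage": stage, "contrast": contrast,
                "estimate": res.estimate, "se": res.se, "statistic": res.statistic,
                "p_value": res.p_value, "method": res.method,
                "significant_after_bonferroni": res.p_value < threshold,
            })
    comp = pd.DataFrame(rows)
    p1 = out / "group_summaries.csv"
    p2 = out / "group_comparisons.csv"
    summaries.to_csv(p1, index=False)
    comp.to_csv(p2, index=False)
    _sidecar(p2, config, stage="describe", bonferroni_threshold=threshold)
    return {"group_summaries": p1, "group_comparisons": p2}


def _reliability_stage(twin_df, config: RunConfig, out: Path) -> dict[str, Path]:
    if config.replicate_csv:
        reps = io.read_replicates(config.replicate_csv)
    elif twin_df is not None:
        # duplicate-measurement fixture built from the observed values
        reps = {}
        for i, (trait, sub) in enumerate(twin_df.groupby("trait")):
            frame = simulate_repeated_measures(
                sub["value"].dropna().to_numpy(), config.error_sd,
                seed=config.seed + 101 + i)
            reps[str(trait)] = reliability.ReplicatePairs(
                str(trait), frame["value1"].to_numpy(), frame["value2"].to_numpy())
    else:
        raise ValueError("reliability stage needs replicate_csv or twin data")
    table = reliability.reliability_table(reps)
    path = out / "reliability.csv"
    table.to_csv(path, index=False)
    _sidecar(path, config, stage="reliability")
    return {"reliability": path}


def _twin_fit_stage(twin_df, config: RunConfig, out: Path) -> dict[str, Path]:
    icc_rows, vc_rows, boot_frames, traces = [], [], [], {}
    for (trait, stage), sub in twin_df.groupby(["trait", "stage"]):
        data = twin_models.GroupedTwinData.from_frame(sub, trait=str(trait),
                                                      stage=str(stage))
        for zyg in ("MZ", "DZ"):
            try:
                res = twin_models.twin_icc(data, zyg, n_boot=config.bootstrap_reps,
                                           seed=config.seed)
            except (ValueError, ZeroDivisionError) as exc:
                logger.warning("%s/%s %s ICC: %s", trait, stage, zyg, exc)
                continue
            icc_rows.append({"trait": trait, "stage": stage, "zygosity": zyg,
                             "icc": res.estimate, "n_pairs": res.n_pairs,
                             "boot_se": res.boot_se})
            boot_frames.append(pd.DataFrame({
                "trait": trait, "stage": stage, "zygosity": zyg,
                "replicate": np.arange(res.replicates.size),
                "icc": res.replicates}))
        sel = twin_models.select_model(data, alpha=config.alpha, seed=config.seed,
                                       n_starts=config.starts)
        best = sel.best
        row = {"trait": trait, "stage": stage, "model": best.spec.name,
               "loglik": best.loglik, "aic": best.aic}
        for key, vc in best.components.items():
            suffix = "" if key == "pooled" else f"_{key}"
            for c in best.spec.component_list():
                row[f"{c}{suffix}"] = vc.shares[c]
                ci = twin_models.profile_ci(best, c)
                if isinstance(ci, dict):
                    ci = ci.get(key, (float("nan"), float("nan")))
                row[f"{c}{suffix}_lo"], row[f"{c}{suffix}_hi"] = ci
            row[f"h2{suffix}"] = vc.h2
        vc_rows.append(row)
        traces[f"{trait}/{stage}"] = sel.trace
    paths = {}
    p = out / "twin_icc.csv"
    pd.DataFrame(icc_rows).to_csv(p, index=False)
    paths["twin_icc"] = p
    if boot_frames:
        p = out / "twin_icc_bootstrap.csv"
        pd.concat(boot_frames, ignore_index=True).to_csv(p, index=False)
        paths["twin_icc_bootstrap"] = p
    p = out / "variance_components.csv"
    pd.DataFrame(vc_rows).to_csv(p, index=False)
    _sidecar(p, config, stage="twin-fit")
    paths["variance_components"] = p
    p = out / "selection_trace.json"
    p.write_text(json.dumps(traces, indent=2))
    paths["selection_trace"] = p
    return paths
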