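"""Classical twin-design variance-component models.

The engine fits ACE/ADE-family structural models to zygosity-by-sex
grouped twin pairs by full maximum likelihood, with optional quantitative
and qualitative sex limitation, likelihood-ratio / AIC model selection,
profile-likelihood confidence intervals and narrow-sense heritability.

Model
-----
Each twin's phenotype is a sum of latent contributions with path
coefficients a, c (or d), e; the implied 2x2 covariance of a pair is

* diagonal:        a^2 + c^2 + d^2 + e^2   (per the twin's sex)
* MZ off-diagonal: a^2 + c^2 + d^2
* same-sex DZ:     0.5 a^2 + c^2 + 0.25 d^2
* opposite-sex DZ: rA a_m a_f + rC c_m c_f + rD d_m d_f

with rA = 0.5, rC = 1, rD = 0.25 unless a qualitative sex-limitation
model frees one of them. C and D are confounded in twins reared together
and are never fitted jointly.

The group log-likelihoods are evaluated from sufficient statistics
(count, mean vector, scatter matrix), so a fit costs the same at 100 or
100,000 pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GROUPS",
    "GroupedTwinData",
    "TwinModelSpec",
    "VarianceComponents",
    "FitResult",
    "TwinICCResult",
    "twin_icc",
    "expected_cov",
    "fit",
    "profile_ci",
    "lrt",
    "select_model",
    "heritability",
]

GROUPS = ("MZF", "MZM", "DZF", "DZM", "DZOS")
_GROUP_SEXES = {
    "MZF": ("F", "F"),
    "MZM": ("M", "M"),
    "DZF": ("F", "F"),
    "DZM": ("M", "M"),
    "DZOS": ("F", "M"),  # female twin first
}
COMPONENTS = ("A", "C", "D", "E")
#: default cross-twin correlation of each latent factor in DZ pairs
_DZ_CORR = {"A": 0.5, "C": 1.0, "D": 0.25, "E": 0.0}
_CORR_CAP = {"rA": 0.5, "rC": 1.0, "rD": 0.25}


class ConvergenceError(RuntimeError):
    """No optimiser start reached a finite optimum."""


# ---------------------------------------------------------------------------
# data container


class GroupedTwinData:
    """Complete twin pairs for one trait x stage, split into the five
    zygosity-by-sex groups.

    ``groups[g]`` is an (n_g, 2) array of pair values; opposite-sex pairs
    are ordered female-first.
    """

    def __init__(self, groups: Mapping[str, np.ndarray], trait: str = "", stage: str = ""):
        self.trait = trait
        self.stage = stage
        self.groups: dict[str, np.ndarray] = {}
        for g, arr in groups.items():
            if g not in GROUPS:
                raise ValueError(f"unknown twin group {g!r}")
            a = np.asarray(arr, dtype=float)
            if a.size == 0:
                continue
            if a.ndim != 2 or a.shape[1] != 2 or not np.all(np.isfinite(a)):
                raise ValueError(f"group {g}: expected a finite (n, 2) array")
            self.groups[g] = a
        self._suff = {
            g: (a.shape[0], a.mean(axis=0), np.cov(a.T, bias=True).reshape(2, 2)
                if a.shape[0] > 1 else np.zeros((2, 2)))
            for g, a in self.groups.items()
        }

    @classmethod
    def from_frame(cls, df, trait: str = "", stage: str = "") -> "GroupedTwinData":
        """Build from the long twin table (family_id, twin, zygosity, sex,
        stage, trait, value); incomplete pairs are dropped."""
        sub = df
        if trait:
            sub = sub[sub["trait"] == trait]
        if stage:
            sub = sub[sub["stage"] == stage]
        sub = sub.dropna(subset=["value"])
        val = sub.pivot(index="family_id", columns="twin", values="value")
        sex = sub.pivot(index="family_id", columns="twin", values="sex")
        zyg = sub.groupby("family_id")["zygosity"].first()
        if not {1, 2} <= set(val.columns):
            raise ValueError("twin column must contain members 1 and 2")
        complete = val[[1, 2]].notna().all(axis=1)
        v = val.loc[complete, [1, 2]].to_numpy(float)
        s1 = sex.loc[complete, 1].to_numpy()
        s2 = sex.loc[complete, 2].to_numpy()
        z = zyg.loc[complete[complete].index].to_numpy()
        # opposite-sex pairs stored female-first
        flip = (s1 != s2) & (s1 == "M")
        v[flip] = v[flip][:, ::-1]
        groups = {
            "MZF": v[(z == "MZ") & (s1 == "F")],
            "MZM": v[(z == "MZ") & (s1 == "M")],
            "DZF": v[(z == "DZ") & (s1 == "F") & (s1 == s2)],
            "DZM": v[(z == "DZ") & (s1 == "M") & (s1 == s2)],
            "DZOS": v[(z == "DZ") & (s1 != s2)],
        }
        return cls(
            {g: arr for g, arr in groups.items() if arr.size},
            trait=trait or (str(sub["trait"].iloc[0]) if len(sub) else ""),
            stage=stage or (str(sub["stage"].iloc[0]) if len(sub) else ""),
        )

    def suff(self, g: str):
        """(n, mean vector, MLE scatter matrix) for group ``g``."""
        return self._suff[g]

    @property
    def n_pairs(self) -> int:
        return sum(a.shape[0] for a in self.groups.values())

    @property
    def sexes_present(self) -> tuple[str, ...]:
        sexes = set()
        for g in self.groups:
            sexes.update(_GROUP_SEXES[g])
        return tuple(s for s in ("F", "M") if s in sexes)

    def zygosity_pairs(self, zygosity: str) -> np.ndarray:
        """All pairs of one zygosity pooled across sex groups."""
        arrs = [a for g, a in self.groups.items() if g.startswith(zygosity)]
        if not arrs:
            return np.empty((0, 2))
        return np.vstack(arrs)

    def resample(self, rng: np.random.Generator) -> "GroupedTwinData":
        """Bootstrap resample of pairs within each group."""
        return GroupedTwinData(
            {g: a[rng.integers(0, a.shape[0], a.shape[0])] for g, a in self.groups.items()},
            trait=self.trait, stage=self.stage,
        )


# ---------------------------------------------------------------------------
# twin ICC


@dataclass
class TwinICCResult:
    zygosity: str
    estimate: float
    n_pairs: int
    replicates: np.ndarray  # bootstrap sample of the coefficient

    @property
    def boot_se(self) -> float:
        return float(self.replicates.std(ddof=1)) if self.replicates.size > 1 else float("nan")


def _pair_icc(pairs: np.ndarray) -> float:
    """One-way random-effects ICC for (n, 2) pair data:
    (MSB - MSW) / (MSB + MSW)."""
    n = pairs.shape[0]
    pm = pairs.mean(axis=1)
    grand = pairs.mean()
    msb = 2.0 * np.sum((pm - grand) ** 2) / (n - 1)
    msw = np.sum((pairs - pm[:, None]) ** 2) / n
    denom = msb + msw
    if denom <= 0:
        raise ZeroDivisionError("zero total variance; twin ICC undefined")
    return float((msb - msw) / denom)


def twin_icc(
    data: GroupedTwinData, zygosity: str, n_boot: int = 1000, seed: int = 0
) -> TwinICCResult:
    """Pair-based intraclass correlation for MZ or DZ twins with a
    seeded pair-resampling bootstrap (for ridge-style density output)."""
    pairs = data.zygosity_pairs(zygosity)
    n = pairs.shape[0]
    if n < 3:
        raise ValueError(f"{zygosity}: need >= 3 pairs for the twin ICC")
    est = _pair_icc(pairs)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        reps[b] = _pair_icc(pairs[rng.integers(0, n, n)])
    return TwinICCResult(zygosity=zygosity, estimate=est, n_pairs=n, replicates=reps)


# ---------------------------------------------------------------------------
# model specification and parameters


@dataclass(frozen=True)
class TwinModelSpec:
    """Which variance components are free and how sexes are handled.

    ``sex_structure``: 'none' (paths shared between sexes),
    'quantitative' (per-sex paths), or 'qualitative' (per-sex paths plus
    one free opposite-sex latent correlation). The free correlation is rA
    (rC fixed at 1) for ACE-family models by default, rD for ADE-family
    models; the alternative free-rC parameterisation is available
    explicitly.
    """

    components: frozenset = frozenset({"A", "E"})
    sex_structure: str = "none"
    free_correlation: str = "auto"

    def __init__(self, components: Iterable[str] = ("A", "E"),
                 sex_structure: str = "none", free_correlation: str = "auto"):
        comp = frozenset(components)
        if not comp <= set(COMPONENTS):
            raise ValueError(f"unknown components {comp - set(COMPONENTS)}")
        if "E" not in comp:
            raise ValueError("E is always included in a twin model")
        if {"C", "D"} <= comp:
            raise ValueError("C and D are confounded and cannot be fitted together")
        if sex_structure not in ("none", "quantitative", "qualitative"):
            raise ValueError(f"unknown sex structure {sex_structure!r}")
        if sex_structure == "qualitative":
            if free_correlation == "auto":
                # ADE-family models free the dominance sharing, ACE-family
                # models the additive sharing (rC pinned at 1); CE frees rC.
                if "D" in comp:
                    free_correlation = "rD"
                elif "A" in comp:
                    free_correlation = "rA"
                else:
                    free_correlation = "rC"
            if free_correlation not in _CORR_CAP:
                raise ValueError(f"unknown free correlation {free_correlation!r}")
            comp_of = {"rA": "A", "rC": "C", "rD": "D"}[free_correlation]
            if comp_of not in comp:
                raise ValueError(
                    f"free correlation {free_correlation} requires component {comp_of}")
        else:
            free_correlation = "none"
        object.__setattr__(self, "components", comp)
        object.__setattr__(self, "sex_structure", sex_structure)
        object.__setattr__(self, "free_correlation", free_correlation)

    @property
    def name(self) -> str:
        order = {"A": 0, "C": 1, "D": 2, "E": 3}
        label = "".join(sorted(self.components, key=order.get))
        tag = {"none": "", "quantitative": "+qsex", "qualitative": "+qualsex"}
        return label + tag[self.sex_structure]

    def component_list(self) -> tuple[str, ...]:
        return tuple(c for c in COMPONENTS if c in self.components)

    def n_parameters(self, sexes: Sequence[str] = ("F", "M")) -> int:
        k = len(sexes)  # one mean per sex present
        per_sex = 2 if self.sex_structure != "none" else 1
        k += per_sex * len(self.components)
        if self.sex_structure == "qualitative":
            k += 1
        return k


@dataclass(frozen=True)
class PathParams:
    """Raw-scale path coefficients per sex plus opposite-sex correlations."""

    paths_f: Mapping[str, float]
    paths_m: Mapping[str, float]
    rA: float = 0.5
    rC: float = 1.0
    rD: float = 0.25

    def variance(self, sex: str) -> float:
        p = self.paths_f if sex == "F" else self.paths_m
        return sum(v * v for v in p.values())


def expected_cov(params: PathParams, group: str) -> np.ndarray:
    """Model-implied 2x2 covariance matrix of a twin pair."""
    s1, s2 = _GROUP_SEXES[group]
    v1, v2 = params.variance(s1), params.variance(s2)
    p1 = params.paths_f if s1 == "F" else params.paths_m
    p2 = params.paths_f if s2 == "F" else params.paths_m
    if group.startswith("MZ"):
        r = {"A": 1.0, "C": 1.0, "D": 1.0, "E": 0.0}
    elif group == "DZOS":
        r = {"A": params.rA, "C": params.rC, "D": params.rD, "E": 0.0}
    else:
        r = _DZ_CORR
    off = sum(r[c] * p1.get(c, 0.0) * p2.get(c, 0.0) for c in COMPONENTS)
    return np.array([[v1, off], [off, v2]])


def standardized_shares(params: PathParams, sex: str) -> dict[str, float]:
    p = params.paths_f if sex == "F" else params.paths_m
    total = sum(v * v for v in p.values())
    return {c: p.get(c, 0.0) ** 2 / total for c in COMPONENTS}


@dataclass
class VarianceComponents:
    """Standardized variance shares (and raw paths) for one sex."""

    sex: str  # 'F', 'M' or 'pooled'
    paths: dict[str, float]
    shares: dict[str, float]

    @property
    def h2(self) -> float:
        return self.shares.get("A", 0.0)


@dataclass
class FitResult:
    spec: TwinModelSpec
    data: GroupedTwinData
    means: dict[str, float]
    params: PathParams
    loglik: float
    k: int
    components: dict[str, VarianceComponents]  # keyed 'pooled' or 'F'/'M'
    grad_norm: float
    n_starts: int
    seed: int
    boundary: bool = False

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def summary_row(self) -> dict:
        row = {"model": self.spec.name, "loglik": self.loglik, "k": self.k,
               "aic": self.aic}
        for key, vc in self.components.items():
            suffix = "" if key == "pooled" else f"_{key}"
            for c in self.spec.component_list():
                row[f"{c}{suffix}"] = vc.shares[c]
            row[f"h2{suffix}"] = vc.h2
        return row


# ---------------------------------------------------------------------------
# likelihood


def _loglik_groups(data: GroupedTwinData, means: Mapping[str, float],
                   params: PathParams) -> float:
    """Sum of bivariate-normal log-likelihoods over groups, from the
    per-group sufficient statistics."""
    total = 0.0
    for g in data.groups:
        n, m, S = data.suff(g)
        sigma = expected_cov(params, g)
        det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] * sigma[1, 0]
        if det <= 1e-300 or sigma[0, 0] <= 0 or sigma[1, 1] <= 0:
            return -np.inf
        inv = np.array([[sigma[1, 1], -sigma[0, 1]], [-sigma[1, 0], sigma[0, 0]]]) / det
        s1, s2 = _GROUP_SEXES[g]
        e = m - np.array([means[s1], means[s2]])
        quad = float(e @ inv @ e) + float(np.sum(inv * S.T))
        total += -n * math.log(2 * math.pi) - 0.5 * n * (math.log(det) + quad)
    return total


def _unpack(theta: np.ndarray, spec: TwinModelSpec, sexes: Sequence[str]):
    """Map the unconstrained optimiser vector to means + PathParams."""
    comp = spec.component_list()
    means = {}
    i = 0
    for s in ("F", "M"):
        if s in sexes:
            means[s] = theta[i]
            i += 1
        else:
            means[s] = 0.0
    if spec.sex_structure == "none":
        shared = {c: theta[i + j] for j, c in enumerate(comp)}
        i += len(comp)
        pf, pm = dict(shared), dict(shared)
    else:
        pf = {c: theta[i + j] for j, c in enumerate(comp)}
        i += len(comp)
        pm = {c: theta[i + j] for j, c in enumerate(comp)}
        i += len(comp)
    corr = {"rA": 0.5, "rC": 1.0, "rD": 0.25}
    if spec.sex_structure == "qualitative":
        cap = _CORR_CAP[spec.free_correlation]
        corr[spec.free_correlation] = cap / (1.0 + math.exp(-theta[i]))
        i += 1
    return means, PathParams(paths_f=pf, paths_m=pm, **corr)


def _moment_start(data: GroupedTwinData, spec: TwinModelSpec) -> dict[str, float]:
    """Falconer-style method-of-moments standardized shares."""
    def corr(z):
        pairs = data.zygosity_pairs(z)
        if pairs.shape[0] < 3:
            return 0.0
        return _pair_icc(pairs)

    r_mz, r_dz = corr("MZ"), corr("DZ")
    shares = {"A": 0.0, "C": 0.0, "D": 0.0, "E": 1.0}
    if "A" in spec.components:
        shares["A"] = min(max(2.0 * (r_mz - r_dz), 0.05), 0.9)
    if "C" in spec.components:
        shares["C"] = min(max(2.0 * r_dz - r_mz, 0.05), 0.9)
    if "D" in spec.components:
        shares["D"] = min(max(2.0 * r_mz - 4.0 * r_dz, 0.05), 0.5)
    used = sum(shares[c] for c in spec.components if c != "E")
    if used >= 0.95:
        shares = {c: (0.95 * v / used if c != "E" else v) for c, v in shares.items()}
        used = 0.95
    shares["E"] = 1.0 - used
    return shares


def _embed_start(spec: TwinModelSpec, sexes: Sequence[str],
                 source: "FitResult", fallback_mean: float) -> np.ndarray:
    """Map a fitted (possibly simpler) model's solution into the parameter
    vector of ``spec``: warm-starting a richer model this way guarantees
    its optimum dominates the nested one."""
    theta = []
    for s in ("F", "M"):
        if s in sexes:
            theta.append(source.means.get(s, fallback_mean))
    pf, pm = source.params.paths_f, source.params.paths_m
    comp = spec.component_list()
    if spec.sex_structure == "none":
        for c in comp:
            theta.append(math.sqrt((pf.get(c, 0.0) ** 2 + pm.get(c, 0.0) ** 2) / 2.0))
    else:
        for p in (pf, pm):
            for c in comp:
                theta.append(p.get(c, 0.0))
    if spec.sex_structure == "qualitative":
        theta.append(12.0)  # logistic scale: correlation essentially at its default cap
    return np.array(theta)


_STRUCTURE_ORDER = {"none": 0, "quantitative": 1, "qualitative": 2}


def _is_nested(sub: TwinModelSpec, full: TwinModelSpec) -> bool:
    """True when ``sub`` is a sub-model of ``full`` (fewer components
    and/or a simpler sex structure)."""
    if not sub.components <= full.components:
        return False
    if _STRUCTURE_ORDER[sub.sex_structure] > _STRUCTURE_ORDER[full.sex_structure]:
        return False
    if sub.sex_structure == "qualitative" and sub.free_correlation != full.free_correlation:
        return False
    return sub != full


def fit(spec: TwinModelSpec, data: GroupedTwinData, seed: int = 0,
        n_starts: int = 5, warm_start: Optional["FitResult"] = None) -> FitResult:
    """Maximise the multi-group bivariate-normal likelihood.

    Paths are optimised as unconstrained real coefficients (variances are
    their squares, so non-negativity holds by construction); a free
    opposite-sex correlation is optimised through a bounded logistic
    transform. ``n_starts`` seeded quasi-Newton starts are drawn around
    Falconer-style method-of-moments values (plus, when ``warm_start`` is
    given, the embedded solution of a nested fit) and the best optimum is
    kept; the result is deterministic given the seed.
    """
    if spec.sex_structure == "qualitative" and "DZOS" not in data.groups:
        raise ValueError("qualitative sex-limitation model needs opposite-sex pairs")
    if len(data.groups) < 2:
        raise ValueError("need at least two twin groups to fit a twin model")
    for g, a in data.groups.items():
        if a.shape[0] < 3:
            raise ValueError(f"group {g} has fewer than 3 pairs")

    sexes = data.sexes_present
    all_vals = np.concatenate([a.ravel() for a in data.groups.values()])
    grand_mean, grand_sd = float(all_vals.mean()), float(all_vals.std())
    grand_sd = max(grand_sd, 1e-8)
    shares0 = _moment_start(data, spec)
    comp = spec.component_list()

    def pack_start(rng=None) -> np.ndarray:
        theta = []
        jitter = (lambda: rng.normal(0, 0.15)) if rng is not None else (lambda: 0.0)
        for s in ("F", "M"):
            if s in sexes:
                theta.append(grand_mean + jitter() * grand_sd * 0.2)
        reps = 1 if spec.sex_structure == "none" else 2
        for _ in range(reps):
            for c in comp:
                theta.append(grand_sd * math.sqrt(max(shares0[c], 1e-3)) * (1 + jitter()))
        if spec.sex_structure == "qualitative":
            theta.append(jitter() * 2.0 + 1.0)  # logistic scale, starts high
        return np.array(theta)

    # flat per-group sufficient statistics for the scalar hot path
    LOG2PI = math.log(2 * math.pi)
    gstats = []
    for g in data.groups:
        n, m, S = data.suff(g)
        s1, s2 = _GROUP_SEXES[g]
        rtype = "MZ" if g.startswith("MZ") else ("OS" if g == "DZOS" else "DZ")
        gstats.append((float(n), m[0], m[1], S[0, 0], S[0, 1], S[1, 1], s1, s2, rtype))
    has_f, has_m = "F" in sexes, "M" in sexes
    n_comp = len(comp)
    idx = {c: j for j, c in enumerate(comp)}
    qual = spec.sex_structure == "qualitative"
    shared_paths = spec.sex_structure == "none"
    cap = _CORR_CAP.get(spec.free_correlation, 0.0)

    def negll(theta: np.ndarray) -> float:
        i = 0
        mu = {}
        if has_f:
            mu["F"] = theta[i]; i += 1
        if has_m:
            mu["M"] = theta[i]; i += 1
        pf = theta[i:i + n_comp]
        i += n_comp
        pm = pf if shared_paths else theta[i:i + n_comp]
        if not shared_paths:
            i += n_comp
        rA, rC, rD = 0.5, 1.0, 0.25
        if qual:
            r = cap / (1.0 + math.exp(-min(max(theta[i], -40.0), 40.0)))
            if spec.free_correlation == "rA":
                rA = r
            elif spec.free_correlation == "rC":
                rC = r
            else:
                rD = r

        def comps(p):
            a = p[idx["A"]] if "A" in idx else 0.0
            c = p[idx["C"]] if "C" in idx else 0.0
            d = p[idx["D"]] if "D" in idx else 0.0
            e = p[idx["E"]]
            return a, c, d, e

        aF, cF, dF, eF = comps(pf)
        aM, cM, dM, eM = comps(pm)
        var = {"F": aF * aF + cF * cF + dF * dF + eF * eF,
               "M": aM * aM + cM * cM + dM * dM + eM * eM}
        off_mz = {"F": aF * aF + cF * cF + dF * dF,
                  "M": aM * aM + cM * cM + dM * dM}
        off_dz = {"F": 0.5 * aF * aF + cF * cF + 0.25 * dF * dF,
                  "M": 0.5 * aM * aM + cM * cM + 0.25 * dM * dM}
        off_os = rA * aF * aM + rC * cF * cM + rD * dF * dM

        ll = 0.0
        for n, m1, m2, s11, s12, s22, s1, s2, rtype in gstats:
            v1, v2 = var[s1], var[s2]
            if rtype == "MZ":
                off = off_mz[s1]
            elif rtype == "DZ":
                off = off_dz[s1]
            else:
                off = off_os
            det = v1 * v2 - off * off
            if det <= 1e-300 or v1 <= 0 or v2 <= 0:
                return 1e12
            i11, i22, i12 = v2 / det, v1 / det, -off / det
            e1, e2 = m1 - mu.get(s1, 0.0), m2 - mu.get(s2, 0.0)
            quad = (i11 * (s11 + e1 * e1) + i22 * (s22 + e2 * e2)
                    + 2.0 * i12 * (s12 + e1 * e2))
            ll += -n * LOG2PI - 0.5 * n * (math.log(det) + quad)
        return -ll

    rng = np.random.default_rng(seed)
    starts = [pack_start(None)]
    if warm_start is not None:
        warm_list = warm_start if isinstance(warm_start, (list, tuple)) else [warm_start]
        starts += [_embed_start(spec, sexes, w, grand_mean) for w in warm_list]
    starts += [pack_start(rng) for _ in range(max(1, n_starts) - 1)]
    best = None
    for x0 in starts:
        res = optimize.minimize(negll, x0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise ConvergenceError(
            f"{spec.name}: no start converged (best objective {best.fun if best else 'n/a'})")

    means, params = _unpack(best.x, spec, sexes)
    # canonical sign: report non-negative path coefficients
    params = PathParams(
        paths_f={c: abs(v) for c, v in params.paths_f.items()},
        paths_m={c: abs(v) for c, v in params.paths_m.items()},
        rA=params.rA, rC=params.rC, rD=params.rD,
    )
    if spec.sex_structure == "none":
        comps = {"pooled": VarianceComponents(
            "pooled", dict(params.paths_f), standardized_shares(params, "F"))}
    else:
        comps = {s: VarianceComponents(
            s, dict(params.paths_f if s == "F" else params.paths_m),
            standardized_shares(params, s)) for s in sexes}
    shares_flat = [sh for vc in comps.values() for sh in vc.shares.values()]
    boundary = any(sh < 1e-4 or sh > 1 - 1e-4 for sh in shares_flat)
    grad_norm = float(np.linalg.norm(best.jac)) if best.jac is not None else float("nan")
    return FitResult(
        spec=spec, data=data,
        means={s: float(means[s]) for s in sexes},
        params=params, loglik=float(-best.fun),
        k=spec.n_parameters(sexes), components=comps,
        grad_norm=grad_norm, n_starts=n_starts, seed=seed, boundary=boundary,
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


def _loglik_given_shares(data: GroupedTwinData, shares: Mapping[str, float]) -> float:
    """Profile log-likelihood of a pooled-path model with the standardized
    shares fixed: the per-sex means are solved by GLS and the total
    variance by its closed-form ML estimate."""
    off_mz = shares.get("A", 0.0) + shares.get("C", 0.0) + shares.get("D", 0.0)
    off_dz = 0.5 * shares.get("A", 0.0) + shares.get("C", 0.0) + 0.25 * shares.get("D", 0.0)
    R = {}
    for g in data.groups:
        r = off_mz if g.startswith("MZ") else off_dz
        R[g] = np.array([[1.0, r], [r, 1.0]])

    A_mat = {"F": np.array([[1.0, 0.0], [1.0, 0.0]]),
             "M": np.array([[0.0, 1.0], [0.0, 1.0]]),
             "FM": np.eye(2)}
    lhs = np.zeros((2, 2))
    rhs = np.zeros(2)
    Rinv = {}
    for g in data.groups:
        det = 1.0 - R[g][0, 1] ** 2
        if det <= 1e-14:
            return -np.inf
        Rinv[g] = np.array([[1.0, -R[g][0, 1]], [-R[g][0, 1], 1.0]]) / det
        s1, s2 = _GROUP_SEXES[g]
        Ag = A_mat["FM"] if g == "DZOS" else A_mat[s1]
        n, m, _ = data.suff(g)
        lhs += n * Ag.T @ Rinv[g] @ Ag
        rhs += n * Ag.T @ Rinv[g] @ m
    # degenerate when a sex is absent: drop its row/col
    keep = np.where(np.abs(np.diag(lhs)) > 1e-12)[0]
    mu = np.zeros(2)
    mu[keep] = np.linalg.solve(lhs[np.ix_(keep, keep)], rhs[keep])

    N = data.n_pairs
    quad_total = 0.0
    logdetR = 0.0
    for g in data.groups:
        n, m, S = data.suff(g)
        s1, s2 = _GROUP_SEXES[g]
        Ag = A_mat["FM"] if g == "DZOS" else A_mat[s1]
        e = m - Ag @ mu
        quad_total += n * (float(e @ Rinv[g] @ e) + float(np.sum(Rinv[g] * S.T)))
        logdetR += n * math.log(1.0 - R[g][0, 1] ** 2)
    V = quad_total / (2.0 * N)
    if V <= 0:
        return -np.inf
    # each pair contributes a bivariate normal: constant term -log(2*pi)
    return -N * math.log(2 * math.pi) - 0.5 * logdetR - N * math.log(V) - N


def _profile_at(data: GroupedTwinData, comp_list: Sequence[str],
                target: str, s: float) -> float:
    """Profile log-likelihood with the target component's share fixed at s."""
    others = [c for c in comp_list if c != target]
    rest = 1.0 - s
    if len(others) == 0:
        return _loglik_given_shares(data, {target: s}) if abs(rest) < 1e-12 else -np.inf
    if len(others) == 1:
        return _loglik_given_shares(data, {target: s, others[0]: rest})

    def obj(w: float) -> float:
        shares = {target: s, others[0]: rest * w, others[1]: rest * (1.0 - w)}
        return -_loglik_given_shares(data, shares)

    res = optimize.minimize_scalar(obj, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    return -res.fun


def profile_ci(fit_result: FitResult, component: str, level: float = 0.95,
               n_boot: int = 200) -> tuple[float, float]:
    """Confidence interval for a standardized variance share.

    For pooled (no-sex-difference) fits: profile likelihood — the set of
    share values whose profile log-likelihood lies within
    chi2_1(level)/2 of the maximum, found by bisection on each side and
    truncated to [0, 1]. For sex-specific fits: seeded pair-resampling
    bootstrap percentile interval (profiling per-sex shares is not
    closed-form here).
    """
    spec = fit_result.spec
    if component not in spec.components:
        raise ValueError(f"component {component!r} not in model {spec.name}")
    if spec.sex_structure != "none":
        return _bootstrap_ci(fit_result, component, level, n_boot)

    data = fit_result.data
    comp_list = spec.component_list()
    if len(comp_list) == 1:  # E-only: the share is identically 1
        return (1.0, 1.0)
    crit = stats.chi2.ppf(level, df=1) / 2.0
    s_hat = fit_result.components["pooled"].shares[component]
    ll_hat = _profile_at(data, comp_list, component, s_hat)
    ll_max = max(fit_result.loglik, ll_hat)
    cut = ll_max - crit

    def g(s: float) -> float:
        return _profile_at(data, comp_list, component, s) - cut

    eps = 1e-7
    lo_edge, hi_edge = eps, 1.0 - eps
    if g(lo_edge) >= 0:
        lower = 0.0
    else:
        lower = optimize.brentq(g, lo_edge, max(s_hat, lo_edge + eps), xtol=1e-4)
    if g(hi_edge) >= 0:
        upper = 1.0
    else:
        upper = optimize.brentq(g, min(s_hat, hi_edge - eps), hi_edge, xtol=1e-4)
    return (float(max(0.0, min(lower, s_hat))), float(min(1.0, max(upper, s_hat))))


def _bootstrap_ci(fit_result: FitResult, component: str, level: float,
                  n_boot: int) -> dict[str, tuple[float, float]]:
    # one resampling pass per fit serves every component; cache the draws
    cache = getattr(fit_result, "_boot_cache", None)
    if cache is None or cache[0] != n_boot:
        rng = np.random.default_rng(fit_result.seed + 17)
        sexes = list(fit_result.components)
        draws = {s: {c: [] for c in COMPONENTS} for s in sexes}
        for _ in range(n_boot):
            try:
                refit = fit(fit_result.spec, fit_result.data.resample(rng),
                            seed=fit_result.seed, n_starts=1)
            except (ConvergenceError, ValueError):
                continue
            for s in sexes:
                for c, v in refit.components[s].shares.items():
                    draws[s][c].append(v)
        cache = (n_boot, draws)
        fit_result._boot_cache = cache
    alpha = 1.0 - level
    return {
        s: (float(np.quantile(by_comp[component], alpha / 2)),
            float(np.quantile(by_comp[component], 1 - alpha / 2)))
        for s, by_comp in cache[1].items() if by_comp[component]
    }


# ---------------------------------------------------------------------------
# model comparison and selection


def lrt(full: FitResult, sub: FitResult, tol: float = 1e-6) -> tuple[float, int, float]:
    """Chi-square likelihood-ratio test of a nested sub-model.

    Returns (chi2, df, p). The naive chi-square reference is used even for
    boundary-constrained drops (variance components tested against zero),
    which is conservative. ``tol`` is a relative slack on the nesting
    check absorbing optimiser round-off.
    """
    if sub.k >= full.k:
        raise ValueError("sub-model must have fewer parameters than the full model")
    slack = tol * max(1.0, abs(full.loglik))
    if full.loglik < sub.loglik - slack:
        raise ValueError(
            f"nesting violated: full lnL {full.loglik:.6f} < sub lnL {sub.loglik:.6f}")
    chi2 = max(0.0, 2.0 * (full.loglik - sub.loglik))
    df = full.k - sub.k
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def heritability(fit_result: FitResult):
    """Narrow-sense heritability: the standardized A share of the fit
    (0 when the model has no A). A float for pooled fits, per-sex dict
    otherwise."""
    comps = fit_result.components
    if "pooled" in comps:
        return comps["pooled"].h2
    return {s: vc.h2 for s, vc in comps.items()}


@dataclass
class SelectionResult:
    best: FitResult
    fits: dict[str, FitResult]
    trace: list = field(default_factory=list)

    @property
    def h2(self):
        return heritability(self.best)


def select_model(data: GroupedTwinData, alpha: float = 0.05, seed: int = 0,
                 n_starts: int = 5, free_correlation: str = "auto") -> SelectionResult:
    """Parsimony-driven model selection over the ACE and ADE families.

    1. For each family, fit the qualitative sex-limitation, quantitative
       sex-limitation and no-sex-difference variants, and walk down the
       sex-structure ladder by LRT, keeping the simpler variant unless it
       loses fit at p < alpha.
    2. Within the accepted sex structure, drop components by LRT
       (ACE -> AE / CE -> E, ADE -> AE / DE -> E); a drop is kept when it
       does not significantly worsen fit.
    3. The surviving parsimonious candidates are compared by AIC; the
       smallest wins. The full decision trace (every lnL, chi2, p, AIC)
       is returned.
    """
    has_os = "DZOS" in data.groups
    fits: dict[str, FitResult] = {}
    trace: list[dict] = []

    def get_fit(components, structure) -> FitResult:
        components = tuple(components)
        if structure == "qualitative" and components == ("E",):
            # E carries no cross-twin correlation, so the qualitative
            # structure degenerates to the quantitative one
            structure = "quantitative"
        spec = TwinModelSpec(components, structure,
                             free_correlation if structure == "qualitative" else "auto")
        if spec.name not in fits:
            # warm-start from every already-fitted nested sub-model, which
            # keeps the nesting chain of optima monotone
            warm = [f for f in fits.values() if _is_nested(f.spec, spec)]
            f = fit(spec, data, seed=seed, n_starts=n_starts, warm_start=warm)
            fits[spec.name] = f
            trace.append({"event": "fit", "model": spec.name, "loglik": f.loglik,
                          "k": f.k, "aic": f.aic})
        return fits[spec.name]

    def lrt_step(full: FitResult, sub: FitResult, decision_for: str):
        if full.loglik < sub.loglik:
            # the sub-model's optimiser outdid the full model's: restore
            # dominance by refitting the full model from the sub's solution
            refit = fit(full.spec, data, seed=seed, n_starts=1, warm_start=sub)
            if refit.loglik > full.loglik:
                fits[full.spec.name] = full = refit
                trace.append({"event": "refit", "model": full.spec.name,
                              "loglik": full.loglik, "k": full.k, "aic": full.aic})
        chi2, df, p = lrt(full, sub)
        trace.append({"event": "lrt", "full": full.spec.name, "sub": sub.spec.name,
                      "chi2": chi2, "df": df, "p": p, "context": decision_for})
        return p, full

    survivors: dict[str, FitResult] = {}
    for family in (("A", "C", "E"), ("A", "D", "E")):
        # sex-structure ladder, fitted simplest-first so each richer model
        # is warm-started from its sub-model
        ladder = ["qualitative", "quantitative", "none"] if has_os else [
            "quantitative", "none"]
        for structure in reversed(ladder):
            get_fit(family, structure)
        current = get_fit(family, ladder[0])
        structure = ladder[0]
        for simpler in ladder[1:]:
            sub = get_fit(family, simpler)
            p, current = lrt_step(current, sub, f"sex structure for {''.join(family)}")
            if p < alpha:
                break
            current, structure = sub, simpler
        trace.append({"event": "sex_structure", "family": "".join(family),
                      "accepted": structure})

        # component drops within the accepted structure; when the dropped
        # component carried the free opposite-sex correlation, the nested
        # sub-model is the quantitative one (the correlation leaves with it)
        parent = current
        mid = family[1]  # C or D
        free_comp = {"rA": "A", "rC": "C", "rD": "D", "none": None}[
            parent.spec.free_correlation]
        branch_best: list[FitResult] = []
        for drop in (mid, "A"):
            kept = tuple(c for c in family if c != drop)
            sub_structure = structure
            if structure == "qualitative" and free_comp not in kept:
                sub_structure = "quantitative"
            sub = get_fit(kept, sub_structure)
            p, parent = lrt_step(parent, sub, f"drop {drop} from {''.join(family)}")
            if p >= alpha:
                e_only = get_fit(("E",), sub_structure)
                p_e, sub = lrt_step(sub, e_only,
                                    f"drop all familial terms from {''.join(kept)}")
                branch_best.append(e_only if p_e >= alpha else sub)
        if not branch_best:
            branch_best.append(parent)
        for f in branch_best:
            survivors[f.spec.name] = f

    best = min(survivors.values(), key=lambda f: f.aic)
    trace.append({"event": "aic_selection",
                  "candidates": {name: f.aic for name, f in survivors.items()},
                  "winner": best.spec.name})
    return SelectionResult(best=best, fits=fits, trace=trace)
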