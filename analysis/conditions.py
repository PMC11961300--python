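"""Study conditions for the synthetic longitudinal twin cohort.

One entry per dentition stage x trait: per-sex trait means and SDs (mm)
and the standardized variance components used to generate twin pairs.
These are the cohort conditions the generator emulates — an Australian
twin sample followed from the primary through the permanent dentition,
with high additive-genetic shares for intra-arch dimensions, moderate
shares for inter-arch occlusal traits, and a shared-environment structure
(with sex-differing environmental weight) for overjet in the primary
dentition.
"""

# stage -> {MZF, MZM, DZF, DZM, DZOS} pair counts: 188, 181 and 134 pairs
# with roughly even MZ sex split and ~one third of DZ pairs opposite-sex
STAGE_PAIRS = {
    "primary": {"MZF": 45, "MZM": 45, "DZF": 33, "DZM": 33, "DZOS": 32},
    "mixed": {"MZF": 44, "MZM": 44, "DZF": 31, "DZM": 31, "DZOS": 31},
    "permanent": {"MZF": 35, "MZM": 34, "DZF": 22, "DZM": 21, "DZOS": 22},
}

# trait: (mean_f, mean_m, sd_f, sd_m, components)
# components: dict with a2/c2/e2 (pooled) or per-sex tuples (f, m)
CONDITIONS = {
    "primary": {
        "max_intercanine_width": (28.0, 29.1, 2.0, 1.9, {"a2": 0.85}),
        "max_intermolar_width": (40.2, 41.7, 2.1, 2.2, {"a2": 0.85}),
        "max_arch_length": (25.6, 26.2, 1.8, 1.5, {"a2": 0.86}),
        "mand_intercanine_width": (22.5, 23.2, 1.8, 2.1, {"a2": 0.75}),
        "mand_intermolar_width": (34.9, 35.9, 1.8, 2.1, {"a2": 0.82}),
        "mand_arch_length": (23.3, 23.9, 1.6, 1.3, {"a2": 0.74}),
        "overbite": (1.0, 1.1, 0.7, 0.8, {"a2": 0.60}),
        "overjet": (2.4, 2.3, 1.4, 0.9, {"c2": (0.39, 0.57)}),
        "molar_relationship_R": (-0.10, 0.04, 1.1, 1.2, {"a2": 0.40}),
        "molar_relationship_L": (-0.07, 0.03, 1.1, 1.1, {"a2": 0.27}),
    },
    "mixed": {
        "max_intercanine_width": (30.7, 31.8, 3.6, 3.2, {"a2": 0.65}),
        "max_intermolar_width": (48.4, 49.8, 2.5, 2.7, {"a2": 0.85}),
        "max_arch_length": (36.9, 38.1, 2.1, 2.0, {"a2": 0.85}),
        "mand_intercanine_width": (24.7, 25.7, 2.7, 2.5, {"a2": 0.45}),
        "mand_intermolar_width": (43.1, 44.5, 2.2, 2.3, {"a2": 0.85}),
        "mand_arch_length": (33.8, 34.8, 1.9, 1.6, {"a2": 0.83}),
        "overbite": (1.6, 1.9, 0.9, 1.2, {"a2": 0.56}),
        "overjet": (3.0, 3.4, 1.1, 1.2, {"a2": 0.51}),
        "molar_relationship_R": (1.7, 1.8, 1.4, 1.4, {"a2": 0.21}),
        "molar_relationship_L": (1.6, 1.6, 1.3, 1.5, {"a2": 0.27}),
    },
    "permanent": {
        "max_intercanine_width": (32.2, 33.7, 3.4, 2.6, {"a2": (0.65, 0.58)}),
        "max_intermolar_width": (49.6, 51.3, 3.0, 3.2, {"a2": 0.86}),
        "max_arch_length": (35.5, 37.3, 2.4, 2.3, {"a2": 0.88}),
        "mand_intercanine_width": (25.0, 25.5, 1.8, 2.0, {"a2": 0.74}),
        "mand_intermolar_width": (43.1, 44.9, 2.4, 2.9, {"a2": 0.81}),
        "mand_arch_length": (31.9, 33.5, 2.3, 2.1, {"a2": 0.86}),
        "overbite": (2.0, 2.4, 1.0, 1.2, {"a2": 0.72}),
        "overjet": (3.1, 3.4, 1.0, 1.0, {"a2": 0.53}),
        "molar_relationship_R": (0.6, 0.6, 1.7, 1.7, {"a2": 0.54}),
        "molar_relationship_L": (0.4, 0.6, 1.6, 1.7, {"a2": 0.45}),
    },
}


def generator_entries(stage: str) -> list[dict]:
    """GeneratorConfig keyword sets for every trait at one stage."""
    from archtwin.simulate import VarianceShares

    entries = []
    for trait, (mf, mm, sf, sm, comp) in CONDITIONS[stage].items():
        def shares_for(ix):
            a2 = comp.get("a2", 0.0)
            c2 = comp.get("c2", 0.0)
            if isinstance(a2, tuple):
                a2 = a2[ix]
            if isinstance(c2, tuple):
                c2 = c2[ix]
            return VarianceShares(a2=a2, c2=c2, e2=1.0 - a2 - c2)

        sh_f, sh_m = shares_for(0), shares_for(1)
        entries.append(dict(
            trait=trait, stage=stage, n_pairs=STAGE_PAIRS[stage],
            mean_f=mf, mean_m=mm, sd_f=sf, sd_m=sm,
            shares_f=sh_f, shares_m=None if sh_m == sh_f else sh_m,
        ))
    return entries
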