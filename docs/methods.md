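# Methods

## Trait geometry

The ten arch traits are defined on named 3D landmarks (mm, right-handed
axes). Intra-arch traits are genuine 3D quantities: the intercanine and
intermolar widths are Euclidean distances between the left/right cusp-tip
landmarks, and arch length is the perpendicular distance from the midpoint
of the central incisors' mesial incisal points to the infinite line
through the two molar distal contact points. They are deliberately *not*
projected into any plane; the occlusal plane serves inter-arch measures
only.

The maxillary occlusal plane passes through the incisal midpoint and the
two molar mesiobuccal cusp tips (second primary molars in the primary
dentition, first permanent molars thereafter). Its normal is oriented so
the mandibular landmark centroid has a positive coordinate along it, which
makes overbite positive for a normal vertical overlap; the anteroposterior
(AP) axis is the in-plane unit vector from the molar-cusp midpoint toward
the incisal midpoint. Overjet is the AP component of (maxillary −
mandibular incisal reference) after in-plane projection; overbite is the
normal component of (mandibular − maxillary reference). The incisal
reference per arch is the midpoint of the two central incisors' mesial
incisal points — a choice the trait definitions leave open; any fixed
incisal point gives the same invariances. Molar relationship is the
in-plane AP component of (maxillary − mandibular molar reference), using
distal contact points in the primary dentition and the maxillary MB cusp
vs the mandibular buccal groove afterwards; positive values are
distocclusion. One global AP axis serves both sides.

All traits are invariant under rigid motions applied jointly to both
arches (tested to 1e-9 mm with random rotations and ±50 mm translations).
Degenerate configurations (coincident distal contacts, collinear plane
points) raise rather than returning garbage; batch extraction logs missing
landmarks and leaves the affected trait empty instead of dropping the
subject.

## Synthetic cohort generator

Twin pairs are generated literally from the path model: per pair, four
independent standard-normal latent factors (A, C, D, E) are drawn with the
prescribed cross-twin correlations — 1 / 0.5 for A, 1 / 1 for C, 1 / 0.25
for D (MZ / same-sex DZ), 0 for E — realised as
`sqrt(r)·shared + sqrt(1−r)·unique`. Opposite-sex pairs use the
sex-limitation correlations rA ∈ [0, 0.5], rC ∈ [0, 1], rD ∈ [0, 0.25]
(defaults 0.5 / 1 / 0.25) and sex-specific path coefficients, the square
roots of standardized shares scaled by the per-sex trait SD. The implied
group covariances are therefore exact, and empirical moments converge at
the usual 1/√n rate. C and D are never jointly nonzero, mirroring their
confounding in twins reared together.

Default study conditions are a primary-dentition cohort of 188 pairs
(90 MZ, 98 DZ, opposite-sex pairs listed female-first and roughly one
third of DZ pairs opposite-sex); `analysis/conditions.py` carries the full
longitudinal calibration (per-sex means/SDs in mm and standardized
components per trait and stage, 188/181/134 pairs across stages). Stages
are generated independently — the models treat each stage separately, so
no cross-stage covariance is imposed. The generator does **not** emulate
informative attrition, non-normal traits, measurement batch effects, or
gene–environment interaction/covariation; passing tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to their violation.

Landmark fixtures invert the geometry: landmarks are placed on a
parametric arch in a canonical frame (occlusal plane z = 0, anterior +y)
so the extracted traits match a requested trait vector to < 1e-6 mm, then
moved by a seeded random rigid motion. In the primary dentition the
mandibular distal contacts serve both the arch-length and the
molar-relationship definitions, so their height is solved numerically
(Brent bracketing on the point-to-line distance); trait combinations in
which the mandibular arch length cannot span the implied AP offset are
rejected as geometrically infeasible.

## Reliability statistics

ICC(A,1) follows the McGraw–Wong two-way, absolute-agreement,
single-measure definition, computed from the two-way ANOVA mean squares
with k = 2 occasions: (MSR − MSE) / (MSR + MSE + 2(MSC − MSE)/n).
Absolute agreement charges systematic occasion offsets to the
denominator. Negative estimates are reported as computed and flagged, not
truncated; zero-variance input raises. Dahlberg's error is
√(Σd²/2n). Both are computed per trait; no ICC confidence intervals are
produced. With simulated error SD 0.2 mm on cohort-scale traits the
resulting ICCs fall in 0.97–0.999 and Dahlberg errors at ~0.2 mm,
matching careful duplicate digitisation.

## Descriptives and clustered comparisons

Summaries use the sample SD (n−1). Zygosity and sex contrasts are tested
in a Gaussian model with fixed effects (intercept, sex, zygosity, stage
dummies when several stages are pooled) and an exchangeable
(compound-symmetry) covariance within twin families, fitted by full ML:
the fixed effects are profiled out by GLS and the two variance parameters
optimised on unconstrained scales (log σ, atanh ρ). Inference is a Wald
z-test on the contrast coefficient — no small-sample (Satterthwaite)
correction is applied. The Bonferroni family is m = 20 (10 traits × 2
contrasts per stage), giving the 0.0025 per-comparison threshold at
α = 0.05. The attrition comparison uses Welch's unequal-variance t-test.
Outliers are flagged at |z| ≥ 3 (reported, never removed); Shapiro–Wilk
normality checks are logged and never gate the analysis.

## Twin-model likelihood and optimisation

Group log-likelihoods are evaluated from sufficient statistics (pair
count, mean vector, ML scatter matrix per zygosity-by-sex group), so a
fit costs the same at 100 or 100,000 pairs. Parameters are the per-sex
means (always sex-specific, equated across zygosity and twin order) and
the path coefficients, optimised as unconstrained reals — variances are
their squares, so non-negativity holds by construction; a free
opposite-sex correlation is optimised through a logistic transform bounded
at its theoretical cap (0.5 for rA, 1 for rC, 0.25 for rD). BFGS with
numerical gradients runs from five seeded starts around Falconer-style
method-of-moments values (a₀² = 2(rMZ − rDZ) clipped into the simplex);
the best optimum is kept and the gradient norm retained as a diagnostic.
Fits are deterministic given the seed. Reported paths are sign-normalised
to non-negative (the likelihood is invariant to path sign). Standardized
shares within 1e-4 of 0 or 1 are flagged as boundary solutions.

In the selection procedure, each richer model is additionally
warm-started from every already-fitted nested sub-model, and an LRT edge
where the sub-model's optimum exceeds the full model's triggers a
dominance-restoring refit of the full model from the sub's solution. This
keeps the nesting chain of optima monotone to numerical tolerance — the
failure mode of independent multistart optimisation at large n.

## Sex limitation

Three structures: *none* (paths shared between sexes), *quantitative*
(per-sex paths), *qualitative* (per-sex paths plus one free opposite-sex
correlation). The qualitative model frees rA with rC fixed at 1 for
ACE-family models and rD for ADE-family models — freeing two opposite-sex
correlations at once is not identified, so only one is estimated; the
free-rC alternative is available by flag. Opposite-sex dominance sharing
defaults to ¼·d_m·d_f.

## Model selection

For each family (ACE, ADE): fit the qualitative, quantitative and no-sex
variants; walk down the sex-structure ladder keeping the simpler variant
unless the LRT rejects at p < .05; within the accepted structure test the
component drops (→AE, →CE/DE, →E), again keeping drops that do not
significantly worsen fit; finally compare the non-nested survivors by
smallest AIC (−2lnL + 2k). Every fit, LRT and decision is recorded in a
JSON trace. Boundary-constrained drops use the naive χ² reference
(conservative), as is common twin-study practice.

A consequence worth stating plainly: the stepwise ladder retains a
strictly larger model whenever a boundary LRT falsely rejects, which
happens with probability ≈ 2.5% per family branch under the naive
reference *regardless of sample size* — stepwise-LRT selection is not
consistent, by construction. Empirically the ladder recovers a CE or AE
truth at n = 5,000 pairs in ≈ 93–97% of replicates. The AIC comparison
between the non-nested AE and CE families, by contrast, separates them
essentially perfectly at that n, and that comparison is what the
selection-consistency test asserts; the full ladder's behaviour is pinned
by fixed-seed unit tests.

## Confidence intervals and heritability

For pooled-path fits, 95% intervals for a standardized share are profile
likelihood: the share is fixed at s, the remaining shares move on the
reduced simplex, and the means and total variance are solved in closed
form (GLS means; V̂ = quadratic form / 2N), giving a cheap exact profile;
the interval is the set with profile lnL within χ²₁(0.95)/2 = 1.92 of the
maximum, found by bisection and truncated to [0, 1]. For sex-specific
fits the interval is a seeded pair-resampling bootstrap percentile
interval (one resampling pass serves all components). Coverage of the
profile intervals is 92–98% over 500 AE simulations at 188 pairs.
Narrow-sense heritability is the standardized A share of the selected
model — 0 when the model contains no A — reported per sex when the
accepted structure is sex-specific.

## Problem sizes

The test suite and acceptance script use: 200 replicates at the
permanent-stage size (69 MZ + 65 DZ pairs) for parameter recovery; 500
replicates at 188 pairs for CI coverage; 100 replicates at 5,000 pairs
for AIC selection consistency; 10⁴–10⁵ pairs for moment-convergence
checks. These sizes give Monte-Carlo error comfortably inside each
test's tolerance.

## Known limitations

Only complete pairs enter the twin models (no raw FIML for missing
co-twins); no multivariate (cross-trait or cross-stage) models; no
covariates in the mean structure beyond sex; the DE model is fittable for
comparison but dominance without additive variance is biologically
implausible and is never selected a priori; bootstrap CIs for sex-specific
shares are percentile-only.
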