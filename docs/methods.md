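# Methods

## Scope and design

`cpcea` implements a within-trial (13-week) economic evaluation of an
intensive group-based upper-limb therapy versus standard care for
children with unilateral cerebral palsy, from a societal perspective.
The analysis is intention-to-treat: children are analyzed in their
randomized arms throughout; arm labels are fixed at generation/ingestion
and never reassigned. There is no discounting (the horizon is a single
quarter) and no aggregation of the seven quality-of-life domains into a
single utility index — the instrument is condition-specific and each
domain is analyzed separately, with no multiplicity adjustment.

## Instrument scoring

The CPQoL-Child parent-proxy form has 66 items answered 1–9. Scoring is
two-stage: items are rescaled by the unique affine map through the
anchors (1 → 0, 9 → 100), i.e. (raw − 1)·12.5, and a domain score is the
mean of its available rescaled items. A domain score is treated as
missing when fewer than half of its items are answered (the
`completeness_threshold`, configurable); missingness is a value, not an
error. Domain scores are kept on their native scale at scoring time;
the pain domain's lower-is-better orientation is applied only in the
cost-effectiveness stage, so descriptive tables match the instrument's
own conventions.

The item → domain allocation is not public; the shipped
`instrument_map.csv` is a documented placeholder partition of 66 items
into the 7 named domains (sizes 11/12/9/8/9/8/9). Every downstream
quantity depends only on domain scores, so the specific allocation is
immaterial to the analysis; users with the licensed scoring key can drop
in their own map CSV.

## Cost model

Societal costs per child, in 2020 AUD, in three fixed categories:
direct intervention (camp registration 425, healthcare staff salaries
1631 per camp child), direct non-intervention (accommodation/travel,
camp consumables 16) and indirect (camp catering 272, caregiver
productivity losses). Camp components are per-child constants in the
intervention arm — an equal-share apportionment of aggregate camp costs,
the reason their interquartile ranges are degenerate — and zero in the
control arm. Productivity losses are valued as caregiver workdays
missed × a daily median-earnings rate keyed by (age band, sex,
education); the shipped earnings table is a synthetic stand-in with
plausible magnitudes (269.20 AUD/day at the default key), not national
survey figures, and is replaceable by CSV. Summaries report medians and
IQRs (linear-interpolation quantiles, the fixed convention throughout)
because cost distributions are right-skewed; arms are compared with the
two-sided Mann-Whitney U test (asymptotic p with tie and continuity
correction). Line items that are deterministic in *both* arms (a fixed
fee versus zero) carry no test and are marked `not_applicable`; a
constant arm against a varying arm is still tested.

## Missing data

Only follow-up quality-of-life scores are treated as missing; costs and
baseline covariates are complete. Missing domain scores are imputed
m = 10 times by chained equations, each variable modelled by predictive
mean matching with k = 5 donors over the remaining analysis columns
(baseline domain scores, arm, age, sex), 10 cycles per imputation.
PMM only reuses observed donor values, so imputations stay in the 0–100
range by construction (and are clipped as a safety invariant). Observed
cells are never altered. Estimates computed per completed dataset are
pooled with Rubin's rules: Q̄ the mean estimate, W̄ the mean
within-imputation variance, B the between-imputation sample variance,
T = W̄ + (1 + 1/m)B, with the classical large-sample degrees of freedom
ν = (m − 1)(1 + W̄/((1 + 1/m)B))² (a Barnard–Rubin small-sample
adjustment is available when a complete-data df is supplied). The
predictor set and PMM choice are assumptions of this package, exposed in
the API, since the trial's own conditional models are unreported.

## Effects and inference

The effect scale is the change score (week 13 − baseline) per domain.
The between-arm contrast of mean change (difference-in-difference) is
tested with the unequal-variance Welch t-test (Satterthwaite df); sample
SDs use the n − 1 denominator. Under multiple imputation the per-dataset
Welch contrasts and squared standard errors are pooled with Rubin's
rules and referred to a t distribution on the Rubin df. The
design-stage sample-size operation uses the plain normal-approximation
formula n = ⌈2(z₁₋α/₂ + z_power)²(σ/δ)²⌉ per group, which gives 26 at
δ = 7, σ = 9, α = .05, power = .80; software that truncates rather than
ceils prints 25 for the same inputs.

## Cost-effectiveness

ΔC and ΔE are intervention-minus-control differences of arm means (ΔE
pooled over imputations). The orientation-corrected benefit
ΔE\* = ±ΔE partitions the incremental plane into dominant / dominated /
trade-off quadrants; the ICER ΔC/ΔE\* is reported (rounded half-away to
whole AUD for display) only in the costlier-and-better quadrant, the
dominance label elsewhere, and a zero benefit with nonzero cost is an
explicit `undefined` outcome, never ±∞.

Uncertainty: children are resampled with replacement within each arm at
the original arm sizes, keeping each child's (cost, effect) pair intact;
B = 10 000 replicates per completed dataset by default, stacked across
the m imputations before percentile extraction (the orderings of
bootstrap-within-MI are not standardized; stacking is simple and
symmetric in m, and is switchable by passing a single dataset).
Uncertainty intervals are equal-tail percentiles of the per-replicate
ICER ratios. This naive-ratio convention reproduces the sign-crossing
intervals typical of published tables but inherits the known quadrant
instability of ratios near ΔE\* = 0; zero-benefit replicates are
excluded with a logged count, quadrant counts are reported alongside,
and the CEAC — P(λ·ΔE\*_b − ΔC_b > 0) over a λ grid (default 0–5000 by
50) — is provided as the ratio-free complement. One master seed spawns
independent per-domain bootstrap streams, recorded in the manifest, so
domains can be recomputed in any order.

## Synthetic trial generator

The generator emulates the study conditions: 27 intervention and 20
control children, matched pairs sharing a 12-month age band, GMFCS and
MACS level (unmatched surplus children get singleton pair labels),
baseline covariate frequencies close to the published roster, the
reported per-domain baseline/follow-up means and SDs per arm, and the
reported cost-component medians/IQRs. Item responses are generated
top-down: a latent (baseline, follow-up) domain score pair is drawn from
a bivariate normal with within-child correlation 0.5 (unreported in the
trial; exposed in config), clipped to [0, 100]; each item adds N(0, 6)
jitter on the 0–100 scale and rounds to the nearest 1–9 category. The
jitter SD of 6 keeps the scored-domain SD inflation under ~2% and the
edge-of-scale clipping bias of domain means below ~0.5 points (the
generator's calibration contract is that scored moments converge to the
configured moments as n grows; the pain domain, configured near 28,
carries the largest such bias).

Skewed cost components use zero-inflated log-normals. For intervention
travel costs the published median (697) is matched exactly with a 30%
point mass at zero, and the log-normal σ = 1.0 is calibrated so the
implied per-child cost spread is consistent with the published
incremental-cost uncertainty interval; the upper quartile is then
matched only approximately (~1770 vs 2458). A two-parameter fit through
both printed quartiles would force σ ≈ 1.35, whose tail implies a
per-child SD (~7400 AUD) several times larger than the printed ΔC
interval supports — the two printed constraints are mutually
inconsistent under a log-normal, and the interval width was judged the
more decision-relevant target. Intervention caregivers miss 0 days
(probability 0.3) or the full 10-workday camp fortnight (median
productivity loss 2692 = 10 × 269.20); control days-missed are
log-normal, matching the printed productivity quartiles.

Missingness: MCAR removes individual item cells at both timepoints at
the configured rate. MAR-on-baseline removes entire week-13 assessments
child-wise — the mechanism that actually makes follow-up domain scores
missing and imputation meaningful — with dropout probability logistic in
the child's standardized mean baseline score (slope −1: lower baseline
QoL, higher dropout), the intercept solved by bisection so the expected
missing fraction of follow-up cells equals the configured rate (default
0.10). Baseline responses and covariates stay complete under MAR.

What the generator does **not** emulate: post-randomization withdrawals,
recruitment/refusal, item-level factor structure or differential item
functioning within a domain (items are exchangeable around the latent
score), correlation between cost components and outcomes, MNAR dropout,
and secondary-caregiver costs. Passing tests therefore demonstrate that
the pipeline recovers known population quantities under the trial's
*reported* first- and second-moment structure, not robustness to the
unmodelled features of real trial data.

## Numerical and reproducibility choices

Quantiles everywhere are linear-interpolation order statistics. Display
rounding: whole AUD for ICERs (half away from zero), 2 decimals for
probabilities and score summaries; all internal arithmetic is
full-precision. Every stochastic stage draws from an independent child
stream of one master seed (numpy `SeedSequence.spawn`), recorded in the
run manifest; the chained-equations engine uses the legacy global
RandomState and is wrapped in a save/seed/restore guard. (config, seed)
fully determines all numeric outputs; the manifest additionally records
a config hash, row counts per stage and wall-clock timing. Problem
sizes used by the test suite — e.g. n = 2000/arm for generator
calibration, 200 repetitions × B = 2000 for the parameter-recovery
study, m = 50 for the many-imputations convergence check — are chosen so
each check's Monte-Carlo error is well inside its assertion tolerance.

## Known limitations

Percentile-of-ratio intervals are unstable when the benefit distribution
straddles zero (documented above; CEAC is the stable alternative).
Welch tests on n = 27/20 change scores have limited power, and the
bootstrap percentile interval slightly undercovers for the heavy-tailed
cost means at these arm sizes (~91–94% observed coverage at nominal
95% in the recovery study). The sample-size operation implements one
documented convention among several in common software. The earnings
table and instrument partition are synthetic placeholders, replaceable
by users holding the licensed originals.
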