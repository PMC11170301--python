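# Methods

## The model

`erpo-avert` implements a counterfactual method-substitution model for
estimating how many extreme risk protection orders (ERPOs) must be issued
to prevent one suicide. The data are a method-stratified tally of suicide
deaths among N intervention subjects; the model turns that tally into a
causal-effect estimate in three steps.

**Step 1 — CFR inversion.** Each suicidal act by method *m* is assumed
fatal with a fixed, known case fatality ratio (CFR) p_m. The number of
suicidal acts (fatal plus nonfatal) is therefore estimated from observed
deaths D_m as

    A_m = D_m / p_m ,        A = Σ_m A_m .

This is the method-of-moments inversion of D_m ~ Binomial(A_m, p_m); it is
unbiased for A_m but noisy when p_m is small (see *Limitations*). Methods
with no observed deaths contribute zero acts — no smoothing or
pseudo-counts, so the factual act distribution has the same support as the
death tally.

**Step 2 — act-conserving redistribution.** The intervention is assumed to
change the *method mix* of suicidal acts but not their *number* (act
conservation). Under a counterfactual method distribution q (proportions
summing to 1), the counterfactual acts are A·q_m.

**Step 3 — counterfactual mortality.** Applying the same CFRs to the
redistributed acts gives the counterfactual death count

    D* = A · Σ_m q_m p_m ,

and the effect estimates

    deaths averted  = D* − D
    risk difference = (D* − D) / N
    NNT             = N / (D* − D)     (undefined when D* ≤ D).

NNT and risk difference are exact reciprocals by construction. When
D* ≤ D the NNT is reported as undefined (the signed risk difference is
retained); the CLI renders zero excess deaths as `inf` and never prints a
negative NNT.

Two counterfactual constructions are built in: an arbitrary distribution
(e.g. the empirically derived act mix of male handgun owners), and the
fixed-firearm-fraction construction in which a fraction *f* of acts involve
firearms and the remaining 1−f mirror the factual nonfirearm act mix. A
sensitivity sweep evaluates NNT over a grid of *f*; under the packaged male
CFR table (firearm CFR 0.904 exceeds every other method's), D*(f) is
strictly increasing and NNT strictly decreasing in *f*, with closed form
D*(f) = A·(f·p_firearm + (1−f)·c̄_NF), c̄_NF the acts-weighted nonfirearm
CFR.

## Packaged worked example

The package ships the Connecticut ERPO inputs as data files: the
method-specific death tally (21 deaths among N = 762 respondents,
1999–2013), the male CFR table (emergency-department based), and the male
handgun-owner act distribution (28% firearm / 54% drug poisoning / …) used
as the counterfactual. `connecticut_scenario()` or
`erpo-avert counterfactual --preset connecticut` reproduce the headline
derivation: 187 estimated acts, ≈55 counterfactual deaths, ≈34 averted,
NNT ≈ 22. Male CFRs are used throughout because the overwhelming majority
of the relevant decedents are male; the stratum is always an explicit
parameter.

### Rounding modes

All arithmetic is full float precision; rounding happens only in report
rendering. The published derivation table, however, redistributed the act
total *after* rounding it to the integer 187 ("28% of 187"), whereas the
unrounded inversion gives 187.2973. The two conventions differ visibly in
the firearm cell (47.33 vs 47.41 expected counterfactual firearm deaths)
and in the first decimal of the NNT (22.35 vs 22.29). The engine's default
is full precision; `run_counterfactual(..., round_total_acts=True)`
reproduces the published intermediate rounding exactly. One printed cell —
5.9 estimated acts for poisoning by gases/vapors — is not reproducible
from its own printed inputs under either convention (2/0.342 = 5.848); the
source presumably used an unrounded CFR for that cell.

Table-4-note arithmetic describing counterfactual deaths as a *division*
of acts by CFR is treated as an erratum: the printed numbers
(52.4 → 47.3 at CFR 0.904) follow only from multiplication, which is also
the model-consistent direction.

## Input validation and units

Method distributions are validated strictly. `normalize_distribution`
accepts raw weights (`units="weights"`, rescaled freely) or declared-scale
inputs (`units="percent"|"fraction"`), for which the fraction-scale sum
must be within ±0.015 of 1 — whole-percent published rows pass, but a
fraction-scale vector mislabelled as percent (or vice versa) is a hard
error rather than a silent rescale. Distribution CSVs declare their scale
in a leading `# units=...` comment. Censored glyphs such as `<1` are not
parsed; files must contain explicit numbers.

## Cohort tabulation

Individual-level records (ownership × sex × died-by-suicide × method) are
tabulated into per-cell death tallies and within-cell percent
distributions; the record invariant — a method is recorded exactly for
suicide decedents — is enforced with offending ids reported. Act
distributions per cell apply the step-1 inversion with a sex-matched CFR
table; they are invariant to scaling all cell counts, and empty cells are
reported with count 0 and an undefined distribution. Published act *totals*
for such cohorts are deliberately not reproduced: whole-percent rounding
and `<1` censoring in the printed mortality distributions make them
unrecoverable, so only the qualitative distribution is checked, on
synthetic data. Percent rendering is half-up at display precision; stored
values are full precision.

## Uncertainty propagation

The source analysis reports point estimates only; the `uncertainty` module
adds a parametric bootstrap. Death tallies are resampled multinomially
conditional on the observed total (deaths are treated as data, not a rate;
an independent-Poisson variant is available), CFRs are optionally
perturbed with conjugate Beta(p·n_eff, (1−p)·n_eff) draws under
user-supplied effective sample sizes (default: fixed), every replicate
reruns the full pipeline, and percentile intervals are reported.
Percentile (not BCa) intervals keep the NNT interval exactly the monotone
transform of the risk-difference interval. Replicates with no excess
deaths have an undefined NNT; their fraction is reported, never silently
dropped. All resampling is driven by one explicit seed split into named
`SeedSequence` streams, so results are bit-reproducible.

Measured calibration at the worked example's scale (187 true acts, ~21
deaths; 200 simulation rounds of 500 replicates, fixed seeds): nominal 95%
intervals for counterfactual deaths cover the simulated truth in 82% of
rounds with total-conditioned multinomial resampling and 84% with Poisson
resampling. The undercoverage is structural, not a defect: when a low-CFR
method happens to record zero deaths, the plug-in bootstrap can never
restore its support, so intervals occasionally sit entirely below the
truth. Intervals at this scale should be read as sanity bands, not exact
95% statements; coverage improves with the death count.

## Synthetic data generator

`generate_cohort` draws individual records with rare ownership (default
prevalence 0.07), rare suicide death (defaults ≈7×10⁻⁴ per person over
the follow-up, chosen to echo a large linked handgun-transfer cohort's
1216-owner / 15 164-nonowner decedent split), ownership-specific male
shares (0.838 / 0.689), and decedent method mixes per ownership × sex cell
with firearm shares 0.88 (owners) vs 0.40 / 0.17 (male / female
nonowners). Published whole-percent mixes censor cells below 1%; those
cells enter as 0.5% weights before normalization. Every parameter is
overridable.

`simulate_acts_and_deaths` is the forward model the estimator inverts:
acts multinomial over methods, deaths binomial per method with CFR p_m.
Because the inversion D/p is exactly unbiased for binomial deaths,
parameter recovery on this simulator validates the pipeline's arithmetic —
it does not validate the model's substantive assumptions on real data:
that published ED-based CFRs transfer to the study population, that act
counts are conserved under intervention, and that a handgun-owner act
distribution approximates the respondents' counterfactual mix (this third,
untestable identifying assumption is the crux of the design). Recovery
tests condition on ≥5 expected deaths per method; at low-CFR methods
(cutting 0.013, drug poisoning 0.025) with few expected deaths, the
estimator is unbiased but extremely noisy — this is also the scientific
weak point of CFR inversion itself. The generator does not simulate
time-varying ownership, divestment, calendar time, or the healthcare
capture process behind the CFR estimates.

## Problem sizes and numerical choices

The headline computation is a 10-vector arithmetic problem and runs in
microseconds. Test-suite simulation sizes: recovery at 10⁵ acts × 200
replicates; cohort recovery at 10⁵ individuals; bootstrap regression at
2000 replicates; coverage at 200 rounds × 500 replicates — sizes at which
Monte-Carlo error is comfortably below the asserted bounds while the whole
suite runs in seconds. Distribution-sum tolerance 0.015 (fraction scale);
act conservation and NNT·RD reciprocity asserted to 1e-9 relative;
equality of round-trip inversion to 1e-12. Ties in percent display round
half-up to match published table style.
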