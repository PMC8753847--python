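# Methods

`airwayphys` re-implements, as an open and testable pipeline, the
physiological and cellular analysis chain used in guinea-pig asthma-model
studies: breath-by-breath obstruction indices from whole-body
plethysmography, histamine responsiveness (PD200), Fura-2 calcium
kinetics, flow-cytometry/qPCR phenotype summaries, and the statistical
layer that correlates cell phenotype with lung function. No animal
recordings are distributed; a seeded synthetic-data module generates
inputs with the statistical structure the analysis assumes, so every stage
can be validated by round-trip against known ground truth.

## Bronchoobstructive index (Bi)

Each breath contributes

    Bi = ((Te − Rt) / Rt) · (PEP / PIP)

with Te the expiratory time (s), Rt the relaxation time (s), and PEP/PIP
the unsigned peak expiratory/inspiratory deflections of the box signal.
This is algebraically the enhanced-pause (Penh) index. Two consequences
are enforced as invariants: Bi is dimensionless and invariant under any
uniform rescaling of the pressure channel, and Bi ≥ 0 whenever Te ≥ Rt.

**Relaxation time.** Rt is operationalized as the time from expiratory
onset until 64% of the expired tidal volume has left, the standard
enhanced-pause convention; it is the only widely used definition
consistent with the Penh form. The fraction is a module constant
(`RT_VOLUME_FRACTION`), interpolated linearly between samples.

**Segmentation.** The box signal is treated as flow-like with inspiration
positive. Breath onsets are signed zero-crossings into the positive lobe;
a breath runs to the next onset, so Te includes any end-expiratory pause.
A flat signal yields zero breaths (not an error); non-uniform sampling is
rejected.

**Inclusion filters.** Breaths enter the analysis only if tidal volume
≥ 1 ml, inspiratory time in [0.15 s, 3 s], and the inspired/expired volume
difference is at most 10%. The volume threshold and the difference
denominator both use the inspired volume (the convention is ambiguous in
the field; the choice is exposed in `FilterRules`). Boundaries are
inclusive; each rejected breath carries the first violated rule; the
filter is idempotent.

**Aggregation.** Per-breath Bi values are averaged over non-overlapping
15-s windows aligned to the recording start (a breath belongs to the
window containing its onset; a partial trailing window counts if it spans
at least 5 s), and the period value is the mean of the window means over
the last 5 min of the period. Windows without accepted breaths are
skipped; a period with none yields an explicit NaN.

**Session summaries.** The baseline period is a 5-min recording started
10 min after chamber placement; post-provocation values follow at 5 and
10 min and then every 15 min. Rmax (obstruction) is the maximum
post-provocation period Bi within the session. The change in baseline Bi
is current-session baseline minus the baseline recorded at sensitization
reinforcement, so rising intrinsic tone is positive; the opposite
convention is a sign flip the correlation stage would absorb into the
sign of `dbaseline_bi` correlations.

## PD200 and the responsiveness ratio

Histamine dose–response sessions use non-cumulative doses spanning
0.001–0.1 mg/ml; the per-dose response is the maximum of the 15-s window
means in the 10 min after delivery (a mean-based summary is available).
PD200 is the dose at which Bi reaches three times baseline, interpolated
linearly in log10 dose between the bracketing steps (doses span two
decades; linear-dose interpolation sits behind a switch). The name derives
from a 200% increase over baseline, i.e. the three-fold level; the
three-fold rule is what is implemented. Curves that never reach threshold
are censored at the top dose; curves already over threshold at the first
dose are censored at the bottom dose. The PD200 ratio is post-challenge
over pre-challenge dose; ratio < 1 is hyperresponsive, > 1
hyporesponsive. Censoring propagates to the ratio as a flag and censored
ratios are excluded from correlation statistics by default, since there is
no standard convention for imputing them.

## Fura-2 calcium calibration and SR-refilling kinetics

The background-subtracted 340/380 ratio R = (F340 − b340)/(F380 − b380)
(samples with non-positive denominator are flagged missing) converts to
concentration by the Grynkiewicz relation

    [Ca²⁺] = Kd · β · (R − Rmin) / (Rmax − R)

with defaults Kd = 386 nM, Rmin = 0.5, Rmax = 11.7, β = 7.5 (the
calibration of the emulated preparation; all four are constructor
arguments). The map is strictly monotone on [Rmin, Rmax). Numerical
handling at the edges is explicit: R ≥ Rmax (saturation, where the formula
diverges) becomes NaN with a flag, R < Rmin is clamped to 0 nM with a
warning. Basal [Ca²⁺] is the mean over a pre-stimulus window with missing
samples excluded.

The SR-refilling readout is the Ca²⁺ undershoot after withdrawal of
10 mM caffeine: within a 60-s search window after withdrawal, the decline
segment runs from the post-withdrawal maximum to the window minimum, and
the reported rate (nM/s) is the magnitude of the least-squares linear
slope over that segment — a full-segment fit rather than a two-point or
initial slope, for robustness at the 0.5-s acquisition rate (an
initial-slope estimator is available via `method="initial"`). If the
minimum never drops below the pre-caffeine baseline, the trace is flagged
as having no undershoot instead of returning a rate. The estimator is
invariant to constant offsets and equivariant under time rescaling.

Because the segment endpoints are themselves selected from noisy samples,
the fitted rate carries a small selection bias (the window minimum tends
to fall in the flat early-recovery region); at the default ratio noise of
0.005 this stays within a few percent of the generating slope.

## Phenotype summaries

Percent marker-positive myocytes: 100·positive/total minus the
isotype-control percentage, clamped at zero (reported percentages are
non-negative; background is under 1% in the emulated assay). Gating is out
of scope — the functions consume already-gated event counts, since no gate
geometry is published for the emulated panel. Relative SERCA2B expression
is plain delta-Ct against 18S, 2^−(Ct_gene − Ct_18S), without
amplification-efficiency correction. GSH enters as a measured per-animal
covariate with no further processing.

## Statistical layer

Associations are Spearman rank correlations (average ranks for ties) with
two-tailed p-values: exact by full enumeration of rank permutations for
n ≤ 9 — the emulated study's group sizes, where the t approximation is
unreliable — and the large-sample approximation otherwise. Pairs with
missing values are removed pairwise and the n used is reported per pair.
No multiple-testing correction is applied to the primary p-values,
matching the reporting style of small-cohort physiology studies; a
Benjamini–Hochberg column is emitted alongside for transparency. Group
comparisons use unpaired t-tests; the pre/post PD200 comparison within a
group uses a paired t-test. The challenge series is tested by one-way
repeated-measures ANOVA (statsmodels `AnovaRM`) with Dunnett many-to-one
contrasts of each challenge against the baseline period
(`scipy.stats.dunnett`); the scipy procedure treats the level samples as
independent, which is conservative here relative to a within-subject
Dunnett adjustment — no installed package provides the latter, and the
omnibus RM-ANOVA carries the within-subject structure.

## Synthetic data generator

The generator defines the conditions under which the pipeline is
validated. What it emulates, and what it does not:

**Breath trains.** Each breath is a smooth inspiratory lobe
PIP·sin(πt/Ti)^p, with p solved so the lobe integral equals TVi
(feasible iff TVi < PIP·Ti), followed by an expiratory lobe whose volume
CDF is a mixture of an exponential CDF (decay constant solved from the
requested Rt) and a linear ramp. The mixture weight and decay constant are
solved jointly (nested Brent root-finds) so that the peak expiratory flow
equals PEP, the 64%-volume time equals Rt and the lobe integral equals
TVe — a pure exponential cannot satisfy all three. Feasibility requires
Rt < 0.64·Te and PEP above a minimum near TVe/Rt. Defaults describe a
resting guinea pig: Ti 0.30 s, Te 0.60 s, Rt 0.25 s, tidal volume 2 ml,
~67 breaths/min. The model makes no claim about box-pressure physics; it
exists so segmentation and feature extraction can be validated by
round-trip, and deliberately out-of-range breaths (QC-filter tests) can be
constructed with `validate=False`.

**Fluorometry.** Traces are built by inverting the Grynkiewicz map on a
known [Ca²⁺](t) profile; Gaussian noise (sd 0.005 ratio units — a
convention, no noise model is published for the emulated instrument) is
added to the ratio and the two channels reconstructed around a constant
net 380 signal of 500 a.u. with 50 a.u. backgrounds. The caffeine preset:
basal level, transient peaking at 600 nM relaxing to basal + 80 nM, then
at withdrawal a linear decline at the requested rate to 40 nM below basal
and an exponential recovery (τ = 40 s). Acquisition interval 0.5 s.

**Cohort.** One row per animal, 6 control / 9 asthma-model by default.
Each variable is control mean + group shift + λ·f + residual noise, with
f ~ N(0,1) a per-animal latent severity factor. Requested correlation
signs are realised by giving each variable a ±1 loading solved from the
sign map by signed-graph bipartition (a frustrated cycle in the map is
unsatisfiable by any one-factor construction and raises an error); each
connected component is oriented so the latent agrees with the group
effects. λ = 0.7 of each variable's noise scale, residuals scaled so total
variance matches the configured noise. Default group effects follow the
emulated study's direction structure: GSH and SERCA2B expression down,
%TGF-β1⁺, Rmax, Δ baseline Bi up, PD200 ratio down in the asthma group;
%IL-13⁺ and %SERCA2b⁺ unshifted. The table also carries raw
10,000-event flow counts (isotype 0.6%) and Ct pairs consistent with the
percentage and expression columns, and a three-challenge Bi series for
the repeated-measures stage.

Limitations of the emulation: real breaths are not smooth two-lobe
shapes and real segmentation contends with movement artefacts and sighs;
real Fura-2 noise is channel-wise and photobleaching-coloured, not white
in the ratio; a one-factor cohort induces correlations between all
variables sharing a sign-graph component, not only the configured pairs,
and cannot represent partial-correlation structure. Passing tests
therefore validate the estimators and bookkeeping, not instrument-level
robustness. The published per-animal correlation coefficients (e.g.
r = −0.5 between PD200 ratio and obstruction) depend on unreleased animal
data and are not reproduction targets; what is reproduced is the sign
structure at scale and parameter recovery of the printed basal and
undershoot values.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configuration and seed give
bit-identical outputs. The validation suite uses trains of 10–40 breaths
at 200 Hz, fluorometry traces of 240–560 samples, cohorts of up to
200/group for sign-structure checks, and 2,000 replicates of the
effect-free cohort for type-I-error calibration — sizes at which every
check is stable yet the full suite runs in well under a minute per module.
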