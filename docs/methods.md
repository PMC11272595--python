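# Methods

## Ideal-observer geometry

The hidden circle has fixed radius 130 px. The search space defaults to
1280 × 715 px, chosen so the circle covers 5.80% of the space; the exact
screen dimensions of the original task are not fixed by that fraction, so
they are configurable. Candidate centers are restricted to positions where
the full circle fits on screen (inset by one radius from every edge): every
trial opens with a visible inside dot and the revealed circle is always
fully drawn, which is incompatible with centers hanging off the edge. The
prior over admissible centers is uniform (maximum entropy; nothing in the
task biases location).

Observations are hard constraints, so the posterior stays uniform on the
surviving candidate set; the boundary convention is *inside iff distance ≤
radius*, applied identically in observation simulation and posterior
updating so a simulated trial can never eliminate the true center.

Candidates are discretized on a square grid, default step 4 px. The
discretization error of EE is bounded well below the narrowest uncertainty
band used in the designs (0.85 px band width at EE ≈ 74 px refers to the
band's *placement*, not its resolution; empirically EE at step 4 stays
within 2·step of the step-1 value, and the test suite asserts agreement
with dense step-1 double-loop summation to 1e-9 on small spaces).

Degenerate cases: an observation inconsistent with every remaining
candidate raises an explicit inconsistency error (corrupted log or wrong
radius); EE of a single-candidate posterior is exactly 0.

## Trial economy and efficiency

Score and expected value follow the task's printed economy: initial
reserves of 95 (low) or 130 (high) credits, sampling costs of 1 or 5
credits per sample, error cost fixed at 1.2 credits per pixel. No score
floor is applied by default (a floor at 0 is configurable). The optimal
sample count s\* is the argmax of EV(s); ties break toward fewer samples,
since at equal expected value not sampling weakly dominates.

The extraction-rate model describes EE over samples as
(EE_start − EE∞)(1−α)^(s−1) + EE∞ with 0 < α < 1 and EE∞ > 0, where
sample index 1 is the trial-onset state (the initially displayed dot is
the "0th sample"). EE_start is shared across trials as the across-trial
mean of onset EE; α and EE∞ are fitted per trial by least squares. Because
EE∞ enters the model linearly once α is fixed, it is profiled out in
closed form and α is found by a 9-point coarse scan plus bounded 1-D
refinement of the mean-squared error — equivalent in objective and
constraints to a bounded multi-start optimizer, but with no local-minimum
risk in the remaining 1-D problem. Near-constant EE sequences leave α
unidentified; they return a boundary fit flagged `flagged` with sse ≈ 0
rather than an error.

### Deviation from optimal sampling

s\* for a logged trial is computed from the trial's *realized* EE curve —
EV evaluated on the sampling dynamics that actually happened — enumerated
over the samples taken. This makes the metric an oversampling measure:
a trial stopped while EV was still rising scores ~0 rather than a negative
deviation. The alternative, extrapolating the fitted exponential to a
fixed horizon, systematically inflates s\* for efficient samplers because
the greedy policy's EE tail decays faster than any single-rate exponential
(the fitted asymptote is driven toward 0 and the extrapolated curve keeps
promising gains that the realized search no longer offers). Undersampling
therefore cannot be quantified from logs alone; the signed
`deviation_from_optimal` primitive is retained for callers who have a full
EV curve from another source. The cost-sensitivity index is the drop in
mean samples from the low- to the high-cost condition at high reserve.

## Stimulus generation

Passive stimuli are 8-dot configurations (4 inside, 4 outside) accepted by
rejection sampling when the EE recomputed from the dots alone lands in the
requested band. Proposals are controlled by a spread parameter: dispersed
inside dots with boundary-hugging outside dots carve small consistent
regions (low EE); clustered inside dots with distant outside dots leave
large ones. Bands above ~0.62·r are unreachable that way — a full
consistent disk tops out at EE ≈ 2r/3 — so high bands use a second
construction in which two pairs of outside dots flank the inside cluster
and delete the middle of the consistent region, leaving a bimodal
posterior whose EE exceeds the full-disk value. Acceptance failure after
10,000 attempts raises an error naming the band.

Catch-trial bands are (17.9, 23.0) and (91.0, 93.3) px: the printed
constraints are EE < 23 and EE > 91 within an overall range of 17.9–93.3,
and both bands lie strictly outside the main two-level-design band
(31.8–73.95).

## Synthetic cohorts

Cohort defaults are the package's reference study conditions: 19 subjects
per group; choice intercept 0.5 ± 0.4; reward sensitivity 1.5 ± 0.3;
uncertainty sensitivity −1.5 ± 0.3; effort sensitivity −1.2 ± 0.3 (per
standardized attribute unit); confidence mapping 100 − 0.9·EE with rating
noise SD 8 on the 0–100 scale; sampling jitter 12 ± 4 px; motor noise 5 px.
Controls have context factor γ = 1 and subjective cost weight w_cost =
1 ± 0.15; the lesion-like group differs only in γ = 0.4 ± 0.05 (blunted
reward/effort weighting under uncertainty) and w_cost = 0.15 ± 0.05
(cost-insensitive oversampling). Uncertainty sensitivity is deliberately
identical across groups — the phenotype of interest is its *intactness*.
Parameters are drawn from clipped normals respecting each parameter's
domain.

Choice predictors are z-scored against the factorial design's moments so
sensitivities are unit-comparable across attributes; in the two-level
uncertainty design, uncertainty enters the choice model as a standardized
presence flag, with EE itself affecting only confidence and localization.

Active sampling approximates the information-optimal next touch by scanning
a 16 × 12 probe lattice for the point minimizing expected posterior EE
(probability-weighted EE of the two conditioned posteriors); exact greedy
search over the full grid would be quadratic in grid size without changing
behaviour at the jitter levels modelled. Inter-sample intervals follow
isi_base + isi_slope / (1 + jitter/10), times a small log-normal factor:
jittery (fast, imprecise) samplers pause less, producing the
speed–efficiency trade-off (shorter ISIs, lower fitted α). Response times
for passive choices are log-normal and purely descriptive.

What the generator does *not* emulate: learning or drift across trials,
within-trial sequential deliberation beyond the one-step stopping rule,
spatial biases (edge avoidance, handedness), lapses and attention failures,
and any mechanistic response-time process. Passing recovery tests therefore
show that the pipeline recovers the phenotypes *under these idealized
conditions*, not that real data would be as clean.

In cohort simulation of the passive designs, each uncertain trial carries
an EE drawn uniformly within its scheduled band rather than a freshly
rejection-sampled dot configuration; the choice and confidence models
consume only the EE scalar, and dot-level generation is exercised
separately by the schedules module.

## Estimation pipeline

Per-subject logistic maximum likelihood replaces the original multilevel
machinery: the claims under test concern recoverable sensitivity
differences, and per-participant estimates are what enter the group
contrasts and brain-behaviour correlations. Complete separation (or a
diverging MLE, |coef| > 15, or non-finite standard errors) triggers a
Firth-penalized refit — Newton iterations with the Jeffreys-prior score
correction, which keeps estimates finite under separation — and raises a
`separation` flag; all-accept/all-reject subjects are returned
non-converged with NaN coefficients rather than silently dropped.

Group contrasts use a Shapiro–Wilk gate at α = 0.05 per group: both normal
→ two-sided t-test with Cohen's d; otherwise (or under degenerate
variance) Wilcoxon rank-sum with Cliff's δ. All tests are two-tailed at
α = 0.05 and no multiplicity correction is applied by default.

Uncertainty-estimation accuracy is the per-subject OLS slope of z-scored,
sign-flipped confidence on EE (positive slope = well calibrated).

Volume analysis: V_adj = V − β(ICV − mean ICV) with β and the mean taken
from a reference control sample (or estimated from the supplied rows), and
a robust regression of sensitivity on adjusted volume using iteratively
reweighted least squares with Tukey bisquare weights (tuning constant
4.685), with optional covariates; R² is computed from the robust fit's
residuals.

## Problem sizes and numerical choices

The test and acceptance workloads use the full printed designs (60/100/125/
210-trial schedules, 19 + 19-subject cohorts, 100 replicate cohorts for
power/calibration, 100 replicates × 60 trajectories for extraction-rate
recovery) but keep per-trial geometry at the default 4-px grid and probe
lattices as above; brute-force oracle checks run on ≤ 100 × 100 spaces at
step 1, where dense enumeration is exact. Optimizer tolerances: 1e-8 on α;
posterior weights are renormalized exactly (uniform over survivors), so no
drift accumulates over observation sequences.
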