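# Methods

## Instrument scoring

The FLI-P checklist is 64 ordered statements in six hierarchical skill
areas (sound awareness; associating sound with meaning; comprehending
simple spoken language; comprehending language in different listening
conditions; listening through discourse and narratives; advanced open-set
listening). Responses are binary — "mostly" (skill shown regularly, across
places and people) or "rarely" — and the score is the count of "mostly"
responses, 0–64.

Two administration rules are implemented exactly as checklist QC, not as
score arithmetic:

* **Ceiling.** Scanning items in ascending order, the first run of
  `run_length` consecutive "rarely" responses ends the assessment. The
  exact run length constituting "a sequence" is not publicly fixed; the
  package defaults to 4, mirroring the four-item basal window, and makes
  it configurable. "Mostly" responses recorded past the ceiling still
  count toward the score but raise a warning, as do assessments with no
  ceiling and unanswered items below the ceiling.
* **Basal.** The four highest-indexed "mostly" items, reported so a later
  administration can re-check them for regression. Informational only.

Unanswered items count as not-"mostly": the score definition counts
explicit "mostly" records and nothing else.

The packaged checklist definition is structurally faithful (64 items, 6
areas) but carries real statement text only for the six publicly printed
exemplar items (indices 1, 8, 19, 31, 42, 56, taken as the first item of
their areas); the remainder are clearly marked placeholders because the
full item set is proprietary. Area boundaries (1–7, 8–18, 19–30, 31–41,
42–55, 56–64) are the package's own contiguous partition anchored at those
exemplars.

## Percentile growth curves

Each percentile of score against age x (months) is a four-parameter
logistic `q(x) = a1 + (a2-a1)/(1+exp(-a3(x-a4)))`: `a1`/`a2` lower/upper
asymptotes (score points), `a3` growth rate (per month), `a4` inflection
age (months). The packaged reference table stores the published parameters
of the 5th, 10th, 16th, 50th, 84th, 90th and 95th percentile curves at
their printed 4-decimal precision. The three highest curves have
`a2 = 64.0000` exactly — the instrument maximum acting as an active bound.

Conventions:

* Ages are continuous decimal months; the valid domain is (0, 72].
* Reported curve values are clamped to [0, 64] (the 5th-percentile curve
  is negative below about one month); unclamped values remain available
  for fitting and simulation.
* Norms are recommended from 3 months upward (few very young children in
  the source data); queries below `min_age` warn but still compute.
* Non-crossing of the family is checked on a grid (tolerance 1e-9) and
  reported, never repaired — the curves are fitted independently and the
  packaged family is verified non-crossing on [3, 72] at 0.1-month steps
  (in fact on all of (0, 72]).

**Score-to-percentile inversion** interpolates monotonically in
normal-score space: table levels tau are mapped to z = Phi^-1(tau) and the
score is linearised in z between bracketing curves. Linear-in-z rather
than linear-in-tau behaves sensibly in the tails and is consistent with
reading the 16th/84th percentiles as ±1 SD. Scores outside the fitted
[5th, 95th] range return the boundary tau with an `outside_fitted_range`
flag — the package does not extrapolate percentile estimates for
individuals. Bands are below-5th / 5th–16th / 16th–84th / 84th–95th /
above-95th.

## Quantile-curve estimation

The conditional tau-quantile is estimated by minimising the check
(pinball) loss `sum r (tau - 1[r<0])` over the parameter box
a1 ∈ [−40, 30], a2 ∈ [a1+1, 64], a3 ∈ (0, 1], a4 ∈ [1, 60]. The bound
a2 ≤ 64 encodes the instrument maximum; for high percentiles it is
typically active.

The loss is piecewise linear in residuals, hence non-smooth in the
parameters, so the optimiser is derivative-free: bounded Nelder–Mead,
restarted from a moment-based initial guess (a2 ← max score, a1 ← min
score, a4 ← age at the half-range score, a3 ← 4·slope/(a2−a1)) plus 15
deterministic jittered perturbations (10% of each box width). Each local
search stops at absolute loss change < 1e-8 or 2,000 evaluations. Fits are
bit-reproducible given data, options and seed. The a2 > a1 ordering is
kept by a penalty rather than reparameterisation, which keeps reported
parameters on their natural scale.

Percentile families are fitted independently per tau (no joint
non-crossing constraint); crossings are diagnosed on a 0.5-month grid and
reported. Records below 3 months participate in fitting — the 3-month rule
governs reporting, not estimation. A brute-force grid minimiser ships as a
testing oracle; property tests assert the continuous optimiser never loses
to it.

Preconditions: at least 20 records spanning at least 12 months of age —
below that the four-parameter sigmoid is not meaningfully identifiable.

## Synthetic cohort generator

The generator emulates the normative study's data structure; it is the
stand-in for raw data that are commercially restricted.

* **Conditional score law.** Only seven conditional quantiles are
  published. The full law is completed by normal-score interpolation: at
  age x the seven curve values pair with z = Phi^-1(tau); a child's latent
  rank u ~ Uniform(0,1) maps to Phi^-1(u); the score is linear in z
  between bracketing curves, linearly extrapolated from the outermost
  segments beyond [0.05, 0.95], then clamped to [0, 64]. This is the
  minimal completion consistent with the ±1 SD reading of the 16th/84th
  percentiles. A `clamp` tail option truncates ranks to [0.05, 0.95]
  instead.
* **Cross-sectional designs.** Twelve contiguous 6-month age blocks with
  per-block counts; ages uniform within block (the within-block age
  distribution is not published). Packaged designs: `target` (36 per
  block, total 432 — the study's minimum recruitment requirement) and
  `actual` (the achieved per-block counts 36, 40, 42, 49, 42, 47, 63, 46,
  53, 36, 36, 36). Those printed per-block counts sum to 526, whereas the
  published block total is 536 and the overall analysed record count 561;
  the packaged design keeps the per-block values and this note records the
  discrepancy. The youngest admissible child is 1.5 months (the youngest
  in the source data), flooring the first block.
* **Scores** are continuous by default (estimation experiments are then
  free of rounding bias) with integer rounding available for realism.
* **Longitudinal model.** Two variability components: a per-child rate
  multiplier r ~ LogNormal(0, sigma_b) acting on *effective age* r·x of
  the median curve (between-child variation in the rate of score increase,
  taken literally as a rate), and independent N(0, sigma_w²) within-child
  assessment noise, clamped to [0, 64]. No published values exist for
  sigma_b or sigma_w; the defaults sigma_b = 0.15 (≈ ±15% rate spread) and
  sigma_w = 2.0 score points (the magnitude of the median-accuracy
  criterion) are the package's documented choice, used only where the
  source is silent.

What passing tests on this generator do **not** show: agreement with the
original raw data's conditional distribution beyond its seven quantiles,
realistic within-block age clustering, item-level response patterns, or
any clinical-population structure (hearing loss, devices, bilingual
exposure are out of scope).

## Monte Carlo sample-size machinery

One replicate: simulate a cohort (bare n with uniform ages, or an
age-block design), refit the tau = 0.5 curve, record the maximum of
|fitted − generating median| over integer ages 1..72 months — including
ages 1–2 even though reporting elsewhere starts at 3, and even though the
design places no children below 1.5 months. The probability that this max
error is ≤ E (default 2 score points) is the fraction of replicates within
the bound; the minimal-n scan returns the smallest candidate reaching the
target probability P (default 0.90). Replicates use 8 Nelder–Mead starts:
on this family the loss reached is identical to 32-start runs, so the
cheaper setting is used inside the replicate loop. Failed fits count as
exceeding the bound (conservative) and are reported, never dropped.

Because the original simulation's distributional assumptions were never
disclosed, the published adequacy of n = 144 is not reproducible and is
not a package claim; the machinery, the accuracy criterion and the
monotone improvement of the probability in n are the deliverables. Under
this package's curve-induced generator the probability at the achieved
design (n = 526) sits near 0.87–0.91 depending on the Monte Carlo draw —
the between-child spread implied by the published percentile curves
(16th–84th ≈ ±8 score points at mid-ages) is evidently wider than the
original simulation assumed.

## Validation and trajectory comparison

* **Binned percentiles.** (0, 72] is partitioned into lower-open,
  upper-closed bins (default 6 months, matching the recruitment blocks);
  sample percentiles use the linear order-statistic interpolation rule
  with plotting position p(k) = (k−1)/(n−1) — the common scientific-
  software default, stated explicitly because the original estimator is
  unnamed. Bins under a minimum count (default 5) carry no values.
  Midpoint differences against curve values form the rough-agreement
  check.
* **Segmented descriptive fit.** Independent least-squares lines on
  (0, 30], (30, 54] and (54, 72] months — half-open segments resolve the
  boundary-month ambiguity of the "0–30 / 31–54 / 55–72" description. On
  synthetic cohorts the early slope exceeds the late slope, the expected
  fast-then-flattening acquisition pattern.
* **Trajectory flags** (defaults documented, all configurable): divergence
  = ≥ 2 consecutive assessments strictly below the 16th-percentile curve;
  plateau = child gains < 2 points across a span of ≥ 6 months while the
  median curve gains ≥ 4 over the same span; converging = the percentile
  band improves across the final two assessments. The packaged Child-A/
  Child-B demonstration trajectories are synthetic illustrations of the
  published clinical patterns (early implantation tracking the median;
  plateau below the envelope with late catch-up), not patient data.

## Numerical choices and degenerate inputs

* Quantile-level keys are exact binary floats (0.05, 0.10, ...) used
  consistently as dict keys; tables validate strict tau ordering.
* Inversion and the quantile function guard against user-supplied crossing
  tables by a running-maximum monotonisation; the packaged table never
  triggers it.
* Exact-node lookup precedes interpolation so that flat segments (curves
  almost merged at 64 near 72 months) cannot blur a round-trip.
* Age-grid endpoints tolerate 1e-6 float overshoot (e.g. `arange` hitting
  72.0000000001).
* Constant-score samples give R² = 1 by convention in segmented fits.
* Empty designs generate empty cohorts; empty tau lists, empty grids and
  non-dividing bin widths raise immediately.

## Problem sizes

Default experiment sizes: 20,000-child cohorts for parameter-recovery
checks (median a2 recovered within ±0.1–0.2 in practice, tolerance ±0.5),
50,000 for fixed-age percentile recovery, 200 replicates for sample-size
probabilities (Monte Carlo SE ≈ 2 percentage points). These sizes make the
recovery experiments decisive while keeping a full run in the minutes
range on a single core.

## Known limitations

* The package cannot refit the original 561-child dataset; equivalence
  with the published fit is assessed by parameter recovery on synthetic
  cohorts, not by refit.
* The conditional law between/beyond the seven published percentiles is a
  modelling choice; quantities sensitive to the extreme tails inherit it.
* Whether "mostly" responses above the ceiling were counted in the
  original scoring is unknown; the package counts them and warns.
* Percentile estimates for individuals are truncated at the 5th/95th
  boundary rather than extrapolated.
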