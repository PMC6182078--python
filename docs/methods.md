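# Methods

## The latent event-scale model

The observational unit is one developmental event observed in one
species at a post-conception (PC) age in days.  Events retained for
modelling must be observed in at least two species, at least one of
them a rodent (the rodent list is configurable; default mouse, rat,
spiny mouse, guinea pig, rabbit).  Duplicate (species, event) rows are
an error, never averaged.

Each event *i* has a latent score x_i and each species *j* a log-linear
trajectory log10(day_ij) = a_j + b_j x_i + eps_ij.  Event timing uses
**log10** days; the marker-decline regressions below use natural logs.
The two conventions are deliberate: the human coefficient pair
(a = 1.53, b = 2.44) places the end of the scale at 10^3.97 ≈ 9,333 PC
days, consistent with a childhood-to-young-adult plateau window, which
fixes the base unambiguously, while the decline fits are defined on
natural-log axes throughout.

### Fitting

Alternating least squares (ALS):

1. initialise x_i as the mean over observing species of the
   within-species min–max-normalised log10 day;
2. per-species OLS of log10(day) on x (closed form, vectorised);
3. per-event update x_i = Σ_j b_j (y_ij − a_j) / Σ_j b_j² over the
   observing species (the weighted projection onto the current
   regressions);
4. affinely rescale scores to [0, 1]; repeat 2–4 until no score moves
   by more than `tol` (default 1e-8) or `max_iter` (default 500).

Final regressions are refit on the converged scale with statsmodels to
obtain standard errors and R².  Preconditions: every species
contributes ≥ 3 events, and the species–event bipartite graph is
connected — disconnected blocks can be shifted independently, making
the scale unidentifiable.  A non-positive fitted slope is an error, not
a warning: it means the table contradicts the model's premise.

**Gauge freedom.**  The scale is identified only up to an affine
transform; min–max rescaling is the gauge fix.  Two consequences are
documented because they shape the tests:

- *Slope recovery* must be measured after aligning gauges.  Generating
  scores drawn from U(0,1) span ~[0.01, 0.99] at n = 80, while the
  fitted scale spans exactly [0, 1]; comparing raw slopes therefore
  shows a deterministic ~2–4% deflation even with zero noise.  Recovery
  experiments regress the fitted scores on the generating ones and
  multiply the fitted slope by that gauge factor before computing bias
  (aligned mean |bias| ≈ 0.003–0.017 under the default noise, versus a
  meaningless ~0.04 raw).
- *A deviation shared by all species is invisible.*  If every species'
  limbic events ran 10% shallower, the event scores would simply shift;
  only species-relative deviations are testable.  The synthetic
  generator therefore applies its limbic slope multiplier to a species
  subset (default: the three primates), matching the study design where
  primates curtail limbic neurogenesis relative to rodents.

### Extension versus refit

New events (derived epochs, plateau events) join a fitted model in one
of two modes.  The default, *extrapolate*, scores each new event by
inverting the frozen per-species regressions — x_j = (log10 day −
a_j)/b_j, combined across observing species by a slope²-weighted mean
(the steeper the regression, the more information a day carries about
x) — then rescales the union of scores and refits the regressions once.
*Refit* reruns the full ALS on the combined table.  Both are exposed;
extrapolation is the default because the published timetable was
extended, not recomputed.

### Translation and prediction

predict_day(reg, x) = 10^(a + b·x); translate_time inverts the source
regression and evaluates the target one, so round trips are exact by
construction (tested to 1e-9 relative error).  Scores outside [0, 1]
extrapolate and trigger a warning rather than an error.

## Neurogenesis epochs from marker declines

Marker series hold the Ki67+ (proliferating) or DCX+ (immature neuron)
fraction as **percent of total granule cells** against PC age.
Fractions normalised per mm² of tissue are not accepted: they are not
comparable across ages or species.  Replicates at an age are averaged
(arithmetic mean of percents) unless disabled per species — the
marmoset series is conventionally kept as individual animals.  Zero
fractions cannot be log-transformed and are dropped with a warning.

The decline fit is OLS of ln(pct) on ln(age) inside a per-(species,
marker) age window chosen to cover the span of monotone decline; a
non-negative slope warns, because a rising fit cannot be solved.
Threshold crossing ages are exp((ln pct − alpha)/beta), flagged when
extrapolated beyond the fitted window.  Default thresholds: Ki67
{2, 0.7, 0.5, 0.3, 0.2, 0.1}%, DCX {3, 2.5, 2, 1.5, 1, 0.5}% — the
published lists are internally inconsistent between sections, so the
thresholds are configuration with these defaults.  Derived events keep
the retention rule: a threshold becomes a model event only if solvable
in ≥ 2 species including a rodent.

Staged observations (e.g. MRI milestones) bracket an event between the
latest age at which it had not occurred and the earliest at which it
had; the event day is the arithmetic midpoint (geometric mean as an
option — the choice is not settled by any published rule).

## Limbic timing test

Per species: OLS of log10(day) on {scale, limbic, scale × limbic} with
sequential (Type-I) F tests in that order (Type-II behind a flag),
matching the convention of the R default the original analysis would
have produced.  The response is log10(day): the published wording
flips predictor/response between sections, and only this orientation
reproduces regressions of the published form.  Requires ≥ 3 events per
limbic class.  Under a randomly assigned limbic flag the interaction
test holds its nominal level (rejection rate 0.03–0.07 at alpha = 0.05
over 1,000 replicates).

## Expression plateaus

The linear-plateau model y = a + b·min(x, c) is fit by profiling the
breakpoint: closed-form OLS of y on min(x, c) at each candidate c over
a 200-point grid, refined by bounded Brent minimisation around the best
cell.  Candidate breakpoints must keep at least two distinct ages on
each side; a fit whose optimum sits on that restricted boundary is
declared non-converged (a line with no interior kink is not a plateau).
Coefficient p-values are asymptotic t-tests (df = n − 3) from the
nonlinear-LS covariance sigma² (J'J)⁻¹, where the Jacobian column for c
is b·1[x > c] — so a near-zero slope leaves the breakpoint
uninformative and its p-value near 1, which is what screens out flat
genes.  Detection retains converged fits with all three p-values below
alpha (0.05 default; a flag relaxes the test to a and b only).

Default analysis windows mirror the study design: human samples between
101 and 999 PC days, mouse P1–P30 converted to PC days with a 19.5-day
gestation (gestation lengths are configuration, per species).  Genes
plateauing in both species — paired through a one-to-one ortholog map —
contribute breakpoint ages; the per-species arithmetic means become two
records of one shared developmental event.

## Single-cell co-detection

Cells × genes counts (MatrixMarket + gene/barcode lists) with a cluster
label per cell; clusters identified as glial/astrocytic/microglial/
endothelial are excluded (the study removed clusters 9–15).  A gene is
detected in a cell when its count exceeds zero — for the anchor and the
markers alike.  The statistic is |marker⁺ ∩ anchor⁺| / |anchor⁺|; of
the readings the loose phrase "number of marker⁺ relative to anchor⁺"
admits, only the intersection form responds to permuting the anchor
labels, so it is the one a permutation test can mean.

The null reassigns the anchor-positive label set uniformly at random
over retained cells with fixed cardinality (1,000 draws by default;
< 100 warns), optionally stratified by cluster.  Equal-tailed 95% and
99% percentile intervals classify the observed ratio as above, within,
or below chance.  Under this null the intersection count is exactly
hypergeometric, which the tests exploit as an independent oracle (KS
distance < 0.02 at 10,000 draws); under independent marker/anchor
assignment the "above the 99% interval" verdict occurs in well under 3%
of replicates.

## Synthetic data

Generators mirror the statistical structure each analysis assumes, and
always return ground truth beside the data:

- **Event tables** — scores U(0,1); Gaussian noise (sd 0.05) on log10
  days; per-record missingness 0.1 constrained by the retention rule;
  22% of events flagged limbic; default species coefficients are the
  published human (1.53, 2.44), macaque (1.44, 1.89), marmoset
  (1.73, 1.27) pairs plus a mouse-like (1.0, 1.0) rodent.  The limbic
  slope multiplier defaults to 1 (no effect); experiments that need the
  early-termination signal set it below 1 for the primate subset.
- **Marker series** — pct = exp(alpha + beta ln age) with log-normal
  noise (alpha 6, beta −1.5, sd 0.1) on a 12-point geometric age grid.
- **Expression** — 50 genes, 40% with true plateaus (breakpoints in the
  central half of the age range, rises ≥ ~8× the 0.05 noise sd), the
  rest alternating linear and flat.
- **Cells** — 2,000 cells in 16 multinomial clusters; anchor positivity
  Bernoulli(0.1) inside designated clusters (7–8, mirroring where
  PROX1 is seen); marker positivity at base rates 0.05–0.08 with
  enrichment rho among anchor⁺ cells (rho = 1 is exact independence;
  the default 5 mirrors clear co-detection); counts are 1 + Poisson(2)
  on positives; clusters 9–15 are the excluded "glial" set.

What the generators do **not** emulate: phylogenetic covariance between
species, heteroscedastic or systematically biased literature ages,
batch effects or library-size variation in counts, correlated gene
modules, and doublets.  Passing tests therefore demonstrate that the
estimators recover the model they assume and hold their nominal levels
— not that the model is correct for any particular real dataset.

## Numerical choices and degenerate inputs

- ALS convergence: max score change < 1e-8; typically < 10 iterations.
- Ties: duplicate (species, event) rows error; duplicate ages in
  marker series are averaged (or kept, per species).
- All-equal scores: rescaling errors ("degenerate scale") rather than
  dividing by zero; zero-variance predictors and single-class limbic
  flags are explicit errors.
- Plateau fits on noiseless data report zero p-values (coefficients are
  exact); a singular Jacobian (slope ~ 0) forces p_c = 1.
- Percentile CIs use linear interpolation (numpy default); the 95%
  interval is nested in the 99% by construction.
- Problem sizes in the test suite and acceptance script (80-event
  tables, 100 recovery seeds, 6-event oracle instances, 10,000-draw
  null comparisons, 200/1,000-replicate calibrations) are chosen so the
  Monte-Carlo error is small against each tolerance while the whole
  suite stays desk-scale.

## Known limitations

- The event scale is a point estimate; no uncertainty is propagated
  from the scores into downstream predictions.
- Decline windows are configuration, as in the original analyses; the
  optional r²-maximising helper is a convenience, not an inference.
- The plateau p-values are asymptotic and mildly anti-conservative for
  the slope when the breakpoint is profiled (selection effect); the
  calibration experiment bounds the practical false-positive rate
  instead of claiming exact level.
- Human/mouse age windows assume the PC-day reading of ambiguous
  published ages; both are configurable.
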