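# Methods

## The task and its design constraints

The paradigm is a two-choice loss-avoidance task with fully predetermined
outcomes. On each trial the participant chooses between two affectively
neutral stimuli (a chair and a plane image); the outcome — lose a fixed
amount (2 currency units) or lose nothing — is predetermined by the
schedule, and is signalled by the valence of an emotional feedback image.
The valence–outcome mapping defines two phases: in phase 1 a positive
image signals a loss and a neutral image signals no loss; phase 2 reverses
the mapping. Crossing image valence with outcome yields a 2 Emotion
(positive, neutral) × 2 Loss (loss, no-loss) within-subject factorial with
36 trials per cell over 144 trials (2 phases × 2 runs × 36 trials).

`task_design.generate_schedule` enforces the design constraints by seeded
rejection sampling over random shuffles of the balanced outcome and
position multisets: 18 loss and 18 no-loss trials per run, no outcome
repeated more than 3 times in a row, no stimulus position repeated more
than 2 times in a row. Rejection sampling was chosen because it is simple,
obviously correct, and fast at these sizes (acceptance probability is high
enough that a few shuffles suffice); an attempt cap (default 10,000)
converts infeasible configurations into an explicit error. ISI and ITI
jitter is drawn from a discrete uniform on {2, 3, 4, 5, 6} s; the interval
was specified for the task but not its distribution, and since none of the
behavioral analyses depend on jitter the choice is cosmetic — it only needs
to be deterministic per seed. The displayed end-of-run loss subtracts an
integer uniform on {0,…,3} from the true cumulative loss (floored at 0) to
mask the predetermined loss counts.

A single frozen schedule (seed 20240101) is shared by all simulated
subjects, mirroring the fixed pseudorandomized order all participants
experienced; per-seed generation remains available.

## The choice model

Each stimulus carries an expected value `V`. After a responded trial the
chosen stimulus's value is updated by the delta rule

    V(t+1) = V(t) + α · (R(t) − V(t)),

with the unchosen value untouched. Choice probabilities come from a
softmax over the two values; the package applies a per-stimulus inverse
temperature (β_chair to V_chair, β_plane to V_plane), matching the model's
six-parameter list (α_chair, α_plane, β_chair, β_plane, V0_chair,
V0_plane); a `shared_beta` mode ties the two β's for the single-β softmax
variant. Outcomes are coded R = 1 for no-loss and R = 0 for loss by
default, which keeps values on the same [0, 1] scale as the initial-value
parameters; a {−1, 0} coding is available as a knob. Probabilities on
trial t use values updated through trial t−1; trial 1 uses V0. Missed
trials trigger no update and are excluded from the fit objective.

Fitting minimises the mean squared error between observed choices (chair =
1, plane = 0) and the model's p(chair) by exhaustive grid search. The grid
density is the main cost/precision dial and is explicit: the default grid
uses 11 evenly spaced points per axis (step 0.1 for α and V0, step 1.0 for
β; ≈1.77 M points), and a 6-point-per-axis coarse grid (46,656 points) is
used for cohort-scale analyses and the test suite, where each
subject-phase fit takes tens of milliseconds. Grid evaluation is
vectorized across grid points inside the trial loop and verified against
scalar enumeration. Ties in MSE are broken by the first point in
lexicographic order over (α_chair, α_plane, β_chair, β_plane, V0_chair,
V0_plane), each axis ascending — deterministic and testable.

Parameter recovery at this trial count (72 trials per phase, six free
parameters) is modest by construction; the suite asserts only a positive
rank correlation between true and recovered learning rates over 50 agents
and the absence of systematic positive α bias for non-learning agents, not
point accuracy.

## Synthetic cohorts

`cohort.sample_cohort` draws a full study dataset with known ground truth:
per-subject model parameters from uniform ranges (α ∈ [0, 0.4], β ∈ [1, 5],
V0 ∈ [0.3, 0.7] — learning rates and choice consistency typical of slow,
noisy learning in a task with uninformative outcomes), choices simulated
on the frozen schedule with counterbalanced phase order and a 1.37%
miss rate (the cohort-mean non-response rate of the task), and a
subject-level condition measure generated from the cell-means model

    cell = μ + s_j + (a/2)·E + (b/2)·L + (c/4)·E·L + ε,

with sign codes E = +1 for positive emotion, L = +1 for no-loss,
s_j ~ N(0, σ_subject), ε ~ N(0, σ_noise). Under this coding `a` and `b`
are marginal-mean differences and `c` is the interaction
difference-of-differences, so generator truth plugs directly into the
factorial contrasts. Rating defaults (μ = 5.7, a = 0.9, b = 3.1, c = 0,
σ_subject = 1.0, σ_noise = 1.5) qualitatively reproduce the published
rating pattern — no-loss rated ≈3 points more pleasant than loss, positive
imagery slightly above neutral, additive structure — without targeting any
printed mean. The rating emulator rounds half-up to integers and clips to
the 1–9 scale.

What the generator does **not** emulate: trial-level rating dynamics
(ratings are one value per condition, as collected), any dependence of the
condition measure on the subject's own choices or prediction errors,
non-Gaussian or heteroscedastic noise, and fMRI data properties (spatial
correlation, hemodynamics). Passing tests therefore demonstrate that the
pipeline is correct and calibrated under a well-specified additive world,
not that real data meet those assumptions.

## Statistics

t tests are classical two-tailed (one-sample df = n−1; paired reduces to a
one-sample test on differences). The exactly-null degenerate case (every
value equal to the reference, e.g. a paired test of identical samples)
returns t = 0, p = 1; any other zero-variance input raises.

The 2 × 2 within-subject ANOVA is computed through per-subject difference
scores: emotion = (PL + PNL) − (NL + NNL), loss = (PL + NL) − (PNL + NNL),
interaction = (PL − PNL) − (NL − NNL). For a 2 × 2 within-subject design
each effect's F(1, n−1) is identically the square of its contrast's
one-sample t — an algebraic identity the suite checks at machine precision
and against pingouin's repeated-measures ANOVA. Noise-free contrasts are
resolved by the limit of the F ratio (zero mean → F = 0; nonzero mean →
F = ∞, p = 0).

Bayes factors are reported as BF01 (null over alternative):

- **t statistics** use the Jeffreys–Zellner–Siow default: a Cauchy(0, r)
  prior on the standardized effect δ, r = 0.707 by default. BF10 is the
  marginal noncentral-t density of the observed t under the prior over the
  point-null density, integrated by adaptive quadrature (relative
  tolerance 1e−8, achieved error reported in the result).
- **Pearson correlations** use the two-sided default with a stretched-beta
  prior of width κ on the population correlation (κ = 1, the uniform
  prior, by default); the exact sampling density of r given ρ (in its
  hypergeometric form) is integrated against the prior, with ρ-free
  factors cancelling in the ratio.

The study did not report its prior scales; these defaults are the common
analysis-software conventions and reproduce four of the six published BF01
values to three decimals from the printed statistics alone (see README on
reproduction); both scales are configuration knobs. The full
model-averaged Bayesian repeated-measures ANOVA is deliberately not
reimplemented: `interaction_bf01` is a contrast-based approximation that
reduces the interaction to its one-sample t and is labelled
`interaction_contrast` in every output. Degenerate noise-free cohorts use
sentinels: all-zero interaction scores → BF01 = ∞ (maximal null support),
constant nonzero scores → BF01 = 0.

## Factorial adjudication

Per measure the pipeline computes main-effect indices per subject
(emotion: (loss + no-loss)_positive − (loss + no-loss)_neutral; loss:
(positive + neutral)_loss − (positive + neutral)_no-loss), correlates them
across subjects at the Bonferroni-corrected level (α_family/k, 0.01 for
the five-ROI case), intersects the two main-effect significance masks
(the conjunction), and labels the integration pattern. The study states no
formal decision rule for "additive"; the package operationalizes one and
records it in its output: interaction p < α → *interactive*; both mains
significant, interaction not, and interaction BF01 ≥ 3 → *additive*; both
mains significant without that null evidence → *partial*; otherwise
*indeterminate*. The null-evidence threshold 3 is the conventional
"moderate" bound and is configurable. The conjunction here operates on a
finite measure list with per-measure tests, a deliberate scope reduction
from voxel-mask intersection after cluster correction.

## Numerical and design choices

- All randomness flows from explicit seeds; cohort generation spawns named
  substreams (parameters, choices, condition noise) from the master seed,
  so stages are independently reproducible. Identical configurations
  produce byte-identical output tables (checked by digest).
- Softmax is computed with max-subtracted logits; with β ≤ 10 and values
  in [0, 1] overflow is impossible, but the stable form is kept for custom
  reward codings.
- Analysis scripts run the 35-subject cohort with the coarse grid (the
  package's standard cohort-scale problem size: 70 subject-phase fits,
  ≈3.4 M grid-point × trial evaluations per fit); the 11-point default
  grid is available for single-subject fits where argmin resolution
  matters.
- The interaction type-I calibration check uses 1,000 replicate additive
  cohorts of n = 35; power monotonicity is checked at n ∈ {10, 35, 100}.

## Known limitations

- Grid-search MSE fitting is the modelled estimator by design; no
  likelihood-based or hierarchical estimation is provided, so standard
  errors on individual parameter estimates are unavailable.
- The interaction Bayes factor approximates the model-averaged
  repeated-measures formulation; the two agree in direction but not in
  value, and outputs label the method explicitly.
- With 72 trials per phase the six-parameter model is weakly identified;
  group-level inferences on fitted parameters are meaningful, individual
  estimates are noisy.
- The cell-means generator is exchangeable across cells apart from its
  fixed effects; it cannot express, e.g., variance differences between
  loss and no-loss outcomes.
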