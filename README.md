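# conflictval

Analysis pipeline for a two-phase, 2 × 2 **Emotion × Loss** outcome-processing
experiment, built for researchers studying how the brain and behavior
integrate conflicting value signals — here, a *positive* emotional image
that signals a *monetary loss*. The central question is whether the two
outcome dimensions combine **additively** (their effects sum, no
interaction) or **interactively** (one modulates the other).

The package implements, end to end and with synthetic ground truth:

1. **Task design** — constrained pseudorandomized schedules for the
   two-phase task (2 phases × 2 runs × 36 trials; 18 predetermined loss
   outcomes per run; outcome streaks ≤ 3, position streaks ≤ 2; jittered
   ISI/ITI; the valence–outcome mapping reverses between phases).
2. **Choice model** — a Rescorla–Wagner learner with softmax choice,

       V(t+1) = V(t) + α·(R(t) − V(t)),      p(chair) = e^{β·V_chair} / (e^{β·V_chair} + e^{β·V_plane})

   with six free parameters (α_chair, α_plane ∈ [0,1]; β_chair, β_plane ∈
   [0,10]; V0_chair, V0_plane ∈ [0,1]), used both generatively (simulated
   agents on the predetermined schedule) and for estimation by exhaustive
   grid search minimising MSE = mean[(choice − p(chair))²].
3. **Inference** — one-sample/paired t tests, the within-subject 2 × 2
   ANOVA via contrasts (F ≡ t² identity), Pearson correlations with
   Bonferroni control, and default-prior Bayes factors: the JZS
   (Cauchy-prior) BF01 for t statistics and the stretched-beta BF01 for
   correlations, both by numerical integration.
4. **Factorial adjudication** — per-measure main-effect indices,
   conjunction of main effects, cross-subject index correlations, and an
   explicit additive / interactive / partial / indeterminate label.

See `docs/methods.md` for the model, the synthetic-cohort generator, and
every numerical convention.

## Worked example

The numbered scripts under `analysis/` run the whole study pipeline on a
synthetic 35-subject cohort (outputs under `results/`):

```bash
python analysis/01_generate_schedule.py      # frozen schedule + design audit
python analysis/02_simulate_cohort.py --seed 1
python analysis/03_fit_agents.py             # grid fits + learning-rate tests
python analysis/04_behavioral_stats.py       # choice + rating statistics
python analysis/05_factorial_inference.py    # adjudication + index correlations
```

With `--seed 1` this prints (abridged):

```
cohort of 35 subjects (seed 1) written to results/cohort; mean response rate 98.8%
fit 70 subject-phases on a 46656-point grid
  phase1_alpha_chair_vs_0: t(34) = 6.583, p = 0.000
  phase1_alpha_chair_vs_plane: t(34) = -0.117, p = 0.908, BF01 5.479
  ...
  rating_anova_emotion: F(1,34) = 9.13, p = 0.0047
  rating_anova_loss: F(1,34) = 113.22, p = 0.0000
  rating_anova_interaction: F(1,34) = 4.80, p = 0.0354, BF01 = 0.67
  rating: ... -> interactive
  rating index correlation: r = 0.336, p = 0.049 (threshold 0.05), BF01 = 0.74
```

Reading the output: the simulated agents learn (fitted learning rates are
positive at the group level) but neither stimulus learns faster than the
other (BF01 ≈ 5.5 favors that null), and the ratings show the built-in
main effects — a large pleasantness drop for loss outcomes and a smaller
boost for positive imagery. This cohort was generated with **no true
interaction** (c = 0), so the significant interaction above (p = 0.035)
is a type-I draw at α = 0.05: a useful reminder that the adjudication
label is per-dataset, and that the anecdotal BF01 = 0.67 correctly
refuses to call the null supported. Across 1,000 replicate null cohorts
the interaction test rejects at its nominal 5% rate (checked in the test
suite).

The same stages are available as a single reproducible command with a
resolved-config and output-digest log:

```bash
conflictval run-all --seed 13 --out runs/demo
```

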