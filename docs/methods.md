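# Methods

## The task model

The simulator (`engine.py`) is an event-driven reconstruction of a
free-operant conditioned-punishment game.  A session is `n_pre_blocks` (2)
reward-training blocks followed by `n_punish_blocks` (3) punishment blocks,
each with a 180 s trading window; pending trade countdowns and cue episodes
resolve to completion after the window closes (the "tail"), during which new
trades cannot start.

Contingency rules, with defaults in parentheses:

- A click on a planet with no countdown running starts a 2 s trade
  (`trade_countdown_s`) that pays `reward_points` (+100) with probability
  `reward_prob` (0.5).  The two planets' countdowns are independent; clicks
  during a countdown are logged but start nothing and do not reset it.
- In the punishment phase, a click is *cue-eligible* when no cue is pending
  or visible.  An eligible click on the punished planet triggers the danger
  cue CS+ with probability `cs_prob` (0.2); the safe planet triggers CS− on
  the same schedule.  The cue appears `cs_delay_s` (1.5 s) after the click
  and lasts `cs_duration_s` (6 s).  Cue rolls blocked by an ongoing cue are
  dropped, not queued (one cue at a time).
- At cue onset, shield availability is drawn once (`shield_avail_prob`,
  0.5); the offer (or an "unavailable" notice) appears after
  `shield_charge_s` (3 s).  Activating an offered shield costs
  `shield_cost_points` (50), cancels the attack, and suspends trading until
  the cue ends.
- An unshielded CS+ ends in an attack removing `attack_fraction` (20%) of
  the current point total, rounded half-up and clamped so a non-positive
  bank loses nothing (attacks can never add points; only shield costs can
  push the bank negative).

Every session is a deterministic function of `(config, policy, seed)`.
Randomness is drawn from per-`(seed, block)` numpy `SeedSequence` streams,
one per purpose (reward, cue, shield), so the draw sequence is stable under
refactorings that do not change the event order within a block.  Policies
are consulted for their next timed action and shown every emitted event
batch, which lets learning agents replan when a cue or shield offer appears.

## Behavioural measures

Each block's timeline is partitioned into ITI, cue-pending, unshielded cue,
shielded cue, and post-trading-tail periods.  Design choices here, where the
underlying task description is silent:

- The 1.5 s pending window and the tail enter **no** rate denominator: the
  cue is invisible in the former and responding is impossible in the latter.
- Clicks are attributed to periods as `(start, end]`: the cue-triggering
  click sits exactly on the ITI/pending boundary and is counted as baseline,
  because the cue it caused is not yet on screen.  Without this, every
  pending window would inherit one guaranteed click and cue-period rates
  would be biased upward by construction.
- Rates are time-weighted (clicks per minute of period time), so shielded
  time never deflates the ITI rate.
- The suppression ratio is computed as CS/(CS+ITI).  The verbal formula
  "CS rate / ITI rate" contradicts the stated anchors (0.5 = equal rates,
  range [0, 1]); the standard ratio satisfies them.  The raw quotient is
  available via `suppression_formula="literal"`.
- Missing values (no unshielded exposure to a cue, no shield offered, no
  baseline clicks) remain missing and are dropped pairwise per analysis;
  nothing is imputed.

Exclusions mirror the engagement screen of the original protocol: a
participant is retained only if every check screen's mean response time is
within [1, 30] s and both catch questions are answered correctly.

## The synthetic cohort

The generator (`agents.py`, `cohort.py`) is **not** a cognitive model fitted
to human data; it exists to produce cohorts with the statistical structure
the analysis is designed to detect, with every generative assumption
recorded in the cohort manifest.  An agent:

- clicks with exponential inter-click intervals at `base_click_rate`
  (60/min), scaled by `1 − suppression_gain · V(cue)` while a cue is visible;
- picks planets by softmax (inverse temperature `softmax_beta` = 0.07 per
  point) over Q(R) = w_reward · E[reward points] − w_punish · (κ_R→CS+ ·
  V_CS+ + κ_R→CS− · V_CS−) · L, with E[reward points] fixed at 50 and a
  nominal attack magnitude L = 200 points;
- updates κ_R→CS, its believed trigger probability, toward the *running
  experienced frequency* of triggers per cue-eligible click at rate
  `alpha_instr`.  Tracking the running frequency rather than each binary
  outcome keeps the estimate from random-walking, which matters because the
  final-block preference ratio is the clustering input;
- updates V(cue), its believed attack probability, by a delta rule at rate
  `alpha_pav` from unshielded cue outcomes (shielded episodes are
  uninformative and update nothing);
- activates an offered shield with probability logistic(`shield_bias` +
  `shield_slope` · V(cue)), 0.5 s after the offer.

The two archetypes differ **only** in `alpha_instr`: 0.2 (sensitive) versus
exactly 0 (insensitive).  Zero, not merely small: with hundreds of eligible
clicks per session even a rate of 0.02 converges to the true contingency,
which would dissolve the dissociation the archetypes encode — an intact
Pavlovian model with absent instrumental knowledge.

Self-reports are noisy readouts of the agent's internal model.  Likelihood
ratings are 100 · κ and 100 · V with truncated-normal noise
(`report_noise_sd` = 10 rating points, truncation keeping [0, 100] support
without boundary spikes), and the *direct* R→Attack report is the capped
chain product of the agent's own reportable links, so at zero noise
direct = chained holds as an identity.  Two sources of between-subject
variance make the reports realistically heterogeneous: idiosyncratic priors
(κ prior ~ N(0.25, 0.10) shared across all response/cue pairs so priors
alone induce no response bias; V prior ~ N(0.10, 0.05)) and a subjective
report gain per link type (~ N(1, 0.25), applied consistently to link and
direct reports, preserving the chain identity).  Without these, all agents
of a cluster converge to the same asymptotic beliefs and the direct-vs-
chained regressions would have no signal variance — unlike human cohorts.

What the generator does *not* emulate: trial-level reaction-time structure,
within-session drifts of motivation, memory decay between blocks,
response-slider anchoring, or any trait-questionnaire correlation with task
behaviour (subscales are pure noise).  Passing tests therefore show that the
pipeline recovers structure *of the kind assumed*, not that the assumed
structure is how humans produce it.  One known consequence: for sensitive
agents the safe response's chained estimate collapses to ≈ 0 by the final
block, so the direct-vs-chained regression in that single cell loses its
signal variance; pooled and insensitive-cluster fits are informative.

## Analysis layer

- **Clustering**: scikit-learn k-means (50 restarts) on the 1-D final-block
  preference ratios, k ∈ {2, 3, 4}, chosen by mean Euclidean silhouette with
  ties to smaller k.  The lowest-mean cluster is labelled *sensitive*.  On
  1-D data this reproduces the exhaustive contiguous-partition optimum
  (property-tested).  A separation index (smallest adjacent cluster-mean gap
  over pooled within-cluster sd) flags non-bimodal cohorts: unimodal samples
  split by k-means typically score 2–3, clearly bimodal ones much higher;
  the pipeline warns below 4 or when a cluster is near-singleton.
- **Chain inferences**: chain(R) = min(100, a·b/100 + c·d/100) with products
  on the probability scale — the only reading on which two 100% links chain
  to 100% and the cap is reachable.  Regressions of direct on chained
  estimates are unweighted OLS with an intercept (reported), pooled over
  blocks and, separately, phase-averaged per subject.
- **Contrast ANOVA**: each single-df within-subject contrast is reduced to
  per-subject scores L; the within effect tests the unweighted grand mean of
  L against zero on the pooled within-group error, F(1, n − g); the
  contrast × group interaction is a one-way ANOVA on L; the between effect a
  one-way ANOVA on subject cell means.  This reproduces the F(1, ·) pattern
  of conventional repeated-measures contrast output and is verified against
  Sum-coded statsmodels fits to 1e-8.
- **PCA**: correlation-matrix eigendecomposition (items are heterogeneous in
  scale); the number of components is the smallest m giving every item a
  communality ≥ 0.5; varimax rotation with Kaiser normalisation (implemented
  here — ~20 lines of the classic SVD iteration); loadings annotated at the
  conventional 0.5 / 0.707 thresholds.
- **Stepwise regression**: SPSS-style forward entry (smallest partial-F p ≤
  0.05) with backward removal (p ≥ 0.10), ties broken by larger r² increment
  then input order; candidates with tolerance < 1e-8 are skipped with a
  warning.  The logistic variant uses likelihood-ratio tests, reports
  in-sample accuracy at a 0.5 threshold and Nagelkerke r² =
  [1 − (L0/L1)^(2/n)] / [1 − L0^(2/n)]; perfect separation is flagged when a
  perfectly classifying fit pins all probabilities at 0/1.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 100 agents × 10 seeds for archetype
recovery and 12–24 agents for distributional checks; calibration runs use
scripted clickers for 60–110 punishment blocks, giving ≥ 5000 eligible
responses and ≥ 2000 cue episodes, with empirical probabilities checked
against 99% binomial confidence bands.  These sizes put Monte-Carlo error
well inside every tolerance while keeping a full test run to about a minute.
Ties in silhouette go to smaller k (parsimony); attack magnitudes round half
away from zero; degenerate inputs (all-identical ratios, constant PCA items,
constant regression predictors, single-class labels) raise or warn
explicitly rather than returning silently wrong numbers.
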