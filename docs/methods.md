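# Methods

`beevr` re-implements, at desk scale, the computational chain of a honey-bee
virtual-reality (VR) color-discrimination experiment: a tethered bee walking
on an air-supported styrofoam ball steers a closed-loop virtual world,
undergoes appetitive/aversive differential conditioning against two colored
cuboids, and — after classification as learner or non-learner in an
unreinforced test — contributes brain samples to an RT-qPCR comparison of
immediate-early-gene (IEG) expression. Real animals are replaced by
synthetic agents and synthetic Cq plates whose ground truth is exported, so
every analysis stage can be validated by parameter recovery instead of by
re-measuring bees.

## World model and kinematics

The world is the 2D floor plane of the VR arena, in cm; the bee starts at
the origin facing +y, headings are counterclockwise-positive in degrees and
normalized to (−180, 180]. The closed loop runs at a fixed tick of 0.017 s.
Ball-surface displacement maps 1:1 onto world displacement.

Two optic sensors sit on the ball's equator 90° apart (one on the body
axis, one lateral). Their vertical flow channels read forward and lateral
translation directly; the common horizontal channel reads the equatorial
arc of a spin about the vertical axis, so yaw in degrees is
`360 · arc / (π · ball_diameter)` with a 5 cm ball. This is the standard
two-sensor trackball decomposition; the original hardware documentation
names the sensors but not the algebra, so the layout above is fixed by
convention and covered by round-trip tests (a pure θ-rotation encoded as
arcs decomposes back to θ to 1e−9).

Stimuli are vertical cuboids with a 4.5 × 4.5 cm base, represented in the
plane by center + half-width; only the frontal width enters the subtended
angle `2·arctan(w/2d)` (the 4.5 cm depth is not modeled because only the
frontal angle is quantified). At the 9 cm start distance the face subtends
28.07° ≈ 28°. The two cuboids start at ±50° from the body axis. Screen
projection is not modeled; all visual quantities are computed in world
coordinates.

## Conditioning protocol

A session is 10 training trials and one unreinforced test, all constants
configurable with defaults at the study values: 60 s trial timeout, 8 s
post-choice freeze, 60 s inter-trial interval, 60 s test. A *choice* is
entering a 3 cm radius of a cuboid center while fixating it within ±5° of
azimuth. Decisions pinned down where the protocol description is loose:

* **Fixation tolerance** — "centering" has no printed number; default ±5°,
  configurable.
* **Choice-radius anchor** — the 3 cm radius is measured to the cuboid
  *center* by default; a `surface` anchor (center distance ≤ 3 cm +
  half-width) is available because the texts admit both readings and
  neither reproduces the printed 53° choice-subtense exactly (53° would
  correspond to a 4.51 cm center distance).
* **Freeze vs timeout budget** — the 8 s freeze happens after the choice
  and outside the 60 s search budget.
* **Side schedule** — "pseudo-random" is implemented as balanced (5 left /
  5 right) with runs of at most 2, drawn reproducibly by rejection
  sampling.
* **Exclusion rule** — a bee with no choice (NC) on ≥ 5 of the 10 training
  trials is excluded; at the boundary NC = 5 this follows the literal
  "unable to choose … in at least 5 trials" reading.
* **Reinforcement** — an event label only (sucrose/saline); no taste or
  satiety model. The test trial runs its full 60 s, records the first
  choice, and delivers nothing.

Learner = first test choice is CS+; non-learner = CS− or no test choice;
the three categories partition every cohort.

## Behavioral analysis

Per-trial motor metrics on the search-phase trajectory: distance (sum of
segment lengths), speed (distance / active search time; the freeze never
enters the denominator), and tortuosity (path length / net start-to-end
displacement; 1 = straight). Tortuosity is undefined (NaN, excluded from
curves) when the net displacement is below 0.1 cm, as for closed loops;
such trials keep their distance and speed.

Learning curves are per-trial percentages of first choices (CS+/CS−/NC,
summing to 1; NC is its own category, nothing imputed) with Wilson score
95% intervals (the interval construction is not named in the source
protocol; Wilson behaves well at the n ≈ 15–20 group sizes involved).

Inference offers two routes:

* A self-contained **permutation test** of the stimulus-by-trial
  interaction. Encoding choices as +1/−1/0 (CS+/CS−/NC), the statistic is
  the OLS slope over trials of the mean encoded value — identical to the
  slope of (CS+ proportion − CS− proportion). The null swaps CS labels
  independently per bee, i.e. flips row signs, which is exchangeable for
  bees without CS-preference dynamics; `p = (1 + #{perm ≥ obs})/(1 + n_perm)`,
  one-sided for rising CS+ preference. A condition-by-trial variant permutes
  learner/non-learner labels across bees. Degenerate inputs give p = 1.
* **Mixed models** delegated to statsmodels: a binomial model of "chose
  CS+" on trial with a bee random intercept (variational Bayes; posterior
  mean/SD z statistics), and linear mixed models of
  distance/speed/tortuosity on condition × trial. Non-convergence is
  flagged in the output table, never raised. The original study's χ²/z
  values are data-dependent and are not reproduction targets; the synthetic
  cohorts validate the analysis structure instead.

## qPCR quantification

Technical triplicates are quality-controlled with the SD > 0.3 cycle rule
(sample SD, n−1 denominator; the replicate farthest from the triplicate
mean is dropped, exact ties broken by dropping the larger Cq; a pair still
above threshold discards the sample — the sample then propagates as a
flagged NaN row, not a silent drop). Relative quantities are
efficiency-corrected, `Qr = (1+E)^ΔCt`, with ΔCt referenced to the highest
retained mean Cq of the gene × region batch pooled across both groups; the
primer efficiencies are assay constants (kakusei 96.4%, Hr38 106%, Egr1
109%, Ef1a 106%, Actin 110%), not estimated. Normalized expression is
Qr divided by the geometric mean of the same sample's reference-gene Qr
values; the per-region policy uses Ef1a + Actin for MB and CB and Actin
alone for OL. A `product` normalization variant exists for sensitivity
analysis only. Reference stability is screened per region with the same
pooled t-test used for the group comparisons; an unstable reference is
removed from that region's policy, but a region is never left without a
reference (the most stable one is retained with a warning).

Group comparisons are pooled-variance two-sample t-tests, two-sided,
df = n₁ + n₂ − 2 (the pooled form is implied by the printed df 29 at group
sizes 17 and 14), per-test α = 0.05 with no multiple-testing correction and
no cross-region or cross-gene comparisons. Zero pooled variance is handled
exactly: t = 0, p = 1 for equal means; an infinite-t flag otherwise.

## Synthetic data

**Walking agent.** Each tick the agent steps `base_speed · tick` forward
and turns at
`gain · Σ_s u_s sin(azimuth_s) / Σ_s u_s + N(0, heading_noise)`,
with drives `u_s = w_s · exp(β · subtense_s)`. The exponential *looming*
term is the one deliberate departure from a plain weighted-attraction sum:
with symmetric weights a plain sum makes "walking between the two cuboids"
a stable equilibrium and lets the far stimulus dominate steering near the
chosen one, so naive agents rarely satisfy the fixation criterion and never
earn reinforcement. Salience normalization makes the closer (larger-
looking) cuboid dominate, so agents commit and center; it reduces to the
plain rule for a single stimulus. Reinforcement updates: a rewarded CS+
choice adds the learning rate to the CS+ weight (capped at 1), a punished
CS− choice subtracts it from the CS− weight (floored at 0.05); learning
rate 0 gives a statistically stimulus-symmetric non-learner.

Defaults — base speed 2.5 cm/s (a typical walking pace on the ball),
heading noise 2.5°/tick, gain 90°/s, β = 0.15/deg, initial weights 0.5,
learner rate 0.25 — were chosen once to produce learner-like behavior:
trial-1 choices near 50/50 with median latencies of a few seconds, low NC
rates, learner acquisition rising toward ceiling across 10 trials, and
non-learner curves flat. The agent is a test harness with the statistical
structure the analyses assume; it makes no claim about bee cognition, and
no attempt is made to fit the real acquisition curves or the real ~35%
keep / 50% learning rates, which depend on real-bee behavior.

**Cq simulator.** Per bee × gene × region, a triplicate
`baseline + group effect + N(0, bee_sd) + N(0, tech_sd)` per replicate,
with each replicate independently shifted by +2 cycles with probability
`outlier_prob` (late amplification). Defaults: bee SD 0.5 cycles
(lognormal biological variance on expression), technical SD 0.1 cycles,
outlier probability 0.02, group sizes 17/14. Baselines put reference genes
near 19–20 cycles and IEGs at 26–30 with small region offsets. The default
design injects the study's headline effect — Egr1 shifted −1 cycle in
learners' MB samples, a true fold change of (1 + 1.09)¹ = 2.09 — and the
truth table exports every (gene, region) fold change. The simulator mimics
the noise structure the pipeline must survive, not plate effects,
inter-run calibrators, or primer-dimer pathologies; passing tests therefore
validate the quantification arithmetic and its calibration, not wet-lab
robustness.

## Numerical and design notes

* Angles are wrapped to (−180, 180] everywhere; a pose update with zero
  motion is exactly the identity.
* The trial loop inlines the pose/view arithmetic for speed; a regression
  test holds it equal (to 1e−9) to the public `update_pose`/`stimulus_view`
  composition.
* The permutation statistic is computed via matrix products
  (sign-flip matrix × per-bee slope vector), making 999 permutations
  essentially free relative to the simulation.
* Degenerate geometry (bee exactly on a stimulus center) raises rather
  than returning an arbitrary azimuth; with continuous noise it has
  probability zero in simulation.
* All randomness flows from integer seeds through
  `numpy.random.default_rng`/`SeedSequence`; same seed ⇒ bit-identical
  cohorts, plates and reports.
* Monte-Carlo scales used by the validation suite — 1000 replicates for the
  type-I calibration, 200 for fold-change recovery, 100 + 100 cohorts of 17
  bees for the behavioral detection rates — balance tight calibration
  bands against a few minutes of total runtime.

## Known limitations

* The agent has no memory of within-trial history, no backward walking, no
  side bias, and its acquisition is faster than real bees'; learner/
  non-learner contrast is therefore sharper than in the original cohorts.
* The binomial mixed model uses a variational approximation; its z values
  are approximations to the likelihood-ratio statistics a lme4-style fit
  would give.
* The qPCR simulator draws bee noise independently per gene × region;
  correlated extraction effects (which normalization partly exists to
  remove) are not emulated, so the normalization step is validated for
  correctness, not for its variance-reduction benefit on real brains.
* The printed behavioral/expression test statistics of the original study
  depend on unreleased per-bee data and are reproduced only structurally
  (group sizes, df, analysis chain), never numerically.
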