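# Methods

This package implements, end to end, the quantitative machinery of a
visual-foraging experiment with two-part "conjunction objects": a generative
simulator of tapping behavior, the preprocessing that turns tap logs into
count data, Bayesian models for switching and preference, a simulation-based
power analysis, and density-based click maps.

## The task and the estimands

A patch shows 84 objects (42 targets, 42 distractors) on a jittered 12 × 7
grid. Each object is a half-disc (radius 23 px) flush on a 46 × 23 px
rectangle; one part is red, the other green, and the color×shape pairing
defines targets vs. distractors. Participants tap all targets. Because the
two diagnostic parts are spatially adjacent within each object, the tap
position reveals which part the forager's attentional template favored.

Estimands:

* **Switching probability** `p_switch`: probability that two successive
  collected targets were tapped on different parts. 0.5 is memoryless
  ("random") switching; below 0.5 indicates runs.
* **Part preference** `p_red`: probability of tapping the red part,
  per participant, also split by experiment half and by ten 2-trial blocks.
* **Split-half reliability** `rho`: correlation of first- vs. second-half
  preferences on the log-odds scale.
* **End-peak factor**: a trial's last inter-target time (ITT) divided by the
  trial's median ITT, averaged per participant; compared between groups with
  a robust Bayesian two-group model.

## Generative model (synthetic data)

The simulator's defaults state the world the analysis is designed for.

* **Geometry.** Canonical frame: origin at the midpoint of the shared edge,
  +y into the half-disc, −y into the rectangle; screen orientations are
  clockwise cardinal rotations. The half-disc centroid is at y = 4r/3π
  ≈ +9.76 px, the rectangle centroid at −11.5 px, and the whole-object
  center of mass at y ≈ −2.15 px, i.e. about 2.1 px inside the rectangular
  part (the rectangle's area 2r² exceeds the half-disc's πr²/2).
* **Attention.** A two-state Markov chain over {disc, rect}: the first
  attended part of a trial is the participant's preferred part with
  probability `p_pref` (default 0.8); each later collection switches parts
  with probability `p_switch_att`. This is the simplest process that
  produces runs. Note the symmetric switch probability makes the chain's
  stationary distribution 50/50, so long-run part *preferences* in simulated
  data are weak (≈0.5) regardless of `preferred_part`; sustained individual
  preferences as strong as real foragers show are outside this generator.
  Consequently the split-half correlation on simulator output is weakly
  identified — recovery of `rho` is instead tested on counts generated
  directly from the bivariate log-odds model.
* **Motor model.** A tap aimed at part P lands at
  `(1−λ)·centroid(P) + λ·COM` plus isotropic Gaussian noise with scale
  `motor_sigma_px` (default 8 px), rotated into screen coordinates. λ
  (default 0.3) models the pull of contact points toward the object's center
  of mass. Because the disc centroid is nearer the part boundary than the
  rectangle centroid (9.76 vs. 11.5 px), noise misclassifies disc-aimed taps
  more often; this pushes observed switching toward 0.5 and also biases
  observed preference slightly toward the rectangle's color.
* **Collection order.** Greedy: nearest unvisited target from the previous
  tap, starting at screen center. Error taps (probability 1.25% per
  collection, the observed error rate) hit the nearest unvisited distractor.
* **Timing.** Cruise ITTs are log-normal (median 700 ms, log-sd 0.35); the
  final ITT is multiplied by `endpeak_mult` (default 10, matching the ~10×
  end peaks of difficult conjunction foraging). Mid-trial slowing is *not*
  modeled, so simulated patch completion times (~38 s) fall short of the
  ~49 s real participants need; all end-peak statistics are unaffected.
* **Seeding.** One RNG stream per participant, spawned from the master seed
  (`numpy` SeedSequence), so every run replays exactly.

## Preprocessing conventions

* Taps are assigned to the nearest object center within an acceptance
  radius (default 40 px; the radius is a display-analysis convention, not a
  measured quantity). Ties break to the lowest object id. Unassigned taps
  are dropped with a warning.
* Part labels: disc if canonical y > 0, rectangle otherwise (boundary to
  rectangle). Classification ignores x.
* Error taps (distractor collections) are excluded before switch and
  preference counting; counts are over collected targets only.
* The first tap's latency from trial start counts as the first ITT, and the
  trial median in the end-peak factor includes the final ITT (both
  switchable). Including the peak in the median is conservative: it can only
  lower the factor, and makes the factor a pure function of the trial's ITT
  vector.

## Inference

All models report the posterior mode and the shortest 95% highest-density
interval, with split-R-hat < 1.01 and effective-sample-size diagnostics
(via arviz). Sampling uses a self-contained slice-within-Gibbs sampler
(Neal 2003 stepping-out/shrinkage) on unconstrained transforms, with a
principal-axis rotation estimated from warm-up covariance so scans slice
along the posterior's main correlation directions. Defaults: 4 chains ×
1000 warm-up + 1000 draws.

* **Switching** — hierarchical beta-binomial:
  `k_i ~ Binomial(m_i, p_i)`, `p_i ~ Beta(μκ, (1−μ)κ)`, `μ ~ Uniform(0,1)`
  (flat), `κ ~ LogNormal(log 10, 1)` (weakly informative; the stated prior
  choice for the concentration, configurable). The `p_i` are conjugate given
  (μ, κ) and are integrated out analytically, so MCMC runs on the 2-D
  marginal; participant draws are recovered exactly from their Beta
  conditionals. Trial counts are summed per participant for the main fit.
* **Preference** — non-hierarchical Beta(1,1)-binomial per participant,
  solved in closed form (posterior Beta(k+1, n−k+1); draws sampled exactly,
  mode k/n, HDI by direct width minimization over the Beta quantile
  function). Individual preferences are modeled without a group level
  because they are idiosyncratic.
* **Split-half correlation** — per participant, half-specific log-odds
  `(θ_i1, θ_i2)` are bivariate normal with means μ_h, scales σ_h and
  correlation ρ; counts are binomial given `logistic(θ)`. Priors:
  μ_h ~ Normal(0, 2.5), σ_h ~ Half-Normal(2.5), ρ ~ Uniform(−1, 1)
  (sampled through tanh with its Jacobian). When preferences have little
  between-participant spread ρ is weakly identified and its HDI legitimately
  spans much of (−1, 1).
* **Two-group comparison** — each group t-distributed with its own mean and
  scale, shared normality ν with ν − 1 ~ Exponential(mean 29); broad
  data-scaled priors on means (Normal(pooled mean, 1000·pooled SD)) and
  scales (uniform on [SD/1000, 1000·SD]). Both the difference and the ratio
  of means are summarized.
* **Mode estimation** — argmax of a Gaussian KDE (Scott's rule) on a 2048
  point grid; for bounded parameters the KDE is boundary-reflected to avoid
  edge bias. Constant draws short-circuit to the constant.
* **HDI** — shortest contiguous interval over sorted draws (requires ≥1000
  draws in the public utility; internal summaries accept ≥100).

## Power analysis

For each simulated experiment: simulate → preprocess → fit the switching
model; "detection" means the group-level 95% HDI lies entirely below 0.5
(a per-participant-majority rule is available). The detection count s out of
n_sims gets the conjugate Beta(s+1, n_sims−s+1) posterior, reported as mode
plus 95% HDI (s = n = 50 gives a lower bound of 0.05^(1/51) ≈ 0.943, the
resolution limit of 50 simulations). Default assumptions are deliberately
conservative: attention switching 0.45, motor noise 8 px, λ = 0.3 — explicit
stand-ins chosen as the hardest plausible world in which the design should
still work. Inner fits run at reduced fidelity (2 chains × 400 + 500);
a marginal R-hat alarm triggers one retry at doubled length before the
simulation is counted as non-converged (reported separately, never as a
detection). When the assumed forager has no motor noise and no error taps,
switch counts are drawn directly from the attention chain (identical by
construction to the tap-level path, and much faster).

## Click maps

Tap densities in the canonical frame use a binned Gaussian KDE: taps are
histogrammed onto a 256 × 256 grid covering the object's bounding box plus a
3-SD margin and convolved with a Gaussian kernel (Scott's rule per axis,
h = sd·n^(−1/6)), making the cost independent of the number of taps.
Highest-density regions threshold the sorted density mass at 10/25/50%; the
mode is the grid argmax. Contours are qualitative: the bandwidth rule, not
the data, fixes their exact shape.

## What a green test establishes — and what it does not

Parameter recovery, calibration and conjugate-equivalence tests certify the
estimators on data from the stated generative world. That world omits, by
design: mid-trial ITT slowing, spatial planning beyond greedy proximity,
sustained individual part preferences, drifts or strategy changes over
blocks, and any dependence of motor noise on movement speed or distance.
Green tests therefore validate the machinery, not the empirical claims one
would make from real tap logs.

## Numerical choices

* Slice sampler: typical width from running warm-up spread (×2.5), max 50
  stepping-out steps, shrinkage to 1e-12 before giving up a slice.
* Beta-HDI width minimization: bounded Brent with the interval endpoints
  checked explicitly (monotone densities put the optimum on a boundary).
* Degenerate inputs: empty trials, <2 ITTs, k > m, out-of-range
  probabilities and over-full grids raise `ValueError` with the violated
  constraint; non-convergence raises a diagnostic error naming the
  parameter and the remedy.
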