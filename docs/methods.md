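# Methods

## The measurement model

One observation unit is a participant × condition block: a sequence of J
categorical trial outcomes y_i = (y_i1, …, y_iJ), each coded
1 = opposing, 2 = following, 3 = nonresponse, 4 = error. The latent class
model assumes R unobserved classes; conditional on class r the trials are
independent (local independence), outcome k on trial j having probability
π_jrk. The marginal log-likelihood maximized is

    ln L = Σ_i ln Σ_r p_r Π_j Π_k π_jrk^{Y_ijk},

with priors p_r on the simplex. The per-trial category count K_j is the
number of categories *observed* at trial j, not a fixed 4: rare codes
(nonresponse, error) are frequently absent from a column, and the free
parameter count R·Σ_j(K_j − 1) + (R − 1) is only meaningful on the observed
support. All likelihood computation runs in the log domain (log-sum-exp over
classes), so a J = 30 product of probabilities as small as 1e-300 per factor
cannot underflow.

### Estimation

EM with random restarts:

* **Initialization.** Each restart draws the N posterior rows from a uniform
  Dirichlet and starts at the M-step. This perturbs all parameters jointly
  and cheaply.
* **E-step** θ_ir ∝ p_r Π_j π_{jr,y_ij}; **M-step** p_r = mean_i θ_ir,
  π_jrk = Σ_i θ_ir 1[y_ij = k] / Σ_i θ_ir (closed form).
* **Defaults** tol = 1e-10 on the ln L change, max_iter = 1000,
  n_restarts = 30 (the analysis convention this pipeline follows). ln L is
  monotone by construction; a decrease beyond rounding aborts loudly.
* **Degeneracy guards.** Priors and outcome probabilities are floored at
  1e-10 before the E-step (then renormalized) so an emptied class or
  category cannot produce log(0).
* **Identification.** Classes are relabeled to descending estimated share
  after fitting, making output order deterministic up to exact ties (broken
  by original index). Descriptive names are attached from the fitted
  profiles: mean opposing probability across trials > 0.6 → "opposer", mean
  following probability > 0.6 → "follower", otherwise "switcher"; the 0.6
  threshold is configurable and purely cosmetic — no computation consumes
  the names.

Fit indices: AIC = −2lnL + 2·npar, BIC = −2lnL + npar·ln N, and the average
posterior assignment entropy −(1/N)Σ_ir θ_ir ln θ_ir (0 for perfect
separation) plus its normalized complement 1 − H/ln R. The model-selection
report flags AIC/BIC minimizers and annotates an AIC increase Δ strictly
inside (2, 4) as the conventional "strong support for the more complex
model" band.

## Latent class regression

The priors become observation-specific via a multinomial logit in a
covariate x_i, p_ir = exp(x_i′β_r) / Σ_q exp(x_i′β_q) with β = 0 for the
reference class. The stimulus-direction covariate enters as a single numeric
code (down-only = 1, up-only = 2, random = 3); a dummy coding is available
behind `covariate_coding="dummy"` but is not the default, because the
target analysis reports exactly one direction coefficient per non-reference
class. The reference class is the largest-share class (the switcher class in
cohorts like the modeled one); `coefficient_inference(reference=r)`
re-expresses the coefficients and their standard errors against any other
class without refitting.

The M-step maximizes the expected multinomial-logit log-likelihood
Σ_i Σ_r θ_ir ln p_ir(β) by Newton's method with step halving, run to
gradient convergence at every M-step. An exact M-step in both π and β keeps
the observed log-likelihood monotone and satisfies the gradient-norm
contract at convergence directly, at negligible cost for the 2·(R−1)
coefficient dimensions involved.

**Degrees-of-freedom guard.** With npar = R·Σ_j(K_j − 1) + (R − 1)(1 + c)
parameters and N observations, a fit with npar ≥ N is refused with a
diagnostic naming the deficit. Three classes on a full 30-trial matrix at
N = 108 is exactly such a case, which is why the pipeline fits phases:
independent regressions on trials 1–10, 11–20 and 21–30 (`fit_phases`), each
of which is identifiable.

**Inference.** Standard errors come from the observed information of the
*profile* log-likelihood in β: a central-difference Hessian in which the
outcome probabilities are re-maximized (warm-started inner EM, tolerance
1e-11) at every perturbed β. Holding π fixed instead systematically
understates the coefficient variance — the Schur-complement term that
profiling supplies is not negligible here. The differencing step (2e-2,
scaled by |β|) is chosen large enough that residual inner-EM error cannot
masquerade as curvature; a Monte-Carlo check against the Fisher information
at the generating parameters reproduces these SEs to within ~1%. t-values
use N − npar residual degrees of freedom, mirroring the small-sample
convention of the target analysis; with hundreds of residual degrees of
freedom the t and normal references coincide for practical purposes.

## Trial classification

* The 1.1-s window is 110 samples at 10-ms sampling: 10 preshift, 20 shift,
  80 postshift. The baseline is the mean preshift f0; cents are computed
  against it, so the preshift mean of the cents series is 0 by construction.
* The threshold statistic is the sample SD (ddof = 1) of the 10 preshift
  cents samples, floored at 1 cent (`sd_floor`) so noiseless synthetic input
  keeps a usable 2-SD criterion.
* Threshold crossings are sought only from shift onset onward; the dominant
  excursion's sign (the sign of cents at the maximum |cents| in the search
  region) decides opposing vs following, with a down-shift opposed by a
  positive deviation.
* Error rule: more than 20% missing frames in the window, or any
  adjacent-frame jump above 600 cents (a half-octave, the signature of an
  octave-type tracking failure), classifies the trial as error before any
  response logic runs. Both thresholds are keyword-configurable.
* Onset: the earliest sample with |cents| above threshold sustained for
  50 ms (5 consecutive samples including the onset sample). Peak: the first
  local maximum of |cents| at or after onset — plateaus resolve to their
  earliest sample, and a monotone excursion peaks at the window's last
  sample. Times are reported relative to shift-stimulus onset.

These conventions (SD in cents with ddof 1, search region, dominant-excursion
sign rule, the error thresholds, first-local-max reading of "first greatest")
are deliberate operationalizations where the verbal description of the
procedure is ambiguous; each is a keyword argument, none is hard-coded.

## The synthetic-data generator

The generator emulates the modeled experiment's design: 36 participants
(configurable), three 30-trial blocks per participant in counterbalanced
order (three block orders, assigned cyclically), one ±250-cent 200-ms shift
per trial at a uniformly drawn grid-aligned onset 500–700 ms post vocal
onset, f0 sampled every 10 ms over 3-s vocalizations.

Latent structure: participants draw a class from configurable shares
(defaults 0.57 switcher / 0.28 opposer / 0.15 follower) with class-conditional
outcome probabilities — switcher (0.49, 0.49, 0.01, 0.01), opposer
(0.85, 0.12, 0.02, 0.01), follower (0.12, 0.85, 0.02, 0.01) — consistent with
the ~1% nonresponse/error rates of the modeled data. An optional per-condition
share map lets the follower share depend on condition (emulating
predictability effects); an optional first-order stickiness parameter turns
the i.i.d. outcome draws into a sticky chain with the same stationary
distribution.

Realized responses are raised-cosine bumps in cents: smooth, and exactly
parameterized by the three measured quantities (onset latency, peak latency,
peak amplitude). Defaults follow the measured response statistics of the
modeled experiment — onset ≈ 213 ms (SD 20) post shift onset, peak ≈ 430 ms
(SD 30), amplitude ≈ 40 cents (SD 8, truncated below at 30), i.i.d. Gaussian
measurement noise of 3 cents, baselines of 120/220 Hz alternating by
participant. Latencies are drawn per trial and rounded to the 10-ms grid, so
the generated peak lies exactly on a sample. The ground-truth table records,
per trial, the analytic time at which the noiseless bump first exceeds the
2-cent noiseless detection threshold (closed form from the raised cosine), so
round-trip tests compare the detector against an independent closed form
rather than against the detector itself. Error trials are realized as a
contiguous missing-frame run covering >20% of the analysis window (chosen
over octave jumps because it is deterministic to detect); per-class kinematic
parameters are configurable, not canonical, since the modeled study reports
only summary ranges.

What the generator does *not* emulate: pitch-tracker idiosyncrasies beyond
missing frames, within-trial drift or vibrato, serial dependence of
kinematics, participant-level amplitude heterogeneity beyond class
membership, and any acoustic signal below the f0 track (no audio). Passing
round-trip tests therefore demonstrates correctness of the windowing,
thresholding and measurement logic under the stated noise model — not
robustness to real pitch-tracker artifacts.

A fast categorical path (`synthesize=False`, `generate_class_sequences`)
skips trace synthesis and draws outcome sequences directly from the latent
model; the estimator studies below use it.

## Simulation studies and problem sizes

The test suite's quantitative studies use sizes chosen to match the modeled
study where it specifies them:

* **Likelihood oracle.** 100 random instances with N ≤ 6, J ≤ 3, R ≤ 3
  against direct linear-domain summation, agreement to 1e-12; exhaustive
  enumeration at N = 2, J = 2 against 1,000 random parameter draws.
* **Recovery.** 20 replicates at N = 108, J = 30, shares
  (0.57, 0.28, 0.15), 3-class fits with 30 restarts; ≥ 18 replicates must
  reach permutation-matched modal agreement ≥ 0.9 and per-class share error
  ≤ 0.07. Share error is measured against the *realized* class composition
  of each replicate: with only ~108 class draws the binomial noise of the
  generator (SD ≈ 0.05 for the majority share) is not an estimator property,
  and the estimator tracks the realized mixture essentially exactly when
  agreement is high.
* **Coefficient coverage.** 100 replicates at N = 500, J = 10 with
  generating coefficients β_opposer = (0.5, −0.3), β_follower = (1.7, −1.1)
  against a switcher reference; per-coefficient 95% Wald coverage must reach
  90%. Across 600 verification replicates coverage sits at ≈ 0.92–0.95 per
  coefficient; fits use 3 restarts, tol 1e-8 and max_iter 2000 here because
  the flat follower–switcher ridge makes the default 1e-10 needlessly slow
  at this size.
* **Round trip.** 12-participant cohorts (1,080 trials); noiseless traces
  must reproduce every opposing/following label with onset and peak times
  within one sample (10 ms) of the analytic truth, 3-cent-noise traces ≥ 95%
  of labels.

## Known limitations

* Local independence is assumed within class; the sticky-chain generator
  option exists precisely to create controlled violations, but the fitted
  model never models serial dependence (no latent transition analysis).
* The bootstrap likelihood-ratio test for choosing R is out of scope; model
  choice rests on AIC/BIC and the Δ-AIC band.
* Wald coverage is asymptotic: at N = 500 with a small, covariate-dependent
  class the per-coefficient coverage of nominal-95% intervals is ≈ 92–95%,
  and seed-to-seed batches of 100 replicates fluctuate by a few points.
* Published per-trial count tables can be reproduced exactly, but fits to the
  original cohort cannot be — the raw per-participant sequences are not
  deposited — so estimator quality is established on synthetic cohorts with
  known truth. One minor discrepancy in the packaged count table: the
  random-condition nonresponse column sums to 17/1080 = 1.57%, which rounds
  half-up to 2% where the published proportion row prints 1%; the eight
  opposing/following percentages all reproduce exactly.
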