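# Methods

This note documents the generative models, estimation procedures and
statistical machinery implemented in `cyclopean`, the defaults they use, and
what the simulations can and cannot establish.

## Stimulus model

**Correlation-modulated noise.** The carrier textures are white Gaussian
noise filtered in the frequency domain by an isotropic log-Gaussian annulus
with a 1-octave full bandwidth at half height (a standard
texture-psychophysics choice; the bandwidth is a parameter of
`make_bandpass_noise`). After filtering, each texture is renormalized to
exactly zero mean and unit variance, which makes the closed-form local
correlation

    rho(x) = M_C(x)^2 / (M_C(x)^2 + M_eye(x)^2)

exact rather than approximate: the two eyes' images share only the
`C_common * M_C` term, and for independent unit-variance carriers the
covariance is M_C^2 while each image's variance is M_C^2 + M_eye^2. The
carrier center frequency is locked to four times the envelope frequency
(`carrier_sf = 4 * fm`). The envelope coordinate runs along the axis
perpendicular to the 45 deg / 135 deg stripes, with its phase origin at the
image center. Default geometry is 512 x 512 px at 40 px/deg (12.8 deg);
display quantization and gamma are not modeled because the simulated
observer never sees pixels — exported PNGs (affine map of [-3, 3] to 8 bits)
are for inspection only.

**Phase gratings.** Horizontal sine gratings at 0.46 c/d (conventional for
the paradigm; configurable), mean luminance 0.5, contrast 1.0 in the
nondominant eye and `contrast_ratio` in the dominant eye, phases +/-22.5 deg
swapped between the two configurations.

## Observer models

**Phase combination.** The generative observer is an amplitude-weighted
linear vector sum, not a full interocular gain-control model. The paradigm
is used here as a *measurement*, and the linear form reproduces everything
the measurement relies on: the zero-phase balance point at a_d = a_n, strict
monotonicity of the percept in the amplitude ratio, the +/-theta0 bound, and
the sign convention (the percept follows the stronger eye; a strengthening
of the nondominant eye drives the measured phase negative). The adjustment
task is abstracted to a direct phase report plus Gaussian noise
(`phase_noise_sd`, default 4 deg per trial); optional quantization to the
report line's pixel grid is available but off by default. A 16-trial session
(2 configurations x 8 repetitions, combined per repetition as
(phi1 - phi2)/2) therefore has a session-mean SE of noise_sd/4 = 1 deg.

**qIOCSF observer.** Responses are Bernoulli draws from a Weibull 2AFC
psychometric function with guess rate 0.5,

    p(correct) = 0.5 + (0.5 - lapse) * (1 - exp(-(M * 10^S(f))^slope)),

with lapse 0.04 and slope 3.5 by default for both the observer and the
fitting model (the two can be set independently; the fitting model's values
are deliberately fixed, as is conventional for this family of adaptive
procedures). `S(f)` is the truncated log-parabola with kappa = log10(2) and
beta' = log10(2^beta), so beta is the full bandwidth in octaves at
half-maximum sensitivity. Sensitivity is the reciprocal of the modulation
threshold, capped so the threshold never exceeds M = 1.

## Adaptive estimation

The posterior lives on a 12 x 12 x 8 x 8 lattice: gamma_max log-spaced in
[2, 200], f_max log-spaced in [0.5, 5] c/d, beta linear in [1, 6] octaves,
delta linear in [0, 1.5] log10 units; the prior is uniform and independent
per axis. Candidate stimuli are 12 frequencies log-spaced in [0.94, 2.54]
c/d crossed with 25 modulations log-spaced in [0.02, 1]. Each trial selects
the candidate minimizing the expected posterior Shannon entropy; ties
(within 1e-12 nats) break toward the lowest frequency, then the lowest
modulation. The entropy computation is decomposed as
sum(w log w) = P @ (p log p) + (P log P) @ p so each trial costs four
matrix-vector products against precomputed likelihood tables; this is an
algebraic identity, and the vectorized update and selection are verified
against explicit-loop enumeration in the tests. Point estimates are marginal
posterior means, taken on the log10 scale for gamma_max and f_max (a MAP
estimate is also exposed). The tested stimulus-frequency axis is interpreted
as the envelope modulation frequency, with the carrier at four times it;
this is recorded as a convention of the implementation, configurable through
the stimulus spec.

With 100 trials, recovery of a mid-grid observer (gamma 10, f_max 1.5,
beta 3, delta 0.5) has a median absolute log10 peak-gain error of about
0.05 across seeded sessions.

## Cohorts and the deprivation model

`make_cohort` draws observers as: baseline balance error ~ Normal(0, 3 deg)
of noise-free phase (emulating imperfect contrast-ratio calibration; the
residual spread of baseline session means is then of order 3 deg, with
measurement noise adding ~1 deg), converted to a dominant-eye weight by
inverting the vector-sum model; gamma_max ~ 10^Normal(1, 0.15); f_max ~
10^Normal(log10 1.5, 0.1); beta ~ Normal(3, 0.4); delta ~ Normal(0.5, 0.15)
(all clipped to the estimation grid's interior).

Under the null model every deprivation parameter is zero (amplitude 0,
gamma multiplier 1) and the IOC sensitivity is constant across sessions.
Under the deprivation model the immediate phase shift is drawn from
Normal(19.2, 7.0) deg — the largest of the cited monocular-deprivation
effects, the one that reproduces the n = 3 sample-size computation — and
decays as exp(-t/tau) with tau = 15 min, so the effect is largely gone by
30-45 min, matching the reported ~30-min persistence. The shift is injected
as a *target perceived phase* and converted to a weight change through the
model inverse. Because the paradigm's noise-free percept is bounded by
+/-22.5 deg, targets are clipped just inside the gamut (0.995 * theta0);
with a Normal(19.2, 7.0) amplitude on top of the baseline spread this
saturation is reached in roughly a third of subjects, so the *measured*
group-mean shift at post-0 is about 17.5 deg rather than the nominal 19.2 —
a property of the paradigm, not an artifact, and the tests check the
measured mean against a Monte-Carlo oracle of the clipped expectation. A
multiplicative gamma_max effect with the same timecourse is available for
probing the sensitivity side of the pipeline and defaults to 1 (no effect).

All randomness is seeded through named substreams
(subject seed, session index, measure), so any single sub-simulation can be
reproduced in isolation and identical (config, seed) runs produce
byte-identical bundles.

## Statistics

The one-way within-subject ANOVA is the classical decomposition
(SS_condition against the subject-by-condition interaction). Mauchly's test
(chi-square approximation) at alpha = 0.05 gates the Greenhouse-Geisser
correction by default; epsilon is computed from orthonormal (Helmert)
contrasts of the sample covariance and is exactly 1 at two conditions. An
"always"/"never" correction mode is exposed. The two-way analysis tests each
main effect and the interaction against its own subject-interaction error
term, with per-effect epsilon from Kronecker-product contrasts. The one-way
path agrees with `pingouin.rm_anova` to machine precision (F, epsilon,
Mauchly W) on random tables, as do two-way F ratios and main-effect
epsilons; results with zero error variance are returned flagged as
degenerate rather than raising.

BF01 is the BIC approximation exp((BIC_alt - BIC_null)/2) with both models
fit as fixed-effects OLS (subject, or subject + condition) — a deliberately
simple substitute for default-prior mixed-model Bayes factors. Its
*magnitudes* are therefore not comparable to those of JASP-style analyses
(the BIC penalty for 4-5 condition parameters at 50-60 observations is
large, so null data routinely yield BF01 in the hundreds); its *direction*
is what the pipeline relies on, and under null cohorts the median BF01 is
well above 1 while strong effects push it below 1.

Power analysis uses the exact noncentral-t distribution for a one-sample
(paired-difference) test, one-tailed by default: the deprivation literature
predicts the direction of the shift, and the one-tailed computation is the
one consistent with the published minimum-n values for these effects
(n = 7 for 1.39 +/- 1.24 dB; n = 3 for 19.2 +/- 7.0 deg), which the tests
verify against `statsmodels`' independent implementation.

## Operating characteristics

On 500 simulated null experiments (n = 10, phase measure, baseline-
normalized change scores), the pipeline's rejection rate is ~0.03-0.05,
within the binomial 99% interval around the nominal alpha = 0.05 (the
Mauchly-gated correction makes it mildly conservative). On 200 deprivation
experiments the one-tailed post-0 contrast rejects essentially always
(power 1.0, required >= 0.95). These replicate counts, and the 100-session
recovery run, are the problem sizes used throughout the test suite.

## What the simulations do not show

The synthetic observers are stationary within a session, respond
independently across trials, and have no attentional drift, learning, or
fusion failures; the phase report abstracts away the alignment task's motor
and positional components beyond an additive bias (which the two-
configuration combination cancels exactly, by construction). Passing tests
therefore establish the correctness and calibration of the *pipeline* — not
that real observers satisfy these generative assumptions. Population
variability settings are calibrated only to printed group-level summary
statistics, since no subject-level data exist to fit; and the BIC Bayes
factor, as noted, matches direction but not magnitude of default-prior
alternatives.
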