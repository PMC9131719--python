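# cyclopean

Simulated dichoptic psychophysics: binocular phase combination and quick
interocular-correlation sensitivity estimation, end to end, with no human in
the loop.

## What this package is for

Short-term monocular deprivation in adults transiently shifts ocular
dominance toward the deprived eye. A natural question is whether a *balanced*
disruption — rapidly alternating occlusion of the two eyes (e.g., 7 Hz,
50/50 duty cycle, so each eye is occluded for ~71 ms at a time) — can drive
the same plasticity. Answering it requires two binocular measurements
repeated across a session schedule (one pre-deprivation baseline and five
post-deprivation sessions at 0/10/20/30/40 min), and the statistical
machinery to decide between "an effect" and "evidence for no effect".

`cyclopean` implements that entire measurement-and-analysis pipeline against
*synthetic observers*, so both outcomes can be exercised: a null regime in
which alternate deprivation does nothing, and a positive-control regime with
the ocular-dominance shifts reported for classical monocular deprivation
(1.39 ± 1.24 dB, 6.3 ± 3.3°, 19.2 ± 7.0° immediate effects).

## The two measurements

**Binocular phase combination.** Each eye views a horizontal sine grating,
phase-shifted by ±θ₀ = ±22.5° in opposite directions; the nondominant eye at
100% contrast, the dominant eye at δ·100%. The perceived (cyclopean) phase
of the fused grating indexes the eyes' relative weights. For an
amplitude-weighted vector-sum observer with effective amplitudes
a_d = w_d·δ and a_n = w_n,

    φ = atan( (a_d − a_n)/(a_d + a_n) · tan θ₀ ),

zero when the eyes contribute equally. Two stimulus configurations with the
offsets swapped are averaged as (φ₁ − φ₂)/2, cancelling any additive report
bias; a session is 2 configurations × 8 repetitions = 16 trials.

**Quick interocular-correlation sensitivity (qIOCSF).** Each eye views a
blend of a shared bandpass-noise carrier and an eye-private carrier, with
blend weights modulated sinusoidally along a 45°/135° oblique axis:

    M_C(x) = ½(1 + M sin 2πf_m x),   M_eye(x) = ½(1 − M sin 2πf_m x),
    I_eye = C_common·M_C + C_eye·M_eye,

so the local interocular correlation is ρ(x) = M_C²/(M_C² + M_eye²) — 50%
everywhere at M = 0, 100% in the correlated stripes at M = 1. The observer
reports the envelope orientation (2AFC). Sensitivity to the modulation M as
a function of spatial frequency follows a truncated log-parabola with four
parameters (peak gain γ_max, peak frequency f_max, bandwidth β in octaves,
low-frequency truncation δ). A Bayesian adaptive procedure (posterior over a
4-D lattice, expected-information-gain stimulus selection) estimates all
four parameters in 100 trials over 0.94–2.54 c/d, summarized by the area
under the log sensitivity function (AULIOCSF).

**Session statistics.** Baseline-normalized change scores are analyzed with
one- and two-way repeated-measures ANOVA (Mauchly-gated Greenhouse–Geisser
correction), a BIC-approximated Bayes factor BF₀₁ for the null, and exact
noncentral-t power analysis for planning sample sizes.

## Worked example

```python
import cyclopean as cy

# one adaptive qIOCSF session against a known synthetic observer
engine = cy.QuickIOCSF()
observer = cy.IOCSFParams(gamma_max=10.0, f_max=1.5, beta_octaves=3.0, trunc_delta=0.5)
result = engine.fit(observer, n_trials=100, seed=1)
print(result.summary())
```

```
Quick IOC sensitivity function estimate
  trials: 100   seed: 1
  parameter       estimate   post. SD  scale
  gamma_max          11.63      0.128  log10
  f_max               1.98      0.217  log10
  beta_octaves       4.321      1.492  linear
  trunc_delta       0.7483      0.467  linear
  AULIOCSF [0.94, 2.54] c/d: 0.4517
```

The true peak gain of 10 is recovered as 11.63 (a log10 error of 0.066,
inside one posterior SD); the AULIOCSF summarizes the estimated curve over
the tested band. A whole simulated experiment and its analysis:

```python
from cyclopean.observers import make_cohort, simulate_experiment, Protocol

cohort = make_cohort(10, model="null", seed=3)            # no deprivation effect
data = simulate_experiment(cohort, Protocol(measures=("phase",)))
model = cy.RepeatedMeasuresAnova(data.phase_table(), baseline="pre", drop_baseline=True)
print(model.fit().summary())
```

```
Repeated-measures ANOVA  (10 subjects x 5 conditions)
  condition: F(4, 36) = 0.6039, p = 0.6623, eps = 0.8697
  BF01 (BIC approximation) = 492.9 [decisive evidence for the null]
```

With a null cohort the post-deprivation change scores show no time effect
and the Bayes factor favors the null, as they should. The same pipeline on
`model="deprivation"` cohorts (19.2 ± 7.0° immediate shift, exponential
decay with a 15-min time constant) rejects the null at post-0 essentially
always at n = 10.

The command line mirrors the library:

```bash
cyclopean power --mean 1.39 --sd 1.24
# minimum n = 7 (power 0.833 at alpha 0.05, one-tailed)
cyclopean simulate --model null --n 10 --seed 1 --out runs/null
cyclopean analyze --data runs/null --measure phase
cyclopean stimulus --m 0.5 --fm 0.5 --orientation 135 --seed 0 --out stim/demo
```

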