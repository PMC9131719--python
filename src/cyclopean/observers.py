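"""Synthetic observers and cohorts.

This is the data generator for the whole pipeline: cohorts of simulated
observers measured on the fixed session schedule (one pre-deprivation session
and five post-deprivation sessions at 0/10/20/30/40 min) with both the
binocular phase-combination task and the quick IOC-sensitivity procedure.

Two generative regimes are supported:

* ``null`` — deprivation leaves the observer untouched (the study-condition
  model): every session measures the same eye weights and the same IOCSF.
* ``deprivation`` — an ocular-dominance shift of amplitude drawn from
  Normal(19.2, 7.0) degrees (the immediate effect size reported for 2.5 h of
  classical monocular deprivation) decays exponentially with time constant
  ``effect_tau`` (15 min by default, so the effect has largely vanished by
  30-45 min).  The shift is injected as a target perceived-phase change and
  converted to an eye-weight change by inverting the vector-sum model, so
  effect sizes are expressed in the degrees units the literature reports.
  Because the paradigm's percept is bounded by +/- theta0, targets are
  clipped just inside that gamut before inversion.

Baseline between-subject variability enters as a residual balance error
(Normal(0, 3) degrees of baseline phase, emulating imperfect contrast-ratio
calibration) plus per-trial Gaussian adjustment noise (SD 4 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .iocsf import IOCSFParams, aulio_csf, log_sensitivity
from .phase import (SESSION_LABELS, perceived_phase_model, simulate_phase_session,
                    weight_ratio_for_phase)
from .qiocsf import GridSpec, QuickIOCSF

__all__ = [
    "ObserverSpec", "PopulationParams", "Protocol", "ExperimentDataset",
    "OcclusionSchedule", "effect_timecourse", "make_cohort",
    "simulate_experiment", "alternation_schedule",
]

SESSION_TIMES: dict[str, float | None] = {
    "pre": None, "post0": 0.0, "post10": 10.0,
    "post20": 20.0, "post30": 30.0, "post40": 40.0,
}


@dataclass(frozen=True)
class ObserverSpec:
    """Ground-truth generative observer."""

    subject_id: str
    iocsf_true: IOCSFParams
    weight_dom: float
    weight_nondom: float
    lapse: float = 0.04
    psychometric_slope: float = 3.5
    phase_noise_sd: float = 4.0
    effect_amplitude: float = 0.0  # degrees of immediate post-deprivation shift
    effect_tau: float = 15.0       # minutes
    iocsf_effect: float = 1.0      # multiplicative gamma_max shift at t=0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse < 0.1:
            raise ValueError("lapse must lie in [0, 0.1)")
        if self.effect_tau <= 0:
            raise ValueError("effect_tau must be positive")
        if self.weight_dom <= 0 or self.weight_nondom <= 0:
            raise ValueError("eye weights must be positive")


@dataclass(frozen=True)
class PopulationParams:
    """Population distributions the cohort generator draws from."""

    effect_mean: float = 19.2      # deg, immediate phase shift (deprivation model)
    effect_sd: float = 7.0
    effect_tau: float = 15.0       # min
    iocsf_effect: float = 1.0      # gamma_max multiplier at t=0 (deprivation model)
    baseline_phase_sd: float = 3.0  # deg, residual calibration error across subjects
    phase_noise_sd: float = 4.0    # deg, per-trial adjustment noise
    lapse: float = 0.04
    psychometric_slope: float = 3.5
    gamma_mean: float = 10.0
    gamma_log10_sd: float = 0.15
    f_max_mean: float = 1.5
    f_max_log10_sd: float = 0.10
    beta_mean: float = 3.0
    beta_sd: float = 0.4
    delta_mean: float = 0.5
    delta_sd: float = 0.15


@dataclass(frozen=True)
class Protocol:
    """Measurement protocol: session schedule and per-session settings."""

    session_times: tuple[tuple[str, float | None], ...] = tuple(SESSION_TIMES.items())
    phase_repetitions: int = 8
    qiocsf_trials: int = 100
    measures: tuple[str, ...] = ("phase", "qiocsf")
    theta0: float = 22.5
    contrast_ratio: float = 1.0
    sens_freqs: tuple[float, ...] = tuple(np.geomspace(0.94, 2.54, 6).round(4))
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        unknown = set(self.measures) - {"phase", "qiocsf"}
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")
        if self.phase_repetitions < 1 or self.qiocsf_trials < 0:
            raise ValueError("invalid per-session trial counts")


@dataclass
class ExperimentDataset:
    """Per-subject, per-session measurements for one simulated experiment."""

    phase_sessions: pd.DataFrame       # subject, session, time_min, perceived_phase, n_trials
    phase_trials: pd.DataFrame         # subject, session, configuration, repetition, reported_phase
    iocsf_sessions: pd.DataFrame       # subject, session, time_min, 4 params, aulio
    iocsf_sensitivity: pd.DataFrame    # subject, session, freq, log_sensitivity
    iocsf_trials: pd.DataFrame         # subject, session, trial_index, fm, M, orientation_true, response_correct
    meta: dict

    def phase_table(self) -> pd.DataFrame:
        """Wide subjects x sessions table of perceived phase."""
        wide = self.phase_sessions.pivot(index="subject", columns="session",
                                         values="perceived_phase")
        return wide[[s for s in SESSION_LABELS if s in wide.columns]]

    def aulio_table(self) -> pd.DataFrame:
        wide = self.iocsf_sessions.pivot(index="subject", columns="session",
                                         values="aulio")
        return wide[[s for s in SESSION_LABELS if s in wide.columns]]

    def sensitivity_table(self) -> pd.DataFrame:
        """Wide table with MultiIndex columns (session, freq) of log sensitivity."""
        wide = self.iocsf_sensitivity.pivot(index="subject", columns=["session", "freq"],
                                            values="log_sensitivity")
        sessions = [s for s in SESSION_LABELS if s in wide.columns.get_level_values(0)]
        return wide.reindex(columns=sessions, level=0)


def effect_timecourse(effect_amplitude: float, effect_tau: float, t_minutes):
    """Exponentially decaying deprivation effect, degrees of phase shift."""
    t = np.asarray(t_minutes, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since deprivation must be nonnegative")
    if effect_tau <= 0:
        raise ValueError("effect_tau must be positive")
    out = effect_amplitude * np.exp(-t / effect_tau)
    return float(out) if out.ndim == 0 else out


def make_cohort(
    n: int,
    model: str = "null",
    population: PopulationParams | None = None,
    seed: int = 0,
    theta0: float = 22.5,
) -> list[ObserverSpec]:
    """Draw a fully seeded cohort of synthetic observers.

    Under ``model="null"`` every deprivation parameter is zeroed out
    (amplitude 0, gamma_max multiplier 1); under ``model="deprivation"`` the
    immediate phase-shift amplitude is Normal(effect_mean, effect_sd).
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 observers")
    if model not in ("null", "deprivation"):
        raise ValueError("model must be 'null' or 'deprivation'")
    pop = population or PopulationParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    cohort: list[ObserverSpec] = []
    for i in range(n):
        # residual calibration error -> baseline weight asymmetry at delta = 1
        phi0 = float(np.clip(rng.normal(0.0, pop.baseline_phase_sd),
                             -(theta0 - 2.5), theta0 - 2.5))
        w_dom = weight_ratio_for_phase(phi0, theta0)
        gamma = float(np.clip(10.0 ** rng.normal(np.log10(pop.gamma_mean),
                                                 pop.gamma_log10_sd), 2.5, 150.0))
        f_max = float(np.clip(10.0 ** rng.normal(np.log10(pop.f_max_mean),
                                                 pop.f_max_log10_sd), 0.6, 4.0))
        beta = float(np.clip(rng.normal(pop.beta_mean, pop.beta_sd), 1.2, 5.5))
        delta = float(np.clip(rng.normal(pop.delta_mean, pop.delta_sd), 0.05, 1.4))
        if model == "deprivation":
            amplitude = float(rng.normal(pop.effect_mean, pop.effect_sd))
            iocsf_effect = pop.iocsf_effect
        else:
            amplitude, iocsf_effect = 0.0, 1.0
        cohort.append(ObserverSpec(
            subject_id=f"S{i + 1:02d}",
            iocsf_true=IOCSFParams(gamma, f_max, beta, delta),
            weight_dom=w_dom, weight_nondom=1.0,
            lapse=pop.lapse, psychometric_slope=pop.psychometric_slope,
            phase_noise_sd=pop.phase_noise_sd,
            effect_amplitude=amplitude, effect_tau=pop.effect_tau,
            iocsf_effect=iocsf_effect,
            seed=int(rng.integers(2**31)),
        ))
    return cohort


def _session_seed(subject_seed: int, session_index: int, measure: str) -> np.random.SeedSequence:
    """Named substream: (subject seed, session index, measure code)."""
    return np.random.SeedSequence([subject_seed, session_index,
                                   {"phase": 0, "qiocsf": 1}[measure]])


def simulate_experiment(
    cohort: list[ObserverSpec],
    protocol: Protocol | None = None,
    engine: QuickIOCSF | None = None,
) -> ExperimentDataset:
    """Measure every observer at every session with the configured tasks.

    Per session, the observer's instantaneous dominant-eye weight is obtained
    by adding the decayed effect to its baseline noise-free phase and
    inverting the vector-sum model (targets clipped just inside the +/-theta0
    gamut); gamma_max is scaled by the decayed multiplicative IOCSF effect.
    All randomness derives from (observer seed, session index, measure).
    """
    protocol = protocol or Protocol()
    theta0 = protocol.theta0
    gamut = theta0 * 0.995
    if "qiocsf" in protocol.measures and engine is None:
        engine = QuickIOCSF(grid=protocol.grid)

    phase_rows, phase_trial_rows = [], []
    iocsf_rows, sens_rows, iocsf_trial_rows = [], [], []
    for obs in cohort:
        phi_base = perceived_phase_model(
            obs.weight_dom, obs.weight_nondom, protocol.contrast_ratio, theta0, 1)
        for s_idx, (label, t) in enumerate(protocol.session_times):
            decay = 0.0 if t is None else float(np.exp(-t / obs.effect_tau))
            shift = obs.effect_amplitude * decay
            target = float(np.clip(phi_base + shift, -gamut, gamut))
            # instantaneous dominant-eye weight reproducing the target percept
            w_dom_t = weight_ratio_for_phase(target, theta0) / protocol.contrast_ratio

            if "phase" in protocol.measures:
                res = simulate_phase_session(
                    w_dom_t, obs.weight_nondom, protocol.contrast_ratio,
                    repetitions=protocol.phase_repetitions,
                    noise_sd=obs.phase_noise_sd,
                    seed=_session_seed(obs.seed, s_idx, "phase"),
                    theta0=theta0, session_label=label,
                )
                phase_rows.append((obs.subject_id, label, t, res.perceived_phase,
                                   res.n_trials))
                phase_trial_rows.extend(
                    (obs.subject_id, label, tr.configuration, tr.repetition,
                     tr.reported_phase)
                    for tr in res.trials
                )

            if "qiocsf" in protocol.measures:
                gamma_t = obs.iocsf_true.gamma_max * (
                    1.0 + (obs.iocsf_effect - 1.0) * decay)
                params_t = replace(obs.iocsf_true, gamma_max=gamma_t)
                fit = engine.fit(
                    params_t, n_trials=protocol.qiocsf_trials,
                    seed=_session_seed(obs.seed, s_idx, "qiocsf"),
                    observer_lapse=obs.lapse, observer_slope=obs.psychometric_slope,
                )
                est = fit.params
                iocsf_rows.append((obs.subject_id, label, t, est.gamma_max,
                                   est.f_max, est.beta_octaves, est.trunc_delta,
                                   fit.aulio()))
                sens = log_sensitivity(np.asarray(protocol.sens_freqs), est)
                sens_rows.extend(
                    (obs.subject_id, label, f, s)
                    for f, s in zip(protocol.sens_freqs, sens)
                )
                iocsf_trial_rows.extend(
                    (obs.subject_id, label, *row)
                    for row in fit.trials.itertuples(index=False)
                )

    meta = {
        "n": len(cohort),
        "model": "deprivation" if any(o.effect_amplitude != 0 for o in cohort) else "null",
        "sessions": [label for label, _ in protocol.session_times],
        "measures": list(protocol.measures),
        "cohort": [
            {
                "subject_id": o.subject_id,
                "iocsf_true": o.iocsf_true.to_dict(),
                "weight_dom": o.weight_dom, "weight_nondom": o.weight_nondom,
                "lapse": o.lapse, "psychometric_slope": o.psychometric_slope,
                "phase_noise_sd": o.phase_noise_sd,
                "effect_amplitude": o.effect_amplitude,
                "effect_tau": o.effect_tau, "iocsf_effect": o.iocsf_effect,
                "seed": o.seed,
            }
            for o in cohort
        ],
    }
    return ExperimentDataset(
        phase_sessions=pd.DataFrame(
            phase_rows, columns=["subject", "session", "time_min",
                                 "perceived_phase", "n_trials"]),
        phase_trials=pd.DataFrame(
            phase_trial_rows, columns=["subject", "session", "configuration",
                                       "repetition", "reported_phase"]),
        iocsf_sessions=pd.DataFrame(
            iocsf_rows, columns=["subject", "session", "time_min", "gamma_max",
                                 "f_max", "beta_octaves", "trunc_delta", "aulio"]),
        iocsf_sensitivity=pd.DataFrame(
            sens_rows, columns=["subject", "session", "freq", "log_sensitivity"]),
        iocsf_trials=pd.DataFrame(
            iocsf_trial_rows, columns=["subject", "session", "trial_index", "fm",
                                       "M", "orientation_true", "response_correct"]),
        meta=meta,
    )


@dataclass(frozen=True)
class OcclusionSchedule:
    """Square-wave alternation timing, milliseconds."""

    frequency_hz: float
    duty: float
    period_ms: float
    per_eye_ms: float

    @property
    def per_eye_ms_rounded(self) -> int:
        return int(round(self.per_eye_ms))


def alternation_schedule(frequency_hz: float, duty: float = 0.5) -> OcclusionSchedule:
    """Per-eye occlusion duration for square-wave alternation.

    At 7 Hz with a 50/50 duty cycle each eye is occluded for
    1000 / (2 * 7) ~= 71 ms per cycle.
    """
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    if not 0.0 < duty < 1.0:
        raise ValueError("duty cycle must lie in (0, 1)")
    period = 1000.0 / frequency_hz
    return OcclusionSchedule(frequency_hz, duty, period, duty * period)
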