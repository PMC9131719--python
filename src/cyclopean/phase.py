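"""Binocular phase-combination measurement.

Two horizontal gratings with equal-and-opposite phase offsets (+/- theta0,
22.5 deg by default) are fused; the perceived (cyclopean) phase indexes the
relative weight of the two eyes in binocular combination.  The generative
observer used throughout the package is an amplitude-weighted linear vector
sum: with effective amplitudes a_d = weight_dom * contrast_ratio and
a_n = weight_nondom,

    phi = atan( (a_d - a_n) / (a_d + a_n) * tan(theta0) )

in configuration 1 (dominant eye at +theta0) and -phi in configuration 2.
Averaging (phi_1 - phi_2) / 2 across the two configurations cancels any
additive report bias.  Sign convention: positive perceived phase follows the
dominant eye's +theta0 component, so a strengthening of the *nondominant*
(deprived) eye drives the measured phase negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PhaseTrial", "PhaseSessionResult", "perceived_phase_model",
    "combine_configurations", "simulate_phase_session",
    "calibrate_balance_ratio", "weight_ratio_for_phase",
]

SESSION_LABELS = ("pre", "post0", "post10", "post20", "post30", "post40")


@dataclass(frozen=True)
class PhaseTrial:
    configuration: int
    repetition: int
    reported_phase: float  # degrees in (-180, 180]

    def __post_init__(self) -> None:
        if self.configuration not in (1, 2):
            raise ValueError("configuration must be 1 or 2")


@dataclass(frozen=True)
class PhaseSessionResult:
    session_label: str
    perceived_phase: float  # degrees, mean of per-repetition combined phases
    n_trials: int
    trials: tuple[PhaseTrial, ...] = ()


def _effective_amplitudes(weight_dom, weight_nondom, contrast_ratio):
    if weight_dom <= 0 or weight_nondom <= 0:
        raise ValueError("eye weights must be positive")
    if not 0.0 < contrast_ratio <= 1.0:
        raise ValueError("contrast_ratio must lie in (0, 1]")
    return weight_dom * contrast_ratio, weight_nondom * 1.0


def perceived_phase_model(
    weight_dom: float,
    weight_nondom: float,
    contrast_ratio: float = 1.0,
    theta0: float = 22.5,
    configuration: int = 1,
) -> float:
    """Noise-free perceived phase (degrees) of the vector-sum observer."""
    if not 0.0 < theta0 < 90.0:
        raise ValueError("theta0 must lie in (0, 90) degrees")
    if configuration not in (1, 2):
        raise ValueError("configuration must be 1 or 2")
    a_d, a_n = _effective_amplitudes(weight_dom, weight_nondom, contrast_ratio)
    phi = np.degrees(np.arctan((a_d - a_n) / (a_d + a_n) * np.tan(np.radians(theta0))))
    return float(phi if configuration == 1 else -phi)


def combine_configurations(phi_config1: float, phi_config2: float) -> float:
    """Bias-cancelling combination (phi_1 - phi_2) / 2, degrees."""
    return (phi_config1 - phi_config2) / 2.0


def weight_ratio_for_phase(phi_deg: float, theta0: float = 22.5) -> float:
    """Invert the vector-sum model: amplitude ratio a_d/a_n giving phase phi.

    Only phases strictly inside (-theta0, theta0) are attainable with
    positive amplitudes.
    """
    k = np.tan(np.radians(phi_deg)) / np.tan(np.radians(theta0))
    if not abs(k) < 1.0:
        raise ValueError(
            f"target phase {phi_deg} deg is outside the open interval +/-{theta0} deg"
        )
    return float((1.0 + k) / (1.0 - k))


def simulate_phase_session(
    weight_dom: float,
    weight_nondom: float,
    contrast_ratio: float = 1.0,
    repetitions: int = 8,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence | None = 0,
    theta0: float = 22.5,
    session_label: str = "pre",
    quantize_deg: float | None = None,
) -> PhaseSessionResult:
    """Simulate one 2-configuration x `repetitions` adjustment session.

    Each trial's report is the model phase plus seeded Gaussian adjustment
    noise (optionally quantized to the pixel grid of the report line); the
    session value is the mean over repetitions of the per-repetition
    configuration-combined phase.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be at least 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    phi1 = perceived_phase_model(weight_dom, weight_nondom, contrast_ratio, theta0, 1)
    phi2 = perceived_phase_model(weight_dom, weight_nondom, contrast_ratio, theta0, 2)

    def report(model_phase: float, rep: int, config: int) -> PhaseTrial:
        value = model_phase + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        if quantize_deg:
            value = round(value / quantize_deg) * quantize_deg
        return PhaseTrial(config, rep, float(value))

    trials: list[PhaseTrial] = []
    combined = np.empty(repetitions)
    for rep in range(repetitions):
        t1 = report(phi1, rep, 1)
        t2 = report(phi2, rep, 2)
        trials.extend((t1, t2))
        combined[rep] = combine_configurations(t1.reported_phase, t2.reported_phase)
    return PhaseSessionResult(
        session_label=session_label,
        perceived_phase=float(combined.mean()),
        n_trials=2 * repetitions,
        trials=tuple(trials),
    )


def calibrate_balance_ratio(
    weight_dom: float,
    weight_nondom: float,
    tolerance: float = 1e-6,
    theta0: float = 22.5,
) -> float:
    """Interocular contrast ratio delta* nulling the noise-free percept.

    Solves |phi(delta)| < tolerance by bracketing root finding on (0, 1];
    analytically delta* = weight_nondom / weight_dom.  If the nondominant eye
    is actually the stronger one (delta* > 1) the ratio is clipped to 1 and a
    warning is issued.
    """
    if weight_dom <= 0 or weight_nondom <= 0:
        raise ValueError("eye weights must be positive")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if weight_nondom > weight_dom:
        warnings.warn(
            "balanced ratio exceeds 1: the nondominant eye is stronger than the "
            "dominant eye (possible mislabeling); returning delta = 1",
            UserWarning,
            stacklevel=2,
        )
        return 1.0

    def phi(delta: float) -> float:
        return perceived_phase_model(weight_dom, weight_nondom, delta, theta0, 1)

    lo = 1e-12
    if phi(1.0) <= 0.0:  # balanced at (or numerically beyond) full contrast
        return 1.0
    delta = float(brentq(phi, lo, 1.0, xtol=min(tolerance * 1e-3, 1e-9)))
    assert abs(phi(delta)) < tolerance
    return delta
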