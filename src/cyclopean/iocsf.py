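"""Truncated log-parabola interocular-correlation sensitivity function (IOCSF).

The model describes log10 sensitivity to interocular correlation modulation as
a function of spatial frequency f (cycles/degree) with four parameters: peak
gain gamma_max, peak frequency f_max, bandwidth beta (octaves, full width at
half maximum) and a low-frequency truncation depth delta (log10 units):

    S'(f) = log10(gamma_max) - kappa * ((log10 f - log10 f_max) / (beta'/2))^2
    S(f)  = log10(gamma_max) - delta      if f < f_max and S'(f) falls below it
          = S'(f)                          otherwise

with kappa = log10(2) and beta' = log10(2^beta), the conventions of the
quick-CSF family of models.  Sensitivity is the reciprocal of the modulation
threshold M_t, capped so that M_t <= 1 (the modulation parameter cannot
exceed one by construction).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["IOCSFParams", "KAPPA", "log_sensitivity", "sensitivity",
           "modulation_threshold", "aulio_csf"]

KAPPA: float = float(np.log10(2.0))


@dataclass(frozen=True)
class IOCSFParams:
    """The four truncated log-parabola parameters.

    gamma_max : peak gain, linear sensitivity units (> 1)
    f_max     : peak spatial frequency, cycles/degree (> 0)
    beta_octaves : full bandwidth at half maximum, octaves (> 0)
    trunc_delta  : low-frequency truncation depth, log10 units (>= 0)
    """

    gamma_max: float
    f_max: float
    beta_octaves: float
    trunc_delta: float

    def __post_init__(self) -> None:
        if self.gamma_max <= 1:
            raise ValueError("gamma_max must exceed 1 (sensitivity above threshold)")
        if self.f_max <= 0:
            raise ValueError("f_max must be positive")
        if self.beta_octaves <= 0:
            raise ValueError("beta_octaves must be positive")
        if self.trunc_delta < 0:
            raise ValueError("trunc_delta must be nonnegative")

    @property
    def kappa(self) -> float:
        return KAPPA

    @property
    def beta_prime(self) -> float:
        """Bandwidth converted to log10-frequency units: log10(2^beta)."""
        return self.beta_octaves * KAPPA

    @property
    def log_gain(self) -> float:
        return float(np.log10(self.gamma_max))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["units"] = {
            "gamma_max": "linear sensitivity (1/modulation threshold)",
            "f_max": "cycles/degree",
            "beta_octaves": "octaves (FWHM)",
            "trunc_delta": "log10 units",
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "IOCSFParams":
        return cls(
            gamma_max=float(d["gamma_max"]), f_max=float(d["f_max"]),
            beta_octaves=float(d["beta_octaves"]), trunc_delta=float(d["trunc_delta"]),
        )


def log_sensitivity(f, params: IOCSFParams):
    """log10 sensitivity S(f) of the truncated log-parabola."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("spatial frequency must be positive")
    log_gain = params.log_gain
    half_width = params.beta_prime / 2.0
    s_parab = log_gain - KAPPA * ((np.log10(f) - np.log10(params.f_max)) / half_width) ** 2
    floor = log_gain - params.trunc_delta
    out = np.where((f < params.f_max) & (s_parab < floor), floor, s_parab)
    return float(out) if out.ndim == 0 else out


def sensitivity(f, params: IOCSFParams):
    """Linear sensitivity 10^S(f)."""
    return 10.0 ** np.asarray(log_sensitivity(f, params))


def modulation_threshold(f, params: IOCSFParams):
    """Modulation threshold M_t(f) = 10^-S(f), capped at 1."""
    thr = np.minimum(1.0, 10.0 ** (-np.asarray(log_sensitivity(f, params))))
    return float(thr) if thr.ndim == 0 else thr


def aulio_csf(
    params: IOCSFParams,
    f_lo: float = 0.94,
    f_hi: float = 2.54,
    n_grid: int = 100,
) -> float:
    """Area under the log IOC sensitivity function (AULIOCSF).

    Trapezoidal integral of max(S(f), 0) over log10 frequency on an evenly
    spaced log10 grid; units are log10-sensitivity x log10-frequency.  The
    default band [0.94, 2.54] c/d is the tested spatial-frequency range.
    """
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    log_f = np.linspace(np.log10(f_lo), np.log10(f_hi), n_grid)
    s = np.maximum(log_sensitivity(10.0**log_f, params), 0.0)
    return float(np.trapezoid(s, log_f))
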