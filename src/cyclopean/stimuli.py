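"""Dichoptic stimulus synthesis.

Two stimulus families are generated here:

* **Correlation-modulated noise pairs.**  Each eye sees a blend of a shared
  ("correlated") bandpass noise carrier and an eye-private carrier with
  identical statistics.  The blend weights vary sinusoidally along an oblique
  axis (45 or 135 deg), so the local interocular correlation is high inside
  the "correlated" stripes and low in between.  With unit-variance,
  independent carriers the expected local Pearson correlation between the two
  eyes' images has the closed form

      rho(x) = M_C(x)^2 / (M_C(x)^2 + M_eye(x)^2),

  which ranges from 50% everywhere at modulation M = 0 to 100% at the stripe
  peak when M = 1.

* **Phase-combination grating pairs.**  Horizontal sinusoidal luminance
  gratings with equal-and-opposite phase offsets (+/- 22.5 deg by default);
  the dominant eye's contrast is scaled by the interocular contrast ratio
  delta while the nondominant eye stays at 100%.  Two configurations swap the
  sign of the offsets so that additive report biases cancel.

All generation is seeded and bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CarrierSet",
    "CorrelationStimulusSpec",
    "DichopticImagePair",
    "PhaseStimulusSpec",
    "PhaseGratingPair",
    "make_bandpass_noise",
    "make_carrier_set",
    "correlation_envelopes",
    "blend_dichoptic",
    "make_correlation_stimulus",
    "expected_local_correlation",
    "make_phase_gratings",
    "export_stimulus",
]

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian profile
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _centered_grid(n: int, pixels_per_degree: float) -> np.ndarray:
    """Pixel coordinates in degrees, origin at the image center."""
    return (np.arange(n) - (n - 1) / 2.0) / pixels_per_degree


@dataclass(frozen=True)
class CorrelationStimulusSpec:
    """One correlation-modulated dichoptic trial stimulus.

    ``carrier_sf`` is locked to four times the envelope frequency ``fm``:
    the noise carrier lives one quarter-cycle finer than the correlation
    envelope that modulates it.
    """

    M: float
    fm: float
    orientation: int = 135
    extent_deg: float = 12.8
    pixels_per_degree: float = 40.0
    seed: int = 0
    octave_bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.M <= 1.0:
            raise ValueError(f"modulation M must lie in [0, 1], got {self.M}")
        if self.orientation not in (45, 135):
            raise ValueError("envelope orientation must be 45 or 135 degrees")
        if self.fm <= 0:
            raise ValueError("envelope frequency fm must be positive")
        if self.extent_deg <= 0 or self.pixels_per_degree <= 0:
            raise ValueError("extent and sampling density must be positive")

    @property
    def carrier_sf(self) -> float:
        return 4.0 * self.fm

    @property
    def n_pixels(self) -> int:
        return int(round(self.extent_deg * self.pixels_per_degree))


@dataclass(frozen=True)
class CarrierSet:
    """Shared and eye-private noise carriers with identical statistics."""

    common: np.ndarray
    left: np.ndarray
    right: np.ndarray
    center_sf: float
    seed: int

    def __post_init__(self) -> None:
        if not (self.common.shape == self.left.shape == self.right.shape):
            raise ValueError("carrier textures must share shape")


@dataclass(frozen=True)
class DichopticImagePair:
    I_left: np.ndarray
    I_right: np.ndarray
    spec: CorrelationStimulusSpec | None = None

    def __post_init__(self) -> None:
        if self.I_left.shape != self.I_right.shape:
            raise ValueError("dichoptic images must share shape")
        if not (np.all(np.isfinite(self.I_left)) and np.all(np.isfinite(self.I_right))):
            raise ValueError("dichoptic images must be finite")


def make_bandpass_noise(
    center_sf: float,
    octave_bandwidth: float = 1.0,
    extent_deg: float = 12.8,
    pixels_per_degree: float = 40.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Isotropic bandpass noise texture, zero mean and unit variance.

    White Gaussian noise is filtered in the frequency domain by a log-Gaussian
    annulus centered on ``center_sf`` (cycles/degree) whose full bandwidth at
    half height is ``octave_bandwidth`` octaves, then renormalized to exactly
    zero mean and unit variance so closed-form correlation predictions hold
    exactly.
    """
    if center_sf <= 0:
        raise ValueError("center_sf must be positive")
    if extent_deg <= 0 or pixels_per_degree <= 0:
        raise ValueError("extent_deg and pixels_per_degree must be positive")
    if octave_bandwidth <= 0:
        raise ValueError("octave_bandwidth must be positive")
    if center_sf >= pixels_per_degree / 2.0:
        raise ValueError(
            f"center_sf={center_sf} c/d violates the Nyquist limit "
            f"{pixels_per_degree / 2.0} c/d at {pixels_per_degree} px/deg"
        )
    n = int(round(extent_deg * pixels_per_degree))
    if n < 4:
        raise ValueError("stimulus smaller than 4 pixels across")

    if rng is None:
        rng = np.random.default_rng(seed)
    white = rng.standard_normal((n, n))

    f1 = np.fft.fftfreq(n, d=1.0 / pixels_per_degree)
    fr = np.hypot(f1[:, None], f1[None, :])
    sigma = octave_bandwidth * _FWHM_TO_SIGMA  # in octaves (log2 units)
    with np.errstate(divide="ignore"):
        log2_ratio = np.where(fr > 0, np.log2(np.maximum(fr, 1e-300) / center_sf), 0.0)
    gain = np.exp(-0.5 * (log2_ratio / sigma) ** 2)
    gain[fr == 0] = 0.0  # kill DC: zero-mean by construction

    tex = np.fft.ifft2(np.fft.fft2(white) * gain).real
    tex -= tex.mean()
    tex /= tex.std()
    return tex


def make_carrier_set(spec: CorrelationStimulusSpec) -> CarrierSet:
    """Three independent seeded carriers (common, left, right) for one trial."""
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(3)]
    textures = [
        make_bandpass_noise(
            spec.carrier_sf,
            spec.octave_bandwidth,
            spec.extent_deg,
            spec.pixels_per_degree,
            rng=r,
        )
        for r in streams
    ]
    return CarrierSet(
        common=textures[0], left=textures[1], right=textures[2],
        center_sf=spec.carrier_sf, seed=spec.seed,
    )


def envelope_coordinate(spec: CorrelationStimulusSpec) -> np.ndarray:
    """Distance (deg) along the axis perpendicular to the envelope stripes.

    The stripe orientation is ``spec.orientation``; the returned coordinate is
    zero at the image center, so the envelope phase origin is center-anchored.
    """
    c = _centered_grid(spec.n_pixels, spec.pixels_per_degree)
    X, Y = np.meshgrid(c, c)
    if spec.orientation == 45:
        return (X - Y) / np.sqrt(2.0)
    return (X + Y) / np.sqrt(2.0)


def correlation_envelopes(
    spec: CorrelationStimulusSpec, x: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Complementary blend envelopes (M_C, M_eye).

    ``M_C(x) = (1 + M sin(2 pi fm x)) / 2`` weights the shared carrier and
    ``M_eye(x) = (1 - M sin(2 pi fm x)) / 2`` weights each eye-private
    carrier (identical for the two eyes); they sum to one at every pixel.
    ``x`` defaults to the oblique coordinate implied by the spec geometry.
    """
    if x is None:
        x = envelope_coordinate(spec)
    x = np.asarray(x, dtype=float)
    s = np.sin(2.0 * np.pi * spec.fm * x)
    m_c = 0.5 * (1.0 + spec.M * s)
    m_eye = 0.5 * (1.0 - spec.M * s)
    return m_c, m_eye


def blend_dichoptic(
    carriers: CarrierSet, envelopes: tuple[np.ndarray, np.ndarray],
    spec: CorrelationStimulusSpec | None = None,
) -> DichopticImagePair:
    """Blend the shared and private carriers under the complementary envelopes."""
    m_c, m_eye = envelopes
    if m_c.shape != carriers.common.shape or m_eye.shape != carriers.common.shape:
        raise ValueError("envelope and carrier shapes must match")
    return DichopticImagePair(
        I_left=carriers.common * m_c + carriers.left * m_eye,
        I_right=carriers.common * m_c + carriers.right * m_eye,
        spec=spec,
    )


def make_correlation_stimulus(spec: CorrelationStimulusSpec) -> DichopticImagePair:
    """Full pipeline: carriers -> envelopes -> blended dichoptic pair."""
    return blend_dichoptic(make_carrier_set(spec), correlation_envelopes(spec), spec)


def expected_local_correlation(M: float, envelope_phase) -> np.ndarray | float:
    """Expected interocular Pearson correlation at a given envelope phase.

    With independent unit-variance carriers the two eyes' images share only
    the ``C_common * M_C`` term, so

        rho = M_C^2 / (M_C^2 + M_eye^2)

    evaluated at ``envelope_phase = 2 pi fm x`` (radians).  At M = 0 this is
    0.5 everywhere; at M = 1 it reaches 1 at the stripe peak (sin = 1) and 0
    at the trough (sin = -1).
    """
    if not 0.0 <= M <= 1.0:
        raise ValueError(f"modulation M must lie in [0, 1], got {M}")
    s = np.sin(np.asarray(envelope_phase, dtype=float))
    m_c = 0.5 * (1.0 + M * s)
    m_eye = 0.5 * (1.0 - M * s)
    rho = m_c**2 / (m_c**2 + m_eye**2)
    return float(rho) if rho.ndim == 0 else rho


@dataclass(frozen=True)
class PhaseStimulusSpec:
    """One binocular phase-combination configuration.

    The nondominant eye's contrast is fixed at 100%; the dominant eye is
    scaled by ``contrast_ratio`` (the interocular contrast ratio delta).
    """

    contrast_ratio: float
    theta0: float = 22.5
    grating_sf: float = 0.46
    configuration: int = 1
    extent_deg: float = 10.0
    pixels_per_degree: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 < self.contrast_ratio <= 1.0:
            raise ValueError("contrast_ratio must lie in (0, 1]")
        if self.configuration not in (1, 2):
            raise ValueError("configuration must be 1 or 2")
        if not 0.0 <= self.theta0 < 90.0:
            raise ValueError("theta0 must lie in [0, 90) degrees")
        if self.grating_sf <= 0:
            raise ValueError("grating_sf must be positive")

    @property
    def n_pixels(self) -> int:
        return int(round(self.extent_deg * self.pixels_per_degree))


@dataclass(frozen=True)
class PhaseGratingPair:
    dominant: np.ndarray
    nondominant: np.ndarray
    spec: PhaseStimulusSpec


def make_phase_gratings(spec: PhaseStimulusSpec) -> PhaseGratingPair:
    """Horizontal sine gratings with equal-and-opposite phase offsets.

    Configuration 1 gives the dominant eye phase ``+theta0`` at contrast
    ``contrast_ratio`` and the nondominant eye ``-theta0`` at full contrast;
    configuration 2 swaps the signs of the offsets.  Mean luminance 0.5.
    """
    n = spec.n_pixels
    y = _centered_grid(n, spec.pixels_per_degree)
    sign = 1.0 if spec.configuration == 1 else -1.0

    def grating(contrast: float, phase_deg: float) -> np.ndarray:
        profile = 0.5 * (
            1.0 + contrast * np.sin(2.0 * np.pi * spec.grating_sf * y + np.deg2rad(phase_deg))
        )
        return np.broadcast_to(profile[:, None], (n, n)).copy()

    return PhaseGratingPair(
        dominant=grating(spec.contrast_ratio, sign * spec.theta0),
        nondominant=grating(1.0, -sign * spec.theta0),
        spec=spec,
    )


def export_stimulus(
    pair: DichopticImagePair, out_prefix: str | Path, clip: float = 3.0
) -> list[Path]:
    """Write a dichoptic pair as 8-bit grayscale PNGs plus a JSON sidecar.

    Pixel values in [-clip, clip] are mapped affinely to [0, 255]; the sidecar
    records the full spec (including seed) so the stimulus can be regenerated.
    """
    import imageio.v3 as iio

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for tag, img in (("left", pair.I_left), ("right", pair.I_right)):
        scaled = np.clip((img + clip) / (2.0 * clip), 0.0, 1.0)
        path = out_prefix.with_name(out_prefix.name + f"_{tag}.png")
        iio.imwrite(path, (scaled * 255).round().astype(np.uint8))
        written.append(path)
    meta = {"clip": clip}
    if pair.spec is not None:
        meta["spec"] = asdict(pair.spec)
    meta_path = out_prefix.with_name(out_prefix.name + "_meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    written.append(meta_path)
    return written
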