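"""Synthetic generators for every input the pipeline consumes.

Three signal classes are emulated, each with the simplest noise model that
matches it: subdural strip recordings under sinusoidal stimulation (additive
Gaussian DAQ-like noise), iEEG stimulation sessions (1/f background by
spectral shaping plus band-limited oscillators, one per canonical band), and
"measured" calibration strip fields (multiplicative gain-like Gaussian
noise on forward-solved truth).  All generators are bit-reproducible given
their spec and seed.

Stimulus intensities are interpreted as peak-to-peak current, so the
measurement chain's peak-to-peak amplitudes recover field amplitudes without
an extra factor of two.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .calibration import DEFAULT_BOUNDS, CalibrationProblem
from .forward import field_along_strip, solve_potential, strip_pair_fields
from .geometry import ConfigurationError, Montage, StripSpec, TissueModel
from .ieeg import BANDS_HZ, Session
from .recording import RecordingEpoch

__all__ = [
    "StimulusWaveform",
    "StripRecordingSpec",
    "IEEGSpec",
    "make_stimulus",
    "make_strip_recording",
    "strip_fields_from_solution",
    "make_ieeg_session",
    "standard_calibration_montages",
    "make_calibration_dataset",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Stimulus waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusWaveform:
    """Sinusoidal or charge-balanced biphasic-pulse stimulus.

    For the biphasic shape each pulse is a single sine cycle of total width
    ``2 * pulse_width_ms`` repeated at ``frequency_hz`` (the repetition rate);
    the per-pulse charge is balanced to machine precision.
    """

    shape: str  # "sinusoidal" | "biphasic"
    amplitude_mA: float
    frequency_hz: float
    pulse_width_ms: float = 0.5

    def __post_init__(self):
        if self.shape not in ("sinusoidal", "biphasic"):
            raise ConfigurationError(f"unknown stimulus shape {self.shape!r}")
        if self.frequency_hz <= 0 or self.pulse_width_ms <= 0:
            raise ConfigurationError("frequency and pulse width must be > 0")


def make_stimulus(spec: StimulusWaveform, fs_hz: float, duration_s: float) -> np.ndarray:
    """Stimulus current time series (mA)."""
    n = int(round(fs_hz * duration_s))
    t = np.arange(n) / fs_hz
    if spec.shape == "sinusoidal":
        if fs_hz < 10 * spec.frequency_hz:
            raise ConfigurationError("sampling rate must be >= 10x the frequency")
        return spec.amplitude_mA * np.sin(2 * np.pi * spec.frequency_hz * t)
    width_s = spec.pulse_width_ms * 1e-3
    if fs_hz < 10 / width_s:
        raise ConfigurationError(
            f"sampling rate {fs_hz} Hz cannot resolve a {spec.pulse_width_ms} ms pulse"
        )
    x = np.zeros(n)
    period = 1.0 / spec.frequency_hz
    n_pulses = int(np.floor(duration_s / period))
    for k in range(n_pulses):
        i0 = int(round(k * period * fs_hz))
        i1 = min(int(round((k * period + 2 * width_s) * fs_hz)), n)
        tt = t[i0:i1] - t[i0]
        pulse = spec.amplitude_mA * np.sin(np.pi * tt / width_s)
        pulse -= pulse.mean()  # exact numerical charge balance per pulse
        x[i0:i1] = pulse
    return x


# ---------------------------------------------------------------------------
# Strip recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StripRecordingSpec:
    """Synthesis parameters for an 8-contact strip epoch.

    ``pair_fields_mV_per_mm`` are the adjacent-pair field amplitudes the
    recording should encode (length ``n_contacts - 1``); contact potentials
    are their cumulative sum times the contact spacing, modulated by a
    unit-peak-to-peak sinusoid at the stimulus frequency, plus i.i.d.
    Gaussian noise.
    """

    pair_fields_mV_per_mm: tuple
    intensity_mA: float = 1.0
    frequency_hz: float = 1000.0
    duration_s: float = 3.0
    fs_hz: float = 20000.0
    spacing_mm: float = 5.0
    noise_sd_mV: float = 0.0
    condition: str = "TES"
    montage_id: str = ""

    def __post_init__(self):
        if self.noise_sd_mV < 0:
            raise ConfigurationError("noise SD must be >= 0")
        if len(self.pair_fields_mV_per_mm) < 1:
            raise ConfigurationError("need at least one pair field")


def make_strip_recording(spec: StripRecordingSpec, seed=0) -> RecordingEpoch:
    """Synthesize a strip epoch whose measurement-chain output recovers
    ``spec.pair_fields_mV_per_mm`` (exactly so when noise SD = 0)."""
    rng = _rng(seed)
    fields = np.asarray(spec.pair_fields_mV_per_mm, dtype=float)
    pots_mV = np.concatenate([[0.0], np.cumsum(fields * spec.spacing_mm)])
    n = int(round(spec.fs_hz * spec.duration_s))
    t = np.arange(n) / spec.fs_hz
    carrier = 0.5 * np.sin(2 * np.pi * spec.frequency_hz * t)  # unit p2p
    data = pots_mV[:, None] * carrier[None, :]
    if spec.noise_sd_mV > 0:
        data = data + rng.normal(0.0, spec.noise_sd_mV, size=data.shape)
    return RecordingEpoch(
        data=data, fs_hz=spec.fs_hz, intensity_mA=spec.intensity_mA,
        frequency_hz=spec.frequency_hz, condition=spec.condition,
        montage_id=spec.montage_id,
    )


def strip_fields_from_solution(solution, strip: StripSpec) -> np.ndarray:
    """Adjacent-pair fields (mV/mm) of a forward solution sampled on a strip."""
    pots = field_along_strip(solution, strip)
    return strip_pair_fields(pots, strip.spacing_mm)


# ---------------------------------------------------------------------------
# iEEG sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IEEGSpec:
    """Statistical model of a stimulation-session iEEG trace.

    The background is 1/f^exponent Gaussian noise; one band-limited
    oscillator per canonical band guarantees signal in every band.  For the
    skull-applied (SES) condition the post-phase amplitude of the alpha and
    beta oscillators is multiplied by ``effect_multipliers``; scalp-applied
    (TES) and baseline sessions have multiplier 1 everywhere.
    """

    background_exponent: float = 1.0
    background_sd_uV: float = 10.0
    # (centre Hz, bandwidth Hz, SD µV) — one oscillator per band
    oscillators: tuple = ((2.0, 1.5, 4.0), (6.0, 2.0, 4.0),
                         (10.0, 2.0, 4.0), (20.0, 4.0, 3.0))
    phase_durations_s: tuple = (30.0, 50.0, 20.0)
    fs_hz: float = 512.0
    effect_multipliers: Mapping[str, float] = dc_field(
        default_factory=lambda: {"alpha": 2.0, "beta": 2.0}
    )

    def __post_init__(self):
        if any(m <= 0 for m in self.effect_multipliers.values()):
            raise ConfigurationError("effect multipliers must be > 0")
        if len(self.phase_durations_s) != 3:
            raise ConfigurationError("protocol has exactly three phases")


def _one_over_f(n: int, fs: float, exponent: float, sd: float,
                rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    s = x.std()
    return x / s * sd if s > 0 else x


def _oscillator(n: int, fs: float, centre: float, bw: float, sd: float,
                rng: np.random.Generator) -> np.ndarray:
    lo = max(centre - bw / 2, 0.1)
    hi = min(centre + bw / 2, fs / 2 * 0.95)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s * sd if s > 0 else x


def _band_of(freq: float) -> str | None:
    for name, (lo, hi) in BANDS_HZ.items():
        if lo <= freq < hi:
            return name
    return None


def make_ieeg_session(spec: IEEGSpec, condition: str, seed=0,
                      intensity_mA: float = 1.0) -> Session:
    """Generate one session under the 30/50/20 s protocol.

    Phases are generated independently (the protocol analyses pre and post
    separately, so cross-phase continuity is not modelled).
    """
    if condition not in ("TES", "SES", "baseline"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    rng = _rng(seed)
    fs = spec.fs_hz
    chunks = []
    for phase_i, dur in enumerate(spec.phase_durations_s):
        n = int(round(dur * fs))
        x = _one_over_f(n, fs, spec.background_exponent, spec.background_sd_uV, rng)
        for centre, bw, sd in spec.oscillators:
            amp = sd
            if phase_i == 2 and condition == "SES":
                band = _band_of(centre)
                amp *= spec.effect_multipliers.get(band, 1.0)
            x = x + _oscillator(n, fs, centre, bw, amp, rng)
        chunks.append(x)
    trace = np.concatenate(chunks)
    d0, d1, d2 = spec.phase_durations_s
    phases = {"pre": (0.0, d0), "stim": (d0, d0 + d1), "post": (d0 + d1, d0 + d1 + d2)}
    return Session(trace=trace, fs_hz=fs, phases=phases,
                   condition=condition, intensity_mA=intensity_mA)


# ---------------------------------------------------------------------------
# Calibration datasets
# ---------------------------------------------------------------------------

def standard_calibration_montages(model: TissueModel,
                                  intensities_mA: tuple = (1.0, 2.0, 3.0),
                                  patch_area_cm2: float = 0.5,
                                  strip_depth_mm: float = 30.0):
    """A calibration battery with enough diversity to identify both unknowns.

    Brain-surface strip fields under current-controlled stimulation constrain
    essentially only the scalp/skull conductivity ratio (the shunt split), so
    the battery combines two strip placements:

    - brain-surface chord strips at ``strip_depth_mm`` under three stimulation
      directions, each driven through both scalp-surface and skull-surface
      patch pairs and at every intensity in ``intensities_mA`` (replicates
      average out multiplicative measurement noise);
    - scalp-layer chord strips (field ~ 1/sigma_scalp) under the first two
      scalp-surface montages, which pin the absolute conductivity scale.

    Returns ``(montages, strips)`` aligned for ``make_calibration_dataset``.
    """
    from .geometry import ElectrodePatch, place_montage

    if model.kind != "shells":
        raise ConfigurationError("the standard battery is defined on shell models")
    r_out = float(model.shells[-1][1])
    half_span = 17.5  # mm, 8 contacts at 5 mm pitch
    s2 = 1.0 / np.sqrt(2.0)
    dirs = [((0.0, 0.0, 1.0), (1.0, 0.0, 0.0)),
            ((s2, 0.0, s2), (s2, 0.0, -s2)),
            ((1.0, 0.0, 0.0), (0.0, 0.0, 1.0))]

    def chord(u, orient, z0):
        u = np.asarray(u, dtype=float)
        orient = np.asarray(orient, dtype=float)
        return StripSpec(tuple(z0 * u - half_span * orient), tuple(orient))

    montages, strips = [], []

    def pair(u, attachment, intensity):
        a = tuple(r_out * np.asarray(u, dtype=float))
        b = tuple(-r_out * np.asarray(u, dtype=float))
        return place_montage(model, [
            ElectrodePatch(a, patch_area_cm2, attachment, "active", intensity),
            ElectrodePatch(b, patch_area_cm2, attachment, "reference", -intensity),
        ])

    for u, orient in dirs:
        for attachment in ("scalp-surface", "skull-surface"):
            for intensity in intensities_mA:
                montages.append(pair(u, attachment, intensity))
                strips.append(chord(u, orient, strip_depth_mm))
    z0 = np.sqrt(r_out ** 2 - half_span ** 2)
    for u, orient in dirs[:2]:
        for intensity in intensities_mA:
            montages.append(pair(u, "scalp-surface", intensity))
            strips.append(chord(u, orient, z0))
    return montages, strips

def make_calibration_dataset(
    model: TissueModel,
    truth_sigma_scalp: float,
    truth_sigma_skull: float,
    montages: Sequence[Montage],
    strips: Sequence[StripSpec],
    noise_fraction: float = 0.0,
    seed=0,
    bounds: dict | None = None,
    weights: tuple = (0.5, 0.5),
) -> CalibrationProblem:
    """Forward-solve strip fields at a ground-truth conductivity pair and wrap
    them, with multiplicative Gaussian noise, as a calibration problem.

    The truth may deliberately lie outside the search bounds (to exercise
    boundary pinning); it is carried in the sealed ``truth`` audit field that
    the calibration loop never reads.
    """
    if truth_sigma_scalp <= 0 or truth_sigma_skull <= 0:
        raise ConfigurationError("truth conductivities must be > 0")
    rng = _rng(seed)
    from dataclasses import replace

    cs = model.conductivities.with_updates(
        provenance="synthetic-truth", scalp=truth_sigma_scalp, skull=truth_sigma_skull
    )
    truth_model = replace(model, conductivities=cs)
    measured = []
    for montage, strip in zip(montages, strips):
        sol = solve_potential(truth_model, montage)
        fields = strip_pair_fields(field_along_strip(sol, strip), strip.spacing_mm)
        if noise_fraction > 0:
            fields = fields * (1.0 + rng.normal(0.0, noise_fraction, size=fields.shape))
        measured.append(np.abs(fields))
    return CalibrationProblem(
        model=model, montages=list(montages), strips=list(strips),
        measured_fields=measured,
        bounds=dict(bounds) if bounds else dict(DEFAULT_BOUNDS),
        weights=weights,
        truth={"sigma_scalp": truth_sigma_scalp, "sigma_skull": truth_sigma_skull},
    )
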