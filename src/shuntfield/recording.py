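"""Measurement chain from raw strip potentials to fields, slopes and ratios.

The in vivo chain is: Butterworth band-pass -> cycle averaging at the stimulus
frequency -> peak-to-peak amplitude per contact -> adjacent-contact potential
difference / spacing = field magnitude (mV/mm).  On top of that sit the
summary analyses: field-per-milliamp slopes, the skull-applied over
scalp-applied shunting ratio, the current required to reach a target field,
and the field-versus-frequency trend.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "RecordingEpoch",
    "FieldMeasurement",
    "SlopeFit",
    "RatioSummary",
    "FrequencyTrend",
    "bandpass",
    "cycle_average",
    "peak_to_peak",
    "strip_gradient",
    "per_milliamp_slope",
    "shunting_ratio",
    "required_current",
    "frequency_trend",
]


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class RecordingEpoch:
    """Multi-channel strip potential recording under sinusoidal stimulation.

    ``data`` is channels x samples in mV; the sampling rate must oversample
    the stimulus by at least 10x.
    """

    data: np.ndarray
    fs_hz: float
    intensity_mA: float
    frequency_hz: float
    condition: str = "TES"  # TES | SES-removed | SES-closed | ...
    montage_id: str = ""

    def __post_init__(self):
        data = np.atleast_2d(np.asarray(self.data, dtype=float))
        object.__setattr__(self, "data", data)
        if data.shape[1] < 1:
            raise AnalysisError("epoch duration must be > 0")
        if self.fs_hz < 10 * self.frequency_hz:
            raise AnalysisError(
                f"sampling rate {self.fs_hz} Hz must be >= 10x the stimulus "
                f"frequency {self.frequency_hz} Hz"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs_hz


@dataclass(frozen=True)
class FieldMeasurement:
    """Per-adjacent-pair field magnitudes derived from one epoch.

    ``summary_mV_per_mm`` is the maximum over pairs (the pair under the active
    electrode dominates); per-pair values are always retained.
    """

    pair_fields_mV_per_mm: np.ndarray
    p2p_mV: np.ndarray
    intensity_mA: float
    frequency_hz: float
    condition: str = ""
    montage_id: str = ""

    def __post_init__(self):
        pf = np.asarray(self.pair_fields_mV_per_mm, dtype=float)
        p2p = np.asarray(self.p2p_mV, dtype=float)
        if np.any(pf < 0) or np.any(p2p < 0):
            raise AnalysisError("field and p2p magnitudes must be >= 0")
        if len(pf) != len(p2p) - 1:
            raise AnalysisError("pair count must equal channel count - 1")
        object.__setattr__(self, "pair_fields_mV_per_mm", pf)
        object.__setattr__(self, "p2p_mV", p2p)

    @property
    def summary_mV_per_mm(self) -> float:
        return float(np.max(self.pair_fields_mV_per_mm))


# ---------------------------------------------------------------------------
# Signal chain
# ---------------------------------------------------------------------------

def bandpass(epoch: RecordingEpoch, low_hz: float, high_hz: float,
             order: int = 4) -> RecordingEpoch:
    """Zero-phase Butterworth band-pass (forward-backward, order doubled)."""
    nyq = epoch.fs_hz / 2
    if not 0 < low_hz < high_hz < nyq:
        raise AnalysisError(f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=epoch.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, epoch.data, axis=1)
    return replace(epoch, data=filtered)


def cycle_average(epoch: RecordingEpoch, frequency_hz: float | None = None,
                  min_cycles: int = 10) -> np.ndarray:
    """Phase-folded single-cycle template per channel.

    Samples are binned by stimulus phase (no cumulative phase drift when the
    frequency does not divide the sampling rate); the trailing incomplete
    cycle is discarded.  Template length is ``round(fs / f)`` samples.
    """
    f = epoch.frequency_hz if frequency_hz is None else frequency_hz
    n = epoch.data.shape[1]
    n_complete = int(np.floor(n / epoch.fs_hz * f))
    if n_complete < min_cycles:
        raise AnalysisError(
            f"epoch holds {n_complete} complete cycles; need >= {min_cycles}"
        )
    L = int(round(epoch.fs_hz / f))
    t_cycles = np.arange(n) / epoch.fs_hz * f
    keep = t_cycles < n_complete
    phase_bin = np.minimum((t_cycles[keep] % 1.0 * L).astype(int), L - 1)
    template = np.zeros((epoch.n_channels, L))
    counts = np.zeros(L)
    np.add.at(counts, phase_bin, 1.0)
    for c in range(epoch.n_channels):
        acc = np.zeros(L)
        np.add.at(acc, phase_bin, epoch.data[c, keep])
        template[c] = acc / np.maximum(counts, 1)
    return template


def peak_to_peak(template: np.ndarray) -> np.ndarray:
    """max - min per channel (mV)."""
    t = np.atleast_2d(np.asarray(template, dtype=float))
    if t.shape[1] == 0:
        raise AnalysisError("template is empty")
    return t.max(axis=1) - t.min(axis=1)


def strip_gradient(p2p_mV: np.ndarray, spacing_mm: float = 5.0,
                   intensity_mA: float = np.nan, frequency_hz: float = np.nan,
                   condition: str = "", montage_id: str = "") -> FieldMeasurement:
    """Adjacent-pair field magnitudes |p2p_i - p2p_{i+1}| / spacing (mV/mm)."""
    p2p = np.asarray(p2p_mV, dtype=float)
    if p2p.ndim != 1 or len(p2p) < 2:
        raise AnalysisError("need >= 2 channels to form a gradient")
    if spacing_mm <= 0:
        raise AnalysisError("contact spacing must be > 0")
    pairs = np.abs(np.diff(p2p)) / spacing_mm
    return FieldMeasurement(pairs, p2p, intensity_mA, frequency_hz,
                            condition, montage_id)


def measure_epoch(epoch: RecordingEpoch, band_hz: tuple = (20.0, 2000.0),
                  spacing_mm: float = 5.0, order: int = 4) -> FieldMeasurement:
    """Full chain: band-pass -> cycle average -> p2p -> gradient."""
    low, high = band_hz
    high = min(high, epoch.fs_hz / 2 * 0.9)
    filt = bandpass(epoch, low, high, order=order)
    template = cycle_average(filt)
    p2p = peak_to_peak(template)
    return strip_gradient(p2p, spacing_mm, epoch.intensity_mA,
                          epoch.frequency_hz, epoch.condition, epoch.montage_id)


# ---------------------------------------------------------------------------
# Summary analyses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlopeFit:
    """Field-per-intensity summary: per-epoch ratios and an origin-constrained
    least-squares slope, with the Pearson correlation of E against I."""

    ratios_mV_per_mm_per_mA: np.ndarray
    median_ratio: float
    iqr: tuple
    slope_mV_per_mm_per_mA: float
    pearson_r: float
    pearson_p: float

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios_mV_per_mm_per_mA))


def per_milliamp_slope(measurements: Sequence[FieldMeasurement]) -> SlopeFit:
    intensities = np.array([m.intensity_mA for m in measurements], dtype=float)
    fields = np.array([m.summary_mV_per_mm for m in measurements], dtype=float)
    if len(np.unique(intensities)) < 2:
        raise AnalysisError("need >= 2 distinct intensities")
    ratios = fields / intensities
    slope = float(np.sum(fields * intensities) / np.sum(intensities ** 2))
    r, p = stats.pearsonr(intensities, fields)
    q1, q3 = np.percentile(ratios, [25, 75])
    return SlopeFit(ratios, float(np.median(ratios)), (float(q1), float(q3)),
                    slope, float(r), float(p))


@dataclass(frozen=True)
class RatioSummary:
    """Per-pair skull-applied / scalp-applied field ratios and their summary."""

    keys: np.ndarray
    ratios: np.ndarray
    mean: float
    sd: float
    anova_F: float | None = None
    anova_p: float | None = None


def shunting_ratio(ses: Sequence[FieldMeasurement], tes: Sequence[FieldMeasurement],
                   pairing: str = "intensity", anova_by: str | None = None) -> RatioSummary:
    """Pair SES and TES measurements by intensity or frequency and summarize
    the per-pair E_ses / E_tes ratio (mean of ratios, not ratio of means).

    ``anova_by='frequency'`` adds a one-way ANOVA of the ratios across
    frequency groups (Bonferroni-corrected pairwise comparisons are left to
    the caller via the returned groups when needed).
    """
    if pairing not in ("intensity", "frequency"):
        raise AnalysisError("pairing must be 'intensity' or 'frequency'")
    key = (lambda m: m.intensity_mA) if pairing == "intensity" else (lambda m: m.frequency_hz)
    tes_by = {}
    for m in tes:
        tes_by.setdefault(key(m), []).append(m)
    keys, ratios, freqs = [], [], []
    for m in ses:
        k = key(m)
        if k not in tes_by or not tes_by[k]:
            raise AnalysisError(f"no TES measurement to pair with SES at {pairing}={k}")
        partner = tes_by[k].pop(0)
        keys.append(k)
        ratios.append(m.summary_mV_per_mm / partner.summary_mV_per_mm)
        freqs.append(m.frequency_hz)
    ratios = np.asarray(ratios)
    F = p = None
    if anova_by == "frequency":
        groups = {}
        for f, r in zip(freqs, ratios):
            groups.setdefault(f, []).append(r)
        usable = [np.asarray(v) for v in groups.values() if len(v) >= 2]
        if len(usable) >= 2:
            F, p = (float(x) for x in stats.f_oneway(*usable))
    return RatioSummary(np.asarray(keys), ratios, float(np.mean(ratios)),
                        float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0,
                        F, p)


def required_current(slope_mV_per_mm_per_mA: float,
                     target_mV_per_mm: float = 1.0) -> float:
    """Current (mA) to reach a target field, rounded to one decimal."""
    if slope_mV_per_mm_per_mA <= 0:
        raise AnalysisError("slope must be > 0")
    return float(round(target_mV_per_mm / slope_mV_per_mm_per_mA, 1))


@dataclass(frozen=True)
class FrequencyTrend:
    spearman_r: float
    spearman_p: float
    percent_change: float


def frequency_trend(measurements: Sequence[FieldMeasurement]) -> FrequencyTrend:
    """Monotonic trend of field against stimulus frequency.

    Returns the Spearman rank correlation (R = 0 by convention for a constant
    series, where ranks are fully tied) and the relative change between the
    lowest- and highest-frequency measurements.
    """
    ms = sorted(measurements, key=lambda m: m.frequency_hz)
    if len({m.frequency_hz for m in ms}) < 3:
        raise AnalysisError("need >= 3 distinct frequencies")
    f = np.array([m.frequency_hz for m in ms])
    e = np.array([m.summary_mV_per_mm for m in ms])
    if np.ptp(e) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.spearmanr(f, e)
    change = (e[-1] - e[0]) / e[0]
    return FrequencyTrend(float(r), float(p), float(change))
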