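"""Pre/post-stimulation iEEG spectral analysis.

A stimulation session is 30 s pre-stim, 50 s stim and 20 s post-stim at
512 Hz.  The stim phase contains the pulse artifact and is excluded from
spectral analysis; power spectra of the pre and post phases are compared as
2-Hz-bin changes over 2-30 Hz and as canonical band-power changes
(delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30 Hz), with paired t-tests
between conditions and Bonferroni correction across bands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "Session",
    "SpectralResult",
    "BANDS_HZ",
    "PROTOCOL_PHASES_S",
    "preprocess",
    "psd",
    "phase_psd",
    "psd_change",
    "band_powers",
    "band_change",
    "compare_conditions",
]

BANDS_HZ: Mapping[str, tuple] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

# phase name -> (start_s, end_s) of the stimulation protocol
PROTOCOL_PHASES_S: Mapping[str, tuple] = {
    "pre": (0.0, 30.0),
    "stim": (30.0, 80.0),
    "post": (80.0, 100.0),
}


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class Session:
    """One stimulation session of iEEG (µV) with phase boundaries in seconds."""

    trace: np.ndarray
    fs_hz: float = 512.0
    phases: Mapping[str, tuple] = None
    condition: str = "baseline"  # TES | SES | baseline
    intensity_mA: float = 0.0

    def __post_init__(self):
        trace = np.asarray(self.trace, dtype=float)
        object.__setattr__(self, "trace", trace)
        phases = dict(self.phases) if self.phases else dict(PROTOCOL_PHASES_S)
        object.__setattr__(self, "phases", phases)
        end = max(t1 for _, t1 in phases.values())
        if trace.shape[-1] < int(end * self.fs_hz):
            raise AnalysisError("trace shorter than the protocol phase boundaries")

    def segment(self, phase: str) -> np.ndarray:
        t0, t1 = self.phases[phase]
        i0, i1 = int(round(t0 * self.fs_hz)), int(round(t1 * self.fs_hz))
        seg = self.trace[..., i0:i1]
        if seg.shape[-1] == 0:
            raise AnalysisError(f"phase {phase!r} segment is empty")
        return seg


def preprocess(session: Session, low_hz: float = 1.0, high_hz: float = 100.0,
               notch_hz: float = 60.0, order: int = 4, notch_q: float = 30.0) -> Session:
    """Zero-phase band-pass plus mains notch; phase boundaries preserved."""
    nyq = session.fs_hz / 2
    if not 0 < low_hz < high_hz < nyq:
        raise AnalysisError(f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz")
    if not 0 < notch_hz < nyq:
        raise AnalysisError(f"notch {notch_hz} Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=session.fs_hz, output="sos")
    x = signal.sosfiltfilt(sos, session.trace, axis=-1)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=session.fs_hz)
    x = signal.filtfilt(b, a, x, axis=-1)
    return replace(session, trace=x)


@dataclass(frozen=True)
class SpectralResult:
    """One-phase PSD (µV²/Hz) on a stated frequency grid."""

    freqs_hz: np.ndarray
    psd: np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.psd) < 0):
            raise AnalysisError("PSD must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


def psd(segment: np.ndarray, fs_hz: float, nperseg: int = 1024,
        overlap: float = 0.5) -> SpectralResult:
    """Welch average of Hamming-windowed periodograms (density scaling, so
    the integrated PSD approximates the signal variance)."""
    x = np.asarray(segment, dtype=float)
    step = int(nperseg * (1 - overlap))
    if x.shape[-1] < nperseg + step:  # fewer than two (overlapping) windows
        raise AnalysisError("segment shorter than two windows")
    f, p = signal.welch(x, fs=fs_hz, window="hamming", nperseg=nperseg,
                        noverlap=int(nperseg * overlap), detrend="constant",
                        scaling="density", axis=-1)
    return SpectralResult(f, p)


def phase_psd(session: Session, phase: str, nperseg: int = 1024,
              overlap: float = 0.5) -> SpectralResult:
    return psd(session.segment(phase), session.fs_hz, nperseg, overlap)


def _integrate(res: SpectralResult, lo: float, hi: float) -> np.ndarray:
    """Bin-integrated power over [lo, hi): sum of psd * df for bin centres in
    the half-open interval, so adjacent bins tile without overlap."""
    sel = (res.freqs_hz >= lo) & (res.freqs_hz < hi)
    if not np.any(sel):
        raise AnalysisError(f"no PSD support in [{lo}, {hi}) Hz")
    return np.sum(res.psd[..., sel], axis=-1) * res.df


def psd_change(pre: SpectralResult, post: SpectralResult,
               lo_hz: float = 2.0, hi_hz: float = 30.0,
               bin_hz: float = 2.0):
    """Per-2-Hz-bin change of bin-integrated power, post - pre (µV²).

    Returns ``(bin_edges, change)``; swapping pre and post negates every bin.
    """
    if pre.freqs_hz.shape != post.freqs_hz.shape or \
            not np.allclose(pre.freqs_hz, post.freqs_hz):
        raise AnalysisError("pre and post PSDs must share a frequency grid")
    edges = np.arange(lo_hz, hi_hz + bin_hz / 2, bin_hz)
    change = np.array([
        _integrate(post, e0, e1) - _integrate(pre, e0, e1)
        for e0, e1 in zip(edges[:-1], edges[1:])
    ])
    return edges, change


def band_powers(res: SpectralResult,
                bands: Mapping[str, tuple] = BANDS_HZ) -> dict:
    return {name: float(_integrate(res, lo, hi)) for name, (lo, hi) in bands.items()}


def band_change(pre: SpectralResult, post: SpectralResult,
                baseline_change: Mapping[str, float] | None = None,
                bands: Mapping[str, tuple] = BANDS_HZ) -> dict:
    """Per-band power change (post - pre) and, when a baseline session's same
    quantity is given, the change normalized by the baseline change magnitude."""
    p0 = band_powers(pre, bands)
    p1 = band_powers(post, bands)
    out = {}
    for name in bands:
        change = p1[name] - p0[name]
        entry = {"change": change}
        if baseline_change is not None:
            denom = abs(baseline_change[name])
            entry["ratio_to_baseline"] = change / denom if denom > 0 else np.inf
        out[name] = entry
    return out


def compare_conditions(
    changes_a: Sequence[Mapping[str, float]],
    changes_b: Sequence[Mapping[str, float]],
    alpha: float = 0.05,
    bands: Sequence[str] = tuple(BANDS_HZ),
):
    """Two-sided paired t-test per band on per-session band changes, with
    Bonferroni correction across bands.

    ``changes_a[i]`` and ``changes_b[i]`` are paired by repetition index.
    Zero-variance difference pairs are reported as p = 1 with a flag rather
    than NaN.  Returns a dict band -> {t, p, p_corrected, significant,
    zero_variance}.
    """
    if len(changes_a) != len(changes_b):
        raise AnalysisError("groups must be paired by repetition index")
    if len(changes_a) < 2:
        raise AnalysisError("need >= 2 paired sessions")
    out = {}
    m = len(bands)
    for band in bands:
        a = np.array([c[band] for c in changes_a], dtype=float)
        b = np.array([c[band] for c in changes_b], dtype=float)
        d = a - b
        if np.allclose(d, d[0]):
            if d[0] == 0:
                out[band] = {"t": 0.0, "p": 1.0, "p_corrected": 1.0,
                             "significant": False, "zero_variance": True}
                continue
            t, p = np.inf * np.sign(d[0]), 0.0
        else:
            t, p = stats.ttest_rel(a, b)
        p_corr = min(1.0, float(p) * m)
        out[band] = {"t": float(t), "p": float(p), "p_corrected": p_corr,
                     "significant": p_corr < alpha, "zero_variance": False}
    return out
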