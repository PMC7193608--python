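import numpy as np
import pytest

from shuntfield import recording as rec
from shuntfield import synthetic_data as synth
from shuntfield.recording import AnalysisError


def test_strip_gradient_hand_example():
    m = rec.strip_gradient(np.array([10.0, 5.0, 0.0]), spacing_mm=5.0)
    assert np.allclose(m.pair_fields_mV_per_mm, [1.0, 1.0])
    assert m.summary_mV_per_mm == 1.0
    flat = rec.strip_gradient(np.full(8, 3.0))
    assert np.allclose(flat.pair_fields_mV_per_mm, 0.0)
    with pytest.raises(AnalysisError):
        rec.strip_gradient(np.array([1.0]))
    with pytest.raises(AnalysisError):
        rec.strip_gradient(np.array([1.0, 2.0]), spacing_mm=0.0)


def _measurement(field, intensity, frequency=1000.0):
    return rec.FieldMeasurement([field], [0.0, field * 5.0], intensity, frequency)


def test_per_milliamp_slope_published_values():
    fields = [0.348, 0.687, 1.019, 1.362, 1.704]
    ms = [_measurement(f, i + 1.0) for i, f in enumerate(fields)]
    fit = rec.per_milliamp_slope(ms)
    assert fit.mean_ratio == pytest.approx(0.341, abs=0.002)
    assert fit.pearson_r > 0.999
    assert fit.iqr[0] <= fit.median_ratio <= fit.iqr[1]
    with pytest.raises(AnalysisError):
        rec.per_milliamp_slope([_measurement(1.0, 2.0), _measurement(2.0, 2.0)])


def test_required_current_rounding():
    assert rec.required_current(0.85, 1.0) == 1.2
    assert rec.required_current(0.20, 1.0) == 5.0
    assert rec.required_current(1.0, 1.0) == 1.0
    with pytest.raises(AnalysisError):
        rec.required_current(0.0, 1.0)


def test_shunting_ratio_rescaling_invariance():
    ses = [_measurement(f, i + 1.0) for i, f in enumerate([2.0, 4.0, 6.0])]
    tes = [_measurement(f, i + 1.0) for i, f in enumerate([1.0, 2.0, 3.0])]
    base = rec.shunting_ratio(ses, tes)
    scaled_ses = [_measurement(3 * m.summary_mV_per_mm, m.intensity_mA) for m in ses]
    scaled_tes = [_measurement(3 * m.summary_mV_per_mm, m.intensity_mA) for m in tes]
    scaled = rec.shunting_ratio(scaled_ses, scaled_tes)
    assert np.allclose(base.ratios, scaled.ratios)
    assert base.mean == pytest.approx(2.0)
    with pytest.raises(AnalysisError):
        rec.shunting_ratio(ses, tes[:-1])


def test_frequency_trend_constant_series():
    ms = [_measurement(1.0, 1.0, f) for f in (20.0, 200.0, 2000.0)]
    trend = rec.frequency_trend(ms)
    assert trend.spearman_r == 0.0
    assert trend.percent_change == 0.0
    with pytest.raises(AnalysisError):
        rec.frequency_trend(ms[:2])


def test_cycle_average_needs_enough_cycles():
    epoch = rec.RecordingEpoch(np.zeros((2, 1000)), fs_hz=20000.0,
                               intensity_mA=1.0, frequency_hz=100.0)
    with pytest.raises(AnalysisError):
        rec.cycle_average(epoch)  # 5 cycles < 10


def test_bandpass_validation():
    epoch = rec.RecordingEpoch(np.zeros((1, 2000)), fs_hz=20000.0,
                               intensity_mA=1.0, frequency_hz=1000.0)
    with pytest.raises(AnalysisError):
        rec.bandpass(epoch, 100.0, 11000.0)  # above Nyquist


def test_measurement_chain_round_trip_noiseless():
    fields = (1.0, 0.5, 0.0, 0.25, 0.75, 0.1, 0.9)
    spec = synth.StripRecordingSpec(pair_fields_mV_per_mm=fields,
                                    intensity_mA=2.0)
    epoch = synth.make_strip_recording(spec, seed=0)
    m = rec.measure_epoch(epoch)
    # the chain carries a small (~2%) common gain from the band-edge filter
    # response and the phase-binned cycle template; it cancels in every
    # ratio analysis, and exact zeros stay exactly zero
    assert np.allclose(m.pair_fields_mV_per_mm, fields, rtol=0.025, atol=1e-9)
    assert m.pair_fields_mV_per_mm[2] <= 1e-12
    assert m.intensity_mA == 2.0


def test_measurement_chain_round_trip_noisy():
    fields = (1.0, 0.5, 0.2, 0.8, 0.4, 0.6, 0.3)
    # noise SD = 10% of the largest contact signal amplitude
    peak_mV = np.cumsum(np.array(fields) * 5.0).max() * 0.5
    spec = synth.StripRecordingSpec(pair_fields_mV_per_mm=fields,
                                    noise_sd_mV=0.1 * peak_mV)
    epoch = synth.make_strip_recording(spec, seed=7)
    m = rec.measure_epoch(epoch)
    err = np.abs(m.pair_fields_mV_per_mm - np.array(fields)) / np.max(fields)
    assert np.all(err <= 0.05)


def test_epoch_and_measurement_validation():
    with pytest.raises(AnalysisError):
        rec.RecordingEpoch(np.zeros((1, 100)), fs_hz=5000.0,
                           intensity_mA=1.0, frequency_hz=1000.0)
    with pytest.raises(AnalysisError):
        rec.FieldMeasurement([-1.0], [0.0, 5.0], 1.0, 1000.0)
    with pytest.raises(AnalysisError):
        rec.FieldMeasurement([1.0, 2.0], [0.0, 5.0], 1.0, 1000.0)
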