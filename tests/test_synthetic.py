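import numpy as np
import pytest

from shuntfield import forward, geometry as g, ieeg
from shuntfield import synthetic_data as synth
from shuntfield.geometry import ConfigurationError


def test_sinusoidal_stimulus():
    spec = synth.StimulusWaveform("sinusoidal", 1.0, 1000.0)
    x = synth.make_stimulus(spec, 20000.0, 0.01)
    assert len(x) == 200
    assert np.max(np.abs(x)) == pytest.approx(1.0, rel=1e-3)
    with pytest.raises(ConfigurationError):
        synth.make_stimulus(spec, 5000.0, 0.01)  # < 10x oversampling


def test_biphasic_stimulus_charge_balance():
    spec = synth.StimulusWaveform("biphasic", 2.0, 1.0, pulse_width_ms=0.5)
    x = synth.make_stimulus(spec, 20000.0, 50.0)
    # 50 pulses, each charge balanced to machine precision
    assert np.abs(x).max() > 0
    per_pulse_charge = np.abs(x[x > 0]).sum() / 50
    assert abs(x.sum()) <= 1e-12 * per_pulse_charge
    with pytest.raises(ConfigurationError):
        synth.make_stimulus(
            synth.StimulusWaveform("biphasic", 1.0, 1.0, pulse_width_ms=0.1),
            20000.0, 1.0)  # fs cannot resolve the pulse
    with pytest.raises(ConfigurationError):
        synth.StimulusWaveform("triangular", 1.0, 1.0)


def test_generators_are_reproducible():
    spec = synth.StripRecordingSpec(pair_fields_mV_per_mm=(1.0, 0.5),
                                    noise_sd_mV=0.3)
    a = synth.make_strip_recording(spec, seed=42)
    b = synth.make_strip_recording(spec, seed=42)
    assert np.array_equal(a.data, b.data)
    c = synth.make_strip_recording(spec, seed=43)
    assert not np.array_equal(a.data, c.data)

    s1 = synth.make_ieeg_session(synth.IEEGSpec(), "SES", seed=9)
    s2 = synth.make_ieeg_session(synth.IEEGSpec(), "SES", seed=9)
    assert np.array_equal(s1.trace, s2.trace)


def test_ieeg_effect_multiplier_power():
    # amplitude x2 on the alpha oscillator -> ~4x its post-phase band power.
    # isolate the oscillator by removing the background and other bands
    spec = synth.IEEGSpec(background_sd_uV=1e-6,
                          oscillators=((10.0, 2.0, 4.0),))
    ses = synth.make_ieeg_session(spec, "SES", seed=1)
    pre = ieeg.phase_psd(ses, "pre")
    post = ieeg.phase_psd(ses, "post")
    p_pre = ieeg.band_powers(pre)["alpha"]
    p_post = ieeg.band_powers(post)["alpha"]
    assert p_post / p_pre == pytest.approx(4.0, rel=0.35)

    tes = synth.make_ieeg_session(spec, "TES", seed=1)
    p_pre_t = ieeg.band_powers(ieeg.phase_psd(tes, "pre"))["alpha"]
    p_post_t = ieeg.band_powers(ieeg.phase_psd(tes, "post"))["alpha"]
    assert p_post_t / p_pre_t == pytest.approx(1.0, rel=0.35)


def test_make_ieeg_session_validation():
    with pytest.raises(ConfigurationError):
        synth.make_ieeg_session(synth.IEEGSpec(), "sham")
    with pytest.raises(ConfigurationError):
        synth.IEEGSpec(effect_multipliers={"alpha": 0.0})
    with pytest.raises(ConfigurationError):
        synth.IEEGSpec(phase_durations_s=(30.0, 50.0))


def test_strip_fields_from_solution_consistency(shell_model):
    montage = g.place_montage(shell_model, [
        g.ElectrodePatch((0, 0, 41.0), 0.5, "skull-surface", "active", 1.0),
        g.ElectrodePatch((0, 0, -41.0), 0.5, "skull-surface", "reference", -1.0),
    ])
    sol = forward.solve_potential(shell_model, montage)
    strip = g.StripSpec((-17.5, 0.0, 30.0), (1.0, 0.0, 0.0))
    fields = synth.strip_fields_from_solution(sol, strip)

    # feed the solved fields through the synthetic recording generator and
    # the measurement chain: end-to-end round trip
    from shuntfield import recording as rec

    spec = synth.StripRecordingSpec(pair_fields_mV_per_mm=tuple(fields))
    epoch = synth.make_strip_recording(spec, seed=0)
    measured = rec.measure_epoch(epoch)
    # within the measurement chain's ~2% systematic gain (common to all pairs)
    assert np.allclose(measured.pair_fields_mV_per_mm, fields,
                       rtol=0.025, atol=1e-9)


def test_make_calibration_dataset_seals_truth(shell_model):
    montages, strips = synth.standard_calibration_montages(
        shell_model, intensities_mA=(1.0,))
    ds = synth.make_calibration_dataset(shell_model, 4e-4, 4e-3,
                                        montages, strips, seed=0)
    assert ds.truth == {"sigma_scalp": 4e-4, "sigma_skull": 4e-3}
    with pytest.raises(ConfigurationError):
        synth.make_calibration_dataset(shell_model, -1.0, 4e-3,
                                       montages, strips)
    # noise changes the measured fields but not the sealed truth
    noisy = synth.make_calibration_dataset(shell_model, 4e-4, 4e-3,
                                           montages, strips,
                                           noise_fraction=0.05, seed=0)
    assert not np.allclose(noisy.measured_fields[0], ds.measured_fields[0])
    assert noisy.truth == ds.truth


def test_standard_battery_shapes(shell_model):
    montages, strips = synth.standard_calibration_montages(shell_model)
    assert len(montages) == len(strips) == 24
    with pytest.raises(ConfigurationError):
        synth.standard_calibration_montages(
            g.build_slab([("scalp", 4.0), ("skull", 4.0)],
                         g.default_conductivities()))
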