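import numpy as np
import pytest
from scipy import stats

from shuntfield import ieeg
from shuntfield import synthetic_data as synth
from shuntfield.ieeg import AnalysisError


@pytest.fixture(scope="module")
def baseline_session():
    return synth.make_ieeg_session(synth.IEEGSpec(), "baseline", seed=11)


def test_session_segments_and_validation(baseline_session):
    pre = baseline_session.segment("pre")
    assert pre.shape[-1] == int(30.0 * 512)
    with pytest.raises(AnalysisError):
        ieeg.Session(np.zeros(100), fs_hz=512.0)  # shorter than the protocol


def test_preprocess_validation(baseline_session):
    with pytest.raises(AnalysisError):
        ieeg.preprocess(baseline_session, low_hz=1.0, high_hz=300.0)
    with pytest.raises(AnalysisError):
        ieeg.preprocess(baseline_session, notch_hz=300.0)
    out = ieeg.preprocess(baseline_session)
    assert out.trace.shape == baseline_session.trace.shape


def test_psd_nonnegative_and_parseval(baseline_session):
    seg = baseline_session.segment("pre")
    res = ieeg.psd(seg, 512.0)
    assert np.all(res.psd >= 0)
    # integrated density approximates the signal variance (Welch w/ Hamming)
    total = np.sum(res.psd) * res.df
    assert total == pytest.approx(np.var(seg), rel=0.2)
    with pytest.raises(AnalysisError):
        ieeg.psd(seg[:512], 512.0)  # shorter than two windows


def test_psd_change_antisymmetry(baseline_session):
    pre = ieeg.phase_psd(baseline_session, "pre")
    post = ieeg.phase_psd(baseline_session, "post")
    edges, fwd = ieeg.psd_change(pre, post)
    _, bwd = ieeg.psd_change(post, pre)
    assert np.allclose(fwd, -bwd)
    assert edges[0] == 2.0 and edges[-1] == 30.0


def test_band_change_ratio_to_baseline(baseline_session):
    pre = ieeg.phase_psd(baseline_session, "pre")
    post = ieeg.phase_psd(baseline_session, "post")
    base = ieeg.band_change(pre, post)
    base_changes = {b: base[b]["change"] for b in base}
    out = ieeg.band_change(pre, post, baseline_change=base_changes)
    for band in out:
        assert out[band]["ratio_to_baseline"] == pytest.approx(
            np.sign(base_changes[band]) if base_changes[band] != 0 else np.inf)


def test_ses_effect_structure():
    spec = synth.IEEGSpec()
    ses = ieeg.preprocess(synth.make_ieeg_session(spec, "SES", seed=3))
    pre = ieeg.phase_psd(ses, "pre")
    post = ieeg.phase_psd(ses, "post")
    changes = ieeg.band_change(pre, post)
    # alpha/beta post amplitudes doubled -> clear positive power change;
    # delta/theta unchanged up to sampling noise
    assert changes["alpha"]["change"] > 3 * abs(changes["delta"]["change"])
    assert changes["beta"]["change"] > 3 * abs(changes["theta"]["change"])


def test_compare_conditions_identical_groups():
    changes = [{b: float(i) for b in ieeg.BANDS_HZ} for i in range(4)]
    res = ieeg.compare_conditions(changes, changes)
    for band in ieeg.BANDS_HZ:
        assert res[band]["p"] == 1.0
        assert res[band]["zero_variance"]
        assert not res[band]["significant"]


def test_compare_conditions_matches_scipy():
    rng = np.random.default_rng(5)
    a = [{b: float(rng.normal()) for b in ieeg.BANDS_HZ} for _ in range(4)]
    b = [{b: float(rng.normal()) for b in ieeg.BANDS_HZ} for _ in range(4)]
    res = ieeg.compare_conditions(a, b)
    for band in ieeg.BANDS_HZ:
        t, p = stats.ttest_rel([x[band] for x in a], [x[band] for x in b])
        assert res[band]["t"] == pytest.approx(float(t), abs=1e-4)
        assert res[band]["p"] == pytest.approx(float(p), abs=1e-4)
        assert res[band]["p_corrected"] == pytest.approx(
            min(1.0, float(p) * len(ieeg.BANDS_HZ)), abs=1e-4)


def test_compare_conditions_validation():
    changes = [{b: 0.0 for b in ieeg.BANDS_HZ}] * 3
    with pytest.raises(AnalysisError):
        ieeg.compare_conditions(changes, changes[:-1])
    with pytest.raises(AnalysisError):
        ieeg.compare_conditions(changes[:1], changes[:1])
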