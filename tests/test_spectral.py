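"""Multitaper band power, power high-pass filtering and epoching."""

import numpy as np
import pandas as pd
import pytest

from stnseq import (
    ContinuousRecording,
    average_channels,
    bipolar_montage,
    continuous_band_power,
    epoch_power,
    highpass_power,
    preprocess_raw,
)
from stnseq.spectral import average_ring_segments

FS = 300.0


def _rec(data, markers=None, ch_names=None):
    if data.ndim == 1:
        data = data[None, :]
    if ch_names is None:
        ch_names = [f"c{i}" for i in range(data.shape[0])]
    if markers is None:
        markers = pd.DataFrame({"sample": [1000], "trial": [0], "cue_index": [1]})
    return ContinuousRecording(data=data, fs=FS, ch_names=ch_names, markers=markers)


@pytest.fixture(scope="module")
def t60():
    return np.arange(int(60 * FS)) / FS


def test_constant_carrier_removed_by_highpass(t60):
    """A steady 21.5 Hz tone has flat log beta power; the 0.5 Hz high-pass
    reduces it to ~0 (DC removal)."""
    rec = _rec(np.sin(2 * np.pi * 21.5 * t60))
    pts = continuous_band_power(rec, "beta")
    inner = slice(40, -40)  # keep clear of filter edge effects
    assert pts.logpower[0][inner].std() < 0.01
    hp = highpass_power(pts)
    assert np.abs(hp.logpower[0][inner]).max() < 0.05


def test_amplitude_modulation_survives_highpass(t60):
    """A 1.25 Hz AM (one cycle per SOA) passes the 0.5 Hz filter with
    less than 10% attenuation."""
    x = (1.0 + 0.5 * np.sin(2 * np.pi * 1.25 * t60)) * np.sin(2 * np.pi * 21.5 * t60)
    pts = continuous_band_power(rec := _rec(x), "beta")
    hp = highpass_power(pts)
    sl = slice(40, -40)
    tt = pts.times[sl]

    def amp_at(series, f):
        z = series - series.mean()
        return 2.0 * np.abs(np.mean(z * np.exp(-2j * np.pi * f * tt)))

    a_pre = amp_at(pts.logpower[0][sl], 1.25)
    a_post = amp_at(hp.logpower[0][sl], 1.25)
    assert a_pre > 0.1  # modulation visible in log power at all
    assert a_post / a_pre > 0.9


def test_band_separation(t60):
    """A 5 Hz tone dominates theta power and leaves beta at the noise floor."""
    rng = np.random.default_rng(0)
    x = np.sin(2 * np.pi * 5.0 * t60) + 0.01 * rng.standard_normal(t60.size)
    rec = _rec(x)
    beta = continuous_band_power(rec, "beta").logpower[0]
    theta = continuous_band_power(rec, "theta").logpower[0]
    assert theta.mean() - beta.mean() > 3.0  # >20 dB separation in log units


def test_parseval_total_power_tracks_variance(rng):
    """Summed multitaper PSD over the full band recovers white-noise variance."""
    x = rng.standard_normal(int(30 * FS)) * 2.0
    rec = _rec(x)
    pts = continuous_band_power(rec, (0.0, FS / 2), mode="binavg")
    var_est = np.exp(pts.logpower[0]).mean() * FS
    assert var_est == pytest.approx(np.var(x), rel=0.05)


def test_scale_invariance_up_to_additive_constant(t60, rng):
    """Rescaling the signal shifts log power by a constant, removed by the
    high-pass."""
    x = rng.standard_normal(t60.size)
    p1 = continuous_band_power(_rec(x), "beta")
    p2 = continuous_band_power(_rec(10.0 * x), "beta")
    shift = p2.logpower - p1.logpower
    np.testing.assert_allclose(shift, 2 * np.log(10), atol=1e-9)
    h1, h2 = highpass_power(p1), highpass_power(p2)
    np.testing.assert_allclose(h1.logpower, h2.logpower, atol=1e-7)


def test_recording_too_short():
    with pytest.raises(ValueError):
        continuous_band_power(_rec(np.zeros(50)), "beta")
    with pytest.raises(ValueError):
        continuous_band_power(_rec(np.zeros(3000)), (2.0, 200.0))  # above Nyquist


class TestEpoching:
    def _power(self, n_sec=40, markers=None, seed=1):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(int(n_sec * FS))
        rec = _rec(x, markers=markers)
        return highpass_power(continuous_band_power(rec, "beta")), rec

    def test_epoch_has_27_samples(self):
        mk = pd.DataFrame({"sample": [3000, 3240], "trial": [0, 0], "cue_index": [1, 2]})
        pts, rec = self._power(markers=mk)
        ep = epoch_power(pts, rec.markers)
        assert ep.data.shape == (2, 27)
        np.testing.assert_allclose(ep.times[0], -0.5)
        np.testing.assert_allclose(ep.times[-1], 0.8)

    def test_marker_at_edge_dropped(self):
        mk = pd.DataFrame({"sample": [0, 3000], "trial": [0, 0], "cue_index": [1, 2]})
        pts, rec = self._power(markers=mk)
        ep = epoch_power(pts, rec.markers)
        assert ep.n_dropped == 1
        assert len(ep.data) == 1

    def test_first_and_last_cue_flagged(self):
        mk = pd.DataFrame(
            {"sample": [3000, 3240, 3480], "trial": [0, 0, 0], "cue_index": [1, 2, 3]}
        )
        pts, rec = self._power(markers=mk)
        ep = epoch_power(pts, rec.markers)
        assert ep.info["is_first"].tolist() == [True, False, False]
        assert ep.info["is_last"].tolist() == [False, False, True]

    def test_requires_filtered_power(self):
        mk = pd.DataFrame({"sample": [3000], "trial": [0], "cue_index": [1]})
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal(int(40 * FS)), markers=mk)
        pts = continuous_band_power(rec, "beta")
        with pytest.raises(ValueError):
            epoch_power(pts, rec.markers)

    def test_injected_burst_recovered(self, rng):
        """A beta burst 100-450 ms after the cue raises the epoch mean there."""
        n = int(60 * FS)
        t = np.arange(n) / FS
        x = rng.standard_normal(n) * 0.5
        onsets = (FS * np.arange(5.0, 50.0, 5.0)).astype(int)
        for on in onsets:
            seg = np.arange(int(0.1 * FS), int(0.45 * FS))
            x[on + seg] += 2.0 * np.sin(2 * np.pi * 21.5 * t[on + seg]) * np.hanning(seg.size)
        mk = pd.DataFrame(
            {"sample": onsets, "trial": np.arange(onsets.size), "cue_index": 1}
        )
        rec = _rec(x, markers=mk)
        ep = epoch_power(highpass_power(continuous_band_power(rec, "beta")), rec.markers)
        in_win = (ep.times >= 0.1) & (ep.times <= 0.45)
        baseline = ep.times < 0.0
        assert ep.data[:, in_win].mean() > ep.data[:, baseline].mean() + 0.5


class TestChannelAveraging:
    def _pts(self, data, names):
        rec = _rec(data, ch_names=names)
        return continuous_band_power(rec, "beta")

    def test_identical_contacts_idempotent(self, rng):
        x = rng.standard_normal(int(20 * FS))
        pts = self._pts(np.vstack([x, x]), ["l0", "l1"])
        out = average_channels(pts, {"left": ["l0", "l1"]})
        np.testing.assert_allclose(out.logpower[0], pts.logpower[0], atol=1e-12)
        assert out.ch_names == ["left", "all"]

    def test_linearity_of_log_power_average(self, rng):
        x = rng.standard_normal(int(20 * FS))
        pts = self._pts(np.vstack([x, x]), ["a", "b"])
        pts.logpower[1] = -pts.logpower[0]  # log-powers x and -x
        out = average_channels(pts, {"g": ["a", "b"]}, include_all=False)
        np.testing.assert_allclose(out.logpower[0], 0.0, atol=1e-12)

    def test_noisy_contact_excluded_from_group(self, rng):
        x = rng.standard_normal((3, int(20 * FS)))
        pts = self._pts(x, ["r0", "r1", "r2_noisy"])
        out = average_channels(pts, {"right": ["r0", "r1"]}, include_all=False)
        np.testing.assert_allclose(
            out.logpower[0], pts.logpower[:2].mean(axis=0), atol=1e-12
        )

    def test_empty_group_rejected(self, rng):
        pts = self._pts(rng.standard_normal((1, int(20 * FS))), ["a"])
        with pytest.raises(ValueError):
            average_channels(pts, {"g": []})


def test_bipolar_and_ring_montage(rng):
    x = rng.standard_normal((3, int(5 * FS)))
    rec = _rec(x, ch_names=["c0", "c1", "c2"])
    bip = bipolar_montage(rec, [("c0", "c1", "b01"), ("c1", "c2", "b12")])
    np.testing.assert_allclose(bip.data[0], x[0] - x[1])
    assert bip.ch_names == ["b01", "b12"]
    ring = average_ring_segments(rec, {"ring": ["c0", "c1", "c2"]})
    np.testing.assert_allclose(ring.data[0], x.mean(axis=0))


def test_preprocess_downsamples_and_rescales_markers(rng):
    mk = pd.DataFrame({"sample": [1200], "trial": [0], "cue_index": [1]})
    rec = ContinuousRecording(
        data=rng.standard_normal((1, 6000)), fs=600.0, ch_names=["c0"], markers=mk
    )
    out = preprocess_raw(rec, target_fs=300.0, hp_freq=1.0)
    assert out.fs == 300.0
    assert out.n_samples == 3000
    assert out.markers["sample"].iloc[0] == 600
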